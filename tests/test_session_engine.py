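"""Sessions: assign returns metadata only, aggregates are gated,
workspaces round-trip, and symbol tables stay isolated."""

import numpy as np
import pandas as pd
import pytest

from fedshield.errors import (
    DisclosureError,
    ForbiddenError,
    ForbiddenFunctionError,
    NotFoundError,
    UnavailableError,
    ValidationError,
)
from fedshield.profiles import DisclosureOptions
from fedshield.session_engine import ExpressionEvaluator

from conftest import RESEARCHER


@pytest.fixture
def ready(node):
    df = pd.DataFrame({
        "bmi": pd.array([22.5, 31.0, 27.2, 19.8, 25.1], dtype="Float64"),
        "age": pd.array([30, 45, 91, 28, 92], dtype="Int64"),
        "smoke": pd.array([True, False, True, False, True], dtype="boolean"),
    })
    node.publish("p1", "core", "tbl", df)
    session = node.server.sessions.create_session(node.researcher_token, "default")
    return node, session, df


def col(symbol, name):
    return {"op": "col", "symbol": symbol, "name": name}


class TestSessionCreation:
    def test_requires_running_profile(self, node):
        node.server.profiles.stop("default")
        node.server.access.grant(node.admin_token, RESEARCHER, "p1") \
            if node.server.datastore.project_exists("p1") else None
        node.server.datastore.create_project("p1")
        node.server.access.grant(node.admin_token, RESEARCHER, "p1")
        with pytest.raises(UnavailableError):
            node.server.sessions.create_session(node.researcher_token, "default")

    def test_anonymous_forbidden(self, node):
        with pytest.raises(ForbiddenError):
            node.server.sessions.create_session(None, "default")

    def test_ungranted_researcher_forbidden(self, node):
        with pytest.raises(ForbiddenError):
            node.server.sessions.create_session(node.researcher_token, "default")

    def test_idle_expiry_discards_symbols(self, tmp_path):
        from conftest import Node

        class Clock:
            t = 0.0
            def __call__(self):
                return self.t

        clock = Clock()
        node = Node(tmp_path, "ttl", clock=clock)
        node.publish("p1", "f", "t", pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        session = node.server.sessions.create_session(node.researcher_token, "default")
        clock.t += 3601
        with pytest.raises(NotFoundError):
            node.server.sessions.get_session(session.id, node.researcher_token)


class TestAssign:
    def test_load_returns_metadata_only(self, ready):
        node, session, df = ready
        ack = node.server.sessions.assign_load(
            session.id, node.researcher_token, "D", "p1", "core", "tbl")
        assert ack == {"status": "ok", "symbol": "D", "n_rows": 5,
                       "columns": ["bmi", "age", "smoke"]}

    def test_load_ungranted_project_forbidden(self, ready):
        node, session, df = ready
        node.server.datastore.create_project("p2")
        node.server.datastore.upload_table("p2", "f", "t", df, fmt="pandas")
        with pytest.raises(ForbiddenError):
            node.server.sessions.assign_load(
                session.id, node.researcher_token, "D", "p2", "f", "t")

    def test_rebind_warns(self, ready):
        node, session, _ = ready
        node.server.sessions.assign_load(
            session.id, node.researcher_token, "D", "p1", "core", "tbl")
        ack = node.server.sessions.assign_load(
            session.id, node.researcher_token, "D", "p1", "core", "tbl")
        assert ack["warning"] == "symbol overwritten"

    def test_derived_expression(self, ready):
        node, session, df = ready
        node.server.sessions.assign_load(
            session.id, node.researcher_token, "D", "p1", "core", "tbl")
        ack = node.server.sessions.assign_expr(
            session.id, node.researcher_token, "double_bmi",
            {"op": "*", "left": col("D", "bmi"), "right": {"op": "const", "value": 2}})
        assert ack["n_rows"] == 5 and ack["columns"] == []
        bound = session.symbols["double_bmi"]
        np.testing.assert_allclose(bound.to_numpy(),
                                   df["bmi"].to_numpy(dtype=float) * 2)

    def test_filter_guard(self, ready):
        node, session, _ = ready
        node.server.sessions.assign_load(
            session.id, node.researcher_token, "D", "p1", "core", "tbl")
        # age > 90 leaves 2 rows: inside the forbidden 1..min_subset-1 band
        with pytest.raises(DisclosureError) as exc:
            node.server.sessions.assign_expr(
                session.id, node.researcher_token, "old",
                {"op": "filter", "symbol": "D",
                 "cond": {"op": ">", "left": col("D", "age"),
                          "right": {"op": "const", "value": 90}}})
        assert exc.value.rule == "min_subset"
        # empty subsets are allowed: nothing is revealed
        ack = node.server.sessions.assign_expr(
            session.id, node.researcher_token, "none",
            {"op": "filter", "symbol": "D",
             "cond": {"op": ">", "left": col("D", "age"),
                      "right": {"op": "const", "value": 1000}}})
        assert ack["n_rows"] == 0

    def test_grammar_violation(self, ready):
        node, session, _ = ready
        with pytest.raises(ValidationError):
            node.server.sessions.assign_expr(
                session.id, node.researcher_token, "x",
                {"op": "exec", "code": "import os"})


class TestExpressionGrammar:
    @pytest.fixture
    def ev(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 4.0], "b": [True, False, True]})
        return ExpressionEvaluator({"D": df}, DisclosureOptions())

    def test_division_by_zero_is_missing(self, ev):
        out = ev.eval({"op": "/", "left": col("D", "x"),
                       "right": {"op": "-", "left": col("D", "x"),
                                 "right": col("D", "x")}})
        assert np.isnan(out).all()

    def test_ifelse_and_logic(self, ev):
        out = ev.eval({"op": "ifelse",
                       "cond": {"op": "&",
                                "left": {"op": ">", "left": col("D", "x"),
                                         "right": {"op": "const", "value": 1.5}},
                                "right": col("D", "b")},
                       "then": {"op": "const", "value": 1},
                       "else": {"op": "const", "value": 0}})
        assert out.tolist() == [0, 0, 1]

    def test_cbind(self, ev):
        out = ev.eval({"op": "cbind", "columns": {
            "x2": {"op": "*", "left": col("D", "x"),
                   "right": {"op": "const", "value": 2}},
            "flag": col("D", "b")}})
        assert list(out.columns) == ["x2", "flag"]
        assert out["x2"].tolist() == [2.0, 4.0, 8.0]

    def test_unknown_symbol_and_column(self, ev):
        with pytest.raises(ValidationError):
            ev.eval(col("ghost", "x"))
        with pytest.raises(ValidationError):
            ev.eval(col("D", "ghost"))

    def test_string_literals_rejected(self, ev):
        with pytest.raises(ValidationError):
            ev.eval({"op": "const", "value": "drop tables"})


class TestAggregate:
    def test_summary_over_bound_vector(self, ready):
        node, session, _ = ready
        node.server.sessions.assign_load(
            session.id, node.researcher_token, "D", "p1", "core", "tbl")
        out = node.server.sessions.aggregate(
            session.id, node.researcher_token, "mean_ds",
            {"values": col("D", "bmi")})
        assert out["n_valid"] == 5
        assert out["value"] == pytest.approx(25.12)

    def test_blacklisted_function_forbidden(self, ready):
        node, session, _ = ready
        node.server.profiles.get("default").blacklist.add("mean_ds")
        with pytest.raises(ForbiddenFunctionError):
            node.server.sessions.aggregate(
                session.id, node.researcher_token, "mean_ds",
                {"values": col("D", "bmi")})

    def test_disclosure_error_names_threshold(self, ready):
        node, session, _ = ready
        node.server.sessions.assign_load(
            session.id, node.researcher_token, "D", "p1", "core", "tbl")
        # bmi / 0 is all-missing, so the mean has 0 valid observations
        node.server.sessions.assign_expr(
            session.id, node.researcher_token, "veiled",
            {"op": "/", "left": col("D", "bmi"),
             "right": {"op": "const", "value": 0}})
        with pytest.raises(DisclosureError) as exc:
            node.server.sessions.aggregate(
                session.id, node.researcher_token, "mean_ds",
                {"values": "veiled"})
        assert exc.value.rule == "min_obs"

    def test_session_isolation(self, ready):
        node, session, _ = ready
        node.server.sessions.assign_load(
            session.id, node.researcher_token, "D", "p1", "core", "tbl")
        other = node.server.sessions.create_session(node.researcher_token, "default")
        with pytest.raises(ValidationError):
            node.server.sessions.aggregate(
                other.id, node.researcher_token, "mean_ds",
                {"values": col("D", "bmi")})

    def test_stopping_profile_kills_sessions(self, ready):
        node, session, _ = ready
        node.server.profiles.stop("default")
        assert node.server.sessions.active_count() == 0
        with pytest.raises(NotFoundError):
            node.server.sessions.get_session(session.id, node.researcher_token)


class TestWorkspaces:
    def test_round_trip_identity(self, ready):
        node, session, df = ready
        mgr = node.server.sessions
        mgr.assign_load(session.id, node.researcher_token, "D", "p1", "core", "tbl")
        mgr.assign_expr(session.id, node.researcher_token, "v",
                        {"op": "*", "left": col("D", "bmi"),
                         "right": {"op": "const", "value": 2}})
        mgr.assign_expr(session.id, node.researcher_token, "w",
                        {"op": "cbind", "columns": {"b2": col("D", "bmi")}})
        ref = mgr.save_workspace(session.id, node.researcher_token, "ws1")
        assert ref.n_symbols == 3
        restored = mgr.restore_workspace(node.researcher_token, "ws1", "default")
        assert list(restored.symbols) == ["D", "v", "w"]
        pd.testing.assert_frame_equal(restored.symbols["D"], df)
        np.testing.assert_allclose(restored.symbols["v"].to_numpy(dtype=float),
                                   session.symbols["v"].to_numpy(dtype=float))

    def test_restore_other_owner_forbidden(self, ready):
        node, session, _ = ready
        mgr = node.server.sessions
        mgr.assign_load(session.id, node.researcher_token, "D", "p1", "core", "tbl")
        mgr.save_workspace(session.id, node.researcher_token, "ws1")
        node.server.access.register_user("eve")
        eve = node.server.access.issue_token("eve").raw
        with pytest.raises(ForbiddenError):
            mgr.restore_workspace(eve, "ws1", "default")

    def test_restore_unknown_not_found(self, ready):
        node, _, _ = ready
        with pytest.raises(NotFoundError):
            node.server.sessions.restore_workspace(
                node.researcher_token, "ghost", "default")
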