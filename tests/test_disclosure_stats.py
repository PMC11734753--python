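"""Guarded statistics, cell suppression, and GLM node contributions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fedshield import disclosure_stats as ds
from fedshield.errors import DisclosureError, ValidationError
from fedshield.profiles import DisclosureOptions

OPTS = DisclosureOptions()  # min_cell=min_subset=min_obs=3, glm_ratio=0.2


class TestGuardedMoments:
    def test_mean_hand_value(self):
        out = ds.mean_ds([1, 2, 3, 4, 5], OPTS)
        assert out.value == 3.0 and out.n_valid == 5 and out.n_missing == 0

    def test_mean_below_threshold_refused(self):
        with pytest.raises(DisclosureError) as exc:
            ds.mean_ds([1, 2], OPTS)
        assert exc.value.rule == "min_obs"

    def test_mean_skips_missing(self):
        out = ds.mean_ds([1, None, 3, 5], OPTS)
        assert out.value == 3.0 and out.n_valid == 3 and out.n_missing == 1

    def test_variance_uses_n_minus_1(self):
        out = ds.var_ds([1.0, 2.0, 3.0], OPTS)
        assert out.value == pytest.approx(1.0)

    def test_moments_are_sufficient(self):
        x = [1.5, 2.5, 4.0, 8.0]
        out = ds.moments_ds(x, OPTS)
        assert out.value == {"n": 4, "sum": 16.0, "sum_sq": 88.5}

    def test_quantiles_grid_and_guard(self):
        rng = np.random.default_rng(5)
        big = rng.normal(size=500)
        out = ds.quantiles_ds(big, OPTS)
        assert set(out.value) == {f"q{p}" for p in (5, 10, 25, 50, 75, 90, 95)}
        assert out.value["q50"] == pytest.approx(np.median(big))
        with pytest.raises(DisclosureError):
            ds.quantiles_ds(rng.normal(size=20), OPTS)  # thin tail buckets

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=40),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, values, rnd):
        """Summaries do not depend on row order."""
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert ds.mean_ds(values, OPTS).value == pytest.approx(
            ds.mean_ds(shuffled, OPTS).value, abs=1e-9, rel=1e-12)
        assert ds.var_ds(values, OPTS).value == pytest.approx(
            ds.var_ds(shuffled, OPTS).value, abs=1e-9, rel=1e-12)


def factor(counts: dict) -> list:
    out = []
    for label, count in counts.items():
        out.extend([label] * count)
    return out


class TestSuppression:
    def test_all_released(self):
        t = ds.table_ds([factor({"A": 10, "B": 7})], OPTS)
        assert t.cells == [10, 7] and t.total == 17

    def test_small_cell_suppressed_and_margin_protected(self):
        t = ds.table_ds([factor({"A": 10, "B": 2})], OPTS)
        assert t.cells == [10, ds.SUPPRESSED]
        # releasing 12 would reveal B = 12 - 10
        assert t.total == ds.SUPPRESSED

    def test_zero_cell_released(self):
        f1 = factor({"A": 5, "B": 5})
        f2 = ["x"] * 5 + ["y"] * 5
        t = ds.table_ds([f1, f2], OPTS)
        # A/y and B/x cells are structural zeros
        assert t.cells[0] == [5, 0] and t.cells[1] == [0, 5]
        assert t.total == 10

    def test_two_way_margins(self):
        f1 = factor({"A": 6, "B": 6})
        f2 = ["x", "x", "x", "x", "x", "y"] + ["x"] * 6
        t = ds.table_ds([f1, f2], OPTS)
        assert t.cells[0] == [5, ds.SUPPRESSED]
        assert t.row_totals[0] == ds.SUPPRESSED  # exactly one suppressed in row
        assert t.cells[1] == [6, 0]
        assert t.row_totals[1] == 6

    def test_non_categorical_rejected(self):
        with pytest.raises(ValidationError):
            ds.table_ds([np.array([1.2, 3.4, 5.6])], OPTS)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(0, 8), min_size=1, max_size=6),
           st.integers(1, 6))
    def test_suppression_soundness_property(self, counts, min_cell):
        """Every released cell is 0 or >= min_cell, for any table."""
        opts = DisclosureOptions(min_cell=min_cell)
        labels = {chr(65 + i): c for i, c in enumerate(counts)}
        t = ds.table_ds([factor(labels)], opts) if sum(counts) else None
        if t is None:
            return
        for cell in t.released_cells():
            assert cell == 0 or cell >= min_cell


class TestGlmContribution:
    def test_gaussian_intercept_only_sums(self):
        df = pd.DataFrame({"y": [2.0, 4.0, 6.0]})
        opts = DisclosureOptions(glm_ratio=0.5)
        c = ds.glm_contribution(df, {"response": "y", "terms": []},
                                "gaussian-identity", [0.0], opts)
        assert c.xtwx == [[3.0]]
        assert c.xtwz == [12.0]
        assert c.deviance == pytest.approx(2.0 ** 2 + 4 ** 2 + 6 ** 2)

    def test_binomial_weights_at_beta_zero(self):
        df = pd.DataFrame({"y": [0, 1, 1, 0, 1], "x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        opts = DisclosureOptions(glm_ratio=0.5)
        c = ds.glm_contribution(df, {"response": "y", "terms": ["x"]},
                                "binomial-logit", [0.0, 0.0], opts)
        # mu = 0.5 everywhere, so W = 0.25 I and XtWX = 0.25 XtX
        x = df["x"].to_numpy()
        assert c.xtwx[0][0] == pytest.approx(0.25 * 5)
        assert c.xtwx[1][1] == pytest.approx(0.25 * (x ** 2).sum())

    def test_ratio_breach_refused(self):
        df = pd.DataFrame({"y": [1.0] * 6, "x": np.arange(6.0)})
        with pytest.raises(DisclosureError) as exc:
            ds.glm_contribution(df, {"response": "y", "terms": ["x"]},
                                "gaussian-identity", [0.0, 0.0], OPTS)
        assert exc.value.rule == "glm_ratio"

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame({"y": np.arange(20.0), "x": np.ones(20)})
        with pytest.raises(ValidationError):
            ds.glm_contribution(df, {"response": "y", "terms": ["x"]},
                                "gaussian-identity", [0.0, 0.0], OPTS)

    def test_missing_rows_dropped(self):
        df = pd.DataFrame({"y": pd.array([1.0, 2.0, None, 4.0, 5.0, 6.0],
                                         dtype="Float64"),
                           "x": pd.array([1, 2, 3, 4, 5, None], dtype="Int64")})
        c = ds.glm_contribution(df, {"response": "y", "terms": ["x"]},
                                "gaussian-identity", [0.0, 0.0],
                                DisclosureOptions(glm_ratio=0.5))
        assert c.n == 4

    def test_two_node_split_matches_pooled_oracle(self):
        """Summed contributions drive IRLS to the pooled-fit coefficients."""
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        n = 400
        x = rng.normal(size=n)
        eta = -0.5 + 0.8 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        df = pd.DataFrame({"y": y, "x": x})
        halves = [df.iloc[:150], df.iloc[150:]]
        formula = {"response": "y", "terms": ["x"]}
        beta = np.zeros(2)
        for _ in range(30):
            contribs = [ds.glm_contribution(h, formula, "binomial-logit",
                                            beta, OPTS) for h in halves]
            xtwx = sum(np.asarray(c.xtwx) for c in contribs)
            xtwz = sum(np.asarray(c.xtwz) for c in contribs)
            beta = np.linalg.solve(xtwx, xtwz)
        oracle = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        assert np.max(np.abs(beta - np.asarray(oracle.params))) < 1e-6


class TestChokePoint:
    def test_summary_violation_named(self):
        payload = ds.GuardedSummary("mean", 1.0, n_valid=2, n_missing=0)
        assert ds.check_disclosure(payload, OPTS) == (False, "min_obs")

    def test_table_violation_named(self):
        t = ds.SuppressedTable(["f"], ["A"], None, [1], None, None, 1)
        assert ds.check_disclosure(t, OPTS) == (False, "min_cell")

    def test_compliant_passes(self):
        payload = ds.mean_ds([1, 2, 3, 4], OPTS)
        assert ds.check_disclosure(payload, OPTS) == (True, None)

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(-100, 100), min_size=0, max_size=12),
        st.integers(1, 6), st.integers(1, 6),
    )
    def test_monotonicity_property(self, values, lo, hi):
        """Raising min_obs never converts a refusal into a release."""
        low, high = sorted((lo, hi))
        def released(min_obs):
            try:
                ds.mean_ds(values, DisclosureOptions(min_obs=min_obs))
                return True
            except DisclosureError:
                return False
        if not released(low):
            assert not released(high)
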