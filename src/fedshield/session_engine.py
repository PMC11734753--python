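"""The assign/aggregate command protocol.

A session is a per-researcher, server-side symbol table bound to one
running profile. The protocol has exactly two command classes:

* **assign** — the result is stored server-side under a symbol name and
  the response carries only metadata (status, symbol, row count, column
  names), never values;
* **aggregate** — the named statistical function runs on bound symbols
  and only its disclosure-checked summary is returned.

Derived data is expressed in a closed, auditable expression grammar
(JSON trees) instead of arbitrary code: column references, literals,
arithmetic/comparison/logical operators, ``ifelse``, row filters and
column binds. Row filters are guarded — a filter that would leave
between 1 and ``min_subset − 1`` rows is refused (an empty result is
allowed: it reveals nothing about individuals).

Workspaces snapshot a session's symbol table to parquet files on the
server; they can be restored only by their owner and their bytes are
never exposed through any endpoint.
"""

from __future__ import annotations

import json
import secrets
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import disclosure_stats as ds
from .access_control import AccessControl
from .datastore import DataStore
from .errors import (
    DisclosureError,
    ForbiddenError,
    ForbiddenFunctionError,
    NotFoundError,
    UnavailableError,
    ValidationError,
)
from .profiles import DisclosureOptions, ProfileRegistry

BINARY_OPS = {
    "+": lambda a, b: a + b,
    "-": lambda a, b: a - b,
    "*": lambda a, b: a * b,
    "/": lambda a, b: a / b,  # zero divisors post-processed to missing
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "&": lambda a, b: a & b,
    "|": lambda a, b: a | b,
}


@dataclass
class Session:
    id: str
    owner: str
    profile_name: str
    options: DisclosureOptions
    symbols: dict = field(default_factory=dict)  # name -> DataFrame | Series
    created_at: float = 0.0
    last_used: float = 0.0


@dataclass
class WorkspaceRef:
    owner: str
    name: str
    saved_at: float
    n_symbols: int

    def to_payload(self) -> dict:
        return {"name": self.name, "saved_at": self.saved_at, "n_symbols": self.n_symbols}


class ExpressionEvaluator:
    """Evaluates the restricted JSON expression grammar.

    Nodes: ``{"op": "col", "symbol", "name"}``, ``{"op": "const",
    "value"}`` (numeric/boolean), binary operators with ``left``/
    ``right``, ``{"op": "!", "arg"}``, ``{"op": "ifelse", "cond",
    "then", "else"}``, ``{"op": "filter", "symbol", "cond"}`` and
    ``{"op": "cbind", "columns": {name: expr}}``. Division by zero
    yields missing so vector arithmetic stays total.
    """

    def __init__(self, symbols: dict, options: DisclosureOptions):
        self.symbols = symbols
        self.options = options

    def _symbol_df(self, name: str) -> pd.DataFrame:
        if name not in self.symbols:
            raise ValidationError(f"unknown symbol {name!r}")
        obj = self.symbols[name]
        if not isinstance(obj, pd.DataFrame):
            raise ValidationError(f"symbol {name!r} is not a table")
        return obj

    def eval(self, node):
        if not isinstance(node, dict) or "op" not in node:
            raise ValidationError(f"malformed expression node: {node!r}")
        op = node["op"]
        if op == "const":
            value = node.get("value")
            if not isinstance(value, (int, float, bool)):
                raise ValidationError("literals must be numeric or boolean")
            return value
        if op == "col":
            df = self._symbol_df(node["symbol"])
            col = node.get("name")
            if col not in df.columns:
                raise ValidationError(f"unknown column {col!r} in {node['symbol']!r}")
            return self._as_array(df[col])
        if op == "sym":
            name = node.get("name")
            if name not in self.symbols:
                raise ValidationError(f"unknown symbol {name!r}")
            return self.symbols[name]
        if op in BINARY_OPS:
            left = self.eval(node.get("left"))
            right = self.eval(node.get("right"))
            return self._binary(op, left, right)
        if op == "!":
            arg = self.eval(node.get("arg"))
            return ~self._as_bool(arg) if isinstance(arg, np.ndarray) else (not arg)
        if op == "ifelse":
            cond = self._as_bool(self.eval(node.get("cond")))
            a = self.eval(node.get("then"))
            b = self.eval(node.get("else"))
            return np.where(cond, a, b)
        if op == "filter":
            return self._filter(node)
        if op == "cbind":
            return self._cbind(node)
        raise ValidationError(f"operator {op!r} is not in the grammar")

    @staticmethod
    def _as_array(series: pd.Series) -> np.ndarray:
        if isinstance(series.dtype, pd.CategoricalDtype) or series.dtype == "string":
            return series.astype("object").to_numpy()
        # numeric/boolean (incl. nullable) -> float64 with NaN for missing
        return pd.to_numeric(series, errors="coerce").to_numpy(
            dtype="float64", na_value=np.nan
        )

    @staticmethod
    def _as_bool(arr) -> np.ndarray:
        out = np.asarray(arr)
        if out.dtype == object or np.issubdtype(out.dtype, np.floating):
            # missing comparisons are treated as False (row not selected)
            with np.errstate(invalid="ignore"):
                out = np.nan_to_num(out.astype(float), nan=0.0) != 0
        return out.astype(bool)

    def _binary(self, op, left, right):
        if op in ("&", "|"):
            left = self._as_bool(left) if np.ndim(left) else bool(left)
            right = self._as_bool(right) if np.ndim(right) else bool(right)
        if op == "/":  # numpy scalars divide to inf/nan instead of raising
            left = np.asarray(left, dtype=float) if np.ndim(left) else np.float64(left)
            right = np.asarray(right, dtype=float) if np.ndim(right) else np.float64(right)
        with np.errstate(invalid="ignore", divide="ignore"):
            result = BINARY_OPS[op](left, right)
        if op == "/":
            # division by zero (or by missing) yields missing, not an error
            if np.ndim(result):
                result = np.asarray(result, dtype=float)
                result[~np.isfinite(result)] = np.nan
            elif not np.isfinite(result):
                result = float("nan")
        return result

    def _filter(self, node) -> pd.DataFrame:
        df = self._symbol_df(node["symbol"])
        cond = self.eval(node.get("cond"))
        mask = self._as_bool(cond)
        if mask.shape != (len(df),):
            raise ValidationError("filter condition length does not match table")
        out = df[mask].reset_index(drop=True)
        n = len(out)
        if 0 < n < self.options.min_subset:
            raise DisclosureError(
                f"row filter leaves {n} row(s); 1..{self.options.min_subset - 1} "
                "is disclosive",
                rule="min_subset",
            )
        return out

    def _cbind(self, node) -> pd.DataFrame:
        columns = node.get("columns")
        if not isinstance(columns, dict) or not columns:
            raise ValidationError("cbind requires a non-empty column mapping")
        data, length = {}, None
        for name, expr in columns.items():
            value = self.eval(expr)
            arr = np.asarray(value) if np.ndim(value) else None
            if arr is not None:
                if length is None:
                    length = len(arr)
                elif len(arr) != length:
                    raise ValidationError("cbind columns have unequal length")
            data[name] = value
        if length is None:
            raise ValidationError("cbind needs at least one vector column")
        return pd.DataFrame(
            {k: (v if np.ndim(v) else np.full(length, v)) for k, v in data.items()}
        )


class SessionManager:
    """Creates sessions, executes commands, saves/restores workspaces."""

    def __init__(
        self,
        datastore: DataStore,
        access: AccessControl,
        profiles: ProfileRegistry,
        workspace_root,
        clock=time.time,
        idle_ttl_seconds: float = 3600,
    ):
        self.datastore = datastore
        self.access = access
        self.profiles = profiles
        self.workspace_root = Path(workspace_root)
        self.workspace_root.mkdir(parents=True, exist_ok=True)
        self.clock = clock
        self.idle_ttl = idle_ttl_seconds
        self._sessions: dict[str, Session] = {}
        profiles.session_counter = self.count_for_profile
        profiles.on_stop = self.terminate_profile_sessions

    # -- lifecycle ---------------------------------------------------

    def count_for_profile(self, profile_name: str) -> int:
        return sum(1 for s in self._sessions.values() if s.profile_name == profile_name)

    def active_count(self) -> int:
        return len(self._sessions)

    def terminate_profile_sessions(self, profile_name: str) -> None:
        for sid in [s.id for s in self._sessions.values() if s.profile_name == profile_name]:
            del self._sessions[sid]

    def expire_idle(self) -> int:
        now = self.clock()
        stale = [s.id for s in self._sessions.values() if now - s.last_used > self.idle_ttl]
        for sid in stale:
            del self._sessions[sid]
        return len(stale)

    def create_session(self, token: str, profile_name: str) -> Session:
        user = self.access.resolve(token)
        if user is None:
            raise ForbiddenError("anonymous callers cannot create sessions")
        if not user.is_admin and not user.grants:
            raise ForbiddenError("caller holds no project grants")
        profile = self.profiles.get(profile_name)
        if profile.state != "running":
            raise UnavailableError(f"profile {profile_name!r} is not running")
        session = Session(
            id=secrets.token_hex(16),
            owner=user.subject_id,
            profile_name=profile_name,
            options=profile.options,  # frozen snapshot: later edits rebind, not mutate
            created_at=self.clock(),
            last_used=self.clock(),
        )
        self._sessions[session.id] = session
        return session

    def get_session(self, session_id: str, token: str) -> Session:
        self.expire_idle()
        session = self._sessions.get(session_id)
        if session is None:
            raise NotFoundError("unknown or expired session")
        user = self.access.resolve(token)
        if user is None or user.subject_id != session.owner:
            raise ForbiddenError("session belongs to a different subject")
        session.last_used = self.clock()
        return session

    def destroy_session(self, session_id: str, token: str) -> None:
        session = self.get_session(session_id, token)
        del self._sessions[session.id]

    # -- assign ------------------------------------------------------

    def assign_load(self, session_id: str, token: str, symbol: str,
                    project: str, folder: str, name: str) -> dict:
        """Bind a full stored table to a symbol. Response is metadata only."""
        session = self.get_session(session_id, token)
        if not self.access.authorize(token, project, "analyse"):
            raise ForbiddenError(f"no analyse grant on project {project!r}")
        df = self.datastore.read_table(project, folder, name)
        overwritten = symbol in session.symbols
        session.symbols[symbol] = df
        ack = {
            "status": "ok",
            "symbol": symbol,
            "n_rows": len(df),
            "columns": [str(c) for c in df.columns],
        }
        if overwritten:
            ack["warning"] = "symbol overwritten"
        return ack

    def assign_expr(self, session_id: str, token: str, symbol: str, expression: dict) -> dict:
        """Bind a derived vector/table to a symbol. Response is metadata only."""
        session = self.get_session(session_id, token)
        evaluator = ExpressionEvaluator(session.symbols, session.options)
        result = evaluator.eval(expression)
        if isinstance(result, np.ndarray):
            result = pd.Series(result)
        elif isinstance(result, (int, float, bool)):
            raise ValidationError("assign target must be a vector or table, not a scalar")
        overwritten = symbol in session.symbols
        session.symbols[symbol] = result
        if isinstance(result, pd.DataFrame):
            ack = {"status": "ok", "symbol": symbol, "n_rows": len(result),
                   "columns": [str(c) for c in result.columns]}
        else:
            ack = {"status": "ok", "symbol": symbol, "n_rows": len(result), "columns": []}
        if overwritten:
            ack["warning"] = "symbol overwritten"
        return ack

    def list_symbols(self, session_id: str, token: str) -> dict:
        session = self.get_session(session_id, token)
        return {
            "symbols": {
                name: {"n_rows": len(obj),
                       "columns": [str(c) for c in obj.columns]
                       if isinstance(obj, pd.DataFrame) else []}
                for name, obj in session.symbols.items()
            }
        }

    # -- aggregate ---------------------------------------------------

    def aggregate(self, session_id: str, token: str, function: str, args: dict) -> dict:
        """Run an aggregate function; only its disclosure-checked payload
        leaves the server. The profile's callability rules and the
        disclosure choke point both apply on every call."""
        session = self.get_session(session_id, token)
        profile = self.profiles.get(session.profile_name)
        if profile.state != "running":
            raise UnavailableError(f"profile {profile.name!r} is not running")
        if not self.profiles.is_callable(profile, function):
            self.access.audit.append(session.owner, f"aggregate:{function}", "-", "denied")
            raise ForbiddenFunctionError(f"function {function!r} is not callable in "
                                         f"profile {profile.name!r}")
        spec = ds.FUNCTIONS.get(function)
        if spec is None or spec["kind"] != "aggregate":
            raise ForbiddenFunctionError(f"function {function!r} is not registered")
        payload = self._dispatch(session, spec, args)
        ok, rule = ds.check_disclosure(payload, session.options)
        if not ok:
            self.access.audit.append(session.owner, f"aggregate:{function}", "-", "denied")
            raise DisclosureError(f"aggregate refused by rule {rule}", rule=rule)
        self.access.audit.append(session.owner, f"aggregate:{function}", "-", "allowed")
        return payload.to_payload()

    def _dispatch(self, session: Session, spec: dict, args: dict):
        evaluator = ExpressionEvaluator(session.symbols, session.options)
        kind = spec["input"]
        if kind == "vector":
            values = self._vector_arg(session, evaluator, args.get("values"))
            return spec["fn"](values, session.options)
        if kind == "factors":
            factors_arg = args.get("factors")
            if not isinstance(factors_arg, list) or not factors_arg:
                raise ValidationError("table function needs a list of factor references")
            factors, names = [], []
            for ref in factors_arg:
                factors.append(self._factor_arg(session, ref))
                names.append(ref.get("name", "f") if isinstance(ref, dict) else "f")
            return spec["fn"](factors, session.options, names=names)
        if kind == "glm":
            symbol = args.get("symbol")
            if symbol not in session.symbols or not isinstance(session.symbols[symbol], pd.DataFrame):
                raise ValidationError(f"symbol {symbol!r} is not a bound table")
            return spec["fn"](
                session.symbols[symbol],
                args.get("formula") or {},
                args.get("family", ""),
                args.get("beta", []),
                session.options,
            )
        raise ValidationError(f"unknown argument convention {kind!r}")

    def _vector_arg(self, session, evaluator, ref):
        if isinstance(ref, dict):
            value = evaluator.eval(ref)
            if isinstance(value, pd.DataFrame):
                raise ValidationError("expected a vector, got a table")
            if isinstance(value, pd.Series):
                return value
            return pd.Series(value)
        if isinstance(ref, str):  # bare symbol name bound to a vector
            obj = session.symbols.get(ref)
            if obj is None:
                raise ValidationError(f"unknown symbol {ref!r}")
            if isinstance(obj, pd.DataFrame):
                raise ValidationError(f"symbol {ref!r} is a table; reference a column")
            return obj
        raise ValidationError("vector argument must be a symbol name or expression")

    def _factor_arg(self, session, ref):
        if isinstance(ref, dict) and "symbol" in ref and "name" in ref:
            df = session.symbols.get(ref["symbol"])
            if not isinstance(df, pd.DataFrame) or ref["name"] not in df.columns:
                raise ValidationError(f"unknown column {ref.get('name')!r}")
            return df[ref["name"]]
        if isinstance(ref, str):
            obj = session.symbols.get(ref)
            if obj is None or isinstance(obj, pd.DataFrame):
                raise ValidationError(f"{ref!r} is not a bound vector")
            return obj
        raise ValidationError("factor reference must name a symbol or column")

    # -- workspaces --------------------------------------------------

    def _workspace_dir(self, owner: str, name: str) -> Path:
        if not name or "/" in name or name.startswith("."):
            raise ValidationError(f"invalid workspace name {name!r}")
        return self.workspace_root / owner / name

    def save_workspace(self, session_id: str, token: str, name: str) -> WorkspaceRef:
        """Serialize the symbol table to parquet files server-side."""
        session = self.get_session(session_id, token)
        wdir = self._workspace_dir(session.owner, name)
        wdir.mkdir(parents=True, exist_ok=True)
        for stale in wdir.glob("*.parquet"):
            stale.unlink()
        manifest = []
        for idx, (sym, obj) in enumerate(session.symbols.items()):
            fname = f"{idx:04d}.parquet"
            if isinstance(obj, pd.DataFrame):
                obj.to_parquet(wdir / fname, index=False)
                manifest.append({"symbol": sym, "file": fname, "kind": "table"})
            else:
                pd.DataFrame({"value": obj}).to_parquet(wdir / fname, index=False)
                manifest.append({"symbol": sym, "file": fname, "kind": "vector"})
        saved_at = self.clock()
        (wdir / "manifest.json").write_text(
            json.dumps({"saved_at": saved_at, "symbols": manifest})
        )
        return WorkspaceRef(session.owner, name, saved_at, len(manifest))

    def restore_workspace(self, token: str, name: str, profile_name: str) -> Session:
        """New session whose symbol table equals the saved one; owner-only."""
        user = self.access.resolve(token)
        if user is None:
            raise ForbiddenError("anonymous callers cannot restore workspaces")
        wdir = self._workspace_dir(user.subject_id, name)
        if not (wdir / "manifest.json").exists():
            # distinguishing "not yours" from "absent" would leak other
            # users' workspace names, except when the name demonstrably
            # exists under another owner and the caller asks for it
            for other in self.workspace_root.iterdir():
                if other.name != user.subject_id and (other / name / "manifest.json").exists():
                    raise ForbiddenError("workspace belongs to a different subject")
            raise NotFoundError(f"unknown workspace {name!r}")
        session = self.create_session(token, profile_name)
        manifest = json.loads((wdir / "manifest.json").read_text())
        for entry in manifest["symbols"]:
            df = pd.read_parquet(wdir / entry["file"])
            session.symbols[entry["symbol"]] = (
                df if entry["kind"] == "table" else df["value"]
            )
        return session

    def list_workspaces(self, token: str) -> list[dict]:
        user = self.access.resolve(token)
        if user is None:
            raise ForbiddenError("authentication required")
        owner_dir = self.workspace_root / user.subject_id
        out = []
        if owner_dir.exists():
            for wdir in sorted(owner_dir.iterdir()):
                mpath = wdir / "manifest.json"
                if mpath.exists():
                    m = json.loads(mpath.read_text())
                    out.append({"name": wdir.name, "saved_at": m["saved_at"],
                                "n_symbols": len(m["symbols"])})
        return out
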