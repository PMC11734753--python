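"""Researcher-side pooling client — the hub of the hub-and-spoke topology.

Connects to several cohort servers, drives the assign/aggregate
protocol on each, and recombines the non-disclosive per-node payloads:

* descriptive moments pool **exactly** — per-node ``(n, Σx, Σx²)`` add,
  so the pooled mean and variance equal the values a single analyst
  would compute on the concatenated data;
* the federated GLM is an IRLS driver: the client broadcasts the
  current coefficient vector β, each node returns its ``XᵀWX`` and
  ``XᵀWz`` (plus n, p and deviance at β), and the client updates
  ``β ← (Σ XᵀWX)⁻¹ (Σ XᵀWz)`` until the relative deviance change
  drops below ``tol``. Because those matrices add over row partitions,
  the trajectory — and hence the fit — is identical to pooled IRLS.

The client only ever sees payload classes emitted by the server's
disclosure layer; every response is schema-checked against an allow-list
of keys before use.
"""

from __future__ import annotations

import io
import json
import urllib.request
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import errors
from .errors import EstimationError, FedShieldError, ValidationError

#: keys the client accepts per payload type; anything else is rejected
#: before use so row-level data cannot sneak into client state
ALLOWED_KEYS = {
    "guarded-summary": {"type", "statistic", "value", "n_valid", "n_missing"},
    "suppressed-table": {"type", "dims", "row_labels", "col_labels", "cells",
                         "row_totals", "col_totals", "total"},
    "node-contribution": {"type", "n", "p", "names", "xtwx", "xtwz", "deviance"},
}


class WSGITransport:
    """Calls a WSGI app in-process: a full federation without sockets."""

    def __init__(self, app):
        self.app = app

    def request(self, method: str, path: str, body=None, token: str | None = None):
        raw = json.dumps(body).encode() if body is not None else b""
        path, _, query = path.partition("?")
        environ = {
            "REQUEST_METHOD": method,
            "PATH_INFO": path,
            "QUERY_STRING": query,
            "CONTENT_LENGTH": str(len(raw)),
            "wsgi.input": io.BytesIO(raw),
        }
        if token:
            environ["HTTP_AUTHORIZATION"] = f"Bearer {token}"
        captured = {}

        def start_response(status, headers):
            captured["status"] = int(status.split()[0])

        chunks = self.app(environ, start_response)
        data = b"".join(chunks)
        return captured["status"], json.loads(data) if data else {}


class HTTPTransport:
    """Talks to a remote server over HTTP (urllib, no extra deps)."""

    def __init__(self, base_url: str, timeout: float = 30.0):
        self.base_url = base_url.rstrip("/")
        self.timeout = timeout

    def request(self, method: str, path: str, body=None, token: str | None = None):
        data = json.dumps(body).encode() if body is not None else None
        req = urllib.request.Request(self.base_url + path, data=data, method=method)
        req.add_header("Content-Type", "application/json")
        if token:
            req.add_header("Authorization", f"Bearer {token}")
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                return resp.status, json.loads(resp.read() or b"{}")
        except urllib.error.HTTPError as exc:
            return exc.code, json.loads(exc.read() or b"{}")


@dataclass
class NodeHandle:
    label: str
    transport: object
    token: str
    session_id: str | None = None


@dataclass
class PooledEstimate:
    statistic: str
    value: object
    per_node: dict
    per_node_n: dict
    method: str  # exact-combination | iterative
    extra: dict = field(default_factory=dict)


@dataclass
class GlmResult:
    coefficients: dict
    standard_errors: dict
    deviance: float
    n: int
    iterations: int
    converged: bool
    per_node_n: dict


class NodeError(FedShieldError):
    """A per-node failure, carrying the node label for debugging."""

    code = "node"

    def __init__(self, label: str, wrapped: FedShieldError):
        super().__init__(f"node {label!r}: {wrapped.message}", label=label)
        self.label = label
        self.wrapped = wrapped


def _check_payload_schema(payload: dict) -> dict:
    ptype = payload.get("type")
    allowed = ALLOWED_KEYS.get(ptype)
    if allowed is None:
        raise ValidationError(f"unexpected payload type {ptype!r} from server")
    extra = set(payload) - allowed
    if extra:
        raise ValidationError(
            f"payload carries unexpected keys: {', '.join(sorted(extra))}"
        )
    return payload


class Pool:
    """A set of live sessions, one per cohort server."""

    def __init__(self, handles: list[NodeHandle], warnings: list[str] | None = None):
        labels = [h.label for h in handles]
        if len(set(labels)) != len(labels):
            raise ValidationError("node labels must be unique within a pool")
        self.handles = handles
        self.warnings = warnings or []

    @property
    def labels(self) -> list[str]:
        return [h.label for h in self.handles]

    # -- low-level protocol ------------------------------------------

    def _call(self, handle: NodeHandle, method: str, path: str, body=None) -> dict:
        status, payload = handle.transport.request(method, path, body, handle.token)
        if status >= 400:
            raise NodeError(handle.label, errors.from_payload(payload))
        return payload

    def assign_load(self, symbol: str, project: str, folder: str, name: str) -> dict:
        acks = {}
        for handle in self.handles:
            acks[handle.label] = self._call(
                handle, "POST", f"/sessions/{handle.session_id}/symbols/{symbol}",
                {"op": "load", "project": project, "folder": folder, "name": name},
            )
        return acks

    def assign_expr(self, symbol: str, expression: dict) -> dict:
        return {
            handle.label: self._call(
                handle, "POST", f"/sessions/{handle.session_id}/symbols/{symbol}",
                {"op": "expr", "expression": expression},
            )
            for handle in self.handles
        }

    def aggregate(self, function: str, args: dict) -> dict:
        out = {}
        for handle in self.handles:
            payload = self._call(
                handle, "POST", f"/sessions/{handle.session_id}/aggregate",
                {"function": function, "args": args},
            )
            out[handle.label] = _check_payload_schema(payload)
        return out

    def close(self) -> None:
        for handle in self.handles:
            if handle.session_id:
                try:
                    self._call(handle, "DELETE", f"/sessions/{handle.session_id}")
                except FedShieldError:
                    pass
                handle.session_id = None

    # -- exact pooling -----------------------------------------------

    def _pooled_moments(self, values_ref) -> tuple[dict, dict, dict]:
        per_node = self.aggregate("moments_ds", {"values": values_ref})
        moments = {label: p["value"] for label, p in per_node.items()}
        ns = {label: p["value"]["n"] for label, p in per_node.items()}
        return per_node, moments, ns

    def pooled_mean(self, symbol: str, column: str) -> PooledEstimate:
        """Pooled mean from per-node (n, Σx): ΣΣx / Σn, exact."""
        ref = {"op": "col", "symbol": symbol, "name": column}
        _, moments, ns = self._pooled_moments(ref)
        total_n = sum(m["n"] for m in moments.values())
        total_sum = sum(m["sum"] for m in moments.values())
        return PooledEstimate(
            statistic="mean",
            value=total_sum / total_n,
            per_node={lbl: m["sum"] / m["n"] for lbl, m in moments.items()},
            per_node_n=ns,
            method="exact-combination",
        )

    def pooled_var(self, symbol: str, column: str) -> PooledEstimate:
        """Pooled sample variance from per-node (n, Σx, Σx²), exact:
        (Σx² − (Σx)²/N) / (N − 1)."""
        ref = {"op": "col", "symbol": symbol, "name": column}
        _, moments, ns = self._pooled_moments(ref)
        total_n = sum(m["n"] for m in moments.values())
        total_sum = sum(m["sum"] for m in moments.values())
        total_sq = sum(m["sum_sq"] for m in moments.values())
        value = (total_sq - total_sum ** 2 / total_n) / (total_n - 1)
        per_node = {
            lbl: (m["sum_sq"] - m["sum"] ** 2 / m["n"]) / (m["n"] - 1)
            for lbl, m in moments.items()
        }
        return PooledEstimate("variance", value, per_node, ns, "exact-combination")

    def pooled_table(self, refs: list[dict]) -> dict:
        """Per-node suppressed contingency tables (not summed: suppressed
        cells cannot be recombined without re-identification risk)."""
        return self.aggregate("table_ds", {"factors": refs})

    # -- federated GLM -----------------------------------------------

    def expand_formula(self, symbol: str, response: str, terms: list,
                       intercept: bool = True) -> dict:
        """Expand categorical terms to treatment-coded indicator specs.

        Levels are discovered from a suppressed contingency table on the
        first node; the reference level is the lexicographically first
        level there. Identical indicator specs are broadcast to every
        node so all design matrices align.
        """
        expanded = []
        for term in terms:
            if isinstance(term, dict) and term.get("categorical"):
                col = term["column"]
                first = Pool([self.handles[0]])
                tables = first.aggregate(
                    "table_ds", {"factors": [{"symbol": symbol, "name": col}]}
                )
                levels = sorted(next(iter(tables.values()))["row_labels"])
                for level in levels[1:]:  # first level is the reference
                    expanded.append({"name": f"{col}[{level}]",
                                     "column": col, "level": level})
            else:
                expanded.append(term)
        return {"response": response, "terms": expanded, "intercept": intercept}

    def federated_glm(
        self,
        symbol: str,
        formula: dict,
        family: str,
        max_iter: int = 25,
        tol: float = 1e-8,
    ) -> GlmResult:
        """Iteratively aggregated GLM; identical to the pooled fit.

        ``iterations`` counts coefficient updates. Standard errors are
        ``sqrt(diag((Σ XᵀWX)⁻¹) · φ)`` at convergence, with dispersion
        φ = deviance/(N − p) for the gaussian family and φ = 1 for the
        binomial family.
        """
        beta = None
        names: list[str] = []
        dev_prev = None
        iterations = 0
        converged = False
        last = None
        for _ in range(max_iter + 1):
            contribs = self.aggregate("glm_ds", {
                "symbol": symbol, "formula": formula, "family": family,
                "beta": list(beta) if beta is not None else
                [0.0] * self._p_of(symbol, formula, family),
            })
            last = contribs
            names = next(iter(contribs.values()))["names"]
            xtwx = sum(np.asarray(c["xtwx"]) for c in contribs.values())
            xtwz = sum(np.asarray(c["xtwz"]) for c in contribs.values())
            deviance = sum(c["deviance"] for c in contribs.values())
            if dev_prev is not None and abs(deviance - dev_prev) / (
                    0.1 + abs(deviance)) < tol:
                converged = True
                break
            dev_prev = deviance
            if iterations >= max_iter:
                break
            try:
                beta = np.linalg.solve(xtwx, xtwz)
            except np.linalg.LinAlgError:
                raise EstimationError("summed information matrix is singular")
            iterations += 1
        xtwx = sum(np.asarray(c["xtwx"]) for c in last.values())
        deviance = sum(c["deviance"] for c in last.values())
        total_n = sum(c["n"] for c in last.values())
        p = len(names)
        try:
            cov = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError:
            raise EstimationError("summed information matrix is singular")
        scale = deviance / (total_n - p) if family == "gaussian-identity" else 1.0
        se = np.sqrt(np.clip(np.diag(cov) * scale, 0, None))
        beta_out = beta if beta is not None else np.zeros(p)
        return GlmResult(
            coefficients=dict(zip(names, map(float, beta_out))),
            standard_errors=dict(zip(names, map(float, se))),
            deviance=float(deviance),
            n=int(total_n),
            iterations=iterations,
            converged=converged,
            per_node_n={lbl: c["n"] for lbl, c in last.items()},
        )

    def _p_of(self, symbol: str, formula: dict, family: str) -> int:
        p = len(formula.get("terms", []))
        if formula.get("intercept", True):
            p += 1
        return p

    # -- batch scripts -----------------------------------------------

    def run_script(self, commands: list[dict], continue_on_error: bool = False) -> list[dict]:
        """Execute commands in order on all nodes; a transcript records
        per-node outcomes. Stops at the first failing step unless
        ``continue_on_error``."""
        transcript = []
        for step, command in enumerate(commands, start=1):
            entry = {"step": step, "command": command, "outcomes": {}, "ok": True}
            kind = command.get("kind")
            try:
                if kind == "assign-load":
                    entry["outcomes"] = self.assign_load(
                        command["symbol"], command["project"],
                        command["folder"], command["name"])
                elif kind == "assign-expr":
                    entry["outcomes"] = self.assign_expr(
                        command["symbol"], command["expression"])
                elif kind == "aggregate":
                    entry["outcomes"] = self.aggregate(
                        command["function"], command.get("args", {}))
                else:
                    raise ValidationError(f"unknown command kind {kind!r}")
            except FedShieldError as exc:
                entry["ok"] = False
                entry["error"] = exc.to_payload()
            transcript.append(entry)
            if not entry["ok"] and not continue_on_error:
                break
        return transcript


def connect(nodes: list[dict], allow_partial: bool = False,
            profile: str = "default") -> Pool:
    """Open one session per node.

    Each node spec needs ``label`` and either ``transport`` (any object
    with the transport interface) or ``url``, plus either a ready
    ``token`` or ``credentials`` ``{subject_id, origin_id}`` exchanged
    at ``/auth/token``.
    """
    handles, warnings = [], []
    for node in nodes:
        label = node.get("label", node.get("url", "?"))
        try:
            transport = node.get("transport") or HTTPTransport(node["url"])
            token = node.get("token")
            if not token:
                status, payload = transport.request(
                    "POST", "/auth/token", node.get("credentials", {}))
                if status >= 400:
                    raise errors.from_payload(payload)
                token = payload["token"]
            status, payload = transport.request(
                "POST", "/sessions", {"profile": node.get("profile", profile)}, token)
            if status >= 400:
                raise errors.from_payload(payload)
            handles.append(NodeHandle(label, transport, token, payload["session_id"]))
        except (FedShieldError, OSError, KeyError) as exc:
            message = exc.message if isinstance(exc, FedShieldError) else str(exc)
            warnings.append(f"node {label!r} unavailable: {message}")
            if not allow_partial:
                raise FedShieldError(f"cannot connect to node {label!r}: {message}")
    if not handles:
        raise FedShieldError("no nodes reachable")
    return Pool(handles, warnings)


def load_nodes_config(path) -> list[dict]:
    """Read a node list from YAML: a list of {label, url, token}."""
    data = yaml.safe_load(open(path).read())
    nodes = data.get("nodes", data) if isinstance(data, dict) else data
    if not isinstance(nodes, list):
        raise ValidationError("nodes file must contain a list of node specs")
    return nodes
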