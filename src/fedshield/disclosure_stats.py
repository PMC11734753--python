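"""Non-disclosive aggregate statistics.

Every quantity a server releases passes through this module: guarded
descriptive moments, cell-suppressed contingency tables, and the
per-node sufficient statistics of a generalized linear model. The
guiding principle is that each released number must be a function of at
least ``min_obs`` observations, each released count must be 0 or at
least ``min_cell``, and a model may not be so over-parameterized that
its coefficients pin down individual records (``glm_ratio``).

Federated pooling rests on two exact identities:

* moments: for a partition of x into nodes, ``n``, ``Σx`` and ``Σx²``
  add across nodes, so the pooled mean and variance recombine exactly;
* GLM: with ``μ = g⁻¹(Xβ)``, IRLS weights ``W`` and working response
  ``z``, the update ``β ← (XᵀWX)⁻¹ XᵀWz`` depends on the data only
  through ``XᵀWX`` and ``XᵀWz``, which add across row partitions.
  A client that sums per-node contributions therefore reproduces the
  pooled fit exactly, iteration by iteration.

Functions here are pure: they take in-memory vectors/tables plus a
:class:`~fedshield.profiles.DisclosureOptions` and either return a
payload dataclass or raise :class:`~fedshield.errors.DisclosureError`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DisclosureError, ValidationError
from .profiles import DisclosureOptions

SUPPRESSED = "SUPPRESSED"

#: released quantile grid (percent); finer grids leak order statistics
QUANTILE_GRID = (5, 10, 25, 50, 75, 90, 95)


@dataclass
class GuardedSummary:
    statistic: str
    value: object  # float | dict of floats
    n_valid: int
    n_missing: int

    def to_payload(self) -> dict:
        return {
            "type": "guarded-summary",
            "statistic": self.statistic,
            "value": self.value,
            "n_valid": self.n_valid,
            "n_missing": self.n_missing,
        }


@dataclass
class SuppressedTable:
    dims: list[str]
    row_labels: list[str]
    col_labels: list[str] | None
    cells: list  # 1-D: list of counts/SUPPRESSED; 2-D: list of rows
    row_totals: list | None
    col_totals: list | None
    total: object  # count or SUPPRESSED

    def to_payload(self) -> dict:
        return {
            "type": "suppressed-table",
            "dims": self.dims,
            "row_labels": self.row_labels,
            "col_labels": self.col_labels,
            "cells": self.cells,
            "row_totals": self.row_totals,
            "col_totals": self.col_totals,
            "total": self.total,
        }

    def released_cells(self) -> list[int]:
        out = []
        rows = self.cells if self.col_labels else [self.cells]
        for row in rows:
            out.extend(c for c in row if c != SUPPRESSED)
        return out


@dataclass
class NodeContribution:
    """Per-node IRLS quantities: XᵀWX, XᵀWz, n, p and deviance at β."""

    n: int
    p: int
    names: list[str]
    xtwx: list[list[float]]
    xtwz: list[float]
    deviance: float

    def to_payload(self) -> dict:
        return {
            "type": "node-contribution",
            "n": self.n,
            "p": self.p,
            "names": self.names,
            "xtwx": self.xtwx,
            "xtwz": self.xtwz,
            "deviance": self.deviance,
        }


def _clean(values) -> tuple[np.ndarray, int]:
    """Numeric array without missing values, plus the missing count."""
    series = pd.Series(values)
    arr = pd.to_numeric(series, errors="coerce").astype(float).to_numpy()
    mask = np.isfinite(arr)
    return arr[mask], int((~mask).sum())


def _guard_n(n_valid: int, opts: DisclosureOptions) -> None:
    if n_valid < opts.min_obs:
        raise DisclosureError(
            f"{n_valid} valid observation(s) < min_obs={opts.min_obs}",
            rule="min_obs",
        )


def mean_ds(values, opts: DisclosureOptions) -> GuardedSummary:
    """Mean over non-missing values; refused below ``min_obs``."""
    arr, n_missing = _clean(values)
    _guard_n(len(arr), opts)
    return GuardedSummary("mean", float(arr.mean()), len(arr), n_missing)


def var_ds(values, opts: DisclosureOptions) -> GuardedSummary:
    """Sample variance (n−1 denominator) over non-missing values."""
    arr, n_missing = _clean(values)
    _guard_n(len(arr), opts)
    return GuardedSummary("variance", float(arr.var(ddof=1)), len(arr), n_missing)


def moments_ds(values, opts: DisclosureOptions) -> GuardedSummary:
    """Sufficient moments (n, Σx, Σx²) for exact cross-node pooling."""
    arr, n_missing = _clean(values)
    _guard_n(len(arr), opts)
    value = {
        "n": len(arr),
        "sum": float(arr.sum()),
        "sum_sq": float((arr ** 2).sum()),
    }
    return GuardedSummary("moments", value, len(arr), n_missing)


def quantiles_ds(values, opts: DisclosureOptions) -> GuardedSummary:
    """Quantiles on the fixed 5/10/25/50/75/90/95 grid.

    Released only when every inter-quantile bucket (including the two
    tails) holds at least ``min_obs`` observations, so no released
    order statistic is pinned down by fewer than ``min_obs`` records.
    """
    arr, n_missing = _clean(values)
    _guard_n(len(arr), opts)
    probs = np.array(QUANTILE_GRID) / 100.0
    qs = np.quantile(arr, probs)
    # bucket each observation between adjacent grid quantiles (8 buckets
    # including both tails); a thin bucket pins a released order
    # statistic down to few records
    bucket = np.searchsorted(qs, arr, side="right")
    counts = np.bincount(bucket, minlength=len(qs) + 1)
    if (counts < opts.min_obs).any():
        raise DisclosureError(
            "an inter-quantile bucket holds fewer than "
            f"min_obs={opts.min_obs} observations",
            rule="min_obs",
        )
    value = {f"q{p}": float(q) for p, q in zip(QUANTILE_GRID, qs)}
    return GuardedSummary("quantiles", value, len(arr), n_missing)


# -- contingency tables ---------------------------------------------


def _suppress(count: int, min_cell: int):
    """Zero is structural and safe; 1..min_cell−1 identifies individuals."""
    return int(count) if (count == 0 or count >= min_cell) else SUPPRESSED


def _margin(cells: list, raw_total: int):
    """Secondary suppression: a margin is released unless exactly one
    cell in its line is suppressed (otherwise total − released cells
    reconstructs the suppressed cell)."""
    n_suppressed = sum(1 for c in cells if c == SUPPRESSED)
    return SUPPRESSED if n_suppressed == 1 else int(raw_total)


def table_ds(factors: list, opts: DisclosureOptions, names: list[str] | None = None) -> SuppressedTable:
    """One- or two-way contingency table with cell suppression.

    Cells with counts in ``1..min_cell−1`` are replaced by the
    ``SUPPRESSED`` marker; zeros are released. Margins are released only
    when they cannot be combined with released cells to reconstruct a
    suppressed cell.
    """
    if not factors or len(factors) > 2:
        raise ValidationError("table_ds takes 1 or 2 categorical vectors")
    raw_series = [pd.Series(f) for f in factors]
    if len({len(s) for s in raw_series}) != 1:
        raise ValidationError("factors must have equal length")
    for s in raw_series:
        # continuous vectors are not categorical: tabulating them would
        # release raw values as labels
        if pd.api.types.is_float_dtype(s.dtype):
            raise ValidationError("table_ds requires categorical input")
    series = [s.astype("string") for s in raw_series]
    names = names or [f"f{i+1}" for i in range(len(series))]
    min_cell = opts.min_cell

    if len(series) == 1:
        counts = series[0].dropna().value_counts().sort_index()
        labels = [str(x) for x in counts.index]
        cells = [_suppress(c, min_cell) for c in counts.to_numpy()]
        total = _margin(cells, int(counts.sum()))
        return SuppressedTable(names, labels, None, cells, None, None, total)

    df = pd.DataFrame({"a": series[0], "b": series[1]}).dropna()
    pivot = pd.crosstab(df["a"], df["b"])
    row_labels = [str(x) for x in pivot.index]
    col_labels = [str(x) for x in pivot.columns]
    raw = pivot.to_numpy()
    cells = [[_suppress(c, min_cell) for c in row] for row in raw]
    row_totals = [_margin(cells[i], int(raw[i].sum())) for i in range(len(row_labels))]
    col_cells = [[cells[i][j] for i in range(len(row_labels))] for j in range(len(col_labels))]
    col_totals = [_margin(col_cells[j], int(raw[:, j].sum())) for j in range(len(col_labels))]
    # grand total: same one-suppressed-line rule applied to the margins
    total = int(raw.sum())
    if (sum(1 for t in row_totals if t == SUPPRESSED) == 1
            or sum(1 for t in col_totals if t == SUPPRESSED) == 1):
        total = SUPPRESSED
    return SuppressedTable(names, row_labels, col_labels, cells, row_totals, col_totals, total)


# -- generalized linear model contributions --------------------------

FAMILIES = ("gaussian-identity", "binomial-logit")


def build_design(df: pd.DataFrame, formula: dict) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix and response from a formula spec.

    ``formula`` is ``{response, terms, intercept}``. Each term is either
    a column name (numeric/boolean) or ``{"name", "column", "level"}``
    describing a treatment-coded indicator ``1[column == level]`` —
    the client broadcasts identical indicator specs to every node so
    design matrices align across cohorts. Rows with any missing value
    in the model columns are dropped (complete-case analysis).
    """
    response = formula["response"]
    terms = formula.get("terms", [])
    intercept = bool(formula.get("intercept", True))
    used_cols = [response]
    for term in terms:
        col = term["column"] if isinstance(term, dict) else term
        if col not in df.columns:
            raise ValidationError(f"unknown model column {col!r}")
        used_cols.append(col)
    if response not in df.columns:
        raise ValidationError(f"unknown model column {response!r}")
    sub = df[list(dict.fromkeys(used_cols))].dropna()
    y = pd.to_numeric(sub[response], errors="coerce").to_numpy(dtype=float)
    cols, names = [], []
    if intercept:
        cols.append(np.ones(len(sub)))
        names.append("(Intercept)")
    for term in terms:
        if isinstance(term, dict):
            indicator = (sub[term["column"]].astype("string") == str(term["level"]))
            cols.append(indicator.to_numpy(dtype=float))
            names.append(term.get("name") or f"{term['column']}[{term['level']}]")
        else:
            series = sub[term]
            if isinstance(series.dtype, pd.CategoricalDtype) or series.dtype == "string":
                raise ValidationError(
                    f"column {term!r} is categorical; expand it to indicator terms"
                )
            cols.append(pd.to_numeric(series, errors="coerce").to_numpy(dtype=float))
            names.append(str(term))
    X = np.column_stack(cols) if cols else np.empty((len(sub), 0))
    return X, y, names


def _deviance(family: str, y: np.ndarray, mu: np.ndarray) -> float:
    if family == "gaussian-identity":
        return float(((y - mu) ** 2).sum())
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    return float(-2.0 * (y * np.log(mu) + (1 - y) * np.log(1 - mu)).sum())


def glm_contribution(
    df: pd.DataFrame,
    formula: dict,
    family: str,
    beta,
    opts: DisclosureOptions,
) -> NodeContribution:
    """One IRLS half-step on this node's data at coefficients ``beta``.

    Gaussian/identity: ``μ = Xβ``, ``W = I``, working response ``z = y``.
    Binomial/logit: ``μ = logit⁻¹(Xβ)``, ``W = diag(μ(1−μ))``,
    ``z = Xβ + (y−μ)/W``. Returns ``XᵀWX``, ``XᵀWz``, the complete-case
    ``n``, parameter count ``p`` and the deviance at ``beta``.

    Refused when ``n < min_obs`` or ``p/n > glm_ratio``; a non-intercept
    column with zero variance after the complete-case drop is a
    validation error (the fit would be singular by construction).
    """
    if family not in FAMILIES:
        raise ValidationError(f"unknown family {family!r}; choose from {FAMILIES}")
    X, y, names = build_design(df, formula)
    n, p = X.shape
    _guard_n(n, opts)
    if p == 0:
        raise ValidationError("model has no parameters")
    if p / n > opts.glm_ratio:
        raise DisclosureError(
            f"p/n = {p}/{n} exceeds glm_ratio={opts.glm_ratio}", rule="glm_ratio"
        )
    for j, name in enumerate(names):
        if name != "(Intercept)" and np.ptp(X[:, j]) == 0:
            raise ValidationError(f"column {name!r} has zero variance after row drop")
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (p,):
        raise ValidationError(f"beta must have length {p}, got {beta.shape}")
    eta = X @ beta
    if family == "gaussian-identity":
        mu = eta
        w = np.ones(n)
        z = y
    else:
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValidationError("binomial response must be 0/1")
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
    xtwx = X.T @ (X * w[:, None])
    xtwz = X.T @ (w * z)
    return NodeContribution(
        n=n,
        p=p,
        names=names,
        xtwx=xtwx.tolist(),
        xtwz=xtwz.tolist(),
        deviance=_deviance(family, y, mu),
    )


# -- the release choke point -----------------------------------------


def check_disclosure(payload, opts: DisclosureOptions) -> tuple[bool, str | None]:
    """Final gate every aggregate return passes; names the first
    violated rule, or (True, None) for a compliant payload."""
    if isinstance(payload, GuardedSummary):
        if payload.n_valid < opts.min_obs:
            return False, "min_obs"
        return True, None
    if isinstance(payload, SuppressedTable):
        for cell in payload.released_cells():
            if cell != 0 and cell < opts.min_cell:
                return False, "min_cell"
        return True, None
    if isinstance(payload, NodeContribution):
        if payload.n < opts.min_obs:
            return False, "min_obs"
        if payload.p / payload.n > opts.glm_ratio:
            return False, "glm_ratio"
        return True, None
    return False, "unknown-payload"


# -- function registry -----------------------------------------------

#: the "base-stats" package: aggregate functions a profile can expose.
#: arg spec keys name the session-engine argument conventions.
FUNCTIONS = {
    "mean_ds": {"kind": "aggregate", "input": "vector", "fn": mean_ds},
    "var_ds": {"kind": "aggregate", "input": "vector", "fn": var_ds},
    "moments_ds": {"kind": "aggregate", "input": "vector", "fn": moments_ds},
    "quantiles_ds": {"kind": "aggregate", "input": "vector", "fn": quantiles_ds},
    "table_ds": {"kind": "aggregate", "input": "factors", "fn": table_ds},
    "glm_ds": {"kind": "aggregate", "input": "glm", "fn": glm_contribution},
}

#: package catalog consumed by the profile registry
PACKAGE_CATALOG = {"base-stats": set(FUNCTIONS)}
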