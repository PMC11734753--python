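"""Synthetic harmonized multi-cohort data with known ground truth.

Emulates the kind of data a federated birth-cohort network holds: each
cohort is a table with the same variable schema (harmonized) but its own
covariate distributions and sample size. Outcomes are generated from a
shared linear predictor so that federated estimates can be checked both
against a pooled fit (exact agreement) and against the generating
coefficients (statistical agreement).

Randomness uses numpy's ``default_rng`` (the PCG64 generator), which is
fully determined by the integer seed and stable across platforms.
Missingness is completely at random, applied per column at a fixed rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: ``dist`` ∈ {normal, bernoulli, categorical}."""

    name: str
    dist: str
    params: tuple = ()
    levels: tuple = ()  # categorical only
    probs: tuple = ()   # categorical only

    def validate(self):
        if self.dist == "normal":
            if len(self.params) != 2 or self.params[1] <= 0:
                raise ValidationError(f"normal covariate {self.name!r} needs (mu, sigma>0)")
        elif self.dist == "bernoulli":
            if len(self.params) != 1 or not (0 <= self.params[0] <= 1):
                raise ValidationError(f"bernoulli covariate {self.name!r} needs p in [0,1]")
        elif self.dist == "categorical":
            if len(self.levels) < 2 or len(self.levels) != len(self.probs):
                raise ValidationError(f"categorical covariate {self.name!r} needs levels+probs")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ValidationError(f"probs for {self.name!r} must sum to 1")
        else:
            raise ValidationError(f"unknown distribution {self.dist!r}")


@dataclass(frozen=True)
class OutcomeSpec:
    """Outcome from a linear predictor over covariates.

    ``beta`` maps term -> coefficient; the key ``"(Intercept)"`` is the
    intercept, other keys name covariates (numeric/bernoulli) or
    ``"col[level]"`` treatment-coded categorical indicators. ``family``
    is ``gaussian`` (adds Normal(0, noise_sd) errors) or ``binomial``
    (Bernoulli with logit link).
    """

    name: str
    family: str
    beta: dict
    noise_sd: float = 1.0

    def validate(self):
        if self.family not in ("gaussian", "binomial"):
            raise ValidationError(f"unknown outcome family {self.family!r}")
        if self.family == "gaussian" and self.noise_sd <= 0:
            raise ValidationError("gaussian outcome needs noise_sd > 0")


@dataclass(frozen=True)
class CohortSpec:
    label: str
    n: int
    seed: int
    covariates: tuple[CovariateSpec, ...]
    outcomes: tuple[OutcomeSpec, ...]
    missing_rate: dict = field(default_factory=dict)  # column -> rate

    def validate(self):
        if self.n < 1:
            raise ValidationError("cohort size must be >= 1")
        for rate in self.missing_rate.values():
            if not (0 <= rate < 1):
                raise ValidationError("missingness rates must be in [0, 1)")
        for cov in self.covariates:
            cov.validate()
        for out in self.outcomes:
            out.validate()


@dataclass
class GroundTruth:
    beta: dict          # outcome name -> {term: coefficient}
    cohort_stats: dict  # label -> {covariate: {"mean":…, "var":…}}


def _linear_predictor(df: pd.DataFrame, beta: dict) -> np.ndarray:
    eta = np.zeros(len(df))
    for term, coef in beta.items():
        if term == "(Intercept)":
            eta += coef
        elif "[" in term:
            col, level = term[:-1].split("[", 1)
            eta += coef * (df[col].astype(str) == level).to_numpy(dtype=float)
        else:
            eta += coef * df[term].to_numpy(dtype=float)
    return eta


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """One reproducible cohort table plus its generating parameters."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    data: dict[str, pd.Series] = {}
    stats: dict[str, dict] = {}
    for cov in spec.covariates:
        if cov.dist == "normal":
            mu, sd = cov.params
            data[cov.name] = pd.Series(rng.normal(mu, sd, spec.n), dtype="Float64")
            stats[cov.name] = {"mean": mu, "var": sd ** 2}
        elif cov.dist == "bernoulli":
            p = cov.params[0]
            data[cov.name] = pd.Series(
                rng.random(spec.n) < p, dtype="boolean"
            ).astype("Int64")
            stats[cov.name] = {"mean": p, "var": p * (1 - p)}
        else:
            draws = rng.choice(len(cov.levels), size=spec.n, p=cov.probs)
            data[cov.name] = pd.Series(
                pd.Categorical.from_codes(draws, categories=list(cov.levels))
            )
            stats[cov.name] = {"probs": dict(zip(cov.levels, cov.probs))}
    df = pd.DataFrame(data)
    for out in spec.outcomes:
        eta = _linear_predictor(df, out.beta)
        if out.family == "gaussian":
            df[out.name] = pd.Series(eta + rng.normal(0, out.noise_sd, spec.n),
                                     dtype="Float64")
        else:
            prob = 1.0 / (1.0 + np.exp(-eta))
            df[out.name] = pd.Series((rng.random(spec.n) < prob).astype("int64"),
                                     dtype="Int64")
    # missing completely at random, after outcome generation so the
    # complete-data mechanism stays interpretable
    for col, rate in spec.missing_rate.items():
        if col not in df.columns:
            raise ValidationError(f"missingness names unknown column {col!r}")
        if rate > 0:
            mask = rng.random(spec.n) < rate
            df.loc[mask, col] = pd.NA
    truth = GroundTruth(
        beta={out.name: dict(out.beta) for out in spec.outcomes},
        cohort_stats={spec.label: stats},
    )
    return df, truth


def generate_network(specs: list[CohortSpec]) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """K harmonized cohorts: identical schemas, shared outcome model."""
    if not specs:
        raise ValidationError("a network needs at least one cohort")
    schemas = set()
    betas = set()
    for spec in specs:
        spec.validate()
        schemas.add(tuple(c.name for c in spec.covariates)
                    + tuple(o.name for o in spec.outcomes))
        betas.add(tuple(sorted(
            (o.name, tuple(sorted(o.beta.items()))) for o in spec.outcomes
        )))
    if len(schemas) != 1:
        raise ValidationError("cohort specs do not share a harmonized schema")
    if len(betas) != 1:
        raise ValidationError("cohorts must share the same outcome model")
    tables: dict[str, pd.DataFrame] = {}
    truth = GroundTruth(beta={}, cohort_stats={})
    for spec in specs:
        df, t = generate_cohort(spec)
        tables[spec.label] = df
        truth.beta = t.beta
        truth.cohort_stats.update(t.cohort_stats)
    return tables, truth


# -- the shipped demo network ----------------------------------------

#: generating coefficients of the demo birth-cohort model
DEMO_BETA_GAUSSIAN = {"(Intercept)": 3.2, "mat_bmi_c": 0.015, "mat_smoke": -0.15}
DEMO_BETA_BINOMIAL = {"(Intercept)": -1.0, "mat_bmi_c": 0.5}
DEMO_SIZES = (400, 650, 900)


def demo_network(seed: int = 2024) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Three birth cohorts (n = 400, 650, 900) with a maternal-BMI
    exposure model: a gaussian birth-weight outcome (kg) and a binomial
    overweight outcome, plus 5% missingness on the exposure.

    Cohorts differ in mean BMI and smoking prevalence, mimicking
    between-cohort heterogeneity in a harmonized network.
    """
    cohort_params = [
        ("cohort-a", DEMO_SIZES[0], 26.5, 0.25),
        ("cohort-b", DEMO_SIZES[1], 24.8, 0.15),
        ("cohort-c", DEMO_SIZES[2], 27.9, 0.30),
    ]
    specs = []
    for k, (label, n, bmi_mu, smoke_p) in enumerate(cohort_params):
        specs.append(
            CohortSpec(
                label=label,
                n=n,
                seed=seed + k,
                covariates=(
                    CovariateSpec("mat_bmi_c", "normal", (bmi_mu - 26.0, 4.0)),
                    CovariateSpec("mat_smoke", "bernoulli", (smoke_p,)),
                    CovariateSpec("mat_edu", "categorical",
                                  levels=("high", "low", "mid"),
                                  probs=(0.4, 0.25, 0.35)),
                ),
                outcomes=(
                    OutcomeSpec("birth_weight", "gaussian",
                                DEMO_BETA_GAUSSIAN, noise_sd=0.45),
                    OutcomeSpec("overweight", "binomial", DEMO_BETA_BINOMIAL),
                ),
                missing_rate={"mat_bmi_c": 0.05},
            )
        )
    return generate_network(specs)


def recovery_network(seed: int = 7) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Three equal cohorts (n = 500 each) with a single-covariate
    logistic outcome, true β = (−1, 0.5): the parameter-recovery
    fixture."""
    specs = [
        CohortSpec(
            label=f"site-{k+1}",
            n=500,
            seed=seed * 1000 + k,
            covariates=(CovariateSpec("x", "normal", (0.0, 1.0)),),
            outcomes=(OutcomeSpec("y", "binomial",
                                  {"(Intercept)": -1.0, "x": 0.5}),),
        )
        for k in range(3)
    ]
    return generate_network(specs)
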