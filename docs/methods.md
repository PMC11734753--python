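# Methods

## The protocol

All analysis happens through exactly two command classes executed inside
a per-researcher server-side *session* (a symbol table bound to one
analysis profile):

* **assign** — binds a stored table or a derived object to a symbol.
  The HTTP response carries `{status, symbol, n_rows, columns}` and
  nothing else; data values never appear in assign responses or error
  bodies.
* **aggregate** — runs a registered statistical function on bound
  symbols and returns its payload only after it has passed the
  disclosure choke point (`check_disclosure`), which every release goes
  through and which names the first violated rule.

Derived data is written in a closed expression grammar (JSON trees:
column references, numeric/boolean literals, the binary operators
`+ − * / == != < <= > >= & |`, unary `!`, `ifelse`, row filters and
column binds) rather than free-form code. A full language interpreter
behind a function whitelist would give the same protocol semantics; the
closed grammar was chosen because it is finitely auditable and keeps the
server self-contained. Division by zero yields a missing value so
vector arithmetic is total; comparisons with missing operands select no
rows in filters.

## Disclosure control

Thresholds live in per-profile `DisclosureOptions` and are snapshotted
into each session at creation, so editing a profile mid-session cannot
race a running analysis.

| parameter | default | meaning |
|---|---|---|
| `min_obs` | 3 | minimum valid observations behind any released moment |
| `min_cell` | 3 | minimum non-zero count in a released table cell |
| `min_subset` | 3 | minimum surviving rows of a row filter (0 allowed) |
| `glm_ratio` | 0.2 | maximum parameters/observations for model fitting |

The defaults follow common statistical-disclosure-control minimum-cell
practice; they are configuration, not a claim about any production
deployment, and every profile can override them.

Rules and their rationale:

* **Zero cells are released.** A structural zero says no one has that
  combination; it identifies nobody.
* **Cell suppression with secondary suppression.** Counts in
  1..`min_cell`−1 become `SUPPRESSED`. A row/column margin is withheld
  when exactly one cell in its line is suppressed (margin − released
  cells would reconstruct it). The grand total applies the same rule one
  level up: it is withheld when exactly one row margin (or one column
  margin) is suppressed. This is the minimal rule that blocks direct
  reconstruction; it does not attempt full linear-programming secondary
  suppression across multiple suppressed cells.
* **Subset guard.** A filter leaving 1..`min_subset`−1 rows is refused
  at assignment time (before any aggregate can touch it); an empty
  result is allowed because it reveals nothing about individuals.
* **Quantiles** are only released on the fixed 5/10/25/50/75/90/95 grid
  and only when every inter-quantile bucket (including both tails)
  contains ≥ `min_obs` observations, so no released order statistic is
  pinned down by fewer than `min_obs` records.
* **Variance** uses the n−1 denominator throughout (client pooling uses
  the same convention, so recombination is exact).
* **GLM contributions** are refused when the complete-case n <
  `min_obs` or p/n > `glm_ratio`; a non-intercept column with zero
  variance after the complete-case drop is a validation error since the
  fit would be singular by construction.
* **Monotonicity.** All guards compare a data-derived count against a
  threshold, so raising any threshold can only turn releases into
  refusals — property-tested, never assumed.

## Federated estimation

Per-node moments (n, Σx, Σx²) recombine into pooled means and variances
with zero approximation error (two floating-point sums differ from the
concatenated computation only at machine precision; tests require
≤ 1e-12).

The federated GLM is a client-driven IRLS loop. Starting at β = 0, each
round broadcasts β; each node returns XᵀWX, XᵀWz, n, p and the deviance
at β for its complete-case rows; the client sums and solves. Because
these quantities are sums over rows, the federation follows exactly the
same iterate path as pooled IRLS. Convergence is declared when
|dev − dev_prev| / (0.1 + |dev|) < `tol` (default 1e-8, the standard GLM
criterion; `max_iter` default 25). `iterations` counts coefficient
updates; the converged round's contributions (already evaluated at the
final β) supply the information matrix for standard errors, with
dispersion φ = deviance/(N − p) for gaussian and φ = 1 for binomial —
matching the conventions of standard GLM software, which the tests use
as an independent oracle on concatenated data. A gaussian intercept-only
fit therefore converges in 2 updates to the pooled mean.

Categorical predictors are expanded client-side into treatment-coded
indicator terms `{name, column, level}`. Levels are discovered from a
suppressed one-way table on the first node and the lexicographically
first level is the reference; the identical term list is broadcast to
all nodes so every design matrix has the same columns in the same order
(misaligned designs would silently sum incompatible matrices). A level
present on some other node but absent from the first node's table would
be dropped from the design; harmonized data should share level sets.

## Storage, identity, profiles

* Tables rest as one parquet file each under
  `<root>/<project>/<folder>/<name>.parquet`; CSV ingest infers column
  kinds (integer → float → boolean → string, with ≤ 20 distinct strings
  stored as categorical — both thresholds configurable) and maps empty
  fields to missing. Nullable pandas dtypes are used throughout so
  missingness survives every round trip.
* Variable subsets implement data-use-agreement scoping: projection
  onto a manifest's variables, all rows, source column order. Row
  filtering at subset time is deliberately not offered — researchers
  filter inside sessions where the subset guard applies.
* The identity provider is pluggable. The shipped issuer signs compact
  HMAC-SHA256 tokens with an injectable clock (TTL default 12 h); an
  optional origin allow-list reproduces the central-analysis-server
  pattern where only a jump host may obtain tokens. The decision table
  is: admins may do everything; granted researchers may `analyse` (and
  list names/schemas of granted projects — listing reveals structure,
  never contents); everyone else nothing; unknown actions are denied
  even for admins. Every decision is appended to a JSON-lines audit log
  with strictly increasing sequence numbers.
* Profiles emulate container lifecycles in-process: sessions require a
  running profile, stopping a profile discards its sessions' unsaved
  symbols, and deletion requires zero live sessions. Callability is
  whitelist-based at both package and function granularity with the
  blacklist always winning. "Packages" are in-process registries of the
  implemented statistical functions.
* Workspaces re-serialize a session's symbol table to parquet files in
  a per-owner directory; restore is owner-only and reproduces the
  symbol table exactly (order, names, values, missingness). Workspace
  bytes are not reachable through any endpoint.
* Sessions expire after 60 min idle (configurable, injectable clock).

## Synthetic cohorts

The generator emulates a harmonized multi-cohort network: every cohort
shares one variable schema and one outcome model, while covariate
distributions and sample sizes differ per cohort. Covariates are
Normal(μ, σ), Bernoulli(p) or categorical with stated probabilities;
outcomes are y = Xβ + N(0, σ_e) (gaussian) or Bernoulli(logit⁻¹(Xβ));
missingness is completely at random per column. All randomness flows
from numpy's `default_rng` (PCG64), so an integer seed fully determines
every table on every platform.

The shipped demo network has three cohorts (n = 400, 650, 900 — small
enough for sub-second test runs, large enough that estimates are
stable) with a maternal-BMI exposure model: birth weight (kg) =
3.2 + 0.015·BMI_c − 0.15·smoking + N(0, 0.45), an overweight indicator
with logit⁻¹(−1 + 0.5·BMI_c), between-cohort differences in mean BMI
(26.5/24.8/27.9) and smoking prevalence (0.25/0.15/0.30), and 5%
missingness on the exposure. The parameter-recovery fixture uses three
cohorts of n = 500 with a single standard-normal covariate and true
logistic β = (−1, 0.5).

What passing tests on this data do **not** show: robustness to
informative missingness, measurement heterogeneity that harmonization
failed to remove, level sets differing across cohorts, or longitudinal
structure — none of which the generator produces.

## Numerical and design notes

* Binomial IRLS weights are floored at 1e-10 and fitted probabilities
  clipped to [1e-12, 1−1e-12] in the deviance, preventing overflow at
  separation; a singular summed information matrix raises an estimation
  error rather than returning garbage.
* The REST layer is a dependency-free WSGI app; upload bodies are JSON
  (`payload` = CSV text or base64 parquet). In tests and the acceptance
  script the same app is called in-process, so the full HTTP
  request/response surface is exercised without sockets.
* Errors carry machine-readable codes (`validation`, `conflict`,
  `not-found`, `auth`, `forbidden`, `forbidden-function`, `disclosure`,
  `unavailable`) so the client can branch; disclosure errors name the
  violated rule, and client-side failures carry the node label so a
  multi-cohort analyst sees *which* cohort refused.
* Argument-level checks on aggregate calls are callability, arity and
  type only; literal values inside expressions are not inspected.

## Known limitations

* Only gaussian/identity and binomial/logit families; no offsets,
  weights or survival/mixed models.
* Secondary suppression is the one-suppressed-cell rule, not an optimal
  suppression pattern; tables with several suppressed cells in a line
  release their margins.
* The local token issuer stands in for a real OpenID Connect
  federation; no TLS termination (a deployment concern).
* Subsets select variables only, not rows.
* In-process profile emulation cannot bound memory/CPU per session the
  way real container orchestration can.
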