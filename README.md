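# fedshield

A lightweight federated-analysis stack for multi-cohort health research:
a cohort **data server** that stores harmonized tables, enforces
project-level permissions and statistical disclosure control, and
executes a strict two-class (assign/aggregate) analysis protocol — plus
a researcher **client** that pools non-disclosive summaries across any
number of servers, including an iteratively aggregated federated GLM.

## Who this is for

Consortia of cohort studies, registries and biobanks often cannot move
individual-level data to a central location, yet want one analyst to be
able to fit a single model across all partners. fedshield implements the
hub-and-spoke alternative: each data owner runs a server behind their
firewall; the analyst's client sends commands and receives **only**
summary statistics that have passed disclosure checks. Individual-level
records never leave any server — by protocol, not by convention.

## The model at the core

Two exact identities make federated analysis equal pooled analysis:

* **Moments.** For a column x partitioned over K nodes, each node
  releases (nₖ, Σxₖ, Σxₖ²). Then the pooled mean is ΣΣxₖ / Σnₖ and the
  pooled sample variance is (ΣΣxₖ² − (ΣΣxₖ)²/N) / (N − 1) — identical
  to computing on the concatenated data, with no approximation.
* **GLM via IRLS.** For a generalized linear model with link g, mean
  μ = g⁻¹(Xβ), IRLS weights W and working response z, the update
  β ← (XᵀWX)⁻¹ XᵀWz touches the data only through XᵀWX and XᵀWz, which
  **sum over row partitions**. The client broadcasts β, each node
  returns its XᵀWX, XᵀWz, n and deviance, the client sums, solves and
  repeats until the relative deviance change < tol. The iteration path —
  and therefore the estimates and standard errors
  √diag((Σ XᵀWX)⁻¹ · φ) — is identical to a pooled fit. Supported
  families: gaussian/identity and binomial/logit.

Every released quantity passes disclosure control: summaries need at
least `min_obs` underlying observations, contingency-table cells are
released only when 0 or ≥ `min_cell` (others are `SUPPRESSED`, with
secondary suppression of reconstructable margins), row filters may not
leave 1..`min_subset`−1 rows, and models are refused when
p/n > `glm_ratio`.

## Worked example

Three synthetic birth cohorts (n = 400, 650, 900) each live on their own
fully wired server; the client connects, binds the harmonized table to a
symbol on every node, and analyses:

```python
from fedshield import ServerConfig, ArmadilloServer, RestApi, connect, demo_network
from fedshield.client import WSGITransport

tables, truth = demo_network(seed=2024)
specs = []
for label, df in tables.items():
    server = ArmadilloServer(ServerConfig(storage_root=f"/tmp/fed/{label}"))
    server.access.register_user("admin@site", is_admin=True)
    server.access.register_user("alice@uni")
    admin = server.access.issue_token("admin@site").raw
    server.datastore.create_project("lifecourse")
    server.datastore.upload_table("lifecourse", "core", "births", df, fmt="pandas")
    server.access.grant(admin, "alice@uni", "lifecourse")
    specs.append({"label": label,
                  "transport": WSGITransport(RestApi(server)),
                  "token": server.access.issue_token("alice@uni").raw})

pool = connect(specs)
pool.assign_load("D", "lifecourse", "core", "births")

mean = pool.pooled_mean("D", "birth_weight")
fit = pool.federated_glm(
    "D", {"response": "birth_weight", "terms": ["mat_bmi_c", "mat_smoke"],
          "intercept": True},
    "gaussian-identity")
```

Output:

```
pooled mean birth weight: 3.1659 kg (per node: {'cohort-a': 3.1626, 'cohort-b': 3.1292, 'cohort-c': 3.1939})
(Intercept)  +3.1919  (SE 0.0124)
mat_bmi_c    +0.0144  (SE 0.0025)
mat_smoke    -0.1456  (SE 0.0252)
n = 1851, iterations = 2, converged = True
```

The pooled mean is recombined exactly from per-node (n, Σx, Σx²); no
node ever returned a row of data. The regression says: average birth
weight 3.19 kg at the reference (cohort-mean maternal BMI, non-smoker);
+14 g per BMI unit; −146 g for maternal smoking — matching a pooled fit
on the concatenated data to ~1e-15, and consistent with the generating
coefficients (3.2, +0.015, −0.15). `mean(birth_weight)` over 1851 rows
(not 1950: 5% of the exposure is missing and the model drops incomplete
rows; the pooled mean uses all 1950).

For remote servers, replace `WSGITransport` with
`fedshield.client.HTTPTransport(url)` and run each server with
`fedshield server --config server.yml`. A batch workflow is
`fedshield client run --nodes nodes.yml --script analysis.json`, and
`fedshield simdata --out dir/` writes the demo cohorts as CSV with their
ground truth.

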