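# isoprov

Strontium and lead isotope provenance analysis for bioarchaeology:
estimating a site's **local isotopic range** from faunal/sediment
baselines, classifying human tooth enamel as local or non-local, and
inferring **individual migration histories** from tooth-mineralization
cohorts.

## Who this is for

Archaeologists and isotope geochemists working with enamel
⁸⁷Sr/⁸⁶Sr and Pb/²⁰⁴Pb measurements who need a reproducible,
statistically explicit alternative to eyeballing "local" on a scatter
plot — in particular when some baseline fauna may themselves be
imports, so that the local range must come from the *dense central
cluster* of the baseline rather than its full spread.

## The method

For a site baseline measured on (²⁰⁶Pb/²⁰⁴Pb, ⁸⁷Sr/⁸⁶Sr):

1. z-score both axes (sample SD);
2. run DBSCAN with *minpts* = 1 — clusters are then exactly the
   connected components of the ε-neighborhood graph, equivalent to a
   single-linkage dendrogram cut at height ε;
3. sweep ε over 1000 regular grid values spanning the non-trivial
   window [min pairwise distance, largest MST edge);
4. rank candidate cluster counts k by the Poisson probability mass
   e^(−λ̂) λ̂ᵏ / k! with λ̂ the mean cluster count over the sweep, and
   take the modal partition of the best-supported k;
5. cross-validate with K-means (SSE scree, chord-rule elbow);
6. report the local range as the per-axis min/max box over the largest
   cluster, in raw units.

Human teeth are classified against the box (inclusive bounds; a
continuous box distance expresses "adjacent"). Teeth group into
cohorts C1 (~0–3 y), C2 (~3–7 y), C3 (~8–16 y); an individual whose
earliest cohort is non-local and whose series converges on the local
range is a first-generation immigrant, with an inferred arrival-age
window. Samples split at ⁸⁷Sr/⁸⁶Sr = 0.716 into two geochemical
catchments, each with its own two-end-member mixing line — ordinary
least squares in (1/[Sr], ⁸⁷Sr/⁸⁶Sr) space, where two-source mixtures
are exactly affine. Cohort comparisons use one-tailed pooled-variance
t-tests and a Shapiro–Wilk normality screen.

A fully seeded synthetic-data generator produces baselines, sediment
leachates and human cohort series with planted ground truth at the
published study conditions (cluster spreads, analytical noise), for
parameter-recovery testing without any data download. See
`docs/methods.md` for the model details and limitations.

## Worked example

```python
import isoprov as ip

study = ip.simulate_study(ip.SimulationConfig(seed=42))
rep = ip.estimate_local_range(study["fauna"], site="Harappa", seed=42)
print(f"epsilon window      : {rep.epsilon_low:.3f} .. {rep.epsilon_high:.3f}")
print(f"lambda-hat          : {rep.selection.lambda_hat:.2f}")
top = rep.selection.ranked_k[:2]
print(f"top solutions       : k={top[0]} ({rep.selection.likelihood_by_k[top[0]]:.3f}), "
      f"k={top[1]} ({rep.selection.likelihood_by_k[top[1]]:.3f})")
print(f"local cluster       : {len(rep.local.member_ids)} fauna")
sr = rep.local.bounds["sr87_86"]; pb = rep.local.bounds["pb206_204"]
print(f"local 87Sr/86Sr     : {sr[0]:.5f} .. {sr[1]:.5f}")
print(f"local 206Pb/204Pb   : {pb[0]:.3f} .. {pb[1]:.3f}")

summaries, fractions = ip.migration_summary_table(study["humans"], rep.local)
print(f"individuals         : {fractions['n_individuals']}")
print(f"immigrant fraction  : {fractions['fraction_immigrant']:.2f}")
one = summaries[0]
print(f"example series      : {one.individual_id} -> {one.classification}, "
      f"arrival {one.arrival_window}")
```

prints

```
epsilon window      : 0.001 .. 2.143
lambda-hat          : 3.59
top solutions       : k=3 (0.213), k=4 (0.191)
local cluster       : 9 fauna
local 87Sr/86Sr     : 0.71684 .. 0.71881
local 206Pb/204Pb   : 18.605 .. 18.889
individuals         : 17
immigrant fraction  : 1.00
example series      : Harappa-IND00 -> immigrant, arrival (3.0, 8.25)
```

Reading it: the ε sweep over the normalized 13-point faunal baseline
most supports a 3-cluster solution; its largest cluster (9 fauna —
exactly the planted locals) defines the local box in raw units. All 17
simulated individuals have non-local first molars converging on the
local range, so each is called a first-generation immigrant whose
residence change happened between the ages of 3 and ~8.25 (the
earliest cohort consistent with the series, plus the time-averaging
resolution of enamel).

The same run is available from the shell:

```sh
isoprov simulate --seed 42 --out sim/
isoprov baseline --samples sim/samples.csv --site Harappa --seed 42 --out base/
isoprov run --config run.yaml     # full multi-site pipeline
```

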