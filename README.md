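# eoniche

Toolkit for asking three linked questions about hothouse-interval (Early
Eocene) floras and their climates:

1. **Was a fossil assemblage unusually diverse?** Abundance-based
   rarefaction standardizes morphospecies richness (the Hill number of
   order q = 0) to a common sample size *m₀* and tests pairwise differences
   Δ = S_A(m₀) − S_B(m₀) with a multinomial bootstrap (percentile CI95,
   two-sided bootstrap *p*, Bonferroni adjustment over the test family).
2. **What climate did it live in?** Multi-GCM monthly temperature,
   precipitation, and evaporation fields are bilinearly regridded to a
   common lon/lat grid, reduced to 22 bioclimatic variables (Var1..Var22),
   ensemble-averaged, extracted at site coordinates, and classified into
   Köppen–Geiger classes and Nix thermal regimes (mega-/meso-/microthermal).
3. **Where was the climate suitable for a taxon?** A presence-background
   (maxnet-style) niche model with linear/quadratic/product/hinge features
   and an L1-penalized exponential-model likelihood is tuned by
   cross-validated AUC and omission rate at the P10 threshold, bootstrapped
   into ensembles, and projected onto target climates on the cloglog scale.

A synthetic-data module generates abundance tables, monthly climate grids,
and occurrence sets with known ground truth, so the whole pipeline is
testable without any external download. See `docs/methods.md` for the
formulas, rule sets, defaults, and limitations.

## Worked example: pairwise richness comparison

```python
import numpy as np
import eoniche as eo

def table(name, S, N, seed):
    rng = np.random.default_rng(seed)
    p = np.exp(1.3 * rng.standard_normal(S)); p /= p.sum()
    return eo.AbundanceTable(name, rng.multinomial(N, p))

tables = [table("LMF-like", 95, 2007, 1), table("poor", 55, 3100, 2),
          table("rich", 130, 4200, 3), table("tiny", 40, 600, 4)]
comps = eo.compare_all(tables, B_reps=200, seed=42)
print(eo.comparisons_to_frame(comps).to_string(index=False))
```

```
             pair   m0  delta  ci_low  ci_high      p p_bonf
LMF-like vs. poor 2007   40.5    34.7     41.1 <0.005 <0.015
LMF-like vs. rich 2007  -22.8   -26.7    -18.9 <0.005 <0.015
    poor vs. rich 2007  -63.3   -63.1    -57.7 <0.005 <0.015
```

The "tiny" assemblage (N = 600) falls below the exclusion threshold
max(1000, 0.5·N₂ₙₐ-smallest) and is dropped; the common sample size becomes
m₀ = 2007 (the smallest retained N), and all C(3,2) = 3 tests run at that
m₀ with K = 3 for the Bonferroni adjustment. Δ > 0 means the first
assemblage is richer at m₀; "<0.005" marks p-values censored below 1/B for
B = 200 bootstrap replicates.

## Worked example: niche recovery with known truth

```python
from eoniche.pipeline import niche_recovery_experiment
r = niche_recovery_experiment(seed=1)
print(f"AUC_test={r['auc_test']:.3f}  OR_P10(train)={r['or_p10_train']:.3f}")
print(r["importance"].head(2).to_string(index=False))
```

```
AUC_test=0.924  OR_P10(train)=0.100
variable  importance  rank
    Var1   99.912975     1
  noise3    0.087025     2
```

Occurrences were generated from a logistic response to mean annual
temperature (Var1); the fitted model recovers the driver as the rank-1
predictor by permutation importance, discriminates presences from the
15,000 background points (holdout AUC 0.92), and omits ~10% of training
presences at its own P10 threshold, as the threshold's definition implies.

## Command line

```sh
eoniche simulate --out runs/demo --seed 1
eoniche diversity --input runs/demo/abundance.csv --reps 200 --seed 42 --out table.csv
eoniche climate derive --in runs/demo/fields.nc --out bioclim.nc
eoniche climate classify --in runs/demo/fields.nc --scheme koppen --out kg.nc
eoniche run --out runs/full --seed 1      # all stages + manifest.json
```

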