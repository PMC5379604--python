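# stabmark

Stability-based variable selection and partial-AUC benchmarking for
two-group high-dimensional biological data (metabolomics, proteomics and
similar autoscaled intensity matrices).

## The problem

Given an *n* × *P* matrix of samples by measured variables — assumed
log-transformed, centred and scaled to unit variance — and a binary group
label (control/treatment), which variables distinguish the groups? With
*P* ≫ *n*, single fits overfit and p-value thresholds are fragile.
**Stability selection** is a secondary-selection wrapper: repeatedly
perturb the data by removing an out-of-bag fraction of samples from each
group and keeping a random fraction of the variables, re-rank the variables
with a base selector in each perturbed dataset, and keep variable *j* when
its *stability fraction*

```
π_j = #{perturbations with j in the top ntop} / #{perturbations including j}
```

reaches `min_present` (default: top 10 in at least half of 200
perturbations). Four base selectors are provided:

- **t** — absolute two-sample *t* statistic (pooled variance; Welch by flag);
- **VIP** — Variable Importance in Projection from a 2-component PLS-DA
  model, `VIP_j = sqrt(P · Σ_a SS_a w_ja² / Σ_a SS_a)` with unit-norm
  weights `w_a` and `SS_a` the class-variation explained by component *a*;
- **LASSO / elastic net** — squared-loss regularization paths (mixing
  α = 1 and 0.5), ranking variables by path entry order, with λ chosen
  where the active set first reaches the expected number of biomarkers.

Two FDR-adjusted comparators select at Benjamini–Hochberg adjusted p < 0.05
(analytic p-values for the *t* test; group-label permutation p-values for
VIP). Performance is measured by walking each method's full variable
ranking against the known truth and integrating the resulting variable-level
ROC curve up to false-positive fraction 0.2 (partial AUC; reported
normalized as pAUC/0.2). A model-based simulator generates standard-MVN
two-group data with independent, block (0.7 within biomarkers / 0.1 within
noise / 0 between) or AR(1) (ρ = 0.5) correlation and a mean shift Δ on a
fraction Q of variables, so the whole benchmark runs with no external data.

## Worked example

```python
from stabmark import datasets, StabilitySelection
from stabmark.evaluation import roc_from_ranking, pauc, operating_point

data = datasets.spiked_fixture(seed=1)        # 36 samples, 60 metabolites, 8 spiked
res = StabilitySelection(data, base="vip").fit()
print(res.summary(max_rows=7))
```

```
 rank variable  stability_fraction  selected
    1      Gly            1.000000      True
    2      Ala            1.000000      True
    3      Thr            1.000000      True
    4      Val            1.000000      True
    5      M40            1.000000      True
    6      Lys            0.948980      True
    7      Ser            0.834862      True
```

```python
curve = roc_from_ranking(res.ranking, data.truth)
print(pauc(curve).normalized)                  # 0.726
print(operating_point(res.selected, data.truth))  # (0.750, 0.154)
```

Seven of the eight spiked metabolites are perfectly or near-perfectly
stable (the eighth, Pyr, carries almost no signal by construction and is
never found); a handful of noise metabolites such as `M40` are spuriously
stable — an intrinsic feature of subsampling one fixed dataset. The
selected set recovers 6/8 true biomarkers (sensitivity 0.750) at the cost
of flagging 15.4% of the noise metabolites, and the full ranking attains a
normalized pAUC of 0.726 at false-positive fraction 0.2. The FDR-adjusted
*t* test on the same data is more conservative: 4 true biomarkers, 1 noise
(sensitivity 0.500, 1-specificity 0.019).

The same pipeline is scriptable from a shell:

```sh
stabmark simulate --n 50 --p 50 --q 0.1 --delta 0.4 --correlation block --seed 1 --out data.csv
stabmark stability --method vip --in data.csv --k 5 --nperturb 200 --seed 1 --out selection.json
stabmark evaluate --selection selection.json --truth data.truth.json --out metrics.json
stabmark grid --preset smoke --seed 2 --out results/
```

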