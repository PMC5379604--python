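# Methods

## Data model and what the simulator emulates

The package targets two-group studies whose intensity matrices have already
been log-transformed, centred and scaled to unit variance, as is standard in
metabolomics pre-treatment. The simulator therefore draws the control group
from a mean-zero multivariate normal with unit variances and a chosen
correlation structure, and the treatment group from the same distribution
with a mean shift Δ applied to k = round(P·Q) "significant" variables
(round half-to-even; generation fails if k = 0 because there would be no
signal to recover). Three correlation structures are supported:

- **independent** — identity correlation;
- **block** — significant variables inter-correlated at 0.7, non-significant
  at 0.1, zero correlation between the two blocks;
- **AR(1)** — ρ^|i−j| with ρ = 0.5 across all variables.

Internally the significant variables occupy the leading k indices (the
block structure needs contiguity); by default a seed-derived column
permutation is then applied so selectors cannot exploit placement. Sampling
uses an eigendecomposition factor of the correlation matrix with
eigenvalues clipped to zero below 1e−10; matrices with eigenvalues below
−1e−10 are rejected with the offending eigenvalue named. Everything is a
pure function of the configuration and seed.

What the simulator does **not** emulate: raw GC–MS signal, missing values,
heteroscedastic or skewed intensities, batch effects, and non-Gaussian
tails. Passing benchmarks here therefore demonstrate correct behaviour
under the idealized post-pre-treatment model, not robustness to real-data
pathologies.

The spiked-in-style fixture (`datasets.spiked_fixture`) mirrors a
spiked-serum experiment: 18 replicates per group, 60 metabolites, 8 true
biomarkers with heterogeneous shifts between 0.05 and 1.6 standard
deviations. The near-zero shift emulates a spiked metabolite that no method
ever detects. It is a synthetic stand-in generated at run time, not the
real dataset. The published selection lists for that experiment are
embedded (`datasets.spiked_reference_example`) with synthetic `M<label>`
IDs for the 52 unnamed non-biomarkers.

## Base selectors

**t test.** Pooled-variance two-sample t by default (the classical variant
in the R lineage this design follows); Welch by flag. Scores are |t|.
Zero within-group variance yields score 0 / p = 1 when the group means
agree, and a finite surrogate score above every regular |t| with p = 0 when
they differ (logged).

**PLS-DA VIP.** NIPALS PLS1 with class membership coded 0/1 and autoscaled,
X centred (assumed pre-scaled), deflation on X only; two components by
default, reduced with a warning when rank does not support them. VIP uses
the standard weight-based definition, so Σ_j VIP_j² = P exactly. The
implementation is validated in the tests against VIP recomputed from
scikit-learn's PLS fit.

**LASSO / elastic net.** Squared loss on the 0/1 class codes (both
variables centred; no intercept), mixing parameter α = 1 (lasso) or 0.5
(elastic net), over 100 log-spaced λ values from λ_max (first empty active
set) down to 1e−3·λ_max via scikit-learn's coordinate-descent paths. The
operating λ is the largest one whose active set holds at least `k_target`
variables — `k_target` = round(P·Q) at the experiment level — or the λ
maximizing the active-set size when the target is never reached. Variables
are *ranked by path entry order* (the λ at which their coefficient first
becomes nonzero), ties by |coefficient| at the operating λ, then by column
index; variables that never enter score 0 and rank last. Entry-order
ranking gives every method a full P-length ranking so variable-level ROC
curves are always defined. Note that active sets are only near-monotone
along a coordinate-descent path — a coefficient can momentarily cross
zero — which does not affect the λ rule.

## Stability engine

Each perturbation removes round(oob_fraction·n_g) samples from each group
(default 0.3) and keeps round(variable_fraction·P) variables (default 0.5),
both uniformly at random and reproducibly from (seed, perturbation index).
Defaults: 200 perturbations, ntop = 10, min_present = 0.5. The stability
fraction divides by the number of perturbations *including* the variable,
since variable subsampling would otherwise bias raw counts downward.
Inside a perturbation the path-selector target is capped at min(k_target,
2·ntop, #included variables): the path only needs enough active variables
to define a top-ntop. Selection uses ≥ min_present (boundary ties
included). The final ranking orders variables by (stability fraction, mean
base score over inclusions) descending, then index; the selected set is a
prefix of it. A base-selector failure on a perturbation is retried once on
a fresh subset, then skipped and counted.

`oob_fraction` and `variable_fraction` are explicit configuration because
the reference R implementation's defaults are not published; users matching
a specific BioMark version should set them accordingly.

## FDR comparators

Benjamini–Hochberg step-up adjustment with strict selection at adjusted
p < 0.05. The t-test route uses analytic two-sided p-values. The VIP route
is necessarily interpretive — VIP scores have no canonical null — and uses
group-label permutation with the add-one estimator
p_j = (1 + #{VIP*_j ≥ VIP_j})/(1 + n_perm), n_perm = 1000 by default
(minimum attainable p = 1/(1+n_perm); reduced to 200 in the desk-scale
benchmark runs). Users comparing against other FDR-VIP implementations
should be aware the null mechanism may differ. FDR rankings order by
adjusted p, ties by raw p, then score, then index.

## Evaluation

The ROC is over **variables**: walking a ranking, each true biomarker
raises tpr by 1/n_true and each noise variable raises fpr by 1/n_false.
The partial AUC integrates the right-continuous step curve over
fpr ∈ [0, 0.2]. Two normalizations are exposed: proportional (raw/0.2,
chance level 0.1 — the benchmark default) and McClish (chance mapped to
0.5). The benchmark reports the proportional convention because the
original standardization behind the published figures is not stated.

Operating points follow the plain definitions: sensitivity = selected true
biomarkers / all true biomarkers, 1−specificity = selected noise / all
noise. In the published spiked-in table the sensitivity column reproduces
exactly from the printed selection lists, while the printed 1−specificity
values (e.g. 0.169 where 10 false selections out of 52 non-biomarkers give
0.192) match no obvious denominator; this package follows the definitions
and does not imitate those values.

Median summaries across replicates carry basic (reverse-percentile)
bootstrap 95% CIs, matching R `boot`'s "basic" algorithm (endpoint
agreement verified against `boot.ci` in development). A caveat documented
here deliberately: for a sample median the basic interval undercovers —
about 87–88% instead of 95% on normal samples of size 200 — because the
bootstrap distribution of a median is lattice-valued. The percentile
interval does slightly better (~92%); we keep the basic interval for
comparability with the original toolchain.

## Benchmark orchestration and scale

`experiment.run_cell` simulates independent replicates of one configuration
and runs all six methods; per-replicate and per-method seeds derive from
`SeedSequence([base_seed, cell_index, replicate, stream])`, so results are
identical under any execution order and partial re-runs reproduce exactly.
Failed replicates are recorded with their reason and dropped from medians
(count reported). The `full-benchmark` preset is the complete factorial —
N ∈ {50, 100}, P ∈ {50, 200, 1000}, Q ∈ {0.1, 0.2, 0.3},
Δ ∈ {0.2, 0.4, 0.8}, three correlation structures, 200 replicates — a
long-running batch job by design. The test and acceptance surface uses
reduced problem sizes chosen as the package's desk-scale defaults: 50–80
replicates per cell at P = 50, and 20 replicates with 100 perturbations and
a 200-permutation VIP null at P = 1000.

## Known limitations and honest divergences

- **Fully informative rankings compress between-method gaps in the
  high-dimensional regime.** Because every method here carries a full
  P-length ranking (stability ties resolved by mean base score; FDR ties by
  raw p then score), all six methods achieve similar median pAUC
  (~0.8) at P = 1000, Δ = 0.8 with independent correlation. Evaluations
  that rank only the selected list and leave the remaining variables in
  arbitrary order penalize methods whose selected sets are small (stability
  selection caps at roughly ntop variables) far more heavily, and produce
  much larger advantages for BH-selected sets in that regime. Users
  comparing against such evaluations should expect smaller between-method
  gaps from this package's rankings.
- **Stability selection on pure noise is not empty.** Perturbations
  resample one fixed dataset, so the few noise variables with extreme
  full-sample statistics stay in the top ntop consistently and a small
  spurious selected set (roughly 5–10 variables at P = 200) is expected
  behaviour, even though the mean stability fraction equals ntop/kept. The
  engine provides no formal error control; pair it with the FDR route when
  false selections are costly.
- The elastic net here uses squared loss on class codes, not logistic loss,
  matching the reference lineage; no multi-class designs, no sparse PLS,
  and no complementary-pairs stability selection variants.
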