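# Methods

## Model and procedure

Let **Y** (N×R) hold R noisy replications of an unobserved subject-level
quantity and **X** (N×P) the observed traits. The null hypothesis for trait
i is that x_i is independent of the process generating every column of
**Y**. Under that null, subject labels are exchangeable, so permuting the
rows of **X** (equivalent to permuting the rows of **Y**, and cheaper when
P < R — the implemented convention) generates valid surrogate data.

The test statistic is a summary of the R first-level p-values. The first
level is a two-sided Pearson-correlation t-test: t = r·√((N−2)/(1−r²))
referred to t(N−2). The statistic-to-p mapping is parametric at both
levels; there is no nested permutation at the first level. Two summaries
are provided:

* geometric mean, exp(mean(log p)) — Fisher-flavoured, sensitive to a few
  very small p-values, i.e. to the alternative "*at least some* replications
  carry the association";
* arithmetic mean — Edgington-flavoured, sensitive only to a bulk shift.

Neither summary is uniform under the null, so the second level estimates
its null distribution by K synchronised row permutations and reports

p_NPC = (#{k: s_k ≤ s_obs} + 1)/(K + 1).

Ties count as extreme, and the identity permutation is never drawn as a
surrogate: the observed data enter only through the +1, which is exactly
the printed estimator. p_NPC therefore lives on the grid
{1/(K+1), …, 1} and can never be smaller than 1/(K+1) — with K = 10,000,
1/10,001.

Because all traits share one permutation scheme, the per-permutation
minimum summary across traits is the correct min-p reference for
family-wise error control: p_FWE,j counts permutations whose minimum
summary is ≤ the observed summary of trait j. FDR correction is
Benjamini–Hochberg (step-up, PRDS form, via statsmodels) on the p_NPC
vector — the form matching the standard reference, not the
Benjamini–Yekutieli variant.

## Ridge-regression baseline

The comparison method regresses each trait on all R replications at once:
b = (YᵀY + λI)⁻¹Yᵀx with Y and x column-centered (the intercept is not
penalised) and λ = lambda_rel × mean(diag(YᵀY)). "Minimal penalty" is
operationalised as lambda_rel = 1e-3, a config knob; a positive penalty is
mandatory when R ≥ N, where the unpenalised system is singular. The fit is
summarised by the standard full-vs-intercept F with df (R, max(N−R−1, 1)) —
the df of the unpenalised model. These df are not exactly right for a
ridge fit, which is immaterial: the parametric p is only a ranking
statistic inside the permutation loop (any monotone transform of F yields
the same p_regr), so validity comes from the permutations.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| K (`--nperm`) | 1,000 (CLI), 10,000 (toy study) | permutation count; resolution of p_NPC is 1/(K+1) |
| combiner | gmean | second-level summary; mean is the low-power alternative |
| p_floor | 1e-300 | floor on first-level p before logs, so exp(mean(log p)) is finite when a correlation is perfect to machine precision; any value ≪ attainable p-values gives identical inference |
| lambda_rel | 1e-3 | relative ridge penalty (dimensionless; scales with the Gram diagonal) |
| blocks | none | exchangeability blocks; within-block shuffling only (no whole-block swapping) — sufficient for family-structure designs, full multi-level exchangeability is out of scope |
| batch_size | 2,000 | permutations per matrix product; memory/speed trade-off only |

Permutations are sampled uniformly with replacement from the
(block-restricted) permutation group, rejecting the identity; no exhaustive
enumeration mode is offered since K ≪ N! in every intended use.

## Synthetic-data generators

**Toy** (`gen_toy`): a ~ N(0,1) of length N = 100 is drawn once per family;
each of 1,000 replicate columns is b = κa + ε with a fresh κ ~ U(0, c) and
fresh ε ~ N(0,1). c ∈ {0, 0.1, 0.2} spans null to moderate coupling. The
columns are replications of the single a–b relation, so one synchronised
scheme tests them jointly.

**FC simulation** (`gen_fc_dataset`): per subject, β_n ~ U(−0.2, 0.2)
(all zero in the null variant), a latent two-channel series of 10,000
samples with s2 = β_n·s1 + ε (ε of SD 1, making the latent correlation
exactly β/√(β²+1)), and trait x_n = β_n/√(β_n²+1) + 0.5·η_n. Each of R
replications samples T = 100 time points uniformly *without* replacement —
independently per replication, as replications are independent noisy
measurements — adds N(0, σ²) noise to both channels, and stores the
Fisher-z of the sample correlation. σ controls difficulty.

**Perturbation** (`perturb_replications`): a random ⌈fraction·R⌉ subset of
columns is shuffled across subjects, destroying those columns' association
with any trait while conserving each column's multiset of values.

What the generators do *not* emulate: temporal autocorrelation (latent
series are white), non-Gaussian traits, missing data, session structure.
Passing tests show the inferential machinery is calibrated and powerful
under exchangeable Gaussian-ish noise; they do not certify behaviour under
autocorrelated or heavy-tailed real data, where the exchangeability
assumption must be justified per design.

## Study sizes

Bundled experiment runs use desk-scale defaults chosen to keep a full
suite run in well under a half hour on one core: toy checks at K = 1,000
(the full K = 10,000 toy study runs in the acceptance script), a null
calibration grid of N = 100, R = 20, three σ values × 50 repetitions at
K = 500, and a power grid of N = 200, R = 50, σ ∈ {0.25, 0.75, 1.5} × 20
repetitions at K = 500. The full-scale grids (30 σ values × 100
repetitions, R = 100, K = 10,000) remain available via
`npcombine reproduce --paper-scale`. A master seed spawns per-cell seeds so
every method sees the same dataset and scheme within a repetition (paired
comparisons).

Because the second-level p is itself a random variable across realizations
of an experiment — exactly uniform under the null — the acceptance script
reports each toy quantity as a mean over 40 independent realizations
rather than one draw.

## Numerical choices

* First-level p via `scipy.special.stdtr` on the t-transform; correlations
  computed as inner products of column-standardised matrices, one BLAS
  product per permutation batch.
* Geometric mean accumulated in log space; no underflow for any input the
  floor admits.
* Degenerate inputs fail loudly: constant columns are named in the error;
  |r| ≥ 1 is rejected by `fisher_z` (the FC generator clips sample
  correlations away from ±1 before the transform).
* Exact text round-trips require `float_precision="round_trip"` when
  reading CSVs; outputs are written with 17 significant digits.
* With all blocks singletons the permutation group is {identity} and the
  scheme constructor refuses to run rather than looping.

## Known limitations

* First-level tests are linear (Pearson); monotone-nonlinear associations
  lose power. The statistic-to-p hook (`p_floor`, combiner choice) does not
  extend to substituting e.g. Spearman — that would be a small extension.
* Min-p FWE becomes very conservative as P grows (the minimum over many
  traits is small under the null); FDR is the practical choice for large P.
* No multivariate combining across traits, no tail (GPD) approximation for
  p-values below 1/(K+1), no whole-block exchangeability.
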