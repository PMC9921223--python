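# Methods

## Data model

A cohort is a set of square, nonnegative streamline-count matrices
`C[i, j]` (streamlines seeded in region *i* entering region *j*) keyed by
(subject, scan), sharing one ordered parcellation per hemisphere.
Hemispheres are always analyzed separately. Diagonals are zeroed on load:
self-streamlines are tractography artifacts. All-zero rows are legal —
corpus-callosum parcels are target-only when tractography is run per
hemisphere with the callosal parcels as extra targets.

Two vectorizations are provided. The default, `symmetric`, takes the
strict upper triangle of `(C + Cᵀ)/2` (length D(D−1)/2, i.e. 17,020 for
D = 185): streamline direction from probabilistic tractography is not
biologically meaningful, so symmetrizing halves the feature count without
losing interpretable signal. `full` keeps every off-diagonal entry
(D(D−1) = 34,040) for sensitivity analyses. Counts are used raw; a
`log1p` flag exists for robustness experiments but is off by default.

## Decomposition

The stacked matrix `M` (features × columns, one column per subject/scan,
scan-major order) is factored by a thin SVD, truncated at numerical rank
(σₖ > max(shape)·eps·σ₁). No mean-centering is applied by default — the
decomposition operates on the raw stacked connectomes, so the first motif
typically captures the shared mean connectome; a `center` flag provides
the PCA-style variant. Motif weights (prevalences) are the raw
right-singular-vector entries; a single-column decomposition therefore has
prevalence exactly 1.

Singular-vector signs are indeterminate, so each motif is flipped to make
its largest-absolute feature entry positive, with the matching weight row
flipped jointly (UΣVᵀ is unchanged). This makes repeated runs
bit-identical and signed edge lists reproducible. The convention cannot
pin the orientation relative to an external reference when a motif's two
largest entries are nearly tied with opposite signs; tests that care about
orientation therefore compare the correlation sign jointly with the
recovered-to-planted cosine sign.

## Statistics

All tests are two-sided and rank-based (no normality assumption):

* **Spearman's rho** on mean ranks. Two-sided p by the t-approximation
  `t = ρ√((n−2)/(1−ρ²))` for n > 10, and by exact permutation enumeration
  of all n! orderings (conditional on observed ties) for n ≤ 10. Constant
  input raises a degenerate-input error instead of returning NaN.
* **Mann–Whitney U** (reported for the first sample): exact null
  distribution when n₁n₂ ≤ 400 and the pooled sample has no ties,
  otherwise the tie-corrected normal approximation with continuity
  correction. When the pooled data is entirely constant the test returns
  U = n₁n₂/2, p = 1 (the normal approximation is 0/0 there).
* **Bonferroni**: min(1, m·p). Family sizes are always taken from the
  actual decomposition rank or connection count, never hard-coded.

Q1/Q2 decompose scan a only and correlate motif weights with day-1
performance / the day-4 − day-1 gain; Q3 decomposes scans a and b jointly
and correlates each subject's per-motif weight change with the gain;
Q4 runs one Mann–Whitney test per connection between two scans' value
distributions, with the connection count as the family. Q4 treats the two
scans as independent samples even though they are paired within subject —
that is the convention followed here; a paired Wilcoxon variant sits
behind a `paired=True` flag. Subjects missing a required scan are dropped
from that question with a warning (families adapt); missing behavioral
days raise rather than impute. In Q3, motif weight changes whose spread is
below 1e−10 (e.g. when scan b is a byte-copy of scan a) are reported as
"no testable change" rather than passed to the correlation, which would
otherwise rank pure floating-point residue.

Optional side analyses correlate motif weights with reading-span and
digit-span covariates under the same Bonferroni family.

## Reporting

For a motif, node strength of a region is the sum of absolute motif
weights over its incident connections; the top-k regions (default 9) and
the strongest signed connections are reported, by default the smallest
edge set covering 50% of the motif's squared norm — an explicit, tunable
criterion standing in for the unexplained edge-count choices common in
chord plots. Result tables are written with fixed float formatting so a
fixed manifest and seed reproduce byte-identical outputs.

## Synthetic cohorts

The generator emulates the structure the analysis assumes:

* **Base connectome**: one draw per cohort of i.i.d. log-normal entries
  (μ = 6.0, σ = 1.2 on the log scale; median ≈ 400 streamlines), shared by
  all subjects — heavy-tailed like real streamline counts. Callosal source
  rows are zeroed.
* **Planted motifs** (default 2): sparse supports of ~2% of cortical
  region pairs, disjoint across motifs, unit-norm, hence exactly
  orthonormal, sign-fixed by the same largest-entry convention as the
  decomposition.
* **Subject weights**: Gaussian with per-motif scales 600, 300, …
  (geometric decay 0.5). Distinct scales give the planted motifs distinct
  explained variance; equal scales would leave them identifiable only up
  to rotation within a degenerate singular subspace. Baseline weights are
  additionally made exactly sample-orthogonal to each other and to the
  constant direction, because chance weight correlations in a 28-subject
  cohort otherwise rotate the recovered motifs within the planted span.
* **Noise and quantization**: i.i.d. Gaussian entry noise (σ = 4),
  clipping at zero, rounding to integer counts. The calibration quantity
  is the spectral signal-to-noise ratio — the planted component's singular
  value over the noise bulk edge, σ_w√n / (σ_n(√F + √n)) ≈ 5.9 at the
  defaults — comfortably above the detectability threshold, at which the
  dominant planted motif is recovered with |cosine| ≥ 0.95 in ≥ 95% of
  seeds.
* **Behavior**: day-1 double-embedding performance maps a standard-normal
  latent through a logistic squashing into [0.58, 0.91] (single
  embeddings: [0.67, 1.00], near ceiling); the latent correlates with the
  coupled motif's scan-a weight at a target Spearman of 0.7 (converted to
  the latent Pearson scale by ρ_P = 2 sin(πρ_S/6)). The day-4 − day-1
  gain (mean 0.08, sd 0.06) is coupled the same way to the plastic
  motif's scan-b − scan-a weight change. Performances become counts out
  of 33 trials per sentence type per day; days 2–3 interpolate. Reading
  span loosely tracks single-embedding ability; digit span is free.
* **Null cohorts** keep the connectome structure but couple nothing:
  behavior latents are fresh noise and no plasticity shift is planted.

What the generator does *not* emulate: spatial autocorrelation of
tractography errors, count-dependent (heteroscedastic) scan noise —
real scan-rescan variability is proportionally larger than σ = 4 — ,
subject-specific base connectomes, or motif overlap with the callosal
rows. Passing recovery tests therefore shows the pipeline is correct and
well-calibrated under its own assumptions, not that real cohorts of this
size carry recoverable signal.

## Problem sizes and numerical choices

Stochastic checks run 100 seeds at full study scale (28 subjects, 185
regions) for recovery and type-I control, and 200 seeds for the power
check at a planted Spearman of 0.6 (asserted loosely at ≥ 40% detection);
large-n coupling checks use 2,000 subjects with a reduced region count
(the coupling acts on weights directly, so the region count is
irrelevant there). Rank tolerance, the 1e−10 no-change threshold in Q3,
the exact-vs-approximate thresholds (n ≤ 10 for Spearman, n₁n₂ ≤ 400 for
Mann–Whitney) and the sign convention are all pinned so results are
bit-for-bit reproducible given the same inputs.

## Known limitations

* The generator's planted weights are sample-orthogonalized, so recovery
  rates on it are slightly optimistic relative to i.i.d. weights.
* Q4's independent-sample convention on paired scans is conservative in
  power; use `paired=True` for the within-subject variant.
* The exact Spearman permutation path is O(n!) and is intended for
  n ≤ 10 only, as specified.
* Degenerate singular subspaces (exactly tied singular values) make
  individual motifs non-identifiable; only the spanned subspace is
  meaningful there, and the noise-free tests compare subspaces via
  principal angles accordingly.
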