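# connectomotif

SVD network-motif analysis of structural brain connectomes and their
relation to behavior.

## The problem

Diffusion-MRI tractography yields, per subject, hemisphere and scan
session, a region × region matrix of streamline counts — a structural
connectome (here 185 regions: 180 HCP-MMP1 cortical parcels plus five
corpus-callosum parcels per hemisphere). A natural question is whether
individual differences in these connectomes predict individual differences
in behavior — for example, performance on a multi-day training task with
syntactically complex (center-embedded) sentences — and whether training
itself changes the white matter.

Testing each of the ~17,000 connections separately wastes power on massive
multiple-comparison correction. Instead, each connectivity matrix is
vectorized and stacked as a column of a data matrix **M**, which is
decomposed by singular value decomposition:

```
M = U Σ Vᵀ
```

* columns of **U** are *network motifs*: orthonormal signed patterns over
  region pairs,
* **Σ** gives each motif's share of the variance across all matrices
  (explained variance σ²ₖ / Σσ²),
* rows of **Vᵀ** give each motif's *prevalence* (weight) in every
  subject and scan.

The number of motifs equals the rank of **M** — the number of stacked
columns for generic data (28 for one scan of 28 subjects, 56 for two).
Motif weights are then related to behavior with nonparametric statistics:

* **Q1** — does baseline connectivity (scan a) correlate with day-1
  performance? Spearman per motif, Bonferroni over the motif family.
* **Q2** — does baseline connectivity correlate with the training gain
  (day 4 − day 1)?
* **Q3** — does the connectivity *change* (scan b − scan a, via the
  per-subject motif-weight change) correlate with the training gain?
* **Q4** — are there group-level connectivity changes (scans b vs. a,
  c vs. a)? One Mann–Whitney U test per connection, Bonferroni over all
  connections.

Behavioral performance is the proportion of correct first answers,
`#correct / (#correct + #incorrect + #missed)`, computed per subject, day
and sentence type (single/double embedding); double-embedding performance
is the default analysis variable since single embeddings sit near ceiling.

Because real cohort data cannot ship with the package, a synthetic cohort
generator produces connectomes with the same statistical structure —
a shared heavy-tailed base connectome, sparse orthonormal planted motifs
whose subject weights drive behavior, scan noise, integer streamline
counts — plus the ground truth needed to verify that every stage of the
pipeline recovers what was planted.

## Worked example

```python
import numpy as np
from connectomotif import (SimulationParams, generate_cohort, run_q1, run_q3,
                           report_motif)

params = SimulationParams(seed=7)           # 28 subjects, 185 regions, scans a/b/c
cohort, behavior, truth = generate_cohort(params)

q1 = run_q1(cohort, behavior)
print(f"Q1: {q1.decomposition.n_motifs} motifs from scan a")
for r in q1.significant:
    print(f"  {r.name}: rho = {r.statistic:+.3f}, "
          f"p_raw = {r.p_raw:.2e}, p_corr = {r.p_corrected:.4f}")

cos = q1.decomposition.motifs.T @ truth.motifs[:, 0]
k = int(np.argmax(np.abs(cos)))
print(f"planted motif recovered as motif_{k+1}, |cosine| = {abs(cos[k]):.3f}")
rep = report_motif(q1.decomposition, k)
print("its top regions:",
      ", ".join(f"{r} ({s:.3f})" for r, s in rep.top_regions[:5]))

q3 = run_q3(cohort, behavior)
print(f"Q3: {q3.decomposition.n_motifs} motifs from scans a+b")
for r in q3.significant:
    print(f"  {r.name}: rho = {r.statistic:+.3f}, "
          f"p_raw = {r.p_raw:.2e}, p_corr = {r.p_corrected:.4f}")
```

prints

```
Q1: 28 motifs from scan a
  motif_1: rho = +0.612, p_raw = 5.33e-04, p_corr = 0.0149
  motif_2: rho = +0.617, p_raw = 4.66e-04, p_corr = 0.0131
planted motif recovered as motif_2, |cosine| = 0.993
its top regions: R067 (1.006), R114 (0.536), R100 (0.517), R028 (0.510), R160 (0.503)
Q3: 56 motifs from scans a+b
  motif_3: rho = +0.756, p_raw = 3.29e-06, p_corr = 0.0002
```

Reading this: the scan-a decomposition of the 28-subject cohort yields 28
motifs; the generator's behavior-coupled motif is recovered as `motif_2`
(cosine 0.993 to the planted pattern) and its weights correlate with
day-1 performance at rho = +0.62, surviving Bonferroni correction over
the 28-motif family. `motif_1` — the shared-base component — also reaches
significance here because the planted motif overlaps the base pattern, so
overall connectome magnitude carries some of the same signal. For Q3 the
joint a+b decomposition yields 56 motifs, and the per-subject weight
change of `motif_3` (the planted plasticity motif) tracks the performance
gain. Node strengths in the region ranking are sums of absolute motif
weights over each region's connections, the data behind chord plots.

The same analysis runs from the shell on any cohort written in the
package's text formats:

```
connectomotif simulate --params sim.yaml --out data/
connectomotif validate --manifest data/cohort.yaml
connectomotif run --manifest data/cohort.yaml --behavior data/behavior.tsv \
    --questions q1,q2,q3,q4 --out results/
```

which writes per-question result tables (TSV), signed edge lists and
region rankings for significant motifs, regression-pair tables, and a JSON
run summary.

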