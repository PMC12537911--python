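# clonetrack

Time-resolved analysis of CD8+ T cell clonal dynamics in tumors: track
clones across sequentially sampled tumors by their TCR sequence, classify
expansion and contraction with a beta-binomial differential-abundance
test, quantify each clone's exhaustion-state composition, derive and score
a transcriptomic *expansion signature*, and link signature scores to
clonal expansion and survival outcomes.

## The problem

Whether cancer immunotherapy works depends on CD8+ T cell clones
proliferating inside the tumor, but a tumor can usually be sampled only
once, so a clone's trajectory is invisible. When an individual carries
several tumors, the frequency of a clone — identified by its TCRβ
V/D/J + CDR3 nucleotide rearrangement, a natural genetic barcode — is
mirrored across the tumors, so excising tumors sequentially (e.g. day 14
left flank, day 21 right flank) turns each tumor into a snapshot of the
same repertoire at a different time. This package implements the
analysis layer of that design, with a synthetic-cohort generator standing
in for sequencing data.

## Methods at a glance

- **Clone merging.** Bulk repertoires merge on identical
  (Vβ, Dβ, Jβ, CDR3nt); single cells link to bulk clones by CDR3β
  nucleotide sequence (cells matching several bulk clones are excluded).
  Read counts are aliquot-corrected by
  `raw × sorted / (sorted − aliquoted)`, and a clone's frequency on day
  *d* is `f_d = Σ_fractions corrected / Σ_fractions Σ_clones corrected`.
- **Expansion calling.** A clone's counts (x₁, N₁), (x₂, N₂) at two
  timepoints are compared by a likelihood-ratio test under beta-binomial
  sampling with overdispersion ρ(f); `log ρ = a + b·log f` is fitted on
  same-timepoint replicate repertoires, which share a latent frequency.
  The statistic Λ = 2[ℓ(f̂₁, f̂₂) − ℓ(f̂)] is referred to χ²₁, with
  Benjamini–Hochberg correction across a subject's clones. Expansion
  magnitude is `E = log₂(f₂/f₁)`. Cohorts without replicate repertoires
  use the strict >1.5-fold cell-count rule instead.
- **State composition.** Sorted-fraction reads give each clone's
  (PD-1⁻, precursor, intermediate, terminal) exhaustion fractions; the
  terminally-exhausted-read filter enriches for tumor-reactive clones.
- **Signature.** Genes overexpressed (Wilcoxon rank-sum, BH-adjusted) in
  precursor exhausted cells of expanding vs contracting clones, minus
  mitochondrial/ribosomal genes. Cells are scored as
  `mean(signature) − mean(expression-matched controls)` with controls
  drawn from average-expression bins; clone scores are precursor-cell
  means or state-composition-weighted averages.
- **Outcome statistics.** Least-squares regression with Wald tests and
  bootstrap CIs, Kruskal–Wallis comparisons, Kaplan–Meier curves and the
  Mantel–Cox log-rank test on a median split of the signature score.

## Worked example

Run the mouse-mode pipeline on the default synthetic cohort (400 clones,
10⁵ reads per repertoire, bilateral tumors on days 14 and 21, 20
single cells per clone per day):

```bash
$ clonetrack run-mouse --seed 202 --out-dir run --log-level WARNING
precursor_score_E_r     0.8303
precursor_score_E_p     3.397e-150
weighted_score_E_r      0.8146
weighted_score_E_p      8.183e-124
manifest: run/manifest.json
```

The two `_r` lines are Pearson correlations between clone-level
expansion-signature scores on day 14 (precursor-cell mean, and the
state-weighted average) and the clones' measured expansion
`E = log₂(f₂₁/f₁₄)`; the `_p` lines are the corresponding two-sided Wald
tests. A score computed *before* the second timepoint predicting the
subsequent expansion with r ≈ 0.8 is the package's central result on
synthetic data. `run/` contains the per-clone table (counts, frequencies,
compositions), the dynamics calls (p, BH q, expanding/contracting/stable,
E), the derived signature (standard and stringent), per-clone scores, and
a manifest with stage-by-stage clone counts for auditing the filter
cascade.

The same library surface works from Python:

```python
from clonetrack import PipelineConfig, SimConfig, run_mouse_pipeline
res = run_mouse_pipeline(PipelineConfig(seed=202), SimConfig(seed=202))
print(res.signature.genes[:5], res.regression_weighted.r)
```

`clonetrack run-human` applies a (ortholog-translated) signature to a
synthetic pre/post-therapy single-cell cohort, compares the largest
expanding vs contracting clones, and stratifies survival by median
score; `clonetrack simulate`, `score` and `survive` expose the
individual stages.

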