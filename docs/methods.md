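# Methods

## Clone identity and merging

A bulk clone is the exact string tuple (Vβ call, Dβ call, Jβ call, CDR3
nucleotide sequence); CDR3s are uppercased on read and a missing D call is
an empty string that participates in the key. No nucleotide-level error
correction is attempted — sequencing platforms collapse most PCR error
upstream, and exact matching keeps clone identity auditable. Single cells
carry only the CDR3β nucleotide sequence, so a cell links to a bulk clone
only when exactly one bulk clone has that CDR3β; cells matching several
(same CDR3, different V) are excluded from expression analyses rather
than guessed. The precursor-cell panel additionally requires a clone to
be seen in single-cell data at both timepoints with non-conflicting TCRα
chains (missing α is not a conflict), which guards against CDR3β
collisions between distinct clones.

Merging is a pure union keyed on the clone tuple and is associative: the
long count table is canonically sorted, so any sample order produces the
identical result, which the tests assert byte-for-byte.

## Corrected counts, frequencies, composition

When a fixed number of cells is aliquoted from a sorted fraction for
single-cell sequencing before bulk library preparation, every clone's
bulk count shrinks by the same factor. The correction
`raw × sorted/(sorted − aliquoted)` restores the pre-aliquot cell scale;
it is exact in expectation and leaves within-fraction frequencies
unchanged. Clone frequency on a day pools corrected counts over all of
that day's datasets, so frequencies sum to one per subject-day by
construction. The four-state composition (PD-1⁻, precursor exhausted,
intermediate exhausted, terminally exhausted) divides a clone's corrected
count in each sorted fraction by its pooled corrected count; a clone with
no reads in any fraction that day has no composition (an error, not a
zero). The tumor-reactive filter keeps clones with terminal-fraction
reads on at least one analysis day; a config switch widens it to any
TIM-3⁺ fraction (terminal or intermediate), since the two readings of
the selection rule differ and only one can be the default.

## The beta-binomial differential-abundance test

The count x of a clone in a repertoire of N reads is modelled as
beta-binomial with mean f and overdispersion ρ, i.e.
x ~ BetaBin(N, α = f·c, β = (1−f)·c) with c = (1−ρ)/ρ, which reduces to
binomial as ρ → 0. Overdispersion is frequency-dependent:
log ρ = a + b·log f, clipped to [ρ_min, 0.5] with ρ_min = 10⁻⁸.

**Training.** Replicate repertoires drawn at the same time (bilateral
tumors excised together, or synthetic nulls) share a latent frequency per
clone, so their disagreement beyond binomial sampling measures ρ. Clones
are pooled across pairs, the pooled estimate f̂ = (x₁+x₂)/(N₁+N₂) bins
them into 10 log-spaced bins (bins with < 20 clones are skipped; < 50
clones in total is an error), a scalar ρ maximises the joint
beta-binomial likelihood per bin (bounded scalar optimisation on log ρ),
and a clone-count-weighted log–log regression through the per-bin
estimates gives (a, b).

Because binning uses the pooled *estimate* rather than the unobservable
latent frequency, the fitted curve is the dispersion *conditioned on the
observed frequency*: regression to the mean sends concordant pairs to low
bins and discordant pairs to high bins, so a generatively constant ρ is
recovered faithfully only where f·c ≳ 1 and is attenuated below. This is
self-consistent — the test plugs in exactly the same pooled estimate —
and the null-calibration test (below) shows the resulting calls are
conservative at realistic depths. The recovery test therefore checks
constant-ρ recovery in the well-populated, high-frequency regime.

**Testing.** For counts (x₁, N₁), (x₂, N₂) the statistic is
Λ = 2[ℓ(f̂₁) + ℓ(f̂₂) − ℓ(f̂_common)] with ρ = ρ(f̂_common), referred to
χ² with 1 df, two-sided. When ρ ≤ ρ_min the likelihood is evaluated as
exactly binomial, so the ρ → 0 limit agrees with a directly evaluated
binomial LRT to < 10⁻⁶ (asserted over the full 31×31 count grid at
N = 30). A clone absent at both timepoints is untestable (p undefined).
Corrected counts are rounded half-to-even to integers before testing,
as are the totals. BH correction runs within one subject-comparison;
q ≤ α with a higher later frequency is "expanding", lower "contracting",
otherwise "stable". The χ² reference was chosen over exact tail
enumeration for speed; the exact binomial oracle is retained on the test
surface.

Cohorts without replicate repertoires (human longitudinal single-cell
biopsies) use the strict >1.5-fold cell-count rule; 0 → k counts as
expanding by definitional necessity, and exact 1.5-fold is stable.

## Signature derivation and scoring

Counts are depth-normalized per cell to 10⁴ and log1p-transformed.
Differential expression between precursor cells of expanding vs
contracting clones uses the two-sided Wilcoxon rank-sum test — exact
null distribution for small untied groups, tie-corrected normal
approximation otherwise — with BH correction across genes. The signature
is the overexpressed genes at adjusted p < α (default 0.05; stringent
0.01) minus genes matching case-insensitive prefixes mt-, Rps, Rpl,
Mrps, Mrpl (which also match the uppercased human symbols); by threshold
monotonicity the stringent list is always a subset.

Scoring follows the expression-matched-control convention: genes are
ranked by dataset-mean normalized expression and cut into 25 equal-size
bins; for each signature gene, 50 control genes are sampled seeded,
without replacement, from its bin (excluding signature genes); the score
is mean(signature) − mean(control union). The subtraction cancels any
per-cell additive shift as an algebraic identity, and the seed makes
control draws reproducible. Bulk samples are scored by the same
operation with each sample as one unit. Clone-level scores are the mean
over a clone's precursor cells on the scoring day, undefined below 5
cells; the weighted clone score weights state-specific means by the
clone's (precursor, intermediate, terminal) composition renormalized
over PD-1⁺ states, with proliferating cells folded into the terminal
state (that cluster is predominantly terminally exhausted). A state with
bulk weight but no scored cells makes the weighted score undefined
rather than silently renormalized. Before scoring any *other* published
signature against the expansion signature, shared genes are removed from
the tested signature so overlap cannot inflate correlations.

Enrichment uses the classic weighted (exponent 1) running-sum statistic:
increments |stat|/Σ|stat over hits| at signature genes, −1/(N−|S|)
elsewhere; ES is the maximum deviation from zero, and the permutation p
resamples equal-size gene sets, two-sided on permutations matching the
observed sign.

## Outcome statistics

Score–expansion association uses least-squares regression with a
two-sided Wald test (normal reference by default; t available) and a
percentile bootstrap CI from case resampling (default 1000 draws,
seeded). Group comparisons use Kruskal–Wallis with optional Bonferroni
correction. Survival uses the Kaplan–Meier product-limit estimator and
the Mantel–Cox log-rank test (via lifelines), after splitting subjects
at the median score; scores exactly at the median go to the Low group
(a tie rule that had to be fixed somewhere), and an all-equal score
vector is a degenerate-split error.

## The synthetic cohort

The generator produces data with the statistical structure the analysis
assumes, plus the latent truth for recovery tests. Defaults were chosen
once to emulate the study conditions and are not tuned per test:

- **Clone sizes**: lognormal(μ=0, σ=2) normalized to frequencies
  (heavy-tailed; a power-law option with exponent α=2 exists because the
  empirical size law is not identified). 400 clones per subject,
  10⁵ reads per repertoire.
- **Bilateral noise**: Dirichlet perturbation with overdispersion
  ρ = 10⁻⁵, giving the near-identical bilateral repertoires the design
  relies on (log-frequency r ≈ 0.98 for clones with ≥ 10 reads).
- **Expansion**: per-clone E ~ Normal(0, 1.5) in log₂ units per
  sampling interval; later latent frequencies are f·2^E renormalized,
  which models within-tumor competition.
- **State composition**: Dirichlet(2, 6, 4, 4) baseline over
  (PD-1⁻, pre, int, term), tilted so expanding clones start
  precursor-rich (2^(0.3·E) on pre vs term), then moved by
  differentiation flux: pre→term at 0.08 per unit positive E, term→pre
  at 0.08 per unit negative E (the "regression" of contracting clones).
- **Expression**: 30 planted signature genes plus 8 planted decoys with
  mitochondrial/ribosomal names (ribosomal genes are genuinely
  expansion-coupled in this biology, so the exclusion filter must do
  real work), 970 background genes; Poisson counts at lognormal library
  sizes (mean 1500); planted rates shift by 2^(0.3·E) in precursor
  cells and half that effect in the other exhausted states, since
  signature expression outside the precursor state also tracks
  expansion. 20 cells per clone per day, precursor-enriched 2× by the
  sorting step. Poisson rather than negative-binomial keeps the null
  analytically transparent; extra dispersion would loosen, not bias,
  the recovery.
- **Survival**: exponential event times with hazard
  h₀·exp(β·score), h₀ = 0.05 per time unit, β = −1 per score unit
  (protective); censoring hits each subject independently with
  probability 0.2 at a uniform fraction of its event time.
- **Human cohort**: 8 subjects × 25 clones; post-therapy cell counts
  scale pre-therapy counts by 2^E; pre-therapy cells carry the planted
  expression coupling under uppercased (human) gene symbols, exercising
  the ortholog translation; 70 % of cells sit in an exhausted cluster.

What the generator does **not** emulate: UMI/read-level error, V(D)J
generation biases and CDR3 sharing between clones (keys are unique by
construction, so the ambiguous-cell path is exercised only in unit
tests), batch effects and dropout structure beyond Poisson sampling,
spatial heterogeneity within tumors, immigration of new clones between
timepoints, and clinical covariates. Passing recovery tests therefore
demonstrates the estimators are correct under the stated model, not that
real tumors satisfy the model.

## Problem sizes and determinism

The test suite and the acceptance script use cohorts of 400 clones
(5 000 for the null-calibration run, where only repertoires are needed),
≈ 16 000 single cells × 1 008 genes, 500 null and 200 effect survival
replicates — sizes at which every recovery quantity is stable run-to-run
while a full suite completes in well under a minute of compute per
component. All randomness flows from explicit seeds through
`numpy.random.default_rng`; identical configs give byte-identical
outputs, which the manifest (config hash, stage counts, output
checksums) makes checkable.

## Known limitations

- The dispersion fit conditions on observed frequency (see above); at
  very low frequencies the test inherits binomial-like behaviour, which
  under-calls genuine changes of rare clones rather than over-calling.
- "Newly detected" clones are a detection statement at finite read
  depth, not evidence of recruitment.
- The weighted clone score is undefined for clones whose bulk
  composition puts weight on a state with no scored cells; analyses drop
  such clones, which slightly favours well-sampled clones.
- Exact-match clone identity treats CDR3 sequencing errors, if any
  survive upstream processing, as distinct clones.
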