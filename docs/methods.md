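# Methods

## Trait construction

A breeding record is a sequence of yearly events (age, attempted flag,
independent-offspring count) plus a death/last-observation age. Only
individuals with at least one breeding attempt are accepted: the analysis
is defined for complete reproductive life histories, and records without an
attempt have no age at first reproduction.

- **Age at first reproduction (AFR)** is the age of the first *attempt*,
  successful or not. Attempts and offspring production are distinct
  concepts here: breeding frequency counts attempts, fecundity counts
  independent offspring, and conflating them would collapse two of the four
  traits.
- **Adult lifespan (AL)** is death age − AFR, i.e. reproductive lifespan.
  Field studies differ in how they operationalize lifespan per species;
  this package exposes only the generic definition.
- **Breeding frequency (BF)** and **fecundity (F)** divide attempt and
  offspring counts by max(AL, 1 year). The one-year floor keeps annual
  rates finite for individuals that die within their first breeding season
  — an annual breeder that breeds once and dies has BF = 1/yr, not ∞.
- **Generation time (T)** is the offspring-weighted mean age of
  reproduction, the standard per-individual demographic definition. It is
  undefined (flagged, not zero) for individuals with no lifetime offspring,
  and such individuals are excluded from the generation-time aggregate
  only. T never enters the ordinations — it is built from the other traits
  and would manufacture correlation — and serves only as the external
  covariate in the regressions.

Species-level tables aggregate individual traits by mean (default), median
or quartiles; quartiles use linear interpolation between order statistics.

## Ordinations

All trait tables are natural-log transformed and z-scored with the sample
(n−1) standard deviation. Fecundity is shifted by +1 before the log at
both levels, so zero-fecundity individuals stay in the analysis.
Standardization is ordinary (non-phylogenetic) and precedes the pPCA, which
then centers on the GLS mean internally; the alternative order (standardize
on phylogenetic moments) is not exposed. Zero-variance columns are dropped
with k reduced — never silently kept — except when individuals are
projected onto axes fitted across species, where a constant trait is
z-scored to an all-zero column so the column set stays aligned with the
loadings.

The phylogenetic PCA follows the Brownian-motion construction: C holds
shared root-to-MRCA branch lengths, a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹Z, and
R = (Z−1a)ᵀC⁻¹(Z−1a)/(n−1) is eigen-decomposed with scores (Z−1a)V. With
C = I this reduces exactly to plain PCA on centered data; the test suite
enforces agreement to 1e−10 and also cross-checks eigenvalues and loadings
against R phytools' `phyl.pca` on a random fixture. A singular C (possible
with zero-length terminal branches) receives a logged ridge of
1e−10·trace(C)/n. Branch lengths are treated as relative time; no unit
conversion or λ/OU model fitting is attempted.

Numerical conventions: covariance (not correlation) mode, since inputs are
pre-standardized; eigenvalues sorted descending with ties resolved by the
solver order; loadings columns unit-norm, oriented so each column's
largest-magnitude entry is positive (tie → lowest trait index); PC1
subsequently re-oriented so adult lifespan loads negatively — the slow end
on the left — with every flip recorded in the run manifest.

Retention uses the broken-stick null b_i = (1/k)Σ_{j=i..k}1/j, applied
sequentially from PC1 with strict inequality and stopping at the first
failure. Only PC1 is ever interpreted downstream, so the sequential rule is
conservative beyond it.

## The verdict and the cross-level comparison

A slow–fast continuum is *present* in an ordination iff (i) PC1 is
retained, (ii) AFR and AL load with a common sign, (iii) BF and F load with
a common sign, and (iv) the two blocks oppose. If any of the four traits
was dropped for zero variance the verdict is *undefined*, not false: a
species whose breeding frequency never varies cannot be assessed.

For the cross-level test, each species' individual data are standardized
*within species* (so each species contributes a mean-zero cloud) and
rotated by the interspecific eigenvectors. The per-species share of rotated
variance on pPC1 uses the sum of per-component score variances as the
denominator; orthonormality makes this equal the pre-rotation total, which
the tests enforce to 1e−8. Alignment is the strict comparison of that share
with the interspecific pPC1 proportion — no significance test is attached.
The projection always uses the average-tree pPCA axes. 95% data ellipses of
the rotated clouds are reported as parameters (center, semi-axes =
√(λ_i·χ²₂(0.95)), orientation); no plotting layer is shipped.

Generation-time regressions are ordinary least squares (not PGLS) at both
levels: species pPC1 scores and within-species PC1 proportions against log
species generation time, and individual PC1 scores against log individual
generation time per species.

The average tree for a tree set is built from the element-wise mean
patristic distance matrix by neighbor joining. The NJ step is implemented
in-package with deterministic (lowest-index) tie-breaks and a midpoint root
on the final edge, so identical inputs reproduce byte-identical output
files; on an additive matrix — e.g. a unanimous tree set — NJ recovers the
input distances exactly. The construction method is stamped into the
output metadata.

## Synthetic data: what it emulates

The generator produces the three inputs the pipeline consumes — records
CSV, Newick tree set, config — plus a ground-truth JSON for parameter
recovery.

**Across species.** A pure-birth (Yule) tree; a latent pace value g per
species evolving by Brownian motion accruing variance σ²_pace = 1 over one
tree depth; log mean traits α_t + β_t·g + ε with α = (1.0, 1.6, −0.3, −0.5)
and β = (−0.4, −0.8, 0.3, 0.5) for (AFR, AL, BF, F) and residual sd 0.05.
These defaults put species at AFR ≈ 1–10 y, AL ≈ 2–40 y, BF ≈ 0.3–1 /y,
F ≈ 0.1–1 /y — the span of mid-sized birds and mammals — with a strong
pace axis (duration traits falling, frequency traits rising along g).
Additional trees for the multi-tree loop are branch-length-jittered copies
(log-normal sd 0.1) of the true tree.

**Within species**, four regimes instantiate competing hypotheses:

- **A — shared pace axis**: each individual shifts all four traits
  coherently (pace sd 0.3, trait noise sd 0.02); the positive control.
- **B — idiosyncratic noise**: independent per-trait log-normal noise
  (sd 0.3); variation without an axis.
- **C — event-level demographic stochasticity**: whole life courses drawn
  year by year from the species rates — maturity at the species AFR plus a
  geometric jitter (p = 0.5), annual survival exp(−1/AL_s), attempts with
  probability min(1, BF_s) (the first adult year always attempts, by the
  definition of first reproduction), offspring Poisson(F_s/BF_s) per
  attempt. Death is recorded at the end of the final breeding season, so
  adult lifespan is 1 + a geometric count with mean 1/(1−exp(−1/AL_s)).
  This is the canonical chance-alone null, and it exercises the
  record-to-trait path end to end rather than injecting traits directly.
- **D — acquisition heterogeneity**: a per-individual log-normal
  acquisition multiplier (sd 0.5) raises survival and fecundity *together*,
  generating the positive performance-trait correlations that mask
  trade-offs when acquisition varies more than allocation.

Regimes A/B synthesize records matching target traits to the nearest
representable attempt/offspring counts; because counts are integers,
frequency and fecundity are quantized at 1/lifespan resolution, and the
"exact rank-1" limit of regime A holds up to that round-off (negligible
for long-lived, fecund species). Survival is converted from target
lifespan by the constant-hazard map exp(−1/AL) — a one-parameter modelling
choice, not an empirical claim. Years are independent; there is no density
dependence, no environmental covariates, no imperfect detection, and no
attempt to mimic any real species from the original data deposit. Passing
tests on these data therefore demonstrate that the *method* recovers or
rejects structure under known generating processes; they say nothing about
detection/recapture uncertainty or density feedback in real monitoring
data.

Default sizes are 17 species × 100 individuals. Property checks in the
test suite run 100 seeded replicates of the full pipeline per regime —
about 1,700 species-level analyses for the within-species null — with all
randomness routed through one seeded generator per replicate.

## Degenerate inputs and limitations

- Records with no attempt, events after death, or offspring without an
  attempt are rejected with line-numbered messages at ingest.
- A species where fewer than two traits vary is skipped (a continuum is
  undefined in one dimension); one constant trait reduces k and leaves the
  verdict undefined; either outcome is isolated per species and never
  aborts the interspecific stage.
- Species-name matching between trait tables and trees is exact and
  case-sensitive; mismatches are listed, not guessed at.
- Adult lifespans of exactly zero are representable in records (rates use
  the one-year floor) but cannot enter log-scale ordinations; such
  individuals surface as named transform errors rather than silent drops.
- The broken-stick rule is a null-model heuristic, not a test with a
  p-value; the verdict inherits that character.
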