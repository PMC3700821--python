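# Methods

## The model

For each occurrence *i* of a canonical motif, the probability of being bound
in vivo is modeled as

    logit P(BV_i = 1) = β0 + β1·INOS_p + β2·INOS_b + β3·INOS_rp
                        + β4·CGI + β5·CLT + β6·CO + β7·DHS

where INOS_p, INOS_b, INOS_rp are the Peak, Background and Relative Peak
values of the intrinsic nucleosome occupancy profile around the motif
(continuous, roughly standard-normal under the shipped synthetic occupancy
model) and CGI, CLT, CO, DHS are binary: motif center inside a CpG island;
nearest homotypic motif within 150 bp; a second (heterotypic) motif within
150 bp; motif center inside a DNase hypersensitive site. Fit quality is
PVE = (1 − deviance/null deviance) × 100 and the AUC of 11-fold
cross-validated scores. The scientific assumptions are those of the
competition framework: occupancy is a function of local sequence only, the
150-bp scale of a nucleosome sets the interaction range for collaborative
competition, and occurrences are treated as independent observations.

Note that INOS_rp = INOS_p − INOS_b identically, so the full three-term INOS
block is rank-deficient by construction. Fits including all three terms use
the minimum-norm (pseudoinverse) solution — the deviance, and therefore PVE,
is unaffected by which representative of the coefficient flat is reported.
The synthetic generator sets β3 = 0 so that coefficient recovery is an
identifiable problem.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| flank half-width | 750 | bp | profile window around a motif/peak center |
| occupancy window | 147 | bp | nucleosome footprint |
| peak region | ±150 | bp | one nucleosome length around the center |
| background region | 150–750 | bp (window centers) | flanks outside the central nucleosome |
| cluster / co-occurrence cut | 150 | bp | collaborative-competition range |
| near / far pair cuts | <150 / 150–900 | bp | co-occurrence analysis bands |
| enrichment normalization | ×(1500−300)/300 | — | peak-to-background density ratio |
| Markov order | 7 | — | conditions each base on the preceding 7-mer |
| simulated sequence length | 150 | bp | one nucleosome of sequence |
| replicates per k-mer | 1,000 | — | Monte-Carlo error ~ sd/√1000 |
| CV folds | 11 | — | stratified by outcome |
| GC content | 0.42 | fraction | mouse-genome-like background |

## Numerical and procedural choices

* **Coordinates** are 0-based half-open throughout (BED semantics). Motif
  center = start + floor(span/2).
* **Canonicalization**: the canonical k-mer is the lexicographic minimum of a
  k-mer and its reverse complement; palindromic matches are reported once per
  locus on the + strand, so occurrence totals are well defined.
* **Enrichment boundary rule**: a match belongs to the peak region iff its
  start lies in [600, 900) of the 1,500-bp flank; background is
  [0, 600) ∪ [900, 1500−span]. Counts are pooled over peaks before the single
  division (one #PK/#BG ratio, matching the formula, rather than a mean of
  per-peak ratios).
* **Profile geometry**: a 1,500-bp flank yields 1,354 windows with center
  offsets −677..+676; the anchor window (offset 0) is the Peak value; the
  background mean uses window centers with |offset| ≥ 150. Windows containing
  N or soft-masked bases carry NaN and are excluded from every average —
  never coerced to zero, which would bias background means toward the
  intercept.
* **Masked scanning**: "masked genome" analyses skip windows containing any
  lowercase or N base across the full pattern span; unmasked analyses match
  case-insensitively (N never matches). The Markov trainer counts only
  uppercase ACGT 8-mers.
* **Markov generation** seeds each sequence with an 8-mer drawn from the
  trained 8-mer frequency table, extends base by base from the preceding
  7-mer's four continuations, and overwrites the fixed motif span *after*
  generation, keeping both flanks identically distributed. Unseen 7-mer
  contexts (possible on toy inputs) back off to the empirical mononucleotide
  distribution. The motif's central span starts at floor((150 − L)/2); gap
  positions of split templates stay Markov-generated.
* **Uniform-location null**: per simulation and chromosome, the observed
  numbers of A and B motifs are redrawn uniformly *without replacement* from
  the valid positions (non-N, unmasked, or a supplied region set). Both an
  empirical p-value, (1 + #{null ≥ obs})/(n_sim + 1), and a Gaussian
  tail estimate from z = (obs − mean)/sd are reported: with 1,000 simulations
  the empirical value saturates at ~10⁻³, so extreme significance levels are
  only expressible through the parametric approximation. For calibration
  checks a tie-randomized variant of the empirical p (randomized PIT) is
  available, which is exactly uniform under the null despite the discreteness
  of simulated counts.
* **Logistic fitting** goes through iteratively reweighted least squares
  (statsmodels GLM, binomial family). The null deviance uses the closed-form
  intercept-only MLE (the base rate). Perfect separation is detected and
  refit with a capped linear predictor (|η| ≤ 35); the result is flagged
  non-converged, with deviance → 0 and PVE → 100 as the saturating limit.
* **Cross-validated AUC** pools out-of-fold scores and computes the
  tie-corrected rank statistic once. Pooled scores keep only the predictor
  contributions: the fold intercept (and any predictor constant within a
  training fold) is excluded, because fold-to-fold intercept noise would
  otherwise impose an uninformative between-fold ordering — a constant
  predictor must pool to all-tied scores (AUC = 1/2), not to a fold artifact.
  Folds are stratified by outcome; at a ~5% positive rate unstratified folds
  can lose every positive. The misclassification-style "CV error" output
  thresholds the calibrated out-of-fold probability at 0.5 and is labeled as
  an interpretation.
* **Bound labeling** uses |motif center − peak center| ≤ 150 bp, the same
  geometry as the Peak region. Peak classification against DHS sets uses
  ≥1 bp interval overlap, with pre-programmed taking precedence over
  re-programmed. Perturbation (A-FOS-style) dependence compares per-million
  normalized tag counts within ±150 bp and requires a strictly >50% drop.

## The synthetic data generator

The generator emulates the study conditions end to end: a multi-chromosome
i.i.d. genome at 42% GC with soft-masked runs (10% by default) and GC-rich
islands recorded as the CpG-island set; a dimer-weight occupancy model
(CpG-containing steps positive, A/T-only steps mildly negative, plus the
pyrimidine–purine CA/TG wrapping step) standardized to mean 0, sd 1 on
background windows; ~20,000 planted split-8-mer occurrences and ~8,000
continuous-7-mer occurrences at uniform non-overlapping positions, a
configurable fraction of the former placed 20–140 bp from one of the latter;
binding labels drawn from the logistic model above with
β = (−4.9, 1.0, 0.5, 0, 0.8, 0.7, 1.2, 1.5), tuned only in the sense that
the intercept holds the ~5% positive rate of genome-wide canonical-motif
data; peaks (±150 bp) at bound motifs; a pre-treatment DHS set covering a
random 15% of motifs and a post-treatment set adding 80% of newly opened
bound peaks (so all three peak classes are populated); and Poisson tag
tracks with elevated rates over peaks, with a perturbed track in which
co-occurrence-driven peaks lose most of their signal.

Crucially, the labels are generated *through the pipeline's own feature
computations* — the generative β and the fitted β meet only through data, so
coefficient recovery is a genuine inverse problem rather than a shared-code
tautology.

What the generator does **not** emulate: sequence composition structure
beyond i.i.d. bases plus planted elements (no repeats with internal
structure, no isochores), spatial correlation of chromatin state beyond the
planted DHS geometry, read-length/fragment-size effects, and any mismatch
between the occupancy model and the true in vitro propensity (the synthetic
model *is* the truth here). Passing tests therefore demonstrate the
machinery's correctness and calibration, not that real genomes satisfy the
model's assumptions.

## Problem sizes

The shipped test suite and the acceptance script run at desk scale by
design: 10,000 i.i.d. flanks for enrichment calibration, a default fixture
of ~20,000 occurrences (4 × 3 Mb chromosomes), 100 fitting replicates at
n = 20,000 for coefficient recovery, 500 repetitions for p-value
calibration, and 1,000 Markov replicates per k-mer. The full control set
(32,896 k-mers × 1,000 replicates) is supported but is a long-running mode;
scaled runs (hundreds of k-mers) estimate the same distribution.

## Known limitations

* The enrichment statistic E is a ratio with a fixed ×4 normalization; with
  match-start assignment a 1,500-bp flank holds 1,193 assignable background
  starts (not 1,200), and E[pk/bg] exceeds (E[pk]/E[bg]) by ~1/E[bg]. Both
  effects bias the mean E on null data upward by ~1% at typical depths. This
  is a property of the published definition, shared by any faithful
  implementation; comparisons *between* k-mers (the statistic's purpose) are
  unaffected.
* Empirical p-values are bounded below by 1/(n_sim + 1); tail claims beyond
  that rest on the Gaussian approximation.
* The logistic model treats motif occurrences as independent; clustered
  motifs inside one peak violate this, as in the original framework.
* PWM scoring, IUPAC degeneracy, peak calling, and read alignment are out of
  scope; inputs are exact k-mer matches, interval sets, and read-start
  tracks.
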