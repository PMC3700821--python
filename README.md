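# nucbind

Most copies of a transcription factor's canonical DNA motif in a mammalian
genome are never bound in vivo. `nucbind` implements a quantitative framework
for asking *which* canonical motifs will be bound, built around the
competition between transcription factors and nucleosomes for the same DNA:
motifs embedded in 147-bp windows that nucleosomes would bind well in vitro
(high intrinsic nucleosome occupancy score, INOS) tend to be the functional
ones, and a second motif within one nucleosome length (~150 bp) can tip the
competition (collaborative competition).

It is aimed at regulatory genomicists working with ChIP-seq peak sets, DNase
hypersensitive site (DHS) intervals, and genome FASTA, who want to go beyond
position weight matrices and score exact k-mers.

## What it computes

* **Motif scanning** over a soft-masked genome for continuous k-mers and
  gapped templates such as the glucocorticoid-receptor split 8-mer
  `N-NNN---NNN-N` (8 informative bases in 13 bp). A k-mer and its reverse
  complement are one species; the 65,536 continuous 8-mers collapse to
  32,896 canonical ones.
* **k-mer enrichment** in peak windows: for ±750-bp windows around peak
  centers, E = (#PK/#BG) × (1500−300)/300, where #PK counts matches starting
  within ±150 bp of the center and #BG counts the rest.
* **Occupancy scoring**: a pluggable linear k-mer model scores every 147-bp
  window; sliding over the ±750-bp flank of a motif gives a profile that is
  decomposed into Peak (central window), Background (mean over windows whose
  centers lie 150–750 bp out), and Relative Peak = Peak − Background.
* **Markov simulation** of per-k-mer occupancy: a 7th-order Markov chain
  trained on genomic 8-mer frequencies generates 150-bp sequences with the
  k-mer fixed at the center; the mean central-window score over 1,000
  replicates is the k-mer's intrinsic occupancy, compared against a fully
  random control set.
* **Co-occurrence nulls**: counts of motif-A/motif-B pairs closer than
  150 bp (and 150–900 bp) against a uniform-location null that redraws the
  observed occurrence counts uniformly over valid genomic positions, with
  empirical and Gaussian tail p-values.
* **The binding model**: per-motif logistic regression
  `BV ~ INOS_p + INOS_b + INOS_rp + CGI + CLT + CO + DHS`, scored by percent
  of variance explained, PVE = (1 − deviance/null deviance) × 100, and
  11-fold cross-validated AUC.
* **Peak classification** against pre-/post-treatment DHS sets
  (pre-programmed / re-programmed / un-programmed), normalized tag-density
  profiles, and perturbation dependence (>50% tag-density drop).
* **Synthetic data** with known ground truth — genome, occupancy model,
  planted motifs, labels drawn from the logistic model on pipeline-computed
  features, peaks, DHS sets, tag tracks — so every stage can be validated as
  an inverse problem.

## Worked example

```python
from nucbind import synthetic_data as sd, binding_model as bm

truth = sd.make_fixture(seed=1)          # ~20,000 planted GR-like motifs
table = truth.features                    # one row per motif occurrence
print(f"occurrences: {len(table)}   bound: {table.BV.sum()} "
      f"({100*table.BV.mean():.1f}%)")

ladder = [
    ("A  (INOS p/b/rp)",     ("INOS_p", "INOS_b", "INOS_rp")),
    ("A+B  (+CGI)",          ("INOS_p", "INOS_b", "INOS_rp", "CGI")),
    ("A+B+C  (+cluster)",    ("INOS_p", "INOS_b", "INOS_rp", "CGI", "CLT")),
    ("A+B+C+D  (+co-occur)", ("INOS_p", "INOS_b", "INOS_rp", "CGI", "CLT", "CO")),
]
for label, preds in ladder:
    res = bm.fit_logistic(table, preds)
    auc = bm.cv_auc(table, preds, seed=1)
    print(f"{label:24s} PVE = {res.pve:5.2f}%   AUC = {auc:.3f}")
```

prints

```
occurrences: 19991   bound: 1156 (5.8%)
A  (INOS p/b/rp)         PVE = 16.95%   AUC = 0.770
A+B  (+CGI)              PVE = 16.96%   AUC = 0.770
A+B+C  (+cluster)        PVE = 18.47%   AUC = 0.787
A+B+C+D  (+co-occur)     PVE = 21.78%   AUC = 0.816
```

About 5.8% of the planted motifs are bound — the regime of genome-wide
canonical-motif studies. The occupancy scores alone explain ~17% of the
binding deviance; each added sequence covariate (CpG-island overlap,
homotypic clustering, co-occurrence of the second motif) strictly improves
the fit, because the labels were generated with positive weights on those
covariates — the fitted ladder recovers the planted structure.

A `nucbind` console command exposes the same steps on files
(`nucbind scan`, `enrich`, `inos`, `kmer-inos`, `cooccur`, `fit`,
`classify`, `tagprofile`, `make-fixture`); each subcommand is a thin wrapper
over the functions above.

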