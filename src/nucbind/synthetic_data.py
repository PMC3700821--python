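"""Self-contained synthetic dataset with known ground truth.

Generates everything the pipeline consumes — a soft-masked multi-
chromosome genome at 42% GC, a calibrated linear nucleosome model,
planted motif occurrences (a gapped "A" motif and a continuous "B"
motif, by default the GR split 8-mer and the AP-1 7-mer), binding
labels drawn from a logistic model on pipeline-computed features, peak
and DHS interval sets, and Poisson tag tracks — so parameter-recovery
tests run as a true inverse problem: the generative coefficients and
the fitted coefficients meet only through the data.

Default scale is ~20,000 motif-A occurrences at a ~5% positive rate,
matching the regime of genome-wide canonical-motif studies while
staying desk-scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nucleosome_scoring as ns
from .binding_model import build_features, label_bound
from .kmer_enrichment import PeakSet, extract_flanks
from .sequence_core import (
    CONTINUOUS_7MER,
    SPLIT_8MER,
    Genome,
    MotifOccurrence,
    MotifPattern,
    canonical_kmer,
    revcomp,
    seq_soft_mask,
    write_fasta,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "make_genome",
    "make_nucleosome_model",
    "plant_motifs",
    "simulate_binding",
    "make_fixture",
    "write_fixture",
]

# Minimum center-to-center distance between planted motifs: just enough to
# keep spans disjoint (max span 13), so chance co-occurrence stays at the
# uniform rate instead of being suppressed by a hard-core placement process.
_MIN_SEPARATION = 30


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset."""

    n_chromosomes: int = 4
    chromosome_length: int = 3_000_000
    gc: float = 0.42                  # mouse-genome-like background GC
    masked_fraction: float = 0.10
    masked_run_length: int = 2_000
    n_cgi_per_chromosome: int = 40
    cgi_length: int = 500
    cgi_gc: float = 0.70
    motif_a: str = "GACATGTC"         # informative bases, split 8-mer template
    motif_b: str = "TGACTCA"          # continuous 7-mer
    n_motif_a: int = 20_000
    n_motif_b: int = 8_000
    cooccur_fraction: float = 0.10    # A motifs planted within 150 bp of a B
    dhs_pre_fraction: float = 0.15    # A motifs covered by a pre-treatment DHS
    dhs_post_fraction: float = 0.80   # bound peaks outside pre-DHS that open
    dhs_halfwidth: int = 300
    # logistic coefficients: const, INOS_p, INOS_b, INOS_rp, CGI, CLT, CO, DHS
    beta: tuple[float, ...] = (-4.9, 1.0, 0.5, 0.0, 0.8, 0.7, 1.2, 1.5)
    peak_halfwidth: int = 150
    tag_rate_bound: float = 0.05      # Poisson reads per bp inside peaks
    tag_rate_background: float = 0.002
    afos_reduction: float = 0.3       # tag rate multiplier at CO-dependent peaks

    def __post_init__(self) -> None:
        if not 0 <= self.gc <= 1:
            raise ValueError("gc must be in [0, 1]")
        if len(self.beta) != 8:
            raise ValueError("beta must have 8 entries (const + 7 predictors)")
        if self.tag_rate_bound <= 0 or self.tag_rate_background <= 0:
            raise ValueError("tag rates must be positive")


@dataclass
class SyntheticTruth:
    """Everything needed to check the pipeline against the generator."""

    config: SyntheticConfig
    genome: Genome
    model: ns.NucleosomeModel
    occurrences_a: list[MotifOccurrence]
    occurrences_b: list[MotifOccurrence]
    cgi_intervals: list[tuple[str, int, int]]
    dhs_pre: list[tuple[str, int, int]]
    dhs_post: list[tuple[str, int, int]]
    features: "object"                # pandas DataFrame incl. BV column
    probabilities: np.ndarray
    labels: np.ndarray
    peaks: PeakSet
    tags_control: dict[str, np.ndarray]
    tags_afos: dict[str, np.ndarray]
    n_excluded: int


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def make_genome(
    config: SyntheticConfig, seed=None
) -> tuple[Genome, list[tuple[str, int, int]]]:
    """i.i.d. genome at the configured GC with soft-masked runs and
    GC-rich islands (recorded as the synthetic CpG-island set)."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    lower = np.frombuffer(b"acgt", dtype=np.uint8)
    chroms: dict[str, str] = {}
    cgi: list[tuple[str, int, int]] = []
    L = config.chromosome_length
    for ci in range(config.n_chromosomes):
        name = f"chr{ci + 1}"
        codes = rng.choice(4, size=L, p=_base_probs(config.gc)).astype(np.uint8)
        seq = bases[codes]
        # GC-rich islands
        if config.n_cgi_per_chromosome and L > config.cgi_length:
            starts = rng.integers(0, L - config.cgi_length, config.n_cgi_per_chromosome)
            for s in np.sort(starts):
                isl = rng.choice(4, size=config.cgi_length, p=_base_probs(config.cgi_gc))
                seq[s : s + config.cgi_length] = bases[isl.astype(np.uint8)]
                cgi.append((name, int(s), int(s) + config.cgi_length))
        # soft-masked runs
        if config.masked_fraction > 0:
            run = min(config.masked_run_length, L)
            n_runs = int(round(config.masked_fraction * L / run))
            mask = np.zeros(L, dtype=bool)
            for s in rng.integers(0, max(L - run, 1), n_runs):
                mask[s : s + run] = True
            low = codes.copy()
            seq = np.where(mask, lower[low], seq)
        chroms[name] = seq.tobytes().decode("ascii")
    return Genome(chroms), cgi


def make_nucleosome_model(seed=None, gc: float = 0.42) -> ns.NucleosomeModel:
    """Dimer-weight occupancy model calibrated to mean 0, sd 1.

    Positive weights on G/C-containing dimers (CpG strongest) and on the
    pyrimidine-purine CA/TG step, mildly negative weights on A/T-only
    dimers; the raw score is standardized against 10,000 random 147-bp
    windows at the background GC so genome-wide window scores come out
    approximately standard normal.
    """
    raw = {
        "CG": 1.0,
        "CC": 0.6,   # pools with GG
        "GC": 0.8,
        "CA": 0.5,   # pools with TG: the pyrimidine-purine wrapping step
        "AG": 0.1,
        "AC": -0.1,
        "GA": 0.0,
        "AA": -0.4,  # pools with TT
        "AT": -0.5,
        "TA": -0.5,
    }
    rng = np.random.default_rng(seed)
    probe = ns.NucleosomeModel(k=2, weights=dict(raw), intercept=0.0, label="raw")
    wins = rng.choice(4, size=(10_000, ns.WINDOW), p=_base_probs(gc)).astype(np.uint8)
    invalid = np.zeros_like(wins, dtype=bool)
    scores = ns._window_scores(probe, wins, invalid)[:, 0]
    mu, sd = float(np.mean(scores)), float(np.std(scores))
    weights = {k: w / sd for k, w in raw.items()}
    return ns.NucleosomeModel(
        k=2, weights=weights, intercept=-mu / sd, label="synthetic-dimer-v1"
    )


def _greedy_separate(candidates: np.ndarray, min_gap: int) -> np.ndarray:
    """Keep a sorted subset of candidate positions pairwise >= min_gap apart."""
    kept = []
    last = -min_gap
    for p in np.sort(candidates):
        if p - last >= min_gap:
            kept.append(p)
            last = p
    return np.array(kept, dtype=np.int64)


def _plantable(seq: str, margin: int, core_halfwidth: int = 80) -> np.ndarray:
    """Centers whose surrounding core window is unmasked ACGT and whose
    full +-margin flank fits the chromosome."""
    mask = seq_soft_mask(seq)
    from .sequence_core import seq_to_codes

    bad = mask | (seq_to_codes(seq) == 255)
    cs = np.concatenate(([0], np.cumsum(bad)))
    width = 2 * core_halfwidth + 1
    n_pos = len(seq) - width + 1
    ok = (cs[width : width + n_pos] - cs[:n_pos]) == 0
    centers = np.flatnonzero(ok) + core_halfwidth
    return centers[(centers >= margin) & (centers < len(seq) - margin)]


def _write_motif(
    chrom_bytes: bytearray, pattern: MotifPattern, motif: str, center: int, strand: str
) -> tuple[int, str]:
    """Overwrite the pattern's informative positions; gaps keep genome bases.

    Returns (start, forward informative text)."""
    start = center - pattern.span // 2
    text = motif if strand == "+" else revcomp(motif)
    for base, off in zip(text, pattern.offsets):
        chrom_bytes[start + off] = ord(base)
    return start, text


def plant_motifs(
    genome: Genome,
    config: SyntheticConfig,
    seed=None,
    margin: int = 900,  # 750-bp flank plus the 150-bp co-placement shift
) -> tuple[Genome, list[MotifOccurrence], list[MotifOccurrence]]:
    """Plant motif A (split 8-mer) and motif B (continuous 7-mer) copies.

    Placement is uniform over unmasked positions with non-overlapping
    spans; ``cooccur_fraction`` of the A motifs are placed 20-140 bp from
    a B motif center.  Orientation is random; ground-truth occurrence
    lists are returned.
    """
    rng = np.random.default_rng(seed)
    pat_a, pat_b = SPLIT_8MER, CONTINUOUS_7MER
    buffers = {c: bytearray(genome[c].encode("ascii")) for c in genome}
    occ_a: list[MotifOccurrence] = []
    occ_b: list[MotifOccurrence] = []
    chrom_names = list(genome)
    lengths = np.array([genome.length(c) for c in chrom_names], dtype=float)
    share = lengths / lengths.sum()
    n_a_chrom = np.round(config.n_motif_a * share).astype(int)
    n_b_chrom = np.round(config.n_motif_b * share).astype(int)

    for chrom, n_a, n_b in zip(chrom_names, n_a_chrom, n_b_chrom):
        plantable = _plantable(genome[chrom], margin)
        need = (n_a + n_b) * 3
        if plantable.size < need:
            raise ValueError(f"chromosome {chrom} too dense to plant motifs")
        cand = rng.choice(plantable, size=need, replace=False)
        sites = _greedy_separate(cand, _MIN_SEPARATION)
        attempts = 0
        while sites.size < n_a + n_b and attempts < 20:
            cand = rng.choice(plantable, size=need, replace=False)
            sites = _greedy_separate(cand, _MIN_SEPARATION)
            attempts += 1
        if sites.size < n_a + n_b:
            raise ValueError(f"cannot place motifs without overlap on {chrom}")
        sites = rng.permutation(sites)[: n_a + n_b]
        b_centers = np.sort(sites[:n_b])
        a_centers = sites[n_b : n_b + n_a].copy()
        # move a fraction of A motifs next to a B motif (within 150 bp),
        # avoiding overlap with any already-placed motif
        n_co = int(round(config.cooccur_fraction * n_a))
        if n_co > 0 and n_b > 0:
            import bisect

            occupied = sorted(int(s) for s in sites)
            chosen_b = rng.choice(n_b, size=min(n_co, n_b), replace=False)
            for i, bi in enumerate(chosen_b):
                for _try in range(20):
                    delta = int(rng.integers(20, 141)) * (1 if rng.random() < 0.5 else -1)
                    c = int(b_centers[bi]) + delta
                    j = bisect.bisect_left(occupied, c)
                    clash = False
                    for nb in occupied[max(j - 1, 0) : j + 1]:
                        if abs(nb - c) < 14 and nb != int(b_centers[bi]):
                            clash = True
                    if abs(c - int(b_centers[bi])) < 14:
                        clash = True
                    if not clash:
                        occupied.pop(bisect.bisect_left(occupied, int(a_centers[i])))
                        a_centers[i] = c
                        bisect.insort(occupied, c)
                        break
        for c in np.sort(b_centers):
            strand = "+" if rng.random() < 0.5 else "-"
            start, text = _write_motif(buffers[chrom], pat_b, config.motif_b, int(c), strand)
            occ_b.append(
                MotifOccurrence(
                    chrom, start, start + pat_b.span, strand, text,
                    canonical_kmer(config.motif_b),
                )
            )
        for c in np.sort(a_centers):
            strand = "+" if rng.random() < 0.5 else "-"
            start, text = _write_motif(buffers[chrom], pat_a, config.motif_a, int(c), strand)
            occ_a.append(
                MotifOccurrence(
                    chrom, start, start + pat_a.span, strand, text,
                    canonical_kmer(config.motif_a),
                )
            )
    planted = Genome({c: buffers[c].decode("ascii") for c in chrom_names})
    return planted, occ_a, occ_b


def _poisson_track(
    genome: Genome,
    peaks: list[tuple[str, int, int]],
    rate_bg: float,
    rate_peak: float,
    rng,
) -> dict[str, np.ndarray]:
    """Read starts: background rate everywhere, elevated rate inside peaks."""
    by_peak: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in peaks:
        by_peak.setdefault(chrom, []).append((s, e))
    out = {}
    for chrom in genome:
        L = genome.length(chrom)
        n_bg = rng.poisson(rate_bg * L)
        reads = [rng.integers(0, L, n_bg)]
        for s, e in by_peak.get(chrom, ()):
            extra = rng.poisson(max(rate_peak - rate_bg, 0) * (e - s))
            reads.append(rng.integers(s, e, extra))
        out[chrom] = np.sort(np.concatenate(reads)).astype(np.int64)
    return out


def simulate_binding(
    genome: Genome,
    model: ns.NucleosomeModel,
    occ_a: list[MotifOccurrence],
    occ_b: list[MotifOccurrence],
    cgi_intervals: list[tuple[str, int, int]],
    config: SyntheticConfig,
    seed=None,
):
    """Draw binding labels from the logistic model on pipeline features.

    Features (occupancy decompositions and the binary covariates) are
    computed with the pipeline's own modules, so the generative
    coefficients and any later fit meet only through the data.  Bound
    motifs emit peaks; DHS-post extends DHS-pre with most newly-opened
    bound peaks; tag tracks are Poisson.
    """
    rng = np.random.default_rng(seed)
    # pre-treatment DHS: a random subset of motif-A sites is already open
    n_pre = int(round(config.dhs_pre_fraction * len(occ_a)))
    pre_idx = set(rng.choice(len(occ_a), size=n_pre, replace=False).tolist())
    hw = config.dhs_halfwidth
    dhs_pre = [
        (o.chrom, max(o.center - hw, 0), min(o.center + hw, genome.length(o.chrom)))
        for i, o in enumerate(occ_a)
        if i in pre_idx
    ]
    flanks, dropped = extract_flanks(
        genome, PeakSet.from_intervals([(o.chrom, o.start, o.end) for o in occ_a])
    )
    if dropped:
        raise RuntimeError("planted occurrences must keep a full flank margin")
    decomp = ns.decompose_flanks(model, flanks)
    table, n_excluded = build_features(
        occ_a, decomp, cgi_intervals, occ_b, dhs_pre,
        bound=np.zeros(len(occ_a), dtype=np.int64),
    )
    beta = np.asarray(config.beta)
    X = table[["INOS_p", "INOS_b", "INOS_rp", "CGI", "CLT", "CO", "DHS"]].to_numpy()
    eta = beta[0] + X @ beta[1:]
    prob = 1.0 / (1.0 + np.exp(-eta))
    labels = (rng.random(len(prob)) < prob).astype(np.int64)
    table = table.copy()
    table["BV"] = labels

    phw = config.peak_halfwidth
    bound = table.loc[labels == 1]
    peak_ivs = [
        (str(r.chrom), int(r.center) - phw, int(r.center) + phw)
        for r in bound.itertuples()
    ]
    peaks = PeakSet.from_intervals(peak_ivs, label="synthetic-bound")

    # post-treatment DHS: pre-existing open sites plus most newly-opened peaks
    dhs_post = list(dhs_pre)
    for iv in peak_ivs:
        if rng.random() < config.dhs_post_fraction:
            dhs_post.append(iv)

    tags_control = _poisson_track(
        genome, peak_ivs, config.tag_rate_background, config.tag_rate_bound, rng
    )
    co_flags = bound["CO"].to_numpy()
    afos_peaks = [
        iv for iv, co in zip(peak_ivs, co_flags) if not co
    ]  # CO peaks lose most signal under the perturbation
    reduced = [
        iv for iv, co in zip(peak_ivs, co_flags) if co
    ]
    rng_afos = rng
    tags_afos = _poisson_track(
        genome, afos_peaks, config.tag_rate_background, config.tag_rate_bound, rng_afos
    )
    if reduced:
        # reduced-rate reads at perturbed peaks
        for chrom, s, e in reduced:
            n = rng_afos.poisson(
                max(config.tag_rate_bound * config.afos_reduction
                    - config.tag_rate_background, 0) * (e - s)
            )
            if n:
                tags_afos[chrom] = np.sort(
                    np.concatenate([tags_afos[chrom], rng_afos.integers(s, e, n)])
                )
    return (
        table,
        prob,
        labels,
        peaks,
        dhs_pre,
        dhs_post,
        tags_control,
        tags_afos,
        n_excluded,
    )


def make_fixture(config: SyntheticConfig | None = None, seed=0) -> SyntheticTruth:
    """Full synthetic dataset from one seed (deterministic)."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    s_genome, s_model, s_plant, s_bind = rng.integers(0, 2**31 - 1, 4)
    genome, cgi = make_genome(config, seed=int(s_genome))
    model = make_nucleosome_model(seed=int(s_model), gc=config.gc)
    planted, occ_a, occ_b = plant_motifs(genome, config, seed=int(s_plant))
    (
        table, prob, labels, peaks, dhs_pre, dhs_post,
        tags_control, tags_afos, n_excluded,
    ) = simulate_binding(planted, model, occ_a, occ_b, cgi, config, seed=int(s_bind))
    return SyntheticTruth(
        config=config,
        genome=planted,
        model=model,
        occurrences_a=occ_a,
        occurrences_b=occ_b,
        cgi_intervals=cgi,
        dhs_pre=dhs_pre,
        dhs_post=dhs_post,
        features=table,
        probabilities=prob,
        labels=labels,
        peaks=peaks,
        tags_control=tags_control,
        tags_afos=tags_afos,
        n_excluded=n_excluded,
    )


def _write_bed(path, rows) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def write_fixture(truth: SyntheticTruth, directory) -> None:
    """Write the documented file set; round-trips through pipeline readers."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_fasta(truth.genome, d / "genome.fa")
    ns.save_model(truth.model, d / "nucleosome_model.tsv")
    from .sequence_core import occurrences_to_bed

    occurrences_to_bed(truth.occurrences_a, d / "occurrences_a.bed")
    occurrences_to_bed(truth.occurrences_b, d / "occurrences_b.bed")
    _write_bed(d / "peaks.bed", [(c, s, e) for c, s, e, _ in truth.peaks.intervals])
    _write_bed(d / "dhs_pre.bed", truth.dhs_pre)
    _write_bed(d / "dhs_post.bed", truth.dhs_post)
    _write_bed(d / "cgi.bed", truth.cgi_intervals)
    _write_bed(
        d / "tags_control.bed",
        [
            (c, int(p), int(p) + 1)
            for c in truth.tags_control
            for p in truth.tags_control[c]
        ],
    )
    _write_bed(
        d / "tags_afos.bed",
        [(c, int(p), int(p) + 1) for c in truth.tags_afos for p in truth.tags_afos[c]],
    )
    truth.features.to_csv(d / "features.tsv", sep="\t", index=False)
    meta = {
        "config": asdict(truth.config),
        "beta": list(truth.config.beta),
        "n_excluded": truth.n_excluded,
    }
    (d / "truth.json").write_text(json.dumps(meta, indent=2) + "\n")
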