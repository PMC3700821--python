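"""Seventh-order Markov sequence generator and per-k-mer occupancy scores.

The generator is trained on the 8-mer frequencies of a genome (counted
orientation-specifically on the + strand).  A sequence is seeded with an
8-mer drawn from the full 8-mer frequency distribution; each subsequent
base is drawn with probability proportional to the counts of the four
8-mers extending the preceding 7-mer.  Contexts never seen in training
fall back to the empirical mononucleotide distribution.

The intrinsic occupancy of a k-mer is estimated by planting its
informative bases at the center of many simulated 150-bp sequences,
scoring the central 147-bp window of each, and averaging (1,000
replicates at full scale).  A control distribution repeats the procedure
with the central bases also Markov-generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .nucleosome_scoring import WINDOW, NucleosomeModel, _window_scores
from .sequence_core import (
    _BASES,
    Genome,
    MotifPattern,
    canonical_kmer,
    code_to_kmer,
    kmer_to_code,
)

__all__ = [
    "ORDER",
    "SIM_LENGTH",
    "MarkovModel",
    "KmerInosResult",
    "ControlDistribution",
    "train_markov",
    "save_markov",
    "load_markov",
    "simulate_sequence",
    "simulate_batch",
    "kmer_inos",
    "control_distribution",
]

ORDER = 7
SIM_LENGTH = 150
_NCTX = 4**ORDER
_N8 = 4 ** (ORDER + 1)


@dataclass
class MarkovModel:
    """8-mer counts (orientation-specific) plus a mononucleotide fallback."""

    counts: np.ndarray  # length 4^8
    fallback: np.ndarray  # length 4, base probabilities for unseen contexts

    _start_cdf: np.ndarray | None = field(default=None, repr=False, compare=False)
    _trans_cdf: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (_N8,):
            raise ValueError(f"counts must have length 4^8 = {_N8}")
        if np.any(self.counts < 0) or self.counts.sum() <= 0:
            raise ValueError("counts must be non-negative with a positive total")
        self.fallback = np.asarray(self.fallback, dtype=np.float64)
        self.fallback = self.fallback / self.fallback.sum()

    @property
    def start_cdf(self) -> np.ndarray:
        if self._start_cdf is None:
            p = self.counts / self.counts.sum()
            self._start_cdf = np.cumsum(p)
        return self._start_cdf

    @property
    def trans_cdf(self) -> np.ndarray:
        """(4^7, 4) cumulative next-base distributions per 7-mer context."""
        if self._trans_cdf is None:
            mat = self.counts.reshape(_NCTX, 4)
            totals = mat.sum(axis=1, keepdims=True)
            probs = np.where(totals > 0, mat / np.maximum(totals, 1), self.fallback)
            self._trans_cdf = np.cumsum(probs, axis=1)
        return self._trans_cdf


def train_markov(source: Genome | str | Mapping[str, float]) -> MarkovModel:
    """Count overlapping 8-mers (+ strand, uppercase ACGT runs only).

    ``source`` may be a Genome, a raw sequence string, or a precomputed
    8-mer -> frequency mapping.
    """
    counts = np.zeros(_N8, dtype=np.float64)
    mono = np.zeros(4, dtype=np.float64)
    if isinstance(source, Mapping):
        for kmer, c in source.items():
            if len(kmer) != ORDER + 1:
                raise ValueError(f"frequency table key {kmer!r} is not an 8-mer")
            counts[kmer_to_code(kmer)] += c
            for i, b in enumerate(kmer):
                mono[_BASES.index(b)] += c
    else:
        seqs = source.chromosomes.values() if isinstance(source, Genome) else [source]
        lut = np.full(256, 255, dtype=np.uint8)
        for i, b in enumerate(_BASES):
            lut[ord(b)] = i  # uppercase only: masked bases are not trained on
        for seq in seqs:
            codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            valid = codes != 255
            mono += np.bincount(codes[valid], minlength=4)
            if len(codes) < ORDER + 1:
                continue
            n_pos = len(codes) - ORDER
            kcode = np.zeros(n_pos, dtype=np.int64)
            ok = np.ones(n_pos, dtype=bool)
            for off in range(ORDER + 1):
                c = codes[off : off + n_pos]
                ok &= c != 255
                kcode = kcode * 4 + np.where(c == 255, 0, c)
            counts += np.bincount(kcode[ok], minlength=_N8)
    if counts.sum() <= 0:
        raise ValueError("no valid 8-mers in training input")
    if mono.sum() <= 0:
        mono = np.ones(4)
    return MarkovModel(counts=counts, fallback=mono / mono.sum())


def save_markov(model: MarkovModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("#fallback=" + ",".join(repr(float(x)) for x in model.fallback) + "\n")
        nz = np.flatnonzero(model.counts)
        for code in nz:
            fh.write(f"{code_to_kmer(int(code), ORDER + 1)}\t{float(model.counts[code])!r}\n")


def load_markov(path) -> MarkovModel:
    counts = np.zeros(_N8)
    fallback = np.ones(4) / 4
    with open(path) as fh:
        for line in fh:
            if line.startswith("#fallback="):
                fallback = np.array(
                    [float(x) for x in line.strip().removeprefix("#fallback=").split(",")]
                )
                continue
            if not line.strip():
                continue
            kmer, c = line.split("\t")
            counts[kmer_to_code(kmer)] = float(c)
    return MarkovModel(counts=counts, fallback=fallback)


def _fixed_template(
    fixed_motif: tuple[str, int] | None, length: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """(positions, base codes) for the fixed bases; '.' positions stay free."""
    if fixed_motif is None:
        return None
    text, start = fixed_motif
    if start < 0 or start + len(text) > length:
        raise ValueError(f"fixed span [{start}, {start + len(text)}) outside sequence")
    pos, codes = [], []
    for i, c in enumerate(text):
        if c == ".":
            continue
        pos.append(start + i)
        codes.append(_BASES.index(c))
    return np.array(pos, dtype=np.int64), np.array(codes, dtype=np.uint8)


def simulate_batch(
    model: MarkovModel,
    n: int,
    length: int = SIM_LENGTH,
    fixed_motif: tuple[str, int] | None = None,
    seed=None,
) -> np.ndarray:
    """Generate ``n`` sequences as an (n, length) base-code matrix.

    The chain is generated first and the fixed motif bases (if any) then
    overwrite their span, keeping the flanks identically distributed on
    both sides of the motif.
    """
    if length < ORDER + 1:
        raise ValueError(f"length must be >= {ORDER + 1}")
    rng = np.random.default_rng(seed)
    out = np.empty((n, length), dtype=np.uint8)
    # initial 8-mer drawn from the 8-mer frequency distribution
    start_codes = np.searchsorted(model.start_cdf, rng.random(n), side="right")
    start_codes = np.minimum(start_codes, _N8 - 1)  # guard float round-off
    ctx = np.asarray(start_codes, dtype=np.int64)
    for j in range(ORDER, -1, -1):
        out[:, j] = ctx % 4
        ctx //= 4
    ctx = np.asarray(start_codes, dtype=np.int64) % _NCTX  # trailing 7-mer
    cdf = model.trans_cdf
    u = rng.random((n, length - ORDER - 1)) if length > ORDER + 1 else None
    for j in range(ORDER + 1, length):
        rows = cdf[ctx]
        b = np.minimum(
            (u[:, j - ORDER - 1, None] > rows).sum(axis=1).astype(np.int64), 3
        )
        out[:, j] = b
        ctx = (ctx * 4 + b) % _NCTX
    tmpl = _fixed_template(fixed_motif, length)
    if tmpl is not None:
        pos, codes = tmpl
        out[:, pos] = codes
    return out


def simulate_sequence(
    model: MarkovModel,
    length: int = SIM_LENGTH,
    fixed_motif: tuple[str, int] | None = None,
    seed=None,
) -> str:
    """One simulated sequence as a string (see ``simulate_batch``)."""
    codes = simulate_batch(model, 1, length, fixed_motif, seed)[0]
    return "".join(_BASES[c] for c in codes)


@dataclass(frozen=True)
class KmerInosResult:
    canonical_id: str
    mean_inos: float
    sd_inos: float
    n_replicates: int


@dataclass(frozen=True)
class ControlDistribution:
    mean: float
    sd: float
    values: np.ndarray


def _central_window_scores(
    nuc_model: NucleosomeModel, codes: np.ndarray
) -> np.ndarray:
    """Score the central 147-bp window of each simulated 150-bp sequence."""
    length = codes.shape[1]
    lo = (length - WINDOW) // 2
    win = codes[:, lo : lo + WINDOW]
    invalid = np.zeros_like(win, dtype=bool)
    return _window_scores(nuc_model, win.astype(np.uint8), invalid)[:, 0]


def _pattern_template(kmer: str, pattern: MotifPattern) -> tuple[str, int]:
    """Fixed-motif template with the k-mer's bases at the pattern offsets
    (gaps stay Markov-generated) centered in the simulated sequence."""
    text = ["."] * pattern.span
    for base, off in zip(kmer, pattern.offsets):
        text[off] = base
    start = (SIM_LENGTH - pattern.span) // 2
    return "".join(text), start


def kmer_inos(
    nuc_model: NucleosomeModel,
    markov: MarkovModel,
    kmer: str,
    pattern: MotifPattern,
    n: int = 1000,
    seed=None,
) -> KmerInosResult:
    """Mean occupancy score of a k-mer over ``n`` simulated embeddings."""
    canon = canonical_kmer(kmer)
    tmpl = _pattern_template(kmer, pattern)
    codes = simulate_batch(markov, n, SIM_LENGTH, fixed_motif=tmpl, seed=seed)
    scores = _central_window_scores(nuc_model, codes)
    return KmerInosResult(
        canonical_id=canon,
        mean_inos=float(np.mean(scores)),
        sd_inos=float(np.std(scores, ddof=1)) if n > 1 else 0.0,
        n_replicates=n,
    )


def control_distribution(
    nuc_model: NucleosomeModel,
    markov: MarkovModel,
    n_kmers: int = 32896,
    n_per: int = 1000,
    seed=None,
) -> ControlDistribution:
    """Distribution of replicate-set mean scores with fully random centers.

    Mirrors the per-k-mer procedure but with no motif fixed: ``n_kmers``
    sets of ``n_per`` simulated sequences each; returns the per-set means.
    Full scale (32,896 x 1,000) is a long-running mode; both counts are
    configurable.
    """
    rng = np.random.default_rng(seed)
    values = np.empty(n_kmers)
    for i in range(n_kmers):
        codes = simulate_batch(markov, n_per, SIM_LENGTH, seed=rng)
        values[i] = float(np.mean(_central_window_scores(nuc_model, codes)))
    return ControlDistribution(
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)) if n_kmers > 1 else 0.0,
        values=values,
    )
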