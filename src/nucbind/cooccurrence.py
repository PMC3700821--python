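"""Heterotypic motif-pair distances and the uniform-location null.

Two motifs co-occurring within one nucleosome length (~150 bp) can
jointly displace a nucleosome that neither displaces alone
(collaborative competition), so the statistic of interest is the count
of motif-A/motif-B pairs closer than 150 bp (near) versus pairs 150-900
bp apart (far).  Significance comes from a uniform-location null: the
observed per-chromosome occurrence counts are kept, but every location
is redrawn uniformly at random (without replacement) from the valid
positions of the chromosome — the whole valid genome, or a supplied
region set such as DNase hypersensitive sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sequence_core import Genome, MotifOccurrence, seq_soft_mask, seq_to_codes

__all__ = [
    "NEAR_CUT",
    "FAR_CUT",
    "PairDistanceSet",
    "NullCooccurrence",
    "pair_distances",
    "distance_histogram",
    "near_far_counts",
    "valid_positions",
    "regions_valid_positions",
    "uniform_null",
    "restricted_null",
    "cooccurrence_pvalue",
]

NEAR_CUT = 150
FAR_CUT = 900


@dataclass
class PairDistanceSet:
    """Center-to-center distances of all A x B pairs within ``max_range``."""

    distances: np.ndarray
    chroms: np.ndarray  # chromosome of each pair
    max_range: int

    def __post_init__(self) -> None:
        if self.distances.size and (
            self.distances.min() < 0 or self.distances.max() > self.max_range
        ):
            raise ValueError("distances outside [0, max_range]")


@dataclass
class NullCooccurrence:
    observed_near: int
    observed_far: int
    null_near: np.ndarray
    null_far: np.ndarray
    n_sim: int

    def __post_init__(self) -> None:
        if len(self.null_near) != self.n_sim or len(self.null_far) != self.n_sim:
            raise ValueError("null lists must have length n_sim")


def _centers_by_chrom(occs: list[MotifOccurrence]) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for occ in occs:
        out.setdefault(occ.chrom, []).append(occ.center)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in out.items()}


def _pair_dists_sorted(a: np.ndarray, b: np.ndarray, max_range: int) -> np.ndarray:
    """All |a_i - b_j| <= max_range for sorted position arrays."""
    if a.size == 0 or b.size == 0:
        return np.zeros(0, dtype=np.int64)
    lo = np.searchsorted(b, a - max_range, side="left")
    hi = np.searchsorted(b, a + max_range, side="right")
    counts = hi - lo
    if counts.sum() == 0:
        return np.zeros(0, dtype=np.int64)
    idx = np.concatenate([np.arange(l, h) for l, h in zip(lo, hi) if h > l])
    rep = np.repeat(a, counts)
    return np.abs(rep - b[idx])


def pair_distances(
    occA: list[MotifOccurrence],
    occB: list[MotifOccurrence],
    max_range: int = FAR_CUT,
) -> PairDistanceSet:
    """Distances of every same-chromosome A x B pair within ``max_range``;
    each unordered pair appears once."""
    by_a = _centers_by_chrom(occA)
    by_b = _centers_by_chrom(occB)
    dists, chroms = [], []
    for chrom in by_a:
        if chrom not in by_b:
            continue
        d = _pair_dists_sorted(by_a[chrom], by_b[chrom], max_range)
        dists.append(d)
        chroms.append(np.full(d.size, chrom, dtype=object))
    if dists:
        distances = np.concatenate(dists)
        chrom_arr = np.concatenate(chroms)
    else:
        distances = np.zeros(0, dtype=np.int64)
        chrom_arr = np.zeros(0, dtype=object)
    return PairDistanceSet(distances=distances, chroms=chrom_arr, max_range=max_range)


def distance_histogram(
    distances: np.ndarray,
    bin_size: int = 50,
    slide: int = 1,
    max_range: int = FAR_CUT,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window counts: for each start s, #distances in [s, s+bin)."""
    if bin_size > max_range:
        raise ValueError("bin size exceeds max range")
    d = np.sort(np.asarray(distances))
    starts = np.arange(0, max_range - bin_size + 1, slide)
    lo = np.searchsorted(d, starts, side="left")
    hi = np.searchsorted(d, starts + bin_size, side="left")
    return starts, hi - lo


def near_far_counts(
    distances: np.ndarray, near_cut: int = NEAR_CUT, far_cut: int = FAR_CUT
) -> tuple[int, int]:
    """(#pairs with d < near_cut, #pairs with near_cut <= d <= far_cut)."""
    d = np.asarray(distances)
    near = int(np.count_nonzero(d < near_cut))
    far = int(np.count_nonzero((d >= near_cut) & (d <= far_cut)))
    return near, far


def valid_positions(
    genome: Genome, span: int = 1, use_masked: bool = True
) -> dict[str, np.ndarray]:
    """Per-chromosome positions where a span-long motif could be placed
    (no N anywhere in the span; no soft-masked base when ``use_masked``)."""
    out: dict[str, np.ndarray] = {}
    for chrom, seq in genome.chromosomes.items():
        codes = seq_to_codes(seq)
        bad = codes == 255
        if use_masked:
            bad |= seq_soft_mask(seq)
        n_pos = len(seq) - span + 1
        if n_pos <= 0:
            out[chrom] = np.zeros(0, dtype=np.int64)
            continue
        cs = np.concatenate(([0], np.cumsum(bad)))
        ok = (cs[span : span + n_pos] - cs[:n_pos]) == 0
        out[chrom] = np.flatnonzero(ok).astype(np.int64)
    return out


def regions_valid_positions(
    regions: dict[str, list[tuple[int, int]]] | list[tuple[str, int, int]],
) -> dict[str, np.ndarray]:
    """Valid-position sets given directly as intervals (e.g. DHS regions)."""
    if isinstance(regions, list):
        by: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in regions:
            by.setdefault(chrom, []).append((start, end))
        regions = by
    out: dict[str, np.ndarray] = {}
    for chrom, ivs in regions.items():
        parts = [np.arange(s, e, dtype=np.int64) for s, e in ivs if e > s]
        pos = np.unique(np.concatenate(parts)) if parts else np.zeros(0, dtype=np.int64)
        out[chrom] = pos
    return out


def _sample_without_replacement(rng, pos: np.ndarray, k: int) -> np.ndarray:
    """k distinct entries of ``pos``, sorted.

    For sparse draws (k much smaller than the pool) rejection sampling of
    indices avoids permuting the whole position array."""
    n = len(pos)
    if k * 20 >= n:
        return np.sort(rng.choice(pos, size=k, replace=False))
    idx = np.unique(rng.integers(0, n, size=int(k * 1.2) + 8))
    while idx.size < k:
        idx = np.unique(np.concatenate([idx, rng.integers(0, n, size=k)]))
    if idx.size > k:
        idx = rng.choice(idx, size=k, replace=False)
    return np.sort(pos[idx])


def uniform_null(
    valid: dict[str, np.ndarray],
    countsA: dict[str, int],
    countsB: dict[str, int],
    n_sim: int = 1000,
    near_cut: int = NEAR_CUT,
    far_cut: int = FAR_CUT,
    seed=None,
    observed_near: int = 0,
    observed_far: int = 0,
) -> NullCooccurrence:
    """Uniform-location null for near/far pair counts.

    Per simulation and chromosome, the observed numbers of A and B motifs
    are placed uniformly at random (each set without replacement) on the
    chromosome's valid positions and the near/far pair counts summed over
    chromosomes.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(set(countsA) | set(countsB))
    for chrom in chroms:
        nA = countsA.get(chrom, 0)
        nB = countsB.get(chrom, 0)
        navail = len(valid.get(chrom, ()))
        if nA > navail or nB > navail:
            raise ValueError(
                f"requested {max(nA, nB)} positions on {chrom!r} "
                f"but only {navail} valid positions exist"
            )
    null_near = np.zeros(n_sim, dtype=np.int64)
    null_far = np.zeros(n_sim, dtype=np.int64)
    for s in range(n_sim):
        near_tot = far_tot = 0
        for chrom in chroms:
            nA = countsA.get(chrom, 0)
            nB = countsB.get(chrom, 0)
            if nA == 0 or nB == 0:
                continue
            pos = valid[chrom]
            a = _sample_without_replacement(rng, pos, nA)
            b = _sample_without_replacement(rng, pos, nB)
            d = _pair_dists_sorted(a, b, far_cut)
            near, far = near_far_counts(d, near_cut, far_cut)
            near_tot += near
            far_tot += far
        null_near[s] = near_tot
        null_far[s] = far_tot
    return NullCooccurrence(
        observed_near=observed_near,
        observed_far=observed_far,
        null_near=null_near,
        null_far=null_far,
        n_sim=n_sim,
    )


def restricted_null(
    regions: dict[str, list[tuple[int, int]]] | list[tuple[str, int, int]],
    countsA: dict[str, int],
    countsB: dict[str, int],
    n_sim: int = 1000,
    near_cut: int = NEAR_CUT,
    far_cut: int = FAR_CUT,
    seed=None,
    observed_near: int = 0,
    observed_far: int = 0,
) -> NullCooccurrence:
    """Uniform-location null restricted to a region set (e.g. DHS)."""
    valid = regions_valid_positions(regions)
    if all(v.size == 0 for v in valid.values()):
        raise ValueError("region set contains no positions")
    return uniform_null(
        valid, countsA, countsB, n_sim, near_cut, far_cut, seed,
        observed_near, observed_far,
    )


def cooccurrence_pvalue(
    obs: int, null: np.ndarray, rng=None
) -> tuple[float, float, float]:
    """(empirical_p, gaussian_p, z) for one-sided enrichment.

    empirical_p = (1 + #{null >= obs}) / (n_sim + 1).  The Gaussian value
    z = (obs - mean)/sd with its upper-tail p is the extreme-tail
    estimate: far beyond the simulation count the empirical p saturates
    at 1/(n_sim+1) while the parametric approximation keeps resolving.
    When ``rng`` is given, empirical_p is the tie-randomized version
    (#{null > obs} + U * (1 + #{null == obs})) / (n_sim + 1), exactly
    uniform under the null — the form used for calibration checks.
    """
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    n = null.size
    if rng is not None:
        greater = int(np.count_nonzero(null > obs))
        ties = int(np.count_nonzero(null == obs))
        emp = (greater + rng.random() * (1 + ties)) / (n + 1)
    else:
        emp = (1 + int(np.count_nonzero(null >= obs))) / (n + 1)
    sd = float(np.std(null, ddof=1)) if n > 1 else 0.0
    if sd == 0:
        return emp, float("nan"), float("nan")
    z = (obs - float(np.mean(null))) / sd
    gauss = float(stats.norm.sf(z))
    return emp, gauss, z
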