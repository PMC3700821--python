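"""Peak-versus-background k-mer enrichment in ChIP-seq peak windows.

For each peak a 1,500-bp window centered on the peak is extracted
(±750 bp).  Matches whose start falls within ±150 bp of the center are
"peak region" counts (#PK); matches starting in the remaining flanks are
"background" counts (#BG).  The enrichment of a k-mer is the density
ratio

    E = (#PK / #BG) * (1500 - 300) / 300 = 4 * #PK / #BG

pooled over all peaks.  Counts are canonicalized so that a k-mer and its
reverse complement pool into a single record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequence_core import (
    _CODE,
    Genome,
    MotifPattern,
    _canonical_code_table,
    _revcomp_code_table,
    code_to_kmer,
    kmer_to_code,
)

__all__ = [
    "FLANK_LENGTH",
    "PEAK_HALFWIDTH",
    "PeakSet",
    "extract_flanks",
    "region_counts",
    "enrichment",
    "enrichment_table",
    "enrichment_table_from_flanks",
]

FLANK_LENGTH = 1500
PEAK_HALFWIDTH = 150  # peak region = +-150 bp around the window center


@dataclass
class PeakSet:
    """Peak intervals with a defined center per peak.

    The center defaults to the interval midpoint; a summit column in the
    source BED (column 7, absolute coordinate) overrides it.
    """

    intervals: list[tuple[str, int, int, int]]  # (chrom, start, end, center)
    label: str = ""

    def __post_init__(self) -> None:
        for chrom, start, end, center in self.intervals:
            if not start <= center < end:
                raise ValueError(
                    f"peak center {center} outside interval {chrom}:{start}-{end}"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def centers(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for chrom, _s, _e, c in self.intervals:
            out.setdefault(chrom, []).append(c)
        return {k: np.array(sorted(v), dtype=np.int64) for k, v in out.items()}

    @classmethod
    def from_bed(cls, path, label: str = "") -> "PeakSet":
        intervals = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, start, end = f[0], int(f[1]), int(f[2])
                center = int(f[6]) if len(f) > 6 and f[6] != "." else (start + end) // 2
                intervals.append((chrom, start, end, center))
        return cls(intervals, label=label or str(path))

    @classmethod
    def from_intervals(cls, intervals, label: str = "") -> "PeakSet":
        full = []
        for iv in intervals:
            if len(iv) == 3:
                chrom, start, end = iv
                full.append((chrom, start, end, (start + end) // 2))
            else:
                full.append(tuple(iv))
        return cls(full, label=label)


def extract_flanks(
    genome: Genome, peaks: PeakSet, half_width: int = 750
) -> tuple[list[str], int]:
    """±half_width sequences around each peak center.

    Peaks whose window would run off a chromosome end are dropped; the
    number dropped is returned alongside the sequences.
    """
    flanks: list[str] = []
    dropped = 0
    for chrom, _s, _e, center in peaks.intervals:
        lo, hi = center - half_width, center + half_width
        if lo < 0 or hi > genome.length(chrom):
            dropped += 1
            continue
        flanks.append(genome.fetch(chrom, lo, hi))
    return flanks, dropped


def _flank_kmer_counts(
    flanks: list[str], pattern: MotifPattern
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (#PK, #BG) per canonical k-mer code over a list of flanks.

    Matches are assigned to regions by start coordinate: peak region
    starts in [600, 900), background starts in [0, 600) u [900, 1500-span].
    Windows containing non-ACGT bases are skipped (case-insensitive).
    """
    k, span = pattern.k, pattern.span
    rc = _revcomp_code_table(k)
    pk = np.zeros(4**k, dtype=np.int64)
    bg = np.zeros(4**k, dtype=np.int64)
    chunk = 2000
    for lo in range(0, len(flanks), chunk):
        block = flanks[lo : lo + chunk]
        arr = np.frombuffer("".join(block).encode("ascii"), dtype=np.uint8)
        codes = _CODE[arr].reshape(len(block), FLANK_LENGTH)
        n_win = FLANK_LENGTH - span + 1
        fwd = np.zeros((len(block), n_win), dtype=np.int64)
        valid = np.ones((len(block), n_win), dtype=bool)
        for off in pattern.offsets:
            c = codes[:, off : off + n_win]
            valid &= c != 255
            fwd = fwd * 4 + np.where(c == 255, 0, c)
        canon = np.minimum(fwd, rc[fwd])
        mid = FLANK_LENGTH // 2
        pk_lo, pk_hi = mid - PEAK_HALFWIDTH, mid + PEAK_HALFWIDTH
        sel = valid[:, pk_lo:pk_hi]
        pk += np.bincount(canon[:, pk_lo:pk_hi][sel], minlength=4**k)
        sel = valid[:, :pk_lo]
        bg += np.bincount(canon[:, :pk_lo][sel], minlength=4**k)
        sel = valid[:, pk_hi:]
        bg += np.bincount(canon[:, pk_hi:][sel], minlength=4**k)
    return pk, bg


def region_counts(
    flank: str, target: str, pattern: MotifPattern
) -> tuple[int, int]:
    """(#PK, #BG) of a single canonical k-mer in one 1,500-bp flank."""
    if len(flank) != FLANK_LENGTH:
        raise ValueError(f"flank length {len(flank)} != {FLANK_LENGTH}")
    pk, bg = _flank_kmer_counts([flank], pattern)
    code = kmer_to_code(target)
    return int(pk[code]), int(bg[code])


def enrichment(pk_total: int, bg_total: int) -> float:
    """E = (#PK/#BG) * (1500-300)/300; NaN when #BG = 0 (undefined)."""
    if bg_total == 0:
        return float("nan")
    return (pk_total / bg_total) * (FLANK_LENGTH - 2 * PEAK_HALFWIDTH) / (2 * PEAK_HALFWIDTH)


def enrichment_table_from_flanks(
    flanks: list[str], pattern: MotifPattern
) -> pd.DataFrame:
    """One EnrichmentRecord row per canonical k-mer, ranked by E descending.

    k-mers with #BG = 0 but #PK > 0 sort to the top (infinitely enriched);
    ties break lexicographically on the canonical id.
    """
    k = pattern.k
    pk, bg = _flank_kmer_counts(flanks, pattern)
    canon_codes = np.unique(_canonical_code_table(k))
    ids = [code_to_kmer(int(c), k) for c in canon_codes]
    pk_c = pk[canon_codes]
    bg_c = bg[canon_codes]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(
            bg_c > 0,
            pk_c / np.maximum(bg_c, 1) * (FLANK_LENGTH - 2 * PEAK_HALFWIDTH) / (2 * PEAK_HALFWIDTH),
            np.where(pk_c > 0, np.inf, np.nan),
        )
    df = pd.DataFrame(
        {"canonical_id": ids, "pk": pk_c, "bg": bg_c, "enrichment": e}
    )
    # NaN (0/0) sinks to the bottom; ties broken lexicographically
    df["_sort"] = np.where(np.isnan(e), -np.inf, e)
    df = df.sort_values(
        ["_sort", "canonical_id"], ascending=[False, True], kind="stable"
    ).drop(columns="_sort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def enrichment_table(
    genome: Genome, peaks: PeakSet, pattern: MotifPattern
) -> pd.DataFrame:
    flanks, _dropped = extract_flanks(genome, peaks)
    return enrichment_table_from_flanks(flanks, pattern)
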