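"""Peak classification against open-chromatin sets and tag-density profiles.

Transcription-factor peaks are partitioned against DNase hypersensitive
sites (DHS) measured before and after treatment: a peak overlapping a
pre-treatment DHS (by >= 1 bp) is *pre-programmed*; otherwise, if it
overlaps a post-treatment DHS it is *re-programmed* (chromatin opened by
the treatment); otherwise it is *un-programmed*.

Tag tracks are read-start positions; density profiles are mean tag
counts in 300-bp bins slid 150 bp at a time across +-1.5 kb of the peak
centers, normalized to tags per million.  A peak is called dependent on
a perturbation (e.g. A-FOS blocking c-Jun) when its library-normalized
tag count within +-150 bp drops by strictly more than 50%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding_model import _merge_intervals
from .kmer_enrichment import PeakSet
from .sequence_core import MotifOccurrence

__all__ = [
    "CLASS_LABELS",
    "TagTrack",
    "classify_peaks",
    "tag_density_profile",
    "peak_tag_counts",
    "afos_dependence",
    "motif_content_table",
]

CLASS_LABELS = ("pre-programmed", "re-programmed", "un-programmed")


@dataclass
class TagTrack:
    """Per-chromosome sorted read-start positions."""

    positions: dict[str, np.ndarray]
    total_tags: int = 0

    def __post_init__(self) -> None:
        self.positions = {
            c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in self.positions.items()
        }
        total = int(sum(p.size for p in self.positions.values()))
        if self.total_tags == 0:
            self.total_tags = total
        elif self.total_tags != total:
            raise ValueError("total_tags does not match position counts")

    @classmethod
    def from_bed(cls, path) -> "TagTrack":
        by: dict[str, list[int]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                by.setdefault(f[0], []).append(int(f[1]))
        return cls({c: np.array(v, dtype=np.int64) for c, v in by.items()})


def _overlaps_any(
    peak: tuple[str, int, int],
    merged: dict[str, tuple[np.ndarray, np.ndarray]],
) -> bool:
    chrom, start, end = peak
    if chrom not in merged:
        return False
    starts, ends = merged[chrom]
    j = np.searchsorted(starts, end, side="left") - 1
    return j >= 0 and ends[j] > start


def classify_peaks(
    tf_peaks: PeakSet,
    dhs_pre: list[tuple[str, int, int]],
    dhs_post: list[tuple[str, int, int]],
) -> list[str]:
    """Label each peak pre-/re-/un-programmed (pre takes precedence)."""
    pre = _merge_intervals(dhs_pre)
    post = _merge_intervals(dhs_post)
    labels = []
    for chrom, start, end, _c in tf_peaks.intervals:
        if _overlaps_any((chrom, start, end), pre):
            labels.append("pre-programmed")
        elif _overlaps_any((chrom, start, end), post):
            labels.append("re-programmed")
        else:
            labels.append("un-programmed")
    return labels


def tag_density_profile(
    track: TagTrack,
    centers: list[tuple[str, int]],
    span: int = 3000,
    bin_size: int = 300,
    slide: int = 150,
) -> pd.DataFrame:
    """Mean tags-per-million per sliding bin across +-span/2 of the centers.

    Bin offsets are relative to the center; a bin at offset s counts
    reads starting in [center + s, center + s + bin_size).
    """
    if track.total_tags == 0:
        raise ValueError("tag track is empty")
    if not centers:
        raise ValueError("no centers supplied")
    offsets = np.arange(-span // 2, span // 2 - bin_size + 1, slide)
    sums = np.zeros(len(offsets))
    for chrom, center in centers:
        pos = track.positions.get(chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, center + offsets, side="left")
        hi = np.searchsorted(pos, center + offsets + bin_size, side="left")
        sums += hi - lo
    density = sums / len(centers) * 1e6 / track.total_tags
    return pd.DataFrame({"offset": offsets, "density": density})


def peak_tag_counts(
    track: TagTrack,
    centers: list[tuple[str, int]],
    half_width: int = 150,
    per_million: bool = True,
) -> np.ndarray:
    """Tag count within +-half_width of each center (library-normalized)."""
    out = np.zeros(len(centers))
    for i, (chrom, center) in enumerate(centers):
        pos = track.positions.get(chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, center - half_width, side="left")
        hi = np.searchsorted(pos, center + half_width, side="left")
        out[i] = hi - lo
    if per_million:
        if track.total_tags == 0:
            raise ValueError("tag track is empty")
        out = out * 1e6 / track.total_tags
    return out


def afos_dependence(
    density_control: np.ndarray, density_afos: np.ndarray
) -> np.ndarray:
    """Dependent iff normalized density drops by strictly more than 50%.

    Returns a float array: 1.0 dependent, 0.0 not, NaN where the control
    density is zero (undefined)."""
    c = np.asarray(density_control, dtype=float)
    a = np.asarray(density_afos, dtype=float)
    if c.shape != a.shape:
        raise ValueError("paired density arrays must have equal shape")
    out = np.where(a < 0.5 * c, 1.0, 0.0)
    out[c == 0] = np.nan
    return out


def motif_content_table(
    peak_classes: list[str],
    peaks: PeakSet,
    occurrences_by_family: dict[str, list[MotifOccurrence]],
    second_occurrences: list[MotifOccurrence],
    co_cut: int = 150,
    afos_dependent: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per peak class and motif family: peak counts and co-occurrence splits.

    For each class and family, reports the number and percent of peaks
    containing a family motif, the percent of those that also have a
    second motif within ``co_cut`` of the family motif, and (when
    ``afos_dependent`` is given, aligned with the peaks) the percent of
    perturbation-dependent peaks split by second-motif presence.
    """
    if len(peak_classes) != len(peaks):
        raise ValueError("one class label per peak required")
    second_centers: dict[str, np.ndarray] = {}
    for occ in second_occurrences:
        second_centers.setdefault(occ.chrom, []).append(occ.center)
    second_centers = {c: np.sort(np.array(v)) for c, v in second_centers.items()}

    def has_second_near(occ: MotifOccurrence) -> bool:
        sc = second_centers.get(occ.chrom)
        if sc is None or sc.size == 0:
            return False
        j = np.searchsorted(sc, occ.center)
        best = np.inf
        if j < sc.size:
            best = min(best, abs(int(sc[j]) - occ.center))
        if j > 0:
            best = min(best, abs(int(sc[j - 1]) - occ.center))
        return best <= co_cut

    rows = []
    for klass in CLASS_LABELS:
        in_class = [i for i, c in enumerate(peak_classes) if c == klass]
        n_class = len(in_class)
        for family, occs in occurrences_by_family.items():
            with_motif: list[int] = []
            motif_has_second: dict[int, bool] = {}
            for i in in_class:
                chrom, start, end, _c = peaks.intervals[i]
                inside = [
                    o for o in occs if o.chrom == chrom and start <= o.center < end
                ]
                if inside:
                    with_motif.append(i)
                    motif_has_second[i] = any(has_second_near(o) for o in inside)
            n_with = len(with_motif)
            pct_with = 100.0 * n_with / n_class if n_class else 0.0
            n_second = sum(motif_has_second[i] for i in with_motif)
            pct_second = 100.0 * n_second / n_with if n_with else 0.0
            pct_dep_with = pct_dep_without = float("nan")
            if afos_dependent is not None and n_with:
                dep = np.asarray(afos_dependent, dtype=float)
                grp_w = [i for i in with_motif if motif_has_second[i]]
                grp_wo = [i for i in with_motif if not motif_has_second[i]]
                if grp_w:
                    vals = dep[grp_w]
                    vals = vals[np.isfinite(vals)]
                    pct_dep_with = 100.0 * vals.mean() if vals.size else float("nan")
                if grp_wo:
                    vals = dep[grp_wo]
                    vals = vals[np.isfinite(vals)]
                    pct_dep_without = 100.0 * vals.mean() if vals.size else float("nan")
            rows.append(
                {
                    "class": klass,
                    "family": family,
                    "n_peaks": n_class,
                    "n_with_motif": n_with,
                    "pct_with_motif": pct_with,
                    "pct_with_second": pct_second,
                    "pct_dependent_with_second": pct_dep_with,
                    "pct_dependent_without_second": pct_dep_without,
                }
            )
    return pd.DataFrame(rows)
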