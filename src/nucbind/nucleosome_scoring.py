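"""Intrinsic nucleosome occupancy scoring with a pluggable linear k-mer model.

The scorer is deliberately model-agnostic: any linear model mapping a
147-bp window to a real score can be supplied as a coefficient file
(canonical k-mer -> weight, plus an intercept).  The window score is

    score = intercept + sum over the 147-k+1 window positions of
            weight[canonical k-mer starting there]

counting overlapping k-mers.  Sliding the window one base at a time over
a 1,500-bp flank yields a 1,354-point profile; its decomposition gives
the three statistics used to model binding:

* Peak value      — score of the single window centered on the anchor;
* Background value — mean score of windows whose centers lie 150-750 bp
  from the anchor (both sides);
* Relative Peak    — Peak minus Background, exactly.

Windows containing N or soft-masked bases carry NaN (undefined) and are
excluded from averages, never treated as zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .sequence_core import (
    _CODE,
    _SOFT,
    _canonical_code_table,
    canonical_kmer,
    code_to_kmer,
    kmer_to_code,
)

__all__ = [
    "WINDOW",
    "FLANK",
    "BACKGROUND_CUT",
    "PROFILE_LENGTH",
    "NucleosomeModel",
    "InosProfile",
    "InosDecomposition",
    "load_model",
    "save_model",
    "score_window",
    "profile",
    "decompose",
    "decompose_flanks",
    "motif_excluded_inos",
    "average_profile",
]

WINDOW = 147          # nucleosome footprint
FLANK = 1500          # +-750 bp around the anchor
HALF_WINDOW = WINDOW // 2  # 73
BACKGROUND_CUT = 150  # background = window centers 150..750 bp from anchor
PROFILE_LENGTH = FLANK - WINDOW + 1  # 1354
#: window-center offsets relative to the anchor: -677 .. +676 (the 1,354
#: windows of a 1,500-bp flank; the rightmost window center sits at +676)
PROFILE_OFFSETS = np.arange(PROFILE_LENGTH) + HALF_WINDOW - FLANK // 2


@dataclass
class NucleosomeModel:
    """Linear k-mer model: canonical k-mer weights plus an intercept."""

    k: int
    weights: dict[str, float]
    intercept: float = 0.0
    label: str = ""

    _lookup: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 8:
            raise ValueError("feature order k must be in 1..8")
        canon: dict[str, float] = {}
        dups = []
        for kmer, w in self.weights.items():
            if len(kmer) != self.k:
                raise ValueError(f"weight key {kmer!r} has length != k={self.k}")
            if not np.isfinite(w):
                raise ValueError(f"non-finite weight for {kmer!r}")
            ck = canonical_kmer(kmer)
            if ck in canon:
                dups.append(kmer)
                canon[ck] += w
            else:
                canon[ck] = w
        if dups:
            warnings.warn(
                f"duplicate canonical weight keys summed: {sorted(dups)}",
                stacklevel=2,
            )
        self.weights = canon

    @property
    def weight_lookup(self) -> np.ndarray:
        """Per-k-mer-code weight vector (applies to either orientation)."""
        if self._lookup is None:
            lut = np.zeros(4**self.k)
            canon = _canonical_code_table(self.k)
            for kmer, w in self.weights.items():
                lut[kmer_to_code(kmer)] = w
            self._lookup = lut[canon]
        return self._lookup


def save_model(model: NucleosomeModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#k={model.k}\t#intercept={model.intercept!r}\n")
        for kmer in sorted(model.weights):
            fh.write(f"{kmer}\t{model.weights[kmer]!r}\n")


def load_model(path, label: str = "") -> NucleosomeModel:
    """Read a coefficient TSV (header ``#k=<int>\\t#intercept=<float>``)."""
    with open(path) as fh:
        header = fh.readline().strip()
        try:
            k_part, int_part = header.split("\t")
            k = int(k_part.removeprefix("#k="))
            intercept = float(int_part.removeprefix("#intercept="))
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"malformed model header (line 1): {header!r}") from exc
        weights: dict[str, float] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                kmer, w = line.split("\t")
                # accumulate so duplicate canonical keys sum (with a warning
                # raised by the model constructor)
                weights[kmer] = weights.get(kmer, 0.0) + float(w)
            except ValueError as exc:
                raise ValueError(f"malformed model row (line {lineno}): {line!r}") from exc
    return NucleosomeModel(k=k, weights=weights, intercept=intercept, label=label or str(path))


@dataclass
class InosProfile:
    """Sliding-window scores over a flank; NaN marks undefined windows."""

    offsets: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.scores):
            raise ValueError("offsets and scores lengths differ")


@dataclass(frozen=True)
class InosDecomposition:
    peak_value: float
    background_value: float
    relative_value: float


def _encode_flanks(flanks: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(codes, invalid) matrices; invalid = N or soft-masked base."""
    n = len(flanks)
    width = len(flanks[0])
    raw = np.frombuffer("".join(flanks).encode("ascii"), dtype=np.uint8).reshape(n, width)
    codes = _CODE[raw]
    invalid = (codes == 255) | _SOFT[raw]
    return codes, invalid


def _window_scores(
    model: NucleosomeModel, codes: np.ndarray, invalid: np.ndarray
) -> np.ndarray:
    """Scores of every 147-bp window (2-D batch; NaN for undefined windows)."""
    k = model.k
    n, width = codes.shape
    n_pos = width - k + 1
    kcode = np.zeros((n, n_pos), dtype=np.int64)
    for off in range(k):
        kcode = kcode * 4 + np.where(
            codes[:, off : off + n_pos] == 255, 0, codes[:, off : off + n_pos]
        )
    w = model.weight_lookup[kcode]
    n_win = width - WINDOW + 1
    per_window = WINDOW - k + 1
    cs = np.concatenate([np.zeros((n, 1)), np.cumsum(w, axis=1)], axis=1)
    scores = model.intercept + cs[:, per_window : per_window + n_win] - cs[:, :n_win]
    bad = np.concatenate(
        [np.zeros((n, 1), dtype=np.int64), np.cumsum(invalid, axis=1)], axis=1
    )
    any_bad = (bad[:, WINDOW : WINDOW + n_win] - bad[:, :n_win]) > 0
    scores[any_bad] = np.nan
    return scores


def score_window(model: NucleosomeModel, window: str) -> float:
    """Score one 147-bp window; NaN if it contains N or masked bases."""
    if len(window) != WINDOW:
        raise ValueError(f"window length {len(window)} != {WINDOW}")
    codes, invalid = _encode_flanks([window])
    return float(_window_scores(model, codes, invalid)[0, 0])


def profile(model: NucleosomeModel, flank: str) -> InosProfile:
    """Score every 147-bp window of a 1,500-bp flank (1,354 windows)."""
    if len(flank) != FLANK:
        raise ValueError(f"flank length {len(flank)} != {FLANK}")
    codes, invalid = _encode_flanks([flank])
    scores = _window_scores(model, codes, invalid)[0]
    return InosProfile(offsets=PROFILE_OFFSETS.copy(), scores=scores)


def decompose(prof: InosProfile) -> InosDecomposition:
    """Peak / Background / Relative Peak values of a profile.

    Peak = score of the window centered on the anchor (offset 0);
    Background = mean over windows with |center offset| >= 150, ignoring
    undefined entries; Relative = Peak - Background exactly.
    """
    anchor = np.flatnonzero(prof.offsets == 0)
    if anchor.size != 1:
        raise ValueError("profile has no unique anchor offset 0")
    peak = float(prof.scores[anchor[0]])
    bg_mask = np.abs(prof.offsets) >= BACKGROUND_CUT
    bg_scores = prof.scores[bg_mask]
    finite = np.isfinite(bg_scores)
    if not finite.any() or not np.isfinite(peak):
        return InosDecomposition(peak, float("nan"), float("nan"))
    background = float(np.mean(bg_scores[finite]))
    return InosDecomposition(peak, background, peak - background)


def decompose_flanks(model: NucleosomeModel, flanks: list[str]) -> np.ndarray:
    """Batch Peak/Background/Relative decomposition, one row per flank.

    Returns an (n, 3) array; rows with undefined peak or background are NaN.
    """
    out = np.full((len(flanks), 3), np.nan)
    anchor = FLANK // 2 - HALF_WINDOW  # window start whose center is the anchor
    bg_mask = np.abs(PROFILE_OFFSETS) >= BACKGROUND_CUT
    chunk = 2000
    for lo in range(0, len(flanks), chunk):
        block = flanks[lo : lo + chunk]
        codes, invalid = _encode_flanks(block)
        scores = _window_scores(model, codes, invalid)
        peak = scores[:, anchor]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            background = np.nanmean(scores[:, bg_mask], axis=1)
        out[lo : lo + len(block), 0] = peak
        out[lo : lo + len(block), 1] = background
        out[lo : lo + len(block), 2] = peak - background
    return out


def motif_excluded_inos(
    model: NucleosomeModel,
    flank: str,
    motif_span: tuple[int, int],
    gc: float = 0.42,
    replicates: int = 1000,
    seed=None,
) -> float:
    """Peak score with the motif bases replaced by random 42%-GC sequence.

    The bases in ``motif_span`` (flank coordinates, inside the central
    147-bp window) are resampled i.i.d. with P(G)=P(C)=gc/2 per replicate
    and the central window rescored; the mean over replicates is returned.
    """
    if len(flank) != FLANK:
        raise ValueError(f"flank length {len(flank)} != {FLANK}")
    start, end = motif_span
    win_lo = FLANK // 2 - HALF_WINDOW
    win_hi = win_lo + WINDOW
    if not (win_lo <= start < end <= win_hi):
        raise ValueError(
            f"motif span {motif_span} not inside central window [{win_lo}, {win_hi})"
        )
    rng = np.random.default_rng(seed)
    window = flank[win_lo:win_hi]
    codes, invalid = _encode_flanks([window])
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    reps_codes = np.repeat(codes, replicates, axis=0)
    reps_invalid = np.repeat(invalid, replicates, axis=0)
    span = slice(start - win_lo, end - win_lo)
    n_span = end - start
    draws = rng.choice(4, size=(replicates, n_span), p=base_p).astype(np.uint8)
    reps_codes[:, span] = draws
    reps_invalid[:, span] = False
    scores = _window_scores(model, reps_codes, reps_invalid)[:, 0]
    return float(np.nanmean(scores))


def average_profile(profiles: list[InosProfile]) -> tuple[InosProfile, np.ndarray]:
    """Per-offset mean over profiles, ignoring undefined entries.

    Returns the mean profile and the per-offset count of defined values.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    offsets = profiles[0].offsets
    mat = np.vstack([p.scores for p in profiles])
    for p in profiles:
        if len(p.scores) != mat.shape[1]:
            raise ValueError("profiles have unequal lengths")
    counts = np.isfinite(mat).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
    return InosProfile(offsets=offsets.copy(), scores=mean), counts
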