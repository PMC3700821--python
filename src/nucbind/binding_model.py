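"""Logistic-regression modeling of transcription factor binding to motifs.

Each canonical motif occurrence gets a row with the binary outcome BV
(1 if the motif sits in a ChIP-seq peak) and predictors:

* ``INOS_p``, ``INOS_b``, ``INOS_rp`` — occupancy-score Peak, Background
  and Relative Peak values of the motif's 1,500-bp flank;
* ``CGI`` — motif center inside a CpG-island interval;
* ``CLT`` — nearest homotypic motif within 150 bp (homotypic cluster);
* ``CO``  — a second motif (e.g. AP-1 near GR) within 150 bp;
* ``DHS`` — motif center inside a DNase hypersensitive site.

The model is P(BV=1) = logistic(b0 + b.x), fit by maximum likelihood.
Fit quality is the percent of variance explained,
PVE = (1 - deviance/null deviance) x 100, plus an 11-fold
cross-validated AUC over pooled out-of-fold scores.

Note that INOS_rp = INOS_p - INOS_b identically, so a fit including all
three INOS terms is rank-deficient; the minimum-norm solution is used
and its deviance (hence PVE) remains well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .kmer_enrichment import PeakSet
from .sequence_core import MotifOccurrence, nearest_neighbor_distances

__all__ = [
    "PREDICTORS",
    "FitResult",
    "label_bound",
    "build_features",
    "fit_logistic",
    "pve",
    "cv_auc",
    "cv_error",
    "percent_bound_by_inos",
]

PREDICTORS = ("INOS_p", "INOS_b", "INOS_rp", "CGI", "CLT", "CO", "DHS")
_BETA_CAP = 30.0


# ---------------------------------------------------------------------------
# feature construction

def _merge_intervals(
    intervals: list[tuple[str, int, int]]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by.setdefault(chrom, []).append((start, end))
    merged = {}
    for chrom, ivs in by.items():
        ivs.sort()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.array(starts), np.array(ends))
    return merged


def _points_in_intervals(
    chroms: list[str], points: np.ndarray, intervals: list[tuple[str, int, int]]
) -> np.ndarray:
    merged = _merge_intervals(intervals)
    out = np.zeros(len(points), dtype=np.int64)
    for i, (chrom, p) in enumerate(zip(chroms, points)):
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        j = np.searchsorted(starts, p, side="right") - 1
        if j >= 0 and p < ends[j]:
            out[i] = 1
    return out


def label_bound(
    occurrences: list[MotifOccurrence],
    peaks: PeakSet,
    window: int = 150,
) -> np.ndarray:
    """BV per occurrence: 1 iff the motif center lies within ``window`` bp
    of some peak center (the Peak-region geometry)."""
    centers = peaks.centers
    out = np.zeros(len(occurrences), dtype=np.int64)
    for i, occ in enumerate(occurrences):
        pc = centers.get(occ.chrom)
        if pc is None or pc.size == 0:
            continue
        j = np.searchsorted(pc, occ.center)
        best = np.inf
        if j < pc.size:
            best = min(best, abs(int(pc[j]) - occ.center))
        if j > 0:
            best = min(best, abs(int(pc[j - 1]) - occ.center))
        if best <= window:
            out[i] = 1
    return out


def build_features(
    occurrences: list[MotifOccurrence],
    decompositions: np.ndarray,
    cgi_intervals: list[tuple[str, int, int]],
    second_occurrences: list[MotifOccurrence],
    dhs_intervals: list[tuple[str, int, int]],
    cluster_cut: int = 150,
    co_cut: int = 150,
    bound: np.ndarray | None = None,
) -> tuple[pd.DataFrame, int]:
    """Assemble the per-motif feature table.

    ``decompositions`` is the (n, 3) Peak/Background/Relative array from
    ``nucleosome_scoring.decompose_flanks`` aligned with ``occurrences``.
    Rows with an undefined decomposition are excluded; the count of
    excluded rows is returned alongside the table.
    """
    n = len(occurrences)
    decompositions = np.asarray(decompositions, dtype=float)
    if decompositions.shape != (n, 3):
        raise ValueError("decompositions must be (n_occurrences, 3)")
    chroms = [o.chrom for o in occurrences]
    centers = np.array([o.center for o in occurrences], dtype=np.int64)

    cgi = _points_in_intervals(chroms, centers, cgi_intervals)
    dhs = _points_in_intervals(chroms, centers, dhs_intervals)
    nn = nearest_neighbor_distances(occurrences)
    clt = (nn <= cluster_cut).astype(np.int64)

    second = {}
    for occ in second_occurrences:
        second.setdefault(occ.chrom, []).append(occ.center)
    second = {c: np.sort(np.array(v)) for c, v in second.items()}
    co = np.zeros(n, dtype=np.int64)
    for i, occ in enumerate(occurrences):
        sc = second.get(occ.chrom)
        if sc is None or sc.size == 0:
            continue
        j = np.searchsorted(sc, occ.center)
        best = np.inf
        if j < sc.size:
            best = min(best, abs(int(sc[j]) - occ.center))
        if j > 0:
            best = min(best, abs(int(sc[j - 1]) - occ.center))
        if best <= co_cut:
            co[i] = 1

    df = pd.DataFrame(
        {
            "chrom": chroms,
            "center": centers,
            "INOS_p": decompositions[:, 0],
            "INOS_b": decompositions[:, 1],
            "INOS_rp": decompositions[:, 2],
            "CGI": cgi,
            "CLT": clt,
            "CO": co,
            "DHS": dhs,
        }
    )
    if bound is not None:
        df.insert(2, "BV", np.asarray(bound, dtype=np.int64))
    ok = np.isfinite(decompositions).all(axis=1)
    n_excluded = int((~ok).sum())
    return df.loc[ok].reset_index(drop=True), n_excluded


# ---------------------------------------------------------------------------
# logistic regression

@dataclass
class FitResult:
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    deviance: float
    null_deviance: float
    pve: float
    converged: bool
    n_rows: int


_ETA_CAP = 35.0  # |linear predictor| cap; p within 7e-16 of {0, 1} beyond it


def _binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    eta = np.clip(eta, -_ETA_CAP, _ETA_CAP)
    p = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-300
    ll = y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)
    return float(-2.0 * np.sum(ll))


def _irls_capped(Xc: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Fallback IRLS with a capped linear predictor (perfect separation).

    Under separation the coefficients run off to infinity; capping the
    working linear predictor lets the fit settle on the separating
    direction with deviance near zero instead of failing."""
    beta = np.zeros(Xc.shape[1])
    converged = False
    for _ in range(100):
        eta = np.clip(Xc @ beta, -_ETA_CAP, _ETA_CAP)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        z = eta + (y - p) / w
        wx = Xc * w[:, None]
        new, *_ = np.linalg.lstsq(Xc.T @ wx, Xc.T @ (w * z), rcond=None)
        if np.max(np.abs(new - beta)) < 1e-8:
            beta = new
            converged = True
            break
        beta = new
    return beta, converged


def _fit_beta(Xc: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """(coefficients, standard errors, converged) for a logistic fit."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=100)
        beta = np.asarray(res.params, dtype=float)
        if np.all(np.isfinite(beta)) and np.max(np.abs(beta)) < _BETA_CAP:
            bse = np.asarray(res.bse, dtype=float)
            return beta, bse, bool(res.converged)
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        pass
    beta, _ = _irls_capped(Xc, y)
    return beta, np.full(Xc.shape[1], np.nan), False


def fit_logistic(table: pd.DataFrame, predictors: tuple[str, ...]) -> FitResult:
    """Maximum-likelihood logistic fit of BV on the chosen predictors."""
    missing = [p for p in predictors if p not in table.columns]
    if missing:
        raise KeyError(f"predictors not in table: {missing}")
    y = table["BV"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome has a single class; cannot fit")
    X = table[list(predictors)].to_numpy(dtype=float)
    Xc = np.column_stack([np.ones(len(y)), X])
    beta, bse, converged = _fit_beta(Xc, y)
    deviance = _binomial_deviance(y, Xc @ beta)
    # intercept-only MLE is p-bar in closed form
    pbar = y.mean()
    null_dev = _binomial_deviance(y, np.full(len(y), np.log(pbar / (1 - pbar))))
    names = ("const",) + tuple(predictors)
    return FitResult(
        coefficients=dict(zip(names, beta.tolist())),
        std_errors=dict(zip(names, bse.tolist())),
        deviance=deviance,
        null_deviance=null_dev,
        pve=pve(deviance, null_dev),
        converged=converged,
        n_rows=len(y),
    )


def pve(deviance: float, null_deviance: float) -> float:
    """Percent of variance explained: (1 - deviance/null deviance) x 100."""
    if null_deviance == 0:
        return float("nan")
    return (1.0 - deviance / null_deviance) * 100.0


def _stratified_oof_scores(
    table: pd.DataFrame, predictors: tuple[str, ...], folds: int, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled out-of-fold linear scores from stratified CV fits.

    Pooled scores keep only the predictor contributions: the fold
    intercept (and any predictor constant within the training fold) is
    excluded, since fold-to-fold intercept noise would otherwise impose
    an uninformative ordering between folds — e.g. a constant predictor
    must pool to all-tied scores (AUC 1/2), not to fold artifacts.
    """
    y = table["BV"].to_numpy(dtype=float)
    X = table[list(predictors)].to_numpy(dtype=float)
    base = 0 if seed is None else int(seed)
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=base + attempt)
        scores = np.empty(len(y))
        eta = np.empty(len(y))
        ok = True
        for train, test in skf.split(X, y):
            if y[train].min() == y[train].max():
                ok = False
                break
            varying = np.flatnonzero(X[train].std(axis=0) > 0)
            Xc_train = np.column_stack([np.ones(len(train)), X[train][:, varying]])
            beta, _, _ = _fit_beta(Xc_train, y[train])
            contrib = X[test][:, varying] @ beta[1:]
            scores[test] = np.clip(contrib, -_ETA_CAP, _ETA_CAP)
            eta[test] = np.clip(beta[0] + contrib, -_ETA_CAP, _ETA_CAP)
        if ok:
            return scores, eta, y
    raise ValueError("could not draw folds with both classes in every training split")


def cv_auc(
    table: pd.DataFrame,
    predictors: tuple[str, ...],
    folds: int = 11,
    seed=None,
) -> float:
    """AUC over pooled out-of-fold scores (stratified folds, one number).

    Computed by the rank statistic with tie-correction (tied scores
    contribute 1/2)."""
    scores, _eta, y = _stratified_oof_scores(table, predictors, folds, seed)
    return float(roc_auc_score(y, scores))


def cv_error(
    table: pd.DataFrame,
    predictors: tuple[str, ...],
    folds: int = 11,
    seed=None,
    threshold: float = 0.5,
) -> float:
    """Cross-validated misclassification rate at a probability threshold.

    One interpretation of a tabulated "CV err."; labeled as such."""
    _scores, eta, y = _stratified_oof_scores(table, predictors, folds, seed)
    p = 1.0 / (1.0 + np.exp(-eta))
    return float(np.mean((p >= threshold) != (y == 1)))


def percent_bound_by_inos(
    table: pd.DataFrame, bin_width: float = 0.3
) -> pd.DataFrame:
    """Histogram of INOS Peak values with percent bound per bin.

    Bins are half-open [left, left + width); empty bins report NaN
    percent.  The bin range is data-driven.
    """
    if table.empty:
        raise ValueError("empty feature table")
    x = table["INOS_p"].to_numpy(dtype=float)
    y = table["BV"].to_numpy(dtype=int)
    lo = np.floor(x.min() / bin_width) * bin_width
    n_bins = int(np.floor((x.max() - lo) / bin_width)) + 1
    idx = np.floor((x - lo) / bin_width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    n_total = np.bincount(idx, minlength=n_bins)
    n_bound = np.bincount(idx, weights=y, minlength=n_bins).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(n_total > 0, 100.0 * n_bound / np.maximum(n_total, 1), np.nan)
    lefts = lo + bin_width * np.arange(n_bins)
    return pd.DataFrame(
        {
            "bin_left": lefts,
            "bin_right": lefts + bin_width,
            "n_total": n_total,
            "n_bound": n_bound,
            "percent": percent,
        }
    )
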