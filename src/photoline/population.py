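"""Cross-recording analyses.

The functional signature of a recording is the polar angle of its weighted
scores on the first two components of an *uncentered* PCA of the dF/F -
acceleration cross-correlations across recordings.  Centering is deliberately
omitted so cross-correlation values keep their relationship to zero and group
sizes do not bias the decomposition.  The angle (0 deg between quadrants I and
IV, increasing counterclockwise) summarizes the timecourse of a recording's
relationship between signaling and acceleration; together with reward and
air-puff response integrals it feeds an unsupervised k-means classification
of recordings into putative subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .locomotion import InsufficientDataError, XCorr, xcorr_traces

ANGLE_CUT_DEG = 45.0            # circle opened where the fewest recordings fall
SOMA_AXON_CONTROL_MAX = 0.12    # mixed-wavelength control peak exclusion


class DegenerateMatrixError(ValueError):
    pass


@dataclass
class PCDecomp:
    loadings: np.ndarray            # components x lags
    scores: np.ndarray              # recordings x components
    score_sds: np.ndarray
    variance_explained: np.ndarray  # percent, uncentered
    lags: np.ndarray | None = None

    @property
    def weighted_scores(self) -> np.ndarray:
        return self.scores[:, :2] * self.score_sds[:2]

    @property
    def angles(self) -> np.ndarray:
        return pc_angle(self.weighted_scores[:, 0], self.weighted_scores[:, 1])

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project held-out rows (e.g. SNc recordings) onto the fitted
        components, unchanged."""
        return np.asarray(X, dtype=float) @ self.loadings.T

    def variance_explained_of(self, X: np.ndarray) -> np.ndarray:
        """Uncentered variance of held-out rows captured per component."""
        X = np.asarray(X, dtype=float)
        scores = self.transform(X)
        total = np.sum(X ** 2)
        return 100.0 * np.sum(scores ** 2, axis=0) / total


def fit_pca_uncentered(xcorr_matrix: np.ndarray,
                       lags: np.ndarray | None = None) -> PCDecomp:
    """Uncentered PCA: eigenvectors of X'X with no mean subtraction.

    Sign convention: each loading is flipped so its largest-magnitude element
    is positive (score signs, hence angles, depend on this; it is fixed and
    deterministic).
    """
    X = np.asarray(xcorr_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise DegenerateMatrixError("need at least 3 recordings")
    if not np.all(np.isfinite(X)):
        raise DegenerateMatrixError("cross-correlation matrix has non-finite rows")
    total = np.sum(X ** 2)
    if total <= 0:
        raise DegenerateMatrixError("matrix of rank 0 (all zeros)")
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    flip = np.sign(vt[np.arange(vt.shape[0]),
                      np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    scores = X @ vt.T
    var = 100.0 * s ** 2 / total
    return PCDecomp(loadings=vt, scores=scores,
                    score_sds=np.std(scores, axis=0, ddof=1),
                    variance_explained=var, lags=lags)


def pc_angle(pc1_w, pc2_w) -> np.ndarray | float:
    """Polar angle in degrees of weighted (PC1, PC2) scores, in [0, 360).

    0 deg sits between quadrants I and IV; angles increase counterclockwise
    (up is 90 deg).  Both scores zero yields NaN (undefined angle).
    """
    pc1_w = np.asarray(pc1_w, dtype=float)
    pc2_w = np.asarray(pc2_w, dtype=float)
    ang = np.degrees(np.arctan2(pc2_w, pc1_w)) % 360.0
    ang = np.where(ang >= 360.0, 0.0, ang)  # fp wraparound of tiny negatives
    ang = np.where((pc1_w == 0) & (pc2_w == 0), np.nan, ang)
    return float(ang) if ang.ndim == 0 else ang


def linearize_angles(angles_deg, cut: float = ANGLE_CUT_DEG) -> np.ndarray:
    """Open the circle at ``cut`` degrees: values re-expressed on
    (cut, cut + 360]."""
    a = np.asarray(angles_deg, dtype=float) % 360.0
    return np.where(a <= cut, a + 360.0, a)


def circular_mean_deg(angles_deg) -> float:
    a = np.radians(np.asarray(angles_deg, dtype=float))
    mean = np.degrees(np.arctan2(np.mean(np.sin(a)),
                                 np.mean(np.cos(a)))) % 360.0
    return float(mean if mean < 360.0 else 0.0)


def angle_difference_deg(a, b) -> np.ndarray | float:
    """Circular difference in [0, 180]."""
    d = np.abs((np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
               % 360.0)
    d = np.where(d > 180.0, 360.0 - d, d)
    return float(d) if d.ndim == 0 else d


def angle_group_test(angles_deg, labels, bonferroni: int | None = None,
                     cut: float = ANGLE_CUT_DEG) -> dict[tuple[str, str], float]:
    """Pairwise two-sided rank-sum tests on linearized angles.

    Angles are re-expressed on (cut, cut + 360] before ranking; p-values are
    multiplied by the Bonferroni factor (default: number of pairs tested) and
    capped at 1.  Groups with fewer than 2 members are dropped.
    """
    angles = linearize_angles(angles_deg, cut)
    labels = np.asarray(labels)
    groups = {}
    for lab in pd.unique(labels):
        vals = angles[labels == lab]
        vals = vals[np.isfinite(vals)]
        if vals.size >= 2:
            groups[lab] = vals
    pairs = list(combinations(groups, 2))
    if bonferroni is None:
        bonferroni = max(1, len(pairs))
    out = {}
    for a, b in pairs:
        if np.array_equal(np.sort(groups[a]), np.sort(groups[b])):
            out[(a, b)] = 1.0
            continue
        p = stats.ranksums(groups[a], groups[b]).pvalue
        out[(a, b)] = float(min(1.0, p * bonferroni))
    return out


@dataclass
class TimingLag:
    lag: float
    boundary_flag: bool
    mode: str


def timing_lag(values: np.ndarray, lags: np.ndarray, mode: str) -> TimingLag:
    """Extremum location of a cross-correlation or triggered average.

    Modes: ``xcorr_min`` (minimum in [0, 1] s, deceleration-locked trough),
    ``xcorr_max`` (maximum in [0, 1] s), ``dff_max`` (maximum dF/F in
    [0, 1] s of an event-triggered average), ``accel_min`` / ``accel_max``
    (acceleration extremum in [-1, 0] s of a transient-peak-triggered
    average; the lag is reported as its positive magnitude).
    """
    values = np.asarray(values, dtype=float)
    lags = np.asarray(lags, dtype=float)
    if mode in ("xcorr_min", "xcorr_max", "dff_max"):
        sel = (lags >= 0.0) & (lags <= 1.0)
    elif mode in ("accel_min", "accel_max"):
        sel = (lags >= -1.0) & (lags <= 0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not sel.any():
        raise InsufficientDataError("input does not span the required interval")
    sub, sublags = values[sel], lags[sel]
    idx = (np.nanargmin(sub) if mode in ("xcorr_min", "accel_min")
           else np.nanargmax(sub))
    lag = float(sublags[idx])
    boundary = idx == 0 or idx == sub.size - 1
    if mode in ("accel_min", "accel_max"):
        lag = abs(lag)
    return TimingLag(lag=lag, boundary_flag=bool(boundary), mode=mode)


# ---------------------------------------------------------------------------
# feature table and classification
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ["reward_response", "airpuff_response",
                   "pc1_score", "pc2_score"]


def build_feature_table(records: list[dict]) -> pd.DataFrame:
    """One row per recording: reward/air-puff responses, PC scores, label,
    coords."""
    df = pd.DataFrame.from_records(records)
    missing = [c for c in FEATURE_COLUMNS + ["subtype_label"]
               if c not in df.columns]
    if missing:
        raise ValueError("feature table missing columns: " + ", ".join(missing))
    return df


@dataclass
class ClassifyResult:
    assignments: np.ndarray          # cluster id per recording
    matching: dict[int, str]         # cluster -> subtype (bijection)
    per_subtype_accuracy: dict[str, float]
    overall_accuracy: float          # percent
    seed: int
    restarts: int


def kmeans_classify(features: pd.DataFrame, k: int = 3, seed: int = 0,
                    restarts: int = 50) -> ClassifyResult:
    """Unsupervised k-means on z-scored functional features, with clusters
    matched to subtypes by the maximum-total-overlap bijection.

    Features are the reward and air-puff response integrals and the PC1/PC2
    scores; each column is z-scored (mean 0, s.d. 1) before clustering.
    """
    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    labels = features["subtype_label"].to_numpy()
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k = {k} exceeds the {n} recordings available")
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=restarts, init="k-means++",
                random_state=seed)
    assign = km.fit_predict(Z)
    subtype_names = list(pd.unique(labels))
    overlap = np.zeros((k, len(subtype_names)))
    for c in range(k):
        for j, s in enumerate(subtype_names):
            overlap[c, j] = np.sum((assign == c) & (labels == s))
    rows, cols = linear_sum_assignment(-overlap)
    matching = {int(c): subtype_names[j] for c, j in zip(rows, cols)}
    per_subtype = {}
    correct = 0
    for c, s in matching.items():
        n_s = int(np.sum(labels == s))
        hit = int(overlap[c, subtype_names.index(s)])
        per_subtype[s] = 100.0 * hit / n_s if n_s else np.nan
        correct += hit
    return ClassifyResult(assignments=assign, matching=matching,
                          per_subtype_accuracy=per_subtype,
                          overall_accuracy=100.0 * correct / n,
                          seed=seed, restarts=restarts)


# ---------------------------------------------------------------------------
# distance / similarity, mixtures, soma-axon
# ---------------------------------------------------------------------------

SUBTYPE_TRIO = ("Vglut2", "Calb1", "Anxa1")


def pairwise_distance_similarity(angles_deg, labels, coords,
                                 bonferroni: int = 1) -> dict:
    """Recording-pair table of anatomical distance vs angle difference.

    Enumerates all within-subtype pairs (per subtype of the trio), all
    cross-subtype ("mismatched") pairs among the trio, and all DAT-DAT pairs.
    Returns the pair table and rank-sum comparisons of each within-subtype
    group against the mismatched group.
    """
    angles = np.asarray(angles_deg, dtype=float)
    labels = np.asarray(labels)
    coords = np.asarray(coords, dtype=float)
    rows = []
    n = angles.size
    for i, j in combinations(range(n), 2):
        li, lj = labels[i], labels[j]
        if not (np.all(np.isfinite(coords[i])) and np.all(np.isfinite(coords[j]))):
            continue
        if li == lj and li in SUBTYPE_TRIO + ("DAT",):
            group = "DAT" if li == "DAT" else f"within-{li}"
        elif li in SUBTYPE_TRIO and lj in SUBTYPE_TRIO:
            group = "mismatched"
        else:
            continue
        rows.append({
            "i": i, "j": j, "group": group,
            "distance_mm": float(np.linalg.norm(coords[i] - coords[j])),
            "angle_diff_deg": float(angle_difference_deg(angles[i], angles[j])),
        })
    table = pd.DataFrame(rows)
    tests = {}
    if len(table):
        mism = table.loc[table.group == "mismatched", "angle_diff_deg"]
        for s in SUBTYPE_TRIO:
            within = table.loc[table.group == f"within-{s}", "angle_diff_deg"]
            if len(within) >= 2 and len(mism) >= 2:
                p = stats.ranksums(within, mism).pvalue
                tests[s] = float(min(1.0, p * bonferroni))
    return {"pairs": table, "tests": tests}


def dat_mixture(calb1_mean_xcorr: np.ndarray, anxa1_mean_xcorr: np.ndarray,
                weights) -> np.ndarray:
    """Predicted mean cross-correlation per depth bin as a weighted average
    of the Anxa1 and Calb1 subtype means: w*anxa1 + (1-w)*calb1.

    ``weights`` is the Anxa1 fraction per depth bin (1 for dorsal striatum
    grading to 0 for ventral).  Returns an array of shape (n_bins, n_lags).
    """
    w = np.atleast_1d(np.asarray(weights, dtype=float))
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("mixture weights must lie in [0, 1]")
    calb1 = np.asarray(calb1_mean_xcorr, dtype=float)
    anxa1 = np.asarray(anxa1_mean_xcorr, dtype=float)
    return w[:, None] * anxa1[None, :] + (1.0 - w)[:, None] * calb1[None, :]


def fit_mixture_weight(observed: np.ndarray, calb1: np.ndarray,
                       anxa1: np.ndarray) -> float:
    """Least-squares Anxa1 fraction explaining an observed mean
    cross-correlation, clipped to [0, 1]."""
    d = np.asarray(anxa1, dtype=float) - np.asarray(calb1, dtype=float)
    num = float(d @ (np.asarray(observed, dtype=float) - calb1))
    den = float(d @ d)
    if den <= 0:
        raise ValueError("Calb1 and Anxa1 templates are identical")
    return float(np.clip(num / den, 0.0, 1.0))


def mixture_fit_quality(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Per-depth-bin Pearson correlation between observed and predicted
    mean cross-correlations."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    return float(np.corrcoef(o, p)[0, 1])


@dataclass
class PairedRecording:
    """Simultaneous SNc (soma) / striatum (axon) recording pair."""

    soma_dff: np.ndarray
    axon_dff: np.ndarray
    soma_dff405: np.ndarray
    axon_dff405: np.ndarray
    bin_rate: float = 100.0
    mask: np.ndarray | None = None
    xcorr: XCorr | None = field(default=None)
    control_xcorr: XCorr | None = field(default=None)
    peak: float = np.nan
    control_peak: float = np.nan
    excluded: bool = False


def soma_axon_xcorr(pair: PairedRecording) -> PairedRecording:
    """Soma-axon dF/F cross-correlation over a +-1 s lag window.

    The movement-artifact control is the average of the two mixed-wavelength
    cross-correlations (soma-470 x axon-405 and soma-405 x axon-470); a pair
    whose control peaks above 0.12 is excluded.
    """
    if pair.soma_dff.size != pair.axon_dff.size:
        raise ValueError("soma and axon traces must share a clock "
                         "(equal length at the same bin rate)")
    rate = pair.bin_rate
    xc = xcorr_traces(pair.soma_dff, pair.axon_dff, mask=pair.mask, rate=rate)
    c1 = xcorr_traces(pair.soma_dff, pair.axon_dff405, mask=pair.mask, rate=rate)
    c2 = xcorr_traces(pair.soma_dff405, pair.axon_dff, mask=pair.mask, rate=rate)
    control = XCorr(lags=c1.lags, values=(c1.values + c2.values) / 2.0,
                    n_bins_used=min(c1.n_bins_used, c2.n_bins_used))
    pair.xcorr = xc
    pair.control_xcorr = control
    pair.peak = xc.peak
    pair.control_peak = control.peak
    pair.excluded = bool(control.peak > SOMA_AXON_CONTROL_MAX)
    return pair


def peak_group_test(peaks_by_group: dict[str, np.ndarray],
                    reference: str = "DAT",
                    bonferroni: int | None = None) -> dict[str, float]:
    """Two-sided Mann-Whitney comparison of soma-axon peak cross-correlations
    between each subtype and the reference group, Bonferroni-corrected."""
    others = [g for g in peaks_by_group if g != reference]
    if bonferroni is None:
        bonferroni = max(1, len(others))
    ref = np.asarray(peaks_by_group[reference], dtype=float)
    out = {}
    for g in others:
        vals = np.asarray(peaks_by_group[g], dtype=float)
        p = stats.mannwhitneyu(vals, ref, alternative="two-sided").pvalue
        out[g] = float(min(1.0, p * bonferroni))
    return out
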