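"""End-to-end convenience layer: one recording -> per-session results;
a cohort of recordings -> feature table, uncentered PCA, angles and
k-means classification.

These functions simply chain the module-level operations in the order the
analysis prescribes; everything they compute can also be produced by calling
the individual modules directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import locomotion as loco
from . import population as pop
from . import stimulus as stim
from .qc import DffRecording, QCReport, compute_dff, qc_report
from .session import BinnedSession

XCORR405_CONTROL_MAX = 0.1   # 405-vs-acceleration peak exclusion


@dataclass
class SessionAnalysis:
    rec: DffRecording
    report: QCReport
    acceleration: np.ndarray
    bouts: loco.BoutMask
    mask: np.ndarray                      # locomotion & artifact-included bins
    xcorr: loco.XCorr | None = None
    xcorr405: loco.XCorr | None = None
    pass_405_control: bool = True
    accel_events: loco.EventSet | None = None
    decel_events: loco.EventSet | None = None
    selection: stim.StimulusSelection | None = None
    reward_response: float = np.nan
    airpuff_response: float = np.nan
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def locomotion_ok(self) -> bool:
        return (self.bouts.pass_total and self.pass_405_control
                and self.xcorr is not None)


def analyze_session(binned: BinnedSession) -> SessionAnalysis:
    """Run the full single-recording pipeline on a binned session."""
    rec = compute_dff(binned)
    report = qc_report(rec)
    accel = loco.compute_acceleration(rec.velocity, rate=rec.bin_rate)
    bouts = loco.segment_locomotion(rec.velocity, rec.stimulus_times,
                                    rate=rec.bin_rate)
    mask = bouts.locomotion_mask & rec.included_mask
    out = SessionAnalysis(rec=rec, report=report, acceleration=accel,
                          bouts=bouts, mask=mask)
    try:
        out.xcorr = loco.xcorr_traces(accel, rec.dff470, mask,
                                      rate=rec.bin_rate)
        out.xcorr405 = loco.xcorr_traces(accel, rec.dff405, mask,
                                         rate=rec.bin_rate)
        out.pass_405_control = out.xcorr405.peak <= XCORR405_CONTROL_MAX
    except loco.InsufficientDataError as err:
        out.errors["xcorr"] = str(err)
    out.accel_events, out.decel_events = loco.detect_accel_events(
        accel, mask, rate=rec.bin_rate)
    out.selection = stim.select_stimulus_events(rec, accel, rate=rec.bin_rate)
    try:
        out.reward_response = stim.response_integral(
            rec.dff470, out.selection.included_rewards,
            rate=rec.bin_rate).response
    except loco.InsufficientDataError as err:
        out.errors["reward"] = str(err)
    try:
        out.airpuff_response = stim.response_integral(
            rec.dff470, out.selection.included_airpuffs,
            rate=rec.bin_rate).response
    except loco.InsufficientDataError as err:
        out.errors["airpuff"] = str(err)
    return out


@dataclass
class CohortAnalysis:
    analyses: list[SessionAnalysis]
    xcorr_matrix: np.ndarray
    lags: np.ndarray
    pca: pop.PCDecomp
    features: pd.DataFrame

    def classify(self, seed: int = 0, restarts: int = 50) -> pop.ClassifyResult:
        return pop.kmeans_classify(self.features, seed=seed, restarts=restarts)

    def mean_angles(self) -> dict[str, float]:
        out = {}
        for lab, grp in self.features.groupby("subtype_label"):
            out[str(lab)] = pop.circular_mean_deg(grp["angle_deg"].to_numpy())
        return out


def analyze_cohort(sessions: list[BinnedSession],
                   fit_labels=pop.SUBTYPE_TRIO) -> CohortAnalysis:
    """Analyze every session and build the cohort-level functional space.

    The uncentered PCA is fitted on the cross-correlations of recordings whose
    subtype label is in ``fit_labels`` (the functionally homogeneous trio);
    any other recordings (e.g. DAT) are projected with the same loadings.
    """
    analyses = [analyze_session(s) for s in sessions]
    usable = [a for a in analyses if a.xcorr is not None]
    if len(usable) < 3:
        raise loco.InsufficientDataError(
            "need at least 3 recordings with cross-correlations")
    lags = usable[0].xcorr.lags
    X = np.vstack([a.xcorr.values for a in usable])
    labels = np.asarray([a.rec.meta.subtype_label for a in usable])
    fit_rows = np.isin(labels, fit_labels)
    pca = pop.fit_pca_uncentered(X[fit_rows] if fit_rows.any() else X,
                                 lags=lags)
    scores = pca.transform(X)
    weighted = scores[:, :2] * pca.score_sds[:2]
    angles = pop.pc_angle(weighted[:, 0], weighted[:, 1])
    rows = []
    for a, sc, ang in zip(usable, scores, np.atleast_1d(angles)):
        rows.append({
            "mouse_id": a.rec.meta.mouse_id,
            "subtype_label": a.rec.meta.subtype_label,
            "reward_response": a.reward_response,
            "airpuff_response": a.airpuff_response,
            "pc1_score": sc[0], "pc2_score": sc[1],
            "angle_deg": ang,
            "coords_x": a.rec.meta.coords[0],
            "coords_y": a.rec.meta.coords[1],
            "coords_z": a.rec.meta.coords[2],
        })
    features = pd.DataFrame(rows)
    return CohortAnalysis(analyses=analyses, xcorr_matrix=X, lags=lags,
                          pca=pca, features=features)
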