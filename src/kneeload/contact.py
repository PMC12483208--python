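"""Compressive tibiofemoral contact force: totals, muscle/intersegmental
decomposition, and early/late-stance peak extraction.

Total contact force is the intersegmental axial reaction plus the sum of
the knee-spanning muscles' compressive components, normalized by the
subject's unaugmented body weight and resampled to a 101-point percent-
stance grid.  Early- and late-stance peaks are the maxima within 15-40%
and 60-90% of stance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MusculoskeletalModel
from .muscle import compressive_component

#: percent-stance output grid
STANCE_GRID = np.linspace(0.0, 100.0, 101)

EARLY_WINDOW = (15.0, 40.0)
LATE_WINDOW = (60.0, 90.0)


class AlignmentError(ValueError):
    pass


@dataclass
class ContactForceTrace:
    """Contact force vs. percent stance, in body weights (compression > 0)."""

    percent_stance: np.ndarray
    total: np.ndarray
    muscle_contrib: np.ndarray
    intersegmental: np.ndarray
    body_weight: float  # N, the normalization denominator

    def __post_init__(self):
        for arr in (self.total, self.muscle_contrib, self.intersegmental):
            if arr.shape != self.percent_stance.shape:
                raise AlignmentError("contact trace components on mismatched grids")


@dataclass
class PeakSummary:
    early_peak: float      # BW
    early_location: float  # % stance
    late_peak: float
    late_location: float


def _resample(pct_in: np.ndarray, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.interp(grid, pct_in, y)


def total_contact_force(
    muscle_forces: dict[str, np.ndarray],
    knee_angle: np.ndarray,
    intersegmental_axial: np.ndarray,
    model: MusculoskeletalModel,
    pct_stance: np.ndarray | None = None,
) -> ContactForceTrace:
    """Total compressive contact force from muscle forces + intersegmental.

    ``muscle_forces`` maps muscle names to tendon-force series (N) on the
    same grid as ``knee_angle`` and ``intersegmental_axial``.  Forces are
    normalized by the subject's unaugmented body weight so percent-change
    outcomes share a fixed denominator across loading conditions.
    """
    knee_angle = np.asarray(knee_angle, dtype=float)
    interseg = np.asarray(intersegmental_axial, dtype=float)
    if knee_angle.shape != interseg.shape:
        raise AlignmentError("knee angle and intersegmental trace lengths differ")
    n = knee_angle.size
    muscle_sum = np.zeros(n)
    for name, force in muscle_forces.items():
        force = np.asarray(force, dtype=float)
        if force.shape != knee_angle.shape:
            raise AlignmentError(f"muscle {name}: force series length differs")
        muscle_sum += compressive_component(model.muscles[name], knee_angle, force)
    bw = model.subject.body_weight
    pct_in = np.linspace(0, 100, n) if pct_stance is None else np.asarray(pct_stance)
    total = (interseg + muscle_sum) / bw
    return ContactForceTrace(
        percent_stance=STANCE_GRID.copy(),
        total=_resample(pct_in, total, STANCE_GRID),
        muscle_contrib=_resample(pct_in, muscle_sum / bw, STANCE_GRID),
        intersegmental=_resample(pct_in, interseg / bw, STANCE_GRID),
        body_weight=bw,
    )


def decompose_contributions(
    total: np.ndarray, intersegmental: np.ndarray,
    percent_stance: np.ndarray | None = None, body_weight: float = np.nan
) -> ContactForceTrace:
    """Muscle contribution as total minus intersegmental, pointwise."""
    total = np.asarray(total, dtype=float)
    interseg = np.asarray(intersegmental, dtype=float)
    if total.shape != interseg.shape:
        raise AlignmentError("total and intersegmental traces on mismatched grids")
    grid = STANCE_GRID.copy() if percent_stance is None else np.asarray(percent_stance)
    if grid.shape != total.shape:
        raise AlignmentError("percent-stance grid does not match traces")
    return ContactForceTrace(
        percent_stance=grid,
        total=total,
        muscle_contrib=total - interseg,
        intersegmental=interseg,
        body_weight=body_weight,
    )


def muscle_share_at_peaks(trace: ContactForceTrace) -> tuple[float, float]:
    """Muscle contribution share (fraction of total) at each peak location."""
    peaks = extract_peaks(trace)
    shares = []
    for loc in (peaks.early_location, peaks.late_location):
        i = int(np.argmin(np.abs(trace.percent_stance - loc)))
        shares.append(trace.muscle_contrib[i] / trace.total[i])
    return tuple(shares)


def extract_peaks(trace: ContactForceTrace) -> PeakSummary:
    """Windowed maxima: early 15-40% and late 60-90% of stance.

    Ties break toward the earlier location.  NaN inside a window is a data
    error.
    """
    out = []
    for lo, hi in (EARLY_WINDOW, LATE_WINDOW):
        mask = (trace.percent_stance >= lo) & (trace.percent_stance <= hi)
        window = trace.total[mask]
        if np.any(np.isnan(window)):
            raise ValueError(f"NaN in contact trace within {lo}-{hi}% stance")
        i = int(np.argmax(window))  # argmax returns the first (earliest) tie
        out.append((float(window[i]), float(trace.percent_stance[mask][i])))
    (early, early_loc), (late, late_loc) = out
    return PeakSummary(early_peak=early, early_location=early_loc,
                       late_peak=late, late_location=late_loc)
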