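"""MD-elimination kinetics from 2D brightfield + MD time-lapse images.

Per frame, the egg is segmented from brightfield (trainable pixel
classifier), eroded 15 px to avoid edge artifacts, and small stray
segments dropped; the MD channel is rolling-ball background-subtracted
and thresholded at the fixed raw-scale cutoff (1200 by default). The
normalized MD intensity (NMI) is

    nmi = (mean over MD-positive egg pixels − mean over MD-negative
           egg pixels) × (MD-positive area / egg area)

which accounts for both MD brightness and MD size. Per-egg NMI time
courses over hours AEL feed the exponential decay fit and the group
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .config import AnalysisConfig
from .segmorph import (
    PixelClassifier,
    erode_mask,
    label_and_filter,
    predict_mask,
    rolling_ball_subtract,
)


@dataclass
class FrameMeasurement:
    """One frame's NMI decomposition."""

    egg_area_px: int
    md_positive_area_px: int
    mean_pos: float
    mean_neg: float
    nmi: float
    time_h: float
    qc_failed: bool = False  # cellularization-failure exclusion flag


def quantify_frame(
    bf: np.ndarray,
    md: np.ndarray,
    clf: PixelClassifier | None,
    cfg: AnalysisConfig,
    egg_class: int = 2,
    time_h: float = 0.0,
    egg_mask_override: np.ndarray | None = None,
    qc_failed: bool = False,
) -> FrameMeasurement:
    """Measure the normalized MD intensity of one frame.

    ``egg_mask_override`` replaces the classifier segmentation (the
    manual-ROI correction hook); otherwise the mask comes from
    ``predict_mask(clf, bf, egg_class)``. Degenerate cases: if no pixel
    exceeds the threshold, nmi = 0; if every egg pixel does, the
    MD-negative mean is taken as 0.
    """
    bf = np.asarray(bf, dtype=np.float64)
    md = np.asarray(md, dtype=np.float64)
    if bf.shape != md.shape:
        raise ValueError("brightfield and MD channels must share shape")

    if egg_mask_override is not None:
        raw_egg = np.asarray(egg_mask_override, dtype=bool)
    else:
        if clf is None:
            raise ValueError("either a classifier or an egg mask override is required")
        raw_egg = predict_mask(clf, bf, egg_class)

    egg = erode_mask(raw_egg, cfg.erosion_px)
    if not egg.any():
        raise ValueError("empty egg mask after erosion")
    objs = label_and_filter(egg, min_size_px=_min_component_area(cfg, egg))
    egg = objs.mask()
    if not egg.any():
        raise ValueError("egg mask empty after small-component removal")

    md_sub = rolling_ball_subtract(
        md, cfg.rolling_ball_radius_px, cfg.rolling_ball_presmooth_sigma
    )
    positive = (md_sub > cfg.threshold_md) & egg
    negative = egg & ~positive

    egg_area = int(egg.sum())
    pos_area = int(positive.sum())
    if pos_area == 0:
        mean_pos, mean_neg, nmi = 0.0, float(md_sub[negative].mean()), 0.0
    else:
        mean_pos = float(md_sub[positive].mean())
        mean_neg = float(md_sub[negative].mean()) if negative.any() else 0.0
        nmi = (mean_pos - mean_neg) * (pos_area / egg_area)
    return FrameMeasurement(
        egg_area_px=egg_area,
        md_positive_area_px=pos_area,
        mean_pos=mean_pos,
        mean_neg=mean_neg,
        nmi=nmi,
        time_h=time_h,
        qc_failed=qc_failed,
    )


def _min_component_area(cfg: AnalysisConfig, mask: np.ndarray) -> int:
    """Small-segment cutoff: explicit config value, else 5% of the
    largest component's area (scale-free default)."""
    if cfg.min_component_area_px is not None:
        return cfg.min_component_area_px
    objs = label_and_filter(mask)
    if objs.n_objects == 0:
        return 0
    return int(0.05 * objs.table["voxel_count"].max())


def build_timecourse(
    frames_by_egg: dict[str, list[FrameMeasurement]],
    times_h: list[float] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Assemble the egg × time NMI matrix.

    Eggs flagged as failed (cellularization) are excluded; the count of
    excluded eggs is returned. Raises if a retained egg misses a
    configured time point.
    """
    if times_h is None:
        all_times = sorted({f.time_h for fs in frames_by_egg.values() for f in fs})
        times_h = list(all_times)
    times = np.asarray(times_h, dtype=float)
    rows, egg_ids = [], []
    n_excluded = 0
    for egg_id, frames in frames_by_egg.items():
        if any(f.qc_failed for f in frames):
            n_excluded += 1
            continue
        by_time = {f.time_h: f.nmi for f in frames}
        missing = [t for t in times if t not in by_time]
        if missing:
            raise ValueError(f"egg {egg_id} missing time points {missing}")
        rows.append([by_time[t] for t in times])
        egg_ids.append(egg_id)
    matrix = np.asarray(rows, dtype=float).reshape(len(rows), len(times))
    return matrix, times, egg_ids, n_excluded


@dataclass
class DecayFit:
    """Exponential decay fit nmi(t) = I0·exp(−k·t)."""

    i0: float
    k: float
    k_stderr: float


def fit_decay(nmi: np.ndarray, times_h: np.ndarray) -> DecayFit:
    """Least-squares fit of I0·exp(−k t) to one egg's NMI series.

    A log-linear regression on the positive values seeds the nonlinear
    fit. A constant series yields k = 0 exactly.
    """
    nmi = np.asarray(nmi, dtype=float)
    times = np.asarray(times_h, dtype=float)
    if nmi.size < 3:
        raise ValueError("need >=3 time points for the decay fit")
    if np.any(nmi < 0):
        raise ValueError("nmi values must be >= 0")
    if np.all(nmi == 0):
        raise ValueError("all-zero NMI series cannot be fitted")
    if np.allclose(nmi, nmi[0]):
        return DecayFit(i0=float(nmi[0]), k=0.0, k_stderr=0.0)

    pos = nmi > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(times[pos], np.log(nmi[pos]), 1)
        p0 = (float(np.exp(intercept)), float(max(-slope, 0.0)))
    else:
        p0 = (float(nmi.max()), 1.0)

    def model(t, i0, k):
        return i0 * np.exp(-k * t)

    popt, pcov = curve_fit(model, times, nmi, p0=p0, maxfev=10000)
    k_err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    return DecayFit(i0=float(popt[0]), k=float(popt[1]), k_stderr=k_err)
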