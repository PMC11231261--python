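"""Vesicle-level two-channel colocalization with envelope background.

Each segmented primary-channel vesicle (≥ 15 µm³) gets a 0.2 µm guard
envelope (not measured) and a 0.3 µm background envelope; the egg-level
background is the unweighted mean of all vesicles' background-envelope
means. A vesicle whose secondary mean falls below its *own* background
envelope is omitted; among the rest, a vesicle is positive when its
background-subtracted secondary mean exceeds zero. Pooled Pearson and
Manders (M1) coefficients are computed over the voxels of all
non-omitted vesicles across eggs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import AnalysisConfig
from .segmorph import LabeledObjects


@dataclass
class VesicleRecord:
    """One vesicle's measurement and positivity call."""

    label: int
    volume_um3: float
    mean_primary: float
    mean_secondary: float
    background_shell_mean: float
    egg_background: float
    normalized_secondary: float
    status: str  # positive | negative | omitted


def _object_crop(labels: np.ndarray, label: int, pad_vox: np.ndarray):
    """Bounding-box slice around one object, expanded to fit envelopes."""
    where = ndimage.find_objects((labels == label).astype(np.int8))[0]
    return tuple(
        slice(max(0, s.start - p), min(dim, s.stop + p))
        for s, p, dim in zip(where, pad_vox, labels.shape)
    )


def measure_vesicles(
    objects: LabeledObjects,
    secondary: np.ndarray,
    cfg: AnalysisConfig,
    primary: np.ndarray | None = None,
) -> list[VesicleRecord]:
    """Measure every vesicle and resolve omission/positivity statuses.

    ``objects`` must already carry the ≥ 15 µm³ volume filter (see
    :func:`pmequant.segmorph.label_and_filter`). Envelope geometry is
    computed per vesicle on its own bounding box, extended by the guard
    + background thickness; voxels belonging to *any* vesicle are never
    counted as background.
    """
    if objects.n_objects == 0:
        raise ValueError("no vesicles to measure after filtering")
    spacing = objects.spacing
    if spacing is None:
        raise ValueError("physical spacing required for envelope geometry")
    secondary = np.asarray(secondary, dtype=np.float64)
    primary = None if primary is None else np.asarray(primary, dtype=np.float64)
    guard, bg = cfg.vesicle_guard_um, cfg.vesicle_background_um
    pad_vox = np.ceil((guard + bg) / np.asarray(spacing)).astype(int) + 1
    any_vesicle = objects.mask()

    raw: list[dict] = []
    for row in objects.table.itertuples(index=False):
        sel = _object_crop(objects.labels, row.label, pad_vox)
        local = objects.labels[sel] == row.label
        dist = ndimage.distance_transform_edt(~local, sampling=spacing)
        bg_shell = (dist > guard) & (dist <= guard + bg) & ~any_vesicle[sel]
        if not bg_shell.any():
            raise ValueError(f"vesicle {row.label}: background envelope is empty")
        sec_in = float(secondary[sel][local].mean())
        sec_bg = float(secondary[sel][bg_shell].mean())
        prim_in = float(primary[sel][local].mean()) if primary is not None else float("nan")
        raw.append(
            {
                "label": int(row.label),
                "volume_um3": float(row.volume_um3),
                "mean_primary": prim_in,
                "mean_secondary": sec_in,
                "background_shell_mean": sec_bg,
            }
        )

    egg_background = float(np.mean([r["background_shell_mean"] for r in raw]))
    records = []
    for r in raw:
        normalized = r["mean_secondary"] - egg_background
        if r["mean_secondary"] < r["background_shell_mean"]:
            status = "omitted"
        elif normalized > 0:
            status = "positive"
        else:
            status = "negative"
        records.append(
            VesicleRecord(
                label=r["label"],
                volume_um3=r["volume_um3"],
                mean_primary=r["mean_primary"],
                mean_secondary=r["mean_secondary"],
                background_shell_mean=r["background_shell_mean"],
                egg_background=egg_background,
                normalized_secondary=normalized,
                status=status,
            )
        )
    return records


def classify_positive(records: list[VesicleRecord]) -> tuple[float, dict]:
    """Positive fraction over non-omitted vesicles, with counts."""
    counts = {
        "positive": sum(r.status == "positive" for r in records),
        "negative": sum(r.status == "negative" for r in records),
        "omitted": sum(r.status == "omitted" for r in records),
    }
    considered = counts["positive"] + counts["negative"]
    fraction = counts["positive"] / considered if considered else float("nan")
    return fraction, counts


def _pooled_voxels(
    objects: LabeledObjects,
    primary: np.ndarray,
    secondary: np.ndarray,
    records: list[VesicleRecord],
) -> tuple[np.ndarray, np.ndarray]:
    keep = [r.label for r in records if r.status != "omitted"]
    sel = np.isin(objects.labels, keep)
    return (
        np.asarray(primary, dtype=np.float64)[sel],
        np.asarray(secondary, dtype=np.float64)[sel],
    )


def pooled_pearson(
    pooled_primary: np.ndarray, pooled_secondary: np.ndarray
) -> float:
    """Pearson correlation of the two channels over pooled vesicle voxels."""
    x = np.asarray(pooled_primary, dtype=np.float64)
    y = np.asarray(pooled_secondary, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need >=2 pooled voxels")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a channel")
    return float(np.corrcoef(x, y)[0, 1])


def manders_m1(
    pooled_primary: np.ndarray,
    pooled_secondary: np.ndarray,
    secondary_background: float,
) -> float:
    """Manders M1: fraction of primary intensity in secondary-positive voxels.

    A voxel is secondary-positive when its background-subtracted
    secondary intensity exceeds zero (the egg-level envelope background
    is the threshold; no Costes procedure).
    """
    x = np.asarray(pooled_primary, dtype=np.float64)
    y = np.asarray(pooled_secondary, dtype=np.float64)
    total = x.sum()
    if total <= 0:
        raise ValueError("zero total primary signal")
    positive = (y - secondary_background) > 0
    return float(x[positive].sum() / total)


def colocalize(
    objects: LabeledObjects,
    primary: np.ndarray,
    secondary: np.ndarray,
    cfg: AnalysisConfig,
) -> dict:
    """Full vesicle colocalization summary for one egg (or pooled scene)."""
    records = measure_vesicles(objects, secondary, cfg, primary=primary)
    fraction, counts = classify_positive(records)
    px, py = _pooled_voxels(objects, primary, secondary, records)
    egg_bg = records[0].egg_background
    return {
        "records": records,
        "positive_fraction": fraction,
        "counts": counts,
        "pcc": pooled_pearson(px, py),
        "m1": manders_m1(px, py, egg_bg),
        "n_vesicles": len(records),
    }
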