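"""Synthetic microscopy scenes with known ground truth.

Generates desk-scale stand-ins for the three imaging assays:

- a 2D brightfield + MD time-lapse of a fertilized egg, with the MD
  channel decaying exponentially over hourly frames,
- a 3D stack with a curved axoneme tube, Atg8a-like puncta whose radial
  density around the axoneme is controlled, and a coaxial
  plasma-membrane tube with a configurable fill fraction,
- a 3D two-channel vesicle field with a known positive fraction.

Every generator is deterministic for (params, seed) and returns a
:class:`TruthManifest` from which the scene can be re-rendered
bit-identically. Noise is additive Gaussian on the ideal signal; there
is no photon statistics or PSF by default (an optional isotropic
Gaussian blur is available) because the downstream measurements never
deconvolve.

Puncta are placed by sampling voxel centers weighted by the requested
radial-density profile evaluated on the exact axoneme distance map, so
each punctum's manifest distance and shell index are exact by
construction.
"""

from __future__ import annotations

import math
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import interpolate, ndimage
from scipy.spatial import cKDTree

from .image import ImageStack

# ---------------------------------------------------------------------------
# Parameter models


class Scene2DParams(BaseModel):
    """Parameters of the 2D kinetics time-lapse scene."""

    model_config = ConfigDict(extra="forbid")

    shape: tuple[int, int] = (160, 224)
    egg_center: tuple[float, float] | None = None  # default: image center
    egg_semiaxes_px: tuple[float, float] = (60.0, 95.0)
    flagellum_points: list[tuple[float, float]] | None = None  # default curve
    md_width_px: float = Field(default=3.0, gt=0)
    i0: float = Field(default=30000.0, gt=0)  # initial MD amplitude, raw scale
    decay_rate: float = Field(default=1.0, ge=0)  # k, per hour
    background: float = Field(default=200.0, ge=0)
    bf_exterior: float = 1000.0
    bf_interior: float = 5000.0
    bf_texture_sd: float = 400.0
    noise_sd: float = Field(default=50.0, ge=0)
    frames_h: list[float] = Field(default_factory=lambda: [0.0, 1.0, 2.0, 3.0])
    pixel_size_um: float = Field(default=0.65, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "Scene2DParams":
        if self.i0 <= self.background:
            raise ValueError("i0 must exceed background")
        return self


class Scene3DParams(BaseModel):
    """Parameters of the 3D axoneme / vesicle scenes.

    One parameter record covers both 3D generators; each uses the
    fields relevant to it.
    """

    model_config = ConfigDict(extra="forbid")

    shape: tuple[int, int, int] = (48, 160, 160)  # (z, y, x)
    spacing_um: tuple[float, float, float] = (0.5, 0.25, 0.25)

    # axoneme scene
    axoneme_points: list[tuple[float, float, float]] | None = None  # µm, (z,y,x)
    axoneme_radius_um: float = Field(default=0.3, gt=0)
    membrane_radius_um: float = Field(default=0.8, gt=0)
    membrane_fill_fraction: float = Field(default=1.0, ge=0, le=1)
    membrane_segments: int = Field(default=20, ge=1)
    n_puncta: int = Field(default=500, ge=0)
    punctum_radius_um: float = Field(default=0.0, ge=0)  # 0 = single voxel
    radial_profile: Literal["uniform", "fixed"] | list[float] = "uniform"
    fixed_distance_um: float = 2.5
    max_distance_um: float = Field(default=10.0, gt=0)

    # vesicle scene
    n_vesicles: int = Field(default=60, ge=0)
    vesicle_radius_um: tuple[float, float] = (2.0, 2.6)  # min, max
    positive_fraction: float = Field(default=0.85, ge=0, le=1)
    envelope_clearance_um: float = Field(default=1.2, gt=0)
    # spectral bleed of the primary marker into the secondary channel
    # (every real two-channel acquisition has some; also what keeps
    # hCD63-negative vesicles above their own guard envelope)
    secondary_bleed_fraction: float = Field(default=0.02, ge=0)

    # intensities (raw 16-bit-class scale)
    signal_intensity: float = 5000.0
    secondary_intensity: float = 3000.0
    background: float = Field(default=100.0, ge=0)
    noise_sd: float = Field(default=30.0, ge=0)
    psf_sigma_um: float = Field(default=0.0, ge=0)

    seed: int = 0


class TruthManifest(BaseModel):
    """Generator ground truth: parameters plus derived per-object truth.

    The manifest alone suffices to re-render the scene bit-identically
    (see :func:`render_from_manifest`).
    """

    model_config = ConfigDict(extra="forbid")

    scene_kind: Literal["kinetics2d", "shells3d", "vesicles3d"]
    params: dict
    truth: dict
    seed: int


# ---------------------------------------------------------------------------
# Geometry helpers


def _sample_curve(points: np.ndarray, n: int = 2000) -> np.ndarray:
    """Densely sample a cubic-spline (or linear, for few points) curve
    through the given control points. Returns (n, ndim)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("curve needs >=2 control points")
    k = min(3, len(points) - 1)
    tck, _ = interpolate.splprep(points.T, s=0, k=k)
    u = np.linspace(0, 1, n)
    return np.stack(interpolate.splev(u, tck), axis=1)


def _distance_to_curve(
    shape: Sequence[int], spacing: Sequence[float], curve_pts: np.ndarray
) -> np.ndarray:
    """Physical distance (µm) from each voxel center to the curve.

    The curve is snapped to the voxel grid and the anisotropic exact
    EDT gives the distance map; with the dense sampling used by the
    generators the snapping error is below half a voxel.
    """
    spacing = np.asarray(spacing, dtype=float)
    idx = np.round(curve_pts / spacing).astype(int)
    idx = np.clip(idx, 0, np.asarray(shape) - 1)
    curve_vox = np.zeros(tuple(shape), dtype=bool)
    curve_vox[tuple(idx.T)] = True
    return ndimage.distance_transform_edt(~curve_vox, sampling=spacing)


def _weighted_sample_without_replacement(
    weights: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Gumbel top-k: weighted sampling without replacement, O(N log N)."""
    positive = weights > 0
    if positive.sum() < n:
        raise ValueError("not enough positive-weight candidates")
    keys = np.full(weights.shape, -np.inf)
    keys[positive] = np.log(weights[positive]) + rng.gumbel(size=int(positive.sum()))
    return np.argpartition(-keys, n - 1)[:n]


def _add_noise(
    ideal: np.ndarray, sd: float, rng: np.random.Generator, psf_sigma_vox: float = 0.0
) -> np.ndarray:
    out = ideal.astype(np.float64)
    if psf_sigma_vox > 0:
        out = ndimage.gaussian_filter(out, psf_sigma_vox)
    if sd > 0:
        out = out + rng.normal(0.0, sd, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# 2D kinetics time-lapse


def _default_flagellum(params: Scene2DParams) -> list[tuple[float, float]]:
    cy, cx = params.egg_center or (params.shape[0] / 2, params.shape[1] / 2)
    ay, ax = params.egg_semiaxes_px
    # gentle S-curve spanning the egg long axis, safely inside the ellipse
    ts = np.linspace(-0.75, 0.75, 7)
    return [(cy + 0.45 * ay * math.sin(3.0 * t), cx + ax * t) for t in ts]


def make_timelapse_2d(
    params: Scene2DParams,
) -> tuple[list[ImageStack], TruthManifest]:
    """Render the 2D egg + decaying-MD time-lapse.

    The brightfield channel shows a textured elliptical egg on a darker
    exterior; the MD channel is ``background + I0·exp(−k·t)`` along a
    tube around the flagellum curve, plus Gaussian noise.
    """
    ny, nx = params.shape
    cy, cx = params.egg_center or (ny / 2, nx / 2)
    ay, ax = params.egg_semiaxes_px
    yy, xx = np.mgrid[0:ny, 0:nx]
    egg = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    if not egg.any():
        raise ValueError("degenerate geometry: egg ellipse outside the image")

    ctrl = params.flagellum_points or _default_flagellum(params)
    curve = _sample_curve(np.asarray(ctrl, dtype=float))
    inside = ((curve[:, 0] - cy) / ay) ** 2 + ((curve[:, 1] - cx) / ax) ** 2
    if np.any(inside > 1.0):
        raise ValueError("flagellum curve leaves the egg")
    dist = _distance_to_curve((ny, nx), (1.0, 1.0), curve)
    tube = dist <= params.md_width_px

    rng = np.random.default_rng(params.seed)
    texture = rng.normal(0.0, params.bf_texture_sd, size=(ny, nx))
    bf_ideal = np.where(egg, params.bf_interior + texture, params.bf_exterior)
    bf_ideal = np.clip(bf_ideal, 0.0, None)

    frames: list[ImageStack] = []
    true_means: list[float] = []
    for t in params.frames_h:
        amp = params.i0 * math.exp(-params.decay_rate * t)
        true_means.append(params.background + amp)
        md_ideal = params.background + amp * tube
        bf = _add_noise(bf_ideal, params.noise_sd, rng)
        md = _add_noise(md_ideal, params.noise_sd, rng)
        stack = ImageStack(
            data=np.stack([bf, md]),
            spacing=(params.pixel_size_um, params.pixel_size_um),
            channels=("brightfield", "md"),
            metadata={"time_h_ael": float(t)},
        )
        frames.append(stack)

    manifest = TruthManifest(
        scene_kind="kinetics2d",
        params=params.model_dump(),
        truth={
            "egg_area_px": int(egg.sum()),
            "tube_area_px": int(tube.sum()),
            "true_md_mean_per_frame": true_means,
            "true_decay_rate": params.decay_rate,
        },
        seed=params.seed,
    )
    return frames, manifest


# ---------------------------------------------------------------------------
# 3D axoneme scene


def _default_axoneme(params: Scene3DParams) -> list[tuple[float, float, float]]:
    nz, ny, nx = params.shape
    sz, sy, sx = params.spacing_um
    zc, yc = nz * sz / 2, ny * sy / 2
    length = nx * sx
    ts = np.linspace(0.12, 0.88, 7)
    # gently curved in y, mid-plane in z
    return [
        (zc, yc + 0.12 * ny * sy * math.sin(2.5 * (t - 0.5)), length * t) for t in ts
    ]


def _shell_index(dist_um: np.ndarray | float, width_um: float = 1.0) -> np.ndarray:
    """Half-open-above shells: shell k covers ((k-1)·w, k·w]."""
    return np.ceil(np.asarray(dist_um) / width_um).astype(int)


def make_axoneme_volume_3d(
    params: Scene3DParams,
) -> tuple[ImageStack, TruthManifest]:
    """Render the axoneme + puncta + membrane 3D scene.

    Channels: ``axoneme`` (tube), ``puncta`` (Atg8a-like objects with
    the requested radial density around the axoneme), ``membrane``
    (coaxial tube, partially filled). The manifest records every
    punctum's exact center distance to the axoneme surface and its
    1 µm shell index, and the realized membrane/axoneme voxel counts.
    """
    shape, spacing = params.shape, params.spacing_um
    ctrl = params.axoneme_points or _default_axoneme(params)
    curve = _sample_curve(np.asarray(ctrl, dtype=float), n=4000)
    lo = curve.min(axis=0)
    hi = curve.max(axis=0)
    extent = [n * s for n, s in zip(shape, spacing)]
    if np.any(lo < 0) or np.any(hi > np.asarray(extent)):
        raise ValueError("axoneme curve leaves the volume")

    dist_curve = _distance_to_curve(shape, spacing, curve)
    axoneme = dist_curve <= params.axoneme_radius_um
    if not axoneme.any():
        raise ValueError("degenerate geometry: axoneme tube contains no voxel")

    # exact distance-to-axoneme-surface map (voxel centers, anisotropic)
    dist_ax = ndimage.distance_transform_edt(~axoneme, sampling=spacing)

    rng = np.random.default_rng(params.seed)

    # --- puncta: sample candidate voxel centers by the radial profile
    candidates = (dist_ax > 0) & (dist_ax <= params.max_distance_um)
    cand_idx = np.flatnonzero(candidates.ravel())
    cand_dist = dist_ax.ravel()[cand_idx]
    if params.radial_profile == "uniform":
        weights = np.ones_like(cand_dist)
    elif params.radial_profile == "fixed":
        half_w = 0.25
        weights = (np.abs(cand_dist - params.fixed_distance_um) <= half_w).astype(float)
    else:
        per_shell = np.asarray(params.radial_profile, dtype=float)
        shells = _shell_index(cand_dist) - 1
        weights = np.where(
            shells < len(per_shell), per_shell[np.clip(shells, 0, len(per_shell) - 1)], 0.0
        )
    if params.n_puncta > 0:
        if weights.sum() <= 0:
            raise ValueError("radial profile admits no candidate voxels")
        chosen = _weighted_sample_without_replacement(weights, params.n_puncta, rng)
        centers_flat = cand_idx[np.sort(chosen)]
    else:
        centers_flat = np.empty(0, dtype=int)

    puncta_mask = np.zeros(shape, dtype=bool)
    centers = np.stack(np.unravel_index(centers_flat, shape), axis=1) if len(centers_flat) else np.empty((0, 3), dtype=int)
    puncta_truth = []
    if len(centers):
        puncta_mask[tuple(centers.T)] = True
        if params.punctum_radius_um > 0:
            dist_pts = ndimage.distance_transform_edt(~puncta_mask, sampling=spacing)
            puncta_mask = dist_pts <= params.punctum_radius_um
        for c, flat in zip(centers, centers_flat):
            d = float(dist_ax.ravel()[flat])
            puncta_truth.append(
                {
                    "center_zyx": [int(v) for v in c],
                    "distance_um": d,
                    "shell_index": int(_shell_index(d)),
                }
            )

    # --- membrane: coaxial tube, fraction of arclength segments retained
    mem_tube = (dist_curve > params.axoneme_radius_um) & (
        dist_curve <= params.membrane_radius_um
    )
    if params.membrane_fill_fraction >= 1.0:
        membrane = mem_tube
    elif params.membrane_fill_fraction <= 0.0:
        membrane = np.zeros(shape, dtype=bool)
    else:
        tree = cKDTree(curve)
        idx_vox = np.flatnonzero(mem_tube.ravel())
        coords = np.stack(np.unravel_index(idx_vox, shape), axis=1) * np.asarray(spacing)
        _, nearest = tree.query(coords, workers=1)
        seg = (nearest * params.membrane_segments // len(curve)).astype(int)
        n_keep = int(round(params.membrane_fill_fraction * params.membrane_segments))
        keep_segs = rng.choice(params.membrane_segments, size=n_keep, replace=False)
        keep = np.isin(seg, keep_segs)
        membrane = np.zeros(shape, dtype=bool)
        membrane.ravel()[idx_vox[keep]] = True

    ax_n = int(axoneme.sum())
    mem_n = int(membrane.sum())

    psf_vox = params.psf_sigma_um / np.mean(spacing) if params.psf_sigma_um else 0.0
    chans = []
    for mask in (axoneme, puncta_mask, membrane):
        ideal = params.background + params.signal_intensity * mask
        chans.append(_add_noise(ideal, params.noise_sd, rng, psf_vox))

    stack = ImageStack(
        data=np.stack(chans),
        spacing=spacing,
        channels=("axoneme", "puncta", "membrane"),
    )
    manifest = TruthManifest(
        scene_kind="shells3d",
        params=params.model_dump(),
        truth={
            "axoneme_voxels": ax_n,
            "membrane_voxels": mem_n,
            "true_membrane_axoneme_ratio": mem_n / ax_n,
            "puncta": puncta_truth,
        },
        seed=params.seed,
    )
    return stack, manifest


# ---------------------------------------------------------------------------
# 3D vesicle scene


def make_vesicle_volume_3d(
    params: Scene3DParams,
) -> tuple[ImageStack, TruthManifest]:
    """Render the two-channel vesicle field.

    Vesicles are non-overlapping spheres (including their guard and
    background envelopes), placed on a jittered grid so placement never
    fails when the requested count fits. The primary channel marks all
    vesicles with a radial (center-bright) profile; the secondary
    channel carries the same profile only in true positives, drawn
    Bernoulli(positive_fraction) per vesicle and recorded exactly in
    the manifest.
    """
    shape = params.shape
    spacing = np.asarray(params.spacing_um)
    extent = np.asarray([n * s for n, s in zip(shape, spacing)])
    r_min, r_max = params.vesicle_radius_um
    if r_min > r_max:
        raise ValueError("vesicle radius range inverted")
    cell = 2.0 * (r_max + params.envelope_clearance_um)
    n_cells = np.floor(extent / cell).astype(int)
    total_cells = int(np.prod(n_cells))
    if total_cells < params.n_vesicles:
        raise ValueError(
            f"cannot place {params.n_vesicles} non-overlapping vesicles: "
            f"only {total_cells} grid cells of {cell:.2f} µm fit the volume"
        )
    rng = np.random.default_rng(params.seed)
    chosen_cells = rng.choice(total_cells, size=params.n_vesicles, replace=False)
    cell_idx = np.stack(np.unravel_index(chosen_cells, tuple(n_cells)), axis=1)

    vesicles = []
    for i, ci in enumerate(cell_idx):
        radius = rng.uniform(r_min, r_max)
        margin = radius + params.envelope_clearance_um
        low = ci * cell + margin
        high = (ci + 1) * cell - margin
        center = rng.uniform(low, high)
        positive = bool(rng.random() < params.positive_fraction)
        vesicles.append(
            {"id": i + 1, "center_um": center.tolist(), "radius_um": float(radius),
             "positive": positive}
        )

    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    primary = np.full(shape, params.background, dtype=np.float64)
    secondary = np.full(shape, params.background, dtype=np.float64)
    for v in vesicles:
        c = np.asarray(v["center_um"])
        r = v["radius_um"]
        reach = r + params.envelope_clearance_um  # soft skirt, cell-bounded
        sel = tuple(
            slice(
                max(0, int((c[a] - reach) / spacing[a]) - 1),
                min(shape[a], int((c[a] + reach) / spacing[a]) + 2),
            )
            for a in range(3)
        )
        d2 = sum((grids[a][sel] - c[a]) ** 2 for a in range(3))
        profile = np.exp(-d2 / (2 * (r / 1.5) ** 2))
        primary[sel] += params.signal_intensity * profile
        secondary[sel] += (
            params.secondary_bleed_fraction * params.signal_intensity * profile
        )
        if v["positive"]:
            secondary[sel] += params.secondary_intensity * profile

    psf_vox = params.psf_sigma_um / float(np.mean(spacing)) if params.psf_sigma_um else 0.0
    primary = _add_noise(primary, params.noise_sd, rng, psf_vox)
    secondary = _add_noise(secondary, params.noise_sd, rng, psf_vox)

    stack = ImageStack(
        data=np.stack([primary, secondary]),
        spacing=tuple(spacing),
        channels=("vesicle_primary", "vesicle_secondary"),
    )
    n_pos = sum(v["positive"] for v in vesicles)
    manifest = TruthManifest(
        scene_kind="vesicles3d",
        params=params.model_dump(),
        truth={
            "vesicles": vesicles,
            "n_positive": n_pos,
            "true_positive_fraction": n_pos / len(vesicles) if vesicles else float("nan"),
        },
        seed=params.seed,
    )
    return stack, manifest


# ---------------------------------------------------------------------------
# Re-rendering


def render_from_manifest(manifest: TruthManifest):
    """Re-render a scene from its manifest (bit-identical to the original)."""
    if manifest.scene_kind == "kinetics2d":
        return make_timelapse_2d(Scene2DParams(**manifest.params))
    if manifest.scene_kind == "shells3d":
        return make_axoneme_volume_3d(Scene3DParams(**manifest.params))
    if manifest.scene_kind == "vesicles3d":
        return make_vesicle_volume_3d(Scene3DParams(**manifest.params))
    raise ValueError(f"unknown scene kind {manifest.scene_kind!r}")
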