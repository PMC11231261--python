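"""Study-scale synthetic experiments: cohorts, contrasts, calibrations.

These runners reproduce, on synthetic ground truth, the quantitative
behaviors the pipelines are designed to measure: exponential-decay
recovery on MD kinetics cohorts, vesicle positivity-fraction recovery,
flat-profile behavior of the distance shells under uniform punctum
density, control-vs-knockdown contrasts, and type-I-error calibration of
the statistical tests. Both the test suite and the reproduction script
drive these functions; problem sizes are desk-scale by design.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from skimage.filters import threshold_otsu

from . import synthgen as sg
from .config import AnalysisConfig
from .kinetics2d import fit_decay, quantify_frame
from .segmorph import label_and_filter, largest_component
from .shell3d import compute_shells, membrane_axoneme_ratio, shell_volume_profile
from .stats import rm_anova_two_way, t_test_unpaired
from .vesicle_coloc import colocalize

# cohort scenes: smaller than the generator defaults so a full cohort
# stays in the minutes range on one CPU
KINETICS_SCENE = dict(shape=(128, 176), egg_semiaxes_px=(48.0, 72.0))


def run_kinetics_cohort(
    n_eggs: int,
    decay_rate: float,
    seed: int,
    cfg: AnalysisConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate and quantify a cohort of eggs; returns (nmi matrix, k̂ per egg).

    Egg segmentation uses the Otsu brightfield fallback — the synthetic
    brightfield egg is high-contrast, and the classifier path is
    exercised by its own benchmark.
    """
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(seed)
    times = np.array([0.0, 1.0, 2.0, 3.0])
    nmi_matrix = np.empty((n_eggs, len(times)))
    k_hat = np.empty(n_eggs)
    for i in range(n_eggs):
        params = sg.Scene2DParams(
            decay_rate=decay_rate, seed=int(rng.integers(2**31)), **KINETICS_SCENE
        )
        frames, _ = sg.make_timelapse_2d(params)
        for j, frame in enumerate(frames):
            bf, md = frame.data
            egg = bf > threshold_otsu(bf)
            fm = quantify_frame(
                bf, md, None, cfg, time_h=times[j], egg_mask_override=egg
            )
            nmi_matrix[i, j] = fm.nmi
        k_hat[i] = fit_decay(nmi_matrix[i], times).k
    return nmi_matrix, k_hat


def run_vesicle_fraction_experiment(
    true_fraction: float,
    n_vesicles: int,
    seeds: range,
) -> tuple[list[float], list[float], list[dict]]:
    """Estimated vs manifest-true positive fraction over several seeds.

    Also returns each scene's full colocalization summary (PCC, M1)."""
    estimates, truths, summaries = [], [], []
    cfg = AnalysisConfig()
    for seed in seeds:
        params = sg.Scene3DParams(
            shape=(64, 256, 256),
            n_vesicles=n_vesicles,
            positive_fraction=true_fraction,
            seed=seed,
        )
        stack, manifest = sg.make_vesicle_volume_3d(params)
        primary = stack.channel("vesicle_primary")
        secondary = stack.channel("vesicle_secondary")
        mask = primary > threshold_otsu(primary)
        objs = label_and_filter(
            mask, spacing=stack.spacing, min_volume_um3=cfg.vesicle_min_volume_um3
        )
        summary = colocalize(objs, primary, secondary, cfg)
        estimates.append(summary["positive_fraction"])
        truths.append(manifest.truth["true_positive_fraction"])
        summaries.append(summary)
    return estimates, truths, summaries


def run_flat_shell_experiment(seed: int, n_puncta: int = 10_000) -> dict:
    """Uniform-density punctum scene: measured profile and flatness GOF.

    Under a flat radial density the per-shell punctum count follows the
    shell volumes (multinomial), so normalized shell volume is flat up
    to sampling noise; returns the χ² goodness-of-fit p-value.
    """
    params = sg.Scene3DParams(
        shape=(32, 128, 128), n_puncta=n_puncta, punctum_radius_um=0.0, seed=seed
    )
    stack, manifest = sg.make_axoneme_volume_3d(params)
    ax = largest_component(
                stack.channel("axoneme") > threshold_otsu(stack.channel("axoneme"))
            )
    puncta = stack.channel("puncta") > threshold_otsu(stack.channel("puncta"))
    cfg = AnalysisConfig()
    part = compute_shells(ax, params.spacing_um, cfg.shell_count, cfg.shell_width_um)
    objs = label_and_filter(puncta, spacing=params.spacing_um)
    profile = shell_volume_profile(objs, part)
    counts = profile.signal_volume_um3 / np.prod(params.spacing_um)
    expected = part.shell_voxels / part.shell_voxels.sum() * counts.sum()
    chi2 = float((((counts - expected) ** 2) / expected).sum())
    p = float(sps.chi2.sf(chi2, df=len(counts) - 1))
    return {
        "profile": profile,
        "chi2": chi2,
        "p_flat": p,
        "normalized_cv": float(
            np.std(profile.normalized_volume) / np.mean(profile.normalized_volume)
        ),
    }


def run_shell_knockdown_contrast(seed: int, n_scenes: int = 6) -> dict:
    """Control (flat density) vs knockdown (density halved within 3 µm).

    Returns mean normalized shell-1..3 volume per group and the relative
    drop of the knockdown profile in those shells.
    """
    cfg = AnalysisConfig()
    rng = np.random.default_rng(seed)
    profiles = {"control": [], "knockdown": []}
    for group, weights in (
        ("control", [1.0] * 10),
        ("knockdown", [0.5, 0.5, 0.5] + [1.0] * 7),
    ):
        for _ in range(n_scenes):
            params = sg.Scene3DParams(
                shape=(32, 96, 96),
                n_puncta=800,
                punctum_radius_um=0.0,
                radial_profile=list(weights),
                seed=int(rng.integers(2**31)),
            )
            stack, _ = sg.make_axoneme_volume_3d(params)
            ax = largest_component(
                stack.channel("axoneme") > threshold_otsu(stack.channel("axoneme"))
            )
            puncta = stack.channel("puncta") > threshold_otsu(stack.channel("puncta"))
            part = compute_shells(
                ax, params.spacing_um, cfg.shell_count, cfg.shell_width_um
            )
            objs = label_and_filter(puncta, spacing=params.spacing_um)
            prof = shell_volume_profile(objs, part)
            profiles[group].append(prof.normalized_volume[:3].mean())
    ctrl = np.array(profiles["control"])
    kd = np.array(profiles["knockdown"])
    _, p = t_test_unpaired(ctrl, kd, welch=True)
    return {
        "control_shell123": float(ctrl.mean()),
        "knockdown_shell123": float(kd.mean()),
        "relative_drop": float(1 - kd.mean() / ctrl.mean()),
        "p": float(p),
    }


def run_membrane_contrast(seed: int, n_scenes: int = 10) -> dict:
    """Membrane clearance contrast: cleared (fill 0.2) vs uncleared (0.8)."""
    rng = np.random.default_rng(seed)
    ratios = {}
    for group, fill in (("control", 0.2), ("knockdown", 0.8)):
        vals = []
        for _ in range(n_scenes):
            params = sg.Scene3DParams(
                shape=(32, 96, 96),
                n_puncta=0,
                membrane_fill_fraction=fill,
                seed=int(rng.integers(2**31)),
            )
            stack, _ = sg.make_axoneme_volume_3d(params)
            ax = largest_component(
                stack.channel("axoneme") > threshold_otsu(stack.channel("axoneme"))
            )
            mem_ch = stack.channel("membrane")
            mem = mem_ch > threshold_otsu(mem_ch) if fill > 0 else np.zeros_like(ax)
            objs = label_and_filter(mem, spacing=params.spacing_um)
            vals.append(
                membrane_axoneme_ratio(objs, ax, params.spacing_um)
                if objs.n_objects
                else 0.0
            )
        ratios[group] = np.array(vals)
    _, p = t_test_unpaired(ratios["control"], ratios["knockdown"], welch=True)
    return {
        "control_ratio": float(ratios["control"].mean()),
        "knockdown_ratio": float(ratios["knockdown"].mean()),
        "p": float(p),
    }


def ttest_type1_rate(
    n_sim: int = 10_000, n1: int = 18, n2: int = 22, alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Null rejection rate of the pooled t test over Gaussian simulations."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sim):
        x = rng.standard_normal(n1)
        y = rng.standard_normal(n2)
        _, p = t_test_unpaired(x, y)
        rejections += p < alpha
    return rejections / n_sim


def rm_anova_type1_rate(
    n_sim: int = 10_000, n_per_group: int = 6, n_time: int = 4,
    alpha: float = 0.05, seed: int = 0,
) -> float:
    """Null rejection rate of the split-plot group test."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(["a", "b"], n_per_group)
    rejections = 0
    for _ in range(n_sim):
        data = rng.standard_normal((2 * n_per_group, n_time))
        res = rm_anova_two_way(data, groups)
        rejections += res.p_group < alpha
    return rejections / n_sim
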