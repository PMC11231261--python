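"""Statistical tests attached to the quantifications.

Split-plot (mixed-design) two-way repeated-measures ANOVA for the
kinetics time courses, Šídák and Holm–Šídák multiple-comparison
adjustment, two-sided Fisher's exact test by full hypergeometric
enumeration, and the pooled-variance unpaired Student t test. The
multivariate-t quantiles of Dunnett's test are out of proportion to its
role here; a seeded Monte-Carlo approximation is available, with Šídák
as the documented default substitute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

# ---------------------------------------------------------------------------
# Split-plot repeated-measures ANOVA


@dataclass
class RMAnovaResult:
    """F statistics and p-values of the mixed (split-plot) design.

    Between-subject factor: group (genotype); within-subject factor:
    time; subjects: eggs. ``ss`` holds the sums-of-squares
    decomposition; degenerate (all-identical) data give zero SS and
    F = 0, p = 1.
    """

    f_group: float
    p_group: float
    f_time: float
    p_time: float
    f_interaction: float
    p_interaction: float
    df: dict = field(default_factory=dict)
    ss: dict = field(default_factory=dict)
    degenerate: bool = False


def rm_anova_two_way(data: np.ndarray, groups: np.ndarray) -> RMAnovaResult:
    """Two-way repeated-measures ANOVA on an egg × time matrix.

    ``data[s, i]`` is subject s at time point i (every subject measured
    at every time point — rows with NaN are dropped with a warning-free
    exclusion); ``groups[s]`` labels the between-subject factor.
    Sphericity corrections are not applied.
    """
    data = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    if data.ndim != 2:
        raise ValueError("data must be a subjects × time matrix")
    complete = ~np.isnan(data).any(axis=1)
    data, groups = data[complete], groups[complete]
    n_subj, n_time = data.shape
    labels, g_idx = np.unique(groups, return_inverse=True)
    n_groups = len(labels)
    if n_groups < 2:
        raise ValueError("need >=2 groups")
    if n_time < 2:
        raise ValueError("need >=2 time points")

    gm = data.mean()
    subj_means = data.mean(axis=1)
    time_means = data.mean(axis=0)
    group_sizes = np.bincount(g_idx)
    group_means = np.array([data[g_idx == j].mean() for j in range(n_groups)])
    cell_means = np.array(
        [data[g_idx == j].mean(axis=0) for j in range(n_groups)]
    )  # (g, t)

    ss_total = float(((data - gm) ** 2).sum())
    ss_between_subj = float(n_time * ((subj_means - gm) ** 2).sum())
    ss_group = float(n_time * (group_sizes * (group_means - gm) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group
    ss_time = float(n_subj * ((time_means - gm) ** 2).sum())
    ss_cells = float(
        (group_sizes[:, None] * (cell_means - gm) ** 2).sum()
    )
    ss_interaction = ss_cells - ss_group - ss_time
    ss_error = ss_total - ss_between_subj - ss_time - ss_interaction

    df_group = n_groups - 1
    df_subj = n_subj - n_groups
    df_time = n_time - 1
    df_inter = df_group * df_time
    df_error = df_subj * df_time

    if ss_total == 0.0:
        return RMAnovaResult(
            f_group=0.0, p_group=1.0, f_time=0.0, p_time=1.0,
            f_interaction=0.0, p_interaction=1.0,
            df={"group": (df_group, df_subj), "time": (df_time, df_error),
                "interaction": (df_inter, df_error)},
            ss={"total": 0.0}, degenerate=True,
        )

    def f_and_p(ss_num, df_num, ss_den, df_den):
        if ss_den <= 0 or df_den <= 0:
            return float("nan"), float("nan")
        f = (ss_num / df_num) / (ss_den / df_den)
        f = max(f, 0.0)
        return float(f), float(sps.f.sf(f, df_num, df_den))

    f_g, p_g = f_and_p(ss_group, df_group, ss_subj_within, df_subj)
    f_t, p_t = f_and_p(ss_time, df_time, ss_error, df_error)
    f_i, p_i = f_and_p(ss_interaction, df_inter, ss_error, df_error)

    return RMAnovaResult(
        f_group=f_g, p_group=p_g,
        f_time=f_t, p_time=p_t,
        f_interaction=f_i, p_interaction=p_i,
        df={"group": (df_group, df_subj), "time": (df_time, df_error),
            "interaction": (df_inter, df_error)},
        ss={
            "total": ss_total,
            "group": ss_group,
            "subjects_within_groups": ss_subj_within,
            "time": ss_time,
            "interaction": ss_interaction,
            "error": ss_error,
        },
    )


# ---------------------------------------------------------------------------
# Multiple-comparison adjustments


def sidak_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Šídák adjustment: p_adj = 1 − (1 − p)^m, clipped to 1."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


def holm_sidak_adjust(p: np.ndarray) -> np.ndarray:
    """Step-down Holm–Šídák adjustment.

    Sort ascending; p_adj(i) = max_{j<=i} [1 − (1 − p(j))^(m−j+1)]
    (1-based), then restore the input order.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        step = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, step)
        adj_sorted[rank] = running
    out = np.empty(m)
    out[order] = np.minimum(1.0, adj_sorted)
    return out


def dunnett_monte_carlo(
    p_t_stats: np.ndarray, df: int, n_comparisons: int, n_sim: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo approximation of Dunnett-style many-to-one adjustment.

    Adjusted p for each observed |t| is the simulated probability that
    the maximum of ``n_comparisons`` correlated (ρ = 0.5) t variates
    with ``df`` degrees of freedom exceeds it.
    """
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_sim)
    z = rng.standard_normal((n_sim, n_comparisons))
    chi = np.sqrt(rng.chisquare(df, n_sim) / df)
    t_sim = ((z0[:, None] + z) / np.sqrt(2.0)) / chi[:, None]
    max_abs = np.abs(t_sim).max(axis=1)
    t_obs = np.abs(np.asarray(p_t_stats, dtype=float))
    return np.array([(max_abs >= t).mean() for t in t_obs])


# ---------------------------------------------------------------------------
# Exact and t tests


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p by full hypergeometric enumeration.

    Sums the probabilities of every table with the observed margins
    whose hypergeometric probability does not exceed the observed
    table's (with a tiny relative tolerance against floating-point
    ties, as is conventional).
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must be 2x2 non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise ValueError("zero margin")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    include = pmf <= p_obs * (1 + 1e-7)
    if include.all():
        return 1.0
    return float(min(1.0, pmf[include].sum()))


def t_test_unpaired(
    x: np.ndarray, y: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Two-tailed unpaired t test; pooled-variance Student by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >=2 observations per sample")
    if not welch and np.var(x, ddof=1) + np.var(y, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)
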