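"""Group statistics and relative-expression computation.

The decision tree mirrors classical neuropathology practice: normality of
each group is assessed with a Kolmogorov-Smirnov test (Lilliefors-style,
with estimated mean/SD and a parametric-bootstrap null); normally
distributed data are compared with a two-tailed t test (two groups) or
ANOVA followed by Tukey's test (more than two), non-normal data with the
Mann-Whitney U test (two groups) or Kruskal-Wallis followed by Dunn's
post-hoc test.  All tests are two-sided with alpha = 0.05.  Correlations
use the tie-corrected Kendall tau-b.  Relative qPCR expression is
computed with the comparative double-delta-Ct method (2^-ddCt) against a
housekeeper gene and a reference group.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtr

from .errors import InputError, ParameterError

__all__ = [
    "GroupComparison",
    "ks_normality",
    "mann_whitney",
    "kruskal_dunn",
    "anova_tukey",
    "compare_groups",
    "kendall_tau_b",
    "ddct_fold",
    "plot_groups",
]

#: Largest combined sample size for which the Mann-Whitney U null
#: distribution is enumerated exactly (C(12, 6) = 924 labelings).
EXACT_MW_LIMIT = 12

#: Largest n for which the Kendall tau-b permutation null is enumerated.
EXACT_TAU_LIMIT = 8


@dataclass
class GroupComparison:
    """Outcome of the group-comparison decision tree.

    ``pairwise`` is a DataFrame (group_i, group_j, p_adj) for omnibus
    methods (Kruskal-Wallis + Dunn, ANOVA + Tukey) and ``None`` for
    two-group tests.  ``normality_p`` records the per-group KS normality
    p-values that steered the branch choice.
    """

    method: str  # mann_whitney | kruskal_dunn | anova_tukey | t_test
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None
    normality_p: dict[str, float]


# ---------------------------------------------------------------------------
# normality


def _lilliefors_D(samples: np.ndarray) -> np.ndarray:
    """Row-wise KS distance to a normal with the row's own mean/SD."""
    m = np.atleast_2d(samples).astype(float)
    n = m.shape[1]
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((m - mu) / sd, axis=1)
    cdf = ndtr(z)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=1)
    d_minus = (cdf - (i - 1) / n).max(axis=1)
    return np.maximum(d_plus, d_minus)


def ks_normality(
    values,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> float:
    """One-sample KS test of normality with estimated parameters.

    Because mean and SD are estimated from the sample, the textbook KS
    null is wrong (anti-conservative); the null distribution of the
    statistic is instead simulated by a seeded parametric bootstrap
    (``n_boot`` resamples, each re-standardised by its own estimates).
    Returns the bootstrap p-value ``(1 + #{D* >= D}) / (n_boot + 1)``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise InputError("need a 1-D sample with n >= 3")
    if not np.all(np.isfinite(x)):
        raise InputError("values must be finite")
    if np.std(x, ddof=1) == 0:
        raise InputError("zero-variance sample: normality test undefined")
    if rng is None:
        rng = np.random.default_rng(0)
    d_obs = float(_lilliefors_D(x[None, :])[0])
    sims = rng.standard_normal((n_boot, len(x)))
    d_null = _lilliefors_D(sims)
    return float((1 + np.sum(d_null >= d_obs)) / (n_boot + 1))


# ---------------------------------------------------------------------------
# Mann-Whitney


def _u_statistic(ranks_x_sum: float, n1: int) -> float:
    return ranks_x_sum - n1 * (n1 + 1) / 2.0


def mann_whitney(x, y, exact_limit: int = EXACT_MW_LIMIT) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p).

    For combined n <= ``exact_limit`` the permutation null of U is
    enumerated exhaustively over all C(n1+n2, n1) group labelings of the
    pooled midranks (ties handled naturally); otherwise the normal
    approximation with tie correction and continuity correction is used.
    U is reported for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise InputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n1].sum(), n1)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_limit:
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = _u_statistic(ranks[list(idx)].sum(), n1)
            total += 1
            if abs(u - mu) >= dev_obs - 1e-9:
                count += 1
        return float(u_obs), count / total

    # normal approximation with tie correction
    n = n1 + n2
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(t_counts**3 - t_counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return float(u_obs), 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    p = 2.0 * (1.0 - ndtr(max(z, 0.0)))
    return float(u_obs), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# omnibus tests with post hocs


def kruskal_dunn(
    groups: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis H test with Dunn's pairwise post-hoc comparisons.

    Dunn's z uses the pooled-rank means with tie correction; adjusted
    pairwise p-values use Bonferroni by default (``adjust`` may be
    ``"bonferroni"``, ``"holm"`` or ``"none"``), so adjusted p-values are
    never smaller than the unadjusted ones and never exceed 1.
    """
    names = list(groups)
    vals = [np.asarray(groups[g], dtype=float) for g in names]
    h, p = sps.kruskal(*vals)
    pooled = np.concatenate(vals)
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(t_counts**3 - t_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    mean_ranks = {}
    start = 0
    for g, v in zip(names, vals):
        mean_ranks[g] = ranks[start : start + len(v)].mean()
        start += len(v)

    pairs = list(itertools.combinations(names, 2))
    raw = []
    for gi, gj in pairs:
        se = math.sqrt(var_base * (1.0 / len(groups[gi]) + 1.0 / len(groups[gj])))
        z = abs(mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else 0.0
        raw.append(2.0 * (1.0 - ndtr(z)))
    raw = np.asarray(raw)
    m = len(pairs)
    if adjust == "bonferroni":
        adj = np.minimum(1.0, raw * m)
    elif adjust == "holm":
        order = np.argsort(raw)
        adj = np.empty_like(raw)
        running = 0.0
        for rank, k in enumerate(order):
            running = max(running, raw[k] * (m - rank))
            adj[k] = min(1.0, running)
    elif adjust == "none":
        adj = raw
    else:
        raise ParameterError(f"unknown adjustment {adjust!r}")
    pairwise = pd.DataFrame(
        {
            "group_i": [a for a, _ in pairs],
            "group_j": [b for _, b in pairs],
            "p_adj": adj,
        }
    )
    return float(h), float(p), pairwise


def anova_tukey(groups: dict[str, np.ndarray]) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA with Tukey's HSD pairwise comparisons."""
    names = list(groups)
    vals = [np.asarray(groups[g], dtype=float) for g in names]
    f, p = sps.f_oneway(*vals)
    res = sps.tukey_hsd(*vals)
    pairs = list(itertools.combinations(range(len(names)), 2))
    pairwise = pd.DataFrame(
        {
            "group_i": [names[i] for i, _ in pairs],
            "group_j": [names[j] for _, j in pairs],
            "p_adj": [float(res.pvalue[i, j]) for i, j in pairs],
        }
    )
    return float(f), float(p), pairwise


# ---------------------------------------------------------------------------
# the decision tree


def _extract_groups(table, variable: str | None) -> dict[str, np.ndarray]:
    if isinstance(table, dict):
        return {str(k): np.asarray(v, dtype=float) for k, v in table.items()}
    df = table
    if variable is not None and "variable" in df.columns:
        df = df[df["variable"] == variable]
    if df.empty:
        raise InputError(f"no rows for variable {variable!r}")
    if df["group"].isna().any():
        raise InputError("missing group labels")
    return {
        str(g): sub["value"].to_numpy(dtype=float) for g, sub in df.groupby("group", sort=True)
    }


def compare_groups(
    table,
    variable: str | None = None,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    force: str | None = None,
    dunn_adjust: str = "bonferroni",
    n_boot: int = 2000,
) -> GroupComparison:
    """Compare labelled measurement groups with the standard decision tree.

    ``table`` is either a tidy DataFrame with columns ``group`` /
    ``value`` (optionally filtered by ``variable``) or a mapping of
    group name to values.  Each group's normality is assessed with the
    seeded KS bootstrap; the parametric branch (t test / ANOVA + Tukey)
    is taken iff every group passes at ``alpha``, otherwise the
    nonparametric branch (Mann-Whitney / Kruskal-Wallis + Dunn).
    ``force`` overrides the gate with ``"parametric"`` or
    ``"nonparametric"``.
    """
    groups = _extract_groups(table, variable)
    if len(groups) < 2:
        raise InputError("need at least two groups")
    for g, v in groups.items():
        if len(v) < 3:
            raise InputError(f"group {g!r} has fewer than 3 values")
        if not np.all(np.isfinite(v)):
            raise InputError(f"group {g!r} contains non-finite values")
    if rng is None:
        rng = np.random.default_rng(0)

    normality_p = {g: ks_normality(v, n_boot=n_boot, rng=rng) for g, v in groups.items()}
    if force == "parametric":
        parametric = True
    elif force == "nonparametric":
        parametric = False
    elif force is None:
        parametric = all(p > alpha for p in normality_p.values())
    else:
        raise ParameterError(f"unknown force value {force!r}")

    names = list(groups)
    if len(groups) == 2:
        a, b = (groups[n] for n in names)
        if parametric:
            t, p = sps.ttest_ind(a, b)
            return GroupComparison("t_test", float(t), float(p), None, normality_p)
        u, p = mann_whitney(a, b)
        return GroupComparison("mann_whitney", u, p, None, normality_p)
    if parametric:
        f, p, pairwise = anova_tukey(groups)
        return GroupComparison("anova_tukey", f, p, pairwise, normality_p)
    h, p, pairwise = kruskal_dunn(groups, adjust=dunn_adjust)
    return GroupComparison("kruskal_dunn", h, p, pairwise, normality_p)


# ---------------------------------------------------------------------------
# Kendall tau-b


def _tau_b_stat(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    s = float(np.sum(dx[iu] * dy[iu]))
    n0 = n * (n - 1) / 2.0
    tx = sum(t * (t - 1) / 2.0 for t in np.unique(x, return_counts=True)[1])
    ty = sum(t * (t - 1) / 2.0 for t in np.unique(y, return_counts=True)[1])
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return s / denom


def kendall_tau_b(x, y, exact_limit: int = EXACT_TAU_LIMIT) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b with a two-sided p-value.

    For n <= ``exact_limit`` the p-value is computed by exhaustive
    enumeration of all n! pairings (permutation null of tau-b, valid
    with ties); for larger n the normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InputError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise InputError("need at least 3 pairs")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise InputError("all-tied input: correlation undefined")

    tau = _tau_b_stat(x, y)
    if n <= exact_limit:
        iu = np.triu_indices(n, k=1)
        dx = np.sign(x[:, None] - x[None, :])[iu]
        n0 = n * (n - 1) / 2.0
        tx = sum(t * (t - 1) / 2.0 for t in np.unique(x, return_counts=True)[1])
        ty = sum(t * (t - 1) / 2.0 for t in np.unique(y, return_counts=True)[1])
        denom = math.sqrt((n0 - tx) * (n0 - ty))
        perms = np.array(list(itertools.permutations(y)))
        dyp = np.sign(perms[:, :, None] - perms[:, None, :])[:, iu[0], iu[1]]
        taus = (dyp @ dx) / denom
        p = float(np.mean(np.abs(taus) >= abs(tau) - 1e-12))
        return float(tau), p
    res = sps.kendalltau(x, y, variant="b", method="asymptotic")
    return float(tau), float(res.pvalue)


# ---------------------------------------------------------------------------
# rendering (cosmetic)


def plot_groups(
    table, variable: str | None = None, comparison: GroupComparison | None = None, ax=None
):
    """Box-plot of labelled groups with jittered points (cosmetic only).

    Mirrors the usual per-individual dot/box presentation of morphometry
    panels; annotates the omnibus p-value when a comparison is supplied.
    Returns the matplotlib Axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    groups = _extract_groups(table, variable)
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(groups) + 1.5, 3.2))
    names = list(groups)
    data = [groups[g] for g in names]
    ax.boxplot(data, tick_labels=names, showfliers=False)
    rng = np.random.default_rng(0)
    for i, v in enumerate(data, start=1):
        ax.plot(i + rng.uniform(-0.08, 0.08, len(v)), v, "o", ms=3, alpha=0.6)
    if variable:
        ax.set_ylabel(variable)
    if comparison is not None:
        ax.set_title(f"{comparison.method}: p = {comparison.p_value:.3g}", fontsize=9)
    return ax


# ---------------------------------------------------------------------------
# relative expression (double-delta Ct)


def ddct_fold(records: pd.DataFrame, reference_group: str) -> pd.DataFrame:
    """Comparative double-delta-Ct relative expression (fold = 2^-ddCt).

    ``records`` needs columns ``sample_id, group, Ct_target,
    Ct_housekeeper`` and optionally ``gene`` (computed per gene).
    ``delta_Ct = Ct_target - Ct_housekeeper`` is the housekeeper-
    normalised expression; ``delta_delta_Ct`` references it to the
    arithmetic-mean delta-Ct of ``reference_group``, so the reference
    group's geometric-mean fold is exactly 1.
    """
    df = records.copy()
    required = {"sample_id", "group", "Ct_target", "Ct_housekeeper"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"missing columns: {sorted(missing)}")
    if df["Ct_housekeeper"].isna().any():
        raise InputError("housekeeper Ct missing for some samples")
    if reference_group not in set(df["group"]):
        raise InputError(f"reference group {reference_group!r} absent")
    df["delta_Ct"] = df["Ct_target"] - df["Ct_housekeeper"]

    gene_col = "gene" if "gene" in df.columns else None
    if gene_col:
        ref_means = (
            df[df["group"] == reference_group].groupby(gene_col)["delta_Ct"].mean()
        )
        if set(df[gene_col]) - set(ref_means.index):
            raise InputError("reference group absent for some genes")
        df["delta_delta_Ct"] = df["delta_Ct"] - df[gene_col].map(ref_means)
    else:
        ref_mean = df.loc[df["group"] == reference_group, "delta_Ct"].mean()
        df["delta_delta_Ct"] = df["delta_Ct"] - ref_mean
    df["fold"] = 2.0 ** (-df["delta_delta_Ct"])
    return df
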