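"""Efficacy statistics: uptake-ratio comparisons and GAG time-course tests.

Uptake of drug conjugated to a polymer is compared against the reference
DEX-P formulation as a ratio of arm means at matched exposure time, with a
one-tailed Welch t-test in the observed direction (the study design allows
both enhanced and suppressed uptake; reporting the tested direction keeps
the convention explicit, at the cost of doubling the effective null
rejection rate relative to a fixed one-sided test).

GAG trajectories are summarized as the cumulative percent variation from
day 0 per sample, then compared across treatment groups by one-way ANOVA
with Tukey's HSD post hoc at family level α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .studentized_range import srange_ppf, srange_sf

__all__ = [
    "UptakeRatioResult",
    "uptake_ratio",
    "uptake_ratios_from_table",
    "gag_cumulative_variation",
    "gag_group_summary",
    "AnovaResult",
    "one_way_anova",
    "TukeyResult",
    "tukey_hsd",
    "flag_significant_uptake",
    "benjamini_hochberg",
]

_TINY_P = 5e-324  # smallest subnormal float; keeps p > 0 for degenerate arms


@dataclass
class UptakeRatioResult:
    """Conjugate/reference uptake comparison at one exposure time."""

    ratio: float
    ci95: tuple[float, float]
    p_one_tailed: float
    direction: str  # "greater" | "less"
    n_conjugate: int
    n_reference: int


def uptake_ratio(
    conjugate,
    reference,
    alpha: float = 0.05,
    pooled: bool = False,
) -> UptakeRatioResult:
    """Ratio of arm means with delta-method CI and observed-direction t-test.

    The 95% CI comes from the delta method on log(ratio):
    Var(log r) ≈ s_c²/(n_c m_c²) + s_r²/(n_r m_r²).  The one-tailed p is a
    Welch t-test (``pooled=True`` switches to the equal-variance test) with
    the alternative set to the observed direction of the difference; equal
    means give p = 0.5 by the one-sided convention.
    """
    c = np.asarray(conjugate, dtype=float)
    r = np.asarray(reference, dtype=float)
    if c.size < 2 or r.size < 2:
        raise ValueError("need at least 2 replicates per arm")
    mc, mr = c.mean(), r.mean()
    if mr == 0:
        raise ValueError("reference arm mean is zero; ratio undefined")
    ratio = mc / mr
    var_log = c.var(ddof=1) / (c.size * mc**2) + r.var(ddof=1) / (r.size * mr**2)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var_log)
    ci = (ratio * np.exp(-half), ratio * np.exp(half))

    direction = "greater" if mc > mr else "less"
    if c.var(ddof=1) == 0 and r.var(ddof=1) == 0:
        p = 0.5 if mc == mr else _TINY_P
    else:
        res = stats.ttest_ind(c, r, equal_var=pooled, alternative=direction)
        p = float(res.pvalue)
        if not p > 0:
            p = _TINY_P
    return UptakeRatioResult(
        ratio=float(ratio), ci95=ci, p_one_tailed=p, direction=direction,
        n_conjugate=int(c.size), n_reference=int(r.size),
    )


def uptake_ratios_from_table(measurements: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Compare every (polymer, endcap, time) conjugate arm to the reference arm.

    ``measurements`` is the tidy table produced by
    :func:`pbaekit.simulate.simulate_uptake_experiment` (columns polymer_id,
    endcap, arm, time_min, replicate, uptake_ug_per_mg).
    """
    ref = measurements[measurements["arm"] == "reference"]
    conj = measurements[measurements["arm"] == "conjugate"]
    rows = []
    for (pid, endcap, t), g in conj.groupby(
        ["polymer_id", "endcap", "time_min"], sort=True
    ):
        ref_vals = ref.loc[ref["time_min"] == t, "uptake_ug_per_mg"]
        res = uptake_ratio(g["uptake_ug_per_mg"], ref_vals, alpha=alpha)
        rows.append(
            {
                "polymer_id": pid, "endcap": endcap, "time_min": t,
                "ratio": res.ratio, "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                "p_one_tailed": res.p_one_tailed, "direction": res.direction,
            }
        )
    return pd.DataFrame(rows)


def gag_cumulative_variation(timecourses: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cumulative GAG variation Δ%(t) = 100·(GAG(t) − GAG(0))/GAG(0).

    Input is tidy (group, sample_id, day, gag_ug); every sample must have a
    positive day-0 measurement.  Returns the same shape with a
    ``gag_variation_pct`` column.
    """
    required = {"group", "sample_id", "day", "gag_ug"}
    missing = required - set(timecourses.columns)
    if missing:
        raise ValueError(f"timecourse table missing columns: {sorted(missing)}")
    out = []
    for (group, sid), g in timecourses.groupby(["group", "sample_id"], sort=True):
        base = g.loc[g["day"] == 0, "gag_ug"]
        if base.empty:
            raise ValueError(f"sample {sid!r} in group {group!r} lacks a day-0 value")
        g0 = float(base.iloc[0])
        if g0 <= 0:
            raise ValueError(f"sample {sid!r} in group {group!r} has non-positive day-0 GAG")
        gg = g.copy()
        gg["gag_variation_pct"] = 100.0 * (gg["gag_ug"] - g0) / g0
        out.append(gg)
    return pd.concat(out, ignore_index=True)


def gag_group_summary(variation: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Mean ± t-based CI of cumulative GAG variation per group and day."""
    rows = []
    for (group, day), g in variation.groupby(["group", "day"], sort=True):
        v = g["gag_variation_pct"].to_numpy()
        mean = v.mean()
        if v.size > 1 and v.std(ddof=1) > 0:
            half = stats.t.ppf(1 - alpha / 2, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
        else:
            half = 0.0
        rows.append(
            {
                "group": group, "day": day, "mean_pct": mean,
                "ci_low": mean - half, "ci_high": mean + half, "n": v.size,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def one_way_anova(groups: dict[str, np.ndarray]) -> AnovaResult:
    """Standard one-way fixed-effects ANOVA across labelled groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = []
    for label, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
        arrays.append(v)
    F, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    return AnovaResult(F=float(F), df_between=k - 1, df_within=n - k, p=float(p))


@dataclass
class TukeyResult:
    comparisons: pd.DataFrame  # group_a, group_b, mean_diff, p_adj, ci_low, ci_high


def tukey_hsd(groups: dict[str, np.ndarray], alpha: float = 0.05) -> TukeyResult:
    """Tukey's HSD: all pairwise comparisons via the studentized range.

    The Tukey–Kramer statistic q_ij = |m_i − m_j| / √(MSW/2 · (1/n_i + 1/n_j))
    is referred to the studentized range distribution for k groups and the
    within-group degrees of freedom (evaluated by numerical integration in
    :mod:`pbaekit.studentized_range`).  Adjusted p-values and simultaneous
    CIs are at family level ``alpha``.  With exactly two groups the procedure
    reduces to the pooled two-sided t-test (q = √2·|t|).
    """
    labels = sorted(groups)
    arrays = [np.asarray(groups[l], dtype=float) for l in labels]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    sizes = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    df_within = int(sizes.sum() - k)
    msw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays) / df_within
    if msw == 0:
        msw = np.finfo(float).tiny  # all groups constant: q -> inf unless equal
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    se = np.array(
        [np.sqrt(msw / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j])) for i, j in pairs]
    )
    diffs = np.array([means[i] - means[j] for i, j in pairs])
    qstat = np.abs(diffs) / se
    pvals = np.atleast_1d(srange_sf(qstat, k, df_within))
    qcrit = srange_ppf(1.0 - alpha, k, df_within)
    rows = [
        {
            "group_a": labels[i], "group_b": labels[j],
            "mean_diff": float(diffs[m]),
            "p_adj": float(min(pvals[m], 1.0)),
            "ci_low": float(diffs[m] - qcrit * se[m]),
            "ci_high": float(diffs[m] + qcrit * se[m]),
        }
        for m, (i, j) in enumerate(pairs)
    ]
    return TukeyResult(comparisons=pd.DataFrame(rows))


def flag_significant_uptake(
    results: pd.DataFrame, alpha: float = 0.05, adjust: bool = False
) -> pd.DataFrame:
    """Mark polymer/time comparisons with p below ``alpha``.

    ``results`` is the output of :func:`uptake_ratios_from_table`.  Multiple
    testing across the library is not adjusted by default; ``adjust=True``
    applies Benjamini–Hochberg to the one-tailed p-values.
    """
    if results.empty:
        return results.assign(significant=pd.Series(dtype=bool))
    out = results.copy()
    p = out["p_one_tailed"].to_numpy()
    if adjust:
        out["p_adjusted"] = benjamini_hochberg(p)
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = p < alpha
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
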