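"""The statistical layer of the longitudinal study.

Matches the analysis plan of the emulated protocol: a two-way ANOVA
(group x day) for caliper data, a linear mixed-effects model (random
intercept per animal, REML) for the in vivo µCT measures, a one-way ANOVA
for terminal ex vivo BV, Kruskal-Wallis with Dunn's multiple-comparison
tests (each treatment group against the untreated control) for ordinal
histopathology scores, an OLS agreement regression of in vivo on ex vivo
BV, and simple cumulative-dose accounting.

Conventions chosen where the protocol is silent:

* Caliper data are analysed as change from baseline (day 0) by default;
  µCT measures on the raw scale.
* Per-day group contrasts are each treatment group versus the untreated
  reference, Bonferroni-adjusted over the comparisons performed.
* Mixed-model contrasts use a Wald t with ``df = n_animals - n_groups``
  (the between-animal degrees of freedom that govern a single-day
  between-group contrast under a random-intercept model).
* Kruskal-Wallis uses midranks with the standard tie-correction factor —
  ordinal 0-4 scores are heavily tied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, RangeError, SingularFitError

__all__ = [
    "RegressionResult",
    "GroupTestResult",
    "fit_agreement_regression",
    "compare_groups_longitudinal",
    "compare_groups_terminal",
    "ordinal_group_test",
    "kruskal_wallis_h",
    "dunn_z",
    "cumulative_dose",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS agreement fit: response = slope * predictor + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_pairs: int
    residual_sd: float


@dataclass(frozen=True)
class GroupTestResult:
    """One statistical contrast (or omnibus test) with its context."""

    test_name: str
    statistic: float
    p_value: float
    contrast: str
    group_stats: dict = field(default_factory=dict)  # group -> (mean, sd, n)
    adjustment: str = "none"
    p_adjusted: float | None = None
    df: float | None = None
    pairwise: tuple = ()


def fit_agreement_regression(pairs) -> RegressionResult:
    """OLS of in vivo BV (response) on ex vivo BV (predictor).

    ``pairs`` is a sequence of (ex_vivo, in_vivo) tuples or an equivalent
    (n, 2) array / DataFrame with columns ``ex_vivo_bv_mm3`` /
    ``in_vivo_bv_mm3``.
    """
    if isinstance(pairs, pd.DataFrame):
        x = pairs["ex_vivo_bv_mm3"].to_numpy(dtype=float)
        y = pairs["in_vivo_bv_mm3"].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise RangeError("pairs must be (n, 2): columns (ex_vivo, in_vivo)")
        x, y = arr[:, 0], arr[:, 1]
    n = x.size
    if n < 3:
        raise DesignError(f"need >= 3 pairs for the agreement regression, got {n}")
    if np.ptp(x) == 0:
        raise SingularFitError("all ex vivo values identical; regression is singular")

    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ssr = float((resid**2).sum())
    sst = float(((y - ym) ** 2).sum())
    r2 = 1.0 if sst == 0 else min(1.0, max(0.0, 1.0 - ssr / sst))
    residual_sd = float(np.sqrt(ssr / (n - 2)))
    return RegressionResult(float(slope), float(intercept), r2, int(n), residual_sd)


# ---------------------------------------------------------------------------
# longitudinal group contrasts
# ---------------------------------------------------------------------------


def _group_stats(df: pd.DataFrame) -> dict:
    out = {}
    for g, sub in df.groupby("group", observed=True):
        v = sub["value"].to_numpy(dtype=float)
        out[str(g)] = (float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0, int(v.size))
    return out


def _t_pvalue(est: float, se: float, df: float) -> tuple[float, float]:
    """(statistic, p) for a Wald t contrast, robust to a zero-variance fit."""
    if se <= 0 or not np.isfinite(se):
        if abs(est) < 1e-12:
            return 0.0, 1.0
        return float(np.inf), 0.0
    t = est / se
    return float(t), float(2.0 * sps.t.sf(abs(t), df))


def _prepare_longitudinal(table, measure, change_from_baseline):
    t = table.loc[table["measure"] == measure, ["animal_id", "group", "day", "value"]]
    if t.empty:
        raise DesignError(f"no rows for measure {measure!r}")
    t = t.copy()
    if change_from_baseline:
        base_day = int(t["day"].min())
        base = t[t["day"] == base_day].set_index("animal_id")["value"]
        t = t[t["day"] != base_day].copy()
        missing = set(t["animal_id"]) - set(base.index)
        if missing:
            raise DesignError(f"animals without baseline: {sorted(missing)[:5]}")
        t["value"] = t["value"].to_numpy() - base.loc[t["animal_id"]].to_numpy()
    groups = sorted(t["group"].unique())
    days = sorted(t["day"].unique())
    if len(groups) < 2:
        raise DesignError(f"need >= 2 groups for {measure!r}, found {groups}")
    if len(days) < 2:
        raise DesignError(f"need >= 2 days for {measure!r}, found {days}")
    counts = t.groupby(["group", "day"], observed=True).size()
    for g in groups:
        for d in days:
            if (g, d) not in counts.index or counts.loc[(g, d)] == 0:
                raise DesignError(f"design cell empty: group {g!r} at day {d}")
    return t, groups, days


def _resolve_reference(groups, reference):
    if reference in groups:
        return reference
    return groups[0]


def compare_groups_longitudinal(
    table: pd.DataFrame,
    measure: str,
    method: str = "mixed_effects",
    reference: str = "untreated",
    change_from_baseline: bool | None = None,
    adjustment: str = "bonferroni",
) -> list[GroupTestResult]:
    """Per-day group contrasts from a group x day longitudinal model.

    ``two_way_anova`` fits fixed effects group, day and group x day by
    OLS; ``mixed_effects`` fits the same cell means with a random
    intercept per animal by REML.  Contrasts are each non-reference group
    versus ``reference`` at each day, Bonferroni-adjusted.  For the
    caliper measure the response defaults to change from baseline.
    """
    if method not in ("two_way_anova", "mixed_effects"):
        raise RangeError(f"unknown method {method!r}")
    if change_from_baseline is None:
        change_from_baseline = measure == "caliper_mm"
    t, groups, days = _prepare_longitudinal(table, measure, change_from_baseline)
    ref = _resolve_reference(groups, reference)

    cell_stats = {
        (str(g), int(d)): (
            float(sub["value"].mean()),
            float(sub["value"].std(ddof=1)) if len(sub) > 1 else 0.0,
            int(len(sub)),
        )
        for (g, d), sub in t.groupby(["group", "day"], observed=True)
    }

    results: list[GroupTestResult] = []
    contrasts = [(d, g) for d in days for g in groups if g != ref]
    m = len(contrasts)

    if method == "two_way_anova":
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        data = t.assign(group=t["group"].astype(str), day=t["day"].astype(str))
        model = smf.ols("value ~ C(group) * C(day)", data=data).fit()
        resid_df = float(model.df_resid)
        mse = float(model.mse_resid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                tab = sm.stats.anova_lm(model, typ=2)
                inter = tab.loc["C(group):C(day)"]
                omni_f, omni_p = float(inter["F"]), float(inter["PR(>F)"])
            except Exception:
                omni_f, omni_p = float("nan"), float("nan")
        if not np.isfinite(omni_p):  # zero-residual degenerate fit
            omni_f, omni_p = float("inf"), 0.0
        results.append(
            GroupTestResult(
                test_name="two_way_anova",
                statistic=omni_f,
                p_value=omni_p,
                contrast="group x day interaction",
                group_stats=_group_stats(t),
                df=resid_df,
            )
        )

        def cell_contrast(g, d):
            m1, _, n1 = cell_stats[(g, d)]
            m2, _, n2 = cell_stats[(ref, d)]
            est = m1 - m2
            se = np.sqrt(mse * (1.0 / n1 + 1.0 / n2))
            return est, se, resid_df

    else:  # mixed_effects
        est_se_df = _mixed_cell_contrasts(t, groups, days)

        def cell_contrast(g, d):
            return est_se_df(g, d, ref)

    for d, g in contrasts:
        est, se, df = cell_contrast(g, d)
        stat, p = _t_pvalue(est, se, df)
        results.append(
            GroupTestResult(
                test_name=method,
                statistic=stat,
                p_value=p,
                contrast=f"{g} vs {ref} at day {d}",
                group_stats={
                    g: cell_stats[(g, d)],
                    ref: cell_stats[(ref, d)],
                },
                adjustment=adjustment,
                p_adjusted=min(1.0, p * m) if adjustment == "bonferroni" else p,
                df=df,
            )
        )
    return results


def _mixed_cell_contrasts(t: pd.DataFrame, groups, days):
    """REML random-intercept fit on cell means; returns a contrast closure.

    Falls back to the plain cell-means contrast with pooled within-cell
    variance when the mixed fit degenerates (e.g. zero residual variance).
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    data = t.copy()
    data["cell"] = data["group"].astype(str) + "@" + data["day"].astype(str)
    cells = sorted(data["cell"].unique())
    exog = pd.get_dummies(data["cell"], dtype=float)[cells]
    n_animals = data["animal_id"].nunique()
    df = float(n_animals - len(groups))

    params = cov = None
    pooled = data.groupby("cell", observed=True)["value"]
    cell_n = pooled.size()
    cell_var = pooled.var(ddof=1).fillna(0.0)
    y_sd = float(data["value"].std(ddof=1)) if len(data) > 1 else 0.0

    if y_sd > 1e-10:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM(
                    data["value"].to_numpy(dtype=float),
                    exog.to_numpy(),
                    groups=data["animal_id"].to_numpy(),
                )
                res = model.fit(reml=True)
            k = exog.shape[1]
            params = dict(zip(cells, np.asarray(res.fe_params, dtype=float)))
            cov = np.asarray(res.cov_params())[:k, :k]
        except (np.linalg.LinAlgError, ValueError):
            params = cov = None

    def contrast(g, d, ref):
        c1, c2 = f"{g}@{d}", f"{ref}@{d}"
        if params is not None:
            i1, i2 = cells.index(c1), cells.index(c2)
            est = params[c1] - params[c2]
            se = float(np.sqrt(max(cov[i1, i1] + cov[i2, i2] - 2 * cov[i1, i2], 0.0)))
        else:  # degenerate: exact cell means, pooled within-cell variance
            m1 = float(pooled.mean().loc[c1])
            m2 = float(pooled.mean().loc[c2])
            est = m1 - m2
            dfw = max(int(cell_n.sum()) - len(cells), 1)
            ssw = float((cell_var * (cell_n - 1).clip(lower=0)).sum())
            mse = ssw / dfw
            se = float(np.sqrt(mse * (1.0 / cell_n.loc[c1] + 1.0 / cell_n.loc[c2])))
        return est, se, df

    return contrast


def compare_groups_terminal(
    table: pd.DataFrame,
    measure: str = "ex_vivo_bv_mm3",
    day: int = 21,
    reference: str = "untreated",
) -> GroupTestResult:
    """One-way ANOVA across groups at the terminal day, plus pairwise contrasts.

    Identical data in every group yields F = 0 and p = 1 (not an error).
    """
    t = table.loc[
        (table["measure"] == measure) & (table["day"] == day),
        ["animal_id", "group", "value"],
    ]
    groups = sorted(t["group"].unique())
    if len(groups) < 2:
        raise DesignError(f"need >= 2 groups at day {day} for {measure!r}")
    samples = {g: t.loc[t["group"] == g, "value"].to_numpy(dtype=float) for g in groups}
    for g, v in samples.items():
        if v.size < 2:
            raise DesignError(f"group {g!r} has {v.size} observation(s); need >= 2")

    allv = np.concatenate(list(samples.values()))
    grand = allv.mean()
    k, n_total = len(groups), allv.size
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in samples.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in samples.values())
    df_b, df_w = k - 1, n_total - k
    if ssw <= 1e-300:
        if ssb <= 1e-300:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), 0.0
        mse = 0.0
    else:
        mse = ssw / df_w
        f_stat = (ssb / df_b) / mse
        p = float(sps.f.sf(f_stat, df_b, df_w))

    ref = _resolve_reference(groups, reference)
    others = [g for g in groups if g != ref]
    pairwise = []
    for g in others:
        est = samples[g].mean() - samples[ref].mean()
        se = np.sqrt(mse * (1.0 / samples[g].size + 1.0 / samples[ref].size))
        stat, praw = _t_pvalue(est, se, df_w)
        pairwise.append(
            GroupTestResult(
                test_name="one_way_anova_contrast",
                statistic=stat,
                p_value=praw,
                contrast=f"{g} vs {ref} at day {day}",
                group_stats={
                    g: (float(samples[g].mean()), float(samples[g].std(ddof=1)), samples[g].size),
                    ref: (float(samples[ref].mean()), float(samples[ref].std(ddof=1)), samples[ref].size),
                },
                adjustment="bonferroni",
                p_adjusted=min(1.0, praw * len(others)),
                df=float(df_w),
            )
        )
    stats_by_group = {
        g: (float(v.mean()), float(v.std(ddof=1)), int(v.size)) for g, v in samples.items()
    }
    return GroupTestResult(
        test_name="one_way_anova",
        statistic=float(f_stat),
        p_value=float(p),
        contrast=f"{measure} across groups at day {day}",
        group_stats=stats_by_group,
        df=float(df_w),
        pairwise=tuple(pairwise),
    )


# ---------------------------------------------------------------------------
# ordinal scores: Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------


def _ranks_and_ties(values: np.ndarray):
    ranks = sps.rankdata(values)  # midranks
    _, counts = np.unique(values, return_counts=True)
    tie_sum = float((counts**3 - counts).sum())
    return ranks, tie_sum


def kruskal_wallis_h(samples: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All observations identical across all groups gives H = 0, p = 1.
    """
    sizes = [len(s) for s in samples]
    if any(n == 0 for n in sizes) or len(samples) < 2:
        raise DesignError("Kruskal-Wallis needs >= 2 non-empty groups")
    allv = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    n_total = allv.size
    ranks, tie_sum = _ranks_and_ties(allv)
    correction = 1.0 - tie_sum / (n_total**3 - n_total) if n_total > 1 else 1.0
    if correction <= 0:  # every observation tied
        return 0.0, 1.0
    h = 0.0
    start = 0
    for n in sizes:
        r = ranks[start : start + n]
        h += r.sum() ** 2 / n
        start += n
    h = (12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)) / correction
    h = max(h, 0.0)
    p = float(sps.chi2.sf(h, len(samples) - 1))
    return float(h), p


def dunn_z(samples: dict[str, np.ndarray], g1: str, g2: str) -> float:
    """Dunn's z for one pairwise comparison on the joint midranks."""
    names = list(samples)
    allv = np.concatenate([np.asarray(samples[g], dtype=float) for g in names])
    n_total = allv.size
    ranks, tie_sum = _ranks_and_ties(allv)
    mean_rank = {}
    start = 0
    for g in names:
        n = len(samples[g])
        mean_rank[g] = ranks[start : start + n].mean()
        start += n
    sigma2 = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    if sigma2 <= 0:
        return 0.0
    n1, n2 = len(samples[g1]), len(samples[g2])
    se = np.sqrt(sigma2 * (1.0 / n1 + 1.0 / n2))
    return float((mean_rank[g1] - mean_rank[g2]) / se)


def ordinal_group_test(
    table: pd.DataFrame,
    score_measure: str,
    reference: str = "untreated",
    day: int = 21,
) -> list[GroupTestResult]:
    """Kruskal-Wallis omnibus + Dunn's z for each group vs the reference.

    Scores must be ordinal 0-4; Dunn p-values are two-sided normal,
    Bonferroni-adjusted over the comparisons performed (each treatment
    group against the untreated control).
    """
    t = table.loc[
        (table["measure"] == score_measure) & (table["day"] == day),
        ["group", "value"],
    ]
    groups = sorted(t["group"].unique())
    if len(groups) < 2:
        raise DesignError(f"need >= 2 groups with {score_measure!r} scores")
    samples = {
        g: t.loc[t["group"] == g, "value"].to_numpy(dtype=float) for g in groups
    }
    for g, v in samples.items():
        if np.any((v < 0) | (v > 4) | (v % 1 != 0)):
            raise RangeError(f"group {g!r} has scores outside the ordinal 0-4 scale")

    h, p = kruskal_wallis_h([samples[g] for g in groups])
    stats_by_group = {
        g: (float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0, int(v.size))
        for g, v in samples.items()
    }
    results = [
        GroupTestResult(
            test_name="kruskal_wallis",
            statistic=h,
            p_value=p,
            contrast=f"{score_measure} across groups at day {day}",
            group_stats=stats_by_group,
            df=float(len(groups) - 1),
        )
    ]
    ref = _resolve_reference(groups, reference)
    others = [g for g in groups if g != ref]
    m = len(others)
    for g in others:
        z = dunn_z(samples, g, ref)
        praw = float(2.0 * sps.norm.sf(abs(z)))
        results.append(
            GroupTestResult(
                test_name="dunn",
                statistic=z,
                p_value=praw,
                contrast=f"{g} vs {ref}: {score_measure}",
                group_stats={g: stats_by_group[g], ref: stats_by_group[ref]},
                adjustment="bonferroni",
                p_adjusted=min(1.0, praw * m),
            )
        )
    return results


def cumulative_dose(n_sessions: int, dose_per_scan_mgy: float) -> float:
    """Total X-ray dose over repeated imaging sessions (mGy)."""
    if n_sessions < 0 or dose_per_scan_mgy < 0:
        raise RangeError("sessions and dose must be non-negative")
    return float(n_sessions) * float(dose_per_scan_mgy)
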