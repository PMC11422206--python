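"""Group-comparison statistics for session-averaged NIRS parameters.

Route mirrors common practice for small physiological cohorts: a single
mean ± 2 SD outlier pass, Shapiro–Wilk normality and Levene variance checks,
then either a parametric route (ANOVA / mixed ANOVA, pairwise t-tests with
Bonferroni correction, Cohen's d) or a nonparametric one (Kruskal–Wallis,
Dunn's z post hoc with Bonferroni, rank-biserial correlation).  α = 0.05,
two-sided throughout.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "PairwiseResult",
    "GroupComparisonResult",
    "remove_outliers",
    "route_test",
    "one_way_anova",
    "kruskal_wallis",
    "mixed_anova",
    "pairwise_bonferroni",
    "cohen_d",
    "d_magnitude",
    "rank_biserial",
    "compare_groups",
]

log = logging.getLogger(__name__)

ALPHA = 0.05


# ---------------------------------------------------------------------------
# outliers and routing

def remove_outliers(values) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass mean ± 2 SD trim (sample SD, n−1 denominator).

    Bounds are computed once on the full input; no re-iteration after
    removal.  Returns (kept values, removed indices).  Inputs with n < 3
    pass through unchanged with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        warnings.warn("fewer than 3 values; outlier rule skipped", stacklevel=2)
        return x, np.array([], dtype=int)
    mean = x.mean()
    sd = x.std(ddof=1)
    mask = (x >= mean - 2 * sd) & (x <= mean + 2 * sd)
    return x[mask], np.flatnonzero(~mask)


@dataclass(frozen=True)
class RouteDecision:
    route: str                       # "parametric" | "nonparametric"
    shapiro_p: tuple[float, ...]
    levene_p: float
    warning: str | None = None


def route_test(groups: list[np.ndarray], alpha: float = ALPHA) -> RouteDecision:
    """Choose the test family from normality and variance-homogeneity checks.

    Nonparametric iff any group fails Shapiro–Wilk or Levene's test at
    ``alpha``.  A degenerate (zero-variance) group forces the nonparametric
    route with a warning.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 3 for a in arrs):
        raise ValueError("each group needs at least 3 values")
    if any(np.ptp(a) == 0 for a in arrs):
        warnings.warn("zero-variance group; forcing nonparametric route", stacklevel=2)
        return RouteDecision("nonparametric", (math.nan,) * len(arrs), math.nan,
                             "zero_variance_group")
    shapiro_p = tuple(float(sps.shapiro(a).pvalue) for a in arrs)
    levene_p = float(sps.levene(*arrs, center="mean").pvalue)
    nonpar = any(p < alpha for p in shapiro_p) or levene_p < alpha
    return RouteDecision("nonparametric" if nonpar else "parametric",
                         shapiro_p, levene_p)


# ---------------------------------------------------------------------------
# omnibus tests

def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Standard between/within F decomposition. Returns (F, p)."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >= 2 groups with n >= 2")
    if all(a.std() == 0 for a in arrs) and len({a.mean() for a in arrs}) == 1:
        return 0.0, 1.0
    res = sps.f_oneway(*arrs)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction. Returns (H, p)."""
    res = sps.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    between: str = "group",
    within: str = "session",
    subject: str = "subject_id",
) -> pd.DataFrame:
    """Mixed (between-group x within-session) ANOVA via pingouin.

    Subjects missing a session are dropped with a log message.  With only
    two within levels, sphericity holds trivially (Mauchly's test is
    degenerate); the returned table notes this in the ``sphericity`` column.
    """
    import pingouin as pg

    df = table[[subject, between, within, dv]].dropna()
    n_levels = df[within].nunique()
    complete = df.groupby(subject)[within].nunique()
    keep = complete[complete == n_levels].index
    dropped = sorted(set(df[subject]) - set(keep))
    if dropped:
        log.info("mixed_anova: dropping incomplete subjects %s", dropped)
        df = df[df[subject].isin(keep)]
    if df[between].nunique() < 2:
        raise ValueError("need >= 2 between-subject groups")
    aov = pg.mixed_anova(data=df, dv=dv, within=within, subject=subject,
                         between=between)
    aov["sphericity"] = (
        "trivial (2 within levels)" if n_levels == 2 else "see Mauchly test"
    )
    return aov


# ---------------------------------------------------------------------------
# effect sizes

def cohen_d(a, b) -> float:
    """Cohen's d with the two-group pooled SD, convention (mean_a − mean_b).

    Returns NaN (flagged via log) when the pooled SD is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    na, nb = a.size, b.size
    pooled = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        log.warning("cohen_d undefined: pooled SD is zero")
        return math.nan
    return float((a.mean() - b.mean()) / pooled)


def d_magnitude(d: float) -> str:
    """Conventional |d| labels: <0.2 negligible, then small/medium/large."""
    ad = abs(d)
    if not np.isfinite(ad):
        return "undefined"
    if ad < 0.2:
        return "negligible"
    if ad < 0.5:
        return "small"
    if ad < 0.8:
        return "medium"
    return "large"


def rank_biserial(a, b) -> float:
    """Rank-biserial correlation for the Mann–Whitney comparison of a vs b.

    Dominance convention: r = (#(a>b) − #(a<b)) / (n_a n_b), ties counting
    zero (equivalently r = 2U_a/(n_a n_b) − 1 with the mid-rank U of a).
    r = −1 when every b exceeds every a, +1 for the reverse, 0 for perfectly
    interleaved samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input")
    u_a = float(sps.mannwhitneyu(a, b, alternative="two-sided").statistic)
    return 2.0 * u_a / (a.size * b.size) - 1.0


# ---------------------------------------------------------------------------
# pairwise comparisons

@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    p_raw: float
    p_corrected: float
    effect_size: float
    effect_kind: str       # "cohen_d" | "rank_biserial"
    magnitude: str = ""


def _mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    method = "exact" if max(a.size, b.size) <= 20 and not _has_ties(a, b) else "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def _dunn_z(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], tuple[float, float]]:
    """Dunn's post hoc z on pooled mid-ranks with tie adjustment."""
    labels = list(groups)
    pooled = np.concatenate([groups[k] for k in labels])
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    i = 0
    for k in labels:
        m = groups[k].size
        mean_ranks[k] = ranks[i:i + m].mean()
        i += m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    out = {}
    for ka, kb in combinations(labels, 2):
        na, nb = groups[ka].size, groups[kb].size
        se = math.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[ka] - mean_ranks[kb]) / se if se > 0 else math.nan
        p = 2.0 * sps.norm.sf(abs(z)) if np.isfinite(z) else math.nan
        out[(ka, kb)] = (z, p)
    return out


def pairwise_bonferroni(
    groups: dict[str, np.ndarray], route: str
) -> list[PairwiseResult]:
    """All pairwise two-sided comparisons with Bonferroni correction.

    Parametric route: independent t-tests and Cohen's d.  Nonparametric:
    Dunn's z on pooled ranks and the rank-biserial correlation.  Corrected
    p = raw p times the number of comparisons, capped at 1.  Pairs with a
    group of n < 2 are skipped with a log message.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    usable = {k: v for k, v in groups.items() if v.size >= 2}
    for k in set(groups) - set(usable):
        log.info("pairwise: skipping group %r with n < 2", k)
    pairs = list(combinations(usable, 2))
    m = len(pairs)
    if m == 0:
        return []
    dunn = _dunn_z(usable) if route == "nonparametric" and len(usable) > 2 else None
    results = []
    for ka, kb in pairs:
        a, b = usable[ka], usable[kb]
        if route == "parametric":
            p_raw = float(sps.ttest_ind(a, b).pvalue)
            es = cohen_d(a, b)
            kind = "cohen_d"
            mag = d_magnitude(es)
        else:
            if dunn is not None:
                p_raw = dunn[(ka, kb)][1]
            else:
                p_raw = _mannwhitney_p(a, b)
            es = rank_biserial(a, b)
            kind = "rank_biserial"
            mag = ""
        if math.isnan(p_raw):
            p_corr = math.nan
        else:
            p_corr = min(1.0, p_raw * m)
        results.append(
            PairwiseResult(ka, kb, float(a.mean()), float(a.std(ddof=1)),
                           float(b.mean()), float(b.std(ddof=1)),
                           p_raw, p_corr, es, kind, mag)
        )
    return results


@dataclass
class GroupComparisonResult:
    parameter: str
    session: str
    route: str
    shapiro_p: tuple[float, ...]
    levene_p: float
    omnibus_stat: float
    omnibus_p: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    n_removed_outliers: int = 0


def compare_groups(
    values_by_group: dict[str, np.ndarray],
    parameter: str = "",
    session: str = "",
    trim_outliers: bool = True,
    alpha: float = ALPHA,
) -> GroupComparisonResult:
    """Full comparison of one parameter across pressure groups.

    Applies the mean ± 2 SD outlier pass per group, chooses the route from
    the assumption checks, runs the omnibus test (one-way ANOVA or
    Kruskal–Wallis) and the Bonferroni-corrected pairwise comparisons with
    the route's effect size.
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    cleaned: dict[str, np.ndarray] = {}
    n_removed = 0
    for k, v in values_by_group.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        if trim_outliers:
            kept, removed = remove_outliers(v)
            n_removed += removed.size
            cleaned[k] = kept
        else:
            cleaned[k] = v
    decision = route_test(list(cleaned.values()), alpha)
    if decision.route == "parametric":
        stat, p = one_way_anova(list(cleaned.values()))
    else:
        stat, p = kruskal_wallis(list(cleaned.values()))
    pw = pairwise_bonferroni(cleaned, decision.route)
    return GroupComparisonResult(
        parameter=parameter,
        session=session,
        route=decision.route,
        shapiro_p=decision.shapiro_p,
        levene_p=decision.levene_p,
        omnibus_stat=stat,
        omnibus_p=p,
        pairwise=pw,
        n_removed_outliers=n_removed,
    )
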