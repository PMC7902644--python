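"""Three-way mixed ANOVA with assumption checks and post-hocs.

The engraftment response — one mean correlation per mouse per day — is
analysed with a split-plot (mixed) ANOVA: two between-subject factors
(diluent, storage week) and one within-subject factor (observation
day).  Sums of squares follow the standard balanced decomposition:
subjects nested in diluent x week cells form the between-subject error
stratum, and the subject x day interaction within cells forms the
within-subject error stratum.  Sphericity of the day covariance is
checked with Mauchly's test and, when violated, within-subject p-values
are recomputed on Greenhouse-Geisser shrunken degrees of freedom.
Generalized eta squared (ges) follows Olejnik & Algina with all design
factors treated as manipulated.  All statistics are computed here from
first principles; no ANOVA library is called.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EFFECTS",
    "AssumptionReport",
    "bonferroni",
    "gg_epsilon",
    "mauchly",
    "levene",
    "box_m",
    "mixed_anova",
    "check_assumptions",
    "simple_main_effects",
    "pairwise_comparisons",
]

EFFECTS = (
    "Diluents",
    "Week",
    "Day",
    "Diluents:Week",
    "Diluents:Day",
    "Week:Day",
    "Diluents:Week:Day",
)


def bonferroni(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Bonferroni adjustment: min(1, p * m)."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * m) if np.ndim(p) else min(
        1.0, float(p) * m
    )


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k within-level covariance.

    epsilon = tr(S*)^2 / ((k-1) tr(S*^2)) with S* the double-centered
    covariance.  Equals 1 under compound symmetry and exactly 1 for
    k = 2 (a single difference score carries no sphericity constraint);
    the lower bound is 1/(k-1).
    """
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    if cov.shape != (k, k) or k < 2:
        raise ValueError("covariance must be k x k with k >= 2")
    if k == 2:
        return 1.0
    h = np.eye(k) - np.ones((k, k)) / k
    s = h @ cov @ h
    denom = (k - 1) * np.trace(s @ s)
    if denom <= 0:
        return 1.0 / (k - 1)
    eps = np.trace(s) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _pooled_within_cov(data: np.ndarray, groups: np.ndarray | None) -> tuple[np.ndarray, int]:
    """Covariance of subject x level data pooled within cells; (S, df)."""
    data = np.asarray(data, dtype=float)
    if groups is None:
        groups = np.zeros(len(data), dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    k = data.shape[1]
    df = len(data) - len(labels)
    if df < 1:
        raise ValueError("need more subjects than cells to pool a covariance")
    s = np.zeros((k, k))
    for g in labels:
        sub = data[groups == g]
        if len(sub) > 1:
            s += (len(sub) - 1) * np.cov(sub, rowvar=False)
    return s / df, df


def mauchly(data: np.ndarray, groups: np.ndarray | None = None) -> tuple[float, float]:
    """Mauchly's test of sphericity on subject x within-level data.

    The covariance is pooled within between-subject cells when
    ``groups`` is given.  W is the ratio of the geometric to arithmetic
    mean eigenvalue of the orthonormalized difference covariance; the
    chi-square approximation uses the standard Box correction.  With
    k = 2 levels sphericity is unconstrained: W = 1, p = 1.
    """
    data = np.asarray(data, dtype=float)
    k = data.shape[1]
    if k < 2:
        raise ValueError("need at least 2 within levels")
    if k == 2:
        return 1.0, 1.0
    s, df = _pooled_within_cov(data, groups)
    # orthonormal contrast basis via QR of the centering projector
    h = np.eye(k) - np.ones((k, k)) / k
    q, _ = np.linalg.qr(h)
    c = q[:, : k - 1].T
    t = c @ s @ c.T
    eig = np.linalg.eigvalsh(t)
    if np.any(eig <= 0):
        return 0.0, 0.0
    d = k - 1
    w = float(np.exp(np.sum(np.log(eig)) - d * np.log(np.mean(eig))))
    # Box's chi-square approximation with the second-order term
    f = 1 - (2 * d**2 + d + 2) / (6.0 * d * df)
    chi2 = -df * f * np.log(w)
    ddof = d * (d + 1) // 2 - 1
    w2 = (
        (d + 2)
        * (d - 1)
        * (d - 2)
        * (2 * d**3 + 6 * d**2 + 3 * d + 2)
        / (288.0 * (df * d * f) ** 2)
    )
    p = stats.chi2.sf(chi2, ddof) + w2 * (
        stats.chi2.sf(chi2, ddof + 4) - stats.chi2.sf(chi2, ddof)
    )
    return w, float(min(1.0, max(0.0, p)))


def levene(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Median-centered (Brown-Forsythe) Levene test for equal variances.

    One-way ANOVA on absolute deviations from each group's median.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    z = [np.abs(values[groups == g] - np.median(values[groups == g])) for g in labels]
    n = np.array([len(zi) for zi in z])
    if (n < 2).any():
        raise ValueError("each group needs at least 2 observations")
    ntot = n.sum()
    gmeans = np.array([zi.mean() for zi in z])
    grand = np.concatenate(z).mean()
    ss_between = (n * (gmeans - grand) ** 2).sum()
    ss_within = sum(((zi - mi) ** 2).sum() for zi, mi in zip(z, gmeans))
    df1, df2 = len(labels) - 1, ntot - len(labels)
    if ss_within == 0:
        return (0.0, 1.0) if ss_between == 0 else (np.inf, 0.0)
    stat = (ss_between / df1) / (ss_within / df2)
    return float(stat), float(stats.f.sf(stat, df1, df2))


def box_m(cell_matrices: list[np.ndarray]) -> tuple[float, float]:
    """Box's M test of equal covariance matrices across cells.

    ``cell_matrices`` holds one subjects x variables matrix per cell.
    Returns the chi-square approximation (statistic, p).
    """
    if len(cell_matrices) < 2:
        raise ValueError("need at least 2 cells")
    mats = [np.asarray(m, dtype=float) for m in cell_matrices]
    k = mats[0].shape[1]
    ns = np.array([len(m) for m in mats])
    if (ns <= k).any():
        raise ValueError("each cell needs more subjects than variables")
    g = len(mats)
    n_tot = int(ns.sum())
    covs = [np.cov(m, rowvar=False) for m in mats]
    pooled = sum((n - 1) * c for n, c in zip(ns, covs)) / (n_tot - g)
    sign, logdet_p = np.linalg.slogdet(pooled)
    if sign <= 0:
        raise ValueError("pooled covariance is singular")
    m_stat = (n_tot - g) * logdet_p
    for n, c in zip(ns, covs):
        sign, logdet = np.linalg.slogdet(c)
        if sign <= 0:
            raise ValueError("a cell covariance is singular")
        m_stat -= (n - 1) * logdet
    c1 = (np.sum(1.0 / (ns - 1)) - 1.0 / (n_tot - g)) * (
        2 * k**2 + 3 * k - 1
    ) / (6.0 * (k + 1) * (g - 1))
    chi2 = m_stat * (1 - c1)
    ddof = (g - 1) * k * (k + 1) // 2
    return float(chi2), float(stats.chi2.sf(chi2, ddof))


@dataclass
class AssumptionReport:
    """Levene per within-level, Box's M, Mauchly, and outlier flags."""

    levene: pd.DataFrame  # day, statistic, p
    box_m: tuple[float, float]
    mauchly: tuple[float, float]
    outliers: pd.DataFrame = field(default_factory=pd.DataFrame)


def _wide(resp: pd.DataFrame, dv: str, subject: str, within: str) -> pd.DataFrame:
    wide = resp.pivot_table(index=subject, columns=within, values=dv, sort=False)
    if wide.isna().any().any():
        raise ValueError("incomplete design: missing (subject, day) cells")
    return wide


def mixed_anova(
    resp: pd.DataFrame,
    dv: str = "engraftment",
    between: tuple[str, str] = ("diluent", "week"),
    within: str = "day",
    subject: str = "mouse_id",
    sphericity_alpha: float = 0.05,
) -> pd.DataFrame:
    """Three-way mixed ANOVA on a tidy balanced response table.

    Returns one row per effect with columns effect, df1, df2, F,
    p_uncorrected, p, ges, p_adj, sphericity_corrected, epsilon.  ``p``
    carries the Greenhouse-Geisser correction for within-subject
    effects when Mauchly's test rejects sphericity at
    ``sphericity_alpha``; ``p_adj`` is Bonferroni over the 7 effects.
    """
    fa, fb = between
    resp = resp.copy()
    levels_a = list(pd.unique(resp[fa]))
    levels_b = list(pd.unique(resp[fb]))
    levels_c = list(pd.unique(resp[within]))
    a, b, k = len(levels_a), len(levels_b), len(levels_c)
    if min(a, b, k) < 2:
        raise ValueError("every factor needs at least 2 levels")

    cells = resp.groupby([fa, fb, within], sort=False)[dv].count()
    if cells.nunique() != 1 or len(cells) != a * b * k:
        raise ValueError("design must be balanced and complete")
    subj_cells = resp.drop_duplicates(subject).groupby([fa, fb]).size()
    n = int(subj_cells.iloc[0])
    if subj_cells.nunique() != 1:
        raise ValueError("unequal subjects per cell")
    if n < 2:
        raise ValueError("need at least 2 subjects per cell")

    y = resp[dv].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()

    def ss_of(factors: list[str]) -> float:
        means = resp.groupby(factors, sort=False)[dv].mean()
        cnt = resp.groupby(factors, sort=False)[dv].count()
        return float((cnt * (means - grand) ** 2).sum())

    ss_a = ss_of([fa])
    ss_b = ss_of([fb])
    ss_ab = ss_of([fa, fb]) - ss_a - ss_b
    ss_c = ss_of([within])
    ss_ac = ss_of([fa, within]) - ss_a - ss_c
    ss_bc = ss_of([fb, within]) - ss_b - ss_c
    ss_abc = (
        ss_of([fa, fb, within]) - ss_a - ss_b - ss_c - ss_ab - ss_ac - ss_bc
    )
    subj_means = resp.groupby(subject, sort=False)[dv].mean()
    ss_between_subj = float(k * ((subj_means - grand) ** 2).sum())
    ss_err_between = ss_between_subj - ss_a - ss_b - ss_ab
    ss_err_within = (
        ss_total - ss_between_subj - ss_c - ss_ac - ss_bc - ss_abc
    )

    df_err_b = a * b * (n - 1)
    df_err_w = a * b * (n - 1) * (k - 1)
    ms_err_b = ss_err_between / df_err_b
    ms_err_w = ss_err_within / df_err_w
    ss_error_all = ss_err_between + ss_err_within

    # sphericity of the within-subject covariance, pooled within cells
    wide = _wide(resp, dv, subject, within)[levels_c]
    subj_cell = resp.drop_duplicates(subject).set_index(subject)
    cell_labels = (
        subj_cell.loc[wide.index, fa].astype(str)
        + "/"
        + subj_cell.loc[wide.index, fb].astype(str)
    ).to_numpy()
    w_stat, w_p = mauchly(wide.to_numpy(), cell_labels)
    s_pooled, _ = _pooled_within_cov(wide.to_numpy(), cell_labels)
    eps = gg_epsilon(s_pooled)
    correct = (w_p < sphericity_alpha) and k > 2

    spec = [
        ("Diluents", ss_a, a - 1, ms_err_b, df_err_b, False),
        ("Week", ss_b, b - 1, ms_err_b, df_err_b, False),
        ("Day", ss_c, k - 1, ms_err_w, df_err_w, True),
        ("Diluents:Week", ss_ab, (a - 1) * (b - 1), ms_err_b, df_err_b, False),
        ("Diluents:Day", ss_ac, (a - 1) * (k - 1), ms_err_w, df_err_w, True),
        ("Week:Day", ss_bc, (b - 1) * (k - 1), ms_err_w, df_err_w, True),
        (
            "Diluents:Week:Day",
            ss_abc,
            (a - 1) * (b - 1) * (k - 1),
            ms_err_w,
            df_err_w,
            True,
        ),
    ]
    rows = []
    for name, ss, df1, ms_err, df2, is_within in spec:
        f = (ss / df1) / ms_err
        p_raw = float(stats.f.sf(f, df1, df2))
        if is_within and correct:
            p_use = float(stats.f.sf(f, eps * df1, eps * df2))
        else:
            p_use = p_raw
        rows.append(
            {
                "effect": name,
                "df1": df1,
                "df2": df2,
                "F": f,
                "p_uncorrected": p_raw,
                "p": p_use,
                "ges": ss / (ss + ss_error_all),
                "sphericity_corrected": bool(is_within and correct),
                "epsilon": eps if is_within else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bonferroni(out["p"].to_numpy(), len(out))
    out.attrs["ss_error_between"] = ss_err_between
    out.attrs["ss_error_within"] = ss_err_within
    out.attrs["ss_total"] = ss_total
    out.attrs["mauchly"] = (w_stat, w_p)
    return out


def check_assumptions(
    resp: pd.DataFrame,
    dv: str = "engraftment",
    between: tuple[str, str] = ("diluent", "week"),
    within: str = "day",
    subject: str = "mouse_id",
    iqr_factor: float = 3.0,
) -> AssumptionReport:
    """Levene at each day, Box's M over cells, Mauchly, extreme outliers.

    Outliers are flagged by the boxplot rule at ``iqr_factor`` times the
    interquartile range beyond the quartiles, per design cell.
    """
    fa, fb = between
    lev_rows = []
    for day, sub in resp.groupby(within, sort=False):
        grp = (sub[fa].astype(str) + "/" + sub[fb].astype(str)).to_numpy()
        stat, p = levene(sub[dv].to_numpy(), grp)
        lev_rows.append({within: day, "statistic": stat, "p": p})

    wide = _wide(resp, dv, subject, within)
    subj_cell = resp.drop_duplicates(subject).set_index(subject)
    cell_of = (
        subj_cell.loc[wide.index, fa].astype(str)
        + "/"
        + subj_cell.loc[wide.index, fb].astype(str)
    )
    mats = [wide[cell_of == c].to_numpy() for c in pd.unique(cell_of)]
    try:
        bm = box_m(mats)
    except ValueError:
        bm = (np.nan, np.nan)
    mk = mauchly(wide.to_numpy(), cell_of.to_numpy())

    flags = []
    for (ai, bi, ci), sub in resp.groupby([fa, fb, within], sort=False):
        v = sub[dv].to_numpy()
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
        for _, row in sub[(sub[dv] < lo) | (sub[dv] > hi)].iterrows():
            flags.append(
                {fa: ai, fb: bi, within: ci, subject: row[subject], dv: row[dv]}
            )
    return AssumptionReport(
        levene=pd.DataFrame(lev_rows),
        box_m=bm,
        mauchly=mk,
        outliers=pd.DataFrame(flags),
    )


def _oneway_f(values: np.ndarray, groups: np.ndarray) -> tuple[float, int, int, float]:
    labels = pd.unique(groups)
    n = np.array([np.sum(groups == g) for g in labels])
    means = np.array([values[groups == g].mean() for g in labels])
    grand = values.mean()
    ss_b = (n * (means - grand) ** 2).sum()
    ss_w = sum(
        ((values[groups == g] - m) ** 2).sum() for g, m in zip(labels, means)
    )
    df1, df2 = len(labels) - 1, len(values) - len(labels)
    if ss_w == 0:
        raise ValueError("zero within-group variance: F undefined")
    f = (ss_b / df1) / (ss_w / df2)
    return float(f), df1, df2, float(stats.f.sf(f, df1, df2))


def simple_main_effects(
    resp: pd.DataFrame,
    factor: str = "diluent",
    strata: tuple[str, ...] = ("day", "week"),
    dv: str = "engraftment",
) -> pd.DataFrame:
    """One-way F test of ``factor`` within every stratum combination.

    p-values are Bonferroni-adjusted over the family of strata.
    """
    rows = []
    for key, sub in resp.groupby(list(strata), sort=False):
        key = key if isinstance(key, tuple) else (key,)
        if sub[factor].nunique() < 2:
            raise ValueError(f"stratum {key} has < 2 levels of {factor}")
        f, df1, df2, p = _oneway_f(sub[dv].to_numpy(), sub[factor].to_numpy())
        rows.append(
            dict(zip(strata, key)) | {"F": f, "df1": df1, "df2": df2, "p": p}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bonferroni(out["p"].to_numpy(), len(out))
    return out


def pairwise_comparisons(
    resp: pd.DataFrame,
    factor: str = "diluent",
    strata: tuple[str, ...] = ("day", "week"),
    dv: str = "engraftment",
) -> pd.DataFrame:
    """Pooled-variance two-sample t-tests between factor levels per stratum.

    Bonferroni adjustment spans all comparisons across all strata.
    """
    rows = []
    for key, sub in resp.groupby(list(strata), sort=False):
        key = key if isinstance(key, tuple) else (key,)
        levels = list(pd.unique(sub[factor]))
        for l1, l2 in combinations(levels, 2):
            x = sub.loc[sub[factor] == l1, dv].to_numpy()
            y = sub.loc[sub[factor] == l2, dv].to_numpy()
            if len(x) < 2 or len(y) < 2:
                raise ValueError(f"level with < 2 subjects in stratum {key}")
            df = len(x) + len(y) - 2
            sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / df
            if sp2 == 0:
                raise ValueError(
                    f"zero pooled variance comparing {l1} vs {l2} in stratum {key}"
                )
            t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
            p = float(2 * stats.t.sf(abs(t), df))
            rows.append(
                dict(zip(strata, key))
                | {"level_1": l1, "level_2": l2, "t": float(t), "df": df, "p": p}
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = bonferroni(out["p"].to_numpy(), len(out))
    return out
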