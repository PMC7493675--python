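"""The cohort statistical battery.

Covers the analyses a two-group regional-leukoaraiosis study runs:

* distribution screening with a log transform (skewness/kurtosis must
  land in [-1, 1]);
* independent-samples t-tests, from raw vectors or from printed
  summary statistics (mean, SD, n per group);
* Pearson chi-square on 2x2 counts (sex ratios), uncorrected;
* Mann-Whitney U with tie-corrected normal-approximation p;
* a mixed-design (split-plot) ANCOVA: between factor group, within
  factor region (depth zones or anterior/posterior), total intracranial
  volume as a between-subject covariate, partial eta squared effect
  sizes;
* partial correlations controlling for the covariate (residual method).

The mixed ANCOVA follows the repeated-measures GLM convention of large
statistics packages: the within-subject part is analyzed in an
orthonormal contrast space where each contrast column is modelled on
intercept + covariate + group, pooling sums of squares across columns.
With g groups, N subjects and k within levels this gives the
within-effect error df (k-1)(N-g-1) — e.g. F(2, 62) for the depth
analysis at N=34, k=3, g=2 — and between-subject error df N-g-1. The
covariate is centered so the within-factor main effect is evaluated at
the covariate mean. Sphericity is assumed by default; a
Greenhouse-Geisser correction is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class StatResult:
    """One test statistic with df, p and (where defined) an effect size."""

    name: str  # "t", "x2", "U", "F", "r"
    value: float
    df: float | tuple[float, float] | None = None
    p: float | None = None
    effect_size: float | None = None  # partial eta squared for F, r for correlations
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "value": self.value,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p": self.p,
            "effect_size": self.effect_size,
            "note": self.note,
        }


# ---------------------------------------------------------------------------
# screening and simple group tests
# ---------------------------------------------------------------------------


@dataclass
class LogScreen:
    transformed: np.ndarray
    skewness: float
    kurtosis: float  # excess kurtosis

    @property
    def within_bounds(self) -> bool:
        return -1.0 <= self.skewness <= 1.0 and -1.0 <= self.kurtosis <= 1.0


def log_screen(values, offset: float = 1.0) -> LogScreen:
    """Natural-log transform ln(x + offset) plus normality screening.

    The default offset 1 admits exact zeros (lesion-free subjects).
    """
    x = np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("log_screen requires non-negative values")
    t = np.log(x + offset)
    import warnings

    with warnings.catch_warnings():
        # near-constant vectors (e.g. all-zero lesion loads) trip scipy's
        # precision warning; skew/kurtosis 0 is the right answer there
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = float(sps.skew(t))
        kurt = float(sps.kurtosis(t))  # Fisher (excess)
    return LogScreen(transformed=t, skewness=skew, kurtosis=kurt)


def two_sample_t(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int, pooled: bool = True
) -> StatResult:
    """Independent-samples t from summary statistics.

    Pooled-variance by default (df = n1+n2-2); Welch with
    ``pooled=False``. Zero variance in both groups with equal means
    returns t = 0 by convention.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return StatResult("t", 0.0, df=float(n1 + n2 - 2), p=1.0)
        raise ValueError("zero variance in both groups with unequal means: t undefined")
    t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=pooled)
    if pooled:
        df: float = float(n1 + n2 - 2)
    else:  # Welch-Satterthwaite
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return StatResult("t", float(t), df=df, p=float(p))


def two_sample_t_from_vectors(x, y, pooled: bool = True) -> StatResult:
    """Independent-samples t from raw vectors (same formula as
    :func:`two_sample_t` applied to the sample moments)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return two_sample_t(
        float(x.mean()), float(x.std(ddof=1)), x.size,
        float(y.mean()), float(y.std(ddof=1)), y.size,
        pooled=pooled,
    )


def chi_square_counts(contingency) -> StatResult:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    table = np.asarray(contingency, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: chi-square undefined")
    x2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return StatResult("x2", float(x2), df=float(df), p=float(p))


def mann_whitney_u(x, y) -> StatResult:
    """Rank-sum U (x-side statistic) with tie-corrected normal p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each sample needs n >= 1")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    r = 1.0 - 2.0 * float(res.statistic) / (x.size * y.size)  # rank-biserial
    return StatResult("U", float(res.statistic), p=float(res.pvalue), effect_size=r)


# ---------------------------------------------------------------------------
# mixed-design ANCOVA
# ---------------------------------------------------------------------------


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of OLS y ~ X (X may be empty)."""
    if X.shape[1] == 0:
        return float(y @ y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis of the deviation-from-mean space."""
    dev = np.eye(k) - np.full((k, k), 1.0 / k)
    q, _ = np.linalg.qr(dev)
    return q[:, : k - 1]


def _effect_code(groups: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero (effect) coding; returns N x (g-1) matrix."""
    levels = sorted(pd.unique(groups).tolist())
    g = len(levels)
    cols = np.zeros((groups.size, g - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = np.where(groups == lev, 1.0, np.where(groups == levels[-1], -1.0, 0.0))
    return cols, levels


class UnbalancedDesignError(ValueError):
    """Within-factor levels missing for some subjects."""


def mixed_ancova(
    long: pd.DataFrame,
    subject: str = "subject",
    group: str = "group",
    within: str = "level",
    value: str = "value",
    covariate: str = "covariate",
    gg: bool = False,
) -> dict[str, StatResult]:
    """Mixed-design ANCOVA on a long table (one row per subject x level).

    Returns StatResults for ``"region"`` (within-factor main effect),
    ``"region_x_covariate"``, ``"region_x_group"`` (the interaction of
    interest) and ``"group"`` (between-subject effect), each with
    partial eta squared = SS_effect / (SS_effect + SS_error).

    The design must be balanced (every subject at every level) and the
    covariate constant within subject; violations raise with the
    offending subjects named.
    """
    df = long[[subject, group, within, value, covariate]].copy()
    wide = df.pivot_table(index=subject, columns=within, values=value, aggfunc="first")
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise UnbalancedDesignError(f"subjects missing within-factor levels: {bad}")
    counts = df.groupby(subject)[within].count()
    if (counts != wide.shape[1]).any():
        bad = counts.index[counts != wide.shape[1]].tolist()
        raise UnbalancedDesignError(f"subjects with duplicated/missing levels: {bad}")
    cov_n = df.groupby(subject)[covariate].nunique()
    if (cov_n != 1).any():
        bad = cov_n.index[cov_n != 1].tolist()
        raise ValueError(f"covariate varies within subjects: {bad}")

    per_subj = df.drop_duplicates(subject).set_index(subject)
    groups = per_subj.loc[wide.index, group].to_numpy()
    covar = per_subj.loc[wide.index, covariate].to_numpy(dtype=float)
    covar = covar - covar.mean()

    Y = wide.to_numpy(dtype=float)
    N, k = Y.shape
    if k < 2:
        raise ValueError("need at least two within-factor levels")
    G, levels = _effect_code(groups)
    g = len(levels)
    if N - g - 1 <= 0:
        raise ValueError("too few subjects for the covariate-adjusted model")

    ones = np.ones((N, 1))
    X_full = np.hstack([ones, covar[:, None], G])
    blocks = {"intercept": [0], "covariate": [1], "group": list(range(2, 2 + g - 1))}

    # within-subject part: orthonormal contrast scores, SS pooled over columns
    C = _orthonormal_contrasts(k)
    Z = Y @ C
    rss_full = [_rss(X_full, Z[:, j]) for j in range(k - 1)]
    ss_err_w = float(np.sum(rss_full))
    df_err_w = (k - 1) * (N - 1 - g)

    def within_effect(block: str, df_eff: int) -> tuple[float, int]:
        keep = [i for i in range(X_full.shape[1]) if i not in blocks[block]]
        X_red = X_full[:, keep]
        ss = float(np.sum([_rss(X_red, Z[:, j]) - rss_full[j] for j in range(k - 1)]))
        return ss, df_eff

    ss_region, df_region = within_effect("intercept", k - 1)
    ss_rxc, df_rxc = within_effect("covariate", k - 1)
    ss_rxg, df_rxg = within_effect("group", (k - 1) * (g - 1))

    # between-subject part: subject means on the same design
    m = Y.mean(axis=1)
    rss_full_b = _rss(X_full, m)
    df_err_b = N - 1 - g
    keep_b = [i for i in range(X_full.shape[1]) if i not in blocks["group"]]
    ss_group = _rss(X_full[:, keep_b], m) - rss_full_b
    df_group = g - 1
    ss_err_b = rss_full_b

    eps = 1.0
    if gg:  # Greenhouse-Geisser epsilon from residual covariance in contrast space
        beta, *_ = np.linalg.lstsq(X_full, Z, rcond=None)
        E = Z - X_full @ beta
        S = E.T @ E / max(N - X_full.shape[1], 1)
        tr = np.trace(S)
        eps = float(tr**2 / ((k - 1) * np.trace(S @ S))) if tr > 0 else 1.0

    def make(name: str, ss_eff: float, df_eff: float, ss_err: float, df_err: float,
             adjust: bool = False) -> StatResult:
        ss_eff = max(ss_eff, 0.0)
        if ss_err <= 0 or df_eff <= 0:
            return StatResult("F", float("nan"), df=(df_eff, df_err), note="degenerate")
        F = (ss_eff / df_eff) / (ss_err / df_err)
        d1, d2 = df_eff, df_err
        if adjust and gg:
            d1, d2 = d1 * eps, d2 * eps
        p = float(sps.f.sf(F, d1, d2))
        pes = ss_eff / (ss_eff + ss_err)
        note = f"GG epsilon={eps:.4f}" if (adjust and gg) else ""
        return StatResult("F", float(F), df=(float(d1), float(d2)), p=p, effect_size=pes, note=note)

    return {
        "region": make("region", ss_region, df_region, ss_err_w, df_err_w, adjust=True),
        "region_x_covariate": make("rxc", ss_rxc, df_rxc, ss_err_w, df_err_w, adjust=True),
        "region_x_group": make("rxg", ss_rxg, df_rxg, ss_err_w, df_err_w, adjust=True),
        "group": make("group", ss_group, df_group, ss_err_b, df_err_b),
    }


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------


def partial_correlation(x, y, z) -> StatResult:
    """Pearson correlation of x and y after residualizing both on z.

    p is from the t transform with n-3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if not (y.size == n and z.size == n):
        raise ValueError("x, y, z must have equal length")
    if n < 4:
        raise ValueError("partial correlation needs n >= 4")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant: correlation undefined")
    Zm = np.column_stack([np.ones(n), z])
    rx = x - Zm @ np.linalg.lstsq(Zm, x, rcond=None)[0]
    ry = y - Zm @ np.linalg.lstsq(Zm, y, rcond=None)[0]
    r = float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    r = max(-1.0, min(1.0, r))
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult("r", r, df=float(df), p=p, effect_size=r)


def partial_correlation_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z confidence interval for a partial correlation with one
    control variable (effective n reduced by 1)."""
    if n - 4 <= 0:
        raise ValueError("n too small for a CI")
    zr = math.atanh(max(-0.999999, min(0.999999, r)))
    se = 1.0 / math.sqrt(n - 4)
    zc = sps.norm.ppf(1 - alpha / 2)
    return math.tanh(zr - zc * se), math.tanh(zr + zc * se)


# ---------------------------------------------------------------------------
# whole-cohort report
# ---------------------------------------------------------------------------

#: cohort-table columns compared between groups in the demographic block,
#: with the test family to use
DEMOGRAPHIC_VARS = {
    "age": "continuous",
    "education": "continuous",
    "charlson": "continuous",
    "moca": "continuous",
    "wtar": "continuous",
    "la_volume_mm3": "continuous",
    "wm_volume_mm3": "continuous",
    "ticv_mm3": "continuous",
    "stroke_volume_ml": "continuous",
    "lacunae_volume_ml": "continuous",
}

THICKNESS_VARS = ("thickness_frontal", "thickness_parietal", "thickness_temporal", "thickness_occipital")


def _group_vectors(cohort: pd.DataFrame, col: str) -> tuple[np.ndarray, np.ndarray, list]:
    levels = sorted(cohort["group"].unique().tolist())
    if len(levels) != 2:
        raise ValueError("the report expects exactly two groups")
    a = cohort.loc[cohort["group"] == levels[0], col].to_numpy(dtype=float)
    b = cohort.loc[cohort["group"] == levels[1], col].to_numpy(dtype=float)
    return a, b, levels


def analysis_report(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    log_offset: float = 1.0,
    pooled: bool = True,
    gg: bool = False,
) -> dict:
    """Run the full battery on a cohort table and return a nested dict.

    Blocks: demographic/volumetric group comparisons (t on raw values,
    falling back to Mann-Whitney U when even the log transform leaves
    skewness/kurtosis outside [-1, 1]; chi-square for sex), the 2x3
    depth-zone mixed ANCOVA and the 2x2 anterior/posterior mixed ANCOVA
    on log-transformed fractions with TICV as covariate, and partial
    correlations (controlling TICV) of each lobe's cortical thickness
    against log total and log infracortical LA.
    """
    cohort = cohort.reset_index(drop=True)
    if cohort["id"].duplicated().any():
        raise ValueError("duplicate subject ids")
    report: dict = {"alpha": alpha, "n": int(len(cohort)), "groups": {}}
    levels = sorted(cohort["group"].unique().tolist())
    for lev in levels:
        report["groups"][str(lev)] = int((cohort["group"] == lev).sum())

    comparisons: dict[str, dict] = {}
    for col, kind in DEMOGRAPHIC_VARS.items():
        if col not in cohort.columns:
            continue
        a, b, _ = _group_vectors(cohort, col)
        screen = log_screen(np.concatenate([a, b]) - min(0.0, float(np.min(np.concatenate([a, b])))),
                            offset=log_offset) if (np.concatenate([a, b]) >= 0).all() else None
        use_u = screen is not None and not screen.within_bounds and kind == "continuous"
        if use_u:
            res = mann_whitney_u(a, b)
        else:
            try:
                res = two_sample_t_from_vectors(a, b, pooled=pooled)
            except ValueError:
                res = mann_whitney_u(a, b)
        comparisons[col] = res.as_dict() | {
            "means": [float(a.mean()), float(b.mean())],
            "sds": [float(a.std(ddof=1)), float(b.std(ddof=1))],
        }
    if "sex" in cohort.columns:
        tab = pd.crosstab(cohort["group"], cohort["sex"]).to_numpy()
        if tab.shape == (2, 2):
            comparisons["sex"] = chi_square_counts(tab).as_dict()
    report["group_comparisons"] = comparisons

    # log-transformed LA fractions for the inferential battery
    def logged(col: str) -> np.ndarray:
        return np.log(cohort[col].to_numpy(dtype=float) + log_offset)

    depth_long = pd.concat(
        [
            pd.DataFrame(
                {
                    "subject": cohort["id"],
                    "group": cohort["group"],
                    "level": zone,
                    "value": np.log(cohort[col].to_numpy(dtype=float) + log_offset),
                    "covariate": cohort["ticv_mm3"],
                }
            )
            for zone, col in (
                ("periventricular", "pv_pct"),
                ("deep", "deep_pct"),
                ("infracortical", "ic_pct"),
            )
        ],
        ignore_index=True,
    )
    depth = mixed_ancova(depth_long, gg=gg)
    report["depth_ancova"] = {k: v.as_dict() for k, v in depth.items()}

    ap_long = pd.concat(
        [
            pd.DataFrame(
                {
                    "subject": cohort["id"],
                    "group": cohort["group"],
                    "level": region,
                    "value": np.log(cohort[col].to_numpy(dtype=float) + log_offset),
                    "covariate": cohort["ticv_mm3"],
                }
            )
            for region, col in (("anterior", "anterior_pct"), ("posterior", "posterior_pct"))
        ],
        ignore_index=True,
    )
    ap = mixed_ancova(ap_long, gg=gg)
    report["anterior_posterior_ancova"] = {k: v.as_dict() for k, v in ap.items()}

    ticv = cohort["ticv_mm3"].to_numpy(dtype=float)
    correlations: dict[str, dict] = {}
    for la_col, la_name in (("total_pct", "total"), ("ic_pct", "infracortical")):
        for thick in THICKNESS_VARS:
            if thick not in cohort.columns:
                continue
            res = partial_correlation(logged(la_col), cohort[thick].to_numpy(dtype=float), ticv)
            correlations[f"{la_name}~{thick}"] = res.as_dict()
    report["thickness_partial_correlations"] = correlations

    # follow-up group t-tests on log zone fractions
    followups: dict[str, dict] = {}
    for zone, col in (("periventricular", "pv_pct"), ("deep", "deep_pct"),
                      ("infracortical", "ic_pct"), ("total", "total_pct")):
        a, b, _ = _group_vectors(cohort.assign(_lg=np.log(cohort[col] + log_offset)), "_lg")
        followups[zone] = two_sample_t_from_vectors(a, b, pooled=pooled).as_dict()
    report["zone_followup_t"] = followups
    return report


def format_report(report: dict) -> str:
    """Human-readable rendering of :func:`analysis_report` output."""
    lines = [f"Cohort report (N = {report['n']}, alpha = {report['alpha']})"]
    lines.append("groups: " + ", ".join(f"{k} n={v}" for k, v in sorted(report["groups"].items())))
    lines.append("")
    lines.append("Group comparisons")
    for var, d in report["group_comparisons"].items():
        stat = f"{d['name']} = {d['value']:.3f}"
        p = f", p = {d['p']:.3f}" if d.get("p") is not None else ""
        lines.append(f"  {var:<18} {stat}{p}")
    for key, title in (("depth_ancova", "Depth-zone mixed ANCOVA (covarying TICV)"),
                       ("anterior_posterior_ancova", "Anterior/posterior mixed ANCOVA (covarying TICV)")):
        lines.append("")
        lines.append(title)
        for eff, d in report[key].items():
            df1, df2 = d["df"]
            lines.append(
                f"  {eff:<20} F({df1:.0f}, {df2:.0f}) = {d['value']:.3f}, "
                f"p = {d['p']:.4f}, partial eta2 = {d['effect_size']:.3f}"
            )
    lines.append("")
    lines.append("Partial correlations with lobe thickness (controlling TICV)")
    for name, d in report["thickness_partial_correlations"].items():
        lines.append(f"  {name:<32} r = {d['value']: .3f}, p = {d['p']:.3f}")
    return "\n".join(lines) + "\n"
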