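"""Cohort statistics: Spearman rank correlation with MacTel stage,
intraclass correlation for grader agreement, and GEE group comparisons.

Stage is an ordinal 0-6 grade, so associations with it use Spearman rank
correlation (no linearity between stages assumed).  Group comparisons
between pooled stages (early 0-2 / moderate 3-5 / advanced 6) use a
Gaussian identity-link GEE with exchangeable working correlation to adjust
for two eyes of one patient, a robust Wald chi-square for the 3-level
group factor, and Bonferroni-corrected pairwise contrasts.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

log = logging.getLogger(__name__)

POOLED_GROUPS = ("early", "moderate", "advanced")

#: EyeRecord columns analysed in the cross-sectional report, in table order.
REPORT_PARAMETERS = (
    "tel_area_mm2",
    "attn_area_mm2",
    "izloss_area_mm2",
    "ezloss_area_mm2",
    "overlap_attn_pct",
    "overlap_izloss_pct",
    "overlap_ezloss_pct",
)


def pool_stage(stage: int) -> str:
    """Pool an ordinal 0-6 severity stage: 0-2 early, 3-5 moderate, 6 advanced."""
    if stage in (0, 1, 2):
        return "early"
    if stage in (3, 4, 5):
        return "moderate"
    if stage == 6:
        return "advanced"
    raise ValueError(f"stage must be an integer in 0..6, got {stage!r}")


# ---------------------------------------------------------------------------
# Spearman


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-tailed exact permutation p for Spearman rho (midranks kept), by
    full enumeration of the n! pairings, vectorized in chunks."""
    n = rx.size
    a = rx - rx.mean()
    b = ry - ry.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return math.nan
    a = a / na
    b = b / nb
    thresh = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    chunk: list[tuple[int, ...]] = []
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 200_000:
            vals = b[np.array(chunk)] @ a
            count += int(np.count_nonzero(np.abs(vals) >= thresh))
            total += len(chunk)
            chunk = []
    if chunk:
        vals = b[np.array(chunk)] @ a
        count += int(np.count_nonzero(np.abs(vals) >= thresh))
        total += len(chunk)
    return count / total


def spearman(x, y, exact_max_n: int = 10) -> CorrelationResult:
    """Spearman rank correlation with midranks for ties.

    The p-value is a two-tailed exact permutation probability for
    n <= ``exact_max_n`` and the t-approximation (t = rho sqrt((n-2)/(1-rho^2)),
    n-2 df) above.  A constant vector has undefined rho (NaN result).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.warning("constant vector: Spearman rho undefined")
        return CorrelationResult(math.nan, math.nan, n)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        p = _exact_spearman_p(rx, ry, rho)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho, p, n)


# ---------------------------------------------------------------------------
# ICC


@dataclass
class ICCResult:
    icc: float
    p_value: float
    n_subjects: int
    n_raters: int


def icc_agreement(measurements) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measures ICC
    (ICC(2,1)) from the two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with MSR/MSC/MSE the subject, rater and residual mean squares.  The
    p-value is the F-test of MSR/MSE.  Zero between-subject variance gives
    ICC <= 0, reported as computed.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need an n_subjects x k_raters table, k >= 2")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported")
    n, k = m.shape
    if n < 5:
        raise ValueError("need at least 5 subjects")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((m - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else math.nan
    if mse == 0:
        p = 0.0 if msr > 0 else math.nan
    else:
        f = msr / mse
        p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return ICCResult(float(icc), p, n, k)


# ---------------------------------------------------------------------------
# GEE group comparison


@dataclass
class GroupTestResult:
    wald_chi2: float
    df: int
    p_value: float
    group_means: dict[str, float]
    group_se: dict[str, float]
    pairwise: dict[str, float] = field(default_factory=dict)  # Bonferroni-adjusted p
    n_obs: int = 0
    n_clusters: int = 0


def gee_group_test(
    records: pd.DataFrame,
    outcome: str,
    group_col: str = "pooled_group",
    cluster_col: str = "patient_id",
) -> GroupTestResult:
    """Compare an outcome between pooled-stage groups with a Gaussian
    identity-link GEE (exchangeable working correlation, robust sandwich
    covariance) clustered on patient.

    Rows with a missing outcome are dropped (pairwise deletion, logged).
    The Wald chi-square tests the joint null of no group differences
    (df = #groups - 1); pairwise contrasts are Bonferroni-adjusted.
    """
    df = records[[outcome, group_col, cluster_col]].copy()
    n_missing = int(df[outcome].isna().sum())
    if n_missing:
        log.info("gee_group_test(%s): dropping %d rows with missing outcome", outcome, n_missing)
        df = df.dropna(subset=[outcome])
    groups = [g for g in POOLED_GROUPS if g in set(df[group_col])]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups for a comparison")
    for g in groups:
        n_cl = df.loc[df[group_col] == g, cluster_col].nunique()
        if n_cl < 2:
            raise ValueError(f"group {g!r} has {n_cl} cluster(s); need >= 2")

    X = pd.get_dummies(
        pd.Categorical(df[group_col], categories=groups), drop_first=True, dtype=float
    )
    X.insert(0, "const", 1.0)
    model = sm.GEE(
        df[outcome].to_numpy(dtype=float),
        X.to_numpy(),
        groups=df[cluster_col].to_numpy(),
        family=sm.families.Gaussian(),
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    import warnings

    from statsmodels.tools.sm_exceptions import IterationLimitWarning

    with warnings.catch_warnings():
        # the mean parameters converge to ctol quickly; the exchangeable
        # dependence parameter can keep oscillating at machine scale —
        # log instead of spamming, and fail only on unusable estimates
        warnings.filterwarnings("error", category=IterationLimitWarning)
        try:
            res = model.fit(maxiter=100, ctol=1e-8)
        except IterationLimitWarning:
            warnings.filterwarnings("ignore", category=IterationLimitWarning)
            res = model.fit(maxiter=100, ctol=1e-8)
            log.warning("gee_group_test(%s): iteration limit reached", outcome)
    if not np.all(np.isfinite(res.params)):
        raise ValueError(f"GEE for {outcome!r} failed to converge to finite estimates")
    beta = np.asarray(res.params)
    V = np.asarray(res.cov_params())  # robust sandwich by default

    # joint Wald: all non-intercept coefficients zero
    q = len(groups) - 1
    R = np.zeros((q, len(beta)))
    R[:, 1:] = np.eye(q)
    rb = R @ beta
    w = float(rb @ np.linalg.solve(R @ V @ R.T, rb))
    p_joint = float(sps.chi2.sf(w, q))

    # group means = contrast of coefficients; robust SEs by the delta rule
    means, ses = {}, {}
    for i, g in enumerate(groups):
        c = np.zeros(len(beta))
        c[0] = 1.0
        if i > 0:
            c[i] = 1.0
        means[g] = float(c @ beta)
        ses[g] = float(np.sqrt(c @ V @ c))

    pairwise = {}
    n_pairs = len(groups) * (len(groups) - 1) // 2
    for i, j in itertools.combinations(range(len(groups)), 2):
        c = np.zeros(len(beta))
        if i > 0:
            c[i] = -1.0
        if j > 0:
            c[j] = 1.0
        est = c @ beta
        se = math.sqrt(c @ V @ c)
        praw = 2.0 * sps.norm.sf(abs(est / se)) if se > 0 else math.nan
        pairwise[f"{groups[i]}_vs_{groups[j]}"] = min(1.0, n_pairs * praw)

    return GroupTestResult(
        wald_chi2=w,
        df=q,
        p_value=p_joint,
        group_means=means,
        group_se=ses,
        pairwise=pairwise,
        n_obs=len(df),
        n_clusters=df[cluster_col].nunique(),
    )


# ---------------------------------------------------------------------------
# cross-sectional report


def cross_sectional_report(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Stage-correlation and by-group tables for a cohort of eye records.

    Returns ``{"correlations": ..., "by_group": ...}``:

    * correlations — Spearman rho and p of each parameter against the
      ordinal stage (rows with a missing parameter dropped pairwise);
    * by_group — group mean ± SD per parameter, with the GEE Wald p and
      Bonferroni pairwise contrasts when more than one group is present.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if len(df) < 4:
        raise ValueError("need >= 4 eyes")
    params = [p for p in REPORT_PARAMETERS if p in df.columns]

    corr_rows = []
    for p in params:
        sub = df[["stage", p]].dropna()
        dropped = len(df) - len(sub)
        if dropped:
            log.info("correlations(%s): %d eye(s) dropped for missing values", p, dropped)
        if len(sub) >= 4 and sub[p].nunique() > 1:
            r = spearman(sub["stage"].to_numpy(), sub[p].to_numpy())
            corr_rows.append({"parameter": p, "rho": r.rho, "p_value": r.p_value, "n": r.n})
        else:
            corr_rows.append({"parameter": p, "rho": math.nan, "p_value": math.nan, "n": len(sub)})
    correlations = pd.DataFrame(corr_rows)

    groups_present = [g for g in POOLED_GROUPS if g in set(df["pooled_group"])]
    rows = []
    for p in params:
        row: dict = {"parameter": p}
        for g in groups_present:
            vals = df.loc[df["pooled_group"] == g, p].dropna()
            row[f"{g}_mean"] = vals.mean() if len(vals) else math.nan
            row[f"{g}_sd"] = vals.std(ddof=1) if len(vals) > 1 else math.nan
            row[f"{g}_n"] = len(vals)
        if len(groups_present) >= 2:
            try:
                gt = gee_group_test(df, p)
                row["gee_wald_chi2"] = gt.wald_chi2
                row["gee_p"] = gt.p_value
                for name, padj in gt.pairwise.items():
                    row[f"p_{name}"] = padj
            except (ValueError, np.linalg.LinAlgError) as exc:
                log.warning("GEE failed for %s: %s", p, exc)
                row["gee_p"] = math.nan
        rows.append(row)
    if len(groups_present) < 2:
        log.warning("single-group cohort: GEE comparison column omitted")
    by_group = pd.DataFrame(rows)
    return {"correlations": correlations, "by_group": by_group}
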