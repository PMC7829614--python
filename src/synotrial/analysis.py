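"""The trial's statistical battery.

Binary endpoints are compared between arms with a risk difference in
percentage points plus an unpooled Wald 95% CI, and tested with an
uncorrected Pearson chi-square (Fisher's exact, two-sided
point-probability method, when any expected cell is below 5).
Continuous endpoints use ANCOVA on change from baseline with treatment
as factor and baseline as covariate, falling back to Quade's rank
analysis of covariance when a Shapiro-Wilk check on the ANCOVA
residuals fails. Within-group changes use the paired Wilcoxon
signed-rank test. The treatment-by-pathotype interaction is a
likelihood-ratio test between nested logistic models. Missing outcomes
assumed missing at random are multiply imputed by chained equations and
pooled with Rubin's rules.

Display rounding matches the convention of the published summary
tables: percentage effects and CI bounds are rounded to one decimal and
then to a whole percent, both half away from zero; unrounded values are
always retained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "PopulationFlags",
    "round_percent",
    "risk_difference",
    "binary_test",
    "ancova_change",
    "rank_ancova_change",
    "ancova_assumptions_met",
    "within_group_change",
    "interaction_lrt",
    "impute_mi",
    "pool_rubin",
    "endpoint_table",
    "safety_table",
    "comparisons_to_frame",
    "BINARY_ENDPOINTS",
    "CONTINUOUS_ENDPOINTS",
]


def _round_half_away(value: float, ndigits: int = 0) -> float:
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(value) * scale + 0.5) / scale, value)


def round_percent(value: float) -> int:
    """Display rounding for percentage effects and CI bounds.

    Rounds to one decimal, then to a whole percent, both half away from
    zero (the double rounding matches tables formatted at one decimal
    before final display).
    """
    if math.isnan(value):
        raise ValueError("cannot round NaN percent")
    return int(_round_half_away(_round_half_away(value, 1), 0))


@dataclass
class ComparisonResult:
    """One two-arm contrast: effect, 95% CI, p-value and provenance.

    Binary contrasts carry the four 2x2 counts and the risk difference
    in percentage points (alt minus ref arm). Continuous contrasts
    carry per-arm least-squares mean changes with standard errors and
    the ref-minus-alt difference (positive when the alternative arm
    improves more on a decreasing scale).
    """

    endpoint: str
    stratum: str
    method: str
    effect: float
    ci_low: float
    ci_high: float
    p_value: float
    n_ref: int = 0
    x_ref: Optional[int] = None
    n_alt: int = 0
    x_alt: Optional[int] = None
    lsmean_ref: Optional[float] = None
    lsmean_se_ref: Optional[float] = None
    lsmean_alt: Optional[float] = None
    lsmean_se_alt: Optional[float] = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if not self.flagged and not math.isnan(self.effect):
            if not (self.ci_low - 1e-9 <= self.effect <= self.ci_high + 1e-9):
                raise ValueError("CI does not contain the point estimate")
        if not math.isnan(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    @property
    def effect_rounded(self) -> int:
        return round_percent(self.effect)

    @property
    def ci_rounded(self) -> Tuple[int, int]:
        return (round_percent(self.ci_low), round_percent(self.ci_high))


@dataclass
class PopulationFlags:
    """Analysis-population membership for one patient."""

    itt: bool
    per_protocol: bool
    safety: bool
    as_treated_arm: str = ""

    def __post_init__(self) -> None:
        if self.per_protocol and not self.itt:
            raise ValueError("per-protocol population is nested in ITT")


# ---------------------------------------------------------------------------
# Binary contrasts


def risk_difference(
    x_ref: int,
    n_ref: int,
    x_alt: int,
    n_alt: int,
    alpha: float = 0.05,
    method: str = "wald",
    endpoint: str = "",
    stratum: str = "",
) -> ComparisonResult:
    """Risk difference (alt minus ref) in percentage points with 95% CI.

    ``wald``: unpooled normal interval. ``newcombe``: score-based
    hybrid (Wilson limits per arm). A degenerate Wald interval (both
    proportions 0 or 1) is returned as [effect, effect] with a warning
    advising an exact method.
    """
    for x, n in ((x_ref, n_ref), (x_alt, n_alt)):
        if n < 1:
            raise ValueError("each arm needs n >= 1")
        if not 0 <= x <= n:
            raise ValueError(f"count {x} outside [0, {n}]")
    p_ref, p_alt = x_ref / n_ref, x_alt / n_alt
    diff = p_alt - p_ref
    z = stats.norm.ppf(1 - alpha / 2)
    if method == "wald":
        se = math.sqrt(p_ref * (1 - p_ref) / n_ref + p_alt * (1 - p_alt) / n_alt)
        if se == 0.0:
            warnings.warn(
                "degenerate Wald interval (zero variance); consider an "
                "exact method",
                stacklevel=2,
            )
        lo, hi = diff - z * se, diff + z * se
    elif method == "newcombe":
        l_ref, u_ref = _wilson(x_ref, n_ref, z)
        l_alt, u_alt = _wilson(x_alt, n_alt, z)
        lo = diff - math.sqrt((p_alt - l_alt) ** 2 + (u_ref - p_ref) ** 2)
        hi = diff + math.sqrt((u_alt - p_alt) ** 2 + (p_ref - l_ref) ** 2)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    p_value, test_method = binary_test(x_ref, n_ref, x_alt, n_alt)
    return ComparisonResult(
        endpoint=endpoint,
        stratum=stratum,
        method=test_method,
        effect=100 * diff,
        ci_low=100 * lo,
        ci_high=100 * hi,
        p_value=p_value,
        n_ref=n_ref,
        x_ref=x_ref,
        n_alt=n_alt,
        x_alt=x_alt,
    )


def _wilson(x: int, n: int, z: float) -> Tuple[float, float]:
    p = x / n
    denom = 1 + z * z / n
    center = p + z * z / (2 * n)
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return (center - half) / denom, (center + half) / denom


def binary_test(x_ref: int, n_ref: int, x_alt: int, n_alt: int) -> Tuple[float, str]:
    """Two-sided test of a 2x2 table: chi-square or Fisher's exact.

    Uncorrected Pearson chi-square unless any expected cell is below 5,
    in which case Fisher's exact (point-probability two-sided) is used.
    The chosen method is returned alongside the p-value.
    """
    table = np.array([[x_ref, n_ref - x_ref], [x_alt, n_alt - x_alt]])
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected < 5).any():
        return float(stats.fisher_exact(table).pvalue), "fisher"
    res = stats.chi2_contingency(table, correction=False)
    return float(res.pvalue), "chisq"


# ---------------------------------------------------------------------------
# Continuous contrasts (ANCOVA and rank ANCOVA)


def ancova_change(
    baseline: Sequence[float],
    followup: Sequence[float],
    arm: Sequence[str],
    ref_arm: str = "rituximab",
    alt_arm: str = "tocilizumab",
    alpha: float = 0.05,
    endpoint: str = "",
    stratum: str = "",
) -> ComparisonResult:
    """ANCOVA on change from baseline: change ~ arm + baseline.

    Reports per-arm least-squares mean changes (covariate held at the
    grand mean) with standard errors, the ref-minus-alt difference with
    its CI, and the p-value of the arm coefficient.
    """
    import statsmodels.api as sm

    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    a = np.asarray(arm)
    keep = ~(np.isnan(b) | np.isnan(f))
    b, f, a = b[keep], f[keep], a[keep]
    is_alt = (a == alt_arm).astype(float)
    if is_alt.sum() < 2 or (1 - is_alt).sum() < 2:
        raise ValueError("need at least 2 patients per arm")
    change = f - b
    X = np.column_stack([np.ones_like(b), is_alt, b])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate (collinear) ANCOVA design")
    fit = sm.OLS(change, X).fit()
    bbar = b.mean()
    lsmeans, lserrs = [], []
    for ind in (0.0, 1.0):
        vec = np.array([1.0, ind, bbar])
        lsmeans.append(float(vec @ fit.params))
        lserrs.append(float(math.sqrt(vec @ fit.cov_params() @ vec)))
    coef = fit.params[1]
    ci = fit.conf_int(alpha=alpha)[1]
    # ref-minus-alt difference: positive when the alt arm's change is
    # more negative (larger improvement on a decreasing scale).
    return ComparisonResult(
        endpoint=endpoint,
        stratum=stratum,
        method="ancova",
        effect=float(-coef),
        ci_low=float(-ci[1]),
        ci_high=float(-ci[0]),
        p_value=float(fit.pvalues[1]),
        n_ref=int((1 - is_alt).sum()),
        n_alt=int(is_alt.sum()),
        lsmean_ref=lsmeans[0],
        lsmean_se_ref=lserrs[0],
        lsmean_alt=lsmeans[1],
        lsmean_se_alt=lserrs[1],
    )


def ancova_assumptions_met(
    baseline: Sequence[float],
    followup: Sequence[float],
    arm: Sequence[str],
    alt_arm: str = "tocilizumab",
    alpha: float = 0.01,
) -> bool:
    """Shapiro-Wilk normality check on the ANCOVA residuals."""
    import statsmodels.api as sm

    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    a = np.asarray(arm)
    keep = ~(np.isnan(b) | np.isnan(f))
    b, f, a = b[keep], f[keep], a[keep]
    X = np.column_stack([np.ones_like(b), (a == alt_arm).astype(float), b])
    resid = sm.OLS(f - b, X).fit().resid
    if np.ptp(resid) == 0:
        return True
    return float(stats.shapiro(resid).pvalue) >= alpha


def rank_ancova_change(
    baseline: Sequence[float],
    followup: Sequence[float],
    arm: Sequence[str],
    ref_arm: str = "rituximab",
    alt_arm: str = "tocilizumab",
    alpha: float = 0.05,
    endpoint: str = "",
    stratum: str = "",
) -> ComparisonResult:
    """Quade's rank analysis of covariance.

    Change and baseline are replaced by their ranks, the rank change is
    regressed on the rank baseline, and the regression residuals are
    compared across arms with a one-way ANOVA. Invariant under monotone
    transforms of the outcome.
    """
    import statsmodels.api as sm

    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    a = np.asarray(arm)
    keep = ~(np.isnan(b) | np.isnan(f))
    b, f, a = b[keep], f[keep], a[keep]
    is_alt = a == alt_arm
    if is_alt.sum() < 2 or (~is_alt).sum() < 2:
        raise ValueError("need at least 2 patients per arm")
    r_change = stats.rankdata(f - b)
    r_base = stats.rankdata(b)
    X = np.column_stack([np.ones_like(r_base), r_base])
    resid = sm.OLS(r_change, X).fit().resid
    res_ref, res_alt = resid[~is_alt], resid[is_alt]
    n1, n2 = len(res_ref), len(res_alt)
    diff = float(res_ref.mean() - res_alt.mean())
    sp2 = ((n1 - 1) * res_ref.var(ddof=1) + (n2 - 1) * res_alt.var(ddof=1)) / (
        n1 + n2 - 2
    )
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    dof = n1 + n2 - 2
    if se == 0:
        p = 1.0 if diff == 0 else 0.0
        lo = hi = diff
    else:
        t = diff / se
        p = 2 * stats.t.sf(abs(t), dof)
        tcrit = stats.t.ppf(1 - alpha / 2, dof)
        lo, hi = diff - tcrit * se, diff + tcrit * se
    return ComparisonResult(
        endpoint=endpoint,
        stratum=stratum,
        method="rank_ancova",
        effect=diff,
        ci_low=lo,
        ci_high=hi,
        p_value=float(p),
        n_ref=n1,
        n_alt=n2,
    )


def within_group_change(
    baseline: Sequence[float], followup: Sequence[float]
) -> float:
    """Two-sided paired Wilcoxon signed-rank p for change from baseline.

    Zero differences are dropped (Wilcoxon convention); all-zero
    differences yield p = 1 with a warning. Exact null distribution for
    n <= 25 pairs, normal approximation beyond.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    keep = ~(np.isnan(b) | np.isnan(f))
    d = f[keep] - b[keep]
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    method = "exact" if d.size <= 25 else "auto"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.wilcoxon(d, method=method).pvalue)


# ---------------------------------------------------------------------------
# Treatment x pathotype interaction


def interaction_lrt(
    response: Sequence[int],
    arm: Sequence[str],
    pathotype: Sequence[str],
) -> float:
    """Likelihood-ratio test for a treatment-by-pathotype interaction.

    Compares nested logistic regressions — response ~ arm + pathotype
    versus response ~ arm + pathotype + arm:pathotype — with the LRT
    statistic 2*(ll_full - ll_reduced) referred to chi-square(1).
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    a = np.asarray(arm)
    g = np.asarray(pathotype)
    keep = ~np.isnan(y)
    y, a, g = y[keep], a[keep], g[keep]
    if len(set(a)) != 2 or len(set(g)) != 2:
        raise ValueError("both factors must have exactly two levels present")
    ia = (a == sorted(set(a))[1]).astype(float)
    ig = (g == sorted(set(g))[1]).astype(float)
    X_red = np.column_stack([np.ones_like(y), ia, ig])
    X_full = np.column_stack([X_red, ia * ig])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_red = sm.Logit(y, X_red).fit(disp=0)
            fit_full = sm.Logit(y, X_full).fit(disp=0)
    except Exception as exc:  # singular Hessian / perfect separation
        raise ValueError(
            "separation detected in the logistic fit; use an exact or "
            "penalized alternative"
        ) from exc
    if not (np.isfinite(fit_full.params).all() and np.abs(fit_full.params).max() < 15):
        raise ValueError(
            "separation detected in the logistic fit; use an exact or "
            "penalized alternative"
        )
    lrt = 2.0 * (fit_full.llf - fit_red.llf)
    lrt = max(lrt, 0.0)
    return float(stats.chi2.sf(lrt, 1))


# ---------------------------------------------------------------------------
# Multiple imputation (chained equations) and Rubin pooling


def impute_mi(
    data: pd.DataFrame,
    m: int = 20,
    seed: int = 0,
    burn: int = 5,
    analysis: Optional[Callable[[pd.DataFrame], Tuple[float, float]]] = None,
) -> Tuple[List[pd.DataFrame], Optional[Dict[str, float]]]:
    """Multiple imputation by chained equations with Rubin pooling.

    Numeric columns with gaps are imputed by chained equations
    (predictive mean matching) for ``m`` completed datasets. When an
    ``analysis`` callable mapping a completed dataset to (estimate,
    variance) is given, the per-dataset results are pooled with Rubin's
    rules and returned alongside the completed datasets.
    """
    from statsmodels.imputation.mice import MICEData

    numeric = data.select_dtypes(include=[np.number])
    if numeric.isna().all(axis=0).any():
        col = numeric.columns[numeric.isna().all(axis=0)][0]
        raise ValueError(f"column {col!r} is fully missing; cannot impute")
    completed: List[pd.DataFrame] = []
    if not numeric.isna().any().any():
        completed = [data.copy() for _ in range(m)]
    else:
        np.random.seed(seed % (2**31))
        imp = MICEData(numeric.reset_index(drop=True))
        imp.update_all(burn)
        for _ in range(m):
            imp.update_all(1)
            filled = data.copy()
            filled[numeric.columns] = imp.data.to_numpy()
            completed.append(filled)
    pooled = None
    if analysis is not None:
        results = [analysis(df) for df in completed]
        pooled = pool_rubin(
            [r[0] for r in results], [r[1] for r in results]
        )
    return completed, pooled


def pool_rubin(
    estimates: Sequence[float], variances: Sequence[float]
) -> Dict[str, float]:
    """Rubin's rules: pooled point estimate and total variance.

    point = mean(estimates); variance = mean(within) +
    (1 + 1/m) * between-imputation variance.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    qbar = float(q.mean())
    ubar = float(u.mean())
    between = float(q.var(ddof=1)) if m > 1 else 0.0
    total = ubar + (1 + 1 / m) * between
    return {"estimate": qbar, "variance": total, "within": ubar, "between": between, "m": m}


# ---------------------------------------------------------------------------
# Endpoint and safety tables

BINARY_ENDPOINTS = [
    "cdai50",
    "cdai_mtr",
    "cdai_lda",
    "das28_esr_lda",
    "das28_crp_lda",
    "das28_esr_rem",
    "das28_crp_rem",
    "eular_esr_mod_good",
    "eular_crp_mod_good",
]

CONTINUOUS_ENDPOINTS = [
    "cdai",
    "das28_esr",
    "das28_crp",
    "haq",
    "facit",
    "sf36_pcs",
    "sf36_mcs",
]


def endpoint_table(
    dataset,
    stratification: str = "histology",
    population: str = "itt",
    ref_arm: str = "rituximab",
    alt_arm: str = "tocilizumab",
) -> List[ComparisonResult]:
    """Week-16 endpoint table for one stratification and population.

    Produces one :class:`ComparisonResult` per endpoint per B-cell
    stratum: binary endpoints via risk difference + chi-square/Fisher,
    continuous change-from-baseline endpoints via ANCOVA with the
    rank-ANCOVA fallback. Empty stratum-arm cells flag the row rather
    than aborting the table.
    """
    from .cohort import analysis_frame

    df = analysis_frame(dataset, stratification=stratification)
    if population == "itt":
        df = df[df["itt"]]
    elif population == "per_protocol":
        df = df[df["itt"] & ~df["protocol_violation"]]
    else:
        raise ValueError(f"unknown population {population!r}")

    results: List[ComparisonResult] = []
    for stratum in ("bcell_poor", "bcell_rich"):
        sub = df[(df["pathotype"] == stratum) & df["evaluable"]]
        ref = sub[sub["treatment"] == ref_arm]
        alt = sub[sub["treatment"] == alt_arm]
        empty = len(ref) == 0 or len(alt) == 0
        for endpoint in BINARY_ENDPOINTS:
            if empty:
                results.append(_flagged(endpoint, stratum))
                continue
            res = risk_difference(
                int(ref[endpoint].sum()),
                len(ref),
                int(alt[endpoint].sum()),
                len(alt),
                endpoint=endpoint,
                stratum=stratum,
            )
            results.append(res)
        for endpoint in CONTINUOUS_ENDPOINTS:
            b = sub[f"{endpoint}_baseline"].to_numpy(dtype=float)
            f = sub[f"{endpoint}_week16"].to_numpy(dtype=float)
            a = sub["treatment"].to_numpy()
            keep = ~(np.isnan(b) | np.isnan(f))
            if empty or (keep & (a == ref_arm)).sum() < 2 or (
                keep & (a == alt_arm)
            ).sum() < 2:
                results.append(_flagged(endpoint, stratum))
                continue
            if ancova_assumptions_met(b, f, a, alt_arm=alt_arm):
                res = ancova_change(
                    b, f, a, ref_arm, alt_arm, endpoint=endpoint, stratum=stratum
                )
            else:
                res = rank_ancova_change(
                    b, f, a, ref_arm, alt_arm, endpoint=endpoint, stratum=stratum
                )
            results.append(res)
    return results


def _flagged(endpoint: str, stratum: str) -> ComparisonResult:
    return ComparisonResult(
        endpoint=endpoint,
        stratum=stratum,
        method="",
        effect=math.nan,
        ci_low=math.nan,
        ci_high=math.nan,
        p_value=math.nan,
        flagged=True,
    )


def safety_table(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    ref_arm: str = "rituximab",
    alt_arm: str = "tocilizumab",
) -> List[ComparisonResult]:
    """Safety summary by as-treated arm.

    ``events`` needs columns patient_id, term, serious; ``patients``
    needs patient_id and as_treated_arm. Recurrent identical events in
    the same patient count once. Reports any-adverse-event and
    any-serious-adverse-event risk differences.
    """
    ev = events.drop_duplicates(subset=["patient_id", "term"])
    arms = patients.set_index("patient_id")["as_treated_arm"]
    results = []
    for endpoint, mask in (
        ("any_adverse_event", np.ones(len(ev), dtype=bool)),
        ("any_serious_adverse_event", ev["serious"].to_numpy(dtype=bool)),
    ):
        affected = set(ev.loc[mask, "patient_id"])
        x_ref = sum(1 for p in arms.index if arms[p] == ref_arm and p in affected)
        x_alt = sum(1 for p in arms.index if arms[p] == alt_arm and p in affected)
        n_ref = int((arms == ref_arm).sum())
        n_alt = int((arms == alt_arm).sum())
        results.append(
            risk_difference(
                x_ref, n_ref, x_alt, n_alt, endpoint=endpoint, stratum="safety"
            )
        )
    return results


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results into a table (one row per contrast)."""
    rows = []
    for r in results:
        row = {
            "endpoint": r.endpoint,
            "stratum": r.stratum,
            "method": r.method,
            "effect": r.effect,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p_value": r.p_value,
            "n_ref": r.n_ref,
            "x_ref": r.x_ref,
            "n_alt": r.n_alt,
            "x_alt": r.x_alt,
            "lsmean_ref": r.lsmean_ref,
            "lsmean_alt": r.lsmean_alt,
            "flagged": r.flagged,
        }
        if not r.flagged and not math.isnan(r.effect) and r.x_ref is not None:
            row["effect_pct"] = r.effect_rounded
            row["ci_low_pct"], row["ci_high_pct"] = r.ci_rounded
        rows.append(row)
    return pd.DataFrame(rows)
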