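"""Inference: one-sample t with FDR, Hedges' g, repeated-measures ANOVA,
Pearson correlation, and within-subject ANOVA power.

All t-tests are two-sided. Multiple-comparison correction is
Benjamini-Hochberg, applied within one comparison panel (the 5 salience
levels of one difference measure, or the 3 aligned bins) rather than across
panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    """One-sample test of a mean difference against zero."""

    label: str
    estimate: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p_raw: float
    p_fdr: float
    hedges_g: float
    g_ci_low: float
    g_ci_high: float
    n: int
    defined: bool = True


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA with generalized eta squared."""

    F: float
    df_effect: int
    df_error: int
    p: float
    ges: float
    ss_effect: float
    ss_subjects: float
    ss_error: float
    posthoc: list[StatResult]


def hedges_g(values) -> tuple[float, float, float]:
    """Hedges' g for a one-sample mean difference, with 95% CI.

    g = (mean / SD) * J with the small-sample correction
    J = 1 - 3 / (4(n-1) - 1). The CI uses the normal approximation
    g +/- 1.96 * SE with SE^2 = 1/n + g^2 / (2(n-1)).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation: g undefined")
    J = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    g = (x.mean() / sd) * J
    se = np.sqrt(1.0 / n + g**2 / (2.0 * (n - 1)))
    return float(g), float(g - 1.96 * se), float(g + 1.96 * se)


def one_sample_t_fdr(matrix, labels=None, alpha: float = 0.05) -> list[StatResult]:
    """Two-sided one-sample t-tests vs 0 per column, BH-corrected as one family.

    ``matrix`` is participants x levels; the columns form the FDR family
    (e.g. the 5 salience levels of one comparison, or 3 aligned bins).
    Zero-variance columns yield a flagged, undefined result with p = 1 for
    nonzero mean impossibility avoidance: if all values are identical and
    nonzero the t statistic is infinite; we flag rather than fabricate.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need >= 2 participants")
    k = X.shape[1]
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    n = X.shape[0]
    df = n - 1
    results = []
    p_raw = np.ones(k)
    for j in range(k):
        col = X[:, j]
        m, sd = col.mean(), col.std(ddof=1)
        if sd == 0:
            if m == 0:
                results.append(
                    StatResult(labels[j], 0.0, 0.0, 0.0, 0.0, df, 1.0, 1.0,
                               0.0, 0.0, 0.0, n, defined=True)
                )
                p_raw[j] = 1.0
            else:
                results.append(
                    StatResult(labels[j], float(m), float(m), float(m),
                               np.nan, df, 1.0, 1.0, np.nan, np.nan, np.nan,
                               n, defined=False)
                )
                p_raw[j] = 1.0
            continue
        se = sd / np.sqrt(n)
        t = m / se
        p = 2.0 * sps.t.sf(abs(t), df)
        tcrit = sps.t.ppf(0.975, df)
        g, glo, ghi = hedges_g(col)
        results.append(
            StatResult(labels[j], float(m), float(m - tcrit * se),
                       float(m + tcrit * se), float(t), df, float(p), np.nan,
                       g, glo, ghi, n)
        )
        p_raw[j] = p
    p_fdr = multipletests(p_raw, alpha=alpha, method="fdr_bh")[1]
    for r, pf in zip(results, p_fdr):
        r.p_fdr = float(max(pf, r.p_raw))
    return results


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


def rm_anova(matrix, labels=None) -> AnovaResult:
    """One-way repeated-measures ANOVA from the within-subject decomposition.

    For a complete participants (n) x levels (k) matrix:
    SS_effect over levels, SS_subjects over participants, SS_error the
    remainder; F = MS_effect / MS_error with df (k-1, (k-1)(n-1));
    generalized eta squared = SS_effect / (SS_effect + SS_subjects +
    SS_error). Post-hoc: paired t-tests between all level pairs, BH-adjusted.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a complete n x k matrix with n, k >= 2")
    if np.isnan(X).any():
        raise ValueError("missing cells are not supported")
    n, k = X.shape
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    grand = X.mean()
    ss_effect = n * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_subjects = k * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_error = ss_total - ss_effect - ss_subjects
    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    ms_effect = ss_effect / df_effect
    ms_error = ss_error / df_error
    F = ms_effect / ms_error if ms_error > 0 else 0.0
    p = float(sps.f.sf(F, df_effect, df_error)) if ms_error > 0 else 1.0
    ges = ss_effect / (ss_effect + ss_subjects + ss_error)

    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    diffs = [X[:, i] - X[:, j] for i, j in pairs]
    posthoc = one_sample_t_fdr(
        np.column_stack(diffs),
        labels=[f"{labels[i]} vs {labels[j]}" for i, j in pairs],
    )
    return AnovaResult(
        F=float(F), df_effect=df_effect, df_error=df_error, p=p,
        ges=float(ges), ss_effect=float(ss_effect),
        ss_subjects=float(ss_subjects), ss_error=float(ss_error),
        posthoc=posthoc,
    )


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p via the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def rm_anova_power(
    f: float,
    n: int,
    m: int,
    alpha: float = 0.05,
    rho: float = 0.5,
    epsilon: float = 1.0,
) -> float:
    """Power of the within-subject main effect in a one-way RM-ANOVA.

    Uses the classical repeated-measures convention: noncentrality
    lambda = f^2 * n * m * epsilon / (1 - rho), with numerator df
    (m-1)*epsilon and denominator df (n-1)*(m-1)*epsilon, where rho is the
    assumed correlation among repeated measures and epsilon the
    nonsphericity correction. f is Cohen's effect size f.
    """
    if f < 0 or not 0 <= rho < 1 or not 0 < epsilon <= 1:
        raise ValueError("invalid power specification")
    if n < 2 or m < 2:
        raise ValueError("need n >= 2 and m >= 2")
    df1 = (m - 1) * epsilon
    df2 = (n - 1) * (m - 1) * epsilon
    lam = f**2 * n * m * epsilon / (1.0 - rho)
    fcrit = sps.f.ppf(1.0 - alpha, df1, df2)
    if lam == 0:
        return float(alpha)
    return float(sps.ncf.sf(fcrit, df1, df2, lam))


def required_n(
    f: float,
    m: int,
    power: float = 0.85,
    alpha: float = 0.05,
    rho: float = 0.5,
    epsilon: float = 1.0,
    n_max: int = 10_000,
) -> int:
    """Smallest N whose RM-ANOVA power reaches the target."""
    if f <= 0 and power > alpha:
        raise ValueError("null effect cannot reach power above alpha")
    for n in range(2, n_max + 1):
        if rm_anova_power(f, n, m, alpha, rho, epsilon) >= power:
            return n
    raise ValueError(f"no N <= {n_max} reaches power {power}")
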