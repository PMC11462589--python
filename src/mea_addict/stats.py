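"""Hypothesis tests used by the screening pipeline.

Three tests cover the pipeline's needs: a fixed-effects one-way ANOVA, a
many-to-one Dunnett comparison of treatment groups against the shared
vehicle control, and a two-group multivariate test on principal-component
scores.  With two groups Wilks' lambda and Hotelling's T-squared are the
same test; both statistics are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "DunnettResult",
    "MultivariateTestResult",
    "one_way_anova",
    "dunnett_test",
    "manova_two_group",
]


@dataclass
class DunnettResult:
    """Many-to-one comparison of k treatments against one control."""

    statistic: np.ndarray  # t statistic per treatment
    p_adjusted: np.ndarray  # familywise-adjusted two-sided p per treatment
    mean_differences: np.ndarray  # treatment mean − control mean
    f_statistic: float  # global one-way ANOVA F
    f_pvalue: float
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return self.p_adjusted < self.alpha


@dataclass
class MultivariateTestResult:
    """Two-group multivariate location test on d-dimensional scores."""

    hotelling_t2: float
    wilks_lambda: float
    f_statistic: float
    df: tuple[int, int]
    pvalue: float


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Fixed-effects one-way ANOVA over ≥2 groups (each n ≥ 2).

    Degenerate input with zero variance in every group returns p = 0 when
    the group means differ and p = 1 when they coincide, with a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need at least 2 groups with n >= 2 each")
    if all(np.ptp(g) == 0 for g in groups):
        means = [g[0] for g in groups]
        warnings.warn("zero within-group variance in all groups", stacklevel=2)
        if np.ptp(means) == 0:
            return 0.0, 1.0
        return np.inf, 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def dunnett_test(
    control: np.ndarray,
    treatments: list[np.ndarray],
    alpha: float = 0.05,
) -> DunnettResult:
    """Two-sided Dunnett many-to-one comparison against a shared control.

    Uses the classic equal-variance form: the adjusted p-values come from
    the multivariate-t distribution of the k simultaneous t statistics,
    with correlation implied by the group sizes.  With a single treatment
    this reduces to the two-sided pooled-variance t-test.
    """
    control = np.asarray(control, dtype=float)
    treatments = [np.asarray(t, dtype=float) for t in treatments]
    if control.size < 2:
        raise ValueError("control needs n >= 2")
    if not treatments or any(t.size < 2 for t in treatments):
        raise ValueError("need at least one treatment group with n >= 2")
    if len(treatments) == 1:
        # exact single-comparison reduction: two-sided pooled-variance t
        t = treatments[0]
        n1, n2 = t.size, control.size
        df = n1 + n2 - 2
        s2 = ((n1 - 1) * t.var(ddof=1) + (n2 - 1) * control.var(ddof=1)) / df
        stat = (t.mean() - control.mean()) / np.sqrt(s2 * (1 / n1 + 1 / n2))
        pvals = np.array([2 * sps.t.sf(abs(stat), df)])
        stats = np.array([stat])
    else:
        # deterministic evaluation of the multivariate-t integral
        res = sps.dunnett(*treatments, control=control, alternative="two-sided",
                          rng=np.random.default_rng(0))
        stats = np.asarray(res.statistic, dtype=float)
        pvals = np.asarray(res.pvalue, dtype=float)
    f, fp = one_way_anova([control, *treatments])
    return DunnettResult(
        statistic=stats,
        p_adjusted=np.clip(pvals, 0.0, 1.0),
        mean_differences=np.array([t.mean() - control.mean() for t in treatments]),
        f_statistic=f,
        f_pvalue=fp,
        alpha=alpha,
    )


def hotelling_two_sample(a: np.ndarray, b: np.ndarray, ridge: float = 1e-8):
    """Core two-sample Hotelling T² computation.

    Returns (T², F, df1, df2).  A singular pooled covariance is regularised
    with a small ridge (scaled to the mean diagonal) and a warning.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n1, d = a.shape
    n2, d2 = b.shape
    if d != d2:
        raise ValueError("groups must share dimensionality")
    if n1 < 2 or n2 < 2 or n1 + n2 - 2 < d:
        raise ValueError("too few observations for a pooled covariance")
    diff = a.mean(axis=0) - b.mean(axis=0)
    S = ((n1 - 1) * np.cov(a, rowvar=False, ddof=1) + (n2 - 1) * np.cov(b, rowvar=False, ddof=1)) / (
        n1 + n2 - 2
    )
    S = np.atleast_2d(S)
    try:
        sol = np.linalg.solve(S, diff)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance; applying ridge regularisation", stacklevel=2)
        scale = np.trace(S) / d if np.trace(S) > 0 else 1.0
        sol = np.linalg.solve(S + ridge * scale * np.eye(d), diff)
    t2 = n1 * n2 / (n1 + n2) * float(diff @ sol)
    df1, df2 = d, n1 + n2 - 1 - d
    if df2 <= 0:
        raise ValueError("not enough observations for the F approximation")
    f_stat = df2 / (d * (n1 + n2 - 2)) * t2
    return t2, f_stat, df1, df2


def manova_two_group(scores_a: np.ndarray, scores_b: np.ndarray) -> MultivariateTestResult:
    """Two-group multivariate test on PC scores (Wilks' lambda form).

    For two groups Wilks' lambda is a monotone transform of Hotelling's
    T-squared — Λ = 1 / (1 + T²/(n₁+n₂−2)) — and both yield the same exact
    F statistic, reported here with its p-value.  Each group needs n ≥ 3.
    """
    a = np.atleast_2d(np.asarray(scores_a, dtype=float))
    b = np.atleast_2d(np.asarray(scores_b, dtype=float))
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("each group needs n >= 3")
    t2, f_stat, df1, df2 = hotelling_two_sample(a, b)
    n_tot = a.shape[0] + b.shape[0]
    lam = 1.0 / (1.0 + t2 / (n_tot - 2))
    p = float(sps.f.sf(f_stat, df1, df2))
    return MultivariateTestResult(
        hotelling_t2=float(t2),
        wilks_lambda=float(lam),
        f_statistic=float(f_stat),
        df=(df1, df2),
        pvalue=min(max(p, 0.0), 1.0),
    )
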