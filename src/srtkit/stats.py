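"""Group-level comparisons between the original and latency-corrected
threshold methods, and the effect of stretch velocity.

Method comparisons are paired per subject: differences are tested for
normality (Shapiro–Wilk) and routed to a two-sided paired t-test when
normal, otherwise to the Wilcoxon signed-rank test.  Effect sizes are
Hedges' g with the small-sample bias correction.  The velocity effect is
the Friedman test over the per-subject x velocity matrix, followed (only
when the omnibus is significant) by pairwise Wilcoxon signed-rank
contrasts with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as _st


@dataclass
class MethodComparison:
    variable: str
    muscle: str
    n: int
    test_used: str  # paired_t | wilcoxon
    statistic: float
    p_value: float
    effect_size_g: float
    ci_95: tuple[float, float] | None = None
    shapiro_p: float | None = None
    degenerate: bool = False


@dataclass
class PairwiseContrast:
    level_a: float
    level_b: float
    statistic: float
    p_raw: float
    p_bonferroni: float


@dataclass
class VelocityEffect:
    muscle: str
    method: str  # original | corrected
    n: int
    friedman_statistic: float
    p_value: float
    posthoc: list[PairwiseContrast] = field(default_factory=list)


def hedges_g(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference with the small-sample correction
    g = [(m1 - m2) / s_pooled] * (1 - 3 / (4 df - 1)),  df = n1 + n2 - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp_sq = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp_sq == 0.0:
        return 0.0
    d = (x.mean() - y.mean()) / np.sqrt(sp_sq)
    return float(d * (1.0 - 3.0 / (4.0 * df - 1.0)))


def check_normality(values: np.ndarray, alpha: float = 0.05) -> tuple[bool, float]:
    """Shapiro–Wilk; a zero-variance vector is treated as degenerate-normal."""
    v = np.asarray(values, dtype=float)
    if np.ptp(v) == 0.0:
        return True, 1.0
    stat, p = _st.shapiro(v)
    return bool(p >= alpha), float(p)


def check_equal_variance(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Levene's test for equality of variances (statistic, p)."""
    stat, p = _st.levene(np.asarray(x, float), np.asarray(y, float))
    return float(stat), float(p)


def compare_paired(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    variable: str = "",
    muscle: str = "",
) -> MethodComparison:
    """Paired comparison of two per-subject value vectors.

    Routes to the paired t-test when the Shapiro–Wilk test does not
    reject normality of the differences at ``alpha``, to the Wilcoxon
    signed-rank test otherwise.  An all-zero difference vector is
    degenerate: no evidence of any difference, reported as p = 1 with
    zero effect size.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    g = hedges_g(x, y)

    if np.all(d == 0.0):
        return MethodComparison(
            variable, muscle, n, "paired_t", 0.0, 1.0, 0.0,
            ci_95=(0.0, 0.0), shapiro_p=1.0, degenerate=True,
        )

    normal, shapiro_p = check_normality(d, alpha)
    if normal and np.ptp(d) > 0.0:
        stat, p = _st.ttest_rel(x, y)
        se = d.std(ddof=1) / np.sqrt(n)
        tcrit = _st.t.ppf(0.975, n - 1)
        ci = (float(d.mean() - tcrit * se), float(d.mean() + tcrit * se))
        return MethodComparison(
            variable, muscle, n, "paired_t", float(stat), float(p), g,
            ci_95=ci, shapiro_p=shapiro_p,
        )
    stat, p = _st.wilcoxon(x, y, zero_method="wilcox")
    return MethodComparison(
        variable, muscle, n, "wilcoxon", float(stat), float(p), g,
        ci_95=None, shapiro_p=shapiro_p,
    )


def velocity_effect(
    srt_by_velocity: np.ndarray,
    velocities: list[float] | tuple[float, ...],
    alpha: float = 0.05,
    muscle: str = "",
    method: str = "",
) -> VelocityEffect:
    """Friedman omnibus over a complete subjects x velocities matrix; on a
    significant omnibus, all C(k,2) pairwise Wilcoxon signed-rank contrasts
    with Bonferroni-multiplied p-values."""
    m = np.asarray(srt_by_velocity, dtype=float)
    if m.ndim != 2 or m.shape[1] != len(velocities):
        raise ValueError("matrix must be subjects x velocities")
    if np.isnan(m).any():
        raise ValueError("incomplete rows; exclude subjects upstream")
    if m.shape[0] < 3:
        raise ValueError("need at least 3 subjects")

    cols = [m[:, j] for j in range(m.shape[1])]
    if all(np.ptp(np.asarray(c)) == 0.0 for c in (m[i, :] for i in range(m.shape[0]))):
        stat, p = 0.0, 1.0
    else:
        stat, p = _st.friedmanchisquare(*cols)
    eff = VelocityEffect(muscle, method, m.shape[0], float(stat), float(p))
    if p < alpha:
        pairs = list(combinations(range(len(velocities)), 2))
        k = len(pairs)
        for i, j in pairs:
            di = m[:, i] - m[:, j]
            if np.all(di == 0.0):
                w, praw = 0.0, 1.0
            else:
                w, praw = _st.wilcoxon(m[:, i], m[:, j], zero_method="wilcox")
            eff.posthoc.append(
                PairwiseContrast(
                    velocities[i], velocities[j], float(w), float(praw),
                    min(1.0, float(praw) * k),
                )
            )
    return eff


def summarize(values: np.ndarray, alpha: float = 0.05) -> str:
    """mean ± SD when normal (Shapiro–Wilk), median (IQR) otherwise."""
    v = np.asarray(values, dtype=float)
    normal, _ = check_normality(v, alpha)
    if normal:
        return f"{v.mean():.3g} ± {v.std(ddof=1):.3g}"
    q1, q3 = np.percentile(v, [25, 75])
    return f"{np.median(v):.3g} ({q3 - q1:.3g})"
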