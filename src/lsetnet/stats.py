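"""Statistical comparison of classifiers: paired t, McNemar, Friedman,
and the Nemenyi critical difference.

All tests are two-tailed at alpha = 0.05 by default.  McNemar is used
without continuity correction: chi^2 = (b - c)^2 / (b + c) on the two
discordant counts.  Friedman uses midranks for ties and no tie
correction.  Degenerate inputs (zero-variance differences, b + c = 0)
are flagged rather than silently mapped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class StatTestResult:
    test: str
    statistic: float
    df: float
    p_value: float
    inputs: dict = field(default_factory=dict)
    alpha: float = 0.05
    two_tailed: bool = True
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < self.alpha


def paired_t(a, b, alpha: float = 0.05) -> StatTestResult:
    """Paired Student's t on per-fold scores: t = dbar / sqrt(s_d^2 / n).

    Sample variance uses the n-1 denominator; df = n - 1; two-tailed p.
    Zero-variance differences give a degenerate result (t = +-inf or
    nan), never a silent zero.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D score vectors with n >= 2")
    d = a - b
    n = len(d)
    dbar = d.mean()
    s2 = d.var(ddof=1)
    if s2 == 0.0:
        stat = np.nan if dbar == 0 else np.inf * np.sign(dbar)
        return StatTestResult("paired_t", float(stat), n - 1, np.nan,
                              inputs={"differences": d.tolist()}, alpha=alpha,
                              degenerate=True)
    t = dbar / np.sqrt(s2 / n)
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return StatTestResult("paired_t", float(t), n - 1, float(p),
                          inputs={"differences": d.tolist()}, alpha=alpha)


def mcnemar(b: int, c: int, alpha: float = 0.05) -> StatTestResult:
    """McNemar's test on discordant counts, without continuity correction."""
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        return StatTestResult("mcnemar", np.nan, 1, np.nan,
                              inputs={"b": b, "c": c}, alpha=alpha, degenerate=True)
    chi2 = (b - c) ** 2 / (b + c)
    p = float(sps.chi2.sf(chi2, df=1))
    return StatTestResult("mcnemar", float(chi2), 1, p,
                          inputs={"b": b, "c": c}, alpha=alpha)


def friedman(scores: np.ndarray, alpha: float = 0.05) -> StatTestResult:
    """Friedman rank test over an (N datasets x k models) score table:

        chi2_F = 12 N / (k (k + 1)) * sum_j R_j^2  -  3 N (k + 1)

    with R_j the column's average rank (midranks for ties); df = k - 1.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2:
        raise ValueError("scores must be a 2-D (datasets x models) table")
    n, k = scores.shape
    if k < 2:
        raise ValueError("need at least 2 models to compare")
    ranks = np.apply_along_axis(sps.rankdata, 1, scores)
    avg = ranks.mean(axis=0)
    chi2 = 12.0 * n / (k * (k + 1)) * float((avg ** 2).sum()) - 3.0 * n * (k + 1)
    chi2 = max(chi2, 0.0)  # guard tiny negative rounding at the all-tied point
    p = float(sps.chi2.sf(chi2, df=k - 1))
    return StatTestResult("friedman", float(chi2), k - 1, p,
                          inputs={"avg_ranks": avg.tolist(), "n": n, "k": k}, alpha=alpha)


# Nemenyi q_alpha values: studentized range q(k, inf) / sqrt(2)
_NEMENYI_Q = {
    0.05: {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850,
           7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164},
    0.01: {2: 2.576, 3: 2.913, 4: 3.113, 5: 3.255, 6: 3.364,
           7: 3.452, 8: 3.526, 9: 3.590, 10: 3.646},
}


def nemenyi_cd(k: int, n: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference: CD = q_alpha(k) * sqrt(k (k + 1) / (6 N)).

    Two average ranks differing by more than CD differ significantly.
    """
    if n < 1:
        raise ValueError("N must be >= 1")
    try:
        table = _NEMENYI_Q[alpha]
    except KeyError:
        raise ValueError(f"alpha must be one of {sorted(_NEMENYI_Q)}") from None
    if k not in table:
        raise ValueError(f"k={k} outside tabulated range {min(table)}..{max(table)}")
    return table[k] * np.sqrt(k * (k + 1) / (6.0 * n))


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
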