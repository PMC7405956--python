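"""The study's statistical battery.

* Bland-Altman agreement between repeat measurements (bias, 1.96·SD limits
  of agreement, and 95% confidence intervals of each).
* Normality-gated two-group comparison: the D'Agostino-Pearson omnibus test
  decides (P > 0.05 in both groups = normal), an F-ratio check flags
  unequal variances, and the comparison runs as a two-tailed unpaired
  t-test for normal/equal-variance data or a Mann-Whitney U test otherwise.
  The gate record makes the chosen path auditable.
* Mann-Whitney U with midranks for ties, reported as min(U₁, U₂); exact
  enumeration of the permutation null for small samples, tie-corrected
  normal approximation (with continuity correction) otherwise.
* Yates-corrected 2×2 chi-square for sex distributions.
* Seeded random selection of one eye per participant.

Standard statistics delegate to scipy.stats; this module fixes the study's
conventions (two-tailed everywhere, U = min, Yates correction, the gate
logic) on top of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "BlandAltmanResult",
    "GroupComparison",
    "bland_altman",
    "mann_whitney_u",
    "unpaired_t",
    "paired_t",
    "chi_square_2x2",
    "dagostino_pearson",
    "compare_groups",
    "select_random_eye",
    "EXACT_MW_MAX_N",
]

#: largest per-group n for which the Mann-Whitney null is enumerated exactly
EXACT_MW_MAX_N = 8

LOA_MULTIPLIER = 1.96


@dataclass
class BlandAltmanResult:
    """Agreement between two paired measurement sets (first − second)."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int
    ci_bias: tuple = (np.nan, np.nan)
    ci_loa_low: tuple = (np.nan, np.nan)
    ci_loa_high: tuple = (np.nan, np.nan)


def bland_altman(first: Sequence[float], second: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman bias and limits of agreement for paired measurements.

    Differences are first − second; bias is their mean, the limits of
    agreement are bias ± 1.96·SD.  95% CIs use the standard large-sample
    variance formulas: SE(bias) = SD/√n and SE(limit) = √3·SD/√n, with the
    t quantile on n−1 df.
    """
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired measurement sets must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo = bias - LOA_MULTIPLIER * sd
    hi = bias + LOA_MULTIPLIER * sd
    t = float(sps.t.ppf(0.975, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    return BlandAltmanResult(
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        sd_diff=sd,
        n=n,
        ci_bias=(bias - t * se_bias, bias + t * se_bias),
        ci_loa_low=(lo - t * se_loa, lo + t * se_loa),
        ci_loa_high=(hi - t * se_loa, hi + t * se_loa),
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(U_a, U_b) from midranks of the pooled sample."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    ra = ranks[: a.size].sum()
    ua = ra - a.size * (a.size + 1) / 2.0
    return float(ua), float(a.size * b.size - ua)


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Mann-Whitney U (reported as min(U₁, U₂)) and the two-tailed p-value.

    Ties receive midranks.  ``method='exact'`` enumerates every assignment
    of the pooled values to the two groups (valid with ties); ``'asymptotic'``
    uses the tie-corrected normal approximation with continuity correction.
    ``'auto'`` picks exact when both groups have ≤ 8 observations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ua, ub = _u_statistic(a, b)
    u = min(ua, ub)
    n1, n2 = a.size, b.size
    if method == "auto":
        method = "exact" if max(n1, n2) <= EXACT_MW_MAX_N else "asymptotic"
    if method == "exact":
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        half = n1 * n2 / 2.0
        dev = abs(ua - half)
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            ra = ranks[list(idx)].sum()
            ua_p = ra - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(ua_p - half) >= dev - 1e-12:
                count += 1
        p = count / total
    elif method == "asymptotic":
        n = n1 + n2
        pooled = np.concatenate([a, b])
        _, t_counts = np.unique(pooled, return_counts=True)
        tie_term = ((t_counts**3 - t_counts).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            return u, 1.0
        mu = n1 * n2 / 2.0
        # continuity correction toward the null
        z = (abs(ua - mu) - 0.5) / np.sqrt(sigma2)
        p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
    else:
        raise ValueError(f"unknown method {method!r}")
    return u, float(min(p, 1.0))


def _finite_t(stat, p, flag_note):
    if np.isnan(stat):
        return 0.0, 1.0, flag_note
    return float(stat), float(p), None


def unpaired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float]:
    """Classical two-tailed unpaired (pooled-variance) t-test: (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("unpaired t-test needs >= 2 observations per group")
    res = sps.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    t, p, _ = _finite_t(res.statistic, res.pvalue, "zero variance")
    return t, df, p


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Classical two-tailed paired t-test: (t, df, p).

    Identical vectors (zero mean difference with zero variance) return
    t = 0, p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("paired t-test needs >= 2 pairs")
    d = x - y
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, x.size - 1, 1.0
    res = sps.ttest_rel(x, y)
    t, p, _ = _finite_t(res.statistic, res.pvalue, "zero variance")
    return t, x.size - 1, p


def chi_square_2x2(table) -> tuple[float, float]:
    """Yates-corrected chi-square on a 2×2 contingency table: (χ², p)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("chi_square_2x2 expects a 2x2 table")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all table margins must be positive")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=True)
    return float(chi2), float(p)


def dagostino_pearson(x: Sequence[float]) -> tuple[float, float]:
    """D'Agostino-Pearson K² omnibus normality test: (K², p).

    Combines transformed sample skewness and kurtosis; p is from χ²(2).
    P > 0.05 is read as "consistent with normality".
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("D'Agostino-Pearson needs n >= 8")
    if np.all(x == x[0]):
        raise ValueError("normality test undefined for a constant sample")
    k2, p = sps.normaltest(x)
    return float(k2), float(p)


@dataclass
class GroupComparison:
    """Result of a normality-gated two-group comparison."""

    test: str  # "t" | "mann-whitney"
    statistic: float
    p: float
    df: int | None = None
    u: float | None = None
    gate: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p": self.p,
            "df": self.df,
            "u": self.u,
            "gate": self.gate,
        }


def _variance_gate(a: np.ndarray, b: np.ndarray, alpha: float) -> tuple[bool, float, float]:
    f = float(a.var(ddof=1) / b.var(ddof=1)) if b.var(ddof=1) > 0 else np.inf
    if not np.isfinite(f) or f <= 0:
        return False, f, 0.0
    p = 2.0 * min(
        sps.f.sf(f, a.size - 1, b.size - 1), sps.f.cdf(f, a.size - 1, b.size - 1)
    )
    p = float(min(p, 1.0))
    return p > alpha, f, p


def compare_groups(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> GroupComparison:
    """Two-group comparison with the study's decision gate.

    Both groups normal (D'Agostino-Pearson P > alpha) *and* variances not
    significantly different (two-tailed F-ratio at alpha) → two-tailed
    unpaired t-test; otherwise Mann-Whitney U.  Groups too small for the
    normality test (n < 8) fall through to Mann-Whitney with a flagged gate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    gate: dict = {"alpha": alpha}
    if min(a.size, b.size) < 8:
        gate["fallback"] = "group too small for the normality test (n < 8)"
        u, p = mann_whitney_u(a, b)
        return GroupComparison(test="mann-whitney", statistic=u, p=p, u=u, gate=gate)
    try:
        _, pa = dagostino_pearson(a)
        _, pb = dagostino_pearson(b)
    except ValueError as e:
        gate["fallback"] = f"normality test failed: {e}"
        u, p = mann_whitney_u(a, b)
        return GroupComparison(test="mann-whitney", statistic=u, p=p, u=u, gate=gate)
    eq_var, f, pf = _variance_gate(a, b, alpha)
    gate.update(
        normality_p_a=pa,
        normality_p_b=pb,
        normal_a=pa > alpha,
        normal_b=pb > alpha,
        variance_f=f,
        variance_p=pf,
        equal_variance=eq_var,
    )
    if pa > alpha and pb > alpha and eq_var:
        t, df, p = unpaired_t(a, b)
        return GroupComparison(test="t", statistic=t, p=p, df=df, gate=gate)
    u, p = mann_whitney_u(a, b)
    return GroupComparison(test="mann-whitney", statistic=u, p=p, u=u, gate=gate)


def select_random_eye(
    eyes_available: Mapping[str, Sequence[str]], seed: int
) -> dict[str, str]:
    """Uniformly pick one eye per participant, deterministically under seed.

    Participants with a single available eye keep that eye.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for pid in sorted(eyes_available):
        eyes = list(eyes_available[pid])
        if not eyes:
            raise ValueError(f"participant {pid} has no available eye")
        out[pid] = eyes[0] if len(eyes) == 1 else str(eyes[int(rng.integers(len(eyes)))])
    return out
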