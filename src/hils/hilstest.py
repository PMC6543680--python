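"""The invariants-based (Hils) test for hybrid species on one quartet.

For an ordered quartet (O, P1, H, P2) drawn from a hybrid species network
that mixes two parental species trees S1 (hybrid with P2) and S2 (hybrid
with P1) with weight ``gamma`` on S1, four linear phylogenetic invariants
in the cumulative site-pattern frequencies,

    f1 = p_iijj - p_ijij        f3 = p_ijii - p_iiji
    f2 = p_ijji - p_ijij        f4 = p_iiij - p_iiji,

satisfy f2 = f4 = 0 on S1 and f1 = f3 = 0 on S2, so each of the ratios
f1/f2, f3/f4 and (f1+f3)/(f2+f4) equals gamma/(1-gamma) on the mixture.
The ratio estimated from observed frequencies yields both a point
estimate of gamma and, via the Geary-Hinkley transformation of a ratio
of correlated normals, the Hils statistic H, which is compared to a
standard normal to test H0: gamma = 0 against H1: gamma > 0.  The same
statistic also covers gamma = 1 by the P1/P2 symmetry of the model.

The ABBA-BABA (Patterson's D) comparison on the same counts is provided
for reference; with taxa ordered (O, P1, H, P2) the ABBA class is iijj
(hybrid and P2 share the derived state) and the BABA class is ijij.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import norm

from .patterns import (
    CLASS_NAMES,
    CumulativeFrequencies,
    QuartetAssignment,
    SitePatternCounts,
    cumulative_frequencies,
)

__all__ = [
    "RATIOS",
    "InvariantSet",
    "MomentEstimates",
    "HilsResult",
    "DResult",
    "UndefinedStatisticError",
    "DegenerateStatisticError",
    "invariants",
    "estimate_gamma",
    "moment_estimates",
    "hils_statistic",
    "hils_test",
    "is_eliminated",
    "abba_baba",
]


class UndefinedStatisticError(ZeroDivisionError):
    """The denominator invariant (or ABBA+BABA total) is zero."""


class DegenerateStatisticError(ArithmeticError):
    """The variance expression under the square root is not positive."""


# class-coefficient vectors over (iijj, ijij, ijji, ijii, iiji, iiij)
_COEF = {
    "f1": np.array([1.0, -1.0, 0.0, 0.0, 0.0, 0.0]),
    "f2": np.array([0.0, -1.0, 1.0, 0.0, 0.0, 0.0]),
    "f3": np.array([0.0, 0.0, 0.0, 1.0, -1.0, 0.0]),
    "f4": np.array([0.0, 0.0, 0.0, 0.0, -1.0, 1.0]),
}

#: ratio name -> (numerator, denominator) coefficient vectors
RATIOS: Mapping[str, tuple[np.ndarray, np.ndarray]] = {
    "f1/f2": (_COEF["f1"], _COEF["f2"]),
    "f3/f4": (_COEF["f3"], _COEF["f4"]),
    "pooled": (_COEF["f1"] + _COEF["f3"], _COEF["f2"] + _COEF["f4"]),
}


@dataclass(frozen=True)
class InvariantSet:
    f1: float
    f2: float
    f3: float
    f4: float


@dataclass(frozen=True)
class MomentEstimates:
    """Plug-in multinomial moments of the numerator/denominator invariants.

    For linear combinations ``c.p_hat`` of multinomial class frequencies,
    ``Var(c.p_hat) = (sum c_i^2 p_i - (c.p)^2)/N`` and similarly for the
    covariance; with the f1/f2 coefficient vectors this reproduces the
    familiar three-term expansions in p_iijj, p_ijij, p_ijji.
    """

    mu_f1: float
    mu_f2: float
    var_f1: float
    var_f2: float
    cov_f1f2: float


@dataclass
class HilsResult:
    assignment: QuartetAssignment | None
    invariants: InvariantSet
    gamma_hat: float | None
    ratio_used: str
    H: float | None
    p_value: float | None
    eliminated: bool
    N: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return (
            not self.eliminated
            and self.p_value is not None
            and self.p_value < self.alpha
        )

    def to_dict(self) -> dict:
        d = {}
        if self.assignment is not None:
            d.update(
                outgroup=self.assignment.outgroup,
                parent1=self.assignment.parent1,
                hybrid=self.assignment.hybrid,
                parent2=self.assignment.parent2,
            )
        d.update(
            f1=self.invariants.f1, f2=self.invariants.f2,
            f3=self.invariants.f3, f4=self.invariants.f4,
            gamma_hat=self.gamma_hat, ratio=self.ratio_used,
            H=self.H, p_value=self.p_value,
            eliminated=self.eliminated, N=self.N,
        )
        return d


@dataclass(frozen=True)
class DResult:
    n_abba: float
    n_baba: float
    D: float
    z: float
    p_value: float


def _freq_vector(freqs: CumulativeFrequencies) -> np.ndarray:
    return np.array([getattr(freqs, f"p_{k}") for k in CLASS_NAMES])


def invariants(freqs: CumulativeFrequencies) -> InvariantSet:
    """Evaluate the four linear invariants on cumulative frequencies."""
    p = _freq_vector(freqs)
    return InvariantSet(*(float(_COEF[k] @ p) for k in ("f1", "f2", "f3", "f4")))


def _ratio_coefs(ratio: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        return RATIOS[ratio]
    except KeyError:
        raise ValueError(f"unknown ratio {ratio!r}; expected one of {list(RATIOS)}") from None


def estimate_gamma(freqs: CumulativeFrequencies, ratio: str = "f1/f2") -> float:
    """Estimate the mixing weight as r/(1+r) for the chosen invariant ratio.

    The estimate is not clamped to [0, 1]; sampling noise can push it
    slightly outside, and unbiasedness summaries rely on that.
    """
    cn, cd = _ratio_coefs(ratio)
    p = _freq_vector(freqs)
    num, den = float(cn @ p), float(cd @ p)
    if den == 0.0:
        raise UndefinedStatisticError("denominator invariant is zero")
    r = num / den
    if r == -1.0:  # ratio on the boundary; the transform has no finite value
        return float("nan")
    return r / (1.0 + r)


def moment_estimates(
    freqs: CumulativeFrequencies, N: float, ratio: str = "f1/f2"
) -> MomentEstimates:
    """Plug-in means, variances and covariance of the two invariants."""
    if N <= 0:
        raise ValueError("N must be positive")
    cn, cd = _ratio_coefs(ratio)
    p = _freq_vector(freqs)
    mu_n, mu_d = float(cn @ p), float(cd @ p)
    var_n = float((cn**2) @ p - mu_n**2) / N
    var_d = float((cd**2) @ p - mu_d**2) / N
    cov = float((cn * cd) @ p - mu_n * mu_d) / N
    return MomentEstimates(mu_n, mu_d, var_n, var_d, cov)


def hils_statistic(
    freqs: CumulativeFrequencies, N: float, ratio: str = "f1/f2"
) -> float:
    """The Geary-Hinkley-transformed invariant ratio under H0: gamma = 0.

    With R = f1_hat/f2_hat and the null ratio of means equal to zero,

        H = f2_hat * R / sqrt(var_f2 * R^2 - 2*cov*R + var_f1),

    which is asymptotically standard normal when gamma = 0.
    """
    m = moment_estimates(freqs, N, ratio)
    cn, cd = _ratio_coefs(ratio)
    p = _freq_vector(freqs)
    f_num, f_den = float(cn @ p), float(cd @ p)
    if f_den == 0.0:
        raise UndefinedStatisticError("denominator invariant is zero")
    r = f_num / f_den
    s2 = m.var_f2 * r * r - 2.0 * m.cov_f1f2 * r + m.var_f1
    if s2 <= 0.0:
        raise DegenerateStatisticError(
            "variance expression under the square root is not positive"
        )
    return float(f_den * r / np.sqrt(s2))


def is_eliminated(freqs: CumulativeFrequencies) -> bool:
    """Parental-pair elimination rule for one hybrid designation.

    The designation is discarded when p_ijij strictly exceeds both
    p_iijj and p_ijji: the pattern in which the two designated parents
    share a state dominating both hybrid-parent sharing patterns implies
    the designated parents are sisters, not the parents of the hybrid.
    """
    return freqs.p_ijij > max(freqs.p_iijj, freqs.p_ijji)


def hils_test(
    counts: SitePatternCounts,
    ratio: str = "f1/f2",
    alpha: float = 0.05,
    pseudocount: float = 0.005,
    pseudocount_mode: str = "off",
    assignment: QuartetAssignment | None = None,
) -> HilsResult:
    """Run the full hybridization test on one quartet's pattern counts.

    Returns a :class:`HilsResult`; when the elimination rule fires, the
    result carries the invariants but no statistic, estimate or p-value.
    The p-value is one-sided upper tail, ``1 - Phi(H)``; the same test
    covers both the gamma = 0 and gamma = 1 boundaries.
    """
    freqs = cumulative_frequencies(counts, pseudocount, pseudocount_mode)
    inv = invariants(freqs)
    if is_eliminated(freqs):
        return HilsResult(assignment, inv, None, ratio, None, None, True,
                          freqs.N, alpha)
    H = hils_statistic(freqs, freqs.N, ratio)
    gamma_hat = estimate_gamma(freqs, ratio)
    p_value = float(norm.sf(H))
    return HilsResult(assignment, inv, gamma_hat, ratio, H, p_value, False,
                      freqs.N, alpha)


def abba_baba(counts: SitePatternCounts) -> DResult:
    """Patterson's D comparison on the same ordered quartet.

    D = (ABBA - BABA) / (ABBA + BABA) with z = (ABBA - BABA)/sqrt(ABBA +
    BABA), the binomial normal approximation, and a two-sided p-value.
    """
    totals = counts.class_totals()
    n_abba, n_baba = totals["iijj"], totals["ijij"]
    tot = n_abba + n_baba
    if tot <= 0:
        raise UndefinedStatisticError("no ABBA or BABA sites observed")
    d = (n_abba - n_baba) / tot
    z = (n_abba - n_baba) / np.sqrt(tot)
    p = float(2.0 * norm.sf(abs(z)))
    return DResult(float(n_abba), float(n_baba), float(d), float(z), p)
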