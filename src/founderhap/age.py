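"""Founder-age estimation from shared-haplotype length.

A haplotype shared identically by descent erodes by recombination at a
rate proportional to the number of meioses separating the carriers from
the common ancestor. Two inversions of that relationship are provided:

* ``estimate_generations_length`` — the classic length approximation
  g = 100 / L_cM, which treats the shared segment as the overlap of two
  haplotypes each g meioses from the founder (expected length 1/g Morgans).
  This is the headline estimator and reproduces 125 generations for an
  800 kb (0.8 cM at 1 cM/Mb) haplotype.
* ``estimate_generations_model`` — a method-of-moments inversion aware of
  the number of homozygous carriers k: the shared interval is the
  intersection of 2k independently eroded segments, so its expected length
  is 1/(k g) Morgans and g = 100 / (k L_cM). At k = 1 this reduces exactly
  to the length approximation.

Under the Haldane segment model the shared length is Gamma(shape 2,
rate 2kg) distributed; the point inversion is therefore right-skewed
(its median is 2/1.678 ≈ 1.19 times the truth). An explicitly labelled
median-unbiased variant is available, and ``mc_confidence`` attaches a
parametric-bootstrap confidence interval.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.special import gammaincinv

from .simulate import sample_shared_length_morgans

__all__ = [
    "AgeMethod",
    "AgeEstimate",
    "GAMMA2_MEDIAN",
    "estimate_generations_length",
    "estimate_generations_model",
    "expected_shared_length",
    "mc_confidence",
]

# Median of Gamma(shape=2, rate=1); the factor by which the point inversion
# of a single Gamma(2)-distributed length overshoots the truth in median.
GAMMA2_MEDIAN: float = float(gammaincinv(2, 0.5))


class AgeMethod(str, enum.Enum):
    LENGTH_APPROXIMATION = "length_approximation"  # g = 100 / L_cM
    MODEL_INVERSION = "model_inversion"  # g = 100 / (k * L_cM)


@dataclass
class AgeEstimate:
    """Point estimate of generations to the most recent common ancestor."""

    g_point: float
    method: AgeMethod
    k: int = 1
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_level: float = 0.95
    n_sims: Optional[int] = None
    seed: Optional[int] = None
    warnings: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.g_point <= 0:
            raise ValueError("generation estimate must be positive")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.g_point <= self.ci_high):
                raise ValueError("confidence interval must bracket the point estimate")


def estimate_generations_length(length_cm: float) -> AgeEstimate:
    """Classic length approximation: g = 100 / L_cM."""
    if length_cm <= 0:
        raise ValueError("haplotype genetic length must be positive")
    return AgeEstimate(g_point=100.0 / length_cm, method=AgeMethod.LENGTH_APPROXIMATION, k=1)


def expected_shared_length(g: float, k: int) -> float:
    """Expected total shared-haplotype length (Morgans) among k carriers.

    Each side of the shared interval is the minimum of 2k Exponential(g)
    extents, so the expected total is 2/(2kg) = 1/(kg) Morgans.
    """
    if g <= 0:
        raise ValueError("g must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 / (k * g)


def estimate_generations_model(
    length_cm: float, k: int, median_unbiased: bool = False
) -> AgeEstimate:
    """Method-of-moments inversion g = 100 / (k * L_cM) for k carriers.

    With ``median_unbiased`` the estimate is multiplied by
    median(Gamma(2,1))/2 ≈ 0.839, which makes it median-unbiased under the
    Gamma(2, 2kg) distribution of the shared length; the default keeps the
    plain inversion.
    """
    if length_cm <= 0:
        raise ValueError("haplotype genetic length must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    g = 100.0 / (k * length_cm)
    if median_unbiased:
        g *= GAMMA2_MEDIAN / 2.0
    est = AgeEstimate(g_point=g, method=AgeMethod.MODEL_INVERSION, k=k)
    if median_unbiased:
        est.warnings.append("median-unbiased correction applied (x median(Gamma(2,1))/2)")
    return est


def _point(length_cm: float, k: int, method: AgeMethod) -> float:
    if method is AgeMethod.LENGTH_APPROXIMATION:
        return 100.0 / length_cm
    return 100.0 / (k * length_cm)


def mc_confidence(
    observed_cm: float,
    k: int,
    method: AgeMethod | str = AgeMethod.MODEL_INVERSION,
    n_sims: int = 1000,
    seed: int = 0,
    ci: str = "pivotal",
    ci_level: float = 0.95,
) -> AgeEstimate:
    """Parametric-bootstrap confidence interval for the generation estimate.

    At the point estimate ĝ, ``n_sims`` shared lengths are simulated from
    the segment model, the estimator is re-applied to each, and the
    2.5/97.5 bootstrap percentiles are formed. With ``ci="pivotal"``
    (default) they are mapped through the scale pivot ĝ*/ĝ — whose
    distribution is exactly that of ĝ/g under the Gamma segment model — to
    the interval [ĝ²/q_hi, ĝ²/q_lo]; ``ci="percentile"`` reports the raw
    percentiles [q_lo, q_hi] instead (anti-conservative here: ~84% actual
    coverage at nominal 95%). Deterministic given ``seed``.
    """
    if observed_cm <= 0:
        raise ValueError("observed genetic length must be positive")
    method = AgeMethod(method)
    if ci not in ("pivotal", "percentile"):
        raise ValueError(f"unknown ci method {ci!r}")
    g_hat = _point(observed_cm, k, method)
    est = AgeEstimate(
        g_point=g_hat, method=method, k=k, n_sims=n_sims, seed=seed, ci_level=ci_level
    )
    if n_sims < 100:
        est.warnings.append(
            f"n_sims={n_sims} is small; confidence interval will be unstable"
        )
    rng = np.random.default_rng(seed)
    lengths_cm = 100.0 * sample_shared_length_morgans(g_hat, k, rng, size=max(n_sims, 1))
    boots = np.array([_point(lc, k, method) for lc in lengths_cm])
    alpha = (1.0 - ci_level) / 2.0
    q_lo, q_hi = np.quantile(boots, [alpha, 1.0 - alpha])
    if ci == "pivotal":
        est.ci_low, est.ci_high = g_hat * g_hat / q_hi, g_hat * g_hat / q_lo
    else:
        est.ci_low, est.ci_high = float(q_lo), float(q_hi)
    # Guard the bracket invariant against degenerate bootstrap draws.
    est.ci_low = min(est.ci_low, g_hat)
    est.ci_high = max(est.ci_high, g_hat)
    return est
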