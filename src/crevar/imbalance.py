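"""Exact two-sided binomial test of cis allelic imbalance ("binomial ATAC").

At a heterozygous regulatory site, reads carrying the reference versus the
mutant allele are an internally calibrated readout of a variant's cis effect
on chromatin accessibility. With ``n`` informative reads, ``k`` reference
reads, and null reference-sampling probability ``pi0`` (0.5 for a balanced
heterozygote), the two-sided exact p-value sums the probability of every
outcome no more likely than the observed one:

    P = sum over { i : Pr(X = i) <= Pr(X = k) } of C(n, i) pi0^i (1-pi0)^(n-i)

Interval estimates use the exact Clopper-Pearson construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AlleleCountSet",
    "BinomialResult",
    "exact_binomial_two_sided",
    "allele_fraction_ci",
    "binomial_atac",
    "fraction_from_ratio",
]

#: relative slack when comparing pmf values, stabilising the "<=" of the
#: two-sided rule under floating point
_PMF_RTOL = 1e-7


@dataclass(frozen=True)
class AlleleCountSet:
    k: int  # reference (wildtype) read count
    n: int  # total informative reads
    pi0: float = 0.5
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.k <= self.n:
            raise ValueError("k must lie in [0, n]")
        if not 0 < self.pi0 < 1:
            raise ValueError("pi0 must lie strictly in (0, 1)")


@dataclass(frozen=True)
class BinomialResult:
    p_two_sided: float
    estimate: float
    ci95: tuple[float, float]
    k: int
    n: int
    ratio: float  # k / (n - k), reference over alternate


def exact_binomial_two_sided(counts: AlleleCountSet) -> float:
    """Two-sided exact binomial p by direct pmf summation."""
    i = np.arange(counts.n + 1)
    pmf = stats.binom.pmf(i, counts.n, counts.pi0)
    threshold = pmf[counts.k] * (1.0 + _PMF_RTOL)
    return float(min(1.0, pmf[pmf <= threshold].sum()))


def allele_fraction_ci(
    counts: AlleleCountSet, confidence: float = 0.95, method: str = "exact",
) -> BinomialResult:
    """Point estimate k/n with an exact (Clopper-Pearson) or Wilson interval."""
    k, n = counts.k, counts.n
    alpha = 1.0 - confidence
    if method == "exact":
        lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
        hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    elif method == "wilson":
        z = stats.norm.ppf(1 - alpha / 2)
        phat = k / n
        denom = 1 + z**2 / n
        centre = phat + z**2 / (2 * n)
        half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2))
        lo, hi = (centre - half) / denom, (centre + half) / denom
    else:
        raise ValueError(f"unknown CI method {method!r}")
    ratio = k / (n - k) if n > k else float("inf")
    return BinomialResult(
        p_two_sided=exact_binomial_two_sided(counts),
        estimate=k / n, ci95=(float(lo), float(hi)), k=k, n=n, ratio=ratio,
    )


def binomial_atac(
    replicates: Sequence[AlleleCountSet], pool: bool = True,
) -> tuple[BinomialResult, list[BinomialResult]]:
    """Pooled-and-per-replicate allelic-imbalance testing.

    Counts are summed across biological replicates and tested once
    (``pool=True``); per-replicate results are always reported alongside.
    """
    if not replicates:
        raise ValueError("no replicates supplied")
    pi0 = replicates[0].pi0
    if any(r.pi0 != pi0 for r in replicates):
        raise ValueError("replicates disagree on pi0")
    per = [allele_fraction_ci(r) for r in replicates]
    if pool:
        pooled = AlleleCountSet(
            k=sum(r.k for r in replicates), n=sum(r.n for r in replicates),
            pi0=pi0, replicate="pooled",
        )
        return allele_fraction_ci(pooled), per
    return per[0], per


def fraction_from_ratio(ratio: float) -> float:
    """Reference-allele fraction implied by a reference/alternate count ratio:
    r / (1 + r)."""
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    return ratio / (1.0 + ratio)
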