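"""Deletion-allele frequency from homozygote counts, with exact Poisson CI.

When a CNV region is typed in a follow-up sample (e.g. by qPCR), the
count k of deletion-homozygous individuals among n estimates the deletion
allele frequency under Hardy-Weinberg as sqrt(k/n).  Because k is a small
count it is modelled as Poisson; the exact (Garwood) chi-square interval
on the expected count maps monotonically to an allele-frequency interval
via f = sqrt(lambda/n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HomozygoteObservation:
    """k deletion-homozygous individuals observed among n sampled."""

    k: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.k <= self.n:
            raise ValueError(f"k={self.k} outside [0, n={self.n}]")


def allele_freq_from_homozygotes(obs: HomozygoteObservation) -> float:
    """HWE point estimate of the deletion-allele frequency, sqrt(k/n)."""
    return float(np.sqrt(obs.k / obs.n))


def poisson_ci_homozygotes(k: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) two-sided Poisson confidence interval on the expected
    homozygote count.

    lower = chi2.ppf(alpha/2, 2k)/2 (0 when k = 0);
    upper = chi2.ppf(1 - alpha/2, 2k + 2)/2.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.chi2.ppf(alpha / 2, 2 * k) / 2)
    upper = float(stats.chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2)
    return lower, upper


def allele_freq_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Percent confidence interval for the deletion-allele frequency.

    Maps the homozygote-count interval through the monotone transform
    f = sqrt(lambda/n) (coverage is preserved) and scales to percent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = poisson_ci_homozygotes(k, level)
    return 100.0 * float(np.sqrt(lo / n)), 100.0 * float(np.sqrt(hi / n))
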