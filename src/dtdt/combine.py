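"""Case-control allele test, dTDT stratum form, and Mantel-Haenszel pooling.

Both component tests are written as observed/expected/variance (O, E, Var)
strata so they pool in the Mantel-Haenszel form

    chi2_MH = (Σ_k (O_k − E_k))² / Σ_k Var_k     (1 df).

The case-control stratum is the 2×2 allele-count table with the exact
hypergeometric variance r1·r2·c1·c2 / (N²·(N−1)) — the classic MH variance,
equal to the Pearson chi-square times (N−1)/N.  The dTDT stratum is the 1×2
transmitted/non-transmitted table: O = Σb, E = (Σb+Σc)/2, Var = (Σb+Σc)/4,
whose chi-square reproduces (Σb−Σc)²/(Σb+Σc) exactly.

The module also carries the small p-value utilities used downstream:
Bonferroni thresholds, mean/variance summaries, and QQ-plot coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .core import chi2_pvalue

__all__ = [
    "AlleleCountTable",
    "StratumStats",
    "MantelHaenszelResult",
    "UndefinedStatisticError",
    "case_control_allele_test",
    "dtdt_stratum_stats",
    "mantel_haenszel_combine",
    "bonferroni_threshold",
    "summarize_pvalues",
    "qq_coordinates",
]


class UndefinedStatisticError(ValueError):
    """The statistic is undefined (zero margin or zero variance); skip the marker."""


@dataclass(frozen=True)
class AlleleCountTable:
    """Allele counts of one SNP in unrelated cases and controls.

    Counts may be real-valued (e.g. reconstructed from reported allele
    frequencies); each group's two allele counts must sum to twice its
    sample size.
    """

    n_cases: float
    n_controls: float
    a1_case: float
    a2_case: float
    a1_ctrl: float
    a2_ctrl: float

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "a1_case", "a2_case", "a1_ctrl", "a2_ctrl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not math.isclose(self.a1_case + self.a2_case, 2 * self.n_cases, abs_tol=1e-6):
            raise ValueError("case allele counts must sum to 2 * n_cases")
        if not math.isclose(self.a1_ctrl + self.a2_ctrl, 2 * self.n_controls, abs_tol=1e-6):
            raise ValueError("control allele counts must sum to 2 * n_controls")

    @classmethod
    def from_frequencies(
        cls, n_cases: float, n_controls: float, f_cs: float, f_cn: float
    ) -> "AlleleCountTable":
        """Build from allele-1 frequencies in cases (f_cs) and controls (f_cn)."""
        for name, f in (("f_cs", f_cs), ("f_cn", f_cn)):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name}={f!r} outside [0, 1]")
        return cls(
            n_cases=n_cases,
            n_controls=n_controls,
            a1_case=2 * n_cases * f_cs,
            a2_case=2 * n_cases * (1 - f_cs),
            a1_ctrl=2 * n_controls * f_cn,
            a2_ctrl=2 * n_controls * (1 - f_cn),
        )

    @property
    def f_cs(self) -> float:
        return self.a1_case / (2 * self.n_cases)

    @property
    def f_cn(self) -> float:
        return self.a1_ctrl / (2 * self.n_controls)

    @property
    def total(self) -> float:
        return 2 * (self.n_cases + self.n_controls)


@dataclass(frozen=True)
class StratumStats:
    """Observed/expected/variance triple of one stratum, ready for MH pooling."""

    observed: float
    expected: float
    variance: float
    source: str

    def __post_init__(self) -> None:
        if self.variance <= 0.0:
            raise UndefinedStatisticError(
                f"{self.source} stratum has non-positive variance {self.variance!r}"
            )

    @property
    def chi2(self) -> float:
        return (self.observed - self.expected) ** 2 / self.variance

    @property
    def p_value(self) -> float:
        return chi2_pvalue(self.chi2)


@dataclass(frozen=True)
class MantelHaenszelResult:
    chi2: float
    p_value: float
    direction: int  # sign of Σ(O − E)


def case_control_allele_test(table: AlleleCountTable) -> StratumStats:
    """O/E/Var of the allele-1-in-cases cell of the 2×2 allele-count table.

    O = a1_case; E = (allele-1 total)(case alleles)/N;
    Var = r1·r2·c1·c2 / (N²·(N−1))  (hypergeometric).

    Raises :class:`UndefinedStatisticError` on a zero margin (monomorphic
    marker or an empty group) — such markers are skipped, not patched.
    """
    N = table.total
    if N <= 1:
        raise UndefinedStatisticError("fewer than two alleles in total")
    r1 = table.a1_case + table.a1_ctrl
    r2 = table.a2_case + table.a2_ctrl
    c1 = 2 * table.n_cases
    c2 = 2 * table.n_controls
    if min(r1, r2, c1, c2) <= 0:
        raise UndefinedStatisticError("zero margin in the 2x2 allele table")
    expected = r1 * c1 / N
    variance = (r1 * r2 * c1 * c2) / (N * N * (N - 1))
    return StratumStats(
        observed=table.a1_case, expected=expected, variance=variance, source="case_control"
    )


def dtdt_stratum_stats(sum_b: float, sum_c: float) -> StratumStats:
    """O/E/Var of the dTDT's 1×2 transmitted/non-transmitted table.

    O = Σb, E = (Σb+Σc)/2, Var = (Σb+Σc)/4; the implied chi-square equals
    (Σb−Σc)²/(Σb+Σc).
    """
    if sum_b < 0 or sum_c < 0:
        raise ValueError("pseudo-counts must be non-negative")
    total = sum_b + sum_c
    if total <= 0:
        raise UndefinedStatisticError("no informative transmission mass")
    return StratumStats(
        observed=sum_b, expected=total / 2.0, variance=total / 4.0, source="dtdt"
    )


def mantel_haenszel_combine(strata: Sequence[StratumStats]) -> MantelHaenszelResult:
    """Pool strata: chi2 = (Σ(O−E))² / ΣVar against a 1-df chi-square."""
    strata = list(strata)
    if not strata:
        raise UndefinedStatisticError("no strata to combine")
    diff = sum(s.observed - s.expected for s in strata)
    var = sum(s.variance for s in strata)
    if var <= 0:
        raise UndefinedStatisticError("total variance is zero")
    chi2 = diff * diff / var
    direction = 0 if diff == 0 else (1 if diff > 0 else -1)
    return MantelHaenszelResult(chi2=chi2, p_value=chi2_pvalue(chi2), direction=direction)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m for m tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha!r} outside (0, 1)")
    if m < 1:
        raise ValueError(f"number of tests m={m!r} must be >= 1")
    return alpha / m


def summarize_pvalues(pvalues: Sequence[float]) -> Tuple[float, float]:
    """(mean, sample variance) of a p-value column.

    Mean uses denominator n; variance uses n − 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size < 2:
        raise ValueError("need at least two p-values to summarize")
    return float(p.mean()), float(p.var(ddof=1))


def qq_coordinates(pvalues: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """(expected, observed) −log10 p-value quantiles for a QQ plot.

    Observed: sorted −log10(p), descending.  Expected: −log10((i − 0.5)/n)
    for rank i = 1..n (the (i − 0.5)/n plotting position).  Without inflation
    the points track the diagonal.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    # ascending p gives descending -log10(p): largest signals first
    observed = -np.log10(np.sort(p))
    ranks = np.arange(1, p.size + 1)
    expected = -np.log10((ranks - 0.5) / p.size)
    return expected, observed
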