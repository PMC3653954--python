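"""Dosage transmission/disequilibrium test (dTDT) for parent-offspring trios.

The classic TDT counts, over heterozygous parents of affected children, how
often allele 1 versus allele 2 is transmitted, and compares the counts b and c
with a one-degree-of-freedom chi-square ``(b - c)**2 / (b + c)``.  When a trio
member is not genotyped but a posterior probability triple over its three
genotypes (a "dosage") is available from family-based inference or imputation,
hard transmission counts are unavailable.  The dTDT generalizes the TDT by
accumulating, per trio, the *expected* numbers of allele-1 and allele-2
transmissions from heterozygous parents implied by the trio's dosages, and
pools these real-valued pseudo-counts into the same chi-square form.

Per trio the pseudo-counts reduce to the closed form

    b_i = 2*p_c11 + p_c12 - p_f11 - p_m11
    c_i = (p_f12 + p_m12) - b_i

where ``p_x11, p_x12, p_x22`` are the genotype-probability triples of father
(f), mother (m) and child (c).  The identity ``b_i + c_i = p_f12 + p_m12``
always holds: a trio contributes exactly its expected number of heterozygous
parents.  When every dosage is 0 or 1 (hard, Mendelian-consistent genotypes)
the dTDT is numerically identical to the classic TDT.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GenotypeDosage",
    "TrioDosageSet",
    "TransmissionIncrement",
    "DtdtResult",
    "child_dosage_from_parents",
    "trio_increments",
    "dtdt_statistic",
    "classic_tdt",
    "chi2_pvalue",
    "chi2_neglog10_pvalue",
]

logger = logging.getLogger(__name__)

# validation slack for probability triples; inference and simulation produce
# triples exact to ~1e-15, file input is renormalized upstream
_SIMPLEX_TOL = 1e-6

# smallest positive subnormal double: keeps p-values in (0, 1] even when the
# chi-square survival function underflows
_TINY_P = 5e-324


@dataclass(frozen=True)
class GenotypeDosage:
    """Posterior probabilities of the three genotypes of a biallelic marker.

    ``p11``, ``p12``, ``p22`` are P(1/1), P(1/2) and P(2/2); they must form a
    probability simplex (each in [0, 1], summing to 1).
    """

    p11: float
    p12: float
    p22: float

    def __post_init__(self) -> None:
        total = self.p11 + self.p12 + self.p22
        if not math.isclose(total, 1.0, rel_tol=0.0, abs_tol=_SIMPLEX_TOL):
            raise ValueError(f"dosage components sum to {total!r}, expected 1")
        for name in ("p11", "p12", "p22"):
            v = getattr(self, name)
            if not (-_SIMPLEX_TOL <= v <= 1.0 + _SIMPLEX_TOL):
                raise ValueError(f"dosage component {name}={v!r} outside [0, 1]")

    @classmethod
    def point_mass(cls, genotype: int) -> "GenotypeDosage":
        """Hard-genotype dosage. ``genotype`` counts copies of allele 2 (0/1/2)."""
        if genotype not in (0, 1, 2):
            raise ValueError(f"genotype code must be 0, 1 or 2, got {genotype!r}")
        probs = [0.0, 0.0, 0.0]
        probs[genotype] = 1.0
        return cls(*probs)

    def as_array(self) -> np.ndarray:
        return np.array([self.p11, self.p12, self.p22])

    @property
    def max_prob(self) -> float:
        """Largest of the three genotype probabilities (call confidence)."""
        return max(self.p11, self.p12, self.p22)

    @property
    def is_hard(self) -> bool:
        """True when the dosage is (numerically) a point mass."""
        return self.max_prob >= 1.0 - _SIMPLEX_TOL


@dataclass(frozen=True)
class TrioDosageSet:
    """The 3x3 table of father/mother/child genotype posteriors at one marker."""

    trio_id: str
    marker_id: str
    father: GenotypeDosage
    mother: GenotypeDosage
    child: GenotypeDosage


@dataclass(frozen=True)
class TransmissionIncrement:
    """Per-trio expected transmission pseudo-counts.

    ``b_i`` and ``c_i`` are the expected numbers of allele-1 and allele-2
    transmissions from heterozygous parents; ``s_i = p_f12 + p_m12`` is the
    expected number of heterozygous parents (the trio's informativeness mass),
    and ``b_i + c_i == s_i`` by construction.  ``clamped`` records whether a
    raw increment fell outside [0, s_i] (possible only for dosage sets that
    are inconsistent with every transmission probability in [0, 1]) and was
    clamped back.
    """

    b_i: float
    c_i: float
    s_i: float
    clamped: bool = False


@dataclass(frozen=True)
class DtdtResult:
    """Pooled dTDT (or classic TDT) result for one marker."""

    marker_id: str
    sum_b: float
    sum_c: float
    t_hat: Optional[float]
    chi2: float
    p_value: float
    n_trios: int
    n_informative: int

    @property
    def neglog10_p(self) -> float:
        """-log10 of the p-value, computed on the log scale (no underflow)."""
        return chi2_neglog10_pvalue(self.chi2)


def chi2_pvalue(chi2: float) -> float:
    """Upper-tail probability of a 1-df chi-square, floored at the smallest
    positive double so downstream logs are finite."""
    return max(float(stats.chi2.sf(chi2, df=1)), _TINY_P)


def chi2_neglog10_pvalue(chi2: float) -> float:
    # 1-df chi-square tail is 2*P(Z > sqrt(x)); log_ndtr stays finite where
    # the direct survival function underflows
    from scipy.special import log_ndtr

    log_p = math.log(2.0) + float(log_ndtr(-math.sqrt(max(chi2, 0.0))))
    return -log_p / math.log(10.0)


def child_dosage_from_parents(
    father: GenotypeDosage, mother: GenotypeDosage, t: float
) -> GenotypeDosage:
    """Child dosage implied by parental dosages and transmission probability.

    ``t`` is the probability that a heterozygous parent transmits allele 1 to
    its affected child.  Under independent transmissions,

        p_c11 = (p_f11 + t*p_f12) * (p_m11 + t*p_m12)
        p_c22 = (p_f22 + (1-t)*p_f12) * (p_m22 + (1-t)*p_m12)
        p_c12 = 1 - p_c11 - p_c22
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"transmission probability t={t!r} outside [0, 1]")
    p_c11 = (father.p11 + t * father.p12) * (mother.p11 + t * mother.p12)
    p_c22 = (father.p22 + (1.0 - t) * father.p12) * (
        mother.p22 + (1.0 - t) * mother.p12
    )
    # algebraically in [0, 1]; guard the float dust at the boundary
    p_c12 = max(1.0 - p_c11 - p_c22, 0.0)
    return GenotypeDosage(p_c11, p_c12, p_c22)


def trio_increments(trio: TrioDosageSet, clamp: bool = True) -> TransmissionIncrement:
    """Expected transmission pseudo-counts for one trio.

    With ``clamp`` (the default) a raw ``b_i`` outside [0, s_i] — which can
    only arise from dosage triples inconsistent with any transmission
    probability in [0, 1], e.g. mixing posteriors from different sources — is
    clamped back into range, preserving ``b_i + c_i = s_i``, and flagged.
    """
    f, m, c = trio.father, trio.mother, trio.child
    s_i = f.p12 + m.p12
    if s_i <= 0.0:
        return TransmissionIncrement(0.0, 0.0, 0.0, clamped=False)
    b_i = 2.0 * c.p11 + c.p12 - f.p11 - m.p11
    clamped = False
    if clamp and not (0.0 <= b_i <= s_i):
        # only flag genuine inconsistencies, not float dust
        if b_i < -1e-12 or b_i > s_i + 1e-12:
            clamped = True
            logger.warning(
                "trio %s marker %s: raw increment b_i=%.6g outside [0, %.6g]; clamped",
                trio.trio_id,
                trio.marker_id,
                b_i,
                s_i,
            )
        b_i = min(max(b_i, 0.0), s_i)
    c_i = s_i - b_i
    return TransmissionIncrement(b_i, c_i, s_i, clamped=clamped)


def dtdt_statistic(
    increments: Iterable[TransmissionIncrement],
    marker_id: str = "",
    weights: Optional[Sequence[float]] = None,
) -> DtdtResult:
    """Pool per-trio pseudo-counts into the dTDT chi-square for one marker.

    chi2 = (sum_b - sum_c)**2 / (sum_b + sum_c), referred to a 1-df
    chi-square; the pooled transmission-probability estimate is
    t_hat = sum_b / (sum_b + sum_c).  With no informative mass the statistic
    is 0 and t_hat undefined.

    ``weights`` (optional, parallel to ``increments``) are multiplicities:
    weight w counts an increment as w identical trios.  Useful when many trios
    share the same dosage configuration.
    """
    increments = list(increments)
    if weights is None:
        weights = [1.0] * len(increments)
    else:
        weights = [float(w) for w in weights]
        if len(weights) != len(increments):
            raise ValueError("weights must parallel increments")
    sum_b = sum(w * inc.b_i for w, inc in zip(weights, increments))
    sum_c = sum(w * inc.c_i for w, inc in zip(weights, increments))
    n_trios = int(round(sum(weights)))
    n_informative = int(round(sum(w for w, inc in zip(weights, increments) if inc.s_i > 0)))
    total = sum_b + sum_c
    if total <= 0.0:
        return DtdtResult(marker_id, sum_b, sum_c, None, 0.0, 1.0, n_trios, n_informative)
    chi2 = (sum_b - sum_c) ** 2 / total
    return DtdtResult(
        marker_id=marker_id,
        sum_b=sum_b,
        sum_c=sum_c,
        t_hat=sum_b / total,
        chi2=chi2,
        p_value=chi2_pvalue(chi2),
        n_trios=n_trios,
        n_informative=n_informative,
    )


def classic_tdt(b: int, c: int, marker_id: str = "") -> DtdtResult:
    """Classic TDT on hard transmission counts from heterozygous parents.

    ``b`` and ``c`` are the observed numbers of allele-1 and allele-2
    transmissions.  Identical to :func:`dtdt_statistic` with unit hard
    increments; kept as the named special case.
    """
    for name, v in (("b", b), ("c", c)):
        if v < 0 or int(v) != v:
            raise ValueError(f"transmission count {name}={v!r} must be a non-negative integer")
    b, c = int(b), int(c)
    total = b + c
    if total == 0:
        return DtdtResult(marker_id, 0.0, 0.0, None, 0.0, 1.0, 0, 0)
    chi2 = (b - c) ** 2 / total
    return DtdtResult(
        marker_id=marker_id,
        sum_b=float(b),
        sum_c=float(c),
        t_hat=b / total,
        chi2=chi2,
        p_value=chi2_pvalue(chi2),
        n_trios=total,  # counts of transmissions, one per heterozygous parent
        n_informative=total,
    )
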