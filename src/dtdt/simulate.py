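"""Trio simulator under penetrance-parameterized disease models.

A biallelic disease locus D (low-risk allele D1, high-risk allele D2) with
Hardy-Weinberg genotype frequencies and penetrances f11, f12, f22 fixes the
population prevalence

    K = f11*p1**2 + 2*f12*p1*p2 + f22*p2**2.

Given K and the penetrances, the disease-allele frequency p1 is the admissible
root of the corresponding quadratic.  A tested SNP locus S is tied to D
through haplotype frequencies parameterized by the LD correlation coefficient
R (allele frequencies at S are set equal to those at D, which lets R span its
full range).  Conditioning on an affected child, the child's SNP genotype
distribution follows from enumerating ordered haplotype pairs weighted by the
penetrance of the implied disease genotype.

Each simulated trio has one affected child carrying a SNP genotype drawn from
that conditional distribution, plus a fully informative microsatellite: both
parents heterozygous with four distinct alleles (father 1/2, mother 3/4), the
child receiving one allele from each parent uniformly.  Because no
recombination fraction enters the model, the microsatellite is generated
independently of the SNP; its role is to mark the parents as linkage-genotyped
for trio extraction.

Three penetrance patterns are supported: dominant (f, g, g), recessive
(f, f, g) and codominant (f, g/2, g).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "DiseaseModel",
    "HaplotypeTable",
    "SimulatedTrio",
    "SettingRecord",
    "InvalidSettingError",
    "NonIdentifiableModelError",
    "solve_risk_allele_freq",
    "haplotype_frequencies",
    "affected_child_genotype_dist",
    "affected_joint_mass",
    "simulate_trio_set",
    "simulate_stratified_set",
    "simulate_hard_trio_counts",
    "parameter_grid",
    "MODELS",
    "penetrances_for_model",
]

logger = logging.getLogger(__name__)

MODELS = ("dominant", "recessive", "codominant")

_RESIDUAL_TOL = 1e-9

# the four child microsatellite genotypes: one paternal allele from {1, 2},
# one maternal from {3, 4}, each combination with probability 1/4
_MS_COMBOS = ((1, 3), (1, 4), (2, 3), (2, 4))


class InvalidSettingError(ValueError):
    """No admissible disease-allele frequency exists for the given setting."""


class NonIdentifiableModelError(ValueError):
    """Every allele frequency satisfies the prevalence identity (flat penetrances)."""


def penetrances_for_model(model: str, f: float, g: float) -> Tuple[float, float, float]:
    """(f11, f12, f22) for a named penetrance pattern."""
    if model == "dominant":
        return (f, g, g)
    if model == "recessive":
        return (f, f, g)
    if model == "codominant":
        return (f, 0.5 * g, g)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def solve_risk_allele_freq(
    K: float, f11: float, f12: float, f22: float
) -> Tuple[float, float]:
    """Solve the prevalence identity for the disease-allele frequencies.

    Returns ``(p1, p2)`` with ``p1`` the root in (0, 1) of

        (f11 - 2*f12 + f22) * p1**2 + 2*(f12 - f22) * p1 + (f22 - K) = 0.

    Raises :class:`InvalidSettingError` when no root lies in (0, 1) and
    :class:`NonIdentifiableModelError` when the penetrances are flat and equal
    to K (every frequency satisfies the identity).
    """
    for name, v in (("K", K), ("f11", f11), ("f12", f12), ("f22", f22)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v!r} outside [0, 1]")
    a = f11 - 2.0 * f12 + f22
    b = 2.0 * (f12 - f22)
    c = f22 - K
    eps = 1e-12
    roots: List[float] = []
    if abs(a) < eps:
        if abs(b) < eps:
            if abs(c) < eps:
                raise NonIdentifiableModelError(
                    "flat penetrances equal to prevalence: every p1 satisfies the identity"
                )
            raise InvalidSettingError("degenerate setting: no admissible p1")
        roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            raise InvalidSettingError("no real root for p1")
        sq = math.sqrt(disc)
        roots = [(-b + sq) / (2.0 * a), (-b - sq) / (2.0 * a)]
    admissible = sorted(r for r in roots if eps < r < 1.0 - eps)
    if not admissible:
        raise InvalidSettingError(f"no root in (0, 1); roots were {roots}")
    if len(admissible) == 2 and not math.isclose(admissible[0], admissible[1]):
        # prefer the larger p1: allele 2 (the higher-penetrance allele) is the
        # rarer risk allele, matching the usual disease-model convention
        logger.info(
            "two admissible roots %s; choosing p1=%.6g (rarer risk allele)",
            admissible,
            admissible[1],
        )
    p1 = admissible[-1]
    residual = f11 * p1 * p1 + 2.0 * f12 * p1 * (1 - p1) + f22 * (1 - p1) ** 2 - K
    if abs(residual) > _RESIDUAL_TOL:
        raise InvalidSettingError(f"prevalence residual {residual!r} exceeds tolerance")
    return p1, 1.0 - p1


@dataclass(frozen=True)
class HaplotypeTable:
    """Haplotype frequencies over disease locus D × SNP locus S.

    ``h[d][s]`` with d, s ∈ {1, 2}: h11 = freq(D1-S1), h12 = freq(D1-S2), etc.
    """

    h11: float
    h12: float
    h21: float
    h22: float

    def __post_init__(self) -> None:
        vals = (self.h11, self.h12, self.h21, self.h22)
        if any(v < -1e-12 for v in vals):
            raise ValueError(f"negative haplotype frequency in {vals}")
        if not math.isclose(sum(vals), 1.0, rel_tol=0.0, abs_tol=1e-9):
            raise ValueError(f"haplotype frequencies sum to {sum(vals)!r}, expected 1")

    def as_array(self) -> np.ndarray:
        """2x2 array indexed [d-1, s-1]."""
        return np.array([[self.h11, self.h12], [self.h21, self.h22]])


def haplotype_frequencies(p1: float, q1: float, R: float) -> HaplotypeTable:
    """Haplotype frequencies implied by an LD correlation coefficient R.

    h11 = p1*q1 + R*sqrt(p1*p2*q1*q2) and so on with alternating signs.
    Negative R is excluded by contract: with p = q it mirrors positive R
    without adding information.
    """
    if not 0.0 < p1 < 1.0 or not 0.0 < q1 < 1.0:
        raise ValueError("allele frequencies must lie in (0, 1)")
    if not 0.0 <= R <= 1.0:
        raise ValueError(f"R={R!r} outside [0, 1]")
    p2, q2 = 1.0 - p1, 1.0 - q1
    d = R * math.sqrt(p1 * p2 * q1 * q2)
    h = (p1 * q1 + d, p1 * q2 - d, p2 * q1 - d, p2 * q2 + d)
    # guaranteed non-negative when p == q and R in [0, 1]; clamp float dust
    h = tuple(0.0 if -1e-12 < v < 0.0 else v for v in h)
    if any(v < 0.0 for v in h):
        raise ValueError(f"R={R} with p1={p1}, q1={q1} yields negative haplotype frequency")
    return HaplotypeTable(*h)


def affected_joint_mass(
    h: HaplotypeTable, f11: float, f12: float, f22: float
) -> np.ndarray:
    """Unnormalized P(SNP genotype, child affected) by exact enumeration.

    Sums over the 16 ordered haplotype pairs: each pair contributes its
    frequency product times the penetrance of the implied disease genotype,
    accumulated by the implied SNP genotype (coded as copies of allele 2).
    The total equals the prevalence K when the model is self-consistent.
    """
    pen = (f11, f12, f22)
    harr = h.as_array()
    joint = np.zeros(3)
    for d_a in range(2):
        for s_a in range(2):
            for d_b in range(2):
                for s_b in range(2):
                    w = harr[d_a, s_a] * harr[d_b, s_b] * pen[d_a + d_b]
                    joint[s_a + s_b] += w
    return joint


def affected_child_genotype_dist(
    h: HaplotypeTable, f11: float, f12: float, f22: float
) -> np.ndarray:
    """P(SNP genotype | child affected): [P(1/1), P(1/2), P(2/2)]."""
    joint = affected_joint_mass(h, f11, f12, f22)
    total = joint.sum()
    if total <= 0.0:
        raise ValueError("all penetrances are zero: no affected children possible")
    return joint / total


@dataclass(frozen=True)
class DiseaseModel:
    """A fully specified simulation setting.

    ``K`` is the prevalence, ``f11 <= f12 <= f22`` are the penetrances of the
    disease-locus genotypes (allele 2 carries risk), ``R`` the LD correlation
    with the tested SNP.  ``p1, p2`` are the derived disease-allele
    frequencies; the SNP allele frequencies ``q1, q2`` are set equal to them.
    """

    model: str
    K: float
    f11: float
    f12: float
    f22: float
    R: float
    p1: float = field(default=None)  # type: ignore[assignment]
    p2: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.p1 is None:
            p1, p2 = solve_risk_allele_freq(self.K, self.f11, self.f12, self.f22)
            object.__setattr__(self, "p1", p1)
            object.__setattr__(self, "p2", p2)
        residual = (
            self.f11 * self.p1**2
            + 2.0 * self.f12 * self.p1 * self.p2
            + self.f22 * self.p2**2
            - self.K
        )
        if abs(residual) > _RESIDUAL_TOL:
            raise ValueError(f"prevalence identity violated: residual {residual!r}")

    @classmethod
    def from_penetrance(
        cls, model: str, K: float, f: float, g: float, R: float
    ) -> "DiseaseModel":
        """Build from the grid parameterization (f = low-genotype penetrance,
        g = high-genotype penetrance)."""
        f11, f12, f22 = penetrances_for_model(model, f, g)
        return cls(model=model, K=K, f11=f11, f12=f12, f22=f22, R=R)

    @property
    def q1(self) -> float:
        return self.p1

    @property
    def q2(self) -> float:
        return self.p2

    def haplotypes(self) -> HaplotypeTable:
        return haplotype_frequencies(self.p1, self.q1, self.R)

    def child_genotype_dist(self) -> np.ndarray:
        return affected_child_genotype_dist(self.haplotypes(), self.f11, self.f12, self.f22)


@dataclass(frozen=True)
class SimulatedTrio:
    """One trio: affected child's SNP genotype plus informative microsatellite.

    ``child_snp`` counts copies of SNP allele 2; microsatellite genotypes are
    allele pairs, father (1, 2) and mother (3, 4) by construction.
    """

    trio_id: str
    child_snp: int
    father_ms: Tuple[int, int] = (1, 2)
    mother_ms: Tuple[int, int] = (3, 4)
    child_ms: Tuple[int, int] = (1, 3)
    affected: bool = True
    label: str = ""


def _roulette(dist: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Roulette-wheel (inverse-CDF) sampling of genotype codes."""
    cum = np.cumsum(dist)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(n), side="right")


def simulate_trio_set(
    model: DiseaseModel,
    n: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    label: str = "",
) -> List[SimulatedTrio]:
    """Simulate ``n`` trios with affected children under ``model``.

    Child SNP genotypes are drawn by roulette wheel from the affected-child
    conditional distribution; the child's microsatellite genotype picks one
    paternal and one maternal allele uniformly.  Deterministic given
    ``seed`` (PCG64).
    """
    if n < 0:
        raise ValueError(f"n={n!r} must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    dist = model.child_genotype_dist()
    snp = _roulette(dist, n, rng)
    ms_idx = rng.integers(0, 4, size=n)
    prefix = f"{label}_" if label else ""
    return [
        SimulatedTrio(
            trio_id=f"{prefix}trio{i + 1}",
            child_snp=int(snp[i]),
            child_ms=_MS_COMBOS[ms_idx[i]],
            label=label,
        )
        for i in range(n)
    ]


def simulate_stratified_set(
    model_a: DiseaseModel,
    model_b: DiseaseModel,
    n_a: int,
    n_b: int,
    seed: Optional[int] = None,
) -> List[SimulatedTrio]:
    """Concatenate two independent simulations (e.g. two subpopulations).

    Sub-streams are spawned from ``seed`` via ``numpy`` ``SeedSequence``; the
    provenance of each trio is kept in its ``label`` (``"a"`` / ``"b"``).
    Pooling strata with different allele frequencies and analysing them with a
    single pooled frequency is the stratification scenario in which the test
    inflates.
    """
    ss_a, ss_b = np.random.SeedSequence(seed).spawn(2)
    trios = simulate_trio_set(model_a, n_a, rng=np.random.default_rng(ss_a), label="a")
    trios += simulate_trio_set(model_b, n_b, rng=np.random.default_rng(ss_b), label="b")
    return trios


def simulate_hard_trio_counts(
    n_trios: int,
    q1: float,
    t: float = 0.5,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Tuple[int, int]:
    """Transmission counts (b, c) from fully genotyped trios.

    Parents are drawn from HWE(q1); each heterozygous parent transmits
    allele 1 with probability ``t``.  Returns the classic-TDT counts for one
    simulated marker — the null-calibration workhorse (t = 0.5 is the null).
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t={t!r} outside [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    prior = np.array([q1 * q1, 2 * q1 * (1 - q1), (1 - q1) ** 2])
    parents = _roulette(prior, 2 * n_trios, rng)
    n_het = int(np.sum(parents == 1))
    b = int(np.sum(rng.random(n_het) < t))
    return b, n_het - b


@dataclass(frozen=True)
class SettingRecord:
    """One cell of the evaluation parameter grid."""

    model: str
    K: float
    R: float
    f: float
    g: float
    valid: bool
    p1: Optional[float] = None


def parameter_grid(
    Ks: Sequence[float] = (0.01, 0.1, 0.2),
    Rs: Sequence[float] = (0.5, 0.7, 0.9, 1.0),
    f_multipliers: Sequence[float] = (0.0, 0.1, 0.3, 0.5, 0.7, 0.9),
) -> List[SettingRecord]:
    """The full evaluation grid: 3 models × 3 K × (4 R × 6 f × 5 g) settings.

    Low-genotype penetrance f ranges over multiples of K; high-genotype
    penetrance g over {1.1K, 0.5, 0.7, 0.9, 1.0}.  Settings without an
    admissible disease-allele frequency are kept with ``valid=False``.
    """
    records: List[SettingRecord] = []
    for model in MODELS:
        for K in Ks:
            gs = (1.1 * K, 0.5, 0.7, 0.9, 1.0)
            for R in Rs:
                for fm in f_multipliers:
                    f = fm * K
                    for g in gs:
                        try:
                            p1, _ = solve_risk_allele_freq(
                                K, *penetrances_for_model(model, f, g)
                            )
                            records.append(SettingRecord(model, K, R, f, g, True, p1))
                        except (InvalidSettingError, NonIdentifiableModelError):
                            records.append(SettingRecord(model, K, R, f, g, False, None))
    return records
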