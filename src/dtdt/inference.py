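"""Exact genotype posteriors for un-genotyped members of nuclear families.

Full-pedigree multipoint inference (Lander-Green style, as implemented in
linkage packages) is out of scope here; this module computes the exact
single-marker posterior for a nuclear family by enumerating the nine ordered
parental genotype pairs under a Hardy-Weinberg founder prior and Mendelian
transmission, conditioning on whichever members are observed.  For a trio with
one observed child this is the textbook parent-posterior; with several
children the evidence accumulates through the product of Mendelian terms.

Genotypes are coded as the number of copies of allele 2: 0 = 1/1, 1 = 1/2,
2 = 2/2; ``None`` marks a missing genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GenotypeDosage, TrioDosageSet

__all__ = [
    "NuclearFamilyObservation",
    "MendelianInconsistencyError",
    "parental_posterior",
    "family_posterior",
    "estimate_allele_freq",
    "apply_dosage_threshold",
    "mendel_matrix",
    "hwe_prior",
]

_FREQ_EPS = 1e-6


class MendelianInconsistencyError(ValueError):
    """Observed genotypes in a family are impossible under Mendelian transmission."""

    def __init__(self, family_id: str, message: str = "") -> None:
        self.family_id = family_id
        super().__init__(
            f"family {family_id!r}: observations are Mendelian-impossible"
            + (f" ({message})" if message else "")
        )


def hwe_prior(q1: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities [P(1/1), P(1/2), P(2/2)]."""
    if not 0.0 < q1 < 1.0:
        raise ValueError(f"allele frequency q1={q1!r} outside (0, 1)")
    q2 = 1.0 - q1
    return np.array([q1 * q1, 2.0 * q1 * q2, q2 * q2])


def mendel_matrix() -> np.ndarray:
    """M[gf, gm, gc] = P(child genotype gc | father gf, mother gm).

    Each parent transmits allele 2 with probability 0, 1/2 or 1 according to
    its genotype; the child's code is the sum of two independent Bernoulli
    transmissions.
    """
    m = np.zeros((3, 3, 3))
    trans2 = np.array([0.0, 0.5, 1.0])  # P(transmit allele 2 | genotype)
    for gf in range(3):
        for gm in range(3):
            tf, tm = trans2[gf], trans2[gm]
            m[gf, gm, 0] = (1 - tf) * (1 - tm)
            m[gf, gm, 1] = tf * (1 - tm) + (1 - tf) * tm
            m[gf, gm, 2] = tf * tm
    return m


_MENDEL = mendel_matrix()


@dataclass(frozen=True)
class NuclearFamilyObservation:
    """Observed single-marker genotypes of one nuclear family.

    ``children_genotypes`` holds one entry per child (``None`` = missing);
    ``father_genotype``/``mother_genotype`` are usually ``None`` — the whole
    point is inferring them.  ``allele1_freq`` is the founder-prior frequency
    of allele 1.
    """

    family_id: str
    children_genotypes: Tuple[Optional[int], ...]
    father_genotype: Optional[int] = None
    mother_genotype: Optional[int] = None
    allele1_freq: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "children_genotypes", tuple(self.children_genotypes))
        if not 0.0 < self.allele1_freq < 1.0:
            raise ValueError(f"allele1_freq={self.allele1_freq!r} outside (0, 1)")
        observed = [g for g in self.all_genotypes() if g is not None]
        if not observed:
            raise ValueError(f"family {self.family_id!r} has no observed genotype")
        for g in observed:
            if g not in (0, 1, 2):
                raise ValueError(f"genotype code {g!r} must be 0, 1, 2 or None")

    def all_genotypes(self) -> List[Optional[int]]:
        return [self.father_genotype, self.mother_genotype, *self.children_genotypes]


def parental_posterior(
    child_genotype: int,
    q1: float,
    trio_id: str = "",
    marker_id: str = "",
) -> TrioDosageSet:
    """Exact parental genotype posteriors given one observed child.

    The child's dosage is a point mass on its observed genotype; each parent's
    dosage is the marginal of P(G_f, G_m | G_c) over the nine ordered parental
    pairs, with HWE(q1) priors and Mendelian transmission.
    """
    fam = NuclearFamilyObservation(
        family_id=trio_id or "trio",
        children_genotypes=(child_genotype,),
        allele1_freq=q1,
    )
    post = family_posterior(fam)
    return TrioDosageSet(
        trio_id=trio_id,
        marker_id=marker_id,
        father=post["father"],
        mother=post["mother"],
        child=post["child_1"],
    )


def family_posterior(family: NuclearFamilyObservation) -> Dict[str, GenotypeDosage]:
    """Exact single-marker posteriors for every member of a nuclear family.

    Enumerates the nine ordered parental genotype pairs, weighting each by the
    HWE founder prior, observed-parent constraints, and the product of
    Mendelian likelihoods over observed children; children conditionally
    independent given the parents.  Keys of the result are ``"father"``,
    ``"mother"`` and ``"child_<k>"`` (1-based).
    """
    prior = hwe_prior(family.allele1_freq)
    fw = prior.copy()
    mw = prior.copy()
    if family.father_genotype is not None:
        mask = np.zeros(3)
        mask[family.father_genotype] = 1.0
        fw = fw * mask
    if family.mother_genotype is not None:
        mask = np.zeros(3)
        mask[family.mother_genotype] = 1.0
        mw = mw * mask

    # joint[gf, gm] ∝ prior terms × Π_observed-children Mendel
    joint = np.outer(fw, mw)
    for g in family.children_genotypes:
        if g is not None:
            joint = joint * _MENDEL[:, :, g]
    total = joint.sum()
    if total <= 0.0:
        raise MendelianInconsistencyError(family.family_id)
    joint /= total

    out: Dict[str, GenotypeDosage] = {
        "father": GenotypeDosage(*joint.sum(axis=1)),
        "mother": GenotypeDosage(*joint.sum(axis=0)),
    }
    for k, g in enumerate(family.children_genotypes, start=1):
        if g is not None:
            out[f"child_{k}"] = GenotypeDosage.point_mass(g)
        else:
            probs = np.einsum("fm,fmc->c", joint, _MENDEL)
            out[f"child_{k}"] = GenotypeDosage(*probs)
    return out


def estimate_allele_freq(
    genotypes: Iterable[Optional[int]], eps: float = _FREQ_EPS
) -> float:
    """Allele-1 frequency from observed genotype codes (copies of allele 2).

    q̂1 = (allele-1 count) / (2 × non-missing count), clipped to
    [eps, 1 - eps] so HWE priors never put zero mass on a genotype.
    """
    observed = [g for g in genotypes if g is not None]
    if not observed:
        raise ValueError("cannot estimate allele frequency: all genotypes missing")
    for g in observed:
        if g not in (0, 1, 2):
            raise ValueError(f"genotype code {g!r} must be 0, 1 or 2")
    n = len(observed)
    allele1 = sum(2 - g for g in observed)
    return float(np.clip(allele1 / (2.0 * n), eps, 1.0 - eps))


def apply_dosage_threshold(
    dosage_table: pd.DataFrame, tau: float = 0.8
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Filter low-confidence dosage rows.

    A row (one individual at one marker) is retained iff its largest genotype
    probability is at least ``tau``; below that the inference is considered
    too uncertain to use.  A cut-off around 0.7-0.8 keeps inference quality
    high without discarding most of the sample.

    Returns ``(filtered_table, report)`` where ``report`` has one row per
    marker with ``retained`` and ``dropped`` counts.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau={tau!r} outside [0, 1]")
    required = {"marker", "p11", "p12", "p22"}
    missing = required - set(dosage_table.columns)
    if missing:
        raise ValueError(f"dosage table missing columns: {sorted(missing)}")
    maxp = dosage_table[["p11", "p12", "p22"]].max(axis=1)
    keep = maxp >= tau
    filtered = dosage_table.loc[keep].reset_index(drop=True)
    report = (
        pd.DataFrame({"marker": dosage_table["marker"], "retained": keep})
        .groupby("marker", sort=True)["retained"]
        .agg(retained="sum", total="count")
        .reset_index()
    )
    report["retained"] = report["retained"].astype(int)
    report["dropped"] = report["total"] - report["retained"]
    return filtered, report[["marker", "retained", "dropped", "total"]]
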