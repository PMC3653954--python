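"""Glue for the simulate → infer → dTDT single-marker pipeline.

Simulated parents carry only the informative microsatellite; their SNP
dosages come from the exact trio posterior given the child's observed SNP
genotype and a population allele frequency.  Because that posterior depends
only on the child's genotype and q1, trios sharing a child genotype share an
increment, so the pooled statistic is computed from the three genotype
classes with multiplicity weights — numerically identical to looping over
trios, and fast enough for replicate studies.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .core import DtdtResult, TrioDosageSet, dtdt_statistic, trio_increments
from .inference import estimate_allele_freq, parental_posterior
from .simulate import DiseaseModel, SimulatedTrio, simulate_trio_set

__all__ = [
    "trio_dosage_sets",
    "dtdt_from_child_genotypes",
    "run_trio_pipeline",
]


def trio_dosage_sets(
    trios: Iterable[SimulatedTrio], q1: float, marker_id: str = "snp1"
) -> List[TrioDosageSet]:
    """Infer parental dosages for simulated trios (child SNP observed only)."""
    return [
        parental_posterior(t.child_snp, q1, trio_id=t.trio_id, marker_id=marker_id)
        for t in trios
    ]


def dtdt_from_child_genotypes(
    child_genotypes: Sequence[int], q1: float, marker_id: str = "snp1"
) -> DtdtResult:
    """dTDT over trios whose parents are inferred from the child genotype alone.

    Groups identical child genotypes and weights the per-class increment by
    its multiplicity; exact, not an approximation.
    """
    counts = Counter(int(g) for g in child_genotypes)
    increments = []
    weights = []
    for g, n in sorted(counts.items()):
        trio = parental_posterior(g, q1, trio_id=f"class_g{g}", marker_id=marker_id)
        increments.append(trio_increments(trio))
        weights.append(n)
    return dtdt_statistic(increments, marker_id=marker_id, weights=weights)


def run_trio_pipeline(
    model: DiseaseModel,
    n_trios: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    q1: Optional[float] = None,
    marker_id: str = "snp1",
) -> DtdtResult:
    """Simulate ``n_trios`` under ``model``, infer parents, run the dTDT.

    ``q1`` is the external allele-frequency estimate used for inference; by
    default the model's own population frequency (what a linkage study with
    good reference data would supply).  Pass ``q1="children"`` to estimate it
    from the affected children instead — biased towards the risk allele, which
    shrinks the apparent transmission distortion.
    """
    trios = simulate_trio_set(model, n_trios, seed=seed, rng=rng)
    if q1 is None:
        freq = model.q1
    elif q1 == "children":
        freq = estimate_allele_freq([t.child_snp for t in trios])
    else:
        freq = float(q1)
    return dtdt_from_child_genotypes(
        [t.child_snp for t in trios], freq, marker_id=marker_id
    )
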