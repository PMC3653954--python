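"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pytest

from dtdt.core import GenotypeDosage, TrioDosageSet
from dtdt.inference import NuclearFamilyObservation


def random_dosage(rng: np.random.Generator) -> GenotypeDosage:
    """A random point on the genotype-probability simplex."""
    p = rng.dirichlet(np.ones(3))
    return GenotypeDosage(*p)


def sample_hard_trio(rng: np.random.Generator, q1: float, t: float = 0.5):
    """Fully genotyped Mendelian trio; genotypes count copies of allele 2.

    Heterozygous parents transmit allele 1 with probability ``t``.
    Returns (gf, gm, gc).
    """
    prior = [q1 * q1, 2 * q1 * (1 - q1), (1 - q1) ** 2]
    gf, gm = rng.choice(3, size=2, p=prior)
    transmitted2 = 0
    for g in (gf, gm):
        if g == 2:
            transmitted2 += 1
        elif g == 1:
            transmitted2 += int(rng.random() >= t)  # allele 1 w.p. t
    return int(gf), int(gm), transmitted2


def count_transmissions(gf: int, gm: int, gc: int) -> Tuple[int, int]:
    """Classic-TDT transmission counts (b, c) from one hard trio.

    Derived by constraint propagation: each parent's transmitted allele is
    fixed by the child genotype minus the other parent's forced contribution;
    the het x het child-het case splits 1/1 deterministically.
    """
    solutions = []
    for tf in (0, 1):
        for tm in (0, 1):
            if gf == 0 and tf == 1 or gf == 2 and tf == 0:
                continue
            if gm == 0 and tm == 1 or gm == 2 and tm == 0:
                continue
            if tf + tm == gc:
                solutions.append((tf, tm))
    assert solutions, f"Mendelian-impossible trio {(gf, gm, gc)}"
    # all solutions agree on the per-het-parent allele-1 count
    b = c = 0
    tf, tm = solutions[0]
    if gf == 1:
        b += 1 - tf
        c += tf
    if gm == 1:
        b += 1 - tm
        c += tm
    return b, c


def brute_force_family_posterior(
    family: NuclearFamilyObservation,
) -> Dict[str, np.ndarray]:
    """Oracle: enumerate all 3**(2 + k) genotype configurations directly."""
    q1 = family.allele1_freq
    q2 = 1.0 - q1
    prior = np.array([q1 * q1, 2 * q1 * q2, q2 * q2])
    trans2 = [0.0, 0.5, 1.0]

    def mendel(gp: int, gq: int, gc: int) -> float:
        tf, tm = trans2[gp], trans2[gq]
        return [
            (1 - tf) * (1 - tm),
            tf * (1 - tm) + (1 - tf) * tm,
            tf * tm,
        ][gc]

    k = len(family.children_genotypes)
    members = ["father", "mother"] + [f"child_{j}" for j in range(1, k + 1)]
    post = {m: np.zeros(3) for m in members}
    total = 0.0
    for config in itertools.product(range(3), repeat=2 + k):
        gf, gm, *kids = config
        w = prior[gf] * prior[gm]
        if family.father_genotype is not None and gf != family.father_genotype:
            continue
        if family.mother_genotype is not None and gm != family.mother_genotype:
            continue
        ok = True
        for j, gc in enumerate(kids):
            obs = family.children_genotypes[j]
            if obs is not None and gc != obs:
                ok = False
                break
            w *= mendel(gf, gm, gc)
        if not ok or w == 0.0:
            continue
        total += w
        post["father"][gf] += w
        post["mother"][gm] += w
        for j, gc in enumerate(kids):
            post[f"child_{j + 1}"][gc] += w
    assert total > 0.0, "oracle: zero total mass"
    return {m: v / total for m, v in post.items()}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
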