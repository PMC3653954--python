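"""Tests for the disease-model trio simulator and the evaluation grid."""

from __future__ import annotations

import math

import numpy as np
import pytest

from dtdt.pipeline import dtdt_from_child_genotypes
from dtdt.simulate import (
    MODELS,
    DiseaseModel,
    HaplotypeTable,
    InvalidSettingError,
    NonIdentifiableModelError,
    affected_child_genotype_dist,
    affected_joint_mass,
    haplotype_frequencies,
    parameter_grid,
    penetrances_for_model,
    simulate_hard_trio_counts,
    simulate_stratified_set,
    simulate_trio_set,
    solve_risk_allele_freq,
)


class TestSolveRiskAlleleFreq:
    def test_dominant_closed_form(self):
        # f11=0, f12=f22=g: K = g*(1 - p1^2)  =>  p1 = sqrt((g-K)/g)
        p1, p2 = solve_risk_allele_freq(0.01, 0.0, 0.5, 0.5)
        assert p1 == pytest.approx(math.sqrt((0.5 - 0.01) / 0.5), abs=1e-12)

    def test_recessive_closed_form(self):
        # f11=f12=0, f22=g: K = g*p2^2  =>  p2 = sqrt(K/g)
        p1, p2 = solve_risk_allele_freq(0.01, 0.0, 0.0, 0.5)
        assert p2 == pytest.approx(math.sqrt(0.01 / 0.5), abs=1e-12)
        assert p1 == pytest.approx(1.0 - math.sqrt(0.02), abs=1e-12)

    def test_prevalence_identity_residual(self):
        for model in MODELS:
            p1, p2 = solve_risk_allele_freq(
                0.1, *penetrances_for_model(model, 0.03, 0.7)
            )
            f11, f12, f22 = penetrances_for_model(model, 0.03, 0.7)
            K = f11 * p1**2 + 2 * f12 * p1 * p2 + f22 * p2**2
            assert K == pytest.approx(0.1, abs=1e-9)

    def test_flat_penetrances_non_identifiable(self):
        with pytest.raises(NonIdentifiableModelError):
            solve_risk_allele_freq(0.01, 0.01, 0.01, 0.01)

    def test_unreachable_prevalence_invalid(self):
        # penetrances all below K: no frequency attains the prevalence
        with pytest.raises(InvalidSettingError):
            solve_risk_allele_freq(0.2, 0.1, 0.1, 0.1)


class TestHaplotypeFrequencies:
    def test_independence_at_r0(self):
        h = haplotype_frequencies(0.3, 0.3, 0.0)
        assert h.h11 == pytest.approx(0.09)
        assert h.h12 == pytest.approx(0.21)

    def test_perfect_ld(self):
        h = haplotype_frequencies(0.3, 0.3, 1.0)
        assert h.as_array() == pytest.approx(np.array([[0.3, 0.0], [0.0, 0.7]]))

    def test_intermediate_value(self):
        p1 = 0.8585786437626904
        h = haplotype_frequencies(p1, p1, 0.7)
        assert h.h11 == pytest.approx(p1**2 + 0.7 * p1 * (1 - p1), abs=1e-12)

    def test_negative_r_excluded(self):
        with pytest.raises(ValueError):
            haplotype_frequencies(0.3, 0.3, -0.5)

    def test_normalization_across_grid(self):
        for s in parameter_grid():
            if not s.valid:
                continue
            h = haplotype_frequencies(s.p1, s.p1, s.R)
            arr = h.as_array().ravel()
            assert arr.sum() == pytest.approx(1.0, abs=1e-9)
            assert (arr >= 0).all()


class TestAffectedChildGenotypeDist:
    def test_perfect_ld_collapses_to_disease_locus(self):
        m = DiseaseModel.from_penetrance("recessive", 0.01, 0.0, 0.5, 1.0)
        dist = m.child_genotype_dist()
        # S == D: P(S=2/2 | affected) = p2^2 * f22 / K
        assert dist[2] == pytest.approx(m.p2**2 * 0.5 / 0.01, abs=1e-9)
        assert dist[0] == pytest.approx(0.0, abs=1e-12)

    def test_no_ld_gives_hwe_regardless_of_penetrance(self):
        m = DiseaseModel.from_penetrance("dominant", 0.1, 0.02, 0.7, 0.0)
        dist = m.child_genotype_dist()
        q1 = m.q1
        assert dist == pytest.approx(
            [q1**2, 2 * q1 * (1 - q1), (1 - q1) ** 2], abs=1e-12
        )

    def test_matches_diplotype_brute_force(self):
        """16-pair enumeration vs an independent sum over (D, S) diplotypes."""
        m = DiseaseModel.from_penetrance("recessive", 0.01, 0.0, 0.5, 0.7)
        h = m.haplotypes().as_array()
        pen = (m.f11, m.f12, m.f22)
        joint = np.zeros(3)
        for da in (0, 1):
            for db in (0, 1):
                for sa in (0, 1):
                    for sb in (0, 1):
                        joint[sa + sb] += h[da, sa] * h[db, sb] * pen[da + db]
        expected = joint / joint.sum()
        assert m.child_genotype_dist() == pytest.approx(expected, abs=1e-12)

    def test_prevalence_identity_across_grid(self):
        """Joint P(S, affected) sums to K for every valid setting."""
        for s in parameter_grid():
            if not s.valid:
                continue
            h = haplotype_frequencies(s.p1, s.p1, s.R)
            mass = affected_joint_mass(h, *penetrances_for_model(s.model, s.f, s.g))
            assert mass.sum() == pytest.approx(s.K, abs=1e-9), s

    def test_all_zero_penetrances_rejected(self):
        h = haplotype_frequencies(0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            affected_child_genotype_dist(h, 0.0, 0.0, 0.0)


class TestSimulateTrioSet:
    @pytest.fixture
    def model(self):
        return DiseaseModel.from_penetrance("recessive", 0.01, 0.0, 0.5, 1.0)

    def test_empty(self, model):
        assert simulate_trio_set(model, 0, seed=1) == []

    def test_determinism(self, model):
        a = simulate_trio_set(model, 50, seed=42)
        b = simulate_trio_set(model, 50, seed=42)
        assert a == b
        c = simulate_trio_set(model, 50, seed=43)
        assert a != c

    def test_microsatellite_structure(self, model):
        for t in simulate_trio_set(model, 20, seed=7):
            assert t.father_ms == (1, 2) and t.mother_ms == (3, 4)
            assert t.child_ms[0] in (1, 2) and t.child_ms[1] in (3, 4)
            assert t.affected

    def test_empirical_frequencies_match_analytic(self):
        m = DiseaseModel.from_penetrance("recessive", 0.01, 0.0, 0.5, 0.9)
        n = 10_000
        trios = simulate_trio_set(m, n, seed=5)
        dist = m.child_genotype_dist()
        counts = np.bincount([t.child_snp for t in trios], minlength=3)
        for g in range(3):
            se = math.sqrt(dist[g] * (1 - dist[g]) / n)
            assert abs(counts[g] / n - dist[g]) < 3 * se + 1e-9

    def test_stratified_partitions_and_reduces(self, model):
        other = DiseaseModel.from_penetrance("dominant", 0.2, 0.0, 0.5, 1.0)
        trios = simulate_stratified_set(model, other, 30, 20, seed=9)
        labels = [t.label for t in trios]
        assert labels == ["a"] * 30 + ["b"] * 20
        # stratum a reproduces a plain simulation under its spawned sub-stream
        ss_a, _ = np.random.SeedSequence(9).spawn(2)
        solo = simulate_trio_set(model, 30, rng=np.random.default_rng(ss_a), label="a")
        assert trios[:30] == solo
        only_a = simulate_stratified_set(model, other, 30, 0, seed=9)
        assert only_a == trios[:30]


class TestHardTrioCounts:
    def test_counts_bounded_and_deterministic(self):
        b, c = simulate_hard_trio_counts(500, q1=0.5, t=0.5, seed=3)
        b2, c2 = simulate_hard_trio_counts(500, q1=0.5, t=0.5, seed=3)
        assert (b, c) == (b2, c2)
        assert 0 <= b + c <= 1000

    def test_full_distortion(self):
        b, c = simulate_hard_trio_counts(200, q1=0.5, t=1.0, seed=3)
        assert c == 0 and b > 0


class TestParameterGrid:
    def test_raw_group_sizes(self):
        grid = parameter_grid()
        assert len(grid) == 3 * 3 * 120
        for model in MODELS:
            for K in (0.01, 0.1, 0.2):
                group = [s for s in grid if s.model == model and s.K == K]
                assert len(group) == 120

    def test_surviving_settings_in_expected_band(self):
        grid = parameter_grid()
        for model in MODELS:
            for K in (0.01, 0.1, 0.2):
                valid = [
                    s for s in grid if s.model == model and s.K == K and s.valid
                ]
                assert 100 <= len(valid) <= 120

    def test_valid_settings_round_trip(self):
        for s in parameter_grid():
            if not s.valid:
                continue
            f11, f12, f22 = penetrances_for_model(s.model, s.f, s.g)
            residual = (
                f11 * s.p1**2
                + 2 * f12 * s.p1 * (1 - s.p1)
                + f22 * (1 - s.p1) ** 2
                - s.K
            )
            assert abs(residual) < 1e-9


class TestNullCentering:
    def test_mean_transmission_difference_centers_at_zero(self):
        """With R=0 the SNP is independent of disease: E[sum_b - sum_c] = 0."""
        m = DiseaseModel.from_penetrance("dominant", 0.1, 0.02, 0.7, 0.0)
        rng = np.random.default_rng(11)
        n, reps = 200, 500
        diffs = []
        for _ in range(reps):
            trios = simulate_trio_set(m, n, rng=rng)
            res = dtdt_from_child_genotypes([t.child_snp for t in trios], m.q1)
            diffs.append(res.sum_b - res.sum_c)
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / math.sqrt(reps)
        assert abs(diffs.mean()) < 3 * se
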