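"""Folding engine: weights, weighted partition function, MFE, Deigan mode."""

import math

import numpy as np
import pytest

from shapefold import (
    build_weights,
    deigan_pseudo_energy,
    fold_deigan,
    hairpin_energy,
    inside,
    loop_weight,
    pair_probabilities,
    score_structure,
    structure_distance,
    uniform_weights,
    weighted_mfe,
)
from shapefold.fixtures import random_sequence, random_structure, synthetic_raw_shape
from shapefold.oracle import brute_force_ensemble, enumerate_structures


class TestWeights:
    def test_beta_zero_gives_unit_weights(self, params):
        w = build_weights(np.array([0.1, 0.9]), 0.0, params.RT)
        assert np.all(w.unpaired == 1.0) and np.all(w.paired == 1.0)

    def test_zero_discrepancy_weight_is_one(self, params):
        w = build_weights(np.array([1.0]), 2.0, params.RT)
        assert w.unpaired[0] == 1.0
        assert w.paired[0] == pytest.approx(math.exp(-2.0 / params.RT))

    def test_uninformative_position_is_symmetric(self, params):
        w = build_weights(np.array([0.5]), 1.5, params.RT)
        expect = math.exp(-0.75 / params.RT)
        assert w.paired[0] == w.unpaired[0] == pytest.approx(expect)

    def test_negative_beta_rejected(self, params):
        with pytest.raises(ValueError):
            build_weights(np.array([0.5]), -1.0, params.RT)

    def test_unresolved_missing_rejected(self, params):
        with pytest.raises(ValueError, match="missing"):
            build_weights(np.array([0.5, np.nan]), 1.0, params.RT)

    def test_loop_weight_recurrence_and_empty_product(self, params, rng):
        w = build_weights(rng.random(6), 1.0, params.RT)
        assert loop_weight(4, 2, w) == 1.0
        for j in range(1, 6):
            assert loop_weight(0, j, w) == pytest.approx(
                loop_weight(0, j - 1, w) * w.unpaired[j]
            )

    def test_per_structure_factorization(self, params, rng):
        """Product of position weights equals exp(-beta d(S,q)/RT) exactly."""
        seq = "GGCGAAACGCC"
        q = rng.random(len(seq))
        beta = 1.3
        w = build_weights(q, beta, params.RT)
        for s in enumerate_structures(seq, params)[:50]:
            x = s.x
            prod = np.prod(np.where(x == 1.0, w.unpaired, w.paired))
            expect = math.exp(-beta * structure_distance(s, q) / params.RT)
            assert prod == pytest.approx(expect, rel=1e-12)


class TestPartitionFunction:
    def test_unpairable_sequence_gives_weight_product(self, params, rng):
        q = rng.random(4)
        w = build_weights(q, 0.8, params.RT)
        t = inside("AAAA", w, params)
        assert t.total() == pytest.approx(float(np.prod(w.unpaired)), rel=1e-12)

    def test_two_structure_closed_form(self, params):
        seq = "GAAAC"
        t = inside(seq, uniform_weights(5, params.RT), params)
        eh = hairpin_energy(seq, 0, 4, params)
        assert t.total() == pytest.approx(1 + math.exp(-eh / params.RT), rel=1e-12)

    def test_six_structure_enumeration_sum(self, params):
        seq = "GGAAACC"
        structures = enumerate_structures(seq, params)
        assert len(structures) == 6
        z = sum(
            math.exp(-score_structure(seq, s, params) / params.RT)
            for s in structures
        )
        t = inside(seq, uniform_weights(7, params.RT), params)
        assert t.total() == pytest.approx(z, rel=1e-12)

    def test_empty_interval_base_case(self, params):
        t = inside("GAAAC", uniform_weights(5, params.RT), params)
        assert t.z(3, 2) == 1.0


class TestPairProbabilities:
    def test_unpairable_sequence(self, params):
        t = inside("AAAA", uniform_weights(4, params.RT), params)
        bpp = pair_probabilities(t, "AAAA", params)
        assert np.all(bpp.p == 0.0)
        assert np.allclose(bpp.unpaired, 1.0)

    def test_two_structure_closed_form(self, params):
        seq = "GAAAC"
        t = inside(seq, uniform_weights(5, params.RT), params)
        bpp = pair_probabilities(t, seq, params)
        eh = math.exp(-hairpin_energy(seq, 0, 4, params) / params.RT)
        assert bpp.p[0, 4] == pytest.approx(eh / (1 + eh), rel=1e-12)

    def test_normalization_per_position(self, params, rng):
        seq = random_sequence(rng, 13)
        q = rng.random(13)
        w = build_weights(q, 1.0, params.RT)
        t = inside(seq, w, params)
        bpp = pair_probabilities(t, seq, params)
        assert np.allclose(bpp.p.sum(axis=1) + bpp.unpaired, 1.0, atol=1e-9)


class TestReduction:
    def test_beta_zero_is_bitwise_plain(self, params, rng):
        seq = random_sequence(rng, 12)
        q = rng.random(12)
        w0 = build_weights(q, 0.0, params.RT)
        wu = uniform_weights(12, params.RT)
        t0 = inside(seq, w0, params)
        tu = inside(seq, wu, params)
        assert np.array_equal(t0.Z, tu.Z) and np.array_equal(t0.ZB, tu.ZB)
        p0 = pair_probabilities(t0, seq, params)
        pu = pair_probabilities(tu, seq, params)
        assert np.array_equal(p0.p, pu.p)
        m0 = weighted_mfe(seq, q, 0.0, params)
        mu = weighted_mfe(seq, None, 0.0, params)
        assert m0.structure == mu.structure and m0.score == mu.score

    def test_all_uninformative_data_is_uniform_tilt(self, params, rng):
        """q = 0.5 everywhere multiplies Z by a constant and preserves p, MFE."""
        seq = random_sequence(rng, 12)
        n, beta = 12, 1.7
        q = np.full(n, 0.5)
        w = build_weights(q, beta, params.RT)
        t = inside(seq, w, params)
        tu = inside(seq, uniform_weights(n, params.RT), params)
        const = n * (-0.5 * beta / params.RT)
        assert t.log_Z == pytest.approx(tu.log_Z + const, abs=1e-12)
        p = pair_probabilities(t, seq, params)
        pu = pair_probabilities(tu, seq, params)
        assert np.allclose(p.p, pu.p, atol=1e-12)
        m = weighted_mfe(seq, q, beta, params)
        mu = weighted_mfe(seq, None, 0.0, params)
        assert m.structure == mu.structure


class TestWeightedMfe:
    def test_unpairable_sequence_scores_data_term_only(self, params, rng):
        q = rng.random(4)
        m = weighted_mfe("AAAA", q, 2.0, params)
        assert m.structure.pairs == ()
        assert m.score == pytest.approx(2.0 * np.sum(1.0 - q))
        assert m.energy == 0.0

    def test_score_decomposes_into_energy_plus_data_term(self, params, rng):
        seq = random_sequence(rng, 14)
        q = rng.random(14)
        m = weighted_mfe(seq, q, 1.2, params)
        d = structure_distance(m.structure, q)
        assert m.score == pytest.approx(m.energy + 1.2 * d, abs=1e-9)

    def test_matches_oracle_minimum(self, params, rng):
        for _ in range(5):
            seq = random_sequence(rng, int(rng.integers(8, 14)))
            q = rng.random(len(seq))
            beta = float(rng.uniform(0, 3))
            ens = brute_force_ensemble(seq, q, beta, params)
            m = weighted_mfe(seq, q, beta, params)
            assert m.score == pytest.approx(ens.mfe_score, rel=1e-9)


class TestDeigan:
    def test_pseudo_energy_closed_forms(self):
        assert deigan_pseudo_energy(0.0) == pytest.approx(-0.8)
        assert deigan_pseudo_energy(math.e - 1) == pytest.approx(1.0)
        assert deigan_pseudo_energy(float("nan")) == 0.0

    def test_all_missing_reduces_to_plain(self, params, rng):
        seq = random_sequence(rng, 12)
        raw = np.full(12, np.nan)
        mfe, tables = fold_deigan(seq, raw, params)
        plain = weighted_mfe(seq, None, 0.0, params)
        tu = inside(seq, uniform_weights(12, params.RT), params)
        assert mfe.structure == plain.structure
        assert tables.total() == pytest.approx(tu.total(), rel=1e-12)

    def test_isolated_pair_receives_no_term(self, params, rng):
        from shapefold import SecondaryStructure

        seq = "GAAAC"
        s = SecondaryStructure(n=5, pairs=((0, 4),))
        bonus = np.full(5, 5.0)  # any bonus; must not appear
        assert score_structure(seq, s, params, stack_bonus=bonus) == score_structure(
            seq, s, params
        )

    def test_helix_interior_positions_counted_twice(self, params):
        from shapefold import SecondaryStructure

        seq = "GGGAAAACCC"
        s = SecondaryStructure(n=10, pairs=((0, 9), (1, 8), (2, 7)))
        bonus = np.arange(10, dtype=float)
        plain = score_structure(seq, s, params)
        with_bonus = score_structure(seq, s, params, stack_bonus=bonus)
        # stacks (0,9)/(1,8) and (1,8)/(2,7): positions 1 and 8 occur twice
        expect = (bonus[0] + bonus[9] + bonus[1] + bonus[8]) + (
            bonus[1] + bonus[8] + bonus[2] + bonus[7]
        )
        assert with_bonus - plain == pytest.approx(expect)

    def test_matches_per_structure_oracle(self, params, rng):
        for _ in range(5):
            seq = random_sequence(rng, int(rng.integers(8, 14)))
            ref = random_structure(seq, params, rng)
            raw = synthetic_raw_shape(ref, rng, missing_frac=0.1)
            bonus = deigan_pseudo_energy(raw)
            ens = brute_force_ensemble(seq, None, 0.0, params, stack_bonus=bonus)
            mfe, tables = fold_deigan(seq, raw, params)
            assert tables.total() == pytest.approx(ens.Z_weighted, rel=1e-9)
            assert mfe.score == pytest.approx(ens.mfe_score, rel=1e-9)
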