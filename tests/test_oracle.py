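"""Enumeration oracle, accuracy scoring, discrepancies, beta search."""

import numpy as np
import pytest

from shapefold import (
    SecondaryStructure,
    accuracy,
    beta_grid_search,
    brute_force_ensemble,
    count_structures,
    discrepancy_positions,
    enumerate_structures,
    weighted_mfe,
)
from shapefold.fixtures import random_sequence


class TestEnumeration:
    @pytest.mark.parametrize(
        "seq, expected", [("AAAAA", 1), ("GAAAC", 2), ("GGAAACC", 6)]
    )
    def test_known_counts(self, params, seq, expected):
        assert len(enumerate_structures(seq, params)) == expected

    def test_matches_counting_recursion(self, params, rng):
        for _ in range(10):
            seq = random_sequence(rng, int(rng.integers(8, 17)))
            structures = enumerate_structures(seq, params)
            assert len(structures) == count_structures(seq, params.theta)
            assert len({s.pairs for s in structures}) == len(structures)

    def test_limit_enforced(self, params):
        with pytest.raises(ValueError, match="limit"):
            enumerate_structures("A" * 25, params)


class TestBruteForceEnsemble:
    def test_probabilities_normalize(self, params, rng):
        seq = random_sequence(rng, 10)
        ens = brute_force_ensemble(seq, rng.random(10), 1.0, params)
        assert ens.prob_weighted.sum() == pytest.approx(1.0)
        assert ens.prob_unweighted.sum() == pytest.approx(1.0)

    def test_beta_zero_is_classic_boltzmann(self, params, rng):
        seq = random_sequence(rng, 10)
        ens = brute_force_ensemble(seq, rng.random(10), 0.0, params)
        assert np.allclose(ens.prob_weighted, ens.prob_unweighted)
        assert ens.Z == pytest.approx(ens.Z_weighted)


class TestAccuracy:
    def test_perfect_prediction(self):
        s = SecondaryStructure(n=10, pairs=((0, 9), (1, 8)))
        acc = accuracy(s, s)
        assert acc.sensitivity == 1.0 and acc.ppv == 1.0

    def test_partial_overlap(self):
        pred = SecondaryStructure(n=11, pairs=((0, 9), (1, 8), (3, 7)))
        ref = SecondaryStructure(n=11, pairs=((0, 9), (1, 8), (2, 6)))
        acc = accuracy(pred, ref)
        assert acc.sensitivity == pytest.approx(2 / 3)
        assert acc.ppv == pytest.approx(2 / 3)

    def test_no_slippage(self):
        # shifted by one on one end: counts as wrong
        pred = SecondaryStructure(n=10, pairs=((0, 8),))
        ref = SecondaryStructure(n=10, pairs=((0, 9),))
        acc = accuracy(pred, ref)
        assert acc.tp == 0

    def test_empty_prediction_gives_null_ppv(self):
        pred = SecondaryStructure(n=10, pairs=())
        ref = SecondaryStructure(n=10, pairs=((0, 9), (1, 8), (2, 7)))
        acc = accuracy(pred, ref)
        assert acc.sensitivity == 0.0 and acc.ppv is None

    def test_swap_symmetry(self, rng, params):
        for _ in range(5):
            seq = random_sequence(rng, 12)
            structures = enumerate_structures(seq, params)
            a = structures[int(rng.integers(len(structures)))]
            b = structures[int(rng.integers(len(structures)))]
            ab, ba = accuracy(a, b), accuracy(b, a)
            assert ab.sensitivity == ba.ppv and ab.ppv == ba.sensitivity

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            accuracy(
                SecondaryStructure(n=5, pairs=()), SecondaryStructure(n=6, pairs=())
            )


class TestDiscrepancies:
    def test_flagging_rules(self):
        ref = SecondaryStructure(n=4, pairs=((0, 3),))
        # paired with high q -> flagged; unpaired with low q -> flagged;
        # 0.5 never flagged at the default threshold
        q = np.array([0.9, 0.2, 0.5, 0.4])
        flagged, rate = discrepancy_positions(q, ref)
        assert flagged == [0, 1]
        assert rate == pytest.approx(0.5)

    def test_missing_positions_excluded(self):
        ref = SecondaryStructure(n=4, pairs=((0, 3),))
        q = np.array([0.9, np.nan, np.nan, np.nan])
        flagged, rate = discrepancy_positions(q, ref)
        assert flagged == [0] and rate == 1.0


class TestBetaGridSearch:
    def test_single_value_grid(self, params, rng):
        seq = "GGGGAAAACCCC"
        ref = weighted_mfe(seq, None, 0.0, params).structure
        q = ref.x
        best, profile = beta_grid_search(
            seq, q, ref, params, grid=np.array([0.7])
        )
        assert best == 0.7 and len(profile) == 1

    def test_flat_profile_breaks_ties_toward_smallest_beta(self, params):
        seq = "GGGGAAAACCCC"
        ref = weighted_mfe(seq, None, 0.0, params).structure
        q = ref.x  # data in perfect agreement with the plain MFE
        best, profile = beta_grid_search(
            seq, q, ref, params, grid=np.arange(0.0, 1.01, 0.25)
        )
        assert best == 0.0
        assert all(row["objective"] == profile[0]["objective"] for row in profile)

    def test_data_recovers_alternative_helix(self, params):
        """Two energetically equal helices: data must decide, beta=0 cannot."""
        seq = "GGGGAAAACCCCAAAAGGGG"
        # the CCCC strand can close the left helix or the (energetically
        # identical) right helix; data is built from the left one
        left = SecondaryStructure(
            n=20, pairs=((0, 11), (1, 10), (2, 9), (3, 8)),
            theta=params.theta, sequence=seq,
        )
        q = left.x
        plain = weighted_mfe(seq, None, 0.0, params).structure
        assert accuracy(plain, left).sensitivity < 1.0
        best, _ = beta_grid_search(
            seq, q, left, params, grid=np.round(np.arange(0.0, 3.01, 0.1), 10)
        )
        assert best is not None and best > 0.0
        recovered = weighted_mfe(seq, q, best, params).structure
        assert accuracy(recovered, left).sensitivity == 1.0
        assert accuracy(recovered, left).ppv == 1.0

    def test_empty_grid(self, params):
        with pytest.raises(ValueError, match="empty"):
            beta_grid_search(
                "GAAAC", np.ones(5), SecondaryStructure(n=5, pairs=()),
                params, grid=np.array([]),
            )
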