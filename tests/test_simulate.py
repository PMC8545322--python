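"""Planted models, Gibbs sampling, corruption and the SP-score."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import ecompass as ec
from ecompass.alphabet import N_AA
from ecompass.errors import DataError
from ecompass.simulate import (
    CONTACT_CUTOFF,
    MIN_CONTACT_SEPARATION,
    _gibbs_sweep,
    _neighbour_lists,
)

from conftest import make_msa


class TestMakePlantedModel:
    def test_planted_geometry(self):
        model = ec.make_planted_model(50, 40, seed=0)
        dist = squareform(pdist(model.coords))
        assert len(model.contact_graph) == 40
        for (a, b) in model.contact_graph:
            assert b - a >= MIN_CONTACT_SEPARATION
            assert dist[a, b] <= CONTACT_CUTOFF

    def test_couplings_only_on_contact_pairs(self):
        model = ec.make_planted_model(30, 10, seed=1)
        tri_i, tri_j = np.triu_indices(30, k=1)
        for k, (a, b) in enumerate(zip(tri_i, tri_j)):
            block = model.potts.couplings[k]
            if (int(a), int(b)) in model.contact_graph:
                assert np.abs(block).max() > 0
            else:
                assert np.abs(block).max() == 0

    def test_seeded_determinism(self):
        m1 = ec.make_planted_model(25, 12, seed=42)
        m2 = ec.make_planted_model(25, 12, seed=42)
        assert np.array_equal(m1.coords, m2.coords)
        assert m1.contact_graph == m2.contact_graph
        assert np.array_equal(m1.potts.couplings, m2.potts.couplings)

    def test_zero_contact_model_matches_softmax_marginals(self):
        model = ec.make_planted_model(8, 0, seed=2)
        gold = ec.sample_msa(model, n=4000, burn_in=30, seed=3)
        states = gold.msa.identity_states()
        expected = np.exp(model.potts.fields[:, :N_AA])
        expected /= expected.sum(axis=1, keepdims=True)
        for col in range(8):
            freq = np.bincount(states[:, col], minlength=N_AA) / 4000
            se = np.sqrt(expected[col] * (1 - expected[col]) / 4000)
            assert (np.abs(freq - expected[col]) < 5 * se + 5e-3).all()


class TestSampleMsa:
    def test_gap_free_and_shaped(self, small_model, small_gold):
        msa = small_gold.msa
        assert msa.n_records == 30 and msa.width == small_model.n_cols
        assert all("-" not in s and "." not in s for _, s in msa.records)

    def test_determinism(self, small_model):
        a = ec.sample_msa(small_model, n=10, burn_in=30, seed=5)
        b = ec.sample_msa(small_model, n=10, burn_in=30, seed=5)
        assert a.msa.records == b.msa.records

    def test_zero_sequences_is_error(self, small_model):
        with pytest.raises(DataError):
            ec.sample_msa(small_model, n=0)

    def test_zero_coupling_pairwise_frequencies_factorise(self):
        model = ec.make_planted_model(6, 0, seed=6)
        gold = ec.sample_msa(model, n=5000, burn_in=20, seed=7)
        states = gold.msa.identity_states()
        f0 = np.bincount(states[:, 0], minlength=N_AA) / 5000
        f1 = np.bincount(states[:, 1], minlength=N_AA) / 5000
        joint = np.zeros((N_AA, N_AA))
        for a, b in zip(states[:, 0], states[:, 1]):
            joint[a, b] += 1
        joint /= 5000
        resid = np.abs(joint - np.outer(f0, f1))
        se = np.sqrt(np.outer(f0, f1) * (1 - np.outer(f0, f1)) / 5000)
        assert (resid < 4 * se + 5e-3).all()

    def test_two_site_sampler_matches_boltzmann(self):
        # 2 columns, strong coupling: the empirical joint over (aa0, aa1)
        # must match the exactly enumerable Boltzmann distribution
        model = ec.make_planted_model(8, 1, coupling_scale=1.0, seed=8)
        (a, b) = next(iter(model.contact_graph))
        gold = ec.sample_msa(model, n=20000, burn_in=60, seed=9)
        states = gold.msa.identity_states()
        # exact marginal over the coupled pair by brute-force enumeration
        h = model.potts.fields[:, :N_AA]
        J = model.potts.coupling_block(a, b)[:N_AA, :N_AA]
        energy = h[a][:, None] + h[b][None, :] + J
        # remaining sites are independent and integrate out
        boltz = np.exp(energy)
        boltz /= boltz.sum()
        joint = np.zeros((N_AA, N_AA))
        for x, y in zip(states[:, a], states[:, b]):
            joint[x, y] += 1
        joint /= len(states)
        se = np.sqrt(boltz * (1 - boltz) / len(states))
        assert (np.abs(joint - boltz) < 5 * se + 2e-3).all()


class TestCorruptAlignment:
    def test_zero_fraction_is_identity(self, small_gold):
        out = ec.corrupt_alignment(small_gold, 0.0, 5, seed=1)
        assert [s for _, s in out.records] == [s for _, s in small_gold.msa.records]
        assert ec.sp_score(small_gold.msa, out) == 1.0

    def test_full_corruption_with_wide_shifts_destroys_alignment(self, small_gold):
        out = ec.corrupt_alignment(
            small_gold, 1.0, max_shift=small_gold.msa.width, seed=2
        )
        assert ec.sp_score(small_gold.msa, out) < 0.35

    def test_sp_strictly_decreasing_in_fraction(self, small_gold):
        sps = [
            ec.sp_score(
                small_gold.msa,
                ec.corrupt_alignment(small_gold, f, 3, seed=11),
            )
            for f in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(a > b for a, b in zip(sps, sps[1:]))

    def test_sequences_preserved(self, small_gold):
        out = ec.corrupt_alignment(small_gold, 0.7, 4, seed=3)
        for (n1, _), (n2, _) in zip(small_gold.msa.records, out.records):
            assert n1 == n2
        for i in range(out.n_records):
            assert out.ungapped(i) == small_gold.msa.ungapped(i)


class TestSpScore:
    def test_identical_alignment_scores_one(self):
        msa = make_msa(["AC-DE", "A-CDE", "ACD-E"])
        assert ec.sp_score(msa, msa) == 1.0

    def test_three_sequence_shift_matches_brute_force(self):
        gold = make_msa(["ACDE", "ACDE", "ACDE"])
        test = make_msa(["ACDE", "-ACD" + "E"[:0] + "E"[0:0] or "ACDE", "ACDE"])
        # record 1 shifted right by one (its E falls off into a new column)
        test = make_msa(["ACDE-", "-ACDE", "ACDE-"])
        got = ec.sp_score(gold, test)
        # brute-force enumeration: pairs (0,1) and (1,2) share no columns
        # for their residues; pair (0,2) keeps all 4 co-alignments
        assert got == pytest.approx(4 / 12)

    def test_disjoint_alignment_scores_zero(self):
        gold = make_msa(["AC--", "--AC"], ids=["x", "y"])
        test = make_msa(["AC--", "AC--"], ids=["x", "y"])
        # gold co-aligns nothing, so the score is undefined
        with pytest.raises(DataError):
            ec.sp_score(gold, test)
        # reversed: the gold co-aligns pairs, the test aligns none of them
        assert ec.sp_score(test, gold) == 0.0

    def test_different_sequence_sets_rejected(self):
        a = make_msa(["ACDE"], ids=["x"])
        b = make_msa(["ACDF"], ids=["x"])
        with pytest.raises(DataError):
            ec.sp_score(a, b)


class TestSRatioExperiment:
    def test_ratio_one_at_zero_corruption_and_table_shape(self):
        models = [ec.make_planted_model(20, 12, seed=s) for s in (31, 32)]
        table = ec.s_ratio_experiment(
            models, [0.0, 0.6], n_sequences=150, burn_in=80, seed=1
        )
        assert len(table) == 4
        zero = table[table.fraction == 0.0]
        assert np.allclose(zero.sp, 1.0)
        assert np.allclose(zero.s_ratio, 1.0)
        assert (table.L.values > 0).all()
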