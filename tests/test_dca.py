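"""Sequence reweighting, the pseudo-likelihood fit, and APC scores."""

import numpy as np
import pytest

import ecompass as ec
from ecompass.alphabet import AMINO_ACIDS
from ecompass.dca import apc, compute_weights, pseudolikelihood_objective
from ecompass.errors import ConfigError, DataError

from conftest import make_msa


def random_msa(rng, n, width, alphabet=AMINO_ACIDS):
    seqs = ["".join(rng.choice(list(alphabet), width)) for _ in range(n)]
    return make_msa(seqs, ids=[f"r{i}" for i in range(n)])


class TestComputeWeights:
    def test_identical_records_share_one_cluster(self):
        msa = make_msa(["ACDEF"] * 5)
        w = compute_weights(msa, 0.8)
        assert np.allclose(w.weights, 0.2)
        assert w.meff == pytest.approx(1.0)

    def test_all_distant_records_weight_one(self):
        msa = make_msa(["AAAAA", "CCCCC", "DDDDD"])
        w = compute_weights(msa, 0.8)
        assert np.allclose(w.weights, 1.0)
        assert w.meff == pytest.approx(3.0)

    def test_matches_quadratic_scan_oracle(self):
        rng = np.random.default_rng(3)
        msa = random_msa(rng, 5, 10, alphabet="AC")
        w = compute_weights(msa, 0.8)
        seqs = [s for _, s in msa.records]
        for i in range(5):
            neigh = sum(
                sum(a == b for a, b in zip(seqs[i], seqs[j])) / 10 >= 0.8
                for j in range(5)
            )
            assert w.weights[i] == pytest.approx(1.0 / neigh)

    def test_nulls_never_match(self):
        msa = make_msa(["A-CDE", "A-CDE"])
        w = compute_weights(msa, 0.8)
        # 4/5 matching scored columns (the shared null is a mismatch)
        assert np.allclose(w.weights, 0.5)

    def test_threshold_validation(self, toy_msa):
        with pytest.raises(ConfigError):
            compute_weights(toy_msa, 1.5)


class TestPseudolikelihoodGradient:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        n_cols = int(rng.integers(3, 7))
        n = int(rng.integers(5, 31))
        msa = random_msa(rng, n, n_cols, alphabet="ACDEFG-")
        weights = compute_weights(msa, 0.8)
        obj, n_params = pseudolikelihood_objective(msa, weights, 0.2)
        x = rng.normal(0.0, 0.1, n_params)
        f0, g = obj(x)
        eps = 1e-5
        picks = rng.choice(n_params, 25, replace=False)
        for k in picks:
            xp, xm = x.copy(), x.copy()
            xp[k] += eps
            xm[k] -= eps
            fd = (obj(xp)[0] - obj(xm)[0]) / (2 * eps)
            denom = max(abs(fd), abs(g[k]), 1e-8)
            assert abs(fd - g[k]) / denom < 1e-4


class TestFitPotts:
    def test_correlated_columns_attain_top_score(self):
        # column 1 deterministically repeats column 0: strongest coupling
        rng = np.random.default_rng(7)
        letters = rng.choice(list("ACDEFGHIKL"), 200)
        noise = rng.choice(list(AMINO_ACIDS), (200, 4))
        seqs = [
            l + l + "".join(row) for l, row in zip(letters, noise)
        ]
        msa = make_msa(seqs, ids=[f"r{i}" for i in range(200)])
        scores = ec.scores_for_msa(msa)
        ii, jj = np.triu_indices(6, k=1)
        top = np.argmax(scores.scores[ii, jj])
        assert (ii[top], jj[top]) == (0, 1)

    def test_independent_columns_show_no_coupling_structure(self):
        # an iid alignment is its own null: the top APC score must be
        # statistically indistinguishable from column-shuffled controls
        rng = np.random.default_rng(8)
        msa = random_msa(rng, 500, 10)
        top = ec.scores_for_msa(msa).scores.max()
        controls = []
        for seed in range(3):
            crng = np.random.default_rng(100 + seed)
            chars = np.array([list(s) for _, s in msa.records])
            for col in range(chars.shape[1]):
                chars[:, col] = chars[crng.permutation(len(chars)), col]
            shuffled = make_msa(
                ["".join(r) for r in chars], ids=[f"r{i}" for i in range(500)]
            )
            controls.append(ec.scores_for_msa(shuffled).scores.max())
        assert top < 1.5 * max(controls)

    def test_single_record_fit_is_regularizer_dominated(self):
        msa = make_msa(["ACDEF"])
        model = ec.fit_potts(msa, compute_weights(msa))
        # no pairwise signal: couplings stay an order of magnitude below
        # the fields, which absorb the single observed residue per column
        assert np.abs(model.couplings).max() < 0.1 * np.abs(model.fields).max()

    def test_single_column_rejected(self):
        msa = make_msa(["A", "C"])
        with pytest.raises(DataError):
            ec.fit_potts(msa, compute_weights(msa))

    def test_record_order_invariance(self):
        rng = np.random.default_rng(9)
        msa = random_msa(rng, 60, 8, alphabet="ACDEFGH")
        perm = rng.permutation(60)
        shuffled = make_msa(
            [msa.records[i][1] for i in perm],
            ids=[msa.records[i][0] for i in perm],
        )
        s1 = ec.scores_for_msa(msa)
        s2 = ec.scores_for_msa(shuffled)
        assert np.allclose(s1.scores, s2.scores, atol=5e-3)

    def test_duplicate_record_invariance_with_reweighting(self):
        # all records mutually distant, so duplicating one only splits its
        # own weight and the fitted scores are unchanged
        rng = np.random.default_rng(10)
        msa = random_msa(rng, 40, 8, alphabet="ACDEFGHIKLMNPQRSTVWY")
        dup = make_msa(
            [s for _, s in msa.records] + [msa.records[0][1]],
            ids=[i for i, _ in msa.records] + ["dup0"],
        )
        s1 = ec.scores_for_msa(msa)
        s2 = ec.scores_for_msa(dup)
        assert np.allclose(s1.scores, s2.scores, atol=5e-3)


class TestFrobeniusApc:
    def test_constant_norms_give_zero(self):
        fro = np.full((4, 4), 3.0)
        np.fill_diagonal(fro, 0.0)
        assert np.allclose(apc(fro), 0.0)

    def test_three_column_hand_example(self):
        fro = np.array([[0.0, 2.0, 1.0], [2.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        out = apc(fro)
        assert out[0, 1] == pytest.approx(2 - (1.5 * 1.5) / (4 / 3))
        assert out[0, 1] == pytest.approx(0.3125)
        assert out[0, 2] == pytest.approx(1 - (1.5 * 1.0) / (4 / 3))
        assert out[1, 2] == pytest.approx(1 - (1.5 * 1.0) / (4 / 3))

    def test_apc_symmetric(self):
        rng = np.random.default_rng(11)
        fro = np.abs(rng.normal(size=(6, 6)))
        fro = (fro + fro.T) / 2
        np.fill_diagonal(fro, 0.0)
        out = apc(fro)
        assert np.allclose(out, out.T)


class TestImportScores:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(12)
        m = rng.normal(size=(3, 3))
        m = (m + m.T) / 2
        path = tmp_path / "scores.mat"
        ec.write_scores(ec.CouplingScores(m), path)
        back = ec.import_scores(path, 3)
        offdiag = ~np.eye(3, dtype=bool)
        assert np.allclose(back.scores[offdiag], m[offdiag], atol=1e-6)

    def test_dimension_mismatch(self, tmp_path):
        path = tmp_path / "scores.mat"
        np.savetxt(path, np.zeros((3, 3)))
        with pytest.raises(DataError, match="shape"):
            ec.import_scores(path, 4)

    def test_large_asymmetry_rejected(self, tmp_path):
        m = np.zeros((3, 3))
        m[0, 1] = 0.5
        path = tmp_path / "scores.mat"
        np.savetxt(path, m)
        with pytest.raises(DataError, match="asymmetric"):
            ec.import_scores(path, 3)
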