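"""Shared fixtures: toy alignments, a hand-written PDB chain, and a small
synthetic comparison world (planted model, gold/corrupted alignments,
bead-chain reference structures) reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

import ecompass as ec
from ecompass.config import RunConfig
from ecompass.msa_io import FLUSH, Msa
from ecompass.pair_mapping import PairArray


# ---------------------------------------------------------------------------
# alignments


def make_msa(seqs, mask=None, dialect=FLUSH, label="toy", ids=None):
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    mask = np.ones(len(seqs[0]), bool) if mask is None else np.asarray(mask, bool)
    return Msa(list(zip(ids, seqs)), mask, dialect, label)


@pytest.fixture
def toy_msa():
    return make_msa(["ACDEF", "ACDEY", "ACDKF", "ACDEF"][:3] + ["AC-EF"])


# ---------------------------------------------------------------------------
# structures


def pdb_atom(serial, name, resname, chain, resseq, xyz, occ=1.0, altloc=" "):
    x, y, z = xyz
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field}{altloc}{resname:<3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {name[0]:>2s}"
    )


@pytest.fixture
def mini_pdb(tmp_path):
    """ALA - GLY - SER chain with an altloc pair on the serine OG.

    Geometry chosen for hand-checkable distances: consecutive C-alphas
    3.8 A apart along x; ALA C-beta at (0, 1.5, 0); SER C-beta at
    (7.6, 1.5, 0); SER OG altloc A (occ 0.6) at (7.6, 1.5, 1.0) and
    altloc B (occ 0.4) at (7.6, 1.5, -1.0).
    """
    lines = [
        pdb_atom(1, "N", "ALA", "A", 1, (-1.0, 0.5, 0.0)),
        pdb_atom(2, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0)),
        pdb_atom(3, "C", "ALA", "A", 1, (1.2, 0.6, 0.0)),
        pdb_atom(4, "O", "ALA", "A", 1, (1.2, 1.8, 0.0)),
        pdb_atom(5, "CB", "ALA", "A", 1, (0.0, 1.5, 0.0)),
        pdb_atom(6, "N", "GLY", "A", 2, (2.8, 0.0, 0.0)),
        pdb_atom(7, "CA", "GLY", "A", 2, (3.8, 0.0, 0.0)),
        pdb_atom(8, "C", "GLY", "A", 2, (5.0, 0.6, 0.0)),
        pdb_atom(9, "O", "GLY", "A", 2, (5.0, 1.8, 0.0)),
        pdb_atom(10, "N", "SER", "A", 3, (6.6, 0.0, 0.0)),
        pdb_atom(11, "CA", "SER", "A", 3, (7.6, 0.0, 0.0)),
        pdb_atom(12, "C", "SER", "A", 3, (8.8, 0.6, 0.0)),
        pdb_atom(13, "O", "SER", "A", 3, (8.8, 1.8, 0.0)),
        pdb_atom(14, "CB", "SER", "A", 3, (7.6, 1.5, 0.0)),
        pdb_atom(15, "OG", "SER", "A", 3, (7.6, 1.5, 1.0), occ=0.6, altloc="A"),
        pdb_atom(16, "OG", "SER", "A", 3, (7.6, 1.5, -1.0), occ=0.4, altloc="B"),
        "END",
    ]
    path = tmp_path / "mini.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# ranked arrays


def make_pair_array(L, positions, rank_order, label="t"):
    """Array of length L with distinguished elements at 0-based
    ``positions`` whose closeness ranks (1 = closest) are ``rank_order``."""
    pairs = np.column_stack([np.arange(L), np.arange(L) + 7])
    scores = np.arange(L, 0, -1).astype(float)
    dist = np.full(L, 99.0)
    disting = np.zeros(L, bool)
    for pos, rk in zip(positions, rank_order):
        disting[pos] = True
        dist[pos] = float(rk)
    return PairArray(label, pairs, scores, dist, disting)


# ---------------------------------------------------------------------------
# the small synthetic comparison world


@pytest.fixture(scope="session")
def small_model():
    return ec.make_planted_model(n_cols=20, n_contacts=12, seed=11)


@pytest.fixture(scope="session")
def small_gold(small_model):
    return ec.sample_msa(small_model, n=30, burn_in=60, seed=12)


@pytest.fixture(scope="session")
def small_world(small_model, small_gold):
    """Two alignments of the same 30 sequences plus 6 bead structures.

    The structures carry the sequences of records 0..5 on per-structure
    noisy copies of the planted coordinates; structure 5 is strongly
    distorted so the discrepancy filter has a genuine outlier.  DC scores
    are fixed random symmetric matrices so no Potts fits are needed.
    """
    rng = np.random.default_rng(99)
    gold = small_gold
    corrupted = ec.corrupt_alignment(gold, 0.5, 3, seed=13)
    structures = []
    for k in range(6):
        jitter = 0.25 if k < 5 else 4.0
        coords = gold.model.coords + rng.normal(0.0, jitter, (gold.model.n_cols, 3))
        structures.append(
            ec.ReferenceStructure.from_coords(
                f"st{k}", gold.msa.ungapped(k), coords
            )
        )

    def random_scores(n_cols, seed):
        r = np.random.default_rng(seed)
        m = r.normal(size=(n_cols, n_cols))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        return ec.CouplingScores(m)

    from ecompass.msa_io import filter_null_columns

    cfg = RunConfig(z=8.0, diversity_cutoff=None)
    s1 = random_scores(gold.msa.n_scored, 21)
    s2 = random_scores(filter_null_columns(corrupted).n_scored, 22)
    return dict(
        msa1=gold.msa, msa2=corrupted, structures=structures,
        scores1=s1, scores2=s2, config=cfg,
    )
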