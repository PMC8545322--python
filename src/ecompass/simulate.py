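"""Gold-standard synthetic alignments from Potts models with planted
contacts, controlled corruption, and the accuracy-vs-score experiment.

The generator plants a sparse Potts model on a compact self-avoiding bead
chain: only column pairs whose beads sit within 8 A (and at least 6 apart
along the chain) carry non-zero couplings.  Gibbs-sampling the model gives
a gap-free *gold standard* alignment — by construction every sampled
sequence is correctly aligned — and the bead chain doubles as the single
reference structure.  Corrupting the gold alignment with random block
shifts then produces test alignments of known, tunable distance from the
truth (measured by the sum-of-pairs SP-score), closing the loop: the
congruence score of a corrupted alignment relative to the gold standard's
(S/S°) can be compared against SP directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from . import dca
from .alphabet import AMINO_ACIDS, N_AA, N_STATES
from .comparison import compare_msas
from .config import RunConfig
from .dca import PottsModel
from .errors import DataError
from .msa_io import FLUSH, Msa
from .structures import ReferenceStructure

logger = logging.getLogger(__name__)

BOND_LENGTH = 3.8  # A, consecutive beads (C-alpha virtual bond)
MIN_CLEARANCE = 3.4  # A, excluded volume between non-adjacent beads
CONTACT_CUTOFF = 8.0  # A, couplings beyond this are identically zero
MIN_CONTACT_SEPARATION = 6  # planted pairs satisfy |i - j| >= 6
FIELD_SCALE = 0.5
DEFAULT_COUPLING_SCALE = 0.5


@dataclass
class PlantedModel:
    """A sparse Potts model realised by a synthetic bead-chain structure."""

    potts: PottsModel
    contact_graph: frozenset  # of (i, j) column pairs, i < j
    coords: np.ndarray  # (n_cols, 3) bead positions, A
    seed: int

    @property
    def n_cols(self) -> int:
        return self.potts.n_cols


@dataclass
class GoldStandard:
    """A sampled gap-free alignment together with its generating model."""

    msa: Msa
    model: PlantedModel


def _compact_walk(n: int, rng: np.random.Generator) -> np.ndarray | None:
    """One attempt at a compact self-avoiding chain inside a sphere."""
    radius = max(2.0 * BOND_LENGTH, 3.0 * n ** (1.0 / 3.0))
    coords = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(200):
            step = rng.normal(size=3)
            step *= BOND_LENGTH / np.linalg.norm(step)
            cand = coords[i - 1] + step
            if np.linalg.norm(cand) > radius:
                continue
            if i > 1 and cdist(cand[None], coords[: i - 1]).min() < MIN_CLEARANCE:
                continue
            coords[i] = cand
            break
        else:
            return None
    return coords


def make_planted_model(
    n_cols: int,
    n_contacts: int,
    coupling_scale: float = DEFAULT_COUPLING_SCALE,
    seed: int = 0,
    max_attempts: int = 50,
) -> PlantedModel:
    """Plant a sparse Potts model on a synthetic compact bead chain.

    The contact graph consists of the ``n_contacts`` spatially closest bead
    pairs at chain separation >= 6 and distance <= 8 A.  Fields are drawn
    Normal(0, 0.5) per amino-acid state; each contact pair receives a
    zero-sum-gauged Normal(0, ``coupling_scale``) 20x20 coupling block.
    All other couplings are exactly zero.
    """
    if n_contacts < 0:
        raise DataError("n_contacts must be non-negative")
    rng = np.random.default_rng(seed)
    coords = None
    for _ in range(max_attempts):
        coords = _compact_walk(n_cols, rng)
        if coords is None:
            continue
        dist = squareform(pdist(coords))
        ii, jj = np.triu_indices(n_cols, k=MIN_CONTACT_SEPARATION)
        eligible = dist[ii, jj] <= CONTACT_CUTOFF
        if eligible.sum() >= n_contacts:
            break
        coords = None
    if coords is None:
        raise DataError(
            f"could not realise {n_contacts} contacts on a {n_cols}-bead "
            f"chain after {max_attempts} attempts"
        )
    order = np.argsort(dist[ii, jj])
    chosen = [k for k in order if eligible[k]][:n_contacts]
    contact_graph = frozenset(
        (int(ii[k]), int(jj[k])) for k in chosen
    )

    fields = np.zeros((n_cols, N_STATES))
    fields[:, :N_AA] = rng.normal(0.0, FIELD_SCALE, size=(n_cols, N_AA))
    tri_i, tri_j = np.triu_indices(n_cols, k=1)
    couplings = np.zeros((len(tri_i), N_STATES, N_STATES))
    pair_index = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(tri_i, tri_j))}
    for (a, b) in sorted(contact_graph):
        block = rng.normal(0.0, coupling_scale, size=(N_AA, N_AA))
        block = (
            block
            - block.mean(axis=0, keepdims=True)
            - block.mean(axis=1, keepdims=True)
            + block.mean()
        )
        couplings[pair_index[(a, b)], :N_AA, :N_AA] = block
    potts = PottsModel(
        n_cols=n_cols,
        fields=fields,
        couplings=couplings,
        metadata={"source": "planted", "coupling_scale": coupling_scale,
                  "seed": seed},
    )
    return PlantedModel(potts, contact_graph, coords, seed)


# ---------------------------------------------------------------------------
# Gibbs sampling


def _neighbour_lists(model: PlantedModel):
    """Per-site list of (partner site, oriented 20x20 coupling block)."""
    nbrs: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(model.n_cols)]
    for (a, b) in sorted(model.contact_graph):
        block = model.potts.coupling_block(a, b)[:N_AA, :N_AA]
        nbrs[a].append((b, block))
        nbrs[b].append((a, block.T))
    return nbrs


def _gibbs_sweep(
    seqs: np.ndarray,
    fields: np.ndarray,
    nbrs,
    rng: np.random.Generator,
) -> None:
    """One in-place Gibbs sweep over all sites of all parallel chains."""
    n, L = seqs.shape
    for i in range(L):
        logits = np.repeat(fields[i, :N_AA][None, :], n, axis=0)
        for j, block in nbrs[i]:
            logits += block[:, seqs[:, j]].T
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        cum = np.cumsum(p, axis=1)
        u = rng.random(n) * cum[:, -1]
        seqs[:, i] = (cum < u[:, None]).sum(axis=1)


def sample_msa(
    model: PlantedModel,
    n: int = 5000,
    burn_in: int = 500,
    thin: int = 10,
    independent_chains: bool = True,
    seed: int = 0,
) -> GoldStandard:
    """Sample a gap-free alignment from a planted Potts model by Gibbs
    sampling over the 20 amino-acid states.

    With ``independent_chains`` (default) each sequence is the endpoint of
    its own chain after ``burn_in`` sweeps; otherwise a single chain is
    thinned every ``thin`` sweeps after burn-in.
    """
    if n <= 0:
        raise DataError("need a positive number of sequences")
    rng = np.random.default_rng(seed)
    fields = model.potts.fields
    nbrs = _neighbour_lists(model)
    L = model.n_cols
    if independent_chains:
        seqs = rng.integers(0, N_AA, size=(n, L), dtype=np.int64)
        for _ in range(burn_in):
            _gibbs_sweep(seqs, fields, nbrs, rng)
    else:
        chain = rng.integers(0, N_AA, size=(1, L), dtype=np.int64)
        for _ in range(burn_in):
            _gibbs_sweep(chain, fields, nbrs, rng)
        rows = []
        for _ in range(n):
            for _ in range(thin):
                _gibbs_sweep(chain, fields, nbrs, rng)
            rows.append(chain[0].copy())
        seqs = np.array(rows)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    width = int(np.ceil(np.log10(max(n, 2))))
    records = [
        (f"sim_{k:0{width}d}", alphabet[seqs[k]].tobytes().decode())
        for k in range(n)
    ]
    msa = Msa(records, np.ones(L, dtype=bool), FLUSH, label="gold")
    return GoldStandard(msa=msa, model=model)


def reference_structure(gold: GoldStandard, record: int = 0) -> ReferenceStructure:
    """The planted bead chain as a reference structure.

    Synthetic stand-in for an experimentally determined chain: one bead per
    column, carrying the residue identities of one sampled record so the
    structure can be located in any realignment of the sequences.
    """
    seq = gold.msa.ungapped(record)
    return ReferenceStructure.from_coords(
        id=f"planted_{gold.model.seed}", sequence=seq, coords=gold.model.coords
    )


# ---------------------------------------------------------------------------
# corruption and SP-score


def corrupt_alignment(
    gold: GoldStandard | Msa,
    fraction: float,
    max_shift: int = 5,
    seed: int = 0,
) -> Msa:
    """Misalign a random subset of records by block gap insertions.

    Each corrupted record receives 1 + Poisson(1) insertion events; every
    event inserts 1..``max_shift`` nulls at a random position, shifting the
    downstream block out of register with the unshifted records.  All rows
    are padded with trailing nulls to a common width, so the result is a
    flush alignment of the same sequence set.
    """
    msa = gold.msa if isinstance(gold, GoldStandard) else gold
    if not 0.0 <= fraction <= 1.0:
        raise DataError("corruption fraction outside [0, 1]")
    if max_shift < 1:
        raise DataError("max_shift must be >= 1")
    rng = np.random.default_rng(seed)
    n = msa.n_records
    n_corrupt = int(round(fraction * n))
    victims = set(rng.choice(n, size=n_corrupt, replace=False).tolist())
    rows: list[str] = []
    for idx, (name, seq) in enumerate(msa.records):
        if idx in victims:
            n_events = 1 + rng.poisson(1.0)
            for _ in range(n_events):
                pos = int(rng.integers(0, len(seq)))
                shift = int(rng.integers(1, max_shift + 1))
                seq = seq[:pos] + "-" * shift + seq[pos:]
        rows.append(seq)
    width = max(len(r) for r in rows)
    records = [
        (name, row + "-" * (width - len(row)))
        for (name, _), row in zip(msa.records, rows)
    ]
    return Msa(records, np.ones(width, dtype=bool), FLUSH, label="corrupted")


def sp_score(gold: Msa, test: Msa) -> float:
    """Fraction of gold co-aligned residue pairs aligned identically in test.

    Records are paired by identifier; both alignments must hold the same
    sequences.  A (sequence-pair, residue-pair) co-alignment is a pair of
    residues from two records sharing a column.
    """
    if sorted(gold.identifiers) != sorted(test.identifiers):
        raise DataError("gold and test alignments hold different record sets")
    test_row = {name: i for i, (name, _) in enumerate(test.records)}
    n = gold.n_records
    # A[u, c] = test column of the residue record u has in gold column c
    A = np.full((n, gold.width), -1, dtype=np.int64)
    for u, (name, _) in enumerate(gold.records):
        gc = gold.residue_columns(u)
        tc = test.residue_columns(test_row[name])
        if len(gc) != len(tc):
            raise DataError(f"record {name}: different sequences in gold and test")
        A[u, gc] = tc
    present = A >= 0
    numerator = 0
    denominator = 0
    for u in range(n - 1):
        both = present[u] & present[u + 1 :]
        denominator += int(both.sum())
        numerator += int(((A[u] == A[u + 1 :]) & both).sum())
    if denominator == 0:
        raise DataError("gold alignment co-aligns no residue pairs")
    return numerator / denominator


# ---------------------------------------------------------------------------
# the S/S-gold vs SP experiment


def s_ratio_experiment(
    models: list[PlantedModel],
    corruption_grid: list[float],
    config: RunConfig | None = None,
    n_sequences: int = 500,
    burn_in: int = 500,
    max_shift: int = 5,
    seed: int = 0,
):
    """Score corrupted alignments against their gold standards.

    For each planted model: sample a gold alignment, fit its DC scores
    once, then for each corruption level realign ... rather, corrupt the
    gold alignment, measure its SP-score, and run the two-MSA comparison
    (gold vs corrupted) using the planted bead chain as the single
    reference structure.  Returns a DataFrame with one row per (model,
    corruption level): SP, S° (gold), S (corrupted) and S/S°.
    """
    import pandas as pd

    if config is None:
        config = RunConfig(
            z=CONTACT_CUTOFF, diversity_cutoff=None, allow_single_structure=True
        )
    rows = []
    for mi, model in enumerate(models):
        ss = np.random.SeedSequence([seed, mi])
        sample_seed, *corrupt_seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in ss.spawn(1 + len(corruption_grid))
        ]
        gold = sample_msa(model, n=n_sequences, burn_in=burn_in, seed=sample_seed)
        ref = reference_structure(gold)
        gold_scores = dca.scores_for_msa(
            gold.msa, config.reweight_threshold, config.reg_strength
        )
        for fraction, cseed in zip(corruption_grid, corrupt_seeds):
            corrupted = corrupt_alignment(gold, fraction, max_shift, seed=cseed)
            sp = sp_score(gold.msa, corrupted)
            # fraction 0 leaves the alignment untouched; refitting it would
            # reproduce gold_scores exactly, so reuse them
            test_scores = gold_scores if fraction == 0.0 else None
            report = compare_msas(
                gold.msa, corrupted, [ref], config,
                scores1=gold_scores, scores2=test_scores,
            )
            v = report.verdicts[0]
            ratio = v.s2 / v.s1 if v.s1 > 0 else float("nan")
            rows.append(
                dict(
                    model=mi, seed=model.seed, fraction=fraction, sp=sp,
                    s_gold=v.s1, s_test=v.s2, s_ratio=ratio, D=v.D, L=v.L,
                )
            )
            logger.info(
                "model %d fraction %.2f: SP %.3f S %.1f S0 %.1f",
                mi, fraction, sp, v.s2, v.s1,
            )
    return pd.DataFrame(rows)
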