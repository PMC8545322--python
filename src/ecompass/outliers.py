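"""Flagging reference structures that are likely misaligned within an MSA.

For the set of reference structures placed in one MSA, the residues of
structure i aligned (by the MSA) to residues in *all* other structures form
the set R_i; these sets occupy the same columns, so they have the same size
for every structure.  The pairwise discrepancy dD_ij is the mean absolute
difference of C-alpha distances over all residue pairs of R_i between
structures i and j, and dD_i its mean over j != i.  A structure whose dD_i
sits >= 2 SD above the mean of the others' is likely misaligned; the
mean/SD are recalculated iteratively after each removal until no structure
exceeds the threshold.  Exclusion never consults the S-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .pair_mapping import MsaSide
from .structures import ReferenceStructure

logger = logging.getLogger(__name__)


@dataclass
class DeltaDTable:
    """Pairwise and per-structure distance discrepancies for one MSA."""

    msa_label: str
    structure_ids: list[str]
    n_shared: int  # |R_i|, identical for all structures
    pair_discrepancy: np.ndarray  # (n, n) Angstrom, symmetric
    per_structure: np.ndarray  # (n,) dD_i
    excluded: set = field(default_factory=set)
    mean: float = float("nan")
    sd: float = float("nan")

    @property
    def n_structures(self) -> int:
        return len(self.structure_ids)

    def frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "structure": self.structure_ids,
                "delta_d": self.per_structure,
                "excluded": [s in self.excluded for s in self.structure_ids],
            }
        )


def delta_d_matrix(
    structures: list[ReferenceStructure],
    sides: list[MsaSide],
    msa_label: str = "",
) -> DeltaDTable:
    """Compute the dD_ij matrix and per-structure means for one MSA.

    ``sides`` gives each structure's residue-to-column map into the MSA
    (the full map, not restricted to scored columns).  All residue pairs of
    R_i contribute — no minimum-separation filter applies here.
    """
    if len(structures) < 2:
        raise DataError("distance-discrepancy analysis needs >= 2 structures")
    col_sets = [set(side.res_to_col.tolist()) for side in sides]
    common = sorted(set.intersection(*col_sets))
    if len(common) < 2:
        raise DataError(
            f"MSA {msa_label or '?'}: fewer than 2 columns carry residues "
            "of every reference structure; the MSA is too gappy across the "
            "structure set"
        )
    common = np.array(common)
    n = len(structures)
    # residue ordinal (0-based) of each structure in each common column
    res_idx = np.empty((n, len(common)), dtype=np.int64)
    for s, side in enumerate(sides):
        col_to_res = {int(c): r for r, c in enumerate(side.res_to_col)}
        res_idx[s] = [col_to_res[int(c)] for c in common]
    ai, bi = np.triu_indices(len(common), k=1)
    # per structure: C-alpha distances over the common-column residue pairs
    dists = np.empty((n, len(ai)))
    for s, st in enumerate(structures):
        dists[s] = st.ca_distance[res_idx[s][ai], res_idx[s][bi]]
    table = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(dists[i] - dists[i + 1 :]).mean(axis=1)
        table[i, i + 1 :] = diff
        table[i + 1 :, i] = diff
    per_structure = table.sum(axis=1) / (n - 1)
    return DeltaDTable(
        msa_label=msa_label,
        structure_ids=[st.id for st in structures],
        n_shared=len(common),
        pair_discrepancy=table,
        per_structure=per_structure,
    )


def iterative_exclusion(table: DeltaDTable, sd_multiplier: float = 2.0) -> DeltaDTable:
    """Iteratively exclude structures with dD_i >= mean + k * SD.

    Uses the sample SD (n-1 denominator), with the candidate's own dD_i
    included in the statistics it is tested against.  The dD_ij matrix is
    frozen; only the mean/SD are recomputed after removals.  SD = 0 (all
    retained values equal) stops the loop without removals.
    """
    if table.n_structures - len(table.excluded) < 3:
        raise DataError("iterative exclusion needs >= 3 retained structures")
    ids = table.structure_ids
    values = table.per_structure
    excluded = set(table.excluded)
    while True:
        retained = [i for i, s in enumerate(ids) if s not in excluded]
        if len(retained) < 2:
            break
        vals = values[retained]
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if sd == 0.0:
            break
        over = [i for i in retained if values[i] >= mean + sd_multiplier * sd]
        if not over:
            break
        for i in over:
            excluded.add(ids[i])
            logger.info(
                "MSA %s: structure %s excluded (dD_i = %.2f, mean %.2f, "
                "SD %.2f)", table.msa_label or "?", ids[i], values[i], mean, sd,
            )
    if len(excluded) == len(ids):
        raise DataError("outlier filter excluded every structure")
    retained = [i for i, s in enumerate(ids) if s not in excluded]
    vals = values[retained]
    return DeltaDTable(
        msa_label=table.msa_label,
        structure_ids=ids,
        n_shared=table.n_shared,
        pair_discrepancy=table.pair_discrepancy,
        per_structure=values,
        excluded=excluded,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
    )


def select_diverse_structures(
    structures: list[ReferenceStructure],
    sides: list[MsaSide],
    identity_cutoff: float = 0.65,
    recommended_minimum: int = 10,
) -> list[int]:
    """Greedy selection of structures below a pairwise identity cutoff.

    Identity between two structures is computed over the residues their
    chains align to the same MSA columns.  Scanning in input order, a
    structure is kept only if its identity to every kept structure is
    <= ``identity_cutoff``.  Returns indices of the kept structures.
    """
    seqs = [
        np.frombuffer(st.sequence.encode("ascii"), dtype=np.uint8)
        for st in structures
    ]
    col_maps = [
        {int(c): r for r, c in enumerate(side.res_to_col)} for side in sides
    ]
    kept: list[int] = []
    for i in range(len(structures)):
        diverse = True
        for j in kept:
            shared = sorted(set(col_maps[i]) & set(col_maps[j]))
            if not shared:
                continue
            ri = np.array([col_maps[i][c] for c in shared])
            rj = np.array([col_maps[j][c] for c in shared])
            ident = float((seqs[i][ri] == seqs[j][rj]).mean())
            if ident > identity_cutoff:
                diverse = False
                break
        if diverse:
            kept.append(i)
    if len(kept) < recommended_minimum:
        logger.warning(
            "only %d diverse reference structures (>= %d recommended); "
            "the binomial vote will have little power",
            len(kept), recommended_minimum,
        )
    return kept
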