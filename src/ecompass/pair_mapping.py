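"""Mapping reference structures into both alignments and building the
comparable ranked pair arrays.

For each structure we locate its chain sequence within one record of each
MSA, map every residue to an alignment column (and, where that column is
scored, to a scored-column index), and form the common residue set R of
positions scored in *both* MSAs.  All residue pairs of R separated by at
least m intervening residues then yield two arrays — one per MSA — holding
the same pairs with the same structural annotations but each MSA's own DC
scores and ranking.  Equal length L and equal distinguished count D between
the two arrays is what makes their statistics directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dca import CouplingScores
from .errors import DataError
from .msa_io import Msa
from .structures import ReferenceStructure

logger = logging.getLogger(__name__)


@dataclass
class MsaSide:
    """One structure's placement within one MSA."""

    row_index: int
    offset: int  # structure position 1 sits at this residue index of the row
    mismatches: int
    res_to_col: np.ndarray  # (n_residues,) alignment column per residue
    res_to_scored: np.ndarray  # (n_residues,) scored index, -1 if unscored


@dataclass
class StructureAlignmentMap:
    """A structure's residue-to-column maps into both MSAs plus R."""

    structure_id: str
    side1: MsaSide
    side2: MsaSide
    r_set: np.ndarray  # sorted residue positions (1-based) scored in both


@dataclass
class PairArray:
    """Ranked DC scores over one structure's comparable residue pairs.

    Entries are sorted by DC score descending (ties by residue pair,
    lexicographic).  ``distances`` and ``distinguished`` are structural
    annotations shared entry-for-entry (as sets) with the partner array
    built from the other MSA.
    """

    msa_label: str
    pairs: np.ndarray  # (L, 2) residue positions, a < b
    dc_scores: np.ndarray  # (L,)
    distances: np.ndarray  # (L,) Angstrom
    distinguished: np.ndarray  # (L,) bool

    @property
    def L(self) -> int:
        return len(self.dc_scores)

    @property
    def D(self) -> int:
        return int(self.distinguished.sum())


def locate_structure_row(
    structure: ReferenceStructure,
    msa: Msa,
    max_mismatch_fraction: float = 0.05,
) -> tuple[int, int, int] | None:
    """Find the MSA record containing the structure's chain sequence.

    The chain sequence must occur as a contiguous window of exactly one
    record's ungapped sequence, allowing up to ``max_mismatch_fraction``
    mismatched positions.  Returns ``(row_index, offset, n_mismatches)``,
    or None (with a warning) when no record matches; several equally good
    matches raise an error demanding an explicit mapping.
    """
    query = np.frombuffer(structure.sequence.encode("ascii"), dtype=np.uint8)
    k = len(query)
    allowed = int(np.floor(max_mismatch_fraction * k))
    hits: list[tuple[int, int, int]] = []  # (mismatches, row, offset)
    for row in range(msa.n_records):
        target = np.frombuffer(msa.ungapped(row).encode("ascii"), dtype=np.uint8)
        n = len(target)
        if n < k:
            continue
        # Hamming distance of the query against every window
        windows = np.lib.stride_tricks.sliding_window_view(target, k)
        mismatches = (windows != query).sum(axis=1)
        best = int(mismatches.min())
        if best <= allowed:
            for off in np.flatnonzero(mismatches == best):
                hits.append((best, row, int(off)))
    if not hits:
        logger.warning(
            "structure %s: sequence not found in MSA %s; structure skipped",
            structure.id, msa.label or "?",
        )
        return None
    best = min(h[0] for h in hits)
    best_hits = [h for h in hits if h[0] == best]
    if len(best_hits) > 1:
        raise DataError(
            f"structure {structure.id}: {len(best_hits)} equally good "
            f"placements in MSA {msa.label or '?'}; supply an explicit "
            "structure-to-record mapping"
        )
    mism, row, off = best_hits[0]
    return row, off, mism


def _map_side(
    structure: ReferenceStructure, msa: Msa, row: int, offset: int, mism: int
) -> MsaSide:
    res_cols = msa.residue_columns(row)
    n = structure.n_residues
    res_to_col = res_cols[offset : offset + n].astype(np.int64)
    scored_index = np.full(msa.width, -1, dtype=np.int64)
    scored_index[msa.scored_columns] = np.arange(msa.n_scored)
    res_to_scored = scored_index[res_to_col]
    return MsaSide(row, offset, mism, res_to_col, res_to_scored)


def build_alignment_map(
    structure: ReferenceStructure,
    msa1: Msa,
    msa2: Msa,
    explicit_rows: dict[str, tuple[int, int]] | None = None,
    max_mismatch_fraction: float = 0.05,
) -> StructureAlignmentMap | None:
    """Place one structure in both MSAs and derive the common set R.

    ``explicit_rows`` may supply ``structure_id -> (row1, row2)`` to bypass
    the sequence search (offsets are then found within those rows only).
    Returns None when the structure cannot be placed in either MSA.
    """
    sides = []
    for msa in (msa1, msa2):
        if explicit_rows and structure.id in explicit_rows:
            row = explicit_rows[structure.id][0 if msa is msa1 else 1]
            sub = msa.subset([row])
            hit = locate_structure_row(structure, sub, max_mismatch_fraction)
            if hit is not None:
                hit = (row, hit[1], hit[2])
        else:
            hit = locate_structure_row(structure, msa, max_mismatch_fraction)
        if hit is None:
            return None
        sides.append(_map_side(structure, msa, *hit))
    side1, side2 = sides
    both = (side1.res_to_scored >= 0) & (side2.res_to_scored >= 0)
    r_set = np.flatnonzero(both) + 1  # 1-based residue positions
    return StructureAlignmentMap(structure.id, side1, side2, r_set)


def candidate_pairs(r_set: np.ndarray, m: int) -> np.ndarray:
    """All pairs (a, b) of R with at least m intervening residues.

    Separation is counted in structure sequence positions: b - a >= m + 1.
    """
    r = np.asarray(r_set)
    a_idx, b_idx = np.triu_indices(len(r), k=1)
    a, b = r[a_idx], r[b_idx]
    keep = (b - a) >= m + 1
    return np.column_stack([a[keep], b[keep]])


def build_pair_arrays(
    amap: StructureAlignmentMap,
    scores1: CouplingScores,
    scores2: CouplingScores,
    contacts: np.ndarray,
    distances: np.ndarray,
    m: int = 5,
    labels: tuple[str, str] = ("1", "2"),
) -> tuple[PairArray, PairArray]:
    """Build the two comparable ranked arrays for one structure.

    ``contacts`` and ``distances`` are the structure's contact matrix and
    minimum-sidechain-distance matrix over residue ordinals.
    """
    if len(amap.r_set) < 2:
        raise DataError(
            f"structure {amap.structure_id}: fewer than 2 residues scored "
            "in both MSAs; structure unusable"
        )
    pairs = candidate_pairs(amap.r_set, m)
    if len(pairs) == 0:
        raise DataError(
            f"structure {amap.structure_id}: no residue pairs satisfy the "
            f"minimum separation of {m} intervening residues"
        )
    a0 = pairs[:, 0] - 1
    b0 = pairs[:, 1] - 1
    dist = distances[a0, b0]
    disting = contacts[a0, b0]
    arrays = []
    for side, scores, label in (
        (amap.side1, scores1, labels[0]),
        (amap.side2, scores2, labels[1]),
    ):
        ci = side.res_to_scored[a0]
        cj = side.res_to_scored[b0]
        dc = scores.scores[ci, cj]
        # sort by score descending; ties by (a, b) lexicographic
        order = np.lexsort((pairs[:, 1], pairs[:, 0], -dc))
        arrays.append(
            PairArray(
                msa_label=label,
                pairs=pairs[order],
                dc_scores=dc[order],
                distances=dist[order],
                distinguished=disting[order],
            )
        )
    k1, k2 = arrays
    assert k1.L == k2.L and k1.D == k2.D, "comparability invariant violated"
    return k1, k2
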