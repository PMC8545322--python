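"""Reference structures: residues, sidechain contacts and C-alpha distances.

Two geometric products feed the pipeline:

* the minimum *sidechain* heavy-atom distance per residue pair, from which
  contacts (distance <= z, default 4 A) mark the distinguished elements of
  the ranked-score arrays; glycine, having no sidechain, uses its C-alpha;
* the C-alpha distance matrix, from which the inter-structure distance
  discrepancy used for outlier detection is computed.

"Sidechain atoms" are heavy atoms from C-beta outward (C-beta included, so
alanine is not atom-less); hydrogens are excluded.  Residues whose
sidechain is entirely unresolved fall back to their C-alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .alphabet import THREE_TO_ONE
from .errors import DataError

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class Residue:
    """One residue: ordinal position, identity, and coordinates."""

    seq_pos: int  # 1-based ordinal position along the chain
    amino_acid: str  # one-letter code ('X' for unknown)
    ca: np.ndarray  # (3,) Angstrom
    sidechain: np.ndarray  # (k, 3) heavy sidechain atoms (>= 1 row)
    author_id: str = ""  # author residue number + insertion code


@dataclass
class ReferenceStructure:
    """A chain's residues plus its precomputed distance matrices."""

    id: str
    residues: list[Residue]
    ca_distance: np.ndarray = field(default=None, repr=False)
    pairwise_min_distance: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.residues:
            raise DataError(f"structure {self.id}: no residues")
        if self.ca_distance is None:
            cas = np.array([r.ca for r in self.residues])
            self.ca_distance = cdist(cas, cas)
        if self.pairwise_min_distance is None:
            self.pairwise_min_distance = _min_sidechain_matrix(self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def contact_matrix(self, z: float = 4.0) -> np.ndarray:
        """Boolean matrix: minimum sidechain distance <= z (diagonal False)."""
        contacts = self.pairwise_min_distance <= z
        np.fill_diagonal(contacts, False)
        return contacts

    @classmethod
    def from_coords(
        cls, id: str, sequence: str, coords: np.ndarray
    ) -> "ReferenceStructure":
        """Build a bead-chain structure (one atom per residue)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(sequence), 3):
            raise DataError("coords shape does not match sequence length")
        residues = [
            Residue(i + 1, aa, coords[i], coords[i : i + 1], str(i + 1))
            for i, aa in enumerate(sequence)
        ]
        return cls(id=id, residues=residues)


def min_sidechain_distance(r1: Residue, r2: Residue) -> float:
    """Minimum Euclidean distance between the two residues' sidechain atoms."""
    return float(cdist(r1.sidechain, r2.sidechain).min())


def _min_sidechain_matrix(residues: list[Residue]) -> np.ndarray:
    atoms = np.concatenate([r.sidechain for r in residues])
    owner = np.concatenate(
        [np.full(len(r.sidechain), i) for i, r in enumerate(residues)]
    )
    d = cdist(atoms, atoms)
    n = len(residues)
    out = np.full((n, n), np.inf)
    np.minimum.at(out, (owner[:, None], owner[None, :]), d)
    return out


def read_structure(path, chain: str) -> ReferenceStructure:
    """Read one chain from a PDB (or mmCIF) coordinate file.

    Keeps one entry per amino-acid residue with a resolved C-alpha;
    residues lacking a C-alpha are skipped with a warning.  Where alternate
    locations exist, the highest-occupancy atom is kept.  Residues are
    renumbered by ordinal chain position (1-based); the author numbering
    (with insertion codes) is retained in ``author_id``.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise DataError(f"cannot read structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise DataError(f"{path}: no models")
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        available = [c.name for c in model]
        raise DataError(
            f"{path}: chain {chain!r} not found (available: {available})"
        )
    residues: list[Residue] = []
    pos = 0
    for res in ch:
        info = gemmi.find_tabulated_residue(res.name)
        if info is not None and not info.is_amino_acid():
            continue
        # altloc resolution: per atom name, keep the highest occupancy
        best: dict[str, gemmi.Atom] = {}
        for atom in res:
            if atom.is_hydrogen():
                continue
            prev = best.get(atom.name)
            if prev is None or atom.occ > prev.occ:
                best[atom.name] = atom
        if "CA" not in best:
            logger.warning(
                "%s chain %s: residue %s %s lacks a C-alpha; skipped",
                path, chain, res.name, res.seqid,
            )
            continue
        pos += 1
        ca = np.array(best["CA"].pos.tolist())
        side = np.array(
            [a.pos.tolist() for name, a in best.items() if name not in BACKBONE_ATOMS]
        )
        if side.size == 0:
            # glycine by design; other residues only when disordered
            if res.name != "GLY":
                logger.warning(
                    "%s chain %s: residue %s %s has no sidechain atoms; "
                    "using C-alpha", path, chain, res.name, res.seqid,
                )
            side = ca[None, :]
        aa = THREE_TO_ONE.get(res.name, "X")
        author = f"{res.seqid.num}{res.seqid.icode}".strip()
        residues.append(Residue(pos, aa, ca, side, author))
    if not residues:
        raise DataError(f"{path} chain {chain}: no residues with a C-alpha")
    name = st.name or str(path)
    return ReferenceStructure(id=f"{name}_{chain}", residues=residues)


def export_matrix_tsv(matrix: np.ndarray, path, fmt: str = "%.3f") -> None:
    """Write a contact or distance matrix as TSV."""
    np.savetxt(path, matrix, fmt=fmt, delimiter="\t")
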