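"""Reading, writing and filtering multiple sequence alignments.

An :class:`Msa` couples the aligned records with a boolean *scored column*
mask.  Downstream coupling analysis only ever sees the scored columns:

* match-state formats (A2M, Stockholm with a ``#=GC RF`` line) declare the
  scored columns themselves — insert columns are never scored;
* flush formats (plain aligned FASTA) start with an all-true mask, and
  :func:`filter_null_columns` masks out columns that are mostly gaps.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .alphabet import NULL_CHARS, encode_identity, rows_to_bytes
from .errors import FormatError

MATCH_STATE = "match_state"
FLUSH = "flush"


@dataclass
class Msa:
    """An alignment: records plus the scored-column mask.

    Parameters
    ----------
    records
        ``(identifier, aligned_sequence)`` pairs in file order.  Sequences
        are over the amino-acid alphabet plus the null characters ``-`` and
        ``.``; any letter (either case) counts as a residue.
    column_mask
        Boolean vector over alignment columns; True marks scored columns.
    source_dialect
        ``"match_state"`` if the mask came from the format itself,
        ``"flush"`` if every column started out scored.
    """

    records: list[tuple[str, str]]
    column_mask: np.ndarray
    source_dialect: str = FLUSH
    label: str = ""
    _bytes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("alignment contains no records")
        width = len(self.records[0][1])
        for name, seq in self.records:
            if len(seq) != width:
                raise FormatError(
                    f"ragged alignment: record {name!r} has length "
                    f"{len(seq)}, expected {width}"
                )
        self.column_mask = np.asarray(self.column_mask, dtype=bool)
        if self.column_mask.shape != (width,):
            raise FormatError("column_mask length does not match alignment width")
        ids = [name for name, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate record identifiers: {dupes[:5]}")

    # -- basic geometry -------------------------------------------------
    @property
    def width(self) -> int:
        return len(self.records[0][1])

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def identifiers(self) -> list[str]:
        return [name for name, _ in self.records]

    @property
    def scored_columns(self) -> np.ndarray:
        """Indices of scored columns, ascending."""
        return np.flatnonzero(self.column_mask)

    @property
    def n_scored(self) -> int:
        return int(self.column_mask.sum())

    # -- array views ----------------------------------------------------
    def as_bytes(self) -> np.ndarray:
        """(n_records, width) uint8 character matrix (cached)."""
        if self._bytes is None:
            self._bytes = rows_to_bytes([seq for _, seq in self.records])
        return self._bytes

    def identity_states(self, scored_only: bool = True) -> np.ndarray:
        """int8 matrix with amino-acid states 0..20 and nulls as -1."""
        enc = encode_identity(self.as_bytes())
        return enc[:, self.column_mask] if scored_only else enc

    def ungapped(self, index: int) -> str:
        """Residue-only sequence of one record, uppercased."""
        _, seq = self.records[index]
        return "".join(c for c in seq if c not in NULL_CHARS).upper()

    def residue_columns(self, index: int) -> np.ndarray:
        """Alignment column of each residue of one record, in order."""
        enc = encode_identity(self.as_bytes()[index])
        return np.flatnonzero(enc >= 0)

    def subset(self, keep: np.ndarray | list[int]) -> "Msa":
        keep = np.asarray(keep, dtype=int)
        return Msa(
            [self.records[i] for i in keep],
            self.column_mask.copy(),
            self.source_dialect,
            self.label,
        )


# ---------------------------------------------------------------------------
# reading


def _parse_fasta_records(text: str) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name = line[1:].split()[0] if len(line) > 1 else ""
            chunks = []
        elif name is None:
            raise FormatError("sequence data before first '>' header")
        else:
            chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    if not records:
        raise FormatError("no FASTA records found (empty file?)")
    return records


def _a2m_mask(records: list[tuple[str, str]]) -> np.ndarray:
    """Match columns of a column-aligned A2M: any uppercase or '-' present."""
    rows = rows_to_bytes([seq for _, seq in records])
    is_upper = (rows >= ord("A")) & (rows <= ord("Z"))
    is_dash = rows == ord("-")
    return (is_upper | is_dash).any(axis=0)


def _parse_stockholm(text: str) -> tuple[list[tuple[str, str]], str | None]:
    seqs: dict[str, list[str]] = {}
    order: list[str] = []
    rf_chunks: list[str] = []
    saw_header = False
    for line in text.splitlines():
        line = line.rstrip()
        if line.startswith("# STOCKHOLM"):
            saw_header = True
            continue
        if not line or line == "//":
            continue
        if line.startswith("#=GC"):
            parts = line.split()
            if len(parts) >= 3 and parts[1] == "RF":
                rf_chunks.append(parts[2])
            continue
        if line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"unparseable Stockholm line: {line!r}")
        name, chunk = parts
        if name not in seqs:
            seqs[name] = []
            order.append(name)
        seqs[name].append(chunk)
    if not saw_header:
        raise FormatError("missing '# STOCKHOLM' header")
    if not order:
        raise FormatError("Stockholm file contains no sequences")
    records = [(name, "".join(seqs[name])) for name in order]
    rf = "".join(rf_chunks) if rf_chunks else None
    return records, rf


def read_msa(path, format: str, label: str = "") -> Msa:
    """Read an alignment file.

    ``format`` is one of ``fasta`` (flush; all columns scored pending
    filtering), ``a2m`` (match columns are those containing uppercase
    residues or ``-``), or ``stockholm`` (match columns from the
    ``#=GC RF`` annotation when present, otherwise flush semantics).
    """
    with open(path) as fh:
        text = fh.read()
    if format == "fasta":
        records = _parse_fasta_records(text)
        msa = Msa(records, np.ones(len(records[0][1]), dtype=bool), FLUSH, label)
    elif format == "a2m":
        records = _parse_fasta_records(text)
        mask = _a2m_mask(records)
        msa = Msa(records, mask, MATCH_STATE, label)
    elif format == "stockholm":
        records, rf = _parse_stockholm(text)
        width = len(records[0][1])
        if rf is not None:
            if len(rf) != width:
                raise FormatError("#=GC RF length does not match alignment width")
            mask = np.array([c not in ".-~" for c in rf], dtype=bool)
            msa = Msa(records, mask, MATCH_STATE, label)
        else:
            msa = Msa(records, np.ones(width, dtype=bool), FLUSH, label)
    else:
        raise FormatError(f"unknown alignment format: {format!r}")
    return msa


def write_msa(msa: Msa, path, format: str) -> None:
    """Write an alignment, encoding the scored-column mask where the format
    can carry it (A2M by case, Stockholm by ``#=GC RF``)."""
    buf = io.StringIO()
    if format == "fasta":
        for name, seq in msa.records:
            buf.write(f">{name}\n{seq}\n")
    elif format == "a2m":
        mask = msa.column_mask
        for name, seq in msa.records:
            chars = []
            for j, c in enumerate(seq):
                if mask[j]:
                    chars.append("-" if c in NULL_CHARS else c.upper())
                else:
                    chars.append("." if c in NULL_CHARS else c.lower())
            buf.write(f">{name}\n{''.join(chars)}\n")
    elif format == "stockholm":
        buf.write("# STOCKHOLM 1.0\n")
        pad = max(len(name) for name, _ in msa.records)
        pad = max(pad, len("#=GC RF"))
        for name, seq in msa.records:
            buf.write(f"{name:<{pad}}  {seq}\n")
        rf = "".join("x" if m else "." for m in msa.column_mask)
        buf.write(f"{'#=GC RF':<{pad}}  {rf}\n//\n")
    else:
        raise FormatError(f"unknown alignment format: {format!r}")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_mask_track(msa: Msa, path) -> None:
    """Export the scored-column mask as a one-line 0/1 text track."""
    with open(path, "w") as fh:
        fh.write("".join("1" if m else "0" for m in msa.column_mask) + "\n")


# ---------------------------------------------------------------------------
# filtering


def filter_null_columns(msa: Msa, max_null_fraction: float = 0.5) -> Msa:
    """Unscore columns whose null fraction strictly exceeds the threshold.

    Applies only to flush alignments; match-state alignments keep the mask
    their format declared.  The sequence text is untouched (mask-only
    operation), so the filter is idempotent.
    """
    if msa.source_dialect == MATCH_STATE:
        return msa
    rows = msa.as_bytes()
    is_null = (rows == ord("-")) | (rows == ord("."))
    frac = is_null.mean(axis=0)
    mask = msa.column_mask & ~(frac > max_null_fraction)
    return replace(msa, column_mask=mask, _bytes=msa._bytes)


def pairwise_identity(states_a: np.ndarray, states_b: np.ndarray) -> float:
    """Identity over positions where both rows carry residues.

    ``states_*`` use the identity encoding (nulls as -1).  Returns NaN when
    the rows share no residue-bearing positions.
    """
    both = (states_a >= 0) & (states_b >= 0)
    n = int(both.sum())
    if n == 0:
        return float("nan")
    return float(((states_a == states_b) & both).sum() / n)


def purge_redundancy(msa: Msa, identity_cutoff: float = 0.95) -> Msa:
    """Greedy first-wins dereplication at an identity cutoff.

    Scanning in file order, a record is dropped when its identity to any
    already-kept record is >= ``identity_cutoff``.  Identity is computed
    over scored columns where *both* records carry residues, with that
    count as the denominator; records sharing no comparable positions with
    a kept record are kept.
    """
    states = msa.identity_states(scored_only=True)
    has_res = states >= 0
    kept: list[int] = []
    for i in range(msa.n_records):
        redundant = False
        for j in kept:
            both = has_res[i] & has_res[j]
            n = int(both.sum())
            if n == 0:
                continue
            ident = ((states[i] == states[j]) & both).sum() / n
            if ident >= identity_cutoff:
                redundant = True
                break
        if not redundant:
            kept.append(i)
    return msa.subset(kept)
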