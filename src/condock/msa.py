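"""Alignment parsing, organism pairing and query-to-column mapping.

Contact descriptors are computed from two multiple sequence alignments, one
per protein partner, whose rows must be matched by source organism: only
organisms with a homolog of *both* partners carry coevolution signal.  This
module parses aligned FASTA / Clustal input, extracts organism tags from
headers, pairs rows across the two alignments, and maps the residues of the
structure's chain onto alignment columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from io import StringIO

from Bio import AlignIO


class AlignmentError(ValueError):
    """Raised for malformed alignment input or failed query mapping."""


GAP = "-"

# Organism extraction: UniProt-style 'OS=...' field, else a bracketed
# suffix '[...]', else the full header.
_OS_RE = re.compile(r"\bOS=(.+?)(?:\s+[A-Z]{2}=|$)")
_BRACKET_RE = re.compile(r"\[([^\]]+)\]\s*$")


def extract_organism(header: str, pattern: str | None = None) -> str:
    """Organism tag from a sequence header.

    A custom regex ``pattern`` (first group = organism) takes precedence;
    otherwise the UniProt ``OS=`` field is tried, then a trailing bracketed
    tag, falling back to the whole header.
    """
    if pattern is not None:
        m = re.search(pattern, header)
        if m:
            return m.group(1).strip()
    m = _OS_RE.search(header)
    if m:
        return m.group(1).strip()
    m = _BRACKET_RE.search(header)
    if m:
        return m.group(1).strip()
    return header.strip()


@dataclass
class Alignment:
    """Rows of (header, organism tag, gapped sequence); row 0 is the query
    unless ``query_index`` says otherwise."""

    rows: list[tuple[str, str, str]]
    query_index: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("alignment has no rows")
        ncol = len(self.rows[0][2])
        for header, _, seq in self.rows:
            if len(seq) != ncol:
                raise AlignmentError(
                    f"ragged alignment: row {header!r} has length "
                    f"{len(seq)}, expected {ncol}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][2])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def query(self) -> str:
        return self.rows[self.query_index][2]

    def organisms(self) -> list[str]:
        return [org for _, org, _ in self.rows]


def parse_alignment(
    text: str,
    fmt: str = "fasta",
    organism_pattern: str | None = None,
    query_index: int = 0,
) -> Alignment:
    """Parse aligned FASTA (``fmt='fasta'``) or Clustal (``fmt='clustal'``).

    Sequences are upper-cased and '.' gaps normalized to '-'.  The organism
    tag is extracted from each header (see :func:`extract_organism`).
    """
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    if not text.strip():
        raise AlignmentError("empty alignment input")
    try:
        msa = AlignIO.read(StringIO(text), fmt)
    except ValueError as exc:
        raise AlignmentError(f"cannot parse {fmt} alignment: {exc}") from exc
    rows = []
    for record in msa:
        header = record.description or record.id
        seq = str(record.seq).upper().replace(".", GAP)
        rows.append((header, extract_organism(header, organism_pattern), seq))
    return Alignment(rows=rows, query_index=query_index)


@dataclass
class PairedAlignment:
    """Two alignments with rows matched by source organism.

    ``matched`` lists (row index in A, row index in B); the first entry is
    always the query pair.  Each organism contributes at most one pair.
    """

    a: Alignment
    b: Alignment
    matched: list[tuple[int, int]]

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    def matched_rows(self) -> list[tuple[str, str]]:
        """Gapped sequences of the matched row pairs, queries first."""
        return [(self.a.rows[i][2], self.b.rows[j][2]) for i, j in self.matched]


def _identity_to_query(seq: str, query: str) -> float:
    """Fraction of identical residues over columns ungapped in both."""
    both = [(s, q) for s, q in zip(seq, query) if s != GAP and q != GAP]
    if not both:
        return 0.0
    return sum(s == q for s, q in both) / len(both)


def _best_row_per_organism(aln: Alignment) -> dict[str, int]:
    """For each organism, the row with highest ungapped identity to the
    query; ties go to the first occurrence."""
    query = aln.query
    best: dict[str, tuple[float, int]] = {}
    for i, (_, org, seq) in enumerate(aln.rows):
        if i == aln.query_index:
            continue
        ident = _identity_to_query(seq, query)
        if org not in best or ident > best[org][0]:
            best[org] = (ident, i)
    return {org: i for org, (_, i) in best.items()}


def pair_rows_by_organism(a: Alignment, b: Alignment) -> PairedAlignment:
    """Match rows of two alignments by organism tag.

    The two query rows are always matched to each other.  For every other
    organism present in both alignments, the row with the highest ungapped
    identity to its own query is chosen (ties -> first occurrence);
    organisms present in only one alignment are dropped.
    """
    best_a = _best_row_per_organism(a)
    best_b = _best_row_per_organism(b)
    matched = [(a.query_index, b.query_index)]
    common = [org for org in best_a if org in best_b]  # insertion order of A
    for org in common:
        matched.append((best_a[org], best_b[org]))
    if len(matched) == 1:
        import warnings

        warnings.warn(
            "no organism shared between the two alignments besides the "
            "queries; descriptors will rest on the query pair alone",
            stacklevel=2,
        )
    return PairedAlignment(a=a, b=b, matched=matched)


def map_query_columns(
    aln: Alignment,
    chain_sequence: str,
    allow_x: bool = True,
) -> dict[int, int]:
    """Map chain residue positions to alignment columns (both 0-based).

    The k-th non-gap position of the query row maps to its column.  The
    degapped query must equal ``chain_sequence``; with ``allow_x`` a
    position matches if either side is ``X`` (unknown residue).
    """
    query = aln.query
    degapped = query.replace(GAP, "")
    if len(degapped) != len(chain_sequence):
        raise AlignmentError(
            f"query row degaps to {len(degapped)} residues but the chain "
            f"has {len(chain_sequence)}"
        )
    mapping: dict[int, int] = {}
    k = 0
    for col, aa in enumerate(query):
        if aa == GAP:
            continue
        expected = chain_sequence[k]
        if aa != expected and not (allow_x and (aa == "X" or expected == "X")):
            raise AlignmentError(
                f"query/chain sequence mismatch at position {k + 1}: "
                f"alignment has {aa!r}, chain has {expected!r}"
            )
        mapping[k] = col
        k += 1
    return mapping
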