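"""Sequence data model, genetic-code tables and FASTA/newick I/O.

Everything downstream (ORF scanning, dN/dS estimation, codon-model
likelihoods, neutral simulation) works on :class:`CodingSequence` — a
nucleotide string plus a reading-frame offset — and, for pairwise work,
:class:`PairwiseCodonAlignment`.  Only the standard genetic code is
supported; the stop set is fixed at {TAA, TAG, TGA}.

Coordinates are 0-based, half-open throughout the library; 1-based
coordinates appear only in CLI reports.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import dendropy
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ALPHABET",
    "BASES",
    "STOP_CODONS",
    "SENSE_CODONS",
    "CODON_TABLE",
    "CodingSequence",
    "GeneticCode",
    "PairwiseCodonAlignment",
    "StopScan",
    "read_fasta",
    "write_fasta",
    "read_tree",
    "iter_codons",
    "count_premature_stops",
    "scan_codons",
    "reverse_complement",
    "is_sense_codon",
]

BASES = "ACGT"
ALPHABET = frozenset("ACGTN-")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def _standard_codon_table() -> dict[str, str]:
    """Codon -> one-letter amino acid, with '*' for the three stops."""
    table = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
    for stop in STOP_CODONS:
        table[stop] = "*"
    # Standard table: 61 sense codons + 3 stops = 64 entries.
    assert len(table) == 64
    return table


CODON_TABLE: dict[str, str] = _standard_codon_table()
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
)


def is_sense_codon(codon: str) -> bool:
    return codon in CODON_TABLE and codon not in STOP_CODONS


@dataclasses.dataclass(frozen=True)
class GeneticCode:
    """The standard genetic code: codon -> amino acid, plus the stop set."""

    table: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(CODON_TABLE)
    )
    stop_set: frozenset[str] = STOP_CODONS

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError("genetic code must map all 64 codons")
        senses = sum(1 for aa in self.table.values() if aa != "*")
        if senses != 61 or len(self.stop_set) != 3:
            raise ValueError("expected 61 sense codons and 3 stops")

    def translate(self, codon: str) -> str:
        return self.table[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_set


@dataclasses.dataclass(frozen=True)
class CodingSequence:
    """A nucleotide sequence with an identified reading frame.

    Parameters
    ----------
    id:
        Record label (FASTA header word).
    bases:
        Upper-case nucleotides over ``{A, C, G, T, N, -}``.
    frame_offset:
        0-based position of the first codon start (0, 1 or 2).
    """

    id: str
    bases: str
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.bases) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}"
            )
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n_codons(self) -> int:
        return (len(self.bases) - self.frame_offset) // 3

    def codons(self) -> list[str]:
        return iter_codons(self)

    def reverse_complement(self) -> "CodingSequence":
        return CodingSequence(self.id, reverse_complement(self.bases), 0)


def reverse_complement(bases: str) -> str:
    return bases.translate(_COMPLEMENT)[::-1]


def iter_codons(seq: CodingSequence) -> list[str]:
    """Codons of ``seq`` respecting its frame offset.

    Trailing 1-2 bases that do not fill a codon are dropped.
    """
    b = seq.bases
    start = seq.frame_offset
    end = start + 3 * ((len(b) - start) // 3)
    return [b[i : i + 3] for i in range(start, end, 3)]


@dataclasses.dataclass(frozen=True)
class StopScan:
    """Breakdown of the codons of one sequence by stop/sense/ambiguous."""

    n_stops: int
    n_sense: int
    n_skipped: int

    @property
    def n_codons(self) -> int:
        return self.n_stops + self.n_sense + self.n_skipped


def scan_codons(seq: CodingSequence) -> StopScan:
    """Classify every in-frame codon as stop, sense, or skipped.

    Codons containing ``N`` or a gap are skipped (the "treated as gaps"
    policy), never counted as stops or sense codons.
    """
    stops = sense = skipped = 0
    for codon in iter_codons(seq):
        if codon in STOP_CODONS:
            stops += 1
        elif codon in CODON_TABLE:
            sense += 1
        else:
            skipped += 1
    return StopScan(stops, sense, skipped)


def count_premature_stops(seq: CodingSequence) -> int:
    """Number of in-frame stop codons (TAA/TAG/TGA) in ``seq``.

    The caller is responsible for excluding a terminal stop codon from
    the scanned region when one is present; every stop counted here is
    treated as premature.
    """
    return scan_codons(seq).n_stops


@dataclasses.dataclass(frozen=True)
class PairwiseCodonAlignment:
    """Two gap-aligned coding sequences compared codon-by-codon.

    Codon columns in which either sequence has a gap or an ambiguous
    base — or a stop codon, which has no degeneracy classification —
    are flagged excluded (pairwise deletion).
    """

    seq_a: CodingSequence
    seq_b: CodingSequence

    def __post_init__(self) -> None:
        if len(self.seq_a.bases) != len(self.seq_b.bases):
            raise ValueError(
                "aligned sequences differ in length: "
                f"{len(self.seq_a.bases)} vs {len(self.seq_b.bases)}"
            )
        if self.seq_a.frame_offset != self.seq_b.frame_offset:
            raise ValueError("aligned sequences must share a frame offset")
        if (len(self.seq_a.bases) - self.seq_a.frame_offset) < 3:
            raise ValueError("alignment shorter than one codon")

    @property
    def n_columns(self) -> int:
        return self.seq_a.n_codons

    def codon_columns(self) -> list[tuple[str, str]]:
        return list(zip(iter_codons(self.seq_a), iter_codons(self.seq_b)))

    def included_columns(self) -> list[tuple[str, str]]:
        """Codon columns that survive pairwise deletion."""
        return [
            (a, b)
            for a, b in self.codon_columns()
            if is_sense_codon(a) and is_sense_codon(b)
        ]

    def slice_codons(self, start: int, stop: int) -> "PairwiseCodonAlignment":
        """Sub-alignment over codon columns [start, stop) (0-based)."""
        off = self.seq_a.frame_offset
        lo, hi = off + 3 * start, off + 3 * stop
        return PairwiseCodonAlignment(
            CodingSequence(self.seq_a.id, self.seq_a.bases[lo:hi], 0),
            CodingSequence(self.seq_b.id, self.seq_b.bases[lo:hi], 0),
        )


class FastaParseError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Read a (wrapped or unwrapped) multi-FASTA file.

    Sequences are upper-cased and RNA ``U`` is mapped to ``T``.  Empty
    records and malformed headers raise :class:`FastaParseError` naming
    the offending line.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        bases = str(rec.seq).upper().replace("U", "T")
        records.append(CodingSequence(rec.id, bases))
    return records


def _validate_fasta_lines(path: Path) -> None:
    header_line = None
    body_seen = True  # tolerate leading blank lines before first header
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                if header_line is not None and not body_seen:
                    raise FastaParseError(
                        f"{path}:{header_line}: record has no sequence"
                    )
                header_line = lineno
                body_seen = False
            else:
                if header_line is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                body_seen = True
    if header_line is None:
        raise FastaParseError(f"{path}: no FASTA records found")
    if not body_seen:
        raise FastaParseError(f"{path}:{header_line}: record has no sequence")


def write_fasta(
    seqs: Iterable[CodingSequence], path: str | Path, width: int = 70
) -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width or None)
        writer.write_file(records)


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a newick tree (branch lengths and internal labels kept)."""
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=False,
    )
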