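"""Stop-to-stop ORF extraction on both strands with frame-based naming.

An ORF here is a maximal run of non-stop codons bounded by stop codons
or by the region ends (no ATG requirement — the elements scanned are
decaying viral-gene remnants, so runs truncated by the region boundary
are eligible).  Runs must be strictly longer than ``min_codons``
(default 50, i.e. at least 51 codons) to be reported.

Naming follows reading-frame correspondence with a reference gene whose
first codon starts at region coordinate ``reference_frame_start``:

* forward-strand ORFs are ORF1/ORF2/ORF3 when position 1 of their first
  codon falls on reference codon position 1/2/3;
* reverse-strand ORFs are ORF-1/ORF-2/ORF-3 when position 1 of their
  first codon (the 3'-most base on the forward strand) is complementary
  to reference codon position 1/2/3;
* when several reported ORFs share a frame name on one strand they are
  suffixed a, b, c ... in 5'->3' order on that strand (partial ORFs).
"""

from __future__ import annotations

import dataclasses

from .seq_core import STOP_CODONS, CodingSequence, reverse_complement

__all__ = ["OrfRecord", "find_orfs", "name_partial_orfs"]


@dataclasses.dataclass
class OrfRecord:
    """One ORF on the forward-strand coordinate system of the region.

    ``start``/``end`` are 0-based half-open forward-strand coordinates
    of the codon run; a bounding stop codon is not included, so
    ``end - start == 3 * n_codons``.
    """

    start: int
    end: int
    strand: str  # '+' or '-'
    n_codons: int
    frame_name: str  # ORF1..ORF3 / ORF-1..ORF-3, optional a/b/c suffix

    @property
    def base_frame_name(self) -> str:
        return self.frame_name.rstrip("abcdefghijklmnopqrstuvwxyz")


def _stop_free_runs(bases: str, offset: int) -> list[tuple[int, int]]:
    """Maximal stop-free codon runs [start, end) in one frame of ``bases``.

    Codons containing N or '-' do not terminate a run; sequence ends
    count as boundaries.
    """
    n_codons = (len(bases) - offset) // 3
    runs: list[tuple[int, int]] = []
    run_start: int | None = None
    for k in range(n_codons):
        pos = offset + 3 * k
        codon = bases[pos : pos + 3]
        if codon in STOP_CODONS:
            if run_start is not None:
                runs.append((run_start, pos))
                run_start = None
        elif run_start is None:
            run_start = pos
    if run_start is not None:
        runs.append((run_start, offset + 3 * n_codons))
    return [(s, e) for s, e in runs if e > s]


def find_orfs(
    region: CodingSequence,
    min_codons: int = 50,
    reference_frame_start: int = 0,
) -> list[OrfRecord]:
    """All ORFs with more than ``min_codons`` codons on both strands.

    Parameters
    ----------
    region:
        The genomic region to scan (forward strand as given).
    min_codons:
        Strict lower bound: only runs with ``n_codons > min_codons``
        are reported.
    reference_frame_start:
        Region coordinate aligned with position 1 of the reference
        gene's first codon; defines which frame is called ORF1/ORF-1.

    Returns
    -------
    list of :class:`OrfRecord`, sorted by ``start``, with a/b/c
    suffixes already applied to frame names shared by several records.
    """
    bases = region.bases
    length = len(bases)
    k0 = reference_frame_start
    records: list[OrfRecord] = []

    for offset in range(3):
        for s, e in _stop_free_runs(bases, offset):
            n = (e - s) // 3
            if n > min_codons:
                frame = (s - k0) % 3 + 1
                records.append(OrfRecord(s, e, "+", n, f"ORF{frame}"))

    rc = reverse_complement(bases)
    for offset in range(3):
        for s_rc, e_rc in _stop_free_runs(rc, offset):
            n = (e_rc - s_rc) // 3
            if n > min_codons:
                start, end = length - e_rc, length - s_rc
                # position 1 of the first reverse codon pairs with
                # forward coordinate end - 1
                frame = (end - 1 - k0) % 3 + 1
                records.append(OrfRecord(start, end, "-", n, f"ORF-{frame}"))

    records = name_partial_orfs(records)
    records.sort(key=lambda r: (r.start, r.strand))
    return records


def name_partial_orfs(records: list[OrfRecord]) -> list[OrfRecord]:
    """Suffix frame names shared by >= 2 records with a, b, c ...

    Suffix order follows coordinate order 5'->3' on each record's own
    strand; single occupants of a frame keep the bare name.
    """
    groups: dict[tuple[str, str], list[OrfRecord]] = {}
    for rec in records:
        groups.setdefault((rec.strand, rec.base_frame_name), []).append(rec)
    for (strand, base), group in groups.items():
        if len(group) < 2:
            continue
        group.sort(key=lambda r: r.start, reverse=(strand == "-"))
        if len(group) > 26:
            raise ValueError(f"more than 26 partial ORFs share frame {base}")
        for i, rec in enumerate(group):
            rec.frame_name = base + chr(ord("a") + i)
    return records
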