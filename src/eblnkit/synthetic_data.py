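"""Seed-deterministic fixture generators with carried ground truth.

Everything the analysis stages consume can be synthesized here: random
stop-free coding sequences, orthologous pairs diverged under a
controlled dN/dS ratio, multi-taxon alignments simulated down a species
tree with per-branch omegas, and ORF-disrupted genomic regions (premature
stops, frameshift-like single-base indels, noncoding flanks) whose true
ORF structure is returned alongside the sequence so downstream checks
are closed-loop.

Pair divergence is parameterized by the synonymous branch length
``t_syn`` (expected synonymous substitutions per synonymous site,
tip-to-tip) so the true dS is known analytically; the realized
nonsynonymous divergence is omega-controlled but only approximately
``omega * t_syn`` on the counting scale, so recovery checks should
compare against simulation-measured truth.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .codon_ml import (
    N_STATES,
    PhyloTree,
    codon_transition_matrix,
    synonymous_fraction,
    synonymous_sites_per_codon,
)
from .seq_core import SENSE_CODONS, STOP_CODONS, CodingSequence, PairwiseCodonAlignment

__all__ = [
    "PairSimSpec",
    "PairSimResult",
    "SimulatedAlignment",
    "DegradedRegion",
    "random_stop_free_sequence",
    "simulate_pair",
    "simulate_tree_alignment",
    "make_degraded_region",
]

_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

# 12-nt cassette containing a stop codon in all three frames of both
# strands; used to insulate fixture templates from their flanks
_STOP_CASSETTE = "CTAACTAACTAA"


def _uniform_freqs() -> np.ndarray:
    return np.full(N_STATES, 1.0 / N_STATES)


def _encode_codons(seq: CodingSequence) -> np.ndarray:
    try:
        return np.array([_CODON_INDEX[c] for c in seq.codons()])
    except KeyError as exc:
        raise ValueError(
            f"sequence {seq.id!r} contains a stop or ambiguous codon"
        ) from exc


def _decode_codons(states: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in states)


def _sample_children(
    P: np.ndarray, parents: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    cum /= cum[:, -1:]
    u = rng.random(len(parents))
    return (u[:, None] > cum[parents]).sum(axis=1)


def random_stop_free_sequence(
    n_codons: int,
    codon_freqs: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
    id: str = "synthetic",
) -> CodingSequence:
    """Random stop-free coding sequence of exactly ``3 * n_codons`` nt.

    Codons are drawn i.i.d. from ``codon_freqs`` over the 61 sense
    codons (uniform by default).
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    freqs = _uniform_freqs() if codon_freqs is None else np.asarray(codon_freqs, float)
    if freqs.shape != (N_STATES,) or np.any(freqs < 0) or freqs.sum() <= 0:
        raise ValueError("codon_freqs must be 61 nonnegative weights")
    freqs = freqs / freqs.sum()
    rng = np.random.default_rng(seed)
    states = rng.choice(N_STATES, size=n_codons, p=freqs)
    return CodingSequence(id, _decode_codons(states), 0)


@dataclasses.dataclass(frozen=True)
class PairSimSpec:
    """Conditions for simulating one orthologous sequence pair.

    t_syn:
        Expected synonymous substitutions per synonymous site between
        the two tips (split evenly over the two lineages).
    """

    n_codons: int
    omega: float
    t_syn: float
    kappa: float = 2.0
    codon_freqs: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.omega < 0 or self.t_syn < 0 or self.kappa <= 0:
            raise ValueError("omega, t_syn must be >= 0 and kappa > 0")


@dataclasses.dataclass(frozen=True)
class PairSimResult:
    """A simulated pair plus the truth that generated it."""

    alignment: PairwiseCodonAlignment
    ancestor: CodingSequence
    spec: PairSimSpec
    branch_length_per_lineage: float  # substitutions per codon


def simulate_pair(ancestor: CodingSequence, spec: PairSimSpec) -> PairSimResult:
    """Evolve two descendants independently from a stop-free ancestor.

    Each lineage gets a codon-model branch length calibrated so the
    expected synonymous divergence per synonymous site between the tips
    equals ``spec.t_syn``.
    """
    freqs = (
        _uniform_freqs()
        if spec.codon_freqs is None
        else np.asarray(spec.codon_freqs, float) / np.asarray(spec.codon_freqs, float).sum()
    )
    parents = _encode_codons(ancestor)
    if len(parents) != spec.n_codons:
        raise ValueError(
            f"ancestor has {len(parents)} codons but spec.n_codons={spec.n_codons}"
        )
    rng = np.random.default_rng(spec.seed)
    S = synonymous_sites_per_codon(spec.kappa, freqs)
    fs = synonymous_fraction(spec.kappa, spec.omega, freqs)
    # expected syn subs per codon at branch length t is t * fs; per syn
    # site divide by S; per-lineage target is t_syn / 2
    t_branch = 0.0 if spec.t_syn == 0 else (spec.t_syn / 2.0) * S / fs
    if t_branch > 0:
        P = codon_transition_matrix(spec.kappa, spec.omega, freqs, t_branch)
        a = _sample_children(P, parents, rng)
        b = _sample_children(P, parents, rng)
    else:
        a = parents.copy()
        b = parents.copy()
    seq_a = CodingSequence(f"{ancestor.id}_d1", _decode_codons(a), 0)
    seq_b = CodingSequence(f"{ancestor.id}_d2", _decode_codons(b), 0)
    return PairSimResult(
        PairwiseCodonAlignment(seq_a, seq_b), ancestor, spec, t_branch
    )


@dataclasses.dataclass(frozen=True)
class SimulatedAlignment:
    """Leaf alignment simulated down a tree, with internal truth kept."""

    alignment: list[CodingSequence]
    internal_states: dict[str, str]  # internal branch label -> codon string
    tree: PhyloTree
    kappa: float
    codon_freqs: np.ndarray
    omega_by_branch: dict[str, float]


def simulate_tree_alignment(
    tree: PhyloTree | str | Path,
    per_branch_omega: dict[str, float],
    kappa: float = 2.0,
    codon_freqs: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
    n_codons: int = 300,
    ancestor: Optional[CodingSequence] = None,
) -> SimulatedAlignment:
    """Simulate a codon alignment at the leaves of a fixed tree.

    Branch lengths are taken from the tree (substitutions per codon);
    every branch label must appear in ``per_branch_omega``.
    """
    if not isinstance(tree, PhyloTree):
        tree = PhyloTree.from_newick(tree)
    freqs = _uniform_freqs() if codon_freqs is None else np.asarray(codon_freqs, float)
    freqs = freqs / freqs.sum()
    missing = set(tree.branch_labels) - set(per_branch_omega)
    if missing:
        raise ValueError(f"omega missing for branches: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    if ancestor is not None:
        root_states = _encode_codons(ancestor)
        n_codons = len(root_states)
    else:
        root_states = rng.choice(N_STATES, size=n_codons, p=freqs)

    states: dict[int, np.ndarray] = {tree.root.index: root_states}
    for node in reversed(tree.postorder):  # preorder
        if node is tree.root:
            continue
        t = node.length
        if t is None:
            raise ValueError(f"branch {node.label!r} has no length")
        if t > 0:
            P = codon_transition_matrix(
                kappa, per_branch_omega[node.label], freqs, t
            )
            states[node.index] = _sample_children(
                P, states[node.parent.index], rng
            )
        else:
            states[node.index] = states[node.parent.index].copy()

    leaves = [
        CodingSequence(n.label, _decode_codons(states[n.index]), 0)
        for n in tree.leaves
    ]
    internal = {
        n.label: _decode_codons(states[n.index])
        for n in tree.postorder
        if not n.is_leaf and n is not tree.root
    }
    return SimulatedAlignment(
        leaves, internal, tree, kappa, freqs, dict(per_branch_omega)
    )


# ---------------------------------------------------------------------------
# degraded genomic regions for the ORF scanner
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ExpectedOrf:
    start: int
    end: int
    strand: str
    frame_name: str
    n_codons: int


@dataclasses.dataclass(frozen=True)
class DegradedRegion:
    """A fixture region and the ORF structure built into it."""

    region: CodingSequence
    template_start: int  # region coordinate of template codon 1
    template_end: int
    reference_frame_start: int  # == template_start
    stop_codon_positions: tuple[int, ...]  # template codon indices mutated
    indel_positions: tuple[int, ...]  # region coords (pre-indel) of indels
    expected_orfs: tuple[ExpectedOrf, ...]
    min_codons: int


def _random_flank(n_nt: int, rng: np.random.Generator) -> str:
    """Random flank guaranteed to contain no long ORF on either strand.

    Built from short random blocks separated by stop cassettes, so
    every reading frame of both strands hits a stop at least every ~20
    codons.
    """
    parts: list[str] = []
    total = 0
    while total < n_nt:
        block = "".join(rng.choice(list("ACGT"), size=45)) + _STOP_CASSETTE
        parts.append(block)
        total += len(block)
    return "".join(parts)[:n_nt]


def _forward_runs(bases: str, offset: int) -> list[tuple[int, int]]:
    """Maximal stop-free codon runs in one forward frame (construction
    oracle used for ground truth; plain stop lookup, no scanner code)."""
    runs = []
    start = None
    n = (len(bases) - offset) // 3
    for k in range(n):
        pos = offset + 3 * k
        if bases[pos : pos + 3] in STOP_CODONS:
            if start is not None:
                runs.append((start, pos))
                start = None
        elif start is None:
            start = pos
    if start is not None:
        runs.append((start, offset + 3 * n))
    return runs


def make_degraded_region(
    orf_template: CodingSequence,
    n_stops: int = 0,
    n_frameshifts: int = 0,
    flank_nt: int = 1000,
    seed: Optional[int] = None,
    min_codons: int = 50,
) -> DegradedRegion:
    """Embed a mutated copy of a stop-free template in a noncoding region.

    ``n_stops`` interior codons are rewritten as stop codons and
    ``n_frameshifts`` single-base deletions are applied, then the
    template is wrapped in stop cassettes and ``flank_nt`` of ORF-free
    random flank on each side.  The returned ground truth lists every
    ORF (stop-to-stop run, both cassette and template stops counted)
    that overlaps the template in the template's own frame and, after
    frameshifts, in the shifted frames — exactly what a scanner
    restricted to template-overlapping forward-strand records of those
    frames must report.
    """
    codons = orf_template.codons()
    if any(c in STOP_CODONS or set(c) - set("ACGT") for c in codons):
        raise ValueError("template must be stop-free and unambiguous")
    n = len(codons)
    mutable = list(range(1, n - 1))
    if n_stops > len(mutable):
        raise ValueError("requested stops exceed mutable codons")
    rng = np.random.default_rng(seed)

    stop_positions = sorted(
        int(i) for i in rng.choice(mutable, size=n_stops, replace=False)
    )
    stops = sorted(STOP_CODONS)
    mutated = list(codons)
    for i in stop_positions:
        mutated[i] = stops[int(rng.integers(len(stops)))]
    body = "".join(mutated)

    # single-base deletions, recorded in pre-indel template coordinates
    indel_sites = sorted(
        int(i)
        for i in rng.choice(
            np.arange(3, len(body) - 3), size=n_frameshifts, replace=False
        )
    )
    shifted = body
    for k, site in enumerate(indel_sites):
        pos = site - k  # earlier deletions shift later coordinates
        shifted = shifted[:pos] + shifted[pos + 1 :]

    left = _random_flank(flank_nt, rng)
    right = _random_flank(flank_nt, rng)
    prefix = left + _STOP_CASSETTE
    region_bases = prefix + shifted + _STOP_CASSETTE + right
    template_start = len(prefix)
    template_end = template_start + len(shifted)
    region = CodingSequence(f"{orf_template.id}_region", region_bases, 0)

    # ground truth: runs overlapping the template in the template frame
    # and in every frame reachable by the applied frameshifts
    frames = sorted(
        {(template_start - k) % 3 for k in range(n_frameshifts + 1)}
    )
    raw: list[tuple[int, int]] = []
    for offset in frames:
        for s, e in _forward_runs(region_bases, offset):
            if e > template_start and s < template_end and (e - s) // 3 > min_codons:
                raw.append((s, e))

    named: dict[str, list[tuple[int, int]]] = {}
    for s, e in sorted(raw):
        base = f"ORF{(s - template_start) % 3 + 1}"
        named.setdefault(base, []).append((s, e))
    expected = []
    for base, group in named.items():
        for i, (s, e) in enumerate(group):
            name = base if len(group) == 1 else base + chr(ord("a") + i)
            expected.append(ExpectedOrf(s, e, "+", name, (e - s) // 3))
    expected.sort(key=lambda r: r.start)

    return DegradedRegion(
        region=region,
        template_start=template_start,
        template_end=template_end,
        reference_frame_start=template_start,
        stop_codon_positions=tuple(stop_positions),
        indel_positions=tuple(indel_sites),
        expected_orfs=tuple(expected),
        min_codons=min_codons,
    )
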