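"""Branch-wise dN/dS by maximum likelihood under a codon substitution model.

The model is the standard 61-sense-codon Markov process: instantaneous
rates are zero for multi-position changes and proportional to

    pi_j                synonymous transversion
    kappa * pi_j        synonymous transition
    omega * pi_j        nonsynonymous transversion
    omega * kappa * pi_j  nonsynonymous transition

for a single-base change i -> j, with each branch's generator scaled so
its branch length is in expected substitutions per codon site-triplet.
Likelihoods are computed by Felsenstein pruning over the 61 states;
columns with gaps or ambiguity are marginalized by summing over the
compatible states rather than deleted.

Two nested branch models are fitted: the *selection* (free-ratio) model
gives every branch its own omega, and the *null* model pins omega = 1 on
specified branches while freeing the rest.  Twice the log-likelihood
difference is referred to a chi-square distribution with degrees of
freedom equal to the number of pinned omegas, with a Bonferroni-corrected
per-test significance level for families of branch tests.

Equilibrium codon frequencies are estimated empirically from the
alignment (observed codon counts, normalized — an F61-style plug-in)
rather than optimized as 60 free parameters.

Fitting is coordinate-wise in the style of phylogenetic ML programs:
each branch's (length, omega) pair is optimized against 'upper' and
'lower' conditional likelihoods of the rest of the tree, with a global
kappa line search per sweep, repeated from several initial omega values
and keeping the best likelihood.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .seq_core import CODON_TABLE, SENSE_CODONS, CodingSequence, iter_codons

__all__ = [
    "CodonModelParams",
    "BranchModelFit",
    "LrtResult",
    "PhyloTree",
    "build_rate_matrix",
    "codon_transition_matrix",
    "empirical_codon_freqs",
    "log_likelihood",
    "fit",
    "lrt",
    "branch_dn_ds",
    "synonymous_fraction",
    "synonymous_sites_per_codon",
    "N_STATES",
]

N_STATES = 61

_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_TRANSITION_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _single_step_pairs() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(i, j, is_transition, is_synonymous) over ordered single-change pairs."""
    I, J, TS, SYN = [], [], [], []
    for a, i in _CODON_INDEX.items():
        for b, j in _CODON_INDEX.items():
            diff = [p for p in range(3) if a[p] != b[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            I.append(i)
            J.append(j)
            TS.append((a[p], b[p]) in _TRANSITION_PAIRS)
            SYN.append(CODON_TABLE[a] == CODON_TABLE[b])
    return (
        np.array(I),
        np.array(J),
        np.array(TS, dtype=bool),
        np.array(SYN, dtype=bool),
    )


_I, _J, _TS, _SYN = _single_step_pairs()

_T_BOUNDS = (1e-7, 20.0)
_W_BOUNDS = (1e-4, 50.0)
_K_BOUNDS = (0.05, 100.0)


# ---------------------------------------------------------------------------
# rate matrix
# ---------------------------------------------------------------------------


def build_rate_matrix(
    kappa: float,
    omega: float,
    codon_freqs: np.ndarray,
    scale: bool = True,
) -> np.ndarray:
    """61 x 61 codon generator; rows sum to zero.

    With ``scale=True`` the matrix is normalized so the mean
    substitution rate at equilibrium is 1, making branch lengths
    expected substitutions per codon.  Zero-frequency target codons
    simply get zero incoming rate.
    """
    if kappa < 0 or omega < 0:
        raise ValueError("kappa and omega must be >= 0")
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (N_STATES,) or np.any(pi < 0):
        raise ValueError("codon_freqs must be 61 nonnegative weights")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("codon_freqs must sum to 1")
    rates = pi[_J] * np.where(_TS, kappa, 1.0) * np.where(_SYN, 1.0, omega)
    Q = np.zeros((N_STATES, N_STATES))
    Q[_I, _J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mu = -float(pi @ np.diag(Q))
        if mu <= 0:
            raise ValueError("degenerate model: zero mean substitution rate")
        Q /= mu
    return Q


def synonymous_fraction(kappa: float, omega: float, codon_freqs: np.ndarray) -> float:
    """Fraction of substitutions that are synonymous at equilibrium."""
    pi = np.asarray(codon_freqs, dtype=float)
    rates = pi[_J] * np.where(_TS, kappa, 1.0) * np.where(_SYN, 1.0, omega)
    flux = pi[_I] * rates
    return float(flux[_SYN].sum() / flux.sum())


def synonymous_sites_per_codon(kappa: float, codon_freqs: np.ndarray) -> float:
    """Mutational-opportunity synonymous sites per codon: 3 x neutral
    synonymous fraction (omega = 1)."""
    return 3.0 * synonymous_fraction(kappa, 1.0, codon_freqs)


class _Spectral:
    """Eigendecomposition of a reversible generator for fast P(t)."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        S = Q * (d[:, None] / d[None, :])
        S = 0.5 * (S + S.T)  # symmetric up to round-off by reversibility
        w, U = np.linalg.eigh(S)
        self.w = w
        self.V = U / d[:, None]
        self.Vi = (U * d[:, None]).T

    def transition(self, t: float) -> np.ndarray:
        P = (self.V * np.exp(self.w * t)) @ self.Vi
        return np.clip(P, 0.0, None)


def codon_transition_matrix(
    kappa: float, omega: float, codon_freqs: np.ndarray, t: float
) -> np.ndarray:
    """P(t) for one branch; rows renormalized to sum to exactly 1."""
    pi = np.asarray(codon_freqs, dtype=float)
    P = _Spectral(build_rate_matrix(kappa, omega, pi), pi).transition(t)
    return P / P.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("label", "length", "children", "parent", "index")

    def __init__(self, label: str | None, length: float | None):
        self.label = label
        self.length = length
        self.children: list["_Node"] = []
        self.parent: Optional["_Node"] = None
        self.index = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted view of an (un)rooted tree for pruning.

    Every non-root node carries one branch, identified by the node's
    label: the taxon name for leaves, the newick internal label when
    present, else an auto-assigned ``b1``, ``b2``, ...  A basal
    bifurcation is collapsed (the two root edges of an unrooted tree
    are not separately identifiable under a reversible model).
    """

    def __init__(self, root: _Node):
        self.root = root
        self.postorder: list[_Node] = []
        self._fill_postorder(root)
        for i, node in enumerate(self.postorder):
            node.index = i
        self._label_branches()

    def _fill_postorder(self, node: _Node) -> None:
        for child in node.children:
            self._fill_postorder(child)
        self.postorder.append(node)

    def _label_branches(self) -> None:
        used = {n.label for n in self.postorder if n.label}
        counter = 1
        for node in self.postorder:
            if node is self.root or node.label:
                continue
            while f"b{counter}" in used:
                counter += 1
            node.label = f"b{counter}"
            used.add(node.label)
        labels = [n.label for n in self.postorder if n is not self.root]
        if len(labels) != len(set(labels)):
            raise ValueError("branch labels are not unique")

    @property
    def branches(self) -> list[_Node]:
        return [n for n in self.postorder if n is not self.root]

    @property
    def branch_labels(self) -> list[str]:
        return [n.label for n in self.branches]

    @property
    def leaves(self) -> list[_Node]:
        return [n for n in self.postorder if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    @classmethod
    def from_newick(cls, source: str | Path) -> "PhyloTree":
        if isinstance(source, Path) or (
            isinstance(source, str) and "(" not in source
        ):
            dtree = dendropy.Tree.get(
                path=str(source), schema="newick", preserve_underscores=True
            )
        else:
            dtree = dendropy.Tree.get(
                data=source, schema="newick", preserve_underscores=True
            )
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        def convert(dnode) -> _Node:
            label = (
                dnode.taxon.label
                if dnode.taxon is not None
                else (dnode.label or None)
            )
            node = _Node(label, dnode.edge.length)
            for dchild in dnode.child_nodes():
                child = convert(dchild)
                child.parent = node
                node.children.append(child)
            return node

        root = convert(dtree.seed_node)
        root.length = None
        if len(root.children) == 2:
            root = cls._collapse_basal_bifurcation(root)
        return cls(root)

    @staticmethod
    def _collapse_basal_bifurcation(root: _Node) -> _Node:
        a, b = root.children
        if a.is_leaf and b.is_leaf:
            # 2-taxon tree: keep the basal bifurcation (only the sum of
            # the two root edges is identifiable, which is fine)
            return root
        if a.is_leaf:
            keep, other = b, a
        else:
            keep, other = a, b
        other.length = (other.length or 0.0) + (keep.length or 0.0)
        other.parent = keep
        keep.children = list(keep.children) + [other]
        keep.length = None
        keep.parent = None
        return keep


# ---------------------------------------------------------------------------
# parameters and fits
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CodonModelParams:
    """Parameters of a branch codon model on a fixed tree."""

    kappa: float
    codon_freqs: np.ndarray
    omega_by_branch: dict[str, float]
    branch_lengths: dict[str, float]

    def __post_init__(self) -> None:
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.codon_freqs.shape != (N_STATES,):
            raise ValueError("codon_freqs must have 61 entries")
        if abs(self.codon_freqs.sum() - 1.0) > 1e-9:
            raise ValueError("codon_freqs must sum to 1")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        for label, w in self.omega_by_branch.items():
            if w < 0 or not math.isfinite(w):
                raise ValueError(f"omega for branch {label!r} must be finite >= 0")
        for label, t in self.branch_lengths.items():
            if t < 0 or not math.isfinite(t):
                raise ValueError(f"length of branch {label!r} must be finite >= 0")

    def copy(self) -> "CodonModelParams":
        return CodonModelParams(
            self.kappa,
            self.codon_freqs.copy(),
            dict(self.omega_by_branch),
            dict(self.branch_lengths),
        )


@dataclasses.dataclass
class BranchModelFit:
    """A fitted branch model: likelihood, parameters, bookkeeping."""

    lnL: float
    params: CodonModelParams
    model_tag: str  # "selection" or "null"
    target_branches: tuple[str, ...]
    init_omega_used: float
    converged: bool
    n_sweeps: int


@dataclasses.dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio test of omega = 1 on the pinned branches."""

    stat: float
    df: int
    p: float
    per_test_alpha: float


# ---------------------------------------------------------------------------
# alignment preparation
# ---------------------------------------------------------------------------


def _codon_state_mask(codon: str) -> np.ndarray:
    """Boolean compatibility of one observed codon with the 61 states.

    N and '-' are wildcards; a codon compatible with no sense codon
    (e.g. an unambiguous stop in the data) is treated as fully missing.
    """
    mask = np.ones(N_STATES, dtype=bool)
    for p, ch in enumerate(codon):
        if ch in "ACGT":
            mask &= np.array([c[p] == ch for c in SENSE_CODONS])
    if not mask.any():
        mask = np.ones(N_STATES, dtype=bool)
    return mask


def _prepare_alignment(
    tree: PhyloTree, alignment: Sequence[CodingSequence]
) -> tuple[list[np.ndarray], np.ndarray]:
    """Pattern-compressed leaf partials.

    Returns (leaf partial arrays in ``tree.leaves`` order, each
    (n_patterns, 61); pattern counts).  Raises on leaf/sequence label
    mismatch, listing the unmatched labels.
    """
    by_label = {s.id: s for s in alignment}
    if len(by_label) != len(alignment):
        raise ValueError("duplicate sequence ids in alignment")
    leaf_labels = tree.leaf_labels
    missing = sorted(set(leaf_labels) - set(by_label))
    extra = sorted(set(by_label) - set(leaf_labels))
    if missing or extra:
        raise ValueError(
            f"tree/alignment mismatch: missing sequences {missing}, "
            f"unmatched sequences {extra}"
        )
    codon_rows = [iter_codons(by_label[label]) for label in leaf_labels]
    n_cols = {len(r) for r in codon_rows}
    if len(n_cols) != 1:
        raise ValueError("aligned sequences differ in codon length")
    (n,) = n_cols
    if n < 1:
        raise ValueError("alignment has no codon columns")

    pattern_index: dict[tuple[str, ...], int] = {}
    counts: list[int] = []
    for col in zip(*codon_rows):
        k = pattern_index.setdefault(col, len(pattern_index))
        if k == len(counts):
            counts.append(0)
        counts[k] += 1
    patterns = list(pattern_index)
    mask_cache: dict[str, np.ndarray] = {}
    partials = []
    for row in range(len(leaf_labels)):
        mat = np.empty((len(patterns), N_STATES))
        for p, col in enumerate(patterns):
            codon = col[row]
            if codon not in mask_cache:
                mask_cache[codon] = _codon_state_mask(codon)
            mat[p] = mask_cache[codon]
        partials.append(mat)
    return partials, np.asarray(counts, dtype=float)


def empirical_codon_freqs(
    alignment: Iterable[CodingSequence], pseudocount: float = 0.5
) -> np.ndarray:
    """F61-style empirical codon frequencies from observed counts.

    A small pseudocount keeps unobserved codons at positive frequency
    so the reversible generator stays well-conditioned.
    """
    counts = np.full(N_STATES, float(pseudocount))
    for seq in alignment:
        for codon in iter_codons(seq):
            i = _CODON_INDEX.get(codon)
            if i is not None:
                counts[i] += 1.0
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------------


class _Engine:
    """Pruning likelihoods plus per-edge conditionals for one dataset."""

    def __init__(
        self, tree: PhyloTree, alignment: Sequence[CodingSequence], pi: np.ndarray
    ):
        self.tree = tree
        self.pi = np.asarray(pi, dtype=float)
        leaf_partials, self.counts = _prepare_alignment(tree, alignment)
        self.leaf_D = dict(zip([n.index for n in tree.leaves], leaf_partials))
        self.n_patterns = len(self.counts)
        self._spectral_cache: dict[tuple[float, float], _Spectral] = {}

    # -- model pieces -------------------------------------------------

    def spectral(self, kappa: float, omega: float) -> _Spectral:
        key = (kappa, omega)
        if key not in self._spectral_cache:
            if len(self._spectral_cache) > 512:
                self._spectral_cache.clear()
            self._spectral_cache[key] = _Spectral(
                build_rate_matrix(kappa, omega, self.pi), self.pi
            )
        return self._spectral_cache[key]

    def edge_P(self, kappa: float, node: _Node, params) -> np.ndarray:
        t, w = params.branch_lengths[node.label], params.omega_by_branch[node.label]
        return self.spectral(kappa, w).transition(t)

    # -- partials -----------------------------------------------------

    def _down(self, params: CodonModelParams):
        """Postorder conditionals D and per-pattern log scalers."""
        D: list[np.ndarray | None] = [None] * len(self.tree.postorder)
        logs = [None] * len(self.tree.postorder)
        for node in self.tree.postorder:
            if node.is_leaf:
                D[node.index] = self.leaf_D[node.index]
                logs[node.index] = np.zeros(self.n_patterns)
                continue
            mat = np.ones((self.n_patterns, N_STATES))
            lg = np.zeros(self.n_patterns)
            for child in node.children:
                P = self.edge_P(params.kappa, child, params)
                mat = mat * (D[child.index] @ P.T)
                lg = lg + logs[child.index]
            scale = mat.max(axis=1)
            scale[scale == 0] = 1.0
            D[node.index] = mat / scale[:, None]
            logs[node.index] = lg + np.log(scale)
        return D, logs

    def _up(self, params: CodonModelParams, D, logsD):
        """Preorder 'upper' conditionals U per non-root node.

        U[v][p, i] is the likelihood of all data outside v's subtree
        given state i at v's parent, root prior included.
        """
        U: list[np.ndarray | None] = [None] * len(self.tree.postorder)
        logsU = [None] * len(self.tree.postorder)
        G = {}
        for node in self.tree.branches:
            P = self.edge_P(params.kappa, node, params)
            G[node.index] = D[node.index] @ P.T

        def visit(u: _Node) -> None:
            for c in u.children:
                if u is self.tree.root:
                    mat = np.tile(self.pi, (self.n_patterns, 1))
                    lg = np.zeros(self.n_patterns)
                else:
                    Pu = self.edge_P(params.kappa, u, params)
                    mat = U[u.index] @ Pu
                    lg = logsU[u.index].copy()
                for w in u.children:
                    if w is c:
                        continue
                    mat = mat * G[w.index]
                    lg = lg + logsD[w.index]
                scale = mat.max(axis=1)
                scale[scale == 0] = 1.0
                U[c.index] = mat / scale[:, None]
                logsU[c.index] = lg + np.log(scale)
                if not c.is_leaf:
                    visit(c)

        visit(self.tree.root)
        return U, logsU

    # -- likelihoods --------------------------------------------------

    def lnl(self, params: CodonModelParams) -> float:
        D, logs = self._down(params)
        root = self.tree.root.index
        site_L = D[root] @ self.pi
        return float(self.counts @ (np.log(site_L) + logs[root]))

    def edge_lnl(
        self,
        Uv: np.ndarray,
        logsUv: np.ndarray,
        Dv: np.ndarray,
        logsDv: np.ndarray,
        P: np.ndarray,
    ) -> float:
        site_L = ((Uv @ P) * Dv).sum(axis=1)
        return float(self.counts @ (np.log(site_L) + logsUv + logsDv))


def log_likelihood(
    tree: PhyloTree | str | Path,
    alignment: Sequence[CodingSequence],
    params: CodonModelParams,
) -> float:
    """Log-likelihood of a codon alignment on a tree at given parameters."""
    if not isinstance(tree, PhyloTree):
        tree = PhyloTree.from_newick(tree)
    engine = _Engine(tree, alignment, params.codon_freqs)
    return engine.lnl(params)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _bounded_log_search(f, lo: float, hi: float, x0: float, xatol: float = 1e-3):
    """Minimize f over [lo, hi] in log space; returns (x, fmin)."""
    res = minimize_scalar(
        lambda y: f(math.exp(y)),
        bounds=(math.log(lo), math.log(hi)),
        method="bounded",
        options={"xatol": xatol},
    )
    x = math.exp(res.x)
    fx = res.fun
    f0 = f(x0)
    if f0 < fx:  # never move uphill from the incumbent
        return x0, f0
    return x, fx


def _optimize_edge(
    engine: _Engine,
    params: CodonModelParams,
    node: _Node,
    free_omega: bool,
    rounds: int = 2,
) -> None:
    """In-place coordinate update of one branch's (length, omega)."""
    D, logsD = engine._down(params)
    U, logsU = engine._up(params, D, logsD)
    Uv, lUv = U[node.index], logsU[node.index]
    Dv, lDv = D[node.index], logsD[node.index]
    label = node.label

    for _ in range(rounds if free_omega else 1):
        spec = engine.spectral(params.kappa, params.omega_by_branch[label])

        def neg_t(t: float) -> float:
            return -engine.edge_lnl(Uv, lUv, Dv, lDv, spec.transition(t))

        t, _fv = _bounded_log_search(
            neg_t, *_T_BOUNDS, params.branch_lengths[label]
        )
        params.branch_lengths[label] = t

        if free_omega:

            def neg_w(w: float) -> float:
                P = engine.spectral(params.kappa, w).transition(t)
                return -engine.edge_lnl(Uv, lUv, Dv, lDv, P)

            w, _fv = _bounded_log_search(
                neg_w, *_W_BOUNDS, params.omega_by_branch[label]
            )
            params.omega_by_branch[label] = w


def _single_fit(
    engine: _Engine,
    tree: PhyloTree,
    init: CodonModelParams,
    free_branches: set[str],
    tol: float,
    max_sweeps: int,
) -> tuple[CodonModelParams, float, bool, int]:
    params = init.copy()
    prev = engine.lnl(params)
    converged = False
    sweeps = 0
    for sweep in range(1, max_sweeps + 1):
        sweeps = sweep

        def neg_kappa(k: float) -> float:
            trial = params.copy()
            trial.kappa = k
            return -engine.lnl(trial)

        k, _ = _bounded_log_search(neg_kappa, *_K_BOUNDS, params.kappa)
        params.kappa = k

        for node in tree.branches:
            _optimize_edge(engine, params, node, node.label in free_branches)

        lnl = engine.lnl(params)
        if lnl - prev < tol and lnl >= prev - tol:
            converged = True
            prev = max(prev, lnl)
            break
        prev = lnl
    return params, prev, converged, sweeps


def fit(
    tree: PhyloTree | str | Path,
    alignment: Sequence[CodingSequence],
    model_tag: str = "selection",
    target_branches: Sequence[str] = (),
    init_omegas: Sequence[float] = (0.4, 1.0, 3.14, 15.0),
    kappa_init: float = 2.0,
    codon_freqs: np.ndarray | None = None,
    warm_start: CodonModelParams | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 50,
    seed: int | None = None,
) -> BranchModelFit:
    """Fit the selection (free-ratio) or null branch model by ML.

    Parameters
    ----------
    model_tag:
        ``"selection"`` frees omega on every branch; ``"null"`` pins
        omega = 1 on ``target_branches`` (required, nonempty) and frees
        the rest.
    init_omegas:
        Starting omega values; the optimization is repeated from each
        and the best likelihood kept (the landscape is multimodal
        enough that a single start can be misleading).
    warm_start:
        Optional full parameter set used as one additional start —
        e.g. the null fit's parameters when fitting the selection model.
    codon_freqs:
        Equilibrium codon frequencies; default: empirical from the
        alignment.
    seed:
        Accepted for interface symmetry and logged; the optimizer
        itself is deterministic.

    Returns the best :class:`BranchModelFit`; if no start converged the
    best point found is returned with ``converged=False``.
    """
    if not isinstance(tree, PhyloTree):
        tree = PhyloTree.from_newick(tree)
    if model_tag not in ("selection", "null"):
        raise ValueError("model_tag must be 'selection' or 'null'")
    target = tuple(target_branches)
    if model_tag == "null" and not target:
        raise ValueError("null model requires nonempty target_branches")
    unknown = set(target) - set(tree.branch_labels)
    if unknown:
        raise ValueError(f"unknown target branches: {sorted(unknown)}")
    if codon_freqs is None:
        codon_freqs = empirical_codon_freqs(alignment)
    engine = _Engine(tree, alignment, codon_freqs)

    pinned = set(target) if model_tag == "null" else set()
    free_branches = set(tree.branch_labels) - pinned

    def start_params(omega0: float) -> CodonModelParams:
        omegas = {
            lab: (1.0 if lab in pinned else float(omega0))
            for lab in tree.branch_labels
        }
        lengths = {
            n.label: (n.length if n.length and n.length > 0 else 0.05)
            for n in tree.branches
        }
        return CodonModelParams(kappa_init, codon_freqs, omegas, lengths)

    starts: list[tuple[float, CodonModelParams]] = [
        (w0, start_params(w0)) for w0 in init_omegas
    ]
    if warm_start is not None:
        ws = warm_start.copy()
        ws.codon_freqs = np.asarray(codon_freqs, dtype=float)
        for lab in pinned:
            ws.omega_by_branch[lab] = 1.0
        starts.append((float("nan"), ws))

    best: BranchModelFit | None = None
    for w0, init in starts:
        params, lnl, converged, sweeps = _single_fit(
            engine, tree, init, free_branches, tol, max_sweeps
        )
        cand = BranchModelFit(
            lnL=lnl,
            params=params,
            model_tag=model_tag,
            target_branches=target,
            init_omega_used=w0,
            converged=converged,
            n_sweeps=sweeps,
        )
        if best is None or cand.lnL > best.lnL:
            best = cand
    assert best is not None
    if not best.converged:
        warnings.warn(
            "branch-model fit did not converge from any start; "
            "best point returned",
            stacklevel=2,
        )
    return best


def branch_dn_ds(params: CodonModelParams, label: str) -> tuple[float, float]:
    """Per-branch (dN, dS) implied by a fitted branch length and omega.

    The branch length t (substitutions per codon) is split into its
    synonymous and nonsynonymous parts by the model's equilibrium
    substitution fractions, then divided by the mutational-opportunity
    site counts S and 3 - S.
    """
    t = params.branch_lengths[label]
    w = params.omega_by_branch[label]
    fs = synonymous_fraction(params.kappa, w, params.codon_freqs)
    S = synonymous_sites_per_codon(params.kappa, params.codon_freqs)
    dS = t * fs / S
    dN = t * (1.0 - fs) / (3.0 - S)
    return dN, dS


def lrt(
    fit_selection: BranchModelFit,
    fit_null: BranchModelFit,
    n_tests: int = 1,
    family_alpha: float = 0.05,
    tolerance: float = 0.5,
) -> LrtResult:
    """LRT of the null (omega = 1 on the pinned branches) vs free-ratio.

    ``stat = 2 (lnL_selection - lnL_null)`` referred to chi-square with
    df = number of pinned omegas.  Small negative statistics (within
    ``tolerance``, optimizer noise) are clamped to zero; larger ones
    raise, signalling optimizer failure.
    """
    if fit_selection.model_tag != "selection" or fit_null.model_tag != "null":
        raise ValueError("pass (selection fit, null fit) in that order")
    df = len(fit_null.target_branches)
    stat = 2.0 * (fit_selection.lnL - fit_null.lnL)
    if stat < -tolerance:
        raise ValueError(
            f"selection lnL below null lnL by {-stat / 2:.4f}: optimizer failure"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    from .pbl_dnds import bonferroni_alpha

    return LrtResult(stat, df, p, bonferroni_alpha(n_tests, family_alpha))
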