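"""Pairwise dN/dS by the Pamilo-Bianchi-Li (PBL) counting method.

Sites are classified by codon-position degeneracy (nondegenerate,
twofold, fourfold: the number of synonymous outcomes among the three
possible single-base changes — all three / none / otherwise), site
counts are averaged over the two sequences, transition and transversion
difference proportions are corrected per class with the Kimura
two-parameter formulas, and

    dS = (L2*A2 + L4*A4) / (L2 + L4) + B4
    dN = A0 + (L0*B0 + L2*B2) / (L0 + L2)

Codons differing at 2-3 positions are resolved by unweighted averaging
over all minimal mutational pathways that avoid stop-codon
intermediates.  Columns containing a gap, an ambiguous base or a stop
codon in either sequence are excluded (pairwise deletion).  Undefined
logarithms (saturated classes) propagate as NA rather than infinities,
mirroring how comparisons with zero synonymous sites are reported.

Standard errors come from a codon-column bootstrap; dN = dS is tested
with a normal Z statistic, with a Bonferroni-corrected per-test alpha
for families of comparisons.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .seq_core import (
    CODON_TABLE,
    SENSE_CODONS,
    STOP_CODONS,
    BASES,
    PairwiseCodonAlignment,
)

__all__ = [
    "DegeneracySiteCounts",
    "ClasswiseChanges",
    "DndsEstimate",
    "WindowScan",
    "classify_degeneracy",
    "count_class_changes",
    "k2p_components",
    "pbl_estimate",
    "bootstrap_se",
    "estimate_with_tests",
    "z_test",
    "bonferroni_alpha",
    "sliding_window",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

_CLASS_INDEX = {0: 0, 2: 1, 4: 2}


def _is_transition(b1: str, b2: str) -> bool:
    return (b1, b2) in _TRANSITIONS


def classify_degeneracy(codon: str, position: int) -> int:
    """Degeneracy class (0, 2 or 4) of one codon position.

    ``position`` is 1-based (1..3).  The class is 4 when all three
    single-base changes at the position are synonymous, 0 when none
    are, and 2 otherwise; changes to stop codons count as
    nonsynonymous.
    """
    if position not in (1, 2, 3):
        raise ValueError("position must be 1, 2 or 3")
    if codon in STOP_CODONS or codon not in CODON_TABLE:
        raise ValueError(f"{codon!r} is not a sense codon")
    aa = CODON_TABLE[codon]
    p = position - 1
    n_syn = 0
    for base in BASES:
        if base == codon[p]:
            continue
        mutant = codon[:p] + base + codon[p + 1 :]
        if CODON_TABLE[mutant] == aa:
            n_syn += 1
    if n_syn == 3:
        return 4
    if n_syn == 0:
        return 0
    return 2


def _build_tables() -> tuple[dict[str, int], np.ndarray, np.ndarray]:
    """Precompute per-codon site counts and per-pair change vectors.

    Returns ``(codon_index, site_counts, pair_changes)`` where
    ``site_counts[i]`` is the (n0, n2, n4) site-class tally of sense
    codon i and ``pair_changes[i, j]`` is the 6-vector
    (ts0, ts2, ts4, tv0, tv2, tv4) of pathway-averaged transition and
    transversion differences between codons i and j, each difference
    split half-and-half between the degeneracy classes of its two
    flanking codons.
    """
    index = {c: i for i, c in enumerate(SENSE_CODONS)}
    degen = {
        (c, p): classify_degeneracy(c, p + 1)
        for c in SENSE_CODONS
        for p in range(3)
    }
    site_counts = np.zeros((61, 3))
    for c, i in index.items():
        for p in range(3):
            site_counts[i, _CLASS_INDEX[degen[(c, p)]]] += 1.0

    def step_vector(x: str, y: str, p: int) -> np.ndarray:
        """Contribution of the single-base change x->y at position p."""
        v = np.zeros(6)
        block = 0 if _is_transition(x[p], y[p]) else 3
        # split the change between the classes of the two codons; a
        # stop codon (possible only on fallback pathways) contributes
        # through its sense partner alone
        sides = [c for c in (x, y) if c not in STOP_CODONS]
        w = 1.0 / len(sides) if sides else 0.0
        for c in sides:
            v[block + _CLASS_INDEX[degen[(c, p)]]] += w
        return v

    pair = np.zeros((61, 61, 6))
    for a, i in index.items():
        for b, j in index.items():
            if j <= i:
                continue
            diff = [p for p in range(3) if a[p] != b[p]]
            if not diff:
                continue
            paths = []
            for order in itertools.permutations(diff):
                cur = a
                steps = []
                blocked = False
                for p in order:
                    nxt = cur[:p] + b[p] + cur[p + 1 :]
                    steps.append((cur, nxt, p))
                    if nxt != b and nxt in STOP_CODONS:
                        blocked = True
                    cur = nxt
                paths.append((blocked, steps))
            usable = [s for blocked, s in paths if not blocked]
            if not usable:  # all minimal pathways cross a stop
                usable = [s for _, s in paths]
            v = np.zeros(6)
            for steps in usable:
                for x, y, p in steps:
                    v += step_vector(x, y, p)
            v /= len(usable)
            pair[i, j] = v
            pair[j, i] = v
    return index, site_counts, pair


_CODON_INDEX, _SITE_COUNTS, _PAIR_CHANGES = _build_tables()


@dataclasses.dataclass(frozen=True)
class DegeneracySiteCounts:
    """Fractional site counts per degeneracy class, averaged over the pair."""

    L0: float
    L2: float
    L4: float

    @property
    def total(self) -> float:
        return self.L0 + self.L2 + self.L4


@dataclasses.dataclass(frozen=True)
class ClasswiseChanges:
    """Transition (P) and transversion (Q) difference proportions per class."""

    P0: float
    P2: float
    P4: float
    Q0: float
    Q2: float
    Q4: float


@dataclasses.dataclass(frozen=True)
class DndsEstimate:
    """One pairwise (or windowed) dN/dS comparison.

    ``None`` marks a not-applicable value: dS is NA when the comparison
    has no synonymous sites or a saturated correction, and NA
    propagates to the ratio and the p-value.
    """

    dN: Optional[float]
    dS: Optional[float]
    n_codons: int
    se_dN: Optional[float] = None
    se_dS: Optional[float] = None
    z: Optional[float] = None
    p: Optional[float] = None
    syn_changes: float = 0.0
    na_reason: Optional[str] = None

    @property
    def ratio(self) -> Optional[float]:
        if self.dN is None or self.dS is None or self.dS == 0:
            return None
        return self.dN / self.dS


def _column_stats(aln: PairwiseCodonAlignment) -> np.ndarray:
    """Per included codon column: (l0, l2, l4, ts0, ts2, ts4, tv0, tv2, tv4).

    Site counts are the average of the two sequences' counts.
    """
    cols = aln.included_columns()
    if not cols:
        raise ValueError("empty comparison: no included codon columns")
    out = np.empty((len(cols), 9))
    for k, (a, b) in enumerate(cols):
        i, j = _CODON_INDEX[a], _CODON_INDEX[b]
        out[k, :3] = 0.5 * (_SITE_COUNTS[i] + _SITE_COUNTS[j])
        out[k, 3:] = _PAIR_CHANGES[i, j]
    return out


def count_class_changes(
    aln: PairwiseCodonAlignment,
) -> tuple[DegeneracySiteCounts, ClasswiseChanges]:
    """Site counts and classwise difference proportions for one pair."""
    sums = _column_stats(aln).sum(axis=0)
    L = sums[:3]
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(L > 0, sums[3:6] / L, 0.0)
        Q = np.where(L > 0, sums[6:9] / L, 0.0)
    return (
        DegeneracySiteCounts(*L),
        ClasswiseChanges(P0=P[0], P2=P[1], P4=P[2], Q0=Q[0], Q2=Q[1], Q4=Q[2]),
    )


def k2p_components(P: float, Q: float) -> tuple[Optional[float], Optional[float]]:
    """Kimura two-parameter components (A, B) for one site class.

    ``A`` is the corrected transition distance, ``B`` the corrected
    transversion distance.  Returns ``(None, None)`` when the
    correction is undefined (log arguments at or below zero), the NA
    convention used throughout.
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w2 <= 0.0:
        return None, None
    B = 0.5 * math.log(1.0 / w2)
    if w1 <= 0.0:
        return None, B
    A = 0.5 * math.log(1.0 / w1) - 0.25 * math.log(1.0 / w2)
    return A, B


def _estimate_from_sums(sums: np.ndarray) -> tuple[Optional[float], Optional[float], Optional[str]]:
    """(dN, dS, na_reason) from summed column stats (9-vector)."""
    L0, L2, L4 = sums[:3]
    ts = sums[3:6]
    tv = sums[6:9]
    A = [0.0, 0.0, 0.0]
    B = [0.0, 0.0, 0.0]
    bad = [False, False, False]
    for c, Lc in enumerate((L0, L2, L4)):
        if Lc <= 0:
            continue
        a, b = k2p_components(ts[c] / Lc, tv[c] / Lc)
        if a is None or b is None:
            bad[c] = True
        else:
            A[c], B[c] = a, b
    na_reason = None
    if L2 + L4 <= 0:
        dS = None
        na_reason = "number of synonymous sites was 0"
    elif bad[1] or bad[2]:
        dS = None
        na_reason = "synonymous correction undefined (saturation)"
    else:
        dS = (L2 * A[1] + L4 * A[2]) / (L2 + L4) + B[2]
    if L0 + L2 <= 0 or bad[0] or bad[1]:
        dN = None
        na_reason = na_reason or "nonsynonymous correction undefined"
    else:
        dN = A[0] + (L0 * B[0] + L2 * B[1]) / (L0 + L2)
    return dN, dS, na_reason


def pbl_estimate(aln: PairwiseCodonAlignment) -> DndsEstimate:
    """PBL dN and dS for one pairwise codon alignment (no SEs)."""
    stats_mat = _column_stats(aln)
    sums = stats_mat.sum(axis=0)
    dN, dS, na_reason = _estimate_from_sums(sums)
    # synonymous differences: transitions at 2- and 4-fold sites plus
    # transversions at 4-fold sites
    syn_changes = float(sums[4] + sums[5] + sums[8])
    return DndsEstimate(
        dN=dN,
        dS=dS,
        n_codons=stats_mat.shape[0],
        syn_changes=syn_changes,
        na_reason=na_reason,
    )


@dataclasses.dataclass(frozen=True)
class BootstrapResult:
    se_dN: Optional[float]
    se_dS: Optional[float]
    n_na_dN: int
    n_na_dS: int


def _vectorized_estimates(sums: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(dN, dS) arrays (NaN = NA) for an array of summed stats (B, 9)."""
    L0, L2, L4 = sums[:, 0], sums[:, 1], sums[:, 2]
    dN = np.full(len(sums), np.nan)
    dS = np.full(len(sums), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.zeros((len(sums), 3))
        B = np.zeros((len(sums), 3))
        ok = np.ones((len(sums), 3), dtype=bool)
        for c in range(3):
            Lc = sums[:, c]
            P = np.where(Lc > 0, sums[:, 3 + c] / np.where(Lc > 0, Lc, 1), 0.0)
            Q = np.where(Lc > 0, sums[:, 6 + c] / np.where(Lc > 0, Lc, 1), 0.0)
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            valid = (w1 > 0) & (w2 > 0)
            Ac = np.where(valid, 0.5 * np.log(1 / np.where(valid, w1, 1)), 0.0)
            Ac -= np.where(valid, 0.25 * np.log(1 / np.where(valid, w2, 1)), 0.0)
            Bc = np.where(valid, 0.5 * np.log(1 / np.where(valid, w2, 1)), 0.0)
            has_sites = Lc > 0
            A[:, c] = np.where(has_sites, Ac, 0.0)
            B[:, c] = np.where(has_sites, Bc, 0.0)
            ok[:, c] = valid | ~has_sites
        syn_sites = L2 + L4
        s_ok = (syn_sites > 0) & ok[:, 1] & ok[:, 2]
        dS[s_ok] = (
            (L2 * A[:, 1] + L4 * A[:, 2])[s_ok] / syn_sites[s_ok] + B[s_ok, 2]
        )
        nonsyn_sites = L0 + L2
        n_ok = (nonsyn_sites > 0) & ok[:, 0] & ok[:, 1]
        dN[n_ok] = (
            A[n_ok, 0]
            + (L0 * B[:, 0] + L2 * B[:, 1])[n_ok] / nonsyn_sites[n_ok]
        )
    return dN, dS


def bootstrap_se(
    aln: PairwiseCodonAlignment,
    n_resamples: int = 1000,
    seed: int | None = None,
) -> BootstrapResult:
    """Bootstrap SEs of dN and dS by resampling codon columns.

    Included codon columns are resampled with replacement
    ``n_resamples`` times; the SE is the standard deviation of the
    resampled estimates.  Resamples with an NA estimate are dropped per
    component and their counts reported.
    """
    stats_mat = _column_stats(aln)
    n_cols = stats_mat.shape[0]
    if n_cols < 2:
        raise ValueError("bootstrap requires at least 2 included codon columns")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_cols, size=(n_resamples, n_cols))
    sums = stats_mat[idx].sum(axis=1)
    dN, dS = _vectorized_estimates(sums)

    def se_of(values: np.ndarray) -> tuple[Optional[float], int]:
        good = values[~np.isnan(values)]
        n_na = len(values) - len(good)
        if len(good) < 2:
            return None, n_na
        return float(np.std(good, ddof=1)), n_na

    se_dN, na_n = se_of(dN)
    se_dS, na_s = se_of(dS)
    return BootstrapResult(se_dN, se_dS, na_n, na_s)


def z_test(est: DndsEstimate) -> tuple[Optional[float], Optional[float]]:
    """Z statistic and two-tailed p-value for the null dN = dS.

    z = (dN - dS) / sqrt(se_dN^2 + se_dS^2).  When both SEs are zero
    the test degenerates: identical rates give (0, 1), anything else is
    NA.  NA inputs give (None, None).
    """
    if est.dN is None or est.dS is None:
        return None, None
    if est.se_dN is None or est.se_dS is None:
        return None, None
    denom = math.hypot(est.se_dN, est.se_dS)
    if denom == 0.0:
        if est.dN == est.dS:
            return 0.0, 1.0
        return None, None
    z = (est.dN - est.dS) / denom
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def estimate_with_tests(
    aln: PairwiseCodonAlignment,
    n_resamples: int = 1000,
    seed: int | None = None,
) -> DndsEstimate:
    """Full pairwise comparison: estimate, bootstrap SEs, Z-test."""
    est = pbl_estimate(aln)
    boot = bootstrap_se(aln, n_resamples=n_resamples, seed=seed)
    est = dataclasses.replace(est, se_dN=boot.se_dN, se_dS=boot.se_dS)
    z, p = z_test(est)
    return dataclasses.replace(est, z=z, p=p)


def bonferroni_alpha(n_tests: int, family_alpha: float = 0.05) -> float:
    """Per-test significance threshold under Bonferroni correction."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


@dataclasses.dataclass(frozen=True)
class WindowScan:
    """Sliding-window dN/dS estimates along a pairwise alignment.

    ``estimates[k]`` covers codon columns
    ``[starts[k], starts[k] + window)``.  Windows in which no
    synonymous difference was observed are flagged (``ratio`` NA): they
    are the 'disconnected' stretches of a windowed selection plot.
    """

    window: int
    step: int
    starts: list[int]
    estimates: list[DndsEstimate]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, e in zip(self.starts, self.estimates):
            rows.append(
                {
                    "start": s,
                    "n_codons": e.n_codons,
                    "dN": e.dN,
                    "dS": e.dS,
                    "ratio": e.ratio,
                    "z": e.z,
                    "p": e.p,
                    "no_synonymous": e.syn_changes == 0,
                }
            )
        return pd.DataFrame(rows)


def sliding_window(
    aln: PairwiseCodonAlignment,
    window: int = 30,
    step: int = 1,
    n_resamples: int = 1000,
    seed: int | None = None,
) -> WindowScan:
    """Windowed PBL scan (default 30-codon windows, 1-codon step).

    Each window gets a full estimate with bootstrap SEs and Z-test.
    Returns an empty scan (with a warning) when the alignment is
    shorter than one window.
    """
    n = aln.n_columns
    if n < window:
        warnings.warn(
            f"alignment of {n} codons is shorter than the {window}-codon window",
            stacklevel=2,
        )
        return WindowScan(window, step, [], [])
    rng = np.random.default_rng(seed)
    starts = list(range(0, n - window + 1, step))
    estimates = []
    for s in starts:
        sub = aln.slice_codons(s, s + window)
        try:
            est = estimate_with_tests(
                sub,
                n_resamples=n_resamples,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        except ValueError:  # window fully excluded by pairwise deletion
            est = DndsEstimate(
                dN=None, dS=None, n_codons=0, na_reason="no included columns"
            )
        estimates.append(est)
    return WindowScan(window, step, starts, estimates)
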