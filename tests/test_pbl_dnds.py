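import math
import subprocess

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from eblnkit import pbl_dnds as pbl
from eblnkit import synthetic_data as sd
from eblnkit.seq_core import (
    SENSE_CODONS,
    CodingSequence,
    PairwiseCodonAlignment,
    write_fasta,
)


def _degeneracy_oracle(codon: str, position: int) -> int:
    """Brute force via Biopython translation (independent of the package's
    genetic-code tables)."""
    aa = str(Seq(codon).translate())
    p = position - 1
    n_syn = sum(
        str(Seq(codon[:p] + b + codon[p + 1 :]).translate()) == aa
        for b in "ACGT"
        if b != codon[p]
    )
    return {3: 4, 0: 0}.get(n_syn, 2)


class TestDegeneracy:
    @pytest.mark.parametrize(
        "codon,pos,expected",
        [("GGG", 3, 4), ("ATG", 1, 0), ("ATT", 3, 2), ("ATA", 3, 2)],
    )
    def test_examples(self, codon, pos, expected):
        assert pbl.classify_degeneracy(codon, pos) == expected

    def test_agrees_with_enumeration_for_all_sense_codons(self):
        for codon in SENSE_CODONS:
            for pos in (1, 2, 3):
                assert pbl.classify_degeneracy(codon, pos) == _degeneracy_oracle(
                    codon, pos
                ), (codon, pos)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            pbl.classify_degeneracy("TAA", 1)


class TestCountClassChanges:
    def test_identical_sequences_have_zero_changes(self, stop_free_300):
        aln = PairwiseCodonAlignment(stop_free_300, stop_free_300)
        sites, changes = pbl.count_class_changes(aln)
        assert all(
            getattr(changes, f) == 0 for f in ("P0", "P2", "P4", "Q0", "Q2", "Q4")
        )
        assert sites.total == pytest.approx(3 * 300)

    def test_single_fourfold_transition(self):
        aln = PairwiseCodonAlignment(
            CodingSequence("a", "GGA"), CodingSequence("b", "GGG")
        )
        sites, changes = pbl.count_class_changes(aln)
        # glycine box: positions 1-2 nondegenerate, position 3 fourfold
        assert (sites.L0, sites.L2, sites.L4) == (2.0, 0.0, 1.0)
        assert changes.P4 == pytest.approx(1.0)
        assert changes.Q4 == 0 and changes.P0 == 0

    def test_two_difference_codon_pathway_average(self):
        # TTT -> GAT: both stop-free pathways (via GTT and via TAT)
        # consist of transversions at nondegenerate positions
        aln = PairwiseCodonAlignment(
            CodingSequence("a", "TTT"), CodingSequence("b", "GAT")
        )
        sites, changes = pbl.count_class_changes(aln)
        assert (sites.L0, sites.L2, sites.L4) == (2.0, 1.0, 0.0)
        assert changes.Q0 == pytest.approx(1.0)  # 2 transversions / 2 sites
        assert changes.P0 == changes.P2 == changes.Q2 == 0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, derandomize=True)
    def test_site_count_conservation(self, seed):
        anc = sd.random_stop_free_sequence(40, seed=seed)
        res = sd.simulate_pair(
            anc, sd.PairSimSpec(40, omega=1.0, t_syn=0.4, seed=seed + 1)
        )
        sites, _ = pbl.count_class_changes(res.alignment)
        n_included = len(res.alignment.included_columns())
        assert sites.total == pytest.approx(3 * n_included)

    def test_empty_comparison_raises(self):
        aln = PairwiseCodonAlignment(
            CodingSequence("a", "NNN"), CodingSequence("b", "AAA")
        )
        with pytest.raises(ValueError, match="empty comparison"):
            pbl.count_class_changes(aln)


class TestK2P:
    def test_zero_distance(self):
        assert pbl.k2p_components(0.0, 0.0) == (0.0, 0.0)

    def test_closed_form_transitions_only(self):
        A, B = pbl.k2p_components(0.1, 0.0)
        assert A == pytest.approx(0.5 * math.log(1 / 0.8), abs=1e-12)
        assert B == 0.0

    def test_boundary_returns_na(self):
        A, _ = pbl.k2p_components(0.4, 0.2)  # 1 - 2P - Q = 0
        assert A is None
        A, B = pbl.k2p_components(0.2, 0.5)  # 1 - 2Q = 0
        assert A is None and B is None


class TestPblEstimate:
    def test_identical_sequences(self, stop_free_300):
        est = pbl.pbl_estimate(
            PairwiseCodonAlignment(stop_free_300, stop_free_300)
        )
        assert est.dN == 0 and est.dS == 0 and est.ratio is None

    def test_fourfold_synonymous_transitions_only(self):
        # 100 glycine codons; 10 columns differ GGA/GGG (third-position
        # transitions).  Hand computation: P4 = 0.1 so
        # dS = A4 = 0.5 ln(1/0.8), dN = 0.
        a = CodingSequence("a", "GGA" * 100)
        b = CodingSequence("b", "GGG" * 10 + "GGA" * 90)
        est = pbl.pbl_estimate(PairwiseCodonAlignment(a, b))
        assert est.dN == 0.0
        assert est.dS == pytest.approx(0.5 * math.log(1 / 0.8), rel=1e-12)

    def test_no_synonymous_sites_gives_na_ds(self):
        # tryptophan/methionine columns have no synonymous sites at all
        a = CodingSequence("a", "TGG" * 30)
        b = CodingSequence("b", "ATG" * 30)
        est = pbl.pbl_estimate(PairwiseCodonAlignment(a, b))
        assert est.dS is None and est.ratio is None
        assert "synonymous sites" in est.na_reason

    def test_matches_independent_li93_implementation(self, tmp_path):
        """Cross-check against seqinr's Li (1993) Ka/Ks on a simulated
        pair; the two counting variants agree to within method variance."""
        anc = sd.random_stop_free_sequence(400, seed=77, id="anc")
        res = sd.simulate_pair(
            anc, sd.PairSimSpec(400, omega=0.5, t_syn=0.3, kappa=3.0, seed=78)
        )
        est = pbl.pbl_estimate(res.alignment)
        fasta = tmp_path / "pair.fa"
        write_fasta([res.alignment.seq_a, res.alignment.seq_b], fasta)
        script = (
            'library(seqinr);'
            f'a <- read.alignment("{fasta}", format="fasta");'
            "k <- kaks(a);"
            'cat(as.numeric(k$ka), as.numeric(k$ks), "\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ka, ks = map(float, out.stdout.split())
        assert est.dN == pytest.approx(ka, rel=0.10)
        assert est.dS == pytest.approx(ks, rel=0.10)

    @pytest.mark.parametrize("omega,expect_below_one", [(1.0, None), (0.25, True)])
    def test_omega_recovery_direction(self, omega, expect_below_one):
        ratios = []
        for rep in range(20):
            anc = sd.random_stop_free_sequence(500, seed=900 + rep)
            res = sd.simulate_pair(
                anc,
                sd.PairSimSpec(500, omega=omega, t_syn=0.3, seed=950 + rep),
            )
            est = pbl.pbl_estimate(res.alignment)
            ratios.append(est.ratio)
        if expect_below_one:
            # sign test: under strong purifying selection essentially
            # every replicate estimates dN/dS < 1
            assert sum(r < 1 for r in ratios) >= 18
        else:
            assert 0.85 < float(np.mean(ratios)) < 1.15


class TestBootstrapAndZ:
    def test_identical_sequences_zero_se(self, stop_free_300):
        res = pbl.bootstrap_se(
            PairwiseCodonAlignment(stop_free_300, stop_free_300), 100, seed=1
        )
        assert res.se_dN == 0.0 and res.se_dS == 0.0

    def test_seeded_determinism(self, stop_free_300):
        res = sd.simulate_pair(
            stop_free_300, sd.PairSimSpec(300, omega=1.0, t_syn=0.2, seed=5)
        )
        b1 = pbl.bootstrap_se(res.alignment, 300, seed=17)
        b2 = pbl.bootstrap_se(res.alignment, 300, seed=17)
        assert b1 == b2

    def test_se_tracks_replicate_sd(self):
        """Bootstrap SE within 30% of the empirical SD over 200
        independently simulated replicates."""
        dns, dss = [], []
        for rep in range(200):
            anc = sd.random_stop_free_sequence(300, seed=5000 + rep)
            res = sd.simulate_pair(
                anc, sd.PairSimSpec(300, omega=0.5, t_syn=0.2, seed=6000 + rep)
            )
            est = pbl.pbl_estimate(res.alignment)
            dns.append(est.dN)
            dss.append(est.dS)
        emp_dn = np.std(dns, ddof=1)
        emp_ds = np.std(dss, ddof=1)
        anc = sd.random_stop_free_sequence(300, seed=5000)
        res = sd.simulate_pair(
            anc, sd.PairSimSpec(300, omega=0.5, t_syn=0.2, seed=6000)
        )
        boot = pbl.bootstrap_se(res.alignment, 500, seed=1)
        assert boot.se_dN == pytest.approx(emp_dn, rel=0.30)
        assert boot.se_dS == pytest.approx(emp_ds, rel=0.30)

    def test_z_statistic(self):
        est = pbl.DndsEstimate(
            dN=0.05, dS=0.05, n_codons=100, se_dN=0.0, se_dS=0.0
        )
        assert pbl.z_test(est) == (0.0, 1.0)
        est = pbl.DndsEstimate(
            dN=0.0196, dS=0.0, n_codons=100, se_dN=0.008, se_dS=0.006
        )
        z, p = pbl.z_test(est)
        assert z == pytest.approx(1.96)
        assert p == pytest.approx(0.05, abs=0.0005)

    def test_na_propagates_to_test(self):
        est = pbl.DndsEstimate(dN=0.1, dS=None, n_codons=10)
        assert pbl.z_test(est) == (None, None)


class TestBonferroni:
    @pytest.mark.parametrize(
        "n,expected", [(108, 0.05 / 108), (1, 0.05), (10, 0.005)]
    )
    def test_thresholds(self, n, expected):
        assert pbl.bonferroni_alpha(n) == pytest.approx(expected)

    def test_108_tests_round_to_published_threshold(self):
        assert round(pbl.bonferroni_alpha(108), 5) == 0.00046


class TestSlidingWindow:
    def test_window_counts(self):
        anc = sd.random_stop_free_sequence(100, seed=2)
        res = sd.simulate_pair(anc, sd.PairSimSpec(100, 1.0, 0.3, seed=3))
        scan = pbl.sliding_window(res.alignment, 30, 1, n_resamples=20, seed=0)
        assert len(scan.starts) == 100 - 30 + 1
        single = sd.random_stop_free_sequence(30, seed=4)
        aln = PairwiseCodonAlignment(single, single)
        assert len(pbl.sliding_window(aln, 30, 1, n_resamples=20).starts) == 1

    def test_short_alignment_warns_and_returns_empty(self):
        seq = sd.random_stop_free_sequence(10, seed=5)
        aln = PairwiseCodonAlignment(seq, seq)
        with pytest.warns(UserWarning, match="shorter"):
            scan = pbl.sliding_window(aln, 30)
        assert scan.estimates == []

    def test_windows_without_synonymous_changes_flagged(self):
        # synonymous fourfold differences confined to codons 45-55
        codons_a = ["GGA"] * 100
        codons_b = ["GGA"] * 100
        for i in range(45, 56):
            codons_b[i] = "GGG"
        aln = PairwiseCodonAlignment(
            CodingSequence("a", "".join(codons_a)),
            CodingSequence("b", "".join(codons_b)),
        )
        scan = pbl.sliding_window(aln, 30, 1, n_resamples=20, seed=1)
        for s, est in zip(scan.starts, scan.estimates):
            overlaps = s + 30 > 45 and s < 56
            assert (est.syn_changes > 0) == overlaps
            if not overlaps:
                assert est.ratio is None

    def test_full_length_window_equals_whole_estimate(self, stop_free_300):
        res = sd.simulate_pair(
            stop_free_300, sd.PairSimSpec(300, 0.8, 0.25, seed=9)
        )
        whole = pbl.pbl_estimate(res.alignment)
        scan = pbl.sliding_window(
            res.alignment, window=300, step=1, n_resamples=10, seed=2
        )
        assert len(scan.estimates) == 1
        assert scan.estimates[0].dN == pytest.approx(whole.dN, abs=1e-12)
        assert scan.estimates[0].dS == pytest.approx(whole.dS, abs=1e-12)
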