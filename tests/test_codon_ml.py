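import math

import numpy as np
import pytest

from eblnkit import codon_ml as cm
from eblnkit import synthetic_data as sd
from eblnkit.seq_core import SENSE_CODONS, CodingSequence

IDX = {c: i for i, c in enumerate(SENSE_CODONS)}


@pytest.fixture(scope="module")
def dirichlet_freqs():
    return np.random.default_rng(1).dirichlet(np.ones(61) * 5)


class TestRateMatrix:
    def test_rows_sum_to_zero_and_unit_mean_rate(self, dirichlet_freqs):
        Q = cm.build_rate_matrix(3.0, 0.4, dirichlet_freqs)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        assert -dirichlet_freqs @ np.diag(Q) == pytest.approx(1.0)

    def test_uniform_neutral_rates_all_equal(self):
        pi = np.full(61, 1 / 61)
        Q = cm.build_rate_matrix(1.0, 1.0, pi, scale=False)
        off = Q[Q > 0]
        assert np.allclose(off, off[0])

    def test_detailed_balance_and_stationarity(self, dirichlet_freqs):
        Q = cm.build_rate_matrix(2.0, 0.7, dirichlet_freqs)
        flux = dirichlet_freqs[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-15
        assert np.abs(dirichlet_freqs @ Q).max() < 1e-15

    def test_transition_matrix_is_stochastic(self, dirichlet_freqs):
        P = cm.codon_transition_matrix(2.0, 0.5, dirichlet_freqs, 0.3)
        assert np.all(P >= 0)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_zero_frequency_target_gets_zero_rate(self):
        pi = np.full(61, 1 / 60)
        pi[IDX["ATG"]] = 0.0
        Q = cm.build_rate_matrix(2.0, 1.0, pi)
        assert np.all(Q[:, IDX["ATG"]][np.arange(61) != IDX["ATG"]] == 0)


class TestLogLikelihood:
    def test_single_sequence_zero_branch_is_log_freqs(self, dirichlet_freqs):
        seq = CodingSequence("A", "ATGGGA")
        tree = cm.PhyloTree.from_newick("(A:0.0);")
        params = cm.CodonModelParams(2.0, dirichlet_freqs, {"A": 1.0}, {"A": 0.0})
        expected = math.log(dirichlet_freqs[IDX["ATG"]]) + math.log(
            dirichlet_freqs[IDX["GGA"]]
        )
        assert cm.log_likelihood(tree, [seq], params) == pytest.approx(expected)

    def test_two_taxon_exhaustive_oracle(self, dirichlet_freqs):
        kappa, omega, t1, t2 = 3.0, 0.4, 0.3, 0.5
        A = CodingSequence("A", "ATGGGA")
        B = CodingSequence("B", "ACGGGG")
        tree = cm.PhyloTree.from_newick("(A:0.3,B:0.5);")
        params = cm.CodonModelParams(
            kappa, dirichlet_freqs, {"A": omega, "B": omega}, {"A": t1, "B": t2}
        )
        lnl = cm.log_likelihood(tree, [A, B], params)
        # brute force over all 61 root-state assignments per column
        P1 = cm.codon_transition_matrix(kappa, omega, dirichlet_freqs, t1)
        P2 = cm.codon_transition_matrix(kappa, omega, dirichlet_freqs, t2)
        brute = 0.0
        for ca, cb in [("ATG", "ACG"), ("GGA", "GGG")]:
            brute += math.log(
                sum(
                    dirichlet_freqs[k] * P1[k, IDX[ca]] * P2[k, IDX[cb]]
                    for k in range(61)
                )
            )
        assert lnl == pytest.approx(brute, abs=1e-10)

    def test_tiny_branch_taylor_limit(self, dirichlet_freqs):
        seq = CodingSequence("A", "ATG")
        other = CodingSequence("B", "ATG")
        tree = cm.PhyloTree.from_newick("(A:0.0,B:0.0);")
        base = math.log(dirichlet_freqs[IDX["ATG"]])
        for t in (1e-6, 1e-4):
            params = cm.CodonModelParams(
                2.0, dirichlet_freqs, {"A": 1.0, "B": 1.0}, {"A": 0.0, "B": t}
            )
            lnl = cm.log_likelihood(tree, [seq, other], params)
            # first order: lnL = log pi + q_ii t + O(t^2)
            assert abs(lnl - base) < 2.5 * t

    def test_gap_column_marginalized(self, dirichlet_freqs):
        A = CodingSequence("A", "ATGGGA")
        B = CodingSequence("B", "ATG---")
        tree = cm.PhyloTree.from_newick("(A:0.1,B:0.2);")
        params = cm.CodonModelParams(
            2.0, dirichlet_freqs, {"A": 1.0, "B": 1.0}, {"A": 0.1, "B": 0.2}
        )
        lnl = cm.log_likelihood(tree, [A, B], params)
        # gap column contributes the single-sequence likelihood of 'GGA'
        short = cm.log_likelihood(
            tree,
            [CodingSequence("A", "ATG"), CodingSequence("B", "ATG")],
            params,
        )
        assert lnl == pytest.approx(
            short + math.log(dirichlet_freqs[IDX["GGA"]]), abs=1e-10
        )

    def test_label_mismatch_lists_names(self, dirichlet_freqs, primate_tree):
        seqs = [CodingSequence("human", "ATG"), CodingSequence("mouse", "ATG")]
        params = cm.CodonModelParams(
            2.0,
            dirichlet_freqs,
            {l: 1.0 for l in primate_tree.branch_labels},
            {l: 0.1 for l in primate_tree.branch_labels},
        )
        with pytest.raises(ValueError, match="mouse"):
            cm.log_likelihood(primate_tree, seqs, params)

    def test_rerooting_invariance(self):
        tree = cm.PhyloTree.from_newick(
            "((A:0.1,B:0.2)n1:0.15,C:0.3,D:0.12);"
        )
        om = {l: 0.7 for l in tree.branch_labels}
        sim = sd.simulate_tree_alignment(tree, om, kappa=2.5, seed=3, n_codons=60)
        pi = np.full(61, 1 / 61)
        lengths = {n.label: n.length for n in tree.branches}
        params = cm.CodonModelParams(2.5, pi, om, lengths)
        lnl_a = cm.log_likelihood(tree, sim.alignment, params)
        rerooted = cm.PhyloTree.from_newick(
            "((C:0.3,D:0.12)x:0.075,(A:0.1,B:0.2)n1:0.075);"
        )
        params_b = cm.CodonModelParams(
            2.5,
            pi,
            {l: 0.7 for l in rerooted.branch_labels},
            {n.label: n.length for n in rerooted.branches},
        )
        assert cm.log_likelihood(rerooted, sim.alignment, params_b) == pytest.approx(
            lnl_a, abs=1e-8
        )


class TestFit:
    def test_identical_sequences_collapse_branch_lengths(self):
        tree = cm.PhyloTree.from_newick("(A:0.1,B:0.1,C:0.1);")
        seq = sd.random_stop_free_sequence(60, seed=8)
        seqs = [CodingSequence(l, seq.bases) for l in "ABC"]
        fitted = cm.fit(tree, seqs, "selection", init_omegas=(1.0,), tol=1e-4)
        assert all(t < 1e-4 for t in fitted.params.branch_lengths.values())

    def test_fitted_point_is_local_optimum(self, primate_tree):
        om = {l: 1.0 for l in primate_tree.branch_labels}
        sim = sd.simulate_tree_alignment(
            primate_tree, om, kappa=4.0, seed=21, n_codons=120
        )
        fitted = cm.fit(
            primate_tree, sim.alignment, "selection", init_omegas=(1.0,), tol=1e-6
        )
        best = fitted.lnL
        engine_lnl = cm.log_likelihood(primate_tree, sim.alignment, fitted.params)
        assert engine_lnl == pytest.approx(best, abs=1e-6)
        for scale in (0.8, 1.25):
            for what in ("kappa", "length", "omega"):
                trial = fitted.params.copy()
                if what == "kappa":
                    trial.kappa *= scale
                elif what == "length":
                    trial.branch_lengths["marmoset"] *= scale
                else:
                    trial.omega_by_branch["marmoset"] = max(
                        1e-4, trial.omega_by_branch["marmoset"] * scale
                    )
                assert (
                    cm.log_likelihood(primate_tree, sim.alignment, trial)
                    <= best + 1e-6
                )

    def test_null_model_pins_omega(self, primate_tree):
        om = {l: 1.0 for l in primate_tree.branch_labels}
        sim = sd.simulate_tree_alignment(
            primate_tree, om, kappa=4.0, seed=22, n_codons=100
        )
        fitted = cm.fit(
            primate_tree,
            sim.alignment,
            "null",
            target_branches=("marmoset",),
            init_omegas=(0.4,),
            tol=1e-4,
        )
        assert fitted.params.omega_by_branch["marmoset"] == 1.0

    def test_null_requires_targets(self, primate_tree):
        with pytest.raises(ValueError, match="target_branches"):
            cm.fit(primate_tree, [], "null")

    def test_unknown_target_branch_rejected(self, primate_tree):
        with pytest.raises(ValueError, match="unknown target"):
            cm.fit(
                primate_tree,
                [CodingSequence(l, "ATG") for l in primate_tree.leaf_labels],
                "null",
                target_branches=("nosuch",),
            )


class TestLrt:
    def _fit(self, lnl, tag, targets=("a",)):
        params = cm.CodonModelParams(
            2.0, np.full(61, 1 / 61), {"a": 1.0}, {"a": 0.1}
        )
        return cm.BranchModelFit(lnl, params, tag, tuple(targets), 1.0, True, 1)

    def test_equal_likelihoods(self):
        res = cm.lrt(self._fit(-100.0, "selection"), self._fit(-100.0, "null"))
        assert res.stat == 0.0 and res.p == 1.0 and res.df == 1

    def test_chi2_quantile(self):
        res = cm.lrt(
            self._fit(-98.08, "selection"), self._fit(-100.0, "null")
        )
        assert res.stat == pytest.approx(3.84)
        assert res.p == pytest.approx(0.05, abs=0.001)

    def test_df_counts_pinned_branches(self):
        res = cm.lrt(
            self._fit(-99.0, "selection", ("a", "b")),
            self._fit(-100.0, "null", ("a", "b")),
        )
        assert res.df == 2

    def test_negative_stat_beyond_tolerance_raises(self):
        with pytest.raises(ValueError, match="optimizer"):
            cm.lrt(self._fit(-101.0, "selection"), self._fit(-100.0, "null"))

    def test_bonferroni_family(self):
        res = cm.lrt(
            self._fit(-99.0, "selection"),
            self._fit(-100.0, "null"),
            n_tests=108,
        )
        assert res.per_test_alpha == pytest.approx(0.05 / 108)


class TestFrequencies:
    def test_empirical_freqs_sum_to_one_and_track_counts(self):
        seqs = [CodingSequence("a", "ATGATGGGA")]
        freqs = cm.empirical_codon_freqs(seqs, pseudocount=0.0)
        assert freqs.sum() == pytest.approx(1.0)
        assert freqs[IDX["ATG"]] == pytest.approx(2 / 3)
        assert freqs[IDX["GGA"]] == pytest.approx(1 / 3)
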