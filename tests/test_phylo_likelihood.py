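import math

import dendropy
import numpy as np
import pytest

from ratepart.msa_io import Alignment
from ratepart.phylo_likelihood import (
    TreeArrays,
    bionj_tree,
    discrete_gamma_rates,
    fit_model,
    fit_model_data,
    jc_distances,
    likelihood_site_rates,
    log_likelihood,
    model_by_name,
    nni_hill_climb,
    optimize_branch_lengths,
    prepare_subset,
)
from ratepart.phylo_likelihood import _pattern_likelihoods, _total_lnl
from ratepart.simulate import scale_tree_depth, simulate_alignment, yule_tree
from ratepart.tree_compare import rf_distance

JC_PARAMS = dict(m=1.0, exch=np.ones(6), freqs=np.full(4, 0.25))


def _jc_fit(aln, tree):
    return fit_model(aln, None, model_by_name("JC"), tree)


class TestDistances:
    def test_identical_sequences_zero(self):
        aln = Alignment.from_sequences(["a", "b", "c"], ["ACGT", "ACGT", "AAAA"])
        D = jc_distances(aln)
        assert D[0, 1] == 0.0

    def test_closed_form(self):
        # 1 mismatch in 10 sites: d = -(3/4) ln(1 - 4*0.1/3)
        aln = Alignment.from_sequences(
            ["a", "b", "c"], ["AAAAAAAAAA", "AAAAAAAAAC", "CCCCCCCCCC"]
        )
        D = jc_distances(aln)
        assert D[0, 1] == pytest.approx(0.10732563, abs=1e-6)

    def test_symmetric_zero_diagonal(self, small_alignment):
        D = jc_distances(small_alignment)
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_saturated_pair_capped(self):
        aln = Alignment.from_sequences(["a", "b", "c"], ["AAAA", "CCCC", "AACC"])
        assert np.isfinite(jc_distances(aln)[0, 1])

    def test_no_comparable_sites(self):
        aln = Alignment.from_sequences(["a", "b", "c"], ["AA--", "--CC", "ACAC"])
        with pytest.raises(ValueError):
            jc_distances(aln)


class TestBioNJ:
    def test_three_taxon_lengths(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = bionj_tree(D, ["A", "B", "C"])
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1,C:3,D:4): additive distances
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = bionj_tree(D, list("ABCD"))
        truth = dendropy.Tree.get(
            data="((A:1,B:2):1,C:3,D:4);", schema="newick"
        )
        assert rf_distance(tree, truth) == 0
        total = sum(e.length for e in tree.preorder_edge_iter() if e.length)
        assert total == pytest.approx(11.0, abs=1e-9)

    def test_edge_count_2n_minus_3(self):
        rs = np.random.default_rng(0)
        n = 9
        X = rs.random((n, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        tree = bionj_tree(D, [f"t{i}" for i in range(n)])
        n_edges = sum(1 for e in tree.preorder_edge_iter() if e.head_node.parent_node)
        assert n_edges == 2 * n - 3

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError):
            bionj_tree(D, list("ABC"))


class TestPruningLikelihood:
    def test_identical_pair_zero_branch(self):
        L = 16
        aln = Alignment.from_sequences(["A", "B"], ["ACGT" * 4] * 2)
        tree = dendropy.Tree.get(data="(A:0.0,B:0.0);", schema="newick")
        ta = TreeArrays(tree, aln.taxa)
        lnl, _, _, _ = _pattern_likelihoods(
            prepare_subset(aln), ta, model_by_name("JC"), JC_PARAMS
        )
        total = lnl @ prepare_subset(aln).weights
        assert total == pytest.approx(L * math.log(0.25), abs=1e-10)

    def test_two_taxon_jc_closed_form(self):
        rs = np.random.default_rng(1)
        seqs = ["".join(rs.choice(list("ACGT"), 60)) for _ in range(2)]
        aln = Alignment.from_sequences(["A", "B"], seqs)
        t = 0.42
        tree = dendropy.Tree.get(data=f"(A:{t / 2},B:{t / 2});", schema="newick")
        data = prepare_subset(aln)
        lnl, _, _, _ = _pattern_likelihoods(
            data, TreeArrays(tree, aln.taxa), model_by_name("JC"), JC_PARAMS
        )
        total = lnl @ data.weights
        match = (1 / 16) * (1 + 3 * math.exp(-4 * t / 3))
        mismatch = (1 / 16) * (1 - math.exp(-4 * t / 3))
        nm = sum(a == b for a, b in zip(*seqs))
        expected = nm * math.log(match) + (60 - nm) * math.log(mismatch)
        assert total == pytest.approx(expected, abs=1e-10)

    def test_compressed_equals_uncompressed(self, sim_alignment_tree):
        aln, tree = sim_alignment_tree
        fitted = _jc_fit(aln, tree)
        total, per_site = log_likelihood(aln, tree, fitted)
        assert total == pytest.approx(per_site.sum(), abs=1e-9)
        # site-by-site evaluation (no shared patterns) agrees
        singles = sum(
            log_likelihood(aln, tree, fitted, sites=[i])[0]
            for i in range(0, aln.n_sites, 97)
        )
        ref = sum(per_site[i] for i in range(0, aln.n_sites, 97))
        assert singles == pytest.approx(ref, abs=1e-9)

    def test_taxon_reorder_invariance(self, sim_alignment_tree):
        aln, tree = sim_alignment_tree
        fitted = _jc_fit(aln, tree)
        order = np.argsort([hash(t) for t in aln.taxa])
        aln2 = Alignment(
            tuple(np.array(aln.taxa)[order]), aln.matrix[order].copy()
        )
        fitted2 = _jc_fit(aln2, tree)
        assert fitted2.lnL == pytest.approx(fitted.lnL, abs=1e-6)

    def test_reroot_invariance(self, sim_alignment_tree):
        """Pulley principle: likelihood does not depend on the rooting."""
        aln, tree = sim_alignment_tree
        fitted = _jc_fit(aln, tree)
        base, _ = log_likelihood(aln, tree, fitted)
        re = tree.clone(depth=1)
        leaf = next(re.leaf_node_iter())
        half = leaf.edge.length / 2
        re.reroot_at_edge(leaf.edge, length1=half, length2=half, update_bipartitions=False)
        other, _ = log_likelihood(aln, re, fitted)
        assert other == pytest.approx(base, abs=1e-9)


class TestGammaInvariant:
    def test_category_rates_mean_one(self):
        for alpha in (0.05, 0.3, 1.0, 7.3, 95.0):
            assert discrete_gamma_rates(alpha).mean() == pytest.approx(1.0, abs=1e-9)

    def test_plus_ig_collapses_to_base(self, sim_alignment_tree):
        aln, tree = sim_alignment_tree
        data = prepare_subset(aln)
        ta = TreeArrays(tree, aln.taxa)
        base = _total_lnl(data, ta, model_by_name("JC"), JC_PARAMS)
        spec_ig = model_by_name("JC+I")
        collapsed = _total_lnl(
            data, ta, spec_ig, dict(JC_PARAMS, p_inv=0.0)
        )
        assert collapsed == pytest.approx(base, abs=1e-9)

    def test_huge_alpha_acts_homogeneous(self, sim_alignment_tree):
        aln, tree = sim_alignment_tree
        data = prepare_subset(aln)
        ta = TreeArrays(tree, aln.taxa)
        base = _total_lnl(data, ta, model_by_name("JC"), JC_PARAMS)
        g = _total_lnl(data, ta, model_by_name("JC+G"), dict(JC_PARAMS, alpha=1e5))
        assert g == pytest.approx(base, abs=1e-3)


class TestFitModel:
    def test_multiplier_recovery(self):
        tree = scale_tree_depth(yule_tree(8, 1.0, rng=np.random.default_rng(5)), 0.5)
        aln = simulate_alignment(tree, 2000, rng=np.random.default_rng(6))
        doubled = scale_tree_depth(tree, 1.0)  # all branches x2 vs truth
        fit = fit_model(aln, None, model_by_name("JC"), doubled)
        assert fit.params["m"] == pytest.approx(0.5, rel=0.1)
        assert not fit.flagged

    def test_nested_models_ordered(self, sim_alignment_tree):
        aln, tree = sim_alignment_tree
        data = prepare_subset(aln)
        ta = TreeArrays(tree, aln.taxa)
        jc = fit_model_data(data, model_by_name("JC"), ta)
        gtr = fit_model_data(data, model_by_name("GTR"), ta)
        assert gtr.lnL >= jc.lnL - 1e-6

    def test_multiplier_within_bounds(self, sim_alignment_tree):
        aln, tree = sim_alignment_tree
        fit = _jc_fit(aln, tree)
        assert 1e-6 < fit.params["m"] < 1e3

    def test_single_pattern_subset_flagged(self, sim_alignment_tree):
        aln, tree = sim_alignment_tree
        mono = Alignment(aln.taxa, np.repeat(aln.matrix[:, :1], 6, axis=1))
        fit = fit_model(mono, None, model_by_name("JC"), tree)
        assert fit.flagged


class TestBranchOptimization:
    def test_likelihood_never_decreases(self, sim_alignment_tree):
        aln, tree = sim_alignment_tree
        spec = model_by_name("GTR+G")
        before = fit_model_data(
            prepare_subset(aln), spec, TreeArrays(tree, aln.taxa), fix_m=True
        ).lnL
        opt = optimize_branch_lengths(tree, aln, spec, max_sweeps=2)
        after = fit_model_data(
            prepare_subset(aln), spec, TreeArrays(opt, aln.taxa), fix_m=True
        ).lnL
        assert after >= before - 1e-6

    def test_doubled_lengths_recovered(self):
        truth = scale_tree_depth(yule_tree(8, 1.0, rng=np.random.default_rng(21)), 0.4)
        aln = simulate_alignment(truth, 5000, rng=np.random.default_rng(22))
        start = scale_tree_depth(truth, 0.8)
        opt = optimize_branch_lengths(start, aln, model_by_name("JC"), max_sweeps=4)
        true_len = {
            lf.taxon.label: lf.edge.length for lf in truth.leaf_node_iter()
        }
        est_len = {lf.taxon.label: lf.edge.length for lf in opt.leaf_node_iter()}
        big = [t for t in true_len if true_len[t] > 0.02]
        rel = [abs(est_len[t] - true_len[t]) / true_len[t] for t in big]
        assert np.median(rel) < 0.2


class TestLikelihoodSiteRates:
    def test_uniform_patterns_uniform_rates(self, sim_alignment_tree):
        aln, tree = sim_alignment_tree
        mono = Alignment(aln.taxa, np.repeat(aln.matrix[:, 5:6], 8, axis=1))
        sr = likelihood_site_rates(mono, None, tree)
        assert np.allclose(sr.rates, sr.rates[0])

    def test_invariant_slower_than_variable(self):
        tree = dendropy.Tree.get(
            data="((A:0.3,B:0.3):0.1,(C:0.3,D:0.3):0.1);", schema="newick"
        )
        aln = Alignment.from_sequences(
            list("ABCD"),
            ["AAAAAAAAAACGTACGTACG",
             "AAAAAAAAAAGTACGTACGA",
             "AAAAAAAAAATACGTACGAC",
             "AAAAAAAAAAACGTACGACG"],
        )
        sr = likelihood_site_rates(aln, None, tree)
        assert sr.rates[:10].mean() < sr.rates[10:].mean()

    def test_large_alpha_rates_one(self, sim_alignment_tree):
        aln, tree = sim_alignment_tree
        data = prepare_subset(aln)
        ta = TreeArrays(tree, aln.taxa)
        fit = fit_model_data(data, model_by_name("GTR+G"), ta)
        fit.params["alpha"] = 5e4
        sr = likelihood_site_rates(aln, None, ta, fitted=fit)
        assert np.abs(sr.rates - 1.0).max() < 1e-3


class TestNNI:
    def test_hill_climb_improves_or_keeps_score(self, sim_alignment_tree):
        aln, tree = sim_alignment_tree
        data = prepare_subset(aln)

        def score(t):
            return fit_model_data(data, model_by_name("JC"), TreeArrays(t, aln.taxa)).lnL

        # start from a perturbed topology
        from ratepart.tree_compare import random_spr_neighbor

        start = random_spr_neighbor(tree, rng=3)
        s0 = score(start)
        improved, s1 = nni_hill_climb(start, score, max_rounds=4)
        assert s1 >= s0 - 1e-9
        assert {lf.taxon.label for lf in improved.leaf_node_iter()} == set(aln.taxa)
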