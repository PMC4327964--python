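import numpy as np
import pytest

from ratepart.kmeans_partitioner import (
    PartitionerConfig,
    PartitioningScheme,
    Subset,
    count_partitioning_schemes,
    iterative_kmeans,
    merge_problematic,
    score_scheme,
    try_split,
)
from ratepart.model_selection import select_best_model
from ratepart.msa_io import Alignment
from ratepart.phylo_likelihood import TreeArrays, model_by_name, prepare_subset
from ratepart.simulate import scale_tree_depth, simulate_alignment, yule_tree

CANDS = [model_by_name(n) for n in ["JC", "JC+G", "HKY", "GTR+G"]]


@pytest.fixture(scope="module")
def two_rate_data():
    """16 taxa; 250 slow sites + 250 fast (10x deeper tree) sites."""
    base = yule_tree(16, 1.0, rng=np.random.default_rng(61))
    slow_tree = scale_tree_depth(base, 0.08)
    fast_tree = scale_tree_depth(base, 0.8)
    a1 = simulate_alignment(slow_tree, 250, rng=np.random.default_rng(62))
    a2 = simulate_alignment(fast_tree, 250, rng=np.random.default_rng(63))
    mat = np.concatenate(
        [a1.matrix, a2.matrix[[a2.taxa.index(t) for t in a1.taxa]]], axis=1
    )
    aln = Alignment(a1.taxa, mat)
    labels = np.r_[np.zeros(250, int), np.ones(250, int)]
    return aln, labels, fast_tree


@pytest.fixture(scope="module")
def fitted_root(two_rate_data):
    aln, _, tree = two_rate_data
    ta = TreeArrays(tree, aln.taxa)
    fitted, sr = select_best_model(aln, ta, metric="bic", candidates=CANDS)
    root = Subset(sites=np.arange(aln.n_sites), fitted=fitted, score=sr)
    scheme = PartitioningScheme(subsets=[root], tree=tree)
    scheme.score = score_scheme(scheme, aln, ta, "bic")
    return aln, ta, scheme


class TestScoreScheme:
    def test_single_subset_equals_model_score_with_scheme_k(self, fitted_root):
        aln, ta, scheme = fitted_root
        sr = score_scheme(scheme, aln, ta, "bic")
        root = scheme.subsets[0]
        k = root.fitted.n_free_params + (2 * aln.n_taxa - 3)
        assert sr.k == k
        assert sr.lnL == pytest.approx(root.fitted.lnL)

    def test_duplicate_site_rejected(self, fitted_root):
        aln, ta, scheme = fitted_root
        root = scheme.subsets[0]
        bad = PartitioningScheme(
            subsets=[root, Subset(sites=np.array([0]), fitted=root.fitted)]
        )
        with pytest.raises(ValueError):
            score_scheme(bad, aln, ta, "bic")

    def test_decomposition_from_per_site_lnl(self, fitted_root):
        aln, ta, scheme = fitted_root
        total_from_sites = sum(s.site_lnl.sum() for s in scheme.subsets)
        assert scheme.score.lnL == pytest.approx(total_from_sites, abs=1e-9)


class TestTrySplit:
    def test_two_rate_subset_split_accepted_and_pure(self, fitted_root, two_rate_data):
        aln, ta, scheme = fitted_root
        _, labels, _ = two_rate_data
        config = PartitionerConfig(candidates=CANDS)
        decision = try_split(
            scheme.subsets[0], scheme, aln, ta, metric="bic",
            rng=np.random.default_rng(0), config=config,
        )
        assert decision.accept
        assert decision.new_value < decision.old_value
        purities = []
        for child in decision.children:
            frac = np.bincount(labels[child.sites], minlength=2) / child.n_sites
            purities.append(frac.max())
        # the split peels off a rate class: at least one child is (nearly)
        # single-block, and both children beat a random assignment
        assert max(purities) >= 0.9
        assert min(purities) >= 0.6
        # children occupy disjoint rate ranges
        r0 = sorted(
            (min(c.centroid for c in decision.children),
             max(c.centroid for c in decision.children))
        )
        assert r0[0] < r0[1]

    def test_invariant_subset_rejected(self, fitted_root):
        aln, ta, scheme = fitted_root
        # constant columns only: a single rate value, nothing to split
        const_sites = [
            i for i in range(aln.n_sites)
            if len(set(aln.matrix[:, i])) == 1
        ]
        assert len(const_sites) >= 2
        root = scheme.subsets[0]
        sub = Subset(sites=np.array(const_sites), fitted=root.fitted)
        sub.carried_site_lnl = None
        fake = PartitioningScheme(subsets=[sub])
        decision = try_split(
            sub, fake, aln, ta, metric="bic", rng=np.random.default_rng(0),
            config=PartitionerConfig(candidates=CANDS),
        )
        assert not decision.accept


class TestIterativeKmeans:
    @pytest.fixture(scope="class")
    def result(self, two_rate_data):
        aln, labels, _ = two_rate_data
        config = PartitionerConfig(candidates=CANDS, bl_opt_sweeps=1, seed=5)
        scheme = iterative_kmeans(
            aln, metric="bic", rate_method="tiger",
            rng=np.random.default_rng(5), config=config,
        )
        return aln, labels, scheme, config

    def test_finds_multiple_subsets_and_improves(self, result):
        aln, labels, scheme, _ = result
        assert scheme.n_subsets >= 2
        first = scheme.history[0]["bic"]
        assert scheme.score.bic < first

    def test_coverage_exactly_once(self, result):
        aln, _, scheme, _ = result
        scheme.validate_coverage(aln.n_sites)
        allsites = np.sort(np.concatenate([s.sites for s in scheme.subsets]))
        assert np.array_equal(allsites, np.arange(aln.n_sites))

    def test_monotone_improvement_across_split_iterations(self, result):
        _, _, scheme, _ = result
        vals = [h["bic"] for h in scheme.history if h["phase"] in ("init", "split")]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        counts = [
            h["n_subsets"] for h in scheme.history if h["phase"] in ("init", "split")
        ]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_no_problematic_subsets_remain(self, result):
        _, _, scheme, _ = result
        assert all(not s.problematic for s in scheme.subsets)

    def test_same_seed_reproduces_scheme(self, result, two_rate_data):
        aln, _, scheme, config = result
        again = iterative_kmeans(
            aln, metric="bic", rate_method="tiger",
            rng=np.random.default_rng(5),
            config=PartitionerConfig(candidates=CANDS, bl_opt_sweeps=1, seed=5),
        )
        assert again.n_subsets == scheme.n_subsets
        for a, b in zip(again.subsets, scheme.subsets):
            assert np.array_equal(a.sites, b.sites)


class TestMergeProblematic:
    def test_no_problematic_unchanged(self, fitted_root):
        aln, ta, scheme = fitted_root
        before = [s.sites.copy() for s in scheme.subsets]
        merge_problematic(scheme, aln, ta, metric="bic",
                          config=PartitionerConfig(candidates=CANDS))
        assert len(scheme.subsets) == len(before)

    def test_merges_into_nearest_centroid(self, two_rate_data):
        aln, _, tree = two_rate_data
        ta = TreeArrays(tree, aln.taxa)
        cfg = PartitionerConfig(candidates=CANDS)
        fit_a, sr_a = select_best_model(
            aln, ta, metric="bic", sites=list(range(0, 240)), candidates=CANDS
        )
        fit_b, sr_b = select_best_model(
            aln, ta, metric="bic", sites=list(range(250, 500)), candidates=CANDS
        )
        prob = Subset(
            sites=np.arange(240, 250), centroid=0.2, problematic=True,
            carried_site_lnl=fit_a.site_lnl[:10].copy(),
        )
        a = Subset(sites=np.arange(0, 240), fitted=fit_a, score=sr_a, centroid=0.25)
        b = Subset(sites=np.arange(250, 500), fitted=fit_b, score=sr_b, centroid=0.9)
        scheme = PartitioningScheme(subsets=[a, b, prob])
        merge_problematic(scheme, aln, ta, metric="bic", config=cfg)
        assert all(not s.problematic for s in scheme.subsets)
        assert len(scheme.subsets) == 2
        sizes = sorted(s.n_sites for s in scheme.subsets)
        assert sizes == [250, 250]  # merged into the 0.25-centroid subset


class TestBellNumbers:
    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 2), (3, 5), (4, 15), (10, 115975)])
    def test_small_values(self, n, expected):
        bell, _ = count_partitioning_schemes(n)
        assert bell == expected

    def test_barcode_alignment_bound(self):
        _, log10 = count_partitioning_schemes(658)
        assert log10 >= 931
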