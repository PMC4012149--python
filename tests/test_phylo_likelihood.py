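import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from partitionkit.data_model import Alignment, Subset
from partitionkit.phylo_likelihood import (
    ALPHA_BOUNDS,
    MIN_BRANCH,
    RATE_MULT_BOUNDS,
    GammaModel,
    GTRParams,
    Tree,
    build_starting_tree,
    discrete_gamma_rates,
    estimate_linked_branch_lengths,
    fit_subset,
    gtr_rate_matrix,
    jc_distance_matrix,
    subset_log_likelihood,
    transition_probabilities,
)
from partitionkit.synthetic_data import BlockModel, random_tree, simulate_alignment

from conftest import brute_force_lnl, random_gtr


def make_aln(seqs, names=None):
    names = names or tuple(f"t{i+1}" for i in range(len(seqs)))
    return Alignment(
        taxon_names=tuple(names),
        matrix=np.array([list(s) for s in seqs], dtype="<U1"),
    )


class TestStartingTree:
    def test_three_taxa_unique_topology(self):
        aln = make_aln(["ACGTACGT", "ACGTACGA", "ACGAACGA"])
        tree = build_starting_tree(aln)
        assert tree.n_taxa == 3
        assert tree.n_branches == 3  # 2T - 3

    def test_fewer_than_three_taxa_rejected(self, tiny_alignment):
        with pytest.raises(ValueError, match="3 taxa"):
            build_starting_tree(tiny_alignment)

    def test_identical_sequences_zero_lengths(self):
        aln = make_aln(["ACGT" * 5] * 4)
        tree = build_starting_tree(aln)
        assert tree.total_length() == pytest.approx(0.0, abs=1e-12)

    def test_saturated_distances_capped_with_warning(self):
        aln = make_aln(["AAAAAAAA", "CCCCCCCC", "GGGGGGGG"])
        with pytest.warns(RuntimeWarning, match="saturated"):
            jc_distance_matrix(aln)

    def test_nj_recovers_true_splits(self):
        """Simulated data on a known 6-taxon tree with a clear internal
        structure: NJ must recover the true unrooted splits."""
        rng = np.random.default_rng(7)
        true = random_tree(6, rng, length_range=(0.15, 0.3))
        aln, _ = simulate_alignment(true, [BlockModel("b", 4000)], 11)
        est = build_starting_tree(aln)
        assert _splits(est) == _splits(true)

    def test_user_tree_used_verbatim(self):
        aln = make_aln(["ACGT", "ACGA", "AGGA", "TGGA"])
        newick = "((t1:0.1,t2:0.2):0.05,t3:0.3,t4:0.4);"
        tree = build_starting_tree(aln, user_newick=newick)
        assert tree.total_length() == pytest.approx(1.05)

    def test_user_tree_taxa_mismatch(self):
        aln = make_aln(["ACGT", "ACGA", "AGGA"])
        with pytest.raises(ValueError, match="mismatch"):
            build_starting_tree(aln, user_newick="(x:1,y:1,z:1);")


def _splits(tree: Tree) -> set:
    kids = tree.children()
    leaves_under = {}
    for node in tree.postorder_internal():
        acc = set()
        for c in kids[node]:
            if c < tree.n_taxa:
                acc.add(tree.taxon_names[c])
            else:
                acc |= leaves_under[c]
        leaves_under[node] = acc
    all_taxa = frozenset(tree.taxon_names)
    splits = set()
    for s in leaves_under.values():
        side = frozenset(s)
        if 1 < len(side) < tree.n_taxa - 1:
            splits.add(frozenset({side, all_taxa - side}))
    return splits


class TestRateMatrix:
    def test_equal_rates_and_freqs_is_jukes_cantor(self):
        q = gtr_rate_matrix(GTRParams())
        expected = np.full((4, 4), 1.0 / 3.0)
        np.fill_diagonal(expected, -1.0)
        np.testing.assert_allclose(q, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_stationarity_and_normalization(self, seed):
        gtr = random_gtr(np.random.default_rng(seed))
        q = gtr_rate_matrix(gtr)
        pi = np.asarray(gtr.freqs)
        np.testing.assert_allclose(pi @ q, np.zeros(4), atol=1e-12)
        np.testing.assert_allclose(q.sum(axis=1), np.zeros(4), atol=1e-12)
        assert pi @ np.diag(q) == pytest.approx(-1.0)
        # detailed balance
        np.testing.assert_allclose(pi[:, None] * q, (pi[:, None] * q).T, atol=1e-12)


class TestDiscreteGamma:
    def test_single_category_is_unit_rate(self):
        np.testing.assert_allclose(discrete_gamma_rates(GammaModel(0.7, k=1)), [1.0])

    def test_huge_alpha_collapses_to_no_variation(self):
        rates = discrete_gamma_rates(GammaModel(1e6, k=4))
        np.testing.assert_allclose(rates, np.ones(4), atol=1e-2)

    def test_rates_increasing_with_unit_mean(self):
        rates = discrete_gamma_rates(GammaModel(0.5, k=4))
        assert np.all(np.diff(rates) > 0)
        assert rates.mean() == pytest.approx(1.0, abs=1e-12)

    def test_matches_quadrature_oracle(self):
        """Category rates equal the conditional means of the gamma density
        within equal-probability bins, computed by numerical integration."""
        alpha, k = 0.5, 4
        dist = gamma_dist(a=alpha, scale=1.0 / alpha)
        bounds = [0.0] + [dist.ppf(i / k) for i in range(1, k)] + [np.inf]
        expected = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            mass, _ = quad(dist.pdf, lo, hi if np.isfinite(hi) else 200)
            mean, _ = quad(lambda x: x * dist.pdf(x), lo, hi if np.isfinite(hi) else 200)
            expected.append(mean / mass)
        expected = np.asarray(expected)
        expected /= expected.mean()
        got = discrete_gamma_rates(GammaModel(alpha, k=k))
        np.testing.assert_allclose(got, expected, atol=1e-6)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        q = gtr_rate_matrix(random_gtr(np.random.default_rng(0)))
        p = transition_probabilities(q, 0.0)
        np.testing.assert_allclose(p, np.eye(4), atol=1e-12)

    def test_long_time_reaches_stationarity(self):
        gtr = random_gtr(np.random.default_rng(1))
        q = gtr_rate_matrix(gtr)
        p = transition_probabilities(q, 1e4, freqs=gtr.freqs)
        for row in p:
            np.testing.assert_allclose(row, gtr.freqs, atol=1e-6)

    def test_jc_closed_form(self):
        q = gtr_rate_matrix(GTRParams())
        p = transition_probabilities(q, 0.3, rate=1.0)
        diag = 0.25 + 0.75 * np.exp(-4.0 * 0.3 / 3.0)
        off = 0.25 - 0.25 * np.exp(-4.0 * 0.3 / 3.0)
        np.testing.assert_allclose(np.diag(p), np.full(4, diag), atol=1e-12)
        np.testing.assert_allclose(p[0, 1], off, atol=1e-12)

    def test_rows_sum_to_one(self):
        gtr = random_gtr(np.random.default_rng(2))
        q = gtr_rate_matrix(gtr)
        p = transition_probabilities(q, 0.7, rate=2.3, freqs=gtr.freqs)
        np.testing.assert_allclose(p.sum(axis=1), np.ones(4), atol=1e-10)

    def test_stationary_freqs_recovered_when_omitted(self):
        gtr = random_gtr(np.random.default_rng(3))
        q = gtr_rate_matrix(gtr)
        with_pi = transition_probabilities(q, 0.5, freqs=gtr.freqs)
        without = transition_probabilities(q, 0.5)
        np.testing.assert_allclose(with_pi, without, atol=1e-9)


class TestSubsetLogLikelihood:
    def test_zero_tree_shared_base_gives_log_freq(self):
        aln = make_aln(["A", "A", "A", "A"])
        tree = build_starting_tree(aln)  # identical seqs -> zero lengths
        sub = Subset(blocks=frozenset({"x"}), sites=(0,))
        gtr = GTRParams(freqs=(0.1, 0.2, 0.3, 0.4))
        lnl = subset_log_likelihood(aln, sub, tree, 1.0, gtr, GammaModel(1.0))
        assert lnl == pytest.approx(np.log(0.1), abs=1e-9)

    def test_site_independence_additivity(self, small_sim):
        aln, blocks, tree = small_sim
        gtr, gamma = GTRParams(), GammaModel(0.8)
        sub_a = Subset(frozenset({"a"}), tuple(range(0, 50)))
        sub_b = Subset(frozenset({"b"}), tuple(range(50, 120)))
        union = Subset(frozenset({"a", "b"}), tuple(range(0, 120)))
        la = subset_log_likelihood(aln, sub_a, tree, 1.0, gtr, gamma)
        lb = subset_log_likelihood(aln, sub_b, tree, 1.0, gtr, gamma)
        lu = subset_log_likelihood(aln, union, tree, 1.0, gtr, gamma)
        assert lu == pytest.approx(la + lb, abs=1e-8)

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_matches_brute_force_enumeration(self, n_taxa):
        """Pruning equals explicit summation over all internal-node state
        combinations, over random GTR+Gamma parameters."""
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(10):
            tree = random_tree(n_taxa, rng)
            gtr = random_gtr(rng)
            gamma = GammaModel(float(rng.uniform(0.3, 3.0)))
            mult = float(rng.uniform(0.3, 3.0))
            aln, _ = simulate_alignment(
                tree, [BlockModel("b", 10, gtr=gtr)], int(rng.integers(2**31))
            )
            sub = Subset(frozenset({"b"}), tuple(range(10)))
            fast = subset_log_likelihood(aln, sub, tree, mult, gtr, gamma)
            slow = brute_force_lnl(aln, range(10), tree, mult, gtr, gamma)
            assert fast == pytest.approx(slow, abs=1e-8)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(5)
        tree = random_tree(5, rng)
        aln, _ = simulate_alignment(tree, [BlockModel("b", 80)], 3)
        sub = Subset(frozenset({"b"}), tuple(range(80)))
        gtr, gamma = random_gtr(rng), GammaModel(1.0)
        l1 = subset_log_likelihood(aln, sub, tree, 1.0, gtr, gamma)
        order = [3, 1, 4, 0, 2]
        aln2 = Alignment(
            taxon_names=tuple(aln.taxon_names[i] for i in order),
            matrix=aln.matrix[order],
        )
        tree2 = Tree.from_newick(tree.to_newick(), aln2.taxon_names)
        l2 = subset_log_likelihood(aln2, sub, tree2, 1.0, gtr, gamma)
        assert l2 == pytest.approx(l1, abs=1e-9)

    def test_rate_multiplier_branch_length_confounding(self, small_sim):
        """Scaling all branch lengths by c and dividing the multiplier by
        c leaves the likelihood unchanged."""
        aln, blocks, tree = small_sim
        sub = Subset.from_blocks(blocks[:1])
        gtr, gamma = GTRParams(), GammaModel(1.0)
        c = 2.0
        scaled = tree.with_lengths([l * c for l in tree.lengths])
        l1 = subset_log_likelihood(aln, sub, tree, 1.0, gtr, gamma)
        l2 = subset_log_likelihood(aln, sub, scaled, 1.0 / c, gtr, gamma)
        assert l2 == pytest.approx(l1, rel=1e-12)

    def test_gap_and_ambiguity_sites_are_finite(self):
        aln = make_aln(["A-GT", "ANGT", "ARG?"])
        tree = build_starting_tree(aln)
        sub = Subset(frozenset({"x"}), (0, 1, 2, 3))
        lnl = subset_log_likelihood(aln, sub, tree, 1.0, GTRParams(), GammaModel(1.0))
        assert np.isfinite(lnl) and lnl < 0


class TestBranchLengthEstimation:
    def test_fixed_point_at_optimum(self, small_sim):
        """Re-optimizing from the fitted lengths barely moves the
        whole-alignment likelihood: the lengths are at a fixed point."""
        aln, blocks, tree = small_sim
        fitted = estimate_linked_branch_lengths(aln, tree)
        again = estimate_linked_branch_lengths(aln, fitted, outer_rounds=1)
        sub = Subset.from_blocks(blocks)
        l_fitted = fit_subset(aln, sub, fitted).lnL
        l_again = fit_subset(aln, sub, again).lnL
        assert abs(l_again - l_fitted) < 0.5

    def test_identical_sequences_drive_lengths_to_floor(self):
        aln = make_aln(["ACGTACGTACGT"] * 4)
        tree = build_starting_tree(aln).with_lengths([0.1] * 6)
        fitted = estimate_linked_branch_lengths(aln, tree)
        for node in fitted.branch_nodes:
            assert fitted.lengths[node] <= 1e-4

    def test_recovers_simulated_lengths(self):
        """Starting from doubled lengths, optimization returns close to
        the generating total tree length on a long alignment."""
        rng = np.random.default_rng(21)
        true = random_tree(5, rng)
        aln, _ = simulate_alignment(true, [BlockModel("b", 5000)], 9)
        start = true.with_lengths([l * 2 for l in true.lengths])
        fitted = estimate_linked_branch_lengths(aln, start)
        assert fitted.total_length() == pytest.approx(true.total_length(), rel=0.15)


class TestFitSubset:
    def test_whole_alignment_multiplier_near_one(self, small_sim):
        aln, blocks, tree = small_sim
        fitted_tree = estimate_linked_branch_lengths(aln, tree)
        sub = Subset.from_blocks(blocks)
        fit = fit_subset(aln, sub, fitted_tree)
        assert 0.85 <= fit.rate_multiplier <= 1.15
        assert fit.subset_rate == pytest.approx(
            fit.rate_multiplier * fitted_tree.total_length()
        )

    def test_rate_contrast_recovered(self, small_sim):
        aln, blocks, tree = small_sim
        fitted_tree = estimate_linked_branch_lengths(aln, tree)
        slow = fit_subset(aln, Subset.from_blocks(blocks[:1]), fitted_tree)
        fast = fit_subset(aln, Subset.from_blocks(blocks[1:]), fitted_tree)
        ratio = fast.rate_multiplier / slow.rate_multiplier
        assert ratio == pytest.approx(4.0, rel=0.35)

    def test_degenerate_constant_subset_flagged(self):
        aln = make_aln(["ACGT" * 3] * 4)
        tree = build_starting_tree(aln).with_lengths([0.05] * 6)
        fit = fit_subset(aln, Subset(frozenset({"x"}), tuple(range(12))), tree)
        assert fit.degenerate
        assert fit.gamma.alpha == ALPHA_BOUNDS[1]
        assert fit.rate_multiplier == RATE_MULT_BOUNDS[0]

    def test_fit_is_local_optimum(self, small_sim):
        """The fitted parameter point beats nearby perturbations."""
        aln, blocks, tree = small_sim
        fitted_tree = estimate_linked_branch_lengths(aln, tree)
        sub = Subset.from_blocks(blocks[:1])
        fit = fit_subset(aln, sub, fitted_tree)
        for factor in (0.7, 1.4):
            worse = subset_log_likelihood(
                aln, sub, fitted_tree, fit.rate_multiplier * factor, fit.gtr, fit.gamma
            )
            assert worse <= fit.lnL + 1e-6
            worse_a = subset_log_likelihood(
                aln, sub, fitted_tree, fit.rate_multiplier, fit.gtr,
                GammaModel(fit.gamma.alpha * factor),
            )
            assert worse_a <= fit.lnL + 1e-6

    def test_determinism(self, small_sim):
        aln, blocks, tree = small_sim
        sub = Subset.from_blocks(blocks[:1])
        f1 = fit_subset(aln, sub, tree)
        f2 = fit_subset(aln, sub, tree)
        assert f1 == f2
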