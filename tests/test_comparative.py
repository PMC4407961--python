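"""Tree handling, BM/OU covariance and likelihood, ancestral reconstruction."""

import math

import dendropy
import numpy as np
import pytest
from scipy.stats import multivariate_normal

from cavepairs.comparative import (
    AncestralEstimate,
    ModelFit,
    Phylogeny,
    ancestral_pair_distance,
    bm_covariance,
    divergence_report,
    fit_model,
    fit_ou_fixed_alpha,
    ou_covariance,
    reconstruct_ancestor,
    select_model,
    sister_species,
)
from cavepairs.errors import CavepairsError, SingularCovarianceError, TreeError
from cavepairs.synthetic import simulate_traits, simulate_tree


# -- independent oracles (coded against dendropy, not the package's indexing) --


def dendropy_depths(newick: str):
    """(labels, tip depth, MRCA-depth function) computed purely with dendropy."""
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted",
                             preserve_underscores=True)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]

    def mrca_depth(*names):
        node = tree.mrca(taxon_labels=list(names))
        return node.root_distance

    depths = {lf.taxon.label: lf.root_distance for lf in tree.leaf_node_iter()}
    return labels, depths, mrca_depth


def ou_pair_cov(sigma2, alpha, ti, tj, sij):
    return (
        sigma2
        / (2 * alpha)
        * math.exp(-alpha * (ti + tj - 2 * sij))
        * (1 - math.exp(-2 * alpha * sij))
    )


@pytest.fixture(params=[0, 1, 2])
def random_small_tree(request):
    n = [5, 8, 10][request.param]
    return simulate_tree(n, birth_rate=1.0, seed=100 + request.param)


class TestReadTree:
    def test_three_tip_depths(self, small_tree):
        assert sorted(small_tree.tip_labels) == ["A", "B", "C"]
        assert np.allclose(small_tree.tip_depths, 2.0)
        assert small_tree.is_ultrametric()

    def test_newick_without_lengths_rejected(self):
        with pytest.raises(TreeError, match="branch lengths required"):
            Phylogeny.from_newick("((A,B),C);")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            Phylogeny.from_newick("((A:1,A:1):1,C:2);")

    def test_44_tip_round_trip(self):
        tree = simulate_tree(44, seed=9)
        back = Phylogeny.from_newick(tree.to_newick())
        assert back.tip_labels == tree.tip_labels
        assert np.allclose(back.tip_depths, tree.tip_depths, atol=1e-9)
        assert np.allclose(back.mrca_depths, tree.mrca_depths, atol=1e-9)

    def test_prune_warns_and_marginalizes_covariance(self):
        tree = simulate_tree(10, seed=4)
        keep = tree.tip_labels[:6]
        with pytest.warns(UserWarning, match="pruning"):
            sub = tree.prune_to(keep)
        full = bm_covariance(tree, 1.3)
        idx = [tree.tip_labels.index(l) for l in sub.tip_labels]
        assert np.allclose(full[np.ix_(idx, idx)], bm_covariance(sub, 1.3), atol=1e-9)

    def test_pruning_preserves_likelihood_of_remaining_tips(self):
        # Gaussian marginalization: the pruned-tree likelihood of the kept tips
        # equals the joint density's marginal, so the ML fit agrees too.
        tree = simulate_tree(12, seed=5)
        traits = simulate_traits(tree, "BM", sigma2=1.0, seed=6)
        keep = tree.tip_labels[:8]
        with pytest.warns(UserWarning):
            sub = tree.prune_to(keep)
        sub_traits = {l: traits[l] for l in keep}
        fit_sub = fit_model(sub, sub_traits, "BM")
        idx = [tree.tip_labels.index(l) for l in sub.tip_labels]
        V = fit_sub.sigma2 * tree.mrca_depths[np.ix_(idx, idx)]
        y = np.array([traits[l] for l in sub.tip_labels])
        direct = multivariate_normal(mean=np.full(8, fit_sub.root_state), cov=V).logpdf(y)
        assert fit_sub.log_likelihood == pytest.approx(direct, abs=1e-8)


class TestBMCovariance:
    def test_three_tip_example(self, small_tree):
        V = bm_covariance(small_tree, 1.0)
        i = {l: k for k, l in enumerate(small_tree.tip_labels)}
        assert V[i["A"], i["B"]] == pytest.approx(1.0)
        assert V[i["A"], i["C"]] == pytest.approx(0.0)
        assert V[i["A"], i["A"]] == pytest.approx(2.0)

    def test_star_tree_has_zero_off_diagonals(self):
        tree = Phylogeny.from_newick("(A:1,B:2,C:3,D:4);")
        V = bm_covariance(tree, 2.0)
        assert np.allclose(V - np.diag(np.diag(V)), 0.0)
        assert np.allclose(np.diag(V), 2.0 * tree.tip_depths)

    def test_matches_dendropy_path_oracle(self, random_small_tree):
        tree = random_small_tree
        labels, depths, mrca_depth = dendropy_depths(tree.to_newick())
        V = bm_covariance(tree, 0.7)
        for a in tree.tip_labels:
            for b in tree.tip_labels:
                i, j = tree.tip_labels.index(a), tree.tip_labels.index(b)
                want = 0.7 * (depths[a] if a == b else mrca_depth(a, b))
                assert V[i, j] == pytest.approx(want, abs=1e-10)


class TestOUCovariance:
    def test_small_alpha_limit_is_bm(self, random_small_tree):
        V_ou = ou_covariance(random_small_tree, alpha=1e-8, sigma2=1.4)
        V_bm = bm_covariance(random_small_tree, 1.4)
        assert np.allclose(V_ou, V_bm, rtol=1e-5)

    def test_single_tip_closed_form(self):
        tree = Phylogeny.from_newick("(A:3,B:5);")
        V = ou_covariance(tree, alpha=0.8, sigma2=2.0)
        i = {l: k for k, l in enumerate(tree.tip_labels)}
        want = 2.0 / (2 * 0.8) * (1 - math.exp(-2 * 0.8 * 3))
        assert V[i["A"], i["A"]] == pytest.approx(want, rel=1e-12)

    def test_matches_pairwise_formula_oracle(self, random_small_tree):
        tree = random_small_tree
        labels, depths, mrca_depth = dendropy_depths(tree.to_newick())
        alpha, sigma2 = 1.7, 0.9
        V = ou_covariance(tree, alpha, sigma2)
        for a in tree.tip_labels:
            for b in tree.tip_labels:
                i, j = tree.tip_labels.index(a), tree.tip_labels.index(b)
                s = depths[a] if a == b else mrca_depth(a, b)
                want = ou_pair_cov(sigma2, alpha, depths[a], depths[b], s)
                assert V[i, j] == pytest.approx(want, abs=1e-10)

    def test_nonpositive_alpha_rejected(self, small_tree):
        with pytest.raises(CavepairsError):
            ou_covariance(small_tree, alpha=0.0, sigma2=1.0)


class TestFitModel:
    def test_two_tip_symmetry_gives_midpoint_root(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        fit = fit_model(tree, {"A": 0.0, "B": 2.0}, "BM")
        assert fit.root_state == pytest.approx(1.0)
        assert fit.alpha == 0.0
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 4)

    @pytest.mark.parametrize("model", ["BM", "OU"])
    def test_loglik_matches_density_oracle(self, model, random_small_tree):
        tree = random_small_tree
        traits = simulate_traits(tree, "OU", sigma2=1.0, alpha=0.5, seed=11)
        fit = fit_model(tree, traits, model)
        if model == "BM":
            V = bm_covariance(tree, fit.sigma2)
        else:
            V = ou_covariance(tree, fit.alpha, fit.sigma2)
        y = np.array([traits[l] for l in tree.tip_labels])
        mvn = multivariate_normal(mean=np.full(y.size, fit.root_state), cov=V)
        assert fit.log_likelihood == pytest.approx(mvn.logpdf(y), abs=1e-8)

    def test_ou_nests_bm_at_small_alpha(self, random_small_tree):
        traits = simulate_traits(random_small_tree, "BM", sigma2=0.8, seed=12)
        bm = fit_model(random_small_tree, traits, "BM")
        ou = fit_ou_fixed_alpha(random_small_tree, traits, alpha=1e-8)
        assert ou.log_likelihood == pytest.approx(bm.log_likelihood, rel=1e-4)

    def test_bm_simulated_data_selects_bm_most_of_the_time(self):
        tree = simulate_tree(200, seed=21)
        wins = 0
        alphas = []
        for rep in range(10):
            traits = simulate_traits(tree, "BM", sigma2=1.0, seed=1000 + rep)
            bm = fit_model(tree, traits, "BM")
            ou = fit_model(tree, traits, "OU")
            wins += bm.aic <= ou.aic
            alphas.append(ou.alpha)
        assert wins >= 6
        assert np.median(alphas) < 0.5  # restraining force near zero on BM data

    def test_duplicate_zero_distance_tips_named_in_error(self):
        tree = Phylogeny.from_newick("((A:0,B:0):2,C:2);")
        with pytest.raises(SingularCovarianceError, match="A"):
            fit_model(tree, {"A": 1.0, "B": 1.0, "C": 0.0}, "BM")

    def test_missing_trait_values_rejected(self, small_tree):
        with pytest.raises(CavepairsError, match="without trait"):
            fit_model(small_tree, {"A": 1.0, "B": 2.0}, "BM")


class TestSelectModel:
    def _fit(self, model, aic):
        return ModelFit(model=model, sigma2=1.0, alpha=0.0 if model == "BM" else 1.0,
                        root_state=0.0, log_likelihood=0.0, aic=aic, n_tips=5)

    def test_lower_aic_wins(self):
        assert select_model([self._fit("OU", 10.0), self._fit("BM", 12.0)]).model == "OU"

    def test_tie_goes_to_fewer_parameters(self):
        assert select_model([self._fit("OU", 10.0), self._fit("BM", 10.0)]).model == "BM"


class TestReconstruction:
    def test_two_tip_equal_branches_averages(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        fit = fit_model(tree, {"A": 0.0, "B": 2.0}, "BM")
        est = reconstruct_ancestor(tree, {"A": 0.0, "B": 2.0}, fit, ("A", "B"))
        # MRCA of the only cherry is the root here; warning is expected upstream
        assert est.mean == pytest.approx(1.0)
        assert est.lower <= est.mean <= est.upper

    def test_zero_length_branch_pins_reconstruction_to_tip(self):
        tree = Phylogeny.from_newick("((A:0.0,B:1):1,C:2);")
        traits = {"A": 1.7, "B": 0.4, "C": -0.2}
        fit = ModelFit(model="BM", sigma2=1.0, alpha=0.0, root_state=0.0,
                       log_likelihood=0.0, aic=0.0, n_tips=3)
        est = reconstruct_ancestor(tree, traits, fit, ("A", "B"))
        assert est.mean == pytest.approx(1.7, abs=1e-9)
        assert est.se == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("model", ["BM", "OU"])
    def test_matches_joint_normal_conditioning_oracle(self, model):
        tree = simulate_tree(10, seed=31)
        traits = simulate_traits(tree, "OU", sigma2=1.2, alpha=0.6, seed=32)
        fit = fit_model(tree, traits, model)
        pair = (tree.tip_labels[0], tree.tip_labels[1])
        est = reconstruct_ancestor(tree, traits, fit, pair)

        labels, depths, mrca_depth = dendropy_depths(tree.to_newick())
        n = tree.n_tips
        s_node = mrca_depth(*pair)

        def cov(ti, tj, sij):
            if fit.model == "BM":
                return fit.sigma2 * sij
            return ou_pair_cov(fit.sigma2, fit.alpha, ti, tj, sij)

        V = np.empty((n, n))
        c = np.empty(n)
        for i, a in enumerate(tree.tip_labels):
            for j, b in enumerate(tree.tip_labels):
                s = depths[a] if a == b else mrca_depth(a, b)
                V[i, j] = cov(depths[a], depths[b], s)
            # shared depth of the MRCA node with tip a: nest a into the pair
            s_na = s_node if a in pair else min(s_node, mrca_depth(pair[0], pair[1], a))
            c[i] = cov(depths[a], s_node, s_na)
        v_node = cov(s_node, s_node, s_node)
        y = np.array([traits[l] for l in tree.tip_labels])
        w = np.linalg.solve(V, c)
        mean = fit.root_state + w @ (y - fit.root_state)
        # GLS prediction variance: conditional variance given the tips plus the
        # propagated variance of the estimated root state
        ones = np.ones(n)
        var = v_node - w @ c + (1.0 - w @ ones) ** 2 / (ones @ np.linalg.solve(V, ones))
        assert est.mean == pytest.approx(mean, abs=1e-8)
        assert est.se == pytest.approx(math.sqrt(max(var, 0.0)), abs=1e-8)

    def test_bm_reconstruction_weights_sum_to_one(self):
        tree = simulate_tree(8, seed=41)
        traits = simulate_traits(tree, "BM", sigma2=1.0, seed=42)
        pair = (tree.tip_labels[2], tree.tip_labels[3])

        def mean_at(tr):
            fit = fit_model(tree, tr, "BM")
            return reconstruct_ancestor(tree, tr, fit, pair).mean

        # the reconstruction (with its GLS root) is linear in tip values; adding
        # a constant to every tip must shift the estimate by that constant
        shifted = {l: v + 3.7 for l, v in traits.items()}
        assert mean_at(shifted) == pytest.approx(mean_at(traits) + 3.7, abs=1e-8)
        # equivalently: per-tip weights (root refit included) sum to 1
        base = mean_at(traits)
        total = 0.0
        for l in tree.tip_labels:
            bumped = dict(traits)
            bumped[l] += 1.0
            total += mean_at(bumped) - base
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_se_grows_toward_root_on_ultrametric_tree(self):
        tree = simulate_tree(12, seed=51)
        assert tree.is_ultrametric(tol=1e-6)
        traits = simulate_traits(tree, "BM", sigma2=1.0, seed=52)
        fit = fit_model(tree, traits, "BM")
        # root estimate: MRCA of two tips on opposite sides of the root
        root_node = None
        import warnings as w

        i = tree.tip_labels[0]
        j = max(
            tree.tip_labels[1:],
            key=lambda l: -tree.mrca_depths[0, tree.tip_labels.index(l)],
        )
        with w.catch_warnings():
            w.simplefilter("ignore")
            se_root = reconstruct_ancestor(tree, traits, fit, (i, j)).se
            for a in tree.tip_labels:
                b = sister_species(tree, a)
                se_first = reconstruct_ancestor(tree, traits, fit, (a, b)).se
                assert se_root >= se_first - 1e-9

    def test_sister_species_on_known_topology(self):
        tree = Phylogeny.from_newick("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")
        assert sister_species(tree, "A") == "B"
        assert sister_species(tree, "C") in ("A", "B")
        assert sister_species(tree, "D") == "E"


class TestDivergence:
    def test_equal_distances_give_unit_factor(self):
        rep = divergence_report(("a", "b"), "channel", 2.0,
                                {"lower": 2.0, "mean": 2.0, "upper": 2.0})
        assert all(f == pytest.approx(1.0) for f in rep.factors.values())

    def test_zero_ancestral_distance_is_undefined(self):
        rep = divergence_report(("a", "b"), "channel", 2.0, {"mean": 0.0})
        assert rep.factors["mean"] is None

    def test_variant_vectors_applied_coordinatewise(self):
        ea = [AncestralEstimate(("a", "x"), "c1", mean=1.0, se=0.5),
              AncestralEstimate(("a", "x"), "c2", mean=-1.0, se=0.25)]
        eb = [AncestralEstimate(("b", "y"), "c1", mean=0.0, se=0.5),
              AncestralEstimate(("b", "y"), "c2", mean=0.0, se=0.25)]
        d_mean = ancestral_pair_distance(ea, eb, "mean")
        assert d_mean == pytest.approx(math.sqrt(1 + 1))
        # symmetric SEs shift both species alike, so lower == upper == mean here
        assert ancestral_pair_distance(ea, eb, "lower") == pytest.approx(d_mean)
        assert ancestral_pair_distance(ea, eb, "upper") == pytest.approx(d_mean)
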