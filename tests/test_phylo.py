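"""Distances, neighbour joining, bootstrap, conservation, consensus."""

import itertools

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctsdyn import phylo, synthetic as syn


def dendropy_path_lengths(newick):
    """Independent leaf-to-leaf path sums via dendropy."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1, t2 in itertools.combinations(tree.taxon_namespace, 2):
        out[tuple(sorted((t1.label, t2.label)))] = pdm.distance(t1, t2)
    return out


class TestPDistance:
    def test_identical_ungapped(self):
        assert phylo.p_distance("ACDE", "ACDE") == (0.0, 4)

    def test_pairwise_deletion(self):
        assert phylo.p_distance("AC-T", "AG-T") == (pytest.approx(1 / 3), 3)

    def test_ambiguity_removed(self):
        p, n = phylo.p_distance("AXCT", "AACT")
        assert n == 3 and p == 0.0

    def test_no_overlap_raises(self):
        with pytest.raises(phylo.NoComparableSitesError):
            phylo.p_distance("A-", "-A")


class TestPoissonGamma:
    def test_zero_p_is_zero_for_any_shape(self):
        for a in (0.5, 1.0, 10.0):
            assert phylo.poisson_gamma_distance(0.0, a) == 0.0

    def test_shape_one_analytic(self):
        assert phylo.poisson_gamma_distance(0.5, 1.0) == pytest.approx(1.0)

    def test_large_shape_recovers_log_correction(self):
        assert phylo.poisson_gamma_distance(0.5, 1e6) == pytest.approx(
            -np.log(0.5), rel=1e-5)

    def test_saturation_raises(self):
        with pytest.raises(phylo.SaturationError):
            phylo.poisson_gamma_distance(1.0, 1.0)

    @given(p=st.floats(0.01, 0.95), a=st.floats(0.2, 50.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_p_and_shape(self, p, a):
        d = phylo.poisson_gamma_distance
        assert d(p + 0.01, a) > d(p, a)
        assert d(p, a) > d(p, a * 1.5)  # decreasing in shape for p > 0


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> additive matrix
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 3],
                      [3, 0, 6, 4],
                      [5, 6, 0, 4],
                      [3, 4, 4, 0]], dtype=float)
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels, d))
        paths = tree.path_lengths()
        for i, j in itertools.combinations(range(4), 2):
            key = tuple(sorted((labels[i], labels[j])))
            assert paths[key] == pytest.approx(d[i, j], abs=1e-9)

    @pytest.mark.parametrize("n_taxa,seed", [(5, 0), (6, 1), (8, 2)])
    def test_additive_matrices_from_random_trees(self, n_taxa, seed):
        true = syn.random_tree(n_taxa, seed=seed)
        true_paths = true.path_lengths()
        labels = sorted(true.leaves)
        d = np.zeros((n_taxa, n_taxa))
        for i, j in itertools.combinations(range(n_taxa), 2):
            d[i, j] = d[j, i] = true_paths[(labels[i], labels[j])]
        nj = phylo.neighbor_joining(phylo.DistanceMatrix(labels, d))
        # cross-check path sums with the independent dendropy oracle
        oracle = dendropy_path_lengths(nj.newick())
        for key, val in true_paths.items():
            assert oracle[key] == pytest.approx(val, abs=1e-5)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(["a", "b", "c"], d))
        paths = tree.path_lengths()
        assert paths[("a", "b")] == pytest.approx(2)
        assert paths[("a", "c")] == pytest.approx(3)
        assert paths[("b", "c")] == pytest.approx(5)

    def test_label_order_invariance(self):
        rng = np.random.default_rng(5)
        true = syn.random_tree(6, seed=9)
        paths = true.path_lengths()
        labels = sorted(true.leaves)
        d = np.zeros((6, 6))
        for i, j in itertools.combinations(range(6), 2):
            d[i, j] = d[j, i] = paths[(labels[i], labels[j])]
        t1 = phylo.neighbor_joining(phylo.DistanceMatrix(labels, d))
        perm = rng.permutation(6)
        t2 = phylo.neighbor_joining(phylo.DistanceMatrix(
            [labels[k] for k in perm], d[np.ix_(perm, perm)]))
        assert t1.bipartitions() == t2.bipartitions()

    def test_agrees_with_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        true = syn.random_tree(7, seed=4)
        paths = true.path_lengths()
        labels = sorted(true.leaves)
        d = np.zeros((7, 7))
        for i, j in itertools.combinations(range(7), 2):
            d[i, j] = d[j, i] = paths[(labels[i], labels[j])]
        mine = phylo.neighbor_joining(phylo.DistanceMatrix(labels, d))
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        ref_parts = set()
        n = len(labels)
        anchor = min(labels)
        for node in ref.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 1 < len(below) < n - 1:
                ref_parts.add(below if anchor not in below
                              else frozenset(labels) - below)
        assert mine.bipartitions() == ref_parts

    def test_nonfinite_rejected(self):
        d = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.]])
        with pytest.raises(ValueError):
            phylo.neighbor_joining(phylo.DistanceMatrix(list("abc"), d))


@pytest.fixture(scope="module")
def clean_msa():
    tree = syn.random_tree(8, seed=3)
    msa, _ = syn.evolve_msa(tree, 1200, seed=3)
    return msa


class TestBootstrap:
    def test_divergent_treelike_data_all_supports_100(self, clean_msa):
        tree = phylo.bootstrap_support(clean_msa, replicates=25, seed=1)
        sups = [n.support for n in tree.root.postorder()
                if n.support is not None]
        assert sups and all(s == 100.0 for s in sups)

    def test_single_replicate_supports_binary(self, clean_msa):
        tree = phylo.bootstrap_support(clean_msa, replicates=1, seed=2)
        sups = {n.support for n in tree.root.postorder()
                if n.support is not None}
        assert sups <= {0.0, 100.0}

    def test_seed_determinism(self, clean_msa):
        t1 = phylo.bootstrap_support(clean_msa, replicates=10, seed=7)
        t2 = phylo.bootstrap_support(clean_msa, replicates=10, seed=7)
        assert t1.newick(with_support=True) == t2.newick(with_support=True)


class TestCountSubstitutions:
    def test_identical_sequences_zero(self):
        msa = phylo.Msa((("a", "ACDE"), ("b", "ACDE"), ("c", "ACDE")))
        assert phylo.count_substitutions(msa) == 0

    def test_pair_differing_at_three_columns(self):
        msa = phylo.Msa((("a", "ACDEF"), ("b", "AGDKY"), ("c", "ACDEF")))
        assert phylo.count_substitutions(msa) == 3

    def test_region_and_consensus_counter(self):
        msa = phylo.Msa((("a", "ACDEF"), ("b", "AGDKY"), ("c", "ACDEF")))
        assert phylo.count_substitutions(msa, region=(0, 2)) == 1
        assert phylo.count_substitutions(msa, method="consensus") == 3

    def test_empty_region_rejected(self):
        msa = phylo.Msa((("a", "ACDE"), ("b", "ACDE")))
        with pytest.raises(ValueError):
            phylo.count_substitutions(msa, region=(2, 2))


class TestConservationProfile:
    def test_normalization_and_rate_class_separation(self):
        tree = syn.random_tree(20, seed=7)
        msa, rates = syn.evolve_msa(tree, 300, tail_region=(250, 300),
                                    tail_factor=5.0, seed=7)
        prof = phylo.conservation_profile(msa, msa.ids[0])
        assert prof.scores.mean() == pytest.approx(0.0, abs=1e-6)
        assert prof.scores.std() == pytest.approx(1.0, abs=1e-6)
        # fast (tail) sites score higher than slow sites
        assert prof.scores[250:].mean() > prof.scores[:250].mean()

    def test_invariant_column_scores_lowest(self):
        tree = syn.random_tree(10, seed=2)
        msa, _ = syn.evolve_msa(tree, 200, seed=2)
        # splice an invariant block into the alignment
        arr = msa.to_array()
        arr[:, :10] = "A"
        msa2 = phylo.Msa(tuple(
            (i, "".join(row)) for i, row in zip(msa.ids, arr)))
        prof = phylo.conservation_profile(msa2, msa2.ids[0])
        assert prof.scores[:10].mean() < prof.scores[10:].mean()
        assert prof.raw_rates[:10].min() == prof.raw_rates.min()

    def test_flat_profile_raises(self):
        msa = phylo.Msa((("a", "ACDE"), ("b", "ACDE"), ("c", "ACDE")))
        with pytest.raises(phylo.FlatProfileError):
            phylo.conservation_profile(msa, "a")

    def test_missing_reference_raises(self):
        msa = phylo.Msa((("a", "ACDE"), ("b", "ACDE"), ("c", "ACDF")))
        with pytest.raises(KeyError):
            phylo.conservation_profile(msa, "zz")


class TestConsensus:
    def test_identical_sequences(self):
        msa = phylo.Msa((("a", "ACDE"), ("b", "ACDE")))
        assert phylo.consensus(msa) == "ACDE"

    def test_plurality_threshold(self):
        msa = phylo.Msa((("a", "A"), ("b", "A"), ("c", "G")))
        assert phylo.consensus(msa, plurality=0.5) == "A"
        msa2 = phylo.Msa((("a", "A"), ("b", "G")))
        assert phylo.consensus(msa2, plurality=0.6) == "x"


class TestCtsVsFullLengthDivergence:
    def test_elevated_tail_rate_raises_cts_distances(self):
        wins = 0
        for seed in range(20):
            tree = syn.random_tree(10, seed=seed)
            msa, _ = syn.evolve_msa(tree, 260, tail_region=(200, 260),
                                    tail_factor=5.0, seed=seed)
            full = phylo.msa_distance_matrix(msa, cap=10.0)
            cts = phylo.msa_distance_matrix(msa, region=(200, 260), cap=10.0)
            iu = np.triu_indices(len(msa), 1)
            if cts.values[iu].mean() > full.values[iu].mean():
                wins += 1
        assert wins >= 19  # >= 95% of replicates
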