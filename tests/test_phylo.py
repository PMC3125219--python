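"""Distances, neighbor joining, pruning likelihood and quartet mapping."""

import itertools

import numpy as np
import pytest

from convphy.models import MLModelSpec, discrete_gamma_rates, eigen_reversible, hky_Q, jc_distance, jtt_model
from convphy.phylo import (
    DistanceMatrix,
    bootstrap_support,
    distance_matrix,
    f84_distance,
    likelihood_mapping,
    ml_branch_lengths,
    ml_pair_distance,
    neighbor_joining,
    nj_tree,
    tree_loglik,
)
from convphy.seqio import Alignment, SequenceRecord
from convphy.trees import Tree, neighbor_joining as nj_core, random_additive_tree, tree_distance_matrix
from tests.conftest import TREE4, small_simulation


def _uniform_pair(n_per_base=300, ts_per_base=10, tv_per_base=20):
    """A sequence pair with uniform composition and controlled changes."""
    bases = "ACGT"
    partner_ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
    partner_tv = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    a, b = [], []
    for base in bases:
        for k in range(n_per_base):
            a.append(base)
            if k < ts_per_base:
                b.append(partner_ts[base])
            elif k < ts_per_base + tv_per_base:
                b.append(partner_tv[base][k % 2])
            else:
                b.append(base)
    return "".join(a), "".join(b)


class TestF84:
    def test_identical(self):
        assert f84_distance("ACGTACGT", "ACGTACGT") == (0.0, 0.0, 0.0)

    def test_jukes_cantor_limit(self):
        # uniform composition with transitions at 1/3 of all changes reduces
        # F84 to the Jukes-Cantor closed form
        a, b = _uniform_pair(300, 10, 20)
        d, s, v = f84_distance(a, b)
        p = s + v
        assert s == pytest.approx(40 / 1200)
        assert d == pytest.approx(jc_distance(p), rel=1e-9)

    def test_saturation_flagged(self):
        a = "A" * 40 + "C" * 40 + "G" * 40 + "T" * 40
        b = "G" * 40 + "T" * 40 + "A" * 40 + "C" * 40  # all transitions
        with pytest.warns(UserWarning, match="saturated"):
            d, s, v = f84_distance(a, b)
        assert np.isinf(d)


class TestMLPairDistance:
    def test_identical_is_zero(self):
        spec = MLModelSpec(model="HKY85", kappa=2.0)
        assert ml_pair_distance("ACGTACGT", "ACGTACGT", spec) == 0.0

    def test_kappa_one_equal_frequencies_matches_jc(self):
        a, b = _uniform_pair(300, 10, 20)
        spec = MLModelSpec(model="HKY85", kappa=1.0, frequencies=np.full(4, 0.25))
        d = ml_pair_distance(a, b, spec)
        assert d == pytest.approx(jc_distance(0.1), abs=1e-6)

    def test_simulation_recovery(self):
        # two sequences separated by a known expected divergence
        aln, _ = small_simulation(seed=7, n_codons=3000, tree="(x:60,y:60);",
                                  rate=0.002)
        from convphy.simulate import OmegaClasses, SimConfig, simulate_gene_family

        cfg = SimConfig(species_tree="(x:60,y:60);", n_codons=4000, mutation_rate=0.002,
                        omega_classes=OmegaClasses((1.0,), (1.0,)), kappa=4.0, seed=7)
        aln, _ = simulate_gene_family(cfg)
        spec = MLModelSpec(model="HKY85", kappa=4.0)
        d = ml_pair_distance(aln.records[0], aln.records[1], spec)
        # 2 * 60 My * 0.002 subs/codon = 0.24/codon = 0.08/nt expected
        assert 0.06 < d < 0.10


class TestNeighborJoining:
    def test_exact_on_additive_matrix(self):
        # ((a:1,b:2):1,(c:3,d:4)) with internal branch 1
        ids = ["a", "b", "c", "d"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 0, 0]], dtype=float
        )
        d[2, 3] = d[3, 2] = 7.0
        tree = nj_core(ids, d)
        assert np.allclose(tree_distance_matrix(tree, ids), d)
        assert frozenset(["a", "b"]) in tree.bipartitions() or frozenset(["c", "d"]) in tree.bipartitions()

    def test_two_taxa(self):
        tree = nj_core(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert {n.name for n in tree.leaves()} == {"a", "b"}
        assert tree.total_length() == pytest.approx(2.0)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            nj_core(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_random_additive_property(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            _, names, dmat = random_additive_tree(n, rng)
            rec = nj_core(names, dmat)
            assert np.allclose(tree_distance_matrix(rec, names), dmat, atol=1e-8)

    def test_matches_scikit_bio(self):
        """Independent oracle: scikit-bio's NJ yields the same topology."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        _, names, dmat = random_additive_tree(6, rng)
        ours = nj_core(names, dmat)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(dmat, names))
        their_splits = set()
        all_names = frozenset(names)
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(names) - 1:
                their_splits.add(min(side, all_names - side, key=lambda s: (len(s), sorted(s))))
        assert ours.bipartitions() == their_splits

    def test_ultrametric_matches_upgma_topology(self):
        # on an ultrametric matrix NJ recovers the UPGMA (average-linkage) tree
        from scipy.cluster.hierarchy import average, to_tree
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(3)
        names = list("abcde")
        # build ultrametric distances from a random clock tree
        from convphy.simulate import build_gene_tree, SimConfig

        tree = Tree.from_newick("(((a:10,b:10):15,c:25):10,(d:20,e:20):15);")
        d = tree_distance_matrix(tree, names)
        rec = nj_core(names, d)
        link = average(squareform(d))
        root, _ = to_tree(link, rd=True)

        def splits(node, acc):
            if node.is_leaf():
                return {names[node.id]}
            left = splits(node.get_left(), acc)
            right = splits(node.get_right(), acc)
            s = left | right
            if 1 < len(s) < len(names) - 1:
                acc.add(min(frozenset(s), frozenset(names) - s, key=lambda x: (len(x), sorted(x))))
            return s

        upgma_splits = set()
        splits(root, upgma_splits)
        assert rec.bipartitions() == upgma_splits

    def test_saturated_taxon_dropped_with_warning(self):
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = 0.5
        d[0, 2] = d[2, 0] = 0.4
        d[1, 2] = d[2, 1] = 0.3
        for k in range(3):
            d[k, 3] = d[3, k] = np.inf
        dm = DistanceMatrix(list("abcd"), d)
        with pytest.warns(UserWarning, match="saturated"):
            tree = neighbor_joining(dm)
        assert set(tree.leaf_names) == {"a", "b", "c"}


def brute_force_lnl(tree, alignment, spec):
    """Sum over all internal-node state assignments (oracle)."""
    from convphy.likelihood import compress_patterns
    from convphy.models import eigen_reversible

    pi = spec.frequencies
    eig = eigen_reversible(spec.base_matrix(pi), pi)
    tarr = tree.to_arrays(alignment.ids)
    codes = alignment.codes()
    S = spec.n_states
    internal = tarr.postorder_internal
    total = 0.0
    for col in codes.T:
        site_l = 0.0
        for assign in itertools.product(range(S), repeat=len(internal)):
            amap = dict(zip(internal, assign))
            prob = pi[amap[tarr.root]]
            for k in range(tarr.n_nodes):
                p = tarr.parent[k]
                if p == -1:
                    continue
                state = col[k] if k < tarr.n_leaves else amap[k]
                P = eig.transition_matrices(np.array([tarr.lengths[k]]))[0]
                prob *= P[amap[p], state]
            site_l += prob
        total += np.log(site_l)
    return total


class TestMLBranchLengths:
    def test_matches_enumeration_oracle(self):
        aln = Alignment([SequenceRecord("a", "AC"), SequenceRecord("b", "AG"),
                         SequenceRecord("c", "CC")])
        tree = Tree.from_newick("(a:0.2,b:0.4,c:0.3);")
        spec = MLModelSpec(model="HKY85", kappa=2.0, n_rate_classes=1,
                           frequencies=np.full(4, 0.25))
        lnl = tree_loglik(tree, aln, spec)
        assert lnl == pytest.approx(brute_force_lnl(tree, aln, spec), abs=1e-8)

    def test_duplicate_column_doubles_contribution(self):
        a1 = Alignment([SequenceRecord("a", "AC"), SequenceRecord("b", "AG"),
                        SequenceRecord("c", "CC")])
        a2 = Alignment([SequenceRecord("a", "ACAC"), SequenceRecord("b", "AGAG"),
                        SequenceRecord("c", "CCCC")])
        tree = Tree.from_newick("(a:0.2,b:0.4,c:0.3);")
        spec = MLModelSpec(n_rate_classes=1, frequencies=np.full(4, 0.25))
        assert tree_loglik(tree, a2, spec) == pytest.approx(2 * tree_loglik(tree, a1, spec), abs=1e-9)

    def test_likelihood_invariant_to_rerooting(self):
        aln, _ = small_simulation(seed=9, n_codons=60)
        spec = MLModelSpec(n_rate_classes=1)
        t1 = Tree.from_newick("((a:0.05,b:0.07):0.02,(c:0.04,d:0.06):0.03);")
        # same unrooted tree written with a different trifurcating root
        t2 = Tree.from_newick("(a:0.05,b:0.07,(c:0.04,d:0.06):0.05);")
        spec = MLModelSpec(n_rate_classes=1, frequencies=np.full(4, 0.25))
        assert tree_loglik(t1, aln, spec) == pytest.approx(tree_loglik(t2, aln, spec), abs=1e-6)

    def test_alpha_recovery_from_simulation(self):
        # rate heterogeneity across sites emerges from mixed omega classes;
        # here we check the optimizer moves alpha off its start and improves lnL
        aln, _ = small_simulation(seed=10, n_codons=400)
        tree = nj_tree(aln, "f84")
        fit0 = ml_branch_lengths(tree, aln, MLModelSpec(n_rate_classes=1), estimate=("branches",))
        fit = ml_branch_lengths(tree, aln, MLModelSpec(n_rate_classes=4))
        assert fit.lnl >= fit0.lnl - 1e-6

    def test_zero_length_alignment_rejected(self):
        with pytest.raises(Exception):
            aln = Alignment([SequenceRecord("a", ""), SequenceRecord("b", "")])


class TestBootstrap:
    def test_identical_clades_get_full_support(self):
        block_a = "AACCGGTT" * 25
        block_b = "AGCCGATT" * 25  # two transitions per 8-column block
        aln = Alignment(
            [
                SequenceRecord("a1", block_a),
                SequenceRecord("a2", block_a),
                SequenceRecord("b1", block_b),
                SequenceRecord("b2", block_b),
            ]
        )
        tree, support = bootstrap_support(
            aln, lambda a: nj_tree(a, "f84"), replicates=100, seed=0
        )
        assert support[frozenset(["a1", "a2"])] == 100

    def test_too_few_replicates_rejected(self, toy_alignment):
        with pytest.raises(ValueError, match="100"):
            bootstrap_support(toy_alignment, lambda a: nj_tree(a), replicates=10)

    def test_support_grows_with_alignment_length(self):
        supports = []
        for n_codons in (80, 800):
            aln, _ = small_simulation(seed=11, n_codons=n_codons)
            _, support = bootstrap_support(
                aln, lambda a: nj_tree(a, "f84"), replicates=100, seed=1
            )
            key = frozenset(["a", "b"])
            supports.append(support.get(key, 0))
        assert supports[1] >= supports[0]


class TestLikelihoodMapping:
    def test_resolved_data_maps_to_corners(self):
        aln, _ = small_simulation(seed=12, n_codons=500)
        res = likelihood_mapping(aln, MLModelSpec(n_rate_classes=1), n_quartets=1, seed=0)
        assert res.resolved > 0.95
        assert sum(res.regions.values()) == pytest.approx(1.0)

    def test_star_data_unresolved(self):
        # identical sequences carry no quartet signal at all
        aln = Alignment([SequenceRecord(n, "ACGTACGTACGT") for n in "abcd"])
        res = likelihood_mapping(aln, MLModelSpec(n_rate_classes=1), n_quartets=1, seed=0)
        assert res.resolved < 0.5

    def test_needs_four_sequences(self, toy_alignment):
        with pytest.raises(ValueError, match=">= 4"):
            likelihood_mapping(toy_alignment, MLModelSpec())


class TestModels:
    def test_discrete_gamma_mean_one(self):
        for alpha in (0.2, 1.0, 5.0):
            rates = discrete_gamma_rates(alpha, 4)
            assert rates.mean() == pytest.approx(1.0)
            assert np.all(np.diff(rates) > 0)

    def test_jtt_matrix_is_reversible_and_normalized(self):
        Q, pi = jtt_model()
        assert pi.sum() == pytest.approx(1.0)
        flux = pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-12)
        assert -np.sum(pi * np.diag(Q)) == pytest.approx(1.0)

    def test_hky_stationary_distribution(self):
        pi = np.array([0.4, 0.3, 0.2, 0.1])
        eig = eigen_reversible(hky_Q(3.0, pi), pi)
        P = eig.transition_matrices(np.array([500.0]))[0]
        assert np.allclose(P, np.tile(pi, (4, 1)), atol=1e-8)
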