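"""GY94 machinery, site-model fits, LRTs and site identification."""

import numpy as np
import pytest
from scipy.linalg import expm

from convphy.codon import (
    CODON_INDEX,
    CodonModelSpec,
    N_CODONS,
    SENSE_CODONS,
    beta_class_omegas,
    codon_Q_matrix,
    fit_site_model,
    lrt,
    mixture_classes,
    positively_selected_sites,
    site_mixture_lnl,
)
from convphy.phylo import nj_tree
from convphy.seqio import CodonAlignment, SequenceRecord
from convphy.simulate import OmegaClasses, SimConfig, simulate_gene_family
from convphy.trees import Tree
from tests.conftest import TREE8, small_simulation


@pytest.fixture(scope="module")
def random_pi():
    return np.random.default_rng(0).dirichlet(np.ones(N_CODONS))


class TestQMatrix:
    def test_omega_zero_kills_nonsynonymous_rates(self, random_pi):
        from convphy.codon import CODON_AA

        Q = codon_Q_matrix(CodonModelSpec(kappa=2.0, pi=random_pi), 0.0, normalized=False)
        for i in range(N_CODONS):
            for j in range(N_CODONS):
                if i != j and CODON_AA[i] != CODON_AA[j]:
                    assert Q[i, j] == 0.0

    def test_detailed_balance(self, random_pi):
        Q = codon_Q_matrix(CodonModelSpec(kappa=3.0, pi=random_pi), 0.7)
        flux = random_pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-14)

    def test_stationary_distribution(self, random_pi):
        Q = codon_Q_matrix(CodonModelSpec(kappa=3.0, pi=random_pi), 0.7)
        P = expm(Q * 300.0)
        assert np.allclose(P, np.tile(random_pi, (N_CODONS, 1)), atol=1e-8)

    def test_multi_nucleotide_changes_forbidden(self, random_pi):
        Q = codon_Q_matrix(CodonModelSpec(pi=random_pi), 1.0, normalized=False)
        i, j = CODON_INDEX["ATG"], CODON_INDEX["TAC"]
        assert Q[i, j] == 0.0

    def test_negative_omega_rejected(self, random_pi):
        with pytest.raises(ValueError):
            codon_Q_matrix(CodonModelSpec(pi=random_pi), -0.1)


class TestMixtureLikelihood:
    def test_matches_enumeration_oracle(self):
        """Pruning equals brute-force summation over root states (M0-like
        single-class and a 2-class mixture)."""
        aln = CodonAlignment(
            [SequenceRecord("a", "ATGAAA"), SequenceRecord("b", "ATGAAG"),
             SequenceRecord("c", "CTGAAA")]
        )
        tree = Tree.from_newick("(a:0.2,b:0.3,c:0.5);")
        spec = CodonModelSpec(kappa=2.0).resolve(aln)
        weights, omegas = np.array([0.6, 0.4]), np.array([0.2, 3.0])
        lnl = site_mixture_lnl(aln, tree, 2.0, weights, omegas, spec)
        classes = mixture_classes(2.0, spec.pi, weights, omegas)
        codes = aln.codon_codes(CODON_INDEX)
        total = 0.0
        for site in range(2):
            site_l = 0.0
            for cl in classes:
                Q = cl.eigen.U @ np.diag(cl.eigen.lam) @ cl.eigen.Uinv
                Ps = [expm(Q * (b * cl.rate)) for b in (0.2, 0.3, 0.5)]
                site_l += cl.weight * sum(
                    spec.pi[r] * Ps[0][r, codes[0, site]] * Ps[1][r, codes[1, site]]
                    * Ps[2][r, codes[2, site]]
                    for r in range(N_CODONS)
                )
            total += np.log(site_l)
        assert lnl == pytest.approx(total, abs=1e-8)

    def test_duplicating_alignment_doubles_lnl(self):
        aln, _ = small_simulation(seed=20, n_codons=30)
        doubled = CodonAlignment(
            [SequenceRecord(r.id, r.seq * 2) for r in aln.records]
        )
        tree = Tree.from_newick("((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05);")
        spec = CodonModelSpec().resolve(aln)
        w, om = np.array([1.0]), np.array([0.5])
        l1 = site_mixture_lnl(aln, tree, 2.0, w, om, spec)
        l2 = site_mixture_lnl(doubled, tree, 2.0, w, om, spec)
        assert l2 == pytest.approx(2 * l1, rel=1e-9)

    def test_beta_discretization_mean(self):
        for p, q in ((0.5, 1.5), (2.0, 2.0), (0.1, 0.2)):
            om = beta_class_omegas(p, q, 10)
            assert om.mean() == pytest.approx(p / (p + q), abs=1e-3)
            assert np.all((om > 0) & (om < 1))


@pytest.fixture(scope="module")
def sim300():
    cfg = SimConfig(species_tree=TREE8, n_codons=300, mutation_rate=0.004,
                    omega_classes=OmegaClasses((0.6, 0.4), (0.2, 1.0)), seed=21)
    return simulate_gene_family(cfg)


@pytest.fixture(scope="module")
def m0_fit(sim300):
    aln, _ = sim300
    return fit_site_model(aln, nj_tree(aln), "M0", branch_mode="full", n_starts=1)


class TestFits:
    def test_m0_omega_recovery(self):
        cfg = SimConfig(species_tree=TREE8, n_codons=500, mutation_rate=0.004,
                        omega_classes=OmegaClasses((1.0,), (0.2,)), seed=22)
        aln, _ = simulate_gene_family(cfg)
        fit = fit_site_model(aln, nj_tree(aln), "M0", branch_mode="full", n_starts=1)
        assert 0.15 <= fit.params["omega"] <= 0.26

    def test_m8a_omega_s_fixed_at_one(self, sim300, m0_fit):
        aln, _ = sim300
        fit = fit_site_model(aln, m0_fit.tree, "M8a", n_starts=1)
        assert fit.params["omega_s"] == 1.0
        assert fit.omegas[-1] == 1.0

    def test_nesting_inequalities(self, sim300, m0_fit):
        aln, _ = sim300
        fits = {
            m: fit_site_model(aln, m0_fit.tree, m, n_starts=1)
            for m in ("M1a", "M2a", "M7", "M8", "M8a")
        }
        assert fits["M2a"].lnl >= fits["M1a"].lnl - 1e-4
        assert fits["M8"].lnl >= fits["M7"].lnl - 1e-4
        assert fits["M8"].lnl >= fits["M8a"].lnl - 1e-4

    def test_proportions_sum_to_one(self, sim300, m0_fit):
        aln, _ = sim300
        fit = fit_site_model(aln, m0_fit.tree, "M2a", n_starts=1)
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_too_few_sequences_rejected(self):
        aln = CodonAlignment([SequenceRecord("a", "ATG"), SequenceRecord("b", "ATG")])
        with pytest.raises(ValueError, match=">= 3"):
            fit_site_model(aln, Tree.from_newick("(a:1,b:1);"), "M0")


class TestLRT:
    def test_identical_fits_give_zero(self, toy_codon_alignment):
        tree = Tree.from_newick("(a:0.1,b:0.1,c:0.1);")
        f1 = fit_site_model(toy_codon_alignment, tree, "M1a", n_starts=1)
        res = lrt(f1, _fake_alt(f1, "M2a"))
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_non_nested_pair_rejected(self, toy_codon_alignment):
        tree = Tree.from_newick("(a:0.1,b:0.1,c:0.1);")
        f1 = fit_site_model(toy_codon_alignment, tree, "M1a", n_starts=1)
        f7 = _fake_alt(f1, "M7")
        with pytest.raises(ValueError, match="nested"):
            lrt(f1, f7)

    def test_boundary_pvalue_reported_for_m8a(self, toy_codon_alignment):
        tree = Tree.from_newick("(a:0.1,b:0.1,c:0.1);")
        f = fit_site_model(toy_codon_alignment, tree, "M8a", n_starts=1)
        alt = _fake_alt(f, "M8")
        alt.lnl = f.lnl + 2.0
        res = lrt(f, alt)
        from scipy.stats import chi2

        assert res.boundary
        assert res.boundary_pvalue == pytest.approx(0.5 * chi2.sf(res.statistic, 1))


def _fake_alt(fit, model):
    import copy

    alt = copy.copy(fit)
    alt.model = model
    return alt


class TestSelectedSites:
    def test_m1a_fit_yields_empty_list(self, toy_codon_alignment):
        tree = Tree.from_newick("(a:0.1,b:0.1,c:0.1);")
        fit = fit_site_model(toy_codon_alignment, tree, "M1a", n_starts=1)
        tab = positively_selected_sites(fit, toy_codon_alignment, "a")
        assert tab.selected(0.9) == []

    def test_reference_position_labels(self):
        # gapped reference: labels follow ungapped residue numbering
        aln = CodonAlignment(
            [
                SequenceRecord("ref", "ATG---AAACAA"),
                SequenceRecord("x", "ATGCCCAAACGA"),
                SequenceRecord("y", "ATGCCAAAGCAA"),
            ]
        )
        tree = Tree.from_newick("(ref:0.1,x:0.1,y:0.1);")
        fit = fit_site_model(aln, tree, "M2a", n_starts=1)
        tab = positively_selected_sites(fit, aln, "ref", threshold=-1.0)
        labels = [r.label for r in tab.rows]
        assert labels[0] == "1M"
        assert labels[1] == "aln2"  # reference gapped at column 2
        assert labels[2] == "2K"
        # posteriors sum to one per site
        assert np.allclose(tab.posteriors.sum(axis=0), 1.0)

    def test_missing_reference_rejected(self, toy_codon_alignment):
        tree = Tree.from_newick("(a:0.1,b:0.1,c:0.1);")
        fit = fit_site_model(toy_codon_alignment, tree, "M2a", n_starts=1)
        with pytest.raises(KeyError):
            positively_selected_sites(fit, toy_codon_alignment, "nope")
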