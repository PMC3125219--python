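"""Sawyer-style fragment detection, run-tail p-values and bootscan."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from convphy.geneconv import (
    ConversionFragment,
    _longest_run_tail,
    bcka_pvalue,
    bootscan,
    call_converted_tracts,
    find_polymorphic_sites,
    global_inner_fragments,
    permutation_pvalue,
    scan_group,
)
from convphy.seqio import Alignment, SequenceRecord
from convphy.simulate import ConversionEvent, OmegaClasses, SimConfig, simulate_gene_family
from tests.conftest import TREE8


def aln_of(*seqs):
    return Alignment([SequenceRecord(f"s{k}", s) for k, s in enumerate(seqs)])


class TestPolymorphicSites:
    def test_identical_sequences_give_empty_table(self):
        assert len(find_polymorphic_sites(aln_of("ACGT", "ACGT"))) == 0

    def test_hand_enumeration(self):
        table = find_polymorphic_sites(aln_of("AAAA", "AATA"))
        assert list(table.columns + 1) == [3]

    def test_gap_and_n_columns_excluded(self):
        table = find_polymorphic_sites(aln_of("A-GTN", "ACCTA"))
        assert list(table.columns + 1) == [3]

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            find_polymorphic_sites(aln_of("ACGT"))

    def test_at_least_max_pair_differences(self):
        aln, _ = simulate_gene_family(
            SimConfig(species_tree=TREE8, n_codons=100, mutation_rate=0.005, seed=1)
        )
        table = find_polymorphic_sites(aln)
        codes = aln.codes()
        max_dif = max(
            int(((codes[i] != codes[j]) & (codes[i] >= 0) & (codes[j] >= 0)).sum())
            for i, j in itertools.combinations(range(len(aln)), 2)
        )
        assert len(table) >= max_dif


class TestFragments:
    def test_pair_differing_everywhere_gives_no_fragment(self):
        aln = aln_of("AAAA", "CCCC", "AACC")
        assert global_inner_fragments(aln, ("s0", "s1")) == []

    def test_identical_pair_is_uninformative(self):
        aln = aln_of("AAAA", "AAAA", "CCCC")
        assert global_inner_fragments(aln, ("s0", "s1")) == []

    def test_run_boundaries_at_outermost_matching_columns(self):
        # polymorphic columns: all; pair matches at columns 2-4 only
        aln = aln_of("ACGTA", "TCGTC", "CAACG")
        frags = global_inner_fragments(aln, ("s0", "s1"))
        assert frags[0].begin == 2 and frags[0].end == 4
        assert frags[0].n_poly == 3 and frags[0].tot_difs == 2

    def test_invariant_to_permuting_monomorphic_columns(self):
        a = "ACGTACGTAC"
        b = "ACGTACGAAC"
        c = "AGGTACGAAC"
        aln1 = aln_of(a, b, c)
        # shuffle only the monomorphic columns
        poly = set(find_polymorphic_sites(aln1).columns.tolist())
        mono = [k for k in range(10) if k not in poly]
        perm = mono[::-1]
        remap = list(range(10))
        for src, dst in zip(mono, perm):
            remap[dst] = src
        aln2 = aln_of(*("".join(s[k] for k in remap) for s in (a, b, c)))
        f1 = global_inner_fragments(aln1, ("s0", "s1"))
        f2 = global_inner_fragments(aln2, ("s0", "s1"))
        assert [(f.n_poly, f.score) for f in f1] == [(f.n_poly, f.score) for f in f2]


class TestRunTailPvalue:
    @pytest.mark.parametrize("m,k,L", [(8, 3, 3), (9, 2, 4), (6, 6, 2), (10, 2, 5)])
    def test_matches_exhaustive_enumeration(self, m, k, L):
        """Exact tail equals brute-force enumeration over all arrangements."""
        n = m + k
        count = hits = 0
        for mism in itertools.combinations(range(n), k):
            arr = np.ones(n, dtype=bool)
            arr[list(mism)] = False
            best = cur = 0
            for x in arr:
                cur = cur + 1 if x else 0
                best = max(best, cur)
            count += 1
            hits += best >= L
        assert _longest_run_tail(m, k, L) == pytest.approx(hits / count, rel=1e-12)

    def test_longer_fragment_smaller_pvalue(self):
        f1 = ConversionFragment(("a", "b"), 1, 10, 5.0, n_poly=10, n_dif=0, tot_difs=50)
        f2 = ConversionFragment(("a", "b"), 1, 20, 9.0, n_poly=20, n_dif=0, tot_difs=50)
        p1 = bcka_pvalue(f1, 1, 300)
        p2 = bcka_pvalue(f2, 1, 300)
        assert p2 < p1

    def test_degenerate_scan_rejected(self):
        f = ConversionFragment(("a", "b"), 1, 5, 1.0, n_poly=3, n_dif=0, tot_difs=2)
        with pytest.raises(ValueError, match="degenerate"):
            bcka_pvalue(f, 1, 0)


class TestPermutationPvalue:
    def test_fragment_spanning_everything_is_maximally_significant(self):
        # strong run: pair matches at a long block, differs elsewhere
        a = "A" * 40 + "C" * 10
        b = "A" * 40 + "G" * 10
        c = "T" * 50
        aln = aln_of(a, b, c)
        frags = global_inner_fragments(aln, ("s0", "s1"))
        p = permutation_pvalue(aln, ("s0", "s1"), frags[0], replicates=500, seed=1)
        assert p < 0.02

    def test_replicate_floor(self):
        with pytest.raises(ValueError, match=">= 100"):
            permutation_pvalue(aln_of("AC", "AG", "CC"), ("s0", "s1"), None, replicates=0)

    def test_deterministic_given_seed(self):
        aln = aln_of("ACGTACAA", "ACGTACGG", "TTTTTTTT")
        f = global_inner_fragments(aln, ("s0", "s1"))[0]
        p1 = permutation_pvalue(aln, ("s0", "s1"), f, 200, seed=3)
        p2 = permutation_pvalue(aln, ("s0", "s1"), f, 200, seed=3)
        assert p1 == p2

    def test_rank_agreement_with_analytic_tail(self):
        """sim_p and bcka_p order fragments the same way (Spearman > 0.9)."""
        sims, kas = [], []
        for rep in range(50):
            cfg = SimConfig(
                species_tree=TREE8, n_codons=120, mutation_rate=0.005,
                conversion_events=(
                    ConversionEvent("aA", "aB", 1 + 30 * (rep % 4), 150 + 30 * (rep % 4), 10.0),
                ),
                duplication_time=359.0, seed=rep,
            )
            aln, _ = simulate_gene_family(cfg)
            scan = scan_group(aln.subset(["aA", "aB", "bA", "bB"]),
                              pairs=[("aA", "aB")], replicates=2000, seed=rep)
            for f in scan.fragments[:4]:
                sims.append(f.sim_p)
                kas.append(f.bcka_p)
        rho, _ = spearmanr(sims, kas)
        assert rho > 0.9


class TestScanAndTracts:
    def test_tract_call_covers_simulated_conversion(self):
        cfg = SimConfig(
            species_tree=TREE8, n_codons=600, mutation_rate=0.0065,
            duplication_time=359.0,
            omega_classes=OmegaClasses((0.6, 0.4), (0.1, 0.6)),
            conversion_events=(ConversionEvent("aA", "aB", 901, 1800, 8.0),),
            seed=5,
        )
        aln, truth = simulate_gene_family(cfg)
        scan = scan_group(aln, pairs=[("aA", "aB")], sim_p=False)
        tracts = call_converted_tracts(scan, ("aA", "aB"))
        tb, te = tracts[0]
        cb, ce = truth.conversions[0].start, truth.conversions[0].end
        inter = max(0, min(te, ce) - max(tb, cb) + 1)
        union = (te - tb + 1) + (ce - cb + 1) - inter
        assert inter / union >= 0.8


class TestBootscan:
    def test_three_sequences_rejected(self):
        aln = aln_of("ACGTACGT", "ACGTACGA", "ACTTACGA")
        with pytest.raises(ValueError, match=">= 4"):
            bootscan(aln, "s0", window=4, step=2, replicates=10)

    def test_window_longer_than_alignment_rejected(self):
        aln = aln_of("ACGTACGT", "ACGTACGA", "ACTTACGA", "GGGGACGA")
        with pytest.raises(ValueError, match="window"):
            bootscan(aln, "s0", window=100)

    def test_identical_partner_gets_full_support(self):
        rng = np.random.default_rng(1)
        base = "".join(rng.choice(list("ACGT"), size=300))
        far1 = "".join(rng.choice(list("ACGT"), size=300))
        far2 = "".join(rng.choice(list("ACGT"), size=300))
        aln = aln_of(base, base, far1, far2)
        prof = bootscan(aln, "s0", window=200, step=50, replicates=50, seed=2)
        k = prof.references.index("s1")
        assert prof.support[:, k].min() > 0.9

    def test_partner_switch_recovers_tract_boundary(self):
        cfg = SimConfig(
            species_tree="((a:40,b:40):60,(c:45,d:45):55);", n_codons=700,
            mutation_rate=0.0065, duplication_time=359.0,
            conversion_events=(ConversionEvent("aA", "aB", 1051, 2100, 5.0),),
            seed=3,
        )
        aln, truth = simulate_gene_family(cfg)
        grp = aln.subset(["aA", "aB", "bA", "bB"])
        prof = bootscan(grp, "aA", window=200, step=20, replicates=100, seed=0)
        kb = prof.references.index("aB")
        inside = prof.support[prof.centers > 1200, kb].mean()
        outside = prof.support[prof.centers < 900, kb].mean()
        assert inside > 0.8 and outside < 0.2
        # the switch happens within one window of the true boundary
        switch = next(c for c, ref in prof.partner_switches() if ref == "aB")
        assert abs(switch - (truth.conversions[0].start + 100)) <= 200 + 20
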