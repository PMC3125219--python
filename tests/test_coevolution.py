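"""Co-evolution scanning, compartment filtering and network export."""

import numpy as np
import pytest

from convphy.coevolution import (
    CompartmentAnnotation,
    CompartmentInterval,
    CoevolutionPair,
    UninformativeSite,
    blosum_matrix,
    coevolution_scan,
    compartment_filter,
    export_network,
    poisson_distance,
    site_substitution_vector,
)
from convphy.seqio import Alignment, SequenceRecord
from convphy.simulate import CoevolvingPair, SimConfig, simulate_gene_family
from tests.conftest import TREE12


def protein_aln(*rows, ids=None):
    ids = ids or [f"s{k}" for k in range(len(rows))]
    return Alignment([SequenceRecord(i, r, "protein") for i, r in zip(ids, rows)])


class TestSubstitutionVector:
    def test_invariant_site_rejected(self):
        aln = protein_aln("AAK", "AAR", "AAK", "AAR")
        with pytest.raises(UninformativeSite, match="invariant"):
            site_substitution_vector(aln, 1)

    def test_gap_site_rejected(self):
        aln = protein_aln("A-K", "AAR", "AAK", "AAR")
        with pytest.raises(UninformativeSite, match="gap"):
            site_substitution_vector(aln, 2)

    def test_two_state_equal_times_has_two_distinct_values(self):
        # A and I share the same BLOSUM80 self-score, so the site vector
        # takes exactly two values: same-residue pairs vs cross pairs
        aln = protein_aln("A", "A", "I", "I")
        times = np.ones(6)
        v = site_substitution_vector(aln, 1, time_correction=times)
        assert len(np.unique(np.round(v, 9))) == 2

    def test_time_scale_equivariance(self):
        aln = protein_aln("KAD", "KAE", "RAD", "RCE")
        t = np.array([1.0, 2.0, 1.5, 0.7, 1.1, 0.9])
        v1 = site_substitution_vector(aln, 1, time_correction=t)
        v2 = site_substitution_vector(aln, 1, time_correction=2 * t)
        assert np.allclose(v2, v1 / 2)

    def test_poisson_distance(self):
        assert poisson_distance("AAAA", "AAAA") == 0.0
        assert poisson_distance("AAAA", "AAAK") == pytest.approx(-np.log(0.75))


def coupled_simulation(seed, coupled=True):
    so = [1.0 if k % 2 else 0.3 for k in range(300)]
    pairs = []
    if coupled:
        for k in range(6):
            a, b = 40 * k + 5, 40 * k + 20
            so[a - 1] = so[b - 1] = 0.15
            pairs.append(CoevolvingPair(a, b, 1.0, "DEKRH"))
    cfg = SimConfig(species_tree=TREE12, n_codons=300, mutation_rate=0.025,
                    site_omega=so, coevolving_pairs=tuple(pairs), seed=seed)
    aln, truth = simulate_gene_family(cfg)
    return aln.to_protein(), pairs


class TestScan:
    def test_engineered_pairs_detected(self):
        prot, pairs = coupled_simulation(900)
        scan = coevolution_scan(prot, n_samplings=10000, alpha=0.001, seed=1)
        found = {frozenset((p.site_a, p.site_b)) for p in scan.pairs}
        truth = {frozenset((p.site_a, p.site_b)) for p in pairs}
        assert len(found & truth) >= 3
        best = max((p for p in scan.pairs if frozenset((p.site_a, p.site_b)) in truth),
                   key=lambda p: abs(p.r))
        assert abs(best.r) > 0.8

    def test_scan_deterministic(self):
        prot, _ = coupled_simulation(901)
        s1 = coevolution_scan(prot, n_samplings=2000, seed=5)
        s2 = coevolution_scan(prot, n_samplings=2000, seed=5)
        assert [(p.site_a, p.site_b, p.r, p.p) for p in s1.pairs] == [
            (p.site_a, p.site_b, p.r, p.p) for p in s2.pairs
        ]

    def test_constant_alignment_returns_empty(self):
        aln = protein_aln(*(["MKLV" * 10] * 6))
        scan = coevolution_scan(aln, n_samplings=500)
        assert scan.pairs == [] and scan.groups == []

    def test_too_few_sequence_pairs_rejected(self):
        aln = protein_aln("MK", "ML")
        with pytest.raises(ValueError, match=">= 4"):
            coevolution_scan(aln)

    def test_inter_mode_detects_cross_protein_coupling(self):
        # one simulated gene split into two "proteins" with cross-half pairs
        from convphy.seqio import SequenceRecord, Alignment
        from convphy.simulate import SimConfig, simulate_gene_family

        so = [1.0 if k % 2 else 0.3 for k in range(300)]
        pairs = []
        for k in range(6):
            a, b = 20 * k + 5, 150 + 20 * k + 5
            so[a - 1] = so[b - 1] = 0.15
            pairs.append(CoevolvingPair(a, b, 1.0, "DEKRH"))
        cfg = SimConfig(species_tree=TREE12, n_codons=300, mutation_rate=0.025,
                        site_omega=so, coevolving_pairs=tuple(pairs), seed=77)
        prot = simulate_gene_family(cfg)[0].to_protein()
        A = Alignment([SequenceRecord(r.id, r.seq[:150], "protein") for r in prot.records])
        B = Alignment([SequenceRecord(r.id, r.seq[150:], "protein") for r in prot.records])
        scan = coevolution_scan(A, B, n_samplings=5000, alpha=0.001, seed=3,
                                name_a="P1", name_b="P2")
        assert all(p.mode == "inter" for p in scan.pairs)
        assert all(1 <= p.site_a <= 150 and 1 <= p.site_b <= 150 for p in scan.pairs)

    def test_inter_mode_requires_pairing_or_matching_ids(self):
        a = protein_aln("MKDE", "MLDE", "MKDA", "MRDE", ids=list("wxyz"))
        b = protein_aln("QKDE", "QLDE", "QKDA", "QRDE", ids=list("stuv"))
        with pytest.raises(ValueError, match="paired_taxa"):
            coevolution_scan(a, b)

    def test_groups_are_connected_components(self):
        prot, _ = coupled_simulation(902)
        scan = coevolution_scan(prot, n_samplings=5000, seed=2)
        n_nodes = len({n for g in scan.groups for n in g})
        assert all(len(g) >= 2 for g in scan.groups)
        assert n_nodes >= 2 * 0 + sum(len(g) for g in scan.groups) // max(1, len(scan.groups))


class TestCompartments:
    @pytest.fixture
    def annotation(self):
        return CompartmentAnnotation(
            {
                "P": [
                    CompartmentInterval(1, 100, "extracellular", "LRR1"),
                    CompartmentInterval(101, 130, "transmembrane"),
                    CompartmentInterval(131, 300, "cytoplasmic", "TIR"),
                ]
            }
        )

    def _pair(self, a, b):
        return CoevolutionPair("P", "P", a, b, "K", "R", 0.9, 1e-4, "intra")

    def test_single_interval_summary(self, annotation):
        pairs, table = compartment_filter([self._pair(10, 20)], annotation)
        assert pairs[0].compartment_a == "extracellular"
        assert len(table) == 1 and table.iloc[0]["n_pairs"] == 1

    def test_transmembrane_pair_counted(self, annotation):
        pairs, table = compartment_filter([self._pair(110, 40)], annotation)
        assert pairs[0].compartment_a == "transmembrane"
        assert pairs[0].compartment_b == "extracellular"

    def test_unannotated_site_warns_unknown(self, annotation):
        with pytest.warns(UserWarning, match="without compartment"):
            pairs, _ = compartment_filter([self._pair(10, 999)], annotation)
        assert pairs[0].compartment_b == "unknown"

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            CompartmentAnnotation(
                {"P": [CompartmentInterval(1, 50, "extracellular"),
                       CompartmentInterval(40, 80, "transmembrane")]}
            )

    def test_tsv_round_trip(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("protein\tstart\tend\tcompartment\tdomain\nP\t1\t100\textracellular\tLRR1\n")
        ann = CompartmentAnnotation.from_tsv(p)
        assert ann.lookup("P", 50) == "extracellular"


class TestNetworkExport:
    def test_one_pair_two_nodes_one_edge(self, tmp_path):
        pair = CoevolutionPair("P", "P", 10, 20, "K", "R", 0.9, 1e-4, "intra")
        g = export_network([pair], tmp_path / "n.graphml", tmp_path / "n.sif")
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1
        assert (tmp_path / "n.graphml").exists()
        assert "coevolves" in (tmp_path / "n.sif").read_text()

    def test_hub_forms_star(self):
        pairs = [
            CoevolutionPair("P", "P", 1, k, "K", "R", 0.8, 1e-4, "intra")
            for k in range(2, 7)
        ]
        g = export_network(pairs)
        assert g.degree["P:1K"] == 5

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            export_network([])


def test_blosum_matrix_is_symmetric():
    B = blosum_matrix()
    assert B.shape == (20, 20)
    assert np.allclose(B, B.T)
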