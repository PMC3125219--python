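import numpy as np
import pytest

from convphy.seqio import Alignment, CodonAlignment, SequenceRecord
from convphy.simulate import OmegaClasses, SimConfig, simulate_gene_family

#: small ultrametric species trees used across the suite (ages in My)
TREE4 = "((a:30,b:30):20,(c:25,d:25):25);"
TREE6 = "((((a:20,b:20):30,c:50):25,(d:40,e:40):35):15,f:90);"
TREE8 = "(((a:25,b:25):25,(c:30,d:30):20):30,((e:35,f:35):20,(g:28,h:28):27):25);"
TREE12 = (
    "((((a:15,b:15):15,(c:20,d:20):10):20,((e:18,f:18):12,(g:10,h:10):20):20):30,"
    "((i:25,j:25):20,(k:30,l:30):15):35);"
)


@pytest.fixture
def toy_alignment():
    return Alignment(
        [
            SequenceRecord("a", "ACGTACGT"),
            SequenceRecord("b", "ACGTACGA"),
            SequenceRecord("c", "ACTTACGA"),
        ]
    )


@pytest.fixture
def toy_codon_alignment():
    return CodonAlignment(
        [
            SequenceRecord("a", "ATGAAACCC"),
            SequenceRecord("b", "ATGAAGCCC"),
            SequenceRecord("c", "CTGAAACCA"),
        ]
    )


def small_simulation(seed=0, n_codons=200, tree=TREE4, rate=0.004, omegas=None):
    oc = omegas or OmegaClasses((0.6, 0.4), (0.2, 1.0))
    cfg = SimConfig(
        species_tree=tree, n_codons=n_codons, mutation_rate=rate, omega_classes=oc, seed=seed
    )
    return simulate_gene_family(cfg)
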