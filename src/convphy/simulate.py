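"""Synthetic gene families with known duplication, conversion and selection.

The generator evolves codon sequences along a duplicated species tree by an
exact event-by-event (Gillespie) simulation of the GY94 process, so that
interval-restricted gene-conversion events can interrupt lineages at exact
times: at a conversion event the donor lineage's current tract overwrites
the acceptor's.  Per-site omega classes (including omega > 1 sites) and
branch-synchronous co-evolving site pairs give every downstream stage a
ground truth to recover.

Time is measured in millions of years (My); ``mutation_rate`` is the
expected number of substitutions per codon site per My at a neutral
(omega = 1) site, so a pair of paralogues separated for T My accumulates
about ``2 * T * mutation_rate`` neutral substitutions per codon.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np

from .codon import CODON_INDEX, N_CODONS, SENSE_CODONS, CODON_AA, CodonModelSpec, codon_Q_matrix
from .seqio import CodonAlignment, SequenceRecord
from .trees import Node, Tree


@dataclass(frozen=True)
class ConversionEvent:
    """Non-reciprocal transfer at ``time`` My: the donor lineage's columns
    ``start``..``end`` (1-based nucleotides, snapped outward to whole
    codons) overwrite the acceptor lineage.  Donor/acceptor name a leaf of
    the gene tree; at ``time`` the event applies to that leaf's ancestral
    lineage, so one event can convert a whole clade."""

    donor: str
    acceptor: str
    start: int
    end: int
    time: float


@dataclass(frozen=True)
class CoevolvingPair:
    """Amino-acid sites (1-based) whose substitutions are coupled.

    ``allowed_residues`` is the pair's residue repertoire: amino-acid
    changes at either site are redirected into this set, and when one site
    changes, the partner immediately substitutes to a random repertoire
    residue with probability ``coupling`` (on the same branch).
    """

    site_a: int
    site_b: int
    coupling: float
    allowed_residues: str = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class OmegaClasses:
    proportions: tuple[float, ...]
    omegas: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.proportions), 1.0):
            raise ValueError("omega class proportions must sum to 1")
        if any(o < 0 for o in self.omegas):
            raise ValueError("omega must be >= 0")


@dataclass
class SimConfig:
    """Full specification of one synthetic gene-family dataset."""

    species_tree: str  # newick, branch lengths in My, ultrametric
    n_codons: int
    mutation_rate: float  # neutral substitutions / codon site / My
    duplication_time: float | None = None
    kappa: float = 2.0
    codon_pi: Sequence[float] | None = None  # None = uniform over sense codons
    omega_classes: OmegaClasses = OmegaClasses((1.0,), (0.2,))
    site_omega: Sequence[float] | None = None  # explicit per-site override
    conversion_events: tuple[ConversionEvent, ...] = ()
    coevolving_pairs: tuple[CoevolvingPair, ...] = ()
    paralogue_suffixes: tuple[str, str] = ("A", "B")
    seed: int = 0

    # -- round-trippable plain-text form --------------------------------
    def to_json(self) -> str:
        d = asdict(self)
        d["codon_pi"] = None if self.codon_pi is None else list(self.codon_pi)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        d["omega_classes"] = OmegaClasses(
            tuple(d["omega_classes"]["proportions"]), tuple(d["omega_classes"]["omegas"])
        )
        d["conversion_events"] = tuple(ConversionEvent(**e) for e in d["conversion_events"])
        d["coevolving_pairs"] = tuple(CoevolvingPair(**p) for p in d["coevolving_pairs"])
        d["paralogue_suffixes"] = tuple(d["paralogue_suffixes"])
        return cls(**d)


@dataclass
class RealizedConversion:
    donor: str
    acceptor: str
    start: int  # 1-based nucleotide columns actually overwritten
    end: int
    time: float
    acceptor_leaves: tuple[str, ...]  # leaves that inherit the tract


@dataclass
class SimulationTruth:
    gene_tree: str  # newick with branch lengths in My
    node_ages: dict[str, float]  # frozenset-of-leaves key serialized as sorted "|"-joined
    duplication_time: float | None
    site_omega: np.ndarray
    conversions: list[RealizedConversion]
    coevolving_pairs: tuple[CoevolvingPair, ...]
    n_codons: int


# ---------------------------------------------------------------------------
# Gene-tree construction
# ---------------------------------------------------------------------------

def _node_ages(tree: Tree) -> None:
    for n in tree.postorder():
        if n.is_leaf:
            n.age = 0.0
        else:
            ages = [c.age + (c.length or 0.0) for c in n.children]
            if max(ages) - min(ages) > 1e-6:
                raise ValueError("species tree is not ultrametric")
            n.age = float(np.mean(ages))


def build_gene_tree(config: SimConfig) -> Tree:
    """Species tree, optionally duplicated at ``duplication_time``.

    The duplication must predate the species root (the tandem-family
    history modelled here); each leaf X becomes XA and XB.
    """
    species = Tree.from_newick(config.species_tree)
    _node_ages(species)
    if config.duplication_time is None:
        return species
    if config.duplication_time <= species.root.age:
        raise ValueError(
            f"duplication time {config.duplication_time} must predate the "
            f"species root age {species.root.age}"
        )
    root = Node()
    root.age = config.duplication_time
    for suffix in config.paralogue_suffixes:
        sub = species.copy()
        _node_ages(sub)
        for leaf in sub.leaves():
            leaf.name = f"{leaf.name}{suffix}"
        sub.root.length = config.duplication_time - sub.root.age
        root.add(sub.root)
    tree = Tree(root)
    _node_ages(tree)
    return tree


# ---------------------------------------------------------------------------
# Simulation core
# ---------------------------------------------------------------------------

class _Process:
    """Per-omega-class jump machinery, scaled to neutral flux."""

    def __init__(self, kappa: float, pi: np.ndarray, omegas: Sequence[float], rate: float):
        spec_template = CodonModelSpec(kappa=kappa, pi=pi)
        Q1 = codon_Q_matrix(spec_template, 1.0, normalized=False)
        neutral_flux = -float(np.sum(pi * np.diag(Q1)))
        self.exit_rate = []
        self.cum_target = []
        self.targets = np.arange(N_CODONS)
        for om in omegas:
            Q = codon_Q_matrix(spec_template, float(om), normalized=False) * (rate / neutral_flux)
            exit_r = -np.diag(Q).copy()
            P = Q.copy()
            np.fill_diagonal(P, 0.0)
            rowsum = P.sum(axis=1, keepdims=True)
            rowsum[rowsum == 0] = 1.0
            self.cum_target.append(np.cumsum(P / rowsum, axis=1))
            self.exit_rate.append(exit_r)
        self.pi = pi


def _resolve_site_omega(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(per-site class index, distinct omega values)."""
    if config.site_omega is not None:
        vals = np.asarray(config.site_omega, dtype=float)
        if len(vals) != config.n_codons:
            raise ValueError("site_omega length must equal n_codons")
        uniq = np.unique(vals)
        idx = np.searchsorted(uniq, vals)
        return idx, uniq
    oc = config.omega_classes
    idx = rng.choice(len(oc.omegas), size=config.n_codons, p=np.asarray(oc.proportions))
    return idx, np.asarray(oc.omegas, dtype=float)


def _evolve_segment(
    seq: np.ndarray,
    duration: float,
    site_class: np.ndarray,
    proc: _Process,
    rng: np.random.Generator,
    pair_map: dict[int, CoevolvingPair],
) -> None:
    """Evolve ``seq`` in place for ``duration`` My (exact jump simulation)."""
    if duration <= 0:
        return
    rates = np.array([proc.exit_rate[site_class[s]][seq[s]] for s in range(len(seq))])
    first = rng.exponential(1.0, size=len(seq)) / np.where(rates > 0, rates, 1e-300)
    def random_codon_for(aa_set: str) -> int:
        aa = aa_set[rng.integers(len(aa_set))]
        choices = [k for k in range(N_CODONS) if CODON_AA[k] == aa]
        return int(choices[rng.integers(len(choices))])

    for s in np.flatnonzero(first < duration):
        t = float(first[s])
        while t < duration:
            cls = site_class[s]
            cum = proc.cum_target[cls][seq[s]]
            new = int(np.searchsorted(cum, rng.random()))
            old_aa, new_aa = CODON_AA[seq[s]], CODON_AA[new]
            if s in pair_map and new_aa != old_aa and new_aa not in pair_map[s].allowed_residues:
                new = random_codon_for(pair_map[s].allowed_residues)  # repertoire
                new_aa = CODON_AA[new]
            seq[s] = new
            if old_aa != new_aa and s in pair_map:
                pair = pair_map[s]
                if pair.coupling > 0 and rng.random() < pair.coupling:
                    partner = pair.site_b - 1 if s == pair.site_a - 1 else pair.site_a - 1
                    seq[partner] = random_codon_for(pair.allowed_residues)
            r = proc.exit_rate[cls][seq[s]]
            if r <= 0:
                break
            t += float(rng.exponential(1.0) / r)


def _snap_codons(start: int, end: int, n_codons: int) -> tuple[int, int]:
    """1-based nucleotide interval -> 0-based codon slice bounds (snapped outward)."""
    c0 = (start - 1) // 3
    c1 = (end - 1) // 3
    if c0 < 0 or c1 >= n_codons:
        raise ValueError(f"conversion region {start}-{end} outside alignment")
    return c0, c1


def simulate_gene_family(config: SimConfig) -> tuple[CodonAlignment, SimulationTruth]:
    """Run the generator; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    tree = build_gene_tree(config)
    leaves = set(tree.leaf_names)

    # validate events against the tree before simulating
    for ev in config.conversion_events:
        for nm in (ev.donor, ev.acceptor):
            if nm not in leaves:
                raise ValueError(f"conversion names unknown leaf {nm!r}")
        if not 0 <= ev.time < tree.root.age:
            raise ValueError(f"conversion time {ev.time} outside tree depth")
        _snap_codons(ev.start, ev.end, config.n_codons)
    for p in config.coevolving_pairs:
        if not (1 <= p.site_a <= config.n_codons and 1 <= p.site_b <= config.n_codons):
            raise ValueError("co-evolving site outside sequence")
        if not 0 <= p.coupling <= 1:
            raise ValueError("coupling must be in [0, 1]")

    pi = (
        np.full(N_CODONS, 1.0 / N_CODONS)
        if config.codon_pi is None
        else np.asarray(config.codon_pi, dtype=float)
    )
    site_class, omegas = _resolve_site_omega(config, rng)
    proc = _Process(config.kappa, pi, omegas, config.mutation_rate)
    pair_map: dict[int, CoevolvingPair] = {}
    for p in config.coevolving_pairs:
        if p.coupling > 0:
            pair_map[p.site_a - 1] = p
            pair_map[p.site_b - 1] = p

    below: dict[int, frozenset[str]] = {}
    for n in tree.postorder():
        below[id(n)] = (
            frozenset([n.name]) if n.is_leaf else frozenset().union(*(below[id(c)] for c in n.children))
        )

    events: list[tuple[float, int, str, object]] = []
    for n in tree.postorder():
        if not n.is_leaf and n is not tree.root:
            events.append((n.age, 0, min(below[id(n)]), "branch", n))
    for k, ev in enumerate(config.conversion_events):
        events.append((ev.time, 1, f"{k:06d}", "conv", ev))
    # old -> young; conversions after branchings at equal times; ties
    # broken by a stable name so runs are reproducible across processes
    events.sort(key=lambda e: (-e[0], e[1], e[2]))

    root_seq = rng.choice(N_CODONS, size=config.n_codons, p=pi)
    live: dict[int, tuple[Node, np.ndarray, float]] = {}
    for c in tree.root.children:
        live[id(c)] = (c, root_seq.copy(), tree.root.age)

    def lineage_of(leaf: str, t: float) -> int:
        for key, (node, _, _) in live.items():
            if leaf in below[id(node)]:
                return key
        raise ValueError(f"no live lineage carries {leaf!r} at time {t}")

    realized: list[RealizedConversion] = []
    for t, _, _, kind, obj in events:
        if kind == "branch":
            node = obj
            key = id(node)
            node_, seq, last = live.pop(key)
            _evolve_segment(seq, last - t, site_class, proc, rng, pair_map)
            for c in node.children:
                live[id(c)] = (c, seq.copy(), t)
        else:
            ev = obj
            dk, ak = lineage_of(ev.donor, t), lineage_of(ev.acceptor, t)
            if dk == ak:
                raise ValueError(
                    f"conversion at {ev.time} My: donor and acceptor lineages "
                    f"have not yet diverged"
                )
            for key in {dk, ak}:
                node, seq, last = live[key]
                _evolve_segment(seq, last - t, site_class, proc, rng, pair_map)
                live[key] = (node, seq, t)
            c0, c1 = _snap_codons(ev.start, ev.end, config.n_codons)
            dnode, dseq, _ = live[dk]
            anode, aseq, _ = live[ak]
            aseq[c0 : c1 + 1] = dseq[c0 : c1 + 1]
            realized.append(
                RealizedConversion(
                    donor=ev.donor,
                    acceptor=ev.acceptor,
                    start=3 * c0 + 1,
                    end=3 * (c1 + 1),
                    time=ev.time,
                    acceptor_leaves=tuple(sorted(below[id(anode)])),
                )
            )

    records = []
    leaf_order = tree.leaf_names
    finished: dict[str, np.ndarray] = {}
    for node, seq, last in live.values():
        _evolve_segment(seq, last - 0.0, site_class, proc, rng, pair_map)
        if node.is_leaf:
            finished[node.name] = seq
        else:  # pragma: no cover - all branching events processed above
            raise RuntimeError("internal lineage left unresolved")
    for name in leaf_order:
        seq = finished[name]
        records.append(SequenceRecord(name, "".join(SENSE_CODONS[k] for k in seq), "dna"))
    alignment = CodonAlignment(records)

    ages = {
        "|".join(sorted(below[id(n)])): float(n.age)
        for n in tree.postorder()
        if not n.is_leaf
    }
    truth = SimulationTruth(
        gene_tree=tree.to_newick(),
        node_ages=ages,
        duplication_time=config.duplication_time,
        site_omega=omegas[site_class],
        conversions=realized,
        coevolving_pairs=config.coevolving_pairs,
        n_codons=config.n_codons,
    )
    return alignment, truth


def null_dataset(config: SimConfig) -> tuple[CodonAlignment, SimulationTruth]:
    """Same conditions with no conversion, no coupling, and all omega <= 1."""
    oc = config.omega_classes
    capped = OmegaClasses(oc.proportions, tuple(min(o, 1.0) for o in oc.omegas))
    site_omega = (
        None
        if config.site_omega is None
        else [min(o, 1.0) for o in config.site_omega]
    )
    null = replace(
        config,
        conversion_events=(),
        coevolving_pairs=(),
        omega_classes=capped,
        site_omega=site_omega,
    )
    return simulate_gene_family(null)


# ---------------------------------------------------------------------------
# The study-shaped preset
# ---------------------------------------------------------------------------

#: 4 birds + 4 mammals, ages in My (amniote split at 315 My)
SPECIES_TREE_8 = (
    "((((Ggal:40,Mgal:40):55,Apla:95):10,Tgut:105):210,"
    "((Hsap:29,Mmul:29):61,(Mmus:74,Rnor:74):16):225);"
)


def tlr_family_preset(seed: int = 0) -> SimConfig:
    """Conditions mirroring the inferred TLR1-family history: a duplication
    at 359 My (before the 310-325 My bird/mammal split), mostly purifying
    selection, and recent species-specific conversion tracts in the
    C-terminal third of an 800-codon gene.  The Hsap event at 44 My predates
    the Hsap/Mmul split and therefore converts the primate ancestor, as
    inferred for the primate TLR1/TLR6 pair."""
    tract = (1601, 2400)  # C-terminal third, nucleotide columns
    events = tuple(
        ConversionEvent(f"{sp}A", f"{sp}B", *tract, time=t)
        for sp, t in (
            ("Ggal", 15.0),
            ("Mgal", 8.0),
            ("Apla", 20.0),
            ("Tgut", 5.0),
            ("Hsap", 44.0),
            ("Mmus", 30.0),
            ("Rnor", 35.0),
        )
    )
    return SimConfig(
        species_tree=SPECIES_TREE_8,
        duplication_time=359.0,
        n_codons=800,
        mutation_rate=0.0065,
        kappa=2.5,
        omega_classes=OmegaClasses((0.6, 0.35, 0.05), (0.05, 0.4, 1.0)),
        conversion_events=events,
        seed=seed,
    )
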