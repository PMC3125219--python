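"""Distances, tree building, ML branch lengths, bootstrap and quartet mapping.

Implements the phylogenetic workhorses for the conversion-aware pipeline:
closed-form F84 distances (with transition/transversion decomposition, used
by the substitution-saturation screen), pairwise maximum-likelihood
distances under HKY85 or JTT, neighbor joining, pruning-based branch-length
and rate-parameter optimization with invariant sites + discrete gamma,
nonparametric bootstrap, and quartet likelihood mapping.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .likelihood import MixtureClass, PruningEngine, compress_patterns
from .models import Eigen, MLModelSpec, eigen_reversible, hky_Q, jtt_model
from .seqio import Alignment
from .trees import Tree, TreeArrays, neighbor_joining as _nj_core


class SaturationWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# Pairwise distances
# ---------------------------------------------------------------------------

def _pair_counts(a: str, b: str) -> tuple[int, int, int, np.ndarray]:
    """(n_sites, n_transitions, n_transversions, base-frequency vector) over
    gap/N-free shared columns."""
    freq = np.zeros(4)
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    n = s = v = 0
    for x, y in zip(a, b):
        i, j = order.get(x), order.get(y)
        if i is None or j is None:
            continue
        n += 1
        freq[i] += 1
        freq[j] += 1
        if i != j:
            if (i, j) in {(0, 2), (2, 0), (1, 3), (3, 1)}:
                s += 1
            else:
                v += 1
    return n, s, v, freq


def f84_distance(seq_a: str, seq_b: str) -> tuple[float, float, float]:
    """Closed-form F84 distance.

    Returns ``(d, s, v)`` where ``s`` and ``v`` are the observed per-site
    transition and transversion proportions.  Uses the empirical base
    frequencies of the pair.  A log-domain violation (saturation) yields
    ``d = inf`` with a :class:`SaturationWarning`.
    """
    n, ns, nv, freq = _pair_counts(seq_a, seq_b)
    if n == 0:
        raise ValueError("no gap-free shared columns")
    P, Q = ns / n, nv / n
    pi = freq / freq.sum()
    pi = np.clip(pi, 1e-6, None)
    pi /= pi.sum()
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    A = piC * piT / piY + piA * piG / piR
    B = piC * piT + piA * piG
    C = piR * piY
    arg1 = 1.0 - P / (2 * A) - (A - B) * Q / (2 * A * C)
    arg2 = 1.0 - Q / (2 * C)
    if arg1 <= 0 or arg2 <= 0:
        warnings.warn("F84 distance saturated (log-domain violation)", SaturationWarning)
        return np.inf, P, Q
    d = -2 * A * np.log(arg1) + 2 * (A - B - C) * np.log(arg2)
    return float(d), float(P), float(Q)


def ml_pair_distance(seq_a, seq_b, model: MLModelSpec) -> float:
    """Two-sequence ML distance under HKY85 (DNA) or JTT (protein).

    ``seq_a``/``seq_b`` may be strings or SequenceRecords.  The distance is
    the branch length maximizing the two-sequence likelihood with the
    model's kappa (HKY) held at its specified value.
    """
    a = seq_a.seq if hasattr(seq_a, "seq") else seq_a
    b = seq_b.seq if hasattr(seq_b, "seq") else seq_b
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    from .seqio import AA_ORDER, NUC_ORDER

    order = NUC_ORDER if model.model == "HKY85" else AA_ORDER
    lut = {c: k for k, c in enumerate(order)}
    S = model.n_states
    counts = np.zeros((S, S))
    freq = np.zeros(S)
    for x, y in zip(a, b):
        i, j = lut.get(x), lut.get(y)
        if i is None or j is None:
            continue
        counts[i, j] += 1
        freq[i] += 1
        freq[j] += 1
    if counts.sum() == 0:
        raise ValueError("no gap-free shared columns")
    if model.model == "HKY85":
        pi = model.frequencies if model.frequencies is not None else np.clip(freq / freq.sum(), 1e-6, None)
        pi = pi / pi.sum()
        eig = eigen_reversible(hky_Q(model.kappa, pi), pi)
    else:
        Q, pi = jtt_model(model.frequencies)
        eig = eigen_reversible(Q, pi)
    if counts.sum() == np.trace(counts):
        return 0.0  # identical over shared columns

    def neg(t: float) -> float:
        P = eig.transition_matrices(np.array([t]))[0]
        with np.errstate(divide="ignore"):
            lp = np.log(np.clip(pi[:, None] * P, 1e-300, None))
        return -float(np.sum(counts * lp))

    res = minimize_scalar(neg, bounds=(1e-8, 20.0), method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"pairwise ML distance failed to converge: {res}")
    return float(res.x)


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with saturation flags."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def saturated_pairs(self) -> list[tuple[str, str]]:
        idx = np.argwhere(~np.isfinite(self.matrix))
        return [
            (self.ids[i], self.ids[j]) for i, j in idx if i < j
        ]

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id"
        )


def distance_matrix(
    alignment: Alignment,
    method: Literal["f84", "ml"] = "f84",
    model: MLModelSpec | None = None,
) -> DistanceMatrix:
    n = len(alignment)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = alignment.records[i], alignment.records[j]
        if method == "f84":
            d[i, j], _, _ = f84_distance(a.seq, b.seq)
        else:
            d[i, j] = ml_pair_distance(a, b, model or MLModelSpec())
        d[j, i] = d[i, j]
    return DistanceMatrix(alignment.ids, d)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """NJ tree from a distance matrix; saturated taxa are dropped with a
    warning rather than clamped."""
    ids, mat = list(dm.ids), dm.matrix.copy()
    while not np.all(np.isfinite(mat)):
        bad = int(np.argmax((~np.isfinite(mat)).sum(axis=1)))
        warnings.warn(
            f"dropping {ids[bad]!r} from NJ: saturated distances", SaturationWarning
        )
        keep = [k for k in range(len(ids)) if k != bad]
        ids = [ids[k] for k in keep]
        mat = mat[np.ix_(keep, keep)]
    return _nj_core(ids, mat)


# ---------------------------------------------------------------------------
# ML branch lengths and rate parameters
# ---------------------------------------------------------------------------

def _empirical_frequencies(alignment: Alignment, n_states: int) -> np.ndarray:
    codes = alignment.codes()
    counts = np.bincount(codes[codes >= 0].ravel(), minlength=n_states).astype(float)
    counts = np.clip(counts, 1.0, None)
    return counts / counts.sum()


@dataclass
class TreeFit:
    tree: Tree
    lnl: float
    spec: MLModelSpec


def _model_classes(spec: MLModelSpec, pi: np.ndarray) -> list[MixtureClass]:
    eig = eigen_reversible(spec.base_matrix(pi), pi)
    weights, rates = spec.rate_classes()
    return [
        MixtureClass(float(w), None if r == 0 else eig, float(r))
        for w, r in zip(weights, rates)
    ]


def ml_branch_lengths(
    tree: Tree,
    alignment: Alignment,
    spec: MLModelSpec,
    estimate: Sequence[str] = ("branches", "alpha", "p_inv", "kappa"),
) -> TreeFit:
    """Optimize branch lengths and rate parameters by pruning likelihood.

    ``estimate`` lists the free quantities; anything not listed is fixed at
    its value in ``spec`` — this supports the two-phase protocol in which
    model parameters are estimated once on the point alignment and then
    fixed for every bootstrap replicate.
    """
    if alignment.length == 0:
        raise ValueError("zero-length alignment")
    tree = tree.copy()
    tarr = tree.to_arrays(alignment.ids)
    patterns, weights, _ = compress_patterns(alignment.codes())
    engine = PruningEngine(tarr, patterns, spec.n_states)
    if spec.frequencies is None and spec.model == "HKY85":
        spec = replace(spec, frequencies=_empirical_frequencies(alignment, 4))
    pi = spec.frequencies if spec.model == "HKY85" else jtt_model(spec.frequencies)[1]

    edge_nodes = tarr.edge_nodes()
    free_branches = "branches" in estimate
    names: list[str] = []
    if spec.model == "HKY85" and "kappa" in estimate:
        names.append("kappa")
    if spec.n_rate_classes > 1 and "alpha" in estimate:
        names.append("alpha")
    if "p_inv" in estimate:
        names.append("p_inv")

    def unpack(x: np.ndarray) -> tuple[np.ndarray, MLModelSpec]:
        k = 0
        bl = tarr.lengths.copy()
        if free_branches:
            bl[edge_nodes] = np.exp(x[: len(edge_nodes)])
            k = len(edge_nodes)
        s = spec
        for nm in names:
            v = x[k]
            k += 1
            if nm == "kappa":
                s = replace(s, kappa=float(np.exp(v)))
            elif nm == "alpha":
                s = replace(s, alpha=float(np.exp(v)))
            else:
                s = replace(s, p_inv=float(v))
        return bl, s

    def neg(x: np.ndarray) -> float:
        bl, s = unpack(x)
        classes = _model_classes(s, pi)
        lnl = engine.mixture_loglik(classes, bl, weights)
        return -lnl if np.isfinite(lnl) else 1e12

    x0: list[float] = []
    bounds: list[tuple[float, float]] = []
    if free_branches:
        init = np.clip(tarr.lengths[edge_nodes], 1e-4, None)
        if np.all(tarr.lengths[edge_nodes] == 0):
            init = np.full(len(edge_nodes), 0.1)
        x0 += list(np.log(init))
        bounds += [(np.log(1e-7), np.log(30.0))] * len(edge_nodes)
    for nm in names:
        if nm == "kappa":
            x0.append(np.log(spec.kappa))
            bounds.append((np.log(0.05), np.log(100.0)))
        elif nm == "alpha":
            x0.append(np.log(spec.alpha))
            bounds.append((np.log(0.05), np.log(50.0)))
        else:
            x0.append(max(spec.p_inv, 1e-3))
            bounds.append((0.0, 0.9))

    if x0:
        res = minimize(neg, np.array(x0), method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-11, "eps": 1e-6})
        bl, fitted = unpack(res.x)
        lnl = -res.fun
    else:
        bl, fitted = tarr.lengths, spec
        lnl = -neg(np.array([]))
    # write branch lengths back onto the tree copy
    for k in edge_nodes:
        tarr.nodes[k].length = float(bl[k])
    return TreeFit(tree=tree, lnl=float(lnl), spec=fitted)


def tree_loglik(tree: Tree, alignment: Alignment, spec: MLModelSpec) -> float:
    """lnL of a tree with its current branch lengths (no optimization)."""
    fit = ml_branch_lengths(tree, alignment, spec, estimate=())
    return fit.lnl


# ---------------------------------------------------------------------------
# Tree search helpers and bootstrap
# ---------------------------------------------------------------------------

def nj_tree(alignment: Alignment, method: Literal["f84", "ml"] = "f84", model: MLModelSpec | None = None) -> Tree:
    return neighbor_joining(distance_matrix(alignment, method, model))


def nni_search(tree: Tree, alignment: Alignment, spec: MLModelSpec, max_rounds: int = 3) -> TreeFit:
    """Nearest-neighbor-interchange hill climbing on lnL.

    Starts from ``tree`` (e.g. NJ) and accepts the best improving swap per
    round until no swap improves; adequate for the <=30-taxon gene-family
    problems this package targets.
    """
    best = ml_branch_lengths(tree, alignment, spec)
    for _ in range(max_rounds):
        improved = False
        for cand in _nni_neighbours(best.tree):
            fit = ml_branch_lengths(cand, alignment, spec)
            if fit.lnl > best.lnl + 1e-6:
                best, improved = fit, True
        if not improved:
            break
    return best


def _nni_neighbours(tree: Tree):
    """Yield NNI rearrangements around each internal edge.

    Node identity is carried across copies by postorder rank, which the
    deterministic traversal preserves.
    """
    post = tree.postorder()
    for idx, n in enumerate(post):
        if n.is_leaf or n.parent is None or len(n.children) < 2:
            continue
        for child_idx in (0, 1):
            t2 = tree.copy()
            post2 = t2.postorder()
            n2 = post2[idx]
            p2 = n2.parent
            sibs2 = [c for c in p2.children if c is not n2]
            if not sibs2:
                continue
            sib2, moved2 = sibs2[0], n2.children[child_idx]
            n2.children.remove(moved2)
            p2.children.remove(sib2)
            n2.add(sib2)
            p2.add(moved2)
            yield t2


def bootstrap_support(
    alignment: Alignment,
    tree_builder: Callable[[Alignment], Tree],
    replicates: int = 1000,
    seed: int = 0,
) -> tuple[Tree, dict[frozenset[str], int]]:
    """Nonparametric bootstrap: column resampling with replacement.

    Returns the point-estimate tree with internal nodes labelled by the
    number of replicates (out of ``replicates``) containing the same
    bipartition, plus the full support map.  Deterministic given ``seed``.
    """
    if replicates < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    point = tree_builder(alignment)
    target = point.bipartitions()
    support = {s: 0 for s in target}
    ncol = alignment.length
    for _ in range(replicates):
        idx = rng.integers(0, ncol, size=ncol)
        rep = tree_builder(alignment.columns(idx))
        for s in rep.bipartitions():
            if s in support:
                support[s] += 1
    # label internal nodes
    all_leaves = frozenset(point.leaf_names)
    below: dict[int, frozenset[str]] = {}
    for n in point.postorder():
        if n.is_leaf:
            below[id(n)] = frozenset([n.name])
        else:
            side = frozenset().union(*(below[id(c)] for c in n.children))
            below[id(n)] = side
            key = min(side, all_leaves - side, key=lambda s: (len(s), sorted(s))) if side != all_leaves else None
            if key in support:
                n.label = str(support[key])
    return point, support


# ---------------------------------------------------------------------------
# Quartet likelihood mapping
# ---------------------------------------------------------------------------

@dataclass
class QuartetMapResult:
    """Quartet posterior-weight census over the likelihood-mapping simplex."""

    n_quartets: int
    resolved: float  # proportion in the three corner regions
    regions: dict[str, float]  # corner1..3, edge12/13/23, center


def _quartet_tree(a: str, b: str, c: str, d: str) -> Tree:
    return Tree.from_newick(f"(({a}:0.1,{b}:0.1):0.1,{c}:0.1,{d}:0.1);")


def likelihood_mapping(
    alignment: Alignment,
    spec: MLModelSpec,
    n_quartets: int = 1000,
    seed: int = 0,
) -> QuartetMapResult:
    """Quartet likelihood mapping (posterior weights of the 3 topologies).

    For each sampled quartet the three resolved topologies are scored by
    ML branch lengths under ``spec`` (rate parameters fixed); the posterior
    weights place the quartet in one of seven simplex regions.  A quartet
    falls in a corner ("resolved") when one topology carries weight > 2/3.
    """
    ids = alignment.ids
    if len(ids) < 4:
        raise ValueError("likelihood mapping needs >= 4 sequences")
    quartets = list(itertools.combinations(ids, 4))
    rng = np.random.default_rng(seed)
    if n_quartets < len(quartets):
        pick = rng.choice(len(quartets), size=n_quartets, replace=False)
        quartets = [quartets[k] for k in pick]
    counts = {k: 0 for k in ("corner1", "corner2", "corner3", "edge12", "edge13", "edge23", "center")}
    for a, b, c, d in quartets:
        sub = alignment.subset([a, b, c, d])
        lnls = []
        for t in ((a, b, c, d), (a, c, b, d), (a, d, b, c)):
            fit = ml_branch_lengths(_quartet_tree(*t), sub, spec, estimate=("branches",))
            lnls.append(fit.lnl)
        w = np.exp(np.array(lnls) - max(lnls))
        w /= w.sum()
        order = np.argsort(w)[::-1]
        if w[order[0]] > 2 / 3:
            counts[f"corner{order[0] + 1}"] += 1
        elif w[order[2]] < 1 / 6:
            i, j = sorted(int(x) + 1 for x in order[:2])
            counts[f"edge{i}{j}"] += 1
        else:
            counts["center"] += 1
    total = len(quartets)
    regions = {k: v / total for k, v in counts.items()}
    resolved = regions["corner1"] + regions["corner2"] + regions["corner3"]
    return QuartetMapResult(n_quartets=total, resolved=resolved, regions=regions)
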