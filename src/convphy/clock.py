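"""Divergence-time estimation under global and local clock models.

The protocol runs in two phases, as is standard for fossil-calibrated
likelihood dating of codon or nucleotide data: first the substitution
nuisance parameters are estimated without a clock (kappa and omega for
codon data, kappa and the gamma shape for nucleotide data), then they are
fixed and node ages plus the substitution rate are optimized under the
clock constraint.  Calibrations are box constraints on node ages (a point
calibration fixes the age); the parameterization guarantees every child is
younger than its parent by construction.

Converted tracts have a two-lineage, star-like history after the transfer,
so conversion events are dated from the pairwise divergence of the
converted region: ``age = d / (2 * rate)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize

from .codon import CODON_INDEX, CodonModelSpec, N_CODONS, fit_site_model, mixture_classes
from .likelihood import MixtureClass, PruningEngine, compress_patterns
from .models import MLModelSpec, eigen_reversible, hky_Q
from .phylo import ml_branch_lengths, _empirical_frequencies, _model_classes
from .seqio import Alignment, CodonAlignment
from .trees import Tree


@dataclass(frozen=True)
class Calibration:
    """Age bounds (My) on the MRCA of ``leaves``; min == max fixes the age."""

    leaves: tuple[str, ...]
    min_age: float
    max_age: float

    def __post_init__(self) -> None:
        if not (0 < self.min_age <= self.max_age):
            raise ValueError("calibration ages must satisfy 0 < min <= max")


@dataclass
class ClockFit:
    model: Literal["global", "local"]
    rates: tuple[float, ...]  # substitutions/site/My (codon site for codon data)
    node_ages: dict[frozenset, float]  # clade (leaf set) -> age in Mya
    lnl: float
    fixed_params: dict[str, float]
    tree: Tree  # dated tree; branch lengths in My, node.age set

    def age_of(self, leaves: Sequence[str]) -> float:
        """Age of the smallest clade containing ``leaves``."""
        want = set(leaves)
        best = None
        for clade, age in self.node_ages.items():
            if want <= clade and (best is None or len(clade) < len(best[0])):
                best = (clade, age)
        if best is None:
            raise KeyError(f"no clade contains {sorted(want)}")
        return best[1]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _mrca_index(tarr, leaves: Sequence[str]) -> int:
    want = {tarr.leaf_order.index(l) for l in leaves}
    below: dict[int, set[int]] = {}
    for k in range(tarr.n_nodes):
        below[k] = {k} if k < tarr.n_leaves else set()
    for k in tarr.postorder_internal:
        for c in tarr.children[k]:
            below[k] |= below[c]
    candidates = [k for k in tarr.postorder_internal if want <= below[k]]
    return min(candidates, key=lambda k: len(below[k]))


def fit_clock(
    alignment: Alignment,
    rooted_tree: Tree,
    calibrations: Sequence[Calibration],
    model: Literal["global", "local"] = "global",
    data_type: Literal["codon", "nucleotide"] = "codon",
    local_branches: Sequence[Sequence[str]] = (),
    n_restarts: int = 2,
) -> ClockFit:
    """Two-phase clock dating.

    ``local_branches`` (local model only) lists clades — given by their
    leaf sets — whose parent edges evolve at a second rate.  Raises on
    contradictory calibrations (a calibrated child older than its parent's
    maximum).
    """
    if not calibrations:
        raise ValueError("at least one calibration is required")
    tree = rooted_tree.copy()
    tarr = tree.to_arrays(alignment.ids)

    # ---- phase 1: nuisance parameters without the clock ---------------
    fixed: dict[str, float] = {}
    if data_type == "codon":
        if not isinstance(alignment, CodonAlignment):
            raise TypeError("codon dating requires a CodonAlignment")
        m0 = fit_site_model(alignment, tree, "M0", branch_mode="full", n_starts=1)
        fixed = {"kappa": m0.kappa, "omega": m0.params["omega"]}
        spec = m0.spec
        classes = mixture_classes(
            fixed["kappa"], spec.pi, np.array([1.0]), np.array([fixed["omega"]])
        )
        patterns, weights, _ = compress_patterns(alignment.codon_codes(CODON_INDEX))
        n_states = N_CODONS
    else:
        mls = MLModelSpec(model="HKY85")
        fit1 = ml_branch_lengths(tree, alignment, mls)
        fixed = {"kappa": fit1.spec.kappa, "alpha": fit1.spec.alpha, "p_inv": fit1.spec.p_inv}
        classes = _model_classes(fit1.spec, fit1.spec.frequencies)
        patterns, weights, _ = compress_patterns(alignment.codes())
        n_states = 4

    engine = PruningEngine(tarr, patterns, n_states)
    cw = np.array([c.weight for c in classes])

    # ---- phase 2: node ages + rate(s) under the clock ------------------
    internal = list(tarr.postorder_internal)
    root = tarr.root
    if any(len(tarr.children[k]) != 2 for k in internal if k != root):
        pass  # multifurcations are allowed; ages still well-defined
    cal_by_node: dict[int, Calibration] = {}
    for cal in calibrations:
        cal_by_node[_mrca_index(tarr, cal.leaves)] = cal
    # contradictory-calibration check along ancestry
    for k, cal in cal_by_node.items():
        p = tarr.parent[k]
        while p != -1:
            pc = cal_by_node.get(p)
            if pc is not None and cal.min_age > pc.max_age:
                raise ValueError(
                    f"calibration conflict: child clade min {cal.min_age} exceeds "
                    f"ancestor max {pc.max_age}"
                )
            p = tarr.parent[p]

    preorder_internal = internal[::-1]  # root first
    free_nodes = [k for k in preorder_internal if k != root]
    n_rates = 2 if model == "local" else 1
    second_rate_nodes: set[int] = set()
    for clade in local_branches:
        second_rate_nodes.add(_mrca_index(tarr, clade) if len(clade) > 1 else tarr.leaf_order.index(clade[0]))
    if model == "local" and not second_rate_nodes:
        raise ValueError("local clock needs local_branches")

    root_cal = cal_by_node.get(root)
    min_root = max((c.min_age for c in cal_by_node.values()), default=1.0)

    def ages_from(x: np.ndarray) -> tuple[np.ndarray, float]:
        """Node ages plus a smooth penalty for calibration violations."""
        ages = np.zeros(tarr.n_nodes)
        penalty = 0.0
        k_par = 0
        if root_cal is not None:
            if root_cal.min_age == root_cal.max_age:
                ages[root] = root_cal.min_age
            else:
                ages[root] = root_cal.min_age + float(_sigmoid(x[k_par])) * (
                    root_cal.max_age - root_cal.min_age
                )
                k_par += 1
        else:
            # root is bounded below by the oldest calibration minimum
            ages[root] = min_root * (1.0 + float(np.exp(x[k_par])))
            k_par += 1
        for k in free_nodes:
            pa = ages[tarr.parent[k]]
            cal = cal_by_node.get(k)
            lo = cal.min_age if cal else 0.0
            hi = min(pa, cal.max_age) if cal else pa
            if cal and cal.min_age == cal.max_age:
                ages[k] = min(cal.min_age, pa)
                if cal.min_age > pa:
                    penalty += 1e3 * (cal.min_age - pa) ** 2
                continue
            if hi < lo:  # ancestor squeezed below this node's calibration
                penalty += 1e3 * (lo - hi) ** 2
                hi = lo
            ages[k] = lo + float(_sigmoid(x[k_par])) * (hi - lo)
            k_par += 1
        return ages, penalty

    n_age_params = (0 if (root_cal and root_cal.min_age == root_cal.max_age) else 1) + sum(
        1 for k in free_nodes if not (cal_by_node.get(k) and cal_by_node[k].min_age == cal_by_node[k].max_age)
    )

    def neg(x: np.ndarray) -> float:
        ages, penalty = ages_from(x[:n_age_params])
        rates = np.exp(x[n_age_params:])
        bl = np.zeros(tarr.n_nodes)
        for k in range(tarr.n_nodes):
            p = tarr.parent[k]
            if p == -1:
                continue
            r = rates[1] if (model == "local" and k in second_rate_nodes) else rates[0]
            bl[k] = max(ages[p] - ages[k], 0.0) * r
        mat = engine.mixture_site_logliks(classes, bl)
        m = mat.max(axis=0)
        m = np.where(np.isfinite(m), m, 0.0)
        with np.errstate(divide="ignore"):
            site_log = m + np.log(np.exp(mat - m).T @ cw)
        lnl = float(site_log @ weights)
        return (-lnl if np.isfinite(lnl) else 1e12) + penalty

    best = None
    rng = np.random.default_rng(7)
    for attempt in range(max(1, n_restarts)):
        x0 = np.concatenate(
            [
                rng.normal(0, 0.5, size=n_age_params) if attempt else np.zeros(n_age_params),
                np.log(np.full(n_rates, 1e-3 * (2.0 ** attempt))),
            ]
        )
        res = minimize(neg, x0, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-11, "eps": 1e-6})
        if best is None or res.fun < best.fun:
            best = res
    ages, _ = ages_from(best.x[:n_age_params])
    rates = tuple(float(v) for v in np.exp(best.x[n_age_params:]))

    below: dict[int, frozenset] = {}
    for k in range(tarr.n_leaves):
        below[k] = frozenset([tarr.leaf_order[k]])
    for k in tarr.postorder_internal:
        below[k] = frozenset().union(*(below[c] for c in tarr.children[k]))
    node_ages = {below[k]: float(ages[k]) for k in tarr.postorder_internal}
    for k, node in enumerate(tarr.nodes):
        node.age = float(ages[k]) if k >= tarr.n_leaves or not node.is_leaf else 0.0
        p = tarr.parent[k]
        if p != -1:
            node.length = float(ages[p] - ages[k])
    return ClockFit(
        model=model,
        rates=rates,
        node_ages=node_ages,
        lnl=-float(best.fun),
        fixed_params=fixed,
        tree=tree,
    )


@dataclass
class ConversionDate:
    age: float  # Mya
    interval: tuple[float, float] | None
    recent_or_ongoing: bool


def date_conversion_event(
    converted_region: Alignment,
    pair: tuple[str, str],
    rate: float,
    rate_interval: tuple[float, float] | None = None,
    data_type: Literal["nucleotide", "codon"] = "nucleotide",
    kappa: float = 2.0,
    omega: float = 0.5,
) -> ConversionDate:
    """Date a conversion from the converted region's pairwise divergence.

    ``rate`` is in substitutions/site/My on the same site unit as the
    divergence (nucleotide site for F84, codon site for codon data);
    ``rate_interval`` propagates rate uncertainty to an age interval.
    Zero divergence flags a recent or ongoing conversion at age 0.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    a, b = converted_region[pair[0]].seq, converted_region[pair[1]].seq
    if data_type == "nucleotide":
        from .phylo import f84_distance

        d, _, _ = f84_distance(a, b)
    else:
        d = _codon_pair_distance(converted_region, pair, kappa, omega)
    if d == 0.0:
        return ConversionDate(0.0, (0.0, 0.0) if rate_interval else None, True)
    age = d / (2.0 * rate)
    interval = None
    if rate_interval is not None:
        lo, hi = rate_interval
        interval = (d / (2.0 * hi), d / (2.0 * lo))
    return ConversionDate(float(age), interval, False)


def _codon_pair_distance(alignment: Alignment, pair: tuple[str, str], kappa: float, omega: float) -> float:
    from scipy.optimize import minimize_scalar

    sub = CodonAlignment([alignment[pair[0]], alignment[pair[1]]])
    spec = CodonModelSpec(kappa=kappa).resolve(sub)
    classes = mixture_classes(kappa, spec.pi, np.array([1.0]), np.array([omega]))
    eig = classes[0].eigen
    rate = classes[0].rate
    codes = sub.codon_codes(CODON_INDEX)
    mask = (codes[0] >= 0) & (codes[1] >= 0)
    ci, cj = codes[0, mask], codes[1, mask]
    if np.all(ci == cj):
        return 0.0

    def neg(t: float) -> float:
        P = eig.transition_matrices(np.array([t * rate]))[0]
        lk = np.clip(spec.pi[ci] * P[ci, cj], 1e-300, None)
        return -float(np.log(lk).sum())

    res = minimize_scalar(neg, bounds=(1e-8, 30.0), method="bounded")
    return float(res.x)
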