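"""Codon substitution models and tests of positive selection.

The substitution process follows Goldman-Yang: instantaneous change between
sense codons differing at exactly one position, at rate proportional to the
target codon's frequency, multiplied by kappa for transitions and by omega
(dN/dS) for amino-acid-changing substitutions.  Heterogeneity of selective
pressure across codon sites is modelled by the standard site-class mixtures

=====  ==========================================================
M0     one omega for all sites
M1a    nearly neutral: (p0, omega0 < 1) + (p1, omega1 = 1)
M2a    M1a + a positive-selection class (p2, omega2 >= 1)
M7     omega ~ Beta(p, q), discretized (default 10 categories)
M8     M7 + an extra class at omega_s > 1 with weight p1
M8a    M8 with omega_s fixed at 1 (boundary null for M8)
=====  ==========================================================

Nested pairs are compared by likelihood-ratio tests and sites under
positive selection identified by naive empirical Bayes posteriors at the
maximum-likelihood estimates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import betainc, gammaln
from scipy.stats import chi2

from .likelihood import MixtureClass, PruningEngine, compress_patterns
from .models import Eigen, eigen_reversible
from .seqio import CODON_TABLE, CodonAlignment
from .trees import Tree

# ---------------------------------------------------------------------------
# Codon state space (61 sense codons, standard code)
# ---------------------------------------------------------------------------

SENSE_CODONS: list[str] = sorted(CODON_TABLE)
CODON_INDEX: dict[str, int] = {c: k for k, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)
CODON_AA: list[str] = [CODON_TABLE[c] for c in SENSE_CODONS]

_TS_PAIRS = {frozenset("AG"), frozenset("CT")}


def _single_change_arrays() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays (i, j, is_transition, is_synonymous) over ordered codon
    pairs differing at exactly one position."""
    I, J, TS, SYN = [], [], [], []
    for a, b in itertools.permutations(range(N_CODONS), 2):
        ca, cb = SENSE_CODONS[a], SENSE_CODONS[b]
        diffs = [(x, y) for x, y in zip(ca, cb) if x != y]
        if len(diffs) != 1:
            continue
        I.append(a)
        J.append(b)
        TS.append(frozenset(diffs[0]) in _TS_PAIRS)
        SYN.append(CODON_AA[a] == CODON_AA[b])
    return (np.array(I), np.array(J), np.array(TS), np.array(SYN))


_I, _J, _TS, _SYN = _single_change_arrays()


@dataclass(frozen=True)
class CodonModelSpec:
    """Kappa and codon-frequency convention for a GY94-type model."""

    kappa: float = 2.0
    freq_mode: Literal["F3x4", "F61", "equal"] = "F3x4"
    pi: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.pi is not None and not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("codon frequencies must sum to 1")

    def resolve(self, alignment: CodonAlignment) -> "CodonModelSpec":
        if self.pi is not None:
            return self
        return replace(self, pi=codon_frequencies(alignment, self.freq_mode))


def codon_frequencies(alignment: CodonAlignment, mode: str = "F3x4") -> np.ndarray:
    """Equilibrium sense-codon frequencies from the data."""
    if mode == "equal":
        return np.full(N_CODONS, 1.0 / N_CODONS)
    if mode == "F61":
        counts = np.ones(N_CODONS)
        codes = alignment.codon_codes(CODON_INDEX)
        idx, c = np.unique(codes[codes >= 0], return_counts=True)
        counts[idx] += c
        return counts / counts.sum()
    if mode != "F3x4":
        raise ValueError(f"unknown frequency mode {mode!r}")
    pos_freq = np.full((3, 4), 0.25)
    nt_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.ones((3, 4))
    for rec in alignment.records:
        for k in range(alignment.n_codons):
            codon = rec.seq[3 * k : 3 * k + 3]
            if "-" in codon or "N" in codon:
                continue
            for p, nt in enumerate(codon):
                counts[p, nt_index[nt]] += 1
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, nt_index[c[0]]] * pos_freq[1, nt_index[c[1]]] * pos_freq[2, nt_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def codon_Q_matrix(spec: CodonModelSpec, omega: float, normalized: bool = True) -> np.ndarray:
    """GY94 rate matrix over the 61 sense codons.

    Multi-nucleotide changes have rate 0; single changes get ``pi_j`` times
    kappa for transitions and times omega for nonsynonymous changes.  With
    ``normalized`` the matrix is scaled to one expected substitution per
    codon site at stationarity (single-class scaling; mixtures are scaled
    jointly by the fitting machinery).
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    pi = spec.pi
    if pi is None:
        raise ValueError("spec has unresolved frequencies; call resolve()")
    Q = np.zeros((N_CODONS, N_CODONS))
    rates = pi[_J] * np.where(_TS, spec.kappa, 1.0) * np.where(_SYN, 1.0, omega)
    Q[_I, _J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalized:
        mu = -float(np.sum(pi * np.diag(Q)))
        if mu > 0:
            Q /= mu
    return Q


def _rate_components(kappa: float, pi: np.ndarray) -> tuple[float, float]:
    """(synonymous, nonsynonymous) flux so mean rate = syn + omega * nonsyn."""
    base = pi[_I] * pi[_J] * np.where(_TS, kappa, 1.0)
    return float(base[_SYN].sum()), float(base[~_SYN].sum())


class _EigenCache:
    """Eigendecompositions keyed by (kappa, omega); pi fixed per instance."""

    def __init__(self, pi: np.ndarray):
        self.pi = pi
        self._store: dict[tuple[float, float], tuple[Eigen, float]] = {}

    def get(self, kappa: float, omega: float) -> tuple[Eigen, float]:
        key = (round(kappa, 12), round(omega, 12))
        hit = self._store.get(key)
        if hit is None:
            spec = CodonModelSpec(kappa=kappa, pi=self.pi)
            Q = codon_Q_matrix(spec, omega, normalized=False)
            mu = -float(np.sum(self.pi * np.diag(Q)))
            eig = eigen_reversible(Q / mu, self.pi)
            hit = (eig, mu)
            if len(self._store) > 4096:
                self._store.clear()
            self._store[key] = hit
        return hit


def mixture_classes(
    kappa: float,
    pi: np.ndarray,
    weights: np.ndarray,
    omegas: np.ndarray,
    cache: _EigenCache | None = None,
) -> list[MixtureClass]:
    """Site-mixture classes scaled so the *mixture* mean rate is 1."""
    if cache is None:
        cache = _EigenCache(pi)
    s, ns = _rate_components(kappa, pi)
    mus = s + np.asarray(omegas) * ns
    F = float(np.sum(weights * mus))
    out = []
    for w, om, mu in zip(weights, omegas, mus):
        eig, _ = cache.get(kappa, float(om))
        out.append(MixtureClass(float(w), eig, float(mu / F)))
    return out


# ---------------------------------------------------------------------------
# Site-class distributions
# ---------------------------------------------------------------------------

def beta_class_omegas(p: float, q: float, n_classes: int = 10) -> np.ndarray:
    """Mean omega of each of ``n_classes`` equal-probability Beta(p,q) bins."""
    from scipy.stats import beta as beta_dist

    edges = beta_dist.ppf(np.linspace(0, 1, n_classes + 1), p, q)
    upper = betainc(p + 1, q, edges)
    means = (upper[1:] - upper[:-1]) * n_classes * p / (p + q)
    return np.clip(means, 1e-8, 1 - 1e-8)


#: free-parameter names per model (kappa and tree scale handled separately)
MODEL_PARAMS: dict[str, list[str]] = {
    "M0": ["omega"],
    "M1a": ["p0", "omega0"],
    "M2a": ["a1", "a2", "omega0", "omega2"],
    "M7": ["p", "q"],
    "M8": ["p0", "p", "q", "omega_s"],
    "M8a": ["p0", "p", "q"],
}

NESTED_PAIRS: dict[tuple[str, str], int] = {
    ("M1a", "M2a"): 2,
    ("M7", "M8"): 2,
    ("M8a", "M8"): 1,
}


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _class_distribution(model: str, params: dict[str, float], k_beta: int) -> tuple[np.ndarray, np.ndarray]:
    """(weights, omegas) of the site mixture for one model."""
    if model == "M0":
        return np.array([1.0]), np.array([params["omega"]])
    if model == "M1a":
        p0 = params["p0"]
        return np.array([p0, 1 - p0]), np.array([params["omega0"], 1.0])
    if model == "M2a":
        e1, e2 = np.exp(params["a1"]), np.exp(params["a2"])
        z = 1.0 + e1 + e2
        w = np.array([e1 / z, e2 / z, 1.0 / z])
        return w, np.array([params["omega0"], 1.0, params["omega2"]])
    if model == "M7":
        om = beta_class_omegas(params["p"], params["q"], k_beta)
        return np.full(k_beta, 1.0 / k_beta), om
    if model in ("M8", "M8a"):
        p0 = params["p0"]
        om = beta_class_omegas(params["p"], params["q"], k_beta)
        omega_s = params.get("omega_s", 1.0)
        w = np.concatenate([np.full(k_beta, p0 / k_beta), [1 - p0]])
        return w, np.concatenate([om, [omega_s]])
    raise ValueError(f"unknown model {model!r}")


@dataclass
class SiteModelFit:
    """Maximum-likelihood fit of one codon site model."""

    model: str
    lnl: float
    kappa: float
    weights: np.ndarray
    omegas: np.ndarray
    params: dict[str, float]
    tree: Tree
    spec: CodonModelSpec
    converged: bool
    n_beta_classes: int = 10

    @property
    def positive_class_mask(self) -> np.ndarray:
        return self.omegas > 1.0

    @property
    def proportion_positive(self) -> float:
        return float(self.weights[self.positive_class_mask].sum())

    def omega_positive(self) -> float | None:
        m = self.positive_class_mask
        if not m.any():
            return None
        return float(np.sum(self.weights[m] * self.omegas[m]) / self.weights[m].sum())


def site_mixture_lnl(
    alignment: CodonAlignment,
    tree: Tree,
    kappa: float,
    weights: np.ndarray,
    omegas: np.ndarray,
    spec: CodonModelSpec | None = None,
    return_site_class: bool = False,
):
    """Mixture log-likelihood of a codon alignment on a tree.

    Per-site likelihood is the class-weighted average of the conditional
    likelihoods; branch lengths are taken from the tree (expected
    substitutions per codon at the mixture level).
    """
    spec = (spec or CodonModelSpec(kappa=kappa)).resolve(alignment)
    tarr = tree.to_arrays(alignment.ids)
    patterns, pw, inverse = compress_patterns(alignment.codon_codes(CODON_INDEX))
    engine = PruningEngine(tarr, patterns, N_CODONS)
    classes = mixture_classes(kappa, spec.pi, weights, omegas)
    res = engine.mixture_loglik(classes, tarr.lengths, pw, return_site_class=return_site_class)
    if return_site_class:
        lnl, mat = res
        return lnl, mat[:, inverse]  # expand patterns back to sites
    return res


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _starts(model: str) -> list[dict[str, float]]:
    """Two starting points; the omega-type parameters start at 0.5 and 2.0
    (clipped into each model's admissible range)."""
    base = {
        "omega": 0.5, "p0": 0.7, "omega0": 0.3, "a1": 1.0, "a2": 0.5,
        "omega2": 2.0, "p": 0.5, "q": 1.5, "omega_s": 2.0,
    }
    alt = dict(base, omega=2.0, omega0=0.8, omega2=1.1, omega_s=1.2, p0=0.9, p=1.5, q=0.5)
    return [base, alt]


_BOUNDS = {
    "omega": (np.log(1e-4), np.log(50.0)),
    "omega0": (-12.0, 12.0),  # logit over (0,1)
    "p0": (-12.0, 12.0),
    "a1": (-12.0, 12.0),
    "a2": (-12.0, 12.0),
    "omega2": (np.log(1e-6), np.log(50.0)),  # omega2 = 1 + exp(x)
    "omega_s": (np.log(1e-6), np.log(50.0)),
    "p": (np.log(0.005), np.log(99.0)),
    "q": (np.log(0.005), np.log(99.0)),
}


def _encode(name: str, value: float) -> float:
    if name in ("p0", "omega0"):
        v = min(max(value, 1e-6), 1 - 1e-6)
        return float(np.log(v / (1 - v)))
    if name in ("omega2", "omega_s"):
        return float(np.log(max(value - 1.0, 1e-6)))
    if name in ("omega", "p", "q"):
        return float(np.log(value))
    return float(value)  # a1, a2 unconstrained


def _decode(name: str, x: float) -> float:
    if name in ("p0", "omega0"):
        return _sigmoid(x)
    if name in ("omega2", "omega_s"):
        return 1.0 + float(np.exp(x))
    if name in ("omega", "p", "q"):
        return float(np.exp(x))
    return float(x)


def fit_site_model(
    alignment: CodonAlignment,
    tree: Tree,
    model: str,
    spec: CodonModelSpec | None = None,
    branch_mode: Literal["scale", "full"] = "scale",
    k_beta: int = 10,
    n_starts: int = 2,
) -> SiteModelFit:
    """Fit one site model by maximum likelihood.

    Protocol: branch lengths come from an M0 fit (run internally when the
    supplied tree carries no lengths); each site model then re-optimizes a
    single shared tree-scale factor together with kappa and its class
    parameters (``branch_mode="full"`` re-optimizes every branch instead).
    The best of ``n_starts`` starting points is kept; the second start is
    warm-started from the first fit's nuisance parameters.
    """
    if len(alignment) < 3:
        raise ValueError("site models need >= 3 sequences")
    if model not in MODEL_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    spec = (spec or CodonModelSpec()).resolve(alignment)
    tree = tree.copy()

    tarr = tree.to_arrays(alignment.ids)
    if model != "M0" and branch_mode == "scale" and np.all(tarr.lengths[tarr.edge_nodes()] == 0):
        m0 = fit_site_model(alignment, tree, "M0", spec=spec, branch_mode="full", n_starts=1)
        tree = m0.tree
        tarr = tree.to_arrays(alignment.ids)

    patterns, pw, _ = compress_patterns(alignment.codon_codes(CODON_INDEX))
    engine = PruningEngine(tarr, patterns, N_CODONS)
    cache = _EigenCache(spec.pi)
    edge_nodes = tarr.edge_nodes()
    base_lengths = tarr.lengths.copy()
    full = branch_mode == "full" or (model == "M0" and np.all(base_lengths[edge_nodes] == 0))
    if np.all(base_lengths[edge_nodes] == 0):
        base_lengths[edge_nodes] = 0.3

    pnames = MODEL_PARAMS[model]

    def neg(x: np.ndarray) -> float:
        k = 0
        if full:
            bl = base_lengths.copy()
            bl[edge_nodes] = np.exp(x[: len(edge_nodes)])
            k = len(edge_nodes)
        else:
            bl = base_lengths * np.exp(x[0])
            k = 1
        kappa = float(np.exp(x[k]))
        k += 1
        params = {nm: _decode(nm, x[k + i]) for i, nm in enumerate(pnames)}
        w, om = _class_distribution(model, params, k_beta)
        classes = mixture_classes(kappa, spec.pi, w, om, cache)
        lnl = engine.mixture_loglik(classes, bl, pw)
        return -lnl if np.isfinite(lnl) else 1e12

    def pack(init: dict[str, float], kappa: float, scale: float) -> tuple[np.ndarray, list]:
        x0, bounds = [], []
        if full:
            x0 += list(np.log(np.clip(base_lengths[edge_nodes] * scale, 1e-5, None)))
            bounds += [(np.log(1e-7), np.log(30.0))] * len(edge_nodes)
        else:
            x0.append(np.log(scale))
            bounds.append((np.log(1e-2), np.log(1e2)))
        x0.append(np.log(kappa))
        bounds.append((np.log(0.05), np.log(100.0)))
        for nm in pnames:
            x0.append(_encode(nm, init[nm]))
            bounds.append(_BOUNDS[nm])
        return np.array(x0), bounds

    best = None
    warm_kappa, warm_scale = spec.kappa, 1.0
    starts = _starts(model)[: max(1, n_starts)]
    for s_i, init in enumerate(starts):
        if s_i > 0 and best is not None:  # warm-start nuisance parameters
            warm_kappa = best[2]
            warm_scale = best[3]
            init = dict(init)
            for nm in ("p", "q", "p0"):
                if nm in pnames and nm in best[4]:
                    init[nm] = best[4][nm]
        x0, bounds = pack(init, warm_kappa, warm_scale)
        res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 400, "maxfun": 2000, "ftol": 1e-10,
                                "eps": 1e-6})
        k = len(edge_nodes) if full else 1
        kappa = float(np.exp(res.x[k]))
        scale = 1.0 if full else float(np.exp(res.x[0]))
        params = {nm: _decode(nm, res.x[k + 1 + i]) for i, nm in enumerate(pnames)}
        cand = (-res.fun, res, kappa, scale, params, res.x)
        if best is None or cand[0] > best[0]:
            best = cand
    lnl, res, kappa, scale, params, xbest = best

    fitted = tree.copy()
    farr = fitted.to_arrays(alignment.ids)
    if full:
        bl = np.exp(xbest[: len(edge_nodes)])
        for pos, node_k in enumerate(edge_nodes):
            farr.nodes[node_k].length = float(bl[pos])
    else:
        for node_k in edge_nodes:
            farr.nodes[node_k].length = float(base_lengths[node_k] * scale)
    if model == "M8a":
        params = dict(params, omega_s=1.0)
    w, om = _class_distribution(model, params, k_beta)
    return SiteModelFit(
        model=model, lnl=float(lnl), kappa=kappa, weights=w, omegas=om,
        params=params, tree=fitted, spec=spec,
        converged=bool(res.success), n_beta_classes=k_beta,
    )


def fit_model_series(
    alignment: CodonAlignment,
    tree: Tree,
    models: Sequence[str] = ("M0", "M1a", "M2a", "M7", "M8", "M8a"),
    spec: CodonModelSpec | None = None,
    branch_mode: Literal["scale", "full"] = "scale",
    n_starts: int = 2,
) -> dict[str, SiteModelFit]:
    """Fit a series of site models sharing the M0 branch-length baseline."""
    spec = (spec or CodonModelSpec()).resolve(alignment)
    fits: dict[str, SiteModelFit] = {}
    m0 = fit_site_model(alignment, tree, "M0", spec=spec, branch_mode="full", n_starts=1)
    fits["M0"] = m0
    for m in models:
        if m == "M0":
            continue
        fits[m] = fit_site_model(
            alignment, m0.tree, m, spec=spec, branch_mode=branch_mode, n_starts=n_starts
        )
    return fits


# ---------------------------------------------------------------------------
# Likelihood-ratio tests
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    null_model: str
    alt_model: str
    statistic: float  # 2(lnL_alt - lnL_null), clamped at 0
    df: int
    pvalue: float
    boundary_pvalue: float | None = None  # 1/2 chi2_0 + 1/2 chi2_1 mixture
    boundary: bool = False


def lrt(null_fit: SiteModelFit, alt_fit: SiteModelFit) -> LRTResult:
    """Likelihood-ratio test between nested site models.

    Valid pairs: M1a in M2a (df 2), M7 in M8 (df 2), M8a in M8 (df 1,
    boundary case; a 50:50 chi2_0/chi2_1 mixture p-value is also reported).
    """
    key = (null_fit.model, alt_fit.model)
    if key not in NESTED_PAIRS:
        raise ValueError(f"models {key} are not a supported nested pair")
    df = NESTED_PAIRS[key]
    stat = max(0.0, 2.0 * (alt_fit.lnl - null_fit.lnl))
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    boundary = key == ("M8a", "M8")
    bp = None
    if boundary:
        bp = 1.0 if stat == 0 else float(0.5 * chi2.sf(stat, 1))
    return LRTResult(null_fit.model, alt_fit.model, stat, df, p, bp, boundary)


# ---------------------------------------------------------------------------
# Site identification (naive empirical Bayes)
# ---------------------------------------------------------------------------

@dataclass
class SiteRow:
    site: int  # 1-based codon column in the alignment
    ref_position: int | None  # 1-based ungapped residue number in reference
    ref_aa: str | None
    p_positive: float

    @property
    def label(self) -> str:
        if self.ref_position is None:
            return f"aln{self.site}"
        return f"{self.ref_position}{self.ref_aa}"


@dataclass
class SitePosteriorTable:
    reference_id: str
    posteriors: np.ndarray  # (n_class, n_sites)
    rows: list[SiteRow]

    def selected(self, threshold: float = 0.9) -> list[SiteRow]:
        return [r for r in self.rows if r.p_positive > threshold]

    def labels(self, threshold: float = 0.9) -> list[str]:
        return [r.label for r in self.selected(threshold)]


def positively_selected_sites(
    fit: SiteModelFit,
    alignment: CodonAlignment,
    reference_id: str,
    threshold: float = 0.9,
) -> SitePosteriorTable:
    """Posterior P(omega > 1) per codon site under the fitted mixture.

    Naive empirical Bayes at the MLEs.  Sites are labelled by the ungapped
    residue number and amino acid of the reference sequence (``286Q``
    style); sites where the reference is gapped keep alignment numbering.
    """
    if not fit.positive_class_mask.any():
        return SitePosteriorTable(reference_id, np.zeros((len(fit.weights), 0)), [])
    if reference_id not in alignment:
        raise KeyError(reference_id)
    _, site_class = site_mixture_lnl(
        alignment, fit.tree, fit.kappa, fit.weights, fit.omegas, fit.spec,
        return_site_class=True,
    )
    logw = np.log(fit.weights)[:, None]
    lp = site_class + logw
    lp -= lp.max(axis=0, keepdims=True)
    post = np.exp(lp)
    post /= post.sum(axis=0, keepdims=True)
    p_pos = post[fit.positive_class_mask].sum(axis=0)

    ref = alignment[reference_id]
    protein = alignment.to_protein()
    ref_aas = protein[reference_id].seq
    rows = []
    ref_pos = 0
    for k in range(alignment.n_codons):
        aa = ref_aas[k]
        if aa != "-":
            ref_pos += 1
            rows.append(SiteRow(k + 1, ref_pos, aa, float(p_pos[k])))
        else:
            rows.append(SiteRow(k + 1, None, None, float(p_pos[k])))
    return SitePosteriorTable(reference_id, post, rows)
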