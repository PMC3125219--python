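"""Reversible substitution models and rate heterogeneity.

Provides HKY85 for DNA, the Jones-Taylor-Thornton (1992) empirical model
for proteins, discrete-gamma rate classes (equal-probability categories,
category rate = within-bin mean), a proportion of invariable sites, and the
spectral machinery shared with the codon models: a reversible rate matrix
is symmetrized with pi^(1/2) so transition matrices come from a real
symmetric eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np
from scipy.linalg import eigh
from scipy.stats import gamma as gamma_dist


@dataclass(frozen=True)
class Eigen:
    """Spectral form of a reversible rate matrix: Q = U diag(lam) U^-1."""

    U: np.ndarray
    Uinv: np.ndarray
    lam: np.ndarray
    pi: np.ndarray

    def transition_matrices(self, t: np.ndarray) -> np.ndarray:
        """P(t) for an array of times; shape (len(t), S, S).

        Small negative entries from roundoff are clamped to 0.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        # rate-matrix eigenvalues are <= 0; clamp roundoff-positive ones
        expl = np.exp(np.minimum(self.lam[None, :] * t[:, None], 0.0))  # (T, S)
        P = np.einsum("ij,tj,jk->tik", self.U, expl, self.Uinv, optimize=True)
        np.clip(P, 0.0, None, out=P)
        return P


def eigen_reversible(Q: np.ndarray, pi: np.ndarray) -> Eigen:
    """Eigendecompose a pi-reversible Q via symmetrization."""
    sq = np.sqrt(pi)
    S = Q * sq[:, None] / sq[None, :]  # D^1/2 Q D^-1/2 is symmetric
    S = 0.5 * (S + S.T)  # guard against roundoff
    lam, V = eigh(S)
    U = V / sq[:, None]
    Uinv = V.T * sq[None, :]
    return Eigen(U=U, Uinv=Uinv, lam=lam, pi=pi)


def normalize_rate(Q: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Scale Q so the expected substitution rate at stationarity is 1."""
    mu = -float(np.sum(pi * np.diag(Q)))
    return Q / mu


def _fill_diagonal(Q: np.ndarray) -> np.ndarray:
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


# ---------------------------------------------------------------------------
# Nucleotide models (state order A C G T)
# ---------------------------------------------------------------------------

PURINES = (0, 2)  # A, G
TRANSITION_PAIRS = {(0, 2), (2, 0), (1, 3), (3, 1)}


def hky_Q(kappa: float, pi: np.ndarray, normalized: bool = True) -> np.ndarray:
    """HKY85 rate matrix over ACGT."""
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kappa if (i, j) in TRANSITION_PAIRS else 1.0)
    Q = _fill_diagonal(Q)
    return normalize_rate(Q, pi) if normalized else Q


def jc_distance(p_diff: float) -> float:
    """Jukes-Cantor closed form for a total difference proportion."""
    x = 1.0 - 4.0 * p_diff / 3.0
    if x <= 0:
        return np.inf
    return -0.75 * np.log(x)


# ---------------------------------------------------------------------------
# JTT protein model
# ---------------------------------------------------------------------------

def _load_jtt() -> tuple[np.ndarray, np.ndarray]:
    text = resources.files("convphy.data").joinpath("jtt.dat").read_text()
    rows = [
        [float(x) for x in line.split()]
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    freqs = np.array(rows.pop())
    R = np.zeros((20, 20))
    for i, vals in enumerate(rows, start=1):
        R[i, : len(vals)] = vals
    R = R + R.T
    return R, freqs / freqs.sum()


_JTT_CACHE: tuple[np.ndarray, np.ndarray] | None = None


def jtt_model(pi: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """JTT rate matrix (normalized) and its frequencies.

    ``pi`` overrides the model's equilibrium frequencies (``+F`` variant).
    """
    global _JTT_CACHE
    if _JTT_CACHE is None:
        _JTT_CACHE = _load_jtt()
    R, default_pi = _JTT_CACHE
    use_pi = default_pi if pi is None else np.asarray(pi, dtype=float)
    Q = R * use_pi[None, :]
    Q = _fill_diagonal(Q.copy())
    return normalize_rate(Q, use_pi), use_pi


# ---------------------------------------------------------------------------
# Rate heterogeneity
# ---------------------------------------------------------------------------

def discrete_gamma_rates(alpha: float, n_classes: int = 4) -> np.ndarray:
    """Mean rates of ``n_classes`` equal-probability gamma(alpha, alpha) bins.

    The class means are computed from the incomplete-gamma identity so the
    overall mean is exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    k = n_classes
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1 / alpha)
    # E[X | a<X<b] * P(a<X<b) = F_{alpha+1}(b) - F_{alpha+1}(a) for mean-1 gamma
    upper = gamma_dist.cdf(edges, a=alpha + 1, scale=1 / alpha)
    rates = (upper[1:] - upper[:-1]) * k
    return rates / rates.mean()


@dataclass
class MLModelSpec:
    """Likelihood model specification for tree inference.

    ``model`` chooses HKY85 (DNA) or JTT (protein); ``n_rate_classes`` gamma
    categories (0 or 1 disables gamma); ``alpha`` the gamma shape;
    ``p_inv`` the proportion of invariable sites; ``kappa`` the HKY85
    transition/transversion rate ratio.
    """

    model: Literal["HKY85", "JTT"] = "HKY85"
    n_rate_classes: int = 4
    alpha: float = 1.0
    p_inv: float = 0.0
    kappa: float = 2.0
    frequencies: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0 <= self.p_inv < 1:
            raise ValueError("p_inv must be in [0, 1)")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")

    @property
    def n_states(self) -> int:
        return 4 if self.model == "HKY85" else 20

    def base_matrix(self, pi: np.ndarray) -> np.ndarray:
        if self.model == "HKY85":
            return hky_Q(self.kappa, pi)
        Q, _ = jtt_model(pi)
        return Q

    def rate_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """(weights, rates) including the invariable class when p_inv > 0.

        Rates are rescaled so the weighted mean rate is 1 (branch lengths
        keep their expected-substitutions meaning).
        """
        if self.n_rate_classes and self.n_rate_classes > 1:
            g_rates = discrete_gamma_rates(self.alpha, self.n_rate_classes)
        else:
            g_rates = np.array([1.0])
        g_w = np.full(len(g_rates), 1.0 / len(g_rates))
        if self.p_inv > 0:
            weights = np.concatenate([[self.p_inv], (1 - self.p_inv) * g_w])
            rates = np.concatenate([[0.0], g_rates])
        else:
            weights, rates = g_w, g_rates
        mean = float(np.sum(weights * rates))
        return weights, rates / mean
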