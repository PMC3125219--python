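"""Felsenstein pruning over site-pattern-compressed alignments.

The engine is model-agnostic: it works on integer state codes (4 for DNA,
20 for protein, 61 for sense codons) plus the spectral form of each rate
class.  Per-node rescaling keeps likelihoods in range for any alignment
size; log-scale accumulators are carried per site pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .models import Eigen
from .trees import TreeArrays


def compress_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical alignment columns.

    Parameters
    ----------
    codes : (n_seq, n_col) integer matrix, -1 for gap/ambiguous.

    Returns
    -------
    patterns : (n_seq, n_pat) matrix of distinct columns.
    weights : (n_pat,) column multiplicities.
    inverse : (n_col,) pattern index of each original column.
    """
    cols = np.ascontiguousarray(codes.T)
    uniq, inverse, counts = np.unique(
        cols.view([("", cols.dtype)] * cols.shape[1]),
        return_inverse=True,
        return_counts=True,
    )
    patterns = uniq.view(cols.dtype).reshape(len(uniq), cols.shape[1]).T
    return np.ascontiguousarray(patterns), counts.astype(float), inverse.ravel()


@dataclass
class MixtureClass:
    """One component of a site mixture: weight, spectral Q, rate multiplier.

    ``eigen`` may be None for a zero-rate (invariable) class.
    """

    weight: float
    eigen: Eigen | None
    rate: float = 1.0


class PruningEngine:
    """Reusable pruning machinery bound to one tree shape and one alignment."""

    def __init__(self, tree: TreeArrays, patterns: np.ndarray, n_states: int):
        if patterns.shape[0] != tree.n_leaves:
            raise ValueError("pattern rows must equal number of leaves")
        self.tree = tree
        self.patterns = patterns
        self.n_states = n_states
        self.n_pat = patterns.shape[1]
        self._missing = [patterns[k] < 0 for k in range(tree.n_leaves)]
        self._safe_codes = [np.where(patterns[k] < 0, 0, patterns[k]) for k in range(tree.n_leaves)]

    # -- single class -----------------------------------------------------
    def class_site_loglik(self, eigen: Eigen | None, branch_lengths: np.ndarray, rate: float = 1.0, pi: np.ndarray | None = None) -> np.ndarray:
        """(n_pat,) log-likelihoods for one rate class."""
        if eigen is None or rate == 0.0:
            return self._invariable_loglik(pi if pi is not None else eigen.pi)
        t = self.tree
        P = eigen.transition_matrices(branch_lengths * rate)  # (n_nodes, S, S)
        partials: dict[int, np.ndarray] = {}
        scale_log = np.zeros(self.n_pat)
        for node in t.postorder_internal:
            res: np.ndarray | None = None
            for c in t.children[node]:
                if c < t.n_leaves:
                    lk = P[c][:, self._safe_codes[c]]
                    if self._missing[c].any():
                        lk = lk.copy()
                        lk[:, self._missing[c]] = 1.0
                else:
                    lk = P[c] @ partials.pop(c)
                res = lk if res is None else res * lk
            mx = res.max(axis=0)
            mx = np.where(mx > 0, mx, 1.0)
            res /= mx
            scale_log += np.log(mx)
            partials[node] = res
        root_lk = eigen.pi @ partials[t.root]
        with np.errstate(divide="ignore"):
            return np.log(root_lk) + scale_log

    def _invariable_loglik(self, pi: np.ndarray) -> np.ndarray:
        """Zero-rate class: the site likelihood is pi of the shared state."""
        out = np.full(self.n_pat, -np.inf)
        state = np.full(self.n_pat, -1, dtype=int)
        constant = np.ones(self.n_pat, dtype=bool)
        for k in range(self.tree.n_leaves):
            codes = self.patterns[k]
            seen = codes >= 0
            first = (state < 0) & seen
            state[first] = codes[first]
            constant &= ~seen | (codes == state) | first
        ok = constant & (state >= 0)
        out[ok] = np.log(pi[state[ok]])
        return out

    # -- mixtures ----------------------------------------------------------
    def mixture_site_logliks(self, classes: Sequence[MixtureClass], branch_lengths: np.ndarray) -> np.ndarray:
        """(n_class, n_pat) per-class site log-likelihoods."""
        pi = next(c.eigen.pi for c in classes if c.eigen is not None)
        return np.vstack(
            [self.class_site_loglik(c.eigen, branch_lengths, c.rate, pi) for c in classes]
        )

    def mixture_loglik(
        self,
        classes: Sequence[MixtureClass],
        branch_lengths: np.ndarray,
        weights: np.ndarray,
        return_site_class: bool = False,
    ):
        """Total lnL of the mixture; optionally also the per-class matrix."""
        logw = np.log(np.array([c.weight for c in classes]))
        mat = self.mixture_site_logliks(classes, branch_lengths)  # (C, n_pat)
        m = mat.max(axis=0)
        m = np.where(np.isfinite(m), m, 0.0)
        with np.errstate(divide="ignore"):
            site_log = m + np.log(np.exp(mat - m).T @ np.exp(logw))
        lnl = float(site_log @ weights)
        if return_site_class:
            return lnl, mat
        return lnl
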