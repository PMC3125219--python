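"""Gene-conversion detection between paralogue pairs.

Two complementary detectors are provided:

* Sawyer-style *global inner fragments*: within a group alignment, the
  polymorphic sites are listed and, for each sequence pair, maximal runs of
  consecutive polymorphic sites at which the pair agrees are scored.  The
  significance of the best runs is assessed both by permuting the order of
  polymorphic sites (simulated p-value) and by the analytic tail of the
  longest-run statistic (a Karlin-Altschul-type maximal-segment p-value,
  computed exactly by inclusion-exclusion), Bonferroni-corrected for the
  number of pair comparisons in the scan.

* *bootscan*: sliding-window bootstrap profiles of which reference each
  query groups with in neighbor-joining trees built from maximum-likelihood
  (F84) distances; a conversion tract shows up as a window interval in
  which the query switches partner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Sequence

import numpy as np

from .phylo import f84_distance
from .seqio import Alignment
from .trees import neighbor_joining as _nj


@dataclass
class PolymorphismTable:
    """Polymorphic alignment columns (0-based, ascending).

    Columns containing any gap or N are excluded so alignment artifacts
    cannot seed fragments.
    """

    columns: np.ndarray
    n_sequences: int
    alignment_length: int

    def __len__(self) -> int:
        return len(self.columns)


def find_polymorphic_sites(alignment: Alignment) -> PolymorphismTable:
    if len(alignment) < 2:
        raise ValueError("polymorphism table needs >= 2 sequences")
    codes = alignment.codes()
    clean = np.all(codes >= 0, axis=0)
    variable = (codes != codes[0]).any(axis=0)
    cols = np.flatnonzero(clean & variable)
    return PolymorphismTable(cols, len(alignment), alignment.length)


@dataclass
class ConversionFragment:
    """A candidate converted tract between one sequence pair.

    ``begin``/``end`` are 1-based inclusive alignment columns at the
    outermost matching polymorphic sites.  ``n_poly`` counts polymorphic
    sites inside the fragment, ``n_dif`` pair mismatches inside it (0 under
    the default no-mismatch setting), ``tot_difs`` pair mismatches over all
    polymorphic sites of the alignment.
    """

    pair: tuple[str, str]
    begin: int
    end: int
    score: float
    n_poly: int
    n_dif: int
    tot_difs: int
    sim_p: float | None = None
    bcka_p: float | None = None


def _pair_match_vector(alignment: Alignment, pair: tuple[str, str], table: PolymorphismTable) -> np.ndarray:
    codes = alignment.codes()
    ia, ib = alignment.ids.index(pair[0]), alignment.ids.index(pair[1])
    return codes[ia, table.columns] == codes[ib, table.columns]


def _runs(match: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) indices into ``match``."""
    out = []
    start = None
    for k, m in enumerate(match):
        if m and start is None:
            start = k
        elif not m and start is not None:
            out.append((start, k - 1))
            start = None
    if start is not None:
        out.append((start, len(match) - 1))
    return out


def global_inner_fragments(
    alignment: Alignment, pair: tuple[str, str], table: PolymorphismTable | None = None
) -> list[ConversionFragment]:
    """Maximal matching runs for one pair, best score first.

    An uninformative pair (identical at every polymorphic site, or with no
    polymorphic sites at all) yields an empty list.  The score of a run of
    ``L`` matching polymorphic sites is ``-L log q`` with ``q`` the pair's
    genome-wide match probability at polymorphic sites, so the score grows
    with both run length and the pair's total divergence.
    """
    if table is None:
        table = find_polymorphic_sites(alignment)
    if len(table) == 0:
        return []
    match = _pair_match_vector(alignment, pair, table)
    tot_difs = int((~match).sum())
    if tot_difs == 0:
        return []  # uninformative: pair identical at all polymorphic sites
    q = 1.0 - tot_difs / len(match)
    if q <= 0:
        return []  # pair differs everywhere: nothing can match
    frags = []
    for s, e in _runs(match):
        L = e - s + 1
        frags.append(
            ConversionFragment(
                pair=pair,
                begin=int(table.columns[s]) + 1,
                end=int(table.columns[e]) + 1,
                score=float(-L * math.log(q)),
                n_poly=L,
                n_dif=0,
                tot_difs=tot_difs,
            )
        )
    frags.sort(key=lambda f: f.score, reverse=True)
    return frags


def _longest_run(match: np.ndarray) -> int:
    best = cur = 0
    for m in match:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def permutation_pvalue(
    alignment: Alignment,
    pair: tuple[str, str],
    fragment: ConversionFragment,
    replicates: int = 10000,
    seed: int = 0,
    table: PolymorphismTable | None = None,
) -> float:
    """Simulated p-value by permuting the order of polymorphic sites.

    ``sim_p = (1 + #{permutations with best score >= observed}) / (R + 1)``;
    with the match probability fixed under permutation this reduces to
    comparing longest runs.  Deterministic given ``seed``.
    """
    if replicates < 100:
        raise ValueError("permutation test needs >= 100 replicates")
    if table is None:
        table = find_polymorphic_sites(alignment)
    match = _pair_match_vector(alignment, pair, table)
    rng = np.random.default_rng(seed)
    n = len(match)
    obs = fragment.n_poly
    # vectorized longest-run over permuted rows
    rows = np.empty((replicates, n), dtype=bool)
    for r in range(replicates):
        rows[r] = match[rng.permutation(n)]
    idx = np.arange(n)
    last_false = np.maximum.accumulate(np.where(~rows, idx[None, :], -1), axis=1)
    runlen = np.where(rows, idx[None, :] - last_false, 0)
    best = runlen.max(axis=1)
    return float((1 + int((best >= obs).sum())) / (replicates + 1))


@lru_cache(maxsize=200000)
def _longest_run_tail(m: int, k: int, L: int) -> float:
    """P(longest success-run >= L) with m successes and k failures in
    uniformly random order — the quantity the Karlin-Altschul formula
    approximates for maximal-segment scores.

    Computed exactly (big-integer inclusion-exclusion over compositions)
    whenever the term count is modest, which covers every fragment long
    enough to be interesting; short runs (many inclusion-exclusion terms,
    p near 1) fall back to the Poisson/KA tail approximation.
    """
    if L > m:
        return 0.0
    if k == 0:
        return 1.0
    n_terms = min(k + 1, m // L + 1)
    if n_terms > 60:  # short runs: p is far from the tail, approximation fine
        n = m + k
        q = m / n
        expected = n * (1.0 - q) * q**L
        return float(-math.expm1(-expected))
    total = math.comb(m + k, k)
    n_below = 0
    j = 0
    sign = 1
    while j <= k + 1 and m - j * L >= 0:
        n_below += sign * math.comb(k + 1, j) * math.comb(m - j * L + k, k)
        sign = -sign
        j += 1
    return float(Fraction(total - n_below, total))


def bcka_pvalue(fragment: ConversionFragment, n_comparisons: int, n_poly_total: int) -> float:
    """Bonferroni-corrected maximal-segment (KA-type) p-value.

    ``n_poly_total`` is the number of polymorphic sites in the scanned
    alignment and ``n_comparisons`` the number of pair comparisons in the
    scan (the Bonferroni factor).  Exact tail of the longest matching run
    given the pair's total mismatch count; capped at 1.
    """
    if n_poly_total <= 0:
        raise ValueError("degenerate scan: no polymorphic sites")
    m = n_poly_total - fragment.tot_difs
    p = _longest_run_tail(m, fragment.tot_difs, fragment.n_poly)
    return min(1.0, p * n_comparisons)


@dataclass
class GroupScan:
    """All-pairs fragment scan of one group alignment (per-pair fragment report)."""

    fragments: list[ConversionFragment]
    n_poly_total: int
    n_comparisons: int
    uninformative_pairs: list[tuple[str, str]] = field(default_factory=list)
    alignment: Alignment | None = field(default=None, repr=False)
    table: PolymorphismTable | None = field(default=None, repr=False)


def _permutation_null_runs(match: np.ndarray, replicates: int, rng: np.random.Generator) -> np.ndarray:
    """Longest matching run under ``replicates`` permutations of site order."""
    n = len(match)
    rows = np.empty((replicates, n), dtype=bool)
    for r in range(replicates):
        rows[r] = match[rng.permutation(n)]
    idx = np.arange(n)
    last_false = np.maximum.accumulate(np.where(~rows, idx[None, :], -1), axis=1)
    return np.where(rows, idx[None, :] - last_false, 0).max(axis=1)


def scan_group(
    alignment: Alignment,
    pairs: Sequence[tuple[str, str]] | None = None,
    replicates: int = 10000,
    seed: int = 0,
    keep: int | None = None,
    sim_p: bool = True,
) -> GroupScan:
    """Scan a group alignment for converted fragments in every pair.

    ``pairs`` defaults to all unordered pairs.  The Bonferroni factor is
    the number of ordered-pair comparisons implied by the scan.  ``keep``
    limits output to the best-scoring fragments per pair (default: all).
    One permutation null of the best-run statistic is shared by all
    fragments of a pair.
    """
    table = find_polymorphic_sites(alignment)
    if pairs is None:
        ids = alignment.ids
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
    n_comparisons = 2 * len(pairs)
    out: list[ConversionFragment] = []
    uninformative = []
    for pnum, pair in enumerate(pairs):
        frags = global_inner_fragments(alignment, pair, table)
        if not frags:
            uninformative.append(pair)
            continue
        if keep is not None:
            frags = frags[:keep]
        null_runs = None
        if sim_p:
            match = _pair_match_vector(alignment, pair, table)
            rng = np.random.default_rng(seed + 1009 * pnum)
            null_runs = _permutation_null_runs(match, replicates, rng)
        for f in frags:
            f.bcka_p = bcka_pvalue(f, n_comparisons, len(table))
            if null_runs is not None:
                f.sim_p = float((1 + int((null_runs >= f.n_poly).sum())) / (replicates + 1))
            out.append(f)
    out.sort(key=lambda f: f.score, reverse=True)
    return GroupScan(out, len(table), n_comparisons, uninformative, alignment, table)


def call_converted_tracts(
    scan: GroupScan,
    pair: tuple[str, str],
    alpha: float = 0.05,
    tract_match_prob: float = 0.95,
    alignment: Alignment | None = None,
    table: PolymorphismTable | None = None,
) -> list[tuple[int, int]]:
    """Seed-and-extend tract calls for one pair.

    A conversion tract older than a few My is interrupted by
    post-conversion substitutions, so the mismatch-free fragments tile it
    and the tract reveals itself as a *dense stretch* of matching
    polymorphic sites rather than one long run.  Calling therefore works
    in two steps: fragments with Bonferroni-corrected maximal-segment
    p < ``alpha`` *seed* a tract (without a seed nothing is called, so the
    family-level false-positive rate is governed by the corrected
    threshold alone); the tract *extent* is the maximal-scoring segment
    containing the seed under per-site log-likelihood-ratio scores for
    tract (match probability ``tract_match_prob``) versus background (the
    pair's global match probability).  Overlapping calls are merged.
    Returns 1-based inclusive column intervals, longest first.

    ``alignment`` and ``table`` default to those recorded on the scan.
    """
    alignment = alignment if alignment is not None else scan.alignment
    table = table if table is not None else scan.table
    if alignment is None or table is None:
        raise ValueError("scan does not carry its alignment; pass alignment=/table=")
    frags = [f for f in scan.fragments if set(f.pair) == set(pair) and f.bcka_p is not None]
    seeds = [f for f in frags if f.bcka_p < alpha]
    if not seeds:
        return []
    match = _pair_match_vector(alignment, tuple(pair), table)
    q0 = float(match.mean())
    q1 = max(tract_match_prob, (1.0 + q0) / 2.0)
    s_match = math.log(q1 / max(q0, 1e-9))
    s_mis = math.log((1.0 - q1) / max(1.0 - q0, 1e-9))
    scores = np.where(match, s_match, s_mis)
    prefix = np.concatenate([[0.0], np.cumsum(scores)])
    col_of = table.columns  # 0-based alignment columns of polymorphic sites
    col_index = {int(c): k for k, c in enumerate(col_of)}

    tracts: list[list[int]] = []
    for f in seeds:
        i0 = col_index[f.begin - 1]
        i1 = col_index[f.end - 1]
        left = int(np.argmin(prefix[: i0 + 1]))  # segment starts at site `left`
        right = i1 + int(np.argmax(prefix[i1 + 1 :])) + 1  # ends at site right-1
        # trim to outermost matching sites
        lo, hi = left, right - 1
        while lo <= hi and not match[lo]:
            lo += 1
        while hi >= lo and not match[hi]:
            hi -= 1
        tracts.append([int(col_of[lo]) + 1, int(col_of[hi]) + 1])
    tracts.sort()
    merged: list[list[int]] = []
    for b, e in tracts:
        if merged and b <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([b, e])
    merged.sort(key=lambda t: t[1] - t[0], reverse=True)
    return [tuple(t) for t in merged]


def regions_from_fragment(fragment: ConversionFragment, alignment_length: int) -> list:
    """N/Central/C region specs implied by one converted tract."""
    from .seqio import RegionSpec

    regions = []
    if fragment.begin > 1:
        regions.append(RegionSpec("N", 1, fragment.begin - 1))
    name = "C" if fragment.end >= alignment_length - 2 else "Central"
    regions.append(RegionSpec(name, fragment.begin, fragment.end if name == "Central" else alignment_length))
    if name == "Central" and fragment.end < alignment_length:
        regions.append(RegionSpec("C", fragment.end + 1, alignment_length))
    return regions


# ---------------------------------------------------------------------------
# Bootscan
# ---------------------------------------------------------------------------

@dataclass
class BootscanProfile:
    query: str
    references: list[str]
    window: int
    step: int
    replicates: int
    centers: np.ndarray  # window center columns (1-based)
    support: np.ndarray  # (n_windows, n_references) sister-grouping fraction

    def partner_switches(self, threshold: float = 0.5) -> list[tuple[int, str]]:
        """(window center, reference) where support first exceeds threshold."""
        out = []
        current = None
        for w in range(len(self.centers)):
            k = int(np.argmax(self.support[w]))
            if self.support[w, k] >= threshold and self.references[k] != current:
                current = self.references[k]
                out.append((int(self.centers[w]), current))
        return out


def _f84_vec(P: np.ndarray, Q: np.ndarray, pi: np.ndarray) -> np.ndarray:
    piA, piC, piG, piT = pi[:, 0], pi[:, 1], pi[:, 2], pi[:, 3]
    piR, piY = piA + piG, piC + piT
    A = piC * piT / piY + piA * piG / piR
    B = piC * piT + piA * piG
    C = piR * piY
    with np.errstate(divide="ignore", invalid="ignore"):
        arg1 = 1.0 - P / (2 * A) - (A - B) * Q / (2 * A * C)
        arg2 = 1.0 - Q / (2 * C)
        d = -2 * A * np.log(arg1) + 2 * (A - B - C) * np.log(arg2)
    d[(arg1 <= 0) | (arg2 <= 0)] = np.inf
    return d


def bootscan(
    alignment: Alignment,
    query: str,
    window: int = 200,
    step: int = 20,
    replicates: int = 1000,
    seed: int = 0,
) -> BootscanProfile:
    """Sliding-window bootstrap NJ profile of the query's sister taxon.

    Per window, columns are resampled with replacement, pairwise F84 ML
    distances computed, an NJ tree built, and the fraction of replicates
    in which the query shares a two-leaf split with each reference
    recorded.  Saturated bootstrap distances are replaced by 1.25x the
    largest finite distance in that replicate (profile use only).
    Deterministic given ``seed``.
    """
    if window > alignment.length:
        raise ValueError("window exceeds alignment length")
    if len(alignment) < 4:
        raise ValueError("bootscan needs >= 4 sequences (NJ)")
    if query not in alignment:
        raise KeyError(query)
    rng = np.random.default_rng(seed)
    ids = alignment.ids
    refs = [i for i in ids if i != query]
    qi = ids.index(query)
    codes = alignment.codes()
    n = len(ids)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    npair = len(pairs)

    # per-column, per-pair classification
    ci = codes[[i for i, _ in pairs], :]
    cj = codes[[j for _, j in pairs], :]
    valid = (ci >= 0) & (cj >= 0)
    diff = valid & (ci != cj)
    ts = diff & (np.abs(ci - cj) == 2)  # A<->G (0,2) and C<->T (1,3)
    tv = diff & ~ts
    base_counts = np.zeros((npair, alignment.length, 4))
    for b in range(4):
        base_counts[:, :, b] = (ci == b) * valid + (cj == b) * valid

    starts = np.arange(0, alignment.length - window + 1, step)
    centers = starts + window // 2 + 1
    support = np.zeros((len(starts), len(refs)))
    ref_index = {r: k for k, r in enumerate(refs)}

    for w, s0 in enumerate(starts):
        sl = slice(s0, s0 + window)
        v_w = valid[:, sl].astype(float)
        ts_w = ts[:, sl].astype(float)
        tv_w = tv[:, sl].astype(float)
        bc_w = base_counts[:, sl, :]
        counts = rng.multinomial(window, np.full(window, 1.0 / window), size=replicates).astype(float)
        for r in range(replicates):
            wvec = counts[r]
            nv = v_w @ wvec
            nv = np.where(nv > 0, nv, 1.0)
            P = (ts_w @ wvec) / nv
            Q = (tv_w @ wvec) / nv
            freq = np.einsum("pwb,w->pb", bc_w, wvec)
            fs = freq.sum(axis=1, keepdims=True)
            pi = np.clip(freq / np.where(fs > 0, fs, 1.0), 1e-6, None)
            pi /= pi.sum(axis=1, keepdims=True)
            d = _f84_vec(P, Q, pi)
            if np.any(~np.isfinite(d)):
                # clamp just above the largest finite distance: a large
                # inflation distorts the NJ Q criterion toward cross joins
                finite = d[np.isfinite(d)]
                fill = 1.25 * max(float(finite.max()) if len(finite) else 0.0, 1.0)
                d = np.where(np.isfinite(d), d, fill)
            dm = np.zeros((n, n))
            for k, (i, j) in enumerate(pairs):
                dm[i, j] = dm[j, i] = d[k]
            tree = _nj(ids, dm)
            # query groups with ref when some split isolates {query, ref}
            partner = None
            all_leaves = frozenset(ids)
            below: dict[int, frozenset] = {}
            for node in tree.postorder():
                if node.is_leaf:
                    below[id(node)] = frozenset([node.name])
                    continue
                side = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = side
                for grp in (side, all_leaves - side):
                    if len(grp) == 2 and query in grp:
                        partner = next(x for x in grp if x != query)
                if partner:
                    break
            if partner is not None:
                support[w, ref_index[partner]] += 1
    support /= replicates
    return BootscanProfile(query, refs, window, step, replicates, centers, support)
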