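"""Conversion-vs-convergence diagnostics and saturation screening.

Two sequences can come to encode the same amino acids either by gene
conversion (which copies the underlying codons) or by convergent/conserved
evolution (which does not constrain silent positions).  The codon-usage
concordance statistic therefore asks, over alignment columns where a pair
of paralogues has the identical amino acid, how often the codon is also
nucleotide-identical — near-total concordance inside a candidate region,
against a much lower background, indicates conversion.

The saturation screen tabulates transitions/transversions against F84
distance for every pair; a transition plateau beyond d ~ 0.7 marks pairs
too diverged for reliable codon-model inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .phylo import f84_distance
from .seqio import Alignment, CodonAlignment, RegionSpec, validate_regions


@dataclass
class RegionConcordance:
    name: str
    n_conserved: int  # columns where the pair's amino acids are identical
    n_identical_codon: int
    fraction: float | None  # None when no conserved columns


@dataclass
class CodonConcordanceReport:
    pair: tuple[str, str]
    regions: list[RegionConcordance]

    @property
    def overall(self) -> float | None:
        n = sum(r.n_conserved for r in self.regions)
        if n == 0:
            return None
        return sum(r.n_identical_codon for r in self.regions) / n

    def fraction(self, name: str) -> float | None:
        for r in self.regions:
            if r.name == name:
                return r.fraction
        raise KeyError(name)


def codon_usage_concordance(
    alignment: CodonAlignment,
    pair: tuple[str, str],
    regions: Sequence[RegionSpec],
) -> CodonConcordanceReport:
    """Identical-codon fraction at conserved amino acids, per region.

    A column counts as conserved when the pair's codons are gap-free and
    encode the same amino acid; it counts as concordant when the codons are
    also nucleotide-identical.  Region coordinates are 1-based nucleotide
    columns; codons partially outside a region are excluded.
    """
    validate_regions(regions, alignment.length)
    a, b = alignment[pair[0]].seq, alignment[pair[1]].seq
    prot = alignment.to_protein()
    pa, pb = prot[pair[0]].seq, prot[pair[1]].seq
    out = []
    for reg in regions:
        first_codon = (reg.start - 1 + 2) // 3  # first codon fully inside
        last_codon = reg.end // 3 - 1
        n_cons = n_id = 0
        for k in range(first_codon, last_codon + 1):
            if pa[k] == "-" or pb[k] == "-" or pa[k] != pb[k]:
                continue
            n_cons += 1
            if a[3 * k : 3 * k + 3] == b[3 * k : 3 * k + 3]:
                n_id += 1
        out.append(
            RegionConcordance(reg.name, n_cons, n_id, (n_id / n_cons) if n_cons else None)
        )
    return CodonConcordanceReport(pair, out)


@dataclass
class SaturationRecord:
    pair: tuple[str, str]
    s: float  # transitions / site
    v: float  # transversions / site
    d: float  # F84 distance


@dataclass
class SaturationReport:
    records: list[SaturationRecord]
    plateau: bool  # transitions flatten beyond d = 0.7

    def saturated_pairs(self, cutoff: float = 0.7) -> list[tuple[str, str]]:
        return [r.pair for r in self.records if not np.isfinite(r.d) or r.d > cutoff]


def saturation_table(alignment: Alignment, breakpoint: float = 0.7) -> SaturationReport:
    """Transitions/transversions vs F84 distance for all pairs.

    The plateau flag is set when the fitted slope of s against d beyond the
    breakpoint falls to <= 10% of the slope below it (each side needs >= 3
    finite points).
    """
    if len(alignment) < 2:
        raise ValueError("need >= 2 sequences")
    import itertools
    import warnings as _w

    recs = []
    for ida, idb in itertools.combinations(alignment.ids, 2):
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            d, s, v = f84_distance(alignment[ida].seq, alignment[idb].seq)
        recs.append(SaturationRecord((ida, idb), s, v, d))
    pts = [(r.d, r.s) for r in recs if np.isfinite(r.d)]
    low = [(d, s) for d, s in pts if d <= breakpoint]
    high = [(d, s) for d, s in pts if d > breakpoint]
    plateau = False
    if len(low) >= 3 and len(high) >= 3:
        sl_low = np.polyfit(*zip(*low), 1)[0]
        sl_high = np.polyfit(*zip(*high), 1)[0]
        plateau = bool(sl_low > 0 and sl_high <= 0.1 * sl_low)
    return SaturationReport(recs, plateau)


Verdict = Literal["conversion", "convergence", "inconclusive"]


def conversion_vs_convergence_verdict(
    report: CodonConcordanceReport,
    candidate_region: str = "C",
    background_fraction: float | None = None,
    margin: float = 0.2,
) -> Verdict:
    """Discriminate gene conversion from convergent evolution.

    ``conversion`` when the candidate region's identical-codon fraction
    exceeds the background (the other regions, or an explicit value) by at
    least ``margin``; ``convergence`` when it does not exceed it at all;
    ``inconclusive`` otherwise or when a side is undefined.
    """
    cand = report.fraction(candidate_region)
    if background_fraction is None:
        others = [
            r.fraction
            for r in report.regions
            if r.name != candidate_region and r.fraction is not None
        ]
        background_fraction = float(np.mean(others)) if others else None
    if cand is None or background_fraction is None:
        return "inconclusive"
    diff = cand - background_fraction
    if diff >= margin:
        return "conversion"
    if diff <= 0:
        return "convergence"
    return "inconclusive"
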