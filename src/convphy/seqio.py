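"""Sequences, alignments and alignment regions.

This module holds the small domain types every analysis stage consumes:
plain sequence records, column-aligned sets of them, in-frame codon
alignments, and named alignment regions (e.g. the N-terminal /
conversion-free and C-terminal / converted blocks of a tandem paralogue
pair).  All user-facing coordinates are 1-based inclusive alignment
columns; internally everything is 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN-")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | set("X-*")

#: residue order used by every numeric routine on protein data
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

NUC_ORDER = "ACGT"

STOP_CODONS = set(standard_dna_table.stop_codons)
CODON_TABLE = dict(standard_dna_table.forward_table)


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


class TranslationMismatch(ValueError):
    """Raised when a CDS does not translate to its protein row."""


Moltype = Literal["dna", "protein"]


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence, possibly gapped.

    ``id`` follows the four-letter species + gene convention used for the
    TLR1 family (e.g. ``GgalTLR1A`` for chicken TLR1A), but any unique
    token is accepted.
    """

    id: str
    seq: str
    moltype: Moltype = "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence id must be non-empty")
        alphabet = DNA_ALPHABET if self.moltype == "dna" else PROTEIN_ALPHABET
        bad = set(self.seq.upper()) - alphabet
        if bad:
            raise ParseError(
                f"illegal characters {sorted(bad)} in sequence {self.id!r} "
                f"for moltype {self.moltype!r}"
            )
        object.__setattr__(self, "seq", self.seq.upper())

    def ungapped(self) -> str:
        return self.seq.replace("-", "")

    def __len__(self) -> int:
        return len(self.seq)


def guess_moltype(seq: str) -> Moltype:
    letters = set(seq.upper()) - {"-", "N", "X", "*"}
    return "dna" if letters <= set("ACGT") else "protein"


class Alignment:
    """An ordered set of equal-length SequenceRecords."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise ParseError("alignment must contain at least one sequence")
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            raise ParseError(f"rows have unequal lengths: {sorted(lengths)}")
        if lengths == {0}:
            raise ParseError("zero-length alignment")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ParseError(f"duplicate sequence ids: {dup}")
        for r in records:
            if set(r.seq) == {"-"}:
                raise ParseError(f"row {r.id!r} consists only of gaps")
        self.records = records
        self._index = {r.id: k for k, r in enumerate(records)}

    # -- basic container behaviour -------------------------------------
    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def moltype(self) -> Moltype:
        return self.records[0].moltype

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        return self.records[self._index[seq_id]]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def subset(self, ids: Iterable[str]) -> "Alignment":
        return type(self)([self[i] for i in ids])

    def columns(self, idx: np.ndarray) -> "Alignment":
        """New alignment restricted to 0-based column indices ``idx``."""
        recs = [
            SequenceRecord(r.id, "".join(r.seq[i] for i in idx), r.moltype)
            for r in self.records
        ]
        return Alignment(recs)

    # -- numeric view ---------------------------------------------------
    def codes(self) -> np.ndarray:
        """(n_seq, n_col) int8 matrix; gap/ambiguous states are -1.

        DNA rows are coded over ACGT, protein rows over the 20 residues in
        :data:`AA_ORDER`.
        """
        order = NUC_ORDER if self.moltype == "dna" else AA_ORDER
        lut = np.full(128, -1, dtype=np.int8)
        for k, c in enumerate(order):
            lut[ord(c)] = k
        mat = np.frombuffer(
            "".join(r.seq for r in self.records).encode(), dtype=np.uint8
        ).reshape(len(self), self.length)
        return lut[mat]


def translate_cds(cds: str, seq_id: str = "?") -> str:
    """Translate an ungapped CDS, tolerating (and stripping) one terminal stop."""
    if len(cds) % 3:
        raise TranslationMismatch(f"{seq_id}: CDS length {len(cds)} not divisible by 3")
    aas = []
    n_codons = len(cds) // 3
    for k in range(n_codons):
        codon = cds[3 * k : 3 * k + 3]
        if codon in STOP_CODONS:
            if k == n_codons - 1:
                log.info("stripped terminal stop codon from %s", seq_id)
                break
            raise TranslationMismatch(f"{seq_id}: internal stop codon at codon {k + 1}")
        aas.append(CODON_TABLE.get(codon, "X"))
    return "".join(aas)


class CodonAlignment(Alignment):
    """A DNA alignment whose columns are in-frame codon triplets.

    The reading frame is anchored at column 1 and in-frame stop codons are
    disallowed (a terminal all-stop column is stripped with a note).
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        super().__init__(records)
        if self.moltype != "dna":
            raise ParseError("codon alignment must hold DNA")
        if self.length % 3:
            raise ParseError(f"length {self.length} not divisible by 3")
        self._strip_terminal_stops()
        self._check_stops()

    def _strip_terminal_stops(self) -> None:
        last = [r.seq[-3:] for r in self.records]
        if any(c in STOP_CODONS for c in last):
            if all(c in STOP_CODONS or c == "---" for c in last):
                log.info("stripped terminal stop-codon column")
                self.records = [
                    SequenceRecord(r.id, r.seq[:-3], r.moltype) for r in self.records
                ]
                self._index = {r.id: k for k, r in enumerate(self.records)}
            # otherwise _check_stops will complain

    def _check_stops(self) -> None:
        for r in self.records:
            for k in range(0, len(r.seq), 3):
                if r.seq[k : k + 3] in STOP_CODONS:
                    raise ParseError(
                        f"in-frame stop codon in {r.id!r} at codon {k // 3 + 1}"
                    )

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon_codes(self, codon_index: dict[str, int]) -> np.ndarray:
        """(n_seq, n_codons) int16 matrix of sense-codon indices; -1 for
        codons containing gaps or ambiguity."""
        out = np.full((len(self), self.n_codons), -1, dtype=np.int16)
        for i, r in enumerate(self.records):
            s = r.seq
            for k in range(self.n_codons):
                out[i, k] = codon_index.get(s[3 * k : 3 * k + 3], -1)
        return out

    def to_protein(self) -> Alignment:
        """Column-wise translation (codon gaps become '-')."""
        recs = []
        for r in self.records:
            aas = []
            for k in range(self.n_codons):
                codon = r.seq[3 * k : 3 * k + 3]
                aas.append("-" if "-" in codon else CODON_TABLE.get(codon, "X"))
            recs.append(SequenceRecord(r.id, "".join(aas), "protein"))
        return Alignment(recs)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, moltype: Moltype | None = None) -> list[SequenceRecord]:
    """Read FASTA, preserving order and gaps.

    Raises :class:`ParseError` on an empty file, duplicate ids or illegal
    characters.  ``moltype`` is guessed per record when not given.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        mt = moltype or guess_moltype(seq)
        records.append(SequenceRecord(rec.id, seq, mt))
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord] | Alignment, path: str | Path) -> None:
    recs = records.records if isinstance(records, Alignment) else list(records)
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in recs]
    SeqIO.write(bio, str(path), "fasta")


def read_alignment(path: str | Path, moltype: Moltype | None = None) -> Alignment:
    return Alignment(read_fasta(path, moltype))


def read_codon_alignment(path: str | Path) -> CodonAlignment:
    return CodonAlignment(read_fasta(path, "dna"))


# ---------------------------------------------------------------------------
# Back translation
# ---------------------------------------------------------------------------

def backtranslate_alignment(
    protein_alignment: Alignment, cds_records: Sequence[SequenceRecord]
) -> CodonAlignment:
    """Expand a protein alignment to codons using the matching CDSs.

    Each amino-acid column becomes one codon column; protein gaps become
    ``---``.  Every protein row must equal the translation of its CDS
    (standard genetic code; one terminal stop tolerated), otherwise a
    :class:`TranslationMismatch` naming the sequence and position is raised.
    """
    cds_by_id = {r.id: r for r in cds_records}
    out = []
    for prot in protein_alignment.records:
        if prot.id not in cds_by_id:
            raise TranslationMismatch(f"no CDS provided for {prot.id!r}")
        cds = cds_by_id[prot.id].ungapped()
        expected = translate_cds(cds, prot.id)
        aligned_aas = prot.seq.replace("-", "")
        if aligned_aas != expected:
            pos = next(
                (k for k, (a, b) in enumerate(zip(aligned_aas, expected)) if a != b),
                min(len(aligned_aas), len(expected)),
            )
            raise TranslationMismatch(
                f"{prot.id}: protein row does not match CDS translation at "
                f"residue {pos + 1} (row has {len(aligned_aas)} residues, "
                f"CDS encodes {len(expected)})"
            )
        codons, k = [], 0
        for aa in prot.seq:
            if aa == "-":
                codons.append("---")
            else:
                codons.append(cds[3 * k : 3 * k + 3])
                k += 1
        out.append(SequenceRecord(prot.id, "".join(codons), "dna"))
    return CodonAlignment(out)


# ---------------------------------------------------------------------------
# Identities
# ---------------------------------------------------------------------------

def pairwise_identity(
    alignment: Alignment, id_a: str, id_b: str, level: Literal["nucleotide", "aminoacid"] | None = None
) -> float:
    """Fraction of matching columns between two rows.

    The denominator excludes every column holding a gap in either row
    (standard pairwise-identity convention); ``N``/``X`` count as
    mismatches.  Symmetric in its two ids.
    """
    a, b = alignment[id_a].seq, alignment[id_b].seq
    num = den = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        den += 1
        if x == y and x not in "NX":
            num += 1
    if den == 0:
        raise ValueError(f"no gap-free shared columns between {id_a!r} and {id_b!r}")
    return num / den


def identity_summary(
    alignment: Alignment, pairs: Sequence[tuple[str, str]]
) -> tuple[float, float]:
    """(mean, sd) of pairwise identities over a list of id pairs.

    The standard deviation uses the n-1 denominator (0.0 for a single pair).
    """
    vals = np.array([pairwise_identity(alignment, a, b) for a, b in pairs])
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    """A named alignment region, 1-based inclusive columns."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid region {self.name}: {self.start}-{self.end}")

    @property
    def slice(self) -> slice:
        return slice(self.start - 1, self.end)

    def __len__(self) -> int:
        return self.end - self.start + 1


def validate_regions(regions: Sequence[RegionSpec], length: int) -> None:
    for r in regions:
        if r.end > length:
            raise ValueError(f"region {r.name} ({r.start}-{r.end}) exceeds alignment length {length}")
    spans = sorted((r.start, r.end, r.name) for r in regions)
    for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError(f"regions {n1} and {n2} overlap")


def partition_regions(
    alignment: Alignment, regions: Sequence[RegionSpec]
) -> dict[str, Alignment]:
    """Cut an alignment into named sub-alignments.

    For codon alignments, region boundaries not on codon boundaries are
    trimmed inward to the enclosing whole codons, with a warning.
    """
    validate_regions(regions, alignment.length)
    is_codon = isinstance(alignment, CodonAlignment)
    out: dict[str, Alignment] = {}
    for r in regions:
        start, end = r.start, r.end
        if is_codon:
            t_start = start + (-(start - 1)) % 3
            t_end = end - end % 3
            if (t_start, t_end) != (start, end):
                warnings.warn(
                    f"region {r.name} trimmed to codon boundaries "
                    f"{t_start}-{t_end} (was {start}-{end})",
                    stacklevel=2,
                )
                start, end = t_start, t_end
        recs = [
            SequenceRecord(x.id, x.seq[start - 1 : end], x.moltype)
            for x in alignment.records
        ]
        out[r.name] = CodonAlignment(recs) if is_codon else Alignment(recs)
    return out


def read_region_tsv(path: str | Path) -> dict[str, list[RegionSpec]]:
    """Region specs from TSV with header ``group name start end``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    need = {"group", "name", "start", "end"}
    if not need <= set(df.columns):
        raise ParseError(f"region TSV must have columns {sorted(need)}")
    out: dict[str, list[RegionSpec]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["group"]), []).append(
            RegionSpec(str(row["name"]), int(row["start"]), int(row["end"]))
        )
    return out
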