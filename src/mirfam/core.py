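"""Shared coordinate and sequence primitives.

Coordinates are 1-based and inclusive throughout the library.  Minus-strand
loci are stored with ``start <= end``; report writers may render them in the
descending ``12993196-12993098(-)`` style, but that is presentation only.

Genomic sequences are handled as DNA (``ACGTN``); miRNA-side sequences as RNA
(``ACGUN``).  :func:`to_dna` / :func:`to_rna` convert between the alphabets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicLocus",
    "GffFeature",
    "to_dna",
    "to_rna",
    "revcomp_dna",
    "revcomp_rna",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "pairs_rna",
]

_DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMPLEMENT = str.maketrans("ACGUNacgun", "UGCANugcan")

#: Canonical RNA pairs, Watson-Crick plus the G:U wobble.
RNA_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")})
GU_PAIRS = frozenset({("G", "U"), ("U", "G")})


def to_dna(seq: str) -> str:
    """Uppercase and convert U -> T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and convert T -> U."""
    return seq.upper().replace("T", "U")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def pairs_rna(a: str, b: str) -> bool:
    """True if the two RNA bases form a canonical or wobble pair."""
    return (a, b) in RNA_PAIRS


@dataclass(frozen=True, order=True)
class GenomicLocus:
    """A stranded, 1-based, inclusive interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 1 <= start <= end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "GenomicLocus") -> int:
        """Overlap length in nt (strand-blind); 0 when disjoint or other chrom."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def gap_to(self, other: "GenomicLocus") -> Optional[int]:
        """Intervening sequence length between two non-overlapping loci.

        ``gap = downstream.start - upstream.end - 1``; None on different
        chromosomes, negative-free (overlapping loci return None as well).
        """
        if self.chrom != other.chrom:
            return None
        a, b = sorted((self, other), key=lambda l: l.start)
        gap = b.start - a.end - 1
        return gap if gap >= 0 else None

    def extract(self, genome: Mapping[str, str]) -> str:
        """Strand-aware DNA sequence of this locus from a chrom->sequence dict."""
        chrom_seq = genome[self.chrom]
        if self.end > len(chrom_seq):
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end} exceeds chromosome "
                f"length {len(chrom_seq)}"
            )
        seq = chrom_seq[self.start - 1 : self.end].upper()
        return revcomp_dna(seq) if self.strand == "-" else seq

    def expanded(self, flank: int, chrom_len: int) -> "GenomicLocus":
        """Locus widened by ``flank`` nt on both sides, clipped to the chromosome."""
        if flank < 0:
            raise ValueError("flank must be >= 0")
        return replace(
            self, start=max(1, self.start - flank), end=min(chrom_len, self.end + flank)
        )

    def display(self) -> str:
        """Report-style rendering; minus strand shown start-high."""
        if self.strand == "-":
            return f"{self.chrom}:{self.end}-{self.start}(-)"
        return f"{self.chrom}:{self.start}-{self.end}(+)"


# ---------------------------------------------------------------------------
# FASTA / GFF3 I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Dict[str, str]:
    """FASTA -> ordered dict of id -> uppercase sequence."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class GffFeature:
    """One GFF3 row; attributes kept as a plain dict."""

    seqid: str
    source: str
    ftype: str
    start: int
    end: int
    score: str
    strand: str
    phase: str
    attributes: Dict[str, str] = field(hash=False)

    @property
    def feature_id(self) -> str:
        return self.attributes.get("ID", f"{self.ftype}:{self.seqid}:{self.start}")

    @property
    def parent(self) -> Optional[str]:
        return self.attributes.get("Parent")

    @property
    def locus(self) -> GenomicLocus:
        return GenomicLocus(self.seqid, self.start, self.end,
                            self.strand if self.strand in "+-" else "+")

    def to_line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items()) or "."
        return "\t".join(
            [self.seqid, self.source, self.ftype, str(self.start), str(self.end),
             self.score, self.strand, self.phase, attrs]
        )


def _parse_gff_line(line: str, lineno: int) -> GffFeature:
    cols = line.rstrip("\n").split("\t")
    if len(cols) != 9:
        raise ValueError(f"malformed GFF3 line {lineno}: expected 9 columns, got {len(cols)}")
    try:
        start, end = int(cols[3]), int(cols[4])
    except ValueError as exc:
        raise ValueError(f"malformed GFF3 line {lineno}: non-integer coordinates") from exc
    if start < 1 or end < start:
        raise ValueError(f"malformed GFF3 line {lineno}: bad interval {start}-{end}")
    attributes: Dict[str, str] = {}
    if cols[8] not in (".", ""):
        for chunk in cols[8].rstrip(";").split(";"):
            if not chunk:
                continue
            if "=" not in chunk:
                raise ValueError(f"malformed GFF3 line {lineno}: attribute {chunk!r}")
            key, value = chunk.split("=", 1)
            attributes[key.strip()] = value.strip()
    return GffFeature(cols[0], cols[1], cols[2], start, end,
                      cols[5], cols[6], cols[7], attributes)


def read_gff3(path: str | Path) -> List[GffFeature]:
    features = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            features.append(_parse_gff_line(line, lineno))
    return features


def write_gff3(features: Sequence[GffFeature], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for feature in features:
            handle.write(feature.to_line() + "\n")
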