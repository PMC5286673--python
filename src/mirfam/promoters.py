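"""Promoter extraction and IUPAC cis-element scanning.

A promoter is the window upstream of a gene's transcription start site
(1,500 bp by default), taken on the gene's strand and reverse-complemented
for minus-strand genes.  When no TSS table is supplied the precursor 5' end
stands in for the TSS -- for plant MIR genes most predicted promoters sit
within the first kilobase upstream of the fold-back, so this default loses
little.

Motifs are IUPAC patterns scanned by exact degenerate matching at every
offset (and on the reverse strand for double-stranded elements); the result
is a genes x motifs presence/absence matrix with an occurrence-count layer,
plus per-motif prevalence percentages grouped by functional class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio.Data.IUPACData import ambiguous_dna_values

from .core import GenomicLocus, revcomp_dna, to_dna

__all__ = [
    "MotifDef",
    "PromoterMatrix",
    "load_motif_catalogue",
    "packaged_motif_catalogue",
    "extract_upstream",
    "scan_motifs",
    "motif_prevalence",
    "iupac_to_regex",
    "revcomp_iupac",
    "expand_iupac_choice",
]

MOTIF_CLASSES = (
    "light",
    "hormone",
    "seed",
    "leaf",
    "biosynthesis/metabolism",
    "cell-cycle/circadian",
    "defense/stress",
    "other",
)

_IUPAC = {k.upper(): v.upper() for k, v in ambiguous_dna_values.items()}


@dataclass(frozen=True)
class MotifDef:
    name: str
    pattern: str  # IUPAC DNA
    motif_class: str = "other"
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"motif {self.name}: empty pattern")
        bad = set(self.pattern.upper()) - set(_IUPAC)
        if bad:
            raise ValueError(f"motif {self.name}: invalid IUPAC letters {sorted(bad)}")
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(
                f"motif {self.name}: unknown class {self.motif_class!r}; "
                f"expected one of {MOTIF_CLASSES}"
            )


_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp_iupac(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (degeneracy-aware)."""
    return pattern.upper().translate(_IUPAC_COMPLEMENT)[::-1]


def iupac_to_regex(pattern: str) -> str:
    """IUPAC DNA pattern -> regex character classes."""
    parts = []
    for letter in pattern.upper():
        options = _IUPAC[letter]
        parts.append(options if len(options) == 1 else f"[{options}]")
    return "".join(parts)


def expand_iupac_choice(pattern: str, rng: np.random.Generator) -> str:
    """One concrete word matching an IUPAC pattern (random degeneracy choice)."""
    return "".join(
        _IUPAC[l][int(rng.integers(len(_IUPAC[l])))] for l in pattern.upper()
    )


def load_motif_catalogue(source) -> List[MotifDef]:
    """Motif catalogue from YAML: list of {name, pattern, class, both_strands}."""
    if hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        with open(source) as handle:
            raw = yaml.safe_load(handle)
    catalogue = []
    for entry in raw["motifs"]:
        catalogue.append(
            MotifDef(
                name=entry["name"],
                pattern=entry["pattern"],
                motif_class=entry.get("class", "other"),
                both_strands=bool(entry.get("both_strands", True)),
            )
        )
    names = [m.name for m in catalogue]
    if len(names) != len(set(names)):
        raise ValueError("duplicate motif names in catalogue")
    return catalogue


def packaged_motif_catalogue() -> List[MotifDef]:
    """The catalogue shipped with the package (editable IUPAC definitions)."""
    with resources.files("mirfam").joinpath("data/motifs.yaml").open() as handle:
        return load_motif_catalogue(handle)


def extract_upstream(
    gene_loci: Mapping[str, GenomicLocus],
    genome: Mapping[str, str],
    tss_table: Optional[Mapping[str, int]] = None,
    window: int = 1500,
) -> Dict[str, Dict]:
    """Upstream promoter windows per gene.

    The TSS defaults to the gene's 5' end.  For a plus-strand TSS at t the
    window is [t - window, t - 1]; minus-strand windows are the mirror image
    and are returned reverse-complemented.  Windows clipped by a chromosome
    end record their realized length and a ``clipped`` flag.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    out: Dict[str, Dict] = {}
    for gene_id in sorted(gene_loci):
        locus = gene_loci[gene_id]
        chrom_seq = genome[locus.chrom]
        tss = (tss_table or {}).get(gene_id)
        if tss is None:
            tss = locus.start if locus.strand == "+" else locus.end
        if not 1 <= tss <= len(chrom_seq):
            raise ValueError(f"{gene_id}: TSS {tss} outside {locus.chrom}")
        if locus.strand == "+":
            start, end = max(1, tss - window), tss - 1
            if end < start:
                seq = ""
            else:
                seq = to_dna(chrom_seq[start - 1 : end])
        else:
            start, end = tss + 1, min(len(chrom_seq), tss + window)
            seq = revcomp_dna(to_dna(chrom_seq[start - 1 : end])) if end >= start else ""
        out[gene_id] = {
            "sequence": seq,
            "tss": tss,
            "realized_length": len(seq),
            "clipped": len(seq) < window,
        }
    return out


@dataclass(frozen=True)
class PromoterMatrix:
    """Genes x motifs occurrence counts with a derived 0/1 presence layer."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative occurrence count")

    @property
    def presence(self) -> pd.DataFrame:
        return (self.counts > 0).astype(int)

    @property
    def gene_ids(self) -> List[str]:
        return list(self.counts.index)


def scan_motifs(
    promoters: Mapping[str, str], catalogue: Sequence[MotifDef]
) -> PromoterMatrix:
    """Scan every promoter for every motif; overlapping matches all count."""
    if not catalogue:
        raise ValueError("empty motif catalogue")
    gene_ids = list(promoters)
    counts = pd.DataFrame(0, index=gene_ids, columns=[m.name for m in catalogue])
    for motif in catalogue:
        body = iupac_to_regex(motif.pattern)
        if motif.both_strands:
            # one alternation so a position matching both orientations
            # (palindromic elements) counts once
            body = f"{body}|{iupac_to_regex(revcomp_iupac(motif.pattern))}"
        pattern = re.compile(f"(?=({body}))")
        for gene_id in gene_ids:
            seq = to_dna(promoters[gene_id])
            counts.loc[gene_id, motif.name] = len(pattern.findall(seq))
    return PromoterMatrix(counts)


def motif_prevalence(
    matrix: PromoterMatrix, catalogue: Sequence[MotifDef]
) -> pd.DataFrame:
    """Percent of genes containing each motif, grouped by motif class."""
    presence = matrix.presence
    if presence.empty:
        raise ValueError("empty promoter matrix")
    classes = {m.name: m.motif_class for m in catalogue}
    rows = []
    for motif in presence.columns:
        pct = round(100.0 * presence[motif].sum() / len(presence), 1)
        rows.append(
            {"motif": motif, "motif_class": classes.get(motif, "other"),
             "n_genes": int(presence[motif].sum()), "prevalence_pct": pct}
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["motif_class", "prevalence_pct", "motif"], ascending=[True, False, True]
    ).reset_index(drop=True)
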