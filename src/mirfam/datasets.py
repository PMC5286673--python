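"""Bundled reference tables for the soybean miR166 family.

Two small TSVs ship with the package:

* the characteristics of the five novel soybean precursors (pre-miR166v-z):
  mature sequence, arm, genomic location and the screen statistics
  (U content, MFE, MFEI, miRNA/miRNA* mismatches, G:U pairs);
* a synthetic reconstruction of the genomic layout of all 26 family loci
  (see the file header for exactly which facts it preserves), used for
  cluster/gene-collapsing analyses when the full coordinate table of the
  21 previously known members is not available.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict

import pandas as pd

from .core import GenomicLocus
from .hairpin import CriteriaReport

__all__ = [
    "novel_precursor_table",
    "novel_precursor_reports",
    "family_loci_synthetic",
]


def _read_tsv(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("mirfam").joinpath(f"data/{name}").open() as handle:
        return pd.read_csv(handle, sep="\t", **kwargs)


def novel_precursor_table() -> pd.DataFrame:
    """Characteristics of the five novel soybean pre-miR166s (v-z)."""
    return _read_tsv("novel_mir166_characteristics.tsv")


def novel_precursor_reports() -> list:
    """The bundled characteristics as CriteriaReport records.

    GC fraction is back-solved from the published MFEI via the index formula
    (GC% = (|MFE|/length x 100) / MFEI); duplex statistics come from the
    table columns.  All seven flags are set True: these precursors passed
    the original screen.
    """
    reports = []
    for _, row in novel_precursor_table().iterrows():
        gc = (abs(row.mfe) / row.precursor_len * 100.0) / (row.mfei * 100.0)
        reports.append(
            CriteriaReport(
                precursor_id=row.id,
                precursor_len=int(row.precursor_len),
                gc_fraction=round(gc, 3),
                u_fraction=float(row.u_content),
                mfe=float(row.mfe),
                mfei=float(row.mfei),
                n_mismatch_vs_reference=int(row.nm_vs_homolog),
                arm=row.arm,
                duplex_unpaired=int(row.nm_star),
                gu_pairs_in_mature=int(row.gu_pairs),
                max_bulge_in_mature=None,
                criteria_flags={f"c{i}": True for i in range(1, 8)},
            )
        )
    return reports


def family_loci_synthetic() -> Dict[str, GenomicLocus]:
    """Synthetic genomic layout of the 26 family loci (id -> locus)."""
    frame = _read_tsv("family_loci_synthetic.tsv", comment="#")
    return {
        row.id: GenomicLocus(row.chrom, int(row.start), int(row.end), row.strand)
        for _, row in frame.iterrows()
    }
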