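"""miRNA target prediction by complementarity scoring.

Sites are scored with the Allen-type penalty scheme used by plant target
predictors: each alignment position contributes 0 for a Watson-Crick pair,
0.5 for a G:U wobble, 1.0 for a mismatch and 2.0 for a gap, with all
penalties doubled in the seed region (miRNA positions 2-13 counted from the
5' end).  The cumulative penalty is the *expectation*; sites at or below
the cutoff (3.0 by default) are reported.

The miRNA pairs antiparallel to the transcript, so a site is compared
against the reverse complement of the mature; at most one gap per site is
considered.  Slicer cleavage is predicted opposite miRNA positions 10-11;
a mismatch in the central region (positions 9-11) flags the hit as likely
translational inhibition instead of cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .core import revcomp_rna, to_rna

__all__ = [
    "TargetScheme",
    "TargetHit",
    "score_site",
    "scan_transcriptome",
    "map_cleavage",
    "collapse_uts",
]

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class TargetScheme:
    """Penalty scheme; defaults follow the Allen scoring convention."""

    mismatch: float = 1.0
    gu: float = 0.5
    gap: float = 2.0
    seed_start: int = 2  # miRNA positions with doubled penalties, inclusive
    seed_end: int = 13
    cutoff: float = 3.0
    max_gaps: int = 1
    central_start: int = 9  # central mismatch => translational inhibition
    central_end: int = 11

    def position_weight(self, mirna_pos: int) -> float:
        return 2.0 if self.seed_start <= mirna_pos <= self.seed_end else 1.0


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    transcript_id: str
    site_span: Tuple[int, int]  # 1-based inclusive on the transcript
    expectation: float
    mirna_aln: str  # mature 5'->3'
    pairing: str  # '|' pair, 'o' wobble, '.' mismatch, '-' gap column
    site_aln: str  # site 3'->5' (antiparallel to the miRNA)
    cleavage_pos: int
    inhibition_mode: str  # "cleavage" or "translation"

    def __post_init__(self) -> None:
        if self.expectation < 0:
            raise ValueError("expectation must be >= 0")
        if not self.site_span[0] <= self.cleavage_pos <= self.site_span[1]:
            raise ValueError("cleavage position must fall inside the site span")


def _column_penalty(mirna_base: str, site_base: str, pos: int, scheme: TargetScheme) -> Tuple[float, str]:
    pair = (mirna_base, site_base)
    if pair in _PAIRS:
        return 0.0, "|"
    if pair in _WOBBLE:
        return scheme.gu * scheme.position_weight(pos), "o"
    return scheme.mismatch * scheme.position_weight(pos), "."


def score_site(
    mirna: str,
    site: str,
    scheme: TargetScheme = TargetScheme(),
) -> Tuple[float, str]:
    """Expectation of the best miRNA/site alignment with at most one gap.

    ``site`` is the target fragment written 3'->5' (i.e. already reversed so
    that position i faces miRNA position i+1); its length may differ from
    the mature's by at most ``max_gaps``.  Returns (expectation, pairing
    string).  Gap penalties are position-weighted like substitutions.
    """
    m = to_rna(mirna)
    s = to_rna(site)
    delta = len(s) - len(m)
    if abs(delta) > scheme.max_gaps:
        raise ValueError(
            f"site length {len(s)} incompatible with mature length {len(m)} "
            f"under {scheme.max_gaps} gap(s)"
        )
    if delta == 0:
        total = 0.0
        marks = []
        for i, (mb, sb) in enumerate(zip(m, s), start=1):
            pen, mark = _column_penalty(mb, sb, i, scheme)
            total += pen
            marks.append(mark)
        return total, "".join(marks)
    best: Optional[Tuple[float, str]] = None
    L = len(m)
    if delta == 1:  # extra target base bulged out (gap column on the miRNA side)
        for g in range(len(s)):  # site index that faces the gap
            total = scheme.gap * scheme.position_weight(min(g + 1, L))
            marks = []
            for i in range(g):
                pen, mark = _column_penalty(m[i], s[i], i + 1, scheme)
                total += pen
                marks.append(mark)
            marks.append("-")
            for i in range(g, L):
                pen, mark = _column_penalty(m[i], s[i + 1], i + 1, scheme)
                total += pen
                marks.append(mark)
            if best is None or total < best[0]:
                best = (total, "".join(marks))
    else:  # delta == -1: a miRNA position faces a gap in the site
        for g in range(1, L + 1):  # unopposed miRNA position, 1-based
            total = scheme.gap * scheme.position_weight(g)
            marks = []
            for pos in range(1, L + 1):
                if pos == g:
                    marks.append("-")
                    continue
                si = pos - 1 if pos < g else pos - 2
                pen, mark = _column_penalty(m[pos - 1], s[si], pos, scheme)
                total += pen
                marks.append(mark)
            if best is None or total < best[0]:
                best = (total, "".join(marks))
    assert best is not None
    return best


def scan_transcriptome(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    scheme: TargetScheme = TargetScheme(),
) -> List[TargetHit]:
    """All target sites with expectation <= cutoff, over all miRNAs.

    Ungapped sites at every offset are scored first; single-gap variants are
    considered when they can beat the cutoff.  Hits are sorted by
    (expectation, mirna, transcript, position); overlapping placements of
    the same miRNA on the same transcript keep the best (leftmost on ties).
    """
    hits: List[TargetHit] = []
    for mirna_id in sorted(mirnas):
        mature = to_rna(mirnas[mirna_id])
        L = len(mature)
        for tx_id in sorted(transcripts):
            tx = to_rna(transcripts[tx_id])
            found: List[Tuple[float, int, int, str]] = []  # (exp, start0, len, marks)
            for off in range(0, len(tx) - L + 1):
                window = tx[off : off + L]
                site = window[::-1]  # 3'->5' against the miRNA
                expectation, marks = score_site(mature, site, scheme)
                if expectation <= scheme.cutoff:
                    found.append((expectation, off, L, marks))
            if scheme.max_gaps >= 1:
                for width in (L - 1, L + 1):
                    for off in range(0, len(tx) - width + 1):
                        site = tx[off : off + width][::-1]
                        expectation, marks = score_site(mature, site, scheme)
                        if expectation <= scheme.cutoff:
                            found.append((expectation, off, width, marks))
            for expectation, off, width, marks in _best_per_region(found):
                span = (off + 1, off + width)
                hit = _finalize_hit(
                    mirna_id, mature, tx_id, tx, span, expectation, marks, scheme
                )
                hits.append(hit)
    hits.sort(key=lambda h: (h.expectation, h.mirna_id, h.transcript_id, h.site_span))
    return hits


def _best_per_region(found: List[Tuple[float, int, int, str]]) -> List[Tuple[float, int, int, str]]:
    """Collapse overlapping candidate placements to the best (leftmost tie-break)."""
    kept: List[Tuple[float, int, int, str]] = []
    for cand in sorted(found, key=lambda c: (c[0], c[1])):
        _, off, width, _ = cand
        if any(not (off + width <= k[1] or k[1] + k[2] <= off) for k in kept):
            continue
        kept.append(cand)
    return kept


def _finalize_hit(
    mirna_id: str,
    mature: str,
    tx_id: str,
    tx: str,
    span: Tuple[int, int],
    expectation: float,
    marks: str,
    scheme: TargetScheme,
) -> TargetHit:
    site = tx[span[0] - 1 : span[1]][::-1]
    cleavage = map_cleavage_position(span, len(mature))
    central = marks_central_mismatch(marks, scheme)
    return TargetHit(
        mirna_id=mirna_id,
        transcript_id=tx_id,
        site_span=span,
        expectation=round(expectation, 2),
        mirna_aln=mature,
        pairing=marks,
        site_aln=site,
        cleavage_pos=cleavage,
        inhibition_mode="translation" if central else "cleavage",
    )


def map_cleavage_position(site_span: Tuple[int, int], mirna_len: int) -> int:
    """Transcript coordinate opposite miRNA position 10.

    The canonical slicer cut falls in the bond between the bases opposite
    miRNA positions 10 and 11; the returned coordinate is the 10th-position
    base (the 5' side of the scissile bond on the transcript's antisense
    reading, i.e. ``site_end - 9``).
    """
    return site_span[1] - 9


def map_cleavage(hit: TargetHit) -> int:
    """Predicted cleavage coordinate for a hit (see map_cleavage_position)."""
    return map_cleavage_position(hit.site_span, len(hit.mirna_aln))


def marks_central_mismatch(marks: str, scheme: TargetScheme = TargetScheme()) -> bool:
    central = marks[scheme.central_start - 1 : scheme.central_end]
    return any(c in ".-" for c in central)


def collapse_uts(hits: Sequence[TargetHit]) -> List[Dict]:
    """Collapse hits to unique target sites (UTS) by exact site sequence.

    Sites are numbered UTS01, UTS02, ... in first-seen order; members list
    the contributing (mirna, transcript, span) triples.  Idempotent: the
    site sequences of the output are pairwise distinct.
    """
    groups: Dict[str, Dict] = {}
    order: List[str] = []
    for hit in hits:
        key = to_rna(hit.site_aln)
        if key not in groups:
            order.append(key)
            groups[key] = {"site_seq": key, "members": []}
        groups[key]["members"].append(
            (hit.mirna_id, hit.transcript_id, hit.site_span)
        )
    out = []
    for idx, key in enumerate(order, start=1):
        entry = groups[key]
        entry["uts_id"] = f"UTS{idx:02d}"
        out.append(entry)
    return out
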