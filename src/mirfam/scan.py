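"""Homology search for family-like precursor loci.

Reference precursor (or mature) sequences are aligned locally against both
strands of the genome; candidate windows that overlap annotated coding or
structural-RNA features (CDS, tRNA, rRNA, snRNA, snoRNA by default) are then
discarded, mirroring the usual homology-screen practice of removing
protein-coding and housekeeping-RNA matches while keeping intron/UTR-hosted
candidates.

The search runs Smith-Waterman local alignment (Biopython's PairwiseAligner)
over overlapping chunks of each chromosome, iteratively masking each
accepted hit so that several nearby loci -- clustered precursors sit within
a few hundred nt of each other -- are all recovered.  This exact search is
adequate for desk-scale genomes; an external seeded aligner can be swapped
in behind :func:`local_align_search` without changing any downstream
contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from Bio import Align

from .core import GenomicLocus, GffFeature, revcomp_dna, to_dna

__all__ = [
    "CandidateHit",
    "ScanParams",
    "local_align_search",
    "exclude_annotated_overlaps",
    "expand_candidate_window",
    "hits_to_bed",
    "DEFAULT_EXCLUDED_TYPES",
]

DEFAULT_EXCLUDED_TYPES = frozenset({"CDS", "tRNA", "rRNA", "snRNA", "snoRNA"})


@dataclass(frozen=True)
class CandidateHit:
    locus: GenomicLocus
    query_id: str
    alignment_score: float
    identity_pct: float
    query_coverage: float

    def __post_init__(self) -> None:
        if not 0 <= self.identity_pct <= 100:
            raise ValueError("identity_pct must be within [0, 100]")
        if not 0 <= self.query_coverage <= 1:
            raise ValueError("query_coverage must be within [0, 1]")


@dataclass(frozen=True)
class ScanParams:
    """Alignment scoring and acceptance thresholds for the homology search."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -2.0
    min_identity_pct: float = 80.0
    min_coverage: float = 0.8
    chunk_size: int = 3000
    max_hits_per_chunk: int = 8


def _make_aligner(params: ScanParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _alignment_stats(alignment, query_len: int) -> Tuple[float, float, int, int]:
    """(identity_pct, coverage, target_start, target_end) of a local alignment."""
    blocks_t, blocks_q = alignment.aligned
    if len(blocks_t) == 0:
        return 0.0, 0.0, 0, 0
    target, query = alignment.target, alignment.query
    matches = 0
    columns = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        if prev_t is not None:  # count gap columns between aligned blocks
            columns += (ts - prev_t) + (qs - prev_q)
        matches += sum(a == b for a, b in zip(target[ts:te], query[qs:qe]))
        columns += te - ts
        prev_t, prev_q = te, qe
    identity = 100.0 * matches / columns if columns else 0.0
    q_span = blocks_q[-1][1] - blocks_q[0][0]
    coverage = q_span / query_len
    return identity, coverage, int(blocks_t[0][0]), int(blocks_t[-1][1])


def _scan_chunk(
    chunk: str,
    query_id: str,
    query: str,
    aligner: Align.PairwiseAligner,
    params: ScanParams,
) -> List[Tuple[int, int, float, float, float]]:
    """All acceptable hits of one query in one chunk, via iterative masking.

    Returns (start0, end0, score, identity, coverage) tuples in chunk
    coordinates (0-based half-open).
    """
    out = []
    working = chunk
    min_score = params.match * len(query) * params.min_coverage * 0.5
    for _ in range(params.max_hits_per_chunk):
        alignments = aligner.align(working, query)
        if not alignments or alignments.score < min_score:
            break
        best = alignments[0]
        identity, coverage, t0, t1 = _alignment_stats(best, len(query))
        if t1 <= t0:
            break
        accepted = identity >= params.min_identity_pct and coverage >= params.min_coverage
        if accepted:
            out.append((t0, t1, float(best.score), identity, coverage))
        # mask the aligned window either way so the loop always progresses
        working = working[:t0] + "N" * (t1 - t0) + working[t1:]
        if not accepted:
            break
    return out


def local_align_search(
    genome: Mapping[str, str],
    queries: Mapping[str, str],
    params: ScanParams = ScanParams(),
) -> List[CandidateHit]:
    """Local-alignment search of all queries against both genome strands.

    Hits passing the identity/coverage thresholds are reported with plus-
    strand coordinates; overlapping hits from the same query keep only the
    best-scoring one.  Sorted by (chrom, start).
    """
    if not genome:
        raise ValueError("empty genome")
    if not queries:
        raise ValueError("no query sequences")
    aligner = _make_aligner(params)
    raw: List[CandidateHit] = []
    for query_id in sorted(queries):
        query = to_dna(queries[query_id])
        if not query.strip("N"):
            warnings.warn(f"query {query_id} is all-N; skipped")
            continue
        step = max(params.chunk_size - (len(query) + 100), params.chunk_size // 2)
        for chrom in sorted(genome):
            chrom_seq = to_dna(genome[chrom])
            L = len(chrom_seq)
            for strand in ("+", "-"):
                target = chrom_seq if strand == "+" else revcomp_dna(chrom_seq)
                for chunk_start in range(0, max(1, L), step):
                    chunk = target[chunk_start : chunk_start + params.chunk_size]
                    if len(chunk) < len(query) // 2:
                        continue
                    for t0, t1, score, identity, coverage in _scan_chunk(
                        chunk, query_id, query, aligner, params
                    ):
                        s, e = chunk_start + t0, chunk_start + t1 - 1  # 0-based incl.
                        if strand == "-":
                            s, e = L - 1 - e, L - 1 - s
                        raw.append(
                            CandidateHit(
                                GenomicLocus(chrom, s + 1, e + 1, strand),
                                query_id, score, round(identity, 3), round(coverage, 3),
                            )
                        )
    return _dedupe_hits(raw)


def _dedupe_hits(hits: Sequence[CandidateHit]) -> List[CandidateHit]:
    """Collapse overlapping same-query hits to the best-scoring one."""
    kept: List[CandidateHit] = []
    for hit in sorted(hits, key=lambda h: -h.alignment_score):
        if any(
            k.query_id == hit.query_id
            and k.locus.strand == hit.locus.strand
            and k.locus.overlap(hit.locus) > 0
            for k in kept
        ):
            continue
        kept.append(hit)
    return sorted(kept, key=lambda h: (h.locus.chrom, h.locus.start, h.locus.strand))


def exclude_annotated_overlaps(
    hits: Sequence[CandidateHit],
    annotation: Sequence[GffFeature],
    excluded_feature_types: Set[str] = DEFAULT_EXCLUDED_TYPES,
    min_overlap_fraction: float = 0.5,
) -> Tuple[List[CandidateHit], List[Tuple[CandidateHit, str]]]:
    """Drop hits overlapping excluded feature types on either strand.

    A hit is excluded iff at least ``min_overlap_fraction`` of its own length
    overlaps a feature of an excluded type; intronic/UTR-hosted hits survive
    because introns and UTRs are not in the excluded set.  Each exclusion
    records the offending feature id and type.
    """
    blockers = [f for f in annotation if f.ftype in excluded_feature_types]
    kept: List[CandidateHit] = []
    excluded: List[Tuple[CandidateHit, str]] = []
    for hit in hits:
        reason = None
        for feature in blockers:
            ov = hit.locus.overlap(feature.locus)
            if ov / hit.locus.length >= min_overlap_fraction:
                reason = f"{feature.ftype}:{feature.feature_id}"
                break
        if reason is None:
            kept.append(hit)
        else:
            excluded.append((hit, reason))
    return kept, excluded


def expand_candidate_window(
    hit: CandidateHit, flank_nt: int, genome: Mapping[str, str]
) -> GenomicLocus:
    """Widen a hit into a folding window, clipped at chromosome ends."""
    return hit.locus.expanded(flank_nt, len(genome[hit.locus.chrom]))


def hits_to_bed(hits: Iterable[CandidateHit]) -> str:
    """BED6 text: name = query id, score = alignment score."""
    lines = []
    for hit in hits:
        loc = hit.locus
        lines.append(
            f"{loc.chrom}\t{loc.start - 1}\t{loc.end}\t{hit.query_id}"
            f"\t{hit.alignment_score:g}\t{loc.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
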