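"""Genomic characterization of a validated precursor family.

Covers the family-level genomics questions: which precursors sit in
same-strand clusters (candidate polycistronic genes), how clusters collapse
into gene loci, whether each precursor is intergenic or hosted inside a gene
(intron / exon / UTR, sense or antisense), which paralog pairs arose by
tandem versus segmental duplication, and how the family is distributed over
chromosomes.

Conventions: coordinates 1-based inclusive; the cluster gap is the
intervening sequence length (end of the upstream precursor to the start of
the downstream one, minus one); clustering uses ``gap <= max_gap`` with the
3-kb default, while tandem duplication uses strictly ``separation < 3 kb``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .core import GenomicLocus, GffFeature

__all__ = [
    "ClusterCall",
    "DuplicationCall",
    "detect_clusters",
    "collapse_to_genes",
    "classify_genomic_context",
    "classify_duplications",
    "summarize_chromosomes",
    "selection_class",
]

MAX_CLUSTER_GAP = 3000
TANDEM_MAX_SEPARATION = 3000  # strict <


@dataclass(frozen=True)
class ClusterCall:
    member_ids: Tuple[str, ...]
    member_loci: Tuple[GenomicLocus, ...]
    gaps: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.member_loci) < 2:
            raise ValueError("a cluster needs at least two members")
        chroms = {l.chrom for l in self.member_loci}
        strands = {l.strand for l in self.member_loci}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError("cluster members must share chromosome and strand")

    @property
    def strand(self) -> str:
        return self.member_loci[0].strand


@dataclass(frozen=True)
class DuplicationCall:
    pair: Tuple[str, str]
    kind: str  # "tandem" or "segmental"
    block_id: Optional[str] = None
    ka_ks: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("tandem", "segmental"):
            raise ValueError(f"unknown duplication kind {self.kind!r}")
        if self.kind == "segmental" and self.block_id is None:
            raise ValueError("segmental duplication requires a block_id")

    @property
    def selection_class(self) -> str:
        return selection_class(self.ka_ks)


def selection_class(ka_ks: Optional[float]) -> str:
    """Ka/Ks interpretation: <1 purifying, =1 neutral, >1 positive."""
    if ka_ks is None:
        return "unknown"
    if ka_ks < 1.0:
        return "purifying"
    if ka_ks > 1.0:
        return "positive"
    return "neutral"


def detect_clusters(
    loci: Mapping[str, GenomicLocus], max_gap: int = MAX_CLUSTER_GAP
) -> List[ClusterCall]:
    """Maximal chains of same-chromosome, same-strand loci with gaps <= max_gap.

    Order-invariant in the input; overlapping loci are rejected (precursor
    loci are genomic intervals that must not collide).
    """
    by_pos = sorted(loci.items(), key=lambda kv: (kv[1].chrom, kv[1].start, kv[0]))
    for (name_a, a), (name_b, b) in zip(by_pos, by_pos[1:]):
        if a.chrom == b.chrom and a.overlap(b) > 0:
            raise ValueError(f"overlapping loci {name_a} and {name_b}")
    # chains run over same-strand loci of a chromosome: an interleaved
    # opposite-strand locus does not interrupt a polycistronic chain
    ordered = sorted(
        loci.items(), key=lambda kv: (kv[1].chrom, kv[1].strand, kv[1].start, kv[0])
    )
    clusters: List[ClusterCall] = []
    chain: List[Tuple[str, GenomicLocus]] = []
    gaps: List[int] = []

    def flush() -> None:
        if len(chain) >= 2:
            clusters.append(
                ClusterCall(
                    tuple(n for n, _ in chain),
                    tuple(l for _, l in chain),
                    tuple(gaps),
                )
            )

    for name, locus in ordered:
        if chain:
            prev = chain[-1][1]
            gap = prev.gap_to(locus)
            same = (
                prev.chrom == locus.chrom
                and prev.strand == locus.strand
                and gap is not None
                and gap <= max_gap
            )
            if same:
                chain.append((name, locus))
                gaps.append(gap)
                continue
            flush()
            chain, gaps = [], []
        chain.append((name, locus))
    flush()
    return clusters


def _gene_name(member_ids: Sequence[str]) -> str:
    """Cluster gene name in joined-suffix style (e.g. mir-e + mir-q -> mir-e/q)."""
    prefix = member_ids[0]
    for other in member_ids[1:]:
        while not other.startswith(prefix):
            prefix = prefix[:-1]
    if prefix and len(prefix) < min(len(m) for m in member_ids):
        suffixes = [m[len(prefix):] for m in member_ids]
        return prefix + "/".join(suffixes)
    return "/".join(member_ids)


def collapse_to_genes(
    loci: Mapping[str, GenomicLocus], clusters: Sequence[ClusterCall]
) -> List[Dict]:
    """Collapse each cluster to a single (polycistronic) gene locus.

    Singleton precursors map to single-member genes; a cluster becomes one
    gene spanning its members, named by joined member suffixes.  The gene
    count is ``n_loci - sum(cluster_size - 1)``.
    """
    clustered: Set[str] = set()
    genes: List[Dict] = []
    for cluster in clusters:
        clustered.update(cluster.member_ids)
        span = GenomicLocus(
            cluster.member_loci[0].chrom,
            min(l.start for l in cluster.member_loci),
            max(l.end for l in cluster.member_loci),
            cluster.strand,
        )
        genes.append(
            {"gene_id": _gene_name(cluster.member_ids),
             "members": list(cluster.member_ids),
             "locus": span,
             "polycistronic": True}
        )
    for name in sorted(loci):
        if name not in clustered:
            genes.append(
                {"gene_id": name, "members": [name], "locus": loci[name],
                 "polycistronic": False}
            )
    genes.sort(key=lambda g: (g["locus"].chrom, g["locus"].start))
    return genes


_SUBFEATURE_PRIORITY = ("five_prime_UTR", "three_prime_UTR", "exon")


def classify_genomic_context(
    loci: Mapping[str, GenomicLocus], annotation: Sequence[GffFeature]
) -> Dict[str, str]:
    """Per-precursor genomic context: intergenic, or host-gene sub-feature.

    Context is picked by overlap priority UTR > exon > intron within the
    host gene; antisense hosting (precursor on the strand opposite its host)
    is prefixed ``antisense-``.  A precursor with no gene overlap is
    intergenic.
    """
    genes = [f for f in annotation if f.ftype == "gene"]
    by_parent: Dict[str, List[GffFeature]] = {}
    for feat in annotation:
        if feat.ftype in ("mRNA",):
            by_parent.setdefault(feat.parent or "", []).append(feat)
    contexts: Dict[str, str] = {}
    for name in sorted(loci):
        locus = loci[name]
        host = next((g for g in genes if locus.overlap(g.locus) == locus.length), None)
        if host is None:
            host = next((g for g in genes if locus.overlap(g.locus) > 0), None)
        if host is None:
            contexts[name] = "intergenic"
            continue
        transcripts = {t.feature_id for t in by_parent.get(host.feature_id, [])}
        subfeatures = [
            f for f in annotation
            if f.ftype in ("exon", "five_prime_UTR", "three_prime_UTR", "CDS")
            and (f.parent in transcripts or f.parent == host.feature_id)
        ]
        label = "intron"
        for ftype in _SUBFEATURE_PRIORITY:
            if any(f.ftype == ftype and locus.overlap(f.locus) > 0 for f in subfeatures):
                label = "UTR" if ftype.endswith("UTR") else "exon"
                break
        if host.strand in "+-" and host.strand != locus.strand:
            label = f"antisense-{label}"
        contexts[name] = label
    return contexts


def classify_duplications(
    loci: Mapping[str, GenomicLocus],
    homolog_pairs: Sequence[Tuple[str, str]],
    block_table=None,
    kaks: Optional[Mapping[Tuple[str, str], float]] = None,
) -> List[DuplicationCall]:
    """Tandem/segmental calls for pre-filtered homologous pairs.

    ``homolog_pairs`` should already be restricted to high-identity paralogs.
    Tandem: same chromosome, intervening distance strictly under 3 kb.
    Segmental: the two loci fall inside the paired intervals of one block
    row (``block_id, chrom_a, start_a, end_a, chrom_b, start_b, end_b``).
    A pair satisfying both is reported twice, once per kind.  Ka/Ks values,
    when supplied, are attached for selection-pressure interpretation; the
    ratios are external inputs (e.g. from a duplicated-gene database), not
    computed here.
    """
    blocks = []
    if block_table is not None:
        for _, row in block_table.iterrows():
            a = GenomicLocus(str(row["chrom_a"]), int(row["start_a"]), int(row["end_a"]))
            b = GenomicLocus(str(row["chrom_b"]), int(row["start_b"]), int(row["end_b"]))
            if a.overlap(b) > 0:
                raise ValueError(f"block {row['block_id']}: a/b intervals overlap")
            blocks.append((str(row["block_id"]), a, b))
    calls: List[DuplicationCall] = []
    for pair in homolog_pairs:
        name_a, name_b = sorted(pair)
        loc_a, loc_b = loci[name_a], loci[name_b]
        ratio = None
        if kaks:
            ratio = kaks.get((name_a, name_b), kaks.get((name_b, name_a)))
        if loc_a.chrom == loc_b.chrom:
            gap = loc_a.gap_to(loc_b)
            if gap is not None and gap < TANDEM_MAX_SEPARATION:
                calls.append(DuplicationCall((name_a, name_b), "tandem", None, ratio))
        for block_id, int_a, int_b in blocks:
            direct = (int_a.overlap(loc_a) == loc_a.length
                      and int_b.overlap(loc_b) == loc_b.length)
            crossed = (int_a.overlap(loc_b) == loc_b.length
                       and int_b.overlap(loc_a) == loc_a.length)
            if direct or crossed:
                calls.append(DuplicationCall((name_a, name_b), "segmental", block_id, ratio))
                break
    return calls


def summarize_chromosomes(loci: Mapping[str, GenomicLocus]) -> Dict[str, int]:
    """Precursor counts per chromosome, in deterministic chromosome order."""
    counts = Counter(l.chrom for l in loci.values())
    return dict(sorted(counts.items()))
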