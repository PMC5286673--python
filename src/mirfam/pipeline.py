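"""End-to-end orchestration: discovery screen and family characterization.

``run_discovery`` chains homology search -> annotation-based exclusion ->
window folding -> seven-point screen, and returns per-candidate criteria
reports plus the validated precursor set.  ``run_characterization`` takes
validated precursors through clustering, gene collapsing, genomic context,
duplication classification, identity/tree analysis, promoter scanning and
target prediction.  All report files are plain TSV with ``#`` metadata
header lines (config hash and seed), so reruns are diffable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .annotate import (
    classify_duplications,
    classify_genomic_context,
    collapse_to_genes,
    detect_clusters,
    summarize_chromosomes,
)
from .conservation import identity_matrix, nj_tree
from .core import GenomicLocus, GffFeature, read_fasta, read_gff3, to_rna
from .hairpin import CriteriaReport, CriteriaThresholds, evaluate_precursor
from .promoters import (
    extract_upstream,
    motif_prevalence,
    packaged_motif_catalogue,
    scan_motifs,
)
from .scan import (
    CandidateHit,
    ScanParams,
    exclude_annotated_overlaps,
    local_align_search,
)
from .targets import TargetScheme, collapse_uts, scan_transcriptome

logger = logging.getLogger("mirfam")

__all__ = [
    "PipelineConfig",
    "DiscoveryResult",
    "run_discovery",
    "run_characterization",
    "summarize_family",
    "criteria_table",
]


@dataclass
class PipelineConfig:
    """All pipeline knobs with their defaults; unknown YAML keys are rejected."""

    rng_seed: int = 0
    flank_nt: int = 60
    engine: str = "vienna"
    min_paralog_identity: float = 85.0
    promoter_window: int = 1500
    thresholds: CriteriaThresholds = field(default_factory=CriteriaThresholds)
    scan: ScanParams = field(default_factory=ScanParams)
    target_scheme: TargetScheme = field(default_factory=TargetScheme)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key, sub_cls in (
            ("thresholds", CriteriaThresholds),
            ("scan", ScanParams),
            ("target_scheme", TargetScheme),
        ):
            if key in kwargs and isinstance(kwargs[key], Mapping):
                sub_known = {f.name for f in dataclasses.fields(sub_cls)}
                sub_unknown = set(kwargs[key]) - sub_known
                if sub_unknown:
                    raise ValueError(f"unknown {key} keys: {sorted(sub_unknown)}")
                kwargs[key] = sub_cls(**kwargs[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ValidatedPrecursor:
    precursor_id: str
    locus: GenomicLocus
    sequence: str  # trimmed precursor RNA
    mature_seq: str
    arm: Optional[str]
    report: CriteriaReport


@dataclass
class DiscoveryResult:
    hits: List[CandidateHit]
    excluded: List[Tuple[CandidateHit, str]]
    reports: List[CriteriaReport]
    validated: List[ValidatedPrecursor]
    report_loci: Dict[str, GenomicLocus] = field(default_factory=dict)

    @property
    def validated_loci(self) -> Dict[str, GenomicLocus]:
        return {v.precursor_id: v.locus for v in self.validated}


def _merge_windows(
    hits: Sequence[CandidateHit], genome: Mapping[str, str], flank_nt: int
) -> List[Tuple[GenomicLocus, List[CandidateHit]]]:
    """Group hits that overlap *before* expansion, then widen each group.

    Merging raw hits keeps clustered precursors (a few tens of nt apart) in
    separate fold windows; expanding after the merge still gives each
    candidate enough flank to fold its full hairpin.
    """
    ordered = sorted(hits, key=lambda h: (h.locus.chrom, h.locus.strand, h.locus.start))
    groups: List[List[CandidateHit]] = []
    for hit in ordered:
        if groups:
            last = groups[-1][-1].locus
            group_end = max(h.locus.end for h in groups[-1])
            if (
                last.chrom == hit.locus.chrom
                and last.strand == hit.locus.strand
                and hit.locus.start <= group_end + 1
            ):
                groups[-1].append(hit)
                continue
        groups.append([hit])
    merged: List[Tuple[GenomicLocus, List[CandidateHit]]] = []
    for group in groups:
        chrom = group[0].locus.chrom
        union = GenomicLocus(
            chrom,
            min(h.locus.start for h in group),
            max(h.locus.end for h in group),
            group[0].locus.strand,
        )
        merged.append((union.expanded(flank_nt, len(genome[chrom])), group))
    return merged


def run_discovery(
    genome: Mapping[str, str],
    references: Mapping[str, str],
    reference_matures: Mapping[str, str],
    annotation: Sequence[GffFeature] = (),
    config: PipelineConfig = None,
) -> DiscoveryResult:
    """Scan -> exclude -> fold -> screen.

    ``references`` are the homology-search queries (precursors and/or
    matures); ``reference_matures`` is the mature set used for arm placement
    and criterion 1.
    """
    config = config or PipelineConfig()
    t0 = time.time()
    hits = local_align_search(genome, references, config.scan)
    logger.info("scan: %d candidate hits (%.1fs)", len(hits), time.time() - t0)
    kept, excluded = exclude_annotated_overlaps(hits, annotation)
    logger.info("exclusion: %d kept, %d removed", len(kept), len(excluded))
    windows = _merge_windows(kept, genome, config.flank_nt)
    logger.info("folding %d candidate windows", len(windows))

    evaluated: List[Tuple[GenomicLocus, CriteriaReport, object]] = []
    for idx, (window, _members) in enumerate(windows, start=1):
        cand_id = f"cand{idx:03d}"
        seq = window.extract(genome)
        try:
            report, fold, assignment = evaluate_precursor(
                cand_id, seq, reference_matures, config.thresholds, config.engine
            )
        except ValueError as exc:  # window too short to be a precursor
            logger.debug("%s skipped: %s", cand_id, exc)
            continue
        # map the trimmed precursor back to genomic coordinates
        trimmed_len = report.precursor_len
        offset = window.extract(genome).find(
            fold.sequence.replace("U", "T")
        )
        if offset >= 0:
            if window.strand == "+":
                locus = GenomicLocus(
                    window.chrom, window.start + offset,
                    window.start + offset + trimmed_len - 1, "+",
                )
            else:
                locus = GenomicLocus(
                    window.chrom, window.end - offset - trimmed_len + 1,
                    window.end - offset, "-",
                )
        else:
            locus = window
        evaluated.append((locus, report, assignment, fold))

    # cross-strand dedupe: a hairpin's reverse complement also aligns, so the
    # same genomic region can be evaluated on both strands; keep the better
    chosen: List[Tuple[GenomicLocus, CriteriaReport, object, object]] = []
    for entry in sorted(
        evaluated,
        key=lambda e: (
            not e[1].passed,
            e[1].n_mismatch_vs_reference
            if e[1].n_mismatch_vs_reference is not None else 99,
            e[1].mfe,
        ),
    ):
        locus = entry[0]
        if any(locus.overlap(c[0]) > 0.5 * min(locus.length, c[0].length) for c in chosen):
            continue
        chosen.append(entry)
    chosen.sort(key=lambda e: (e[0].chrom, e[0].start))

    reports: List[CriteriaReport] = []
    validated: List[ValidatedPrecursor] = []
    report_loci: Dict[str, GenomicLocus] = {}
    for idx, (locus, report, assignment, fold) in enumerate(chosen, start=1):
        pid = f"pre{idx:03d}"
        report.precursor_id = pid
        reports.append(report)
        report_loci[pid] = locus
        if report.passed:
            validated.append(
                ValidatedPrecursor(
                    precursor_id=pid,
                    locus=locus,
                    sequence=fold.sequence,
                    mature_seq=assignment.mature_seq if assignment else "",
                    arm=assignment.arm if assignment else None,
                    report=report,
                )
            )
    logger.info(
        "screen: %d candidates, %d validated precursors", len(reports), len(validated)
    )
    return DiscoveryResult(hits, excluded, reports, validated, report_loci)


def criteria_table(reports: Sequence[CriteriaReport]) -> pd.DataFrame:
    """Criteria reports as a table mirroring the usual screen summary columns."""
    rows = []
    for r in reports:
        row = {
            "id": r.precursor_id,
            "LP": r.precursor_len,
            "GC": round(r.gc_fraction, 3),
            "U_content": round(r.u_fraction, 3),
            "MFE": round(r.mfe, 2),
            "MFEI": round(r.mfei, 2),
            "NM": r.n_mismatch_vs_reference,
            "arm": r.arm,
            "duplex_unpaired": r.duplex_unpaired,
            "GU_pairs": r.gu_pairs_in_mature,
            "max_bulge": r.max_bulge_in_mature,
            "passed": r.passed,
        }
        for i, (name, flag) in enumerate(r.criteria_flags.items(), start=1):
            row[f"c{i}_{name}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_family(reports: Sequence[CriteriaReport]) -> Dict[str, float]:
    """Summary statistics over a set of criteria reports.

    MFE extremes, MFEI extremes and mean (two decimals), length range and
    count -- the numbers usually quoted for a family screen.
    """
    if not reports:
        raise ValueError("no reports to summarize")
    mfes = [r.mfe for r in reports]
    mfeis = [r.mfei for r in reports]
    lengths = [r.precursor_len for r in reports]
    return {
        "count": len(reports),
        "mfe_min": round(min(mfes), 2),  # most negative
        "mfe_max": round(max(mfes), 2),
        "mfei_min": round(min(mfeis), 2),
        "mfei_max": round(max(mfeis), 2),
        "mfei_mean": round(sum(mfeis) / len(mfeis), 2),
        "length_min": min(lengths),
        "length_max": max(lengths),
    }


def run_characterization(
    genome: Mapping[str, str],
    precursors: Mapping[str, str],  # id -> precursor RNA
    loci: Mapping[str, GenomicLocus],
    matures: Optional[Mapping[str, str]] = None,
    annotation: Sequence[GffFeature] = (),
    block_table: Optional[pd.DataFrame] = None,
    kaks: Optional[Mapping[Tuple[str, str], float]] = None,
    tss_table: Optional[Mapping[str, int]] = None,
    transcripts: Optional[Mapping[str, str]] = None,
    motif_catalogue=None,
    config: PipelineConfig = None,
) -> Dict[str, object]:
    """Family characterization over validated precursors.

    Degrades gracefully: without a block table segmental classification is
    skipped (tandem still called); without a TSS table the precursor 5' end
    is used; without transcripts target prediction is skipped.
    """
    config = config or PipelineConfig()
    out: Dict[str, object] = {}

    clusters = detect_clusters(loci)
    out["clusters"] = clusters
    genes = collapse_to_genes(loci, clusters)
    out["genes"] = genes
    out["contexts"] = classify_genomic_context(loci, annotation)
    out["chromosome_counts"] = summarize_chromosomes(loci)

    if len(precursors) >= 2:
        matrix = identity_matrix(precursors)
        out["precursor_identity"] = matrix
        pairs = [
            (matrix.ids[i], matrix.ids[j])
            for i in range(len(matrix.ids))
            for j in range(i + 1, len(matrix.ids))
            if matrix.values[i, j] >= config.min_paralog_identity
        ]
        if block_table is None:
            logger.warning("no block table: segmental duplication classification skipped")
        out["duplications"] = classify_duplications(loci, pairs, block_table, kaks)
        if len(precursors) >= 3:
            out["precursor_tree"] = nj_tree(matrix, seqs=precursors,
                                            bootstrap_reps=0, rng_seed=config.rng_seed)
    if matures and len(set(matures.values())) >= 3:
        out["mature_identity"] = identity_matrix(matures)

    gene_loci = {g["gene_id"]: g["locus"] for g in genes}
    if tss_table is None:
        logger.info("no TSS table: using precursor/gene 5' ends as TSS")
    promoters = extract_upstream(gene_loci, genome, tss_table, config.promoter_window)
    out["promoters"] = promoters
    catalogue = motif_catalogue if motif_catalogue is not None else packaged_motif_catalogue()
    matrix = scan_motifs(
        {g: p["sequence"] for g, p in promoters.items() if p["sequence"]}, catalogue
    )
    out["promoter_matrix"] = matrix
    out["motif_prevalence"] = motif_prevalence(matrix, catalogue)

    if transcripts:
        mirna_set = matures or {
            pid: seq for pid, seq in precursors.items()
        }
        hits = scan_transcriptome(mirna_set, transcripts, config.target_scheme)
        out["target_hits"] = hits
        out["uts"] = collapse_uts(hits)
    return out


def write_reports(
    result: Dict[str, object],
    outdir: str | Path,
    config: PipelineConfig,
) -> List[Path]:
    """Write characterization reports as '#'-headed TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = (
        f"# mirfam report\n# config_hash={config.config_hash()} "
        f"rng_seed={config.rng_seed}\n"
    )
    written: List[Path] = []

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        with open(path, "w") as handle:
            handle.write(header)
            frame.to_csv(handle, sep="\t", index=False)
        written.append(path)

    if "clusters" in result:
        emit("clusters.tsv", pd.DataFrame(
            [{"members": ",".join(c.member_ids), "chrom": c.member_loci[0].chrom,
              "strand": c.strand, "gaps": ",".join(map(str, c.gaps))}
             for c in result["clusters"]]))
    if "genes" in result:
        emit("genes.tsv", pd.DataFrame(
            [{"gene_id": g["gene_id"], "members": ",".join(g["members"]),
              "locus": g["locus"].display(), "polycistronic": g["polycistronic"]}
             for g in result["genes"]]))
    if "contexts" in result:
        emit("contexts.tsv", pd.DataFrame(
            [{"precursor": k, "context": v} for k, v in result["contexts"].items()]))
    if "duplications" in result:
        emit("duplications.tsv", pd.DataFrame(
            [{"a": d.pair[0], "b": d.pair[1], "kind": d.kind,
              "block_id": d.block_id or "", "ka_ks": d.ka_ks,
              "selection": d.selection_class}
             for d in result["duplications"]]))
    if "precursor_identity" in result:
        m = result["precursor_identity"]
        path = outdir / "precursor_identity.tsv"
        with open(path, "w") as handle:
            handle.write(header)
            m.to_frame().to_csv(handle, sep="\t")
        written.append(path)
    if "precursor_tree" in result:
        path = outdir / "precursor_tree.nwk"
        path.write_text(result["precursor_tree"] + "\n")
        written.append(path)
    if "promoter_matrix" in result:
        pm = result["promoter_matrix"]
        path = outdir / "promoter_matrix.tsv"
        with open(path, "w") as handle:
            handle.write(header)
            pm.presence.to_csv(handle, sep="\t")
        written.append(path)
    if "motif_prevalence" in result:
        emit("motif_prevalence.tsv", result["motif_prevalence"])
    if "target_hits" in result:
        emit("target_hits.tsv", pd.DataFrame(
            [{"mirna": h.mirna_id, "transcript": h.transcript_id,
              "start": h.site_span[0], "end": h.site_span[1],
              "expectation": h.expectation, "pairing": h.pairing,
              "cleavage_pos": h.cleavage_pos, "mode": h.inhibition_mode}
             for h in result["target_hits"]]))
    return written
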