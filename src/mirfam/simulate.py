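"""Synthetic genomes, promoters and transcriptomes with ground-truth manifests.

The generator plants hairpin precursors with controlled duplex properties
(mismatches, G:U wobbles, one bulge, arm of the mature), decoy loci that a
correct screen must reject, same-strand precursor clusters at chosen gaps,
tandem/segmental duplicate pairs, host genes for intragenic precursors, and
promoters/transcripts with planted motifs and target sites.  Every planted
feature is recorded in a :class:`TruthManifest` so that each pipeline stage
can be scored for exact recovery.

Construction conventions
------------------------
* A planted "mismatch" puts an unpairable base (one that can neither
  Watson-Crick- nor wobble-pair with the mature base) on the star strand;
  a planted G:U puts U opposite a mature G, or G opposite a mature U; a
  planted bulge is a *run* of consecutive such unpairable positions.  The
  planted-mismatch count is therefore the expected number of unpaired mature
  residues, and the bulge run its longest stretch; the star keeps the mature
  length so the helix register cannot slip during refolding.
* The loop is drawn from {A, C} (cannot pair with itself); the flanks form a
  perfectly complementary lower helix, mirroring the extended fold-back of
  real precursors that gives them their low MFE.  Paralog-pair implants can
  share flanks and loop (``clone_of``) like true duplicates.
* Minus-strand implants are stored reverse-complemented in the genome; the
  manifest locus carries the plus-coordinate interval with strand "-".
* All randomness derives from one integer seed; identical configs and seeds
  give byte-identical FASTA/GFF3/manifest output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (
    GenomicLocus,
    GffFeature,
    revcomp_dna,
    revcomp_rna,
    to_dna,
    to_rna,
    write_fasta,
    write_gff3,
)
from .hairpin import HairpinFold

__all__ = [
    "ImplantSpec",
    "ImplantTruth",
    "TruthManifest",
    "GenomeConfig",
    "build_hairpin_precursor",
    "generate_toy_genome",
    "generate_promoters",
    "generate_transcriptome",
    "dinucleotide_shuffle",
    "mutate_mature",
    "default_config",
    "default_queries",
    "write_outputs",
    "REFERENCE_MATURES",
]

#: Family mature sequences used as the default homology references: the two
#: distinct mature variants of the soybean miR166 family (21-mers).
REFERENCE_MATURES: Dict[str, str] = {
    "miR166-ref1": "UCGGACCAGGCUUCAUUCCCC",
    "miR166-ref2": "UCUCGGACCAGGCUUCAUUCC",
}

_FLANK_ALPHABET = np.array(list("AC"))
_GENOME_ALPHABET = np.array(list("ACGT"))

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {"G": "U", "U": "G"}


# ---------------------------------------------------------------------------
# Implant specification and hairpin construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImplantSpec:
    """Blueprint for one planted hairpin precursor."""

    name: str
    mature_seq: str
    arm: str = "3p"
    loop_len: int = 9
    planted_mismatches: int = 0
    planted_gu: int = 0
    planted_bulge_len: int = 0
    flank_len: int = 20
    strand: str = "+"
    chrom: str = "chr1"
    offset: int = 1  # 1-based position of the precursor start on the chromosome
    mature_mutations: int = 0  # substitutions applied to the mature vs its reference
    clone_of: Optional[str] = None  # share flanks/loop with this implant (paralog pair)

    def __post_init__(self) -> None:
        mature = to_rna(self.mature_seq)
        if not (20 <= len(mature) <= 24):
            raise ValueError(f"{self.name}: mature must be 20-24 nt, got {len(mature)}")
        if set(mature) - set("ACGU"):
            raise ValueError(f"{self.name}: mature must be unambiguous RNA")
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"{self.name}: arm must be 5p or 3p")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: strand must be + or -")
        if self.loop_len < 3:
            raise ValueError(f"{self.name}: loop_len must be >= 3")
        for fname in ("planted_mismatches", "planted_gu", "planted_bulge_len",
                      "flank_len", "mature_mutations"):
            if getattr(self, fname) < 0:
                raise ValueError(f"{self.name}: {fname} must be non-negative")
        if self.planted_mismatches + self.planted_gu > len(mature):
            raise ValueError(
                f"{self.name}: planted_mismatches + planted_gu "
                f"({self.planted_mismatches} + {self.planted_gu}) exceeds the "
                f"mature length {len(mature)}"
            )
        if self.planted_bulge_len > max(0, self.planted_mismatches):
            raise ValueError(
                f"{self.name}: planted_bulge_len {self.planted_bulge_len} exceeds "
                f"planted_mismatches {self.planted_mismatches} (the bulge is the "
                "longest run of unpaired mature residues)"
            )
        if self.offset < 1:
            raise ValueError(f"{self.name}: offset must be 1-based positive")

    @property
    def total_length(self) -> int:
        mature_len = len(self.mature_seq)
        return 2 * self.flank_len + 2 * mature_len + self.loop_len

    def expected_duplex(self) -> Tuple[int, int, int]:
        """(unpaired, G:U, longest bulge) the construction plants."""
        bulge = self.planted_bulge_len
        if bulge == 0 and self.planted_mismatches > 0:
            bulge = 1  # isolated mismatches are runs of one
        return self.planted_mismatches, self.planted_gu, bulge

    def expected_fail_criteria(
        self, max_mismatch: int = 2, max_unpaired: int = 5, max_gu: int = 5, max_bulge: int = 3
    ) -> Tuple[int, ...]:
        """Screen criteria this implant is built to violate (empty = pass)."""
        fails = []
        if self.mature_mutations > max_mismatch:
            fails.append(1)
        unpaired, gu, bulge = self.expected_duplex()
        if unpaired > max_unpaired:
            fails.append(3)
        if gu > max_gu:
            fails.append(4)
        if bulge > max_bulge:
            fails.append(5)
        return tuple(fails)


def _choose_positions(spec: ImplantSpec, mature: str) -> Tuple[List[int], List[int]]:
    """Deterministic interior positions for (unpaired, G:U) plantings.

    Unpaired positions: one bulge run plus isolated singletons, all within
    the mature interior (>= 2 nt from both ends), singletons separated by at
    least one paired position.  G:U positions need a G or U mature base.
    """
    L = len(mature)
    interior = list(range(2, L - 2))
    bulge_len = spec.planted_bulge_len
    n_single = spec.planted_mismatches - bulge_len
    unpaired: List[int] = []
    cursor = 2
    if bulge_len:
        unpaired.extend(range(cursor, cursor + bulge_len))
        cursor += bulge_len + 2
    for _ in range(n_single):
        if cursor >= L - 2:
            raise ValueError(
                f"{spec.name}: cannot place {spec.planted_mismatches} unpaired "
                f"residues (bulge {bulge_len}) in the interior of a {L}-nt mature"
            )
        unpaired.append(cursor)
        cursor += 3  # >= 2 paired residues between singletons keeps runs short
    taken = set(unpaired)
    gu_positions = [i for i in interior if i not in taken and mature[i] in _WOBBLE]
    if len(gu_positions) < spec.planted_gu:
        raise ValueError(
            f"{spec.name}: only {len(gu_positions)} interior G/U bases available "
            f"for {spec.planted_gu} planted G:U pairs"
        )
    # spread the wobbles from the 3' side, away from the singleton mismatches
    gu = gu_positions[::-1][: spec.planted_gu]
    return unpaired, sorted(gu)


def build_hairpin_precursor(
    spec: ImplantSpec,
    rng: Optional[np.random.Generator] = None,
    parts: Optional[Tuple[str, str]] = None,
) -> Tuple[str, HairpinFold]:
    """Construct a precursor realizing the spec; returns (RNA, expected fold).

    The expected fold records the constructed pairing (mature vs star) with
    flanks and loop unpaired; its ``mfe`` is not meaningful (0.0, engine
    "constructed") -- folding engines assign real energies downstream.
    """
    rng = rng or np.random.default_rng(0)
    mature = to_rna(spec.mature_seq)
    L = len(mature)
    unpaired_pos, gu_pos = _choose_positions(spec, mature)
    bulge_run = set(range(2, 2 + spec.planted_bulge_len)) if spec.planted_bulge_len else set()
    single_mm = [i for i in unpaired_pos if i not in bulge_run]

    # per-mature-position star partner base; planted defects use the
    # anti-pairing map (partner can neither Watson-Crick- nor wobble-pair),
    # so the star keeps its length and the helix register stays planted
    anti = {"A": "C", "C": "A", "G": "A", "U": "C"}
    partner_base: List[Optional[str]] = []
    for i, base in enumerate(mature):
        if i in bulge_run or i in single_mm:
            partner_base.append(anti[base])
        elif i in gu_pos:
            partner_base.append(_WOBBLE[base])
        else:
            partner_base.append(_WC[base])

    # star arm read 5'->3' along the precursor = partners in reverse mature order
    star_arm = [b for b in (partner_base[i] for i in reversed(range(L))) if b is not None]
    # index into star_arm for mature position i: number of kept positions > i
    kept_gt = [sum(1 for j in range(i + 1, L) if partner_base[j] is not None) for i in range(L)]

    # the flanks form a perfect lower helix: real precursors extend the fold
    # well beyond the miRNA/miRNA* duplex, which is what gives them their low
    # MFE relative to same-length shuffles.  ``parts`` fixes (flank5, loop),
    # letting paralog-pair implants share their backbone like true duplicates.
    if parts is not None:
        flank5, loop = parts
        if len(flank5) != spec.flank_len or len(loop) != spec.loop_len:
            raise ValueError(f"{spec.name}: cloned parts do not match flank/loop lengths")
    else:
        loop = "".join(rng.choice(_FLANK_ALPHABET, size=spec.loop_len))
        flank5 = "".join(rng.choice(np.array(list("ACGU")), size=spec.flank_len))
    flank3 = revcomp_rna(flank5)

    f5, S = len(flank5), len(star_arm)
    # defect positions keep a star base (kept_gt counts it) but stay unpaired
    paired_idx = [
        i for i in range(L)
        if partner_base[i] is not None and i not in single_mm and i not in bulge_run
    ]
    if spec.arm == "5p":
        sequence = flank5 + mature + loop + "".join(star_arm) + flank3
        pairs = [(f5 + i, f5 + L + spec.loop_len + kept_gt[i]) for i in paired_idx]
    else:
        sequence = flank5 + "".join(star_arm) + loop + mature + flank3
        pairs = [(f5 + kept_gt[i], f5 + S + spec.loop_len + i) for i in paired_idx]
    total = len(sequence)
    pairs.extend((k, total - 1 - k) for k in range(f5))
    structure = ["."] * len(sequence)
    for a, b in pairs:
        structure[a], structure[b] = "(", ")"
    fold = HairpinFold(sequence, "".join(structure), 0.0, engine="constructed")
    return sequence, fold


def mutate_mature(mature: str, n: int, rng: np.random.Generator) -> str:
    """Apply n interior substitutions (used to plant criterion-1 failures)."""
    mature = to_rna(mature)
    if n == 0:
        return mature
    positions = rng.choice(np.arange(2, len(mature) - 2), size=n, replace=False)
    out = list(mature)
    for pos in positions:
        choices = [b for b in "ACGU" if b != out[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Truth manifest
# ---------------------------------------------------------------------------

@dataclass
class ImplantTruth:
    name: str
    locus: GenomicLocus
    spec: ImplantSpec
    precursor_rna: str
    expected_pass: bool
    expected_fail_criteria: Tuple[int, ...]
    expected_duplex: Tuple[int, int, int]


@dataclass
class TruthManifest:
    """Everything the generator planted, for recovery scoring."""

    rng_seed: int
    implanted_loci: List[ImplantTruth] = field(default_factory=list)
    decoy_loci: List[Tuple[GenomicLocus, str]] = field(default_factory=list)
    cluster_truth: List[Tuple[str, str, int]] = field(default_factory=list)
    duplication_truth: List[Tuple[Tuple[str, str], str, Optional[str]]] = field(default_factory=list)
    motif_truth: Dict[str, List[Tuple[str, int, str]]] = field(default_factory=dict)
    target_truth: List[Dict] = field(default_factory=list)

    def to_json(self) -> str:
        def encode(obj):
            if isinstance(obj, GenomicLocus):
                return {"chrom": obj.chrom, "start": obj.start, "end": obj.end,
                        "strand": obj.strand}
            if isinstance(obj, (ImplantSpec, ImplantTruth)):
                return asdict(obj)
            raise TypeError(f"cannot serialize {type(obj)}")

        return json.dumps(
            {
                "rng_seed": self.rng_seed,
                "implanted_loci": [asdict(t) for t in self.implanted_loci],
                "decoy_loci": [[asdict(l), c] for l, c in self.decoy_loci],
                "cluster_truth": self.cluster_truth,
                "duplication_truth": self.duplication_truth,
                "motif_truth": self.motif_truth,
                "target_truth": self.target_truth,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        raw = json.loads(text)
        manifest = cls(rng_seed=raw["rng_seed"])
        for item in raw["implanted_loci"]:
            manifest.implanted_loci.append(
                ImplantTruth(
                    name=item["name"],
                    locus=GenomicLocus(**item["locus"]),
                    spec=ImplantSpec(**item["spec"]),
                    precursor_rna=item["precursor_rna"],
                    expected_pass=item["expected_pass"],
                    expected_fail_criteria=tuple(item["expected_fail_criteria"]),
                    expected_duplex=tuple(item["expected_duplex"]),
                )
            )
        manifest.decoy_loci = [(GenomicLocus(**l), c) for l, c in raw["decoy_loci"]]
        manifest.cluster_truth = [tuple(x) for x in raw["cluster_truth"]]
        manifest.duplication_truth = [
            (tuple(pair), kind, block) for pair, kind, block in raw["duplication_truth"]
        ]
        manifest.motif_truth = {
            k: [tuple(v) for v in vals] for k, vals in raw["motif_truth"].items()
        }
        manifest.target_truth = raw["target_truth"]
        return manifest


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    chrom_lengths: Dict[str, int]
    implants: List[ImplantSpec]
    decoys: Dict[str, int] = field(default_factory=dict)  # class -> count
    segmental_pairs: List[Tuple[str, str]] = field(default_factory=list)
    host_genes: Dict[str, str] = field(default_factory=dict)  # implant -> context
    rng_seed: int = 0

    _VALID_DECOYS = ("shuffled", "coding_like", "trna_like")
    _VALID_CONTEXTS = ("intron", "exon", "UTR", "antisense-intron")

    def __post_init__(self) -> None:
        names = [s.name for s in self.implants]
        if len(set(names)) != len(names):
            raise ValueError("implant names must be unique")
        for cls in self.decoys:
            if cls not in self._VALID_DECOYS:
                raise ValueError(f"unknown decoy class {cls!r}")
        for name, ctx in self.host_genes.items():
            if name not in names:
                raise ValueError(f"host_genes refers to unknown implant {name!r}")
            if ctx not in self._VALID_CONTEXTS:
                raise ValueError(f"unknown genomic context {ctx!r}")
        for a, b in self.segmental_pairs:
            if a not in names or b not in names:
                raise ValueError(f"segmental pair ({a}, {b}) refers to unknown implant")


def _random_chromosome(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(_GENOME_ALPHABET, size=length)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 200) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul-Erikson style).

    Adjacency lists of the transition multigraph are shuffled and walked from
    the original first base; walks that strand early are retried.
    """
    seq = seq.upper()
    if len(seq) < 3:
        return seq
    for _ in range(max_tries):
        adjacency: Dict[str, List[str]] = {}
        for a, b in zip(seq, seq[1:]):
            adjacency.setdefault(a, []).append(b)
        for key in adjacency:
            rng.shuffle(adjacency[key])
        out = [seq[0]]
        node = seq[0]
        for _ in range(len(seq) - 1):
            nxt_list = adjacency.get(node)
            if not nxt_list:
                break
            node = nxt_list.pop()
            out.append(node)
        if len(out) == len(seq):
            return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to complete a walk")


def _make_coding_like(length: int, rng: np.random.Generator) -> str:
    """An ORF-looking sequence: ATG + sense codons + stop."""
    n_codons = max(10, (length - 6) // 3)
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(_GENOME_ALPHABET, size=3))
        if codon not in stops and codon != "ATG":
            codons.append(codon)
    return "ATG" + "".join(codons) + "TAA"


_TRNA_HALF = "GCGGAUUUAGCUCAGUUGGGAGAGCGCCAGACUGAA"  # cloverleaf-ish scaffold


def _make_trna_like(rng: np.random.Generator) -> str:
    half = to_dna(_TRNA_HALF)
    return half + "GAT" + revcomp_dna(half[:20]) + "CCA"


def generate_toy_genome(
    config: GenomeConfig,
) -> Tuple[Dict[str, str], List[GffFeature], "pdFrame", TruthManifest]:
    """Build genome FASTA dict, GFF3 features, block table and truth manifest.

    Deterministic for a fixed config + seed; every manifest coordinate is
    verified against the emitted sequence before returning.
    """
    import pandas as pd

    rng = np.random.default_rng(config.rng_seed)
    chroms = {name: _random_chromosome(length, rng)
              for name, length in sorted(config.chrom_lengths.items())}
    manifest = TruthManifest(rng_seed=config.rng_seed)
    features: List[GffFeature] = []
    occupied: Dict[str, List[Tuple[int, int, str]]] = {c: [] for c in chroms}

    def _collides(chrom: str, start: int, end: int) -> Optional[str]:
        for s, e, name in occupied.get(chrom, []):
            if start <= e and end >= s:
                return name
        return None

    # --- implants ---------------------------------------------------------
    reference_by_name: Dict[str, str] = {}
    built_parts: Dict[str, Tuple[str, str]] = {}
    for spec in config.implants:
        mature = to_rna(spec.mature_seq)
        if spec.mature_mutations:
            mature = mutate_mature(mature, spec.mature_mutations, rng)
        realized = ImplantSpec(**{**asdict(spec), "mature_seq": mature})
        parts = None
        if spec.clone_of is not None:
            if spec.clone_of not in built_parts:
                raise ValueError(f"{spec.name}: clone_of {spec.clone_of!r} not built yet")
            parts = built_parts[spec.clone_of]
        precursor_rna, expected_fold = build_hairpin_precursor(realized, rng, parts)
        f5, Lm = realized.flank_len, len(mature)
        built_parts[spec.name] = (
            precursor_rna[:f5],
            precursor_rna[f5 + Lm : f5 + Lm + realized.loop_len]
            if realized.arm == "5p"
            else precursor_rna[f5 + Lm : f5 + Lm + realized.loop_len],
        )
        length = len(precursor_rna)
        if spec.chrom not in chroms:
            raise ValueError(f"{spec.name}: unknown chromosome {spec.chrom}")
        start, end = spec.offset, spec.offset + length - 1
        if end > len(chroms[spec.chrom]):
            raise ValueError(
                f"{spec.name}: implant {start}-{end} exceeds {spec.chrom} length "
                f"{len(chroms[spec.chrom])}"
            )
        other = _collides(spec.chrom, start, end)
        if other is not None:
            raise ValueError(f"implants {spec.name} and {other} overlap on {spec.chrom}")
        occupied[spec.chrom].append((start, end, spec.name))
        dna = to_dna(precursor_rna)
        if spec.strand == "-":
            dna = revcomp_dna(dna)
        chroms[spec.chrom][start - 1 : end] = list(dna)
        locus = GenomicLocus(spec.chrom, start, end, spec.strand)
        reference_by_name[spec.name] = precursor_rna
        fails = realized.expected_fail_criteria()
        manifest.implanted_loci.append(
            ImplantTruth(
                name=spec.name,
                locus=locus,
                spec=realized,
                precursor_rna=precursor_rna,
                expected_pass=not fails,
                expected_fail_criteria=fails,
                expected_duplex=realized.expected_duplex(),
            )
        )

    # --- host genes for intragenic implants -------------------------------
    for name, context in sorted(config.host_genes.items()):
        truth = next(t for t in manifest.implanted_loci if t.name == name)
        loc = truth.locus
        chrom_len = len(chroms[loc.chrom])
        gene_start = max(1, loc.start - 400)
        gene_end = min(chrom_len, loc.end + 400)
        strand = loc.strand if context != "antisense-intron" else ("-" if loc.strand == "+" else "+")
        gid = f"host_{name}"
        base = dict(seqid=loc.chrom, source="mirfam_sim", score=".", phase=".", strand=strand)
        features.append(GffFeature(ftype="gene", start=gene_start, end=gene_end,
                                   attributes={"ID": gid}, **base))
        features.append(GffFeature(ftype="mRNA", start=gene_start, end=gene_end,
                                   attributes={"ID": gid + ".t1", "Parent": gid}, **base))
        if context in ("intron", "antisense-intron"):
            # two exons flanking the implant: the implant sits in the intron
            features.append(GffFeature(ftype="exon", start=gene_start, end=loc.start - 10,
                                       attributes={"ID": gid + ".e1", "Parent": gid + ".t1"}, **base))
            features.append(GffFeature(ftype="exon", start=loc.end + 10, end=gene_end,
                                       attributes={"ID": gid + ".e2", "Parent": gid + ".t1"}, **base))
        elif context == "exon":
            features.append(GffFeature(ftype="exon", start=gene_start, end=gene_end,
                                       attributes={"ID": gid + ".e1", "Parent": gid + ".t1"}, **base))
        elif context == "UTR":
            features.append(GffFeature(ftype="exon", start=gene_start, end=gene_end,
                                       attributes={"ID": gid + ".e1", "Parent": gid + ".t1"}, **base))
            features.append(GffFeature(ftype="five_prime_UTR", start=gene_start, end=loc.end + 20,
                                       attributes={"ID": gid + ".u1", "Parent": gid + ".t1"}, **base))

    # --- decoys ------------------------------------------------------------
    chrom_names = sorted(chroms)
    decoy_counter = 0
    for decoy_class in sorted(config.decoys):
        for _ in range(config.decoys[decoy_class]):
            decoy_counter += 1
            if decoy_class == "shuffled":
                template = (reference_by_name[sorted(reference_by_name)[0]]
                            if reference_by_name else _TRNA_HALF * 3)
                seq = dinucleotide_shuffle(to_dna(template), rng)
            elif decoy_class == "coding_like":
                seq = _make_coding_like(300, rng)
            else:
                seq = _make_trna_like(rng)
            for _attempt in range(200):
                chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                start = int(rng.integers(1, len(chroms[chrom]) - len(seq)))
                end = start + len(seq) - 1
                if _collides(chrom, start, end) is None:
                    break
            else:
                raise RuntimeError("could not place decoy without collisions")
            name = f"decoy_{decoy_class}_{decoy_counter}"
            occupied[chrom].append((start, end, name))
            chroms[chrom][start - 1 : end] = list(seq)
            locus = GenomicLocus(chrom, start, end, "+")
            manifest.decoy_loci.append((locus, decoy_class))
            if decoy_class == "coding_like":
                base = dict(seqid=chrom, source="mirfam_sim", score=".", phase=".", strand="+")
                features.append(GffFeature(ftype="gene", start=start, end=end,
                                           attributes={"ID": name}, **base))
                features.append(GffFeature(ftype="CDS", start=start, end=end,
                                           attributes={"ID": name + ".cds", "Parent": name},
                                           **{**base, "phase": "0"}))
            elif decoy_class == "trna_like":
                features.append(GffFeature(seqid=chrom, source="mirfam_sim", ftype="tRNA",
                                           start=start, end=end, score=".", strand="+",
                                           phase=".", attributes={"ID": name}))

    genome = {name: "".join(arr) for name, arr in chroms.items()}

    # --- verify every implant round-trips through the FASTA ----------------
    for truth in manifest.implanted_loci:
        extracted = truth.locus.extract(genome)
        if to_rna(extracted) != truth.precursor_rna:
            raise AssertionError(f"implant {truth.name} does not round-trip")

    # --- cluster truth: same chrom+strand consecutive implants, gap <= 3 kb -
    by_pos = sorted(manifest.implanted_loci, key=lambda t: (t.locus.chrom, t.locus.start))
    for a, b in zip(by_pos, by_pos[1:]):
        if a.locus.chrom == b.locus.chrom and a.locus.strand == b.locus.strand:
            gap = a.locus.gap_to(b.locus)
            if gap is not None and gap <= 3000:
                manifest.cluster_truth.append((a.name, b.name, gap))

    # --- duplication truth --------------------------------------------------
    blocks = []
    for a_name, b_name in (tuple(p) for p in config.segmental_pairs):
        a = next(t.locus for t in manifest.implanted_loci if t.name == a_name)
        b = next(t.locus for t in manifest.implanted_loci if t.name == b_name)
        block_id = f"blk{len(blocks) + 1:03d}"
        blocks.append(
            dict(block_id=block_id,
                 chrom_a=a.chrom, start_a=max(1, a.start - 50),
                 end_a=min(len(genome[a.chrom]), a.end + 50),
                 chrom_b=b.chrom, start_b=max(1, b.start - 50),
                 end_b=min(len(genome[b.chrom]), b.end + 50))
        )
        manifest.duplication_truth.append(((a_name, b_name), "segmental", block_id))
    for a_name, b_name, gap in manifest.cluster_truth:
        if gap < 3000:
            manifest.duplication_truth.append(((a_name, b_name), "tandem", None))

    block_table = pd.DataFrame(
        blocks, columns=["block_id", "chrom_a", "start_a", "end_a",
                         "chrom_b", "start_b", "end_b"]
    )
    features.sort(key=lambda f: (f.seqid, f.start, f.ftype))
    return genome, features, block_table, manifest


# ---------------------------------------------------------------------------
# Promoters and transcriptome
# ---------------------------------------------------------------------------

def generate_promoters(
    n: int,
    length: int,
    motif_catalogue: Mapping[str, str],
    plant_plan: Mapping[str, Sequence[Tuple[str, Optional[int], str]]],
    rng_seed: int = 0,
) -> Tuple[Dict[str, str], Dict[str, List[Tuple[str, int, str]]]]:
    """Uniform-background promoters with planted motif instances.

    ``plant_plan`` maps promoter id -> list of (motif_name, 1-based position
    or None for random, strand "+"/"-").  IUPAC degeneracies are resolved to
    a random concrete word; minus-strand plantings insert the reverse
    complement.  Returns (promoter dict, motif truth with realized positions).
    """
    from .promoters import expand_iupac_choice  # local import to avoid a cycle

    rng = np.random.default_rng(rng_seed)
    for motif_name, pattern in motif_catalogue.items():
        if len(pattern) > length:
            raise ValueError(f"motif {motif_name} ({len(pattern)} nt) longer than promoter")
    promoters: Dict[str, str] = {}
    truth: Dict[str, List[Tuple[str, int, str]]] = {}
    ids = [f"prom{i + 1:02d}" for i in range(n)]
    for pid in ids:
        seq = list(rng.choice(_GENOME_ALPHABET, size=length))
        truth[pid] = []
        taken: List[Tuple[int, int]] = []
        for motif_name, position, strand in plant_plan.get(pid, []):
            pattern = motif_catalogue[motif_name]
            word = expand_iupac_choice(pattern, rng)
            if strand == "-":
                word = revcomp_dna(word)
            if position is None:
                for _try in range(200):
                    pos = int(rng.integers(1, length - len(word) + 2))
                    if all(pos > e or pos + len(word) - 1 < s for s, e in taken):
                        break
                else:
                    raise RuntimeError(f"cannot place motif {motif_name} in {pid}")
            else:
                pos = position
                if pos < 1 or pos + len(word) - 1 > length:
                    raise ValueError(f"motif {motif_name} at {pos} exceeds promoter {pid}")
            seq[pos - 1 : pos - 1 + len(word)] = list(word)
            taken.append((pos, pos + len(word) - 1))
            truth[pid].append((motif_name, pos, strand))
        promoters[pid] = "".join(seq)
    return promoters, truth


def generate_transcriptome(
    site_plan: Sequence[Dict],
    mirnas: Mapping[str, str],
    transcript_length: int = 600,
    rng_seed: int = 0,
) -> Tuple[Dict[str, str], List[Dict]]:
    """Transcripts with implanted miRNA target sites of known composition.

    ``site_plan`` entries: dict with keys ``transcript``, ``mirna``,
    ``position`` (1-based site start), ``mismatch_positions`` and
    ``gu_positions`` (1-based positions along the miRNA, 5'->3').  The site
    is the reverse complement of the mature with the requested defects; the
    truth list records the planted span and composition.
    """
    rng = np.random.default_rng(rng_seed)
    transcripts: Dict[str, str] = {}
    truth: List[Dict] = []
    order: List[str] = []
    for entry in site_plan:
        tid = entry["transcript"]
        if tid not in transcripts:
            transcripts[tid] = "".join(rng.choice(_GENOME_ALPHABET, size=transcript_length))
            order.append(tid)
        mature = to_rna(mirnas[entry["mirna"]])
        mm = set(entry.get("mismatch_positions", ()))
        gu = set(entry.get("gu_positions", ()))
        if mm & gu:
            raise ValueError("a miRNA position cannot be both mismatch and G:U")
        site_rna: List[str] = []
        for i, base in enumerate(mature, start=1):  # i: miRNA position from its 5' end
            if i in mm:
                site_rna.append(base)  # identity: never pairs
            elif i in gu:
                if base not in _WOBBLE:
                    raise ValueError(f"planted G:U needs G/U at miRNA position {i}")
                site_rna.append(_WOBBLE[base])
            else:
                site_rna.append(_WC[base])
        # target strand read 5'->3': reverse of the per-position partner list
        site_dna = to_dna("".join(reversed(site_rna)))
        pos = entry["position"]
        seq = list(transcripts[tid])
        if pos < 1 or pos + len(site_dna) - 1 > len(seq):
            raise ValueError(f"site at {pos} exceeds transcript {tid}")
        seq[pos - 1 : pos - 1 + len(site_dna)] = list(site_dna)
        transcripts[tid] = "".join(seq)
        truth.append(
            dict(
                transcript=tid,
                mirna=entry["mirna"],
                span=[pos, pos + len(site_dna) - 1],
                mismatch_positions=sorted(mm),
                gu_positions=sorted(gu),
            )
        )
    return {tid: transcripts[tid] for tid in order}, truth


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_config(rng_seed: int = 0) -> GenomeConfig:
    """The canonical synthetic study: 12 implants on 6 chromosomes.

    Eight implants are built to pass the seven-point screen -- among them two
    same-strand cluster pairs at 90 and 158 nt gaps (the printed intra-cluster
    gap range), one of which doubles as a segmental pair on a shared block,
    and three intragenic cases (intron, UTR, antisense-intron host genes).
    Four implants are built to fail exactly one criterion each: two diverge
    from the reference mature by 4-5 substitutions (criterion 1), one carries
    six unpaired mature residues (criterion 3), one a 4-nt bulge (criterion 5).
    Decoys: two dinucleotide-shuffled precursors, two ORF-like loci, two
    tRNA-like loci.
    """
    ref1 = REFERENCE_MATURES["miR166-ref1"]
    ref2 = REFERENCE_MATURES["miR166-ref2"]

    def spec(name, chrom, offset, strand="+", mature=ref1, **kw):
        return ImplantSpec(name=name, mature_seq=mature, chrom=chrom, offset=offset,
                           strand=strand, **kw)

    # cluster members: the second offset realizes the configured gap exactly
    imp01 = spec("imp01", "chrA", 5000, planted_mismatches=2, planted_gu=1)
    imp03 = spec("imp03", "chrB", 8000, strand="-", planted_mismatches=3,
                 planted_gu=2, planted_bulge_len=2)
    implants = [
        # cluster pair 1 (chrA, + strand, gap 90 nt) -- also a tandem pair
        imp01,
        spec("imp02", "chrA", imp01.offset + imp01.total_length + 90,
             planted_mismatches=1, planted_gu=2, clone_of="imp01"),
        # cluster pair 2 (chrB, - strand, gap 158 nt)
        imp03,
        spec("imp04", "chrB", imp03.offset + imp03.total_length + 158,
             strand="-", planted_mismatches=2, clone_of="imp03"),
        # segmental partners of pair 1 members, on chrC
        spec("imp05", "chrC", 4000, planted_mismatches=2, planted_gu=1, clone_of="imp01"),
        spec("imp06", "chrC", 20000, planted_mismatches=1, clone_of="imp02"),
        # intragenic singletons
        spec("imp07", "chrD", 6000, planted_mismatches=1, planted_gu=1),   # intron
        spec("imp08", "chrD", 15000, strand="-", mature=ref2, planted_mismatches=1),  # UTR
        # criterion-violating implants
        spec("imp09", "chrE", 3000, mature_mutations=4),                   # fails 1
        spec("imp10", "chrE", 9000, planted_mismatches=6),                 # fails 3
        spec("imp11", "chrF", 3000, planted_mismatches=4, planted_bulge_len=4),  # fails 5
        spec("imp12", "chrF", 9000, strand="-", mature_mutations=4),       # fails 1
    ]
    return GenomeConfig(
        chrom_lengths={"chrA": 30000, "chrB": 30000, "chrC": 30000,
                       "chrD": 30000, "chrE": 30000, "chrF": 30000},
        implants=implants,
        decoys={"shuffled": 2, "coding_like": 2, "trna_like": 2},
        segmental_pairs=[("imp01", "imp05"), ("imp02", "imp06")],
        host_genes={"imp07": "intron", "imp08": "UTR", "imp05": "antisense-intron"},
        rng_seed=rng_seed,
    )


def default_queries() -> Dict[str, str]:
    """Homology-search reference set: archetype precursors plus matures.

    The archetype precursor for each reference mature is the defect-free
    hairpin (no genomic flanks); the bare matures catch family loci whose
    precursor arms have diverged while the mature stayed conserved.
    """
    queries: Dict[str, str] = {}
    rng = np.random.default_rng(0)
    for ref_id in sorted(REFERENCE_MATURES):
        mature = REFERENCE_MATURES[ref_id]
        seq, _ = build_hairpin_precursor(
            ImplantSpec(name=ref_id, mature_seq=mature, flank_len=0), rng
        )
        queries[f"{ref_id}-pre"] = seq
        queries[f"{ref_id}-mat"] = mature
    return queries


def write_outputs(
    genome: Mapping[str, str],
    features: Sequence[GffFeature],
    block_table,
    manifest: TruthManifest,
    outdir: str | Path,
) -> Dict[str, Path]:
    """Write genome.fa, annotation.gff3, blocks.tsv and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff3",
        "blocks": outdir / "blocks.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(genome, paths["genome"])
    write_gff3(features, paths["annotation"])
    block_table.to_csv(paths["blocks"], sep="\t", index=False)
    paths["manifest"].write_text(manifest.to_json())
    return paths
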