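# Methods

`mirfam` reimplements, as a reusable desk-scale pipeline, the homology-based
workflow used to discover and characterize plant miRNA families of the
miR166 type: scan a genome for precursor-like loci by similarity to known
family members, validate each candidate hairpin against a seven-point
screen, then describe the family genomically (clusters, duplications),
evolutionarily (identity structure, trees), and functionally (promoter
cis-elements, predicted targets).  A synthetic-genome generator provides
ground truth for every stage, so correctness is tested as exact recovery
rather than by eyeballing.

## The seven-point precursor screen

A candidate window is folded to its minimum-free-energy (MFE) nested
secondary structure, the best-matching reference mature is placed on it, and
seven criteria are evaluated:

1. the mature matches a known family mature with at most
   `max_mature_mismatch` substitutions (default 2 — "identical or nearly
   identical" operationalized);
2. the mature lies on a single arm of the hairpin (its paired partners all
   fall on one side of its own span; self-pairing or two-sided pairing means
   the placement straddles the loop);
3. at most 5 mature positions are unpaired in the miRNA/miRNA\* duplex;
4. at most 5 mature positions pair through G:U wobbles;
5. the longest run of consecutive unpaired mature positions (the bulge) is
   at most 3 nt;
6. MFE ≤ −33.0 kcal/mol (at or below the canonical rRNA benchmark fold
   energy, so candidate folds are more stable than housekeeping RNAs);
7. MFEI ≥ 0.70, where `MFEI = (|MFE| / L × 100) / GC%`.  The index
   normalizes fold energy for length and base composition; miRNA precursors
   typically score ≥ 0.85, whereas tRNA/rRNA/mRNA fall below.  The 0.70
   default admits the weakest published family member (MFEI 0.71) with no
   margin to spare, which is the point of a screen bound.

Criteria 3–5 are counted over the mature region only.  The miRNA\* span is
inferred from the pairing with a 2-nt 3′ overhang (standard Dicer geometry;
the convention matters only for deciding whether a partner position belongs
to the star).  All bounds live in `CriteriaThresholds` and are configurable.

**Precursor boundary.** The fold window (hit ± 60 nt by default) is trimmed
to the maximal helix containing the mature: starting from the outermost base
pair touching the mature span, the helix is extended outward while
consecutive positions pair with each other, then padded by 3 nt.  The
trimmed sequence is refolded and re-screened, so reported lengths, MFE and
MFEI refer to the precursor, not the arbitrary window.

## Folding engines

The default engine is ViennaRNA's MFE fold (python bindings, default Turner
parameters) — the thermodynamics behind published MFE/MFEI values, so the
criterion-6/7 defaults keep their literature meaning.  A compact bundled
engine (`engine="stacking"`) implements Zuker-style recursions over nested
structures with a small stacking table and size-dependent loop penalties; it
exists as a dependency-free fallback and as an independent cross-check (the
test-suite verifies both engines recover identical pair sets on clean
stems).  Its energies are not numerically interchangeable with ViennaRNA's;
because every energy criterion is a configurable threshold, the screen
remains usable with either engine, but the shipped defaults assume Vienna.

## Homology search

Smith–Waterman local alignment (Biopython `PairwiseAligner`; match +1,
mismatch −1, gap −2 linear) over overlapping 3-kb chunks of both genome
strands, with iterative masking of each accepted hit so that clustered loci
tens of nt apart are all recovered.  Acceptance requires ≥ 80% identity over
≥ 80% of the query.  The reference set combines archetype precursors and
bare matures: precursor queries anchor well-conserved loci, mature queries
catch members whose arms diverged while the mature stayed conserved (and
admit chance background hits, which the fold screen then rejects — that
division of labour is intentional).  Candidates overlapping annotated CDS,
tRNA, rRNA, snRNA or snoRNA features over at least half their length are
excluded; intron- and UTR-hosted candidates survive because introns and UTRs
are not excluded types.  Overlapping windows evaluated on both strands (a
clean hairpin is nearly strand-symmetric) are deduplicated toward the
passing, lower-mismatch, lower-MFE reading.

## Family characterization

*Clusters.* Same-chromosome, same-strand precursors whose intervening
sequence gap (`downstream.start − upstream.end − 1`) is ≤ 3000 nt chain into
clusters; the gap semantics (not start-to-start distance) are what make the
published 90–158 nt intra-cluster distances reproducible.  The 3-kb cluster
bound is inclusive; the tandem-duplication bound below is strict — the two
rules are phrased differently in the source material and both readings are
exposed in config.  An interleaved opposite-strand locus does not break a
chain.  Clusters collapse to single polycistronic gene loci named by joined
member suffixes (`miR166e/q`), so 26 precursors with four 2-member clusters
yield 22 genes.

*Duplications.* For paralog pairs (pairwise global identity ≥ 85 — see
below), a pair is tandem when the same-chromosome separation is strictly
under 3 kb, and segmental when both members fall entirely inside the paired
intervals of one row of a duplicated-block table (PGDD-style TSV).  Ka/Ks
ratios are joined from an external table when given — they are retrieved
inputs, never computed here — and interpreted as purifying (< 1), neutral
(= 1) or positive (> 1).

The 85% paralog-identity prefilter is deliberately below the published
93.8% within-pair floor: discovered precursor boundaries carry a few
nucleotides of random genomic overhang from helix-extension trimming, which
costs measured identity even for identical cores.  85% keeps every true
pair in the synthetic study with margin while excluding the 55–70%
background regime.

*Conservation.* Percent identity = identical columns / alignment columns
after stripping terminal-gap columns; internal gaps count against identity
(conventions differ between alignment viewers, so this one is stated).
Trees are neighbor-joining on `100 − identity` distances.  Maximum-likelihood
inference is out of scope; topology-level statements (paralog pairs as
cherries, quartet splits) are the tested surface, and NJ recovers additive
distances exactly, which is what those tests exercise.  Optional split
support uses a pairwise-column bootstrap: columns of each pairwise alignment
are resampled independently, the identity matrix and NJ tree recomputed, and
split recovery counted.  No multiple alignment is built anywhere; this is a
deliberate simplification, and support values from it are not comparable to
MSA-based bootstraps.

*Promoters.* The promoter is the 1,500-bp window upstream of the TSS on the
gene's strand, reverse-complemented for minus-strand genes and clipped (with
a flag) at chromosome ends.  Without a TSS table the precursor 5′ end
stands in — for plant MIR genes most predicted promoters lie within the
first kilobase upstream of the fold-back, so the default loses little.  The
cis-element catalogue is data, not code: a YAML of IUPAC consensi in the
PlantCARE style (TATA-box, CAAT-box, Skn-1, GCN4, HSE, ARE, MBS, LTR,
RY-element, HD-ZIP III binding site, …) with editable patterns, because no
canonical machine-readable definition of these elements is bundled with any
installed library.  Scanning is exact degenerate matching at every offset;
double-stranded elements are matched as a single forward/reverse-complement
alternation so palindromic motifs count once per offset.  Presence is
existence; prevalence is the percent of genes containing a motif, reported
to one decimal.

*Targets.* Allen-type penalty scoring: mismatch 1.0, G:U 0.5, gap 2.0, all
doubled at miRNA positions 2–13 (5′-numbered seed); a site is reported when
its cumulative penalty ("expectation") is ≤ 3.0.  The scheme is recorded in
`TargetScheme` so alternates can be swapped; it is a declared convention,
not a claim of bit-compatibility with any web service version.  At most one
gap per site is considered (site length within ±1 of the mature), searched
by exhaustive gap-position enumeration; ties go to the leftmost site.
Cleavage is predicted at the bond opposite miRNA positions 10–11 (the
reported coordinate is the transcript base opposite position 10, i.e.
`site_end − 9`); a mismatch opposite positions 9–11 flags the hit as likely
translational inhibition instead.  Unique target sites (UTS) are exact
sequence deduplicates numbered in first-seen order.

## The synthetic study

`simulate.default_config()` defines the study conditions: six 30-kb
chromosomes; twelve implanted precursors; six decoys (two dinucleotide
shuffles of a family precursor, two ORF-like loci annotated as CDS, two
tRNA-like loci annotated as tRNA).  Eight implants are built to pass the
screen, among them two same-strand cluster pairs at 90 and 158 nt gaps (the
endpoints of the published intra-cluster range), two segmental duplicate
pairs on block-table rows, and three intragenic cases (intron, UTR and
antisense-intron host genes).  Four implants are built to fail exactly one
criterion each: two matures diverged by 4 substitutions (criterion 1), one
duplex with six unpaired residues (criterion 3), one with a 4-nt bulge
(criterion 5).

Hairpin construction plants defects by substituting star bases that can
neither Watson–Crick- nor wobble-pair (the star keeps the mature's length, so
the helix register cannot slip when a thermodynamic folder refolds the
sequence); a bulge is a consecutive run of such positions, singletons are
spaced ≥ 3 apart.  Defect magnitudes for fail-implants were chosen with
margin against their bound (6 > 5 unpaired, 4 > 3 bulge, 4 > 2 mismatches)
because an MFE folder may repair one or two planted defects by local
rearrangement; with these margins, recovery of the exact planted pass/fail
flags is stable across generator seeds.  Flanks form a perfect lower helix
(real precursors extend well beyond the miRNA/miRNA\* duplex — that lower
stem is what produces MFEs in the published −46 to −90 kcal/mol range);
paralog-pair implants share flanks and loop via `clone_of`, as true
duplicates would.

What the generator does **not** emulate: realistic nucleotide evolution,
whole-genome duplication history, intron/exon structure beyond what context
classification needs, transcript isoforms, or base-composition heterogeneity
along chromosomes.  Passing recovery tests therefore demonstrates the
pipeline's logic is correct under controlled conditions, not that its
defaults are optimal for any particular real genome.

All randomness in a run derives from one integer seed; rerunning any stage
with the same config and seed is byte-identical, and reports carry the
config hash and seed in their headers.

## Problem sizes

The default synthetic study (180 kb of genome, 4 queries, ~17 candidate
windows) runs the full discovery-plus-characterization pipeline in a few
seconds on one CPU; the complete test-suite, including the oracle suites
(400 constructed hairpins for duplex statistics, 110+ random coordinate sets
for clustering, 150 scored alignments, 240 shuffle folds), completes in well
under a minute.  These sizes were chosen to keep every property testable
exhaustively; nothing in the method is specific to them, and the scan cost
grows linearly in genome length times query count.

## Known limitations

* The screen's energy criteria are calibrated for ViennaRNA default
  parameters; the bundled stacking engine needs recalibrated thresholds.
* The homology search is exact but quadratic per chunk — appropriate for
  desk-scale genomes and plasmid/contig screens, not for scanning a full
  1-Gb genome (an external seeded aligner can be substituted behind
  `local_align_search`).
* Strand assignment of a defect-free palindromic hairpin is ambiguous by
  construction; the discovery dedupe breaks the tie toward the reading with
  fewer mature mismatches, which real (imperfect) precursors make unique.
* Identity-based paralog pairing depends on discovered boundaries; with very
  short or heavily trimmed precursors the 85% prefilter may need lowering.
* `collapse_unique` deduplicates exact sequences only; near-identical
  matures (1 nt apart) remain distinct representatives, matching the
  UmiR/UTS bookkeeping convention.
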