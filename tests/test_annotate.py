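import numpy as np
import pandas as pd
import pytest

from mirfam.annotate import (
    ClusterCall,
    DuplicationCall,
    classify_duplications,
    classify_genomic_context,
    collapse_to_genes,
    detect_clusters,
    selection_class,
    summarize_chromosomes,
)
from mirfam.core import GenomicLocus, GffFeature


def L(chrom, start, end, strand="+"):
    return GenomicLocus(chrom, start, end, strand)


def cluster_oracle(loci, max_gap=3000):
    """All-pairs O(n^2) grouping: chain same-chrom/strand neighbours."""
    groups = {}
    for name, loc in loci.items():
        groups.setdefault((loc.chrom, loc.strand), []).append((name, loc))
    clusters = []
    for members in groups.values():
        members.sort(key=lambda kv: kv[1].start)
        chain = [members[0]]
        for item in members[1:]:
            prev = chain[-1][1]
            gap = item[1].start - prev.end - 1
            if 0 <= gap <= max_gap:
                chain.append(item)
            else:
                if len(chain) >= 2:
                    clusters.append(tuple(n for n, _ in chain))
                chain = [item]
        if len(chain) >= 2:
            clusters.append(tuple(n for n, _ in chain))
    return sorted(clusters)


def random_locus_set(rng, n=12):
    loci = {}
    attempts = 0
    while len(loci) < n and attempts < 500:
        attempts += 1
        chrom = f"chr{rng.integers(1, 4)}"
        start = int(rng.integers(1, 60_000))
        end = start + int(rng.integers(80, 200))
        strand = "+" if rng.random() < 0.5 else "-"
        cand = GenomicLocus(chrom, start, end, strand)
        if any(cand.overlap(l) > 0 for l in loci.values()):
            continue
        loci[f"l{len(loci):02d}"] = cand
    return loci


class TestDetectClusters:
    def test_matches_all_pairs_oracle_on_random_sets(self):
        """detect_clusters agrees with the brute-force oracle on 120 random sets."""
        rng = np.random.default_rng(11)
        for _ in range(120):
            loci = random_locus_set(rng)
            got = sorted(tuple(c.member_ids) for c in detect_clusters(loci))
            assert got == cluster_oracle(loci)

    def test_paired_loci_at_90nt_form_cluster(self):
        loci = {"a": L("c1", 1000, 1098, "-"), "b": L("c1", 1189, 1290, "-")}
        (cluster,) = detect_clusters(loci)
        assert cluster.member_ids == ("a", "b")
        assert cluster.gaps == (90,)

    def test_gap_boundary_3000_inclusive_3001_excluded(self):
        base = {"a": L("c1", 1000, 1099)}
        assert len(detect_clusters({**base, "b": L("c1", 4100, 4200)})) == 1  # gap 3000
        assert detect_clusters({**base, "b": L("c1", 4101, 4200)}) == []  # gap 3001

    def test_opposite_strands_never_cluster(self):
        loci = {"a": L("c1", 1000, 1100, "+"), "b": L("c1", 1201, 1300, "-")}
        assert detect_clusters(loci) == []

    def test_input_permutation_invariance(self):
        loci = {"a": L("c1", 1000, 1100), "b": L("c1", 1300, 1400),
                "c": L("c1", 9000, 9100), "d": L("c2", 50, 150)}
        fwd = detect_clusters(loci)
        rev = detect_clusters(dict(reversed(list(loci.items()))))
        assert [c.member_ids for c in fwd] == [c.member_ids for c in rev]

    def test_translation_invariance(self):
        loci = {"a": L("c1", 1000, 1100), "b": L("c1", 1300, 1400)}
        shifted = {k: L(v.chrom, v.start + 5000, v.end + 5000) for k, v in loci.items()}
        assert [c.gaps for c in detect_clusters(loci)] == \
            [c.gaps for c in detect_clusters(shifted)]

    def test_overlapping_loci_rejected_naming_pair(self):
        loci = {"a": L("c1", 1000, 1100), "b": L("c1", 1050, 1200)}
        with pytest.raises(ValueError, match="a and b"):
            detect_clusters(loci)


class TestCollapseToGenes:
    def test_26_loci_with_four_pair_clusters_collapse_to_22(self):
        loci = {}
        pos = 1000
        for i in range(4):  # four 2-member clusters
            loci[f"p{i}a"] = L(f"c{i}", pos, pos + 99)
            loci[f"p{i}b"] = L(f"c{i}", pos + 200, pos + 299)
        for i in range(18):  # singletons far apart
            loci[f"s{i:02d}"] = L(f"c{i % 6}", 50_000 + 10_000 * i, 50_099 + 10_000 * i)
        assert len(loci) == 26
        genes = collapse_to_genes(loci, detect_clusters(loci))
        assert len(genes) == 22

    def test_no_clusters_identity(self):
        loci = {"a": L("c1", 1000, 1100), "b": L("c1", 90_000, 90_100)}
        assert len(collapse_to_genes(loci, [])) == 2

    def test_three_member_cluster_among_five(self):
        loci = {"a": L("c1", 1000, 1100), "b": L("c1", 1200, 1300),
                "c": L("c1", 1400, 1500), "d": L("c2", 1000, 1100),
                "e": L("c3", 1000, 1100)}
        genes = collapse_to_genes(loci, detect_clusters(loci))
        assert len(genes) == 3

    def test_cluster_gene_named_by_joined_suffixes(self):
        loci = {"miR166e": L("c1", 1000, 1099), "miR166q": L("c1", 1258, 1357)}
        genes = collapse_to_genes(loci, detect_clusters(loci))
        assert genes[0]["gene_id"] == "miR166e/q"
        assert genes[0]["polycistronic"]


def host_gene_features(chrom, gene_start, gene_end, strand, exons, utr=None):
    base = dict(seqid=chrom, source="t", score=".", phase=".", strand=strand)
    feats = [
        GffFeature(ftype="gene", start=gene_start, end=gene_end,
                   attributes={"ID": "g1"}, **base),
        GffFeature(ftype="mRNA", start=gene_start, end=gene_end,
                   attributes={"ID": "t1", "Parent": "g1"}, **base),
    ]
    for i, (s, e) in enumerate(exons):
        feats.append(GffFeature(ftype="exon", start=s, end=e,
                                attributes={"ID": f"e{i}", "Parent": "t1"}, **base))
    if utr:
        feats.append(GffFeature(ftype="five_prime_UTR", start=utr[0], end=utr[1],
                                attributes={"ID": "u1", "Parent": "t1"}, **base))
    return feats


class TestGenomicContext:
    def test_utr_hosted_sense(self):
        feats = host_gene_features("c1", 1000, 3000, "+", [(1000, 3000)], utr=(1000, 1500))
        contexts = classify_genomic_context({"p": L("c1", 1100, 1200, "+")}, feats)
        assert contexts["p"] == "UTR"

    def test_antisense_intron(self):
        feats = host_gene_features("c1", 1000, 3000, "-", [(1000, 1400), (2600, 3000)])
        contexts = classify_genomic_context({"p": L("c1", 1800, 1900, "+")}, feats)
        assert contexts["p"] == "antisense-intron"

    def test_intergenic_without_gene_overlap(self):
        feats = host_gene_features("c1", 1000, 3000, "+", [(1000, 3000)])
        contexts = classify_genomic_context({"p": L("c1", 5000, 5100, "+")}, feats)
        assert contexts["p"] == "intergenic"


BLOCKS = pd.DataFrame(
    [{"block_id": "446", "chrom_a": "c1", "start_a": 900, "end_a": 1400,
      "chrom_b": "c7", "start_b": 5000, "end_b": 5600}]
)


class TestDuplications:
    def test_block_pair_called_segmental_with_block_id(self):
        loci = {"a": L("c1", 1000, 1100), "b": L("c7", 5200, 5300)}
        (call,) = classify_duplications(loci, [("a", "b")], BLOCKS)
        assert (call.kind, call.block_id) == ("segmental", "446")

    def test_close_same_chromosome_pair_is_tandem(self):
        loci = {"a": L("c1", 1000, 1100), "b": L("c1", 1251, 1350)}
        (call,) = classify_duplications(loci, [("a", "b")], None)
        assert call.kind == "tandem"

    def test_tandem_boundary_is_strict(self):
        loci = {"a": L("c1", 1000, 1100), "b": L("c1", 4101, 4200)}  # gap 3000
        assert classify_duplications(loci, [("a", "b")], None) == []

    def test_kaks_below_one_is_purifying(self):
        loci = {"a": L("c1", 1000, 1100), "b": L("c1", 1251, 1350)}
        (call,) = classify_duplications(loci, [("a", "b")], None,
                                        kaks={("a", "b"): 0.4})
        assert call.selection_class == "purifying"
        assert selection_class(1.0) == "neutral"
        assert selection_class(1.7) == "positive"
        assert selection_class(None) == "unknown"

    def test_overlapping_block_intervals_rejected(self):
        bad = pd.DataFrame(
            [{"block_id": "x", "chrom_a": "c1", "start_a": 100, "end_a": 500,
              "chrom_b": "c1", "start_b": 400, "end_b": 900}]
        )
        loci = {"a": L("c1", 150, 200), "b": L("c1", 450, 500)}
        with pytest.raises(ValueError, match="overlap"):
            classify_duplications(loci, [("a", "b")], bad)

    def test_segmental_requires_block_id_invariant(self):
        with pytest.raises(ValueError):
            DuplicationCall(("a", "b"), "segmental", block_id=None)


class TestSummarizeChromosomes:
    def test_empty_and_count_conservation(self):
        assert summarize_chromosomes({}) == {}
        rng = np.random.default_rng(0)
        loci = random_locus_set(rng, n=15)
        counts = summarize_chromosomes(loci)
        assert sum(counts.values()) == 15
        assert list(counts) == sorted(counts)
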