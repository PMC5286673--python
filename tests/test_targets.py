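import numpy as np
import pytest

from mirfam.core import revcomp_rna, to_dna, to_rna
from mirfam.simulate import REFERENCE_MATURES, generate_transcriptome
from mirfam.targets import (
    TargetScheme,
    collapse_uts,
    map_cleavage,
    scan_transcriptome,
    score_site,
)

MATURE = REFERENCE_MATURES["miR166-ref1"]
WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
WOBBLE = {"G": "U", "U": "G"}


def perfect_site(mature):
    """Site written 3'->5': per-position Watson-Crick partner of the miRNA."""
    return "".join(WC[b] for b in to_rna(mature))


def penalty_oracle(mature, site, scheme=TargetScheme()):
    """Independent per-position penalty sum for an ungapped alignment."""
    total = 0.0
    for pos, (mb, sb) in enumerate(zip(to_rna(mature), to_rna(site)), start=1):
        weight = 2.0 if scheme.seed_start <= pos <= scheme.seed_end else 1.0
        if (mb, sb) in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}:
            continue
        if (mb, sb) in {("G", "U"), ("U", "G")}:
            total += 0.5 * weight
        else:
            total += 1.0 * weight
    return total


class TestScoreSite:
    def test_perfect_complement_scores_zero(self):
        expectation, marks = score_site(MATURE, perfect_site(MATURE))
        assert expectation == 0.0
        assert set(marks) == {"|"}

    def test_single_gu_in_seed_scores_one(self):
        site = list(perfect_site(MATURE))
        # position 3 (seed): mature G -> opposite U instead of C
        assert MATURE[2] == "G"
        site[2] = "U"
        expectation, marks = score_site(MATURE, "".join(site))
        assert expectation == 1.0  # 0.5 doubled in seed
        assert marks[2] == "o"

    def test_mismatch_outside_seed_plus_gu(self):
        site = list(perfect_site(MATURE))
        site[14] = MATURE[14]  # mismatch at position 15 (weight 1): +1.0
        assert MATURE[15] == "U"
        site[15] = "G"  # G:U at position 16: +0.5
        expectation, _ = score_site(MATURE, "".join(site))
        assert expectation == 1.5

    def test_matches_oracle_on_random_defect_compositions(self, rng):
        """score_site equals the per-position penalty oracle (120 alignments)."""
        for _ in range(120):
            site = list(perfect_site(MATURE))
            k = int(rng.integers(0, 5))
            for pos in rng.choice(21, size=k, replace=False):
                if MATURE[pos] in WOBBLE and rng.random() < 0.5:
                    site[pos] = WOBBLE[MATURE[pos]]
                else:
                    site[pos] = MATURE[pos]
            expectation, _ = score_site(MATURE, "".join(site))
            assert expectation == pytest.approx(penalty_oracle(MATURE, "".join(site)))

    def test_monotone_under_added_mismatches(self, rng):
        """Turning any paired position into a mismatch never lowers the score."""
        site = list(perfect_site(MATURE))
        site[4] = MATURE[4]
        base, _ = score_site(MATURE, "".join(site))
        for pos in range(21):
            if site[pos] == MATURE[pos]:
                continue
            worse = list(site)
            worse[pos] = MATURE[pos]
            got, _ = score_site(MATURE, "".join(worse))
            assert got >= base

    def test_gap_penalty_counted(self):
        shorter = perfect_site(MATURE)[:-1]  # one miRNA base unopposed
        expectation, marks = score_site(MATURE, shorter)
        assert "-" in marks
        assert expectation >= 2.0

    def test_incompatible_length_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            score_site(MATURE, perfect_site(MATURE)[:-3])


class TestScanTranscriptome:
    def test_exact_reverse_complement_site_scores_zero(self):
        tx = "A" * 50 + to_dna(revcomp_rna(MATURE)) + "A" * 50
        hits = scan_transcriptome({"v": MATURE}, {"t": tx})
        assert hits[0].expectation == 0.0
        assert hits[0].site_span == (51, 71)

    def test_site_above_cutoff_absent(self):
        # penalty 3.5: seed mismatch (2.0) + mismatch at 15 (1.0) + G:U at 16 (0.5)
        site = list(perfect_site(MATURE))
        site[4] = MATURE[4]
        site[14] = MATURE[14]
        site[15] = "G"
        assert penalty_oracle(MATURE, "".join(site)) == 3.5
        tx = "A" * 40 + to_dna("".join(reversed(site))) + "A" * 40
        hits = scan_transcriptome({"v": MATURE}, {"t": tx})
        assert all(h.expectation <= 3.0 for h in hits)
        assert not any(h.site_span == (41, 61) and h.expectation == 3.5 for h in hits)

    def test_empty_transcriptome(self):
        assert scan_transcriptome({"v": MATURE}, {}) == []

    def test_implanted_sites_recovered_exactly(self):
        """Recall and precision 1.0 for planted sites at expectation <= 3."""
        plan = [
            dict(transcript="t1", mirna="miR166-ref1", position=60),
            dict(transcript="t1", mirna="miR166-ref1", position=300,
                 mismatch_positions=[15], gu_positions=[16]),  # 1.5
            dict(transcript="t2", mirna="miR166-ref1", position=100,
                 mismatch_positions=[3]),  # 2.0 (seed)
            dict(transcript="t2", mirna="miR166-ref1", position=400,
                 mismatch_positions=[3, 15], gu_positions=[16]),  # 3.5 > cutoff
        ]
        tx, truth = generate_transcriptome(plan, REFERENCE_MATURES, rng_seed=12)
        hits = scan_transcriptome({"miR166-ref1": REFERENCE_MATURES["miR166-ref1"]}, tx)
        spans = {(h.transcript_id, h.site_span) for h in hits}
        expected_present = {("t1", (60, 80)), ("t1", (300, 320)), ("t2", (100, 120))}
        assert expected_present <= spans
        assert ("t2", (400, 420)) not in spans
        by_span = {(h.transcript_id, h.site_span): h for h in hits}
        assert by_span[("t1", (60, 80))].expectation == 0.0
        assert by_span[("t1", (300, 320))].expectation == 1.5
        assert by_span[("t2", (100, 120))].expectation == 2.0
        # precision: every reported hit is a planted site or scores <= 3 honestly
        assert all(h.expectation <= 3.0 for h in hits)

    def test_hits_sorted_by_expectation_then_coordinates(self):
        plan = [
            dict(transcript="t1", mirna="miR166-ref1", position=60,
                 mismatch_positions=[15]),
            dict(transcript="t1", mirna="miR166-ref1", position=300),
        ]
        tx, _ = generate_transcriptome(plan, REFERENCE_MATURES, rng_seed=1)
        hits = scan_transcriptome({"miR166-ref1": REFERENCE_MATURES["miR166-ref1"]}, tx)
        expectations = [h.expectation for h in hits]
        assert expectations == sorted(expectations)


class TestCleavage:
    def test_cleavage_opposite_positions_10_11(self):
        tx = "A" * 39 + to_dna(revcomp_rna(MATURE)) + "A" * 40
        (hit,) = [h for h in scan_transcriptome({"v": MATURE}, {"t": tx})
                  if h.expectation == 0.0]
        assert hit.site_span == (40, 60)
        assert map_cleavage(hit) == 51  # base opposite miRNA position 10
        assert hit.site_span[0] <= hit.cleavage_pos <= hit.site_span[1]
        assert hit.inhibition_mode == "cleavage"

    def test_central_mismatch_flags_translation_mode(self):
        site = list(perfect_site(MATURE))
        site[9] = MATURE[9]  # mismatch at position 10 (central)
        tx = "A" * 40 + to_dna("".join(reversed(site))) + "A" * 40
        hits = scan_transcriptome({"v": MATURE}, {"t": tx})
        central = [h for h in hits if h.site_span == (41, 61)]
        assert central and central[0].inhibition_mode == "translation"


class TestCollapseUts:
    def _hits(self):
        tx1 = "C" * 30 + to_dna(revcomp_rna(MATURE)) + "C" * 30
        hits_a = scan_transcriptome({"v": MATURE}, {"species1_tx": tx1})
        hits_b = scan_transcriptome({"v": MATURE}, {"species2_tx": tx1})
        return hits_a + hits_b

    def test_identical_sites_across_species_collapse(self):
        uts = collapse_uts(self._hits())
        assert len(uts) == 1
        assert len(uts[0]["members"]) == 2
        assert uts[0]["uts_id"] == "UTS01"

    def test_distinct_sites_stay_distinct(self):
        tx1 = "C" * 30 + to_dna(revcomp_rna(MATURE)) + "C" * 30
        site2 = list(perfect_site(MATURE))
        site2[14] = MATURE[14]
        tx2 = "G" * 30 + to_dna("".join(reversed(site2))) + "G" * 30
        hits = scan_transcriptome({"v": MATURE}, {"a": tx1, "b": tx2})
        exact = [h for h in hits if h.expectation <= 1.0]
        uts = collapse_uts(exact)
        assert len(uts) == len({u["site_seq"] for u in uts}) == 2

    def test_idempotent_on_own_output(self):
        uts = collapse_uts(self._hits())
        seqs = {u["uts_id"]: u["site_seq"] for u in uts}
        assert len(set(seqs.values())) == len(seqs)
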