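"""Hairpin evaluation: folding, mature-arm placement and the seven-point screen.

A candidate precursor passes the screen when

1. its best mature placement matches a known family mature with at most
   ``max_mature_mismatch`` substitutions;
2. the mature lies entirely on one arm of the hairpin (no loop overlap);
3. at most ``max_duplex_unpaired`` mature positions are unpaired in the
   miRNA/miRNA* duplex;
4. at most ``max_gu_pairs`` mature positions pair through G:U wobbles;
5. the longest run of consecutive unpaired mature positions (the bulge) is
   at most ``max_bulge`` nt;
6. the minimum folding free energy (MFE) is at or below ``max_mfe`` kcal/mol;
7. the minimum folding free energy index,
   ``MFEI = (|MFE| / length x 100) / GC%``, is at least ``min_mfei``.

Counts for criteria 3-5 are taken over the mature region only.  The miRNA*
span is inferred from the pairing with a 2-nt 3' overhang (Dicer geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .core import GU_PAIRS, RNA_PAIRS, to_rna
from .fold import fold_sequence, pair_table

__all__ = [
    "HairpinFold",
    "MatureAssignment",
    "CriteriaThresholds",
    "CriteriaReport",
    "fold_hairpin",
    "assign_mature",
    "duplex_stats",
    "composition_stats",
    "compute_mfei",
    "apply_criteria",
    "trim_to_hairpin",
    "evaluate_precursor",
    "MIN_PRECURSOR_LEN",
]

MIN_PRECURSOR_LEN = 40


@dataclass(frozen=True)
class HairpinFold:
    """A folded precursor: RNA sequence, nested dot-bracket pairing and MFE."""

    sequence: str
    pairing: str
    mfe: float
    engine: str = "vienna"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.pairing):
            raise ValueError("sequence and pairing must have equal length")
        partners = pair_table(self.pairing)  # validates balance/nesting
        for i, j in enumerate(partners):
            if j is not None and i < j:
                pair = (self.sequence[i], self.sequence[j])
                if pair not in RNA_PAIRS:
                    raise ValueError(
                        f"non-complementary pair {pair} at positions {i + 1},{j + 1}"
                    )

    @property
    def partners(self) -> List[Optional[int]]:
        return pair_table(self.pairing)

    def loop_span(self) -> Optional[Tuple[int, int]]:
        """1-based span of the apical loop: between the innermost '(' and ')'.

        None when the structure has no pair at all.
        """
        last_open = self.pairing.rfind("(")
        if last_open == -1:
            return None
        first_close = self.pairing.index(")", last_open)
        return last_open + 2, first_close  # 1-based unpaired region


@dataclass(frozen=True)
class MatureAssignment:
    """Placement of a reference mature miRNA on a folded precursor."""

    mature_seq: str
    mature_span: Tuple[int, int]  # 1-based inclusive on the precursor
    arm: Optional[str]  # "5p", "3p", or None when straddling the loop
    star_span: Optional[Tuple[int, int]]
    n_mismatch_vs_reference: int
    reference_id: str


def fold_hairpin(sequence: str, engine: str = "vienna") -> HairpinFold:
    """Fold a candidate precursor window into its MFE nested structure."""
    seq = to_rna(sequence)
    if len(seq) < MIN_PRECURSOR_LEN:
        raise ValueError(
            f"sequence of {len(seq)} nt is shorter than the minimum plausible "
            f"precursor ({MIN_PRECURSOR_LEN} nt)"
        )
    structure, mfe = fold_sequence(seq, engine=engine)
    return HairpinFold(seq, structure, mfe, engine=engine)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _arm_of_span(partners: Sequence[Optional[int]], span: Tuple[int, int]) -> Optional[str]:
    """Arm carrying a span: 5p when its partners lie downstream, 3p upstream.

    None (loop overlap / criterion-2 failure) when the span pairs with itself,
    pairs to both sides, or pairs nowhere -- all signatures of a placement
    that is not confined to one arm of the duplex.
    """
    lo, hi = span
    left = right = inside = 0
    for pos in range(lo - 1, hi):
        partner = partners[pos]
        if partner is None:
            continue
        if lo - 1 <= partner <= hi - 1:
            inside += 1
        elif partner < lo - 1:
            left += 1
        else:
            right += 1
    if inside or (left and right) or (not left and not right):
        return None
    return "5p" if right else "3p"


def assign_mature(
    fold: HairpinFold,
    reference_matures: Mapping[str, str],
    max_mismatch: int = 2,
) -> Optional[MatureAssignment]:
    """Best placement of any reference mature on the precursor.

    Candidates are ranked by (over-threshold, mismatches, arm-less, reference
    id, position); placements whose pairing is not confined to one arm get
    ``arm=None`` and later fail criterion 2.  Returns None only when no
    reference fits on the precursor at all.  A best placement with more than
    ``max_mismatch`` substitutions is still returned (criterion 1 fails
    downstream); the cutoff only breaks ties toward in-threshold placements.
    """
    if not reference_matures:
        raise ValueError("reference mature set is empty")
    seq = fold.sequence
    partners = fold.partners
    best = None
    for ref_id in sorted(reference_matures):
        ref = to_rna(reference_matures[ref_id])
        if len(ref) > len(seq):
            continue
        for off in range(len(seq) - len(ref) + 1):
            window = seq[off : off + len(ref)]
            mm = _hamming(window, ref)
            span = (off + 1, off + len(ref))
            arm = _arm_of_span(partners, span)
            key = (mm > max_mismatch, mm, arm is None, ref_id, off)
            if best is None or key < best[0]:
                best = (key, window, span, arm, mm, ref_id)
    if best is None:
        return None
    _, window, span, arm, mm, ref_id = best
    star_span = _infer_star_span(fold, span) if arm is not None else None
    return MatureAssignment(window, span, arm, star_span, mm, ref_id)


def _infer_star_span(fold: HairpinFold, mature_span: Tuple[int, int]) -> Optional[Tuple[int, int]]:
    """miRNA* span from the pairing, with a 2-nt 3' overhang."""
    partners = fold.partners
    paired = [partners[i] for i in range(mature_span[0] - 1, mature_span[1]) if partners[i] is not None]
    if not paired:
        return None
    lo, hi = min(paired) + 1, max(paired) + 1
    return lo, min(hi + 2, len(fold.sequence))


def duplex_stats(fold: HairpinFold, assignment: MatureAssignment) -> Tuple[int, int, int]:
    """(unpaired, G:U pairs, longest bulge) over the mature region.

    A mature position counts as unpaired when it has no partner or its
    partner falls outside the inferred miRNA* span; the bulge is the longest
    run of consecutive unpaired mature positions.
    """
    partners = fold.partners
    seq = fold.sequence
    lo, hi = assignment.mature_span
    star = assignment.star_span
    unpaired = gu = 0
    run = max_run = 0
    for pos in range(lo - 1, hi):
        partner = partners[pos]
        in_star = partner is not None and star is not None and star[0] <= partner + 1 <= star[1]
        if partner is None or not in_star:
            unpaired += 1
            run += 1
            max_run = max(max_run, run)
        else:
            run = 0
            if (seq[pos], seq[partner]) in GU_PAIRS:
                gu += 1
    return unpaired, gu, max_run


def composition_stats(sequence: str) -> Tuple[float, float]:
    """(gc_fraction, u_fraction) over non-N positions."""
    seq = to_rna(sequence)
    counted = [c for c in seq if c != "N"]
    if not counted:
        raise ValueError("sequence has no unambiguous bases")
    n = len(counted)
    gc = sum(c in "GC" for c in counted) / n
    u = counted.count("U") / n
    return gc, u


def compute_mfei(mfe: float, length: int, gc_fraction: float) -> float:
    """Minimum folding free energy index, positive by convention.

    ``MFEI = (|MFE| / length x 100) / GC%`` with GC% on the 0-100 scale; the
    index normalises folding energy for length and base composition so that
    genuine miRNA precursors (typically MFEI > 0.85) separate from tRNA,
    rRNA and mRNA folds.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if gc_fraction <= 0:
        raise ValueError("MFEI undefined for GC fraction 0")
    return (abs(mfe) / length * 100.0) / (gc_fraction * 100.0)


@dataclass(frozen=True)
class CriteriaThresholds:
    """Screen thresholds; defaults follow the family-screen conventions."""

    max_mature_mismatch: int = 2
    max_duplex_unpaired: int = 5
    max_gu_pairs: int = 5
    max_bulge: int = 3
    max_mfe: float = -33.0  # at or below the rRNA benchmark fold energy
    min_mfei: float = 0.70


CRITERION_NAMES = (
    "mature_matches_reference",
    "mature_within_one_arm",
    "duplex_unpaired_le_max",
    "gu_pairs_le_max",
    "bulge_le_max",
    "mfe_low_enough",
    "mfei_high_enough",
)


@dataclass
class CriteriaReport:
    """Per-precursor record of the seven screening criteria and its statistics."""

    precursor_id: str
    precursor_len: int
    gc_fraction: float
    u_fraction: float
    mfe: float
    mfei: float
    n_mismatch_vs_reference: Optional[int]
    arm: Optional[str]
    duplex_unpaired: Optional[int]
    gu_pairs_in_mature: Optional[int]
    max_bulge_in_mature: Optional[int]
    criteria_flags: Dict[str, bool] = field(default_factory=dict)
    failures: List[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(self.criteria_flags.values())

    @property
    def failed_criteria(self) -> Tuple[int, ...]:
        return tuple(
            i + 1 for i, name in enumerate(CRITERION_NAMES) if not self.criteria_flags[name]
        )


def apply_criteria(
    precursor_id: str,
    fold: HairpinFold,
    assignment: Optional[MatureAssignment],
    thresholds: CriteriaThresholds = CriteriaThresholds(),
) -> CriteriaReport:
    """Evaluate the seven-point screen for one folded precursor."""
    gc, u = composition_stats(fold.sequence)
    mfei = compute_mfei(fold.mfe, len(fold.sequence), gc) if gc > 0 else 0.0
    flags: Dict[str, bool] = {}
    failures: List[str] = []

    if assignment is None:
        stats: Tuple[Optional[int], Optional[int], Optional[int]] = (None, None, None)
        flags["mature_matches_reference"] = False
        failures.append("no reference mature placement on the precursor")
        flags["mature_within_one_arm"] = False
        flags["duplex_unpaired_le_max"] = False
        flags["gu_pairs_le_max"] = False
        flags["bulge_le_max"] = False
        n_mismatch = arm = None
    else:
        n_mismatch = assignment.n_mismatch_vs_reference
        arm = assignment.arm
        flags["mature_matches_reference"] = n_mismatch <= thresholds.max_mature_mismatch
        if not flags["mature_matches_reference"]:
            failures.append(
                f"{n_mismatch} mismatches vs {assignment.reference_id} "
                f"(max {thresholds.max_mature_mismatch})"
            )
        flags["mature_within_one_arm"] = arm in ("5p", "3p")
        if not flags["mature_within_one_arm"]:
            failures.append("mature placement straddles the hairpin loop")
        if flags["mature_within_one_arm"]:
            unpaired, gu_pairs, bulge = duplex_stats(fold, assignment)
        else:
            unpaired, gu_pairs, bulge = len(assignment.mature_seq), 0, len(assignment.mature_seq)
        stats = (unpaired, gu_pairs, bulge)
        flags["duplex_unpaired_le_max"] = unpaired <= thresholds.max_duplex_unpaired
        if not flags["duplex_unpaired_le_max"]:
            failures.append(
                f"{unpaired} unpaired mature residues (max {thresholds.max_duplex_unpaired})"
            )
        flags["gu_pairs_le_max"] = gu_pairs <= thresholds.max_gu_pairs
        if not flags["gu_pairs_le_max"]:
            failures.append(f"{gu_pairs} G:U pairs in mature (max {thresholds.max_gu_pairs})")
        flags["bulge_le_max"] = bulge <= thresholds.max_bulge
        if not flags["bulge_le_max"]:
            failures.append(f"bulge of {bulge} nt in mature (max {thresholds.max_bulge})")

    flags["mfe_low_enough"] = fold.mfe <= thresholds.max_mfe
    if not flags["mfe_low_enough"]:
        failures.append(f"MFE {fold.mfe:.2f} above {thresholds.max_mfe:.2f} kcal/mol")
    flags["mfei_high_enough"] = mfei >= thresholds.min_mfei
    if not flags["mfei_high_enough"]:
        failures.append(f"MFEI {mfei:.2f} below {thresholds.min_mfei:.2f}")

    return CriteriaReport(
        precursor_id=precursor_id,
        precursor_len=len(fold.sequence),
        gc_fraction=gc,
        u_fraction=u,
        mfe=fold.mfe,
        mfei=mfei,
        n_mismatch_vs_reference=n_mismatch if assignment else None,
        arm=arm if assignment else None,
        duplex_unpaired=stats[0],
        gu_pairs_in_mature=stats[1],
        max_bulge_in_mature=stats[2],
        criteria_flags=flags,
        failures=failures,
    )


def trim_to_hairpin(
    fold: HairpinFold, assignment: MatureAssignment, pad: int = 3
) -> Tuple[int, int]:
    """1-based span of the maximal hairpin containing the mature arm, +/- pad.

    Starting from the outermost base pair touching the mature span, the helix
    is extended outwards while consecutive positions stay paired with each
    other, then padded by ``pad`` nt and clipped to the precursor.
    """
    partners = fold.partners
    lo, hi = assignment.mature_span
    paired = [
        (min(i, partners[i]), max(i, partners[i]))
        for i in range(lo - 1, hi)
        if partners[i] is not None
    ]
    if not paired:
        return 1, len(fold.sequence)
    i, j = min(p[0] for p in paired), max(p[1] for p in paired)
    while i > 0 and j < len(fold.sequence) - 1 and partners[i - 1] == j + 1:
        i, j = i - 1, j + 1
    return max(1, i + 1 - pad), min(len(fold.sequence), j + 1 + pad)


def evaluate_precursor(
    precursor_id: str,
    sequence: str,
    reference_matures: Mapping[str, str],
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    engine: str = "vienna",
    trim: bool = True,
) -> Tuple[CriteriaReport, HairpinFold, Optional[MatureAssignment]]:
    """Fold, (optionally) trim to the mature-bearing hairpin, and screen."""
    fold = fold_hairpin(sequence, engine=engine)
    assignment = assign_mature(fold, reference_matures, thresholds.max_mature_mismatch)
    if trim and assignment is not None and assignment.arm is not None:
        lo, hi = trim_to_hairpin(fold, assignment)
        trimmed = fold.sequence[lo - 1 : hi]
        if len(trimmed) >= MIN_PRECURSOR_LEN and len(trimmed) < len(fold.sequence):
            fold = fold_hairpin(trimmed, engine=engine)
            assignment = assign_mature(fold, reference_matures, thresholds.max_mature_mismatch)
    report = apply_criteria(precursor_id, fold, assignment, thresholds)
    return report, fold, assignment
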