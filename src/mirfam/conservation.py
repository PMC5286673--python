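"""Sequence conservation and relatedness within a miRNA family.

Pairwise percent identity from global (Needleman-Wunsch) alignment,
unique-sequence collapsing (the UmiR/UTS bookkeeping used when pooling
family members across species), identity-distribution comparison via the
two-sample Kolmogorov-Smirnov statistic, and neighbor-joining trees (with an
optional pairwise-column bootstrap) written as Newick.

Identity convention: identical columns divided by alignment columns after
stripping terminal-gap columns; internal gaps count against identity.
Distances for tree building are ``100 - identity``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from scipy import stats as _stats
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .core import to_rna

__all__ = [
    "AlignScoring",
    "IdentityMatrix",
    "UniqueSet",
    "global_identity",
    "identity_matrix",
    "collapse_unique",
    "identity_ecdf_compare",
    "nj_tree",
    "is_cherry",
]


@dataclass(frozen=True)
class AlignScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0  # linear


def _make_global_aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap
    aligner.extend_gap_score = scoring.gap
    return aligner


def global_identity(
    seq_a: str, seq_b: str, scoring: AlignScoring = AlignScoring()
) -> float:
    """Percent identity of the optimal global alignment of two sequences.

    Terminal-gap columns are excluded from the denominator; internal gap
    columns count as non-identical.  Traceback ties are resolved
    deterministically by taking the aligner's first reported alignment.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    a, b = to_rna(seq_a), to_rna(seq_b)
    if a == b:
        return 100.0
    alignment = _make_global_aligner(scoring).align(a, b)[0]
    col_a, col_b = str(alignment[0]), str(alignment[1])
    # strip terminal-gap columns: contiguous gap columns at either boundary
    start, end = 0, len(col_a)
    while start < end and (col_a[start] == "-" or col_b[start] == "-"):
        start += 1
    while end > start and (col_a[end - 1] == "-" or col_b[end - 1] == "-"):
        end -= 1
    columns = end - start
    if columns <= 0:
        return 0.0
    matches = sum(col_a[i] == col_b[i] and col_a[i] != "-" for i in range(start, end))
    return 100.0 * matches / columns


@dataclass(frozen=True)
class IdentityMatrix:
    ids: Tuple[str, ...]
    values: np.ndarray  # symmetric, diagonal 100

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("identity matrix diagonal must be 100")
        if v.min() < 0 or v.max() > 100:
            raise ValueError("identities must lie in [0, 100]")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def value(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


def identity_matrix(
    seqs: Mapping[str, str], scoring: AlignScoring = AlignScoring()
) -> IdentityMatrix:
    """All-pairs global identity; symmetric by construction."""
    ids = list(seqs)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids")
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    n = len(ids)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_identity(seqs[ids[i]], seqs[ids[j]], scoring)
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(tuple(ids), values)


@dataclass(frozen=True)
class UniqueSet:
    """Deduplicated sequences with membership bookkeeping."""

    representatives: Tuple[Tuple[str, Tuple[str, ...]], ...]  # (seq, member ids)
    total_input: int

    def __post_init__(self) -> None:
        seqs = [s for s, _ in self.representatives]
        if len(seqs) != len(set(seqs)):
            raise ValueError("representative sequences must be distinct")
        if sum(len(m) for _, m in self.representatives) != self.total_input:
            raise ValueError("membership does not account for all inputs")

    def __len__(self) -> int:
        return len(self.representatives)


def collapse_unique(seqs: Mapping[str, str]) -> UniqueSet:
    """Exact-sequence deduplication (case- and U/T-normalized); idempotent.

    The representative of each group is its first member in input order.
    """
    groups: Dict[str, List[str]] = {}
    order: List[str] = []
    for name, seq in seqs.items():
        key = to_rna(seq)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(name)
    return UniqueSet(
        tuple((seq, tuple(groups[seq])) for seq in order), total_input=len(seqs)
    )


def identity_ecdf_compare(
    matrix_a: IdentityMatrix, matrix_b: IdentityMatrix
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Compare two identity distributions (upper triangles) by two-sample KS.

    Returns (sorted identities of a, of b, KS statistic D in [0, 1]).
    """
    sample_a = np.sort(matrix_a.upper_triangle())
    sample_b = np.sort(matrix_b.upper_triangle())
    if sample_a.size == 0 or sample_b.size == 0:
        raise ValueError("both matrices need at least one off-diagonal pair")
    d = float(_stats.ks_2samp(sample_a, sample_b, method="asymp").statistic)
    return sample_a, sample_b, d


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _nj_from_identity(ids: Sequence[str], values: np.ndarray) -> TreeNode:
    distances = 100.0 - values
    np.fill_diagonal(distances, 0.0)
    dm = DistanceMatrix(distances, ids=list(ids))
    return nj(dm)


def _splits(tree: TreeNode, taxa: frozenset) -> set:
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            out.add(min(side, taxa - side, key=sorted))
    return out


def nj_tree(
    matrix: IdentityMatrix,
    seqs: Optional[Mapping[str, str]] = None,
    bootstrap_reps: int = 0,
    rng_seed: int = 0,
    scoring: AlignScoring = AlignScoring(),
) -> str:
    """Neighbor-joining tree from an identity matrix, as a Newick string.

    Distances are ``100 - identity``.  With ``bootstrap_reps > 0`` and the
    sequences supplied, split support is estimated by resampling columns of
    each pairwise alignment (a pairwise-column bootstrap; no multiple
    alignment is built), recomputing the matrix and tree, and counting split
    recovery; support percentages are attached as internal node names.
    """
    if len(matrix.ids) < 3:
        raise ValueError("need at least three taxa")
    tree = _nj_from_identity(matrix.ids, matrix.values.copy())
    if bootstrap_reps and seqs is not None:
        rng = np.random.default_rng(rng_seed)
        taxa = frozenset(matrix.ids)
        counts: Dict[frozenset, int] = {}
        aligner = _make_global_aligner(scoring)
        ids = list(matrix.ids)
        # cache the aligned column pairs once per pair
        pair_columns: Dict[Tuple[int, int], Tuple[str, str]] = {}
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                alignment = aligner.align(to_rna(seqs[ids[i]]), to_rna(seqs[ids[j]]))[0]
                pair_columns[(i, j)] = (str(alignment[0]), str(alignment[1]))
        for _ in range(bootstrap_reps):
            values = np.full((len(ids), len(ids)), 100.0)
            for (i, j), (col_a, col_b) in pair_columns.items():
                n = len(col_a)
                idx = rng.integers(0, n, size=n)
                matches = sum(col_a[k] == col_b[k] and col_a[k] != "-" for k in idx)
                values[i, j] = values[j, i] = 100.0 * matches / n
            rep_tree = _nj_from_identity(ids, values)
            for split in _splits(rep_tree, taxa):
                counts[split] = counts.get(split, 0) + 1
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(taxa) - 1:
                key = min(side, taxa - side, key=sorted)
                node.name = str(round(100.0 * counts.get(key, 0) / bootstrap_reps))
    import io

    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def is_cherry(newick: str, taxon_a: str, taxon_b: str) -> bool:
    """True when the two taxa are sisters in the unrooted tree.

    Tested as a bipartition: some edge must separate exactly {a, b} from all
    remaining taxa (either side of the split may be the pair).
    """
    tree = TreeNode.read([newick])
    taxa = frozenset(t.name for t in tree.tips())
    pair = frozenset((taxon_a, taxon_b))
    if not pair <= taxa:
        raise KeyError("taxon not in tree")
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if side == pair or taxa - side == pair:
            return True
    return False
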