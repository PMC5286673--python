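import numpy as np
import pytest

from mirfam.conservation import (
    AlignScoring,
    IdentityMatrix,
    collapse_unique,
    global_identity,
    identity_ecdf_compare,
    identity_matrix,
    is_cherry,
    nj_tree,
)
from mirfam.datasets import novel_precursor_table

MAT_V = "UCGGACCAGGCUUCAUUCCCC"
MAT_Z = "UCUCGGACCAGGCUUCAUUCC"


def nw_identity_oracle(a, b, match=1, mismatch=-1, gap=-2):
    """Exhaustive Needleman-Wunsch DP with full traceback-free identity.

    Computes the identity of one optimal alignment by dynamic programming
    over (score, matches, columns), tie-broken toward diagonal moves; the
    terminal-gap convention matches the implementation's.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    score = [[NEG] * (m + 1) for _ in range(n + 1)]
    back = [[None] * (m + 1) for _ in range(n + 1)]
    score[0][0] = 0
    for i in range(1, n + 1):
        score[i][0] = i * gap
        back[i][0] = "u"
    for j in range(1, m + 1):
        score[0][j] = j * gap
        back[0][j] = "l"
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = score[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            u = score[i - 1][j] + gap
            l = score[i][j - 1] + gap
            best = max(d, u, l)
            score[i][j] = best
            back[i][j] = "d" if d == best else ("u" if u == best else "l")
    # traceback
    cols = []
    i, j = n, m
    while i or j:
        move = back[i][j]
        if move == "d":
            cols.append((a[i - 1], b[j - 1]))
            i, j = i - 1, j - 1
        elif move == "u":
            cols.append((a[i - 1], "-"))
            i -= 1
        else:
            cols.append(("-", b[j - 1]))
            j -= 1
    cols.reverse()
    start, end = 0, len(cols)
    while start < end and "-" in cols[start]:
        start += 1
    while end > start and "-" in cols[end - 1]:
        end -= 1
    window = cols[start:end]
    if not window:
        return 0.0
    matches = sum(x == y and x != "-" for x, y in window)
    return 100.0 * matches / len(window)


class TestGlobalIdentity:
    def test_identical_sequences(self):
        assert global_identity(MAT_V, MAT_V) == 100.0

    def test_published_mature_pair_matches_dp_oracle(self):
        got = global_identity(MAT_V, MAT_Z)
        assert got == pytest.approx(nw_identity_oracle(MAT_V, MAT_Z))

    def test_disjoint_alphabets_give_zero(self):
        assert global_identity("AAAA", "CCCC") == 0.0

    def test_symmetry(self):
        assert global_identity(MAT_V, MAT_Z) == global_identity(MAT_Z, MAT_V)

    def test_substitution_pairs_match_oracle(self, rng):
        # equal-length, substitution-only pairs have a unique optimal
        # alignment (the diagonal), so implementation and oracle must agree
        # exactly; gapped co-optima may legitimately differ in identity
        for _ in range(25):
            n = int(rng.integers(20, 40))
            a = "".join(rng.choice(list("ACGU"), size=n))
            b = list(a)
            for pos in rng.choice(n, size=int(rng.integers(1, 5)), replace=False):
                b[pos] = [x for x in "ACGU" if x != b[pos]][int(rng.integers(3))]
            b = "".join(b)
            assert global_identity(a, b) == pytest.approx(nw_identity_oracle(a, b))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_identity("", "ACGU")


class TestIdentityMatrix:
    def test_three_identical_sequences_all_100(self):
        m = identity_matrix({"a": MAT_V, "b": MAT_V, "c": MAT_V})
        assert np.allclose(m.values, 100.0)

    def test_permutation_invariance_after_realignment(self):
        seqs = {"a": MAT_V, "b": MAT_Z, "c": "ACGUACGUACGUACGUACGUA"}
        fwd = identity_matrix(seqs)
        rev = identity_matrix(dict(reversed(list(seqs.items()))))
        assert fwd.value("a", "b") == rev.value("a", "b")
        assert fwd.value("b", "c") == rev.value("b", "c")

    def test_entries_equal_direct_calls(self):
        seqs = {"a": MAT_V, "b": MAT_Z, "c": "ACGUACGUACGUACGUACGUA"}
        m = identity_matrix(seqs)
        for x in seqs:
            for y in seqs:
                if x < y:
                    assert m.value(x, y) == pytest.approx(
                        global_identity(seqs[x], seqs[y]))

    def test_symmetry_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            IdentityMatrix(("a", "b"), np.array([[100.0, 50.0], [60.0, 100.0]]))


class TestCollapseUnique:
    def test_membership_counts(self):
        u = collapse_unique({"x": "AAA", "y": "AAA", "z": "AAU"})
        assert [(s, len(m)) for s, m in u.representatives] == [("AAA", 2), ("AAU", 1)]

    def test_empty_input(self):
        assert len(collapse_unique({})) == 0

    def test_case_and_ut_normalization(self):
        u = collapse_unique({"a": "acgt", "b": "ACGU"})
        assert len(u) == 1

    def test_idempotent(self):
        u = collapse_unique({"x": "AAA", "y": "AAA", "z": "AAU"})
        again = collapse_unique({f"r{i}": s for i, (s, _) in enumerate(u.representatives)})
        assert [s for s, _ in again.representatives] == [s for s, _ in u.representatives]

    def test_novel_family_matures_collapse_to_two(self):
        table = novel_precursor_table()
        seqs = dict(zip(table.id, table.mature_seq))
        u = collapse_unique(seqs)
        assert len(u) == 2
        counts = sorted(len(m) for _, m in u.representatives)
        assert counts == [1, 4]  # v,w,x,y identical; z distinct


class TestEcdfCompare:
    def _matrix(self, values):
        n = len(values)
        ids = tuple(f"s{i}" for i in range(n))
        return IdentityMatrix(ids, np.array(values, dtype=float))

    def test_identical_samples_give_zero(self):
        m = identity_matrix({"a": MAT_V, "b": MAT_Z, "c": "ACGUACGUACGUACGUACGUA"})
        _, _, d = identity_ecdf_compare(m, m)
        assert d == 0.0

    def test_disjoint_supports_give_one(self):
        lo = self._matrix([[100, 10, 20], [10, 100, 30], [20, 30, 100]])
        hi = self._matrix([[100, 80, 90], [80, 100, 85], [90, 85, 100]])
        _, _, d = identity_ecdf_compare(lo, hi)
        assert d == 1.0

    def test_partial_overlap_matches_step_function_oracle(self):
        a = self._matrix([[100, 10, 20], [10, 100, 30], [20, 30, 100]])
        b = self._matrix([[100, 20, 40], [20, 100, 50], [40, 50, 100]])
        sample_a, sample_b, d = identity_ecdf_compare(a, b)

        def ecdf(sample, x):
            return np.mean(sample <= x)

        grid = np.concatenate([sample_a, sample_b])
        oracle = max(abs(ecdf(sample_a, x) - ecdf(sample_b, x)) for x in grid)
        assert d == pytest.approx(oracle)


class TestNjTree:
    def test_three_taxa_single_topology(self):
        m = IdentityMatrix(("a", "b", "c"),
                           np.array([[100, 90, 80], [90, 100, 85], [80, 85, 100.0]]))
        newick = nj_tree(m)
        assert newick.count(",") == 2 and newick.endswith(";")

    def test_four_taxon_additive_matrix_recovers_generating_split(self):
        # additive tree: ((a,b),(c,d)) with internal edge 6
        dist = np.array([[0, 2, 8, 8], [2, 0, 8, 8],
                         [8, 8, 0, 2], [8, 8, 2, 0]], dtype=float)
        m = IdentityMatrix(("a", "b", "c", "d"), 100.0 - dist + np.diag([0.0] * 4))
        newick = nj_tree(m)
        assert is_cherry(newick, "a", "b")
        assert is_cherry(newick, "c", "d")
        assert not is_cherry(newick, "a", "c")

    def test_clones_are_sisters_at_zero_distance(self):
        seqs = {"a": MAT_V, "b": MAT_V, "c": MAT_Z, "d": "ACGUACGUACGUACGUACGUA"}
        m = identity_matrix(seqs)
        newick = nj_tree(m)
        assert is_cherry(newick, "a", "b")

    def test_ten_paralog_pairs_form_cherries(self, rng):
        """Pairs with >=94% within-pair identity group as cherries in the NJ tree."""
        seqs = {}
        bases = np.array(list("ACGU"))
        for p in range(10):
            template = "".join(rng.choice(bases, size=100))
            partner = list(template)
            for pos in rng.choice(100, size=3, replace=False):  # 3% divergence
                partner[pos] = [b for b in "ACGU" if b != partner[pos]][
                    int(rng.integers(3))]
            seqs[f"p{p}a"] = template
            seqs[f"p{p}b"] = "".join(partner)
        m = identity_matrix(seqs)
        for p in range(10):
            assert m.value(f"p{p}a", f"p{p}b") >= 94.0
        newick = nj_tree(m)
        for p in range(10):
            assert is_cherry(newick, f"p{p}a", f"p{p}b")

    def test_bootstrap_deterministic_for_seed(self):
        seqs = {"a": MAT_V, "b": MAT_V[:-1] + "A", "c": MAT_Z,
                "d": "ACGUACGUACGUACGUACGUA"}
        m = identity_matrix(seqs)
        t1 = nj_tree(m, seqs=seqs, bootstrap_reps=30, rng_seed=5)
        t2 = nj_tree(m, seqs=seqs, bootstrap_reps=30, rng_seed=5)
        assert t1 == t2

    def test_too_few_taxa_rejected(self):
        m = IdentityMatrix(("a", "b"), np.array([[100.0, 90], [90, 100]]))
        with pytest.raises(ValueError):
            nj_tree(m)
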