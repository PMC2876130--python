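"""Multiple sequence alignment (progressive, affine gaps) and alignment metrics.

This is a functional stand-in for an off-the-shelf aligner: optimal
pairwise global alignment under affine-gap scoring, then profile-profile
merging along a UPGMA guide tree built from pairwise identities.
Tie-breaking in the traceback is fixed (diagonal, then gap in the second
sequence, then gap in the first) so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree

from planac.io_formats import MultipleAlignment, Sequence

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scores: a gap of length L costs gap_open + (L-1)*gap_extend."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0 < self.match):
            raise ValueError("require gap_open <= gap_extend <= 0 < match")
        if not self.mismatch < self.match:
            raise ValueError("require mismatch < match")


def _profile_col_score(cols_a: str, cols_b: str, scheme: ScoringScheme) -> float:
    """Mean substitution score over residue-bearing cross pairs."""
    total = 0.0
    n = 0
    for x in cols_a:
        if x == "-":
            continue
        for y in cols_b:
            if y == "-":
                continue
            total += scheme.match if x == y else scheme.mismatch
            n += 1
    return total / n if n else 0.0


def _align_profiles(
    rows_a: list[str], rows_b: list[str], scheme: ScoringScheme
) -> tuple[list[str], list[str], float]:
    """Affine-gap global alignment of two gap-containing profiles (Gotoh)."""
    na, nb = len(rows_a[0]), len(rows_b[0])
    cols_a = ["".join(r[i] for r in rows_a) for i in range(na)]
    cols_b = ["".join(r[j] for r in rows_b) for j in range(nb)]
    sub = np.empty((na, nb))
    for i in range(na):
        for j in range(nb):
            sub[i, j] = _profile_col_score(cols_a[i], cols_b[j], scheme)

    go, ge = scheme.gap_open, scheme.gap_extend
    M = np.full((na + 1, nb + 1), NEG_INF)
    X = np.full((na + 1, nb + 1), NEG_INF)  # gap in B (consume A)
    Y = np.full((na + 1, nb + 1), NEG_INF)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, na + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, nb + 1):
        Y[0, j] = go + (j - 1) * ge
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + sub[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            Y[i, j] = max(M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge)

    score = max(M[na, nb], X[na, nb], Y[na, nb])

    def _pick(i: int, j: int) -> str:
        # tie preference: diagonal, then gap in B, then gap in A
        best = max(M[i, j], X[i, j], Y[i, j])
        if np.isclose(M[i, j], best):
            return "M"
        if np.isclose(X[i, j], best):
            return "X"
        return "Y"

    i, j = na, nb
    state = _pick(i, j)
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if i == 0:
            out_a.append("-" * len(rows_a))
            out_b.append(cols_b[j - 1])
            j -= 1
            continue
        if j == 0:
            out_a.append(cols_a[i - 1])
            out_b.append("-" * len(rows_b))
            i -= 1
            continue
        if state == "M":
            out_a.append(cols_a[i - 1])
            out_b.append(cols_b[j - 1])
            i, j = i - 1, j - 1
            state = _pick(i, j)
        elif state == "X":
            cur = X[i, j]
            out_a.append(cols_a[i - 1])
            out_b.append("-" * len(rows_b))
            if np.isclose(cur, M[i - 1, j] + go):
                state = "M"
            elif np.isclose(cur, X[i - 1, j] + ge):
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:
            cur = Y[i, j]
            out_a.append("-" * len(rows_a))
            out_b.append(cols_b[j - 1])
            if np.isclose(cur, M[i, j - 1] + go):
                state = "M"
            elif np.isclose(cur, X[i, j - 1] + go):
                state = "X"
            else:
                state = "Y"
            j -= 1
    out_a.reverse()
    out_b.reverse()
    new_a = ["".join(col[k] for col in out_a) for k in range(len(rows_a))]
    new_b = ["".join(col[k] for col in out_b) for k in range(len(rows_b))]
    return new_a, new_b, float(score)


def pairwise_align(
    a: Sequence, b: Sequence, scheme: ScoringScheme | None = None
) -> tuple[MultipleAlignment, float]:
    """Optimal global alignment of two sequences under affine-gap scoring."""
    scheme = scheme or ScoringScheme()
    rows_a, rows_b, score = _align_profiles([a.residues], [b.residues], scheme)
    aln = MultipleAlignment(((a.id, rows_a[0]), (b.id, rows_b[0])))
    return aln, score


def _upgma_merge_order(dist: np.ndarray) -> list[tuple]:
    """UPGMA join order as a nested tuple tree of leaf indices."""
    n = dist.shape[0]
    if n == 2:
        return [(0, 1)]
    condensed = dist[np.triu_indices(n, k=1)]
    Z = linkage(condensed, method="average")
    root = to_tree(Z)
    order = []

    def visit(node):
        if node.is_leaf():
            return (node.id,)
        left = visit(node.left)
        right = visit(node.right)
        order.append((left, right))
        return left + right

    visit(root)
    return order


def progressive_align(
    seqs: list[Sequence], scheme: ScoringScheme | None = None
) -> MultipleAlignment:
    """Progressive multiple alignment along a UPGMA guide tree.

    Distances are 1 - pairwise identity; rows come back in input order.
    """
    scheme = scheme or ScoringScheme()
    n = len(seqs)
    if n < 2:
        raise ValueError("progressive_align requires at least 2 sequences")
    if n == 2:
        return pairwise_align(seqs[0], seqs[1], scheme)[0]

    dist = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        aln, _ = pairwise_align(seqs[i], seqs[j], scheme)
        d = 1.0 - percent_identity(aln)
        dist[i, j] = dist[j, i] = d

    profiles: dict[tuple, tuple[list[int], list[str]]] = {
        (i,): ([i], [seqs[i].residues]) for i in range(n)
    }
    for left, right in _upgma_merge_order(dist):
        ids_l, rows_l = profiles.pop(left)
        ids_r, rows_r = profiles.pop(right)
        new_l, new_r, _ = _align_profiles(rows_l, rows_r, scheme)
        profiles[left + right] = (ids_l + ids_r, new_l + new_r)

    (members, rows), = profiles.values()
    by_index = dict(zip(members, rows))
    return MultipleAlignment(
        tuple((seqs[i].id, by_index[i]) for i in range(n))
    )


# ---------------------------------------------------------------------------
# metrics


def percent_identity(aln: MultipleAlignment) -> float:
    """Mean pairwise identity.

    For each row pair: identical residue pairs divided by the number of
    columns where at least one of the two rows has a residue (gap-gap
    columns do not count against the pair).
    """
    if aln.n_rows < 2:
        raise ValueError("identity needs at least 2 rows")
    vals = []
    for (_, ra), (_, rb) in combinations(aln.rows, 2):
        matches = 0
        scored = 0
        for x, y in zip(ra, rb):
            if x == "-" and y == "-":
                continue
            scored += 1
            if x == y:
                matches += 1
        vals.append(matches / scored if scored else 0.0)
    return float(np.mean(vals))


def gap_content(aln: MultipleAlignment) -> float:
    """Fraction of gap characters in the alignment matrix."""
    gaps = sum(row.count("-") for _, row in aln.rows)
    return gaps / (aln.n_rows * aln.n_cols)


def _residue_pairs(aln: MultipleAlignment) -> set:
    """All aligned residue pairs ((id_a, pos_a), (id_b, pos_b))."""
    pos = {rid: -1 for rid, _ in aln.rows}
    pairs = set()
    for j in range(aln.n_cols):
        present = []
        for rid, row in aln.rows:
            if row[j] != "-":
                pos[rid] += 1
                present.append((rid, pos[rid]))
        for a, b in combinations(present, 2):
            pairs.add((a, b) if a <= b else (b, a))
    return pairs


def compare_alignments(a: MultipleAlignment, b: MultipleAlignment) -> float:
    """Sum-of-pairs overlap: 2|A∩B| / (|A|+|B|) over aligned residue pairs."""
    seqs_a = {s.id: s.residues for s in a.sequences()}
    seqs_b = {s.id: s.residues for s in b.sequences()}
    if seqs_a != seqs_b:
        raise ValueError("alignments are over different sequence sets")
    pa, pb = _residue_pairs(a), _residue_pairs(b)
    if not pa and not pb:
        return 1.0
    return 2 * len(pa & pb) / (len(pa) + len(pb))
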