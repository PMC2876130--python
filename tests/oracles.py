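"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: exhaustive enumeration with
direct rescoring, sharing no code with the package's dynamic programs.
"""

from __future__ import annotations

from functools import lru_cache


# ---------------------------------------------------------------------------
# nested structures / folding


def enumerate_structures(n, can_pair, min_hairpin=3):
    """All nested pair sets (as frozensets) for positions 0..n-1."""

    @lru_cache(maxsize=None)
    def interval(i, j):
        if i >= j:
            return [frozenset()]
        out = []
        # i unpaired
        for s in interval(i + 1, j):
            out.append(s)
        # i paired with k
        for k in range(i + min_hairpin + 1, j + 1):
            if not can_pair(i, k):
                continue
            for inner in interval(i + 1, k - 1):
                for outer in interval(k + 1, j):
                    out.append(inner | outer | {(i, k)})
        return out

    return interval(0, n - 1)


def score_structure(seq, pairs, pair_energy, stack_bonus):
    total = 0.0
    pairset = set(pairs)
    for i, j in pairset:
        total += pair_energy(seq[i], seq[j])
        if (i + 1, j - 1) in pairset:
            total += stack_bonus
    return total


def brute_force_mfe(seq, pair_energies, stack_bonus=-1.0, min_hairpin=3):
    """(best_energy, one best pair set) by full enumeration."""

    def can_pair(i, k):
        return (seq[i], seq[k]) in pair_energies

    def pe(a, b):
        return pair_energies[(a, b)]

    best = (0.0, frozenset())
    for s in enumerate_structures(len(seq), can_pair, min_hairpin):
        e = score_structure(seq, s, pe, stack_bonus)
        if e < best[0]:
            best = (e, s)
    return best


def brute_force_constrained(seq, constraints, pair_energies,
                            stack_bonus=-1.0, min_hairpin=3):
    """Minimum energy over structures containing all constraint pairs."""

    def can_pair(i, k):
        return (seq[i], seq[k]) in pair_energies

    def pe(a, b):
        return pair_energies[(a, b)]

    want = frozenset(map(tuple, constraints))
    best = None
    for s in enumerate_structures(len(seq), can_pair, min_hairpin):
        if not want <= s:
            continue
        e = score_structure(seq, s, pe, stack_bonus)
        if best is None or e < best:
            best = e
    return best


# ---------------------------------------------------------------------------
# global sequence alignment (affine gaps)


def enumerate_alignments(a, b):
    """Yield all global alignments as lists of column pairs.

    Columns are (x, y) with '-' for gaps; gap-gap columns never occur.
    """
    if not a and not b:
        yield []
        return
    if a:
        for rest in enumerate_alignments(a[1:], b):
            yield [(a[0], "-")] + rest
    if b:
        for rest in enumerate_alignments(a, b[1:]):
            yield [("-", b[0])] + rest
    if a and b:
        for rest in enumerate_alignments(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest


def score_alignment_affine(columns, match, mismatch, gap_open, gap_extend):
    """Affine scoring: a gap run of length L costs gap_open+(L-1)*gap_extend."""
    total = 0.0
    prev_gap = None  # which side was gapped in the previous column
    for x, y in columns:
        if x == "-" or y == "-":
            side = "a" if x == "-" else "b"
            total += gap_extend if prev_gap == side else gap_open
            prev_gap = side
        else:
            total += match if x == y else mismatch
            prev_gap = None
    return total


def brute_force_pairwise(a, b, match, mismatch, gap_open, gap_extend):
    return max(
        score_alignment_affine(cols, match, mismatch, gap_open, gap_extend)
        for cols in enumerate_alignments(a, b)
    )


# ---------------------------------------------------------------------------
# forest alignment

# forests are nested tuples: ('U', base) or ('P', (b5, b3), (children...))


def forest_to_tuples(forest):
    """Convert a planac StructureForest to plain nested tuples."""

    def conv(node):
        if node.kind == "U":
            return ("U", node.entries[0])
        return ("P", node.entries[0], tuple(conv(c) for c in node.children))

    return tuple(conv(n) for n in forest.roots)


def _gap_cost_tree(t, pair_gap, base_gap):
    if t[0] == "U":
        return base_gap
    return pair_gap + sum(_gap_cost_tree(c, pair_gap, base_gap) for c in t[2])


def brute_force_forest_score(F, G, pair_match=4.0, base_match=1.0,
                             base_mismatch=0.0, pair_gap=-2.0, base_gap=-1.0,
                             pair_residue_bonus=0.0):
    """Optimal alignment score under the tree-alignment model, no memo.

    Gapping a node aligns its children with a prefix of the facing
    sibling interval (brackets stay nested).
    """

    def gap_forest(forest):
        return sum(_gap_cost_tree(t, pair_gap, base_gap) for t in forest)

    def rec(F, G):
        if not F and not G:
            return 0.0
        if not F:
            return gap_forest(G)
        if not G:
            return gap_forest(F)
        f0, g0 = F[0], G[0]
        cands = []
        if f0[0] == g0[0] == "U":
            s = base_match if f0[1] == g0[1] else base_mismatch
            cands.append(s + rec(F[1:], G[1:]))
        if f0[0] == g0[0] == "P":
            s = pair_match + (pair_residue_bonus if f0[1] == g0[1] else 0.0)
            cands.append(s + rec(f0[2], g0[2]) + rec(F[1:], G[1:]))
        if f0[0] == "U":
            cands.append(base_gap + rec(F[1:], G))
        else:
            for k in range(len(G) + 1):
                cands.append(pair_gap + rec(f0[2], G[:k]) + rec(F[1:], G[k:]))
        if g0[0] == "U":
            cands.append(base_gap + rec(F, G[1:]))
        else:
            for k in range(len(F) + 1):
                cands.append(pair_gap + rec(F[:k], g0[2]) + rec(F[k:], G[1:]))
        return max(cands)

    return rec(tuple(F), tuple(G))


# ---------------------------------------------------------------------------
# misc


def pairwise_identity_bruteforce(row_a, row_b):
    """Identity of one row pair per the gap-aware definition."""
    scored = sum(
        1 for x, y in zip(row_a, row_b) if not (x == "-" and y == "-")
    )
    matches = sum(
        1 for x, y in zip(row_a, row_b)
        if x == y and x != "-"
    )
    return matches / scored if scored else 0.0


def aligned_pairs_bruteforce(rows):
    """Explicit enumeration of aligned residue pairs ((id,pos),(id,pos))."""
    counters = {rid: -1 for rid, _ in rows}
    out = set()
    ncols = len(rows[0][1])
    for j in range(ncols):
        present = []
        for rid, row in rows:
            if row[j] != "-":
                counters[rid] += 1
                present.append((rid, counters[rid]))
        for i in range(len(present)):
            for k in range(i + 1, len(present)):
                a, b = present[i], present[k]
                out.add((a, b) if a <= b else (b, a))
    return out
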