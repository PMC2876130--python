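"""Sequence-agnostic alignment of RNA secondary structures as ordered forests.

Structures are encoded as ordered forests whose nodes are either a PAIR
(carrying the two paired residues and a subforest) or an UNPAIRED base.
Two forests are aligned globally under the tree-alignment model: a pair
node aligns to a pair node or to a gap, a base node to a base node or a
gap, and when a node is gapped its subforest aligns inside the gap node
while the remaining siblings align outside it — so aligned brackets
never cross.  Pair-to-pair scores ignore residue identity, which is what
lets the alignment recover compensatory base changes.

Profile forests (per-row entry vectors on every node) support the
progressive multiple structure alignment, and the implied sequence
alignment is read off the aligned forest's in-order traversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree

from planac.io_formats import MultipleAlignment, Sequence, parse_dotbracket
from planac.folding import FoldResult

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ForestScore:
    """Elementary scores for forest alignment.

    Pair-to-pair alignments score ``pair_match`` regardless of residues
    (a CG aligned to an AU is a structural match — the compensatory
    case); ``pair_residue_bonus`` optionally rewards identical residue
    pairs and defaults to 0 so compensatory changes are score-neutral.
    """

    pair_match: float = 4.0
    pair_residue_bonus: float = 0.0
    base_match: float = 1.0
    base_mismatch: float = 0.0
    pair_gap: float = -2.0
    base_gap: float = -1.0

    def __post_init__(self) -> None:
        if not self.pair_match > self.pair_gap:
            raise ValueError("require pair_match > pair_gap")
        if not self.base_match >= self.base_mismatch >= self.base_gap:
            raise ValueError("require base_match >= base_mismatch >= base_gap")


class _Node:
    """Profile forest node; entries has one slot per row (None = gap row)."""

    __slots__ = ("kind", "entries", "children", "uid")
    _counter = 0

    def __init__(self, kind, entries, children=()):
        self.kind = kind  # 'P' or 'U'
        self.entries = tuple(entries)
        self.children = tuple(children)
        _Node._counter += 1
        self.uid = _Node._counter

    def n_nongap(self) -> int:
        return sum(1 for e in self.entries if e is not None)


@dataclass(frozen=True)
class StructureForest:
    """Ordered forest encoding one (sequence, structure) pair."""

    roots: tuple
    seq: Sequence

    def size(self) -> int:
        def count(nodes):
            return sum(1 + count(n.children) for n in nodes)

        return count(self.roots)


def forest_from_structure(seq: Sequence, structure: str) -> StructureForest:
    """Encode a sequence with a dot-bracket structure as an ordered forest."""
    if len(structure) != len(seq.residues):
        raise ValueError(
            f"structure length {len(structure)} != sequence length "
            f"{len(seq.residues)}"
        )
    pairs = dict(parse_dotbracket(structure))
    res = seq.residues

    def build(lo: int, hi: int) -> list[_Node]:
        nodes = []
        i = lo
        while i < hi:
            if i in pairs:
                j = pairs[i]
                nodes.append(
                    _Node("P", [(res[i], res[j])], build(i + 1, j))
                )
                i = j + 1
            else:
                nodes.append(_Node("U", [res[i]]))
                i += 1
        return nodes

    return StructureForest(tuple(build(0, len(res))), seq)


def structure_from_forest(forest: StructureForest) -> tuple[str, str]:
    """In-order traversal back to (residues, dot-bracket)."""
    res: list[str] = []
    db: list[str] = []

    def walk(nodes):
        for n in nodes:
            if n.kind == "U":
                res.append(n.entries[0])
                db.append(".")
            else:
                r5, r3 = n.entries[0]
                res.append(r5)
                db.append("(")
                walk(n.children)
                res.append(r3)
                db.append(")")

    walk(forest.roots)
    return "".join(res), "".join(db)


# ---------------------------------------------------------------------------
# alignment columns / result


@dataclass(frozen=True)
class StructureAlignment:
    """An aligned profile forest over n input rows."""

    roots: tuple
    ids: tuple[str, ...]
    score: float = field(default=0.0, compare=False)

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    def columns(self):
        """Yield (kind, entries) with kind in {open, close, base};
        entries hold one residue or None per row."""
        out = []

        def walk(nodes):
            for n in nodes:
                if n.kind == "U":
                    out.append(("base", n.entries))
                else:
                    fives = tuple(e[0] if e else None for e in n.entries)
                    threes = tuple(e[1] if e else None for e in n.entries)
                    out.append(("open", fives))
                    walk(n.children)
                    out.append(("close", threes))

        walk(self.roots)
        return out

    def consensus_dotbracket(self) -> str:
        return "".join(
            {"open": "(", "close": ")", "base": "."}[kind]
            for kind, _ in self.columns()
        )

    def project(self, row: int) -> tuple[str, str]:
        """(residues, dot-bracket) of one row, gaps removed."""
        res: list[str] = []
        db: list[str] = []
        for kind, entries in self.columns():
            e = entries[row]
            if e is None:
                continue
            res.append(e)
            db.append({"open": "(", "close": ")", "base": "."}[kind])
        return "".join(res), "".join(db)


def implied_sequence_alignment(y: StructureAlignment) -> MultipleAlignment:
    """The residue-level alignment read off the aligned forest."""
    cols = y.columns()
    rows = []
    for r in range(y.n_rows):
        rows.append(
            (y.ids[r], "".join(e[r] if e[r] is not None else "-"
                               for _, e in cols))
        )
    return MultipleAlignment(tuple(rows))


# ---------------------------------------------------------------------------
# pairwise (profile) forest alignment


class _ForestAligner:
    """Global forest alignment of two profile forests (tree-alignment model).

    Subproblems are contiguous sibling intervals; gapping a pair node
    aligns its subforest with a prefix of the facing interval and the
    remaining siblings with the suffix, which keeps brackets nested.
    """

    def __init__(self, rows_a: int, rows_b: int, score: ForestScore):
        self.na = rows_a
        self.nb = rows_b
        self.sc = score
        self.memo: dict = {}
        self.gap_memo: dict = {}

    # -- elementary scores ------------------------------------------------

    def match_score(self, a: _Node, b: _Node) -> float:
        sc = self.sc
        total = 0.0
        if a.kind == "P":
            for ea in a.entries:
                for eb in b.entries:
                    if ea is None and eb is None:
                        continue
                    if ea is None or eb is None:
                        total += sc.pair_gap
                    else:
                        total += sc.pair_match
                        if ea == eb:
                            total += sc.pair_residue_bonus
        else:
            for ea in a.entries:
                for eb in b.entries:
                    if ea is None and eb is None:
                        continue
                    if ea is None or eb is None:
                        total += sc.base_gap
                    else:
                        total += sc.base_match if ea == eb else sc.base_mismatch
        return total

    def gap_node(self, n: _Node, other_rows: int) -> float:
        sc = self.sc
        per = sc.pair_gap if n.kind == "P" else sc.base_gap
        return per * n.n_nongap() * other_rows

    def gap_forest(self, forest: tuple, other_rows: int) -> float:
        key = (tuple(n.uid for n in forest), other_rows)
        if key in self.gap_memo:
            return self.gap_memo[key]
        total = sum(
            self.gap_node(n, other_rows) + self.gap_forest(n.children, other_rows)
            for n in forest
        )
        self.gap_memo[key] = total
        return total

    # -- DP ----------------------------------------------------------------

    def align(self, F: tuple, G: tuple) -> float:
        key = (tuple(n.uid for n in F), tuple(n.uid for n in G))
        if key in self.memo:
            return self.memo[key]
        if not F and not G:
            val = 0.0
        elif not F:
            val = self.gap_forest(G, self.na)
        elif not G:
            val = self.gap_forest(F, self.nb)
        else:
            f0, g0 = F[0], G[0]
            best = NEG_INF
            if f0.kind == g0.kind:
                best = (
                    self.match_score(f0, g0)
                    + self.align(f0.children, g0.children)
                    + self.align(F[1:], G[1:])
                )
            # gap f0: its children align with a prefix of G
            base = self.gap_node(f0, self.nb)
            if f0.kind == "U":
                cand = base + self.align(F[1:], G)
                if cand > best:
                    best = cand
            else:
                for k in range(len(G) + 1):
                    cand = (
                        base
                        + self.align(f0.children, G[:k])
                        + self.align(F[1:], G[k:])
                    )
                    if cand > best:
                        best = cand
            # gap g0: symmetric
            base = self.gap_node(g0, self.na)
            if g0.kind == "U":
                cand = base + self.align(F, G[1:])
                if cand > best:
                    best = cand
            else:
                for k in range(len(F) + 1):
                    cand = (
                        base
                        + self.align(F[:k], g0.children)
                        + self.align(F[k:], G[1:])
                    )
                    if cand > best:
                        best = cand
            val = best
        self.memo[key] = val
        return val

    # -- traceback to a merged profile forest ------------------------------

    def _merge_match(self, a: _Node, b: _Node, children) -> _Node:
        return _Node(a.kind, a.entries + b.entries, children)

    def _gap_side(self, n: _Node, other_rows: int, side: str) -> _Node:
        pad = (None,) * other_rows
        entries = n.entries + pad if side == "a" else pad + n.entries
        children = tuple(
            self._gap_side(c, other_rows, side) for c in n.children
        )
        return _Node(n.kind, entries, children)

    def _all_gaps(self, forest: tuple, other_rows: int, side: str):
        return tuple(self._gap_side(n, other_rows, side) for n in forest)

    def trace(self, F: tuple, G: tuple) -> tuple:
        target = self.align(F, G)
        if not F and not G:
            return ()
        if not F:
            return self._all_gaps(G, self.na, "b")
        if not G:
            return self._all_gaps(F, self.nb, "a")
        f0, g0 = F[0], G[0]
        eps = 1e-9
        if f0.kind == g0.kind:
            cand = (
                self.match_score(f0, g0)
                + self.align(f0.children, g0.children)
                + self.align(F[1:], G[1:])
            )
            if abs(cand - target) < eps:
                node = self._merge_match(
                    f0, g0, self.trace(f0.children, g0.children)
                )
                return (node,) + self.trace(F[1:], G[1:])
        base = self.gap_node(f0, self.nb)
        if f0.kind == "U":
            if abs(base + self.align(F[1:], G) - target) < eps:
                return (
                    self._gap_side(f0, self.nb, "a"),
                ) + self.trace(F[1:], G)
        else:
            for k in range(len(G) + 1):
                cand = (
                    base
                    + self.align(f0.children, G[:k])
                    + self.align(F[1:], G[k:])
                )
                if abs(cand - target) < eps:
                    inner = self.trace(f0.children, G[:k])
                    pad = (None,) * self.nb
                    node = _Node("P", f0.entries + pad, inner)
                    return (node,) + self.trace(F[1:], G[k:])
        base = self.gap_node(g0, self.na)
        if g0.kind == "U":
            if abs(base + self.align(F, G[1:]) - target) < eps:
                return (
                    self._gap_side(g0, self.na, "b"),
                ) + self.trace(F, G[1:])
        else:
            for k in range(len(F) + 1):
                cand = (
                    base
                    + self.align(F[:k], g0.children)
                    + self.align(F[k:], G[1:])
                )
                if abs(cand - target) < eps:
                    inner = self.trace(F[:k], g0.children)
                    pad = (None,) * self.na
                    node = _Node("P", pad + g0.entries, inner)
                    return (node,) + self.trace(F[k:], G[1:])
        raise RuntimeError("forest alignment traceback failed")  # pragma: no cover


def _align_profile_forests(
    roots_a: tuple, rows_a: int, ids_a, roots_b: tuple, rows_b: int, ids_b,
    score: ForestScore,
) -> StructureAlignment:
    aligner = _ForestAligner(rows_a, rows_b, score)
    s = aligner.align(roots_a, roots_b)
    merged = aligner.trace(roots_a, roots_b)
    return StructureAlignment(merged, tuple(ids_a) + tuple(ids_b), s)


def pairwise_forest_align(
    f1: StructureForest, f2: StructureForest, score: ForestScore | None = None
) -> tuple[StructureAlignment, float]:
    """Optimal global alignment of two structure forests."""
    score = score or ForestScore()
    result = _align_profile_forests(
        f1.roots, 1, (f1.seq.id,), f2.roots, 1, (f2.seq.id,), score
    )
    return result, result.score


def forest_align_score(
    f1: StructureForest, f2: StructureForest, score: ForestScore | None = None
) -> float:
    """Alignment score only (no traceback)."""
    score = score or ForestScore()
    return _ForestAligner(1, 1, score).align(f1.roots, f2.roots)


# ---------------------------------------------------------------------------
# multiple structure alignment


def multiple_structure_align(
    folds: list[tuple[Sequence, FoldResult]],
    score: ForestScore | None = None,
) -> StructureAlignment:
    """Progressive multiple alignment of folded structures.

    The guide tree is UPGMA over distances derived from pairwise forest
    alignment scores, normalized by self-alignment scores.
    """
    score = score or ForestScore()
    n = len(folds)
    if n < 2:
        raise ValueError("need at least 2 structures")
    forests = [
        forest_from_structure(seq, fr.dotbracket) for seq, fr in folds
    ]
    if n == 2:
        return pairwise_forest_align(forests[0], forests[1], score)[0]

    self_scores = [forest_align_score(f, f, score) for f in forests]
    dist = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        s = forest_align_score(forests[i], forests[j], score)
        denom = max(self_scores[i], self_scores[j])
        d = 1.0 - s / denom if denom > 0 else 1.0
        dist[i, j] = dist[j, i] = max(d, 0.0)

    condensed = dist[np.triu_indices(n, k=1)]
    Z = linkage(condensed, method="average")
    root = to_tree(Z)

    def visit(node):
        """Return (roots, row_indices) of the merged profile."""
        if node.is_leaf():
            return forests[node.id].roots, [node.id]
        roots_l, idx_l = visit(node.left)
        roots_r, idx_r = visit(node.right)
        ids_l = [folds[i][0].id for i in idx_l]
        ids_r = [folds[i][0].id for i in idx_r]
        merged = _align_profile_forests(
            roots_l, len(idx_l), ids_l, roots_r, len(idx_r), ids_r, score
        )
        return merged.roots, idx_l + idx_r

    roots, order = visit(root)

    # restore input row order
    perm = [order.index(i) for i in range(n)]

    def reorder(nodes):
        out = []
        for nd in nodes:
            entries = tuple(nd.entries[p] for p in perm)
            out.append(_Node(nd.kind, entries, reorder(nd.children)))
        return tuple(out)

    return StructureAlignment(
        reorder(roots), tuple(seq.id for seq, _ in folds)
    )
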