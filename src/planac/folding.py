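"""Nested-structure energy minimization.

A single interval dynamic program backs three entry points:

* :func:`mfe_fold` — unconstrained single-sequence folding,
* :func:`constrained_fold` — folding forced to contain mandatory pairs
  while remaining free to add compatible ones,
* :func:`alifold` — consensus folding of an alignment, scoring column
  pairs by averaged pair energies plus a covariance pseudo-energy.

The energy model is a deliberately small surrogate for a full
nearest-neighbor parameter set: per-pair energies, a flat stacking bonus
and a minimum hairpin size.  It is pluggable, and small enough that
exhaustive enumeration can serve as a test oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

from planac.io_formats import MultipleAlignment, Sequence, write_dotbracket

INF = math.inf

_DEFAULT_PAIR_ENERGIES = {
    ("C", "G"): -3.0, ("G", "C"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}


@dataclass(frozen=True)
class EnergyModel:
    """Simplified pair/stack energy model (kcal/mol-like units)."""

    pair_energies: dict = field(
        default_factory=lambda: dict(_DEFAULT_PAIR_ENERGIES)
    )
    stack: float = -1.0
    min_hairpin: int = 3

    def __post_init__(self) -> None:
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        if self.stack > 0:
            raise ValueError("stack bonus must be <= 0")

    def pair_energy(self, b1: str, b2: str) -> float | None:
        """Energy of pairing b1 with b2, or None if forbidden."""
        return self.pair_energies.get((b1, b2))

    def can_pair(self, b1: str, b2: str) -> bool:
        return (b1, b2) in self.pair_energies

    def stack_bonus(self, outer: tuple[str, str], inner: tuple[str, str]) -> float:
        """Bonus for ``inner`` directly stacked inside ``outer``."""
        return self.stack


@dataclass(frozen=True)
class FoldResult:
    """A nested structure with its model energy."""

    pairs: tuple[tuple[int, int], ...]
    energy: float
    length: int

    @property
    def dotbracket(self) -> str:
        return write_dotbracket(self.pairs, self.length)


@dataclass(frozen=True)
class ConsensusStructure:
    """Structure on alignment columns with consensus energy E_A."""

    pairs: tuple[tuple[int, int], ...]
    energy: float
    n_cols: int
    covariance: dict = field(default_factory=dict, compare=False)

    @property
    def dotbracket(self) -> str:
        return write_dotbracket(self.pairs, self.n_cols)


def structure_energy(seq: Sequence, pairs, model: EnergyModel) -> float:
    """Recompute the model energy of an explicit structure."""
    pairset = set(map(tuple, pairs))
    total = 0.0
    for i, j in pairset:
        e = model.pair_energy(seq.residues[i], seq.residues[j])
        if e is None:
            raise ValueError(f"forbidden pair ({i},{j}) in structure")
        total += e
        if (i + 1, j - 1) in pairset:
            total += model.stack_bonus(
                (seq.residues[i], seq.residues[j]),
                (seq.residues[i + 1], seq.residues[j - 1]),
            )
    return total


# ---------------------------------------------------------------------------
# generic interval DP


class _FoldEngine:
    """Minimizes sum of pair energies + stacking over nested structures.

    ``pair_e(i, j)`` returns the energy of pairing positions/columns i, j
    or None if that pair is not allowed.  ``stack_e(i, j)`` is the bonus
    added when (i+1, j-1) is also paired.  ``mandatory`` maps each end of
    a forced pair to its partner; forced pairs must appear and positions
    owned by them may not pair elsewhere or stay unpaired.
    """

    def __init__(self, n, pair_e, stack_e, min_hairpin, mandatory=None):
        self.n = n
        self.pair_e = pair_e
        self.stack_e = stack_e
        self.min_hairpin = min_hairpin
        self.mandatory = dict(mandatory or {})
        self._pairs_sorted = sorted(
            (i, j) for i, j in self.mandatory.items() if i < j
        )
        self.V = lru_cache(maxsize=None)(self._V)
        self.W = lru_cache(maxsize=None)(self._W)

    def _allowed(self, i: int, j: int) -> bool:
        if j - i - 1 < self.min_hairpin:
            return False
        if self.mandatory.get(i, j) != j or self.mandatory.get(j, i) != i:
            return False
        return self.pair_e(i, j) is not None

    def _split_ok(self, i: int, k: int, j: int) -> bool:
        # splitting [i, j] into [i, k-1] | [k, j] must not cut a forced pair
        for a, b in self._pairs_sorted:
            if i <= a < k <= b <= j:
                return False
        return True

    def _V(self, i: int, j: int) -> float:
        """Best energy with (i, j) paired; INF if infeasible."""
        if not self._allowed(i, j):
            return INF
        best = self.W(i + 1, j - 1, False)
        if self._allowed(i + 1, j - 1):
            stacked = self.V(i + 1, j - 1) + self.stack_e(i, j)
            if stacked < best:
                best = stacked
        if best == INF:
            return INF
        return self.pair_e(i, j) + best

    def _W(self, i: int, j: int, allow_full: bool = True) -> float:
        """Best energy over [i, j]; if not allow_full, pair (i, j) itself
        is excluded (used beneath a closing pair to control stacking)."""
        if i > j:
            return 0.0
        best = INF
        if j not in self.mandatory:
            best = self.W(i, j - 1, True)
        lo = i if allow_full else i + 1
        for k in range(lo, j - self.min_hairpin):
            if not self._allowed(k, j):
                continue
            if k in self.mandatory and self.mandatory[k] != j:
                continue
            if not self._split_ok(i, k, j):
                continue
            v = self.V(k, j)
            if v == INF:
                continue
            left = self.W(i, k - 1, True)
            if left == INF:
                continue
            if v + left < best:
                best = v + left
        return best

    def solve(self):
        """Return (pairs, energy); deterministic traceback."""
        if self.n == 0:
            return (), 0.0
        energy = self.W(0, self.n - 1, True)
        if energy == INF:
            raise ValueError("no feasible structure under the constraints")
        pairs: list[tuple[int, int]] = []
        stack = [("W", 0, self.n - 1, True)]
        while stack:
            kind, i, j, flag = stack.pop()
            if kind == "W":
                if i > j:
                    continue
                target = self.W(i, j, flag)
                if target == 0.0 and not any(
                    i <= a <= j for a in self.mandatory
                ):
                    continue
                # prefer leaving j unpaired (fewer pairs), then smallest k
                if j not in self.mandatory and math.isclose(
                    self.W(i, j - 1, True), target
                ):
                    stack.append(("W", i, j - 1, True))
                    continue
                lo = i if flag else i + 1
                done = False
                for k in range(lo, j - self.min_hairpin):
                    if not self._allowed(k, j):
                        continue
                    if k in self.mandatory and self.mandatory[k] != j:
                        continue
                    if not self._split_ok(i, k, j):
                        continue
                    v = self.V(k, j)
                    left = self.W(i, k - 1, True)
                    if v < INF and left < INF and math.isclose(v + left, target):
                        stack.append(("W", i, k - 1, True))
                        stack.append(("V", k, j, None))
                        done = True
                        break
                if not done:  # pragma: no cover - defensive
                    raise RuntimeError("traceback failed in W")
            else:  # V
                pairs.append((i, j))
                target = self.V(i, j) - self.pair_e(i, j)
                inner_plain = self.W(i + 1, j - 1, False)
                if math.isclose(inner_plain, target):
                    stack.append(("W", i + 1, j - 1, False))
                elif self._allowed(i + 1, j - 1) and math.isclose(
                    self.V(i + 1, j - 1) + self.stack_e(i, j), target
                ):
                    stack.append(("V", i + 1, j - 1, None))
                else:  # pragma: no cover - defensive
                    raise RuntimeError("traceback failed in V")
        return tuple(sorted(pairs)), energy


# ---------------------------------------------------------------------------
# public folding operations


def mfe_fold(seq: Sequence, model: EnergyModel | None = None) -> FoldResult:
    """Minimum free energy nested structure of a single sequence."""
    model = model or EnergyModel()
    res = seq.residues

    def pair_e(i, j):
        return model.pair_energy(res[i], res[j])

    def stack_e(i, j):
        return model.stack_bonus((res[i], res[j]), (res[i + 1], res[j - 1]))

    engine = _FoldEngine(len(res), pair_e, stack_e, model.min_hairpin)
    pairs, energy = engine.solve()
    return FoldResult(pairs, energy, len(res))


def _validate_constraints(seq: Sequence, constraints, model: EnergyModel):
    pairs = sorted(map(tuple, constraints))
    n = len(seq.residues)
    used: set[int] = set()
    for i, j in pairs:
        if not (0 <= i < j < n):
            raise ValueError(f"constraint ({i},{j}) out of range")
        if j - i - 1 < model.min_hairpin:
            raise ValueError(
                f"constraint ({i},{j}) violates the minimum hairpin size"
            )
        if not model.can_pair(seq.residues[i], seq.residues[j]):
            raise ValueError(
                f"constraint ({i},{j}) is non-canonical for {seq.id!r}: "
                f"{seq.residues[i]}-{seq.residues[j]}"
            )
        if i in used or j in used:
            raise ValueError(f"position reused by constraint ({i},{j})")
        used.update((i, j))
    for a, b in pairs:
        for c, d in pairs:
            if a < c < b < d:
                raise ValueError(
                    f"constraints ({a},{b}) and ({c},{d}) cross"
                )
    return pairs


def constrained_fold(
    seq: Sequence, constraints, model: EnergyModel | None = None
) -> FoldResult:
    """Minimum-energy structure containing all mandatory pairs.

    Mirrors constrained MFE folding: the result is a superset of the
    constraints and may add further pairs nested around or between them.
    """
    model = model or EnergyModel()
    pairs = _validate_constraints(seq, constraints, model)
    res = seq.residues
    mandatory: dict[int, int] = {}
    for i, j in pairs:
        mandatory[i] = j
        mandatory[j] = i

    def pair_e(i, j):
        return model.pair_energy(res[i], res[j])

    def stack_e(i, j):
        return model.stack_bonus((res[i], res[j]), (res[i + 1], res[j - 1]))

    engine = _FoldEngine(len(res), pair_e, stack_e, model.min_hairpin, mandatory)
    out_pairs, energy = engine.solve()
    missing = set(map(tuple, pairs)) - set(out_pairs)
    if missing:  # pragma: no cover - guarded by engine
        raise RuntimeError(f"constraints dropped by folding: {missing}")
    return FoldResult(out_pairs, energy, len(res))


def alifold(
    aln: MultipleAlignment,
    model: EnergyModel | None = None,
    cov_weight: float = 1.0,
    q: float = 0.5,
    mismatch_penalty: float = 3.0,
    halfgap_penalty: float = 2.0,
) -> ConsensusStructure:
    """Consensus folding of an alignment with covariance pseudo-energies.

    A column pair is eligible when at least a fraction ``q`` of the rows
    holding residues in both columns can form a canonical pair.  Its
    energy averages the pair energies of the pairing rows, credits
    distinct pair types (covariance), and penalizes rows that cannot
    pair; rows with a gap in exactly one of the two columns pay a milder
    penalty, rows gapped in both are neutral.
    """
    model = model or EnergyModel()
    if aln.n_rows < 2:
        raise ValueError("alifold requires at least 2 rows")
    n = aln.n_cols
    rows = [row for _, row in aln.rows]

    def column_stats(i, j):
        pair_types = {}
        n_mismatch = 0
        n_halfgap = 0
        for row in rows:
            x, y = row[i], row[j]
            if x == "-" and y == "-":
                continue
            if x == "-" or y == "-":
                n_halfgap += 1
                continue
            e = model.pair_energy(x, y)
            if e is None:
                n_mismatch += 1
            else:
                pair_types[(x, y)] = pair_types.get((x, y), 0) + 1
        return pair_types, n_mismatch, n_halfgap

    pair_cache: dict[tuple[int, int], tuple[float, float] | None] = {}

    def score_pair(i, j):
        if (i, j) in pair_cache:
            return pair_cache[(i, j)]
        pair_types, n_mismatch, n_halfgap = column_stats(i, j)
        n_pairing = sum(pair_types.values())
        result = None
        if n_pairing >= 1:
            gap_free = n_pairing + n_mismatch
            if n_pairing / gap_free >= q:
                mean_e = (
                    sum(model.pair_energy(*p) * c for p, c in pair_types.items())
                    / n_pairing
                )
                cov_credit = cov_weight * (
                    -(len(pair_types) - 1)
                    + mismatch_penalty * n_mismatch
                    + halfgap_penalty * n_halfgap
                )
                result = (mean_e + cov_credit, cov_credit)
        pair_cache[(i, j)] = result
        return result

    def pair_e(i, j):
        s = score_pair(i, j)
        return None if s is None else s[0]

    def stack_e(i, j):
        bonuses = []
        for row in rows:
            if (
                model.can_pair(row[i], row[j])
                and model.can_pair(row[i + 1], row[j - 1])
            ):
                bonuses.append(
                    model.stack_bonus((row[i], row[j]), (row[i + 1], row[j - 1]))
                )
        return sum(bonuses) / len(bonuses) if bonuses else 0.0

    engine = _FoldEngine(n, pair_e, stack_e, model.min_hairpin)
    pairs, energy = engine.solve()
    covariance = {p: score_pair(*p)[1] for p in pairs}
    return ConsensusStructure(pairs, energy, n, covariance)


def project_consensus(
    consensus: ConsensusStructure,
    aln: MultipleAlignment,
    row_index: int,
    model: EnergyModel | None = None,
) -> tuple[tuple[int, int], ...]:
    """Project consensus pairs onto one ungapped row.

    A pair is kept when the row holds residues at both columns and they
    can pair canonically; kept pairs are re-indexed to ungapped sequence
    coordinates.
    """
    model = model or EnergyModel()
    row = aln.rows[row_index][1]
    if consensus.n_cols != len(row):
        raise ValueError("consensus and alignment disagree on column count")
    # ungapped coordinate of each column
    coord = []
    c = 0
    for ch in row:
        coord.append(c if ch != "-" else None)
        if ch != "-":
            c += 1
    kept = []
    for i, j in consensus.pairs:
        if row[i] == "-" or row[j] == "-":
            continue
        if not model.can_pair(row[i], row[j]):
            continue
        if coord[j] - coord[i] - 1 < model.min_hairpin:
            continue
        kept.append((coord[i], coord[j]))
    return tuple(sorted(kept))
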