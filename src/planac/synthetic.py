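"""Seeded generation of RNA families with a known consensus structure.

Families descend from a random ancestor compatible with a given
consensus: paired sites hold canonical pairs, compensatory events swap
both partners to another canonical pair, substitutions hit unpaired
sites, and indels are confined to loops so the reference consensus stays
well-defined in every row.  The generator is the test and evaluation
substrate of the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from planac.folding import ConsensusStructure, EnergyModel
from planac.io_formats import MultipleAlignment, Sequence, parse_dotbracket
from planac.seqalign import percent_identity

BASES = "ACGU"
WC_PAIRS = [("C", "G"), ("G", "C"), ("A", "U"), ("U", "A")]


@dataclass(frozen=True)
class FamilySpec:
    structure: str
    n_sequences: int = 5
    sub_rate: float = 0.3
    comp_rate: float = 0.3
    break_rate: float = 0.0
    indel_rate: float = 0.2
    indel_mean: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "comp_rate", "break_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_sequences < 2:
            raise ValueError("n_sequences must be >= 2")


#: default consensus for twilight-band families: two stems, mixed loops
DEFAULT_STRUCTURE = "..(((....)))...((((....))))..."


def _validate_structure(structure: str) -> list[tuple[int, int]]:
    pairs = parse_dotbracket(structure)
    paired = set()
    for i, j in pairs:
        paired.update((i, j))
    for i, j in pairs:
        inner = range(i + 1, j)
        if not any(k in paired for k in inner) and j - i - 1 < 3:
            raise ValueError(
                f"hairpin loop of pair ({i},{j}) is shorter than 3"
            )
    return pairs


def _mutate_base(rng, base: str) -> str:
    choices = [b for b in BASES if b != base]
    return choices[rng.integers(len(choices))]


def generate_family(
    spec: FamilySpec,
) -> tuple[list[Sequence], MultipleAlignment, ConsensusStructure]:
    """Generate sequences, their reference alignment and reference consensus."""
    pairs = _validate_structure(spec.structure)
    L = len(spec.structure)
    rng = np.random.default_rng(spec.seed)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    unpaired = [k for k in range(L) if k not in partner]

    # ancestor compatible with the consensus
    ancestor = [""] * L
    for i, j in pairs:
        b5, b3 = WC_PAIRS[rng.integers(len(WC_PAIRS))]
        ancestor[i], ancestor[j] = b5, b3
    for k in unpaired:
        ancestor[k] = BASES[rng.integers(4)]

    # unpaired runs (loops) eligible for indels
    runs = []
    start = None
    for k in range(L + 1):
        if k < L and k in set(unpaired):
            if start is None:
                start = k
        else:
            if start is not None and k - start >= 2:
                runs.append((start, k))
            start = None

    rows_cells: list[list[str]] = []
    rows_ins: list[dict[int, str]] = []
    for _ in range(spec.n_sequences):
        cells = list(ancestor)
        ins: dict[int, str] = {}
        for i, j in pairs:
            if rng.random() < spec.comp_rate:
                current = (cells[i], cells[j])
                alts = [p for p in WC_PAIRS if p != current]
                b5, b3 = alts[rng.integers(len(alts))]
                cells[i], cells[j] = b5, b3
            elif rng.random() < spec.break_rate:
                side = i if rng.random() < 0.5 else j
                cells[side] = _mutate_base(rng, cells[side])
        for k in unpaired:
            if rng.random() < spec.sub_rate:
                cells[k] = _mutate_base(rng, cells[k])
        for lo, hi in runs:
            if rng.random() < spec.indel_rate:
                size = 1 + rng.geometric(1.0 / max(spec.indel_mean, 1.0)) - 1
                if rng.random() < 0.5:  # deletion within the loop
                    size = min(size, hi - lo - 1)
                    for k in range(lo, lo + size):
                        cells[k] = ""
                else:  # insertion after the first loop position
                    ins[lo] = "".join(
                        BASES[rng.integers(4)] for _ in range(size)
                    )
        rows_cells.append(cells)
        rows_ins.append(ins)

    # assemble reference alignment columns
    col_of_pos: list[int] = []
    aligned_rows = ["" for _ in range(spec.n_sequences)]
    col = 0
    for p in range(L):
        col_of_pos.append(col)
        for r in range(spec.n_sequences):
            aligned_rows[r] += rows_cells[r][p] or "-"
        col += 1
        width = max(len(rows_ins[r].get(p, "")) for r in range(spec.n_sequences))
        if width:
            for r in range(spec.n_sequences):
                insert = rows_ins[r].get(p, "")
                aligned_rows[r] += insert + "-" * (width - len(insert))
            col += width

    ids = [f"seq{r + 1}" for r in range(spec.n_sequences)]
    ref_aln = MultipleAlignment(tuple(zip(ids, aligned_rows)))
    seqs = ref_aln.sequences()

    ref_pairs = tuple(
        sorted((col_of_pos[i], col_of_pos[j]) for i, j in pairs)
    )
    model = EnergyModel()
    energy = 0.0
    for i, j in ref_pairs:
        vals = [
            model.pair_energy(row[i], row[j])
            for _, row in ref_aln.rows
            if model.can_pair(row[i], row[j])
        ]
        if vals:
            energy += sum(vals) / len(vals)
    consensus = ConsensusStructure(ref_pairs, energy, ref_aln.n_cols)
    return seqs, ref_aln, consensus


# ---------------------------------------------------------------------------


def make_twilight_pathology(seed: int = 0) -> list[Sequence]:
    """A family built around the gap-shift trap.

    A conserved anchor helix aligns well, while a second helix carries
    compensatory changes and sits next to loops of varying length, so
    sequence alignment shifts its strands and the consensus misses its
    pairs; the literal motif ``AAGGAAAACCAA`` (helix flanked by
    homopolymer loops, with a one-sided deletion in the partner) is
    embedded in the family.
    """
    rng = np.random.default_rng(seed)
    del rng  # reserved: the family is fixed, the seed keeps the API uniform
    return [
        Sequence("path1", "GGGGGACUUUCCCCCAAGGAAAACCAA"),
        Sequence("path2", "GGGGGACUUUCCCCCAACAAAAGAA"),
        Sequence("path3", "GGGGGACUUUCCCCCAAUAAAAAAUAA"),
        Sequence("path4", "GGGGGACUUUCCCCCAAGAAAAACAA"),
    ]


def sweep(
    identity_targets,
    n_families: int = 1,
    seed: int = 0,
    structure: str = DEFAULT_STRUCTURE,
    n_sequences: int = 5,
    tolerance: float = 0.05,
    max_attempts: int = 16,
) -> list[tuple[FamilySpec, tuple]]:
    """Families whose reference-alignment identities approximate targets.

    A single divergence knob drives substitution and compensatory rates;
    it is tuned per family by bisection against the measured identity of
    the reference alignment.
    """
    out = []
    fam_index = 0
    for target in identity_targets:
        if not 0.0 < target < 1.0:
            raise ValueError(f"identity target {target} outside (0, 1)")
        for _ in range(n_families):
            fam_seed = int(
                np.random.default_rng([seed, fam_index]).integers(2**31)
            )
            fam_index += 1
            lo, hi = 0.0, 1.0
            chosen = None
            for _ in range(max_attempts):
                theta = (lo + hi) / 2
                spec = FamilySpec(
                    structure=structure,
                    n_sequences=n_sequences,
                    sub_rate=theta,
                    comp_rate=theta * 0.8,
                    indel_rate=theta * 0.4,
                    seed=fam_seed,
                )
                family = generate_family(spec)
                ident = percent_identity(family[1])
                if abs(ident - target) <= tolerance:
                    chosen = (spec, family)
                    break
                if ident > target:  # too similar -> more divergence
                    lo = theta
                else:
                    hi = theta
            if chosen is None:
                raise RuntimeError(
                    f"could not reach identity target {target} "
                    f"within {max_attempts} attempts"
                )
            out.append(chosen)
    return out
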