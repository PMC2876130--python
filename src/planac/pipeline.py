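"""The fine-tuning driver.

Plan A: align the sequences, then fold the alignment jointly.  The
fine-tuning loop disassembles the alignment, refolds every sequence
under the consensus pairs projected onto it, aligns the refolded
structures irrespective of sequence, extracts the implied sequence
alignment, and re-folds it jointly.  The new state is accepted only if
the structure conservation index strictly improves, and the loop repeats
from the refolding step; otherwise the previous state is the result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd
from scipy.signal import savgol_filter

from planac.folding import (
    ConsensusStructure,
    EnergyModel,
    alifold,
    constrained_fold,
    mfe_fold,
    project_consensus,
)
from planac.io_formats import MultipleAlignment, Sequence
from planac.seqalign import (
    ScoringScheme,
    gap_content,
    percent_identity,
    progressive_align,
)
from planac.structalign import (
    ForestScore,
    implied_sequence_alignment,
    multiple_structure_align,
)


@dataclass(frozen=True)
class SciReport:
    """Consensus energy over mean individual MFE."""

    consensus_energy: float
    individual_mfes: tuple[float, ...]
    mean_mfe: float
    sci: float

    def __str__(self) -> str:  # 4 decimals in human-facing output
        return f"{self.sci:.4f}"


def sci(consensus_energy: float, individual_mfes) -> SciReport:
    """Structure conservation index: E_A divided by the mean MFE.

    Degenerate case: 0/0 is defined as 0; a nonzero consensus energy
    over a zero mean is an error.
    """
    mfes = tuple(float(e) for e in individual_mfes)
    if not mfes:
        raise ValueError("sci needs at least one individual energy")
    mean = sum(mfes) / len(mfes)
    if mean == 0.0:
        if consensus_energy == 0.0:
            value = 0.0
        else:
            raise ZeroDivisionError(
                "SCI undefined: mean individual MFE is 0 but consensus "
                f"energy is {consensus_energy}"
            )
    else:
        value = consensus_energy / mean
    return SciReport(float(consensus_energy), mfes, mean, value)


@dataclass(frozen=True)
class PipelineConfig:
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    energy_model: EnergyModel = field(default_factory=EnergyModel)
    cov_weight: float = 1.0
    forest_score: ForestScore = field(default_factory=ForestScore)
    max_iterations: int = 10
    epsilon: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass(frozen=True)
class IterationRecord:
    index: int
    alignment: MultipleAlignment
    consensus: ConsensusStructure
    sci_report: SciReport
    accepted: bool


def _fold_alignment(aln: MultipleAlignment, config: PipelineConfig):
    return alifold(aln, config.energy_model, cov_weight=config.cov_weight)


def run_plan_a(
    seqs: list[Sequence],
    config: PipelineConfig | None = None,
    aligned: MultipleAlignment | None = None,
):
    """Align (or take a supplied alignment) and fold jointly."""
    config = config or PipelineConfig()
    if aligned is None:
        if len(seqs) < 2:
            raise ValueError("need at least 2 sequences")
        aligned = progressive_align(seqs, config.scoring)
    consensus = _fold_alignment(aligned, config)
    mfes = [mfe_fold(s, config.energy_model).energy for s in seqs]
    return aligned, consensus, sci(consensus.energy, mfes)


def run_planacstar(
    seqs: list[Sequence],
    config: PipelineConfig | None = None,
    aligned: MultipleAlignment | None = None,
):
    """Iterative fine-tuning; returns (alignment, consensus, sci, trace).

    The individual MFEs in the SCI denominator are alignment-independent
    and computed once from unconstrained folding.
    """
    config = config or PipelineConfig()
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    model = config.energy_model
    mfes = [mfe_fold(s, model).energy for s in seqs]

    aln, consensus, x = run_plan_a(seqs, config, aligned=aligned)
    trace = [IterationRecord(0, aln, consensus, x, True)]

    while len(trace) < config.max_iterations:
        # project consensus pairs onto each sequence, refold under them
        folds = []
        for i, seq in enumerate(seqs):
            constraints = project_consensus(consensus, aln, i, model)
            folds.append((seq, constrained_fold(seq, constraints, model)))
        y = multiple_structure_align(folds, config.forest_score)
        aln_star = implied_sequence_alignment(y)
        consensus_star = _fold_alignment(aln_star, config)
        x_star = sci(consensus_star.energy, mfes)
        if x_star.sci > x.sci + config.epsilon:
            aln, consensus, x = aln_star, consensus_star, x_star
            trace.append(
                IterationRecord(len(trace), aln, consensus, x, True)
            )
        else:
            break

    return aln, consensus, x, trace


def report(trace: list[IterationRecord]) -> tuple[str, dict]:
    """Human-readable and machine-readable per-iteration summary."""
    if not trace:
        raise ValueError("empty trace")
    rows = []
    for rec in trace:
        rows.append(
            {
                "iteration": rec.index,
                "sci": round(rec.sci_report.sci, 4),
                "consensus_energy": rec.consensus.energy,
                "identity": round(percent_identity(rec.alignment), 4),
                "gap_content": round(gap_content(rec.alignment), 4),
                "n_consensus_pairs": len(rec.consensus.pairs),
                "accepted": rec.accepted,
            }
        )
    summary = {"iterations": rows, "final_sci": rows[-1]["sci"]}
    lines = [
        f"{'iter':>4} {'SCI':>8} {'E_A':>8} {'ident':>6} {'gaps':>6} {'pairs':>5}"
    ]
    for r in rows:
        lines.append(
            f"{r['iteration']:>4} {r['sci']:>8.4f} {r['consensus_energy']:>8.2f}"
            f" {r['identity']:>6.3f} {r['gap_content']:>6.3f}"
            f" {r['n_consensus_pairs']:>5}"
        )
    text = "\n".join(lines)
    json.dumps(summary)  # must round-trip
    return text, summary


def evaluate_curve(
    families: list[list[Sequence]],
    config: PipelineConfig | None = None,
    window: int = 5,
    polyorder: int = 2,
) -> pd.DataFrame:
    """Identity vs SCI (Plan A and fine-tuned) with Savitzky-Golay smoothing.

    One row per family, sorted by reference-free measured identity of the
    Plan A alignment; smoothed columns are added for both SCI series.
    """
    config = config or PipelineConfig()
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if len(families) < window:
        raise ValueError("need at least `window` families")
    rows = []
    for fam in families:
        aln_a, _, sci_a = run_plan_a(fam, config)
        _, _, sci_c, _ = run_planacstar(fam, config)
        rows.append(
            {
                "identity": percent_identity(aln_a),
                "sci_plan_a": sci_a.sci,
                "sci_planacstar": sci_c.sci,
            }
        )
    df = pd.DataFrame(rows).sort_values("identity", kind="mergesort")
    df = df.reset_index(drop=True)
    for col in ("sci_plan_a", "sci_planacstar"):
        df[col + "_smooth"] = savgol_filter(
            df[col].to_numpy(), window, polyorder
        )
    return df
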