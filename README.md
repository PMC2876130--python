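# planac

Structure-guided fine-tuning of RNA multiple alignments in the
"twilight zone" (30–55% pairwise sequence identity), where sequence
alignment systematically obscures the covariance signal that consensus
structure prediction relies on.

The pipeline:

1. build a multiple sequence alignment (progressive, affine gaps, UPGMA
   guide tree);
2. fold the alignment jointly into a consensus structure with
   covariance pseudo-energies, and score it with the structure
   conservation index (SCI = consensus energy / mean individual MFE);
3. project the consensus pairs onto each ungapped sequence;
4. refold every sequence under those pairs as mandatory constraints
   (additional compatible pairs may form);
5. align the refolded structures as ordered forests, ignoring residue
   identity — this is what recovers compensatory base changes;
6. read the implied sequence alignment off the structure alignment;
7. refold the new alignment jointly and keep it only if the SCI
   strictly improved; repeat from step 3 while it does.

Folding uses a small pluggable surrogate energy model (per-pair
energies, a flat stacking bonus, minimum hairpin size) rather than full
nearest-neighbor parameter tables; the model is small enough that every
dynamic program in the package is checked against exhaustive
enumeration oracles in the test suite.

## Library

```python
from planac import (
    Sequence, run_plan_a, run_planacstar, PipelineConfig,
    FamilySpec, generate_family, make_twilight_pathology,
)

seqs = make_twilight_pathology(0)
aln, consensus, sci_report, trace = run_planacstar(seqs)
print(consensus.dotbracket, sci_report.sci)
```

Modules:

- `planac.io_formats` — FASTA / CLUSTAL / Stockholm (`#=GC SS_cons`) /
  Vienna two-line records; dot-bracket parsing and validation.
- `planac.seqalign` — affine-gap pairwise and progressive alignment,
  percent identity (gap-aware, per-pair denominators), gap content,
  alignment comparison.
- `planac.folding` — MFE folding, constrained folding (result must
  contain the mandatory pairs), consensus folding of alignments with
  covariance credits, consensus projection.
- `planac.structalign` — ordered-forest encoding of structures,
  pairwise and progressive multiple structure alignment, implied
  sequence alignment extraction.
- `planac.pipeline` — SCI, the iteration driver (`run_planacstar`),
  the align-then-fold baseline (`run_plan_a`), evaluation curves with
  Savitzky–Golay smoothing, reporting.
- `planac.synthetic` — seeded generator of families with a known
  consensus, compensatory substitutions, loop-confined indels, and
  identity-targeted sweeps; also the deliberate gap-shift pathology
  family used in tests.

## CLI

```sh
planac align in.fasta -o out.aln --format clustal
planac fold in.fasta                # Vienna two-line output
planac fold in.fasta -C cons.db     # constrained folding
planac alifold in.aln               # consensus structure + energy
planac structal folds.vienna -o out.stk
planac run in.fasta [--aligned in.aln] [--max-iter K] -o outdir
planac synth --seed 4 -o family.fasta --ref ref.stk
```

`planac run` writes the final alignment (CLUSTAL and Stockholm with
SS_cons), the consensus dot-bracket with its energy and SCI, a JSON
iteration trace, and a text log. Exit codes: 0 success, 2 usage error,
3 malformed input, 4 bad configuration.

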