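"""Sequence, alignment and dot-bracket I/O.

Coordinates are 0-based everywhere in the library.  The gap character is
``-`` on output; ``.`` and ``~`` are accepted as gaps on alignment input.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
GAP_CHARS = frozenset("-.~")

#: IUPAC ambiguity codes mapped to the set of concrete bases they denote.
IUPAC_AMBIGUITY = {
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


class FormatError(ValueError):
    """Raised on malformed input files or structure strings."""


def _normalize_residues(raw: str, *, allow_ambiguity: bool = False) -> str:
    """Uppercase, map T->U, optionally resolve IUPAC ambiguity codes."""
    out = []
    for ch in raw.upper():
        if ch == "T":
            ch = "U"
        if ch in RNA_ALPHABET:
            out.append(ch)
        elif ch in IUPAC_AMBIGUITY:
            if not allow_ambiguity:
                raise FormatError(
                    f"ambiguity code {ch!r} not supported; only concrete "
                    "A/C/G/U sequences are accepted (pass "
                    "allow_ambiguity=True to map codes to a concrete base)"
                )
            out.append(IUPAC_AMBIGUITY[ch][0])
        else:
            raise FormatError(f"invalid residue {ch!r}")
    return "".join(out)


@dataclass(frozen=True)
class Sequence:
    """An ungapped RNA sequence over {A, C, G, U}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        norm = self.residues.upper().replace("T", "U")
        if norm != self.residues:
            object.__setattr__(self, "residues", norm)
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-RNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MultipleAlignment:
    """Gapped rows over common columns.

    All-gap columns are removed on construction; an optional consensus
    structure annotation (``ss_cons``) is adjusted consistently.
    """

    rows: tuple[tuple[str, str], ...]
    ss_cons: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        rows = tuple((str(i), str(r).upper()) for i, r in self.rows)
        if not rows:
            raise ValueError("alignment has no rows")
        width = len(rows[0][1])
        if any(len(r) != width for _, r in rows):
            raise ValueError("ragged alignment: rows differ in length")
        ids = [i for i, _ in rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")
        # normalize gaps and residues
        norm_rows = []
        for rid, row in rows:
            chars = []
            for ch in row:
                if ch in GAP_CHARS:
                    chars.append("-")
                else:
                    chars.append(_normalize_residues(ch))
            norm_rows.append((rid, "".join(chars)))
        keep = [
            j for j in range(width)
            if any(r[j] != "-" for _, r in norm_rows)
        ]
        if not keep:
            raise ValueError("alignment has no residue-bearing columns")
        ss = self.ss_cons
        if len(keep) != width:
            norm_rows = [
                (rid, "".join(row[j] for j in keep)) for rid, row in norm_rows
            ]
            if ss is not None:
                ss = "".join(ss[j] for j in keep)
        object.__setattr__(self, "rows", tuple(norm_rows))
        object.__setattr__(self, "ss_cons", ss)
        for rid, row in self.rows:
            if not row.replace("-", ""):
                raise ValueError(f"row {rid!r} is all gaps")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.rows)

    def row(self, i: int) -> str:
        return self.rows[i][1]

    def degapped(self, i: int) -> Sequence:
        rid, row = self.rows[i]
        return Sequence(rid, row.replace("-", ""))

    def sequences(self) -> list[Sequence]:
        return [self.degapped(i) for i in range(self.n_rows)]


# ---------------------------------------------------------------------------
# dot-bracket


def parse_dotbracket(text: str) -> list[tuple[int, int]]:
    """Parse dot-bracket into a sorted list of 0-based pairs (i, j), i < j."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(text):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise FormatError(
                    f"unbalanced dot-bracket: unmatched ')' at position {pos}"
                )
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise FormatError(f"invalid dot-bracket character {ch!r} at {pos}")
    if stack:
        raise FormatError(
            f"unbalanced dot-bracket: unmatched '(' at position {stack[-1]}"
        )
    return sorted(pairs)


def write_dotbracket(pairs, length: int) -> str:
    """Serialize nested pairs to dot-bracket; rejects crossing pairs."""
    chars = ["."] * length
    seen: set[int] = set()
    plist = sorted(pairs)
    for i, j in plist:
        if not (0 <= i < j < length):
            raise ValueError(f"pair ({i},{j}) out of range for length {length}")
        if i in seen or j in seen:
            raise ValueError(f"position reused by pair ({i},{j})")
        seen.update((i, j))
        chars[i], chars[j] = "(", ")"
    for a, b in plist:
        for c, d in plist:
            if a < c < b < d:
                raise ValueError(
                    f"pairs ({a},{b}) and ({c},{d}) would create "
                    "non-nested base pairing"
                )
    return "".join(chars)


_WUSS_OPEN = "(<[{"
_WUSS_CLOSE = ")>]}"


def normalize_wuss(text: str) -> str:
    """Normalize a WUSS consensus line to plain dot-bracket."""
    out = []
    for ch in text:
        if ch in _WUSS_OPEN:
            out.append("(")
        elif ch in _WUSS_CLOSE:
            out.append(")")
        else:
            out.append(".")
    return "".join(out)


# ---------------------------------------------------------------------------
# FASTA


def _as_handle(path_or_text: str | os.PathLike):
    if isinstance(path_or_text, str) and (
        not path_or_text
        or path_or_text.lstrip().startswith(">")
        or "\n" in path_or_text
    ):
        return io.StringIO(path_or_text)
    return open(path_or_text)


def read_fasta(path_or_text, *, allow_ambiguity: bool = False) -> list[Sequence]:
    """Read FASTA from a path or a raw text block.

    DNA-alphabet input (``T``) is accepted and mapped to ``U``; IUPAC
    ambiguity codes are rejected unless ``allow_ambiguity`` is set, in
    which case each code maps to the first concrete base of its set.
    """
    with _as_handle(path_or_text) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise FormatError("no FASTA records found")
    seqs = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seqs.append(
            Sequence(rec.id, _normalize_residues(str(rec.seq),
                                                 allow_ambiguity=allow_ambiguity))
        )
    return seqs


def write_fasta(seqs, width: int = 60) -> str:
    out = []
    for s in seqs:
        out.append(f">{s.id}")
        for k in range(0, len(s.residues), width):
            out.append(s.residues[k:k + width])
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# alignments (aligned-FASTA / CLUSTAL / Stockholm)

_DIALECTS = {"clustal": "clustal", "stockholm": "stockholm",
             "aligned-fasta": "fasta"}


def read_alignment(path_or_text, dialect: str = "aligned-fasta") -> MultipleAlignment:
    """Read an alignment; Stockholm ``#=GC SS_cons`` is kept (normalized)."""
    if dialect not in _DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}"
        )
    if isinstance(path_or_text, str) and "\n" in path_or_text:
        handle = io.StringIO(path_or_text)
    else:
        handle = open(path_or_text)
    with handle:
        try:
            aln = AlignIO.read(handle, _DIALECTS[dialect])
        except ValueError as exc:
            raise FormatError(f"cannot parse {dialect} alignment: {exc}") from exc
    ss = aln.column_annotations.get("secondary_structure")
    return MultipleAlignment(
        tuple((rec.id, str(rec.seq)) for rec in aln),
        ss_cons=normalize_wuss(ss) if ss else None,
    )


def write_alignment(aln: MultipleAlignment, dialect: str = "clustal") -> str:
    if dialect not in _DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}"
        )
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=rid, description="") for rid, row in aln.rows]
    )
    if dialect == "stockholm" and aln.ss_cons is not None:
        msa.column_annotations["secondary_structure"] = aln.ss_cons
    out = io.StringIO()
    AlignIO.write(msa, out, _DIALECTS[dialect])
    return out.getvalue()


# ---------------------------------------------------------------------------
# Vienna two-line records (sequence + dot-bracket + optional energy)


def write_vienna(entries) -> str:
    """Write (Sequence, dotbracket, energy) triples as Vienna records."""
    out = []
    for seq, db, energy in entries:
        if len(db) != len(seq.residues):
            raise ValueError(f"structure length mismatch for {seq.id!r}")
        out.append(f">{seq.id}")
        out.append(seq.residues)
        if energy is None:
            out.append(db)
        else:
            out.append(f"{db} ({energy:.2f})")
    return "\n".join(out) + "\n"


def read_vienna(path_or_text) -> list[tuple[Sequence, str, float | None]]:
    with _as_handle(path_or_text) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    entries = []
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise FormatError(f"expected '>' header, got {lines[i]!r}")
        sid = lines[i][1:].split()[0]
        if i + 2 >= len(lines) + 1:
            raise FormatError(f"truncated Vienna record for {sid!r}")
        seq = Sequence(sid, lines[i + 1].strip())
        struct_line = lines[i + 2].strip()
        energy = None
        if "(" in struct_line and struct_line.endswith(")") and " " in struct_line:
            db, _, tail = struct_line.rpartition(" ")
            try:
                energy = float(tail.strip("()"))
            except ValueError:
                db = struct_line
        else:
            db = struct_line
        parse_dotbracket(db)  # validate
        if len(db) != len(seq.residues):
            raise FormatError(f"structure length mismatch for {sid!r}")
        entries.append((seq, db, energy))
        i += 3
    return entries
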