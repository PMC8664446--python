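"""Nucleotide-sequence primitives shared by the whole toolkit.

Conventions used everywhere downstream:

* sequences are DNA over ``{A, C, G, T, N}``, uppercased on ingest;
* motif patterns may use the full IUPAC alphabet (``R``, ``Y``, ``V`` ...);
* all coordinates are 0-based, half-open, on the plus strand of the
  reference sequence; strand is carried separately (BED convention);
* an ``N`` in a *subject* sequence matches no pattern symbol — an unknown
  base can never be asserted to satisfy a motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_CLASSES",
    "NucSequence",
    "IupacPattern",
    "revcomp",
    "matches_iupac",
    "iupac_to_regex",
    "read_fasta",
    "write_fasta",
    "InvalidAlphabetError",
    "FastaParseError",
]

#: Degeneracy classes of the IUPAC nucleotide code (subject bases each
#: symbol stands for).  ``N`` deliberately expands to ACGT only: a subject
#: ``N`` is in no class, so it never matches (see module docstring).
IUPAC_CLASSES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)

SUBJECT_ALPHABET = frozenset("ACGTN")


class InvalidAlphabetError(ValueError):
    """A sequence or pattern contains a character outside its alphabet."""


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _check_alphabet(s: str, alphabet: frozenset[str], what: str) -> None:
    bad = set(s) - alphabet
    if bad:
        raise InvalidAlphabetError(
            f"{what} contains invalid character(s): {sorted(bad)!r}"
        )


def revcomp(seq: str) -> str:
    """Reverse complement using the full IUPAC complement table.

    Works on patterns as well as plain sequences (``R``↔``Y``,
    ``V``↔``B``, ``N``↔``N`` ...).  Involution:
    ``revcomp(revcomp(s)) == s``.
    """
    s = seq.upper()
    _check_alphabet(s, frozenset(IUPAC_CLASSES), "sequence")
    return s.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucSequence:
    """A named DNA sequence over ``{A, C, G, T, N}`` (uppercased on ingest)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        _check_alphabet(self.seq, SUBJECT_ALPHABET, f"sequence {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.id, revcomp(self.seq))


@dataclass(frozen=True)
class IupacPattern:
    """A degenerate DNA motif, e.g. the PAMs ``NGG``, ``NNGRRT``, ``TTTV``."""

    pattern: str
    degenerate_positions: frozenset[int] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.upper())
        if not self.pattern:
            raise ValueError("pattern must be non-empty")
        _check_alphabet(self.pattern, frozenset(IUPAC_CLASSES), "pattern")
        degen = frozenset(
            i for i, c in enumerate(self.pattern) if c not in "ACGT"
        )
        object.__setattr__(self, "degenerate_positions", degen)

    def __len__(self) -> int:
        return len(self.pattern)

    def reverse_complement(self) -> "IupacPattern":
        return IupacPattern(revcomp(self.pattern))


def matches_iupac(pattern: IupacPattern | str, window: str) -> bool:
    """True iff every base of ``window`` is in the degeneracy class of the
    corresponding pattern symbol.

    A subject ``N`` matches nothing (not even pattern ``N``).  Raises on
    length mismatch — callers slice exact-width windows.
    """
    pat = pattern.pattern if isinstance(pattern, IupacPattern) else pattern.upper()
    w = window.upper()
    if len(pat) != len(w):
        raise ValueError(
            f"window length {len(w)} != pattern length {len(pat)}"
        )
    _check_alphabet(w, SUBJECT_ALPHABET, "window")
    return all(b in IUPAC_CLASSES[p] for p, b in zip(pat, w))


def iupac_to_regex(pattern: IupacPattern | str) -> str:
    """Compile an IUPAC motif to a plain-character regex.

    Character classes enumerate ACGT members only, so a subject ``N`` can
    never match — consistent with :func:`matches_iupac`.
    """
    pat = pattern.pattern if isinstance(pattern, IupacPattern) else pattern.upper()
    parts = []
    for c in pat:
        members = "".join(sorted(IUPAC_CLASSES[c]))
        parts.append(members if len(members) == 1 else f"[{members}]")
    return "".join(parts)


def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a (multi-record) FASTA file; sequences are uppercased.

    Soft-masking (lowercase) is ignored.  Raises :class:`FastaParseError`
    with a line number on malformed input.
    """
    path = Path(path)
    # Pre-validate framing so errors carry a line number (SeqIO is lenient).
    with open(path) as fh:
        saw_header = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise FastaParseError("empty FASTA header", lineno)
                saw_header = True
            elif not saw_header:
                raise FastaParseError(
                    "sequence data before first '>' header", lineno
                )
        if not saw_header:
            raise FastaParseError("no FASTA records found", 1)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(NucSequence(rec.id, str(rec.seq)))
    return records


def write_fasta(
    records: Iterable[NucSequence], path: str | Path, width: int = 60
) -> None:
    """Write records in input order, wrapped at ``width`` columns."""
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)
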