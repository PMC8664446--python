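"""PAM-site discovery and editable-genome coverage.

Each CRISPR/Cas system recognizes targets flanked by its own protospacer
adjacent motif (PAM): NGG for SpCas9, NNGRRT for SaCas9 and TTTV for
AsCas12a.  A genomic nucleotide is *editable* by a system if substituting
it would block re-cleavage of the edited allele — i.e. it lies in the
PAM-proximal seed window of some protospacer (11 nt for the Cas9s, 17 nt
for Cas12a) or it is a non-degenerate base of the PAM itself.  Degenerate
PAM symbols (N, R, V) tolerate any member of their class, so changing them
cannot break recognition and they are excluded.

Scanning covers both strands; minus-strand sites are found as matches of
the reverse-complemented motif on the plus strand, and every coordinate is
reported in plus-strand space (0-based, half-open) with the strand carried
separately.  Coverage is a per-nucleotide, strand-collapsed position set:
a base reachable from either strand or from overlapping sites counts once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .seq_core import IupacPattern, NucSequence, iupac_to_regex

__all__ = [
    "CasSystemSpec",
    "PamSite",
    "CoverageReport",
    "SPCAS9",
    "SACAS9",
    "ASCAS12A",
    "ALL_SYSTEMS",
    "get_system",
    "find_pam_sites",
    "editable_positions",
    "coverage_fraction",
    "write_sites_bed",
    "write_coverage_tsv",
    "read_coverage_tsv",
]


@dataclass(frozen=True)
class CasSystemSpec:
    """Parameters of one CRISPR/Cas system.

    ``editable_window_len`` is the length of the PAM-proximal protospacer
    window whose mismatches abolish re-cleavage; together with the
    non-degenerate PAM bases it defines the editable-nucleotide set.
    ``cut_offsets`` are the distances of the two strand nicks from the
    PAM-proximal protospacer end (equal for the blunt-cutting Cas9s,
    staggered for Cas12a); they are informational for cut-site prediction
    and never enter coverage math.
    """

    name: str
    pam: IupacPattern
    pam_side: str  # "three_prime" (PAM follows protospacer) | "five_prime"
    spacer_len: int
    editable_window_len: int
    cut_offsets: tuple[int, int]

    def __post_init__(self) -> None:
        if self.pam_side not in ("three_prime", "five_prime"):
            raise ValueError(f"bad pam_side {self.pam_side!r}")
        if not 0 < self.editable_window_len <= self.spacer_len:
            raise ValueError("editable_window_len must be in (0, spacer_len]")

    @property
    def pam_len(self) -> int:
        return len(self.pam)

    @property
    def nondegenerate_pam_indices(self) -> tuple[int, ...]:
        return tuple(
            i
            for i in range(len(self.pam))
            if i not in self.pam.degenerate_positions
        )


SPCAS9 = CasSystemSpec(
    name="SpCas9",
    pam=IupacPattern("NGG"),
    pam_side="three_prime",
    spacer_len=20,
    editable_window_len=11,
    cut_offsets=(3, 3),
)
SACAS9 = CasSystemSpec(
    name="SaCas9",
    pam=IupacPattern("NNGRRT"),
    pam_side="three_prime",
    spacer_len=21,
    editable_window_len=11,
    cut_offsets=(3, 3),
)
ASCAS12A = CasSystemSpec(
    name="AsCas12a",
    pam=IupacPattern("TTTV"),
    pam_side="five_prime",
    spacer_len=23,
    editable_window_len=17,
    cut_offsets=(18, 23),
)

ALL_SYSTEMS: tuple[CasSystemSpec, ...] = (SPCAS9, SACAS9, ASCAS12A)

_SYSTEMS_BY_NAME = {s.name: s for s in ALL_SYSTEMS}
_SYSTEM_ALIASES = {
    "sp": "SpCas9",
    "spcas9": "SpCas9",
    "sa": "SaCas9",
    "sacas9": "SaCas9",
    "as12a": "AsCas12a",
    "as": "AsCas12a",
    "ascas12a": "AsCas12a",
    "enascas12a": "AsCas12a",
}


def get_system(name: str) -> CasSystemSpec:
    """Look up a system by canonical name or short alias (sp/sa/as12a)."""
    key = _SYSTEM_ALIASES.get(name.lower(), name)
    try:
        return _SYSTEMS_BY_NAME[key]
    except KeyError:
        raise KeyError(
            f"unknown Cas system {name!r}; valid: "
            f"{sorted(_SYSTEMS_BY_NAME)} or aliases {sorted(_SYSTEM_ALIASES)}"
        ) from None


@dataclass(frozen=True)
class PamSite:
    """One PAM occurrence, with its protospacer, in plus-strand coordinates.

    ``truncated`` marks sites whose protospacer window runs off the contig
    edge; their intervals are clipped to the contig.
    """

    seq_id: str
    strand: str  # "+" | "-"
    pam_interval: tuple[int, int]
    protospacer_interval: tuple[int, int]
    system: str
    truncated: bool = False

    @property
    def footprint(self) -> tuple[int, int]:
        """Union of PAM and protospacer intervals (contiguous by design)."""
        a0, a1 = self.pam_interval
        b0, b1 = self.protospacer_interval
        return (min(a0, b0), max(a1, b1))


def _iter_matches(
    seq: str, system: CasSystemSpec
) -> Iterator[tuple[int, str]]:
    """Yield (pam_start_on_plus, strand) for all — including overlapping —
    PAM matches on both strands."""
    fwd = re.compile("(?=" + iupac_to_regex(system.pam) + ")")
    rev = re.compile(
        "(?=" + iupac_to_regex(system.pam.reverse_complement()) + ")"
    )
    for m in fwd.finditer(seq):
        yield m.start(), "+"
    for m in rev.finditer(seq):
        yield m.start(), "-"


def _protospacer_ideal(
    pam_start: int, strand: str, system: CasSystemSpec
) -> tuple[int, int]:
    """Unclipped protospacer interval in plus-strand coordinates."""
    L, S = system.pam_len, system.spacer_len
    pam_is_3prime_on_plus = (system.pam_side == "three_prime") == (
        strand == "+"
    )
    if pam_is_3prime_on_plus:
        # protospacer lies 5' (left, in plus coordinates) of the PAM
        return (pam_start - S, pam_start)
    return (pam_start + L, pam_start + L + S)


def find_pam_sites(
    seq: NucSequence, system: CasSystemSpec
) -> list[PamSite]:
    """Every PAM occurrence of ``system`` on either strand of ``seq``.

    Overlapping occurrences are all reported.  Sites whose protospacer is
    clipped at a contig edge carry ``truncated=True``.  Output is sorted
    by (PAM start, strand).
    """
    n = len(seq)
    sites = []
    for pam_start, strand in _iter_matches(seq.seq, system):
        ideal = _protospacer_ideal(pam_start, strand, system)
        clipped = (max(ideal[0], 0), min(ideal[1], n))
        sites.append(
            PamSite(
                seq_id=seq.id,
                strand=strand,
                pam_interval=(pam_start, pam_start + system.pam_len),
                protospacer_interval=clipped,
                system=system.name,
                truncated=clipped != ideal,
            )
        )
    sites.sort(key=lambda s: (s.pam_interval[0], s.strand))
    return sites


def _editable_intervals(
    pam_start: int,
    strand: str,
    system: CasSystemSpec,
) -> tuple[tuple[int, int], list[int]]:
    """(window interval, non-degenerate PAM positions), unclipped, on plus."""
    L, W = system.pam_len, system.editable_window_len
    pam_is_3prime_on_plus = (system.pam_side == "three_prime") == (
        strand == "+"
    )
    if pam_is_3prime_on_plus:
        window = (pam_start - W, pam_start)
    else:
        window = (pam_start + L, pam_start + L + W)
    if strand == "+":
        pam_pos = [pam_start + i for i in system.nondegenerate_pam_indices]
    else:
        pam_pos = [
            pam_start + (L - 1 - i)
            for i in system.nondegenerate_pam_indices
        ]
    return window, pam_pos


def editable_positions(
    site: PamSite, system: CasSystemSpec
) -> set[int]:
    """Plus-strand positions editable via this site: the PAM-proximal
    ``editable_window_len`` protospacer positions plus the non-degenerate
    PAM bases.  Out-of-contig positions of truncated sites are dropped.

    Full-length sites yield exactly 13 positions for SpCas9 (11 + GG),
    13 for SaCas9 (11 + G,T) and 20 for AsCas12a (17 + TTT).
    """
    if site.system != system.name:
        raise ValueError(
            f"site is for {site.system}, not {system.name}"
        )
    pam_start = site.pam_interval[0]
    window, pam_pos = _editable_intervals(pam_start, site.strand, system)
    # Clip to the contig: we only know the right bound via the protospacer
    # clip for truncated sites, so recompute from the footprint context.
    lo = 0
    hi = max(site.footprint[1], window[1], pam_start + system.pam_len)
    if site.truncated:
        # positions beyond either contig edge are invalid; the clipped
        # protospacer interval tells us the contig bounds touched
        ideal = _protospacer_ideal(pam_start, site.strand, system)
        if ideal[0] < site.protospacer_interval[0]:
            lo = 0
        if ideal[1] > site.protospacer_interval[1]:
            hi = site.protospacer_interval[1]
    pos = set(range(max(window[0], lo), min(window[1], hi)))
    pos.update(p for p in pam_pos if lo <= p < hi)
    return pos


def _editable_mask(seq: NucSequence, system: CasSystemSpec) -> np.ndarray:
    """Boolean per-nucleotide editability mask for one contig/system.

    Fast path used by :func:`coverage_fraction`: marks window slices and
    PAM positions directly from the match stream without materializing
    :class:`PamSite` objects.
    """
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    for pam_start, strand in _iter_matches(seq.seq, system):
        window, pam_pos = _editable_intervals(pam_start, strand, system)
        a, b = max(window[0], 0), min(window[1], n)
        if a < b:
            mask[a:b] = True
        for p in pam_pos:
            if 0 <= p < n:
                mask[p] = True
    return mask


@dataclass(frozen=True)
class CoverageReport:
    """Editable-nucleotide counts/fractions per system and per combination.

    ``per_combination`` maps every non-empty subset of the scanned systems
    (as a sorted name tuple) to the size of the union of the member
    systems' editable-position sets.  Fractions use the total length of
    the supplied sequences as denominator.
    """

    genome_length: int
    per_system: dict[str, tuple[int, float]]
    per_combination: dict[tuple[str, ...], tuple[int, float]]


def _subsets(names: Sequence[str]) -> list[tuple[str, ...]]:
    out: list[tuple[str, ...]] = []
    for bits in range(1, 1 << len(names)):
        out.append(
            tuple(sorted(n for i, n in enumerate(names) if bits >> i & 1))
        )
    out.sort(key=lambda t: (len(t), t))
    return out


def coverage_fraction(
    genome: Sequence[NucSequence],
    systems: Sequence[CasSystemSpec] = ALL_SYSTEMS,
) -> CoverageReport:
    """Fraction of genome nucleotides editable with each system and with
    every non-empty combination of the supplied systems.

    A nucleotide covered via either strand, or by several overlapping
    sites, counts once (position-set union).
    """
    if not genome:
        raise ValueError("genome must be non-empty")
    if not systems:
        raise ValueError("systems must be non-empty")
    total = sum(len(s) for s in genome)
    names = [s.name for s in systems]
    counts = {name: 0 for name in names}
    combo_counts = {combo: 0 for combo in _subsets(names)}
    for contig in genome:
        masks = {s.name: _editable_mask(contig, s) for s in systems}
        for name in names:
            counts[name] += int(masks[name].sum())
        for combo in combo_counts:
            union = masks[combo[0]].copy()
            for name in combo[1:]:
                union |= masks[name]
            combo_counts[combo] += int(union.sum())
    per_system = {
        name: (c, c / total) for name, c in counts.items()
    }
    per_combination = {
        combo: (c, c / total) for combo, c in combo_counts.items()
    }
    return CoverageReport(
        genome_length=total,
        per_system=per_system,
        per_combination=per_combination,
    )


def write_sites_bed(sites: Iterable[PamSite], path: str | Path) -> None:
    """BED6 track of site footprints (protospacer+PAM union), name=system."""
    with open(path, "w") as fh:
        for s in sites:
            a, b = s.footprint
            fh.write(
                f"{s.seq_id}\t{a}\t{b}\t{s.system}\t0\t{s.strand}\n"
            )


def write_coverage_tsv(report: CoverageReport, path: str | Path) -> None:
    """One row per non-empty system combination, fractions to 6 decimals."""
    with open(path, "w") as fh:
        fh.write("members\teditable_count\tgenome_length\tfraction\n")
        for combo, (count, frac) in report.per_combination.items():
            fh.write(
                f"{','.join(combo)}\t{count}\t{report.genome_length}"
                f"\t{frac:.6f}\n"
            )


def read_coverage_tsv(path: str | Path) -> dict[tuple[str, ...], float]:
    """Parse a coverage TSV back to {combination: fraction} (round-trip)."""
    out: dict[tuple[str, ...], float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("members\t"):
            raise ValueError("not a coverage TSV")
        for line in fh:
            members, _count, _length, frac = line.rstrip("\n").split("\t")
            out[tuple(members.split(","))] = float(frac)
    return out
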