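"""Seeded synthetic-genome generator.

Stands in for the real reference genome in tests and demos: an i.i.d.
background at a requested GC content (G and C each at gc/2, A and T each
at (1-gc)/2), with protospacer+PAM sites planted at exact positions and
strands.  A ``polyA`` background contains no PAM of any of the three
systems on either strand, so every scanner hit there is a planted one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pam_scan import CasSystemSpec, get_system
from .seq_core import NucSequence, matches_iupac, revcomp

__all__ = ["PlantedSite", "SyntheticGenomeSpec", "synth_genome"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedSite:
    """One protospacer+PAM to write into the background.

    ``position`` is the plus-strand start of the full footprint
    (protospacer+PAM); for minus-strand plants the reverse complement of
    the site sequence is written there.
    """

    system: str
    spacer: str
    pam: str
    contig: int  # 0-based contig index
    position: int
    strand: str = "+"

    def footprint_seq(self, spec: CasSystemSpec) -> str:
        """Plus-strand sequence of the planted footprint."""
        if len(self.spacer) != spec.spacer_len:
            raise ValueError(
                f"spacer is {len(self.spacer)} nt; {spec.name} expects "
                f"{spec.spacer_len}"
            )
        if not matches_iupac(spec.pam, self.pam):
            raise ValueError(
                f"PAM {self.pam!r} does not match {spec.name} pattern "
                f"{spec.pam.pattern}"
            )
        if spec.pam_side == "three_prime":
            site = self.spacer + self.pam
        else:
            site = self.pam + self.spacer
        return site if self.strand == "+" else revcomp(site)


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    n_contigs: int = 1
    contig_len: int = 5000
    gc: float = 0.38  # yeast-like genomic GC
    seed: int = 0
    background: str = "random"  # random | polyA (PAM-free)
    planted_sites: tuple[PlantedSite, ...] = field(default_factory=tuple)


def synth_genome(spec: SyntheticGenomeSpec) -> list[NucSequence]:
    """Deterministic genome for a spec: same spec -> same sequences.

    Raises if planted footprints overlap one another or run off a contig.
    """
    if not 0 <= spec.gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    if spec.background not in ("random", "polyA"):
        raise ValueError("background must be 'random' or 'polyA'")
    rng = np.random.default_rng(spec.seed)
    p = np.array(
        [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
    )
    contigs: list[list[str]] = []
    for _ in range(spec.n_contigs):
        if spec.background == "polyA":
            contigs.append(["A"] * spec.contig_len)
        else:
            draw = rng.choice(4, size=spec.contig_len, p=p)
            contigs.append(list(_BASES[draw]))

    occupied: dict[int, list[tuple[int, int]]] = {}
    for site in spec.planted_sites:
        sys_spec = get_system(site.system)
        seq = site.footprint_seq(sys_spec)
        if not 0 <= site.contig < spec.n_contigs:
            raise ValueError(f"contig index {site.contig} out of range")
        a, b = site.position, site.position + len(seq)
        if a < 0 or b > spec.contig_len:
            raise ValueError(
                f"planted site [{a}, {b}) exceeds contig length "
                f"{spec.contig_len}"
            )
        for x, y in occupied.setdefault(site.contig, []):
            if a < y and x < b:
                raise ValueError(
                    f"planted sites overlap on contig {site.contig}: "
                    f"[{a},{b}) vs [{x},{y})"
                )
        occupied[site.contig].append((a, b))
        contigs[site.contig][a:b] = list(seq)

    return [
        NucSequence(f"synth_{i + 1}", "".join(c))
        for i, c in enumerate(contigs)
    ]
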