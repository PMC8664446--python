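"""Guide (spacer) representation, validation and cut/re-cleavage logic.

The re-cleavage test is the operational definition behind editable-genome
coverage: an edit "takes" only if the repaired allele can no longer be cut
by the same Cas–gRNA complex, which requires a mismatch in the PAM-proximal
seed window or a broken PAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .pam_scan import CasSystemSpec, PamSite
from .seq_core import matches_iupac, revcomp, NucSequence

__all__ = [
    "GuideTarget",
    "CutPrediction",
    "GuideIssue",
    "extract_guide",
    "predict_cut",
    "validate_guide",
    "is_recut_resistant",
    "UnusableSiteError",
]

BSAI_SITE = "GGTCTC"
BSAI_SITE_RC = "GAGACC"


class UnusableSiteError(ValueError):
    """Site cannot back a guide (e.g. protospacer truncated at contig edge)."""


@dataclass(frozen=True)
class GuideIssue:
    """One structured validation finding.

    ``severity`` is "warning" (design may proceed, surfaced to the user) or
    "error" (design must be rejected).
    """

    code: str  # POLYT | INTERNAL_BSAI | LENGTH
    severity: str
    message: str


@dataclass(frozen=True)
class GuideTarget:
    """A chosen target: spacer 5'→3' as transcribed plus the genomic PAM.

    ``locus`` optionally records where the protospacer sits in the genome:
    (seq_id, strand, protospacer_interval in plus-strand coordinates).
    """

    system: str
    spacer: str
    pam_seen: str
    locus: Optional[tuple[str, str, tuple[int, int]]] = None
    warnings: tuple[GuideIssue, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class CutPrediction:
    """Predicted strand-nick coordinates (plus-strand, half-open boundaries)."""

    top_strand_cut: int
    bottom_strand_cut: int

    @property
    def blunt(self) -> bool:
        return self.top_strand_cut == self.bottom_strand_cut


def extract_guide(
    genome: NucSequence, site: PamSite, system: CasSystemSpec
) -> GuideTarget:
    """Read the spacer and PAM for a scanned site, 5'→3' on the site strand.

    Minus-strand sites return the reverse complement of the plus-strand
    windows, so the spacer string is what the gRNA will carry.
    """
    if site.truncated:
        raise UnusableSiteError(
            f"site at {site.seq_id}:{site.pam_interval} is truncated at the "
            "contig edge and cannot back a full-length guide"
        )
    if site.system != system.name:
        raise ValueError(f"site is for {site.system}, not {system.name}")
    p0, p1 = site.protospacer_interval
    m0, m1 = site.pam_interval
    spacer = genome.seq[p0:p1]
    pam = genome.seq[m0:m1]
    if site.strand == "-":
        spacer, pam = revcomp(spacer), revcomp(pam)
    return GuideTarget(
        system=system.name,
        spacer=spacer,
        pam_seen=pam,
        locus=(site.seq_id, site.strand, (p0, p1)),
    )


def predict_cut(site: PamSite, system: CasSystemSpec) -> CutPrediction:
    """Cleavage boundaries from the system's cut offsets.

    Offsets are distances from the PAM-proximal protospacer end for the
    (protospacer-strand, opposite-strand) nicks: (3, 3) gives the Cas9s'
    blunt cut 3 bp from the PAM; (18, 23) gives Cas12a's staggered cut
    distal to the PAM.
    """
    if site.truncated:
        raise UnusableSiteError("cannot predict cut for a truncated site")
    if site.system != system.name:
        raise ValueError(f"site is for {site.system}, not {system.name}")
    p0, p1 = site.protospacer_interval
    pam_is_3prime_on_plus = (system.pam_side == "three_prime") == (
        site.strand == "+"
    )
    off_proto, off_other = system.cut_offsets
    if pam_is_3prime_on_plus:
        # PAM-proximal end is the protospacer's right edge on plus
        cuts = (p1 - off_proto, p1 - off_other)
    else:
        cuts = (p0 + off_proto, p0 + off_other)
    if site.strand == "+":
        top, bottom = cuts
    else:
        bottom, top = cuts
    return CutPrediction(top_strand_cut=top, bottom_strand_cut=bottom)


def validate_guide(guide: GuideTarget, vector) -> list[GuideIssue]:
    """Pre-flight checks of a spacer against a backbone vector.

    * POLYT (warning): a run of >= 4 T in the spacer as transcribed acts as
      an RNA-Pol-III terminator, so on the pSNR52 (Pol III) backbone the
      sgRNA may be truncated and editing efficiency drops sharply.  Pol II
      (pGAL1) backbones are unaffected.
    * INTERNAL_BSAI (error): the spacer carries a BsaI recognition site on
      either strand, which would be re-cut during Golden Gate Assembly and
      destroy directional cloning.
    * LENGTH (error): spacer length does not match the system.
    """
    from .oligo_design import VectorSpec  # local import to avoid a cycle
    from .pam_scan import get_system

    issues: list[GuideIssue] = []
    system = get_system(guide.system)
    if len(guide.spacer) != system.spacer_len:
        issues.append(
            GuideIssue(
                "LENGTH",
                "error",
                f"spacer is {len(guide.spacer)} nt; {system.name} expects "
                f"{system.spacer_len} nt",
            )
        )
    if isinstance(vector, VectorSpec) and vector.promoter_class == "polIII_SNR52":
        if "TTTT" in guide.spacer:
            issues.append(
                GuideIssue(
                    "POLYT",
                    "warning",
                    "spacer contains a T4 stretch; RNA polymerase III "
                    "(pSNR52) may pause or terminate within the sgRNA",
                )
            )
    if BSAI_SITE in guide.spacer or BSAI_SITE_RC in guide.spacer:
        issues.append(
            GuideIssue(
                "INTERNAL_BSAI",
                "error",
                "spacer contains a BsaI recognition site (GGTCTC/GAGACC); "
                "Golden Gate Assembly would re-cleave the insert",
            )
        )
    return issues


def _expected_window(guide: GuideTarget, system: CasSystemSpec) -> str:
    """The unedited protospacer+PAM window in guide orientation."""
    if system.pam_side == "three_prime":
        return guide.spacer + guide.pam_seen
    return guide.pam_seen + guide.spacer


def is_recut_resistant(
    edited_locus: str, guide: GuideTarget, system: CasSystemSpec
) -> bool:
    """Would the edited allele escape re-cleavage by this guide?

    ``edited_locus`` is the post-edit sequence read 5'→3' in the guide's
    orientation over the same span the protospacer+PAM occupied (spacer
    then PAM for the Cas9s; PAM then spacer for Cas12a).

    Resistant iff (a) the PAM no longer matches the PAM pattern, or (b) at
    least one mismatch to the original protospacer falls inside the
    PAM-proximal editable window (positions 1..editable_window_len from
    the PAM), or (c) an indel shifted the register (window longer than the
    protospacer+PAM span).  Mismatches confined to PAM-distal protospacer
    positions, or to degenerate PAM positions whose new base still fits the
    pattern, leave the site cleavable.
    """
    if guide.system != system.name:
        raise ValueError(f"guide is for {guide.system}, not {system.name}")
    expected = _expected_window(guide, system)
    window = edited_locus.upper()
    if len(window) < len(expected):
        raise ValueError(
            f"edited window ({len(window)} nt) shorter than protospacer+PAM "
            f"({len(expected)} nt)"
        )
    if len(window) > len(expected):
        return True  # rule (c): indel disrupts the register
    if system.pam_side == "three_prime":
        proto_new = window[: system.spacer_len]
        pam_new = window[system.spacer_len :]
        # protospacer index counted from the PAM: position 1 = last base
        dist_from_pam = lambda i: system.spacer_len - i  # noqa: E731
    else:
        pam_new = window[: system.pam_len]
        proto_new = window[system.pam_len :]
        dist_from_pam = lambda i: i + 1  # noqa: E731
    if not matches_iupac(system.pam, pam_new):
        return True  # rule (a)
    for i, (old, new) in enumerate(zip(guide.spacer, proto_new)):
        if old != new and dist_from_pam(i) <= system.editable_window_len:
            return True  # rule (b)
    return False
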