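"""HDR donor fragments for the three editing modes.

* insertion — a gene fragment (e.g. a fluorescent-protein ORF) dropped at a
  junction, flanked by 45-bp homology arms by default (the 15/25/35/45-bp
  arm-length series is supported for efficiency titrations);
* deletion — a 100-bp donor made of the 50-bp sequences flanking an ORF,
  fusing them to excise the ORF completely;
* point mutation — a fragment centered on the edited bases; the design is
  rejected outright if the edit would leave the locus re-cleavable by any
  of the guides used, since an edit that does not block re-cutting cannot
  be recovered.

All coordinates are 0-based half-open on the plus strand; donor
construction is strand-agnostic (minus-strand ORFs are handled by the
caller supplying the interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .guide_design import GuideTarget, is_recut_resistant
from .pam_scan import CasSystemSpec, get_system
from .seq_core import NucSequence, revcomp

__all__ = [
    "DonorDesign",
    "design_insertion_donor",
    "design_deletion_donor",
    "design_point_mutation_donor",
    "apply_donor",
    "recut_check_in_edited",
    "DonorDesignError",
    "RecutRejectedError",
]

DEFAULT_INSERTION_ARM_LEN = 45
DEFAULT_DELETION_ARM_LEN = 50
DEFAULT_POINT_MUTATION_ARM_LEN = 45
DEFAULT_TEMPLATE_ANNEAL_LEN = 20


class DonorDesignError(ValueError):
    """Donor construction contract violated (bounds, empty insert, ...)."""


class RecutRejectedError(DonorDesignError):
    """A point-mutation design whose edit does not block re-cleavage."""

    def __init__(self, failed_guides: list[str]):
        super().__init__(
            "edit leaves the locus cleavable by guide(s): "
            + ", ".join(failed_guides)
            + " (mutations must fall in the editable window or PAM; "
            "pass override=True to force)"
        )
        self.failed_guides = failed_guides


@dataclass(frozen=True)
class DonorDesign:
    """A donor fragment with its homology arms and amplification primers.

    ``payload_interval`` is the genomic span the payload replaces
    (zero-width for pure insertion); ``payload`` is what goes in between
    the arms, so simulated HDR is
    ``genome[:start] + payload + genome[end:]``.
    """

    mode: str  # insertion | deletion | point_mutation
    seq_id: str
    donor_seq: str
    up_arm: str
    down_arm: str
    arm_len: int
    payload: str
    payload_interval: tuple[int, int]
    fwd_primer: str
    rev_primer: str
    recut_checks: dict[str, bool] = field(default_factory=dict)
    override: bool = False

    def __post_init__(self) -> None:
        assert self.donor_seq.startswith(self.up_arm)
        assert self.donor_seq.endswith(self.down_arm)
        assert len(self.up_arm) == len(self.down_arm) == self.arm_len


def _arms(
    genome: NucSequence, start: int, end: int, arm_len: int
) -> tuple[str, str]:
    if arm_len <= 0:
        raise DonorDesignError("arm_len must be positive")
    if start - arm_len < 0 or end + arm_len > len(genome):
        raise DonorDesignError(
            f"homology arms [{start - arm_len}, {end + arm_len}) fall "
            f"outside contig {genome.id!r} of length {len(genome)}"
        )
    return (
        genome.seq[start - arm_len : start],
        genome.seq[end : end + arm_len],
    )


def design_insertion_donor(
    genome: NucSequence,
    insert: str,
    position: int,
    arm_len: int = DEFAULT_INSERTION_ARM_LEN,
    template_anneal_len: int = DEFAULT_TEMPLATE_ANNEAL_LEN,
) -> DonorDesign:
    """Donor = up_arm + insert + down_arm around the junction ``position``
    (the up arm ends immediately before it).

    The primers are arm-tailed: forward = up_arm + the insert's first
    ``template_anneal_len`` nt, reverse = revcomp(last
    ``template_anneal_len`` nt of the insert + down_arm), so PCR on the
    insert template yields the full donor.  In-frame placement for tag
    insertions is the caller's responsibility.
    """
    insert = insert.upper()
    if not insert:
        raise DonorDesignError("insert must be non-empty")
    if len(insert) < template_anneal_len:
        raise DonorDesignError(
            "insert shorter than template_anneal_len; primers would overlap"
        )
    up, down = _arms(genome, position, position, arm_len)
    return DonorDesign(
        mode="insertion",
        seq_id=genome.id,
        donor_seq=up + insert + down,
        up_arm=up,
        down_arm=down,
        arm_len=arm_len,
        payload=insert,
        payload_interval=(position, position),
        fwd_primer=up + insert[:template_anneal_len],
        rev_primer=revcomp(insert[-template_anneal_len:] + down),
    )


def design_deletion_donor(
    genome: NucSequence,
    orf_interval: tuple[int, int],
    arm_len: int = DEFAULT_DELETION_ARM_LEN,
) -> DonorDesign:
    """Donor fusing the ORF's flanking sequences (2 x arm_len, 100 bp by
    default); HDR with it excises [start, end) completely.

    Short enough to order as an annealed ODN duplex: the "primers" are the
    two full-length strands.
    """
    start, end = orf_interval
    if not 0 <= start <= end <= len(genome):
        raise DonorDesignError(
            f"ORF interval [{start}, {end}) invalid for contig of length "
            f"{len(genome)}"
        )
    up, down = _arms(genome, start, end, arm_len)
    donor = up + down
    return DonorDesign(
        mode="deletion",
        seq_id=genome.id,
        donor_seq=donor,
        up_arm=up,
        down_arm=down,
        arm_len=arm_len,
        payload="",
        payload_interval=(start, end),
        fwd_primer=donor,
        rev_primer=revcomp(donor),
    )


def design_point_mutation_donor(
    genome: NucSequence,
    edits: list[tuple[int, str]],
    guides: list[GuideTarget],
    arm_len: int = DEFAULT_POINT_MUTATION_ARM_LEN,
    override: bool = False,
) -> DonorDesign:
    """Donor centered on the edited bases with ``arm_len`` flanks.

    Every guide used to cut the locus is checked against the edited
    allele: if any guide could still cleave (all mutations outside its
    editable window and PAM intact), the design is rejected — a silent
    warning would produce unrecoverable experiments.  ``override=True``
    records the failing checks but returns the design anyway.
    """
    if not edits:
        raise DonorDesignError("edits must be non-empty")
    for pos, base in edits:
        if not 0 <= pos < len(genome):
            raise DonorDesignError(f"edit position {pos} outside contig")
        if base.upper() not in "ACGT":
            raise DonorDesignError(f"edit base {base!r} not in ACGT")
    positions = [p for p, _ in edits]
    lo, hi = min(positions), max(positions) + 1
    up, down = _arms(genome, lo, hi, arm_len)
    window = list(genome.seq[lo:hi])
    for pos, base in edits:
        window[pos - lo] = base.upper()
    payload = "".join(window)
    edited = NucSequence(
        genome.id, genome.seq[:lo] + payload + genome.seq[hi:]
    )
    recut_checks: dict[str, bool] = {}
    for guide in guides:
        key = f"{guide.system}:{guide.spacer}"
        recut_checks[key] = recut_check_in_edited(
            edited, (lo, hi), len(payload), guide
        )
    failed = [k for k, ok in recut_checks.items() if not ok]
    if failed and not override:
        raise RecutRejectedError(failed)
    return DonorDesign(
        mode="point_mutation",
        seq_id=genome.id,
        donor_seq=up + payload + down,
        up_arm=up,
        down_arm=down,
        arm_len=arm_len,
        payload=payload,
        payload_interval=(lo, hi),
        fwd_primer=up + payload + down,
        rev_primer=revcomp(up + payload + down),
        recut_checks=recut_checks,
        override=override,
    )


def apply_donor(genome: NucSequence, design: DonorDesign) -> NucSequence:
    """Simulated HDR: replace the genomic span between the arms with the
    donor payload.  Arms are checked against the genome before applying."""
    start, end = design.payload_interval
    if genome.id != design.seq_id:
        raise DonorDesignError(
            f"donor targets {design.seq_id!r}, not {genome.id!r}"
        )
    if genome.seq[start - design.arm_len : start] != design.up_arm:
        raise DonorDesignError("up arm does not match the genome")
    if genome.seq[end : end + design.arm_len] != design.down_arm:
        raise DonorDesignError("down arm does not match the genome")
    return NucSequence(
        genome.id, genome.seq[:start] + design.payload + genome.seq[end:]
    )


def _guide_footprint(
    guide: GuideTarget, system: CasSystemSpec
) -> tuple[int, int]:
    """Plus-strand protospacer+PAM interval from the guide's locus."""
    if guide.locus is None:
        raise ValueError("guide has no locus; cannot place it in the genome")
    _, strand, (p0, p1) = guide.locus
    pam_is_3prime_on_plus = (system.pam_side == "three_prime") == (
        strand == "+"
    )
    if pam_is_3prime_on_plus:
        return (p0, p1 + system.pam_len)
    return (p0 - system.pam_len, p1)


def recut_check_in_edited(
    edited: NucSequence,
    replaced_span: tuple[int, int],
    payload_len: int,
    guide: GuideTarget,
) -> bool:
    """Is the edited allele resistant to re-cleavage by ``guide``?

    Locates the guide's original protospacer+PAM footprint, shifts its
    coordinates by the edit's length change where it lies downstream of
    the replaced span, extracts the corresponding window from the edited
    contig in guide orientation, and applies the resistance rules.  A
    footprint that ran off the contig (e.g. after a large deletion near
    the end) counts as resistant — the site no longer exists.
    """
    system = get_system(guide.system)
    w0, _ = _guide_footprint(guide, system)
    a, b = replaced_span
    shift = payload_len - (b - a)
    if w0 >= b:
        w0 += shift
    # window length is fixed; re-anchor at the (possibly shifted) start
    expected_len = system.spacer_len + system.pam_len
    if w0 < 0 or w0 + expected_len > len(edited):
        return True
    window = edited.seq[w0 : w0 + expected_len]
    if guide.locus is not None and guide.locus[1] == "-":
        window = revcomp(window)
    return is_recut_resistant(window, guide, system)
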