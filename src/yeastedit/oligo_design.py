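"""Golden Gate ODN design for the four genome-editing backbone vectors.

Each backbone carries two BsaI sites whose digestion exposes two distinct
4-nt overhangs; a synthesized ODN pair annealing into a duplex with
matching 5' extensions drops the target-specific cassette in with defined
orientation.  For the three Cas9 backbones the cassette is a
target-compatible hammerhead ribozyme followed by the spacer (the spacer
sits 5' of the vector-resident sgRNA scaffold); the hammerhead's stem-I
antisense arm is the reverse complement of the spacer's first nucleotides,
so ribozyme self-cleavage leaves the spacer's first base as the transcript
5' end.  For the Cas12a backbone the cassette is the spacer alone (the
crRNA scaffold, U4AU4 9-mer and HDV ribozyme are vector-resident, and the
spacer sits 3' of the scaffold).

Overhangs, flanks, scaffolds and the hammerhead core are registry DATA,
not code; see :func:`load_registry`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .guide_design import (
    BSAI_SITE,
    BSAI_SITE_RC,
    GuideIssue,
    GuideTarget,
    validate_guide,
)
from .seq_core import revcomp

__all__ = [
    "VectorSpec",
    "VectorRegistry",
    "HammerheadDesign",
    "OligoPair",
    "AssemblyPrediction",
    "load_registry",
    "design_hammerhead",
    "design_oligos",
    "predict_assembled_insert",
    "recover_spacer",
    "DesignRejectedError",
    "AssemblyFailureError",
]

#: Default antisense-arm (stem I) length of the minimal hammerhead design.
HAMMERHEAD_ARM_LEN = 6


class DesignRejectedError(ValueError):
    """A requested design violates a hard constraint (e.g. internal BsaI)."""


class AssemblyFailureError(ValueError):
    """The predicted Golden Gate product retains a BsaI recognition site."""


@dataclass(frozen=True)
class VectorSpec:
    """Golden Gate context of one backbone vector.

    ``flank_left``/``flank_right`` are the vector plus-strand sequences
    immediately outside the BsaI-generated overhang positions, used to
    predict the assembled insert.  ``left_overhang`` coheres with the
    promoter-side vector end.
    """

    name: str
    system: str
    promoter_class: str  # polII_GAL1 | polIII_SNR52
    left_overhang: str
    right_overhang: str
    needs_hammerhead: bool
    insert_position: str  # spacer_5prime_of_scaffold | spacer_3prime_of_scaffold
    flank_left: str
    flank_right: str
    scaffold_seq: str
    scaffold_elements: tuple[str, ...]
    hammerhead_core: str | None = None
    hammerhead_arm_len: int = HAMMERHEAD_ARM_LEN

    def __post_init__(self) -> None:
        for oh in (self.left_overhang, self.right_overhang):
            if len(oh) != 4 or set(oh) - set("ACGT"):
                raise ValueError(f"{self.name}: overhang {oh!r} must be 4 nt ACGT")
        if self.left_overhang == self.right_overhang:
            raise ValueError(
                f"{self.name}: identical overhangs would make assembly "
                "non-directional"
            )
        if self.needs_hammerhead and not self.hammerhead_core:
            raise ValueError(f"{self.name}: hammerhead vector needs a core")
        expected_pos = (
            "spacer_3prime_of_scaffold"
            if self.system == "AsCas12a"
            else "spacer_5prime_of_scaffold"
        )
        if self.insert_position != expected_pos:
            raise ValueError(
                f"{self.name}: insert_position must be {expected_pos} for "
                f"{self.system}"
            )
        if self.needs_hammerhead != (self.system != "AsCas12a"):
            raise ValueError(
                f"{self.name}: hammerhead required iff system is a Cas9"
            )
        for label, s in (
            ("flank_left", self.flank_left),
            ("flank_right", self.flank_right),
        ):
            if BSAI_SITE in s or BSAI_SITE_RC in s:
                raise ValueError(
                    f"{self.name}: {label} retains a BsaI recognition site"
                )


@dataclass(frozen=True)
class VectorRegistry:
    """The set of known backbone vectors, keyed by short name."""

    version: str
    vectors: dict[str, VectorSpec]

    def get(self, name: str) -> VectorSpec:
        key = name.lower().replace("_", "-")
        aliases = {
            "sp-pgal1": "sp-gal1",
            "sp-psnr52": "sp-snr52",
            "sa-pgal1": "sa-gal1",
            "as12a-pgal1": "as12a",
            "as-12a": "as12a",
        }
        key = aliases.get(key, key)
        try:
            return self.vectors[key]
        except KeyError:
            raise KeyError(
                f"unknown vector {name!r}; valid: {sorted(self.vectors)}"
            ) from None


def load_registry(path: str | Path | None = None) -> VectorRegistry:
    """Load a vector registry from YAML.

    With no argument, loads the registry shipped with the package
    (``data/registry_synthetic.yaml`` — a synthetic stand-in for the
    authors' deposited vector files: element sequences that are canonical
    public parts are real, overhangs and flanks are representative
    invented data honoring every contract).  ``path`` may be the YAML file
    or a directory containing ``registry*.yaml``.
    """
    if path is None:
        src = resources.files("yeastedit").joinpath(
            "data/registry_synthetic.yaml"
        )
        raw = yaml.safe_load(src.read_text())
    else:
        p = Path(path)
        if p.is_dir():
            candidates = sorted(p.glob("registry*.yaml")) or sorted(
                p.glob("*.yaml")
            )
            if not candidates:
                raise FileNotFoundError(f"no registry YAML under {p}")
            p = candidates[0]
        raw = yaml.safe_load(p.read_text())
    vectors = {}
    for key, v in raw["vectors"].items():
        vectors[key] = VectorSpec(
            name=v["name"],
            system=v["system"],
            promoter_class=v["promoter_class"],
            left_overhang=v["left_overhang"].upper(),
            right_overhang=v["right_overhang"].upper(),
            needs_hammerhead=bool(v["needs_hammerhead"]),
            insert_position=v["insert_position"],
            flank_left=v["flank_left"].upper(),
            flank_right=v["flank_right"].upper(),
            scaffold_seq=v["scaffold_seq"].upper(),
            scaffold_elements=tuple(v["scaffold_elements"]),
            hammerhead_core=(
                v.get("hammerhead_core") or raw.get("hammerhead_core")
            )
            if v["needs_hammerhead"]
            else None,
            hammerhead_arm_len=int(
                v.get("hammerhead_arm_len", HAMMERHEAD_ARM_LEN)
            ),
        )
    return VectorRegistry(version=str(raw.get("registry_version", "0")), vectors=vectors)


@dataclass(frozen=True)
class HammerheadDesign:
    """A target-compatible hammerhead ribozyme (DNA-coded).

    ``antisense_arm`` (stem I) base-pairs with the spacer's first
    nucleotides on the nascent transcript; self-cleavage at the arm/spacer
    junction leaves the spacer's first base as the 5' end.
    """

    antisense_arm: str
    core_scaffold: str

    @property
    def full_seq(self) -> str:
        return self.antisense_arm + self.core_scaffold


def design_hammerhead(
    spacer: str, core_scaffold: str, arm_len: int = HAMMERHEAD_ARM_LEN
) -> HammerheadDesign:
    """Hammerhead whose stem-I arm is revcomp of the spacer's first
    ``arm_len`` nucleotides.  Deterministic."""
    spacer = spacer.upper()
    if len(spacer) < arm_len:
        raise ValueError(
            f"spacer ({len(spacer)} nt) shorter than hammerhead arm "
            f"({arm_len} nt)"
        )
    if not core_scaffold:
        raise ValueError("hammerhead core scaffold must be non-empty")
    return HammerheadDesign(
        antisense_arm=revcomp(spacer[:arm_len]),
        core_scaffold=core_scaffold.upper(),
    )


@dataclass(frozen=True)
class OligoPair:
    """The two 5'→3' ODN strands to order for one target/vector.

    Annealing leaves 4-nt 5' extensions equal to the vector's two
    overhangs; the duplex core carries no BsaI site on either strand.
    """

    top: str
    bottom: str
    duplex_core: str
    top_overhang: str
    bottom_overhang: str
    vector: str
    target_name: str
    warnings: tuple[GuideIssue, ...] = field(default_factory=tuple)

    def order_sheet(self) -> list[dict]:
        return [
            {
                "name": f"{self.target_name}_{self.vector}_top",
                "sequence": self.top,
                "length": len(self.top),
            },
            {
                "name": f"{self.target_name}_{self.vector}_bottom",
                "sequence": self.bottom,
                "length": len(self.bottom),
            },
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "target": self.target_name,
                "vector": self.vector,
                "oligos": self.order_sheet(),
                "warnings": [w.code for w in self.warnings],
            },
            indent=2,
        )


def _find_bsai(seq: str) -> int | None:
    for motif in (BSAI_SITE, BSAI_SITE_RC):
        i = seq.find(motif)
        if i != -1:
            return i
    return None


def design_oligos(
    guide: GuideTarget,
    vector: VectorSpec,
    target_name: str = "target",
) -> OligoPair:
    """Compute the ODN pair for Golden Gate Assembly on ``vector``.

    Cas9 backbones: duplex core = hammerhead (arm + core) + spacer.
    Cas12a backbone: duplex core = spacer.
    Hard failures (system/vector mismatch, BsaI inside the duplex core,
    validation errors) raise; validation warnings are carried through.
    """
    if guide.system != vector.system:
        raise ValueError(
            f"guide is for {guide.system} but vector {vector.name} hosts "
            f"{vector.system}"
        )
    issues = validate_guide(guide, vector)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise DesignRejectedError(
            "; ".join(f"{e.code}: {e.message}" for e in errors)
        )
    warnings = tuple(i for i in issues if i.severity == "warning")
    if vector.needs_hammerhead:
        hh = design_hammerhead(
            guide.spacer, vector.hammerhead_core, vector.hammerhead_arm_len
        )
        duplex_core = hh.full_seq + guide.spacer
    else:
        duplex_core = guide.spacer
    offset = _find_bsai(duplex_core)
    if offset is not None:
        raise DesignRejectedError(
            f"duplex core contains a BsaI recognition site at offset "
            f"{offset}; choose another target"
        )
    return OligoPair(
        top=vector.left_overhang + duplex_core,
        bottom=vector.right_overhang + revcomp(duplex_core),
        duplex_core=duplex_core,
        top_overhang=vector.left_overhang,
        bottom_overhang=vector.right_overhang,
        vector=vector.name,
        target_name=target_name,
        warnings=warnings,
    )


@dataclass(frozen=True)
class AssemblyPrediction:
    """In-silico Golden Gate product around the insert, plus the guide RNA
    predicted after ribozyme/terminator/tRNA processing (RNA alphabet)."""

    insert: str
    processed_rna: str


def predict_assembled_insert(
    pair: OligoPair, vector: VectorSpec
) -> AssemblyPrediction:
    """Assembled region = flank_left + ligated duplex + flank_right.

    Successful Golden Gate eliminates both BsaI sites; a residual
    recognition sequence in the product raises
    :class:`AssemblyFailureError`.  The processed RNA is spacer+scaffold
    for the Cas9 backbones (hammerhead trims the 5' end to the spacer's
    first base; HDV or the SUP4 terminator defines the 3' end) and
    scaffold+spacer for Cas12a (tRNA and HDV trimming).
    """
    if pair.vector != vector.name:
        raise ValueError(
            f"pair was designed for {pair.vector}, not {vector.name}"
        )
    insert = (
        vector.flank_left
        + pair.top_overhang
        + pair.duplex_core
        + revcomp(pair.bottom_overhang)
        + vector.flank_right
    )
    offset = _find_bsai(insert)
    if offset is not None:
        raise AssemblyFailureError(
            f"assembled product retains a BsaI recognition site at offset "
            f"{offset}"
        )
    spacer = _spacer_from_core(pair.duplex_core, vector)
    if vector.insert_position == "spacer_5prime_of_scaffold":
        rna = spacer + vector.scaffold_seq
    else:
        rna = vector.scaffold_seq + spacer
    return AssemblyPrediction(
        insert=insert, processed_rna=rna.replace("T", "U")
    )


def _spacer_from_core(duplex_core: str, vector: VectorSpec) -> str:
    if vector.needs_hammerhead:
        prefix = vector.hammerhead_arm_len + len(vector.hammerhead_core)
        spacer = duplex_core[prefix:]
        if revcomp(spacer[: vector.hammerhead_arm_len]) != duplex_core[
            : vector.hammerhead_arm_len
        ]:
            raise ValueError(
                "duplex core is not a hammerhead+spacer cassette for "
                f"{vector.name}"
            )
        return spacer
    return duplex_core


def recover_spacer(insert: str, vector: VectorSpec) -> str:
    """Parse the spacer back out of a predicted assembled insert.

    Inverse of design+assembly; raises if the insert does not carry the
    vector's flanks and overhang scars where expected.
    """
    prefix = vector.flank_left + vector.left_overhang
    suffix = revcomp(vector.right_overhang) + vector.flank_right
    if not insert.startswith(prefix) or not insert.endswith(suffix):
        raise ValueError(
            f"insert does not match the {vector.name} assembly layout"
        )
    duplex_core = insert[len(prefix) : len(insert) - len(suffix)]
    return _spacer_from_core(duplex_core, vector)
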