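"""Locate or download the S288C R64-2-1 reference genome.

The published editable-fraction numbers are computed on the S288C
reference genome, release R64-2-1, nuclear sequences only (mitochondrial
genome and the 2-micron plasmid excluded).  The archive is ~12 MB and is
not bundled; :func:`fetch_reference_genome` downloads and unpacks it once,
and :func:`locate_reference_genome` finds an existing copy in the standard
cache locations.
"""

from __future__ import annotations

import gzip
import shutil
import tarfile
import urllib.request
from pathlib import Path

R64_URL = (
    "http://sgd-archive.yeastgenome.org/sequence/S288C_reference/"
    "genome_releases/S288C_reference_genome_R64-2-1_20150113.tgz"
)
FSA_NAME = "S288C_reference_sequence_R64-2-1_20150113.fsa"

#: Header substrings identifying non-nuclear sequences in the R64-2-1
#: reference FASTA (mitochondrion; the archive's reference_sequence file
#: carries no 2-micron record, but the token is listed for safety).
NON_NUCLEAR_TOKENS = ("mitochondrion", "chrmt", "NC_001224", "2-micron", "2micron")

_SEARCH_DIRS = (
    Path("scratch/reference"),
    Path.home() / ".cache" / "yeastedit",
)


def locate_reference_genome() -> Path | None:
    """Return the path of a cached R64-2-1 reference FASTA, if any."""
    for d in _SEARCH_DIRS:
        p = d / FSA_NAME
        if p.exists():
            return p
    return None


def fetch_reference_genome(dest: str | Path | None = None) -> Path:
    """Download and unpack the reference genome; returns the FASTA path.

    Requires network access.  ``dest`` defaults to the user cache
    directory.
    """
    dest_dir = Path(dest) if dest else _SEARCH_DIRS[-1]
    dest_dir.mkdir(parents=True, exist_ok=True)
    out = dest_dir / FSA_NAME
    if out.exists():
        return out
    tgz = dest_dir / "S288C_reference_genome_R64-2-1_20150113.tgz"
    urllib.request.urlretrieve(R64_URL, tgz)
    with tarfile.open(tgz) as tar:
        member = next(
            m for m in tar.getmembers() if m.name.endswith(FSA_NAME + ".gz")
        )
        tar.extract(member, dest_dir, filter="data")
        gz_path = dest_dir / member.name
    with gzip.open(gz_path, "rb") as fin, open(out, "wb") as fout:
        shutil.copyfileobj(fin, fout)
    return out
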