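"""File formats, run configuration, and manifests.

Plain-text formats throughout: FASTQ (optionally gzipped) in, FASTA plus a
TSV sidecar for references, TSV tables out, JSON run manifests, YAML
configuration. All writers are deterministic so that identical inputs give
byte-identical outputs (timestamps excluded from manifest comparisons).
"""

from __future__ import annotations

import gzip
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pandas as pd
import yaml
from Bio import SeqIO

from .readprep import ReadRecord

__all__ = [
    "RunConfig",
    "ReferenceRegion",
    "FastqFormatError",
    "read_fastq",
    "write_fastq",
    "write_table",
    "read_table",
    "load_references",
    "run_manifest",
    "write_manifest",
]

_VERSION = "0.1.0"


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ records, naming the offending line."""


@dataclass
class RunConfig:
    """Parameters shared across pipeline stages.

    Thresholds follow the analysis defaults used throughout the package:
    per-position interface calls use ``interface_threshold`` (score strictly
    above flags a residue as interface, default 0.1) and barcode outliers
    are removed at ``|z| > z_threshold`` (default 2.0; tighter values such
    as 0.5 or 0.25 further shrink the SD and are worth exploring for
    small replicate sets).
    """

    seed: int = 0
    label_t0: str = "T0"
    label_tf: str = "TF"
    reference_fasta: Optional[str] = None
    reference_sidecar: Optional[str] = None
    umi_offset: int = 0
    umi_length: int = 10
    barcode_length: int = 0
    dephaser_anchor: str = "TATGGC"
    max_phase: int = 7
    min_base_quality: int = 20
    max_frac_below: float = 0.1
    pseudocount: float = 0.5
    z_threshold: float = 2.0
    interface_threshold: float = 0.1
    min_t0_count: int = 1
    min_substitutions: int = 3

    def __post_init__(self) -> None:
        import math

        if self.umi_offset < 0 or self.umi_length < 0 or self.barcode_length < 0:
            raise ValueError("UMI/barcode spec must be non-negative")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if not self.z_threshold > 0:
            raise ValueError("z_threshold must be positive")
        if not 0 <= self.interface_threshold <= 1:
            raise ValueError("interface_threshold must lie in [0, 1]")
        if self.min_t0_count < 0:
            raise ValueError("min_t0_count must be >= 0")
        for name in ("pseudocount", "z_threshold", "interface_threshold",
                     "max_frac_below"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if set(self.dephaser_anchor) - set("ACGT"):
            raise ValueError("dephaser_anchor must be an ACGT string")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass(frozen=True)
class ReferenceRegion:
    """A sequenced region of the target protein.

    ``sequence`` is the nucleotide reference for the payload span (after
    the region's 5' anchor). ``frame_offset`` bases precede the first full
    codon; ``first_residue`` is the 1-based protein number of that codon.
    """

    name: str
    sequence: str
    frame_offset: int
    first_residue: int
    anchor5: str
    anchor3: str = ""

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"region {self.name!r}: non-ACGT reference")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"region {self.name!r}: frame_offset must be 0..2")
        if self.first_residue < 1:
            raise ValueError(f"region {self.name!r}: first_residue must be >= 1")
        if (len(self.sequence) - self.frame_offset) % 3 != 0:
            raise ValueError(
                f"region {self.name!r}: coding span not a multiple of 3"
            )
        if not self.anchor5:
            raise ValueError(f"region {self.name!r}: empty 5' anchor")

    @property
    def coding(self) -> str:
        return self.sequence[self.frame_offset :]

    @property
    def n_residues(self) -> int:
        return len(self.coding) // 3

    @property
    def residue_range(self) -> range:
        """1-based residue numbers covered, as a half-open range."""
        return range(self.first_residue, self.first_residue + self.n_residues)


def _open_text(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: Union[str, Path]) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a FASTQ or gzipped FASTQ file.

    Sequences are uppercased and qualities Phred+33 decoded. Malformed or
    truncated records raise :class:`FastqFormatError` naming the line.
    """
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise FastqFormatError(
                    f"{path}: line {lineno}: expected '@' header, got "
                    f"{header.strip()!r}"
                )
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FastqFormatError(
                    f"{path}: truncated record starting at line {lineno}"
                )
            lineno += 3
            seq = seq.strip()
            qual = qual.strip()
            if not plus.startswith("+"):
                raise FastqFormatError(
                    f"{path}: line {lineno - 1}: expected '+' separator"
                )
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"{path}: line {lineno}: quality length differs from "
                    f"sequence length"
                )
            yield ReadRecord(
                id=header[1:].strip().split()[0] if header[1:].strip() else "",
                sequence=seq.upper(),
                qualities=[ord(c) - 33 for c in qual],
            )


def write_fastq(
    records: Iterable[tuple[str, str, Sequence[int]]], path: Union[str, Path]
) -> int:
    """Write (id, sequence, qualities) tuples as FASTQ; returns the count."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as fh:
        for rid, seq, quals in records:
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")
            n += 1
    return n


def write_table(records, path: Union[str, Path]) -> None:
    """Write tabular results as TSV with a header.

    Accepts a DataFrame or a list of dicts/dataclasses sharing one schema.
    Column order is the schema order; floats are rendered with 6
    significant digits so round-trips are lossless at that precision.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [asdict(r) if hasattr(r, "__dataclass_fields__") else dict(r)
                for r in records]
        if rows:
            schema = list(rows[0])
            for i, r in enumerate(rows[1:], start=2):
                if list(r) != schema:
                    raise ValueError(f"record {i} does not match the schema")
            df = pd.DataFrame(rows, columns=schema)
        else:
            df = pd.DataFrame()
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_references(
    fasta: Union[str, Path], sidecar: Union[str, Path]
) -> list[ReferenceRegion]:
    """Load reference regions from FASTA plus a TSV sidecar.

    Sidecar columns: name, frame_offset, first_residue, anchor5, anchor3
    (anchor3 may be empty). 5' anchors must be unique across regions; a
    shared anchor would make payload assignment ambiguous and is rejected
    at load time.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    side = pd.read_csv(sidecar, sep="\t", dtype=str).fillna("")
    regions = []
    for _, row in side.iterrows():
        name = row["name"]
        if name not in seqs:
            raise ValueError(f"sidecar region {name!r} missing from FASTA")
        regions.append(
            ReferenceRegion(
                name=name,
                sequence=seqs[name],
                frame_offset=int(row["frame_offset"]),
                first_residue=int(row["first_residue"]),
                anchor5=row["anchor5"],
                anchor3=row.get("anchor3", ""),
            )
        )
    anchors = [r.anchor5 for r in regions]
    if len(set(anchors)) != len(anchors):
        raise ValueError("reference regions share a 5' anchor; must be unique")
    return regions


def _checksum(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_manifest(
    config: RunConfig,
    inputs: Sequence[Union[str, Path]] = (),
    stage_counts: Optional[dict] = None,
) -> dict:
    """Build a JSON-able provenance record for a completed stage.

    Missing input files raise before any checksum is recorded, so a
    manifest never describes a run that could not have happened.
    """
    for p in inputs:
        if not Path(p).exists():
            raise FileNotFoundError(f"manifest input missing: {p}")
    return {
        "tool": "b2hquant",
        "version": _VERSION,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "inputs": {str(p): _checksum(p) for p in inputs},
        "stage_counts": dict(stage_counts or {}),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }


def write_manifest(manifest: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
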