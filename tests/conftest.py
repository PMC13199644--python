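import numpy as np
import pandas as pd
import pytest

from b2hquant.io import ReferenceRegion
from b2hquant.readprep import ReadRecord


@pytest.fixture
def write_fastq_text(tmp_path):
    """Write literal FASTQ text and return its path."""

    def _write(text: str, name: str = "reads.fastq"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def make_read(seq: str, rid: str = "r1", q: int = 40, umi=None) -> ReadRecord:
    rec = ReadRecord(id=rid, sequence=seq, qualities=[q] * len(seq))
    if umi is not None:
        rec.umi = umi
    return rec


@pytest.fixture
def toy_region() -> ReferenceRegion:
    # codes MKLV starting at residue 1
    return ReferenceRegion(
        name="r1",
        sequence="ATGAAACTGGTG",
        frame_offset=0,
        first_residue=1,
        anchor5="GGTACC",
    )


@pytest.fixture
def flat_counts() -> pd.DataFrame:
    """Count table where every variant's counts are unchanged T0 -> TF."""
    rows = [
        ("wt", None, None, None, 50, 50),
        ("synonymous", None, None, None, 30, 30),
        ("single_missense", 5, "K", "R", 40, 40),
        ("single_missense", 7, "L", "A", 25, 25),
    ]
    return pd.DataFrame(
        [
            {
                "region": "r1", "klass": k, "position": p, "ref_aa": ra,
                "alt_aa": aa, "codon": None, "barcode": "",
                "c_before": b, "c_after": a,
            }
            for k, p, ra, aa, b, a in rows
        ]
    )
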