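"""Raw-read preparation for growth-coupled selection sequencing.

Amplicon reads from low-complexity peptide libraries carry, in order: a
variable-length dephaser prefix (staggers base composition on the
sequencer), a constant anchor, a unique molecular identifier (UMI), an
optional clone barcode, and the payload to be matched against a reference.
This module turns raw reads into deduplicated payload counts:

    trim_dephaser -> extract_umi -> [extract_barcode] -> quality_filter
        -> dedupe_umis

All offsets into reads are 0-based half-open.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "ReadRecord",
    "UmiGroup",
    "trim_dephaser",
    "extract_umi",
    "extract_barcode",
    "quality_filter",
    "dedupe_umis",
    "payload_counts",
]


@dataclass
class ReadRecord:
    """One sequencing read and the features extracted from it.

    ``payload`` starts life equal to ``sequence`` and shrinks as the
    dephaser/anchor, UMI and barcode are peeled off; ``payload_qualities``
    tracks it base-for-base. ``status`` is ``"ok"`` or a reject reason code
    (``no_anchor``, ``short_umi``, ``short_barcode``, ``low_quality``).
    """

    id: str
    sequence: str
    qualities: Sequence[int]
    dephaser_len: Optional[int] = None
    umi: Optional[str] = None
    barcode: Optional[str] = None
    payload: str = ""
    payload_qualities: Sequence[int] = field(default_factory=list)
    status: str = "ok"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence and quality lengths differ"
            )
        if not self.payload:
            self.payload = self.sequence
            self.payload_qualities = list(self.qualities)

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass(frozen=True)
class UmiGroup:
    """A deduplicated molecule: one (UMI, barcode, payload) identity.

    ``reads`` is the number of raw reads collapsed into the group; each
    group contributes exactly 1 to deduplicated counts. ``barcode`` is ""
    for unbarcoded libraries.
    """

    umi: str
    payload: str
    reads: int
    barcode: str = ""

    def __post_init__(self) -> None:
        if self.reads < 1:
            raise ValueError("a UMI group holds at least one read")


def trim_dephaser(read: ReadRecord, anchor: str, max_phase: int) -> ReadRecord:
    """Locate the constant anchor after the dephaser and trim both off.

    The anchor must occur exactly (no mismatches) starting at a position in
    ``[0, max_phase]``. Reads where it does not are flagged ``no_anchor``
    rather than raising: dropped reads are a normal part of the data.
    """
    if not anchor:
        raise ValueError("anchor must be non-empty")
    if max_phase < 0:
        raise ValueError("max_phase must be >= 0")
    if not read.ok:
        return read
    idx = read.payload.find(anchor, 0, max_phase + len(anchor))
    if idx == -1:
        return replace(read, status="no_anchor")
    start = idx + len(anchor)
    return replace(
        read,
        dephaser_len=idx,
        payload=read.payload[start:],
        payload_qualities=list(read.payload_qualities[start:]),
    )


def _extract_slice(read: ReadRecord, offset: int, length: int, which: str) -> ReadRecord:
    if offset < 0 or length < 0:
        raise ValueError("offset and length must be >= 0")
    if not read.ok:
        return read
    if len(read.payload) < offset + length:
        return replace(read, status=f"short_{which}")
    tag = read.payload[offset : offset + length]
    payload = read.payload[:offset] + read.payload[offset + length :]
    quals = list(read.payload_qualities[:offset]) + list(
        read.payload_qualities[offset + length :]
    )
    kwargs = {which: tag}
    return replace(read, payload=payload, payload_qualities=quals, **kwargs)


def extract_umi(read: ReadRecord, offset: int, length: int) -> ReadRecord:
    """Cut the UMI out of the payload; too-short payloads are flagged."""
    return _extract_slice(read, offset, length, "umi")


def extract_barcode(read: ReadRecord, offset: int, length: int) -> ReadRecord:
    """Cut a clone barcode out of the payload (same slicing rule as UMIs)."""
    return _extract_slice(read, offset, length, "barcode")


def quality_filter(read: ReadRecord, min_q: int, max_frac_below: float) -> bool:
    """Keep a read unless too many payload bases fall below ``min_q``.

    Returns True (keep) iff the fraction of payload bases with quality
    strictly below ``min_q`` is <= ``max_frac_below`` (strict inequality
    drops; a read exactly at the limit is kept). Empty payloads are kept.
    """
    quals = read.payload_qualities
    if not len(quals):
        return True
    frac = sum(1 for q in quals if q < min_q) / len(quals)
    return not frac > max_frac_below


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    seen = False
    for x, y in zip(a, b):
        if x != y:
            if seen:
                return False
            seen = True
    return seen


def dedupe_umis(
    reads: Iterable[ReadRecord], merge_hamming1: bool = False
) -> list[UmiGroup]:
    """Collapse reads into molecules keyed by (UMI, payload).

    With ``merge_hamming1``, the directional rule absorbs a group into
    another with identical payload whose UMI is at Hamming distance 1 and
    whose read count is at least twice the child's — conservative
    sequencing-error correction on the UMI itself. Single pass, largest
    parents first; off by default.

    Output order is deterministic (payload, then read count descending,
    then UMI) regardless of input order.
    """
    counts: Counter[tuple[str, str, str]] = Counter()
    for read in reads:
        if read.umi is None:
            raise ValueError(f"read {read.id!r} has no UMI; extract_umi first")
        counts[(read.umi, read.barcode or "", read.payload)] += 1

    by_payload: dict[tuple[str, str], dict[str, int]] = {}
    for (umi, barcode, payload), n in counts.items():
        by_payload.setdefault((barcode, payload), {})[umi] = n

    groups: list[UmiGroup] = []
    for barcode, payload in sorted(by_payload):
        umis = by_payload[(barcode, payload)]
        if merge_hamming1 and len(umis) > 1:
            # visit children smallest-first so merges feed the big groups
            order = sorted(umis, key=lambda u: (umis[u], u))
            parents = sorted(umis, key=lambda u: (-umis[u], u))
            merged: dict[str, str] = {}
            for child in order:
                for parent in parents:
                    if parent == child or parent in merged:
                        continue
                    if umis[parent] >= 2 * umis[child] and _hamming1(parent, child):
                        merged[child] = parent
                        break
            for child, parent in merged.items():
                umis[parent] += umis.pop(child)
        for umi in sorted(umis, key=lambda u: (-umis[u], u)):
            groups.append(
                UmiGroup(umi=umi, payload=payload, reads=umis[umi], barcode=barcode)
            )
    return groups


def payload_counts(
    groups: Iterable[UmiGroup], by_barcode: bool = False
) -> pd.Series:
    """Deduplicated molecule count per payload (each group counts once).

    With ``by_barcode`` the index is (barcode, payload) tuples.
    """
    tally: Counter = Counter()
    for g in groups:
        key = (g.barcode, g.payload) if by_barcode else g.payload
        tally[key] += 1
    return pd.Series(tally, dtype="int64").sort_index()
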