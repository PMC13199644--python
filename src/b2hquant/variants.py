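"""Codon-level variant calling against reference regions.

Deduplicated payloads are assigned to a region by its unique 5' anchor,
compared codon-by-codon to the reference after the frame offset, and
classified as wt / synonymous / single_missense / multi / indel /
unassigned. Counts from regions covering disjoint residue ranges of the
same target are then assembled into one protein-wide table.

Protein positions are 1-based throughout; the standard genetic code is
used with no ambiguity codes (any non-ACGT base makes a read unassigned).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .io import ReferenceRegion
from .readprep import UmiGroup

__all__ = [
    "VariantCall",
    "CLASSES",
    "ENRICHABLE_CLASSES",
    "match_region",
    "call_variant",
    "call_payload",
    "count_variants",
    "counts_to_table",
    "assemble_regions",
    "class_summary",
    "call_groups",
]

CLASSES = ("wt", "synonymous", "single_missense", "multi", "indel", "unassigned")
#: classes that enter enrichment; multi/indel/unassigned are tallied apart
ENRICHABLE_CLASSES = ("wt", "synonymous", "single_missense")


@dataclass(frozen=True)
class VariantCall:
    """Classification of one payload against one reference region."""

    region: str
    klass: str
    position: Optional[int] = None  # 1-based protein numbering
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    codon: Optional[str] = None
    barcode: str = ""

    @property
    def variant_id(self) -> str:
        if self.klass == "single_missense":
            return f"{self.ref_aa}{self.position}{self.alt_aa}"
        return self.klass


def _translate(nt: str) -> str:
    return str(Seq(nt).translate())


def match_region(
    payload: str, references: Sequence[ReferenceRegion]
) -> tuple[Optional[ReferenceRegion], str]:
    """Assign a payload to the region whose 5' anchor prefixes it.

    Returns (region, payload-with-anchors-stripped); (None, payload) when
    no anchor matches. The 3' anchor, when configured, is stripped if
    present at the end.
    """
    for region in references:
        if payload.startswith(region.anchor5):
            trimmed = payload[len(region.anchor5) :]
            if region.anchor3 and trimmed.endswith(region.anchor3):
                trimmed = trimmed[: -len(region.anchor3)]
            return region, trimmed
    return None, payload


def call_variant(payload: str, region: ReferenceRegion, barcode: str = "") -> VariantCall:
    """Classify a gap-free payload against its region reference.

    Length mismatches are treated as indels (amplicons fully cover each
    region, so a partial read is rejected rather than partially called).
    """
    if set(payload) - set("ACGT"):
        return VariantCall(region=region.name, klass="unassigned", barcode=barcode)
    if len(payload) != len(region.sequence):
        return VariantCall(region=region.name, klass="indel", barcode=barcode)
    if payload == region.sequence:
        return VariantCall(region=region.name, klass="wt", barcode=barcode)

    ref_coding = region.coding
    alt_coding = payload[region.frame_offset :]
    aa_diffs: list[tuple[int, str, str, str]] = []  # codon idx, ref, alt, alt codon
    for i in range(0, len(ref_coding), 3):
        rc, ac = ref_coding[i : i + 3], alt_coding[i : i + 3]
        if rc != ac:
            ra, aa = _translate(rc), _translate(ac)
            if ra != aa:
                aa_diffs.append((i // 3, ra, aa, ac))

    if not aa_diffs:
        return VariantCall(region=region.name, klass="synonymous", barcode=barcode)
    if len(aa_diffs) == 1:
        idx, ref_aa, alt_aa, codon = aa_diffs[0]
        return VariantCall(
            region=region.name,
            klass="single_missense",
            position=region.first_residue + idx,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            codon=codon,
            barcode=barcode,
        )
    return VariantCall(region=region.name, klass="multi", barcode=barcode)


def call_payload(
    payload: str, references: Sequence[ReferenceRegion], barcode: str = ""
) -> VariantCall:
    """match_region + call_variant; unmatched payloads come back unassigned."""
    region, trimmed = match_region(payload, references)
    if region is None:
        return VariantCall(region="", klass="unassigned", barcode=barcode)
    return call_variant(trimmed, region, barcode=barcode)


def count_variants(
    calls: Iterable[tuple[VariantCall, int]] | Iterable[VariantCall],
    sample: str,
    codon_level: bool = False,
) -> pd.DataFrame:
    """Tally calls (optionally weighted) into a per-sample count table.

    ``calls`` may be VariantCalls or (call, count) pairs. Missense identity
    pools codons encoding the same amino acid unless ``codon_level``.
    Columns: region, klass, position, ref_aa, alt_aa, codon, barcode,
    sample, count. All classes appear; downstream enrichment keeps only
    wt/synonymous/single_missense rows.
    """
    tally: Counter[tuple] = Counter()
    for item in calls:
        call, n = item if isinstance(item, tuple) else (item, 1)
        codon = call.codon if codon_level else None
        key = (call.region, call.klass, call.position, call.ref_aa,
               call.alt_aa, codon, call.barcode)
        tally[key] += n
    rows = [
        {
            "region": k[0], "klass": k[1], "position": k[2], "ref_aa": k[3],
            "alt_aa": k[4], "codon": k[5], "barcode": k[6],
            "sample": sample, "count": n,
        }
        for k, n in sorted(tally.items(), key=lambda kv: tuple(map(str, kv[0])))
    ]
    return pd.DataFrame(
        rows,
        columns=["region", "klass", "position", "ref_aa", "alt_aa", "codon",
                 "barcode", "sample", "count"],
    )


_KEY = ["region", "klass", "position", "ref_aa", "alt_aa", "codon", "barcode"]


def counts_to_table(counts_t0: pd.DataFrame, counts_tf: pd.DataFrame) -> pd.DataFrame:
    """Merge before/after count tables into rows with c_before / c_after.

    Variants absent from one sample get a zero count there.
    """
    t0 = counts_t0.drop(columns="sample").rename(columns={"count": "c_before"})
    tf = counts_tf.drop(columns="sample").rename(columns={"count": "c_after"})
    # harmonize key dtypes: a sample may have e.g. only positionless rows
    t0[_KEY] = t0[_KEY].astype(object)
    tf[_KEY] = tf[_KEY].astype(object)
    merged = t0.merge(tf, how="outer", on=_KEY)
    merged[["c_before", "c_after"]] = (
        merged[["c_before", "c_after"]].fillna(0).astype("int64")
    )
    return merged.sort_values(_KEY, key=lambda s: s.astype(str)).reset_index(drop=True)


def assemble_regions(
    tables: Sequence[pd.DataFrame], regions: Sequence[ReferenceRegion]
) -> pd.DataFrame:
    """Union per-region tables into one protein-wide table.

    Positions are already in global 1-based numbering (each region knows
    its first residue), so assembly is a provenance-keeping concatenation
    after verifying that the residue ranges are disjoint.
    """
    covered: set[int] = set()
    for region in regions:
        rng = set(region.residue_range)
        if covered & rng:
            raise ValueError(
                f"region {region.name!r} overlaps residues already covered"
            )
        covered |= rng
    if not tables:
        return pd.DataFrame()
    out = pd.concat(tables, ignore_index=True)
    return out.sort_values(
        [c for c in _KEY if c in out.columns], key=lambda s: s.astype(str)
    ).reset_index(drop=True)


def class_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-class total counts (conservation check against input groups)."""
    return (
        counts.groupby("klass", dropna=False)["count"]
        .sum()
        .reindex(CLASSES, fill_value=0)
        .rename_axis("klass")
        .reset_index()
    )


def call_groups(
    groups: Iterable[UmiGroup], references: Sequence[ReferenceRegion]
) -> list[tuple[VariantCall, int]]:
    """Call every deduplicated molecule; caches by payload for speed."""
    cache: dict[str, VariantCall] = {}
    out = []
    for g in groups:
        base = cache.get(g.payload)
        if base is None:
            base = call_payload(g.payload, references)
            cache[g.payload] = base
        call = base if base.barcode == g.barcode else VariantCall(
            region=base.region, klass=base.klass, position=base.position,
            ref_aa=base.ref_aa, alt_aa=base.alt_aa, codon=base.codon,
            barcode=g.barcode,
        )
        out.append((call, 1))
    return out
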