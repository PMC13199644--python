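"""End-to-end convenience wrappers: FASTQ -> counts -> enrichment -> scores."""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from . import readprep
from .enrichment import enrich_table
from .interface import perturbation_profile
from .io import ReferenceRegion, RunConfig, read_fastq
from .variants import assemble_regions, call_groups, count_variants, counts_to_table

__all__ = ["prepare_reads", "count_sample", "run_enrichment_pipeline"]


def prepare_reads(
    fastq: Union[str, Path], config: RunConfig
) -> tuple[list[readprep.UmiGroup], pd.DataFrame]:
    """Dephaser/UMI/barcode extraction, quality filter, UMI dedup.

    Returns (deduplicated molecule groups, reject tally with reason codes).
    """
    rejects: Counter[str] = Counter()
    kept: list[readprep.ReadRecord] = []
    for read in read_fastq(fastq):
        read = readprep.trim_dephaser(read, config.dephaser_anchor,
                                      config.max_phase)
        read = readprep.extract_umi(read, config.umi_offset, config.umi_length)
        if config.barcode_length:
            read = readprep.extract_barcode(read, 0, config.barcode_length)
        if not read.ok:
            rejects[read.status] += 1
            continue
        if not readprep.quality_filter(read, config.min_base_quality,
                                       config.max_frac_below):
            rejects["low_quality"] += 1
            continue
        kept.append(read)
    groups = readprep.dedupe_umis(kept)
    reject_df = pd.DataFrame(
        sorted(rejects.items()), columns=["reason", "reads"]
    )
    return groups, reject_df


def count_sample(
    fastq: Union[str, Path],
    references: Sequence[ReferenceRegion],
    config: RunConfig,
    sample: str,
) -> pd.DataFrame:
    """Deduplicated variant counts for one sample's FASTQ."""
    groups, _ = prepare_reads(fastq, config)
    calls = call_groups(groups, references)
    return count_variants(calls, sample)


def run_enrichment_pipeline(
    t0_fastq: Union[str, Path],
    tf_fastq: Union[str, Path],
    references: Sequence[ReferenceRegion],
    config: RunConfig,
) -> dict[str, pd.DataFrame]:
    """Full stack: reads in, enrichment table and perturbation profile out."""
    counts_t0 = count_sample(t0_fastq, references, config, config.label_t0)
    counts_tf = count_sample(tf_fastq, references, config, config.label_tf)
    table = counts_to_table(counts_t0, counts_tf)
    table = assemble_regions([table], references)
    enriched = enrich_table(table, pseudocount=config.pseudocount,
                            min_t0_count=config.min_t0_count)
    profile = perturbation_profile(
        enriched,
        min_substitutions=config.min_substitutions,
        threshold=config.interface_threshold,
    )
    return {"counts": table, "enrichment": enriched, "profile": profile}
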