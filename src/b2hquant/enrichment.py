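"""Wild-type-normalized enrichment and barcode replicate statistics.

For each variant i the enrichment under selection is

    E_i = (c_i^after / c_i^before) / Ẽ_wt

where Ẽ_wt is the median enrichment over wild-type and synonymous
sequences (E_wtx = c_wtx^after / c_wtx^before). E_i = 1 means the
variant's population frequency behaved exactly like wild type across
selection; E_i > 1 marks enrichment (gain of fitness / binding) and
E_i < 1 depletion. Barcoded clone replicates additionally yield an
absolute enrichment E_abs (frequency ratio), z-score outlier flags, and
a coefficient of variation used as a stochasticity proxy.

Zero counts: a pseudocount p (default 0.5) is added to BOTH counts of a
ratio only when either is zero; ratios of nonzero counts are untouched.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .variants import ENRICHABLE_CLASSES

__all__ = [
    "BarcodeStats",
    "OutlierResult",
    "ratio_with_pseudocount",
    "wt_enrichment",
    "median_wt",
    "enrichment",
    "absolute_enrichment",
    "remove_outliers",
    "barcode_stats",
    "enrich_table",
    "barcode_table_stats",
]


@dataclass(frozen=True)
class BarcodeStats:
    """Replicate-barcode summary for one peptide/clone."""

    peptide: str
    n_total: int
    n_retained: int
    mean: float
    sd: float
    cv_percent: float  # 100 * sd / mean


@dataclass(frozen=True)
class OutlierResult:
    retained: list
    removed: list
    z: list
    notice: Optional[str] = None


def ratio_with_pseudocount(c_after: float, c_before: float, pseudocount: float) -> float:
    """after/before ratio, padding both counts with p only on a zero."""
    if c_after < 0 or c_before < 0:
        raise ValueError("counts must be >= 0")
    if c_after == 0 or c_before == 0:
        c_after += pseudocount
        c_before += pseudocount
    if c_before == 0:
        return math.nan
    return c_after / c_before


def wt_enrichment(
    c_wt_before: int, c_wt_after: int, pseudocount: float = 0.5
) -> Optional[float]:
    """E_wtx for one wild-type/synonymous sequence; None when uninformative."""
    if c_wt_before == 0 and c_wt_after == 0:
        warnings.warn("wild-type record with zero counts in both samples excluded")
        return None
    return ratio_with_pseudocount(c_wt_after, c_wt_before, pseudocount)


def median_wt(wt_values: Sequence[float]) -> float:
    """Ẽ_wt: median over eligible wild-type/synonymous enrichments."""
    values = [v for v in wt_values if v is not None and math.isfinite(v)]
    if not values:
        raise ValueError(
            "no eligible wild-type/synonymous records; normalization impossible"
        )
    return float(np.median(values))


def enrichment(
    c_before: int, c_after: int, e_wt_median: float, pseudocount: float = 0.5
) -> float:
    """Normalized enrichment E_i = (c_after/c_before) / Ẽ_wt."""
    if not e_wt_median > 0:
        raise ValueError("wild-type median enrichment must be positive")
    raw = ratio_with_pseudocount(c_after, c_before, pseudocount)
    return raw / e_wt_median


def absolute_enrichment(freq_before: float, freq_after: float) -> float:
    """E_abs: ratio of a clone's population frequency after vs before."""
    if freq_before < 0 or freq_after < 0:
        raise ValueError("frequencies must be >= 0")
    if freq_before == 0:
        return math.nan
    return freq_after / freq_before


def remove_outliers(values: Sequence[float], z_threshold: float) -> OutlierResult:
    """Single-pass two-sided z-score outlier removal.

    z is computed once on the original set with the sample SD (n-1);
    values with |z| strictly above the threshold are removed. With n < 3
    or zero SD nothing is removed. Deliberately not iterated: one pass
    keeps the retained/removed partition interpretable against the
    original mean and SD.
    """
    if not z_threshold > 0:
        raise ValueError("z_threshold must be positive")
    values = list(values)
    if len(values) < 3:
        return OutlierResult(values, [], [0.0] * len(values),
                             notice="fewer than 3 values; nothing removed")
    arr = np.asarray(values, dtype=float)
    sd = arr.std(ddof=1)
    if sd == 0:
        return OutlierResult(values, [], [0.0] * len(values))
    z = (arr - arr.mean()) / sd
    keep = np.abs(z) <= z_threshold
    return OutlierResult(
        retained=[v for v, k in zip(values, keep) if k],
        removed=[v for v, k in zip(values, keep) if not k],
        z=list(z),
    )


def barcode_stats(peptide: str, values: Sequence[float], n_total: Optional[int] = None
                  ) -> BarcodeStats:
    """Mean, sample SD and CV% over retained barcode enrichments."""
    values = list(values)
    if len(values) < 2:
        raise ValueError("need at least 2 retained barcode values")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    cv = 100.0 * sd / mean if mean > 0 else math.nan
    return BarcodeStats(
        peptide=peptide,
        n_total=n_total if n_total is not None else len(values),
        n_retained=len(values),
        mean=mean,
        sd=sd,
        cv_percent=cv,
    )


def enrich_table(
    counts: pd.DataFrame,
    pseudocount: float = 0.5,
    min_t0_count: int = 1,
) -> pd.DataFrame:
    """Full enrichment table from a merged c_before/c_after count table.

    Keeps wt/synonymous/single_missense rows, computes per-sample
    frequencies over those assigned reads, E_abs, the wild-type median
    Ẽ_wt (from wt/synonymous rows with c_before >= min_t0_count), E_i and
    log2 E_i (-inf sentinel for E_i = 0).

    Rows with c_before < min_t0_count are dropped before anything is
    computed: variants that were (nearly) absent before selection are
    dominated by sequencing-error artifacts and carry no usable
    enrichment signal.
    """
    df = counts[counts["klass"].isin(ENRICHABLE_CLASSES)].copy()
    df = df[df["c_before"] >= min_t0_count]
    if df.empty:
        raise ValueError("no enrichable variant rows in count table")

    tot_before = df["c_before"].sum()
    tot_after = df["c_after"].sum()
    df["freq_before"] = df["c_before"] / tot_before if tot_before else math.nan
    df["freq_after"] = df["c_after"] / tot_after if tot_after else math.nan
    df["E_abs"] = [
        absolute_enrichment(fb, fa) if fb > 0 else math.nan
        for fb, fa in zip(df["freq_before"], df["freq_after"])
    ]

    wt_mask = df["klass"].isin(("wt", "synonymous")) & (
        df["c_before"] >= min_t0_count
    )
    wt_values = [
        wt_enrichment(int(b), int(a), pseudocount)
        for b, a in zip(df.loc[wt_mask, "c_before"], df.loc[wt_mask, "c_after"])
    ]
    e_wt = median_wt(wt_values)

    df["E_wt_median"] = e_wt
    df["E_i"] = [
        enrichment(int(b), int(a), e_wt, pseudocount)
        for b, a in zip(df["c_before"], df["c_after"])
    ]
    df["log2_E_i"] = [
        math.log2(e) if e > 0 else -math.inf for e in df["E_i"]
    ]
    return df.reset_index(drop=True)


def barcode_table_stats(
    enriched: pd.DataFrame,
    barcode_map: pd.DataFrame,
    z_threshold: float = 2.0,
    value_column: str = "E_abs",
) -> pd.DataFrame:
    """Per-peptide replicate statistics from a barcoded enrichment table.

    ``barcode_map`` has columns (barcode, peptide). Outliers are removed
    per peptide on ``value_column`` (default E_abs) before the CV is
    computed; columns with and without removal are both reported so the
    effect of the filter is visible.
    """
    merged = enriched.merge(barcode_map, on="barcode", how="inner")
    rows = []
    for peptide, grp in merged.groupby("peptide", sort=True):
        values = [v for v in grp[value_column] if math.isfinite(v)]
        if len(values) < 2:
            continue
        raw = barcode_stats(peptide, values)
        res = remove_outliers(values, z_threshold)
        kept = barcode_stats(peptide, res.retained, n_total=len(values)) \
            if len(res.retained) >= 2 else raw
        rows.append({
            "peptide": peptide,
            "n_barcodes": raw.n_total,
            "n_retained": kept.n_retained,
            "mean_raw": raw.mean,
            "cv_raw_percent": raw.cv_percent,
            "mean": kept.mean,
            "sd": kept.sd,
            "cv_percent": kept.cv_percent,
        })
    return pd.DataFrame(rows)
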