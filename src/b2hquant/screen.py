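"""Designed-peptide binder-screen quantification.

Libraries of candidate binders share a fixed architecture: a variable
N-terminal extension (11-16 aa), a short linker (GSK, GSEK or GSEAK), and
a constant C-terminal scaffold peptide (20 aa), giving full peptides of
34-41 residues. Reads are matched to the manifest by exact nucleotide
identity ("expected sequences" counting), frequencies and enrichment are
computed per design, and the composition of top-ranked sets is broken
down by linker or design category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .enrichment import ratio_with_pseudocount

__all__ = [
    "LINKERS",
    "DEFAULT_SCAFFOLD",
    "reverse_translate",
    "build_manifest",
    "match_designs",
    "screen_enrichment",
    "composition_breakdown",
    "position_frequency_matrix",
    "fold_improvement",
]

LINKERS = ("GSK", "GSEK", "GSEAK")
#: constant C-terminal scaffold peptide (a weakened parent binder)
DEFAULT_SCAFFOLD = "WARLARRTAGAGGVTLNGAG"
CATEGORIES = ("ai", "rational", "control")

EXTENSION_LENGTHS = range(11, 17)
FULL_LENGTH_MIN, FULL_LENGTH_MAX = 34, 41

# one representative codon per amino acid (E. coli-preferred) for
# deterministic reverse translation of designed peptides
_CODON = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGC",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCG", "Q": "CAG", "R": "CGT", "S": "AGC", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAT",
}


def reverse_translate(peptide: str) -> str:
    """Deterministic coding sequence for an amino-acid string."""
    try:
        return "".join(_CODON[a] for a in peptide)
    except KeyError as exc:
        raise ValueError(f"not a standard amino acid: {exc.args[0]!r}") from None


def build_manifest(
    extensions: Sequence[str],
    linkers: Sequence[str] = LINKERS,
    scaffold: str = DEFAULT_SCAFFOLD,
    categories: Optional[Mapping[str, str]] = None,
    pair_linkers: bool = False,
    coding: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Assemble and validate a design manifest.

    By default every extension is crossed with every linker; with
    ``pair_linkers`` extensions and linkers are zipped pairwise.
    ``categories`` maps extension -> category (default "ai"). Full-peptide
    lengths outside [34, 41] and duplicate peptides are rejected.
    Columns: id, extension, linker, category, peptide, coding.
    """
    categories = dict(categories or {})
    if pair_linkers:
        if len(extensions) != len(linkers):
            raise ValueError("paired mode needs equal-length lists")
        pairs = list(zip(extensions, linkers))
    else:
        pairs = [(e, l) for e in extensions for l in linkers]

    rows = []
    seen: set[str] = set()
    for ext, linker in pairs:
        if len(ext) not in EXTENSION_LENGTHS:
            raise ValueError(
                f"extension {ext!r}: length {len(ext)} outside 11-16"
            )
        if linker not in LINKERS:
            raise ValueError(f"unknown linker {linker!r}")
        peptide = ext + linker + scaffold
        if not FULL_LENGTH_MIN <= len(peptide) <= FULL_LENGTH_MAX:
            raise ValueError(
                f"peptide {peptide!r}: length {len(peptide)} outside "
                f"{FULL_LENGTH_MIN}-{FULL_LENGTH_MAX}"
            )
        if peptide in seen:
            raise ValueError(f"duplicate full peptide {peptide!r}")
        seen.add(peptide)
        cds = coding[peptide] if coding and peptide in coding \
            else reverse_translate(peptide)
        if str(Seq(cds).translate()) != peptide:
            raise ValueError(f"coding sequence does not translate to {peptide!r}")
        category = categories.get(ext, "ai")
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        rows.append({
            "id": f"{ext}-{linker}",
            "extension": ext,
            "linker": linker,
            "category": category,
            "peptide": peptide,
            "coding": cds,
        })
    return pd.DataFrame(
        rows, columns=["id", "extension", "linker", "category", "peptide",
                       "coding"],
    )


def match_designs(
    payloads: Iterable[str] | Mapping[str, int],
    manifest: pd.DataFrame,
    amino_acid_level: bool = False,
) -> tuple[pd.Series, int]:
    """Exact-match payload counting against the manifest.

    ``payloads`` is a stream of nucleotide payloads or a payload -> count
    mapping (e.g. deduplicated molecule counts). Returns (counts per
    design id, number of unmatched payloads). ``amino_acid_level``
    tolerates synonymous synthesis variants by matching translations.
    """
    if amino_acid_level:
        lut = dict(zip(manifest["peptide"], manifest["id"]))
        def key(p: str) -> Optional[str]:
            if len(p) % 3 or set(p) - set("ACGT"):
                return None
            return lut.get(str(Seq(p).translate()))
    else:
        lut = dict(zip(manifest["coding"], manifest["id"]))
        key = lut.get  # type: ignore[assignment]

    if not len(set(manifest["coding"])) == len(manifest):
        raise ValueError("manifest coding sequences must be unique")

    items = payloads.items() if isinstance(payloads, Mapping) else (
        (p, 1) for p in payloads
    )
    counts = {d: 0 for d in manifest["id"]}
    unmatched = 0
    for payload, n in items:
        design = key(payload)
        if design is None:
            unmatched += n
        else:
            counts[design] += n
    return pd.Series(counts, name="count"), unmatched


def screen_enrichment(
    counts_t0: pd.Series,
    counts_tf: pd.Series,
    manifest: pd.DataFrame,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Frequencies, enrichment and ranks per design.

    Frequencies are computed over matched designs per sample; enrichment
    is freq_TF / freq_T0 with the shared zero-count pseudocount rule
    applied to counts. Ranking is by descending enrichment with ties
    broken by TF count then id, so reports are reproducible.
    """
    df = manifest[["id", "extension", "linker", "category"]].copy()
    df["c_before"] = counts_t0.reindex(df["id"]).fillna(0).astype(int).values
    df["c_after"] = counts_tf.reindex(df["id"]).fillna(0).astype(int).values
    tot0, totf = df["c_before"].sum(), df["c_after"].sum()
    if tot0 == 0 or totf == 0:
        raise ValueError("a sample has no matched reads")
    df["freq_before"] = df["c_before"] / tot0
    df["freq_after"] = df["c_after"] / totf
    scale = tot0 / totf
    df["enrichment"] = [
        ratio_with_pseudocount(a, b, pseudocount) * scale
        for a, b in zip(df["c_after"], df["c_before"])
    ]
    df["flagged"] = (df["c_before"] == 0) | (df["c_after"] == 0)
    df = df.sort_values(
        ["enrichment", "c_after", "id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def composition_breakdown(
    result: pd.DataFrame, top_n: int, facet: str
) -> pd.DataFrame:
    """Fraction of the top-N most frequent designs per facet level.

    Top-N is taken by TF frequency (ties by id); every facet level present
    in the manifest is reported, including zeros. Fractions sum to 1.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if top_n > len(result):
        raise ValueError("top_n exceeds the number of designs")
    if facet not in ("linker", "category"):
        raise ValueError("facet must be 'linker' or 'category'")
    top = result.sort_values(
        ["freq_after", "id"], ascending=[False, True]
    ).head(top_n)
    levels = LINKERS if facet == "linker" else CATEGORIES
    levels = [l for l in levels if l in set(result[facet])] or sorted(
        set(result[facet])
    )
    frac = top[facet].value_counts().reindex(levels, fill_value=0) / top_n
    return frac.rename("fraction").rename_axis(facet).reset_index()


def position_frequency_matrix(
    sequences: Sequence[str],
    weights: Optional[Sequence[float]] = None,
    gap: str = "-",
) -> pd.DataFrame:
    """Per-position residue fractions over variable-length peptides.

    Sequences are anchored at their C terminus (the constant scaffold
    junction) and padded N-terminally with the gap character, since
    extensions vary in length while everything downstream is fixed.
    Columns are positions (1-based after padding); each column's fractions
    sum to 1 over its non-gap mass. This matrix is the numeric content of
    a sequence logo.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences")
    if weights is None:
        w = np.ones(len(seqs))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(seqs) or (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be non-negative and sum > 0")
    width = max(len(s) for s in seqs)
    padded = [gap * (width - len(s)) + s for s in seqs]
    residues = sorted(set("".join(padded)) - {gap})
    mat = pd.DataFrame(0.0, index=residues,
                       columns=pd.RangeIndex(1, width + 1, name="position"))
    for s, wi in zip(padded, w):
        for pos, aa in enumerate(s, start=1):
            if aa != gap:
                mat.loc[aa, pos] += wi
    col_mass = mat.sum(axis=0)
    mat = mat.div(col_mass.where(col_mass > 0, np.nan), axis=1).fillna(0.0)
    return mat


def fold_improvement(kd_reference_nm: float, kd_new_nm: float
                     ) -> tuple[float, float]:
    """Affinity gain of a new binder vs a reference, as Kd_ref / Kd_new.

    Returns (raw ratio, nearest-ten rounded form) — the rounded form is
    the conventional "N-fold improvement" statement.
    """
    if not (kd_reference_nm > 0 and kd_new_nm > 0):
        raise ValueError("Kd values must be positive")
    ratio = kd_reference_nm / kd_new_nm
    return ratio, round(ratio / 10.0) * 10.0
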