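"""Per-position interface perturbation scores from variant enrichment.

Mutations at interface residues tend to disrupt binding, so positions
whose substitutions are systematically depleted under selection flag the
binding surface. Each observed missense substitution contributes a
deleterious effect d = clamp(1 - E_i, 0, 1) (E_i is the wild-type-
normalized enrichment; gains of interaction clamp to 0 because the score
measures loss of interaction only), and the perturbation score of a
position is the mean d over its substitutions. Positions scoring strictly
above a threshold (default 0.1) are called interface.

The clamp(1 - E) transform is one reasonable loss-of-interaction mapping,
not the only one; ``transform="neg_log2"`` switches to
d = max(0, -log2 E) rescaled by the maximum positional score, which
weights strong depletions more heavily.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "log2_normalized_enrichment",
    "deleterious_effect",
    "perturbation_score",
    "perturbation_profile",
    "call_interface",
    "export_structure_attributes",
    "heatmap_matrix",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def log2_normalized_enrichment(e_i: float) -> float:
    """log2 of normalized enrichment; 0 means wild-type-like."""
    if not e_i > 0:
        raise ValueError("enrichment must be positive (pseudocounts upstream)")
    return math.log2(e_i)


def deleterious_effect(e_i: float) -> float:
    """Loss-of-interaction effect of one substitution, in [0, 1]."""
    if e_i < 0:
        raise ValueError("enrichment must be >= 0")
    return min(max(1.0 - e_i, 0.0), 1.0)


def perturbation_score(enrichments: Sequence[float], min_substitutions: int = 3
                       ) -> float:
    """Mean deleterious effect at one position.

    Returns NaN (position unassessed) when fewer than ``min_substitutions``
    substitutions were observed — an average over one or two mutations is
    noise-dominated.
    """
    values = list(enrichments)
    if len(values) < min_substitutions:
        return math.nan
    return float(np.mean([deleterious_effect(e) for e in values]))


def perturbation_profile(
    enriched: pd.DataFrame,
    min_substitutions: int = 3,
    threshold: float = 0.1,
    transform: str = "one_minus",
) -> pd.DataFrame:
    """Per-position profile from an enrichment table.

    Uses single_missense rows only; stop-codon substitutions (alt '*')
    are excluded since they conflate expression loss with binding loss.
    Columns: position, n_substitutions, mean_log2_E, score, assessed,
    interface (score strictly > threshold).
    """
    if transform not in ("one_minus", "neg_log2"):
        raise ValueError(f"unknown transform {transform!r}")
    sub = enriched[
        (enriched["klass"] == "single_missense") & (enriched["alt_aa"] != "*")
    ]
    rows = []
    for position, grp in sub.groupby("position", sort=True):
        e = grp["E_i"].to_numpy(dtype=float)
        n = len(e)
        assessed = n >= min_substitutions
        if not assessed:
            score = math.nan
        elif transform == "one_minus":
            score = float(np.mean([deleterious_effect(x) for x in e]))
        else:
            score = float(np.mean([max(0.0, -math.log2(x)) for x in e]))
        rows.append({
            "position": int(position),
            "n_substitutions": n,
            "mean_log2_E": float(np.mean([math.log2(x) for x in e if x > 0]))
            if (e > 0).any() else math.nan,
            "score": score,
            "assessed": assessed,
        })
    profile = pd.DataFrame(
        rows, columns=["position", "n_substitutions", "mean_log2_E", "score",
                       "assessed"],
    )
    if transform == "neg_log2" and not profile.empty:
        top = profile["score"].max()
        if top > 0:
            profile["score"] = profile["score"] / top
    profile["interface"] = profile["score"] > threshold
    return profile


def call_interface(profile: pd.DataFrame, threshold: float = 0.1) -> set[int]:
    """Positions with perturbation score strictly above the threshold."""
    if profile.empty:
        return set()
    mask = profile["assessed"] & (profile["score"] > threshold)
    return set(int(p) for p in profile.loc[mask, "position"])


def export_structure_attributes(
    profile: pd.DataFrame, chain_id: str = "A", sentinel: float = -1.0
) -> pd.DataFrame:
    """Per-residue attribute table for molecular-viewer coloring.

    Unassessed positions are emitted with the sentinel score so viewers
    can distinguish "not measured" from "score 0".
    """
    if profile["position"].duplicated().any():
        raise ValueError("duplicate positions in profile")
    rows = []
    for _, row in profile.sort_values("position").iterrows():
        assessed = bool(row["assessed"])
        rows.append({
            "chain": chain_id,
            "residue": int(row["position"]),
            "score": float(row["score"]) if assessed else sentinel,
            "interface": bool(row["interface"]) if assessed else False,
        })
    return pd.DataFrame(rows, columns=["chain", "residue", "score", "interface"])


def heatmap_matrix(enriched: pd.DataFrame, value: str = "log2_E_i") -> pd.DataFrame:
    """Positions x amino-acids matrix of enrichment values for display."""
    sub = enriched[enriched["klass"] == "single_missense"]
    mat = sub.pivot_table(index="position", columns="alt_aa", values=value,
                          aggfunc="mean")
    return mat.reindex(columns=[a for a in AMINO_ACIDS + "*" if a in mat.columns])
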