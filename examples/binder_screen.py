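"""Rank a designed-peptide library after growth-coupled selection.

Generates a 1,134-member extension-linker-scaffold library with planted
affinities (bimodal for AI designs, unimodal for rational ones), selects
it in silico in a turbidostat regime, counts exact-matching payloads, and
reports enrichment ranks, linker composition of the top 100, and the fold
affinity improvement of a hypothetical validated hit.
"""

import numpy as np

from b2hquant import (
    SelectionModel,
    apply_selection,
    composition_breakdown,
    fold_improvement,
    make_screen_library,
    match_designs,
    screen_enrichment,
)

manifest, truth = make_screen_library(seed=42)
model = SelectionModel(mode="turbidostat")
truth = apply_selection(truth, model)

# draw sequencing counts directly from the population frequencies
rng = np.random.default_rng(42)
depth = 200 * len(manifest)
payloads_t0 = dict(zip(truth["payload"], rng.multinomial(depth, truth["p0"])))
payloads_tf = dict(zip(truth["payload"], rng.multinomial(depth, truth["pf"])))

counts_t0, _ = match_designs(payloads_t0, manifest)
counts_tf, _ = match_designs(payloads_tf, manifest)
result = screen_enrichment(counts_t0, counts_tf, manifest)

print(f"library: {len(manifest)} designs; selection: "
      f"{model.effective_generations:.0f} effective generations")
print("top 5 by enrichment:")
print(result.head(5)[["id", "category", "linker", "enrichment", "rank"]]
      .to_string(index=False, float_format="%.1f"))
print("\nlinker composition of the top 100 (by final frequency):")
print(composition_breakdown(result, 100, "linker").to_string(index=False))
print("\ncategory composition of the top 100:")
print(composition_breakdown(result, 100, "category").to_string(index=False))

raw, rounded = fold_improvement(10600.0, 152.0)
print(f"\nfold improvement of a 152 nM hit over the 10.6 uM scaffold: "
      f"{raw:.2f} (~{rounded:.0f}-fold)")
# Enrichment > 1 marks designs whose frequency grew under selection; the
# composition table shows which linkers/categories dominate the winners.
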