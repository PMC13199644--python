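# Methods

## Model and procedure

### Read model

Reads are treated as single-end, forward-orientation, pre-merged
payloads laid out as

    [dephaser prefix, 0..max_phase bases] [anchor] [UMI] [barcode?] [payload]

The dephaser anchor is located by exact string match with its start in
`[0, max_phase]`; no mismatches are tolerated in the anchor (it is a
short constant sequence, and base-call noise is handled by the quality
filter instead). Reads failing anchor, UMI or barcode extraction, or
with more than `max_frac_below` (default 0.1) of payload bases under
`min_base_quality` (default Q20), are rejected with a reason code.
Nucleotide offsets are 0-based half-open; protein positions are 1-based.

### PCR deduplication

Molecules are keyed by (UMI, barcode, payload); each key counts once
regardless of its read multiplicity, which makes deduplicated counts
invariant under read duplication and input order. An optional
*directional* merge absorbs a UMI into a Hamming-distance-1 neighbour
with the same payload and at least twice its read count. It is off by
default: it corrects UMI sequencing errors but can merge genuinely
distinct molecules in saturated UMI spaces, so it is opt-in.

### Variant calling

A payload is assigned to the reference region whose unique 5′ anchor
prefixes it, then compared codon-by-codon after the frame offset using
the standard genetic code. Classification: identical nucleotides → `wt`;
identical translation → `synonymous`; exactly one amino-acid-changing
codon → `single_missense`; more → `multi`; any length mismatch →
`indel` (amplicons fully cover their region by design, so partial reads
carry no safe call); non-ACGT bases → `unassigned`. Missense identity
pools codons encoding the same amino acid (a `codon_level` switch keeps
them apart). Regions covering disjoint residue ranges of one target are
assembled into a single table keyed by global residue numbering.

### Enrichment

For each wild-type or synonymous sequence with T0 count ≥
`min_t0_count`, E_wtx = c_after/c_before; their median Ẽ_wt anchors the
scale, and every variant gets E_i = (c_after/c_before)/Ẽ_wt. The
pseudocount policy adds p (default 0.5) to *both* counts of a ratio only
when either is zero — nonzero data are never perturbed, ratios stay
finite, and scale invariance (multiplying all counts by a constant) is
preserved whenever pseudocounts are inactive. Variants with
c_before < `min_t0_count` are dropped entirely: variants absent before
selection are dominated by sequencing-error artifacts, and with a
pseudocount they would otherwise produce spuriously extreme enrichments.
A sensible `min_t0_count` scales with per-variant coverage (we use
roughly a tenth of the expected T0 count per variant in simulated runs).

Barcoded replicates use the absolute enrichment E_abs =
freq_after/freq_before per (barcode, peptide), with frequencies computed
over reads assigned to known variants only. Outlier removal is a single
two-sided z-score pass (sample SD, n−1) on the original set at threshold
2.0 by default; it is deliberately not iterated, so removed values are
exactly those with |z| > threshold under the original mean/SD. Tighter
thresholds (0.5, 0.25) are configurable. CV = 100·SD/mean is reported
before and after removal.

### Perturbation scores

Per position, the score is the arithmetic mean of d = clamp(1 − E_i, 0, 1)
over observed missense substitutions, excluding stop codons (they
conflate expression with binding) and requiring ≥ 3 substitutions
(`min_substitutions`) — a one-mutation average is noise-dominated.
Gains of interaction clamp to 0 rather than offsetting losses: the score
measures loss of interaction only, so a position with mixed strong gains
and losses still flags if its losses are consistent. Interface calls are
strict: score > threshold (default 0.1). The clamp transform is bounded,
wild-type-anchored (E = 1 → d = 0) and compatible with the 0.1
threshold scale; an alternative `neg_log2` transform
(d = max(0, −log2 E), rescaled by the profile maximum) weights strong
depletions more heavily and is selectable per run.

### Binder screens

Designs follow extension (11–16 aa) + linker (GSK/GSEK/GSEAK) + constant
20-aa scaffold, full lengths 34–41 aa, validated at manifest build time
along with translation consistency and uniqueness. Counting is exact
nucleotide matching against manifest coding sequences (an
amino-acid-level mode tolerates synonymous synthesis variants).
Enrichment is the frequency ratio with the shared pseudocount rule;
ranking ties break by TF count then id so reports are reproducible.
Position frequency matrices anchor sequences at the C terminus (the
scaffold junction is constant; extensions vary), pad N-terminally, and
normalize each column over its non-gap mass.

### Assay metrics

- Normalized MFI: 100·(x − low)/(high − low); affine-invariant; values
  outside [0, 100] are legitimate.
- MIC50: least-squares fit of G(c) = 100/(1 + (c/MIC50)^h) with top and
  bottom fixed at 100/0 (OD is normalized to the antibiotic-free culture,
  and full inhibition approaches zero growth); a 4-parameter variant is
  behind a flag. Initialization: MIC50 from linear interpolation at 50%
  growth, h = 1; fits whose data never cross ~50% growth are refused
  ("range not bracketed"), and MIC50 outside the tested range is flagged
  extrapolated.
- Kd–signal correlation: R² of ordinary least squares of signal on
  log10(Kd) — affinities span orders of magnitude, so the log is the
  natural predictor; censored entries (e.g. "> 100,000 nM") are excluded.
- CSP: Δδ = √(ΔδHN² + (0.17·ΔδN)²) by default (0.17 rescales the wider
  nitrogen ppm range); the alternative reading √(ΔδHN² + 0.17·ΔδN²) is
  selectable. Bins partition [0, ∞): background ≤ 0.09 < low < 0.18 ≤
  medium < 0.26 ≤ high (ppm).

## Simulator

The generator is a first-class, tested component; it emulates the
features the pipeline must be robust to and defines the conditions under
which the recovery guarantees are demonstrated.

- **Kd → fitness**: w = w_min + (w_max − w_min)/(1 + 10^((log10 Kd −
  log10 K_half)/s)), defaults w_min 0.2, w_max 2.0 (relative growth
  factors per generation), K_half ≈ 1.6 μM, s = 0.7 decades. These
  defaults place saturation around 100 nM, reproducing the observed
  plateau of growth-coupled readouts in the nanomolar range (nanomolar
  and tens-of-nanomolar binders become indistinguishable) while keeping
  micromolar binders clearly separated. The mapping is phenomenological,
  not a pharmacodynamic model.
- **Selection**: deterministic exponential growth, p′ ∝ p·wᵍ, with
  multinomial sampling noise entering only at read emission; no explicit
  death process. Batch mode defaults to g = 5; turbidostat mode applies
  the same rule with a larger, independently set effective g (default
  20), reflecting continuous dilution at fixed OD over 24 h+.
- **Read emission**: molecules drawn multinomially from sample
  frequencies; each gets a fresh random UMI (length 10), a uniform
  0–7-base dephaser prefix, and a geometric number of PCR copies
  (heavy-tailed enough to exercise dedup); substitution errors hit every
  base iid; qualities encode the error rate (Q40 when zero). All
  randomness flows from one `numpy` Generator seeded once, so identical
  seeds give byte-identical FASTQ.
- **Libraries**: positional libraries place all 19 substitutions at each
  chosen position (one representative codon per amino acid), plus
  wild-type and wobble-base synonymous controls per region; the screen
  library defaults to 1,134 designs (1,050 AI + 81 rational + 3
  controls), AI affinities bimodal (a ~15% strong mode near 100 nM
  against a weak majority near 20 μM), rational designs unimodal near
  1 μM, controls at the 10.6 μM scaffold affinity.

What the simulator does **not** emulate: indel sequencing errors,
quality-score variation along reads, PCR chimeras and recombination,
amplification bias, strain physiology (jackpot clones, escape
mutations), and paired-end structure. Passing recovery tests therefore
demonstrates correctness of the analysis logic under realistic counting
noise, substitution error and PCR duplication — not robustness to every
artifact of real libraries.

## Problem sizes and numerical choices

Simulated demonstrations use a 156-residue target with 6–12 mutagenized
positions (~120–240 variants), 100–200 molecules per variant per sample,
0.1% substitution error and PCR duplication means of 1.2–1.8; these
sizes give stable statistics (interface recovery is exact, enrichment–
fitness Pearson r ≥ 0.95 across seeds) while keeping any single run in
seconds. MIC50 recovery is checked noiselessly (agreement to 1e-6
relative) and under 2% multiplicative OD noise across 100 seeds
(relative error < 10%). Floats in TSV outputs carry 6 significant
digits; writer/reader round trips are lossless at that precision.
Median over an even number of wild-type enrichments is the mean of the
central pair. Degenerate inputs fail loudly (no wild-type records, zero
SD sets, unbracketed dose-response data) rather than returning silent
defaults.

## Known limitations

- The deleterious-effect transform and the 0.1 interface threshold are a
  matched pair; swapping in the `neg_log2` transform rescales scores to
  the profile maximum, so thresholds are not directly comparable across
  transforms.
- Exact-match design counting discards reads with any payload error;
  at realistic error rates this costs coverage roughly linearly in
  payload length but does not bias ranks.
- The UMI space (4^10) is large but finite; at extreme per-payload
  molecule counts, UMI collisions deflate molecule counts slightly and
  symmetrically across samples.
- Indels are rejected, not genotyped; libraries are assumed codon-exact.
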