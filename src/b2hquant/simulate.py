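"""Synthetic selection-experiment generator with known ground truth.

Everything the analysis stack consumes can be produced here with planted
truth: positional single-mutant libraries over a target protein,
barcoded peptide sets, designed-binder screen libraries, growth-coupled
selection (batch or turbidostat), and FASTQ emission with dephasers,
UMIs, PCR duplicates and substitution sequencing errors. All randomness
derives from a single seed, so fixtures are reproducible byte for byte.

The Kd -> fitness mapping is phenomenological: a logistic curve in
log10(Kd) that saturates for strong binders, reproducing the observed
plateau of selection readouts in the nanomolar range. Selection then
propagates frequencies deterministically as p_i' ∝ p_i * w_i^g with
multinomial sampling noise entering only at read emission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io import ReferenceRegion, write_fastq
from .screen import (
    DEFAULT_SCAFFOLD,
    LINKERS,
    build_manifest,
    reverse_translate,
)

__all__ = [
    "SelectionModel",
    "ReadLayout",
    "kd_to_fitness",
    "simulate_selection",
    "apply_selection",
    "make_positional_library",
    "make_screen_library",
    "simulate_reads",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_BASES = np.frombuffer(b"ACGT", dtype="S1")

# anchors assigned to successive regions; distinct so payloads assign uniquely
_REGION_ANCHORS = ("GGTACCTA", "GAGCTCAA", "CCATGGTT", "TCTAGAGG", "CTCGAGCA")


@dataclass(frozen=True)
class SelectionModel:
    """Kd -> per-generation growth factor, and how long selection runs.

    ``w_min``/``w_max`` are relative growth factors per generation for
    non-binders and saturating binders; ``log10_khalf`` (log10 nM) is the
    affinity of half-maximal fitness and ``slope`` its softness in
    decades. ``generations`` applies in batch mode; turbidostat mode uses
    the independently set ``turbidostat_generations`` (continuous dilution
    at fixed OD keeps cultures growing far longer than a batch).
    """

    w_min: float = 0.2
    w_max: float = 2.0
    log10_khalf: float = 3.2  # ~1.6 uM: readout saturates by ~100 nM
    slope: float = 0.7
    generations: float = 5.0
    turbidostat_generations: float = 20.0
    mode: str = "batch"

    def __post_init__(self) -> None:
        if not (self.w_max >= self.w_min > 0):
            raise ValueError("need w_max >= w_min > 0")
        if not self.slope > 0:
            raise ValueError("slope must be positive")
        if self.mode not in ("batch", "turbidostat"):
            raise ValueError("mode must be 'batch' or 'turbidostat'")

    @property
    def effective_generations(self) -> float:
        return (self.turbidostat_generations if self.mode == "turbidostat"
                else self.generations)


def kd_to_fitness(kd_nm: float, model: SelectionModel) -> float:
    """Logistic fitness in log10(Kd), saturating for strong binders."""
    if not kd_nm > 0:
        raise ValueError("Kd must be positive")
    x = (math.log10(kd_nm) - model.log10_khalf) / model.slope
    return model.w_min + (model.w_max - model.w_min) / (1.0 + 10.0**x)


def simulate_selection(
    t0_freqs: Sequence[float],
    fitness: Sequence[float],
    generations: Optional[float] = None,
    model: Optional[SelectionModel] = None,
) -> np.ndarray:
    """Propagate frequencies through g generations of exponential growth.

    p_i' = p_i w_i^g / sum_j p_j w_j^g. Pass either an explicit number of
    generations or a model (whose mode picks batch vs turbidostat g).
    """
    p = np.asarray(t0_freqs, dtype=float)
    w = np.asarray(fitness, dtype=float)
    if not math.isclose(p.sum(), 1.0, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError("frequencies must sum to 1")
    if (w <= 0).any():
        raise ValueError("fitness values must be positive")
    if generations is None:
        generations = (model or SelectionModel()).effective_generations
    grown = p * w**generations
    total = grown.sum()
    if total == 0:
        raise ValueError("population went extinct (all-zero growth)")
    return grown / total


def apply_selection(truth: pd.DataFrame, model: SelectionModel) -> pd.DataFrame:
    """Fill the expected post-selection frequency column ``pf``.

    ``truth`` needs ``p0`` and either ``fitness`` or ``kd_nm``.
    """
    truth = truth.copy()
    if "fitness" not in truth.columns:
        truth["fitness"] = [kd_to_fitness(k, model) for k in truth["kd_nm"]]
    truth["pf"] = simulate_selection(truth["p0"], truth["fitness"], model=model)
    return truth


@dataclass(frozen=True)
class ReadLayout:
    """Physical layout of an emitted read.

    prefix (0..max_phase random bases) + anchor + UMI + [barcode] + payload.
    """

    dephaser_anchor: str = "TATGGC"
    max_phase: int = 7
    umi_length: int = 10
    barcode_length: int = 0


def _synonymous_codon(codon: str) -> Optional[str]:
    from Bio.Seq import Seq

    aa = str(Seq(codon).translate())
    for base in "ACGT":
        alt = codon[:2] + base
        if alt != codon and str(Seq(alt).translate()) == aa:
            return alt
    return None


def make_positional_library(
    target_aa: str,
    positions: Sequence[int],
    alphabet: str = AMINO_ACIDS,
    interface_fitness: Optional[dict[int, float]] = None,
    n_regions: int = 1,
    n_synonymous: int = 3,
) -> tuple[list[ReferenceRegion], pd.DataFrame]:
    """All single-aa substitutions at the listed positions, plus controls.

    The target is reverse-translated deterministically and split into
    ``n_regions`` contiguous regions (each with its own unique 5' anchor),
    mirroring amplicon sequencing of independent regions of one protein.
    Each region contributes a wild-type template and ``n_synonymous``
    synonymous wild-type variants (wobble-base changes). Fitness defaults
    to 1.0 (wild-type-like) except at positions present in
    ``interface_fitness``. T0 frequencies are uniform over templates.

    Returns (reference regions, truth table with columns id, region,
    klass, position, alt_aa, payload, fitness, p0).
    """
    interface_fitness = dict(interface_fitness or {})
    n_res = len(target_aa)
    for pos in positions:
        if not 1 <= pos <= n_res:
            raise ValueError(f"position {pos} outside target (1..{n_res})")
    if n_regions < 1 or n_regions > len(_REGION_ANCHORS):
        raise ValueError(f"n_regions must be 1..{len(_REGION_ANCHORS)}")

    target_nt = reverse_translate(target_aa)
    bounds = np.linspace(0, n_res, n_regions + 1).astype(int)
    regions: list[ReferenceRegion] = []
    rows: list[dict] = []

    for r in range(n_regions):
        lo, hi = int(bounds[r]), int(bounds[r + 1])  # 0-based residue span
        coding = target_nt[lo * 3 : hi * 3]
        region = ReferenceRegion(
            name=f"region{r + 1}",
            sequence=coding,
            frame_offset=0,
            first_residue=lo + 1,
            anchor5=_REGION_ANCHORS[r],
        )
        regions.append(region)

        def payload(nt: str) -> str:
            return region.anchor5 + nt

        rows.append({
            "id": f"{region.name}_wt", "region": region.name, "klass": "wt",
            "position": pd.NA, "alt_aa": "", "payload": payload(coding),
            "fitness": 1.0,
        })
        made_syn = 0
        for ci in range(hi - lo):
            if made_syn >= n_synonymous:
                break
            codon = coding[ci * 3 : ci * 3 + 3]
            alt = _synonymous_codon(codon)
            if alt is None:
                continue
            nt = coding[: ci * 3] + alt + coding[ci * 3 + 3 :]
            made_syn += 1
            rows.append({
                "id": f"{region.name}_syn{made_syn}", "region": region.name,
                "klass": "synonymous", "position": pd.NA, "alt_aa": "",
                "payload": payload(nt), "fitness": 1.0,
            })
        for pos in positions:
            if not lo + 1 <= pos <= hi:
                continue
            ci = pos - 1 - lo
            ref_aa = target_aa[pos - 1]
            for alt_aa in alphabet:
                if alt_aa == ref_aa:
                    continue
                nt = (coding[: ci * 3] + reverse_translate(alt_aa)
                      + coding[ci * 3 + 3 :])
                rows.append({
                    "id": f"{ref_aa}{pos}{alt_aa}", "region": region.name,
                    "klass": "missense", "position": pos, "alt_aa": alt_aa,
                    "payload": payload(nt),
                    "fitness": interface_fitness.get(pos, 1.0),
                })

    truth = pd.DataFrame(rows)
    truth["p0"] = 1.0 / len(truth)
    return regions, truth


def _random_extensions(rng: np.random.Generator, n: int,
                       taken: set[str]) -> list[str]:
    out: list[str] = []
    aas = list(AMINO_ACIDS)
    while len(out) < n:
        length = int(rng.integers(11, 17))
        ext = "".join(rng.choice(aas, size=length))
        if ext not in taken:
            taken.add(ext)
            out.append(ext)
    return out


def make_screen_library(
    n_ai: int = 1050,
    n_rational: int = 81,
    n_control: int = 3,
    seed: int = 0,
    scaffold: str = DEFAULT_SCAFFOLD,
    scaffold_kd_nm: float = 10600.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Designed-binder screen library with planted affinities.

    Random 11-16 aa extensions are crossed with the three linkers
    (n designs per category, defaults summing to 1,134). Planted Kd is
    bimodal for the AI category (a minority of strong binders against a
    weak majority), unimodal-intermediate for rational designs, and the
    unmodified scaffold affinity for controls. Returns (manifest, truth);
    truth adds kd_nm, fitness placeholder-free columns and uniform p0.
    """
    if min(n_ai, n_rational, n_control) < 0 or n_ai + n_rational + n_control < 1:
        raise ValueError("need at least one design")
    rng = np.random.default_rng(seed)
    taken: set[str] = set()
    frames = []
    for category, n in (("ai", n_ai), ("rational", n_rational),
                        ("control", n_control)):
        if n == 0:
            continue
        n_ext = -(-n // len(LINKERS))  # ceil: extensions crossed with linkers
        exts = _random_extensions(rng, n_ext, taken)
        manifest = build_manifest(exts, LINKERS, scaffold,
                                  categories={e: category for e in exts})
        frames.append(manifest.head(n))
    manifest = pd.concat(frames, ignore_index=True)

    kd = np.empty(len(manifest))
    for i, category in enumerate(manifest["category"]):
        if category == "ai":
            # bimodal: ~15% strong (around 100 nM), rest weak (around 20 uM)
            if rng.random() < 0.15:
                kd[i] = 10.0 ** rng.normal(2.0, 0.4)
            else:
                kd[i] = 10.0 ** rng.normal(4.3, 0.3)
        elif category == "rational":
            kd[i] = 10.0 ** rng.normal(3.0, 0.4)
        else:
            kd[i] = scaffold_kd_nm
    truth = manifest[["id", "coding", "category", "linker"]].copy()
    truth = truth.rename(columns={"coding": "payload"})
    truth["kd_nm"] = kd
    truth["p0"] = 1.0 / len(truth)
    return manifest, truth


def attach_barcodes(truth: pd.DataFrame, n_barcodes: int = 10, seed: int = 0,
                    barcode_length: int = 12) -> pd.DataFrame:
    """Expand each template into replicate barcoded clones.

    Mirrors coupling every peptide to a set of unique DNA barcodes; T0
    frequency is split equally among a template's barcodes.
    """
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    rows = []
    for _, row in truth.iterrows():
        for _ in range(n_barcodes):
            while True:
                bc = "".join(rng.choice(list("ACGT"), size=barcode_length))
                if bc not in seen:
                    seen.add(bc)
                    break
            new = row.to_dict()
            new["barcode"] = bc
            new["p0"] = row["p0"] / n_barcodes
            rows.append(new)
    return pd.DataFrame(rows)


def _apply_errors(seq: np.ndarray, rng: np.random.Generator,
                  error_rate: float) -> np.ndarray:
    n_err = rng.binomial(seq.size, error_rate)
    if n_err == 0:
        return seq
    pos = rng.choice(seq.size, size=n_err, replace=False)
    out = seq.copy()
    for p in pos:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def simulate_reads(
    truth: pd.DataFrame,
    depth: int,
    t0_path: Union[str, Path],
    tf_path: Union[str, Path],
    error_rate: float = 0.0,
    pcr_mean: float = 1.0,
    seed: int = 0,
    layout: ReadLayout = ReadLayout(),
    truth_path: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Emit FASTQ for the T0 and TF samples of a simulated experiment.

    ``truth`` needs ``payload``, ``p0`` and ``pf`` columns (and
    ``barcode`` when the layout carries one). ``depth`` molecules per
    sample are drawn multinomially from the sample's frequencies; each
    molecule receives a unique random UMI, a uniform 0..max_phase
    dephaser prefix, and a geometric number of PCR copies with the given
    mean; substitution errors hit every emitted base iid. Base qualities
    encode the error rate (Q40 when it is zero). Returns the truth table
    with emitted molecule/read counts per sample; optionally writes it
    as TSV.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= error_rate < 1:
        raise ValueError("error rate must lie in [0, 1)")
    if pcr_mean < 1:
        raise ValueError("pcr_mean must be >= 1")
    rng = np.random.default_rng(seed)
    q = 40 if error_rate == 0 else min(40, round(-10 * math.log10(error_rate)))
    truth = truth.reset_index(drop=True).copy()
    has_barcode = layout.barcode_length > 0

    for sample, freq_col, path in (("T0", "p0", t0_path), ("TF", "pf", tf_path)):
        freqs = np.asarray(truth[freq_col], dtype=float)
        freqs = freqs / freqs.sum()
        molecules = rng.multinomial(depth, freqs)
        truth[f"molecules_{sample}"] = molecules
        reads_out = []
        n_reads = np.zeros(len(truth), dtype=int)
        for i, m in enumerate(molecules):
            payload = truth.at[i, "payload"]
            barcode = truth.at[i, "barcode"] if has_barcode else ""
            for _ in range(m):
                phase = int(rng.integers(0, layout.max_phase + 1))
                prefix = "".join(rng.choice(list("ACGT"), size=phase))
                umi = "".join(rng.choice(list("ACGT"), size=layout.umi_length))
                template = (prefix + layout.dephaser_anchor + umi + barcode
                            + payload)
                copies = int(rng.geometric(1.0 / pcr_mean))
                arr = np.frombuffer(template.encode(), dtype="S1")
                for _ in range(copies):
                    read = _apply_errors(arr, rng, error_rate)
                    reads_out.append(read.tobytes().decode())
                n_reads[i] += copies
        truth[f"reads_{sample}"] = n_reads
        write_fastq(
            ((f"{sample}:{j}", seq, [q] * len(seq))
             for j, seq in enumerate(reads_out)),
            path,
        )
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth
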