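import numpy as np
import pandas as pd
import pytest

from b2hquant.screen import (
    DEFAULT_SCAFFOLD,
    LINKERS,
    build_manifest,
    composition_breakdown,
    fold_improvement,
    match_designs,
    position_frequency_matrix,
    reverse_translate,
    screen_enrichment,
)

EXT11 = "ARNDCQEGHIL"          # 11 aa
EXT16 = "ARNDCQEGHILKMFPS"     # 16 aa


class TestBuildManifest:
    def test_length_bounds_span(self):
        manifest = build_manifest([EXT11, EXT16])
        lengths = manifest["peptide"].str.len()
        # shortest: 11 + GSK(3) + 20 = 34; longest: 16 + GSEAK(5) + 20 = 41
        assert lengths.min() == 34 and lengths.max() == 41

    def test_out_of_range_extension_rejected(self):
        with pytest.raises(ValueError, match="outside 11-16"):
            build_manifest(["ARNDCQEGHI"])  # 10 aa

    def test_duplicate_peptide_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_manifest([EXT11, EXT11])

    def test_coding_translates_to_peptide(self):
        from Bio.Seq import Seq

        manifest = build_manifest([EXT11])
        for _, row in manifest.iterrows():
            assert str(Seq(row["coding"]).translate()) == row["peptide"]

    def test_peptide_structure(self):
        manifest = build_manifest([EXT11], linkers=["GSK"])
        assert manifest.iloc[0]["peptide"] == EXT11 + "GSK" + DEFAULT_SCAFFOLD


class TestMatchDesigns:
    @pytest.fixture
    def manifest(self):
        return build_manifest([EXT11, EXT16])

    def test_exact_match_counts(self, manifest):
        cds = manifest.iloc[0]["coding"]
        counts, unmatched = match_designs([cds, cds, "AAAA"], manifest)
        assert counts[manifest.iloc[0]["id"]] == 2
        assert unmatched == 1

    def test_single_mismatch_unmatched(self, manifest):
        cds = manifest.iloc[0]["coding"]
        mutated = ("C" if cds[0] != "C" else "G") + cds[1:]
        counts, unmatched = match_designs([mutated], manifest)
        assert counts.sum() == 0 and unmatched == 1

    def test_amino_acid_level_tolerates_synonymous(self, manifest):
        cds = manifest.iloc[0]["coding"]
        syn = ("TTA" if cds[:3] == "TTG" else
               {"GCG": "GCC", "AGC": "TCT"}.get(cds[:3], None))
        if syn is None:  # build a synonymous first codon generically
            from Bio.Seq import Seq
            aa = str(Seq(cds[:3]).translate())
            syn = next(c for c in
                       (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
                       if c != cds[:3] and str(Seq(c).translate()) == aa)
        variant = syn + cds[3:]
        counts, unmatched = match_designs([variant], manifest,
                                          amino_acid_level=True)
        assert counts.sum() == 1 and unmatched == 0

    def test_empty_stream_zero_counts(self, manifest):
        counts, unmatched = match_designs([], manifest)
        assert counts.sum() == 0 and unmatched == 0

    def test_conservation(self, manifest):
        payloads = list(manifest["coding"]) * 3 + ["TTTT"] * 5
        counts, unmatched = match_designs(payloads, manifest)
        assert counts.sum() + unmatched == len(payloads)


class TestScreenEnrichment:
    @pytest.fixture
    def manifest(self):
        return build_manifest([EXT11, EXT16])

    def test_unchanged_frequency_enrichment_one(self, manifest):
        counts = pd.Series(10, index=manifest["id"])
        result = screen_enrichment(counts, counts * 3, manifest)
        assert result["enrichment"].tolist() == pytest.approx([1.0] * 6)

    def test_frequency_shift(self, manifest):
        c0 = pd.Series(100, index=manifest["id"])
        cf = c0.copy()
        cf.iloc[0] = 700  # freq 1/6 -> 7/12: enrichment 3.5
        result = screen_enrichment(c0, cf, manifest)
        top = result.iloc[0]
        assert top["enrichment"] == pytest.approx(3.5)
        assert top["rank"] == 1

    def test_absent_at_tf_near_zero_flagged(self, manifest):
        c0 = pd.Series(100, index=manifest["id"])
        cf = c0.copy()
        cf.iloc[0] = 0
        result = screen_enrichment(c0, cf, manifest, pseudocount=0.5)
        row = result[result["c_after"] == 0].iloc[0]
        assert row["enrichment"] < 0.05 and row["flagged"]

    def test_deterministic_tie_breaking(self, manifest):
        c0 = pd.Series(10, index=manifest["id"])
        r1 = screen_enrichment(c0, c0, manifest)
        r2 = screen_enrichment(c0, c0, manifest)
        assert r1["id"].tolist() == r2["id"].tolist()
        assert r1["id"].tolist() == sorted(r1["id"].tolist())


class TestCompositionBreakdown:
    def make_result(self, linker_counts: dict[str, int]) -> pd.DataFrame:
        rows = []
        i = 0
        for linker, n in linker_counts.items():
            for _ in range(n):
                rows.append({
                    "id": f"d{i:04d}", "linker": linker, "category": "ai",
                    "freq_after": 1.0 - i * 1e-4,
                })
                i += 1
        return pd.DataFrame(rows)

    def test_single_linker_dominates(self):
        result = self.make_result({"GSK": 10})
        frac = composition_breakdown(result, 10, "linker")
        assert frac.set_index("linker")["fraction"]["GSK"] == 1.0

    def test_printed_split(self):
        # top 100 split 66/21/13 across the three linkers
        result = self.make_result({"GSK": 66, "GSEK": 21, "GSEAK": 13})
        frac = composition_breakdown(result, 100, "linker")
        assert frac["fraction"].tolist() == pytest.approx([0.66, 0.21, 0.13])

    def test_zero_level_reported(self):
        result = self.make_result({"GSK": 5, "GSEK": 5, "GSEAK": 2})
        frac = composition_breakdown(result, 10, "linker")
        assert set(frac["linker"]) == set(LINKERS)
        assert frac["fraction"].sum() == pytest.approx(1.0)

    def test_fractions_sum_to_one_any_top_n(self):
        result = self.make_result({"GSK": 7, "GSEK": 9, "GSEAK": 4})
        for n in (1, 5, 13, 20):
            frac = composition_breakdown(result, n, "linker")
            assert frac["fraction"].sum() == pytest.approx(1.0)

    def test_bad_top_n_rejected(self):
        result = self.make_result({"GSK": 5})
        with pytest.raises(ValueError):
            composition_breakdown(result, 0, "linker")
        with pytest.raises(ValueError):
            composition_breakdown(result, 6, "linker")


class TestPositionFrequencyMatrix:
    def test_single_sequence_one_hot(self):
        mat = position_frequency_matrix(["ACD"])
        assert mat.loc["A", 1] == 1.0 and mat.loc["D", 3] == 1.0
        assert np.allclose(mat.sum(axis=0), 1.0)

    def test_equal_weight_split(self):
        mat = position_frequency_matrix(["ACD", "AFD"])
        assert mat.loc["C", 2] == 0.5 and mat.loc["F", 2] == 0.5

    def test_weighted_hand_computation(self):
        mat = position_frequency_matrix(["AC", "AD", "AD"],
                                        weights=[0.5, 0.25, 0.25])
        assert mat.loc["C", 2] == pytest.approx(0.5)
        assert mat.loc["D", 2] == pytest.approx(0.5)

    def test_c_terminal_anchoring_pads_left(self):
        # shorter sequence right-aligned: its residues share the last columns
        mat = position_frequency_matrix(["KKAC", "AC"])
        assert mat.loc["A", 3] == 1.0  # both sequences have A there
        assert mat.loc["K", 1] == 1.0  # only the long one contributes mass

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            position_frequency_matrix([])


class TestFoldImprovement:
    def test_printed_values_round_to_70(self):
        raw, rounded = fold_improvement(10600, 152)
        assert raw == pytest.approx(69.7368, rel=1e-4)
        assert rounded == 70

    def test_equal_kds(self):
        raw, rounded = fold_improvement(55, 55)
        assert raw == 1.0 and rounded == 0

    def test_intermediate_binder(self):
        raw, _ = fold_improvement(10600, 581)
        assert raw == pytest.approx(18.24, abs=0.005)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_improvement(0, 10)


def test_reverse_translate_rejects_nonstandard():
    with pytest.raises(ValueError):
        reverse_translate("AXZ")
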