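import numpy as np
import pandas as pd
import pytest

from b2hquant.io import RunConfig
from b2hquant.pipeline import prepare_reads, run_enrichment_pipeline
from b2hquant.readprep import payload_counts
from b2hquant.simulate import (
    ReadLayout,
    SelectionModel,
    apply_selection,
    attach_barcodes,
    kd_to_fitness,
    make_positional_library,
    make_screen_library,
    simulate_reads,
    simulate_selection,
)

TARGET = ("MAKRVQVLGRSSEVQALA" * 9)[:156]


class TestKdToFitness:
    MODEL = SelectionModel(w_min=0.2, w_max=2.0, log10_khalf=3.2, slope=0.7)

    def test_strong_binder_saturates(self):
        assert kd_to_fitness(1e-3, self.MODEL) == pytest.approx(2.0, abs=1e-2)

    def test_midpoint(self):
        assert kd_to_fitness(10**3.2, self.MODEL) == pytest.approx(1.1)

    def test_weak_binder_floor(self):
        assert kd_to_fitness(1e8, self.MODEL) == pytest.approx(0.2, abs=1e-2)

    def test_plateau_in_nanomolar_range(self):
        """Selection readout saturates: 93 nM and 2 nM binders are
        near-indistinguishable while micromolar binders are not."""
        w93 = kd_to_fitness(93, self.MODEL)
        w2 = kd_to_fitness(2, self.MODEL)
        w_um = kd_to_fitness(10_600, self.MODEL)
        assert abs(w93 - w2) / w2 < 0.15
        assert w_um < 0.5 * w93

    def test_monotone_nonincreasing_in_kd(self):
        kds = np.logspace(-1, 6, 50)
        ws = [kd_to_fitness(k, self.MODEL) for k in kds]
        assert all(a >= b for a, b in zip(ws, ws[1:]))

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            kd_to_fitness(0, self.MODEL)


class TestSimulateSelection:
    def test_neutral_identity(self):
        p = np.array([0.2, 0.3, 0.5])
        out = simulate_selection(p, [1.5, 1.5, 1.5], generations=4)
        assert out == pytest.approx(p)

    def test_two_variant_hand_computation(self):
        out = simulate_selection([0.5, 0.5], [2.0, 1.0], generations=1)
        assert out == pytest.approx([2 / 3, 1 / 3])

    def test_zero_generations_identity(self):
        p = [0.1, 0.9]
        assert simulate_selection(p, [5.0, 0.1], generations=0) == \
            pytest.approx(p)

    def test_turbidostat_mode_harsher(self):
        model_b = SelectionModel(mode="batch")
        model_t = SelectionModel(mode="turbidostat")
        p = [0.5, 0.5]
        w = [2.0, 1.0]
        pb = simulate_selection(p, w, model=model_b)
        pt = simulate_selection(p, w, model=model_t)
        assert pt[0] > pb[0]

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_selection([0.5, 0.6], [1, 1], generations=1)

    def test_stringency_widens_log2_spread(self):
        """Longer selection strictly increases the variance of log2
        frequency changes: stronger conditions, stronger effects."""
        rng = np.random.default_rng(0)
        p0 = rng.dirichlet(np.ones(50))
        w = rng.uniform(0.4, 1.6, 50)
        variances = []
        for g in (1, 3, 6, 12):
            pf = simulate_selection(p0, w, generations=g)
            variances.append(np.var(np.log2(pf / p0)))
        assert all(a < b for a, b in zip(variances, variances[1:]))


class TestPositionalLibrary:
    def test_one_position_gives_19_substitutions(self):
        regions, truth = make_positional_library(TARGET, [5], n_synonymous=0)
        missense = truth[truth["klass"] == "missense"]
        assert len(missense) == 19
        assert len(truth) == 20  # + wt

    def test_empty_positions_wt_only(self):
        _, truth = make_positional_library(TARGET, [], n_synonymous=0)
        assert truth["klass"].tolist() == ["wt"]

    def test_planted_fitness_passthrough(self):
        planted = {3: 0.3, 8: 0.3, 12: 0.3}
        _, truth = make_positional_library(
            TARGET, list(planted) + [20], interface_fitness=planted
        )
        missense = truth[truth["klass"] == "missense"]
        at_interface = missense[missense["position"].isin(planted)]
        elsewhere = missense[~missense["position"].isin(planted)]
        assert (at_interface["fitness"] == 0.3).all()
        assert (elsewhere["fitness"] == 1.0).all()

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError, match="outside target"):
            make_positional_library(TARGET, [200])

    def test_region_split_covers_disjoint_ranges(self):
        regions, _ = make_positional_library(TARGET, [], n_regions=3)
        covered = []
        for r in regions:
            covered.extend(r.residue_range)
        assert sorted(covered) == list(range(1, len(TARGET) + 1))


class TestScreenLibrary:
    def test_default_sizes_to_1134_with_valid_lengths(self):
        manifest, truth = make_screen_library(seed=0)
        assert len(manifest) == 1134
        lengths = manifest["peptide"].str.len()
        assert lengths.between(34, 41).all()

    def test_control_count_exact(self):
        manifest, _ = make_screen_library(n_ai=30, n_rational=9, n_control=3,
                                          seed=1)
        assert (manifest["category"] == "control").sum() == 3

    def test_same_seed_identical(self):
        m1, t1 = make_screen_library(n_ai=30, n_rational=9, n_control=3, seed=2)
        m2, t2 = make_screen_library(n_ai=30, n_rational=9, n_control=3, seed=2)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_ai_kd_bimodal_vs_rational(self):
        _, truth = make_screen_library(n_ai=600, n_rational=300, n_control=3,
                                       seed=3)
        ai = np.log10(truth.loc[truth["category"] == "ai", "kd_nm"])
        # a notable strong-binder mode well below the weak majority
        strong = (ai < 3).mean()
        assert 0.05 < strong < 0.3


class TestSimulateReads:
    def setup_library(self, seed=0):
        regions, truth = make_positional_library(TARGET[:30], [4, 9],
                                                 n_synonymous=1)
        truth = apply_selection(truth, SelectionModel(generations=2))
        return regions, truth

    def test_noiseless_dedup_recovers_molecule_counts(self, tmp_path):
        regions, truth = self.setup_library()
        out = simulate_reads(
            truth, 1500, tmp_path / "t0.fastq", tmp_path / "tf.fastq",
            error_rate=0.0, pcr_mean=2.5, seed=11,
        )
        groups, rejects = prepare_reads(tmp_path / "t0.fastq", RunConfig())
        assert rejects.empty
        observed = payload_counts(groups)
        expected = out.set_index("payload")["molecules_T0"]
        expected = expected[expected > 0]
        assert observed.sort_index().equals(expected.sort_index())

    def test_same_seed_byte_identical(self, tmp_path):
        regions, truth = self.setup_library()
        for run in ("a", "b"):
            simulate_reads(truth, 300, tmp_path / f"t0_{run}.fastq",
                           tmp_path / f"tf_{run}.fastq", error_rate=0.002,
                           pcr_mean=1.5, seed=5)
        assert (tmp_path / "t0_a.fastq").read_bytes() == \
            (tmp_path / "t0_b.fastq").read_bytes()
        assert (tmp_path / "tf_a.fastq").read_bytes() == \
            (tmp_path / "tf_b.fastq").read_bytes()

    def test_observed_frequencies_within_binomial_bounds(self):
        """At depth 10,000 and 4 variants, observed molecule frequencies
        fall within 3 binomial SDs of the planted ones for >= 95% of seeds."""
        p = np.array([0.4, 0.3, 0.2, 0.1])
        ok = 0
        n = 10_000
        for seed in range(100):
            rng = np.random.default_rng(seed)
            draws = rng.multinomial(n, p) / n
            sd = np.sqrt(p * (1 - p) / n)
            ok += bool((np.abs(draws - p) <= 3 * sd).all())
        assert ok >= 95

    def test_truth_tsv_written(self, tmp_path):
        regions, truth = self.setup_library()
        simulate_reads(truth, 200, tmp_path / "t0.fastq", tmp_path / "tf.fastq",
                       seed=1, truth_path=tmp_path / "truth.tsv")
        back = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
        assert {"molecules_T0", "molecules_TF", "reads_T0"} <= set(back.columns)

    def test_invalid_parameters_rejected(self):
        _, truth = self.setup_library()
        with pytest.raises(ValueError):
            simulate_reads(truth, 0, "x", "y")
        with pytest.raises(ValueError):
            simulate_reads(truth, 10, "x", "y", error_rate=1.0)


class TestBarcodes:
    def test_attach_barcodes_splits_frequency(self):
        _, truth = make_positional_library(TARGET[:12], [], n_synonymous=0)
        barcoded = attach_barcodes(truth, n_barcodes=10, seed=0)
        assert len(barcoded) == 10
        assert barcoded["p0"].sum() == pytest.approx(1.0)
        assert barcoded["barcode"].is_unique

    def test_bottleneck_severity_increases_cv(self):
        """Harsher clone bottlenecks make per-barcode enrichment noisier."""
        rng = np.random.default_rng(7)
        cvs = []
        for bottleneck in (2000, 200, 20):
            e = []
            for _ in range(10):  # 10 barcodes of one peptide
                n0 = rng.poisson(bottleneck)
                nf = rng.poisson(bottleneck)
                e.append(nf / max(n0, 1))
            e = np.asarray(e)
            cvs.append(100 * e.std(ddof=1) / e.mean())
        assert cvs[0] < cvs[1] < cvs[2]


class TestEndToEnd:
    def test_neutral_null_enrichment_near_one(self, tmp_path):
        """With all fitness equal, few variants deviate from E=1 by more
        than 3 counting-noise SDs."""
        regions, truth = make_positional_library(TARGET[:60], [10, 30, 50],
                                                 n_synonymous=2)
        truth = apply_selection(truth, SelectionModel(generations=3))
        assert truth["pf"].tolist() == pytest.approx(truth["p0"].tolist())
        depth = 100 * len(truth)
        simulate_reads(truth, depth, tmp_path / "t0.fastq",
                       tmp_path / "tf.fastq", error_rate=0.0, pcr_mean=1.2,
                       seed=3)
        res = run_enrichment_pipeline(tmp_path / "t0.fastq",
                                      tmp_path / "tf.fastq", regions,
                                      RunConfig(min_t0_count=10))
        enr = res["enrichment"]
        # counting noise: Var(log E) ~ 1/c_before + 1/c_after
        sd = np.sqrt(1 / enr["c_before"] + 1 / enr["c_after"])
        deviates = (np.abs(np.log(enr["E_i"])) > 3 * sd).mean()
        assert deviates <= 0.05
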