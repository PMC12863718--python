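import dataclasses
import filecmp
import json

import numpy as np
import pandas as pd
import pytest

from tric4 import reference
from tric4.association import build_gcn_table
from tric4.c4 import call_sample
from tric4.cohort import (
    DEFAULT_HAPLOTYPE_FREQS,
    SimulationConfig,
    calibrate_baseline_scale,
    haplotype_alleles,
    sample_genotypes,
    simulate_cohort,
    simulate_coverage,
    simulate_expression,
    simulate_outcomes,
    write_fixture_bundle,
)
from tric4.errors import ConfigError
from tric4.io import call_cohort_from_vcf, read_coverage_long, read_metadata
from tric4.c4 import WindowBed
from tric4.survival import prepare_endpoint


class TestSampleGenotypes:
    def test_determinism(self):
        cfg = SimulationConfig(n_subjects=300)
        a = sample_genotypes(cfg, 5)
        b = sample_genotypes(cfg, 5)
        pd.testing.assert_frame_equal(a, b)

    def test_seed_changes_output(self):
        cfg = SimulationConfig(n_subjects=300)
        a = sample_genotypes(cfg, 5)
        c = sample_genotypes(cfg, 6)
        assert not a["trisnp_genotype"].equals(c["trisnp_genotype"])

    def test_dr3_homozygote_fraction_matches_reference(self):
        df = sample_genotypes(SimulationConfig(n_subjects=10_000), 1)
        frac = (df["hla_genotype"] == "DR3/DR3").mean()
        assert abs(frac - 0.208) <= 0.015

    def test_degenerate_single_haplotype(self):
        cfg = SimulationConfig(
            n_subjects=50, sampling_mode="hardy_weinberg",
            haplotype_freqs={("DR3", "101"): 1.0})
        df = sample_genotypes(cfg, 2)
        assert (df["hla_genotype"] == "DR3/DR3").all()
        assert (df["trisnp_genotype"] == "101/101").all()

    def test_bad_frequencies_rejected(self):
        cfg = SimulationConfig(
            n_subjects=10, sampling_mode="hardy_weinberg",
            haplotype_freqs={("DR3", "101"): 0.5})
        with pytest.raises(ConfigError):
            sample_genotypes(cfg, 1)

    def test_hw_frequencies_converge(self):
        # LLN check: chromosome-level frequencies approach config values
        cfg = SimulationConfig(n_subjects=100_000,
                               sampling_mode="hardy_weinberg")
        df = sample_genotypes(cfg, 4)
        pooled = pd.concat([
            df[["hap1_hla", "hap1_trisnp"]].rename(
                columns={"hap1_hla": "hla", "hap1_trisnp": "code"}),
            df[["hap2_hla", "hap2_trisnp"]].rename(
                columns={"hap2_hla": "hla", "hap2_trisnp": "code"}),
        ])
        obs = pooled.value_counts(normalize=True)
        for (hla, code), expected in DEFAULT_HAPLOTYPE_FREQS.items():
            if expected < 0.01:
                continue
            assert abs(obs.get((hla, code), 0.0) - expected) < 0.01

    def test_haplotype_allele_objects(self):
        df = sample_genotypes(SimulationConfig(n_subjects=20), 3)
        for _, row in df.iterrows():
            a1, a2 = haplotype_alleles(row)
            assert a1.n_c4a + a1.n_c4b in (1, 2)
            assert row["total_gcn"] == (a1.n_c4a + a1.n_c4b
                                        + a2.n_c4a + a2.n_c4b)

    def test_c4a_null_only_in_101_homozygotes(self):
        # C4A-null requires two C4A-free chromosomes, which the default
        # structure model couples almost exclusively to 101
        df = sample_genotypes(SimulationConfig(n_subjects=5000), 6)
        nulls = df[df["gcn_a"] == 0]
        assert (nulls["trisnp_101_dosage"] == 2).mean() > 0.90

    def test_gcn_dosage_table_near_reference_margins(self):
        # 188 samples drawn with the reference dosage margins (10/53/125)
        # and the fitted per-chromosome conditionals approximate the
        # reference C4A row fractions (multinomial noise bound)
        from tric4.cohort import DEFAULT_C4_STRUCTURE, draw_c4_structure
        rng = np.random.default_rng(18)
        calls = []
        for dose, n in ((0, 10), (1, 53), (2, 125)):
            for _ in range(n):
                codes = ["101"] * dose + ["010"] * (2 - dose)
                gcn_a = sum(draw_c4_structure(c, DEFAULT_C4_STRUCTURE, rng)[0]
                            for c in codes)
                calls.append((gcn_a, dose))
        table = build_gcn_table(calls)
        ref = reference.c4a_dosage_table()
        ref_frac = ref.row_totals / ref.grand_total
        obs = np.zeros(4)
        for i, lab in enumerate(table.row_labels):
            if int(lab) < 4:
                obs[int(lab)] = table.row_totals[i] / table.grand_total
        assert np.abs(obs - ref_frac).max() < 0.03


class TestOutcomes:
    def test_null_model_exchangeable(self):
        cfg = SimulationConfig(n_subjects=4000)
        eps = {k: dataclasses.replace(v, log_hrs={}, trisnp_dr3_extra=0.0)
               for k, v in cfg.endpoints.items()}
        cfg = dataclasses.replace(cfg, endpoints=eps)
        df = simulate_cohort(cfg, 12)
        frame, _ = prepare_endpoint(df, "T1D")
        from lifelines.statistics import logrank_test
        g1 = frame[frame["trisnp_101_dosage"] == 0]
        g2 = frame[frame["trisnp_101_dosage"] == 2]
        res = logrank_test(g1["time"], g2["time"],
                           g1["event"], g2["event"])
        assert res.p_value > 0.01

    def test_t1d_event_fraction_at_defaults(self):
        df = simulate_cohort(SimulationConfig(n_subjects=20_000), 7)
        frame, _ = prepare_endpoint(df, "T1D")
        assert frame["event"].mean() == pytest.approx(0.052, abs=0.006)

    def test_event_times_positive_and_censoring_bounded(self, small_cohort):
        frame, _ = prepare_endpoint(small_cohort, "CD")
        assert (frame["time"] > 0).all()
        assert frame["time"].max() <= 180.0

    def test_calibration_hits_target(self):
        cfg = SimulationConfig(n_subjects=4000)
        scale = calibrate_baseline_scale(cfg, "T1D", 0.10, n=4000,
                                        seed=5, tol=0.01)
        eps = dict(cfg.endpoints)
        eps["T1D"] = dataclasses.replace(eps["T1D"], scale=scale)
        cfg2 = dataclasses.replace(cfg, endpoints=eps)
        df = simulate_cohort(cfg2, 99)
        frame, _ = prepare_endpoint(df, "T1D")
        assert frame["event"].mean() == pytest.approx(0.10, abs=0.02)


class TestCoverageSimulation:
    def test_c4a_deleted_signal_model(self):
        cfg = SimulationConfig(n_subjects=400)
        df = sample_genotypes(cfg, 13)
        profiles = simulate_coverage(df, cfg, 13)
        from tric4.c4 import DEFAULT_C4_CONFIG as C
        from tric4.c4 import normalize_profile
        picked = [(p, row) for p, (_, row) in zip(profiles, df.iterrows())
                  if row["gcn_a"] == 0 and row["total_gcn"] == 2]
        assert picked, "no C4A-null diploid subject drawn"
        prof, row = picked[0]
        prof = normalize_profile(prof)
        ua = prof.region_mean(prof.norm_uniq, C.c4a_unique_region)
        call_region = prof.region_mean(prof.norm_all, C.c4_total_region,
                                       exclude=C.herv_regions)
        assert ua < 0.1
        assert call_region == pytest.approx(1.0, abs=0.15)

    def test_unique_coverage_histogram_shape(self):
        # C4A deletions concentrate in DR3 homozygotes, mirroring the
        # zero-coverage peak seen in that subset
        cfg = SimulationConfig(n_subjects=600)
        df = sample_genotypes(cfg, 14)
        df = df[df["hla_genotype"] == "DR3/DR3"].reset_index(drop=True)
        profiles = simulate_coverage(df, cfg, 14)
        from tric4.c4 import DEFAULT_C4_CONFIG as C
        from tric4.c4 import normalize_profile
        ua = []
        for p in profiles:
            p = normalize_profile(p)
            ua.append(p.region_mean(p.norm_uniq, C.c4a_unique_region))
        ua = np.array(ua)
        # mass at zero (C4A deletions) and a peak near 0.3 (single copy)
        assert (ua < 0.04).mean() > 0.2
        single = ua[(ua > 0.2) & (ua < 0.4)]
        assert len(single) > 0
        assert np.median(single) == pytest.approx(0.3, abs=0.05)

    def test_noiseless_recovery(self):
        cfg = SimulationConfig(n_subjects=100)
        cfg = dataclasses.replace(
            cfg, coverage=dataclasses.replace(cfg.coverage, noise_cv=0.0))
        df = sample_genotypes(cfg, 15)
        profiles = simulate_coverage(df, cfg, 15)
        ok = [call_sample(p).total_gcn == t
              for p, t in zip(profiles, df["total_gcn"])]
        assert all(ok)


class TestExpressionSimulation:
    def test_determinism(self):
        cfg = SimulationConfig(n_subjects=40)
        df = sample_genotypes(cfg, 16)
        a = simulate_expression(df, cfg, 16)
        b = simulate_expression(df, cfg, 16)
        pd.testing.assert_frame_equal(a.counts, b.counts)


@pytest.fixture(scope="module")
def bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    cfg = SimulationConfig(n_subjects=250)
    manifest = write_fixture_bundle(cfg, 77, out)
    return out, cfg, manifest


class TestFixtureBundle:
    def test_manifest(self, bundle):
        out, cfg, manifest = bundle
        assert manifest["seed"] == 77
        on_disk = json.loads((out / "manifest.json").read_text())
        assert on_disk == manifest

    def test_vcf_round_trip_recovers_genotypes(self, bundle):
        out, cfg, _ = bundle
        calls = call_cohort_from_vcf(out / "genotypes.vcf")
        meta = read_metadata(out / "meta.tsv")
        merged = calls.merge(meta, on="subject_id")
        assert (merged["genotype"] == merged["trisnp_genotype"]).all()
        assert (merged["trisnp_101_dosage_x"]
                == merged["trisnp_101_dosage_y"]).all()
        # mode-imputed B8 dosage matches the simulated truth
        assert (merged["b8_dosage_x"] == merged["b8_dosage_y"]).mean() > 0.99

    def test_coverage_round_trip_recovers_gcn(self, bundle):
        out, cfg, _ = bundle
        windows = WindowBed.from_bed(out / "windows.bed")
        profiles = read_coverage_long(out / "coverage.tsv", windows)
        meta = read_metadata(out / "meta.tsv").set_index("subject_id")
        sim = pd.read_csv(out / "meta.tsv", sep="\t")
        df = sample_genotypes(cfg, 77)
        truth = df.set_index("subject_id")
        hits = []
        for p in profiles:
            call = call_sample(p)
            row = truth.loc[call.sample_id]
            hits.append((call.total_gcn, call.gcn_a, call.gcn_b)
                        == (row["total_gcn"], row["gcn_a"], row["gcn_b"]))
        assert np.mean(hits) >= 0.99

    def test_byte_identical_rerun(self, bundle, tmp_path):
        out, cfg, _ = bundle
        again = tmp_path / "again"
        write_fixture_bundle(cfg, 77, again)
        for name in ("genotypes.vcf", "meta.tsv", "windows.bed",
                     "coverage.tsv", "counts.tsv", "covars.tsv"):
            assert filecmp.cmp(out / name, again / name, shallow=False), name

    def test_expression_files_consistent(self, bundle):
        out, _, _ = bundle
        counts = pd.read_csv(out / "counts.tsv", sep="\t", index_col="gene")
        covars = pd.read_csv(out / "covars.tsv", sep="\t")
        assert list(counts.columns) == covars["sample_id"].tolist()
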