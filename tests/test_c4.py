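import numpy as np
import pytest

from tric4.c4 import (
    C4Call,
    C4RegionConfig,
    CoverageProfile,
    DEFAULT_C4_CONFIG,
    WindowBed,
    call_paralog_gcn,
    call_sample,
    call_total_gcn,
    make_windows,
    normalize_profile,
    window_depth,
)
from tric4.cohort import SimulationConfig, sample_genotypes, simulate_coverage
from tric4.errors import DomainError, NormalizationError, WindowMismatchError

CFG = DEFAULT_C4_CONFIG


def flat_profile(flank_depth=30.0, c4_depth=None, uniq_a=None, uniq_b=None,
                 uniq_background=0.0):
    """Deterministic profile with uniform depth per region class."""
    windows = make_windows(start=CFG.flank_regions[0][0],
                           end=CFG.flank_regions[1][1])
    n = len(windows)
    depth_all = np.full(n, flank_depth)
    depth_uniq = np.full(n, uniq_background)
    c4_mask = windows.mask(CFG.c4_total_region)
    depth_all[c4_mask] = c4_depth if c4_depth is not None else flank_depth
    if uniq_a is not None:
        depth_uniq[windows.mask(CFG.c4a_unique_region)] = uniq_a
    if uniq_b is not None:
        depth_uniq[windows.mask(CFG.c4b_unique_region)] = uniq_b
    return CoverageProfile("s1", windows, depth_all, depth_uniq)


class TestWindows:
    def test_make_windows_tiling(self):
        w = make_windows("chr6", 0, 5500, 1000)
        assert len(w) == 6
        assert w.lengths[-1] == 500
        assert (w.lengths[:-1] == 1000).all()

    def test_mhc_default_span(self):
        w = make_windows()
        assert w.starts[0] == 28_510_000
        assert w.ends[-1] == 33_482_000

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            WindowBed("chr6", np.array([0, 500]), np.array([1000, 1500]))

    def test_bed_round_trip(self, tmp_path):
        w = make_windows("chr6", 100, 4100, 1000)
        path = tmp_path / "w.bed"
        w.to_bed(path)
        back = WindowBed.from_bed(path)
        assert back.chrom == "chr6"
        assert (back.starts == w.starts).all()
        assert (back.ends == w.ends).all()


class TestWindowDepth:
    def test_arithmetic(self):
        w = make_windows("chr6", 0, 2000, 1000)
        prof = window_depth("s", w, [30000, 0], [15000, 0])
        assert prof.depth_all[0] == pytest.approx(30.0)
        assert prof.depth_all[1] == 0.0
        assert prof.depth_uniq[0] == pytest.approx(15.0)

    def test_poisson_fixture_oracle(self):
        rng = np.random.default_rng(5)
        per_base = rng.poisson(30, 1000)
        w = make_windows("chr6", 0, 1000, 1000)
        prof = window_depth("s", w, [per_base.sum()], [per_base.sum()])
        assert prof.depth_all[0] == pytest.approx(per_base.mean())
        assert abs(prof.depth_all[0] - 30.0) < 1.0

    def test_mismatch(self):
        w = make_windows("chr6", 0, 3000, 1000)
        with pytest.raises(WindowMismatchError):
            window_depth("s", w, [1.0, 2.0], [1.0, 2.0, 3.0])


class TestNormalize:
    def test_self_normalization(self):
        prof = normalize_profile(flat_profile(30.0, c4_depth=30.0))
        c4 = prof.region_mean(prof.norm_all, CFG.c4_total_region)
        assert c4 == pytest.approx(2.0)

    def test_half_depth_gives_one(self):
        prof = normalize_profile(flat_profile(30.0, c4_depth=15.0))
        c4 = prof.region_mean(prof.norm_all, CFG.c4_total_region)
        assert c4 == pytest.approx(1.0)

    def test_unique_region_scaling(self):
        prof = normalize_profile(flat_profile(40.0, uniq_a=6.0))
        ua = prof.region_mean(prof.norm_uniq, CFG.c4a_unique_region)
        assert ua == pytest.approx(0.3)

    def test_zero_flank_raises(self):
        with pytest.raises(NormalizationError):
            normalize_profile(flat_profile(0.0))


class TestCallTotal:
    @pytest.mark.parametrize("value,expected", [
        (0.95, 2), (1.55, 3), (2.10, 4),
        (1.4, 2), (1.9, 3),   # boundaries assign to the lower class
        (0.0, 2),
    ])
    def test_thresholds(self, value, expected):
        assert call_total_gcn(value) == expected

    def test_negative_raises(self):
        with pytest.raises(DomainError):
            call_total_gcn(-0.1)

    def test_monotone(self):
        grid = np.linspace(0, 3, 301)
        calls = [call_total_gcn(v) for v in grid]
        assert all(a <= b for a, b in zip(calls, calls[1:]))


class TestCallParalog:
    @pytest.mark.parametrize("ua,ub,total,expected", [
        (0.01, 0.58, 2, (0, 2)),   # C4A null
        (0.30, 0.29, 2, (1, 1)),
        (0.61, 0.30, 3, (2, 1)),
        (0.90, 0.30, 4, (3, 1)),   # ratio 3 > 2.5
        (0.58, 0.60, 4, (2, 2)),
    ])
    def test_heuristic(self, ua, ub, total, expected):
        a, b, _ = call_paralog_gcn(ua, ub, total)
        assert (a, b) == expected

    def test_b_null(self):
        a, b, _ = call_paralog_gcn(0.60, 0.01, 2)
        assert (a, b) == (2, 0)

    def test_both_null_flagged(self):
        a, b, flags = call_paralog_gcn(0.0, 0.0, 2)
        assert (a, b) == (0, 2)
        assert "both_paralogs_null" in flags

    def test_split_sums_to_total_exhaustive(self):
        for ua in np.linspace(0, 1.2, 13):
            for ub in np.linspace(0, 1.2, 13):
                for total in (2, 3, 4):
                    a, b, _ = call_paralog_gcn(ua, ub, total)
                    assert a + b == total

    def test_swap_symmetry_outside_null_branch(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            ua, ub = rng.uniform(0.05, 1.2, 2)
            if ua == ub:
                continue
            for total in (2, 3, 4):
                a1, b1, _ = call_paralog_gcn(ua, ub, total)
                a2, b2, _ = call_paralog_gcn(ub, ua, total)
                assert (a1, b1) == (b2, a2)

    def test_bad_total(self):
        with pytest.raises(DomainError):
            call_paralog_gcn(0.3, 0.3, 5)


class TestCallSample:
    def test_c4a_deleted_101_like_sample(self):
        prof = flat_profile(30.0, c4_depth=15.0, uniq_a=0.0, uniq_b=9.0)
        call = call_sample(prof)
        assert (call.total_gcn, call.gcn_a, call.gcn_b) == (2, 0, 2)
        assert call.a_null and not call.b_null

    def test_balanced_four_copy(self):
        prof = flat_profile(30.0, c4_depth=30.0, uniq_a=9.0, uniq_b=8.7)
        call = call_sample(prof)
        assert (call.total_gcn, call.gcn_a, call.gcn_b) == (4, 2, 2)

    def test_all_zero_profile_errors(self):
        with pytest.raises(NormalizationError):
            call_sample(flat_profile(0.0))

    def test_low_total_flag(self):
        prof = flat_profile(30.0, c4_depth=6.0, uniq_a=4.0, uniq_b=4.0)
        call = call_sample(prof)
        assert call.total_gcn == 2
        assert "total_coverage_below_diploid_peak" in call.qc_flags

    def test_invariant_enforced_by_type(self):
        with pytest.raises(ValueError):
            C4Call("s", 3, 1, 1)


class TestRecovery:
    def test_noiseless_round_trip_exact(self):
        import dataclasses
        cfg = SimulationConfig(n_subjects=150)
        cfg = dataclasses.replace(
            cfg, coverage=dataclasses.replace(cfg.coverage, noise_cv=0.0))
        df = sample_genotypes(cfg, 21)
        profiles = simulate_coverage(df, cfg, 21)
        for prof, (_, row) in zip(profiles, df.iterrows()):
            call = call_sample(prof)
            assert call.total_gcn == row["total_gcn"]
            assert (call.gcn_a, call.gcn_b) == (row["gcn_a"], row["gcn_b"])

    def test_recovery_at_ten_percent_cv(self):
        import dataclasses
        cfg = SimulationConfig(n_subjects=300)
        cfg = dataclasses.replace(
            cfg, coverage=dataclasses.replace(cfg.coverage, noise_cv=0.10))
        df = sample_genotypes(cfg, 22)
        profiles = simulate_coverage(df, cfg, 22)
        calls = [call_sample(p) for p in profiles]
        total_ok = np.mean([c.total_gcn == t for c, t in
                            zip(calls, df["total_gcn"])])
        split_ok = np.mean([(c.gcn_a, c.gcn_b) == (a, b) for c, a, b in
                            zip(calls, df["gcn_a"], df["gcn_b"])])
        assert total_ok >= 0.99
        assert split_ok >= 0.97


class TestUniqMatrix:
    def test_heatmap_matrix_shape_and_values(self):
        from tric4.c4 import norm_uniq_matrix
        profs = [flat_profile(30.0, uniq_a=4.5), flat_profile(30.0, uniq_a=0.0)]
        profs[1].sample_id = "s2"
        mat = norm_uniq_matrix(profs)
        n_c4_windows = flat_profile().windows.mask(CFG.c4_total_region).sum()
        assert mat.shape == (2, n_c4_windows)
        a_cols = [c for c in mat.columns
                  if CFG.c4a_unique_region[0] <= c < CFG.c4a_unique_region[1]]
        assert mat.loc["s1", a_cols].mean() == pytest.approx(0.3)
        assert mat.loc["s2", a_cols].mean() == pytest.approx(0.0)
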