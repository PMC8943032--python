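import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from modiolus.curvature import curvature_profile
from modiolus.insertion import offset_trajectory
from modiolus.measures import DerivedMeasures, derive_measures, derive_measures_table
from modiolus.anatomy import individualize
from modiolus.stats import correlate
from modiolus.synthetic import (
    CLINICAL_NOISE,
    MethodNoiseProfile,
    SyntheticPopulationConfig,
    add_measurement_noise,
    build_correlation,
    generate_cohort,
    generate_population,
    generate_segments,
    population_config,
    segment_table,
)


class TestConfig:
    def test_correlation_matrices_positive_definite(self):
        for lat_mod in (0.7, 0.37):
            c = build_correlation(lat_mod)
            assert np.linalg.eigvalsh(c).min() > 0
            assert np.allclose(np.diag(c), 1.0)
            assert c[0, 2] == pytest.approx(lat_mod, abs=0.02)

    def test_invalid_correlation_rejected(self):
        bad = np.array(
            [[1, 0.99, -0.99, 0], [0.99, 1, 0.9, 0], [-0.99, 0.9, 1, 0], [0, 0, 0, 1.0]]
        )
        with pytest.raises(ValueError):
            SyntheticPopulationConfig(
                n=10, mean=(9, 7, 5, 3), sd=(0.4,) * 4, correlation=bad
            )

    def test_unknown_profile(self):
        with pytest.raises(ValueError):
            population_config("mri")


class TestGeneratePopulation:
    def test_large_sample_means_match_calibration(self):
        cfg = population_config("corrosion", n=10_000, seed=5)
        pop = generate_population(cfg)
        # tolerance 4*sd/sqrt(n) per measure
        for col, mean, sd in zip(
            ["A_lat", "B_lat", "A_mod", "B_mod"], cfg.mean, cfg.sd
        ):
            assert pop[col].mean() == pytest.approx(mean, abs=4 * sd / 100.0)

    def test_sd_to_zero_limit(self):
        cfg = SyntheticPopulationConfig(
            n=20, mean=(9.24, 6.80, 5.46, 3.17), sd=(1e-9,) * 4,
            correlation=np.eye(4), seed=1,
        )
        pop = generate_population(cfg)
        assert np.allclose(pop[["A_lat", "B_lat", "A_mod", "B_mod"]], cfg.mean)

    def test_deterministic_under_seed(self):
        cfg = population_config("clinical", n=50, seed=9)
        pd.testing.assert_frame_equal(generate_population(cfg), generate_population(cfg))

    def test_physical_ordering_enforced(self):
        pop = generate_population(population_config("clinical", n=500, seed=2))
        assert (pop["A_lat"] > pop["A_mod"]).all()
        assert (pop["B_lat"] > pop["B_mod"]).all()

    def test_truncation_bias_negligible(self):
        """Rejection at ±4 SD / physical ordering moves means < 0.5% of SD."""
        cfg = population_config("corrosion", n=50_000, seed=7)
        pop = generate_population(cfg)
        for col, mean, sd in zip(
            ["A_lat", "B_lat", "A_mod", "B_mod"], cfg.mean, cfg.sd
        ):
            assert abs(pop[col].mean() - mean) < 0.005 * sd + 4 * sd / np.sqrt(cfg.n)

    def test_parameter_recovery_over_replicates(self):
        """500 cohorts of n=108: mean Pearson r within 0.7±0.05 and mean
        CV of A_mod within 0.0586±0.01 of the corrosion calibration."""
        rs, cvs = [], []
        for seed in range(500):
            pop = generate_population(population_config("corrosion", n=108, seed=seed))
            rs.append(correlate(pop["A_lat"], pop["A_mod"]).statistic)
            cvs.append(pop["A_mod"].std(ddof=1) / pop["A_mod"].mean())
        assert np.mean(rs) == pytest.approx(0.7, abs=0.05)
        assert np.mean(cvs) == pytest.approx(0.0586, abs=0.01)


class TestGenerateSegments:
    @given(st.integers(0, 10_000))
    def test_round_trip_inverse(self, seed):
        rng = np.random.default_rng(seed)
        a_mod = rng.uniform(4.0, 6.5)
        b_mod = rng.uniform(2.5, 4.0)
        m = DerivedMeasures(
            A_lat=a_mod + rng.uniform(2.0, 5.0),
            B_lat=b_mod + rng.uniform(2.0, 4.0),
            A_mod=a_mod, B_mod=b_mod, r0=a_mod,
        )
        seg = generate_segments(m, seed)
        back = derive_measures(seg)
        assert back.A_lat == pytest.approx(m.A_lat, rel=1e-12)
        assert back.A_mod == pytest.approx(m.A_mod, rel=1e-12)
        assert back.B_lat == pytest.approx(m.B_lat, rel=1e-12)
        assert back.B_mod == pytest.approx(m.B_mod, rel=1e-12)
        assert seg.A_segments[0] < back.r0 < back.A_lat

    def test_outer_segments_sum_constraint(self):
        m = DerivedMeasures(A_lat=7.0, B_lat=6.0, A_mod=5.0, B_mod=4.0, r0=4.0)
        seg = generate_segments(m, 3)
        assert seg.A_segments[0] + seg.A_segments[6] == pytest.approx(2.0, rel=1e-12)

    def test_cohort_outer_segment_mean(self):
        """Corrosion calibration implies mean A1+A7 ≈ 9.24 − 5.46 = 3.78 mm."""
        pop = generate_population(population_config("corrosion", n=2000, seed=4))
        segs = segment_table(pop, seed=4)
        outer = segs["A1"] + segs["A7"]
        assert outer.mean() == pytest.approx(3.78, abs=0.05)

    def test_invalid_measures_rejected(self):
        with pytest.raises(ValueError):
            DerivedMeasures(A_lat=5.0, B_lat=6.0, A_mod=5.0, B_mod=4.0, r0=4.0)


class TestMeasurementNoise:
    def test_identity_profile(self):
        pop = generate_population(population_config("corrosion", n=30, seed=1))
        out = add_measurement_noise(pop, MethodNoiseProfile())
        pd.testing.assert_frame_equal(out, pop)

    def test_clinical_offset_shifts_modiolar_means(self):
        """The soft-tissue offset moves mean A_mod from ≈5.46 to ≈4.66."""
        pop = generate_population(population_config("corrosion", n=4000, seed=8))
        noisy = add_measurement_noise(pop, CLINICAL_NOISE, seed=8)
        assert noisy["A_mod"].mean() == pytest.approx(5.46 - 0.80, abs=0.03)
        assert noisy["B_mod"].mean() == pytest.approx(3.17 - 0.35, abs=0.03)

    def test_noise_attenuates_correlation(self):
        """Independent measurement noise dilutes the lateral-modiolar
        correlation (classical attenuation)."""
        pop = generate_population(population_config("corrosion", n=10_000, seed=6))
        clean = correlate(pop["A_lat"], pop["A_mod"]).statistic
        noisy_tab = add_measurement_noise(
            pop, MethodNoiseProfile(noise_sd=0.3), seed=6
        )
        noisy = correlate(noisy_tab["A_lat"], noisy_tab["A_mod"]).statistic
        assert noisy < clean

    def test_clinical_cohort_correlation_below_corrosion(self):
        """At matched n, the clinical profile's lateral-modiolar
        correlation sits well below the corrosion one."""
        cor = generate_population(population_config("corrosion", n=1000, seed=10))
        cli = generate_population(population_config("clinical", n=1000, seed=10))
        r_cor = correlate(cor["A_lat"], cor["A_mod"]).statistic
        r_cli = correlate(cli["A_lat"], cli["A_mod"]).statistic
        assert r_cli < r_cor - 0.2


class TestFullPipelineSmoke:
    def test_generated_cohort_flows_through_geometry(self):
        """Measures → spiral scaling → insertion → curvature stays finite."""
        cohort = generate_cohort("corrosion", n=5, seed=12)
        derived = derive_measures_table(cohort)
        assert derived.attrs["n_incomplete"] == 0
        for _, rec in derived.iterrows():
            modiolar, lateral = individualize(
                rec["A_lat"], rec["B_lat"], rec["A_mod"], rec["B_mod"]
            )
            traj = offset_trajectory(modiolar, lateral, 0.8, theta_max=500.0,
                                     truncate=True)
            tr = traj.transition
            assert np.isfinite([tr.l_str, tr.IA_str, tr.l_crit]).all()
            prof = curvature_profile(modiolar, lateral, 0.8)
            assert np.isfinite(prof.basal_max_r_fold)
            assert np.isfinite(prof.r_pre[10:]).all()
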