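"""Measurement plumbing: velocity arithmetic, transfer-time estimation,
voxelwise g-ratio maps, the packaged cohort table and the synthetic
cohort generator."""

import numpy as np
import pytest

from axonmorph import (
    CurrentDensitySeries,
    InvalidParameterError,
    PeakDetectionError,
    SubjectMeasurement,
    SynthCohortSpec,
    estimate_ihtt,
    load_table1,
    split_ihtt_sd,
    synth_cohort,
    velocity_from_tract,
    voxel_g_ratio,
)
from axonmorph.invivo import read_g_samples

# published per-subject velocities and confidence intervals (m/s); the
# second subject's lower endpoint is the value implied by the published
# length and transfer time (149.38/14.59 = 10.24)
PRINTED_VELOCITIES = [
    (13.23, 10.63, 17.52), (12.75, 10.24, 16.88), (11.38, 9.15, 15.08),
    (11.63, 9.34, 15.40), (13.17, 10.58, 17.44), (14.63, 11.75, 19.37),
    (13.48, 10.83, 17.85), (12.79, 10.28, 16.94), (13.05, 10.49, 17.29),
    (12.14, 9.75, 16.08), (13.27, 10.66, 17.57), (14.70, 11.81, 19.47),
    (15.74, 12.64, 20.85), (13.17, 10.58, 17.45),
]


class TestVelocityFromTract:
    def test_units_cancel(self):
        """mm/ms equals m/s with no numeric factor."""
        v, ci = velocity_from_tract(100.0, 10.0, 0.0)
        assert v == pytest.approx(10.0, rel=1e-14)
        assert ci == (pytest.approx(10.0), pytest.approx(10.0))

    def test_cohort_table_regression(self):
        """Every packaged subject reproduces the printed velocity and CI
        endpoints to ±0.01 m/s; the cohort mean is 13.22 m/s."""
        subjects = load_table1()
        assert len(subjects) == 14
        for s, (v, lo, hi) in zip(subjects, PRINTED_VELOCITIES):
            assert s.velocity_mps == pytest.approx(v, abs=0.01)
            assert s.velocity_ci_mps[0] == pytest.approx(lo, abs=0.01)
            assert s.velocity_ci_mps[1] == pytest.approx(hi, abs=0.01)
        assert np.mean([s.velocity_mps for s in subjects]) == pytest.approx(13.22, abs=0.01)

    def test_sd_must_stay_below_ihtt(self):
        with pytest.raises(InvalidParameterError):
            velocity_from_tract(100.0, 10.0, 10.0)
        with pytest.raises(InvalidParameterError):
            velocity_from_tract(100.0, -1.0)


class TestIhttEstimation:
    def test_twelve_sample_offset_matches_group_granularity(self, make_cd_series, cd_time_axis):
        """Peaks 12 samples apart at 1024 Hz give IHTT = 11.719 ms — the
        granularity behind the published group value."""
        contra = make_cd_series(141.0)
        ipsi = CurrentDensitySeries(cd_time_axis, np.roll(contra.amplitude, 12))
        res = estimate_ihtt(contra, ipsi)
        assert res.ihtt_ms == pytest.approx(12 / 1024 * 1000, abs=1e-9)

    def test_published_peak_latencies(self, make_cd_series):
        """Bumps at 141 and 152 ms yield an ~11 ms transfer time with
        peaks at those latencies."""
        res = estimate_ihtt(make_cd_series(141.0), make_cd_series(152.0))
        assert res.ihtt_ms == pytest.approx(11.0, abs=1.0)
        assert res.contra_peak_ms == pytest.approx(141.0, abs=1.0)
        assert res.ipsi_peak_ms == pytest.approx(152.0, abs=1.0)

    def test_amplitude_rescaling_invariance(self, make_cd_series):
        a = estimate_ihtt(make_cd_series(141.0), make_cd_series(152.0))
        b = estimate_ihtt(make_cd_series(141.0, amplitude=3.7), make_cd_series(152.0, amplitude=0.2))
        assert a.ihtt_ms == b.ihtt_ms

    def test_identical_series_zero_ihtt(self, make_cd_series):
        s = make_cd_series(140.0)
        assert estimate_ihtt(s, s).ihtt_ms == 0.0

    def test_ordering_violation_raises(self, make_cd_series):
        with pytest.raises(PeakDetectionError):
            estimate_ihtt(make_cd_series(152.0), make_cd_series(141.0))

    def test_flat_series_raises(self, make_cd_series, cd_time_axis):
        flat = CurrentDensitySeries(cd_time_axis, np.ones_like(cd_time_axis))
        with pytest.raises(PeakDetectionError):
            estimate_ihtt(flat, make_cd_series(150.0))

    def test_peak_significance_against_baseline(self, make_cd_series, cd_time_axis):
        """Per-subject peak amplitudes clearly above baseline give a small
        signed-rank p-value."""
        contra = make_cd_series(141.0)
        ipsi = make_cd_series(152.0)
        scales = np.linspace(0.8, 1.2, 12)[:, None]
        res = estimate_ihtt(
            contra, ipsi,
            subject_contra=scales * contra.amplitude[None, :],
            subject_ipsi=scales * ipsi.amplitude[None, :],
        )
        assert res.contra_p_value < 0.01
        assert res.ipsi_p_value < 0.01

    def test_nonuniform_time_axis_rejected(self):
        t = np.array([0.0, 1.0, 3.0, 6.0])
        with pytest.raises(InvalidParameterError):
            CurrentDensitySeries(t, np.zeros(4), (0.0, 1.0), (1.0, 5.0))


class TestSplitIhttSd:
    def test_identical_splits_zero_sd(self, make_cd_series):
        pair = (make_cd_series(141.0), make_cd_series(152.0))
        assert split_ihtt_sd([pair] * 4) == pytest.approx(0.0, abs=1e-12)

    def test_matches_sample_sd_of_split_ihtts(self, make_cd_series):
        """Splits engineered with known peak offsets reproduce the sample
        sd of those offsets (e.g. {10.74, 11.72, 12.70, 13.67} → ≈1.26 ms)."""
        offsets = [10.74, 11.72, 12.70, 13.67]
        splits = [(make_cd_series(141.0), make_cd_series(141.0 + o)) for o in offsets]
        got = split_ihtt_sd(splits)
        # peak latencies snap to the 1024 Hz sample grid
        assert got == pytest.approx(np.std(offsets, ddof=1), abs=0.15)
        assert got == pytest.approx(1.26, abs=0.15)

    def test_jittered_splits_match_generator_sd(self, make_cd_series):
        rng = np.random.default_rng(77)
        offsets = 11.72 + rng.normal(0.0, 2.0, 4)
        splits = [(make_cd_series(141.0), make_cd_series(141.0 + o)) for o in offsets]
        assert split_ihtt_sd(splits) == pytest.approx(np.std(offsets, ddof=1), abs=0.3)

    def test_requires_four_splits(self, make_cd_series):
        pair = (make_cd_series(141.0), make_cd_series(152.0))
        with pytest.raises(InvalidParameterError):
            split_ihtt_sd([pair] * 3)


class TestVoxelGRatio:
    def test_reference_arithmetic(self):
        """MT_sat=1.5, v_iso=0.1, v_ic=0.6 → MVF=0.345, AVF≈0.354,
        g≈0.712."""
        g = voxel_g_ratio(1.5, 0.1, 0.6)
        assert float(g) == pytest.approx(0.7115, abs=0.001)

    def test_limiting_conventions(self):
        assert float(voxel_g_ratio(0.0, 0.1, 0.6)) == pytest.approx(1.0)  # no myelin
        # MVF == AVF -> g = 1/sqrt(2); solve mt_sat so that both match
        mt = 0.9
        mvf = 0.23 * mt
        v_ic = mvf / (1 - mvf)
        assert float(voxel_g_ratio(mt, 0.0, v_ic)) == pytest.approx(1 / np.sqrt(2), rel=1e-9)

    def test_undefined_voxels_masked_not_raised(self):
        g = voxel_g_ratio(np.array([1.5, 2.0]), np.array([0.1, 0.0]), np.array([0.6, 0.0]))
        assert not g.mask[0] and g.mask[1]

    def test_output_range_where_defined(self):
        rng = np.random.default_rng(3)
        mt = rng.uniform(0.0, 3.0, 500)
        viso = rng.uniform(0.0, 0.9, 500)
        vic = rng.uniform(0.01, 1.0, 500)
        g = voxel_g_ratio(mt, viso, vic)
        assert np.all((g.compressed() > 0) & (g.compressed() <= 1))

    def test_domain_validation(self):
        with pytest.raises(InvalidParameterError):
            voxel_g_ratio(1.0, 1.5, 0.5)
        with pytest.raises(InvalidParameterError):
            voxel_g_ratio(10.0, 0.1, 0.5)  # alpha_cal*mt_sat >= 1


class TestSyntheticCohort:
    def test_zero_noise_subjects_identical_to_spec_means(self):
        spec = SynthCohortSpec(
            n_subjects=3, between_g_sd=0.0, within_g_sd=0.0,
            tract_length_sd_mm=0.0, ihtt_between_sd_ms=0.0,
        )
        subs = synth_cohort(spec)
        for s in subs:
            assert s.g_mean == pytest.approx(spec.mean_g, abs=1e-12)
            assert s.tract_length_mm == pytest.approx(spec.tract_length_mean_mm)
            assert s.velocity_mps == pytest.approx(
                spec.tract_length_mean_mm / spec.ihtt_mean_ms, rel=1e-12
            )

    def test_seeded_reproducibility(self):
        a = synth_cohort(SynthCohortSpec(n_subjects=4, seed=5))
        b = synth_cohort(SynthCohortSpec(n_subjects=4, seed=5))
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.g_samples, sb.g_samples)
            assert sa.tract_length_mm == sb.tract_length_mm

    def test_velocity_dispersion_matches_design(self):
        """The length/IHTT Gaussians imply velocities ≈ N(10, 0.8) m/s."""
        vs = [s.velocity_mps for s in synth_cohort(SynthCohortSpec(n_subjects=400, seed=1))]
        assert np.mean(vs) == pytest.approx(10.0, abs=0.15)
        assert np.std(vs) == pytest.approx(0.8, abs=0.2)

    def test_subject_measurement_validation(self):
        with pytest.raises(InvalidParameterError):
            SubjectMeasurement("X", 100.0, 10.0, g_mean=1.5)
        with pytest.raises(InvalidParameterError):
            SubjectMeasurement("X", 100.0, 10.0)  # neither g_mean nor samples
        s = SubjectMeasurement("X", 100.0, 10.0, g_samples=np.array([0.6, 0.7, 0.8]))
        assert s.g_mean == pytest.approx(0.7)


def test_read_g_samples_with_and_without_header(tmp_path):
    p1 = tmp_path / "with_header.csv"
    p1.write_text("g_mri\n0.69\n0.71\n")
    p2 = tmp_path / "bare.csv"
    p2.write_text("0.69\n0.71\n")
    assert np.allclose(read_g_samples(p1), [0.69, 0.71])
    assert np.allclose(read_g_samples(p2), [0.69, 0.71])
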