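"""Phantom, waveform and paired-flow generators."""

import numpy as np
import pytest

from aortoflow.imaging import image_quality
from aortoflow.stats import bland_altman
from aortoflow.synthetic import (
    InletWaveform,
    PhantomSpec,
    generate_inlet_waveform,
    generate_paired_flows,
    generate_phantom,
    paper_regime_spec,
)


class TestPhantom:
    def test_noiseless_lumen_is_exact(self):
        spec = PhantomSpec(noise_sd=0.0, seed=3)
        vol, mask = generate_phantom(spec)
        assert np.all(vol.voxels[mask.voxels] == spec.object_intensity)
        assert np.all(vol.voxels[~mask.voxels] == spec.background_intensity)
        # analytic cylinder volume within voxel-discretization tolerance
        nz = spec.grid_shape[2]
        analytic = np.pi * spec.lumen_radius**2 * nz * spec.voxel_spacing[2]
        perimeter_band = (
            2 * np.pi * spec.lumen_radius * max(spec.voxel_spacing[:2]) * nz
        )
        assert abs(mask.volume_mm3() - analytic) < perimeter_band

    def test_mask_independent_of_noise_and_seed(self):
        base = generate_phantom(PhantomSpec(seed=1))[1]
        for seed, sd in ((2, 3.59), (3, 10.0), (1, 0.0)):
            other = generate_phantom(PhantomSpec(seed=seed, noise_sd=sd))[1]
            assert np.array_equal(base.voxels, other.voxels)

    def test_noise_independence_across_seeds(self):
        spec1, spec2 = PhantomSpec(seed=10), PhantomSpec(seed=11)
        v1 = generate_phantom(spec1)[0].voxels
        v2 = generate_phantom(spec2)[0].voxels
        assert not np.array_equal(v1, v2)
        assert np.all(np.abs(v1 - v2) < 6.0 * spec1.noise_sd * np.sqrt(2))

    def test_regime_matches_printed_image_quality(self):
        """Default regime reproduces CNR ~ 3.65 (and BI ~ 27.9) from ROIs."""
        vol, _ = generate_phantom(paper_regime_spec(seed=5))
        iq = image_quality(vol)
        assert iq.cnr == pytest.approx(3.65, rel=0.10)
        assert iq.bi == pytest.approx(27.85, rel=0.10)

    def test_flap_voxels_are_background(self):
        spec = PhantomSpec(flap_present=True, seed=2, noise_sd=0.0)
        vol, mask = generate_phantom(spec)
        no_flap = generate_phantom(
            PhantomSpec(seed=2, noise_sd=0.0)
        )[1]
        flap_vox = no_flap.voxels & ~mask.voxels
        assert flap_vox.any()
        assert np.all(vol.voxels[flap_vox] == spec.background_intensity)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(grid_shape=(0, 4, 4)),
            dict(flap_present=True, flap_thickness=25.0),
            dict(noise_sd=-1.0),
            dict(object_intensity=50.0, background_intensity=60.0),
            dict(flap_offset=1.5),
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            PhantomSpec(**bad)


class TestWaveform:
    def test_mean_velocity_contract(self):
        wf = generate_inlet_waveform("real", 0.2, 1.0)
        assert wf.mean() == pytest.approx(0.2, abs=1e-3)

    def test_high_intensity_scales_mean_and_peak(self):
        real = generate_inlet_waveform("real", 0.2, 1.0)
        high = generate_inlet_waveform("high", 0.2, 1.0)
        assert high.peak() == pytest.approx(1.5 * real.peak(), rel=1e-12)
        assert high.mean() == pytest.approx(1.5 * real.mean(), rel=1e-9)

    def test_covers_one_cardiac_cycle(self):
        wf = generate_inlet_waveform("real", 0.1, period=1.0)
        assert wf.time_samples[0] == 0.0
        assert wf.time_samples[-1] == pytest.approx(1.0, abs=1e-12)
        assert wf.velocity_samples[0] == pytest.approx(wf.velocity_samples[-1])

    @pytest.mark.parametrize("period", [0.5, 0.8, 1.0])
    @pytest.mark.parametrize("kind,factor", [("real", 1.0), ("high", 1.5)])
    def test_mean_within_half_percent_any_kind(self, period, kind, factor):
        wf = generate_inlet_waveform(kind, 0.15, period)
        assert wf.mean() == pytest.approx(0.15 * factor, rel=5e-3)

    def test_nonnegative_and_systolic_peak(self):
        wf = generate_inlet_waveform("real", 0.1, 1.0, peak_to_mean=2.5)
        assert np.all(wf.velocity_samples >= 0)
        assert wf.peak() == pytest.approx(2.5 * 0.1, rel=1e-9)
        assert wf.time_samples[np.argmax(wf.velocity_samples)] < 0.4

    def test_periodic_interpolation(self):
        wf = generate_inlet_waveform("real", 0.1, 1.0)
        assert wf(2.35) == pytest.approx(wf(0.35), rel=1e-12)

    @pytest.mark.parametrize("mean,period", [(-0.1, 1.0), (0.1, 0.0), (0.0, 1.0)])
    def test_invalid_arguments_rejected(self, mean, period):
        with pytest.raises(ValueError):
            generate_inlet_waveform("real", mean, period)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            generate_inlet_waveform("medium", 0.1, 1.0)


class TestPairedFlows:
    def test_degenerate_noise_gives_exact_bias(self):
        a, b = generate_paired_flows(20, true_bias=0.05, sd=0.0, seed=1)
        assert np.allclose(b - a, 0.05)

    def test_deterministic_under_seed(self):
        a1, b1 = generate_paired_flows(50, 0.02, 0.01, seed=42)
        a2, b2 = generate_paired_flows(50, 0.02, 0.01, seed=42)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_minimum_pairs_enforced(self):
        with pytest.raises(ValueError):
            generate_paired_flows(2, 0.0, 0.01, seed=0)

    def test_bias_recovered_at_large_n(self):
        """Mean difference converges to the planted bias (3 SE tolerance)."""
        n, sd = 10_000, 0.02
        a, b = generate_paired_flows(n, true_bias=0.05, sd=sd, seed=7)
        res = bland_altman(b, a)
        assert res.bias == pytest.approx(0.05, abs=3.0 * sd / np.sqrt(n))
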