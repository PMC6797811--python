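"""Preprocessing-chain tests: denoise, segment, resample, normalize, rasterize."""

import time
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsecnn.preprocess import (
    AMP_MAX,
    N_POINTS,
    DegenerateCycleError,
    NormalizedCycle,
    PulseCycle,
    denoise,
    image_to_values,
    normalize_amplitude,
    preprocess_record,
    rasterize,
    read_png,
    resample_cycle,
    segment_cycles,
    segmentation_feet,
    write_png,
)
from pulsecnn.synthetic import CLASS_SPECS, RawPulseSignal, generate_record


class TestDenoise:
    def test_constant_signal_unchanged(self):
        sig = RawPulseSignal(np.full(256, 3.0), fs=100.0)
        out = denoise(sig)
        np.testing.assert_allclose(out.samples, sig.samples, atol=1e-9)

    def test_clean_record_barely_changed(self, clean_record):
        out = denoise(clean_record)
        rng_amp = clean_record.samples.max() - clean_record.samples.min()
        rmse = np.sqrt(np.mean((out.samples - clean_record.samples) ** 2))
        assert rmse < 0.02 * rng_amp

    def test_improves_rmse_at_10db(self, h1_spec=None):
        from pulsecnn.synthetic import DATASET1_SPECS, snr_db_to_noise_sd
        rec = generate_record(DATASET1_SPECS["H1"], 10,
                              noise_sd=snr_db_to_noise_sd(10.0),
                              rng=np.random.default_rng(11))
        out = denoise(rec)
        rmse_before = np.sqrt(np.mean((rec.samples - rec.clean) ** 2))
        rmse_after = np.sqrt(np.mean((out.samples - rec.clean) ** 2))
        assert rmse_after < rmse_before

    def test_preserves_length_and_fs(self, noisy_record):
        out = denoise(noisy_record)
        assert len(out.samples) == len(noisy_record.samples)
        assert out.fs == noisy_record.fs

    def test_nearly_idempotent(self, noisy_record):
        once = denoise(noisy_record)
        twice = denoise(once)
        first_change = np.sqrt(np.mean((once.samples - noisy_record.samples) ** 2))
        second_change = np.sqrt(np.mean((twice.samples - once.samples) ** 2))
        assert second_change < 0.1 * first_change

    def test_level_too_deep_rejected(self):
        sig = RawPulseSignal(np.ones(32), fs=100.0)
        with pytest.raises(ValueError, match="too short"):
            denoise(sig, level=8)


class TestSegmentation:
    def test_ten_cycle_record_recovered(self, clean_record, noisy_record):
        cycles = segment_cycles(clean_record)
        assert len(cycles) == 10
        feet = segmentation_feet(cycles, clean_record)
        for b in clean_record.true_boundaries:
            assert np.min(np.abs(feet - b)) <= 3
        # at 20 dB SNR the count is still exact and feet stay close
        den = denoise(noisy_record)
        noisy_cycles = segment_cycles(den)
        assert len(noisy_cycles) == 10
        noisy_feet = segmentation_feet(noisy_cycles, den)
        for b in noisy_record.true_boundaries:
            assert np.min(np.abs(noisy_feet - b)) <= 5

    def test_single_cycle(self, h1_spec):
        rec = generate_record(h1_spec, 1, rng=np.random.default_rng(0))
        assert len(segment_cycles(rec)) == 1

    def test_flat_signal_warns_and_returns_empty(self):
        sig = RawPulseSignal(np.zeros(500), fs=100.0)
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            assert segment_cycles(sig) == []
        assert any("no detectable" in str(x.message) for x in w)

    def test_cycles_partition_analyzable_span(self, noisy_record):
        den = denoise(noisy_record)
        cycles = segment_cycles(den)
        total = sum(len(c.samples) for c in cycles)
        feet = segmentation_feet(cycles, den)
        assert total == len(den.samples) - feet[0]


class TestResample:
    def test_output_length_is_200(self, clean_record):
        cyc = segment_cycles(clean_record)[0]
        assert len(resample_cycle(cyc)) == N_POINTS

    def test_identity_on_uniform_200(self):
        v = np.sin(np.linspace(0, 3, 200))
        cyc = PulseCycle(v, fs=100.0)
        np.testing.assert_allclose(resample_cycle(cyc), v, atol=1e-12)

    def test_linear_ramp_exact(self):
        ramp = np.arange(50.0)
        out = resample_cycle(PulseCycle(ramp, fs=100.0), 200)
        line = np.linspace(0.0, 49.0, 200)
        assert out[0] == 0.0 and out[-1] == 49.0
        np.testing.assert_allclose(out, line, atol=1e-12)

    def test_endpoints_preserved(self, clean_record):
        cyc = segment_cycles(clean_record)[1]
        out = resample_cycle(cyc)
        assert out[0] == cyc.samples[0]
        assert out[-1] == cyc.samples[-1]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            resample_cycle(np.array([1.0]), 200)


class TestNormalize:
    def test_affine_map_forced(self):
        v = np.full(200, 2.0)
        v[0], v[100] = 1.0, 3.0
        out = normalize_amplitude(v)
        assert out.values.min() == 0.0
        assert out.values.max() == AMP_MAX
        assert out.values[50] == pytest.approx(100.0)

    def test_idempotent(self):
        v = np.random.default_rng(0).random(200)
        once = normalize_amplitude(v).values
        twice = normalize_amplitude(once).values
        np.testing.assert_allclose(twice, once, atol=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateCycleError):
            normalize_amplitude(np.full(200, 5.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_any_nonconstant_input_hits_bounds(self, seed):
        v = np.random.default_rng(seed).random(200) * 37.0 - 5.0
        out = normalize_amplitude(v).values
        assert out.min() == 0.0
        assert out.max() == AMP_MAX


class TestRasterize:
    def test_dimensions(self, clean_record):
        cyc = segment_cycles(clean_record)[0]
        img = rasterize(normalize_amplitude(resample_cycle(cyc)))
        assert img.pixels.shape == (200, 200)

    def test_alternating_extremes_fill_full_height(self):
        """Connectivity is forced: each pair of adjacent columns spans the
        whole image height between the alternating extremes."""
        v = np.tile([0.0, 200.0], 100)
        fg = rasterize(NormalizedCycle(v)).pixels != 0
        for x in range(199):
            assert np.all(fg[:, x] | fg[:, x + 1])

    def test_one_contiguous_run_per_column(self, clean_record):
        for cyc in segment_cycles(clean_record):
            img = rasterize(normalize_amplitude(resample_cycle(cyc)))
            fg = img.pixels != 0
            assert fg.any(axis=0).all()
            # a single run has exactly one 0->1 transition per column
            transitions = np.diff(fg.astype(int), axis=0) == 1
            assert np.all(transitions.sum(axis=0) + fg[0].astype(int) == 1)

    def test_round_trip_within_one_unit(self, clean_record):
        for cyc in segment_cycles(clean_record):
            norm = normalize_amplitude(resample_cycle(cyc))
            rec = image_to_values(rasterize(norm))
            assert np.max(np.abs(rec - norm.values)) <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            NormalizedCycle(np.full(200, 300.0))


class TestChainAndIO:
    @pytest.mark.parametrize("label", ["H1", "Hn", "At", "BV"])
    def test_pipeline_contract_and_speed(self, label):
        rec = generate_record(CLASS_SPECS[label], 10, noise_sd=0.1,
                              wander_amplitude=0.05,
                              rng=np.random.default_rng(3), subject_id="S9")
        t0 = time.perf_counter()
        out = preprocess_record(rec)
        elapsed = time.perf_counter() - t0
        assert elapsed < 1.0  # well under a second per record
        assert len(out) == 10
        for _cyc, norm, img in out:
            assert norm.values.shape == (200,)
            assert norm.values.min() == 0.0 and norm.values.max() == 200.0
            assert img.pixels.shape == (200, 200)

    def test_png_round_trip(self, tmp_path, clean_record):
        cyc = segment_cycles(clean_record)[0]
        img = rasterize(normalize_amplitude(resample_cycle(cyc)))
        p = tmp_path / "x.png"
        write_png(img, p)
        np.testing.assert_array_equal(read_png(p), img.pixels)
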