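"""Drift, eddy-current, averaging and Hankel-SVD water-removal behaviour."""

import numpy as np
import pytest

from gabaquant.core import FID, frequency_shift
from gabaquant.fit import SingletPrior, fit_singlets
from gabaquant.hlsvd import NoSignalError
from gabaquant.preprocess import (
    PreprocessConfig,
    combine,
    correct_drift,
    eddy_correct,
    estimate_water_offset,
    preprocess_blocks,
    remove_water,
)
from gabaquant.simulate import SimulationConfig, simulate_megapress


class TestWaterOffset:
    def test_known_offset(self, mega_params, line_fid_factory):
        fid = line_fid_factory(mega_params, freq_hz=12.5, label="WATER_REF")
        assert estimate_water_offset(fid) == pytest.approx(12.5, abs=0.1)

    def test_on_carrier(self, mega_params, line_fid_factory):
        fid = line_fid_factory(mega_params, freq_hz=0.0, label="WATER_REF")
        assert estimate_water_offset(fid) == pytest.approx(0.0, abs=0.1)

    def test_robust_to_noise(self, mega_params, line_fid_factory):
        clean = line_fid_factory(mega_params, freq_hz=7.0, amplitude=100.0,
                                 label="WATER_REF")
        rng = np.random.default_rng(0)
        errors = []
        for _ in range(100):
            noisy = clean.with_samples(
                clean.samples + rng.normal(0, 1.0, len(clean))
                + 1j * rng.normal(0, 1.0, len(clean))
            )
            errors.append(abs(estimate_water_offset(noisy) - 7.0))
        assert max(errors) < 0.5

    def test_all_zero_rejected(self, mega_params):
        fid = FID(np.zeros(mega_params.n_points), mega_params, "WATER_REF")
        with pytest.raises(NoSignalError):
            estimate_water_offset(fid)


class TestDriftCorrection:
    def _sim(self, drift):
        cfg = SimulationConfig(n_blocks=5, pairs_per_block=2, noise_sd=0.0,
                               drift_hz_per_block=drift,
                               true_amplitudes={"water": 100.0, "tCr": 3.0, "GABA+": 0.5})
        return simulate_megapress(cfg)

    def test_zero_drift_is_noop(self):
        fids = self._sim(0.0)
        corrected, offsets = correct_drift(fids)
        for orig, new in zip(fids, corrected):
            assert np.max(np.abs(orig.samples - new.samples)) < 1e-10
        assert all(abs(v) < 1e-6 for v in offsets.values())

    def test_linear_drift_removed(self):
        corrected, _ = correct_drift(self._sim(1.0))
        residual = [
            estimate_water_offset(f) for f in corrected if f.label == "WATER_REF"
        ]
        assert np.ptp(residual) < 0.2

    def test_correction_narrows_averaged_linewidth(self):
        fids = self._sim(2.0)
        corrected, _ = correct_drift(fids)

        def fwhm(transients):
            avg = transients[0].with_samples(
                np.mean([f.samples for f in transients], axis=0)
            )
            spec = avg.spectrum(zero_fill_to=8192)
            mag = spec.magnitude
            half = mag.max() / 2
            return np.sum(mag > half)

        offs = lambda fs: [f for f in fs if f.label == "OFF"]
        assert fwhm(offs(corrected)) <= fwhm(offs(fids))

    def test_block_without_water_reference_rejected(self, mega_params, line_fid_factory):
        off = line_fid_factory(mega_params, freq_hz=10.0, label="OFF")
        off.block_index = 0
        with pytest.raises(ValueError, match="WATER_REF"):
            correct_drift([off])


class TestEddyCorrection:
    def test_shared_phase_ramp_cancels(self, mega_params, line_fid_factory):
        t = mega_params.time_axis()
        ramp = np.exp(1j * (0.8 * np.sin(2 * np.pi * 3 * t) + 0.3))
        water = line_fid_factory(mega_params, freq_hz=0.0, amplitude=100.0,
                                 label="WATER_REF")
        metab = line_fid_factory(mega_params, freq_hz=0.0, amplitude=2.0)
        corrected = eddy_correct(metab.with_samples(metab.samples * ramp),
                                 water.with_samples(water.samples * ramp))
        # on-resonance line: envelope must come out purely real
        assert np.max(np.abs(corrected.samples.imag)) < 1e-10

    def test_identity_without_phase_error(self, mega_params, line_fid_factory):
        water = line_fid_factory(mega_params, freq_hz=0.0, label="WATER_REF")
        metab = line_fid_factory(mega_params, freq_hz=40.0)
        corrected = eddy_correct(metab, water)
        assert np.max(np.abs(corrected.samples - metab.samples)) < 1e-12

    def test_quadratic_phase_removed(self, mega_params, line_fid_factory):
        t = mega_params.time_axis()
        quad = np.exp(1j * 30.0 * t**2)
        water = line_fid_factory(mega_params, freq_hz=0.0, amplitude=10.0,
                                 label="WATER_REF")
        metab = line_fid_factory(mega_params, freq_hz=0.0, amplitude=1.0)
        corrected = eddy_correct(metab.with_samples(metab.samples * quad),
                                 water.with_samples(water.samples * quad))
        phase = np.angle(corrected.samples[np.abs(corrected.samples) > 1e-6])
        assert np.max(np.abs(phase)) < 1e-10


class TestWaterRemoval:
    def test_pure_water_removed(self, mega_params, line_fid_factory):
        water = line_fid_factory(mega_params, freq_hz=0.0, amplitude=50.0)
        cleaned = remove_water(water, PreprocessConfig())
        assert cleaned.energy < 1e-6 * water.energy

    def test_metabolite_amplitude_preserved(self, mega_params, line_fid_factory):
        water_hz = mega_params.ppm_to_hz(4.7)
        tcr_hz = mega_params.ppm_to_hz(3.03)
        water = line_fid_factory(mega_params, freq_hz=water_hz, amplitude=50.0,
                                 linewidth_hz=7.0)
        tcr = line_fid_factory(mega_params, freq_hz=tcr_hz, amplitude=3.0)
        combined = water.with_samples(water.samples + tcr.samples)
        cleaned = remove_water(combined, PreprocessConfig())
        prior = SingletPrior(name="tCr", shift_ppm=3.03)
        fitted = fit_singlets(cleaned, [prior])
        assert fitted.amplitudes["tCr"] == pytest.approx(3.0, rel=0.01)

    def test_empty_band_is_identity(self, mega_params, line_fid_factory):
        fid = line_fid_factory(mega_params, freq_hz=100.0)
        cfg = PreprocessConfig(water_band_ppm=(9.0, 9.5))
        cleaned = remove_water(fid, cfg)
        assert np.array_equal(cleaned.samples, fid.samples)

    def test_idempotent_within_energy_tolerance(self, mega_params, line_fid_factory):
        water = line_fid_factory(mega_params, freq_hz=2.0, amplitude=50.0)
        tcr = line_fid_factory(mega_params, freq_hz=mega_params.ppm_to_hz(3.03),
                               amplitude=3.0)
        fid = water.with_samples(water.samples + tcr.samples)
        once = remove_water(fid, PreprocessConfig())
        twice = remove_water(once, PreprocessConfig())
        assert abs(twice.energy - once.energy) < 0.01 * once.energy


class TestCombine:
    def test_identical_copies_average_to_themselves(self, mega_params, line_fid_factory):
        on = line_fid_factory(mega_params, freq_hz=10.0, label="ON")
        off = line_fid_factory(mega_params, freq_hz=20.0, label="OFF")
        avg_off, diff = combine([on, on, off, off])
        assert np.allclose(avg_off.samples, off.samples)
        assert np.allclose(diff.samples, on.samples - off.samples)

    def test_on_equals_off_gives_zero_difference(self, mega_params, line_fid_factory):
        a = line_fid_factory(mega_params, freq_hz=10.0, label="ON")
        b = a.with_samples(a.samples, label="OFF")
        _, diff = combine([a, b])
        assert np.max(np.abs(diff.samples)) == 0.0

    def test_averaging_reduces_noise_like_sqrt_n(self, mega_params):
        rng = np.random.default_rng(5)
        sd, n = 1.0, 64
        offs = [
            FID(rng.normal(0, sd, 1024) + 1j * rng.normal(0, sd, 1024), mega_params, "OFF")
            for _ in range(n)
        ]
        on = FID(np.zeros(1024), mega_params, "ON")
        avg_off, _ = combine([on] + offs)
        assert np.std(avg_off.samples.real) == pytest.approx(sd / np.sqrt(n), rel=0.1)

    def test_mixed_params_rejected(self, mega_params, press_params, line_fid_factory):
        a = line_fid_factory(mega_params, freq_hz=0.0, label="ON")
        b = line_fid_factory(press_params, freq_hz=0.0, label="OFF")
        with pytest.raises(ValueError, match="mixed"):
            combine([a, b])


class TestChain:
    def test_drift_eddy_order_immaterial_below_noise_floor(self):
        cfg = SimulationConfig(n_blocks=3, pairs_per_block=2, noise_sd=0.1,
                               drift_hz_per_block=0.5, seed=2,
                               true_amplitudes={"water": 100.0, "tCr": 3.0, "GABA+": 0.5})
        fids = simulate_megapress(cfg)

        def by_block(transients):
            blocks = {}
            for f in transients:
                blocks.setdefault(f.block_index, []).append(f)
            return blocks

        def eddy_stage(transients):
            # every transient corrected against its block's water reference;
            # the water reference is corrected by itself (becomes zero-phase)
            out = []
            for idx, members in sorted(by_block(transients).items()):
                water = next(f for f in members if f.label == "WATER_REF")
                out.extend(eddy_correct(f, water) for f in members)
            return out

        def run(order):
            if order == "drift_first":
                corrected, _ = correct_drift(fids)
                corrected = eddy_stage(corrected)
            else:
                corrected = eddy_stage(fids)
                corrected, _ = correct_drift(corrected)
            return combine([f for f in corrected if f.label in ("ON", "OFF")])

        off_a, _ = run("drift_first")
        off_b, _ = run("eddy_first")
        noise_floor = cfg.noise_sd / np.sqrt(3 * 2)
        assert np.max(np.abs(off_a.samples - off_b.samples)) < noise_floor

    def test_full_preprocess_result(self):
        cfg = SimulationConfig(n_blocks=3, pairs_per_block=2, noise_sd=0.0,
                               drift_hz_per_block=1.0, residual_water_amplitude=3.0,
                               phase0_deg=20.0,
                               true_amplitudes={"water": 100.0, "tCr": 3.0, "GABA+": 0.5})
        result = preprocess_blocks(simulate_megapress(cfg))
        assert result.water_amplitude == pytest.approx(100.0, rel=1e-6)
        assert all(abs(v) < 0.2 for v in result.residual_offsets_hz.values())
        assert result.block_offsets_hz[2] == pytest.approx(2.0, abs=0.05)
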