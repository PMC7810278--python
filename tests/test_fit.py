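"""Fitting-engine correctness: exact recovery, Monte-Carlo bias, CRLB."""

import numpy as np
import pytest

from gabaquant.core import FID, MEGA_PRESS_DEFAULTS
from gabaquant.fit import (
    BasisModel,
    FitResults,
    SingletModel,
    SingletPrior,
    crlb_amplitudes,
    fit_basis,
    fit_error_percent,
    fit_singlets,
)
from gabaquant.simulate import BasisSet, MetaboliteModel, default_difference_basis

PARAMS = MEGA_PRESS_DEFAULTS


def _singlet_fid(amp, freq_hz, lw=5.0, phase=0.0, params=PARAMS):
    t = params.time_axis()
    s = amp * np.exp(1j * phase) * np.exp((2j * np.pi * freq_hz - np.pi * lw) * t)
    return FID(s, params, "OFF")


TCR_PRIOR = SingletPrior(name="tCr", shift_ppm=3.027)
OFF_PRIORS = [
    SingletPrior(name="tCho", shift_ppm=3.185),
    SingletPrior(name="tCr", shift_ppm=3.027),
    SingletPrior(name="tNAA", shift_ppm=2.008),
]


class TestSinglets:
    def test_noiseless_exact_recovery(self):
        fid = _singlet_fid(2.5, PARAMS.ppm_to_hz(3.027))
        res = fit_singlets(fid, [TCR_PRIOR])
        assert res.amplitudes["tCr"] == pytest.approx(2.5, rel=1e-6)
        assert res.converged

    def test_three_singlet_monte_carlo_mean(self):
        """tCho/tCr/tNAA pattern at SNR 50: mean amplitudes within 2 % of truth."""
        truth = {"tCho": 2.6, "tCr": 3.4, "tNAA": 4.6}
        clean = np.zeros(PARAMS.n_points, complex)
        for prior in OFF_PRIORS:
            clean += _singlet_fid(truth[prior.name], PARAMS.ppm_to_hz(prior.shift_ppm)).samples
        sd = truth["tCr"] / 50.0
        rng = np.random.default_rng(12)
        sums = {name: 0.0 for name in truth}
        n_rep = 100
        for _ in range(n_rep):
            noisy = clean + rng.normal(0, sd, len(clean)) + 1j * rng.normal(0, sd, len(clean))
            res = fit_singlets(FID(noisy, PARAMS, "OFF"), OFF_PRIORS)
            for name in truth:
                sums[name] += res.amplitudes[name]
        for name in truth:
            assert sums[name] / n_rep == pytest.approx(truth[name], rel=0.02)

    def test_amplitude_ratio_equals_peak_area_ratio(self):
        """Equal-width singlets: time-domain amplitudes match frequency areas.

        The oracle integrates each line's spectrum over a symmetric window
        around its position; for equal linewidths the capture fractions
        cancel in the ratio. Lines are integrated in isolation so sinc
        leakage from the truncated FID of one line cannot bleed into the
        other's window.
        """
        line_a, line_b = _singlet_fid(2.0, PARAMS.ppm_to_hz(3.2)), \
            _singlet_fid(5.0, PARAMS.ppm_to_hz(2.0))
        fid = line_a.with_samples(line_a.samples + line_b.samples)
        priors = [
            SingletPrior(name="a", shift_ppm=3.2),
            SingletPrior(name="b", shift_ppm=2.0),
        ]
        res = fit_singlets(fid, priors)
        spec_a = line_a.spectrum(zero_fill_to=16384)
        spec_b = line_b.spectrum(zero_fill_to=16384)
        area_a = np.sum(spec_a.values.real[np.abs(spec_a.ppm - 3.2) < 0.35])
        area_b = np.sum(spec_b.values.real[np.abs(spec_b.ppm - 2.0) < 0.35])
        amp_ratio = res.amplitudes["a"] / res.amplitudes["b"]
        assert amp_ratio == pytest.approx(area_a / area_b, rel=0.01)

    def test_phase_estimated(self):
        fid = _singlet_fid(2.5, PARAMS.ppm_to_hz(3.027), phase=np.deg2rad(25.0))
        res = fit_singlets(fid, [TCR_PRIOR])
        assert res.phase0_deg == pytest.approx(25.0, abs=0.1)
        assert res.amplitudes["tCr"] == pytest.approx(2.5, rel=1e-6)


def _diff_fid(amps, basis, params=PARAMS, noise_sd=0.0, rng=None):
    rendered = basis.render(params)
    clean = np.zeros(params.n_points, complex)
    for name, a in amps.items():
        clean += a * rendered[name].samples
    if noise_sd:
        clean = clean + rng.normal(0, noise_sd, len(clean)) \
            + 1j * rng.normal(0, noise_sd, len(clean))
    return FID(clean, params, "DIFF")


class TestBasisFit:
    def test_noiseless_exact_recovery(self, basis):
        fid = _diff_fid({"GABA+": 1.0, "Glu": 2.0}, basis)
        res = fit_basis(fid, basis)
        assert res.amplitudes["GABA+"] == pytest.approx(1.0, rel=1e-6)
        assert res.amplitudes["Glu"] == pytest.approx(2.0, rel=1e-6)

    def test_monte_carlo_bias_and_crsd_consistency(self, basis):
        """SNR 20, 100 noise draws: GABA+ bias < 3 %, SD consistent with CRSD."""
        amps = {"GABA+": 1.0, "Glu": 2.0, "Gln": 0.6, "NAA": 2.5, "NAAG": 0.4}
        rendered = basis.render(PARAMS)
        sd = abs(rendered["GABA+"].samples[0]) / 20.0
        rng = np.random.default_rng(21)
        est, crsds = [], []
        for _ in range(100):
            fid = _diff_fid(amps, basis, noise_sd=sd, rng=rng)
            res = fit_basis(fid, basis)
            est.append(res.amplitudes["GABA+"])
            crsds.append(res.crsd["GABA+"])
        est = np.array(est)
        assert abs(est.mean() - 1.0) < 0.03
        assert est.std() / np.mean(crsds) == pytest.approx(1.0, abs=0.25)

    def test_shifted_basis_recovers_offset(self, basis):
        from gabaquant.core import frequency_shift

        fid = _diff_fid({"GABA+": 1.0, "Glu": 2.0}, basis)
        shifted = frequency_shift(fid, 3.0)
        res = fit_basis(shifted, basis)
        assert res.delta_f_hz == pytest.approx(3.0, abs=0.05)
        assert res.amplitudes["GABA+"] == pytest.approx(1.0, rel=0.01)
        assert res.amplitudes["Glu"] == pytest.approx(2.0, rel=0.01)

    def test_basis_params_mismatch_rejected(self, basis, press_params):
        small = PARAMS
        other = basis.render(
            press_params.__class__(tr_ms=2000, te_ms=68, bandwidth_hz=4000,
                                   n_points=512, f0_mhz=127.74)
        )
        fid = _diff_fid({"GABA+": 1.0}, basis, params=small)
        with pytest.raises(ValueError, match="different acquisition"):
            BasisModel(fid, other)

    def test_rank_deficient_basis_warns(self):
        m = MetaboliteModel(name="x", lines=((3.0, 1.0, 0.0),))
        dup = BasisSet(models={"a": m, "b": m})
        fid = _diff_fid({"a": 1.0}, dup)
        with pytest.warns(UserWarning, match="condition number"):
            BasisModel(fid, dup)


class TestCRLB:
    def test_doubling_noise_doubles_crsd(self, basis):
        fid = _diff_fid({"GABA+": 1.0, "Glu": 2.0}, basis)
        res = fit_basis(fid, basis)
        c1 = crlb_amplitudes(res, fid, noise_sigma=0.1)
        c2 = crlb_amplitudes(res, fid, noise_sigma=0.2)
        for name in c1:
            assert c2[name] == pytest.approx(2.0 * c1[name], rel=1e-10)

    def test_single_lorentzian_matches_analytic_fisher(self):
        """CRSD equals the closed-form single damped-exponential bound.

        Independent oracle: the Fisher information of the model
        a*exp(i*phi)*exp((2*pi*i*f - pi*W) t) in parameters (phi, a, f, W) is
        assembled here from hand-derived derivatives and inverted directly.
        """
        amp, f_hz, lw, sigma = 2.5, PARAMS.ppm_to_hz(3.027), 5.0, 0.05
        fid = _singlet_fid(amp, f_hz, lw=lw)
        res = fit_singlets(fid, [TCR_PRIOR], noise_sigma=sigma)

        t = PARAMS.time_axis()
        s = amp * np.exp((2j * np.pi * f_hz - np.pi * lw) * t)
        d_phi = 1j * s
        d_a = s / amp
        d_f = 2j * np.pi * t * s
        d_w = -np.pi * t * s
        jac = np.column_stack([d_phi, d_a, d_f, d_w])
        fisher = np.real(jac.conj().T @ jac) / sigma**2
        expected = np.sqrt(np.linalg.inv(fisher)[1, 1])
        assert res.crsd["tCr"] == pytest.approx(expected, rel=0.01)

    def test_scale_equivariance(self, basis):
        fid = _diff_fid({"GABA+": 1.0, "Glu": 2.0}, basis)
        rng = np.random.default_rng(3)
        noisy = fid.with_samples(
            fid.samples + rng.normal(0, 0.02, len(fid)) + 1j * rng.normal(0, 0.02, len(fid))
        )
        res1 = fit_basis(noisy, basis)
        res2 = fit_basis(noisy.with_samples(10.0 * noisy.samples), basis)
        for name in res1.amplitudes:
            assert res2.amplitudes[name] == pytest.approx(10 * res1.amplitudes[name], rel=1e-4)
            assert res2.crsd[name] == pytest.approx(10 * res1.crsd[name], rel=1e-3)


class TestFitError:
    @pytest.mark.parametrize(
        "crsd,amp,expected", [(0.015, 1.0, 1.5), (0.0, 1.0, 0.0), (0.1, 20.0, 0.5)]
    )
    def test_percentage_arithmetic(self, crsd, amp, expected):
        res = FitResults(
            amplitudes={"x": amp}, frequencies_hz={}, dampings_hz={},
            phase0_deg=0.0, crsd={"x": crsd},
            residual=FID(np.zeros(PARAMS.n_points), PARAMS, "DIFF"), model=None,
        )
        assert fit_error_percent(res)["x"] == pytest.approx(expected)

    def test_zero_amplitude_reported_missing(self):
        res = FitResults(
            amplitudes={"x": 0.0}, frequencies_hz={}, dampings_hz={},
            phase0_deg=0.0, crsd={"x": 0.1},
            residual=FID(np.zeros(PARAMS.n_points), PARAMS, "DIFF"), model=None,
        )
        assert "x" not in fit_error_percent(res)


class TestRecoveryGrid:
    def test_bias_and_interval_coverage(self, basis):
        """Across amplitudes {0.5, 1, 2} x SNR {10, 20, 50}: relative bias
        < 5 % per cell and pooled +-1.96*CRSD coverage in [90 %, 99 %]."""
        rendered = basis.render(PARAMS)
        unit = abs(rendered["GABA+"].samples[0])
        rng = np.random.default_rng(7)
        n_rep = 20
        covered = total = 0
        for true_amp in (0.5, 1.0, 2.0):
            for snr in (10, 20, 50):
                sd = true_amp * unit / snr
                amps = {"GABA+": true_amp, "Glu": 2.0, "NAA": 2.5}
                ests = []
                for _ in range(n_rep):
                    fid = _diff_fid(amps, basis, noise_sd=sd, rng=rng)
                    res = fit_basis(fid, basis)
                    a, c = res.amplitudes["GABA+"], res.crsd["GABA+"]
                    ests.append(a)
                    covered += abs(a - true_amp) <= 1.96 * c
                    total += 1
                assert abs(np.mean(ests) - true_amp) / true_amp < 0.05
        assert 0.90 <= covered / total <= 0.99
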