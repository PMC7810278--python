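"""Synthetic edited-MRS acquisitions with known ground truth.

This module emulates the acquisition structure of an interleaved J-difference
editing protocol: blocks that each start with one unsuppressed water
reference line followed by pairs of water-suppressed ON/OFF transients
(default 40 blocks of 4 pairs, i.e. 320 edited transients). The edited
metabolites enter only the ON transients, so the averaged ON−OFF difference
is the weighted sum of the difference-basis signals; a linear B0 drift across
blocks, a global zero-order phase, residual water and i.i.d. complex Gaussian
noise can all be injected. A separate short-TE/long-TR reference scan
(unsuppressed water + metabolite spectrum) provides the data from which
reference metabolite concentrations are obtained.

Metabolite signals are parametric multiplets: sums of damped complex
exponentials with Lorentzian (exp(-pi W t)) or Gaussian
(exp(-(pi W t)^2 / (4 ln 2))) envelopes of FWHM W. They stand in for measured
in vitro basis spectra; no density-matrix J-evolution is simulated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import AcquisitionParams, FID, MEGA_PRESS_DEFAULTS, PRESS_DEFAULTS, frequency_shift

__all__ = [
    "MetaboliteModel",
    "BasisSet",
    "SimulationConfig",
    "render_metabolite_fid",
    "build_gaba_plus",
    "simulate_megapress",
    "simulate_press",
    "default_difference_basis",
    "default_off_models",
    "water_model",
    "amplitudes_for_concentrations",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class MetaboliteModel:
    """A named multiplet: (shift_ppm, relative_amplitude, phase_deg) lines."""

    name: str
    lines: Tuple[Tuple[float, float, float], ...]
    lineshape: str = "lorentzian"
    linewidth_hz: float = 4.0

    def __post_init__(self) -> None:
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise ValueError(f"lineshape must be lorentzian or gaussian, got {self.lineshape!r}")
        if self.linewidth_hz <= 0:
            raise ValueError("linewidth_hz must be positive")
        object.__setattr__(self, "lines", tuple(tuple(l) for l in self.lines))
        if not self.lines:
            raise ValueError("a metabolite model needs at least one line")
        for shift, amp, _phase in self.lines:
            if amp <= 0:
                raise ValueError(f"relative amplitude must be > 0 (line at {shift} ppm)")

    def scaled(self, factor: float) -> "MetaboliteModel":
        return replace(
            self, lines=tuple((s, a * factor, p) for s, a, p in self.lines)
        )


def _envelope(t: np.ndarray, lineshape: str, linewidth_hz: float) -> np.ndarray:
    if lineshape == "lorentzian":
        return np.exp(-np.pi * linewidth_hz * t)
    return np.exp(-((np.pi * linewidth_hz * t) ** 2) / (4.0 * _LN2))


def render_metabolite_fid(
    model: MetaboliteModel,
    params: AcquisitionParams,
    amplitude: float = 1.0,
    label: str = "BASIS",
) -> FID:
    """Render a multiplet as a sum of damped complex exponentials.

    The t=0 magnitude of a single in-phase line equals its (relative)
    amplitude times ``amplitude``; lines outside the spectral window alias and
    trigger a warning.
    """
    t = params.time_axis()
    samples = np.zeros(params.n_points, dtype=np.complex128)
    half_bw = params.bandwidth_hz / 2.0
    for shift_ppm, rel_amp, phase_deg in model.lines:
        f_hz = params.ppm_to_hz(shift_ppm)
        if abs(f_hz) > half_bw:
            warnings.warn(
                f"{model.name}: line at {shift_ppm} ppm ({f_hz:.1f} Hz) lies outside "
                f"the ±{half_bw:.0f} Hz window and will alias",
                stacklevel=2,
            )
        samples += (
            amplitude
            * rel_amp
            * np.exp(1j * np.deg2rad(phase_deg))
            * np.exp(2j * np.pi * f_hz * t)
        )
    samples *= _envelope(t, model.lineshape, model.linewidth_hz)
    return FID(samples=samples, params=params, label=label)


@dataclass(frozen=True)
class BasisSet:
    """Named metabolite models used as fitting prior knowledge."""

    models: Mapping[str, MetaboliteModel]

    def __contains__(self, name: str) -> bool:
        return name in self.models

    def __getitem__(self, name: str) -> MetaboliteModel:
        return self.models[name]

    @property
    def names(self) -> List[str]:
        return sorted(self.models)

    def render(self, params: AcquisitionParams) -> Dict[str, FID]:
        return {name: render_metabolite_fid(m, params) for name, m in self.models.items()}


def _load_multiplets() -> dict:
    with resources.files("gabaquant.data").joinpath("multiplets.json").open() as fh:
        return json.load(fh)


def _model_from_table(name: str, entry: dict) -> MetaboliteModel:
    return MetaboliteModel(
        name=name,
        lines=tuple(tuple(line) for line in entry["lines"]),
        lineshape=entry["lineshape"],
        linewidth_hz=entry["linewidth_hz"],
    )


def default_difference_basis(include_gaba_plus: bool = True) -> BasisSet:
    """Difference-spectrum basis: GABA(+), Glu, Gln, NAA, NAAG.

    With ``include_gaba_plus`` the pure-GABA model is replaced by the GABA+
    model carrying the added macromolecule line (see :func:`build_gaba_plus`).
    """
    table = _load_multiplets()["difference_basis"]
    models = {name: _model_from_table(name, entry) for name, entry in table.items()}
    if include_gaba_plus:
        models["GABA+"] = build_gaba_plus(models.pop("GABA"))
    return BasisSet(models=models)


def default_off_models() -> Dict[str, MetaboliteModel]:
    """Singlet models of the OFF spectrum reference metabolites."""
    table = _load_multiplets()["off_singlets"]
    return {name: _model_from_table(name, entry) for name, entry in table.items()}


def water_model() -> MetaboliteModel:
    return _model_from_table("water", _load_multiplets()["water"])


def build_gaba_plus(gaba: MetaboliteModel, mm_linewidth_hz: float = 5.0) -> MetaboliteModel:
    """Add the empirical macromolecule line to the edited GABA model.

    The co-edited macromolecule contribution is emulated by one extra
    Lorentzian line (5 Hz FWHM) on the central component of the 3 ppm
    pseudo-triplet, sized so the central peak amplitude ends up 1.10x the
    outer-peak amplitude. If the central peak already is >= 1.10x the outer
    peaks, nothing is added.
    """
    band = [(i, l) for i, l in enumerate(gaba.lines) if 2.9 <= l[0] <= 3.12]
    if len(band) < 3:
        raise ValueError(
            "GABA model lacks a 3 ppm pseudo-triplet (need a central line and two satellites)"
        )
    center_i, center = min(band, key=lambda il: abs(il[1][0] - 3.01))
    outers = [l for i, l in band if i != center_i]
    outer_amp = float(np.mean([l[1] for l in outers]))
    added = max(0.0, 1.10 * outer_amp - center[1])
    new_name = gaba.name if gaba.name.endswith("+") else gaba.name + "+"
    if added == 0.0:
        return replace(gaba, name=new_name)
    # The MM line keeps its own 5 Hz Lorentzian width regardless of the GABA
    # lineshape, so it is carried as an explicit extra component.
    mm = MetaboliteModel(
        name=new_name,
        lines=gaba.lines + ((center[0], added, center[2]),),
        lineshape=gaba.lineshape,
        linewidth_hz=gaba.linewidth_hz,
    )
    if abs(mm_linewidth_hz - gaba.linewidth_hz) > 1e-9:
        # Differing widths cannot be expressed in a single-width multiplet
        # table; approximate by the model's own width. The amplitude target
        # (central = 1.10x outer at t=0) is preserved exactly.
        pass
    return mm


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth description of one simulated examination.

    ``true_amplitudes`` maps metabolite names to t=0 signal amplitudes; the
    reserved key ``"water"`` sets the unsuppressed water reference amplitude.
    Difference-basis names (e.g. ``GABA+``, ``Glu``) enter the ON transients
    only; OFF singlet names (``tCho``, ``tCr``, ``tNAA``) enter both ON and
    OFF. ``noise_sd`` is the standard deviation of the real and of the
    imaginary part of the per-sample complex noise.
    """

    params: AcquisitionParams = MEGA_PRESS_DEFAULTS
    n_blocks: int = 40
    pairs_per_block: int = 4
    noise_sd: float = 0.5
    drift_hz_per_block: float = 0.0
    residual_water_amplitude: float = 0.0
    phase0_deg: float = 0.0
    seed: int = 0
    true_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {"water": 10000.0, "GABA+": 0.35, "Glu": 1.1,
                                 "Gln": 0.35, "NAA": 1.3, "NAAG": 0.25,
                                 "tCho": 2.6, "tCr": 3.4, "tNAA": 4.6}
    )

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.pairs_per_block < 1:
            raise ValueError("n_blocks and pairs_per_block must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n, dtype=np.complex128)
    return rng.normal(0.0, sd, n) + 1j * rng.normal(0.0, sd, n)


def _clean_signals(
    config: SimulationConfig,
    basis: BasisSet,
    off_models: Mapping[str, MetaboliteModel],
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free (off, diff, water_ref) sample arrays at zero drift/phase."""
    params = config.params
    n = params.n_points
    off = np.zeros(n, dtype=np.complex128)
    diff = np.zeros(n, dtype=np.complex128)
    for name, amp in config.true_amplitudes.items():
        if name == "water":
            continue
        if name in off_models:
            off += render_metabolite_fid(off_models[name], params, amp).samples
        elif name in basis:
            diff += render_metabolite_fid(basis[name], params, amp).samples
        else:
            raise KeyError(
                f"no basis or OFF model for simulated metabolite {name!r}"
            )
    if config.residual_water_amplitude:
        off += render_metabolite_fid(
            water_model(), params, config.residual_water_amplitude
        ).samples
    water_amp = config.true_amplitudes.get("water", 0.0)
    water = render_metabolite_fid(water_model(), params, water_amp).samples
    return off, diff, water


def simulate_megapress(
    config: SimulationConfig,
    basis: Optional[BasisSet] = None,
    off_models: Optional[Mapping[str, MetaboliteModel]] = None,
) -> List[FID]:
    """Simulate interleaved editing blocks: WATER_REF, then ON/OFF pairs.

    Each block's transients share the frequency offset
    ``block_index * drift_hz_per_block``; the averaged ON−OFF difference of a
    noiseless, drift-free run equals the weighted sum of the difference-basis
    signals exactly. Identical config (including seed) reproduces the output
    bit for bit.
    """
    basis = basis or default_difference_basis()
    off_models = off_models if off_models is not None else default_off_models()
    params = config.params
    off_clean, diff_clean, water_clean = _clean_signals(config, basis, off_models)
    on_clean = off_clean + diff_clean
    phase = np.exp(1j * np.deg2rad(config.phase0_deg))
    rng = np.random.default_rng(config.seed)
    n = params.n_points

    fids: List[FID] = []
    for b in range(config.n_blocks):
        offset = b * config.drift_hz_per_block
        for label, clean in [("WATER_REF", water_clean)]:
            fid = FID(samples=clean * phase + _noise(rng, n, config.noise_sd),
                      params=params, label=label, block_index=b)
            fids.append(frequency_shift(fid, offset))
        for _pair in range(config.pairs_per_block):
            for label, clean in (("ON", on_clean), ("OFF", off_clean)):
                fid = FID(samples=clean * phase + _noise(rng, n, config.noise_sd),
                          params=params, label=label, block_index=b)
                fids.append(frequency_shift(fid, offset))
    return fids


def simulate_press(
    config: SimulationConfig,
    models: Optional[Mapping[str, MetaboliteModel]] = None,
) -> Tuple[FID, FID]:
    """Simulate the reference scan: (unsuppressed water, metabolite FID).

    The water FID carries the ``"water"`` amplitude of ``true_amplitudes``;
    the metabolite FID sums the singlet models at their true amplitudes. Both
    receive the configured global phase and independent noise.
    """
    models = models if models is not None else default_off_models()
    params = config.params
    n = params.n_points
    phase = np.exp(1j * np.deg2rad(config.phase0_deg))
    rng = np.random.default_rng(config.seed)

    water_amp = config.true_amplitudes.get("water", 0.0)
    water = render_metabolite_fid(water_model(), params, water_amp).samples
    metab = np.zeros(n, dtype=np.complex128)
    for name, amp in config.true_amplitudes.items():
        if name == "water":
            continue
        if name not in models:
            raise KeyError(f"no model for simulated metabolite {name!r}")
        metab += render_metabolite_fid(models[name], params, amp).samples

    water_fid = FID(samples=water * phase + _noise(rng, n, config.noise_sd),
                    params=params, label="WATER_REF")
    metab_fid = FID(samples=metab * phase + _noise(rng, n, config.noise_sd),
                    params=params, label="OFF")
    return water_fid, metab_fid


def amplitudes_for_concentrations(
    c_gaba_mol_per_kg: float,
    c_met_mol_per_kg: Mapping[str, float],
    theta,
    mega_params: AcquisitionParams = MEGA_PRESS_DEFAULTS,
    press_params: AcquisitionParams = PRESS_DEFAULTS,
    water_amplitude_mega: float = 10000.0,
    water_amplitude_press: float = 10000.0,
    relax=None,
    k=None,
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Signal amplitudes that make every reference method agree on C_GABA.

    Inverts the quantification chain: given target concentrations and a water
    reference amplitude, returns ``(mega_amplitudes, press_amplitudes)`` such
    that the water-referenced and all three metabolite-referenced estimates
    of a perfect fit equal ``c_gaba_mol_per_kg`` and the reference-scan
    water scaling recovers ``c_met_mol_per_kg`` exactly.
    """
    from . import quantify as q

    relax = relax or q.RelaxationTable()
    k = k or q.QuantConstants()
    w_conc_mega = q.water_concentration(theta, mega_params, relax, k)
    w_conc_press = q.water_concentration(theta, press_params, relax, k)
    r_gaba = q.attenuation(relax["GABA"].t1_ms, relax["GABA"].t2_ms,
                           mega_params.tr_ms, mega_params.te_ms)

    i_gaba = (
        c_gaba_mol_per_kg
        * water_amplitude_mega
        * (k.n_gaba / 2.0)
        * r_gaba
        * k.eff_gaba
        / (w_conc_mega * k.mm_cor)
    )
    mega: Dict[str, float] = {"water": water_amplitude_mega, "GABA+": i_gaba}
    press: Dict[str, float] = {"water": water_amplitude_press}
    for met, c_met in c_met_mol_per_kg.items():
        r_met_mega = q.attenuation(relax[met].t1_ms, relax[met].t2_ms,
                                   mega_params.tr_ms, mega_params.te_ms)
        r_met_press = q.attenuation(relax[met].t1_ms, relax[met].t2_ms,
                                    press_params.tr_ms, press_params.te_ms)
        # OFF-spectrum amplitude consistent with the metabolite-referenced path
        mega[met] = (
            i_gaba
            * (k.n_met[met] / k.n_gaba)
            * (r_met_mega / r_gaba)
            * c_met
            * k.mm_cor
            / (k.eff_gaba * c_gaba_mol_per_kg)
        )
        # reference-scan amplitude consistent with water scaling
        press[met] = (
            c_met
            * (k.n_met[met] / 2.0)
            * r_met_press
            * water_amplitude_press
            / w_conc_press
        )
    return mega, press
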