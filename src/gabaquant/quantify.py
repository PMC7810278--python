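"""Absolute GABA quantification with water or metabolite internal references.

The edited GABA+ intensity from the difference spectrum is converted to a
concentration in mol/kg wet weight ("molal" scale) either against the
unsuppressed water line,

    C_GABA = (I_GABA / I_H2O) * (2 / N_GABA) * (1 / R_GABA)
             * W_conc * MM_cor / eff_GABA,

or against a reference metabolite (tCho, tCr or tNAA) fitted in the OFF
spectrum,

    C_GABA = (I_GABA / I_MET) * (N_MET / N_GABA) * (R_MET / R_GABA)
             * C_MET * MM_cor / eff_GABA,

where R = exp(-TE/T2) * [1 - exp(-TR/T1)] is the relaxation attenuation
factor of each species at the echo/repetition time of the editing sequence,
N is the number of protons contributing to the resonance, MM_cor corrects for
the co-edited macromolecule fraction of GABA+ (about half of the 3 ppm edited
signal) and eff_GABA is the editing efficiency. The water reference W_conc is
the voxel water concentration corrected for gray matter / white matter / CSF
partial volume and per-compartment relaxation:

    W_conc = W_H2O * (f_GM R_GM + f_WM R_WM + f_CSF R_CSF) / (1 - f_CSF),
    f_x = c_x * theta_x / (c_GM theta_GM + c_WM theta_WM + c_CSF theta_CSF),

with theta_x the tissue volume fractions, c_x the relative MR-visible water
densities and W_H2O = 55.51 mol/kg the molal concentration of pure water.
Division by (1 - f_CSF) expresses the concentration per kg of CSF-free tissue.

All concentrations are carried internally in mol/kg and reported in mmol/kg.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Dict, Mapping, Optional, Tuple

from .core import AcquisitionParams

__all__ = [
    "TissueFractions",
    "RelaxationEntry",
    "RelaxationTable",
    "QuantConstants",
    "attenuation",
    "water_fractions",
    "water_concentration",
    "gaba_water_ref",
    "gaba_metabolite_ref",
    "metabolite_concentration_press",
    "QuantReport",
    "quant_report",
]


def _load_defaults() -> dict:
    with resources.files("gabaquant.data").joinpath("relaxation_constants.json").open() as fh:
        return json.load(fh)


_DEFAULTS = _load_defaults()


@dataclass(frozen=True)
class TissueFractions:
    """GM/WM/CSF volume fractions of the spectroscopy voxel (sum to 1)."""

    theta_gm: float
    theta_wm: float
    theta_csf: float

    def __post_init__(self) -> None:
        for name in ("theta_gm", "theta_wm", "theta_csf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = self.theta_gm + self.theta_wm + self.theta_csf
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"volume fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class RelaxationEntry:
    """Longitudinal (T1) and transverse (T2) relaxation times of one species."""

    species: str
    t1_ms: float
    t2_ms: float

    def __post_init__(self) -> None:
        if self.t1_ms <= 0 or self.t2_ms <= 0:
            raise ValueError("relaxation times must be positive")


def _default_relaxation() -> Dict[str, RelaxationEntry]:
    return {
        name: RelaxationEntry(species=name, **vals)
        for name, vals in _DEFAULTS["relaxation_ms"].items()
    }


@dataclass(frozen=True)
class RelaxationTable:
    """Lookup of relaxation times per species; defaults are 3 T literature values."""

    entries: Mapping[str, RelaxationEntry] = field(default_factory=_default_relaxation)

    def __getitem__(self, species: str) -> RelaxationEntry:
        try:
            return self.entries[species]
        except KeyError:
            raise KeyError(
                f"no relaxation entry for {species!r}; known: {sorted(self.entries)}"
            ) from None

    def replace(self, **overrides: RelaxationEntry) -> "RelaxationTable":
        merged = dict(self.entries)
        merged.update(overrides)
        return RelaxationTable(entries=merged)


_K = _DEFAULTS["constants"]


@dataclass(frozen=True)
class QuantConstants:
    """Physical constants of the quantification chain.

    ``w_h2o`` is the molal concentration of pure water (mol/kg); ``c_gm``,
    ``c_wm``, ``c_csf`` the relative densities of MR-visible water per
    compartment; ``mm_cor`` the macromolecule correction of the edited 3 ppm
    signal; ``eff_gaba`` the editing efficiency; ``n_gaba``/``n_met`` the
    proton counts of the quantified resonances.
    """

    w_h2o: float = _K["w_h2o_mol_per_kg"]
    c_gm: float = _K["c_gm"]
    c_wm: float = _K["c_wm"]
    c_csf: float = _K["c_csf"]
    mm_cor: float = _K["mm_cor"]
    eff_gaba: float = _K["eff_gaba"]
    n_gaba: int = _K["n_gaba"]
    n_met: Mapping[str, int] = field(default_factory=lambda: dict(_K["n_met"]))

    def __post_init__(self) -> None:
        for name in ("w_h2o", "c_gm", "c_wm", "c_csf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mm_cor", "eff_gaba"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def attenuation(t1_ms: float, t2_ms: float, tr_ms: float, te_ms: float) -> float:
    """Relaxation attenuation R = exp(-TE/T2) * [1 - exp(-TR/T1)].

    The fraction of equilibrium magnetization observed at echo time TE under
    repetition time TR; tends to 1 as TE -> 0 and TR -> infinity.
    """
    for name, v in (("t1_ms", t1_ms), ("t2_ms", t2_ms), ("tr_ms", tr_ms), ("te_ms", te_ms)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return math.exp(-te_ms / t2_ms) * (1.0 - math.exp(-tr_ms / t1_ms))


def water_fractions(
    theta: TissueFractions, k: Optional[QuantConstants] = None
) -> Tuple[float, float, float]:
    """Mole fractions of voxel water per compartment: f_x = c_x θ_x / Σ c θ."""
    k = k or QuantConstants()
    denom = k.c_gm * theta.theta_gm + k.c_wm * theta.theta_wm + k.c_csf * theta.theta_csf
    if denom <= 0:
        raise ValueError("all-zero tissue fractions: no water in voxel")
    f_gm = k.c_gm * theta.theta_gm / denom
    f_wm = k.c_wm * theta.theta_wm / denom
    f_csf = k.c_csf * theta.theta_csf / denom
    return f_gm, f_wm, f_csf


def water_concentration(
    theta: TissueFractions,
    params: AcquisitionParams,
    relax: Optional[RelaxationTable] = None,
    k: Optional[QuantConstants] = None,
) -> float:
    """Partial-volume- and relaxation-corrected voxel water concentration (mol/kg).

    Usable directly as the LCModel-style water scaling value (WCONC).
    ``params`` supplies the TR/TE at which the water attenuation factors are
    evaluated — the editing sequence's for water-referenced editing data, the
    reference sequence's for water-scaled reference spectra.
    """
    relax = relax or RelaxationTable()
    k = k or QuantConstants()
    f_gm, f_wm, f_csf = water_fractions(theta, k)
    if f_csf >= 1.0 - 1e-12:
        raise ValueError("voxel is entirely CSF: no tissue to quantify")
    r = {
        comp: attenuation(relax[f"water_{comp}"].t1_ms, relax[f"water_{comp}"].t2_ms,
                          params.tr_ms, params.te_ms)
        for comp in ("GM", "WM", "CSF")
    }
    return k.w_h2o * (f_gm * r["GM"] + f_wm * r["WM"] + f_csf * r["CSF"]) / (1.0 - f_csf)


def gaba_water_ref(
    i_gaba: float,
    i_water: float,
    w_conc: float,
    r_gaba: float,
    k: Optional[QuantConstants] = None,
) -> float:
    """Water-referenced GABA concentration (mol/kg).

    C = (I_GABA/I_H2O) * (2/N_GABA) * (1/R_GABA) * W_conc * MM_cor / eff_GABA.
    """
    k = k or QuantConstants()
    if i_water <= 0:
        raise ValueError(f"water intensity must be positive, got {i_water}")
    return (
        (i_gaba / i_water)
        * (2.0 / k.n_gaba)
        * (1.0 / r_gaba)
        * w_conc
        * k.mm_cor
        / k.eff_gaba
    )


def gaba_metabolite_ref(
    ratio: float,
    met_name: str,
    c_met: float,
    params: Optional[AcquisitionParams] = None,
    relax: Optional[RelaxationTable] = None,
    k: Optional[QuantConstants] = None,
) -> float:
    """Metabolite-referenced GABA concentration (same units as ``c_met``).

    C = (I_GABA/I_MET) * (N_MET/N_GABA) * (R_MET/R_GABA) * C_MET
        * MM_cor / eff_GABA,
    with both attenuation factors evaluated at the editing sequence's TR/TE.
    """
    k = k or QuantConstants()
    relax = relax or RelaxationTable()
    from .core import MEGA_PRESS_DEFAULTS

    params = params or MEGA_PRESS_DEFAULTS
    if ratio < 0:
        raise ValueError(f"intensity ratio must be >= 0, got {ratio}")
    if met_name not in k.n_met:
        raise ValueError(f"unknown reference metabolite {met_name!r}; known: {sorted(k.n_met)}")
    r_met = attenuation(relax[met_name].t1_ms, relax[met_name].t2_ms, params.tr_ms, params.te_ms)
    r_gaba = attenuation(relax["GABA"].t1_ms, relax["GABA"].t2_ms, params.tr_ms, params.te_ms)
    return (
        ratio
        * (k.n_met[met_name] / k.n_gaba)
        * (r_met / r_gaba)
        * c_met
        * k.mm_cor
        / k.eff_gaba
    )


def metabolite_concentration_press(
    i_met: float,
    i_water: float,
    met_name: str,
    theta: TissueFractions,
    params: AcquisitionParams,
    relax: Optional[RelaxationTable] = None,
    k: Optional[QuantConstants] = None,
) -> float:
    """Water-scaled metabolite concentration (mol/kg) from a reference scan.

    C_MET = (I_MET/I_H2O) * (2/N_MET) * (1/R_MET) * W_conc with all relaxation
    factors at the reference sequence's (long TR, short TE) timing — the same
    partial-volume-corrected water scaling the editing data uses.
    """
    k = k or QuantConstants()
    relax = relax or RelaxationTable()
    if i_water <= 0:
        raise ValueError("water intensity must be positive")
    if met_name not in k.n_met:
        raise ValueError(f"unknown reference metabolite {met_name!r}")
    r_met = attenuation(relax[met_name].t1_ms, relax[met_name].t2_ms, params.tr_ms, params.te_ms)
    w_conc = water_concentration(theta, params, relax, k)
    return (i_met / i_water) * (2.0 / k.n_met[met_name]) * (1.0 / r_met) * w_conc


@dataclass
class QuantReport:
    """Intensity ratios and absolute concentrations with full provenance.

    ``concentrations_mmol_per_kg`` has one entry per internal reference
    (``water``, ``tCho``, ``tCr``, ``tNAA``); references that could not be
    computed are listed under ``missing``. ``constants_used`` echoes every
    constant that entered the arithmetic.
    """

    ratios: Dict[str, float]
    concentrations_mmol_per_kg: Dict[str, float]
    fit_error_percent: Dict[str, float]
    constants_used: Dict[str, object]
    missing: list = field(default_factory=list)
    config_hash: Optional[str] = None

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "QuantReport":
        return cls(**json.loads(text))

    def to_frame(self):
        """One row per reference method (pandas DataFrame)."""
        import pandas as pd

        rows = [
            {"reference": ref, "c_gaba_mmol_per_kg": c}
            for ref, c in self.concentrations_mmol_per_kg.items()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def quant_report(
    diff_amplitudes: Mapping[str, float],
    off_amplitudes: Mapping[str, float],
    water_amplitude: float,
    theta: TissueFractions,
    mega_params: AcquisitionParams,
    c_met_mol_per_kg: Mapping[str, float],
    relax: Optional[RelaxationTable] = None,
    k: Optional[QuantConstants] = None,
    fit_error_percent: Optional[Mapping[str, float]] = None,
    gaba_name: str = "GABA+",
    config_hash: Optional[str] = None,
) -> QuantReport:
    """Assemble ratios and all four reference-method concentrations.

    ``diff_amplitudes`` come from the difference-spectrum basis fit,
    ``off_amplitudes`` from the singlet fit of the averaged OFF spectrum,
    ``water_amplitude`` from the interleaved water reference, and
    ``c_met_mol_per_kg`` from the separately quantified reference scan.
    """
    relax = relax or RelaxationTable()
    k = k or QuantConstants()
    missing: list = []
    ratios: Dict[str, float] = {}
    conc: Dict[str, float] = {}

    i_gaba = diff_amplitudes.get(gaba_name)
    if i_gaba is None:
        missing.append(gaba_name)
    else:
        r_gaba = attenuation(relax["GABA"].t1_ms, relax["GABA"].t2_ms,
                             mega_params.tr_ms, mega_params.te_ms)
        if water_amplitude and water_amplitude > 0:
            w_conc = water_concentration(theta, mega_params, relax, k)
            conc["water"] = 1e3 * gaba_water_ref(i_gaba, water_amplitude, w_conc, r_gaba, k)
        else:
            missing.append("water")
        for met in ("tCho", "tCr", "tNAA"):
            i_met = off_amplitudes.get(met)
            if i_met is None or i_met <= 0:
                missing.append(met)
                continue
            ratios[f"{gaba_name}/{met}"] = i_gaba / i_met
            if met in c_met_mol_per_kg:
                conc[met] = 1e3 * gaba_metabolite_ref(
                    i_gaba / i_met, met, c_met_mol_per_kg[met], mega_params, relax, k
                )
            else:
                missing.append(f"C_{met}")

    constants_used: Dict[str, object] = {
        "w_h2o_mol_per_kg": k.w_h2o,
        "c_gm": k.c_gm,
        "c_wm": k.c_wm,
        "c_csf": k.c_csf,
        "mm_cor": k.mm_cor,
        "eff_gaba": k.eff_gaba,
        "n_gaba": k.n_gaba,
        "n_met": dict(k.n_met),
        "tr_ms": mega_params.tr_ms,
        "te_ms": mega_params.te_ms,
        "theta": {"gm": theta.theta_gm, "wm": theta.theta_wm, "csf": theta.theta_csf},
        "relaxation_ms": {
            name: {"t1_ms": e.t1_ms, "t2_ms": e.t2_ms} for name, e in relax.entries.items()
        },
        "c_met_mol_per_kg": dict(c_met_mol_per_kg),
    }
    return QuantReport(
        ratios=ratios,
        concentrations_mmol_per_kg=conc,
        fit_error_percent=dict(fit_error_percent or {}),
        constants_used=constants_used,
        missing=missing,
        config_hash=config_hash,
    )
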