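"""Preprocessing of interleaved editing blocks.

Fixed pipeline order (documented contract):

1. drift correction — each block's water reference gives one frequency
   offset, removed from all transients of that block;
2. eddy-current correction — the water reference's sample-wise phase is
   subtracted (Klose method);
3. averaging — mean OFF, and mean(ON) − mean(OFF) difference;
4. residual-water removal — Hankel-SVD components inside the water band are
   subtracted from the averaged OFF FID;
5. zero filling happens only at display/spectrum time, never before fitting.

Zero-order phase is deliberately *not* corrected here: both fitting engines
estimate it as a free parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import FID, frequency_shift
from .hlsvd import NoSignalError, hlsvd_decompose, reconstruct

__all__ = [
    "PreprocessConfig",
    "estimate_water_offset",
    "estimate_water_amplitude",
    "correct_drift",
    "eddy_correct",
    "remove_water",
    "combine",
    "preprocess_blocks",
    "PreprocessResult",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    ``hlsvd_order`` is the damped-sinusoid model order of the water filter;
    ``water_band_ppm`` the (low, high) chemical-shift band whose components
    are removed; ``zero_fill_to`` the spectrum interpolation length;
    ``apodization_hz`` optional exponential line broadening (off by default —
    the pipeline runs on unapodized FIDs).
    """

    hlsvd_order: int = 25
    water_band_ppm: Tuple[float, float] = (4.4, 5.0)
    zero_fill_to: int = 8192
    apodization_hz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.hlsvd_order < 1:
            raise ValueError("hlsvd_order must be >= 1")
        lo, hi = self.water_band_ppm
        if lo >= hi:
            raise ValueError("water_band_ppm must be (low, high) with low < high")


def estimate_water_offset(water: FID, order: int = 8) -> float:
    """Frequency offset (Hz) of the dominant water component from the carrier.

    The unsuppressed water line is modelled by a low-order Hankel-SVD
    decomposition; the frequency of the largest-amplitude component is the
    carrier offset used for retrospective B0 drift correction.
    """
    comps = hlsvd_decompose(water.samples, water.params.dwell_s, order=order,
                            max_points=min(512, len(water)))
    return float(comps.frequency_hz[comps.dominant])


def estimate_water_amplitude(water: FID, order: int = 8) -> float:
    """t=0 magnitude of the dominant water component (the I_H2O intensity)."""
    comps = hlsvd_decompose(water.samples, water.params.dwell_s, order=order,
                            max_points=min(512, len(water)))
    return float(np.abs(comps.amplitude[comps.dominant]))


def _group_blocks(fids: Sequence[FID]) -> Dict[int, List[FID]]:
    blocks: Dict[int, List[FID]] = {}
    for fid in fids:
        if fid.block_index is None:
            raise ValueError(f"FID with label {fid.label} has no block_index")
        blocks.setdefault(fid.block_index, []).append(fid)
    return blocks


def correct_drift(fids: Sequence[FID]) -> Tuple[List[FID], Dict[int, float]]:
    """Remove each block's B0 offset, estimated from its water reference.

    Returns the corrected transients (order preserved) and the per-block
    offsets that were removed. Every block must contain a WATER_REF.
    """
    blocks = _group_blocks(fids)
    offsets: Dict[int, float] = {}
    for idx, members in blocks.items():
        waters = [f for f in members if f.label == "WATER_REF"]
        if not waters:
            raise ValueError(f"block {idx} has no WATER_REF transient")
        offsets[idx] = estimate_water_offset(waters[0])
    return [frequency_shift(f, -offsets[f.block_index]) for f in fids], offsets


def eddy_correct(fid: FID, water: FID, eps: float = 1e-12) -> FID:
    """Klose eddy-current correction: subtract the water reference's phase.

    Each sample is rotated by −arg(water[t]); time-dependent phase errors
    shared by water and metabolite signals (eddy currents) cancel. Where the
    water magnitude falls below ``eps`` times its maximum the phase is
    unreliable and the correction tapers to zero (with a warning).
    """
    mag = np.abs(water.samples)
    peak = mag.max()
    if peak == 0:
        raise NoSignalError("water reference is all zero")
    valid = mag > eps * peak
    phase = np.where(valid, np.angle(water.samples), 0.0)
    if not valid.all():
        warnings.warn(
            f"water reference magnitude below threshold at {np.sum(~valid)} samples; "
            "eddy correction tapered to zero there",
            stacklevel=2,
        )
    return fid.with_samples(fid.samples * np.exp(-1j * phase))


def remove_water(fid: FID, cfg: PreprocessConfig) -> FID:
    """Subtract Hankel-SVD components inside the water band.

    Components whose frequencies fall within ``water_band_ppm`` are
    reconstructed over the full FID length and subtracted; out-of-band signal
    passes through. An empty band is the identity.
    """
    if cfg.hlsvd_order >= len(fid) // 2:
        raise ValueError("hlsvd_order must be < half the FID length")
    lo_ppm, hi_ppm = cfg.water_band_ppm
    lo_hz = fid.params.ppm_to_hz(lo_ppm)
    hi_hz = fid.params.ppm_to_hz(hi_ppm)
    try:
        comps = hlsvd_decompose(fid.samples, fid.params.dwell_s, cfg.hlsvd_order)
    except NoSignalError:
        return fid.with_samples(fid.samples.copy())
    in_band = (comps.frequency_hz >= lo_hz) & (comps.frequency_hz <= hi_hz)
    if not in_band.any():
        return fid.with_samples(fid.samples.copy())
    water = reconstruct(comps.select(in_band), len(fid), fid.params.dwell_s)
    return fid.with_samples(fid.samples - water)


def combine(fids: Sequence[FID]) -> Tuple[FID, FID]:
    """Average the ON and OFF transients: returns (mean OFF, mean ON − mean OFF)."""
    ons = [f for f in fids if f.label == "ON"]
    offs = [f for f in fids if f.label == "OFF"]
    if not ons or not offs:
        raise ValueError("need at least one ON and one OFF transient")
    params = offs[0].params
    for f in ons + offs:
        if f.params != params:
            raise ValueError("mixed acquisition parameters in combine()")
    mean_off = np.mean([f.samples for f in offs], axis=0)
    mean_on = np.mean([f.samples for f in ons], axis=0)
    off_fid = FID(samples=mean_off, params=params, label="OFF")
    diff_fid = FID(samples=mean_on - mean_off, params=params, label="DIFF")
    return off_fid, diff_fid


@dataclass
class PreprocessResult:
    """Averaged OFF and DIFF FIDs, the water amplitude, and diagnostics."""

    off: FID
    diff: FID
    water_amplitude: float
    block_offsets_hz: Dict[int, float]
    residual_offsets_hz: Dict[int, float]


def preprocess_blocks(fids: Sequence[FID], cfg: Optional[PreprocessConfig] = None) -> PreprocessResult:
    """Full chain on raw interleaved blocks.

    drift-correct → eddy-correct (per block, against that block's corrected
    water reference) → average → remove residual water from the averaged OFF.
    The water amplitude is estimated from the average of the drift-corrected
    water references.
    """
    cfg = cfg or PreprocessConfig()
    corrected, offsets = correct_drift(fids)
    blocks = _group_blocks(corrected)

    residual: Dict[int, float] = {}
    eddy_done: List[FID] = []
    waters: List[FID] = []
    for idx in sorted(blocks):
        members = blocks[idx]
        water = next(f for f in members if f.label == "WATER_REF")
        residual[idx] = estimate_water_offset(water)
        waters.append(water)
        for f in members:
            if f.label in ("ON", "OFF"):
                eddy_done.append(eddy_correct(f, water))

    mean_water = waters[0].with_samples(np.mean([w.samples for w in waters], axis=0))
    water_amplitude = estimate_water_amplitude(mean_water)

    off_fid, diff_fid = combine(eddy_done)
    if cfg.apodization_hz:
        from .core import apodize

        off_fid = apodize(off_fid, cfg.apodization_hz)
        diff_fid = apodize(diff_fid, cfg.apodization_hz)
    off_fid = remove_water(off_fid, cfg)
    return PreprocessResult(
        off=off_fid,
        diff=diff_fid,
        water_amplitude=water_amplitude,
        block_offsets_hz=offsets,
        residual_offsets_hz=residual,
    )
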