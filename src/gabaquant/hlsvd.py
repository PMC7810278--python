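"""Hankel-SVD decomposition of an FID into damped complex sinusoids.

State-space (Kung/HTLS) variant: the FID is arranged into a Hankel matrix,
truncated to a chosen model order by SVD, and the signal poles are recovered
from the shift-invariance of the left singular vectors; complex amplitudes
follow from a linear least-squares fit of the resulting damped exponentials
to the data. This is the workhorse behind residual-water modelling/removal
and water-reference frequency and amplitude estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = ["HLSVDComponents", "hlsvd_decompose", "reconstruct", "NoSignalError"]


class NoSignalError(ValueError):
    """Raised when a decomposition is requested of an (effectively) empty FID."""


@dataclass(frozen=True)
class HLSVDComponents:
    """Damped-sinusoid model: x(t) ≈ Σ_k c_k · exp((−α_k + 2πi f_k) t).

    ``amplitude`` are the complex c_k (magnitude + phase at t = 0),
    ``frequency_hz`` the f_k relative to the carrier, ``decay_per_s`` the
    exponential decay rates α_k (a Lorentzian of FWHM W has α = πW).
    """

    amplitude: np.ndarray
    frequency_hz: np.ndarray
    decay_per_s: np.ndarray
    dwell_s: float

    def __len__(self) -> int:
        return len(self.amplitude)

    def select(self, mask: np.ndarray) -> "HLSVDComponents":
        return HLSVDComponents(
            amplitude=self.amplitude[mask],
            frequency_hz=self.frequency_hz[mask],
            decay_per_s=self.decay_per_s[mask],
            dwell_s=self.dwell_s,
        )

    @property
    def dominant(self) -> int:
        """Index of the largest-|amplitude| component."""
        return int(np.argmax(np.abs(self.amplitude)))


def hlsvd_decompose(
    samples: np.ndarray,
    dwell_s: float,
    order: int,
    max_points: int = 1024,
) -> HLSVDComponents:
    """Model the leading ``max_points`` samples with ``order`` damped sinusoids.

    The Hankel matrix is built from at most ``max_points`` samples (the tail
    of a decayed FID adds noise, not information, and the SVD cost grows
    cubically). Amplitudes are then fitted over those same samples.
    """
    x = np.asarray(samples, dtype=np.complex128)
    if x.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    n = min(len(x), int(max_points))
    x = x[:n]
    if order < 1:
        raise ValueError("model order must be >= 1")
    if order >= n // 2:
        raise ValueError(f"model order {order} too large for {n} samples")
    if not np.any(np.abs(x) > 0):
        raise NoSignalError("all-zero FID: nothing to decompose")

    nrows = n // 2 + 1
    ncols = n - nrows + 1
    h = scipy.linalg.hankel(x[:nrows], x[nrows - 1:])
    u, s, _vh = scipy.linalg.svd(h, full_matrices=False)
    k = min(order, int(np.sum(s > s[0] * 1e-12)))
    uk = u[:, :k]
    # shift-invariance: rows 1..end of Uk = rows 0..end-1 of Uk @ Z
    z, *_ = scipy.linalg.lstsq(uk[:-1], uk[1:], lapack_driver="gelsd")
    poles = scipy.linalg.eigvals(z)
    # discard numerically exploding poles (growing exponentials from noise)
    poles = poles[np.abs(poles) < 1.2]
    if len(poles) == 0:
        raise NoSignalError("no stable signal poles found")

    freq = np.angle(poles) / (2.0 * np.pi * dwell_s)
    decay = -np.log(np.clip(np.abs(poles), 1e-12, None)) / dwell_s
    t = np.arange(n) * dwell_s
    basis = np.exp(np.outer(t, -decay + 2j * np.pi * freq))
    amp, *_ = scipy.linalg.lstsq(basis, x, lapack_driver="gelsd")
    return HLSVDComponents(
        amplitude=amp, frequency_hz=freq, decay_per_s=decay, dwell_s=dwell_s
    )


def reconstruct(components: HLSVDComponents, n: int, dwell_s: float | None = None) -> np.ndarray:
    """Evaluate the damped-sinusoid model on an ``n``-point time grid."""
    dwell = components.dwell_s if dwell_s is None else dwell_s
    t = np.arange(n) * dwell
    basis = np.exp(np.outer(t, -components.decay_per_s + 2j * np.pi * components.frequency_hz))
    return basis @ components.amplitude
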