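"""Time-domain fitting engines with Cramér–Rao uncertainty.

Two model classes, both fitted by bounded trust-region nonlinear least
squares on the complex time-domain samples (stacked real/imaginary):

* :class:`SingletModel` — prior-knowledge singlet fitting of the averaged
  OFF spectrum (the AMARES idea): each peak has an amplitude, a frequency
  bounded around its prior chemical shift, and a linewidth bounded by the
  prior; a single zero-order phase is shared by all peaks.
* :class:`BasisModel` — basis-set fitting of the averaged difference
  spectrum (the QUEST idea): a nonnegative weight per basis metabolite, a
  common frequency shift, a common extra damping (Gaussian for designated
  metabolites, Lorentzian otherwise) and a zero-order phase. The amplitudes
  are profiled out with nonnegative least squares at every step of the
  3-parameter outer optimisation.

``fit()`` returns a results object carrying amplitudes, lineshape
parameters, the Cramér–Rao standard deviations (CRSD) of the amplitudes —
square roots of the amplitude diagonal of the inverse Fisher information
over *all* free real parameters — and the percentage fit error
100·CRSD/amplitude. The noise variance entering the Fisher information is
estimated from the last 10 % of the fit residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.optimize

from .core import FID, AcquisitionParams

__all__ = [
    "SingletPrior",
    "FitResults",
    "SingletModel",
    "BasisModel",
    "FitConvergenceError",
    "fit_singlets",
    "fit_basis",
    "crlb_amplitudes",
    "fit_error_percent",
]

_LN2 = np.log(2.0)


class FitConvergenceError(RuntimeError):
    """Optimizer failed; ``.results`` carries the best solution found."""

    def __init__(self, message: str, results: "FitResults"):
        super().__init__(message)
        self.results = results


@dataclass(frozen=True)
class SingletPrior:
    """Prior knowledge for one singlet: position, tolerance, lineshape bounds."""

    name: str
    shift_ppm: float
    shift_tol_ppm: float = 0.05
    lineshape: str = "lorentzian"
    linewidth_init_hz: float = 5.0
    linewidth_bounds_hz: Tuple[float, float] = (0.5, 25.0)

    def __post_init__(self) -> None:
        if self.shift_tol_ppm < 0:
            raise ValueError("shift_tol_ppm must be >= 0")
        lo, hi = self.linewidth_bounds_hz
        if not lo < hi:
            raise ValueError("linewidth_bounds_hz must be (low, high) with low < high")
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise ValueError("lineshape must be lorentzian or gaussian")


def _envelope(t: np.ndarray, lineshape: str, w_hz: float) -> np.ndarray:
    if lineshape == "lorentzian":
        return np.exp(-np.pi * w_hz * t)
    return np.exp(-((np.pi * w_hz * t) ** 2) / (4.0 * _LN2))


def _denv_dw(t: np.ndarray, lineshape: str, w_hz: float) -> np.ndarray:
    """d/dW of the envelope, divided by the envelope (log-derivative)."""
    if lineshape == "lorentzian":
        return -np.pi * t
    return -(np.pi**2) * t**2 * w_hz / (2.0 * _LN2)


def _noise_sigma(residual: np.ndarray, frac: float = 0.1) -> float:
    """Per-channel noise SD from the residual tail (last ``frac`` of samples)."""
    ntail = max(8, int(len(residual) * frac))
    tail = residual[-ntail:]
    return float(np.sqrt(0.5 * np.mean(np.abs(tail) ** 2)))


def _crsd_from_jacobian(
    jac: np.ndarray, names: Sequence[str], amp_idx: Sequence[int], sigma: float
) -> Dict[str, float]:
    """CRSDs of amplitudes from the complex model Jacobian over all parameters."""
    fisher = np.real(jac.conj().T @ jac)
    if sigma <= 0:
        return {name: 0.0 for name in names}
    try:
        cov = np.linalg.inv(fisher) * sigma**2
    except np.linalg.LinAlgError:
        u, s, _ = np.linalg.svd(fisher)
        bad = np.abs(u[:, -1]) > 0.3
        pairs = [names[i] if i < len(names) else f"param{i}" for i in np.flatnonzero(bad)]
        raise np.linalg.LinAlgError(
            f"singular Fisher information; near-degenerate parameters: {pairs}"
        ) from None
    diag = np.clip(np.diag(cov), 0.0, None)
    return {name: float(np.sqrt(diag[i])) for name, i in zip(names, amp_idx)}


@dataclass
class FitResults:
    """Estimates, uncertainties and diagnostics of a time-domain fit.

    Attributes
    ----------
    amplitudes : dict
        t=0-equivalent signal amplitude per component.
    frequencies_hz, dampings_hz : dict
        Fitted frequency offsets and linewidth/extra-damping values.
    phase0_deg : float
        Global zero-order phase.
    crsd : dict
        Cramér–Rao standard deviation of each amplitude.
    residual : FID
        Data minus fitted model.
    """

    amplitudes: Dict[str, float]
    frequencies_hz: Dict[str, float]
    dampings_hz: Dict[str, float]
    phase0_deg: float
    crsd: Dict[str, float]
    residual: FID
    model: object
    converged: bool = True
    delta_f_hz: Optional[float] = None
    noise_sigma: float = 0.0
    cost: float = 0.0
    _jacobian: Optional[np.ndarray] = field(default=None, repr=False)
    _param_names: Optional[List[str]] = field(default=None, repr=False)
    _amp_indices: Optional[List[int]] = field(default=None, repr=False)

    @property
    def fit_error_percent(self) -> Dict[str, float]:
        """Percentage ratio of CRSD to fitted amplitude (undefined at zero)."""
        out: Dict[str, float] = {}
        for name, amp in self.amplitudes.items():
            if amp > 0:
                out[name] = 100.0 * self.crsd.get(name, 0.0) / amp
        return out

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} fit "
            f"({'converged' if self.converged else 'NOT converged'})",
            f"  zero-order phase: {self.phase0_deg:8.3f} deg",
        ]
        if self.delta_f_hz is not None:
            lines.append(f"  common shift:     {self.delta_f_hz:8.3f} Hz")
        lines.append(f"  noise sigma:      {self.noise_sigma:.4g}")
        lines.append(
            f"  {'component':<10}{'amplitude':>12}{'freq (Hz)':>12}"
            f"{'width (Hz)':>12}{'CRSD':>12}{'error %':>9}"
        )
        errs = self.fit_error_percent
        for name in self.amplitudes:
            lines.append(
                f"  {name:<10}{self.amplitudes[name]:>12.5g}"
                f"{self.frequencies_hz.get(name, float('nan')):>12.3f}"
                f"{self.dampings_hz.get(name, float('nan')):>12.3f}"
                f"{self.crsd.get(name, float('nan')):>12.3g}"
                f"{errs.get(name, float('nan')):>9.2f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None, zero_fill_to: int = 8192):
        """Overlay data, fitted model and residual spectra (real part)."""
        import matplotlib.pyplot as plt

        data = self.model.fid
        fitted = data.with_samples(data.samples - self.residual.samples)
        if ax is None:
            _, ax = plt.subplots()
        for fid, style, label in (
            (data, "k-", "data"),
            (fitted, "r-", "fit"),
            (self.residual, "b-", "residual"),
        ):
            sp = fid.spectrum(zero_fill_to=zero_fill_to)
            ax.plot(sp.ppm, sp.values.real, style, lw=0.8, label=label)
        if not ax.xaxis_inverted():
            ax.invert_xaxis()
        ax.set_xlabel("chemical shift (ppm)")
        ax.legend()
        return ax


class SingletModel:
    """Constrained singlet fitting of an (averaged, water-free) OFF FID."""

    def __init__(self, fid: FID, priors: Sequence[SingletPrior]):
        if not priors:
            raise ValueError("need at least one singlet prior")
        self.fid = fid
        self.priors = list(priors)
        self._t = fid.params.time_axis(len(fid))
        self._y = fid.samples

    # parameter vector: [phi0, a_1..K, f_1..K, w_1..K]
    def _unpack(self, theta: np.ndarray):
        k = len(self.priors)
        return theta[0], theta[1 : 1 + k], theta[1 + k : 1 + 2 * k], theta[1 + 2 * k :]

    def _components(self, theta: np.ndarray) -> np.ndarray:
        phi, amps, freqs, widths = self._unpack(theta)
        comps = np.empty((len(self.priors), len(self._t)), dtype=np.complex128)
        for i, prior in enumerate(self.priors):
            comps[i] = (
                amps[i]
                * np.exp(2j * np.pi * freqs[i] * self._t)
                * _envelope(self._t, prior.lineshape, widths[i])
            )
        return comps * np.exp(1j * phi)

    def _model(self, theta: np.ndarray) -> np.ndarray:
        return self._components(theta).sum(axis=0)

    def _residual(self, theta: np.ndarray) -> np.ndarray:
        r = self._model(theta) - self._y
        return np.concatenate([r.real, r.imag])

    def _complex_jacobian(self, theta: np.ndarray) -> np.ndarray:
        phi, amps, freqs, widths = self._unpack(theta)
        comps = self._components(theta)
        s = comps.sum(axis=0)
        k = len(self.priors)
        jac = np.empty((len(self._t), 1 + 3 * k), dtype=np.complex128)
        jac[:, 0] = 1j * s
        for i, prior in enumerate(self.priors):
            unit = (
                np.exp(1j * phi)
                * np.exp(2j * np.pi * freqs[i] * self._t)
                * _envelope(self._t, prior.lineshape, widths[i])
            )
            jac[:, 1 + i] = unit
            jac[:, 1 + k + i] = 2j * np.pi * self._t * comps[i]
            jac[:, 1 + 2 * k + i] = _denv_dw(self._t, prior.lineshape, widths[i]) * comps[i]
        return jac

    def _jac(self, theta: np.ndarray) -> np.ndarray:
        jc = self._complex_jacobian(theta)
        return np.vstack([jc.real, jc.imag])

    def _initial_guess(self) -> np.ndarray:
        params = self.fid.params
        k = len(self.priors)
        freqs = np.array([params.ppm_to_hz(p.shift_ppm) for p in self.priors])
        widths = np.array([p.linewidth_init_hz for p in self.priors])
        cols = np.column_stack(
            [
                np.exp(2j * np.pi * f * self._t) * _envelope(self._t, p.lineshape, w)
                for p, f, w in zip(self.priors, freqs, widths)
            ]
        )
        c, *_ = np.linalg.lstsq(cols, self._y, rcond=None)
        weights = np.abs(c)
        if weights.sum() > 0:
            phi = float(np.angle(np.sum(c * weights)))
        else:
            phi = 0.0
        amps = np.clip(np.abs(c), 1e-12, None)
        return np.concatenate([[phi], amps, freqs, widths])

    def fit(self, max_nfev: int = 400, noise_sigma: Optional[float] = None) -> FitResults:
        params = self.fid.params
        k = len(self.priors)
        theta0 = self._initial_guess()
        f_lo, f_hi, w_lo, w_hi = [], [], [], []
        for p in self.priors:
            f0 = params.ppm_to_hz(p.shift_ppm)
            tol = p.shift_tol_ppm * params.f0_mhz
            f_lo.append(f0 - tol)
            f_hi.append(f0 + tol if tol > 0 else f0 + 1e-12)
            w_lo.append(p.linewidth_bounds_hz[0])
            w_hi.append(p.linewidth_bounds_hz[1])
        lower = np.concatenate([[-np.pi], np.zeros(k), f_lo, w_lo])
        upper = np.concatenate([[np.pi], np.full(k, np.inf), f_hi, w_hi])
        theta0 = np.clip(theta0, lower + 1e-12, upper - 1e-12)

        sol = scipy.optimize.least_squares(
            self._residual,
            theta0,
            jac=self._jac,
            bounds=(lower, upper),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=max_nfev,
        )
        return self._package(sol, noise_sigma)

    def _package(self, sol, noise_sigma: Optional[float]) -> FitResults:
        theta = sol.x
        phi, amps, freqs, widths = self._unpack(theta)
        residual = self._model(theta) - self._y
        sigma = _noise_sigma(residual) if noise_sigma is None else noise_sigma
        names = [p.name for p in self.priors]
        jac = self._complex_jacobian(theta)
        amp_idx = list(range(1, 1 + len(names)))
        crsd = _crsd_from_jacobian(jac, names, amp_idx, sigma)
        results = FitResults(
            amplitudes={n: float(a) for n, a in zip(names, amps)},
            frequencies_hz={n: float(f) for n, f in zip(names, freqs)},
            dampings_hz={n: float(w) for n, w in zip(names, widths)},
            phase0_deg=float(np.rad2deg(phi)),
            crsd=crsd,
            residual=self.fid.with_samples(-residual),
            model=self,
            converged=sol.status > 0,
            noise_sigma=sigma,
            cost=float(sol.cost),
            _jacobian=jac,
            _param_names=names,
            _amp_indices=amp_idx,
        )
        if sol.status <= 0:
            raise FitConvergenceError(
                f"singlet fit did not converge: {sol.message}", results
            )
        return results


class BasisModel:
    """Basis-set fitting of the averaged difference FID.

    Free parameters: nonnegative amplitude per basis metabolite, a common
    frequency shift, a common extra damping (Gaussian FWHM for names in
    ``gauss_lineshape_for``, Lorentzian otherwise), and a zero-order phase.
    """

    def __init__(
        self,
        fid: FID,
        basis: Union[Mapping[str, FID], "object"],
        gauss_lineshape_for: Iterable[str] = ("GABA+",),
    ):
        self.fid = fid
        basis_fids = self._render(basis, fid.params)
        for name, bfid in basis_fids.items():
            if bfid.params.bandwidth_hz != fid.params.bandwidth_hz or len(bfid) != len(fid):
                raise ValueError(
                    f"basis FID {name!r} was rendered with different acquisition "
                    "parameters than the data"
                )
        self.names = sorted(basis_fids)
        self.basis = np.column_stack([basis_fids[n].samples for n in self.names])
        self.gauss_names = frozenset(gauss_lineshape_for)
        self._t = fid.params.time_axis(len(fid))
        self._y = fid.samples
        cond = np.linalg.cond(self.basis)
        if cond > 1e8:
            warnings.warn(
                f"basis set is nearly rank-deficient (condition number {cond:.3g})",
                stacklevel=2,
            )

    @staticmethod
    def _render(basis, params: AcquisitionParams) -> Dict[str, FID]:
        if hasattr(basis, "render"):
            return basis.render(params)
        return dict(basis)

    def _columns(self, df: float, g: float, phi: float) -> np.ndarray:
        shift = np.exp(2j * np.pi * df * self._t) * np.exp(1j * phi)
        cols = self.basis * shift[:, None]
        env_l = _envelope(self._t, "lorentzian", g) if g > 0 else np.ones_like(self._t)
        env_g = _envelope(self._t, "gaussian", g) if g > 0 else np.ones_like(self._t)
        for i, name in enumerate(self.names):
            cols[:, i] *= env_g if name in self.gauss_names else env_l
        return cols

    def _profiled(self, theta: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        df, g, phi = theta
        cols = self._columns(df, g, phi)
        a_mat = np.vstack([cols.real, cols.imag])
        y = np.concatenate([self._y.real, self._y.imag])
        amps, _ = scipy.optimize.nnls(a_mat, y)
        return amps, a_mat @ amps - y

    def _residual(self, theta: np.ndarray) -> np.ndarray:
        return self._profiled(theta)[1]

    def fit(
        self,
        multistart_df_hz: Sequence[float] = (-5.0, 0.0, 5.0),
        df_bounds_hz: Tuple[float, float] = (-20.0, 20.0),
        g_max_hz: float = 25.0,
        max_nfev: int = 200,
        noise_sigma: Optional[float] = None,
    ) -> FitResults:
        lower = np.array([df_bounds_hz[0], 0.0, -np.pi])
        upper = np.array([df_bounds_hz[1], g_max_hz, np.pi])
        y_norm = np.linalg.norm(self._y)
        best = None
        for df0 in multistart_df_hz:
            theta0 = np.clip(np.array([df0, 0.5, 0.0]), lower + 1e-9, upper - 1e-9)
            sol = scipy.optimize.least_squares(
                self._residual,
                theta0,
                bounds=(lower, upper),
                method="trf",
                diff_step=1e-6,
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=max_nfev,
            )
            if best is None or sol.cost < best.cost:
                best = sol
            if y_norm > 0 and np.sqrt(2 * best.cost) / y_norm < 1e-9:
                break
        return self._package(best, noise_sigma)

    def _complex_jacobian(self, theta: np.ndarray, amps: np.ndarray) -> np.ndarray:
        df, g, phi = theta
        cols = self._columns(df, g, phi)
        s = cols @ amps
        m = len(self.names)
        jac = np.empty((len(self._t), m + 3), dtype=np.complex128)
        jac[:, :m] = cols
        jac[:, m] = 2j * np.pi * self._t * s
        dg = np.zeros(len(self._t), dtype=np.complex128)
        for i, name in enumerate(self.names):
            shape = "gaussian" if name in self.gauss_names else "lorentzian"
            dg += amps[i] * cols[:, i] * _denv_dw(self._t, shape, g)
        jac[:, m + 1] = dg
        jac[:, m + 2] = 1j * s
        return jac

    def _package(self, sol, noise_sigma: Optional[float]) -> FitResults:
        theta = sol.x
        df, g, phi = theta
        amps, res_stacked = self._profiled(theta)
        n = len(self._t)
        residual = res_stacked[:n] + 1j * res_stacked[n:]
        sigma = _noise_sigma(residual) if noise_sigma is None else noise_sigma
        jac = self._complex_jacobian(theta, amps)
        amp_idx = list(range(len(self.names)))
        crsd = _crsd_from_jacobian(jac, self.names, amp_idx, sigma)
        results = FitResults(
            amplitudes={n_: float(a) for n_, a in zip(self.names, amps)},
            frequencies_hz={n_: float(df) for n_ in self.names},
            dampings_hz={n_: float(g) for n_ in self.names},
            phase0_deg=float(np.rad2deg(phi)),
            crsd=crsd,
            residual=self.fid.with_samples(-residual),
            model=self,
            converged=sol.status > 0,
            delta_f_hz=float(df),
            noise_sigma=sigma,
            cost=float(sol.cost),
            _jacobian=jac,
            _param_names=list(self.names),
            _amp_indices=amp_idx,
        )
        if sol.status <= 0:
            raise FitConvergenceError(f"basis fit did not converge: {sol.message}", results)
        return results


def fit_singlets(fid: FID, priors: Sequence[SingletPrior], **kwargs) -> FitResults:
    """Fit prior-constrained singlets to an OFF FID (AMARES-style)."""
    return SingletModel(fid, priors).fit(**kwargs)


def fit_basis(
    diff: FID,
    basis,
    gauss_lineshape_for: Iterable[str] = ("GABA+",),
    **kwargs,
) -> FitResults:
    """Fit a weighted basis combination to a difference FID (QUEST-style)."""
    return BasisModel(diff, basis, gauss_lineshape_for=gauss_lineshape_for).fit(**kwargs)


def crlb_amplitudes(fit: FitResults, fid: FID, noise_sigma: Optional[float] = None) -> Dict[str, float]:
    """Recompute amplitude CRSDs of a fit from its Jacobian and residual.

    The Fisher information F = (1/σ²)·Re(Jᴴ J) is built over all free real
    parameters; σ is estimated from the last 10 % of the residual of ``fid``
    unless given.
    """
    if fit._jacobian is None:
        raise ValueError("fit does not carry Jacobian information")
    sigma = noise_sigma if noise_sigma is not None else _noise_sigma(fit.residual.samples)
    return _crsd_from_jacobian(fit._jacobian, fit._param_names, fit._amp_indices, sigma)


def fit_error_percent(fit: FitResults) -> Dict[str, float]:
    """Percentage fit error: 100 · CRSD / amplitude per component."""
    return fit.fit_error_percent
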