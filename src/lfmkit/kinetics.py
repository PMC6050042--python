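"""FRAP and optical-pulse-labeling kinetics.

Fluorescence recovery after photobleaching is modelled as a single
exponential, ``y(t) = A (1 - exp(-tau t))``, where ``A`` is the mobile
fraction (plateau) and ``tau`` the recovery rate. Downstream of the fit:

* half-time of recovery ``t_half = ln(2) / tau``;
* an effective diffusion coefficient ``D = 0.88 w^2 / (4 t_half)`` with the
  bleach-spot squared radius approximated as ``w^2 = area / pi`` (spot-bleach
  circular-ROI, in-plane diffusion approximation);
* the minimal Stokes radius of a globular protein of mass M kDa,
  ``r_min = 0.66 M^(1/3)`` nm;
* apparent viscosity from the Einstein-Stokes relation
  ``eta = k_B T / (6 pi D r)``.

Optical pulse labeling (photoconverted Dendra2) decay is fit log-linearly:
``ln I(t) = ln I0 - k t``, half-life ``ln(2) / k``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

BOLTZMANN_J_PER_K = 1.380649e-23

__all__ = [
    "FRAPTrace",
    "FRAPFit",
    "OPLTrace",
    "HalfLifeFit",
    "normalize_frap",
    "FrapRecoveryModel",
    "fit_recovery",
    "half_time",
    "diffusion_coefficient",
    "stokes_radius",
    "viscosity",
    "OplDecayModel",
    "fit_opl_halflife",
]


@dataclass
class FRAPTrace:
    """Normalized post-bleach recovery of a bleached sub-granule ROI.

    ``recovery`` is the ROI's share of the pre-bleach whole-granule
    integrated density, with the immediate post-bleach floor subtracted, so
    the trace starts at ~0 and recovers toward the mobile fraction.
    """

    times_s: np.ndarray
    recovery: np.ndarray
    bleach_roi_area_um2: float | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.recovery = np.asarray(self.recovery, dtype=float)
        if self.times_s.shape != self.recovery.shape:
            raise ValueError("times and values must match in length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class OPLTrace:
    """Photoconverted-channel mean intensity over time for one cell."""

    times_h: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times_h.shape != self.intensity.shape:
            raise ValueError("times and intensities must match in length")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be strictly positive")


@dataclass
class FRAPFit:
    """Everything derived from one bleach experiment."""

    A: float
    tau: float  # 1/s
    t_half_s: float
    residual_rms: float
    w2_um2: float | None = None
    D_um2_per_s: float | None = None
    temperature_K: float | None = None
    stokes_radius_nm: float | None = None
    molecular_weight_kda: float | None = None
    viscosity_pa_s: float | None = None

    def summary(self) -> str:
        lines = [
            "FRAP single-exponential recovery fit",
            f"plateau A = {self.A:.4f}, tau = {self.tau:.5f} /s, "
            f"t1/2 = {self.t_half_s:.2f} s (rms residual {self.residual_rms:.4f})",
        ]
        if self.D_um2_per_s is not None:
            lines.append(
                f"w^2 = {self.w2_um2:.4f} um^2, D = {self.D_um2_per_s:.5f} um^2/s"
            )
        if self.viscosity_pa_s is not None:
            lines.append(
                f"r = {self.stokes_radius_nm:.2f} nm (M = "
                f"{self.molecular_weight_kda:.1f} kDa), T = "
                f"{self.temperature_K:.2f} K, eta = {self.viscosity_pa_s:.4f} Pa s"
            )
        return "\n".join(lines)


def normalize_frap(
    pre_bleach_frames: np.ndarray,
    post_bleach_frames: np.ndarray,
    granule_mask: np.ndarray,
    bleach_roi_mask: np.ndarray,
    times_s: np.ndarray | None = None,
    bleach_roi_area_um2: float | None = None,
) -> FRAPTrace:
    """Normalize a bleach series to a recovery trace.

    The whole-granule integrated density is taken from the pre-bleach
    frames; each post-bleach frame's ROI integrated density is expressed as
    a fraction of it, and the immediate post-bleach value of that fraction
    is subtracted as the floor. Frames are assumed registered (see
    ``imaging.register_stack``).
    """
    pre = np.asarray(pre_bleach_frames, dtype=float)
    post = np.asarray(post_bleach_frames, dtype=float)
    if pre.ndim == 2:
        pre = pre[None]
    if post.ndim == 2:
        post = post[None]
    granule_mask = np.asarray(granule_mask, dtype=bool)
    roi = np.asarray(bleach_roi_mask, dtype=bool)
    if not granule_mask.any() or not roi.any():
        raise ValueError("masks must be nonempty")
    if (roi & ~granule_mask).any():
        raise ValueError("bleach ROI must lie inside the granule mask")
    granule_pre = np.mean([f[granule_mask].sum() for f in pre])
    roi_pre_frac = np.mean([f[roi].sum() for f in pre]) / granule_pre
    frac = np.array([f[roi].sum() for f in post]) / granule_pre
    floor = frac[0]
    if floor >= roi_pre_frac - 1e-12:
        raise ValueError("ineffective bleach: no post-bleach intensity drop")
    if times_s is None:
        times_s = np.arange(len(post), dtype=float)
    return FRAPTrace(
        times_s=np.asarray(times_s, dtype=float),
        recovery=frac - floor,
        bleach_roi_area_um2=bleach_roi_area_um2,
    )


class FrapRecoveryModel:
    """Nonlinear least-squares fit of ``y(t) = A (1 - exp(-tau t))``.

    Initialization: ``A0 = max(y)``; ``tau0`` from a log-linear fit of
    ``1 - y/A0``. Bounds ``A in (0, 1.5]``, ``tau > 0``; three perturbed
    restarts before declaring non-convergence.
    """

    def __init__(self, trace: FRAPTrace):
        if len(trace.times_s) < 5:
            raise ValueError("need at least 5 points to fit recovery")
        self.trace = trace

    @staticmethod
    def _model(t, A, tau):
        return A * (1.0 - np.exp(-tau * t))

    def _initial_guess(self):
        t, y = self.trace.times_s, self.trace.recovery
        A0 = float(np.max(y))
        if A0 <= 0:
            raise ValueError("non-convergence: trace has no recovery signal")
        resid = 1.0 - np.clip(y / (A0 * 1.05), 1e-9, 1 - 1e-9)
        pos = t > 0
        slope = np.polyfit(t[pos], np.log(resid[pos]), 1)[0]
        tau0 = max(-slope, 1.0 / (t[-1] + 1e-12))
        return min(A0, 1.4), tau0

    def fit(
        self,
        compute_transport: bool = False,
        temperature_K: float = 310.15,
        molecular_weight_kda: float | None = None,
        bleach_roi_area_um2: float | None = None,
    ) -> FRAPFit:
        t, y = self.trace.times_s, self.trace.recovery
        A0, tau0 = self._initial_guess()
        if t[-1] * tau0 < 1.0:
            warnings.warn(
                "trace span is shorter than the recovery timescale; "
                "plateau may be poorly identified",
                stacklevel=2,
            )
        last_err: Exception | None = None
        rng = np.random.default_rng(12345)
        for attempt in range(4):
            if attempt == 0:
                p0 = (A0, tau0)
            else:
                p0 = (
                    float(np.clip(A0 * np.exp(rng.normal(0, 0.3)), 1e-3, 1.5)),
                    tau0 * float(np.exp(rng.normal(0, 0.7))),
                )
            try:
                popt, _ = optimize.curve_fit(
                    self._model,
                    t,
                    y,
                    p0=p0,
                    bounds=([1e-9, 1e-9], [1.5, np.inf]),
                    maxfev=10000,
                )
                break
            except (RuntimeError, ValueError) as err:  # pragma: no cover
                last_err = err
        else:
            raise ValueError(
                f"non-convergence after restarts (last error: {last_err})"
            )
        A_hat, tau_hat = float(popt[0]), float(popt[1])
        resid = y - self._model(t, A_hat, tau_hat)
        fit = FRAPFit(
            A=A_hat,
            tau=tau_hat,
            t_half_s=half_time(tau_hat),
            residual_rms=float(np.sqrt(np.mean(resid**2))),
        )
        if compute_transport:
            area = bleach_roi_area_um2 or self.trace.bleach_roi_area_um2
            if area is None:
                raise ValueError("bleach ROI area required for transport stage")
            fit.w2_um2 = area / math.pi
            fit.D_um2_per_s = diffusion_coefficient(area, fit.t_half_s)
            fit.temperature_K = temperature_K
            if molecular_weight_kda is not None:
                fit.molecular_weight_kda = molecular_weight_kda
                fit.stokes_radius_nm = stokes_radius(molecular_weight_kda)
                fit.viscosity_pa_s = viscosity(
                    fit.D_um2_per_s, temperature_K, fit.stokes_radius_nm
                )
        return fit


def fit_recovery(trace: FRAPTrace, **kwargs) -> FRAPFit:
    """Convenience wrapper: fit a trace and optionally the transport chain."""
    return FrapRecoveryModel(trace).fit(**kwargs)


def plot_recovery(trace: FRAPTrace, fit: FRAPFit | None = None, ax=None):
    """Recovery trace with the fitted exponential overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(trace.times_s, trace.recovery, ".", color="0.4", ms=4)
    if fit is not None:
        t = np.linspace(0, trace.times_s[-1], 300)
        ax.plot(t, fit.A * (1 - np.exp(-fit.tau * t)), color="C1")
        ax.axhline(fit.A, color="C1", lw=0.8, ls="--")
    ax.set_xlabel("time post-bleach (s)")
    ax.set_ylabel("normalized recovery")
    return ax


def half_time(tau: float) -> float:
    """Half-time of a single-exponential recovery: ``t_half = ln(2)/tau``."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return math.log(2.0) / tau


def diffusion_coefficient(bleach_roi_area_um2: float, t_half_s: float) -> float:
    """Spot-bleach effective diffusion: ``D = 0.88 w^2 / (4 t_half)``.

    The squared bleach-spot radius is approximated from the ROI area as
    ``w^2 = area / pi``.
    """
    if bleach_roi_area_um2 <= 0 or t_half_s <= 0:
        raise ValueError("area and half-time must be positive")
    w2 = bleach_roi_area_um2 / math.pi
    return 0.88 * w2 / (4.0 * t_half_s)


def stokes_radius(molecular_weight_kda: float) -> float:
    """Minimal bounding-sphere radius of a globular protein, in nm.

    ``r_min = 0.66 M^(1/3)`` with M in kDa.
    """
    if molecular_weight_kda <= 0:
        raise ValueError("molecular weight must be positive")
    return 0.66 * molecular_weight_kda ** (1.0 / 3.0)


def viscosity(D_um2_per_s: float, temperature_K: float, radius_nm: float) -> float:
    """Apparent viscosity from Einstein-Stokes: ``eta = k_B T / (6 pi D r)``.

    Inputs in um^2/s, K and nm; result in Pa s (SI conversion internal).
    """
    if D_um2_per_s <= 0 or temperature_K <= 0 or radius_nm <= 0:
        raise ValueError("all inputs must be positive")
    D_si = D_um2_per_s * 1e-12  # m^2/s
    r_si = radius_nm * 1e-9  # m
    return BOLTZMANN_J_PER_K * temperature_K / (6.0 * math.pi * D_si * r_si)


@dataclass
class HalfLifeFit:
    """Log-linear decay fit of a photoconversion trace."""

    k_per_h: float
    half_life_h: float
    r_squared: float
    intercept_log: float
    valid: bool

    def summary(self) -> str:
        tag = "" if self.valid else " [INVALID: signal not decaying]"
        return (
            f"OPL log-linear decay: k = {self.k_per_h:.5f} /h, half-life = "
            f"{self.half_life_h:.2f} h, R^2 = {self.r_squared:.4f}{tag}"
        )


class OplDecayModel:
    """Ordinary least squares on ``(t, ln I)``; half-life ``ln(2)/k``."""

    def __init__(self, trace: OPLTrace):
        if len(trace.times_h) < 3:
            raise ValueError("need at least 3 points")
        self.trace = trace

    def fit(self) -> HalfLifeFit:
        t = self.trace.times_h
        logI = np.log(self.trace.intensity)
        res = stats.linregress(t, logI)
        k = -res.slope
        valid = k > 0
        return HalfLifeFit(
            k_per_h=float(k),
            half_life_h=float(math.log(2.0) / k) if valid else float("nan"),
            r_squared=float(res.rvalue**2),
            intercept_log=float(res.intercept),
            valid=bool(valid),
        )


def fit_opl_halflife(trace: OPLTrace) -> HalfLifeFit:
    return OplDecayModel(trace).fit()
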