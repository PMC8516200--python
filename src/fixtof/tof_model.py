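"""Exponential modelling of formalin-diffusion TOF signals.

An ultrasound pulse crossing a formalin bath slows down as formalin
displaces interstitial fluid, so the time-of-flight (TOF) differential of
a submerged specimen decays toward osmotic equilibrium.  Empirically the
spatially averaged signal follows a single exponential

    TOF(t) = A * exp(-t / tau) + C

with amplitude ``A`` (ns), decay constant ``tau`` (hours) and offset ``C``
(ns).  This module holds the trace container, the nonlinear least-squares
fit, and the rate-of-diffusion mathematics built on it:

* the *normalized slope* — the derivative of the amplitude-normalized
  curve, in percent TOF change per hour,

      m(t) = 100 * (-1/tau) * exp(-t/tau)   [%/hr]

* the *completion time* — when |m| falls to a threshold slope ``s``
  (a fraction per hour; 0.074 for the default −7.4 %/hr criterion),

      t_done = -tau * ln(s * tau)

* delta-method confidence machinery for the decay constant and for the
  fitted mean curve, used by the three-condition real-time monitor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidArgumentError,
    InvalidFitError,
    MalformedTraceError,
)

__all__ = [
    "TofTrace",
    "ExpFit",
    "MonitorConfig",
    "CompletionTime",
    "spatial_average",
    "fit_exponential",
    "normalized_slope",
    "completion_time",
    "readiness",
    "fit_confidence",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class TofTrace:
    """Position-resolved TOF readings for one specimen.

    Parameters
    ----------
    sample_id
        Identifier of the specimen.
    times
        Elapsed times in hours, strictly increasing, ``>= 0``.
    positions
        Vertical transducer positions in mm (typically every 1 mm,
        5–9 per tissue).
    raw_tof
        ``(n_times, n_positions)`` grid of TOF differentials in ns;
        missing readings are NaN.
    calibration_tof
        Baseline TOF in ns measured through formalin only; subtracted
        from the spatial average to isolate the tissue's contribution.
    averaged_tof
        Per-time spatially averaged, calibration-subtracted signal (ns);
        populated by :func:`spatial_average`.
    metadata
        Free-form annotations (synthetic traces carry ground truth here).
    """

    sample_id: str
    times: np.ndarray
    positions: np.ndarray
    raw_tof: np.ndarray
    calibration_tof: float
    averaged_tof: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.raw_tof = np.asarray(self.raw_tof, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise MalformedTraceError("times must be a non-empty 1-D sequence")
        if np.any(np.diff(self.times) <= 0):
            raise MalformedTraceError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise MalformedTraceError("times must be non-negative")
        if self.raw_tof.shape != (self.times.size, self.positions.size):
            raise MalformedTraceError(
                f"raw_tof shape {self.raw_tof.shape} does not match "
                f"(n_times={self.times.size}, n_positions={self.positions.size})"
            )
        if self.averaged_tof is not None:
            self.averaged_tof = np.asarray(self.averaged_tof, dtype=float)
            if self.averaged_tof.shape != self.times.shape:
                raise MalformedTraceError("averaged_tof must have one value per time")

    @property
    def n_times(self) -> int:
        return int(self.times.size)


class ExpFit(NamedTuple):
    """Fitted single-exponential parameters with uncertainty.

    ``covariance`` is the 3x3 covariance of ``(A, tau, C)`` — the
    residual-variance-scaled inverse of the Gauss–Newton normal matrix at
    the solution.  ``dof = n_points - 3``.
    """

    amplitude_A: float
    decay_tau: float
    offset_C: float
    covariance: np.ndarray
    residual_variance: float
    n_points: int

    @property
    def dof(self) -> int:
        return self.n_points - 3

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the fitted mean curve A*exp(-t/tau) + C."""
        return self.amplitude_A * np.exp(-np.asarray(t, dtype=float) / self.decay_tau) + self.offset_C


class CompletionTime(float):
    """Completion time in hours; ``clamped`` is True when the sample was
    already below the threshold slope at t=0 and the time was clamped to 0."""

    clamped: bool

    def __new__(cls, hours: float, clamped: bool = False) -> "CompletionTime":
        obj = super().__new__(cls, hours)
        obj.clamped = clamped
        return obj


@dataclass(frozen=True)
class MonitorConfig:
    """Constants of the three-condition real-time validation model.

    slope_threshold
        Readiness criterion as a fraction per hour (0.074 = 7.4 %/hr).
    past_window, past_reference, past_rel_tol
        Condition #1: the last ``past_window`` consecutive checks must each
        find the current decay constant within ``past_rel_tol`` relative
        difference of the mean of the preceding ``past_reference`` estimates.
    present_ci_max
        Condition #2: full width of the 95% CI of the latest decay constant
        must be strictly below this many hours.
    future_band_max
        Condition #3: the pointwise 95% confidence band of the fitted TOF
        curve across all times (past, present and future) must be strictly
        narrower than this many ns.
    ci_level
        Confidence level for conditions #2 and #3.
    min_points_for_fit
        Points required before the first fit (3 parameters + 2 dof).
    horizon_hours, future_grid_points
        Evaluation grid for the future band; the asymptotic (t -> inf)
        width is always included as well.
    """

    slope_threshold: float = 0.074
    past_window: int = 10
    past_reference: int = 6
    past_rel_tol: float = 0.02
    present_ci_max: float = 0.7
    future_band_max: float = 2.0
    ci_level: float = 0.95
    min_points_for_fit: int = 5
    horizon_hours: float = 24.0
    future_grid_points: int = 200

    def __post_init__(self) -> None:
        for name in ("slope_threshold", "past_rel_tol", "present_ci_max",
                     "future_band_max", "horizon_hours"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        if not 0 < self.ci_level < 1:
            raise InvalidArgumentError("ci_level must be in (0, 1)")
        if self.min_points_for_fit < 4:
            raise InvalidArgumentError("min_points_for_fit must leave dof >= 1")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def spatial_average(trace: TofTrace) -> TofTrace:
    """Average readings across positions and subtract the calibration.

    Missing (NaN) position readings are skipped, not imputed.  Returns a
    new trace with ``averaged_tof`` populated; the raw grid is untouched.

    Raises
    ------
    MalformedTraceError
        If some time has no non-missing reading (the offending time is
        named in the message).
    """
    counts = np.sum(~np.isnan(trace.raw_tof), axis=1)
    if np.any(counts == 0):
        bad = trace.times[counts == 0][0]
        raise MalformedTraceError(f"no TOF readings at time {bad:g} hr")
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(trace.raw_tof, axis=1) - trace.calibration_tof
    return replace(trace, averaged_tof=avg)


def _model(t: np.ndarray, A: float, tau: float, C: float) -> np.ndarray:
    return A * np.exp(-t / tau) + C


def fit_exponential(
    times: Sequence[float],
    signal: Sequence[float],
    min_points: int = 5,
) -> ExpFit:
    """Least-squares fit of ``signal ~ A*exp(-t/tau) + C``.

    Initialization is deterministic: ``C0`` = last observed value,
    ``A0`` = first − last, ``tau0`` = time span / 3; the solver is damped
    least squares (trust-region reflective) with the bound ``tau > 0``.

    Raises
    ------
    InsufficientDataError
        Fewer than ``min_points`` samples.
    NonIdentifiableError
        Degenerate (zero-variance) signal — tau is unidentifiable.
    FitFailureError
        Solver failure, with diagnostics attached.
    """
    from .errors import NonIdentifiableError

    t = np.asarray(times, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise InvalidArgumentError("times and signal must be 1-D and equal length")
    if t.size < min_points:
        raise InsufficientDataError(
            f"need at least {min_points} points, got {t.size}"
        )
    if np.any(np.diff(t) <= 0):
        raise InvalidArgumentError("times must be strictly increasing")
    if np.ptp(y) == 0.0:
        raise NonIdentifiableError(
            "signal has zero variance; decay constant is unidentifiable"
        )

    span = t[-1] - t[0]
    p0 = np.array([y[0] - y[-1], span / 3.0, y[-1]])
    if p0[0] == 0.0:
        p0[0] = np.ptp(y)
    lower = np.array([-np.inf, 1e-9, -np.inf])
    upper = np.array([np.inf, np.inf, np.inf])
    try:
        popt, pcov = optimize.curve_fit(
            _model, t, y, p0=p0, bounds=(lower, upper),
            method="trf", maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover - rare solver failure
        raise FitFailureError(
            f"exponential fit did not converge: {exc}",
            diagnostics={"p0": p0.tolist(), "n": int(t.size)},
        ) from exc

    resid = y - _model(t, *popt)
    dof = t.size - 3
    s2 = float(resid @ resid / dof) if dof > 0 else float("nan")
    pcov = np.asarray(pcov, dtype=float)
    if not np.all(np.isfinite(pcov)):
        raise FitFailureError(
            "singular normal matrix; parameter covariance undefined",
            diagnostics={"popt": popt.tolist()},
        )
    return ExpFit(
        amplitude_A=float(popt[0]),
        decay_tau=float(popt[1]),
        offset_C=float(popt[2]),
        covariance=pcov,
        residual_variance=s2,
        n_points=int(t.size),
    )


def normalized_slope(fit: ExpFit, t_o: float) -> float:
    """Rate of diffusion: derivative of the amplitude-normalized curve.

    Returns ``100 * (-1/tau) * exp(-t_o/tau)`` in percent per hour —
    always negative, with magnitude strictly decreasing in ``t_o``.
    """
    if fit.decay_tau <= 0:
        raise InvalidFitError("decay_tau must be > 0")
    if t_o < 0:
        raise InvalidArgumentError("t_o must be >= 0")
    tau = fit.decay_tau
    return 100.0 * (-1.0 / tau) * np.exp(-t_o / tau)


def completion_time(fit: ExpFit, slope_threshold: float = 0.074) -> CompletionTime:
    """Hours of cold diffusion until |normalized slope| reaches the threshold.

    ``slope_threshold`` is a fraction per hour (0.074 for 7.4 %/hr).
    Closed form: ``t_done = -tau * ln(slope_threshold * tau)``.  When the
    sample is already below the threshold at t=0 (``slope_threshold*tau >= 1``)
    the result is clamped to 0 with ``.clamped`` set.
    """
    if slope_threshold <= 0:
        raise InvalidArgumentError("slope_threshold must be > 0")
    if fit.decay_tau <= 0:
        raise InvalidArgumentError("decay_tau must be > 0")
    arg = slope_threshold * fit.decay_tau
    if arg >= 1.0:
        return CompletionTime(0.0, clamped=True)
    return CompletionTime(-fit.decay_tau * np.log(arg), clamped=False)


def readiness(fit: ExpFit, t: float, config: MonitorConfig | None = None) -> bool:
    """True when the rate of diffusion at ``t`` has slowed to the criterion,
    i.e. |m(t)| <= 100 * slope_threshold (%/hr)."""
    config = config or MonitorConfig()
    return abs(normalized_slope(fit, t)) <= 100.0 * config.slope_threshold


def _band_gradient(fit: ExpFit, t: np.ndarray) -> np.ndarray:
    """Gradient of the mean curve w.r.t. (A, tau, C), shape (len(t), 3)."""
    tau = fit.decay_tau
    e = np.exp(-t / tau)
    g = np.empty((t.size, 3))
    g[:, 0] = e
    g[:, 1] = fit.amplitude_A * t / tau**2 * e
    g[:, 2] = 1.0
    return g


def fit_confidence(
    fit: ExpFit,
    level: float = 0.95,
    eval_times: Sequence[float] | None = None,
) -> tuple[float, np.ndarray]:
    """Confidence-interval widths for the decay constant and the mean curve.

    Returns ``(tau_ci_width, band_widths)``: the full width of the
    t-distribution CI of tau (``dof = n - 3``) and the full widths of the
    pointwise delta-method confidence band of the fitted mean curve at
    ``eval_times`` (empty array when ``eval_times`` is None).
    """
    if fit.dof < 1:
        raise InsufficientDataError("confidence intervals require dof >= 1")
    tq = stats.t.ppf(0.5 + level / 2.0, fit.dof)
    tau_var = max(float(fit.covariance[1, 1]), 0.0)
    tau_ci_width = 2.0 * tq * np.sqrt(tau_var)
    if eval_times is None:
        return tau_ci_width, np.empty(0)
    t = np.asarray(eval_times, dtype=float)
    g = _band_gradient(fit, t)
    var = np.maximum(np.einsum("ij,jk,ik->i", g, fit.covariance, g), 0.0)
    band_widths = 2.0 * tq * np.sqrt(var)
    return tau_ci_width, band_widths


def asymptotic_band_width(fit: ExpFit, level: float = 0.95) -> float:
    """Width of the mean-curve confidence band as t -> infinity.

    The exponential terms vanish, leaving only the offset-parameter
    variance: ``2 * t_q * sqrt(cov[C, C])``.
    """
    if fit.dof < 1:
        raise InsufficientDataError("confidence intervals require dof >= 1")
    tq = stats.t.ppf(0.5 + level / 2.0, fit.dof)
    return 2.0 * tq * np.sqrt(max(float(fit.covariance[2, 2]), 0.0))
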