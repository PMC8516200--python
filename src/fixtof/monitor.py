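"""Three-condition streaming validation of TOF diffusion signals.

Early in an experiment a sparse, noisy TOF curve can produce wildly
wrong decay constants, so a completion-time prediction is only trusted
once the fit has demonstrably converged to the tissue's true diffusion
profile.  After every new spatially averaged point the signal is refit
and three independent conditions are checked:

* **past** — the decay constant has stabilised: each of the last 10
  checks found the current tau within 2% of the mean of the preceding
  6 estimates;
* **present** — the 95% CI of the latest decay constant is narrower
  than 0.7 hours;
* **future** — the 95% confidence band of the fitted TOF curve is
  narrower than 2 ns across all times, past, present and future.

The first update at which all three hold simultaneously *validates* the
signal; the completion time predicted from that fit is latched and never
revoked by later data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import tof_model
from .errors import FixtofError, OrderingError
from .tof_model import ExpFit, MonitorConfig, TofTrace

__all__ = [
    "MonitorState",
    "CohortReport",
    "update",
    "condition_past",
    "condition_present",
    "condition_future",
    "evaluate_cohort",
]


@dataclass
class MonitorState:
    """Streaming state of the real-time validation model for one specimen.

    ``fit_history`` holds one fit per update once ``min_points_for_fit``
    is reached; ``condition_flags`` the (past, present, future) booleans
    per fit.  ``validated_at``/``predicted_done_at`` are set exactly once,
    at the first update where all three conditions hold.
    """

    config: MonitorConfig = field(default_factory=MonitorConfig)
    sample_id: str = ""
    times: list[float] = field(default_factory=list)
    tofs: list[float] = field(default_factory=list)
    fit_history: list[ExpFit] = field(default_factory=list)
    fit_times: list[float] = field(default_factory=list)
    condition_flags: list[tuple[bool, bool, bool]] = field(default_factory=list)
    validated_at: float | None = None
    predicted_done_at: float | None = None
    event_log: list[dict] = field(default_factory=list)

    @property
    def validated(self) -> bool:
        return self.validated_at is not None


def condition_past(fit_history: Sequence[ExpFit], config: MonitorConfig) -> bool:
    """Condition #1 (past): the decay constant has converged.

    A single check at fit *i* (needing ``past_reference`` earlier fits)
    passes when ``|tau_i - mean(tau_{i-6..i-1})| / mean < past_rel_tol``.
    True iff the last ``past_window`` checks all exist and all pass; with
    the 10/6 defaults the earliest possible pass is the 16th fit.
    """
    k, w, tol = config.past_reference, config.past_window, config.past_rel_tol
    n = len(fit_history)
    if n < k + w:
        return False
    taus = np.array([f.decay_tau for f in fit_history])
    for i in range(n - w, n):  # last w checks, 0-based fit index i
        ref = taus[i - k:i].mean()
        if ref <= 0 or abs(taus[i] - ref) / ref >= tol:
            return False
    return True


def condition_present(latest_fit: ExpFit | None, config: MonitorConfig) -> bool:
    """Condition #2 (present): 95% CI of the latest decay constant is
    strictly narrower than ``present_ci_max`` hours."""
    if latest_fit is None or latest_fit.dof < 1:
        return False
    tau_ci_width, _ = tof_model.fit_confidence(latest_fit, config.ci_level)
    return bool(tau_ci_width < config.present_ci_max)


def condition_future(latest_fit: ExpFit | None, config: MonitorConfig) -> bool:
    """Condition #3 (future): pointwise 95% confidence band of the fitted
    TOF curve is strictly narrower than ``future_band_max`` ns across all
    times — a dense grid on [0, horizon_hours] plus the asymptotic
    (t -> infinity) width."""
    if latest_fit is None or latest_fit.dof < 1:
        return False
    grid = np.linspace(0.0, config.horizon_hours, config.future_grid_points)
    _, widths = tof_model.fit_confidence(latest_fit, config.ci_level, grid)
    w_inf = tof_model.asymptotic_band_width(latest_fit, config.ci_level)
    return max(float(widths.max()), w_inf) < config.future_band_max


def update(state: MonitorState, time: float, averaged_tof: float) -> MonitorState:
    """Feed one spatially averaged TOF point into the monitor.

    Appends the point; once ``min_points_for_fit`` is reached, refits the
    exponential, evaluates the three conditions, and — on their first
    simultaneous satisfaction — latches ``validated_at`` and the predicted
    completion time.  The decision is never revoked.  Mutates and returns
    ``state``.
    """
    if state.times and time <= state.times[-1]:
        raise OrderingError(
            f"time {time:g} does not exceed last seen time {state.times[-1]:g}"
        )
    state.times.append(float(time))
    state.tofs.append(float(averaged_tof))
    if len(state.times) < state.config.min_points_for_fit:
        return state

    try:
        fit = tof_model.fit_exponential(
            state.times, state.tofs, min_points=state.config.min_points_for_fit
        )
    except FixtofError as exc:
        state.event_log.append(
            {"t": time, "event": "fit_failed", "reason": str(exc)}
        )
        return state

    state.fit_history.append(fit)
    state.fit_times.append(float(time))
    flags = (
        bool(condition_past(state.fit_history, state.config)),
        bool(condition_present(fit, state.config)),
        bool(condition_future(fit, state.config)),
    )
    state.condition_flags.append(flags)
    state.event_log.append(
        {
            "t": time,
            "event": "fit",
            "tau_hr": fit.decay_tau,
            "past": flags[0],
            "present": flags[1],
            "future": flags[2],
        }
    )
    if not state.validated and all(flags):
        state.validated_at = float(time)
        done = tof_model.completion_time(fit, state.config.slope_threshold)
        state.predicted_done_at = float(done)
        state.event_log.append(
            {
                "t": time,
                "event": "validated",
                "predicted_done_hr": float(done),
                "clamped": done.clamped,
            }
        )
    return state


def run_trace(trace: TofTrace, config: MonitorConfig | None = None) -> MonitorState:
    """Replay a complete trace through the monitor, point by point."""
    config = config or MonitorConfig()
    if trace.averaged_tof is None:
        trace = tof_model.spatial_average(trace)
    state = MonitorState(config=config, sample_id=trace.sample_id)
    for t, y in zip(trace.times, trace.averaged_tof):
        update(state, float(t), float(y))
    return state


@dataclass
class CohortReport:
    """Retrospective evaluation of the monitor over a cohort of traces.

    Per-sample records hold the completion time from the full-trace fit
    (``true_done``), the completion time predicted at validation, the
    validation time, ``lead_time = true_done - validated_at`` and
    ``abs_error = |predicted - true|``.  Traces that never validate are
    recorded as censored and excluded from the summary means.
    """

    records: list[dict] = field(default_factory=list)
    n_censored: int = 0

    @property
    def n_validated(self) -> int:
        return len([r for r in self.records if not r["censored"]])

    def _mean(self, key: str) -> float:
        vals = [r[key] for r in self.records if not r["censored"]]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_abs_error(self) -> float:
        """Mean |predicted − true| completion time, hours."""
        return self._mean("abs_error")

    @property
    def mean_lead_time(self) -> float:
        """Mean (true completion − validation time), hours."""
        return self._mean("lead_time")

    @property
    def mean_validated_at(self) -> float:
        return self._mean("validated_at")

    @property
    def mean_predicted_done(self) -> float:
        return self._mean("predicted_done")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame.from_records(self.records)


def evaluate_cohort(
    traces: Sequence[TofTrace], config: MonitorConfig | None = None
) -> CohortReport:
    """Stream every trace through the monitor and score the predictions.

    The ground truth for each trace is the completion time of the fit on
    the complete trace — the fit at the end of the experiment.
    """
    config = config or MonitorConfig()
    report = CohortReport()
    for trace in traces:
        if trace.averaged_tof is None:
            trace = tof_model.spatial_average(trace)
        state = run_trace(trace, config)
        full_fit = tof_model.fit_exponential(
            trace.times, trace.averaged_tof, min_points=config.min_points_for_fit
        )
        true_done = float(tof_model.completion_time(full_fit, config.slope_threshold))
        rec: dict = {
            "sample_id": trace.sample_id,
            "true_done": true_done,
            "censored": not state.validated,
        }
        if state.validated:
            rec.update(
                predicted_done=state.predicted_done_at,
                validated_at=state.validated_at,
                lead_time=true_done - state.validated_at,
                abs_error=abs(state.predicted_done_at - true_done),
            )
        else:
            rec.update(
                predicted_done=float("nan"),
                validated_at=float("nan"),
                lead_time=float("nan"),
                abs_error=float("nan"),
            )
            report.n_censored += 1
        report.records.append(rec)
    return report
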