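"""Hemodynamic response descriptors from the power-Doppler movie.

Three quantities summarise the evoked response of an acquisition: the
number of significantly active pixels, the steady-state ΔCBV (mean percent
change over the 7-20 s post-onset window of a 20 s stimulation block), and
the 10 %-90 % rise time of the trial-averaged evoked trace (step-response
convention, linear interpolation at the threshold crossings).

Undefined metrics — no active pixels, a non-positive plateau, a response
that never reaches the upper threshold — propagate as NaN with a reason
code, never as silent zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .activation import ActivationMap, count_active
from .doppler import PowerDopplerMovie
from .synthetic import StimulusProtocol

__all__ = [
    "EvokedTrace",
    "DescriptorSet",
    "extract_evoked_trace",
    "steady_state_dcbv",
    "rise_time",
    "compute_descriptors",
    "DEFAULT_STEADY_WINDOW_S",
    "DEFAULT_RISE_THRESHOLDS",
    "DEFAULT_BASELINE_WINDOW_S",
]

logger = logging.getLogger(__name__)

DEFAULT_STEADY_WINDOW_S = (7.0, 20.0)
DEFAULT_RISE_THRESHOLDS = (0.10, 0.90)
DEFAULT_BASELINE_WINDOW_S = 10.0


class UndefinedMetricError(ValueError):
    """Raised when a descriptor is requested on data where it has no value."""


@dataclass
class EvokedTrace:
    """Trial-averaged ΔCBV time course, in % of the pre-onset baseline."""

    time_s: np.ndarray  # relative to stimulation onset; uniform grid
    dcbv_pct: np.ndarray
    n_trials_averaged: int

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.dcbv_pct = np.asarray(self.dcbv_pct, dtype=float)
        if self.time_s.shape != self.dcbv_pct.shape:
            raise ValueError("time and value arrays must match")
        if len(self.time_s) > 1:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("time grid must be uniform")


@dataclass
class DescriptorSet:
    """The three per-acquisition hemodynamic descriptors."""

    n_active_pixels: int
    delta_cbv_pct: float  # NaN when undefined
    rise_time_s: float  # NaN when undefined
    window_steady_s: tuple[float, float] = DEFAULT_STEADY_WINDOW_S
    rise_thresholds: tuple[float, float] = DEFAULT_RISE_THRESHOLDS
    flags: dict[str, str] = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "n_active_pixels": self.n_active_pixels,
            "delta_cbv_pct": self.delta_cbv_pct,
            "rise_time_s": self.rise_time_s,
        }


def extract_evoked_trace(
    movie: PowerDopplerMovie,
    active_mask: np.ndarray,
    protocol: StimulusProtocol,
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
) -> EvokedTrace:
    """Average the movie over active pixels and over stimulation epochs.

    The movie is first averaged over ``active_mask``; one epoch per
    stimulation is cut from ``baseline_window_s`` before onset to the end
    of the rest period; per epoch, ΔCBV% = 100 * (signal - baseline mean)
    / baseline mean with the baseline the pre-onset window; epochs are
    averaged point-wise.  Frame k holds the block starting at
    ``k / frame_rate`` seconds.
    """
    active_mask = np.asarray(active_mask, dtype=bool)
    if active_mask.shape != movie.power.shape[:2]:
        raise ValueError("active_mask shape mismatch")
    if not active_mask.any():
        raise UndefinedMetricError("no active pixels: evoked trace undefined")
    if baseline_window_s <= 0:
        raise ValueError("baseline_window_s must be > 0")

    fr = movie.frame_rate_hz
    signal = movie.power[active_mask].mean(axis=0)  # (n_frames,)
    n_pre = int(round(baseline_window_s * fr))
    n_epoch = int(round((baseline_window_s + protocol.cycle_s) * fr))
    if n_pre < 1:
        raise ValueError("baseline window shorter than one frame")

    epochs = []
    for onset in protocol.onsets_s():
        i0 = int(round((onset - baseline_window_s) * fr))
        if i0 < 0 or i0 + n_epoch > len(signal):
            raise ValueError("stimulation epochs do not fit within the movie")
        seg = signal[i0: i0 + n_epoch]
        baseline = seg[:n_pre].mean()
        if baseline <= 0:
            raise UndefinedMetricError("non-positive baseline power")
        epochs.append(100.0 * (seg - baseline) / baseline)
    mean_epoch = np.mean(epochs, axis=0)
    time_s = (np.arange(n_epoch) - n_pre) / fr
    return EvokedTrace(time_s=time_s, dcbv_pct=mean_epoch, n_trials_averaged=len(epochs))


def steady_state_dcbv(trace: EvokedTrace, window_s: tuple[float, float] = DEFAULT_STEADY_WINDOW_S) -> float:
    """Mean ΔCBV% over the steady-state window after stimulus onset."""
    lo, hi = window_s
    if lo >= hi:
        raise ValueError("window start must precede its end")
    sel = (trace.time_s >= lo) & (trace.time_s <= hi)
    if not sel.any():
        raise ValueError(f"steady-state window {window_s} falls outside the trace")
    return float(trace.dcbv_pct[sel].mean())


def _first_crossing(time_s: np.ndarray, y: np.ndarray, level: float, start_idx: int = 0) -> float | None:
    """Time of the first crossing of ``level`` at or after ``start_idx``.

    Ties exactly at the threshold resolve to the earliest frame; between
    frames the crossing is located by linear interpolation.
    """
    for i in range(start_idx, len(y)):
        if y[i] >= level:
            if i == start_idx or y[i] == level or y[i - 1] >= level:
                return float(time_s[i])
            frac = (level - y[i - 1]) / (y[i] - y[i - 1])
            return float(time_s[i - 1] + frac * (time_s[i] - time_s[i - 1]))
    return None


def rise_time(
    trace: EvokedTrace,
    thresholds: tuple[float, float] = DEFAULT_RISE_THRESHOLDS,
    steady_ref: float | None = None,
) -> float:
    """10 %-90 % rise time of the evoked response, in seconds.

    Time between the first crossing of ``low * steady_ref`` and the first
    subsequent crossing of ``high * steady_ref`` after stimulus onset
    (t >= 0), with linear interpolation between frames.  ``steady_ref``
    defaults to the steady-state window mean.  Returns NaN when the
    reference is non-positive or the upper level is never reached.
    """
    low, high = thresholds
    if not 0 < low < high < 1:
        raise ValueError("thresholds must satisfy 0 < low < high < 1")
    if steady_ref is None:
        steady_ref = steady_state_dcbv(trace)
    if not np.isfinite(steady_ref) or steady_ref <= 0:
        logger.warning("rise_time: non-positive steady-state reference (%.3g)", steady_ref)
        return float("nan")
    onset = int(np.searchsorted(trace.time_s, 0.0))
    t_low = _first_crossing(trace.time_s, trace.dcbv_pct, low * steady_ref, onset)
    if t_low is None:
        logger.warning("rise_time: lower threshold never crossed")
        return float("nan")
    after = int(np.searchsorted(trace.time_s, t_low))
    t_high = _first_crossing(trace.time_s, trace.dcbv_pct, high * steady_ref, after)
    if t_high is None:
        logger.warning("rise_time: upper threshold never crossed")
        return float("nan")
    return max(t_high - t_low, 0.0)


def compute_descriptors(
    movie: PowerDopplerMovie,
    activation_map: ActivationMap,
    roi: np.ndarray | None,
    protocol: StimulusProtocol,
    steady_window_s: tuple[float, float] = DEFAULT_STEADY_WINDOW_S,
    rise_thresholds: tuple[float, float] = DEFAULT_RISE_THRESHOLDS,
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
) -> DescriptorSet:
    """Bundle active-pixel count, steady-state ΔCBV and rise time for one run.

    The trace metrics use the roi-restricted active pixels; with zero
    active pixels the count is 0 and both trace metrics come back NaN with
    a reason code in ``flags``.
    """
    n = count_active(activation_map, roi)
    flags: dict[str, str] = {}
    if n == 0:
        flags["delta_cbv_pct"] = flags["rise_time_s"] = "no_active_pixels"
        return DescriptorSet(0, float("nan"), float("nan"), steady_window_s, rise_thresholds, flags)
    mask = activation_map.active if roi is None else (activation_map.active & np.asarray(roi, dtype=bool))
    trace = extract_evoked_trace(movie, mask, protocol, baseline_window_s)
    dcbv = steady_state_dcbv(trace, steady_window_s)
    rt = rise_time(trace, rise_thresholds, steady_ref=dcbv if dcbv > 0 else None)
    if dcbv <= 0:
        flags["rise_time_s"] = "non_positive_plateau"
        rt = float("nan")
    elif not np.isfinite(rt):
        flags["rise_time_s"] = "threshold_not_crossed"
    return DescriptorSet(n, float(dcbv), float(rt), steady_window_s, rise_thresholds, flags)
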