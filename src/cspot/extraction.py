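"""Multi-unit spike extraction by baseline-derived amplitude thresholding.

Multi-unit activity is taken from a high-pass filtered voltage trace by
thresholding: the threshold is derived from a baseline stretch of the
recording (mean -/+ k standard deviations, k = 4 by default with negative
polarity, conventional for extracellular multi-unit work), and each
threshold-crossing event yields one spike time. Crossings within a dead
time of the previous accepted spike are suppressed. No spike sorting and
no artifact rejection are attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["ExtractionParams", "InvalidWindowError", "derive_threshold", "detect_spikes"]

DEFAULT_SD_MULTIPLIER = 4.0
DEFAULT_DEAD_TIME_S = 0.0005


class InvalidWindowError(ValueError):
    """Raised when a baseline window is empty or outside the trace."""


@dataclass(frozen=True)
class ExtractionParams:
    """Thresholding parameters.

    ``threshold`` is signed for negative/positive polarity; for
    ``absolute`` polarity it is a positive excursion magnitude compared
    against ``|trace|``. ``diff_filter`` optionally applies a first-order
    difference as a crude high-pass substitute (off by default; the
    recordings modelled here are already high-pass filtered).
    """

    threshold: float
    polarity: str = "negative"
    dead_time_s: float = DEFAULT_DEAD_TIME_S
    baseline_window_s: Optional[tuple[float, float]] = None
    diff_filter: bool = False

    def __post_init__(self) -> None:
        if self.polarity not in ("negative", "positive", "absolute"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.dead_time_s < 0:
            raise ValueError("dead_time_s must be >= 0")


def _window_samples(
    trace: np.ndarray, sampling_rate_hz: float, window_s: tuple[float, float]
) -> np.ndarray:
    start, end = window_s
    # epsilons absorb float error when a window edge lands on a sample
    i0 = int(np.floor(start * sampling_rate_hz + 1e-9))
    i1 = int(np.ceil(end * sampling_rate_hz - 1e-9))
    if i0 < 0 or i1 > trace.size or i1 <= i0:
        raise InvalidWindowError(
            f"baseline window {window_s} s outside trace of "
            f"{trace.size / sampling_rate_hz:.3f} s"
        )
    return trace[i0:i1]


def derive_threshold(
    trace: np.ndarray,
    sampling_rate_hz: float,
    baseline_window_s: tuple[float, float],
    k: float = DEFAULT_SD_MULTIPLIER,
    polarity: str = "negative",
) -> float:
    """Threshold = baseline mean -/+ k * baseline SD, per polarity.

    Negative polarity subtracts, positive adds; absolute returns the
    (positive) excursion ``k * SD`` to be compared against ``|trace|``.
    """
    trace = np.asarray(trace, dtype=float)
    seg = _window_samples(trace, sampling_rate_hz, baseline_window_s)
    mean = float(seg.mean())
    sd = float(seg.std())
    if polarity == "negative":
        return mean - k * sd
    if polarity == "positive":
        return mean + k * sd
    if polarity == "absolute":
        return k * sd
    raise ValueError(f"unknown polarity {polarity!r}")


def detect_spikes(
    trace: np.ndarray, sampling_rate_hz: float, params: ExtractionParams
) -> np.ndarray:
    """Spike times (s) of threshold-crossing events, dead-time suppressed.

    A crossing is the first sample at which the signal passes the
    threshold coming from the sub-threshold side; runs of consecutive
    supra-threshold samples yield a single event at their first sample.
    """
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be > 0")
    x = np.asarray(trace, dtype=float)
    if params.diff_filter and x.size:
        x = np.diff(x, prepend=x[0])
    if x.size == 0:
        return np.empty(0)

    if params.polarity == "negative":
        above = x < params.threshold
    elif params.polarity == "positive":
        above = x > params.threshold
    else:
        above = np.abs(x) > params.threshold

    if not above.any():
        return np.empty(0)
    onsets = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    times = onsets / sampling_rate_hz
    if params.dead_time_s <= 0 or times.size < 2:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= params.dead_time_s:
            kept.append(t)
    return np.asarray(kept)
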