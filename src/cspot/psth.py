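"""Stimulus-aligned spike-count rasters and peri-stimulus time histograms.

A PSTH holds, for one channel and one block of stimulations, the spike
counts in half-open 1 ms bins of latency relative to stimulation onset,
summed over the block's stimulations. The default analysis window spans
-500 ms (the spontaneous-activity baseline) to +100 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = ["PSTH", "PSTHConfigurationError", "build_psth", "block_psths", "align_latencies"]

DEFAULT_WINDOW_MS = (-500.0, 100.0)
DEFAULT_BIN_MS = 1.0

#: Absolute nudge (ms) applied before flooring latencies into bins, so that
#: spikes generated at exact bin boundaries are not pushed into the lower
#: bin by float rounding of (spike - stim).
_BIN_EDGE_NUDGE_MS = 1e-6


class PSTHConfigurationError(ValueError):
    """Raised when window/bin geometry is inconsistent."""


@dataclass
class PSTH:
    """Binned spike counts aligned on stimulation onset.

    ``counts[b]`` is the number of (spike, stimulation) pairs whose latency
    falls in the half-open bin ``[window[0] + b*bin_width, ...)``, summed
    over the block's ``n_stims`` stimulations.
    """

    counts: np.ndarray
    bin_width_ms: float
    window_ms: tuple[float, float]
    n_stims: int
    channel_id: Optional[int] = None
    block_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n_bins = _n_bins(self.window_ms, self.bin_width_ms)
        if self.counts.shape != (n_bins,):
            raise PSTHConfigurationError(
                f"expected {n_bins} bins for window {self.window_ms} at "
                f"{self.bin_width_ms} ms, got {self.counts.shape}"
            )

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def bin_starts_ms(self) -> np.ndarray:
        return self.window_ms[0] + self.bin_width_ms * np.arange(self.n_bins)

    def bin_slice(self, lo_ms: float, hi_ms: float) -> slice:
        """Index slice of bins fully covering the half-open window [lo, hi)."""
        w0, w1 = self.window_ms
        if lo_ms < w0 - 1e-9 or hi_ms > w1 + 1e-9:
            raise PSTHConfigurationError(
                f"window [{lo_ms}, {hi_ms}) ms outside PSTH window {self.window_ms}"
            )
        i0 = int(round((lo_ms - w0) / self.bin_width_ms))
        i1 = int(round((hi_ms - w0) / self.bin_width_ms))
        return slice(i0, i1)

    def latency_to_bin(self, latency_ms: float) -> int:
        return int(round((latency_ms - self.window_ms[0]) / self.bin_width_ms))


def _n_bins(window_ms: tuple[float, float], bin_width_ms: float) -> int:
    lo, hi = window_ms
    if hi <= lo:
        raise PSTHConfigurationError(f"empty window {window_ms}")
    span = hi - lo
    n = span / bin_width_ms
    if abs(n - round(n)) > 1e-9:
        raise PSTHConfigurationError(
            f"bin width {bin_width_ms} ms does not divide window {window_ms}"
        )
    return int(round(n))


def align_latencies(
    spike_times_s: np.ndarray,
    stim_times_s: np.ndarray,
    window_ms: tuple[float, float],
) -> np.ndarray:
    """All spike latencies (ms) relative to each stimulation, within the window.

    Returns the concatenated latencies of every (spike, stimulation) pair
    with ``window[0] <= spike - stim < window[1]``; the raster
    representation underlying the PSTH.
    """
    spikes = np.asarray(spike_times_s, dtype=float)
    stims = np.asarray(stim_times_s, dtype=float)
    w0, w1 = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    lo = np.searchsorted(spikes, stims + w0, side="left")
    hi = np.searchsorted(spikes, stims + w1, side="left")
    counts = hi - lo
    if counts.sum() == 0:
        return np.empty(0)
    # flat indices of spikes[lo[k]:hi[k]] for every stimulation k
    flat = np.repeat(lo - np.concatenate(([0], np.cumsum(counts)[:-1])), counts)
    flat = flat + np.arange(counts.sum())
    aligned_stims = np.repeat(stims, counts)
    return (spikes[flat] - aligned_stims) * 1000.0


def build_psth(
    spike_times_s: np.ndarray,
    stim_times_s: np.ndarray,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    bin_width_ms: float = DEFAULT_BIN_MS,
    channel_id: Optional[int] = None,
    block_index: Optional[int] = None,
) -> PSTH:
    """Bin spike latencies relative to stimulation onsets.

    Bins are half-open ``[lo, hi)``; a spike at latency exactly 8 ms lands
    in the bin starting at 8 ms. ``stim_times_s`` must be sorted.
    """
    n_bins = _n_bins(window_ms, bin_width_ms)
    lat = align_latencies(spike_times_s, stim_times_s, window_ms)
    if lat.size:
        bins = np.floor(
            (lat - window_ms[0]) / bin_width_ms + _BIN_EDGE_NUDGE_MS
        ).astype(int)
        # latencies an epsilon below window end would otherwise overflow
        np.clip(bins, 0, n_bins - 1, out=bins)
        counts = np.bincount(bins, minlength=n_bins)
    else:
        counts = np.zeros(n_bins, dtype=int)
    return PSTH(
        counts=counts,
        bin_width_ms=bin_width_ms,
        window_ms=tuple(window_ms),
        n_stims=int(np.asarray(stim_times_s).size),
        channel_id=channel_id,
        block_index=block_index,
    )


def block_psths(
    spike_trains: Mapping[int, np.ndarray],
    schedule,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    bin_width_ms: float = DEFAULT_BIN_MS,
) -> dict[int, list[PSTH]]:
    """One PSTH per (channel, block) for a whole recording.

    ``spike_trains`` maps channel id to a sorted spike-time array in
    seconds; ``schedule`` is an :class:`~cspot.protocol.EventSchedule`.
    Spikes outside the recording extent are ignored with a warning.
    """
    out: dict[int, list[PSTH]] = {}
    for channel, spikes in spike_trains.items():
        spikes = np.asarray(spikes, dtype=float)
        if spikes.size and (spikes[0] < 0 or spikes[-1] > schedule.duration_s):
            warnings.warn(
                f"channel {channel}: spikes outside [0, {schedule.duration_s:.1f}] s "
                "are ignored",
                stacklevel=2,
            )
        out[channel] = [
            build_psth(
                spikes,
                schedule.stims_in_block(b),
                window_ms=window_ms,
                bin_width_ms=bin_width_ms,
                channel_id=channel,
                block_index=b,
            )
            for b in range(schedule.n_blocks)
        ]
    return out
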