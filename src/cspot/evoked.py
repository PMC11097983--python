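"""Evoked-response detection and block-series normalization.

First- and second-series analysis: for each block's PSTH a threshold
(baseline mean + 3 SD over the 500 pre-stimulus 1 ms bins) is computed,
the cortically-evoked response peak is located within 50 ms of
stimulation, onset and offset are the boundaries of the contiguous run of
supra-threshold bins around the peak, magnitude is the spike count over
[onset, offset] minus the expected baseline count for the same span, and
the per-block magnitudes are normalized to the mean of the blocks recorded
before the bicuculline injection.

The SD entering the threshold is the population SD of the per-bin counts
of the block's own baseline window: the threshold is compared against
per-bin counts, so its dispersion must be per-bin count dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .psth import PSTH, PSTHConfigurationError, block_psths

__all__ = [
    "BaselineStats",
    "EvokedResponse",
    "NormalizedSeries",
    "NormalizationError",
    "baseline_threshold",
    "detect_response",
    "response_magnitude",
    "normalize_series",
    "EvokedSeriesModel",
    "EvokedSeriesResults",
]


class NormalizationError(ValueError):
    """Raised when the normalization baseline is degenerate."""


@dataclass(frozen=True)
class BaselineStats:
    """Baseline per-bin mean/SD of one block PSTH and the derived threshold."""

    mean: float
    sd: float
    threshold: float


@dataclass(frozen=True)
class EvokedResponse:
    """A detected cortically-evoked response in one block PSTH.

    Latencies are bin-start times in ms after stimulation onset;
    ``onset_ms <= peak_latency_ms <= offset_ms``.
    """

    peak_latency_ms: float
    onset_ms: float
    offset_ms: float
    baseline_mean: float
    baseline_sd: float
    threshold: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class NormalizedSeries:
    """Per-block magnitudes expressed relative to the pre-bicuculline mean."""

    values: np.ndarray
    baseline_block_indices: tuple[int, ...]
    convention: str  # 'percent_of_baseline' or 'percent_change'


def baseline_threshold(
    psth: PSTH,
    sd_multiplier: float = 3.0,
    baseline_window_ms: tuple[float, float] = (-500.0, 0.0),
) -> BaselineStats:
    """Mean, population SD and mean + k*SD over the pre-stimulus bins."""
    try:
        sl = psth.bin_slice(*baseline_window_ms)
    except PSTHConfigurationError as err:
        raise PSTHConfigurationError(
            f"PSTH window {psth.window_ms} does not cover the baseline window "
            f"{baseline_window_ms}"
        ) from err
    seg = psth.counts[sl].astype(float)
    if seg.size == 0:
        raise PSTHConfigurationError("empty baseline window")
    mean = float(seg.mean())
    sd = float(seg.std())  # population SD over baseline bins
    return BaselineStats(mean=mean, sd=sd, threshold=mean + sd_multiplier * sd)


def detect_response(
    psth: PSTH,
    stats: BaselineStats,
    response_window_ms: tuple[float, float] = (0.0, 50.0),
) -> Optional[EvokedResponse]:
    """Locate the evoked response, or return None if nothing crosses threshold.

    The peak is the maximum-count bin within the response window (earliest
    bin on ties). Onset and offset are the first and last bins of the
    contiguous run of strictly supra-threshold bins containing the peak.
    """
    sl = psth.bin_slice(*response_window_ms)
    seg = psth.counts[sl].astype(float)
    if seg.size == 0:
        return None
    peak = int(np.argmax(seg))  # argmax takes the earliest on ties
    if not seg[peak] > stats.threshold:
        return None
    i = peak
    while i > 0 and seg[i - 1] > stats.threshold:
        i -= 1
    k = peak
    while k < seg.size - 1 and seg[k + 1] > stats.threshold:
        k += 1
    bw = psth.bin_width_ms
    lo = response_window_ms[0]
    return EvokedResponse(
        peak_latency_ms=lo + peak * bw,
        onset_ms=lo + i * bw,
        offset_ms=lo + k * bw,
        baseline_mean=stats.mean,
        baseline_sd=stats.sd,
        threshold=stats.threshold,
    )


def response_magnitude(psth: PSTH, response: EvokedResponse) -> float:
    """Spike count over [onset, offset] minus the baseline count expected there."""
    i = psth.latency_to_bin(response.onset_ms)
    k = psth.latency_to_bin(response.offset_ms)
    n_bins = k - i + 1
    return float(psth.counts[i : k + 1].sum() - response.baseline_mean * n_bins)


def normalize_series(
    magnitudes: Sequence[float],
    baseline_blocks: Sequence[int],
    convention: str = "percent_of_baseline",
) -> NormalizedSeries:
    """Express per-block magnitudes relative to the mean of the baseline blocks.

    'percent_of_baseline' reports 100 for no change; 'percent_change'
    reports 0 for no change.
    """
    mags = np.asarray(magnitudes, dtype=float)
    idx = list(baseline_blocks)
    if not idx:
        raise NormalizationError("no baseline blocks given")
    ref = float(mags[idx].mean())
    if ref == 0:
        raise NormalizationError("baseline magnitude mean is zero")
    values = 100.0 * mags / ref
    if convention == "percent_change":
        values = values - 100.0
    elif convention != "percent_of_baseline":
        raise ValueError(f"unknown convention {convention!r}")
    return NormalizedSeries(
        values=values, baseline_block_indices=tuple(idx), convention=convention
    )


class EvokedSeriesModel:
    """Block-wise evoked-response analysis of a multichannel recording.

    Parameters
    ----------
    dataset
        A :class:`~cspot.simulate.Dataset`, or a mapping of channel id to
        sorted spike-time array (then ``schedule`` must be given).
    schedule
        The :class:`~cspot.protocol.EventSchedule`; taken from the dataset
        when omitted.
    config
        :class:`~cspot.config.AnalysisConfig`; defaults are the study
        conditions.

    ``fit()`` detects the evoked response in every (channel, block) PSTH
    and normalizes each channel's magnitude series to its pre-bicuculline
    blocks; blocks without a detectable response contribute magnitude 0.
    """

    def __init__(self, dataset, schedule=None, config: Optional[AnalysisConfig] = None):
        if hasattr(dataset, "spike_trains"):
            self.spike_trains = dataset.spike_trains
            schedule = schedule if schedule is not None else dataset.schedule
        else:
            self.spike_trains = dict(dataset)
        if schedule is None:
            raise ValueError("an event schedule is required")
        self.schedule = schedule
        self.config = config or AnalysisConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schedule, config=None) -> "EvokedSeriesModel":
        """Build from a long-format spike table (channel_id, spike_time_s)."""
        trains = {
            int(ch): np.sort(np.asarray(g["spike_time_s"], dtype=float))
            for ch, g in df.groupby("channel_id")
        }
        return cls(trains, schedule=schedule, config=config)

    _COLUMNS = [
        "channel_id", "block", "condition", "detected", "onset_ms", "offset_ms",
        "peak_ms", "duration_ms", "threshold", "magnitude", "normalized_pct",
    ]

    def fit(self) -> "EvokedSeriesResults":
        cfg = self.config
        if not self.spike_trains:
            return EvokedSeriesResults(
                self, pd.DataFrame(columns=self._COLUMNS), {}
            )
        psths = block_psths(
            self.spike_trains, self.schedule, cfg.window_ms, cfg.bin_width_ms
        )
        baseline_blocks = self.schedule.pre_bicuculline_blocks
        rows = []
        for channel, series in psths.items():
            mags = np.zeros(len(series))
            for b, psth in enumerate(series):
                stats = baseline_threshold(
                    psth, cfg.evoked_sd_multiplier, cfg.baseline_window_ms
                )
                resp = detect_response(psth, stats, cfg.response_window_ms)
                mag = response_magnitude(psth, resp) if resp is not None else 0.0
                mags[b] = mag
                rows.append(
                    {
                        "channel_id": channel,
                        "block": b,
                        "condition": self.schedule.block_labels[b],
                        "detected": resp is not None,
                        "onset_ms": resp.onset_ms if resp else np.nan,
                        "offset_ms": resp.offset_ms if resp else np.nan,
                        "peak_ms": resp.peak_latency_ms if resp else np.nan,
                        "duration_ms": resp.duration_ms if resp else np.nan,
                        "threshold": stats.threshold,
                        "magnitude": mag,
                    }
                )
            try:
                norm = normalize_series(mags, baseline_blocks, cfg.normalization)
                norm_values = norm.values
            except NormalizationError:
                norm_values = np.full(len(series), np.nan)
            for b in range(len(series)):
                rows[-len(series) + b]["normalized_pct"] = norm_values[b]
        table = pd.DataFrame(rows, columns=self._COLUMNS)
        return EvokedSeriesResults(self, table, psths)


class EvokedSeriesResults:
    """Fitted per-block evoked responses and normalized series."""

    def __init__(self, model: EvokedSeriesModel, table: pd.DataFrame, psths):
        self.model = model
        self.table = table
        self.psths = psths

    @property
    def baseline_blocks(self) -> list[int]:
        return self.model.schedule.pre_bicuculline_blocks

    def magnitudes(self) -> pd.DataFrame:
        """Channel x block matrix of response magnitudes."""
        return self.table.pivot(index="channel_id", columns="block", values="magnitude")

    def normalized(self) -> pd.DataFrame:
        """Channel x block matrix of normalized magnitudes (percent)."""
        return self.table.pivot(
            index="channel_id", columns="block", values="normalized_pct"
        )

    def summary(self) -> str:
        t = self.table
        det = t["detected"].mean() * 100
        lines = [
            "Evoked-response series",
            "======================",
            f"channels: {t['channel_id'].nunique()}   blocks: {t['block'].nunique()}"
            f"   detected responses: {det:.1f}% of block PSTHs",
            f"normalization baseline blocks: {self.baseline_blocks}",
            "",
            "Per-condition mean normalized magnitude "
            f"({self.model.config.normalization}):",
        ]
        by = (
            t.groupby("condition", sort=False)["normalized_pct"]
            .agg(["mean", "sem", "count"])
            .rename(columns={"count": "n"})
        )
        lines.append(by.to_string(float_format=lambda v: f"{v:9.2f}"))
        return "\n".join(lines)

    def plot_timecourse(self, ax=None):
        """Mean +/- SEM normalized magnitude per block across channels."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = self.table.groupby("block")["normalized_pct"]
        mean, sem = g.mean(), g.sem().fillna(0.0)
        ax.errorbar(mean.index, mean.values, yerr=sem.values, fmt="o-", capsize=2)
        ref = 100.0 if self.model.config.normalization == "percent_of_baseline" else 0.0
        ax.axhline(ref, color="grey", lw=0.8, ls="--")
        pairing = self.model.schedule.blocks_with("pairing")
        if pairing:
            ax.axvspan(pairing[0] - 0.5, pairing[-1] + 0.5, alpha=0.15, color="tab:blue")
        ax.set_xlabel("block")
        ax.set_ylabel(f"response magnitude ({self.model.config.normalization})")
        return ax
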