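"""Recovery and calibration experiments on synthetic data.

These runners reproduce, on simulated recordings, the quantitative checks
the analysis is expected to satisfy under the study conditions: jitter
bounds of the stimulation train, false-positive and recovery behaviour of
the potentiation classifier, flatness of null normalized series, the
duration/latency dissociation under potentiation of existing response
components, and the calibration and power of the randomization F test.

All runners accept a master ``seed``; per-replicate seeds are spawned from
it so runs are reproducible end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps

from .config import AnalysisConfig
from .evoked import EvokedSeriesModel
from .potentiation import PotentiationModel
from .protocol import experiment1_protocol, experiment3_protocol, generate_stim_times
from .simulate import (
    ChannelModel,
    ResponseComponent,
    default_channel_models,
    simulate_experiment,
)
from .stats import randomization_f_test

__all__ = [
    "isi_bounds",
    "null_calibration",
    "recovery",
    "duration_latency_dissociation",
    "f_test_calibration",
    "f_test_power",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def isi_bounds(n_isis: int = 10_000, rate_hz: float = 0.5, jitter: float = 0.3,
               seed: int = 0) -> tuple[float, float]:
    """(min, max) of generated inter-stimulus intervals in seconds."""
    from .protocol import StimProtocol

    p = StimProtocol(rate_hz, jitter, block_size=n_isis, n_blocks=1,
                     flash_delay_s=None)
    sched = generate_stim_times(p, seed)
    isis = np.diff(np.concatenate(([0.0], sched.stim_times)))
    return float(isis.min()), float(isis.max())


@dataclass
class NullCalibration:
    flagged: int
    total: int
    slopes: list[float]
    slope_cis: list[tuple[float, float]]

    @property
    def flagged_fraction(self) -> float:
        return self.flagged / self.total

    @property
    def ci_zero_coverage(self) -> float:
        return float(np.mean([lo <= 0.0 <= hi for lo, hi in self.slope_cis]))


def null_calibration(
    n_seeds: int = 20,
    seed: int = 0,
    n_channels: int = 16,
    n_responsive: int = 6,
    config: Optional[AnalysisConfig] = None,
) -> NullCalibration:
    """Null simulations (responsive channels, no potentiation).

    Runs both pipelines on each simulated array: the potentiation
    classifier (counting flagged channels) and the block-response series
    (per-seed regression of the channel-mean normalized series on block,
    with its 95% CI).
    """
    proto = experiment3_protocol()
    flagged = total = 0
    slopes: list[float] = []
    cis: list[tuple[float, float]] = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        models = default_channel_models(
            n_channels, n_responsive, 0, pairing_onset_block=None, rng=rng
        )
        ds, _ = simulate_experiment(proto, models, seed=s)
        pot = PotentiationModel(ds, config=config).fit()
        flagged += pot.n_potentiated
        total += n_channels
        ev = EvokedSeriesModel(ds, config=config).fit()
        series = ev.normalized().mean(axis=0)  # channel-mean per block
        x = np.asarray(series.index, dtype=float)
        lr = sps.linregress(x, series.to_numpy())
        half = 1.96 * lr.stderr
        slopes.append(float(lr.slope))
        cis.append((float(lr.slope - half), float(lr.slope + half)))
    return NullCalibration(flagged, total, slopes, cis)


@dataclass
class RecoveryResult:
    gain: float
    n_true: int
    n_detected: int
    latency_errors_ms: list[float]
    #: mean total potentiation magnitude over truly potentiating channels,
    #: counting missed channels as 0
    mean_total_magnitude: float
    false_positive_fraction: float

    @property
    def sensitivity(self) -> float:
        return self.n_detected / self.n_true

    @property
    def mean_abs_latency_error_ms(self) -> float:
        return float(np.mean(self.latency_errors_ms)) if self.latency_errors_ms else float("nan")


def recovery(
    gain: float = 2.0,
    n_seeds: int = 20,
    seed: int = 0,
    n_channels: int = 16,
    n_responsive: int = 6,
    n_potentiating: int = 4,
    config: Optional[AnalysisConfig] = None,
) -> RecoveryResult:
    """Ground-truth recovery of potentiating channels at a given gain.

    Potentiation applies to the short-latency (monosynaptic) component and
    begins at the gated reinforcement epoch with per-channel onset jitter.
    """
    proto = experiment3_protocol()
    onset = proto.labels.index("pairing")
    n_true = n_det = n_fp = n_null = 0
    lat_err: list[float] = []
    totals: list[float] = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        models = default_channel_models(
            n_channels, n_responsive, n_potentiating,
            pairing_onset_block=onset, potentiation_gain=gain, rng=rng,
        )
        ds, truth = simulate_experiment(proto, models, seed=s)
        res = PotentiationModel(ds, config=config).fit()
        calls = {c.channel_id: c for c in res.calls_list}
        for ch, is_pot in truth.potentiated.items():
            call = calls[ch]
            if is_pot:
                n_true += 1
                if call.potentiated:
                    n_det += 1
                    true_lat = min(truth.latencies_ms[ch])
                    lat_err.append(abs(call.latency_ms - true_lat))
                    totals.append(call.total_magnitude)
                else:
                    totals.append(0.0)
            else:
                n_null += 1
                n_fp += call.potentiated
    return RecoveryResult(
        gain=gain,
        n_true=n_true,
        n_detected=n_det,
        latency_errors_ms=lat_err,
        mean_total_magnitude=float(np.mean(totals)),
        false_positive_fraction=n_fp / n_null if n_null else float("nan"),
    )


@dataclass
class DissociationResult:
    duration_diffs_ms: list[float]
    onset_diffs_ms: list[float]

    @property
    def mean_duration_increase_ms(self) -> float:
        return float(np.mean(self.duration_diffs_ms))

    @property
    def mean_onset_shift_ms(self) -> float:
        return float(np.mean(self.onset_diffs_ms))


def duration_latency_dissociation(
    n_seeds: int = 20, seed: int = 0, gain: float = 2.0
) -> DissociationResult:
    """Paired gain-vs-no-gain comparison of evoked duration and onset.

    Both existing components (mono- and multisynaptic) potentiate. Onset
    is compared over monosynaptic-peak responses only (peak < 12 ms), the
    latency class the onset claim concerns.
    """
    proto = experiment1_protocol()
    onset_blk = proto.labels.index("pairing")
    comps = (
        ResponseComponent(7.5, 0.6, 0.4, potentiable=True, decay_tail_ms=2.5),
        ResponseComponent(18.5, 1.5, 0.25, potentiable=True, decay_tail_ms=4.0),
    )
    post_blocks = [b for b, lab in enumerate(proto.labels) if lab == "post"][2:]
    dur: list[float] = []
    ons: list[float] = []
    for s in _child_seeds(seed, n_seeds):
        base = ChannelModel(30.0, comps)
        pot = ChannelModel(
            30.0, comps, potentiation_onset_block=onset_blk, potentiation_gain=gain
        )
        d0, _ = simulate_experiment(proto, [base], seed=s)
        d1, _ = simulate_experiment(proto, [pot], seed=s)
        t0 = EvokedSeriesModel(d0).fit().table
        t1 = EvokedSeriesModel(d1).fit().table
        m0 = t0[t0.block.isin(post_blocks) & t0.detected]
        m1 = t1[t1.block.isin(post_blocks) & t1.detected]
        dur.append(m1.duration_ms.mean() - m0.duration_ms.mean())
        mono0 = m0[m0.peak_ms < 12.0]
        mono1 = m1[m1.peak_ms < 12.0]
        ons.append(mono1.onset_ms.mean() - mono0.onset_ms.mean())
    return DissociationResult(dur, ons)


def _baseline_periods_dataset(seed: int, drug_scale: float, n_channels: int = 8):
    """Blocks 1-12 (pre-drug + post-drug baseline) of a third-series array."""
    proto = experiment3_protocol(n_pairing=1, n_post=0)
    rng = np.random.default_rng(seed)
    models = default_channel_models(
        n_channels, n_channels, 0, pairing_onset_block=None,
        drug_scale=drug_scale, rng=rng,
    )
    ds, _ = simulate_experiment(proto, models, seed=seed)
    return ds


def f_test_calibration(
    n_reps: int = 200,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    n_channels: int = 8,
) -> float:
    """Type-I error rate of the randomization F test under the null."""
    rejections = 0
    seeds = _child_seeds(seed, 2 * n_reps)
    for i in range(n_reps):
        ds = _baseline_periods_dataset(seeds[2 * i], drug_scale=1.0,
                                       n_channels=n_channels)
        comparison = PotentiationModel(ds).fit().period_comparison()
        res = randomization_f_test(comparison, n_permutations, seed=seeds[2 * i + 1])
        rejections += res.p <= alpha
    return rejections / n_reps


def f_test_power(
    drug_scale: float = 0.5,
    n_reps: int = 50,
    n_permutations: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    n_channels: int = 8,
) -> float:
    """Rejection rate under a multiplicative drug suppression of the response."""
    rejections = 0
    seeds = _child_seeds(seed, 2 * n_reps)
    for i in range(n_reps):
        ds = _baseline_periods_dataset(seeds[2 * i], drug_scale=drug_scale,
                                       n_channels=n_channels)
        comparison = PotentiationModel(ds).fit().period_comparison()
        res = randomization_f_test(comparison, n_permutations, seed=seeds[2 * i + 1])
        rejections += res.p <= alpha
    return rejections / n_reps
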