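"""Generative model of the stimulation/reinforcement recordings.

Each channel is a multi-unit site: a homogeneous Poisson background (near
30 Hz, the spontaneous multi-unit rate measured in the lidocaine controls)
superposed with stimulus-locked evoked components. A component emits, per
stimulation, a Poisson-distributed number of spikes (mean = its
spikes-per-stimulus probability times any active gain) at a Gaussian-
jittered latency. Short-latency (<12 ms) components stand for monosynaptic
cortical drive, longer-latency (>12 ms) ones for multisynaptic routes.

Potentiation multiplies the potentiable components by a gain from a
per-channel onset block onward, ramping linearly over a configurable number
of blocks (the paper-style timecourses grow gradually); it can also switch
on a brand-new component at a previously silent latency. A systemic drug
scales every component from the drug epoch onward.

Because this is multi-unit activity, background and evoked processes are
superposed independently with no refractory interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .protocol import EventSchedule, StimProtocol, generate_stim_times

__all__ = [
    "ResponseComponent",
    "ChannelModel",
    "GroundTruth",
    "Dataset",
    "simulate_channel",
    "simulate_experiment",
    "simulate_raw_trace",
    "default_channel_models",
    "SPIKE_TEMPLATE",
]

#: Post-stimulus detection window (ms) that evoked components must fall in.
RESPONSE_WINDOW_MS = (0.0, 50.0)


@dataclass(frozen=True)
class ResponseComponent:
    """One latency-locked evoked component of a channel's response.

    ``probability`` is the expected number of emitted spikes per
    stimulation (Poisson mean, may exceed 1); ``latency_jitter_ms`` is the
    SD of the Gaussian spread of each spike around ``latency_ms``, and
    ``decay_tail_ms`` adds an exponential right tail (mean of the added
    exponential delay). The resulting ex-Gaussian latency distribution has
    the sharp rise and slow decay of cortically-evoked multi-unit volleys:
    onset is set by the tight monosynaptic volley while the falling phase
    reflects progressively recruited polysynaptic activity, which is why a
    stronger response lengthens without starting earlier. Jittered
    latencies are truncated at 0 so no evoked spike precedes its
    stimulation.
    """

    latency_ms: float
    latency_jitter_ms: float = 1.0
    probability: float = 0.3
    potentiable: bool = False
    decay_tail_ms: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = RESPONSE_WINDOW_MS
        if not (lo <= self.latency_ms < hi):
            raise ValueError(
                f"component latency {self.latency_ms} ms outside [{lo}, {hi}) ms"
            )
        if self.probability < 0:
            raise ValueError("component probability must be >= 0")
        if self.latency_jitter_ms < 0:
            raise ValueError("latency jitter must be >= 0")
        if self.decay_tail_ms < 0:
            raise ValueError("decay tail must be >= 0")


@dataclass(frozen=True)
class ChannelModel:
    """Generative parameters of one recording channel."""

    baseline_rate_hz: float = 30.0
    components: tuple[ResponseComponent, ...] = ()
    potentiation_onset_block: Optional[int] = None
    potentiation_gain: float = 1.0
    ramp_blocks: int = 4
    new_component_on_potentiation: Optional[ResponseComponent] = None
    drug_scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if self.baseline_rate_hz < 0:
            raise ValueError("baseline_rate_hz must be >= 0")
        if self.potentiation_onset_block is not None and self.potentiation_gain < 1:
            raise ValueError("potentiation_gain must be >= 1 when an onset block is set")
        if self.drug_scale < 0:
            raise ValueError("drug_scale must be >= 0")
        if self.ramp_blocks < 1:
            raise ValueError("ramp_blocks must be >= 1")

    @property
    def potentiates(self) -> bool:
        return self.potentiation_onset_block is not None and (
            self.potentiation_gain > 1 or self.new_component_on_potentiation is not None
        )

    def potentiated_latencies_ms(self) -> tuple[float, ...]:
        """Latencies at which this channel's response is potentiated."""
        if not self.potentiates:
            return ()
        lats = [c.latency_ms for c in self.components if c.potentiable]
        if self.new_component_on_potentiation is not None:
            lats.append(self.new_component_on_potentiation.latency_ms)
        return tuple(sorted(lats))

    def potentiation_fraction(self, block: np.ndarray) -> np.ndarray:
        """Ramp fraction in [0, 1] of full potentiation, per block index."""
        if self.potentiation_onset_block is None:
            return np.zeros(np.shape(block))
        k = np.asarray(block) - self.potentiation_onset_block + 1
        return np.clip(k / self.ramp_blocks, 0.0, 1.0)


@dataclass
class GroundTruth:
    """Per-channel generative labels for recovery testing."""

    potentiated: dict[int, bool]
    latencies_ms: dict[int, tuple[float, ...]]
    onset_block: dict[int, Optional[int]]

    @property
    def potentiated_channels(self) -> list[int]:
        return sorted(ch for ch, flag in self.potentiated.items() if flag)


@dataclass
class Dataset:
    """Simulated (or loaded) multichannel recording plus its schedule."""

    spike_trains: dict[int, np.ndarray]
    schedule: EventSchedule

    @property
    def channels(self) -> list[int]:
        return sorted(self.spike_trains)


def _component_gains(
    model: ChannelModel,
    component: ResponseComponent,
    schedule: EventSchedule,
) -> np.ndarray:
    """Per-stimulation multiplicative gain for one component."""
    gains = np.ones(schedule.n_stims)
    drug_onset = schedule.drug_onset_block
    if drug_onset is not None and model.drug_scale != 1.0:
        gains[schedule.block_index >= drug_onset] *= model.drug_scale
    if component.potentiable and model.potentiation_onset_block is not None:
        frac = model.potentiation_fraction(schedule.block_index)
        gains *= 1.0 + (model.potentiation_gain - 1.0) * frac
    return gains


def simulate_channel(
    model: ChannelModel, schedule: EventSchedule, seed: int | np.random.Generator
) -> np.ndarray:
    """One channel's sorted spike-time array (seconds) for a schedule.

    Background spikes are a homogeneous Poisson process at
    ``baseline_rate_hz`` over the recording; each stimulation adds, per
    component, ``Poisson(probability * gain)`` spikes at the component's
    jittered latency. A newly-recruited component (if configured) emits
    nothing before the potentiation onset block and ramps in like the
    potentiation gain.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if schedule.n_stims == 0:
        raise ValueError("schedule is empty")
    pieces: list[np.ndarray] = []

    n_bg = rng.poisson(model.baseline_rate_hz * schedule.duration_s)
    if n_bg:
        pieces.append(rng.uniform(0.0, schedule.duration_s, n_bg))

    components = list(model.components)
    ramp_in: list[bool] = [False] * len(components)
    if model.new_component_on_potentiation is not None:
        components.append(model.new_component_on_potentiation)
        ramp_in.append(True)

    for component, is_new in zip(components, ramp_in):
        gains = _component_gains(model, component, schedule)
        mean = component.probability * gains
        if is_new:
            # a recruited component is silent pre-onset and ramps in
            mean = component.probability * model.potentiation_fraction(
                schedule.block_index
            )
            drug_onset = schedule.drug_onset_block
            if drug_onset is not None and model.drug_scale != 1.0:
                mean = mean.copy()
                mean[schedule.block_index >= drug_onset] *= model.drug_scale
        counts = rng.poisson(mean)
        total = int(counts.sum())
        if total == 0:
            continue
        stim_of_spike = np.repeat(schedule.stim_times, counts)
        lat = np.full(total, component.latency_ms)
        if component.latency_jitter_ms > 0:
            lat = lat + rng.normal(0.0, component.latency_jitter_ms, total)
        if component.decay_tail_ms > 0:
            lat = lat + rng.exponential(component.decay_tail_ms, total)
        lat = np.maximum(lat, 0.0)  # truncate: no evoked spike before its stimulus
        pieces.append(stim_of_spike + lat / 1000.0)

    if not pieces:
        return np.empty(0)
    spikes = np.concatenate(pieces)
    spikes = spikes[(spikes >= 0) & (spikes <= schedule.duration_s)]
    spikes.sort()
    return spikes


def simulate_experiment(
    protocol: StimProtocol,
    channel_models: Sequence[ChannelModel],
    seed: int,
) -> tuple[Dataset, GroundTruth]:
    """Simulate a full multichannel experiment.

    Channels are driven by the same stimulation schedule but independent
    spike-generation streams (spawned sub-seeds), so identical seeds
    reproduce identical datasets and distinct seeds decorrelate the
    background activity.
    """
    if not channel_models:
        raise ValueError("need at least one channel model")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(channel_models) + 1)
    schedule = generate_stim_times(protocol, np.random.default_rng(child[0]))
    trains: dict[int, np.ndarray] = {}
    for ch, (model, sub) in enumerate(zip(channel_models, child[1:])):
        trains[ch] = simulate_channel(model, schedule, np.random.default_rng(sub))
    truth = GroundTruth(
        potentiated={ch: m.potentiates for ch, m in enumerate(channel_models)},
        latencies_ms={ch: m.potentiated_latencies_ms() for ch, m in enumerate(channel_models)},
        onset_block={ch: m.potentiation_onset_block if m.potentiates else None
                     for ch, m in enumerate(channel_models)},
    )
    return Dataset(spike_trains=trains, schedule=schedule), truth


#: Biphasic extracellular spike template (dominant negative deflection),
#: unit peak amplitude, one value per sample at the trace sampling rate.
SPIKE_TEMPLATE = np.array([-1.0, -0.55, -0.15, 0.3, 0.25, 0.12, 0.04])


def simulate_raw_trace(
    spike_times_s: np.ndarray,
    waveform_amplitude: float,
    noise_sd: float,
    sampling_rate_hz: float,
    seed: int | np.random.Generator,
    duration_s: Optional[float] = None,
) -> np.ndarray:
    """Sampled voltage trace: Gaussian noise plus a spike template per spike.

    The template's dominant negative deflection starts at the spike sample,
    so threshold crossings recover spike times to within one sample. Used
    to exercise the extraction module; no waveform-shape realism beyond the
    single template is attempted.
    """
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spikes = np.asarray(spike_times_s, dtype=float)
    if duration_s is None:
        duration_s = float(spikes[-1]) + 0.01 if spikes.size else 0.1
    n = int(np.ceil(duration_s * sampling_rate_hz)) + SPIKE_TEMPLATE.size
    trace = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    tpl = waveform_amplitude * SPIKE_TEMPLATE
    idx = np.round(spikes * sampling_rate_hz).astype(int)
    for i in idx:
        if 0 <= i:
            trace[i : i + tpl.size] += tpl[: max(0, min(tpl.size, n - i))]
    return trace


def default_channel_models(
    n_channels: int = 16,
    n_responsive: int = 6,
    n_potentiating: int = 4,
    *,
    baseline_rate_hz: float = 30.0,
    potentiation_gain: float = 2.0,
    pairing_onset_block: Optional[int] = None,
    onset_jitter_blocks: int = 2,
    ramp_blocks: int = 4,
    drug_scale: float = 1.0,
    new_component_latency_ms: Optional[float] = None,
    mono_potentiable: bool = True,
    multi_potentiable: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> list[ChannelModel]:
    """Build a 16-channel array model with a responsive subset.

    A contiguous run of ``n_responsive`` channels responds to cortical
    stimulation (responsive sites cluster on adjacent array channels), each
    with a monosynaptic component at 7.5 ms and a multisynaptic component
    at 18.5 ms. The first ``n_potentiating`` responsive channels potentiate
    from ``pairing_onset_block`` (plus a per-channel onset jitter of 0 to
    ``onset_jitter_blocks`` blocks) onward.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if n_responsive > n_channels or n_potentiating > n_responsive:
        raise ValueError("need n_potentiating <= n_responsive <= n_channels")
    start = int(rng.integers(0, n_channels - n_responsive + 1))
    responsive = list(range(start, start + n_responsive))
    potentiating = set(responsive[:n_potentiating])

    models: list[ChannelModel] = []
    for ch in range(n_channels):
        if ch not in responsive:
            models.append(ChannelModel(baseline_rate_hz=baseline_rate_hz,
                                       drug_scale=drug_scale))
            continue
        comps = (
            ResponseComponent(7.5, 0.6, 0.4, potentiable=mono_potentiable,
                              decay_tail_ms=2.5),
            ResponseComponent(18.5, 1.5, 0.25, potentiable=multi_potentiable,
                              decay_tail_ms=4.0),
        )
        if ch in potentiating and pairing_onset_block is not None:
            onset = pairing_onset_block + int(rng.integers(0, onset_jitter_blocks + 1))
            new_comp = None
            if new_component_latency_ms is not None:
                new_comp = ResponseComponent(
                    new_component_latency_ms, 0.6, 0.3, potentiable=True
                )
            models.append(
                ChannelModel(
                    baseline_rate_hz=baseline_rate_hz,
                    components=comps,
                    potentiation_onset_block=onset,
                    potentiation_gain=potentiation_gain,
                    ramp_blocks=ramp_blocks,
                    new_component_on_potentiation=new_comp,
                    drug_scale=drug_scale,
                )
            )
        else:
            models.append(
                ChannelModel(
                    baseline_rate_hz=baseline_rate_hz,
                    components=comps,
                    drug_scale=drug_scale,
                )
            )
    return models
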