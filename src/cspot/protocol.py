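"""Stimulation protocols and event schedules.

The experiments modelled here deliver single-pulse motor-cortex stimulation
at a jittered nominal rate (0.5, 0.33 or 0.2 Hz), grouped into blocks of 120
stimulations. In designated condition epochs each stimulation is paired with
a brief whole-field light flash at a fixed delay (typically +250 ms), and a
disinhibitory bicuculline injection into the superior colliculus gates the
sensory signal into the striatum for a limited number of blocks.

Condition structure is carried per block as a label string:

``baseline``
    pre-manipulation blocks (first-series experiments).
``light``
    flash paired with each stimulation, colliculus still inhibited.
``pre``
    pre-drug baseline blocks (third-series experiments).
``drug`` / ``drug_light``
    post-systemic-drug baseline blocks, without / with the flash.
``pairing``
    flash paired with stimulation during collicular disinhibition
    (the gated reinforcement epoch).
``post``
    recording continues after the disinhibition has worn off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "ProtocolError",
    "StimProtocol",
    "EventSchedule",
    "Epoch",
    "generate_stim_times",
    "experiment1_protocol",
    "experiment2_protocol",
    "experiment3_protocol",
    "FLASH_LABELS",
    "DRUG_LABELS",
    "POST_BICUCULLINE_LABELS",
]


class ProtocolError(ValueError):
    """Raised for invalid stimulation-protocol parameters."""


#: Block labels in which each stimulation is paired with a light flash.
FLASH_LABELS = frozenset({"light", "drug_light", "pairing"})
#: Block labels recorded after the systemic drug (or vehicle) injection.
DRUG_LABELS = frozenset({"drug", "drug_light"})
#: Block labels recorded after the collicular bicuculline injection.
POST_BICUCULLINE_LABELS = frozenset({"pairing", "post"})


@dataclass(frozen=True)
class StimProtocol:
    """Parameters of a jittered single-pulse stimulation train.

    Parameters
    ----------
    nominal_rate_hz
        Average stimulation rate. Inter-stimulus intervals are drawn
        uniformly from ``[T*(1-j), T*(1+j)]`` with ``T = 1/rate`` and ``j``
        the jitter fraction, so at 0.5 Hz with 30% jitter every interval
        lies in [1.4 s, 2.6 s].
    jitter_fraction
        Fractional half-width of the interval distribution, in [0, 1).
    block_size
        Stimulations per block (120 in all multi-unit experiments).
    n_blocks
        Number of blocks; total stimulation count is
        ``block_size * n_blocks``.
    flash_delay_s
        Delay of the reinforcing flash relative to each stimulation, in
        seconds. May be negative (flash before the pulse) or ``None``
        (no flash configured).
    flash_duration_s
        Flash duration in seconds (10 ms by default).
    block_labels
        One condition label per block (see module docstring). Defaults to
        ``"baseline"`` for every block.
    """

    nominal_rate_hz: float
    jitter_fraction: float = 0.3
    block_size: int = 120
    n_blocks: int = 1
    flash_delay_s: Optional[float] = 0.25
    flash_duration_s: float = 0.010
    block_labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if not self.nominal_rate_hz > 0:
            raise ProtocolError(f"nominal_rate_hz must be > 0, got {self.nominal_rate_hz}")
        if not (0 <= self.jitter_fraction < 1):
            raise ProtocolError(
                f"jitter_fraction must lie in [0, 1), got {self.jitter_fraction}"
            )
        if self.block_size <= 0 or self.n_blocks <= 0:
            raise ProtocolError("block_size and n_blocks must be positive")
        if self.block_labels is not None:
            object.__setattr__(self, "block_labels", tuple(self.block_labels))
            if len(self.block_labels) != self.n_blocks:
                raise ProtocolError(
                    f"{len(self.block_labels)} block labels for {self.n_blocks} blocks"
                )

    @property
    def mean_isi_s(self) -> float:
        return 1.0 / self.nominal_rate_hz

    @property
    def n_stims(self) -> int:
        return self.block_size * self.n_blocks

    @property
    def labels(self) -> tuple[str, ...]:
        if self.block_labels is None:
            return ("baseline",) * self.n_blocks
        return self.block_labels


@dataclass(frozen=True)
class Epoch:
    """A contiguous condition epoch, for schedule serialization."""

    label: str
    start_s: float
    end_s: float
    first_block: int
    last_block: int
    light_paired: bool
    colliculus_gated: bool


@dataclass
class EventSchedule:
    """Realised stimulation/flash times plus block and condition structure.

    ``flash_times`` is aligned with ``stim_times``; entries are NaN for
    stimulations that were not paired with a flash.
    """

    stim_times: np.ndarray
    block_index: np.ndarray
    block_labels: tuple[str, ...]
    block_size: int
    duration_s: float
    flash_times: Optional[np.ndarray] = None
    flash_delay_s: Optional[float] = None
    flash_duration_s: float = 0.010

    def __post_init__(self) -> None:
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        self.block_index = np.asarray(self.block_index, dtype=int)
        self.block_labels = tuple(self.block_labels)
        if self.stim_times.shape != self.block_index.shape:
            raise ProtocolError("stim_times and block_index must be aligned")

    # -- basic geometry -------------------------------------------------
    @property
    def n_stims(self) -> int:
        return self.stim_times.size

    @property
    def n_blocks(self) -> int:
        return len(self.block_labels)

    def stims_in_block(self, block: int) -> np.ndarray:
        return self.stim_times[self.block_index == block]

    # -- condition bookkeeping ------------------------------------------
    def blocks_with(self, labels) -> list[int]:
        wanted = {labels} if isinstance(labels, str) else set(labels)
        return [b for b, lab in enumerate(self.block_labels) if lab in wanted]

    @property
    def pre_drug_blocks(self) -> list[int]:
        """Blocks of the pre-drug baseline period (third-series label 'pre')."""
        return self.blocks_with("pre")

    @property
    def profile_blocks(self) -> list[int]:
        """The 8 post-drug blocks used for the average baseline response."""
        return self.blocks_with(DRUG_LABELS)

    @property
    def post_bicuculline_blocks(self) -> list[int]:
        return self.blocks_with(POST_BICUCULLINE_LABELS)

    @property
    def pre_bicuculline_blocks(self) -> list[int]:
        post = POST_BICUCULLINE_LABELS
        return [b for b, lab in enumerate(self.block_labels) if lab not in post]

    @property
    def pairing_onset_block(self) -> Optional[int]:
        pairing = self.blocks_with("pairing")
        return pairing[0] if pairing else None

    @property
    def drug_onset_block(self) -> Optional[int]:
        drug = self.blocks_with(DRUG_LABELS)
        return drug[0] if drug else None

    def epochs(self) -> list[Epoch]:
        """Contiguous condition epochs with their time extents."""
        out: list[Epoch] = []
        b = 0
        while b < self.n_blocks:
            lab = self.block_labels[b]
            first = b
            while b + 1 < self.n_blocks and self.block_labels[b + 1] == lab:
                b += 1
            stims_first = self.stims_in_block(first)
            stims_last = self.stims_in_block(b)
            end = self.duration_s if b == self.n_blocks - 1 else float(
                self.stims_in_block(b + 1)[0]
            )
            out.append(
                Epoch(
                    label=lab,
                    start_s=float(stims_first[0]),
                    end_s=end,
                    first_block=first,
                    last_block=b,
                    light_paired=lab in FLASH_LABELS,
                    colliculus_gated=lab == "pairing",
                )
            )
            b += 1
        return out


def generate_stim_times(
    protocol: StimProtocol, seed: int | np.random.Generator
) -> EventSchedule:
    """Draw a jittered stimulation train for ``protocol``.

    Consecutive inter-stimulus intervals are independent uniform draws on
    ``[T*(1-j), T*(1+j)]``; the first stimulation falls one such interval
    after the recording start, leaving headroom for the 500 ms pre-stimulus
    baseline window. Flash times are ``stim + flash_delay`` in blocks whose
    label pairs the flash (see :data:`FLASH_LABELS`).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = protocol.n_stims
    t = protocol.mean_isi_s
    j = protocol.jitter_fraction
    isis = rng.uniform(t * (1 - j), t * (1 + j), size=n)
    stim_times = np.cumsum(isis)
    block_index = np.arange(n) // protocol.block_size
    labels = protocol.labels
    duration = float(stim_times[-1] + t * (1 + j))

    flash_times = None
    if protocol.flash_delay_s is not None:
        flash_blocks = {b for b, lab in enumerate(labels) if lab in FLASH_LABELS}
        flash_times = np.full(n, np.nan)
        if flash_blocks:
            mask = np.isin(block_index, sorted(flash_blocks))
            flash_times[mask] = stim_times[mask] + protocol.flash_delay_s

    return EventSchedule(
        stim_times=stim_times,
        block_index=block_index,
        block_labels=labels,
        block_size=protocol.block_size,
        duration_s=duration,
        flash_times=flash_times,
        flash_delay_s=protocol.flash_delay_s,
        flash_duration_s=protocol.flash_duration_s,
    )


def experiment1_protocol(
    n_baseline: int = 6,
    n_light: int = 6,
    n_pairing: int = 3,
    n_post: int = 9,
    flash_delay_s: float = 0.25,
    block_size: int = 120,
) -> StimProtocol:
    """First-series protocol: 0.5 Hz stimulation, flash at +250 ms.

    Six baseline blocks, six flash-paired blocks without collicular gating,
    then the bicuculline pairing epoch (disinhibition lasts 10-20 min, i.e.
    roughly 3 blocks at 0.5 Hz) and continued post-pairing recording.
    """
    labels = (
        ("baseline",) * n_baseline
        + ("light",) * n_light
        + ("pairing",) * n_pairing
        + ("post",) * n_post
    )
    return StimProtocol(
        nominal_rate_hz=0.5,
        jitter_fraction=0.3,
        block_size=block_size,
        n_blocks=len(labels),
        flash_delay_s=flash_delay_s,
        block_labels=labels,
    )


def experiment2_protocol(
    flash_delay_s: float = 0.25,
    n_baseline: int = 3,
    n_light: int = 3,
    n_pairing: int = 2,
    n_post: int = 8,
    block_size: int = 120,
) -> StimProtocol:
    """Second-series protocol: 0.2 Hz stimulation, variable flash delay."""
    labels = (
        ("baseline",) * n_baseline
        + ("light",) * n_light
        + ("pairing",) * n_pairing
        + ("post",) * n_post
    )
    return StimProtocol(
        nominal_rate_hz=0.2,
        jitter_fraction=0.3,
        block_size=block_size,
        n_blocks=len(labels),
        flash_delay_s=flash_delay_s,
        block_labels=labels,
    )


def experiment3_protocol(
    n_pre: int = 4,
    n_drug: int = 4,
    n_drug_light: int = 4,
    n_pairing: int = 3,
    n_post: int = 9,
    flash_delay_s: float = 0.25,
    block_size: int = 120,
) -> StimProtocol:
    """Third-series (16-channel array) protocol: 0.33 Hz stimulation.

    Four pre-drug blocks, four post-drug blocks, four post-drug blocks with
    the (ungated) flash — the latter eight form the average-baseline-response
    window — then the bicuculline pairing epoch and post-pairing recording.
    """
    labels = (
        ("pre",) * n_pre
        + ("drug",) * n_drug
        + ("drug_light",) * n_drug_light
        + ("pairing",) * n_pairing
        + ("post",) * n_post
    )
    return StimProtocol(
        nominal_rate_hz=1.0 / 3.0,
        jitter_fraction=0.3,
        block_size=block_size,
        n_blocks=len(labels),
        flash_delay_s=flash_delay_s,
        block_labels=labels,
    )
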