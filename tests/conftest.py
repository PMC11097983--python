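import numpy as np
import pytest

from cspot.protocol import EventSchedule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_schedule(
    n_stims=10,
    isi_s=2.0,
    block_size=5,
    block_labels=None,
    flash_delay_s=None,
):
    """Hand-built regular schedule for unit tests."""
    stim_times = isi_s * np.arange(1, n_stims + 1)
    block_index = np.arange(n_stims) // block_size
    n_blocks = int(block_index[-1]) + 1
    if block_labels is None:
        block_labels = ("baseline",) * n_blocks
    flash_times = None
    if flash_delay_s is not None:
        flash_times = stim_times + flash_delay_s
    return EventSchedule(
        stim_times=stim_times,
        block_index=block_index,
        block_labels=block_labels,
        block_size=block_size,
        duration_s=float(stim_times[-1] + isi_s),
        flash_times=flash_times,
        flash_delay_s=flash_delay_s,
    )


@pytest.fixture
def schedule_factory():
    return make_schedule
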