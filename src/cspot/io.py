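"""On-disk formats: tab-delimited tables and YAML schedules.

All tables are UTF-8 tab-delimited text with a mandatory header row and
``#``-prefixed comment lines; times on disk are seconds with six decimal
places, latencies in result tables are milliseconds.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .protocol import EventSchedule
from .simulate import Dataset, GroundTruth

__all__ = [
    "write_spike_table",
    "read_spike_table",
    "write_event_table",
    "read_event_table",
    "write_schedule",
    "read_schedule",
    "write_ground_truth",
    "read_ground_truth",
    "save_dataset",
    "load_dataset",
    "write_table",
    "read_table",
]

_TIME_FMT = "%.6f"


def write_table(path, df: pd.DataFrame, comment: Optional[str] = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_spike_table(path, spike_trains: Mapping[int, np.ndarray]) -> None:
    """Long-format spike table: channel_id, spike_time_s."""
    frames = [
        pd.DataFrame(
            {
                "channel_id": ch,
                "spike_time_s": [(_TIME_FMT % t) for t in np.asarray(times)],
            }
        )
        for ch, times in sorted(spike_trains.items())
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["channel_id", "spike_time_s"])
    )
    write_table(path, df)


def read_spike_table(path) -> dict[int, np.ndarray]:
    df = read_table(path)
    out: dict[int, np.ndarray] = {}
    for ch, g in df.groupby("channel_id"):
        out[int(ch)] = np.sort(np.asarray(g["spike_time_s"], dtype=float))
    return out


def write_event_table(path, schedule: EventSchedule) -> None:
    """Event table: event_time_s, event_kind in {stim, flash}, block_index."""
    rows = {
        "event_time_s": [(_TIME_FMT % t) for t in schedule.stim_times],
        "event_kind": ["stim"] * schedule.n_stims,
        "block_index": list(schedule.block_index),
    }
    df = pd.DataFrame(rows)
    if schedule.flash_times is not None:
        mask = ~np.isnan(schedule.flash_times)
        flashes = pd.DataFrame(
            {
                "event_time_s": [(_TIME_FMT % t) for t in schedule.flash_times[mask]],
                "event_kind": "flash",
                "block_index": schedule.block_index[mask],
            }
        )
        df = pd.concat([df, flashes], ignore_index=True)
        df = df.sort_values(
            "event_time_s", key=lambda s: s.astype(float), kind="stable"
        ).reset_index(drop=True)
    write_table(path, df)


def read_event_table(path) -> pd.DataFrame:
    return read_table(path)


def write_schedule(path, schedule: EventSchedule) -> None:
    """Condition epochs and block structure as a YAML mapping."""
    doc = {
        "block_size": int(schedule.block_size),
        "n_blocks": int(schedule.n_blocks),
        "block_labels": list(schedule.block_labels),
        "duration_s": float(schedule.duration_s),
        "flash_delay_s": None
        if schedule.flash_delay_s is None
        else float(schedule.flash_delay_s),
        "flash_duration_s": float(schedule.flash_duration_s),
        "epochs": [
            {
                "label": e.label,
                "start_s": round(e.start_s, 6),
                "end_s": round(e.end_s, 6),
                "first_block": e.first_block,
                "last_block": e.last_block,
                "light_paired": e.light_paired,
                "colliculus_gated": e.colliculus_gated,
            }
            for e in schedule.epochs()
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_schedule(path, event_table: pd.DataFrame) -> EventSchedule:
    """Rebuild an EventSchedule from its YAML sidecar plus the event table."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    stims = event_table[event_table["event_kind"] == "stim"].sort_values("event_time_s")
    stim_times = np.asarray(stims["event_time_s"], dtype=float)
    block_index = np.asarray(stims["block_index"], dtype=int)
    flashes = event_table[event_table["event_kind"] == "flash"]
    flash_times = None
    if len(flashes):
        flash_times = np.full(stim_times.size, np.nan)
        delay = doc.get("flash_delay_s")
        ft = np.asarray(flashes["event_time_s"], dtype=float)
        fb = np.asarray(flashes["block_index"], dtype=int)
        # flashes pair 1:1 with the stimulations of their block, in order
        for b in np.unique(fb):
            idx = np.flatnonzero(block_index == b)
            times_b = np.sort(ft[fb == b])
            flash_times[idx[: times_b.size]] = times_b
        if delay is None and len(ft):
            delay = float(np.median(ft[fb == fb[0]] - stim_times[block_index == fb[0]][: (fb == fb[0]).sum()]))
        doc["flash_delay_s"] = delay
    return EventSchedule(
        stim_times=stim_times,
        block_index=block_index,
        block_labels=tuple(doc["block_labels"]),
        block_size=int(doc["block_size"]),
        duration_s=float(doc["duration_s"]),
        flash_times=flash_times,
        flash_delay_s=doc.get("flash_delay_s"),
        flash_duration_s=float(doc.get("flash_duration_s", 0.010)),
    )


def write_ground_truth(path, truth: GroundTruth) -> None:
    rows = []
    for ch in sorted(truth.potentiated):
        rows.append(
            {
                "channel_id": ch,
                "potentiated": int(truth.potentiated[ch]),
                "latencies_ms": ";".join(
                    f"{lat:g}" for lat in truth.latencies_ms.get(ch, ())
                ),
                "onset_block": -1
                if truth.onset_block.get(ch) is None
                else int(truth.onset_block[ch]),
            }
        )
    write_table(path, pd.DataFrame(rows))


def read_ground_truth(path) -> GroundTruth:
    df = read_table(path).fillna({"latencies_ms": ""})
    potentiated, latencies, onset = {}, {}, {}
    for _, row in df.iterrows():
        ch = int(row["channel_id"])
        potentiated[ch] = bool(row["potentiated"])
        lats = str(row["latencies_ms"])
        latencies[ch] = tuple(float(v) for v in lats.split(";") if v not in ("", "nan"))
        onset[ch] = None if int(row["onset_block"]) < 0 else int(row["onset_block"])
    return GroundTruth(potentiated=potentiated, latencies_ms=latencies, onset_block=onset)


def save_dataset(
    out_dir,
    dataset: Dataset,
    truth: Optional[GroundTruth] = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_spike_table(out / "spikes.tsv", dataset.spike_trains)
    write_event_table(out / "events.tsv", dataset.schedule)
    write_schedule(out / "schedule.yaml", dataset.schedule)
    if truth is not None:
        write_ground_truth(out / "ground_truth.tsv", truth)


def load_dataset(in_dir) -> tuple[Dataset, Optional[GroundTruth]]:
    src = Path(in_dir)
    trains = read_spike_table(src / "spikes.tsv")
    events = read_event_table(src / "events.tsv")
    schedule = read_schedule(src / "schedule.yaml", events)
    truth = None
    gt_path = src / "ground_truth.tsv"
    if gt_path.exists():
        truth = read_ground_truth(gt_path)
    return Dataset(spike_trains=trains, schedule=schedule), truth
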