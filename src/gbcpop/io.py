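"""Plain-text persistence: spike-time files, JSON configs, result tables.

Spike-time files are comma-delimited text with header columns
``trial,fiber,time_ms`` and an optional leading metadata comment::

    # trial_duration_ms=25.00 n_trials=100 n_fibers=20
    trial,fiber,time_ms
    0,0,1.23

Times are written with two decimals (0.01 ms resolution), so a
write -> read round trip is exact on the simulation grid.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .model import SpikeData

__all__ = ["write_spike_times", "read_spike_times", "RunConfig"]

_HEADER = "trial,fiber,time_ms"


def write_spike_times(path, fibers: Sequence[SpikeData]) -> None:
    """Write fiber spike trains to the delimited spike-time format."""
    path = Path(path)
    n_trials = fibers[0].n_trials if fibers else 0
    duration = fibers[0].trial_duration if fibers else 0.0
    lines = [
        f"# trial_duration_ms={duration:.2f} n_trials={n_trials} n_fibers={len(fibers)}",
        _HEADER,
    ]
    for fi, fiber in enumerate(fibers):
        if fiber.n_trials != n_trials:
            raise ValueError("all fibers must have the same number of trials")
        for ti, spikes in enumerate(fiber.trials):
            for t in spikes:
                lines.append(f"{ti},{fi},{t:.2f}")
    path.write_text("\n".join(lines) + "\n")


def read_spike_times(path, trial_duration: Optional[float] = None) -> List[SpikeData]:
    """Read a spike-time file back into one SpikeData per fiber.

    Raises a parse error naming the offending line for malformed rows or
    times that are not strictly increasing within a (fiber, trial) group.
    An empty file with a valid header yields zero-spike trains (sized from
    the metadata comment when present).
    """
    path = Path(path)
    meta = {}
    rows = []
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                for key, val in re.findall(r"(\w+)=([\d.eE+-]+)", line):
                    meta[key] = float(val)
                continue
            if not header_seen:
                if line.replace(" ", "") != _HEADER:
                    raise ValueError(
                        f"{path}:{lineno}: expected header '{_HEADER}', got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            try:
                trial, fiber, t = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            if trial < 0 or fiber < 0:
                raise ValueError(f"{path}:{lineno}: negative trial or fiber id")
            rows.append((lineno, trial, fiber, t))
    if not header_seen:
        raise ValueError(f"{path}: missing header '{_HEADER}'")

    n_fibers = int(meta.get("n_fibers", 0))
    n_trials = int(meta.get("n_trials", 0))
    if rows:
        n_fibers = max(n_fibers, max(r[2] for r in rows) + 1)
        n_trials = max(n_trials, max(r[1] for r in rows) + 1)
    if trial_duration is None:
        if "trial_duration_ms" in meta:
            trial_duration = meta["trial_duration_ms"]
        elif rows:
            trial_duration = max(r[3] for r in rows)
        else:
            trial_duration = 0.0

    grouped = [[[] for _ in range(n_trials)] for _ in range(n_fibers)]
    last = {}
    for lineno, trial, fiber, t in rows:
        key = (fiber, trial)
        if key in last and t <= last[key]:
            raise ValueError(
                f"{path}:{lineno}: spike times not strictly increasing "
                f"within fiber {fiber}, trial {trial}"
            )
        last[key] = t
        grouped[fiber][trial].append(t)
    return [
        SpikeData(
            trials=[np.asarray(ts) for ts in trials],
            trial_duration=float(trial_duration),
            meta={"source": str(path), "fiber": fi},
        )
        for fi, trials in enumerate(grouped)
    ]


@dataclasses.dataclass
class RunConfig:
    """Serializable run configuration for the CLI drivers.

    ``grid`` maps parameter names to override value lists (empty = full
    default grid); ``an`` holds surrogate-parameter overrides; ``desk``
    selects the reduced desk-scale preset.
    """

    grid: dict = dataclasses.field(default_factory=dict)
    an: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    n_trials: int = 1000
    spont_duration: float = 100_000.0  # ms
    desk: bool = False

    _FIELDS = ("grid", "an", "seed", "n_trials", "spont_duration", "desk")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        unknown = set(data) - set(cls._FIELDS)
        if unknown:
            raise ValueError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({k: getattr(self, k) for k in self._FIELDS}, indent=2) + "\n"
        )
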