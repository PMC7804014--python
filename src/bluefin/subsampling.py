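"""Systematic random subsampling of a year of recordings for annotation.

A site-year (one instrument, roughly one year of recording) is split into
chunks -- mostly hour-long, shorter for duty-cycled instruments -- and a
target of roughly 200 chunks is selected for manual annotation by *systematic
random* sampling: every ``t_s``-th chunk starting from a uniformly random
offset in ``[1, t_s]``.  The spacing is the largest that still fits about the
target number of chunks (and never fewer than 150) between the first and last
chunk.  For hourly chunks, spacings sharing a factor with 24 would visit only
a subset of clock hours, so the spacing is additionally decreased until it is
coprime with 24, guaranteeing broad hour-of-day coverage (with ~200 chunks
over a ~year, every clock hour is visited 5-10 times).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class RecordingInventory:
    """Ordered chunks of one site-year.

    ``timestamps`` are chunk start times (numpy datetime64, strictly
    increasing); ``duration_s`` is each chunk's time span and ``recorded_s``
    the audio actually recorded inside it under the instrument's duty cycle.
    """

    timestamps: np.ndarray
    duration_s: np.ndarray
    recorded_s: np.ndarray
    site_year: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.duration_s = np.asarray(self.duration_s, dtype=float)
        self.recorded_s = np.asarray(self.recorded_s, dtype=float)
        if not (
            len(self.timestamps) == len(self.duration_s) == len(self.recorded_s)
        ):
            raise ValueError("inventory columns must have equal length")
        if len(self.timestamps) == 0:
            raise ValueError("inventory must contain at least one chunk")
        if np.any(np.diff(self.timestamps.astype("int64")) <= 0):
            raise ValueError("chunk timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    @classmethod
    def hourly(
        cls,
        start: str | np.datetime64,
        n_chunks: int,
        recorded_s: float = 3600.0,
        site_year: str = "",
    ) -> "RecordingInventory":
        """Hour-long chunks at one-hour intervals from ``start``.

        ``recorded_s`` < 3600 models a duty-cycled instrument (e.g. 300 for
        5 min/h, 1500 for 25 min/h)."""
        t0 = np.datetime64(start, "s")
        stamps = t0 + np.arange(n_chunks) * np.timedelta64(3600, "s")
        return cls(
            timestamps=stamps,
            duration_s=np.full(n_chunks, 3600.0),
            recorded_s=np.full(n_chunks, float(recorded_s)),
            site_year=site_year,
        )

    @property
    def is_hourly(self) -> bool:
        return bool(np.all(self.duration_s == 3600.0))


@dataclass(frozen=True)
class SubsamplePlan:
    """A systematic random selection of chunks.

    ``indices`` are 0-based chunk indices ``r-1, r-1+t_s, ...`` where the
    random start ``r`` was drawn uniformly from ``[1, t_s]`` under ``seed``.
    """

    indices: np.ndarray
    spacing: int
    start: int
    seed: int
    site_year: str = ""

    def __len__(self) -> int:
        return len(self.indices)


def _choose_spacing(n_chunks: int, target_n: int, hourly: bool) -> int:
    floor_n = max(150, int(math.ceil(0.75 * target_n)))
    t_s = max(1, n_chunks // max(target_n, floor_n))
    if hourly:
        # decrease until coprime with 24 so every clock hour is visited
        while math.gcd(t_s, 24) != 1:
            t_s -= 1
    return max(t_s, 1)


def plan_subsample(
    inventory: RecordingInventory, target_n: int, seed: int
) -> SubsamplePlan:
    """Plan a systematic random subsample of about ``target_n`` chunks.

    If the inventory holds no more than ``target_n`` chunks, every chunk is
    selected (with a warning when the target exceeds the inventory).
    """
    if target_n < 1:
        raise ValueError("target_n must be at least 1")
    n = len(inventory)
    if target_n >= n:
        if target_n > n:
            warnings.warn(
                f"target of {target_n} chunks exceeds inventory of {n}; "
                "selecting all chunks",
                stacklevel=2,
            )
        return SubsamplePlan(
            indices=np.arange(n),
            spacing=1,
            start=1,
            seed=seed,
            site_year=inventory.site_year,
        )
    t_s = _choose_spacing(n, target_n, inventory.is_hourly)
    rng = np.random.default_rng(seed)
    r = int(rng.integers(1, t_s + 1))
    indices = np.arange(r - 1, n, t_s)
    return SubsamplePlan(
        indices=indices,
        spacing=t_s,
        start=r,
        seed=seed,
        site_year=inventory.site_year,
    )


def coverage_by_clock_hour(
    plan: SubsamplePlan, inventory: RecordingInventory
) -> np.ndarray:
    """24-bin histogram of selected chunks by hour of day; sums to len(plan)."""
    stamps = inventory.timestamps[plan.indices]
    hours = (
        (stamps.astype("datetime64[h]") - stamps.astype("datetime64[D]"))
        .astype("timedelta64[h]")
        .astype(int)
    )
    return np.bincount(hours, minlength=24)


def audio_hours(plan: SubsamplePlan, inventory: RecordingInventory) -> float:
    """Total duty-recorded audio duration of the selected chunks, in hours."""
    return float(inventory.recorded_s[plan.indices].sum() / 3600.0)
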