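"""Epoched EEG container.

An :class:`EpochSet` bundles a trials × channels × samples array (µV), the
sample times (ms relative to stimulus onset), channel names, and a per-trial
metadata table.  All pipeline stages consume and return this container.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

CONDITIONS = ("V", "AV_c", "AV_i", "A")
VISUAL_CONDITIONS = ("V", "AV_c", "AV_i")

#: Columns every trial table must carry.
TRIAL_COLUMNS = (
    "participant",
    "condition",
    "visual_field",
    "visual_side",
    "sound_side",
    "is_target",
    "response_latency_ms",
)


@dataclass
class EpochSet:
    """Trials × channels × samples of scalp potential with trial metadata.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)`` in µV.
    times
        Strictly increasing, uniformly spaced sample times in ms relative to
        stimulus onset.
    channel_names
        One unique name per channel row.
    trial_table
        One row per trial; see :data:`TRIAL_COLUMNS`.
    srate
        Sampling rate in Hz (must match the spacing of ``times``).
    """

    data: np.ndarray
    times: np.ndarray
    channel_names: tuple[str, ...]
    trial_table: pd.DataFrame
    srate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError("data must be trials × channels × samples")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length does not match data")
        if self.data.shape[2] != self.times.size:
            raise ValueError("times length does not match data")
        if len(self.trial_table) != self.data.shape[0]:
            raise ValueError(
                f"trial table has {len(self.trial_table)} rows for "
                f"{self.data.shape[0]} trials"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, 1000.0 / self.srate, rtol=1e-6, atol=1e-6):
                raise ValueError("times spacing inconsistent with srate")
        missing = set(TRIAL_COLUMNS) - set(self.trial_table.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        self.trial_table = self.trial_table.reset_index(drop=True)

    # -- basic helpers -------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epoch set") from None

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean sample mask for an inclusive ms window."""
        lo, hi = window
        if lo > hi:
            raise ValueError("window must be (low, high)")
        if lo < self.times[0] or hi > self.times[-1]:
            raise ValueError(
                f"window {window} outside epoch times "
                f"[{self.times[0]}, {self.times[-1]}] ms"
            )
        # half-sample tolerance keeps the endpoints inclusive
        tol = 500.0 / self.srate
        return (self.times >= lo - tol) & (self.times <= hi + tol)

    def select(self, mask) -> "EpochSet":
        """Subset trials by boolean mask or integer index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool and mask.size != self.n_trials:
            raise ValueError("boolean mask length mismatch")
        return replace(
            self,
            data=self.data[mask],
            trial_table=self.trial_table.iloc[mask].reset_index(drop=True),
        )

    def copy(self) -> "EpochSet":
        return replace(
            self, data=self.data.copy(), trial_table=self.trial_table.copy()
        )


def concat_epochs(sets: list[EpochSet]) -> EpochSet:
    """Stack epoch sets sharing times and channels along the trial axis."""
    if not sets:
        raise ValueError("nothing to concatenate")
    first = sets[0]
    for other in sets[1:]:
        if other.channel_names != first.channel_names:
            raise ValueError("channel sets differ")
        if not np.allclose(other.times, first.times):
            raise ValueError("time axes differ")
    return EpochSet(
        data=np.concatenate([s.data for s in sets], axis=0),
        times=first.times,
        channel_names=first.channel_names,
        trial_table=pd.concat([s.trial_table for s in sets], ignore_index=True),
        srate=first.srate,
    )
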