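"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Invalid parameters (band edges, coupling matrices, thresholds...)."""


class ChannelError(KeyError):
    """A channel label is missing or would collide after renaming."""


class LengthError(ValueError):
    """A signal is too short for the requested operation."""


class WindowError(ValueError):
    """A Theiler-window candidate set is empty."""


@dataclass
class Recording:
    """A block of multichannel signal data.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values, channel-major. Units are microvolts by convention.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        One label per channel (e.g. 10-20 electrode names).
    substituted : frozenset of str
        Labels of channels whose data came from a substitute lead. Carried
        through so downstream scoring can remove the systematic bias that
        lead substitution introduces.
    meta : dict
        Free-form provenance (filter settings, seeds, ...).
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    substituted: frozenset[str] = frozenset()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigurationError("data must be 2-D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ConfigurationError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.labels.index(label)]
        except ValueError:
            raise ChannelError(label) from None

    def copy_with(self, **changes) -> "Recording":
        return replace(self, **changes)

    def epochs(self, epoch_samples: int) -> list["Recording"]:
        """Split into consecutive non-overlapping epochs; the tail remainder
        shorter than ``epoch_samples`` is dropped."""
        if epoch_samples < 1:
            raise ConfigurationError("epoch length must be >= 1 sample")
        n = self.n_samples // epoch_samples
        return [
            self.copy_with(data=self.data[:, i * epoch_samples:(i + 1) * epoch_samples])
            for i in range(n)
        ]


@dataclass
class CohortDataset:
    """A collection of recordings with subject/family/group annotations.

    ``table`` holds one row per observation (subject x wave) with at least the
    columns subject_id, family_id, group, wave, sex; optional covariates
    (gmv, wmv, coupling) and metric columns may be appended by later stages.
    ``recordings`` maps (subject_id, wave) to the corresponding Recording.
    """

    table: pd.DataFrame
    recordings: dict[tuple[str, int], Recording] = field(default_factory=dict)

    REQUIRED = ("subject_id", "family_id", "group", "wave", "sex")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ConfigurationError(f"covariate table missing columns: {missing}")

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.table["group"]:
            if g not in seen:
                seen.append(g)
        return seen

    def recording(self, subject_id: str, wave: int) -> Recording:
        return self.recordings[(subject_id, wave)]
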