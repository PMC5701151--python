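"""The in-memory container for one subject's multichannel recording."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Recording:
    """One subject's channels x samples signal array.

    Attributes
    ----------
    subject_id
        Unique subject label.
    data
        Real-valued array of shape ``(n_channels, n_samples)``.
    sample_rate
        Sampling rate in Hz.
    channel_labels
        One label per channel row.
    group
        Cohort group (1 or 2) for two-group designs; ``None`` for
        recordings outside a group design.
    """

    subject_id: str
    data: np.ndarray
    sample_rate: float
    channel_labels: list[str] = field(default_factory=list)
    group: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:03d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None

    def copy_with(self, data: np.ndarray, sample_rate: float | None = None
                  ) -> "Recording":
        """New Recording with replaced data (and optionally rate),
        keeping identity metadata."""
        return Recording(
            subject_id=self.subject_id,
            data=np.asarray(data, dtype=np.float64),
            sample_rate=self.sample_rate if sample_rate is None else sample_rate,
            channel_labels=list(self.channel_labels),
            group=self.group,
        )
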