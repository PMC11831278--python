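"""In-memory containers for continuous recordings and fixed-length epochs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Recording:
    """One continuous multichannel EEG recording.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array of average-referenced potentials
        in microvolts.
    fs
        Sampling rate in Hz.
    ch_names
        Channel labels, one per row of ``data``.
    subject, group, condition
        Study-design metadata. ``condition`` is one of ``resting``,
        ``drug`` or ``neutral`` in the default design.
    """

    data: np.ndarray
    fs: float
    ch_names: tuple[str, ...]
    subject: str = ""
    group: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("channel-name count does not match data rows")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


@dataclass
class Epoch:
    """One 7-s (by default) band-tagged analysis epoch."""

    data: np.ndarray
    fs: float
    band: str
    subject: str
    group: str
    condition: str
    trial: int
    ch_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        if self.data.ndim != 2:
            raise ValueError("Epoch.data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Epoch contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "Epoch":
        return replace(self, **kw)
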