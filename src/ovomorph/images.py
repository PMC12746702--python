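"""In-memory containers for multi-channel images and label masks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MultiChannelImage", "LabelMask"]


@dataclass
class MultiChannelImage:
    """A pixel grid with named channels and a physical pixel size.

    ``data`` has shape (rows, cols, n_channels); ``pixel_size`` is in
    micrometres per pixel. Intensities are non-negative floats (arbitrary
    units).
    """

    data: np.ndarray
    channels: tuple[str, ...]
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[:, :, None]
        if self.data.ndim != 3:
            raise ValueError(f"expected (rows, cols, channels) array, got shape {self.data.shape}")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.data.shape[2]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[2]} planes"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"channel names must be unique, got {self.channels}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 2D float array."""
        if name not in self.channels:
            raise KeyError(f"no channel '{name}'; have {self.channels}")
        return self.data[:, :, self.channels.index(name)]


@dataclass
class LabelMask:
    """Integer label image (0 = background) for one compartment.

    Each positive label is expected to form a single 8-connected component.
    """

    labels: np.ndarray
    compartment: str
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)
        if self.compartment not in ("nucleus", "cell"):
            raise ValueError(f"compartment must be 'nucleus' or 'cell', got {self.compartment!r}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def ids(self) -> np.ndarray:
        """Sorted positive label ids present in the mask."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_objects(self) -> int:
        return len(self.ids)

    def area_um2(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.pixel_size**2
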