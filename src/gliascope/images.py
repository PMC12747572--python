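"""In-memory image containers with physical metadata.

Axis conventions (0-based indices everywhere):

* volumetric stacks  — ``(C, Z, Y, X)`` in memory, stored on disk as ZCYX TIFF
* time-lapse movies  — ``(T, Y, X)``
* multichannel 2-D   — ``(C, Y, X)``

Physical units are micrometres and seconds throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError


@dataclass
class VolumetricImage:
    """Multichannel 3-D intensity grid with isotropic-per-axis voxel pitch.

    Parameters
    ----------
    data
        Array of shape ``(C, Z, Y, X)``.
    voxel_pitch_um
        Edge length of one voxel along ``(Z, Y, X)`` in μm.
    channel_names
        Optional channel labels, e.g. ``("membrane", "nucleus")``.
    """

    data: np.ndarray
    voxel_pitch_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise SpecError(
                f"VolumetricImage expects (C, Z, Y, X); got shape {self.data.shape}"
            )
        if any(p <= 0 for p in self.voxel_pitch_um):
            raise SpecError("voxel_pitch_um must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def channel(self, index_or_name: int | str) -> np.ndarray:
        if isinstance(index_or_name, str):
            index_or_name = self.channel_names.index(index_or_name)
        return self.data[index_or_name]


@dataclass
class CalciumMovie:
    """Single-channel fluorescence time lapse.

    ``frames`` has shape ``(T, Y, X)``; ``frame_rate_hz`` is the acquisition
    rate (native recordings here are 10 Hz over 5 min).
    """

    frames: np.ndarray
    frame_rate_hz: float = 10.0
    pixel_pitch_um: float = 0.65

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise SpecError(f"CalciumMovie expects (T, Y, X); got {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise SpecError("CalciumMovie needs at least 2 frames")
        if self.frame_rate_hz <= 0:
            raise SpecError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class MultichannelImage:
    """2-D multichannel image, shape ``(C, Y, X)`` (e.g. live/dead fields)."""

    data: np.ndarray
    pixel_pitch_um: float = 1.0
    channel_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise SpecError(f"MultichannelImage expects (C, Y, X); got {self.data.shape}")

    def channel(self, index_or_name: int | str) -> np.ndarray:
        if isinstance(index_or_name, str):
            index_or_name = self.channel_names.index(index_or_name)
        return self.data[index_or_name]
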