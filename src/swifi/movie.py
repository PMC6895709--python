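"""Movie container and two-channel chip layout.

A movie is a frame-indexed stack in which the two spectral channels sit
side by side on one chip (donor left, acceptor right for a ``left_right``
split).  Acquisition metadata (pixel size, frame time, excitation
schedule) travels with the pixel data so downstream stages never need
out-of-band bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelLayout", "Movie"]


@dataclass
class ChannelLayout:
    """Geometry of the two emission channels on the camera chip.

    Parameters
    ----------
    split : {"left_right", "top_bottom"}
        How the chip is divided between the channels.
    split_index : int or None
        Column (``left_right``) or row (``top_bottom``) at which the
        second channel starts.  ``None`` means half the frame, which is
        only valid for an even extent.
    channel_offset : (float, float)
        Registration shift ``(dx, dy)`` in pixels mapping a donor-channel
        coordinate to the matching acceptor-channel coordinate.
    roles : (str, str)
        Role of the first and second chip half.
    """

    split: str = "left_right"
    split_index: int | None = None
    channel_offset: tuple[float, float] = (0.0, 0.0)
    roles: tuple[str, str] = ("donor", "acceptor")

    def __post_init__(self) -> None:
        if self.split not in ("left_right", "top_bottom"):
            raise ValueError(f"unknown split {self.split!r}")
        if set(self.roles) != {"donor", "acceptor"}:
            raise ValueError("roles must name donor and acceptor")

    def resolve_split(self, frame_shape: tuple[int, int]) -> int:
        extent = frame_shape[1] if self.split == "left_right" else frame_shape[0]
        if self.split_index is not None:
            if not 0 < self.split_index < extent:
                raise ValueError("split_index outside frame")
            return int(self.split_index)
        if extent % 2:
            raise ValueError(
                "odd frame extent: an explicit split_index is required"
            )
        return extent // 2


@dataclass
class Movie:
    """Frame stack plus acquisition metadata.

    ``data`` has shape ``(n_frames, height, width)`` and holds both
    channels side by side as laid out by ``layout``.
    """

    data: np.ndarray
    pixel_size_nm: float
    frame_time_ms: float
    excitation: np.ndarray  # per-frame label, "D" or "A"
    layout: ChannelLayout = field(default_factory=ChannelLayout)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("movie data must be (n_frames, height, width)")
        self.excitation = np.asarray(self.excitation)
        if len(self.excitation) != self.n_frames:
            raise ValueError("excitation schedule length != frame count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def channel(self, role: str) -> np.ndarray:
        """View of one channel's stack, shape (n_frames, ny, nx)."""
        s = self.layout.resolve_split(self.frame_shape)
        first = self.layout.roles[0] == role
        if role not in ("donor", "acceptor"):
            raise ValueError(f"unknown channel role {role!r}")
        if self.layout.split == "left_right":
            return self.data[:, :, :s] if first else self.data[:, :, s:]
        return self.data[:, :s, :] if first else self.data[:, s:, :]

    def channel_shape(self, role: str) -> tuple[int, int]:
        arr = self.channel(role)
        return arr.shape[1], arr.shape[2]
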