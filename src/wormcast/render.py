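"""Synthetic-domain rendering: circles on a gray background.

The forecaster never sees micrographs. Both simulated plates and (externally
reduced) real captures are represented in a shared synthetic domain: a
constant gray background with one filled circle per worm at its centroid.
This module rasterizes per-day worm positions into that representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .simulate import WormTrajectory

__all__ = ["ImageSpec", "FrameSequence", "render_frame", "render_sequence", "write_frames"]


@dataclass(frozen=True)
class ImageSpec:
    """Geometry and intensities of a synthetic-domain frame."""

    side: int = 64
    background_level: int = 128
    blob_radius: int = 2
    blob_level: int = 255

    def __post_init__(self) -> None:
        for name in ("background_level", "blob_level"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must be an 8-bit intensity")
        if self.blob_level == self.background_level:
            raise ValueError("blobs must be distinguishable from the background")
        if self.blob_radius < 1:
            raise ValueError("blob_radius must be at least 1 pixel")
        if self.side < 4 * self.blob_radius:
            raise ValueError("image side must be at least 4x the blob radius")


@dataclass(frozen=True)
class FrameSequence:
    """Ordered per-day frames of one plate."""

    frames: np.ndarray  # (n_days, side, side) uint8
    day_index: np.ndarray  # (n_days,) int

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.uint8)
        days = np.asarray(self.day_index, dtype=int)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "day_index", days)
        if frames.ndim != 3 or frames.shape[1] != frames.shape[2]:
            raise ValueError("frames must be (n_days, side, side)")
        if frames.shape[0] != days.shape[0]:
            raise ValueError("one frame per day required")

    def __len__(self) -> int:
        return self.frames.shape[0]


def render_frame(positions: Sequence[tuple[float, float]] | np.ndarray, spec: ImageSpec) -> np.ndarray:
    """Rasterize worm centroids into one synthetic-domain frame.

    Coordinates are pixels with the origin at the top-left corner, x rightward
    and y downward; each position is the centre of a filled disc of
    ``blob_radius``. Overlapping discs merge into one flat region. A centre
    outside the image raises rather than silently clipping.
    """
    img = np.full((spec.side, spec.side), spec.background_level, dtype=np.uint8)
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    if pos.shape[0] == 0:
        return img
    if np.any(pos < 0) or np.any(pos >= spec.side):
        raise ValueError("worm position outside image bounds")
    r = spec.blob_radius
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disc = (xx * xx + yy * yy) <= r * r
    for x, y in pos:
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - r, 0), min(cx + r + 1, spec.side)
        y0, y1 = max(cy - r, 0), min(cy + r + 1, spec.side)
        patch = disc[(y0 - cy + r):(y1 - cy + r), (x0 - cx + r):(x1 - cx + r)]
        region = img[y0:y1, x0:x1]
        region[patch] = spec.blob_level
    return img


def render_sequence(trajectories: Sequence[WormTrajectory], spec: ImageSpec) -> FrameSequence:
    """Render every day of a plate; dead worms appear at their frozen spot."""
    if not trajectories:
        raise ValueError("at least one trajectory required")
    n_days = trajectories[0].positions.shape[0]
    if any(tr.positions.shape[0] != n_days for tr in trajectories):
        raise ValueError("trajectories must share the same day range")
    frames = np.empty((n_days, spec.side, spec.side), dtype=np.uint8)
    for d in range(n_days):
        day_positions = np.array([tr.positions[d] for tr in trajectories])
        frames[d] = render_frame(day_positions, spec)
    return FrameSequence(frames=frames, day_index=np.arange(n_days))


def write_frames(seq: FrameSequence, out_dir: str | Path, plate_id: int) -> "list[dict]":
    """Write one PNG per day; returns manifest rows (plate_id, day, path)."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for frame, day in zip(seq.frames, seq.day_index):
        path = out_dir / f"plate{plate_id}_day{int(day)}.png"
        Image.fromarray(frame, mode="L").save(path)
        rows.append({"plate_id": plate_id, "day": int(day), "path": str(path)})
    return rows
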