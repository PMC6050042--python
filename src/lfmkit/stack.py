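"""Containers for time-lapse image data and tracked cells.

A :class:`TimeLapseStack` holds an ordered series of multi-channel 2D frames
with timestamps in hours post-transfection. Stacks round-trip to multi-page
TIFF (one file per channel) plus a YAML sidecar carrying timestamps, channel
names and pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml


@dataclass
class TimeLapseStack:
    """Ordered, timestamped multi-channel 2D image series.

    Parameters
    ----------
    timestamps_h : array of float
        Acquisition times in hours post-transfection, strictly increasing.
    channels : dict of str -> ndarray
        Each value has shape ``(n_frames, height, width)``, nonnegative AU.
    pixel_size_um : float, optional
        Physical pixel size in micrometres per pixel.
    """

    timestamps_h: np.ndarray
    channels: dict[str, np.ndarray]
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.timestamps_h = np.asarray(self.timestamps_h, dtype=float)
        if self.timestamps_h.ndim != 1:
            raise ValueError("timestamps must be one-dimensional")
        if np.any(np.diff(self.timestamps_h) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.channels:
            raise ValueError("stack needs at least one channel")
        shapes = set()
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} must be (frames, y, x)")
            if arr.shape[0] != self.n_frames:
                raise ValueError(
                    f"channel {name!r} has {arr.shape[0]} frames, "
                    f"expected {self.n_frames}"
                )
            shapes.add(arr.shape[1:])
            self.channels[name] = arr
        if len(shapes) != 1:
            raise ValueError("all channels must share one frame shape")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps_h)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def frame(self, index: int, channel: str) -> np.ndarray:
        if channel not in self.channels:
            raise KeyError(f"no channel named {channel!r}")
        return self.channels[channel][index]

    def write(self, directory: str | Path, stem: str = "stack") -> Path:
        """Write one multi-page TIFF per channel plus a YAML sidecar.

        Returns the sidecar path.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        files = {}
        for name, arr in self.channels.items():
            path = directory / f"{stem}_{name}.tif"
            tifffile.imwrite(
                path, arr.astype(np.float32), photometric="minisblack"
            )
            files[name] = path.name
        meta = {
            "timestamps_h": [float(t) for t in self.timestamps_h],
            "channels": files,
            "pixel_size_um": self.pixel_size_um,
        }
        sidecar = directory / f"{stem}.yaml"
        sidecar.write_text(yaml.safe_dump(meta, sort_keys=False))
        return sidecar

    @classmethod
    def read(cls, sidecar: str | Path) -> "TimeLapseStack":
        sidecar = Path(sidecar)
        meta = yaml.safe_load(sidecar.read_text())
        channels = {
            name: tifffile.imread(sidecar.parent / fname).astype(float)
            for name, fname in meta["channels"].items()
        }
        return cls(
            timestamps_h=np.asarray(meta["timestamps_h"], dtype=float),
            channels=channels,
            pixel_size_um=meta.get("pixel_size_um"),
        )


@dataclass
class CellROI:
    """A segmented cell region in one frame.

    Coordinates are 0-based pixel indices with ``x`` the column and ``y`` the
    row; the mask is the per-pixel membership set for the ROI.
    """

    frame_index: int
    label: int
    mask: np.ndarray  # boolean, full-frame shape
    centroid: tuple[float, float]  # (x, y)
    area: int
    eccentricity: float
    mean_intensity: dict[str, float] = field(default_factory=dict)
    integrated_intensity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("ROI area must be positive")


@dataclass
class CellTrack:
    """One tracked neuron: ordered observations plus its survival outcome.

    ``observations`` pairs each frame timestamp with the cell's ROI, or None
    when the cell was not found in that frame. ``status`` is one of
    ``"alive"`` (alive at end of imaging), ``"dead"``, or ``"lost"`` (left the
    field). Exactly one of ``death_time_days`` / ``censor_time_days`` is the
    record's exit time.
    """

    track_id: int
    group: str | None
    observations: list[tuple[float, CellROI | None]]
    status: str = "alive"
    death_time_days: float | None = None
    censor_time_days: float | None = None

    @property
    def rois(self) -> list[CellROI]:
        return [roi for _, roi in self.observations if roi is not None]

    @property
    def exit_time_days(self) -> float:
        if self.status == "dead":
            assert self.death_time_days is not None
            return self.death_time_days
        assert self.censor_time_days is not None
        return self.censor_time_days

    @property
    def event(self) -> int:
        return 1 if self.status == "dead" else 0

    def roi_at_time(self, time_h: float, tol_h: float = 1e-6) -> CellROI | None:
        for t, roi in self.observations:
            if abs(t - time_h) <= tol_h:
                return roi
        return None


def tracks_to_dataframe(tracks: Sequence[CellTrack]):
    """Flatten tracks to a tidy per-observation table (one row per ROI)."""
    import pandas as pd

    rows = []
    for tr in tracks:
        for t, roi in tr.observations:
            if roi is None:
                continue
            row = {
                "track_id": tr.track_id,
                "group": tr.group,
                "time_h": t,
                "area_px": roi.area,
                "eccentricity": roi.eccentricity,
                "x": roi.centroid[0],
                "y": roi.centroid[1],
            }
            for ch, v in roi.mean_intensity.items():
                row[f"mean_{ch}"] = v
            rows.append(row)
    return pd.DataFrame(rows)
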