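"""Segmentation, tracking, death calling and registration for neuron stacks.

The pipeline mirrors automated longitudinal microscopy analysis: threshold
the morphology channel per frame, label connected components into ROIs,
link ROIs across frames by mutual nearest centroids, then classify each
track's fate from its intensity and shape history. Death is called at the
first frame where the soma's fluorescence collapses, the ROI disappears for
good, or the soma rounds up with declining intensity thereafter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation
from scipy import ndimage

from .stack import CellROI, CellTrack, TimeLapseStack

__all__ = [
    "segment_frame",
    "segment_stack",
    "track_cells",
    "call_death",
    "extract_timeseries",
    "register_stack",
]


def segment_frame(
    stack: TimeLapseStack,
    frame_index: int,
    channel: str = "morphology",
    min_area: int = 20,
    max_area: int = 2000,
    threshold: str | float = "otsu",
    absolute_floor: float = 0.0,
    min_solidity: float = 0.0,
) -> list[CellROI]:
    """Segment one frame into cell ROIs.

    Pixels above threshold are labelled into connected components, filtered
    by area (``min_area <= area <= max_area``) and solidity. ``threshold``
    is either ``"otsu"`` (per-frame Otsu on the chosen channel, never below
    ``absolute_floor``) or a number used directly. A blank frame yields an
    empty list.
    """
    if channel not in stack.channels:
        raise KeyError(f"no channel named {channel!r}")
    if min_area >= max_area:
        raise ValueError("min_area must be < max_area")
    img = stack.frame(frame_index, channel)
    if threshold == "otsu":
        if np.ptp(img) == 0:
            return []
        thr = max(float(threshold_otsu(img)), absolute_floor)
    else:
        thr = float(threshold)
    binary = img > thr
    if not binary.any():
        return []
    labels = measure.label(binary, connectivity=2)
    rois: list[CellROI] = []
    next_label = 1
    for prop in measure.regionprops(labels):
        if not (min_area <= prop.area <= max_area):
            continue
        if min_solidity > 0 and prop.solidity < min_solidity:
            continue
        mask = labels == prop.label
        cy, cx = prop.centroid
        means = {}
        integrated = {}
        for name in stack.channel_names:
            vals = stack.frame(frame_index, name)[mask]
            means[name] = float(vals.mean())
            integrated[name] = float(vals.sum())
        rois.append(
            CellROI(
                frame_index=frame_index,
                label=next_label,
                mask=mask,
                centroid=(cx, cy),
                area=int(prop.area),
                eccentricity=float(prop.eccentricity),
                mean_intensity=means,
                integrated_intensity=integrated,
            )
        )
        next_label += 1
    return rois


def segment_stack(stack: TimeLapseStack, **kwargs) -> list[list[CellROI]]:
    """Segment every frame; returns one ROI list per frame."""
    return [segment_frame(stack, i, **kwargs) for i in range(stack.n_frames)]


def track_cells(
    stack: TimeLapseStack,
    per_frame_rois: list[list[CellROI]],
    max_displacement: float = 15.0,
    group: str | None = None,
) -> list[CellTrack]:
    """Link per-frame ROIs into tracks by greedy mutual-nearest centroids.

    Each frame-to-frame step pairs ROIs whose centroids are mutual nearest
    neighbours within ``max_displacement`` pixels; ties resolve by smaller
    distance then smaller label id. An unmatched previous ROI leaves its
    track open (candidate death or loss, decided later by
    :func:`call_death`); an unmatched new ROI starts a new track.
    """
    if stack.n_frames == 0:
        raise ValueError("empty stack")
    if len(per_frame_rois) != stack.n_frames:
        raise ValueError("need one ROI list per frame")

    tracks: list[CellTrack] = []
    # live_tracks maps track index -> last ROI seen
    live: dict[int, CellROI] = {}

    def new_track(first_frame: int, roi: CellROI) -> int:
        obs: list[tuple[float, CellROI | None]] = [
            (stack.timestamps_h[i], None) for i in range(first_frame)
        ]
        obs.append((stack.timestamps_h[first_frame], roi))
        tracks.append(CellTrack(track_id=len(tracks), group=group, observations=obs))
        return len(tracks) - 1

    for roi in per_frame_rois[0]:
        idx = new_track(0, roi)
        live[idx] = roi

    for f in range(1, stack.n_frames):
        t = stack.timestamps_h[f]
        current = per_frame_rois[f]
        pairs = []
        for ti, prev_roi in live.items():
            px, py = prev_roi.centroid
            for j, roi in enumerate(current):
                cx, cy = roi.centroid
                d = float(np.hypot(cx - px, cy - py))
                if d <= max_displacement:
                    pairs.append((d, ti, j, roi.label))
        # greedy by distance, then label id for determinism
        pairs.sort(key=lambda p: (p[0], p[3], p[1]))
        used_tracks: set[int] = set()
        used_rois: set[int] = set()
        assigned: dict[int, int] = {}
        for d, ti, j, _ in pairs:
            if ti in used_tracks or j in used_rois:
                continue
            used_tracks.add(ti)
            used_rois.add(j)
            assigned[ti] = j
        for ti in list(live):
            if ti in assigned:
                roi = current[assigned[ti]]
                tracks[ti].observations.append((t, roi))
                live[ti] = roi
            else:
                tracks[ti].observations.append((t, None))
        for j, roi in enumerate(current):
            if j not in used_rois:
                idx = new_track(f, roi)
                live[idx] = roi
    return tracks


def call_death(
    track: CellTrack,
    stack: TimeLapseStack,
    morphology_channel: str = "morphology",
    fluorescence_floor: float = 0.25,
    roundness_jump: float = 0.5,
) -> CellTrack:
    """Classify a track's fate and set its exit time.

    Death is called at the first frame satisfying, in order of precedence:

    a. the morphology-channel mean intensity falls below
       ``fluorescence_floor`` times its initial value;
    b. the ROI vanishes and never reappears;
    c. eccentricity drops by at least ``roundness_jump`` (absolute, the soma
       rounds up) and the intensity declines from that frame on.

    Otherwise the track is censored at its last observation. Times are
    reported in days post-transfection.
    """
    obs = [(t, roi) for t, roi in track.observations]
    seen = [(t, roi) for t, roi in obs if roi is not None]
    if not seen:
        track.status = "lost"
        track.censor_time_days = obs[-1][0] / 24.0
        return track
    if len(seen) == 1:
        # a single detection: the vanish rule (b) still applies; the
        # intensity/shape rules need a history
        last_t = seen[0][0]
        after = [t for t, roi in obs if roi is None and t > last_t]
        if after:
            track.status = "dead"
            track.death_time_days = min(after) / 24.0
            track.censor_time_days = None
        else:
            track.status = "alive" if last_t == obs[-1][0] else "lost"
            track.censor_time_days = last_t / 24.0
        return track

    first_t = seen[0][0]
    init_intensity = seen[0][1].mean_intensity[morphology_channel]
    init_ecc = seen[0][1].eccentricity
    intensities = [roi.mean_intensity[morphology_channel] for _, roi in seen]

    death_time_h: float | None = None

    # rule (a): fluorescence collapse
    for (t, roi), inten in zip(seen, intensities):
        if t > first_t and inten < fluorescence_floor * init_intensity:
            death_time_h = t
            break

    # rule (b): ROI vanishes and never reappears
    if death_time_h is None:
        last_seen_t = seen[-1][0]
        after = [t for t, roi in obs if roi is None and t > last_seen_t]
        if after:
            death_time_h = min(after)

    # rule (c): rounding with declining intensity thereafter
    if death_time_h is None:
        prev_ecc = init_ecc
        for k, (t, roi) in enumerate(seen[1:], start=1):
            if prev_ecc - roi.eccentricity >= roundness_jump:
                tail = intensities[k:]
                if len(tail) >= 2 and all(
                    b <= a for a, b in zip(tail, tail[1:])
                ):
                    death_time_h = t
                    break
            prev_ecc = roi.eccentricity

    if death_time_h is not None:
        track.status = "dead"
        track.death_time_days = death_time_h / 24.0
        track.censor_time_days = None
        # a dead track keeps no ROIs after death
        track.observations = [
            (t, roi if t < death_time_h else None) for t, roi in obs
        ]
    else:
        track.status = "alive" if seen[-1][0] == obs[-1][0] else "lost"
        track.death_time_days = None
        track.censor_time_days = seen[-1][0] / 24.0
    return track


def extract_timeseries(
    track: CellTrack, channel: str
) -> list[tuple[float, float]]:
    """Per-frame (time in hours, mean intensity) for frames with an ROI.

    Missing frames are omitted, not interpolated.
    """
    rois = [(t, roi) for t, roi in track.observations if roi is not None]
    if not rois:
        raise ValueError("track has no ROIs")
    if any(channel not in roi.mean_intensity for _, roi in rois):
        raise KeyError(f"no channel named {channel!r}")
    return [(t, roi.mean_intensity[channel]) for t, roi in rois]


@dataclass
class RegistrationResult:
    stack: TimeLapseStack
    shifts: np.ndarray  # (n_frames, 2) applied (row, col) shifts


def register_stack(
    stack: TimeLapseStack,
    reference_frame_index: int = 0,
    channel: str | None = None,
    upsample_factor: int = 20,
) -> RegistrationResult:
    """Rigid (translation) registration of every frame to a reference frame.

    Uses phase cross-correlation on ``channel`` (default: first channel) and
    applies the recovered shift to all channels. Featureless frames trigger a
    warning and keep the identity transform.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least two frames to register")
    channel = channel or stack.channel_names[0]
    ref = stack.frame(reference_frame_index, channel)
    shifts = np.zeros((stack.n_frames, 2))
    out = {name: arr.copy() for name, arr in stack.channels.items()}
    for f in range(stack.n_frames):
        if f == reference_frame_index:
            continue
        moving = stack.frame(f, channel)
        if np.ptp(moving) == 0 or np.ptp(ref) == 0:
            warnings.warn(
                f"frame {f}: featureless image, keeping identity transform",
                stacklevel=2,
            )
            continue
        # classic cross-correlation: spectral whitening ("phase"
        # normalization) misestimates subpixel shifts on smooth
        # fluorescence scenes with little high-frequency content
        shift, _, _ = phase_cross_correlation(
            ref, moving, upsample_factor=upsample_factor, normalization=None
        )
        shifts[f] = shift
        for name in out:
            out[name][f] = ndimage.shift(
                stack.channels[name][f], shift, order=1, mode="constant"
            )
    registered = TimeLapseStack(
        timestamps_h=stack.timestamps_h.copy(),
        channels=out,
        pixel_size_um=stack.pixel_size_um,
    )
    return RegistrationResult(stack=registered, shifts=shifts)
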