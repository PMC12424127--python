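"""Image-analysis chain: trim/downsample, background subtraction,
segmentation, centroid linking, and track curation.

The workflow mirrors a micropipette chemotaxis recording: starting 1 min
after chemoattractant release, a 10 min window is trimmed from the full
series and downsampled to one acquisition per 15 s; each frame is
background-subtracted and thresholded; connected components become
intensity-weighted centroids; centroids are linked frame-to-frame by
greedy globally-nearest-neighbour assignment (no gap closing — a missed
detection ends the track); and only tracks covering at least 20
consecutive acquisitions (5 min) enter the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .walks import Trajectory

__all__ = [
    "FrameSeries",
    "TrackSet",
    "trim_and_downsample",
    "subtract_background",
    "segment_frame",
    "segment_series",
    "link_tracks",
    "filter_min_length",
    "exclude_tracks",
    "assign_population",
    "measure_track_intensities",
    "MIN_TRACK_LENGTH",
]

#: minimum consecutive acquisitions per track (20 frames = 5 min at 15 s)
MIN_TRACK_LENGTH = 20


@dataclass
class FrameSeries:
    """An ordered image stack with acquisition geometry."""

    images: np.ndarray  # (n_frames, rows, cols)
    frame_interval: float  # s
    pixel_size: float  # um / px
    channel: str = ""
    t0_offset: float = 0.0  # chemoattractant release time relative to frame 0, s

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n_frames, rows, cols) stack")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        """Frame times on the series clock (frame 0 at t = 0), s."""
        return np.arange(len(self)) * self.frame_interval


@dataclass
class TrackSet:
    """Linked tracks plus the parameters and provenance that made them."""

    tracks: list[Trajectory]
    linking: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


def trim_and_downsample(
    series: FrameSeries,
    start_after_release: float = 60.0,
    window: float = 600.0,
    target_interval: float = 15.0,
) -> FrameSeries:
    """Trim to the analysis window and thin frames to the target cadence.

    Keeps frames at the smallest stride whose resulting interval is at
    least ``target_interval``, starting from the first frame at or after
    release + ``start_after_release``.  If the window extends past the end
    of the series it is truncated with a warning.
    """
    if target_interval < series.frame_interval:
        raise ValueError("target_interval must be >= frame_interval")
    t_start = series.t0_offset + start_after_release
    first = max(0, int(np.ceil(round(t_start / series.frame_interval, 9))))
    if first >= len(series):
        raise ValueError("analysis window starts after the series ends")
    stride = int(np.ceil(round(target_interval / series.frame_interval, 9)))
    idx = np.arange(first, len(series), stride)
    t_end = t_start + window
    keep = idx[series.frame_times[idx] <= t_end + 1e-9]
    if series.frame_times[-1] < t_end - 1e-9:
        warnings.warn(
            "analysis window extends past the end of the series; truncated",
            stacklevel=2,
        )
    return FrameSeries(
        images=series.images[keep],
        frame_interval=series.frame_interval * stride,
        pixel_size=series.pixel_size,
        channel=series.channel,
        t0_offset=series.t0_offset - series.frame_times[keep[0]],
    )


def subtract_background(series: FrameSeries, percentile: float = 5.0) -> FrameSeries:
    """Subtract a per-frame scalar background, clipping at zero.

    The background of each frame is estimated as a low percentile of its
    intensity distribution (default 5th) — a deterministic stand-in for
    the mode of the background peak.
    """
    imgs = series.images.astype(float)
    bg = np.percentile(imgs, percentile, axis=(1, 2), keepdims=True)
    return FrameSeries(
        images=np.clip(imgs - bg, 0.0, None),
        frame_interval=series.frame_interval,
        pixel_size=series.pixel_size,
        channel=series.channel,
        t0_offset=series.t0_offset,
    )


def segment_frame(
    image: np.ndarray,
    min_area: int = 9,
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold one frame and return centroids (px) and areas (px^2).

    A global Otsu threshold (unless ``threshold`` is given) splits
    foreground from background; connected components (8-connectivity)
    smaller than ``min_area`` are discarded; the remaining components
    yield intensity-weighted centroids as (x, y) = (col, row) pixel
    coordinates, ordered by (y, x) of the centroid.
    An all-background (constant) image yields no detections.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if np.any(img < 0):
        raise ValueError("image must be non-negative")
    if img.max() == img.min():
        return np.empty((0, 2)), np.empty(0)
    thr = threshold_otsu(img) if threshold is None else threshold
    mask = img > thr
    lab = label(mask, connectivity=2)
    cents, areas = [], []
    for region in regionprops(lab, intensity_image=img):
        if region.area < min_area:
            continue
        cy, cx = region.centroid_weighted
        cents.append((cx, cy))
        areas.append(region.area)
    if not cents:
        return np.empty((0, 2)), np.empty(0)
    cents = np.asarray(cents, dtype=float)
    areas = np.asarray(areas, dtype=float)
    order = np.lexsort((cents[:, 0], cents[:, 1]))
    return cents[order], areas[order]


def segment_series(
    series: FrameSeries,
    min_area: int = 9,
    threshold: float | None = None,
) -> list[np.ndarray]:
    """Per-frame centroids in um (pixel coordinates times pixel size)."""
    return [
        segment_frame(img, min_area=min_area, threshold=threshold)[0]
        * series.pixel_size
        for img in series.images
    ]


def link_tracks(
    per_frame_centroids: list[np.ndarray],
    frame_interval: float,
    max_disp: float,
    min_length: int = MIN_TRACK_LENGTH,
    t_first_frame: float = 0.0,
) -> TrackSet:
    """Greedy globally-nearest-neighbour linking of per-frame centroids.

    Candidate (track, detection) pairs within ``max_disp`` (um) are taken
    in ascending distance (ties broken by detection (y, x), then track
    (y, x) of the last position); each track and detection is used at most
    once per frame.  Unmatched detections start new tracks; unmatched
    tracks terminate — there is no gap closing, so every track covers
    consecutive frames.  Tracks shorter than ``min_length`` frames are
    removed.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be > 0")
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    open_tracks: list[dict] = []
    done: list[dict] = []
    for f, dets in enumerate(per_frame_centroids):
        dets = np.asarray(dets, dtype=float).reshape(-1, 2)
        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        if open_tracks and dets.size:
            last = np.array([tr["pos"][-1] for tr in open_tracks])
            d = np.linalg.norm(last[:, None, :] - dets[None, :, :], axis=2)
            ti, di = np.nonzero(d <= max_disp)
            keys = sorted(
                range(ti.size),
                key=lambda k: (
                    d[ti[k], di[k]],
                    dets[di[k], 1],
                    dets[di[k], 0],
                    last[ti[k], 1],
                    last[ti[k], 0],
                ),
            )
            for k in keys:
                t, j = int(ti[k]), int(di[k])
                if t in matched_tracks or j in matched_dets:
                    continue
                open_tracks[t]["pos"].append(dets[j])
                open_tracks[t]["frames"].append(f)
                matched_tracks.add(t)
                matched_dets.add(j)
        # terminate unmatched tracks
        still_open = []
        for t, tr in enumerate(open_tracks):
            if t in matched_tracks:
                still_open.append(tr)
            else:
                done.append(tr)
        open_tracks = still_open
        # unmatched detections seed new tracks (in (y, x) order)
        new_idx = [j for j in range(dets.shape[0]) if j not in matched_dets]
        new_idx.sort(key=lambda j: (dets[j, 1], dets[j, 0]))
        for j in new_idx:
            open_tracks.append({"pos": [dets[j]], "frames": [f]})
    done.extend(open_tracks)
    done.sort(key=lambda tr: (tr["frames"][0], tr["pos"][0][1], tr["pos"][0][0]))
    tracks = [
        Trajectory(
            cell_id=i,
            times=t_first_frame + np.asarray(tr["frames"], dtype=float) * frame_interval,
            positions=np.asarray(tr["pos"], dtype=float),
        )
        for i, tr in enumerate(done)
    ]
    ts = TrackSet(
        tracks=tracks,
        linking={"max_disp": max_disp, "min_length": min_length,
                 "frame_interval": frame_interval},
    )
    return filter_min_length(ts, min_length)


def filter_min_length(trackset: TrackSet, min_length: int = MIN_TRACK_LENGTH) -> TrackSet:
    """Keep tracks covering at least ``min_length`` consecutive frames.

    Idempotent: applying it twice equals applying it once.
    """
    kept = [tr for tr in trackset.tracks if len(tr) >= min_length]
    prov = dict(trackset.provenance)
    prov.setdefault("filters", []).append(
        {"min_length": min_length, "removed": len(trackset.tracks) - len(kept)}
    )
    return TrackSet(tracks=kept, linking=dict(trackset.linking), provenance=prov)


def exclude_tracks(trackset: TrackSet, exclude_ids: list = ()) -> TrackSet:
    """Manual-curation hook: drop an explicit, logged list of track ids.

    The default (excluding nothing) is the reproducible path; the
    exclusion list is recorded in the provenance so any curation is
    visible.
    """
    excl = set(exclude_ids)
    kept = [tr for tr in trackset.tracks if tr.cell_id not in excl]
    prov = dict(trackset.provenance)
    prov.setdefault("curation", []).append({"excluded_ids": sorted(excl, key=str)})
    return TrackSet(tracks=kept, linking=dict(trackset.linking), provenance=prov)


def measure_track_intensities(
    track: Trajectory,
    series: FrameSeries,
    frame_indices: np.ndarray | None = None,
    radius_px: int = 2,
) -> np.ndarray:
    """Mean intensity in a small window around the track at every frame."""
    if frame_indices is None:
        frame_indices = np.round(
            (track.times - track.times[0]) / series.frame_interval
        ).astype(int) + int(round(track.times[0] / series.frame_interval))
    vals = np.empty(len(track))
    rows, cols = series.images.shape[1:]
    for i, (f, pos) in enumerate(zip(frame_indices, track.positions)):
        cx = int(round(pos[0] / series.pixel_size))
        cy = int(round(pos[1] / series.pixel_size))
        x0, x1 = max(0, cx - radius_px), min(cols, cx + radius_px + 1)
        y0, y1 = max(0, cy - radius_px), min(rows, cy + radius_px + 1)
        vals[i] = float(series.images[f, y0:y1, x0:x1].mean())
    return vals


def assign_population(
    intensities_a: np.ndarray,
    intensities_b: np.ndarray,
    ratio_threshold: float = 1.2,
    labels: tuple[str, str] = ("population_A", "population_B"),
) -> str:
    """Classify a track by its dominant dye channel.

    Two co-plated cell lines are loaded with spectrally distinct dyes;
    the label is the channel with the higher track-median intensity.  If
    the median ratio is within ``ratio_threshold`` of 1 the track is
    "unassigned" and excluded from per-population summaries.
    """
    a = np.asarray(intensities_a, dtype=float)
    b = np.asarray(intensities_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both channel intensity series are required")
    med_a = float(np.median(a))
    med_b = float(np.median(b))
    if med_a <= 0 and med_b <= 0:
        return "unassigned"
    if med_b <= 0:
        return labels[0]
    ratio = med_a / med_b
    if ratio >= ratio_threshold:
        return labels[0]
    if ratio <= 1.0 / ratio_threshold:
        return labels[1]
    return "unassigned"
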