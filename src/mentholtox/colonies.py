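"""Time-lapse colony morphometry and motility from label masks.

Each frame pairs an integer label mask (0 = background, one label per
colony) with a phase-contrast intensity image. Extracted features:

- area: exact pixel count of the label (optionally µm² via pixel size);
- brightness/total-area ratio: fraction of colony pixels brighter than a
  threshold, a proxy for dead cells sitting on top of the colony;
- major/minor axis ratio of the equivalent ellipse from second central
  moments of the pixel set (>= 1; 1 for a circle);
- motility of the tracked centroid: total distance (path length) and total
  displacement (net start-to-end separation).

Colonies are tracked across frames by nearest centroid under a maximum-step
gate; only tracks present in every frame enter downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MaskFrame",
    "ColonyTrack",
    "colony_area",
    "brightness_area_ratio",
    "axis_ratio",
    "centroid",
    "track_colonies",
    "motility_features",
    "normalize_series",
    "feature_table",
]


@dataclass(frozen=True)
class MaskFrame:
    """One time point: label mask + phase-contrast image."""

    label_image: np.ndarray
    phase_image: np.ndarray
    timestamp_h: float
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        lab = np.asarray(self.label_image)
        ph = np.asarray(self.phase_image, dtype=float)
        object.__setattr__(self, "label_image", lab)
        object.__setattr__(self, "phase_image", ph)
        if lab.shape != ph.shape:
            raise ValueError("label and phase images must share a shape")
        if not np.issubdtype(lab.dtype, np.integer) or lab.min() < 0:
            raise ValueError("labels must be non-negative integers")

    def labels(self) -> np.ndarray:
        lab = np.unique(self.label_image)
        return lab[lab > 0]


@dataclass
class ColonyTrack:
    """Per-colony time series of centroids and per-frame labels."""

    colony_id: int
    frame_indices: list[int] = field(default_factory=list)
    timestamps_h: list[float] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    areas: list[float] = field(default_factory=list)
    full_length: bool = True

    def __len__(self) -> int:
        return len(self.frame_indices)


def _pixel_coords(frame: MaskFrame, colony_id: int) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.nonzero(frame.label_image == colony_id)
    if rows.size == 0:
        raise ValueError(
            f"colony {colony_id} absent from frame at t={frame.timestamp_h} h"
        )
    return rows, cols


def colony_area(frame: MaskFrame, colony_id: int, physical: bool = False) -> float:
    """Pixel count of the label; µm² when ``physical`` and pixel size known."""
    rows, _ = _pixel_coords(frame, colony_id)
    area = float(rows.size)
    if physical:
        if frame.pixel_size_um is None:
            raise ValueError("physical units requested but pixel_size_um unset")
        area *= frame.pixel_size_um ** 2
    return area


def centroid(frame: MaskFrame, colony_id: int) -> tuple[float, float]:
    """(row, col) centroid of the label's pixel set (pixel-centered)."""
    rows, cols = _pixel_coords(frame, colony_id)
    return float(rows.mean()), float(cols.mean())


def brightness_area_ratio(
    frame: MaskFrame,
    colony_id: int,
    k_sd: float = 2.0,
    absolute_threshold: float | None = None,
) -> float:
    """Fraction of colony pixels brighter than the threshold, in [0, 1].

    Default adaptive rule: intensity > within-colony mean + ``k_sd`` × SD.
    A fixed ``absolute_threshold`` overrides it. A constant-intensity colony
    under the adaptive rule yields 0 with a warning.
    """
    rows, cols = _pixel_coords(frame, colony_id)
    intens = frame.phase_image[rows, cols]
    if absolute_threshold is not None:
        thr = absolute_threshold
    else:
        sd = float(intens.std())
        if sd == 0.0:
            warnings.warn(
                f"colony {colony_id}: constant intensity, adaptive ratio is 0",
                stacklevel=2,
            )
            return 0.0
        thr = float(intens.mean()) + k_sd * sd
    return float(np.count_nonzero(intens > thr)) / intens.size


def axis_ratio(frame: MaskFrame, colony_id: int, min_area: int = 5) -> float:
    """Major/minor axis ratio of the moment-equivalent ellipse (>= 1)."""
    rows, cols = _pixel_coords(frame, colony_id)
    if rows.size < min_area:
        raise ValueError(
            f"colony {colony_id}: area {rows.size} px below minimum {min_area}"
        )
    coords = np.column_stack([rows, cols]).astype(float)
    cov = np.cov(coords, rowvar=False, bias=True)
    eigvals = np.sort(np.linalg.eigvalsh(cov))
    minor, major = eigvals
    if minor <= 0:  # degenerate line of pixels
        return float("inf")
    return float(np.sqrt(major / minor))


def track_colonies(
    movie: list[MaskFrame], gate_fraction: float = 0.25
) -> list[ColonyTrack]:
    """Link labels across frames by nearest centroid under a step gate.

    The gate is ``gate_fraction`` × the colony's equivalent diameter per
    frame. Conflicting candidates are resolved by minimal displacement
    (ties go to the lower label id, logged). Colonies that disappear are
    truncated and flagged ``full_length=False``; labels that appear
    mid-movie start new, non-full-length tracks.
    """
    if len(movie) < 2:
        raise ValueError("tracking needs >= 2 frames")
    tracks: list[ColonyTrack] = []
    for lab in movie[0].labels():
        tr = ColonyTrack(colony_id=int(lab))
        _append(tr, 0, movie[0], int(lab))
        tracks.append(tr)
    next_id = int(max((t.colony_id for t in tracks), default=0)) + 1

    for fi in range(1, len(movie)):
        frame = movie[fi]
        labels = [int(x) for x in frame.labels()]
        cents = {lab: centroid(frame, lab) for lab in labels}
        open_tracks = [t for t in tracks if t.frame_indices[-1] == fi - 1 and t.full_length]
        # candidate (distance, track, label) pairs within each track's gate
        candidates = []
        for tr in open_tracks:
            last = np.asarray(tr.centroids[-1])
            gate = gate_fraction * 2.0 * np.sqrt(tr.areas[-1] / np.pi)
            for lab in labels:
                d = float(np.hypot(*(np.asarray(cents[lab]) - last)))
                if d <= gate:
                    candidates.append((d, tr.colony_id, lab, tr))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        used_tracks: set[int] = set()
        used_labels: set[int] = set()
        for d, tid, lab, tr in candidates:
            if tid in used_tracks or lab in used_labels:
                continue
            _append(tr, fi, frame, lab)
            used_tracks.add(tid)
            used_labels.add(lab)
        for tr in open_tracks:
            if tr.colony_id not in used_tracks:
                tr.full_length = False  # lost: truncated
        for lab in labels:
            if lab not in used_labels:
                tr = ColonyTrack(colony_id=next_id, full_length=False)
                _append(tr, fi, frame, lab)
                tracks.append(tr)
                next_id += 1
    n_frames = len(movie)
    for tr in tracks:
        if len(tr) != n_frames:
            tr.full_length = False
    return tracks


def _append(tr: ColonyTrack, frame_index: int, frame: MaskFrame, label: int) -> None:
    tr.frame_indices.append(frame_index)
    tr.timestamps_h.append(frame.timestamp_h)
    tr.labels.append(label)
    tr.centroids.append(centroid(frame, label))
    tr.areas.append(colony_area(frame, label))


def motility_features(track: ColonyTrack) -> dict:
    """Total distance (path length) and total displacement of the centroid."""
    if len(track) < 2:
        raise ValueError("motility needs a track with >= 2 frames")
    pts = np.asarray(track.centroids, dtype=float)
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return {
        "total_distance": float(steps.sum()),
        "total_displacement": float(np.linalg.norm(pts[-1] - pts[0])),
    }


def normalize_series(values: np.ndarray) -> np.ndarray:
    """Divide a per-frame feature series by its first value (first == 1)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0 or values[0] <= 0:
        raise ValueError("first value must be positive for normalization")
    return values / values[0]


def feature_table(
    movie: list[MaskFrame],
    tracks: list[ColonyTrack] | None = None,
    full_length_only: bool = True,
    k_sd: float = 2.0,
) -> pd.DataFrame:
    """Tidy per-colony, per-frame feature table.

    Columns: colony_id, time_h, area, normalized_area, brightness_ratio,
    axis_ratio, cum_distance, displacement.
    """
    if tracks is None:
        tracks = track_colonies(movie)
    rows = []
    for tr in tracks:
        if full_length_only and not tr.full_length:
            continue
        pts = np.asarray(tr.centroids, dtype=float)
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        norm_area = normalize_series(np.asarray(tr.areas))
        for i, fi in enumerate(tr.frame_indices):
            frame = movie[fi]
            lab = tr.labels[i]
            rows.append({
                "colony_id": tr.colony_id,
                "time_h": tr.timestamps_h[i],
                "area": tr.areas[i],
                "normalized_area": norm_area[i],
                "brightness_ratio": brightness_area_ratio(frame, lab, k_sd=k_sd),
                "axis_ratio": axis_ratio(frame, lab),
                "cum_distance": float(cum[i]),
                "displacement": float(np.linalg.norm(pts[i] - pts[0])),
            })
    return pd.DataFrame(rows)
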