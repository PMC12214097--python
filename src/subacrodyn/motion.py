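"""Landmark-trajectory kinematics for dynamic subacromial ultrasound.

During repeated arm abduction/adduction the greater tuberosity of the humerus
rotates beneath the acromion. On a dynamic ultrasound clip both structures are
labeled frame by frame, and the vertical acromiohumeral distance (VAHD) is the
depth-axis offset of the greater tuberosity marker from the horizontal plane
through the lateral edge of the acromion. Each movement cycle produces a
"peak" of sub-acromial excursion (a local *minimum* of the VAHD series) framed
by two "troughs" (returns to neutral, local maxima). The minimal VAHD (mVAHD)
within the abduction phase (trough -> peak) and the adduction phase
(peak -> trough) of each cycle is the quantity of clinical interest, reported
per posture as Fab / Fad (full-can abduction / adduction) and Eab / Ead
(empty-can abduction / adduction), in centimeters.

Axis convention: y increases with depth from the transducer, so
``vahd = gt_y - acromion_y`` and smaller values mean a narrower subacromial
space. Negative values (greater tuberosity superficial to the acromial plane)
are retained and flagged, never clipped.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "TrajectoryClip",
    "RelativeTrack",
    "PhaseSegment",
    "MotionMetricsResult",
    "InsufficientCyclesError",
    "compute_relative_track",
    "resample_to_labeling_rate",
    "segment_cycles",
    "extract_mvahd",
    "metric_code",
    "read_clip_csv",
    "write_clip_csv",
]

Posture = Literal["full_can", "empty_can"]
Phase = Literal["abduction", "adduction"]

#: (posture, phase) -> conventional metric code
_METRIC_CODES = {
    ("full_can", "abduction"): "Fab",
    ("full_can", "adduction"): "Fad",
    ("empty_can", "abduction"): "Eab",
    ("empty_can", "adduction"): "Ead",
}

DEFAULT_SCAN_DEPTH_CM = 3.0  # 30 mm scanning depth
DEFAULT_LABELING_FPS = 4.0  # frames labeled per second
DEFAULT_MIN_PROMINENCE_CM = 0.1
DEFAULT_EXPECTED_CYCLES = 3


class InsufficientCyclesError(ValueError):
    """Raised when fewer complete trough-peak-trough cycles exist than requested."""

    def __init__(self, found: int, expected: int):
        self.found = found
        self.expected = expected
        super().__init__(
            f"insufficient cycles: found {found} complete trough-peak-trough "
            f"cycle(s), expected {expected}"
        )


def metric_code(posture: str, phase: str) -> str:
    """Return the conventional posture/phase code (Fab, Fad, Eab or Ead)."""
    try:
        return _METRIC_CODES[(posture, phase)]
    except KeyError:
        raise ValueError(f"unknown posture/phase pair: ({posture!r}, {phase!r})")


@dataclass
class TrajectoryClip:
    """Time-ordered landmark frames for one posture recording of one shoulder.

    Parameters
    ----------
    t
        Frame times in seconds since clip start, strictly increasing.
    acromion_xy, gt_xy
        ``(n, 2)`` arrays of landmark coordinates in cm: the lateral edge of
        the acromion and the greater tuberosity (or, when the tuberosity is
        unclear, the most prominent point of the humeral head; see
        ``landmark_source``). x is the mediolateral image axis, y is depth.
    fps
        Labeling rate in frames per second.
    scan_depth
        Imaging depth in cm; y coordinates must lie within ``[0, scan_depth]``.
    """

    t: np.ndarray
    acromion_xy: np.ndarray
    gt_xy: np.ndarray
    subject_id: str = ""
    side: Literal["left", "right"] = "right"
    posture: Posture = "full_can"
    fps: float = DEFAULT_LABELING_FPS
    landmark_source: Literal["greater_tuberosity", "humeral_prominence"] = (
        "greater_tuberosity"
    )
    scan_depth: float = DEFAULT_SCAN_DEPTH_CM

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acromion_xy = np.asarray(self.acromion_xy, dtype=float)
        self.gt_xy = np.asarray(self.gt_xy, dtype=float)

    def __len__(self) -> int:
        return self.t.shape[0]

    def validate(self) -> None:
        if self.acromion_xy.shape != (len(self), 2) or self.gt_xy.shape != (
            len(self),
            2,
        ):
            raise ValueError("landmark arrays must be (n_frames, 2)")
        for name, arr in (("t", self.t), ("acromion", self.acromion_xy),
                          ("gt", self.gt_xy)):
            bad = np.flatnonzero(~np.isfinite(arr).reshape(len(self), -1).all(axis=1))
            if bad.size:
                raise ValueError(
                    f"non-finite {name} coordinate at frame index {int(bad[0])}"
                )
        if np.any(self.t < 0):
            raise ValueError("frame times must be >= 0")
        if len(self) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        for name, y in (("acromion_y", self.acromion_xy[:, 1]),
                        ("gt_y", self.gt_xy[:, 1])):
            if np.any(y < 0) or np.any(y > self.scan_depth):
                raise ValueError(
                    f"{name} outside [0, {self.scan_depth}] cm scan depth"
                )

    def translated(self, dx: float, dy: float) -> "TrajectoryClip":
        """Return a copy with both landmarks shifted by the same vector."""
        off = np.array([dx, dy], dtype=float)
        return replace(
            self, acromion_xy=self.acromion_xy + off, gt_xy=self.gt_xy + off
        )


@dataclass
class RelativeTrack:
    """Greater-tuberosity position relative to the lateral acromion edge.

    ``dx = gt_x - acromion_x`` (positive toward medial) and
    ``vahd = gt_y - acromion_y`` (positive when the tuberosity lies deeper
    than the acromial plane). Same length and times as the source clip.
    """

    t: np.ndarray
    dx: np.ndarray
    vahd: np.ndarray

    def __len__(self) -> int:
        return self.t.shape[0]


@dataclass(frozen=True)
class PhaseSegment:
    """One movement-phase span of a cycle, by inclusive frame indices."""

    phase: Phase
    cycle_index: int  # 1-based
    start_idx: int
    end_idx: int

    def __post_init__(self) -> None:
        if self.start_idx >= self.end_idx:
            raise ValueError("start_idx must be < end_idx")
        if self.cycle_index < 1:
            raise ValueError("cycle_index is 1-based")


@dataclass
class MotionMetricsResult:
    """Per-posture, per-phase minimal VAHD with per-cycle detail (cm)."""

    posture: Posture
    per_cycle_minima: pd.DataFrame  # index cycle_index, columns abduction/adduction
    mvahd_ab: float
    mvahd_ad: float
    aggregation: Literal["mean_of_cycle_minima", "global_min"]
    n_cycles: int
    warnings: list[str] = field(default_factory=list)

    @property
    def metric_keys(self) -> dict[str, str]:
        """Phase -> conventional metric code for this posture."""
        return {ph: metric_code(self.posture, ph) for ph in ("abduction", "adduction")}

    def as_dict(self) -> dict:
        return {
            "posture": self.posture,
            "aggregation": self.aggregation,
            "n_cycles": self.n_cycles,
            metric_code(self.posture, "abduction"): self.mvahd_ab,
            metric_code(self.posture, "adduction"): self.mvahd_ad,
            "per_cycle_minima": {
                phase: [float(v) for v in self.per_cycle_minima[phase]]
                for phase in self.per_cycle_minima.columns
            },
            "warnings": list(self.warnings),
        }


def compute_relative_track(clip: TrajectoryClip) -> RelativeTrack:
    """Express the greater tuberosity relative to the acromion's lateral edge.

    Raises ``ValueError`` (with the frame index) on non-finite coordinates.
    Negative VAHD frames are kept but reported via ``warnings.warn``.
    """
    clip.validate()
    dx = clip.gt_xy[:, 0] - clip.acromion_xy[:, 0]
    vahd = clip.gt_xy[:, 1] - clip.acromion_xy[:, 1]
    n_neg = int(np.sum(vahd < 0))
    if n_neg:
        warnings.warn(
            f"{n_neg} frame(s) with negative VAHD (greater tuberosity superficial "
            "to the acromial plane); values retained",
            stacklevel=2,
        )
    return RelativeTrack(t=clip.t.copy(), dx=dx, vahd=vahd)


def resample_to_labeling_rate(
    clip: TrajectoryClip, target_fps: float = DEFAULT_LABELING_FPS
) -> TrajectoryClip:
    """Decimate a clip to the labeling rate by nearest-time frame selection.

    Acquisition runs at a high frame rate (e.g. 300 fps) but landmarks are
    labeled on a sparser grid (default 4 fps). Frames nearest to the target
    time grid are retained with their original timestamps; no upsampling.
    """
    if target_fps <= 0:
        raise ValueError("target_fps must be positive")
    if target_fps > clip.fps:
        raise ValueError(
            f"target_fps ({target_fps}) exceeds source fps ({clip.fps}); "
            "upsampling is not supported"
        )
    t = clip.t
    n_grid = int(np.floor((t[-1] - t[0]) * target_fps)) + 1
    grid = t[0] + np.arange(n_grid) / target_fps
    # nearest source frame per grid time; ties resolve to the earlier frame
    pos = np.searchsorted(t, grid)
    pos = np.clip(pos, 1, len(t) - 1)
    left, right = t[pos - 1], t[pos]
    idx = np.where(grid - left <= right - grid, pos - 1, pos)
    idx = np.unique(idx)  # sorted, deduplicated
    return replace(
        clip,
        t=t[idx],
        acromion_xy=clip.acromion_xy[idx],
        gt_xy=clip.gt_xy[idx],
        fps=target_fps,
    )


def _local_maximum(vahd: np.ndarray, lo: int, hi: int) -> int:
    """Index of the maximum of vahd on [lo, hi]; plateau ties -> earliest."""
    return lo + int(np.argmax(vahd[lo : hi + 1]))


def segment_cycles(
    track: RelativeTrack,
    min_prominence: float = DEFAULT_MIN_PROMINENCE_CM,
    expected_cycles: int = DEFAULT_EXPECTED_CYCLES,
) -> list[PhaseSegment]:
    """Split the VAHD time-location curve into abduction/adduction segments.

    Local minima of the VAHD series with prominence >= ``min_prominence`` are
    the excursion peaks (greater tuberosity beneath the acromion); the local
    maxima bounding each peak are the troughs (neutral position). Abduction
    spans trough -> peak, adduction spans peak -> trough, both inclusive of
    their boundary indices (phase membership of the shared peak frame is
    decided downstream at minima extraction). The first ``expected_cycles``
    complete cycles are returned.

    Raises
    ------
    InsufficientCyclesError
        If fewer than ``expected_cycles`` complete trough-peak-trough cycles
        are found (including the flat-series case).
    """
    if len(track) < 8:
        raise ValueError("at least 8 frames are required for segmentation")
    if min_prominence <= 0:
        raise ValueError("min_prominence must be positive")
    if expected_cycles < 1:
        raise ValueError("expected_cycles must be >= 1")
    vahd = track.vahd
    peaks, _ = find_peaks(-vahd, prominence=min_prominence)
    n = len(vahd)
    cycles: list[tuple[int, int, int]] = []  # (left trough, peak, right trough)
    for k, p in enumerate(peaks):
        lo = peaks[k - 1] if k > 0 else 0
        hi = peaks[k + 1] if k + 1 < len(peaks) else n - 1
        left = _local_maximum(vahd, lo, p)
        right = _local_maximum(vahd, p, hi)
        if left < p < right:
            cycles.append((left, p, right))
    if len(cycles) < expected_cycles:
        raise InsufficientCyclesError(found=len(cycles), expected=expected_cycles)
    segments: list[PhaseSegment] = []
    for i, (left, p, right) in enumerate(cycles[:expected_cycles], start=1):
        segments.append(PhaseSegment("abduction", i, left, p))
        segments.append(PhaseSegment("adduction", i, p, right))
    return segments


def extract_mvahd(
    clip: TrajectoryClip,
    min_prominence: float = DEFAULT_MIN_PROMINENCE_CM,
    expected_cycles: int = DEFAULT_EXPECTED_CYCLES,
    aggregation: Literal["mean_of_cycle_minima", "global_min"] = "mean_of_cycle_minima",
    peak_membership: Literal["abduction", "both"] = "abduction",
) -> MotionMetricsResult:
    """Extract per-phase minimal VAHD values from a labeled clip.

    Per cycle and phase the minimum VAHD over the segment's frames is taken;
    the posture-level mVAHD is the mean of the per-cycle minima (default) or
    the global minimum over all frames of that phase.

    ``peak_membership`` decides which phase owns the shared excursion-peak
    frame. The default assigns it to abduction (the descending limb ends at
    the peak; adduction starts at the following frame), which makes the two
    phase minima separately identifiable; ``"both"`` includes the peak frame
    in both phases, in which case the adduction minimum can never exceed the
    abduction minimum.
    """
    if aggregation not in ("mean_of_cycle_minima", "global_min"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    result_warnings: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        track = compute_relative_track(clip)
    result_warnings.extend(str(w.message) for w in caught)
    segments = segment_cycles(track, min_prominence, expected_cycles)

    minima: dict[str, dict[int, float]] = {"abduction": {}, "adduction": {}}
    for seg in segments:
        start = seg.start_idx
        if seg.phase == "adduction" and peak_membership == "abduction":
            start = seg.start_idx + 1
        if start > seg.end_idx:
            raise ValueError("empty adduction segment after peak-frame exclusion")
        minima[seg.phase][seg.cycle_index] = float(
            np.min(track.vahd[start : seg.end_idx + 1])
        )
    per_cycle = pd.DataFrame(minima).sort_index()
    per_cycle.index.name = "cycle_index"
    if per_cycle.empty:
        raise ValueError("aggregation over zero cycles")
    if aggregation == "mean_of_cycle_minima":
        mvahd_ab = float(per_cycle["abduction"].mean())
        mvahd_ad = float(per_cycle["adduction"].mean())
    else:
        mvahd_ab = float(per_cycle["abduction"].min())
        mvahd_ad = float(per_cycle["adduction"].min())
    return MotionMetricsResult(
        posture=clip.posture,
        per_cycle_minima=per_cycle,
        mvahd_ab=mvahd_ab,
        mvahd_ad=mvahd_ad,
        aggregation=aggregation,
        n_cycles=len(per_cycle),
        warnings=result_warnings,
    )


# ---------------------------------------------------------------------------
# Landmark CSV I/O
#
# One clip per file. Header comment lines carry clip metadata
# (#subject=, #side=, #posture=, #fps=, #landmark_source=), followed by
#   frame,t_s,acromion_x_cm,acromion_y_cm,gt_x_cm,gt_y_cm,landmark_source

_CLIP_COLUMNS = [
    "frame",
    "t_s",
    "acromion_x_cm",
    "acromion_y_cm",
    "gt_x_cm",
    "gt_y_cm",
    "landmark_source",
]


def read_clip_csv(path: str | Path) -> TrajectoryClip:
    """Read a landmark trajectory CSV (with ``#key=value`` metadata lines)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _CLIP_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    source = meta.get("landmark_source")
    if source is None and "landmark_source" in df.columns:
        source = str(df["landmark_source"].iloc[0])
    clip = TrajectoryClip(
        t=df["t_s"].to_numpy(),
        acromion_xy=df[["acromion_x_cm", "acromion_y_cm"]].to_numpy(),
        gt_xy=df[["gt_x_cm", "gt_y_cm"]].to_numpy(),
        subject_id=meta.get("subject", path.stem),
        side=meta.get("side", "right"),  # type: ignore[arg-type]
        posture=meta.get("posture", "full_can"),  # type: ignore[arg-type]
        fps=float(meta.get("fps", DEFAULT_LABELING_FPS)),
        landmark_source=source or "greater_tuberosity",  # type: ignore[arg-type]
        scan_depth=float(meta.get("scan_depth", DEFAULT_SCAN_DEPTH_CM)),
    )
    clip.validate()
    return clip


def write_clip_csv(clip: TrajectoryClip, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"#subject={clip.subject_id}\n"
        f"#side={clip.side}\n"
        f"#posture={clip.posture}\n"
        f"#fps={clip.fps}\n"
        f"#scan_depth={clip.scan_depth}\n"
        f"#landmark_source={clip.landmark_source}\n"
    )
    df = pd.DataFrame(
        {
            "frame": np.arange(len(clip)),
            "t_s": clip.t,
            "acromion_x_cm": clip.acromion_xy[:, 0],
            "acromion_y_cm": clip.acromion_xy[:, 1],
            "gt_x_cm": clip.gt_xy[:, 0],
            "gt_y_cm": clip.gt_xy[:, 1],
            "landmark_source": clip.landmark_source,
        }
    )
    with path.open("w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
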