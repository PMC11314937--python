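"""Trajectory clustering, speed statistics and passage filtering.

After layer sorting, each layer of the information matrix carries
piecewise-continuous trajectories.  A *cluster* is one contiguous run of
present detections on one layer, interpreted as a single candidate duct
passage.  Counting then applies two physical plausibility filters:

* Criterion 3 — clusters spanning fewer than ``min_cluster_size`` frames
  are rejected.  The threshold is anchored in the speed distribution of
  the crickets: a genuine passage shorter than 15 frames would require a
  speed above the 95th percentile (about 120 px/frame against a mean of
  50), so such clusters are overwhelmingly detector noise.
* Criterion 4 — clusters whose net x-displacement is negative travelled
  back toward the origin box and are discarded (the animal never reached
  the destination box).

Cluster boundaries are defined by absence (any missing run longer than
``gap_tolerance_frames`` splits) and, additionally, by implausibly large
single-step jumps: when one passage ends at the duct exit and another
individual's detections continue on the same layer without an empty
frame in between, the positional discontinuity — far larger than any
cricket moves in one frame — marks the passage boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .stream_model import InfoMatrix

__all__ = [
    "TrajectoryCluster",
    "SpeedStats",
    "CountingConfig",
    "FilterResult",
    "segment_clusters",
    "speed_stats",
    "filter_clusters",
    "count_passages",
    "clusters_to_table",
]

DirectionMode = Literal["discard_backward", "net_flow", "keep_all"]


@dataclass
class CountingConfig:
    """Tunable constants of the counting stage.

    min_cluster_size:
        Minimum number of detection frames for a cluster to count as a
        passage (default 15, the frame count a passage at the 95th
        percentile speed needs to traverse the duct).
    gap_tolerance_frames:
        Missing runs up to this length are bridged inside a cluster
        (default 0: every absence splits).
    direction_mode:
        ``discard_backward`` rejects net-backward clusters,
        ``net_flow`` counts forward minus backward, ``keep_all`` counts
        every kept cluster.
    fps:
        Acquisition frame rate, frames per second.
    pixel_pitch_um:
        Physical size of one pixel in micrometres; converts px/frame
        speeds to mm/s via ``mm/s = px/frame * fps * pitch_mm``.
    jump_split_px:
        Single-step displacement above which a cluster is split even
        without a missing frame (``None`` disables).  The default, 400 px,
        sits more than three times above the 95th-percentile per-frame
        displacement, so no plausible within-passage step triggers it.
    """

    min_cluster_size: int = 15
    gap_tolerance_frames: int = 0
    direction_mode: DirectionMode = "discard_backward"
    fps: float = 5.0
    pixel_pitch_um: float = 48.1
    jump_split_px: float | None = 400.0

    def __post_init__(self) -> None:
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.gap_tolerance_frames < 0:
            raise ValueError("gap_tolerance_frames must be >= 0")
        if self.direction_mode not in ("discard_backward", "net_flow", "keep_all"):
            raise ValueError(f"unknown direction_mode {self.direction_mode!r}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


@dataclass
class TrajectoryCluster:
    """One contiguous candidate passage on one layer."""

    layer: int
    frames: np.ndarray  # strictly increasing frame indices
    xs: np.ndarray
    ys: np.ndarray
    classes: np.ndarray  # per-frame sex votes (0 male / 1 female)
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        self.classes = np.asarray(self.classes, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.frames.size < 1:
            raise ValueError("cluster must contain at least one frame")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("cluster frames must be strictly increasing")

    @property
    def size(self) -> int:
        return int(self.frames.size)

    @property
    def net_dx(self) -> float:
        """x(last) - x(first), px; its sign defines crossing direction."""
        return float(self.xs[-1] - self.xs[0])

    @property
    def direction(self) -> str:
        return "forward" if self.net_dx > 0 else "backward"

    @property
    def step_speeds(self) -> np.ndarray:
        """Per-step speeds in px/frame (distance over frame gap)."""
        if self.size < 2:
            return np.empty(0)
        d = np.hypot(np.diff(self.xs), np.diff(self.ys))
        return d / np.diff(self.frames)

    @property
    def mean_speed(self) -> float:
        """Mean per-step speed, px/frame (0 for singleton clusters)."""
        s = self.step_speeds
        return float(s.mean()) if s.size else 0.0


def segment_clusters(
    matrix: InfoMatrix,
    gap_tolerance: int = 0,
    jump_split_px: float | None = 400.0,
) -> list[TrajectoryCluster]:
    """Cut each layer's trajectory into candidate passages.

    Boundaries fall at missing runs longer than ``gap_tolerance`` and at
    single-step jumps exceeding ``jump_split_px``.  Every present
    detection belongs to exactly one cluster.
    """
    clusters: list[TrajectoryCluster] = []
    per_layer: dict[int, list] = {}
    for (f, lay) in sorted(matrix.records):
        per_layer.setdefault(lay, []).append(matrix.records[(f, lay)])

    for lay in sorted(per_layer):
        recs = per_layer[lay]
        runs: list[list] = [[recs[0]]]
        for prev, rec in zip(recs[:-1], recs[1:]):
            split = rec.frame - prev.frame > gap_tolerance + 1
            if not split and jump_split_px is not None:
                jump = np.hypot(rec.cx - prev.cx, rec.cy - prev.cy)
                split = jump > jump_split_px
            if split:
                runs.append([])
            runs[-1].append(rec)
        for run in runs:
            clusters.append(
                TrajectoryCluster(
                    layer=lay,
                    frames=np.array([r.frame for r in run]),
                    xs=np.array([r.cx for r in run]),
                    ys=np.array([r.cy for r in run]),
                    classes=np.array([r.sex_class for r in run]),
                    probs=np.array([r.prob for r in run]),
                )
            )
    return clusters


@dataclass
class SpeedStats:
    """Pooled per-step speed distribution of a set of clusters."""

    mean_px_per_frame: float
    p95_px_per_frame: float
    histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin edges)
    mean_mm_per_s: float
    n_steps: int

    def to_dict(self) -> dict:
        counts, edges = self.histogram
        return {
            "mean_px_per_frame": self.mean_px_per_frame,
            "p95_px_per_frame": self.p95_px_per_frame,
            "mean_mm_per_s": self.mean_mm_per_s,
            "n_steps": self.n_steps,
            "histogram_counts": counts.tolist(),
            "histogram_edges": edges.tolist(),
        }


def speed_stats(
    clusters: Sequence[TrajectoryCluster],
    config: CountingConfig | None = None,
    bins: int = 40,
) -> SpeedStats:
    """Pooled speed statistics over all cluster steps.

    Speeds are pooled per step (not per cluster mean), matching a
    per-frame histogram.  The 95th percentile uses the linear
    interpolation definition.  Raises ``ValueError`` when every cluster
    is a singleton (no steps to measure).
    """
    if config is None:
        config = CountingConfig()
    speeds = np.concatenate(
        [c.step_speeds for c in clusters] or [np.empty(0)]
    )
    if speeds.size == 0:
        raise ValueError("speed statistics undefined: no cluster has >= 2 frames")
    mean = float(speeds.mean())
    p95 = float(np.percentile(speeds, 95))
    hist = np.histogram(speeds, bins=bins)
    mm_per_s = mean * config.fps * config.pixel_pitch_um / 1000.0
    return SpeedStats(mean, p95, hist, mm_per_s, int(speeds.size))


@dataclass
class FilterResult:
    """Exhaustive, disjoint partition of the candidate clusters."""

    kept: list[TrajectoryCluster] = field(default_factory=list)
    rejected_small: list[TrajectoryCluster] = field(default_factory=list)
    rejected_backward: list[TrajectoryCluster] = field(default_factory=list)


def filter_clusters(
    clusters: Iterable[TrajectoryCluster], config: CountingConfig
) -> FilterResult:
    """Apply Criterion 3 (minimum size) and Criterion 4 (direction).

    A cluster is ``rejected_small`` iff its size is below
    ``min_cluster_size``; among the remainder, ``rejected_backward`` iff
    it travelled net backward and ``direction_mode`` is
    ``discard_backward``.  Under ``net_flow`` and ``keep_all`` backward
    clusters stay in ``kept`` (net-flow accounting happens at counting
    time).
    """
    res = FilterResult()
    for c in clusters:
        if c.size < config.min_cluster_size:
            res.rejected_small.append(c)
        elif config.direction_mode == "discard_backward" and c.direction == "backward":
            res.rejected_backward.append(c)
        else:
            res.kept.append(c)
    return res


def count_passages(kept_clusters: Sequence[TrajectoryCluster]) -> int:
    """Each kept cluster is one counted individual passage."""
    return len(kept_clusters)


def clusters_to_table(
    result: FilterResult, sexes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Flatten a filter result into an auditable cluster table.

    ``sexes`` optionally provides the per-kept-cluster sex decision (in
    the order of ``result.kept``) to append as a column.
    """
    rows = []
    groups = [
        (result.kept, True, ""),
        (result.rejected_small, False, "small"),
        (result.rejected_backward, False, "backward"),
    ]
    kept_idx = 0
    for clusters, kept, reason in groups:
        for c in clusters:
            sex = ""
            if kept and sexes is not None:
                sex = sexes[kept_idx]
                kept_idx += 1
            rows.append(
                {
                    "layer": c.layer,
                    "first_frame": int(c.frames[0]),
                    "last_frame": int(c.frames[-1]),
                    "size": c.size,
                    "net_dx": c.net_dx,
                    "mean_speed": c.mean_speed,
                    "direction": c.direction,
                    "kept": kept,
                    "rejection_reason": reason,
                    "sex": sex,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "layer",
            "first_frame",
            "last_frame",
            "size",
            "net_dx",
            "mean_speed",
            "direction",
            "kept",
            "rejection_reason",
            "sex",
        ],
    )
    df = df.sort_values(["first_frame", "layer"], kind="stable").reset_index(drop=True)
    df.insert(0, "cluster_id", np.arange(len(df)))
    return df
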