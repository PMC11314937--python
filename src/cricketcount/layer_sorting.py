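"""Kinematic layer sorting (Criterion 2).

The upstream detector fills layers in an arbitrary per-frame order, so
when two crickets share the duct the same individual may sit on layer 1
in one frame and on layer 2 in the next.  Sorting relabels the layer
slots so that each individual keeps a continuous trajectory: a slot
exchange is performed at a frame when *both* cross-layer velocities are
lower in magnitude than both straight velocities, with an acceleration
comparison breaking inconclusive cases.  Velocities bridge runs of
missing frames: across a gap the finite difference is taken between the
frames flanking the gap, divided by the elapsed time.

The pass is greedy and left-to-right; every decision is conditioned on
the already-sorted past.  Records move as whole 4-field units (class and
confidence travel with the centroid), so the per-frame multiset of
detections is preserved exactly.  A frame holding a single detection may
likewise be moved to the other slot when continuity demands it — this is
what keeps an individual on layer 2 for its whole passage after its
companion has left the duct — which means a sorted matrix need not be
layer-dense any more.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .stream_model import DetectionRecord, InfoMatrix

__all__ = [
    "LayerTrack",
    "SortDiagnostics",
    "gap_velocity",
    "gap_acceleration",
    "sort_layers",
    "total_speed_objective",
]

SwapRule = Literal["conjunctive", "summed"]


@dataclass
class LayerTrack:
    """Positions of one layer over the full frame range of a stream.

    ``positions`` is an ``(n_frames, 2)`` array of centroid coordinates
    in pixels with NaN rows where the layer is empty.  Gaps (missing
    runs) are allowed and are bridged by the velocity / acceleration
    helpers below.
    """

    layer: int
    positions: np.ndarray

    @classmethod
    def from_matrix(cls, matrix: InfoMatrix, layer: int) -> "LayerTrack":
        return cls(layer=layer, positions=matrix.layer_positions(layer))

    def present(self, frame: int) -> bool:
        return bool(np.isfinite(self.positions[frame]).all())

    def prev_present(self, frame: int) -> int | None:
        """Last frame strictly before ``frame`` with a defined position."""
        for f in range(frame - 1, -1, -1):
            if self.present(f):
                return f
        return None


def gap_velocity(track: LayerTrack, frame: int, dt: float) -> np.ndarray | None:
    """Gap-bridging velocity (px/s per axis) of a track at ``frame``.

    ``v(f) = (p(f) - p(f')) / (t(f) - t(f'))`` where ``f'`` is the last
    present frame before ``f``; for consecutive present frames this is
    the ordinary one-step finite difference.  Returns ``None`` when
    either endpoint is missing (missing in, missing out).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if frame < 0 or frame >= len(track.positions) or not track.present(frame):
        return None
    f_prev = track.prev_present(frame)
    if f_prev is None:
        return None
    return (track.positions[frame] - track.positions[f_prev]) / ((frame - f_prev) * dt)


def gap_acceleration(track: LayerTrack, frame: int, dt: float) -> np.ndarray | None:
    """Gap-bridging acceleration (px/s^2 per axis) of a track at ``frame``.

    Finite difference of :func:`gap_velocity` between ``frame`` and the
    preceding present frame; ``None`` whenever either bracketing velocity
    is undefined.
    """
    v_here = gap_velocity(track, frame, dt)
    if v_here is None:
        return None
    f_prev = track.prev_present(frame)
    assert f_prev is not None  # v_here defined implies a previous frame
    v_prev = gap_velocity(track, f_prev, dt)
    if v_prev is None:
        return None
    return (v_here - v_prev) / ((frame - f_prev) * dt)


@dataclass
class SortDiagnostics:
    """Audit record of one sorting pass."""

    swapped_frames: list[int] = field(default_factory=list)
    objective_before: float = 0.0  # summed |v| over both layers, px/s
    objective_after: float = 0.0

    def to_dict(self) -> dict:
        return {
            "swapped_frames": list(self.swapped_frames),
            "objective_before": self.objective_before,
            "objective_after": self.objective_after,
        }


def total_speed_objective(matrix: InfoMatrix, dt: float | None = None) -> float:
    """Summed gap-velocity magnitude (px/s) over all layers and frames."""
    if dt is None:
        dt = matrix.dt
    total = 0.0
    for layer in range(1, max(matrix.n_layers, 1) + 1):
        track = LayerTrack.from_matrix(matrix, layer)
        present = np.flatnonzero(np.isfinite(track.positions[:, 0]))
        for f0, f1 in zip(present[:-1], present[1:]):
            step = (track.positions[f1] - track.positions[f0]) / ((f1 - f0) * dt)
            total += float(np.hypot(*step))
    return total


@dataclass
class _TrackState:
    """Per-slot running history used by the greedy pass."""

    last_frame: int | None = None
    last_pos: np.ndarray | None = None
    last_vel: np.ndarray | None = None  # velocity at last_frame, px/s

    def velocity_to(
        self, pos: np.ndarray, frame: int, dt: float, max_link_gap: int | None
    ) -> np.ndarray | None:
        if self.last_frame is None:
            return None
        gap = frame - self.last_frame
        if max_link_gap is not None and gap > max_link_gap:
            return None  # history too stale to carry continuity evidence
        return (pos - self.last_pos) / (gap * dt)

    def acceleration_to(
        self, pos: np.ndarray, frame: int, dt: float, max_link_gap: int | None
    ) -> np.ndarray | None:
        v = self.velocity_to(pos, frame, dt, max_link_gap)
        if v is None or self.last_vel is None:
            return None
        return (v - self.last_vel) / ((frame - self.last_frame) * dt)

    def append(self, pos: np.ndarray, frame: int, dt: float) -> None:
        if self.last_frame is not None:
            self.last_vel = (pos - self.last_pos) / ((frame - self.last_frame) * dt)
        self.last_frame = frame
        self.last_pos = pos


def _norm(v: np.ndarray | None) -> float | None:
    return None if v is None else float(np.hypot(*v))


def _should_swap(
    tracks: tuple[_TrackState, _TrackState],
    contents: tuple[DetectionRecord | None, DetectionRecord | None],
    frame: int,
    dt: float,
    rule: SwapRule,
    max_link_gap: int | None,
    plausible_step_px: float,
) -> bool:
    """Decide whether to exchange the two slot contents at ``frame``.

    ``straight`` terms are the velocities each track would take by
    keeping the emitted arrangement, ``cross`` terms the velocities under
    the exchange.  Undefined terms (a track with no usable past offers no
    continuity evidence) are excluded from the comparison; with no
    defined evidence at all the frame is left as emitted.
    """
    c1, c2 = contents
    t1, t2 = tracks
    pos = {
        i: np.array([c.cx, c.cy]) if c is not None else None
        for i, c in ((0, c1), (1, c2))
    }

    def vel(track_idx: int, cand_idx: int) -> float | None:
        p = pos[cand_idx]
        if p is None:
            return None
        return _norm(tracks[track_idx].velocity_to(p, frame, dt, max_link_gap))

    if (c1 is None) != (c2 is None):
        # Single detection: decide which track it continues.  Raw
        # gap-bridged velocity magnitudes are not comparable here — a
        # staler track's velocity is diluted by its longer gap, and
        # magnitude alone ignores direction (a track moving forward is
        # not continued by a detection "reached" at high backward speed).
        # Score each track by how far the hypothesised velocity deviates
        # from its last observed velocity; fall back to the magnitude
        # when a track has no velocity history yet.
        this_idx = 0 if c1 is not None else 1
        p = pos[this_idx]
        t_this, t_other = tracks[this_idx], tracks[1 - this_idx]
        if t_this.last_frame is not None and (
            t_other.last_frame is None or t_other.last_frame < t_this.last_frame
        ):
            return False  # receiving track staler than the emitted slot's

        def score(track: _TrackState) -> tuple[float | None, np.ndarray | None]:
            v = track.velocity_to(p, frame, dt, max_link_gap)
            if v is None:
                return None, None
            if track.last_vel is None:
                return _norm(v), v
            return _norm(v - track.last_vel), v

        s_this, _ = score(t_this)
        s_other, v_other = score(t_other)
        if s_other is None:
            return False
        if s_this is None:
            # The emitted slot's track is dead (no usable history): follow
            # the live track instead, but only when the implied step is a
            # physically plausible cricket move — otherwise this is a
            # fresh entry that must not be captured by an old trajectory.
            return _norm(v_other) * dt <= plausible_step_px
        return s_other < s_this

    # Two detections: undefined velocity terms (a track that just
    # appeared, or whose history is too stale) are excluded from the
    # comparison; with no defined term on either side there is no
    # continuity evidence and the frame is never swapped.
    s_vals = [v for i in (0, 1) if pos[i] is not None
              and (v := vel(i, i)) is not None]
    c_vals = [v for i in (0, 1) if pos[1 - i] is not None
              and (v := vel(i, 1 - i)) is not None]
    if not s_vals or not c_vals:
        return False

    if rule == "summed":
        if sum(c_vals) < sum(s_vals):
            return True
        if sum(c_vals) > sum(s_vals):
            return False
    else:
        if max(c_vals) < min(s_vals):
            return True
        if max(s_vals) < min(c_vals):
            return False

    # Velocity comparison inconclusive: fall back to acceleration.
    def acc(track_idx: int, cand_idx: int) -> float | None:
        p = pos[cand_idx]
        if p is None:
            return None
        return _norm(tracks[track_idx].acceleration_to(p, frame, dt, max_link_gap))

    a_straight = [a for i in (0, 1) if pos[i] is not None
                  and (a := acc(i, i)) is not None]
    a_cross = [a for i in (0, 1) if pos[1 - i] is not None
               and (a := acc(i, 1 - i)) is not None]
    if not a_straight or not a_cross:
        return False
    return sum(a_cross) < sum(a_straight)  # still tied -> keep


def sort_layers(
    matrix: InfoMatrix,
    dt: float | None = None,
    *,
    rule: SwapRule = "conjunctive",
    max_link_gap: int | None = 25,
    plausible_step_px: float = 400.0,
) -> tuple[InfoMatrix, SortDiagnostics]:
    """Relabel the two layer slots so each individual keeps one layer.

    Parameters
    ----------
    matrix:
        Detection stream truncated to at most two layers (apply
        :func:`cricketcount.stream_model.truncate_layers` first).
    dt:
        Frame period in seconds; defaults to ``1 / matrix.fps``.
    rule:
        ``"conjunctive"`` swaps only when both cross velocities are
        strictly lower than both straight velocities (acceleration breaks
        mixed verdicts); ``"summed"`` compares the summed velocity
        magnitudes instead.
    max_link_gap:
        Longest missing run, in frames, across which a track still
        carries continuity evidence.  Beyond it a reappearing detection
        is treated as a fresh entry rather than linked to a passage long
        gone.  ``None`` disables the limit.
    plausible_step_px:
        Largest single-frame displacement a cricket is credited with;
        used when a lone detection must choose between a dead slot and a
        live track on the other layer.

    Returns the sorted matrix (which may no longer be layer-dense) and
    diagnostics listing the exchanged frames and the summed-speed
    objective before and after.
    """
    if matrix.n_layers > 2:
        raise ValueError(
            "sort_layers requires at most 2 layers; apply truncate_layers first"
        )
    if dt is None:
        dt = matrix.dt
    if dt <= 0:
        raise ValueError("dt must be positive")

    out: dict[tuple[int, int], DetectionRecord] = {}
    tracks = (_TrackState(), _TrackState())
    diag = SortDiagnostics(objective_before=total_speed_objective(matrix, dt))

    index = matrix.by_frame()
    for f in sorted(index):
        slots: list[DetectionRecord | None] = [None, None]
        for rec in index[f]:
            slots[rec.layer - 1] = rec
        c1, c2 = slots
        if c1 is None and c2 is None:
            continue
        if _should_swap(tracks, (c1, c2), f, dt, rule, max_link_gap,
                        plausible_step_px):
            c1, c2 = c2, c1
            diag.swapped_frames.append(f)
        for slot_idx, rec in enumerate((c1, c2)):
            if rec is None:
                continue
            pos = np.array([rec.cx, rec.cy])
            tracks[slot_idx].append(pos, f, dt)
            out[(f, slot_idx + 1)] = replace(rec, layer=slot_idx + 1)

    sorted_matrix = replace(matrix, records=out)
    diag.objective_after = total_speed_objective(sorted_matrix, dt)
    return sorted_matrix, diag
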