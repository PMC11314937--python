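"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and shares no code with the
package's implementations: costs are recomputed from positions alone,
and the sorting oracle enumerates every swap pattern instead of running
a greedy pass.
"""

from __future__ import annotations

import itertools

import numpy as np

from cricketcount import InfoMatrix


def naive_gap_velocity(positions: np.ndarray, frame: int, dt: float):
    """Recompute the gap-bridging velocity from a position array alone."""
    if frame >= len(positions) or not np.isfinite(positions[frame]).all():
        return None
    prev = [f for f in range(frame) if np.isfinite(positions[f]).all()]
    if not prev:
        return None
    f0 = prev[-1]
    return (positions[frame] - positions[f0]) / ((frame - f0) * dt)


def naive_gap_acceleration(positions: np.ndarray, frame: int, dt: float):
    v1 = naive_gap_velocity(positions, frame, dt)
    if v1 is None:
        return None
    prev = [f for f in range(frame) if np.isfinite(positions[f]).all()]
    f0 = prev[-1]
    v0 = naive_gap_velocity(positions, f0, dt)
    if v0 is None:
        return None
    return (v1 - v0) / ((frame - f0) * dt)


def squared_speed_cost(matrix: InfoMatrix) -> float:
    """Summed squared gap-bridged step speed (px/frame)^2 over all layers."""
    cost = 0.0
    for layer in range(1, max(matrix.n_layers, 1) + 1):
        pts = sorted(
            (f, matrix.records[(f, lay)])
            for (f, lay) in matrix.records
            if lay == layer
        )
        for (f0, r0), (f1, r1) in zip(pts[:-1], pts[1:]):
            v = np.array([r1.cx - r0.cx, r1.cy - r0.cy]) / (f1 - f0)
            cost += float(v @ v)
    return cost


def brute_force_sort(matrix: InfoMatrix) -> tuple[float, InfoMatrix]:
    """Globally optimal layer assignment by exhaustive search.

    Enumerates all 2^(#two-detection frames) swap patterns (frames with a
    single detection keep layer 1) and returns the assignment minimising
    the summed squared gap-bridged velocity, together with its cost.
    """
    index = matrix.by_frame()
    two_det_frames = [f for f, recs in index.items() if len(recs) == 2]
    best_cost = np.inf
    best = None
    for pattern in itertools.product([False, True], repeat=len(two_det_frames)):
        swapped = dict(zip(two_det_frames, pattern))
        records = {}
        for f, recs in index.items():
            recs = list(recs)
            if swapped.get(f):
                recs = recs[::-1]
            for lay, rec in enumerate(recs, start=1):
                records[(f, lay)] = rec.__class__(
                    rec.frame, lay, rec.sex_class, rec.prob, rec.cx, rec.cy
                )
        candidate = InfoMatrix(
            n_frames=matrix.n_frames,
            fps=matrix.fps,
            frame_width=matrix.frame_width,
            frame_height=matrix.frame_height,
            records=records,
        )
        cost = squared_speed_cost(candidate)
        if cost < best_cost:
            best_cost = cost
            best = candidate
    assert best is not None
    return best_cost, best


def layer1_run_count(matrix: InfoMatrix) -> int:
    """Presence runs on layer 1 alone: the transparent uncorrected baseline."""
    frames = sorted(f for (f, lay) in matrix.records if lay == 1)
    if not frames:
        return 0
    return 1 + sum(f1 - f0 > 1 for f0, f1 in zip(frames[:-1], frames[1:]))
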