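import numpy as np
import pytest

from cricketcount import (
    LayerTrack,
    gap_acceleration,
    gap_velocity,
    sort_layers,
    total_speed_objective,
    truncate_layers,
)
from cricketcount.simulator import SimConfig, simulate

from conftest import make_matrix
from oracles import (
    brute_force_sort,
    naive_gap_acceleration,
    naive_gap_velocity,
    squared_speed_cost,
)


def track_from_x(xs, y=500.0):
    """Build a LayerTrack from per-frame x positions (None = missing)."""
    pos = np.full((len(xs), 2), np.nan)
    for f, x in enumerate(xs):
        if x is not None:
            pos[f] = (x, y)
    return LayerTrack(layer=1, positions=pos)


class TestGapVelocity:
    def test_one_step_difference(self):
        track = track_from_x([100.0, 110.0])
        v = gap_velocity(track, 1, dt=0.2)
        assert v == pytest.approx([50.0, 0.0])

    def test_bridges_missing_run(self):
        track = track_from_x([None] * 10 + [100.0, None, None, 130.0])
        v = gap_velocity(track, 13, dt=0.2)
        assert v == pytest.approx([50.0, 0.0])  # 30 px over 0.6 s

    def test_stationary_track_is_zero_everywhere(self):
        track = track_from_x([42.0] * 8)
        for f in range(1, 8):
            assert gap_velocity(track, f, dt=0.2) == pytest.approx([0.0, 0.0])

    def test_missing_in_missing_out(self):
        track = track_from_x([100.0, None, 120.0])
        assert gap_velocity(track, 0, dt=0.2) is None  # no past
        assert gap_velocity(track, 1, dt=0.2) is None  # absent frame


class TestGapAcceleration:
    def test_constant_velocity_gives_zero(self):
        track = track_from_x([10.0 * f for f in range(10)])
        for f in range(2, 10):
            assert gap_acceleration(track, f, dt=0.2) == pytest.approx([0.0, 0.0])

    def test_velocity_step_arithmetic(self):
        # v jumps from 50 px/s to 60 px/s over one 0.2 s frame: a = 50 px/s^2
        track = track_from_x([0.0, 10.0, 22.0])
        a = gap_acceleration(track, 2, dt=0.2)
        assert a == pytest.approx([50.0, 0.0])

    def test_matches_naive_recomputation_on_gappy_track(self, rng):
        xs = list(np.cumsum(rng.normal(10, 5, size=200)))
        for i in rng.choice(200, size=60, replace=False):
            xs[i] = None
        track = track_from_x(xs)
        dt = 0.2
        for f in range(200):
            ours = gap_acceleration(track, f, dt)
            ref = naive_gap_acceleration(track.positions, f, dt)
            if ref is None:
                assert ours is None
            else:
                assert ours == pytest.approx(ref)
            v_ref = naive_gap_velocity(track.positions, f, dt)
            v_ours = gap_velocity(track, f, dt)
            assert (v_ours is None) == (v_ref is None)
            if v_ref is not None:
                assert v_ours == pytest.approx(v_ref)


def two_track_matrix(xs_a, xs_b, prob=0.9):
    """Two trajectories emitted on layers 1/2 (None = that slot empty)."""
    rows = []
    for f, (xa, xb) in enumerate(zip(xs_a, xs_b)):
        if xa is not None:
            rows.append((f, 1, 0, prob, float(xa), 500.0))
        if xb is not None:
            rows.append((f, 2, 1, prob, float(xb), 520.0))
    return make_matrix(rows)


class TestSortLayers:
    def test_detector_swap_is_undone(self):
        # Track A walks right; B enters far away; one frame has the layer
        # contents exchanged by the detector.
        xs_a = [100, 110, 120, 410, 140, 150]
        xs_b = [400, 405, 408, 130, 420, 428]
        m = two_track_matrix(xs_a, xs_b)
        sorted_m, diag = sort_layers(m)
        assert diag.swapped_frames == [3]
        x1 = [sorted_m.records[(f, 1)].cx for f in range(6)]
        x2 = [sorted_m.records[(f, 2)].cx for f in range(6)]
        assert x1 == [100, 110, 120, 130, 140, 150]
        assert x2 == [400, 405, 408, 410, 420, 428]
        # class labels travelled with the centroids
        assert sorted_m.records[(3, 1)].sex_class == 1
        assert sorted_m.records[(3, 2)].sex_class == 0

    def test_single_layer_is_identity(self, single_track_matrix):
        sorted_m, diag = sort_layers(single_track_matrix)
        assert sorted_m == single_track_matrix
        assert diag.swapped_frames == []

    def test_rejects_more_than_two_layers(self):
        rows = [(0, lay, 0, 0.9, 10.0 * lay, 50.0) for lay in (1, 2, 3)]
        with pytest.raises(ValueError, match="truncate"):
            sort_layers(make_matrix(rows))

    def test_lone_survivor_keeps_its_layer(self):
        # A crosses and leaves; B keeps walking: continuity keeps B on
        # layer 2 even though the detector emits it on layer 1.
        xs_a = [1800, 1850, 1900, None, None, None]
        xs_b = [900, 910, 920, None, None, None]
        rows = []
        for f, (xa, xb) in enumerate(zip(xs_a, xs_b)):
            if xa is not None:
                rows.append((f, 1, 0, 0.9, float(xa), 500.0))
            if xb is not None:
                rows.append((f, 2, 1, 0.9, float(xb), 500.0))
        for f, x in ((3, 930.0), (4, 940.0), (5, 950.0)):
            rows.append((f, 1, 1, 0.9, x, 500.0))
        sorted_m, _ = sort_layers(make_matrix(rows))
        for f in (3, 4, 5):
            assert (f, 1) not in sorted_m.records
            assert sorted_m.records[(f, 2)].cx == pytest.approx(900.0 + 10 * f)

    def _shuffled_stream(self, seed, miss=0.0):
        cfg = SimConfig(
            n_frames=30,
            duct_length_px=300.0,
            duct_height_px=200.0,
            arrival_rate=0.1,
            speed_mean_px_per_frame=50.0,
            speed_sd_px_per_frame=12.0,
            speed_within_sd_px_per_frame=5.0,
            speed_floor_px_per_frame=20.0,
            backward_fraction=0.0,
            reversal_prob=0.0,
            miss_prob=miss,
            layer_shuffle_prob=0.4,
            occlusion_flip_prob=0.0,
            spurious_female_prob=0.0,
            seed=seed,
        )
        return simulate(cfg)

    @staticmethod
    def _max_in_duct(truth):
        import numpy as np

        occ = np.zeros(truth.n_frames, dtype=int)
        for c in truth.crossings:
            occ[c.frames[0] : c.frames[-1] + 1] += 1
        return int(occ.max()) if len(occ) else 0

    def test_conservation_and_idempotence(self):
        for seed in range(20):
            matrix, _ = self._shuffled_stream(seed, miss=0.1)
            matrix, _ = truncate_layers(matrix, 2)
            sorted_m, _ = sort_layers(matrix)
            for f in range(matrix.n_frames):
                before = sorted(
                    (r.cx, r.cy, r.sex_class, r.prob)
                    for r in matrix.detections_in(f)
                )
                after = sorted(
                    (r.cx, r.cy, r.sex_class, r.prob)
                    for r in sorted_m.detections_in(f)
                )
                assert before == after
            twice, diag2 = sort_layers(sorted_m)
            assert twice == sorted_m
            assert diag2.swapped_frames == []

    def test_objective_never_increases(self):
        """On duct-geometry streams (passages long relative to the
        co-occupancy windows) the summed speed of the layer trajectories
        never goes up, however noisy the emission."""
        for seed in range(20):
            cfg = SimConfig(
                n_frames=6000,
                arrival_rate=0.01,
                miss_prob=0.02,
                layer_shuffle_prob=0.3,
                backward_fraction=0.02,
                reversal_prob=0.01,
                seed=seed,
            )
            matrix, _ = simulate(cfg)
            matrix, _ = truncate_layers(matrix, 2)
            _, diag = sort_layers(matrix)
            assert diag.objective_after <= diag.objective_before + 1e-9

    def test_matches_exhaustive_optimum_on_small_streams(self):
        """Greedy assignment vs brute-force enumeration on random streams.

        Whenever the two individuals stay kinematically separable the
        greedy pass must reproduce the ground-truth identity partition.
        Whenever its output also stays layer-dense (no lone detection was
        moved to the empty slot, i.e. the assignment lies in the space
        the exhaustive search enumerates) its summed squared velocity is
        compared to the exhaustive optimum: it matches it in the large
        majority of streams and never exceeds twice its cost.  The rare
        above-optimum cases are streams where the raw-cost optimum links
        a trailing detection across two different individuals — cheaper
        in squared speed, wrong in identity; the partition assertion is
        what pins down correctness there.
        """
        cost_ratios = []
        checked_partition = 0
        for seed in range(160):
            matrix, truth = self._shuffled_stream(seed)
            if self._max_in_duct(truth) > 2:
                continue  # three simultaneous tracks are out of scope
            matrix, _ = truncate_layers(matrix, 2)
            if not matrix.records:
                continue
            index = matrix.by_frame()
            if sum(len(v) == 2 for v in index.values()) > 12:
                continue  # keep enumeration tractable
            sorted_m, _ = sort_layers(matrix, max_link_gap=None)
            best_cost, _ = brute_force_sort(matrix)

            # ground-truth identity per emitted record, keyed by position
            owner = {}
            for c in truth.crossings:
                for j, emitted in enumerate(c.emitted):
                    if emitted and c.layers[j] is not None and c.layers[j] <= 2:
                        owner[(c.frames[j], round(c.xs[j], 6))] = c.id
            co_frames = [f for f, recs in index.items() if len(recs) == 2]
            separable = all(
                abs(index[f][0].cx - index[f][1].cx) > 80.0 for f in co_frames
            )
            try:
                sorted_m.validate(require_dense=True)
                in_space = True
            except Exception:
                in_space = False
            if separable and in_space:
                cost = squared_speed_cost(sorted_m)
                cost_ratios.append(cost / best_cost if best_cost > 0 else 1.0)
            if separable:
                # within each co-occupied run, each layer holds one individual
                for f0, f1 in zip(co_frames[:-1], co_frames[1:]):
                    if f1 - f0 > 1:
                        continue
                    owners0 = {owner[(f0, round(r.cx, 6))] for r in index[f0]}
                    owners1 = {owner[(f1, round(r.cx, 6))] for r in index[f1]}
                    if owners0 != owners1:
                        continue  # episode boundary: a different pair co-occupies
                    for lay in (1, 2):
                        a = sorted_m.records.get((f0, lay))
                        b = sorted_m.records.get((f1, lay))
                        if a is None or b is None:
                            continue
                        assert (
                            owner[(f0, round(a.cx, 6))]
                            == owner[(f1, round(b.cx, 6))]
                        )
                checked_partition += 1
        assert len(cost_ratios) >= 30
        n_optimal = sum(r <= 1.0 + 1e-9 for r in cost_ratios)
        assert n_optimal >= 0.8 * len(cost_ratios)
        assert max(cost_ratios) < 2.0
        assert checked_partition >= 50

    def test_objective_diagnostics_match_recomputation(self):
        matrix, _ = self._shuffled_stream(7)
        matrix, _ = truncate_layers(matrix, 2)
        sorted_m, diag = sort_layers(matrix)
        assert diag.objective_before == pytest.approx(total_speed_objective(matrix))
        assert diag.objective_after == pytest.approx(
            total_speed_objective(sorted_m)
        )
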