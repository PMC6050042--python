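"""Segmentation, tracking, death calling, registration."""

import numpy as np
import pytest

from conftest import make_blob_frame
from lfmkit import imaging
from lfmkit.stack import CellROI, CellTrack, TimeLapseStack


def _stack_from_frames(frames, channel="morphology"):
    return TimeLapseStack(
        timestamps_h=24.0 * (1 + np.arange(len(frames))),
        channels={channel: np.array(frames)},
    )


class TestSegmentFrame:
    def test_three_separated_blobs_give_three_rois(self):
        frame = make_blob_frame((96, 96), [(20, 20), (60, 30), (40, 70)])
        stack = _stack_from_frames([frame])
        rois = imaging.segment_frame(stack, 0)
        assert len(rois) == 3
        labels = {r.label for r in rois}
        assert len(labels) == 3

    def test_small_blob_excluded_by_area_filter(self):
        frame = make_blob_frame((96, 96), [(30, 30)], sigma=3.0)
        frame += make_blob_frame((96, 96), [(70, 70)], sigma=0.8)
        stack = _stack_from_frames([frame])
        rois = imaging.segment_frame(stack, 0, min_area=25)
        assert len(rois) == 1

    def test_blank_frame_returns_empty_list(self):
        stack = _stack_from_frames([np.zeros((64, 64))])
        assert imaging.segment_frame(stack, 0) == []

    def test_missing_channel_raises(self):
        stack = _stack_from_frames([np.zeros((64, 64))])
        with pytest.raises(KeyError):
            imaging.segment_frame(stack, 0, channel="gfp")

    def test_roi_intensity_identity(self):
        frame = make_blob_frame((64, 64), [(32, 32)])
        stack = _stack_from_frames([frame])
        roi = imaging.segment_frame(stack, 0)[0]
        assert roi.integrated_intensity["morphology"] == pytest.approx(
            roi.mean_intensity["morphology"] * roi.area, rel=1e-6
        )

    def test_rois_are_disjoint(self, small_field):
        _, stack, _ = small_field
        rois = imaging.segment_frame(stack, 0)
        total = np.zeros(stack.frame_shape, dtype=int)
        for r in rois:
            total += r.mask
        assert total.max() <= 1

    def test_detection_f1_on_simulated_field(self, small_field):
        cfg, stack, truth = small_field
        rois = imaging.segment_frame(stack, 0)
        detected = np.array([r.centroid for r in rois])
        alive = truth.cells[truth.cells.death_frame > 0]
        tp = 0
        for _, row in alive.iterrows():
            d = np.hypot(detected[:, 0] - row.x0, detected[:, 1] - row.y0)
            tp += (d <= cfg.soma_radius_px).any()
        precision = tp / max(len(detected), 1)
        recall = tp / len(alive)
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 >= 0.9


class TestTracking:
    def test_stationary_cells_yield_full_tracks(self):
        frame = make_blob_frame((96, 96), [(25, 25), (70, 60)])
        stack = _stack_from_frames([frame] * 10)
        rois = imaging.segment_stack(stack)
        tracks = imaging.track_cells(stack, rois)
        assert len(tracks) == 2
        assert all(len(t.rois) == 10 for t in tracks)

    def test_slow_motion_keeps_single_track(self):
        frames = [
            make_blob_frame((96, 96), [(20 + 2 * f, 40)]) for f in range(10)
        ]
        stack = _stack_from_frames(frames)
        tracks = imaging.track_cells(
            stack, imaging.segment_stack(stack), max_displacement=10
        )
        assert len(tracks) == 1
        assert len(tracks[0].rois) == 10

    def test_track_purity_on_simulated_field(self, small_field):
        cfg, stack, truth = small_field
        tracks = imaging.track_cells(stack, imaging.segment_stack(stack))
        paths = truth.extras["paths"]
        pure = total = 0
        for tr in tracks:
            ids = []
            for t, roi in tr.observations:
                if roi is None:
                    continue
                f = int(np.argmin(np.abs(stack.timestamps_h - t)))
                d = np.hypot(
                    paths[:, f, 0] - roi.centroid[0],
                    paths[:, f, 1] - roi.centroid[1],
                )
                ids.append(int(np.argmin(d)))
            if ids:
                total += 1
                pure += len(set(ids)) == 1
        assert total > 0
        assert pure / total >= 0.95

    def test_no_two_tracks_share_a_roi(self, small_field):
        _, stack, _ = small_field
        tracks = imaging.track_cells(stack, imaging.segment_stack(stack))
        seen = set()
        for tr in tracks:
            for t, roi in tr.observations:
                if roi is None:
                    continue
                key = (t, roi.label)
                assert key not in seen
                seen.add(key)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            stack = _stack_from_frames([np.zeros((8, 8))])
            imaging.track_cells(stack, [])


def _make_track(intensities, eccentricities=None, start_h=24.0):
    obs = []
    n = len(intensities)
    ecc = eccentricities or [0.8] * n
    for i, (inten, e) in enumerate(zip(intensities, ecc)):
        t = start_h + 24.0 * i
        if inten is None:
            obs.append((t, None))
            continue
        mask = np.zeros((8, 8), bool)
        mask[0, 0] = True
        obs.append(
            (
                t,
                CellROI(
                    frame_index=i, label=1, mask=mask, centroid=(0, 0),
                    area=1, eccentricity=e,
                    mean_intensity={"morphology": float(inten)},
                    integrated_intensity={"morphology": float(inten)},
                ),
            )
        )
    return CellTrack(track_id=0, group="g", observations=obs)


def _dummy_stack(n_frames):
    return _stack_from_frames([np.zeros((8, 8))] * n_frames)


class TestCallDeath:
    def test_fluorescence_collapse_sets_death_frame(self):
        tr = _make_track([100, 98, 97, 96, 10, 9])
        tr = imaging.call_death(tr, _dummy_stack(6), fluorescence_floor=0.25)
        assert tr.status == "dead"
        # collapse at the 5th frame: 24 h * 5 = 120 h = 5 days
        assert tr.death_time_days == pytest.approx(5.0)

    def test_stable_trace_censored_at_end(self):
        tr = _make_track([100] * 10)
        tr = imaging.call_death(tr, _dummy_stack(10))
        assert tr.status == "alive"
        assert tr.event == 0
        assert tr.censor_time_days == pytest.approx(10.0)

    def test_vanishing_roi_is_death(self):
        tr = _make_track([100, 99, None, None, None])
        tr = imaging.call_death(tr, _dummy_stack(5))
        assert tr.status == "dead"
        assert tr.death_time_days == pytest.approx(3.0)

    def test_rounding_with_decline_is_death(self):
        tr = _make_track(
            [100, 95, 80, 70, 60],
            eccentricities=[0.8, 0.8, 0.1, 0.1, 0.1],
        )
        tr = imaging.call_death(tr, _dummy_stack(5), roundness_jump=0.5)
        assert tr.status == "dead"
        assert tr.death_time_days == pytest.approx(3.0)

    def test_no_roi_after_death(self):
        tr = _make_track([100, 98, 10, 9, 8])
        tr = imaging.call_death(tr, _dummy_stack(5))
        after = [
            roi
            for t, roi in tr.observations
            if t / 24.0 > tr.death_time_days
        ]
        assert all(r is None for r in after)

    def test_called_death_times_match_truth(self, small_field):
        cfg, stack, truth = small_field
        tracks = imaging.track_cells(stack, imaging.segment_stack(stack))
        for tr in tracks:
            imaging.call_death(tr, stack)
        paths = truth.extras["paths"]
        hits = n_dying = 0
        for tr in tracks:
            first = next(roi for _, roi in tr.observations if roi is not None)
            d = np.hypot(
                paths[:, 0, 0] - first.centroid[0],
                paths[:, 0, 1] - first.centroid[1],
            )
            row = truth.cells.iloc[int(np.argmin(d))]
            if row.event == 1 and row.death_frame > 0:
                n_dying += 1
                if tr.status == "dead":
                    hits += abs(
                        tr.death_time_days - row.observed_death_day
                    ) <= 1.0 + 1e-9
        assert n_dying > 0
        assert hits / n_dying >= 0.9

    def test_count_conservation(self, small_field):
        """alive-at-t + dead-by-t + lost-by-t = total tracks, every frame."""
        _, stack, _ = small_field
        tracks = imaging.track_cells(stack, imaging.segment_stack(stack))
        for tr in tracks:
            imaging.call_death(tr, stack)
        for t in stack.timestamps_h / 24.0:
            alive = dead = lost = 0
            for tr in tracks:
                if tr.status == "dead" and tr.death_time_days <= t:
                    dead += 1
                elif tr.status == "lost" and tr.censor_time_days <= t:
                    lost += 1
                else:
                    alive += 1
            assert alive + dead + lost == len(tracks)


class TestExtractTimeseries:
    def test_constant_cell_gives_constant_series(self):
        tr = _make_track([50, 50, 50, 50])
        ts = imaging.extract_timeseries(tr, "morphology")
        assert [v for _, v in ts] == [50, 50, 50, 50]

    def test_series_ends_at_death(self):
        tr = _make_track([100, 99, 10, 9])
        tr = imaging.call_death(tr, _dummy_stack(4))
        ts = imaging.extract_timeseries(tr, "morphology")
        assert len(ts) == sum(
            roi is not None for _, roi in tr.observations
        )
        assert max(t for t, _ in ts) / 24.0 < tr.death_time_days

    def test_empty_track_raises(self):
        tr = CellTrack(track_id=0, group=None, observations=[(24.0, None)])
        with pytest.raises(ValueError):
            imaging.extract_timeseries(tr, "morphology")


class TestRegistration:
    @staticmethod
    def _scene(seed=0):
        rng = np.random.default_rng(seed)
        return make_blob_frame(
            (72, 72), [tuple(rng.uniform(15, 57, 2)) for _ in range(6)]
        )

    def test_zero_drift_gives_identity(self):
        base = self._scene()
        stack = _stack_from_frames([base, base.copy()])
        res = imaging.register_stack(stack)
        assert np.allclose(res.shifts, 0.0)

    def test_integer_shift_recovered_exactly(self):
        base = self._scene()
        moved = np.roll(np.roll(base, 3, axis=0), 5, axis=1)
        stack = _stack_from_frames([base, moved])
        res = imaging.register_stack(stack)
        assert np.allclose(res.shifts[1], (-3, -5))

    def test_subpixel_shift_recovered(self):
        from scipy import ndimage

        base = self._scene(1)
        moved = ndimage.shift(base, (1.5, 0.0), order=3)
        stack = _stack_from_frames([base, moved])
        res = imaging.register_stack(stack)
        assert abs(res.shifts[1][0] + 1.5) <= 0.25
        assert abs(res.shifts[1][1]) <= 0.25

    def test_featureless_frame_warns_identity(self):
        base = self._scene(2)
        stack = _stack_from_frames([base, np.zeros_like(base)])
        with pytest.warns(UserWarning, match="featureless"):
            res = imaging.register_stack(stack)
        assert np.allclose(res.shifts[1], 0.0)
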