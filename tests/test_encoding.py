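"""Feature-image encoding: normalization, resampling, flattening, windows."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from opposcreen.core_io import Sample, SessionRecord, TaskGeometry, TrialTrajectory
from opposcreen.encoding import (
    FeatureImage,
    MissingLapError,
    encode_cohort,
    encode_image,
    flatten,
    normalize_distance,
    slice_window,
    window_label,
)

from conftest import straight_trial


def session_with(trials, hand_id="h1", group="healthy"):
    return SessionRecord(hand_id, group, "right", trials)


def full_session(duration=1.0, lap=2):
    return session_with([straight_trial(direction=d, lap=lap, duration=duration)
                         for d in range(1, 13)])


class TestNormalizeDistance:
    def test_center_is_zero(self, geometry):
        assert normalize_distance(Sample(0, 0.0, 0.0), geometry) == 0.0

    def test_circle_is_one(self, geometry):
        assert normalize_distance(Sample(0, 2.0, 0.0), geometry) == 1.0

    def test_three_four_five_triangle(self, geometry):
        # distance 1.0 cm on a 2-cm circle
        assert normalize_distance(Sample(0, 0.6, 0.8), geometry) == pytest.approx(0.5)

    def test_overshoot_clips(self, geometry):
        assert normalize_distance(Sample(0, 5.0, 0.0), geometry) == 1.0


class TestEncodeImage:
    def test_instant_collection_all_white_column_zero(self, geometry):
        trials = [TrialTrajectory(d, 2, [Sample(0.0, 0, 0), Sample(0.02, 0, 2.0)],
                                  True, collect_time=0.02)
                  for d in range(1, 13)]
        img = encode_image(session_with(trials), geometry=geometry)
        assert np.allclose(img.intensities[:, 0], 1.0)
        assert np.allclose(img.intensities[:, 1:], 0.0)

    def test_motionless_never_collected_is_all_zero(self, geometry):
        samples = [Sample(float(t), 0.0, 0.0) for t in np.arange(0, 5, 0.1)]
        trials = [TrialTrajectory(d, 2, list(samples), False) for d in range(1, 13)]
        img = encode_image(session_with(trials), geometry=geometry)
        assert np.allclose(img.intensities, 0.0)

    def test_constant_speed_reach_is_linear_ramp(self, geometry):
        img = encode_image(full_session(duration=2.0), geometry=geometry)
        row = img.intensities[0]
        expected = np.arange(20) * 0.1 / 2.0  # d(t)/radius on the frame grid
        assert np.allclose(row[:20], expected, atol=1e-9)
        assert row[20] == 1.0  # white reach frame
        assert np.allclose(row[21:], 0.0)  # black fill after the reach

    def test_reach_frame_white_and_suffix_black_everywhere(self, study_cohort,
                                                           geometry):
        for s in study_cohort[:8]:
            img = encode_image(s, geometry=geometry)
            assert img.intensities.min() >= 0.0
            assert img.intensities.max() <= 1.0
            for d, trial in s.trials_for_lap(2).items():
                row = img.intensities[d - 1]
                if trial.collected:
                    frame = min(round(trial.collect_time * 10), 49)
                    assert row[frame] == 1.0
                    assert np.all(row[frame + 1:] == 0.0)

    def test_timed_out_trial_has_no_forced_white(self, geometry):
        # stalls at 60% of the radius
        samples = [Sample(float(t), 0.0, 1.2) for t in np.arange(0, 5, 0.1)]
        samples[0] = Sample(0.0, 0.0, 0.0)
        trials = [TrialTrajectory(d, 2, list(samples), False) for d in range(1, 13)]
        img = encode_image(session_with(trials), geometry=geometry)
        assert img.intensities.max() < 1.0

    def test_missing_lap_raises(self, geometry):
        with pytest.raises(MissingLapError):
            encode_image(full_session(lap=1), lap=2, geometry=geometry)

    def test_missing_direction_zero_filled_and_flagged(self, geometry):
        trials = [straight_trial(direction=d) for d in range(1, 12)]
        img = encode_image(session_with(trials), geometry=geometry)
        assert img.flagged_directions == [12]
        assert np.allclose(img.intensities[11], 0.0)

    def test_idempotent_on_gridded_trial(self, geometry):
        """Re-encoding a trajectory already on the frame grid changes nothing."""
        img1 = encode_image(full_session(duration=2.0), geometry=geometry)
        # rebuild trials from the gridded rows and re-encode
        trials = []
        for d in range(1, 13):
            row = img1.intensities[d - 1]
            samples = [Sample(float(i) / 10, float(v * 2.0), 0.0)
                       for i, v in enumerate(row[:21])]
            trials.append(TrialTrajectory(d, 2, samples, True, collect_time=2.0))
        img2 = encode_image(session_with(trials), geometry=geometry)
        assert np.allclose(img1.intensities, img2.intensities, atol=1e-9)


class TestFlattenAndWindows:
    def test_flatten_length_600(self, geometry):
        vec = flatten(encode_image(full_session(), geometry=geometry))
        assert vec.shape == (600,)

    def test_flatten_is_row_major(self, geometry):
        img = FeatureImage(np.zeros((12, 50)), geometry)
        img.intensities[2, 7] = 1.0  # direction 3, frame 7
        vec = flatten(img)
        assert vec[(3 - 1) * 50 + 7] == 1.0
        assert vec.sum() == 1.0

    def test_zero_image_flattens_to_zero_vector(self, geometry):
        assert not flatten(FeatureImage(np.zeros((12, 50)), geometry)).any()

    def test_window_slice_contiguous(self, geometry):
        img = FeatureImage(np.tile(np.arange(1, 13)[:, None] / 12.0, (1, 50)),
                           geometry)
        vec = slice_window(img, 8, 4)
        assert vec.shape == (200,)
        assert np.allclose(np.unique(vec), np.array([8, 9, 10, 11]) / 12.0)

    def test_window_wraparound(self, geometry):
        img = FeatureImage(np.tile(np.arange(1, 13)[:, None] / 12.0, (1, 50)),
                           geometry)
        vec = slice_window(img, 12, 4)
        assert np.allclose(np.unique(vec), np.array([1, 2, 3, 12]) / 12.0)

    def test_full_width_window_preserves_multiset(self, geometry):
        img = encode_image(full_session(), geometry=geometry)
        for start in (1, 5, 12):
            vec = slice_window(img, start, 12)
            assert np.allclose(np.sort(vec), np.sort(flatten(img)))

    def test_window_start_out_of_range(self, geometry):
        img = FeatureImage(np.zeros((12, 50)), geometry)
        with pytest.raises(ValueError):
            slice_window(img, 0)
        with pytest.raises(ValueError):
            slice_window(img, 13)

    @pytest.mark.parametrize("start,expected", [
        (1, "1-4"), (8, "8-11"), (9, "9-12"), (10, "10-1"),
        (11, "11-2"), (12, "12-3"),
    ])
    def test_window_labels_match_wraparound(self, start, expected):
        assert window_label(start, 4) == expected


@settings(max_examples=25, deadline=None, derandomize=True)
@given(n_directions=st.integers(2, 16), timeout=st.floats(1.0, 8.0),
       sample_rate=st.sampled_from([5.0, 10.0, 20.0]))
def test_flatten_length_tracks_geometry(n_directions, timeout, sample_rate):
    """flatten(encode(...)) has length n_directions x frames for any geometry."""
    geom = TaskGeometry(radius=2.0, n_directions=n_directions,
                        timeout=timeout, sample_rate=sample_rate)
    trials = [straight_trial(direction=d, duration=min(1.0, timeout / 2))
              for d in range(1, n_directions + 1)]
    vec = flatten(encode_image(session_with(trials), geometry=geom))
    assert vec.shape == (n_directions * geom.frames_per_trial,)
    assert ((vec >= 0) & (vec <= 1)).all()


def test_encode_cohort_shapes(small_cohort):
    full = encode_cohort(small_cohort)
    assert full.shape == (len(small_cohort), 3 + 600)
    win = encode_cohort(small_cohort, start_direction=8, width=4)
    assert win.shape == (len(small_cohort), 3 + 200)
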