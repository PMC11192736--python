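import numpy as np
import pytest
from hypothesis import given, strategies as st

from dyadcoord import crqa
from dyadcoord.errors import (
    AlignmentError,
    DegenerateSignalError,
    TooShortError,
    TuningError,
)

from conftest import brute_ami, brute_fnn, brute_maxline, brute_rec_pct, brute_recurrence


class TestAverageMutualInformation:
    def test_zero_lag_equals_entropy_and_dominates(self, rng):
        x = rng.standard_normal(400)
        ami = crqa.average_mutual_information(x, 20)
        # I(X;X) = H(X) under the same binning
        bins = min(64, int(np.ceil(np.sqrt(400))))
        counts, _ = np.histogram(x, bins=bins)
        p = counts[counts > 0] / counts.sum()
        assert ami[0] == pytest.approx(-np.sum(p * np.log2(p)), abs=1e-9)
        assert np.argmax(ami) == 0

    def test_shuffled_copy_carries_no_information(self, rng):
        x = np.sin(2 * np.pi * 1.4 * np.arange(1000) / 50.0)
        shuffled = rng.permutation(x)
        ami = crqa.average_mutual_information(shuffled, 20)
        null = [crqa.average_mutual_information(rng.permutation(x), 20)[1:].mean()
                for _ in range(20)]
        assert np.all(ami[1:] < np.mean(null) + 3 * np.std(null) + 0.05)

    def test_sinusoid_first_minimum_near_quarter_period(self):
        x = np.sin(2 * np.pi * 1.4 * np.arange(2000) / 50.0)
        ami = crqa.average_mutual_information(x, 30)
        delay = crqa.select_delay(ami)
        quarter = 50.0 / 1.4 / 4  # ~8.9 samples
        assert abs(delay - quarter) <= 2

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSignalError):
            crqa.average_mutual_information(np.ones(100), 10)


class TestSelectDelay:
    def test_first_local_minimum(self):
        assert crqa.select_delay(np.array([3.0, 1.0, 2.0, 0.5])) == 1

    def test_strictly_decreasing_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            assert crqa.select_delay(np.linspace(5, 1, 10)) == 9

    def test_v_shape_minimum_at_24(self):
        curve = np.concatenate([np.linspace(5, 1, 25), np.linspace(1.2, 3, 10)])
        assert crqa.select_delay(curve) == 24


class TestFalseNearestNeighbours:
    def test_sinusoid_unfolds_by_dim_two(self):
        x = np.sin(2 * np.pi * 1.4 * np.arange(500) / 50.0)
        fnn = crqa.false_nearest_neighbours(x, delay=9, max_dim=3)
        assert fnn[1] < 0.01

    def test_white_noise_never_unfolds(self, rng):
        x = rng.standard_normal(600)
        fnn = crqa.false_nearest_neighbours(x, delay=1, max_dim=5)
        assert np.all(fnn > 0.1)

    def test_max_dim_one_boundary(self, rng):
        fnn = crqa.false_nearest_neighbours(rng.standard_normal(100), 1, 1)
        assert fnn.shape == (1,)


class TestSelectEmbeddingDim:
    def test_first_local_minimum(self):
        assert crqa.select_embedding_dim(np.array([0.8, 0.02, 0.03])) == 2

    def test_monotone_decreasing_uses_threshold(self):
        curve = np.array([0.5, 0.2, 0.05, 0.005, 0.001])
        assert crqa.select_embedding_dim(curve) == 4

    def test_constructed_minimum_at_seven(self):
        curve = np.array([0.9, 0.7, 0.5, 0.4, 0.3, 0.25, 0.2, 0.22, 0.3])
        assert crqa.select_embedding_dim(curve) == 7


class TestEmbed:
    def test_dim_one_identity(self, rng):
        x = rng.standard_normal(50)
        emb = crqa.embed(x, 1, 5)
        assert emb.n_embedded == 50
        np.testing.assert_array_equal(emb.points[:, 0], x)

    def test_small_example_geometry(self):
        x = np.arange(10.0)
        emb = crqa.embed(x, 3, 2)
        assert emb.n_embedded == 6
        np.testing.assert_array_equal(emb.points[0], [0.0, 2.0, 4.0])

    def test_study_scale_count(self, rng):
        emb = crqa.embed(rng.standard_normal(4200), 7, 24)
        assert emb.n_embedded == 4200 - 6 * 24  # 4056

    def test_insufficient_length(self):
        with pytest.raises(TooShortError):
            crqa.embed(np.arange(10.0), 4, 4)


HAND_EX = crqa.EmbeddedSeries(points=np.array([[0.0], [1.0], [2.0]]), dim=1, delay=1)
HAND_EY = crqa.EmbeddedSeries(points=np.array([[0.0], [2.0], [4.0]]), dim=1, delay=1)


class TestRecurrenceMatrix:
    def test_hand_example(self):
        R = crqa.cross_recurrence_matrix(HAND_EX, HAND_EY, radius=1.0)
        np.testing.assert_array_equal(
            R, np.array([[1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=bool))
        assert crqa.recurrence_rate(R) == pytest.approx(400.0 / 9.0)

    def test_saturation_and_vacuum(self, rng):
        ex = crqa.embed(rng.standard_normal(40), 2, 3)
        ey = crqa.embed(rng.standard_normal(40), 2, 3)
        D_max = np.sqrt(((ex.points[:, None] - ey.points[None]) ** 2).sum(-1)).max()
        assert crqa.recurrence_rate(
            crqa.cross_recurrence_matrix(ex, ey, D_max + 1)) == 100.0
        assert crqa.recurrence_rate(
            crqa.cross_recurrence_matrix(ex, ey, 1e-12)) == 0.0

    def test_dim_mismatch(self, rng):
        ex = crqa.embed(rng.standard_normal(40), 2, 3)
        ey = crqa.embed(rng.standard_normal(40), 3, 3)
        with pytest.raises(AlignmentError):
            crqa.cross_recurrence_matrix(ex, ey, 1.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.floats(min_value=0.05, max_value=3.0))
    def test_transpose_symmetry(self, seed, radius):
        r = np.random.default_rng(seed)
        ex = crqa.embed(r.standard_normal(30), 2, 2)
        ey = crqa.embed(r.standard_normal(30), 2, 2)
        R_xy = crqa.cross_recurrence_matrix(ex, ey, radius)
        R_yx = crqa.cross_recurrence_matrix(ey, ex, radius)
        np.testing.assert_array_equal(R_xy, R_yx.T)
        assert crqa.maxline(R_xy) == crqa.maxline(R_yx)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_rate_monotone_in_radius(self, seed):
        r = np.random.default_rng(seed)
        ex = crqa.embed(r.standard_normal(40), 2, 2)
        ey = crqa.embed(r.standard_normal(40), 2, 2)
        radii = np.linspace(0.01, 4.0, 12)
        rates = [crqa.recurrence_rate(crqa.cross_recurrence_matrix(ex, ey, rad))
                 for rad in radii]
        assert all(b >= a for a, b in zip(rates, rates[1:]))


class TestMaxline:
    def test_identical_series_full_diagonal(self, rng):
        ex = crqa.embed(rng.standard_normal(30), 2, 2)
        R = crqa.cross_recurrence_matrix(ex, ex, radius=1e-9)
        assert crqa.maxline(R) == ex.n_embedded

    def test_all_zeros(self):
        assert crqa.maxline(np.zeros((5, 5), dtype=bool)) == 0

    def test_hand_matrix(self):
        R = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 1]], dtype=bool)
        assert crqa.maxline(R) == 3
        assert crqa.maxline(R) == brute_maxline(R.tolist())

    def test_runs_below_min_line_count_as_zero(self):
        R = np.eye(4, dtype=bool)
        R[1, 1] = False
        R[3, 3] = False  # only isolated points remain
        assert crqa.maxline(R, min_line=2) == 0


class TestTuneRadius:
    def test_target_hundred_is_max_distance(self, rng):
        ex = crqa.embed(rng.standard_normal(50), 2, 2)
        ey = crqa.embed(rng.standard_normal(50), 2, 2)
        tuned = crqa.tune_radius(ex, ey, target_rr=100.0)
        assert tuned.rec_pct == 100.0

    def test_synthetic_dyad_reaches_five_percent(self):
        from dyadcoord.preprocess import preprocess_trial
        from dyadcoord.simulate import simulate_dyad_trial

        row = {"participant_id": "p1", "gaze_condition": "direct",
               "lsas": 55.43, "aq": 9.99}
        pair, _ = simulate_dyad_trial(row, "spontaneous", seed=5)
        pp = preprocess_trial(pair)
        x = (pp.participant.x - pp.participant.x.mean()) / pp.participant.x.std()
        y = (pp.avatar.x - pp.avatar.x.mean()) / pp.avatar.x.std()
        ex = crqa.embed(x, 7, 24)
        ey = crqa.embed(y, 7, 24)
        tuned = crqa.tune_radius(ex, ey, target_rr=5.0, tol=0.5)
        assert 4.5 <= tuned.rec_pct <= 5.5

    def test_unattainable_target_reports_closest(self):
        pts = crqa.EmbeddedSeries(points=np.arange(10.0)[:, None], dim=1, delay=1)
        with pytest.raises(TuningError) as err:
            crqa.tune_radius(pts, pts, target_rr=1e-4, tol=0.5)
        assert err.value.closest_rate >= 10.0  # identical points floor the rate


class TestBruteForceEquivalence:
    """Spot-checks against the naive oracles (full sweep in acceptance suite)."""

    @pytest.mark.parametrize("seed", range(5))
    def test_ami_matches(self, seed):
        x = np.random.default_rng(seed).standard_normal(150)
        ours = crqa.average_mutual_information(x, 8)
        ref = brute_ami(x, 8)
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_recurrence_and_maxline_match(self, seed):
        r = np.random.default_rng(seed)
        ex = crqa.embed(r.standard_normal(60), 2, 3)
        ey = crqa.embed(r.standard_normal(60), 2, 3)
        radius = 0.8
        R = crqa.cross_recurrence_matrix(ex, ey, radius)
        R_ref = brute_recurrence(ex.points.tolist(), ey.points.tolist(), radius)
        np.testing.assert_array_equal(R, R_ref)
        assert crqa.recurrence_rate(R) == pytest.approx(brute_rec_pct(R_ref.tolist()))
        assert crqa.maxline(R) == brute_maxline(R_ref.tolist())

    @pytest.mark.parametrize("seed", range(3))
    def test_fnn_matches(self, seed):
        x = np.random.default_rng(seed).standard_normal(120)
        ours = crqa.false_nearest_neighbours(x, delay=2, max_dim=3)
        ref = brute_fnn(x, delay=2, max_dim=3)
        np.testing.assert_allclose(ours, ref, atol=1e-12)


def test_crqa_metrics_end_to_end(rng):
    t = np.arange(1500) / 50.0
    x = np.sin(2 * np.pi * 1.4 * t) + 0.2 * rng.standard_normal(len(t))
    y = np.sin(2 * np.pi * 1.4 * t + 0.4) + 0.2 * rng.standard_normal(len(t))
    res = crqa.crqa_metrics(x, y, crqa.CRQAParams(delay=9, dim=3))
    assert 4.5 <= res.rec_pct <= 5.5
    assert res.maxline >= 2
    assert res.n_x == res.n_y == 1500 - 2 * 9
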