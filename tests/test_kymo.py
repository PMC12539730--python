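import numpy as np
import pytest

from stenpol.kymo import (PatchRecord, binarize, detect_firings,
                          excited_level, extract_patches, firing_durations,
                          patch_count_series, polarity_metrics,
                          sweep_heatmaps, temporal_autocorrelation)
from stenpol.synth import (SyntheticKymoSpec, SyntheticPatch,
                           generate_synthetic_kymo)


class TestAutocorrelation:
    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(0)
        res = temporal_autocorrelation(rng.normal(size=(5, 200)))
        assert np.allclose(res["curves"][:, 0], 1.0)

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(1)
        res = temporal_autocorrelation(rng.normal(size=(50, 2000)),
                                       max_lag=100)
        assert np.all(np.abs(res["mean"][1:]) < 3 / np.sqrt(2000))

    def test_square_wave_periodicity(self):
        # closed form for the biased estimator at one full period:
        # identical samples overlap on n - T points, so ac(T) = 1 - T/n
        T, reps = 100, 12
        n = T * reps
        x = np.tile(np.r_[np.ones(T // 2), -np.ones(T // 2)], reps)
        res = temporal_autocorrelation(x[None, :], max_lag=T)
        assert res["mean"][T] == pytest.approx(1.0 - T / n, abs=1e-12)

    def test_flat_trace_flagged(self):
        arr = np.vstack([np.ones(100), np.random.default_rng(2).normal(
            size=100)])
        res = temporal_autocorrelation(arr, max_lag=10)
        assert list(res["flat_traces"]) == [0]
        assert np.all(res["curves"][0, 1:] == 0.0)
        assert res["curves"][0, 0] == 1.0

    def test_baseline_mean_curve_decays_over_first_minute(self, baseline_runs):
        curves = np.concatenate(
            [temporal_autocorrelation(k["ras"], max_lag=60)["curves"]
             for k in baseline_runs])
        mean = curves.mean(axis=0)
        # monotone decay within the noise envelope of the ensemble
        envelope = curves.std(axis=0) / np.sqrt(curves.shape[0])
        assert np.all(np.diff(mean) <= 3 * envelope[1:])
        assert mean[60] < 0.5 * mean[5]


class TestFirings:
    def test_constant_subthreshold_gives_nothing(self):
        assert detect_firings(np.full(300, 0.1), threshold=0.5) == []

    def test_single_pulse_duration(self):
        tr = np.zeros(400)
        tr[100:150] = 1.0
        ev = detect_firings(tr, threshold=0.5, min_duration=5,
                            merge_window=5)
        assert len(ev) == 1
        assert ev[0].duration == pytest.approx(50.0)
        assert ev[0].peak == 1.0

    def test_close_pulses_merge(self):
        tr = np.zeros(400)
        tr[100:130] = 1.0
        tr[140:170] = 1.0            # 10 s gap < 30 s merge window
        ev = detect_firings(tr, threshold=0.5)
        assert len(ev) == 1
        assert ev[0].duration == pytest.approx(70.0)

    def test_short_events_dropped(self):
        tr = np.zeros(400)
        tr[10:14] = 1.0
        assert detect_firings(tr, threshold=0.5, min_duration=10,
                              merge_window=0) == []

    def test_pooled_durations_on_synthetic_pulses(self):
        k = np.zeros((4, 500))
        for i, w in enumerate((40, 60, 80, 100)):
            k[i, 50:50 + w] = 1.0
        durs = firing_durations([k], basal=0.0, species="ras")
        assert durs.size == 4
        assert durs.mean() == pytest.approx(70.0)


class TestBinarize:
    def test_flat_kymograph_all_false(self):
        assert not binarize(np.full((10, 20), 0.3), threshold=0.5).any()
        assert not binarize(np.full((10, 20), 0.7), threshold=0.5).any()

    def test_rectangular_patch_exact(self):
        arr = np.zeros((20, 50))
        arr[5:10, 10:30] = 1.0
        mask = binarize(arr, basal=0.0, excited=1.0)    # midpoint 0.5
        expected = np.zeros_like(arr, bool)
        expected[5:10, 10:30] = True
        assert np.array_equal(mask, expected)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        arr = rng.random((30, 30))
        counts = [binarize(arr, threshold=t).sum()
                  for t in (0.2, 0.4, 0.6, 0.8)]
        assert sorted(counts, reverse=True) == counts


class TestPatches:
    def test_area_filter_at_fifty_pixels(self):
        small = np.zeros((30, 30), bool)
        small[0:7, 0:7] = True               # 49 px
        assert extract_patches(small) == []
        big = np.zeros((30, 30), bool)
        big[0:7, 0:7] = True
        big[7, 0:2] = True                   # 51 px
        assert len(extract_patches(big)) == 1

    def test_time_aligned_patch_has_zero_orientation(self):
        mask = np.zeros((40, 400), bool)
        mask[10:14, 50:350] = True
        (rec,) = extract_patches(mask)
        assert rec.orientation < 2.0
        assert rec.duration == pytest.approx(300.0, abs=1.0)

    def test_periodic_wrap_merges_across_seam(self):
        mask = np.zeros((40, 200), bool)
        mask[0:5, 20:60] = True
        mask[35:40, 20:60] = True            # same patch across the seam
        recs = extract_patches(mask)
        assert len(recs) == 1
        assert recs[0].angular_extent == pytest.approx(10 * 9.0)   # 10 sites

    def test_ellipse_orientation_recovered(self):
        spec = SyntheticKymoSpec(
            n_points=120, n_times=600,
            patches=(SyntheticPatch(t0=300, theta0=180, duration=240,
                                    width=120, amplitude=1.0,
                                    orientation=45.0, shape="ellipse"),))
        arr, _ = generate_synthetic_kymo(spec)
        (rec,) = extract_patches(arr > 0.5,
                                 degrees_per_site=spec.degrees_per_site)
        assert rec.orientation == pytest.approx(45.0, abs=3.0)


class TestCountsAndPolarity:
    def test_empty_records(self):
        counts = patch_count_series([], 100)
        assert counts.sum() == 0
        pm = polarity_metrics([], 100)
        assert pm.dominant_patch_count == 0 and not pm.is_polarized

    def test_single_full_length_patch(self):
        rec = PatchRecord(area=500, t_start=0.0, t_end=99.0,
                          angular_extent=40.0, orientation=5.0,
                          centroid_t=50.0, centroid_angle=180.0)
        counts = patch_count_series([rec], 100)
        assert np.all(counts == 1)
        pm = polarity_metrics([rec], 100)
        assert pm.is_polarized
        assert pm.fraction_time_polarized == pytest.approx(1.0)
        assert pm.dominant_patch_count == 1

    def test_disjoint_patches_counted_by_majority(self):
        recs = [PatchRecord(100, 0.0, 29.0, 30.0, 2.0, 15.0, 0.0),
                PatchRecord(100, 60.0, 79.0, 30.0, 2.0, 70.0, 90.0)]
        counts = patch_count_series(recs, 100)
        assert set(np.unique(counts)) == {0, 1}
        pm = polarity_metrics(recs, 100)
        assert pm.dominant_patch_count == 0      # zero-count majority

    def test_steep_orientation_excluded(self):
        rec = PatchRecord(5000, 0.0, 99.0, 350.0, 75.0, 50.0, 0.0)
        pm = polarity_metrics([rec], 100, orientation_max=90.0)
        assert not pm.is_polarized

    def test_two_parallel_fronts_not_polarized(self):
        recs = [PatchRecord(800, 0.0, 99.0, 30.0, 2.0, 50.0, 0.0),
                PatchRecord(790, 0.0, 99.0, 30.0, 2.0, 50.0, 180.0)]
        pm = polarity_metrics(recs, 100)
        assert pm.dominant_patch_count == 2
        assert not pm.is_polarized

    def test_width_criterion_variant(self):
        rec = PatchRecord(800, 0.0, 99.0, 100.0, 2.0, 50.0, 0.0)
        assert polarity_metrics([rec], 100).is_polarized
        assert not polarity_metrics([rec], 100,
                                    criterion="width").is_polarized


class TestFixtureRecovery:
    def test_patch_geometry_recovered_under_noise(self):
        dps = 360.0 / 126
        spec = SyntheticKymoSpec(
            n_points=126, n_times=1200, noise_sd=0.08, seed=4,
            patches=(SyntheticPatch(t0=300, theta0=90, duration=80,
                                    width=40, amplitude=1.0),
                     SyntheticPatch(t0=800, theta0=270, duration=200,
                                    width=60, amplitude=1.0),))
        arr, truth = generate_synthetic_kymo(spec)
        recs = extract_patches(binarize(arr, basal=0.0, excited=1.0),
                               degrees_per_site=dps)
        assert len(recs) == 2
        recs_by_t = sorted(recs, key=lambda r: r.centroid_t)
        for rec, p in zip(recs_by_t, truth):
            assert rec.duration == pytest.approx(p.duration, abs=2.0)
            assert rec.angular_extent == pytest.approx(p.width, abs=2 * dps)

    @pytest.mark.parametrize("angle", [0.0, 20.0, 40.0, 60.0])
    def test_orientation_sweep(self, angle):
        spec = SyntheticKymoSpec(
            n_points=126, n_times=1000, noise_sd=0.05, seed=6,
            patches=(SyntheticPatch(t0=500, theta0=180, duration=300,
                                    width=120, amplitude=1.0,
                                    orientation=angle, shape="ellipse"),))
        arr, _ = generate_synthetic_kymo(spec)
        (rec,) = extract_patches(binarize(arr, basal=0.0, excited=1.0),
                                 degrees_per_site=spec.degrees_per_site)
        assert rec.orientation == pytest.approx(angle, abs=3.0)


def test_sweep_heatmap_aggregation():
    import pandas as pd
    rows = []
    for a in (0.0, 1.0):
        for b in (0.0, 1.0):
            for rep in range(3):
                rows.append({"a_act": a, "a_myo": b,
                             "log10_ras_activity": a - b + 0.01 * rep,
                             "total_distance": 1.0,
                             "final_displacement": 0.5,
                             "is_polarized": a == 1.0})
    hm = sweep_heatmaps(pd.DataFrame(rows), "a_act", "a_myo")
    assert hm["polarized_count"].loc[0.0, 1.0] == 3
    assert hm["polarized_count"].loc[0.0, 0.0] == 0
    assert hm["log10_ras_activity"].loc[0.0, 1.0] == pytest.approx(1.01)
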