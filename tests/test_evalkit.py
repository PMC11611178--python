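"""Smoothing, metric suite vs a brute-force oracle, unit conversions,
cross-correlation alignment, and LOSO bookkeeping."""

import numpy as np
import pytest

import lumenflow as lf
from lumenflow.errors import ConfigError, DataError
from lumenflow.evalkit import (SmootherConfig, _moving_average, compute_metrics,
                               loso_evaluate, samples_to_mm, smooth,
                               xcorr_peak_lag)
from lumenflow.tracker_net import DiameterTrace
from lumenflow.training import TrainConfig


def _trace(values):
    return DiameterTrace(values=np.asarray(values, dtype=np.float64))


class TestSavitzkyGolay:
    def test_degree5_polynomial_reproduced_exactly(self):
        """A local order-5 fit is exact on any polynomial of degree <= 5."""
        t = np.linspace(-1, 1, 200)
        poly = 2 - t + 0.5 * t ** 2 - 3 * t ** 3 + t ** 4 + 0.25 * t ** 5
        out = smooth(_trace(poly)).values
        assert np.max(np.abs(out - poly)) < 1e-10

    def test_degree6_polynomial_not_reproduced(self):
        t = np.linspace(-5, 5, 200)
        poly = t ** 6
        out = smooth(_trace(poly)).values
        assert np.max(np.abs(out - poly)) > 1e-4

    def test_constant_trace_unchanged(self):
        out = smooth(_trace(np.full(100, 7.25)))
        assert np.allclose(out.values, 7.25)
        assert out.smoothed

    def test_reduces_white_noise_variance(self):
        rng = np.random.default_rng(0)
        t = np.arange(1000) / 500.0
        clean = 300 + 8 * np.sin(2 * np.pi * 1.0 * t)
        noisy = clean + rng.normal(0, 2.0, t.size)
        out = smooth(_trace(noisy)).values
        resid_before = np.var(noisy - clean)
        resid_after = np.var(out - clean)
        assert resid_after < 0.4 * resid_before

    def test_too_short_trace_rejected(self):
        with pytest.raises(DataError, match="window"):
            smooth(_trace(np.zeros(10)))

    def test_bad_configs_rejected(self):
        with pytest.raises(ConfigError):
            SmootherConfig(window=30)
        with pytest.raises(ConfigError):
            SmootherConfig(order=31)
        with pytest.raises(ConfigError):
            SmootherConfig(kind="median")


class TestMovingAverage:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        x = rng.random(80)
        got = _moving_average(x, 31)
        want = np.array([x[max(i - 15, 0):min(i + 16, 80)].mean()
                         for i in range(80)])
        assert np.allclose(got, want, atol=1e-12)

    def test_smooth_dispatch(self):
        x = np.random.default_rng(2).random(50)
        out = smooth(_trace(x), SmootherConfig(kind="moving_average", window=5))
        assert np.allclose(out.values, _moving_average(x, 5))


def oracle_metrics(pred, ref):
    """Independent from-the-definitions implementation of the metric suite."""
    pred, ref = np.asarray(pred, float), np.asarray(ref, float)
    n = len(pred)
    mp, mr = sum(pred) / n, sum(ref) / n
    cov = sum((p - mp) * (r - mr) for p, r in zip(pred, ref)) / n
    vp = sum((p - mp) ** 2 for p in pred) / n
    vr = sum((r - mr) ** 2 for r in ref) / n
    r = cov / (vp * vr) ** 0.5
    err = pred - ref
    diff = ref - pred
    md = diff - diff.mean()
    m2, m3, m4 = (sum(md ** k) / n for k in (2, 3, 4))
    return {
        "pearson_r": r,
        "r_squared": 1 - sum(err ** 2) / sum((ref - mr) ** 2),
        "ccc": 2 * cov / (vp + vr + (mp - mr) ** 2),
        "mae": sum(abs(err)) / n,
        "mse": sum(err ** 2) / n,
        "rmse": (sum(err ** 2) / n) ** 0.5,
        "mad_median": float(np.median(np.abs(err))),
        "mad_mean": sum(abs(err)) / n,
        "t_value": r * ((n - 2) / (1 - r ** 2)) ** 0.5,
        "skewness": m3 / m2 ** 1.5,
        "excess_kurtosis": m4 / m2 ** 2 - 3.0,
        "n": n,
    }


class TestComputeMetrics:
    def test_matches_oracle_to_1e10(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            ref = 300 + 10 * np.sin(np.linspace(0, 20, 400)) + rng.normal(0, 1, 400)
            pred = ref + rng.normal(0.5, 2.0, 400)
            got = compute_metrics(pred, ref).as_dict()
            want = oracle_metrics(pred, ref)
            for key, val in want.items():
                assert got[key] == pytest.approx(val, abs=1e-10), key

    def test_perfect_prediction(self):
        ref = np.sin(np.linspace(0, 10, 100)) + 5
        m = compute_metrics(ref.copy(), ref)
        assert m.pearson_r == pytest.approx(1.0)
        assert m.r_squared == pytest.approx(1.0)
        assert m.ccc == pytest.approx(1.0)
        assert m.mae == 0.0 and m.rmse == 0.0

    def test_r_squared_is_not_pearson_squared(self):
        """A biased but perfectly correlated prediction: r = 1 but the
        coefficient of determination drops below 1."""
        ref = np.sin(np.linspace(0, 10, 100)) + 5
        m = compute_metrics(ref + 3.0, ref)
        assert m.pearson_r == pytest.approx(1.0)
        assert m.r_squared < 0.0  # bias of 3 dwarfs the signal variance

    def test_input_validation(self):
        with pytest.raises(DataError):
            compute_metrics(np.zeros(2), np.zeros(2))
        with pytest.raises(DataError, match="constant"):
            compute_metrics(np.arange(5.0), np.full(5, 2.0))
        with pytest.raises(DataError):
            compute_metrics(np.zeros(5), np.zeros(6))


class TestSamplesToMM:
    def test_depth_scale(self):
        assert samples_to_mm(1.0) == pytest.approx(0.02465)
        assert samples_to_mm(np.array([100.0]))[0] == pytest.approx(2.465)

    def test_bad_scale_rejected(self):
        with pytest.raises(ConfigError):
            samples_to_mm(1.0, depth_scale_um=0.0)


class TestXcorrPeakLag:
    def test_aligned_series(self):
        t = np.linspace(0, 20, 1000)
        x = np.sin(t)
        assert xcorr_peak_lag(x + 5, 3 * x - 2) == 0

    def test_detects_known_shift(self):
        rng = np.random.default_rng(4)
        x = np.cumsum(rng.normal(size=2000))
        shifted = np.roll(x, 17)
        assert xcorr_peak_lag(shifted, x) == 17


@pytest.fixture(scope="module")
def result(small_cohort):
    cfg = TrainConfig(roi_epochs=2, tracker_epochs=2,
                      frames_per_epoch_roi=128,
                      frames_per_epoch_tracker=128, seed=0)
    return loso_evaluate(small_cohort, train_cfg=cfg, seed=5)


class TestLosoEvaluate:
    def test_table_structure(self, result, small_cohort):
        table, _ = result
        assert len(table) == small_cohort.n_subjects + 1
        assert list(table.subject)[-1] == "average"
        for col in ("pearson_r", "rmse", "mad_mean", "roi_mae",
                    "ref_diameter_mean", "xcorr_peak_lag", "n"):
            assert col in table.columns

    def test_average_row_is_unweighted_mean(self, result):
        table, _ = result
        body = table.iloc[:-1]
        avg = table.iloc[-1]
        assert avg.rmse == pytest.approx(body.rmse.mean())
        assert avg.pearson_r == pytest.approx(body.pearson_r.mean())

    def test_provenance_records_fold_seeds(self, result):
        _, prov = result
        assert prov["seed"] == 5 and prov["master_seed"] == 11
        assert [f["fold_seed"] for f in prov["folds"]] == [5 * 1009, 5 * 1009 + 1]
        for fold in prov["folds"]:
            assert fold["n_test_frames"] == 300
            assert np.isfinite(fold["tracker_final_train_loss"])

    def test_single_subject_rejected(self, small_cohort):
        single = lf.Cohort(spec=small_cohort.spec, master_seed=11,
                           subjects=small_cohort.subjects[:1])
        with pytest.raises(ConfigError):
            loso_evaluate(single)
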