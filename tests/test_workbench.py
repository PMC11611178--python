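"""Dataset I/O round-trips, checkpoints, run configuration, and the
end-to-end pipeline runner (smoke + determinism)."""

import json

import numpy as np
import pytest

import lumenflow as lf
from lumenflow import workbench
from lumenflow.errors import DataError
from lumenflow.roi_net import ROIDetector
from lumenflow.tracker_net import DiameterTracker
from lumenflow.training import TrainConfig
from lumenflow.workbench import (RunConfig, load_roi_checkpoint, read_dataset,
                                 run_pipeline, save_checkpoint, write_dataset)


class TestDatasetRoundTrip:
    def test_bit_identical(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.h5"
        write_dataset(small_cohort, path)
        back = read_dataset(path)
        assert back.master_seed == small_cohort.master_seed
        assert back.spec == small_cohort.spec
        assert back.n_subjects == small_cohort.n_subjects
        for orig, rt in zip(small_cohort.subjects, back.subjects):
            assert np.array_equal(orig.rf.samples, rt.rf.samples)
            assert np.array_equal(orig.annotation.diameter, rt.annotation.diameter)
            assert np.array_equal(orig.annotation.center, rt.annotation.center)
            assert rt.config == orig.config

    def test_envelope_and_extras_survive(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.h5"
        workbench.add_envelopes(small_cohort)
        small_cohort.subjects[0].extras["quality"] = np.arange(5.0)
        try:
            write_dataset(small_cohort, path)
            back = read_dataset(path)
            assert np.array_equal(back.subjects[0].envelope,
                                  small_cohort.subjects[0].envelope)
            assert np.array_equal(back.subjects[0].extras["quality"],
                                  np.arange(5.0))
        finally:
            small_cohort.subjects[0].extras.pop("quality")

    def test_missing_rf_named_in_error(self, small_cohort, tmp_path):
        import h5py
        path = tmp_path / "broken.h5"
        write_dataset(small_cohort, path)
        with h5py.File(path, "a") as fh:
            del fh["subject_1/rf"]
        with pytest.raises(DataError, match="subject_1/rf"):
            read_dataset(path)

    def test_empty_file_rejected(self, tmp_path):
        import h5py
        path = tmp_path / "empty.h5"
        with h5py.File(path, "w") as fh:
            fh.attrs["schema_version"] = 1
        with pytest.raises(DataError, match="no subject"):
            read_dataset(path)


class TestCheckpoints:
    def test_roi_round_trip_preserves_predictions(self, tmp_path):
        det = ROIDetector(lf.ROIConfig(), seed=4)
        path = tmp_path / "roi.npz"
        save_checkpoint(path, det, seed=4)
        back = load_roi_checkpoint(path)
        env = np.random.default_rng(0).random((3, 1020))
        assert np.array_equal(det.predict_centers(env), back.predict_centers(env))

    def test_tracker_round_trip_preserves_predictions(self, small_envelopes,
                                                      small_walls, tmp_path):
        """Round trip must preserve the batch-norm running statistics,
        not just the trainable weights — train briefly so they move."""
        cfg = TrainConfig(tracker_epochs=1, frames_per_epoch_tracker=64, seed=0)
        model, _ = lf.train_tracker(small_envelopes, small_walls, train_cfg=cfg)
        path = tmp_path / "trk.npz"
        save_checkpoint(path, model, seed=0)
        back = workbench.load_tracker_checkpoint(path)
        windows = small_envelopes[:8, 200:601]
        assert np.array_equal(model.predict(windows), back.predict(windows))

    def test_kind_mismatch_rejected(self, tmp_path):
        det = ROIDetector(lf.ROIConfig(), seed=0)
        path = tmp_path / "roi.npz"
        save_checkpoint(path, det, seed=0)
        with pytest.raises(DataError, match="tracker"):
            workbench.load_tracker_checkpoint(path)

    def test_tracker_checkpoint_stores_all_params(self, tmp_path):
        model = DiameterTracker(seed=0)
        path = tmp_path / "trk.npz"
        save_checkpoint(path, model, seed=0)
        with np.load(path, allow_pickle=False) as fh:
            stored = sum(fh[k].size for k in fh.files if k.startswith("param_"))
            assert bytes(fh["_kind"]) == b"tracker"
        assert stored == model.n_params()


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(n_subjects=3, frames_per_subject=120, seed=9)
        path = tmp_path / "run.yaml"
        cfg.to_yaml(path)
        back = RunConfig.from_yaml(path)
        assert back == cfg
        assert isinstance(back.tracker.conv_channels, tuple)

    def test_partial_yaml_uses_defaults(self, tmp_path):
        path = tmp_path / "partial.yaml"
        path.write_text("n_subjects: 4\n")
        cfg = RunConfig.from_yaml(path)
        assert cfg.n_subjects == 4
        assert cfg.frames_per_subject == 2000


@pytest.fixture(scope="module")
def tiny_run_config():
    return RunConfig(
        n_subjects=2, frames_per_subject=100, seed=3,
        train=TrainConfig(roi_epochs=2, tracker_epochs=2,
                          frames_per_epoch_roi=64,
                          frames_per_epoch_tracker=64, seed=3))


class TestRunPipeline:
    def test_smoke_writes_full_report(self, tiny_run_config, tmp_path):
        out = run_pipeline(tiny_run_config, tmp_path / "run1")
        for name in ("metrics.csv", "config.json", "provenance.json",
                     "manifest.json", "cohort.h5", "roi.ckpt.npz",
                     "tracker.ckpt.npz"):
            assert (out / name).exists(), name
        manifest = json.loads((out / "manifest.json").read_text())
        assert "metrics.csv" in manifest
        import pandas as pd
        table = pd.read_csv(out / "metrics.csv")
        assert len(table) == 3  # 2 subjects + average

    def test_end_to_end_deterministic(self, tiny_run_config, tmp_path):
        out1 = run_pipeline(tiny_run_config, tmp_path / "a")
        out2 = run_pipeline(tiny_run_config, tmp_path / "b")
        assert ((out1 / "metrics.csv").read_text()
                == (out2 / "metrics.csv").read_text())
        ck1 = np.load(out1 / "tracker.ckpt.npz")
        ck2 = np.load(out2 / "tracker.ckpt.npz")
        for key in ck1.files:
            if key.startswith("param_"):
                assert np.array_equal(ck1[key], ck2[key]), key
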