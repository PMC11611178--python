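"""Dataset container I/O, run configuration, and the reproducible
end-to-end pipeline runner.

Cohorts live in a single HDF5 file: one group per subject
(``/subject_<k>/rf``, optional ``/subject_<k>/envelope``,
``/subject_<k>/annotation/{anterior,posterior,center,diameter}``, optional
``labels/response``), subject-group attributes carrying the phantom
configuration, and file attributes carrying the acquisition constants and
master seed. Runs write a self-describing report directory: metrics.csv,
the resolved configuration, checkpoints, and a manifest with content
hashes so a run can be replayed and verified.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .errors import DataError
from .evalkit import SmootherConfig, loso_evaluate
from .labeling import response_matrix
from .phantom import (AcquisitionSpec, Cohort, GroundTruthAnnotation,
                      MModeRecord, PhantomSubjectConfig, SubjectRecording,
                      make_cohort)
from .preprocess import envelope_stack
from .roi_net import ROIConfig, ROIDetector
from .tracker_net import DiameterTracker, TrackerConfig
from .training import TrainConfig

__all__ = ["RunConfig", "read_dataset", "write_dataset", "run_pipeline",
           "save_checkpoint", "load_roi_checkpoint", "load_tracker_checkpoint"]

SCHEMA_VERSION = 1


@dataclasses.dataclass
class RunConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    acquisition: AcquisitionSpec = dataclasses.field(default_factory=AcquisitionSpec)
    roi: ROIConfig = dataclasses.field(default_factory=ROIConfig)
    tracker: TrackerConfig = dataclasses.field(default_factory=TrackerConfig)
    smoother: SmootherConfig = dataclasses.field(default_factory=SmootherConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    n_subjects: int = 6
    frames_per_subject: int = 2000
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for key, typ in [("acquisition", AcquisitionSpec), ("roi", ROIConfig),
                         ("tracker", TrackerConfig), ("smoother", SmootherConfig),
                         ("train", TrainConfig)]:
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                for f in dataclasses.fields(typ):
                    if f.name in sub and isinstance(sub[f.name], list):
                        sub[f.name] = tuple(sub[f.name])
                kwargs[key] = typ(**sub)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def write_dataset(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to HDF5 (see module docstring for the schema)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["master_seed"] = cohort.master_seed
        for f in dataclasses.fields(AcquisitionSpec):
            fh.attrs[f.name] = getattr(cohort.spec, f.name)
        for k, subject in enumerate(cohort.subjects):
            grp = fh.create_group(f"subject_{k}")
            grp.create_dataset("rf", data=subject.rf.samples)
            ann = grp.create_group("annotation")
            for name in ("anterior", "posterior", "center", "diameter"):
                ann.create_dataset(name, data=getattr(subject.annotation, name))
            for f in dataclasses.fields(PhantomSubjectConfig):
                value = getattr(subject.config, f.name)
                if f.name == "artifact_bands":
                    value = np.asarray(value, dtype=np.float64).reshape(-1, 2)
                grp.attrs[f.name] = value
            if subject.envelope is not None:
                grp.create_dataset("envelope", data=subject.envelope)
            for name, arr in subject.extras.items():
                grp.create_dataset(name, data=arr)


def read_dataset(path: str | Path) -> Cohort:
    """Read a cohort HDF5 file; unknown per-subject datasets are preserved
    in each subject's ``extras`` dict."""
    with h5py.File(path, "r") as fh:
        spec_kwargs = {f.name: fh.attrs[f.name].item()
                       if hasattr(fh.attrs[f.name], "item") else fh.attrs[f.name]
                       for f in dataclasses.fields(AcquisitionSpec)
                       if f.name in fh.attrs}
        spec_kwargs["depth_samples"] = int(spec_kwargs.get("depth_samples", 1020))
        spec = AcquisitionSpec(**spec_kwargs)
        master_seed = int(fh.attrs.get("master_seed", 0))
        subjects = []
        keys = sorted((k for k in fh if k.startswith("subject_")),
                      key=lambda s: int(s.split("_")[1]))
        if not keys:
            raise DataError(f"{path}: no subject groups found")
        for key in keys:
            grp = fh[key]
            if "rf" not in grp:
                raise DataError(f"{path}: missing required dataset /{key}/rf")
            if "annotation" not in grp:
                raise DataError(f"{path}: missing required group /{key}/annotation")
            cfg_kwargs = {}
            for f in dataclasses.fields(PhantomSubjectConfig):
                if f.name not in grp.attrs:
                    continue
                value = grp.attrs[f.name]
                if f.name == "artifact_bands":
                    value = tuple(tuple(row) for row in np.asarray(value).reshape(-1, 2))
                elif f.name == "seed":
                    value = int(value)
                elif isinstance(value, np.generic):
                    value = value.item()
                cfg_kwargs[f.name] = value
            config = PhantomSubjectConfig(**cfg_kwargs)
            annotation = GroundTruthAnnotation(
                anterior=grp["annotation/anterior"][...],
                posterior=grp["annotation/posterior"][...],
                center=grp["annotation/center"][...],
                diameter=grp["annotation/diameter"][...],
            )
            record = MModeRecord(samples=grp["rf"][...], spec=spec, kind="rf")
            envelope = grp["envelope"][...] if "envelope" in grp else None
            extras: dict = {}

            def _collect(name: str, obj, extras=extras) -> None:
                if (isinstance(obj, h5py.Dataset)
                        and name.split("/")[0] not in ("rf", "annotation",
                                                       "envelope")):
                    extras[name] = obj[...]

            grp.visititems(_collect)
            subjects.append(SubjectRecording(config=config, rf=record,
                                             annotation=annotation,
                                             envelope=envelope, extras=extras))
    return Cohort(spec=spec, master_seed=master_seed, subjects=subjects)


def add_envelopes(cohort: Cohort, decimation: int = 1) -> Cohort:
    """Fill each subject's normalized envelope stack (depth, frames)."""
    for subject in cohort.subjects:
        subject.envelope = envelope_stack(subject.rf.samples, decimation
                                          ).astype(np.float32)
    return cohort


def add_labels(cohort: Cohort) -> Cohort:
    """Attach response-vector labels under each subject's extras."""
    for subject in cohort.subjects:
        length = subject.rf.samples.shape[0]
        labels = response_matrix(subject.annotation.anterior,
                                 subject.annotation.posterior, length)
        subject.extras["labels/response"] = labels.T.astype(np.float32)
    return cohort


def save_checkpoint(path: str | Path, model: ROIDetector | DiameterTracker,
                    seed: int) -> None:
    """Serialize parameter and state tensors + config + seed to an .npz file."""
    named = {}
    prefix = "roi" if isinstance(model, ROIDetector) else "tracker"
    for i, p in enumerate(model.params()):
        named[f"param_{i}"] = p
    for i, b in enumerate(model.buffers()):
        named[f"buffer_{i}"] = b
    named["_config_json"] = np.bytes_(json.dumps(dataclasses.asdict(model.config)))
    named["_seed"] = np.int64(seed)
    named["_kind"] = np.bytes_(prefix)
    np.savez(path, **named)


def _restore(model, fh) -> None:
    for i, p in enumerate(model.params()):
        p[...] = fh[f"param_{i}"]
    for i, b in enumerate(model.buffers()):
        b[...] = fh[f"buffer_{i}"]


def load_roi_checkpoint(path: str | Path) -> ROIDetector:
    with np.load(path, allow_pickle=False) as fh:
        if bytes(fh["_kind"]) != b"roi":
            raise DataError(f"{path}: not an ROI-detector checkpoint")
        cfg_dict = json.loads(bytes(fh["_config_json"]).decode())
        detector = ROIDetector(ROIConfig(**cfg_dict))
        _restore(detector, fh)
    return detector


def load_tracker_checkpoint(path: str | Path) -> DiameterTracker:
    with np.load(path, allow_pickle=False) as fh:
        if bytes(fh["_kind"]) != b"tracker":
            raise DataError(f"{path}: not a diameter-tracker checkpoint")
        cfg_dict = json.loads(bytes(fh["_config_json"]).decode())
        for key in ("conv_channels", "fc_widths"):
            cfg_dict[key] = tuple(cfg_dict[key])
        tracker = DiameterTracker(TrackerConfig(**cfg_dict))
        _restore(tracker, fh)
    return tracker


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """simulate → preprocess → LOSO evaluation, with full provenance.

    Writes metrics.csv, config.json, the cohort HDF5 file, and a manifest
    of content hashes into ``out_dir``; identical (config, seed) pairs
    reproduce identical metrics.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = make_cohort(config.n_subjects, config.frames_per_subject,
                         master_seed=config.seed, spec=config.acquisition)
    add_envelopes(cohort, config.roi.decimation)
    data_path = out / "cohort.h5"
    write_dataset(cohort, data_path)

    table, provenance = loso_evaluate(cohort, config.roi, config.tracker,
                                      config.smoother, config.train,
                                      seed=config.seed)

    # final deployment models trained on the full cohort
    from .roi_net import train_roi
    from .tracker_net import train_tracker
    env_all = np.concatenate([s.envelope.T for s in cohort.subjects]).astype(np.float32)
    walls_all = np.concatenate(
        [np.column_stack([s.annotation.anterior, s.annotation.posterior])
         for s in cohort.subjects])
    final_cfg = dataclasses.replace(config.train, seed=config.seed)
    detector, _ = train_roi(env_all, walls_all, config.roi, final_cfg)
    tracker, _ = train_tracker(env_all, walls_all, config.tracker, final_cfg)
    save_checkpoint(out / "roi.ckpt.npz", detector, config.seed)
    save_checkpoint(out / "tracker.ckpt.npz", tracker, config.seed)

    metrics_path = out / "metrics.csv"
    table.to_csv(metrics_path, index=False)
    with open(out / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    manifest = {p.name: _sha256(p) for p in sorted(out.iterdir())
                if p.name != "manifest.json" and p.is_file()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
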