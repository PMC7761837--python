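"""End-to-end orchestration: simulate -> denoise -> segment -> train ->
generate -> evaluate.

Every stage is a pure function of (inputs, config, seed); each stage's
output is persisted under the run directory so a run can be inspected or
resumed, and the summary carries per-class synthetic counts (always equal
to the original counts) plus mean evaluation metrics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .denoise import ThresholdMode, denoise
from .gan import GanConfig, GanModel, generate_synthetic, save_model, train_per_class
from .io import (FixtureSpec, SignalRecord, SignalType, generate_fixture,
                 read_record, write_record)
from .metrics import evaluate
from .segmentation import (SegmentMatrix, resample_to_min,
                           segment_by_annotation, segment_by_rr_median,
                           zscore_set)

__all__ = ["PipelineConfig", "run_pipeline", "load_config",
           "write_segments_csv", "read_segments_csv"]

log = logging.getLogger("synsiggan")


@dataclass
class PipelineConfig:
    """Everything one run needs; YAML-loadable, flag-overridable."""

    # input: either a fixture spec (simulate) or a CSV path
    input_path: str | None = None
    signal_type: str = "ECG"
    n_segments: int = 64
    segment_length_range: tuple[int, int] = (58, 70)
    fs: float = 360.0
    noise_snr_db: float = 10.0
    class_labels: tuple[str, ...] = ("NB",)

    # stage toggles
    do_denoise: bool = True
    do_train: bool = True

    # denoising
    levels: int = 4
    window: int = 32
    threshold_mode: str = "hard"
    wavelet: str = "db2"

    # segmentation
    segment_mode: str = "annotation"      # or "rr"
    resample_tol: float = 1e-6

    # adversarial stage
    gan: GanConfig = field(default_factory=GanConfig)

    seed: int = 0
    out_dir: str = "synsiggan_run"

    def fixture_spec(self) -> FixtureSpec:
        return FixtureSpec(SignalType(self.signal_type), self.n_segments,
                           tuple(self.segment_length_range), self.fs,
                           self.noise_snr_db, tuple(self.class_labels),
                           self.seed)


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML mapping (nested ``gan:`` section)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gan_raw = raw.pop("gan", {})
    for key in ("conv_filters", "kernel_sizes", "pool_sizes"):
        if key in gan_raw:
            gan_raw[key] = tuple(gan_raw[key])
    for key in ("segment_length_range", "class_labels"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(gan=GanConfig(**gan_raw), **raw)


def write_segments_csv(matrix: SegmentMatrix, path) -> None:
    """Columnar long-form container: class,segment,sample,value."""
    with open(path, "w") as fh:
        fh.write("class,segment,sample,value\n")
        for label in sorted(matrix.matrices):
            rows = matrix.matrices[label]
            for k, row in enumerate(rows):
                for i, v in enumerate(row):
                    fh.write(f"{label},{k},{i},{v:.17g}\n")


def read_segments_csv(path) -> SegmentMatrix:
    data: dict[str, dict[int, list[float]]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            label, k, _i, v = line.rstrip("\n").split(",")
            data.setdefault(label, {}).setdefault(int(k), []).append(float(v))
    matrices = {label: np.array([segs[k] for k in sorted(segs)])
                for label, segs in data.items()}
    flags = {label: np.zeros(m.shape[0], dtype=bool)
             for label, m in matrices.items()}
    return SegmentMatrix(matrices, flags)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage(name, config):
    start = time.perf_counter()

    def done(**extra):
        log.info("stage=%s seed=%d config=%s duration=%.2fs %s", name,
                 config.seed, _config_hash(config),
                 time.perf_counter() - start,
                 " ".join(f"{k}={v}" for k, v in extra.items()))

    return done


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the staged pipeline; returns a JSON-serialisable summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "config_hash": _config_hash(config),
                     "stages": [], "paths": {}}

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- acquire -------------------------------------------------------------
    done = _stage("acquire", config)
    try:
        if config.input_path:
            record = read_record(config.input_path, "CSV")
        else:
            record = generate_fixture(config.fixture_spec())
        raw_path = out / "raw.csv"
        write_record(record, raw_path)
        summary["paths"]["raw"] = str(raw_path)
    except Exception as exc:
        fail("acquire", exc)
    done(n_samples=len(record))
    summary["stages"].append("acquire")

    # --- denoise -------------------------------------------------------------
    if config.do_denoise:
        done = _stage("denoise", config)
        try:
            record = denoise(record, config.levels, config.window,
                             ThresholdMode(config.threshold_mode),
                             config.wavelet)
            den_path = out / "denoised.csv"
            write_record(record, den_path)
            summary["paths"]["denoised"] = str(den_path)
        except Exception as exc:
            fail("denoise", exc)
        done()
        summary["stages"].append("denoise")

    # --- segment -------------------------------------------------------------
    done = _stage("segment", config)
    try:
        segset = (segment_by_rr_median(record) if config.segment_mode == "rr"
                  else segment_by_annotation(record))
        matrix = resample_to_min(zscore_set(segset), config.resample_tol)
        seg_path = out / "segments.csv"
        write_segments_csv(matrix, seg_path)
        summary["paths"]["segments"] = str(seg_path)
        summary["original_counts"] = {k: int(v) for k, v in matrix.n.items()}
    except Exception as exc:
        fail("segment", exc)
    done(classes=len(matrix.matrices))
    summary["stages"].append("segment")

    if not config.do_train:
        return summary

    # --- train + generate + evaluate ----------------------------------------
    done = _stage("train", config)
    try:
        trained = train_per_class(matrix, config.gan)
    except Exception as exc:
        fail("train", exc)
    done(classes=len(trained))
    summary["stages"].append("train")

    done = _stage("generate+evaluate", config)
    synthetic_counts, per_class_metrics = {}, {}
    try:
        for k, (label, (model, trace)) in enumerate(sorted(trained.items())):
            model_path = out / f"model_{label}.npz"
            save_model(model, model_path)
            summary["paths"][f"model_{label}"] = str(model_path)

            originals = matrix.matrices[label]
            n = originals.shape[0]
            synth = generate_synthetic(model, n,
                                       seed=(config.seed + 7919 * (k + 1)) % (2 ** 31))
            synthetic_counts[label] = len(synth)
            synth_rec = SignalRecord(np.concatenate(synth), config.fs,
                                     SignalType(config.signal_type),
                                     record_id=f"synthetic-{label}")
            synth_path = out / f"synthetic_{label}.csv"
            write_record(synth_rec, synth_path)
            summary["paths"][f"synthetic_{label}"] = str(synth_path)

            mean_report, _ = evaluate(zip(originals, synth))
            per_class_metrics[label] = dataclasses.asdict(mean_report)
            per_class_metrics[label]["final_g_loss"] = trace.g_loss[-1]
            per_class_metrics[label]["final_d_loss"] = trace.d_loss[-1]
    except Exception as exc:
        fail("generate+evaluate", exc)
    done()
    summary["stages"] += ["generate", "evaluate"]
    summary["synthetic_counts"] = synthetic_counts
    summary["metrics"] = per_class_metrics
    summary["count_parity"] = all(
        synthetic_counts[c] == summary["original_counts"][c]
        for c in synthetic_counts)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    summary["paths"]["summary"] = str(out / "summary.json")
    return summary
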