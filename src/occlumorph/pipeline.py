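"""End-to-end orchestration: simulate -> extract -> EFA -> grade ->
consensus -> classify -> report.

A run is described by a plain-text YAML config (schema in
``docs/methods.md``), executed with :func:`run_pipeline`, and leaves
behind every intermediate artifact (outline CSVs, coefficient CSVs,
distance tables, condition reports) plus a manifest with the config
hash, seed, artifact checksums, per-stage timings and warnings — so
every number in the final report can be re-derived from saved
intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .classify import ConditionResults, ForestConfig, run_conditions
from .contours import binarize, extract_contour, load_image
from .efa import canonicalize
from .shapes import ConsensusConfig, TracingBundle, error_summary, filter_tracings
from .synthetic import (WorkerNoiseModel, generate_population,
                        simulate_worker_tracings, write_dataset)

__all__ = ["RunConfig", "RunManifest", "load_config", "run_pipeline",
           "validate_inputs"]


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for a full pipeline run."""

    seed: int = 0
    out_dir: str = "occlumorph_run"
    template_preset: str = "lm2_three_tribe"   # or "default_four_tribe"
    coeff_sd_scale: float = 0.03
    noise: WorkerNoiseModel = field(default_factory=WorkerNoiseModel)
    harmonics: int = 10
    landmarks: int = 150
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    resamples: int = 20
    drop_normalized_entries: bool = False
    write_masks: bool = False

    def __post_init__(self) -> None:
        if self.landmarks < 3:
            raise ValueError("landmarks (K) must be >= 3")
        if self.resamples < 1:
            raise ValueError("resamples must be >= 1")

    def templates(self):
        presets = {"lm2_three_tribe": synthetic.lm2_templates,
                   "default_four_tribe": synthetic.default_templates,
                   "mini_three_tribe": synthetic.mini_templates}
        if self.template_preset not in presets:
            raise ValueError(f"unknown template preset {self.template_preset!r}; "
                             f"choose from {sorted(presets)}")
        return presets[self.template_preset](coeff_sd_scale=self.coeff_sd_scale,
                                             H=self.harmonics)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timings: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run config; unknown keys are rejected loudly."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    simple = {"seed", "out_dir", "template_preset", "coeff_sd_scale",
              "harmonics", "landmarks", "resamples",
              "drop_normalized_entries", "write_masks"}
    for key, value in raw.items():
        if key in simple:
            kwargs[key] = value
        elif key == "noise":
            kwargs["noise"] = WorkerNoiseModel(**value)
        elif key == "consensus":
            kwargs["consensus"] = ConsensusConfig(**value)
        elif key == "forest":
            kwargs["forest"] = ForestConfig(**value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return RunConfig(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig) -> tuple[RunManifest, dict]:
    """Execute every stage and write artifacts under ``config.out_dir``.

    Returns the manifest and the report dict (also written as
    ``report.json``).  Deterministic stages are bit-reproducible under
    a fixed seed; forest training and resampling are seeded.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config), seed=config.seed)
    caught: list[str] = []

    def timed(stage):
        class _T:
            def __enter__(self_t):
                self_t.t0 = time.perf_counter()
                self_t.ctx = warnings.catch_warnings(record=True)
                self_t.records = self_t.ctx.__enter__()
                warnings.simplefilter("always")
                return self_t

            def __exit__(self_t, *exc):
                manifest.timings[stage] = time.perf_counter() - self_t.t0
                for w in self_t.records:
                    caught.append(f"{stage}: {w.message}")
                self_t.ctx.__exit__(*exc)
        return _T()

    # 1. simulate
    with timed("simulate"):
        dataset = generate_population(config.templates(), seed=config.seed,
                                      K=config.landmarks)
        dataset = simulate_worker_tracings(dataset, config.noise,
                                           seed=config.seed + 1)
        paths = write_dataset(dataset, out / "synthetic",
                              masks=config.write_masks)

    # 2-3. extract + EFA (canonical landmark regeneration for every outline)
    with timed("canonicalize"):
        truth = {s.specimen_id: canonicalize(s.landmarks, H=config.harmonics,
                                             K=config.landmarks)
                 for s in dataset.specimens}
        traced = {sid: [canonicalize(t, H=config.harmonics, K=config.landmarks)
                        for t in ts]
                  for sid, ts in dataset.tracings.items()}

    # 4. grade
    with timed("grade"):
        bundles = []
        for s in dataset.specimens:
            b = TracingBundle(specimen_id=s.specimen_id,
                              gold=truth[s.specimen_id],
                              tracings=traced.get(s.specimen_id, []))
            bundles.append(filter_tracings(b, config.consensus))
        rows = [{"specimen_id": b.specimen_id, "tracing_id": tid,
                 "distance": float(d), "kept": bool(k)}
                for b in bundles
                for tid, d, k in zip(b.tracing_ids, b.distances, b.kept)]
        grades = pd.DataFrame(rows,
                              columns=["specimen_id", "tracing_id",
                                       "distance", "kept"])
        grades.to_csv(out / "tracing_grades.csv", index=False)
        graded = [b for b in bundles if len(b.tracings)]
        summary, hist = error_summary(graded, dataset.metadata(),
                                      group_by="tooth_position") \
            if graded else (pd.DataFrame(), pd.DataFrame())
        summary.to_csv(out / "error_summary_by_position.csv", index=False)
        hist.to_csv(out / "error_histogram.csv", index=False)

    # 5-6. consensus + classification conditions
    with timed("classify"):
        results = run_conditions(
            dataset, consensus=config.consensus, forest=config.forest,
            H=config.harmonics, R=config.resamples, seed=config.seed,
            drop_normalized_entries=config.drop_normalized_entries)
        pd.DataFrame({"resample": np.arange(config.resamples),
                      "log_loss": results.single_worker_log_losses}
                     ).to_csv(out / "single_worker_log_losses.csv", index=False)

    # 7. report
    with timed("report"):
        report = _build_report(config, grades, results)
        (out / "report.json").write_text(json.dumps(report, indent=2))

    manifest.warnings = caught
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest.artifacts[str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest, report


def _build_report(config: RunConfig, grades: pd.DataFrame,
                  results: ConditionResults) -> dict:
    conditions = {}
    for name, rep in results.reports.items():
        conditions[name] = {
            "log_loss": rep.log_loss,
            "classification_rate": rep.classification_rate,
            "classification_rate_pct": round(100 * rep.classification_rate),
            "confusion": {"classes": list(rep.confusion.classes),
                          "counts": rep.confusion.counts.tolist()},
            "n_dropped": rep.n_dropped,
        }
    losses = results.single_worker_log_losses
    return {
        "seed": config.seed,
        "n_tracings": int(len(grades)),
        "n_rejected": int((~grades["kept"]).sum()) if len(grades) else 0,
        "median_worker_distance": float(grades["distance"].median())
        if len(grades) else None,
        "conditions": conditions,
        "single_worker_log_loss": {"mean": float(losses.mean()),
                                   "min": float(losses.min()),
                                   "max": float(losses.max())},
    }


def validate_inputs(image_dir: str | Path,
                    metadata: pd.DataFrame | str | Path | None = None) -> dict:
    """Ingest check for a directory of tracing images.

    Lists unreadable files, wrong formats (e.g. GIMP .xcf project files
    submitted instead of rendered images), empty masks, masks touching
    the image border, and image stems missing from the metadata table.
    Nothing is silently dropped; this only reports.
    """
    image_dir = Path(image_dir)
    if metadata is not None and not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata)
    known = set(metadata["specimen_id"]) if metadata is not None else None
    report = {"ok": [], "rejects": [], "warnings": []}
    for path in sorted(image_dir.iterdir()):
        if path.is_dir():
            continue
        if path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            report["rejects"].append(
                {"file": path.name,
                 "reason": f"unsupported format {path.suffix!r}"})
            continue
        try:
            img = load_image(path)
        except Exception as exc:  # unreadable / truncated file
            report["rejects"].append({"file": path.name,
                                      "reason": f"unreadable: {exc}"})
            continue
        mask = binarize(img)
        if mask.is_empty:
            report["rejects"].append({"file": path.name,
                                      "reason": "no tracing found"})
            continue
        if mask.touches_border():
            report["warnings"].append({"file": path.name,
                                       "reason": "foreground touches border"})
        if known is not None and path.stem.split("_")[0] not in known:
            report["warnings"].append({"file": path.name,
                                       "reason": "specimen not in metadata"})
        report["ok"].append(path.name)
    return report
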