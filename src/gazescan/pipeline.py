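"""End-to-end pipeline: simulate -> render -> preprocess -> train -> correlate.

One :class:`RunConfig` (serializable to a single JSON document, one seed
for everything) drives all stages.  Outputs land in a run directory with
a machine-readable ``summary.json``; each completed stage leaves a
marker containing the config hash, so re-running with an unchanged
config skips completed stages, while any config change invalidates them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from .classify import (
    ModelConfig,
    PARTICIPANT_WISE,
    save_model,
    train_crossval,
)
from .correlation import correlate_cohort
from .errors import ConfigError, GazeScanError
from .io import (
    ImageEntry,
    read_gaze_records,
    read_manifest,
    write_manifest,
)
from .preprocess import PreprocessConfig, preprocess_images
from .render import DEFAULT_DIMS, render_recording, save_images
from .synth import CohortSpec, generate_cohort

log = logging.getLogger("gazescan.pipeline")


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable to one JSON file."""

    outdir: str = "gazescan_run"
    seed: int = 0
    simulate: bool = False
    # simulation
    n_asd: int = 29
    n_td: int = 30
    recordings_per_participant: int = 2
    duration_s: float = 4.0
    identical_profiles: bool = False
    # rendering
    render_dims: tuple[int, int] = DEFAULT_DIMS
    max_points: int = 200
    min_points: int = 20
    g_min: float = 0.1
    invert_gray: bool = False
    # preprocessing
    target_dims: tuple[int, int] = (256, 256)
    augment_per_image: int = 5
    # training
    conv_filters: tuple[int, ...] = (32, 32, 64, 64)
    dense_width: int = 512
    epochs: int = 3
    folds: int = 3
    validation_fraction: float = 0.2
    batch_size: int = 32
    learning_rate: float = 1e-3
    split_mode: str = PARTICIPANT_WISE
    train_on_augmented: bool = True
    # correlation
    include_non_asd: bool = False
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def model_config(self) -> ModelConfig:
        w, h = self.target_dims
        return ModelConfig(
            conv_filters=tuple(self.conv_filters),
            dense_width=self.dense_width,
            input_dims=(h, w, 1),
            epochs=self.epochs,
            folds=self.folds,
            validation_fraction=self.validation_fraction,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=self.seed,
        )

    @classmethod
    def from_json_file(cls, path: str | Path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        for key in ("render_dims", "target_dims", "conv_filters"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


class _Stages:
    """Marker-file bookkeeping for resumable stages."""

    def __init__(self, outdir: Path, config_hash: str):
        self.dir = outdir / ".stages"
        self.dir.mkdir(parents=True, exist_ok=True)
        self.hash = config_hash

    def done(self, name: str) -> bool:
        marker = self.dir / f"{name}.done"
        return marker.exists() and marker.read_text().strip() == self.hash

    def mark(self, name: str) -> None:
        (self.dir / f"{name}.done").write_text(self.hash)


def run_pipeline(
    config: RunConfig,
    gaze_dir: str | Path | None = None,
    manifest_path: str | Path | None = None,
) -> dict:
    """Run every stage and return the summary dictionary.

    Inputs are either simulated (``config.simulate``) or read from
    ``gaze_dir`` (delimited gaze exports) plus ``manifest_path``.  Any
    stage failure aborts with the stage name in the exception.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = _Stages(outdir, config.config_hash())
    (outdir / "run_config.json").write_text(config.to_json())
    summary_path = outdir / "summary.json"
    summary: dict = (
        json.loads(summary_path.read_text()) if summary_path.exists() else {}
    )
    if (
        summary.get("config_hash") == config.config_hash()
        and all(stages.done(s) for s in ("render", "train", "correlate"))
    ):
        log.info("all stages up to date for config %s; skipping run",
                 config.config_hash())
        summary["resumed"] = True
        return summary
    summary["config_hash"] = config.config_hash()

    def save_summary() -> None:
        summary_path.write_text(json.dumps(summary, indent=1, default=str))

    # ---- stage: inputs -------------------------------------------------
    stage = "inputs"
    if config.simulate:
        spec = CohortSpec(
            n_asd=config.n_asd,
            n_td=config.n_td,
            recordings_per_participant=config.recordings_per_participant,
            duration_s=config.duration_s,
            seed=config.seed,
        )
        if config.identical_profiles:
            from .synth import td_profile

            spec.profile_asd = td_profile()
        manifest, recordings = generate_cohort(spec)
        log.info("simulated %d participants, %d recordings",
                 len(manifest.participants), len(recordings))
    else:
        if manifest_path is None or gaze_dir is None:
            raise ConfigError(
                "pipeline needs --simulate or both a gaze directory and a "
                f"manifest (got gaze_dir={gaze_dir!r}, manifest={manifest_path!r})"
            )
        manifest_path, gaze_dir = Path(manifest_path), Path(gaze_dir)
        if not manifest_path.exists():
            raise ConfigError(f"[{stage}] manifest not found: {manifest_path}")
        manifest = read_manifest(manifest_path)
        recordings = []
        files = sorted(gaze_dir.glob("*.csv")) + sorted(gaze_dir.glob("*.tsv"))
        if not files:
            raise ConfigError(f"[{stage}] no gaze exports under {gaze_dir}")
        for f in files:
            recordings.extend(read_gaze_records(f))
    summary["inputs"] = {
        "participants": len(manifest.participants),
        "recordings": len(recordings),
    }
    save_summary()

    # ---- stage: render -------------------------------------------------
    stage = "render"
    image_dir = outdir / "images"
    all_segments, all_images = [], []
    labels = {p.participant_id: p.group for p in manifest.participants}
    for rec in recordings:
        try:
            segs, imgs = render_recording(
                rec,
                dims=config.render_dims,
                max_points=config.max_points,
                min_points=config.min_points,
                g_min=config.g_min,
                invert_gray=config.invert_gray,
                label=labels.get(rec.participant_id),
            )
        except GazeScanError as exc:
            raise GazeScanError(
                f"[{stage}] failed on recording "
                f"{rec.participant_id}/{rec.stimulus_id}: {exc}"
            ) from exc
        all_segments.extend(segs)
        all_images.extend(imgs)
    manifest.images = [
        ImageEntry(
            image=f"{img.name}.png",
            participant_id=img.participant_id,
            stimulus_id=img.stimulus_id,
            segment=img.segment_index,
        )
        for img in all_images
    ]
    if not stages.done(stage):
        save_images(all_images, image_dir)
        write_manifest(manifest, outdir / "manifest.json")
        stages.mark(stage)
    else:
        log.info("render outputs up to date, skipping write")
    assert len(all_images) == sum(1 for _ in all_segments)
    summary["render"] = {"images": len(all_images), "segments": len(all_segments)}
    save_summary()

    # ---- stage: preprocess --------------------------------------------
    stage = "preprocess"
    pconfig = PreprocessConfig(
        target_dims=config.target_dims,
        augment_per_image=config.augment_per_image,
        seed=config.seed,
    )
    processed, augmented = preprocess_images(all_images, pconfig)
    summary["preprocess"] = {
        "processed": len(processed),
        "augmented": len(augmented),
        "all_black": sum("all_black" in img.flags for img in processed),
    }
    save_summary()

    # ---- stage: train --------------------------------------------------
    stage = "train"
    mconfig = config.model_config()
    try:
        models, report = train_crossval(
            manifest,
            processed,
            mconfig,
            split_mode=config.split_mode,
            augmented=augmented if config.train_on_augmented else None,
        )
    except GazeScanError as exc:
        raise GazeScanError(f"[{stage}] {exc}") from exc
    if not stages.done(stage):
        report.to_json(outdir / "evaluation.json")
        with open(outdir / "roc_points.csv", "w") as fh:
            fh.write("fold,fpr,tpr\n")
            for f in report.folds:
                for a, b in zip(f.fpr, f.tpr):
                    fh.write(f"{f.fold},{a},{b}\n")
        save_model(models[0], mconfig, outdir / "model_fold0.npz")
        stages.mark(stage)
    summary["train"] = report.summary()
    save_summary()

    # ---- stage: correlate ----------------------------------------------
    stage = "correlate"
    try:
        mic, pairs = correlate_cohort(
            manifest, all_segments, include_non_asd=config.include_non_asd
        )
        if not stages.done(stage):
            pairs.to_csv(outdir / "velocity_cars_pairs.csv")
            (outdir / "mic.json").write_text(
                json.dumps({"mic": mic, "n_pairs": len(pairs)})
            )
            stages.mark(stage)
        summary["correlate"] = {"mic": round(mic, 4), "n_pairs": len(pairs)}
    except GazeScanError as exc:
        log.warning("[%s] skipped: %s", stage, exc)
        summary["correlate"] = {"error": str(exc)}
        stages.mark(stage)
    save_summary()
    return summary
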