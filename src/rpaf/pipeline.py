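"""End-to-end orchestration: simulate -> prep -> RP -> train -> evaluate.

Every stochastic stage derives its seed deterministically from one master
seed, so a run is fully reproducible from its YAML config.  Artifacts are
written under ``output_dir/run_id`` with a manifest of content hashes;
reruns reuse cached RP image tensors when the underlying records are
unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from rpaf.dataset import LeadImageDataset, build_lead_image_dataset
from rpaf.evaluation import MetricsReport, confusion, metrics
from rpaf.lead_selection import SelectionConfig
from rpaf.parnet_adv import ModelConfig, TrainedModel, build_model, predict, train
from rpaf.recurrence import RpConfig
from rpaf.signal_prep import PrepConfig, balance_and_split, select_single_label, write_record
from rpaf.synthetic_ecg import SynthConfig, generate_dataset, child_seed

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Nested configuration of a full pipeline run."""

    synth: SynthConfig = SynthConfig()
    prep: PrepConfig = PrepConfig()
    rp: RpConfig = RpConfig()
    model: ModelConfig = ModelConfig()
    selection: SelectionConfig = SelectionConfig()
    n_per_class: int = 40
    leads: tuple[str, ...] = ("II", "V1")
    run_id: str = "run"
    output_dir: str = "runs"
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        offsets = {"synth": 0, "prep": 1, "model": 2, "selection": 3, "grid": 4}
        return child_seed(self.seed, offsets[stage])

    def resolved(self) -> "RunConfig":
        """Propagate the master seed into each stage config."""
        return replace(
            self,
            synth=replace(self.synth, seed=self.stage_seed("synth")),
            prep=replace(self.prep, seed=self.stage_seed("prep")),
            model=replace(self.model, seed=self.stage_seed("model")),
            selection=replace(self.selection, seed=self.stage_seed("selection")),
        )


_SECTION_TYPES = {
    "synth": SynthConfig,
    "prep": PrepConfig,
    "rp": RpConfig,
    "model": ModelConfig,
    "selection": SelectionConfig,
}


def _coerce(cls, mapping: dict):
    defaults = cls()
    kwargs = {}
    valid = {f.name for f in dataclasses.fields(cls) if f.init}
    for key, val in mapping.items():
        if key not in valid:
            raise ValueError(f"unknown key {key!r} for {cls.__name__}")
        current = getattr(defaults, key)
        if isinstance(current, tuple) and isinstance(val, (list, tuple)):
            val = tuple(val)
        kwargs[key] = val
    return replace(defaults, **kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file of (possibly partial) sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in raw:
            kwargs[name] = _coerce(cls, raw.pop(name) or {})
    for key in ("n_per_class", "run_id", "output_dir", "seed"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if "leads" in raw:
        kwargs["leads"] = tuple(raw.pop("leads"))
    if raw:
        raise ValueError(f"unknown top-level config keys: {sorted(raw)}")
    return RunConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def evaluate_model(model: TrainedModel, dataset: LeadImageDataset, leads: Sequence[str]) -> MetricsReport:
    X = dataset.stack(leads)
    pred = predict(model, X).argmax(axis=1)
    return metrics(confusion(dataset.labels, pred, positive=1))


def run_end_to_end(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write artifacts + manifest.

    Returns a dict with the trained model, the test-set MetricsReport and
    the artifact directory.  RP image tensors are cached: a rerun whose
    record files hash identically reuses the cached tensors.
    """
    cfg = cfg.resolved()
    out = Path(cfg.output_dir) / cfg.run_id
    rec_dir = out / "records"
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    old_manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {"files": {}}

    # stage 1: simulate
    records = generate_dataset(cfg.synth, cfg.n_per_class, seed=cfg.synth.seed)
    rec_files = {}
    for rec in records:
        p = write_record(rec, rec_dir / f"{rec.record_id}.csv")
        rec_files[str(p.relative_to(out))] = _sha256(p)

    # stage 2: prep (single-label filter, balance, inter-patient split)
    kept = select_single_label(records)
    train_records, test_records = balance_and_split(kept, cfg.prep)

    # stage 3: RP conversion (cached)
    images_path = out / "images" / "rp_images.npz"
    records_unchanged = all(old_manifest["files"].get(k) == v for k, v in rec_files.items()) and images_path.exists()
    if records_unchanged:
        log.info("rp-convert: cache hit, reusing %s", images_path)
        with np.load(images_path, allow_pickle=False) as data:
            def _restore(prefix, recs):
                return LeadImageDataset(
                    images={l: data[f"{prefix}_{l}"] for l in cfg.leads},
                    labels=data[f"{prefix}_labels"],
                    record_ids=[r.record_id for r in recs],
                )
            train_ds = _restore("train", train_records)
            test_ds = _restore("test", test_records)
        converted = False
    else:
        train_ds = build_lead_image_dataset(train_records, cfg.leads, cfg.prep, cfg.rp)
        test_ds = build_lead_image_dataset(test_records, cfg.leads, cfg.prep, cfg.rp)
        images_path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for prefix, ds in (("train", train_ds), ("test", test_ds)):
            for l, arr in ds.images.items():
                arrays[f"{prefix}_{l}"] = arr
            arrays[f"{prefix}_labels"] = ds.labels
        np.savez(images_path, **arrays)
        converted = True

    # stage 4: train
    model_cfg = replace(cfg.model, in_channels=3 * len(cfg.leads))
    model = build_model(model_cfg)
    train(model, train_ds.stack(cfg.leads), train_ds.labels)
    ckpt = model.save(out / "model" / "checkpoint.npz")

    # stage 5: evaluate
    report = evaluate_model(model, test_ds, cfg.leads)
    metrics_path = out / "metrics.json"
    metrics_path.write_text(
        json.dumps({"test": report.rounded(), "counts": dataclasses.asdict(report.counts)}, indent=1)
    )

    files = dict(rec_files)
    for p in (images_path, ckpt, ckpt.with_suffix(".json"), metrics_path):
        files[str(p.relative_to(out))] = _sha256(p)
    manifest = {
        "run_id": cfg.run_id,
        "seed": cfg.seed,
        "converted_images": converted,
        "files": files,
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return {"model": model, "report": report, "output_dir": out, "manifest": manifest}


def run_grid(
    cfg: RunConfig,
    freqs: Sequence[float] = (200.0, 300.0, 500.0),
    lengths: Sequence[float] = (5.0, 10.0),
    n_seeds: int = 1,
) -> list[dict]:
    """Sampling-rate x segment-length grid of AF-detection performance.

    For each (frequency, length) cell and each seed, a balanced synthetic
    dataset generated at the source rate is resampled and truncated, imaged
    and classified; the row records the five test-set metrics.  Source
    records are shared within a seed so cells differ only in conditioning.
    """
    cfg = cfg.resolved()
    rows = []
    for s in range(n_seeds):
        seed = child_seed(cfg.stage_seed("grid"), s)
        records = generate_dataset(cfg.synth, cfg.n_per_class, seed=seed)
        for freq in freqs:
            for seg_len in lengths:
                prep = replace(cfg.prep, target_fs=float(freq), segment_len=float(seg_len), seed=seed)
                train_records, test_records = balance_and_split(records, prep)
                train_ds = build_lead_image_dataset(train_records, cfg.leads, prep, cfg.rp)
                test_ds = build_lead_image_dataset(test_records, cfg.leads, prep, cfg.rp)
                model_cfg = replace(cfg.model, in_channels=3 * len(cfg.leads), seed=seed)
                model = build_model(model_cfg)
                train(model, train_ds.stack(cfg.leads), train_ds.labels)
                rep = evaluate_model(model, test_ds, cfg.leads)
                row = {"frequency_hz": freq, "length_s": seg_len, "seed_index": s}
                row.update(rep.rounded())
                rows.append(row)
    return rows


def grid_table(rows: list[dict]) -> str:
    """Render grid rows as a TSV table (frequency x length layout)."""
    cols = ["frequency_hz", "length_s", "seed_index", "f1", "precision", "recall", "specificity", "accuracy"]
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append("\t".join(str(row[c]) for c in cols))
    return "\n".join(lines)
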