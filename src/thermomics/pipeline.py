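"""End-to-end orchestration: simulate -> lowrank -> features -> encode -> classify.

A run is fully determined by its :class:`RunConfig` and global seed (with
seeded-random backbone weights). Stages write their intermediates into the
run directory; expensive stages (simulation, deep features) are cached by a
content hash of the configuration slice that feeds them, so re-runs skip
unchanged work.
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
import pandas as pd
import yaml

from . import classify as _classify
from . import deep_features as _deep
from . import lowrank as _lowrank
from . import thermal_io as _io
from . import thermoencoder as _enc
from . import phantom_sim as _sim
from .errors import ConfigError

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("thermomics")


@dataclass
class RunConfig:
    """Per-stage parameters for one reproducible pipeline run."""

    seed: int = 0
    outdir: str = "thermomics_run"
    method: str = "sparse_pct"              # {pct, sparse_pct, both}

    # cohort (synthetic phantom) or external data
    n_healthy: int = 30
    n_symptomatic: int = 30
    cohort: dict = field(default_factory=dict)      # CohortConfig overrides
    data_dir: str | None = None                     # external sequences instead
    data_dialect: str = "txt_matrix"
    roi_table: str | None = None                    # required for external data

    # lowrank
    k: int = 3
    lambda1: float = 0.05
    lambda2: float = 0.0
    avatar_side: int = 224

    # deep features
    weights: str = "seeded_random"
    weights_path: str | None = None
    backbone_seed: int = 0

    # autoencoder
    ae_dims: tuple[int, ...] = (2048, 1024, 256, 64, 16)
    ae_epochs: int = 500
    ae_batch_size: int = 128
    ae_l1: float = 1e-5

    # classification
    n_trees: int = 1000
    n_bootstrap: int = 2000
    feature_sets: tuple[str, ...] = (
        "latent_only", "clinical_only", "latent_plus_clinical",
    )

    def validate(self) -> None:
        if self.method not in ("pct", "sparse_pct", "both"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.data_dir is not None and self.roi_table is None:
            raise ConfigError(
                "external data_dir given without roi_table: per-subject ROIs "
                "are required before any processing"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ae_dims"] = list(self.ae_dims)
        d["feature_sets"] = list(self.feature_sets)
        return d


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "ae_dims" in raw:
        raw["ae_dims"] = tuple(raw["ae_dims"])
    if "feature_sets" in raw:
        raw["feature_sets"] = tuple(raw["feature_sets"])
    return RunConfig(**raw)


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def _stage_cached(stage_dir: Path, key: str) -> bool:
    marker = stage_dir / ".stage_hash"
    return marker.exists() and marker.read_text().strip() == key


def _mark_stage(stage_dir: Path, key: str) -> None:
    (stage_dir / ".stage_hash").write_text(key)


def _load_cohort(cfg: RunConfig, outdir: Path):
    """Simulate (or read) the cohort; returns (sequences, records, rois)."""
    if cfg.data_dir is not None:
        rois = _io.read_roi_table(cfg.roi_table)
        records, sequences = [], []
        cohort_csv = Path(cfg.data_dir) / "cohort.csv"
        if not cohort_csv.exists():
            raise ConfigError(f"external cohort table not found: {cohort_csv}")
        df = pd.read_csv(cohort_csv)
        for row in df.itertuples():
            rec = _sim.CohortRecord(
                subject_id=str(row.subject_id), age=float(row.age),
                family_history=str(row.family_history),
                hormone_therapy=bool(row.hormone_therapy), label=str(row.label),
            )
            records.append(rec)
            seq = _io.read_sequence(Path(cfg.data_dir) / rec.subject_id,
                                    dialect=cfg.data_dialect,
                                    subject_id=rec.subject_id, label=rec.label)
            sequences.append(seq)
        return sequences, records, rois

    sim_dir = outdir / "cohort"
    sim_dir.mkdir(parents=True, exist_ok=True)
    key = _hash({"n_h": cfg.n_healthy, "n_s": cfg.n_symptomatic,
                 "seed": cfg.seed, "cohort": cfg.cohort})
    cohort_cfg = _sim.CohortConfig(**cfg.cohort)
    if _stage_cached(sim_dir, key):
        log.info("simulate: cache hit, reading %s", sim_dir)
        df = pd.read_csv(sim_dir / "cohort.csv")
        records = [_sim.CohortRecord(str(r.subject_id), float(r.age),
                                     str(r.family_history), bool(r.hormone_therapy),
                                     str(r.label)) for r in df.itertuples()]
        sequences = [_io.read_sequence(sim_dir / rec.subject_id, dialect="tiff",
                                       frame_interval=cohort_cfg.frame_interval,
                                       subject_id=rec.subject_id, label=rec.label)
                     for rec in records]
    else:
        t0 = time.time()
        sequences, records = _sim.generate_cohort(
            cfg.n_healthy, cfg.n_symptomatic, seed=cfg.seed, config=cohort_cfg)
        for seq in sequences:
            _io.write_sequence(seq, sim_dir / seq.subject_id / "sequence.tiff",
                               dialect="tiff")
        pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
            sim_dir / "cohort.csv", index=False)
        _mark_stage(sim_dir, key)
        log.info("simulate: %d subjects in %.1f s", len(sequences), time.time() - t0)
    return sequences, records, None


def _features_for_method(cfg: RunConfig, method: str, sequences, rois,
                         outdir: Path) -> pd.DataFrame:
    feat_dir = outdir / f"features_{method}"
    feat_dir.mkdir(parents=True, exist_ok=True)
    key = _hash({"method": method, "k": cfg.k, "l1": cfg.lambda1,
                 "l2": cfg.lambda2, "side": cfg.avatar_side,
                 "weights": cfg.weights, "bseed": cfg.backbone_seed,
                 "seed": cfg.seed, "n": len(sequences),
                 "cohort": cfg.cohort})
    csv_path = feat_dir / "features.csv"
    if _stage_cached(feat_dir, key) and csv_path.exists():
        log.info("features[%s]: cache hit", method)
        return pd.read_csv(csv_path, index_col="subject_id")

    backbone = _deep.Backbone(weights=cfg.weights, seed=cfg.backbone_seed,
                              weights_path=cfg.weights_path)
    t0 = time.time()
    rows = {}
    for seq in sequences:
        roi = rois.get(seq.subject_id) if rois else None
        hm = _io.build_heat_matrix(seq, roi=roi)
        if method == "pct":
            bs = _lowrank.pct(hm, k=cfg.k)
        else:
            bs = _lowrank.sparse_pct(hm, k=cfg.k, lambda1=cfg.lambda1,
                                     lambda2=cfg.lambda2)
        avatar = _lowrank.make_avatar(bs, side=cfg.avatar_side)
        fv = _deep.extract_features(avatar, backbone)
        rows[seq.subject_id] = fv.values
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"f{i:04d}" for i in range(df.shape[1])]
    df.index.name = "subject_id"
    df.to_csv(csv_path)
    _mark_stage(feat_dir, key)
    log.info("features[%s]: %d subjects in %.1f s", method, len(rows),
             time.time() - t0)
    return df


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns {method: {feature_set: EvalReport}}.

    Also writes per-stage intermediates, a comparison table for
    ``method="both"``, and a manifest JSON into ``cfg.outdir``.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")

    sequences, records, rois = _load_cohort(cfg, outdir)
    methods = ["sparse_pct", "pct"] if cfg.method == "both" else [cfg.method]

    results: dict[str, dict[str, _classify.EvalReport]] = {}
    all_rows = []
    for method in methods:
        feats = _features_for_method(cfg, method, sequences, rois, outdir)
        scaled, scaler = _enc.scale_features(feats.to_numpy())
        spec = _enc.AutoencoderSpec(dims=cfg.ae_dims, l1_weight=cfg.ae_l1,
                                    seed=cfg.seed)
        tcfg = _enc.TrainConfig(batch_size=cfg.ae_batch_size, epochs=cfg.ae_epochs)
        t0 = time.time()
        _model, latent = _enc.train_autoencoder(
            scaled, spec, tcfg, scaler=scaler, subject_ids=list(feats.index))
        log.info("autoencoder[%s]: %d epochs in %.1f s", method,
                 cfg.ae_epochs, time.time() - t0)
        codes_df = pd.DataFrame(latent.codes, index=feats.index,
                                columns=[f"latent_{i}" for i in
                                         range(latent.codes.shape[1])])
        codes_df.to_csv(outdir / f"codes_{method}.csv")
        pd.DataFrame(latent.loss_history.get("train", []),
                     columns=["train_bce"]).to_csv(
            outdir / f"ae_loss_{method}.csv", index_label="epoch")

        variants = [
            _classify.build_design_matrix(
                latent.codes, records, subject_ids=list(feats.index),
                feature_set=fs)
            for fs in cfg.feature_sets
        ]
        table, reports = _classify.compare_feature_sets(
            variants, seed=cfg.seed, n_trees=cfg.n_trees,
            n_bootstrap=cfg.n_bootstrap)
        for name, rep in reports.items():
            rep.save_json(outdir / f"report_{method}_{name}.json")
        _classify.plot_roc(reports, outdir / f"roc_{method}.png")
        table.insert(0, "method", method)
        all_rows.append(table)
        results[method] = reports

    comparison = pd.concat(all_rows, ignore_index=True)
    comparison.to_csv(outdir / "comparison.csv", index=False)
    manifest = {
        "config": cfg.to_dict(),
        "n_subjects": len(records),
        "methods": methods,
        "results": {
            m: {fs: {"accuracy_pct": r.accuracy,
                     "interval_pct": list(r.accuracy_interval),
                     "roc_auc": r.roc_auc}
                for fs, r in reps.items()}
            for m, reps in results.items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return results
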