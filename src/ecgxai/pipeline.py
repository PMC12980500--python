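"""Pipeline stages behind the command-line interface.

Each stage reads its inputs from, and writes its artifacts under, the run's
output directory:

    data/{train,val,test}/    dataset containers (float32 array + manifest)
    models/<class>_s<seed>    checkpoint .npz + .json sidecar
    maps/                     attribution map stores
    reports/                  experiment CSVs, metrics table, run manifest

A stage records a hash of the configuration slice it depends on in
``manifest.json``; re-running an unchanged stage is a no-op. Report CSVs are
written with 6-significant-digit floats so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .attribution import MethodConfig
from .config import RunConfig
from .exceptions import ConfigurationError
from .experiments import (run_cascading_randomization, run_inter_method,
                          run_perturbation, run_self_consistency)
from .maps import aggregate
from .metrics import compute_metrics
from .model import ECGResNetClassifier, experiment_grid
from .synth import CLASSES, SyntheticDataset, generate_dataset, split_by_patient

log = logging.getLogger("ecgxai")

FLOAT_FMT = "%.6g"


def _outdir(cfg: RunConfig) -> Path:
    return Path(cfg.output_dir)


def _stage_hash(cfg: RunConfig, blocks: list[str]) -> str:
    payload = {"seed": cfg.seed}
    d = cfg.as_dict()
    for b in blocks:
        payload[b] = d[b]
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _manifest_path(cfg: RunConfig) -> Path:
    return _outdir(cfg) / "manifest.json"


def _read_manifest(cfg: RunConfig) -> dict:
    p = _manifest_path(cfg)
    return json.loads(p.read_text()) if p.exists() else {}


def _mark_done(cfg: RunConfig, stage: str, h: str, extra: dict | None = None) -> None:
    m = _read_manifest(cfg)
    m[stage] = {"hash": h, "seed": cfg.seed}
    if extra:
        m[stage].update(extra)
    _manifest_path(cfg).parent.mkdir(parents=True, exist_ok=True)
    _manifest_path(cfg).write_text(json.dumps(m, indent=1, sort_keys=True))


def _is_done(cfg: RunConfig, stage: str, h: str, probe: Path) -> bool:
    m = _read_manifest(cfg)
    return stage in m and m[stage].get("hash") == h and probe.exists()


def _require(path: Path, producer: str) -> None:
    if not path.exists():
        raise ConfigurationError(
            f"missing prerequisite {path}; run the '{producer}' stage first")


def _method_config(cfg: RunConfig) -> MethodConfig:
    m = cfg.methods
    return MethodConfig(ig_steps=m.ig_steps, sg_samples=m.sg_samples,
                        sg_noise=m.sg_noise, shapley_segments=m.shapley_segments,
                        shapley_samples=m.shapley_samples,
                        shap_baselines=m.shap_baselines,
                        gradcam_tap=m.gradcam_tap, seed=cfg.seed_for("exp"))


# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> None:
    h = _stage_hash(cfg, ["data"])
    out = _outdir(cfg) / "data"
    if _is_done(cfg, "simulate", h, out / "test" / "manifest.csv"):
        log.info("simulate: up to date, skipping")
        return
    d = cfg.data
    ds = generate_dataset(
        d.n_patients, d.mean_records_per_patient, d.prevalences, d.noise_sd,
        seed=cfg.seed_for("data"), record_duration_s=d.record_length_s,
        sampling_rate=d.sampling_rate)
    train, val, test = split_by_patient(ds, d.n_val_patients, d.n_test_patients,
                                        seed=cfg.seed_for("split"))
    for name, part in (("train", train), ("val", val), ("test", test)):
        part.save(out / name)
    log.info("simulate: %d records (%d train / %d val / %d test)",
             len(ds), len(train), len(val), len(test))
    _mark_done(cfg, "simulate", h, {"n_records": len(ds)})


def load_splits(cfg: RunConfig):
    base = _outdir(cfg) / "data"
    _require(base / "train" / "manifest.csv", "simulate")
    return (SyntheticDataset.load(base / "train"),
            SyntheticDataset.load(base / "val"),
            SyntheticDataset.load(base / "test"))


def _model_path(cfg: RunConfig, class_name: str, seed_idx: int) -> Path:
    return _outdir(cfg) / "models" / f"{class_name}_s{seed_idx}"


def _build_classifier(cfg: RunConfig, train_ds, job_seed: int) -> ECGResNetClassifier:
    m = cfg.model
    L = train_ds.records[0].signal.shape[1]
    return ECGResNetClassifier(
        n_conv_layers=m.n_conv_layers, kernel_size=m.kernel_size,
        base_channels=m.base_channels, halve_every=m.halve_every,
        dropout_rate=m.dropout_rate, input_length=L, epochs=m.epochs,
        batch_size=m.batch_size, lr=m.lr, patience=m.patience,
        random_state=job_seed)


def stage_train(cfg: RunConfig) -> None:
    h = _stage_hash(cfg, ["data", "model", "grid"])
    jobs = experiment_grid(cfg.grid.classes, cfg.grid.n_seeds)
    probe = _model_path(cfg, *jobs[-1]).with_suffix(".json")
    if _is_done(cfg, "train", h, probe):
        log.info("train: up to date, skipping")
        return
    train, val, test = load_splits(cfg)
    Xtr, Xva, Xte = train.signals(), val.signals(), test.signals()
    rows = []
    for ji, (class_name, seed_idx) in enumerate(jobs):
        ytr, yva = train.labels_for(class_name), val.labels_for(class_name)
        if len(np.unique(ytr)) < 2 or len(np.unique(yva)) < 2:
            log.warning("train: %s seed %d skipped (single-class labels in split)",
                        class_name, seed_idx)
            continue
        clf = _build_classifier(cfg, train, cfg.seed_for("train", ji))
        clf.fit(Xtr, ytr, Xva, yva,
                groups=[r.patient_id for r in train.records],
                val_groups=[r.patient_id for r in val.records])
        eio.save_model(clf, _model_path(cfg, class_name, seed_idx))
        yte = test.labels_for(class_name)
        if len(np.unique(yte)) == 2:
            mt = compute_metrics(clf.predict_proba(Xte)[:, 1], yte, clf.threshold_)
            rows.append({"class": class_name, "seed": seed_idx, **mt.as_dict()})
        log.info("train: %s seed %d val AUROC %.3f", class_name, seed_idx,
                 clf.best_val_auroc_)
    rep = _outdir(cfg) / "reports"
    rep.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(rep / "model_metrics.csv", index=False,
                              float_format=FLOAT_FMT)
    _mark_done(cfg, "train", h, {"n_jobs": len(jobs)})


def _load_trained(cfg: RunConfig, class_name: str, seed_idx: int):
    p = _model_path(cfg, class_name, seed_idx)
    _require(p.with_suffix(".json"), "train")
    return eio.load_model(p)


def select_records(ds: SyntheticDataset, class_name: str, n: int, seed: int):
    """Up to n test records, stratified so both label values are present."""
    y = ds.labels_for(class_name)
    rng = np.random.default_rng(seed)
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    n_pos = min(len(pos), max(1, n // 2))
    n_neg = min(len(neg), n - n_pos)
    idx = np.sort(np.concatenate([rng.choice(pos, n_pos, replace=False),
                                  rng.choice(neg, n_neg, replace=False)]))
    sigs = [ds.records[i].signal for i in idx]
    return sigs, y[idx], idx


def _baseline_draws(cfg: RunConfig, train_ds) -> np.ndarray:
    rng = np.random.default_rng(cfg.seed_for("baselines"))
    k = min(cfg.methods.shap_baselines, len(train_ds))
    idx = rng.choice(len(train_ds), k, replace=False)
    return np.stack([train_ds.records[i].signal for i in idx])


def stage_attribute(cfg: RunConfig) -> None:
    """Map store for each configured class's seed-0 model on test records."""
    h = _stage_hash(cfg, ["data", "model", "grid", "methods", "experiments"])
    out = _outdir(cfg) / "maps"
    probe = out / "attribute.done"
    if _is_done(cfg, "attribute", h, probe):
        log.info("attribute: up to date, skipping")
        return
    from .attribution import compute_attribution
    train, _, test = load_splits(cfg)
    baselines = _baseline_draws(cfg, train)
    mcfg = _method_config(cfg)
    for class_name in cfg.grid.classes:
        model = _load_trained(cfg, class_name, 0)
        sigs, _, idx = select_records(test, class_name, cfg.experiments.n_records,
                                      cfg.seed_for("exp"))
        for method in cfg.methods.names:
            stack = np.stack([compute_attribution(method, model, x, target=class_name,
                                                  config=mcfg, baselines=baselines,
                                                  model_tag=f"{class_name}_s0").values
                              for x in sigs])
            eio.save_maps(stack, f"{class_name}_s0", method, out,
                          config={"record_indices": idx.tolist(), "hash": mcfg.hash()})
    probe.write_text("ok")
    _mark_done(cfg, "attribute", h)


def _exp_inputs(cfg: RunConfig, class_name: str):
    train, _, test = load_splits(cfg)
    sigs, labels, _ = select_records(test, class_name, cfg.experiments.n_records,
                                     cfg.seed_for("exp"))
    return sigs, labels, _baseline_draws(cfg, train)


def stage_exp1(cfg: RunConfig) -> None:
    h = _stage_hash(cfg, ["data", "model", "grid", "methods", "experiments"])
    rep = _outdir(cfg) / "reports"
    if _is_done(cfg, "exp1", h, rep / "exp1_matrix.csv"):
        log.info("exp1: up to date, skipping")
        return
    e = cfg.experiments
    cls = e.randomization_class
    model = _load_trained(cfg, cls, 0)
    sigs, _, baselines = _exp_inputs(cfg, cls)
    scores, matrix = run_inter_method(
        model, sigs, cfg.methods.names, _method_config(cfg), baselines,
        smooth=e.smooth, window=e.smooth_window, polyorder=e.smooth_polyorder,
        kind=e.corr_kind)
    rep.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(rep / "exp1_matrix.csv", float_format=FLOAT_FMT)
    matrix.attrs["sd"].to_csv(rep / "exp1_matrix_sd.csv", float_format=FLOAT_FMT)
    agg = aggregate(scores, ["method_a", "method_b"])
    agg.to_csv(rep / "exp1_pairs.csv", index=False, float_format=FLOAT_FMT)
    _mark_done(cfg, "exp1", h)


def stage_exp2(cfg: RunConfig) -> None:
    h = _stage_hash(cfg, ["data", "model", "grid", "methods", "experiments"])
    rep = _outdir(cfg) / "reports"
    if _is_done(cfg, "exp2", h, rep / "exp2_self_consistency.csv"):
        log.info("exp2: up to date, skipping")
        return
    if cfg.grid.n_seeds < 2:
        raise ConfigurationError("exp2 needs grid.n_seeds >= 2")
    e = cfg.experiments
    frames = []
    for class_name in cfg.grid.classes:
        models = {}
        for s in range(cfg.grid.n_seeds):
            p = _model_path(cfg, class_name, s)
            if p.with_suffix(".json").exists():
                models[s] = eio.load_model(p)
        if len(models) < 2:
            log.warning("exp2: class %s skipped (missing seed models)", class_name)
            continue
        sigs, _, baselines = _exp_inputs(cfg, class_name)
        df = run_self_consistency(models, sigs, cfg.methods.names,
                                  _method_config(cfg), baselines, smooth=e.smooth,
                                  window=e.smooth_window,
                                  polyorder=e.smooth_polyorder, kind=e.corr_kind)
        df["class"] = class_name
        frames.append(df)
    if not frames:
        raise ConfigurationError("exp2: no class had >= 2 trained seed models")
    scores = pd.concat(frames, ignore_index=True)
    rep.mkdir(parents=True, exist_ok=True)
    aggregate(scores, ["method"]).to_csv(rep / "exp2_self_consistency.csv",
                                         index=False, float_format=FLOAT_FMT)
    aggregate(scores, ["method", "class"]).to_csv(
        rep / "exp2_self_consistency_by_class.csv", index=False, float_format=FLOAT_FMT)
    _mark_done(cfg, "exp2", h)


def stage_exp3(cfg: RunConfig) -> None:
    h = _stage_hash(cfg, ["data", "model", "grid", "methods", "experiments"])
    rep = _outdir(cfg) / "reports"
    if _is_done(cfg, "exp3", h, rep / "exp3_randomization.csv"):
        log.info("exp3: up to date, skipping")
        return
    e = cfg.experiments
    cls = e.randomization_class
    model = _load_trained(cfg, cls, 0)
    sigs, labels, baselines = _exp_inputs(cfg, cls)
    traj = run_cascading_randomization(
        model, sigs, labels, cfg.methods.names, seed=cfg.seed_for("exp"),
        config=_method_config(cfg), baselines=baselines, smooth=e.smooth,
        window=e.smooth_window, polyorder=e.smooth_polyorder, kind=e.corr_kind)
    rep.mkdir(parents=True, exist_ok=True)
    traj.as_frame().to_csv(rep / "exp3_randomization.csv", index=False,
                           float_format=FLOAT_FMT)
    _mark_done(cfg, "exp3", h)


def stage_exp4(cfg: RunConfig) -> None:
    h = _stage_hash(cfg, ["data", "model", "grid", "methods", "experiments"])
    rep = _outdir(cfg) / "reports"
    if _is_done(cfg, "exp4", h, rep / "exp4_perturbation.csv"):
        log.info("exp4: up to date, skipping")
        return
    e = cfg.experiments
    cls = e.randomization_class
    sigs, labels, baselines = _exp_inputs(cfg, cls)
    frames = []
    for s in range(cfg.grid.n_seeds):
        p = _model_path(cfg, cls, s)
        if not p.with_suffix(".json").exists():
            continue
        model = eio.load_model(p)
        traj = run_perturbation(
            model, sigs, labels, cfg.methods.names, n_steps=e.perturb_steps,
            step_frac=e.perturb_step_frac, noise_sd=e.perturb_noise_sd,
            seed=cfg.seed_for("perturb", s), config=_method_config(cfg),
            baselines=baselines, noise_mode=e.perturb_noise_mode)
        df = traj.as_frame()
        df["seed"] = s
        frames.append(df)
    if not frames:
        raise ConfigurationError(f"exp4: no trained model for class {cls}")
    long = pd.concat(frames, ignore_index=True)
    agg = (long.groupby(["step", "cumulative_fraction", "method"])["auroc"]
           .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
                n="count").reset_index())
    rep.mkdir(parents=True, exist_ok=True)
    agg.to_csv(rep / "exp4_perturbation.csv", index=False, float_format=FLOAT_FMT)
    _mark_done(cfg, "exp4", h)


def stage_report(cfg: RunConfig, plots: bool = False) -> None:
    rep = _outdir(cfg) / "reports"
    _require(rep / "model_metrics.csv", "train")
    summary = {"config": cfg.as_dict(), "stages": _read_manifest(cfg)}
    for name in ("exp1_matrix", "exp2_self_consistency", "exp3_randomization",
                 "exp4_perturbation"):
        f = rep / f"{name}.csv"
        summary[name] = "present" if f.exists() else "missing"
    (rep / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    if plots:
        _write_plots(cfg, rep)


def _write_plots(cfg: RunConfig, rep: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        log.warning("matplotlib unavailable; skipping plots")
        return
    f = rep / "exp1_matrix.csv"
    if f.exists():
        m = pd.read_csv(f, index_col=0)
        fig, ax = plt.subplots(figsize=(7, 6))
        im = ax.imshow(m.to_numpy(), vmin=-1, vmax=1, cmap="coolwarm")
        ax.set_xticks(range(len(m)), m.columns, rotation=90)
        ax.set_yticks(range(len(m)), m.index)
        fig.colorbar(im)
        fig.tight_layout()
        fig.savefig(rep / "exp1_matrix.png", dpi=120)
        plt.close(fig)
    for name, ycol in (("exp3_randomization", "mean"), ("exp4_perturbation", "mean")):
        f = rep / f"{name}.csv"
        if not f.exists():
            continue
        df = pd.read_csv(f)
        fig, ax = plt.subplots(figsize=(7, 4))
        xcol = "step" if name.startswith("exp3") else "cumulative_fraction"
        for method, grp in df.groupby("method"):
            ax.plot(grp[xcol], grp[ycol], label=method, lw=1)
        ax.set_xlabel(xcol)
        ax.set_ylabel("correlation" if name.startswith("exp3") else "AUROC")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(rep / f"{name}.png", dpi=120)
        plt.close(fig)


STAGES = {
    "simulate": stage_simulate,
    "train": stage_train,
    "attribute": stage_attribute,
    "exp1": stage_exp1,
    "exp2": stage_exp2,
    "exp3": stage_exp3,
    "exp4": stage_exp4,
    "report": stage_report,
}


def run_all(cfg: RunConfig, plots: bool = False) -> None:
    stage_simulate(cfg)
    stage_train(cfg)
    stage_attribute(cfg)
    for w in cfg.experiments.which:
        STAGES[f"exp{w}"](cfg)
    stage_report(cfg, plots=plots)
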