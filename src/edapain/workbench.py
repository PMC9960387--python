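"""I/O, experiment configuration and the command-line surface.

Window tables are long-format CSV (subject_id, label, rep, fs, sample_index,
value), one row per sample, which keeps variable window lengths representable
and round-trips exactly. Simulated datasets get a JSON sidecar recording the
protocol, seed and simulation parameters so every artifact is reproducible
from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import evaluation, forest, gradcam, neural, plots, rules
from .features import FeatureConfig, extract_features
from .preprocess import dl_pipeline
from .synth import (BVDB_PROTOCOL, PMDB_PROTOCOL, EDAWindow, SimParams,
                    StimulusProtocol, WindowSet, desk_protocol,
                    generate_dataset, sim_params_dict)

__all__ = ["read_windows", "write_windows", "ExperimentConfig", "run_experiment",
           "cli"]

log = logging.getLogger("edapain")

_COLUMNS = ["subject_id", "label", "rep", "fs", "sample_index", "value"]


def write_windows(windowset: WindowSet, path) -> None:
    """Write the long-format window table in deterministic row order."""
    frames = []
    label_order = {lab: i for i, lab in enumerate(windowset.protocol.labels)}
    ordered = sorted(windowset.windows,
                     key=lambda w: (w.subject_id, label_order[w.label], w.rep))
    for w in ordered:
        n = len(w)
        frames.append(pd.DataFrame({
            "subject_id": np.repeat(w.subject_id, n),
            "label": np.repeat(w.label, n),
            "rep": np.repeat(w.rep, n),
            "fs": np.repeat(w.fs, n),
            "sample_index": np.arange(n),
            "value": w.values,
        }))
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=_COLUMNS)
    table.to_csv(path, index=False)


def write_sidecar(path, protocol: StimulusProtocol, seed: int,
                  params: SimParams) -> None:
    sidecar = {
        "protocol": asdict(protocol) | {"labels": list(protocol.labels)},
        "seed": seed,
        "sim_params": sim_params_dict(params),
    }
    with open(path, "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_windows(path) -> WindowSet:
    """Parse a long-format window table back into a validated WindowSet."""
    table = pd.read_csv(path)
    unknown = set(table.columns) - set(_COLUMNS)
    if unknown:
        raise ValueError(f"unknown columns in window table: {sorted(unknown)}")
    missing = set(_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"window table lacks columns: {sorted(missing)}")
    if table.empty:
        return WindowSet(windows=[], protocol=StimulusProtocol(
            name="empty", n_subjects=0, labels=("none",), reps_per_label=0,
            fs=1.0, window_s=1.0))
    fs_values = table["fs"].unique()
    if len(fs_values) != 1:
        raise ValueError(f"mixed sampling rates in one table: {fs_values}")
    fs = float(fs_values[0])
    if fs <= 0:
        raise ValueError("non-positive sampling rate")

    windows = []
    lengths = set()
    labels_in_order: list[str] = []
    for (sid, label, rep), grp in table.groupby(
            ["subject_id", "label", "rep"], sort=True):
        grp = grp.sort_values("sample_index")
        if not np.array_equal(grp["sample_index"].to_numpy(),
                              np.arange(len(grp))):
            raise ValueError(
                f"non-contiguous sample indices for subject {sid!r} rep {rep}")
        lengths.add(len(grp))
        if label not in labels_in_order:
            labels_in_order.append(label)
        windows.append(EDAWindow(values=grp["value"].to_numpy(dtype=float),
                                 fs=fs, label=str(label), subject_id=str(sid),
                                 rep=int(rep)))
    if len(lengths) != 1:
        bad = windows[-1]
        raise ValueError(
            f"ragged windows (lengths {sorted(lengths)}); last parsed window: "
            f"subject {bad.subject_id!r} rep {bad.rep}")
    n = lengths.pop()
    subjects = sorted({w.subject_id for w in windows})
    reps = 1 + max(w.rep for w in windows)
    protocol = StimulusProtocol(
        name=Path(str(path)).stem, n_subjects=len(subjects),
        labels=tuple(labels_in_order), reps_per_label=reps, fs=fs,
        window_s=n / fs)
    return WindowSet(windows=windows, protocol=protocol)


# ---------------------------------------------------------------------------
# experiment configuration

_PROTOCOLS = {"bvdb": BVDB_PROTOCOL, "pmdb": PMDB_PROTOCOL}

_CONFIG_KEYS = {
    "protocol", "n_subjects", "reps_per_label", "fs", "window_s", "model",
    "seed", "output_dir", "positive_label", "negative_label", "target_fs",
    "span_s", "epochs", "batch_size", "learning_rate", "run_rfe",
    "rfe_n_trees", "sim_params", "holdout_subjects",
}

_MODELS = ("forest", "mlp", "cnn", "hybrid", "rule")


@dataclass
class ExperimentConfig:
    seed: int
    output_dir: str
    protocol: str = "desk"
    n_subjects: int = 50
    reps_per_label: int = 4
    fs: float = 32.0
    window_s: float = 10.0
    model: str = "forest"
    positive_label: str = "high_pain"
    negative_label: str = "no_pain"
    target_fs: float = 256.0  # deep-learning pipeline resample rate
    span_s: float = 1.0
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-4
    run_rfe: bool = False
    rfe_n_trees: int = 40
    holdout_subjects: int = 10  # neural-network held-out split
    sim_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {_MODELS}")
        if self.protocol not in (*_PROTOCOLS, "desk"):
            raise ValueError(f"unknown protocol {self.protocol!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        unknown = set(d) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d or "output_dir" not in d:
            raise ValueError("config requires 'seed' and 'output_dir'")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(data)

    def make_protocol(self) -> StimulusProtocol:
        if self.protocol in _PROTOCOLS:
            return _PROTOCOLS[self.protocol]
        return desk_protocol(self.n_subjects, self.reps_per_label, self.fs,
                             self.window_s)

    def make_sim_params(self) -> SimParams:
        d = dict(self.sim_params)
        for key in ("spont_amp_range", "baseline_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "amplitude_means" in d and d["amplitude_means"] is not None:
            d["amplitude_means"] = dict(d["amplitude_means"])
        return SimParams(**d)


def _forest_procedure(feats: pd.DataFrame, labels: np.ndarray, cfg, seed: int):
    cols = [c for c in feats.columns if c not in ("subject_id", "label")]
    X = feats[cols]

    def run(train_mask, test_mask):
        f = forest.fit_forest(X[train_mask], labels[train_mask],
                              cfg.negative_label, cfg.positive_label,
                              forest.ForestConfig(seed=seed))
        return forest.predict_label(f, X[test_mask])

    return run


def run_experiment(config: ExperimentConfig) -> dict:
    """Simulate, fit, evaluate and explain per the config; returns the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "outputs": [],
    }

    def emit(name: str):
        manifest["outputs"].append(name)
        return out / name

    stage = "simulate"
    try:
        protocol = config.make_protocol()
        params = config.make_sim_params()
        ws = generate_dataset(protocol, params, seed=config.seed)
        two_class = ws.subset([config.negative_label, config.positive_label]) \
            if {config.negative_label, config.positive_label} <= set(protocol.labels) \
            else ws
        write_windows(two_class, emit("windows.csv"))
        write_sidecar(emit("windows.json"), protocol, config.seed, params)
        log.info("simulated %d windows", len(ws))

        results: dict = {}
        if config.model == "rule":
            stage = "rules"
            for rule in rules.RULE_IDS:
                results[rule] = rules.rule_accuracy(
                    rule, two_class, config.positive_label, config.negative_label)
        elif config.model in ("forest", "hybrid", "mlp", "cnn"):
            stage = "features" if config.model in ("forest", "hybrid") else "preprocess"
            labels = two_class.labels()
            groups = two_class.subject_ids()
            if config.model == "forest":
                feats = extract_features(two_class)
                stage = "evaluate"
                report = evaluation.evaluate(
                    _forest_procedure(feats, labels, config, config.seed),
                    labels, groups, config.negative_label, config.positive_label)
                report.to_json(emit("report.json"))
                report.confusion_frame().to_csv(emit("confusion.csv"))
                plots.plot_confusion(report.confusion, report.classes,
                                     emit("confusion.png"))
                cols = [c for c in feats.columns
                        if c not in ("subject_id", "label")]
                f_all = forest.fit_forest(
                    feats[cols], labels, config.negative_label,
                    config.positive_label, forest.ForestConfig(seed=config.seed))
                imp = forest.impurity_importance(f_all).sort_values(
                    ascending=False)
                imp.to_csv(emit("importance.csv"))
                plots.plot_importance(imp, emit("importance.png"))
                results["loso_mean_accuracy"] = report.mean_accuracy
                results["loso_pooled_accuracy"] = report.pooled_accuracy
                if config.run_rfe:
                    stage = "rfe"
                    rfe = forest.run_rfe(
                        feats[cols], labels, groups, config.negative_label,
                        config.positive_label,
                        forest.ForestConfig(n_trees=config.rfe_n_trees,
                                            seed=config.seed))
                    rfe.curve().to_csv(emit("rfe_curve.csv"), index=False)
                    plots.plot_rfe_curve(rfe.curve(), emit("rfe_curve.png"))
                    results["rfe_best_accuracy"] = rfe.best_accuracy
                    results["rfe_full_accuracy"] = rfe.full_feature_accuracy
                    results["rfe_best_n_features"] = len(rfe.best_features)
            else:
                stage = "train"
                X = np.stack([
                    dl_pipeline(w.values, w.fs, config.target_fs, config.span_s)
                    for w in two_class.windows])
                y = (labels == config.positive_label).astype(int)
                subjects = sorted(set(groups.tolist()))
                held = set(subjects[-config.holdout_subjects:])
                test_mask = np.isin(groups, list(held))
                builder = neural.build_mlp if config.model == "mlp" \
                    else neural.build_cnn
                model = builder(X.shape[1], seed=config.seed)
                tc = neural.TrainConfig(batch_size=config.batch_size,
                                        learning_rate=config.learning_rate,
                                        epochs=config.epochs, seed=config.seed)
                history = neural.train_classifier(
                    model, X[~test_mask][:, :, None], y[~test_mask], tc)
                pred = neural.predict_label_indices(model, X[test_mask][:, :, None])
                results["holdout_accuracy"] = float((pred == y[test_mask]).mean())
                results["final_loss"] = history[-1]
                model.save(emit("model.npz"))
                if config.model == "cnn":
                    stage = "xai"
                    slope = {}
                    for cls_idx, name in ((0, config.negative_label),
                                          (1, config.positive_label)):
                        r = gradcam.dataset_slope_importance(model, X, cls_idx)
                        slope[name] = r.to_dict()
                    with open(emit("slope_importance.json"), "w") as fh:
                        json.dump(slope, fh, indent=2)
                    plots.plot_slope_importance(slope,
                                                emit("slope_importance.png"))
                    results["slope_importance"] = slope
                if config.model == "hybrid":
                    stage = "hybrid"
                    deep = neural.penultimate_features(model, X[:, :, None])
                    deep_df = pd.DataFrame(
                        deep, columns=[f"deep_{i}" for i in range(deep.shape[1])])
                    report = evaluation.evaluate(
                        _forest_procedure(deep_df, labels, config, config.seed),
                        labels, groups, config.negative_label,
                        config.positive_label)
                    results["hybrid_loso_mean_accuracy"] = report.mean_accuracy
        manifest["results"] = results
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# command line

@click.group()
def cli() -> None:
    """Explainable EDA pain-recognition workbench."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")


@cli.command()
@click.option("--protocol", default="desk",
              type=click.Choice(["desk", "bvdb", "pmdb"]))
@click.option("--seed", type=int, required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--n-subjects", type=int, default=50, show_default=True)
@click.option("--reps", type=int, default=4, show_default=True)
def simulate(protocol, seed, out, n_subjects, reps):
    """Generate a synthetic window table and its JSON sidecar."""
    proto = _PROTOCOLS.get(protocol) or desk_protocol(n_subjects, reps)
    params = SimParams()
    ws = generate_dataset(proto, params, seed=seed)
    write_windows(ws, out)
    write_sidecar(str(out) + ".json", proto, seed, params)
    click.echo(f"wrote {len(ws)} windows to {out}")


@cli.command()
@click.option("--input", "input_path", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
def features(input_path, out):
    """Extract the hand-crafted feature matrix from a window table."""
    ws = read_windows(input_path)
    extract_features(ws).to_csv(out, index=False)
    click.echo(f"wrote features for {len(ws)} windows to {out}")


@cli.command("rules")
@click.option("--rule", type=click.Choice(rules.RULE_IDS), required=True)
@click.option("--input", "input_path", type=click.Path(exists=True), required=True)
@click.option("--positive", required=True)
@click.option("--negative", required=True)
@click.option("--table", "table_path", type=click.Path(), default=None)
def rules_cmd(rule, input_path, positive, negative, table_path):
    """Apply one Boolean pain rule and print its accuracy."""
    ws = read_windows(input_path)
    table = rules.rule_decision_table(rule, ws, positive, negative)
    if table_path:
        table.to_csv(table_path, index=False)
    click.echo(f"{rule} accuracy: {table['correct'].mean():.4f}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True),
              required=True)
def run(config_path):
    """Run a full experiment from a YAML/JSON config."""
    cfg = ExperimentConfig.from_file(config_path)
    manifest = run_experiment(cfg)
    click.echo(json.dumps(manifest["results"], indent=2))


@cli.command("gradcam")
@click.option("--model", "model_path", type=click.Path(exists=True), required=True)
@click.option("--input", "input_path", type=click.Path(exists=True), required=True)
@click.option("--target-fs", type=float, default=256.0, show_default=True)
@click.option("--class-idx", type=int, default=1, show_default=True)
@click.option("--out-dir", type=click.Path(), required=True)
@click.option("--max-windows", type=int, default=8, show_default=True)
def gradcam_cmd(model_path, input_path, target_fs, class_idx, out_dir,
                max_windows):
    """Per-window saliency overlays as PNG for one target class."""
    ws = read_windows(input_path)
    X = np.stack([dl_pipeline(w.values, w.fs, target_fs) for w in ws.windows])
    model = neural.build_cnn(X.shape[1])
    model.load(model_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for w, row in list(zip(ws.windows, X))[:max_windows]:
        sal = gradcam.gradcam(model, row, class_idx)
        name = f"saliency_{w.subject_id}_{w.label}_r{w.rep}_c{class_idx}.png"
        plots.plot_saliency_overlay(
            row, sal.upsampled, out / name,
            title=f"{w.subject_id} {w.label} rep {w.rep}")
        click.echo(str(out / name))


@cli.command("slope-importance")
@click.option("--model", "model_path", type=click.Path(exists=True), required=True)
@click.option("--input", "input_path", type=click.Path(exists=True), required=True)
@click.option("--target-fs", type=float, default=256.0, show_default=True)
@click.option("--class-idx", type=int, default=1, show_default=True)
def slope_importance_cmd(model_path, input_path, target_fs, class_idx):
    """Dataset-level rising/falling saliency split for one class."""
    ws = read_windows(input_path)
    X = np.stack([dl_pipeline(w.values, w.fs, target_fs) for w in ws.windows])
    model = neural.build_cnn(X.shape[1])
    model.load(model_path)
    result = gradcam.dataset_slope_importance(model, X, class_idx)
    click.echo(json.dumps(result.to_dict(), indent=2))
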