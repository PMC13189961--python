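"""Configuration, logging and the umbrella CLI.

A run is described by a single YAML file with nested sections (simdata,
windows, model, train, loss, eval, explain) plus a global seed and output
root.  Defaults are merged in, every key is validated against the module
invariants, and unknown keys are rejected.  The resolved configuration (and
its hash) is written alongside every artifact so that mixed-config
evaluation can be refused.

``run_pipeline`` executes simulate → windows → train → evaluate → explain in
order, leaving a run directory with the cohort manifest, window store,
checkpoint, metrics JSON, threshold result, attribution samples, resolved
config and a structured log.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import click
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import evaluation, explain as explain_mod, net, simdata, train as train_mod, windows
from .errors import ConfigurationError

log = logging.getLogger("dsfnet")


# ---------------------------------------------------------------------------
# Configuration schema
# ---------------------------------------------------------------------------


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimdataSection(_Section):
    n_patients: int = Field(20, ge=3)
    duration_s: int = Field(450, ge=15)
    end_prevalence: float = Field(0.3, ge=0.0, le=1.0)
    imbalance_target: float = Field(40.0, gt=0)
    intensity: float = Field(3.0, ge=0.0)
    noise_sd: float = Field(1.0, ge=0.0)
    write_csv: bool = False


class WindowsSection(_Section):
    L: int = Field(15, ge=1)
    S: int = Field(1, ge=1)
    horizon: int = Field(1800, ge=1)
    guard: int = Field(1800, ge=0)
    split_ratios: tuple[int, int, int] = (8, 1, 1)


class ModelSection(_Section):
    conv_channels: tuple[int, int] = (16, 32)
    dropout_p: float = Field(0.3, ge=0.0, lt=1.0)
    mlp_hidden: int = Field(64, ge=1)
    d_model: int = Field(128, ge=1)
    n_heads: int = Field(4, ge=1)
    n_layers: int = Field(2, ge=1)
    dim_ff: int = Field(256, ge=1)
    transformer_dropout: float = Field(0.1, ge=0.0, lt=1.0)
    use_waveform_branch: bool = True
    use_temporal_fusion: bool = True
    use_positional_encoding: bool = True


class TrainSection(_Section):
    lr: float = Field(1e-4, gt=0)
    batch_size: int = Field(128, ge=1)
    max_epochs: int = Field(5, ge=1)
    patience: int = Field(3, ge=1)


class LossSection(_Section):
    omega_pos: float = Field(160.0, gt=0)


class EvalSection(_Section):
    histogram_bins: int = Field(100, ge=2)


class ExplainSection(_Section):
    steps: int = Field(50, ge=1)
    rule: str = "riemann_right"
    n_sample_windows: int = Field(2, ge=0)

    @field_validator("rule")
    @classmethod
    def _check_rule(cls, v):
        if v not in ("riemann_right", "trapezoid"):
            raise ValueError(f"rule must be riemann_right|trapezoid, got {v!r}")
        return v


class RunConfig(_Section):
    seed: int = 0
    out_root: str = "runs"
    simdata: SimdataSection = SimdataSection()
    windows: WindowsSection = WindowsSection()
    model: ModelSection = ModelSection()
    train: TrainSection = TrainSection()
    loss: LossSection = LossSection()
    eval: EvalSection = EvalSection()
    explain: ExplainSection = ExplainSection()

    def resolved(self) -> dict:
        return json.loads(self.model_dump_json())

    @property
    def hash(self) -> str:
        return net.state_hash(self.resolved())

    def window_config(self) -> windows.WindowConfig:
        w = self.windows
        return windows.WindowConfig(L=w.L, S=w.S, horizon=w.horizon, guard=w.guard)

    def model_configuration(self) -> net.ModelConfig:
        m = self.model
        return net.ModelConfig(
            conv_channels=tuple(m.conv_channels), dropout_p=m.dropout_p,
            mlp_dims=(14, m.mlp_hidden, 32), d_model=m.d_model, n_heads=m.n_heads,
            n_layers=m.n_layers, dim_ff=m.dim_ff,
            transformer_dropout=m.transformer_dropout, T=self.windows.L,
            use_waveform_branch=m.use_waveform_branch,
            use_temporal_fusion=m.use_temporal_fusion,
            use_positional_encoding=m.use_positional_encoding, seed=self.seed)

    def train_configuration(self) -> train_mod.TrainConfig:
        t = self.train
        return train_mod.TrainConfig(lr=t.lr, batch_size=t.batch_size,
                                     max_epochs=t.max_epochs, patience=t.patience,
                                     seed=self.seed)


def load_config(path=None) -> RunConfig:
    """Load + validate a YAML run configuration; None/empty file → defaults."""
    if path is None:
        return RunConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig(**data)
    except Exception as exc:  # pydantic ValidationError carries the key path
        raise ConfigurationError(f"invalid configuration: {exc}") from exc


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.resolved(), indent=1))


# ---------------------------------------------------------------------------
# Logging
# ---------------------------------------------------------------------------


def setup_logging(run_dir: Path | None = None, level=logging.INFO):
    root = logging.getLogger("dsfnet")
    root.setLevel(level)
    root.handlers = []
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    root.addHandler(sh)
    for name in ("dsfnet.train", "dsfnet.windows"):
        logging.getLogger(name).setLevel(level)
    if run_dir is not None:
        fh = logging.FileHandler(Path(run_dir) / "run.log")
        fh.setFormatter(fmt)
        root.addHandler(fh)
        logging.getLogger().addHandler(fh)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _stage(name: str, t0: float) -> None:
    log.info("stage=%s wall_s=%.1f", name, time.time() - t0)


def run_pipeline(cfg: RunConfig, run_dir=None) -> Path:
    """simulate → windows → train → evaluate → explain, one reproducible run."""
    run_dir = Path(run_dir) if run_dir is not None else \
        Path(cfg.out_root) / time.strftime("run-%Y%m%d-%H%M%S")
    run_dir.mkdir(parents=True, exist_ok=True)
    setup_logging(run_dir)
    save_config(cfg, run_dir / "config.resolved.json")
    stage = "simulate"
    try:
        t0 = time.time()
        sd = cfg.simdata
        cohort = simdata.simulate_cohort(
            n_patients=sd.n_patients, duration_s=sd.duration_s,
            end_prevalence=sd.end_prevalence, imbalance_target=sd.imbalance_target,
            seed=cfg.seed, intensity=sd.intensity, noise_sd=sd.noise_sd)
        (run_dir / "cohort").mkdir(exist_ok=True)
        if sd.write_csv:
            simdata.write_cohort(cohort, run_dir / "cohort")
        else:
            manifest = {"patients": {p.patient_id: {"end_onsets": p.end_onsets}
                                     for p in cohort.patients},
                        "seed": cfg.seed, "config_hash": cfg.hash,
                        "generator_version": simdata.GENERATOR_VERSION}
            (run_dir / "cohort" / "manifest.json").write_text(json.dumps(manifest))
        _stage(stage, t0)

        stage = "windows"
        t0 = time.time()
        wcfg = cfg.window_config()
        split = windows.split_by_patient(cohort, ratios=tuple(cfg.windows.split_ratios),
                                         seed=cfg.seed)
        store = windows.materialize_windows(cohort, split, wcfg,
                                            run_dir / "windows", cfg.hash)
        log.info("stage=windows n_windows=%d positives=%d", store.n_windows,
                 int((store.labels == 1).sum()))
        _stage(stage, t0)

        stage = "train"
        t0 = time.time()
        state = train_mod.train_model(store, split, cfg.model_configuration(),
                                      cfg.train_configuration(),
                                      train_mod.LossConfig(cfg.loss.omega_pos))
        net.save_checkpoint(run_dir / "checkpoint.npz", state.model, state.norm,
                            extra={"config_hash": cfg.hash,
                                   "store_hash": store.config_hash,
                                   "best_epoch": state.best_epoch,
                                   "best_val_loss": state.best_val_loss})
        import pandas as pd
        pd.DataFrame(state.history).to_csv(run_dir / "history.csv", index=False)
        _stage(stage, t0)

        stage = "evaluate"
        t0 = time.time()
        result = evaluate_run(run_dir, store=store, cfg=cfg)
        _stage(stage, t0)

        stage = "explain"
        t0 = time.time()
        explain_run(run_dir, store=store, cfg=cfg)
        _stage(stage, t0)
        log.info("run complete: %s auc=%.4f f1=%.4f", run_dir,
                 result["test"]["auc"], result["test"]["f1"])
        return run_dir
    except Exception as exc:
        log.error("pipeline aborted in stage=%s: %s", stage, exc)
        (run_dir / "FAILED").write_text(f"stage={stage}\n{exc}\n")
        raise


def _load_run(run_dir, store=None):
    run_dir = Path(run_dir)
    ckpt = run_dir / "checkpoint.npz"
    if not ckpt.exists():
        raise ConfigurationError(f"no checkpoint at {ckpt}; train first")
    model, norm, extra = net.load_checkpoint(ckpt)
    if store is None:
        store = windows.WindowStore(run_dir / "windows")
    if extra.get("store_hash") not in (None, store.config_hash):
        raise ConfigurationError(
            f"checkpoint was trained against a different window store "
            f"(hash {extra.get('store_hash')} != {store.config_hash})")
    return model, norm, extra, store


def evaluate_run(run_dir, store=None, cfg=None, split_name: str = "test") -> dict:
    """Optimise τ* on validation scores, evaluate the requested split at τ*."""
    run_dir = Path(run_dir)
    model, norm, extra, store = _load_run(run_dir, store)
    split = store.split_ids()
    state = train_mod.TrainState(best_val_loss=np.nan, best_epoch=-1, history=[],
                                 model=model, norm=norm)
    val_preds = train_mod.predict_split(state, store, split.val_ids)
    thr = evaluation.optimize_threshold(val_preds)
    target_ids = getattr(split, f"{split_name}_ids")
    preds = train_mod.predict_split(state, store, target_ids)
    report = evaluation.evaluate_predictions(preds, thr.tau_star)
    dist = evaluation.score_distribution(
        preds, bins=cfg.eval.histogram_bins if cfg else 100)
    out = {
        "config_hash": extra.get("config_hash"),
        "threshold": {"tau_star": thr.tau_star, "f1_at_tau_val": thr.f1_at_tau},
        split_name: report.to_dict(),
        "score_overlap": dist.overlap,
    }
    (run_dir / "metrics.json").write_text(json.dumps(out, indent=1))
    import pandas as pd
    pd.DataFrame({"bin_left": dist.bin_edges[:-1], "hist_pos": dist.hist_pos,
                  "hist_neg": dist.hist_neg}).to_csv(
        run_dir / "score_histogram.csv", index=False)
    return out


def explain_run(run_dir, store=None, cfg=None, window_spec: str | None = None,
                out_dir=None) -> list:
    """Attribute sample windows (highest-scoring positives by default)."""
    run_dir = Path(run_dir)
    model, norm, extra, store = _load_run(run_dir, store)
    ecfg = cfg.explain if cfg else ExplainSection()
    out_dir = Path(out_dir) if out_dir else run_dir / "attributions"
    out_dir.mkdir(exist_ok=True)
    if window_spec:
        pid, end = window_spec.split(":")
        picks = [(pid, int(end))]
    else:
        pos_idx = np.flatnonzero(store.labels == 1)
        if pos_idx.size == 0:
            pos_idx = np.arange(min(store.n_windows, ecfg.n_sample_windows))
        state = train_mod.TrainState(np.nan, -1, [], model, norm)
        scores = train_mod._predict(model, store, pos_idx, norm)
        top = pos_idx[np.argsort(scores)[::-1][:ecfg.n_sample_windows]]
        picks = [(store.window_pids[i], int(store.window_ends[i])) for i in top]
    results = []
    for pid, end in picks:
        frames = store.window(pid, end)
        attr = explain_mod.integrated_gradients(model, norm, frames,
                                                steps=ecfg.steps, rule=ecfg.rule)
        matrix, table = explain_mod.vital_sign_heatmap(attr)
        table.to_csv(out_dir / f"{pid}_{end}_vitals_heatmap.csv")
        for name, df in explain_mod.saliency_tables(attr).items():
            df.to_csv(out_dir / f"{pid}_{end}_{name}_saliency.csv", index=False)
        (out_dir / f"{pid}_{end}_meta.json").write_text(json.dumps({
            "patient": str(pid), "end_index": end, "steps": attr.steps,
            "baseline": attr.baseline_spec, "f_x": attr.f_x,
            "f_baseline": attr.f_baseline,
            "completeness_gap": attr.completeness_gap,
            "config_hash": extra.get("config_hash")}))
        results.append(attr)
    return results


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
def cli():
    """DSF-style early-deterioration warning: simulate, window, train, evaluate, explain."""


@cli.command()
@click.option("--n-patients", default=30, show_default=True)
@click.option("--duration", "duration_s", default=1800, show_default=True)
@click.option("--prevalence", default=0.2, show_default=True)
@click.option("--imbalance", default=160.0, show_default=True,
              help="negative:positive window ratio target (1:R)")
@click.option("--intensity", default=1.0, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_dir", required=True, type=click.Path())
def simulate(n_patients, duration_s, prevalence, imbalance, intensity, seed, out_dir):
    """Generate a synthetic cohort and write one CSV per patient + manifest."""
    setup_logging()
    cohort = simdata.simulate_cohort(n_patients=n_patients, duration_s=duration_s,
                                     end_prevalence=prevalence,
                                     imbalance_target=imbalance, seed=seed,
                                     intensity=intensity)
    simdata.write_cohort(cohort, out_dir)
    click.echo(f"wrote cohort of {n_patients} patients to {out_dir}")


@cli.command("windows")
@click.option("--in", "in_dir", required=True, type=click.Path(exists=True))
@click.option("--L", "window_l", default=15, show_default=True)
@click.option("--S", "stride", default=1, show_default=True)
@click.option("--horizon", default=1800, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_dir", required=True, type=click.Path())
def windows_cmd(in_dir, window_l, stride, horizon, seed, out_dir):
    """Window a cohort directory into a memory-mapped store with splits."""
    setup_logging()
    cohort = simdata.read_cohort(in_dir)
    wcfg = windows.WindowConfig(L=window_l, S=stride, horizon=horizon)
    split = windows.split_by_patient(cohort, seed=seed)
    store = windows.materialize_windows(cohort, split, wcfg, out_dir)
    click.echo(f"{store.n_windows} windows "
               f"({int((store.labels == 1).sum())} positive) at {out_dir}")


@cli.command("all")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "run_dir", type=click.Path(), default=None)
@click.option("--seed", default=None, type=int)
def run_all(config_path, run_dir, seed):
    """Run the full pipeline from a YAML config (defaults if omitted)."""
    cfg = load_config(config_path)
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": seed})
    out = run_pipeline(cfg, run_dir)
    click.echo(f"run directory: {out}")


@cli.command("train")
@click.option("--store", "store_dir", required=True, type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "run_dir", required=True, type=click.Path())
def train_cmd(store_dir, config_path, run_dir):
    """Train on an existing window store (its embedded split)."""
    cfg = load_config(config_path)
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    setup_logging(run_dir)
    store = windows.WindowStore(store_dir)
    split = store.split_ids()
    if split is None:
        raise ConfigurationError("window store carries no split; rebuild with one")
    state = train_mod.train_model(store, split, cfg.model_configuration(),
                                  cfg.train_configuration(),
                                  train_mod.LossConfig(cfg.loss.omega_pos))
    net.save_checkpoint(run_dir / "checkpoint.npz", state.model, state.norm,
                        extra={"config_hash": cfg.hash,
                               "store_hash": store.config_hash,
                               "best_epoch": state.best_epoch,
                               "best_val_loss": state.best_val_loss})
    import pandas as pd
    pd.DataFrame(state.history).to_csv(run_dir / "history.csv", index=False)
    save_config(cfg, run_dir / "config.resolved.json")
    click.echo(f"best epoch {state.best_epoch}, val loss {state.best_val_loss:.4f}")


@cli.command("evaluate")
@click.option("--run", "run_dir", required=True, type=click.Path(exists=True))
@click.option("--store", "store_dir", type=click.Path(exists=True), default=None)
@click.option("--split", "split_name", default="test", show_default=True,
              type=click.Choice(["train", "val", "test"]))
def evaluate_cmd(run_dir, store_dir, split_name):
    """Evaluate a trained run at the F1-optimal validation threshold."""
    setup_logging()
    store = windows.WindowStore(store_dir) if store_dir else None
    out = evaluate_run(run_dir, store=store, split_name=split_name)
    click.echo(json.dumps(out, indent=1))


@cli.command("explain")
@click.option("--run", "run_dir", required=True, type=click.Path(exists=True))
@click.option("--store", "store_dir", type=click.Path(exists=True), default=None)
@click.option("--window", "window_spec", default=None,
              help="PATIENT:END_INDEX (default: top-scoring positive windows)")
@click.option("--out", "out_dir", type=click.Path(), default=None)
def explain_cmd(run_dir, store_dir, window_spec, out_dir):
    """Write Integrated-Gradients saliency CSVs for sample windows."""
    setup_logging()
    store = windows.WindowStore(store_dir) if store_dir else None
    results = explain_run(run_dir, store=store, window_spec=window_spec,
                          out_dir=out_dir)
    for r in results:
        click.echo(f"F(x)={r.f_x:.4f} ΔF={r.delta_f:.4f} "
                   f"completeness_gap={r.completeness_gap:.2e}")


if __name__ == "__main__":
    cli()
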