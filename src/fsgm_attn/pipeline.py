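"""End-to-end experiment orchestration with reproducible configuration.

A run proceeds through dependency-ordered stages — stimuli, fixture
training, readouts, tuning, gradients, attention sweeps, signal-detection
summaries, propagation (ratio) analyses — each writing CSV/JSON artifacts to
the output directory and recording its status in a manifest.  A stage
failure is recorded and its downstream dependents are skipped rather than
aborting the run.  Every random choice funnels through the single run seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, attention, evaluate, gradients, network, stimuli, tuning

__all__ = ["RunConfig", "RunManifest", "run_experiment", "summarize"]

logger = logging.getLogger("fsgm_attn")

STAGE_DEPS = {
    "fixture": (),
    "readouts": ("fixture",),
    "tuning": ("fixture",),
    "gradients": ("readouts", "tuning"),
    "sweep": ("readouts", "tuning"),
    "sdt": ("readouts", "tuning"),
    "ratios": ("tuning",),
}

STAGE_ORDER = ["fixture", "readouts", "tuning", "gradients", "sweep", "sdt", "ratios"]


@dataclass
class RunConfig:
    """Declarative description of one experiment run."""

    seed: int = 0
    output_dir: str = "fsgm_run"
    # stimuli
    canvas_size: int = stimuli.DEFAULT_SIZE
    frequency: float = stimuli.DEFAULT_FREQUENCY
    n_train_per_class: int = 8
    n_test_per_condition: int = 40
    # fixture architecture / training
    n_maps: tuple[int, ...] = (8, 16, 16, 32, 32)
    pool_after: tuple[int, ...] = (2, 4)
    epochs: int = 40
    accuracy_floor: float = 0.10
    # attention grid
    attention_layers: tuple[int, ...] = ()  # empty = last layer only
    beta_max: float = 1.2
    beta_step: float = attention.BETA_STEP
    attention_source: str = "tuning"
    attention_mode: str = "multiplicative"
    # stages to run
    tasks: tuple[str, ...] = ("tuning", "gradients", "sweep", "sdt", "ratios")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("n_maps", "pool_after", "attention_layers", "tasks"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)  # name -> {status, artifacts, seconds}
    versions: dict = field(default_factory=dict)
    wall_clock: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _versions() -> dict:
    import scipy
    import sklearn

    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
    }


def run_experiment(config: RunConfig) -> RunManifest:
    """Execute all requested stages in dependency order; write a manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = RunManifest(
        config_hash=config.config_hash(), seed=config.seed, versions=_versions()
    )
    logger.info("run %s starting (seed=%d)", manifest.config_hash, config.seed)
    t_start = time.time()
    state: dict = {}
    requested = set(config.tasks) | {"fixture", "readouts"} if config.tasks else set()
    done: set[str] = set()
    failed: set[str] = set()

    def _stage(name):
        if name not in requested and name not in ("fixture", "readouts"):
            return False
        if name not in requested:
            return False
        deps = STAGE_DEPS[name]
        if any(d in failed or (d in requested and d not in done) for d in deps):
            manifest.stages[name] = {"status": "skipped", "artifacts": []}
            return False
        return True

    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(2**31)) for name in STAGE_ORDER}

    for name in STAGE_ORDER:
        if not _stage(name):
            continue
        t0 = time.time()
        logger.info("stage %s starting", name)
        try:
            artifacts = _STAGES[name](config, state, out, seeds[name])
            manifest.stages[name] = {
                "status": "ok",
                "artifacts": [str(a) for a in artifacts],
                "seconds": round(time.time() - t0, 2),
            }
            done.add(name)
        except Exception as exc:  # stage isolation: record, skip dependents
            logger.exception("stage %s failed", name)
            failed.add(name)
            manifest.stages[name] = {
                "status": "failed",
                "error": f"{type(exc).__name__}: {exc}",
                "artifacts": [],
                "seconds": round(time.time() - t0, 2),
            }
    manifest.wall_clock = round(time.time() - t_start, 2)
    manifest.to_json(out / "manifest.json")
    logger.info("run finished in %.1fs", manifest.wall_clock)
    return manifest


# --------------------------------------------------------------------------
# stage implementations


def _arch(config: RunConfig) -> network.ArchitectureConfig:
    return network.ArchitectureConfig(
        n_maps=config.n_maps,
        pool_after=config.pool_after,
        input_size=config.canvas_size,
    )


def _layers(config: RunConfig, model) -> tuple[int, ...]:
    return config.attention_layers or (model.arch.n_layers,)


def _stage_fixture(config, state, out, seed):
    model = network.train_fixture_network(
        arch=_arch(config),
        config=network.TrainingConfig(
            epochs=config.epochs, accuracy_floor=config.accuracy_floor
        ),
        seed=seed,
        n_per_class=config.n_train_per_class,
    )
    state["model"] = model
    path = model.save(out / "model")
    (out / "fixture.json").write_text(
        json.dumps({"holdout_accuracy": model.holdout_accuracy})
    )
    return [path, out / "fixture.json"]


def _stage_readouts(config, state, out, seed):
    model = state["model"]
    rng = np.random.default_rng(seed)
    train = stimuli.full_field_training_set(
        max(4, config.n_train_per_class), size=config.canvas_size, seed=rng
    )
    state["readout_train"] = train
    network.attach_binary_readouts(
        model, list(stimuli.ORIENTATIONS), train, seed=seed
    )
    network.attach_color_readout(model, train, seed=seed)
    network.compute_layer_means(model, stimuli.stack_pixels(train))
    model.save(out / "model")
    return [out / "model"]


def _stage_tuning(config, state, out, seed):
    model = state["model"]
    train = state["readout_train"]
    x = stimuli.stack_pixels(train)
    oris = list(stimuli.ORIENTATIONS)
    labels = [
        oris.index(next(iter(img.labels)).orientation) for img in train.items
    ]
    record = tuning.record_responses(model, x, labels, oris)
    table = tuning.compute_tuning_values(record)
    state["tuning"] = table
    state["tuning_record"] = record
    path = out / "tuning.csv"
    table.to_frame().to_csv(path, index=False)
    return [path]


def _test_sets(config, state, seed):
    if "test_sets" in state:
        return state["test_sets"]
    rng = np.random.default_rng(seed)
    sets = {}
    for ori in stimuli.ORIENTATIONS:
        recipe = stimuli.two_grating_recipe(ori, config.canvas_size, config.frequency)
        sets[ori] = stimuli.build_balanced_detection_set(
            ori, config.n_test_per_condition, recipe, seed=rng
        )
    state["test_sets"] = sets
    return sets


def _stage_gradients(config, state, out, seed):
    model = state["model"]
    table = state["tuning"]
    sets = _test_sets(config, state, seed)
    images_by_condition = {
        ori: (stimuli.stack_pixels(s), s.is_positive) for ori, s in sets.items()
    }
    grads = gradients.compute_task_gradients(model, images_by_condition)
    state["gradients"] = grads
    corr = gradients.correlate_tuning_gradients(table, grads, n_shuffles=20, seed=seed)
    path_csv = out / "gradients.csv"
    grads.to_frame().to_csv(path_csv, index=False)
    path_corr = out / "tuning_gradient_correlation.json"
    path_corr.write_text(json.dumps(corr, indent=2, default=float))
    return [path_csv, path_corr]


def _stage_sweep(config, state, out, seed):
    model = state["model"]
    table = state["tuning"]
    sets = _test_sets(config, state, seed)
    grid = attention.default_beta_grid(
        "orientation", step=config.beta_step, beta_max=config.beta_max
    )
    rows = []
    for layer in _layers(config, model):
        for ori, s in sets.items():
            cfg = attention.AttentionConfig(
                source=config.attention_source,
                layers=(layer,),
                mode=config.attention_mode,
                attended_condition=ori,
            )
            frame, best = attention.sweep_beta(
                model,
                stimuli.stack_pixels(s),
                s.is_positive,
                ori,
                cfg,
                grid,
                table=table,
            )
            frame.insert(0, "condition", ori)
            frame.insert(0, "layers", layer)
            frame["best_beta"] = best
            rows.append(frame)
    sweep = pd.concat(rows, ignore_index=True)
    state["sweep"] = sweep
    path = out / "sweep.csv"
    sweep.to_csv(path, index=False)
    return [path]


def _stage_sdt(config, state, out, seed):
    model = state["model"]
    table = state["tuning"]
    sets = _test_sets(config, state, seed)
    layer = _layers(config, model)[-1]
    rows = []
    for ori, s in sets.items():
        x = stimuli.stack_pixels(s)
        base = evaluate.evaluate_detection(model, x, s.is_positive, ori)
        m0 = evaluate.sdt_metrics(base.tp, base.fp)
        cfg = attention.AttentionConfig(
            source=config.attention_source,
            layers=(layer,),
            beta=0.75,
            mode=config.attention_mode,
            attended_condition=ori,
        )
        field = attention.build_attention_field(cfg, table, model)
        att = evaluate.evaluate_detection(model, x, s.is_positive, ori, attention=field)
        m1 = evaluate.sdt_metrics(att.tp, att.fp)
        rows.append(
            {
                "condition": ori,
                "criteria_base": m0.criteria,
                "criteria_attn": m1.criteria,
                "dprime_base": m0.sensitivity,
                "dprime_attn": m1.sensitivity,
                "performance_base": base.performance,
                "performance_attn": att.performance,
            }
        )
    frame = pd.DataFrame(rows)
    path = out / "sdt.csv"
    frame.to_csv(path, index=False)
    return [path]


def _stage_ratios(config, state, out, seed):
    model = state["model"]
    table = state["tuning"]
    layers = _layers(config, model)
    rows = []
    for layer in layers:
        cfg = attention.AttentionConfig(
            source="tuning",
            layers=(layer,),
            beta=analysis.RATIO_BETA,
            attended_condition=stimuli.ORIENTATIONS[0],
        )
        record = analysis.record_activity_ratios(model, table, cfg)
        for rec_layer in range(layer, model.arch.n_layers + 1):
            fit = analysis.fsgm_ratio_fit(record, table, rec_layer)
            fm = analysis.feature_matching_fraction(record, table, rec_layer)
            rows.append(
                {
                    "applied_layer": layer,
                    "recorded_layer": rec_layer,
                    "median_slope": float(np.nanmedian(fit.slope[fit.valid]))
                    if fit.valid.any()
                    else np.nan,
                    "median_intercept_minus_1": float(
                        np.nanmedian(fit.intercept[fit.valid]) - 1.0
                    )
                    if fit.valid.any()
                    else np.nan,
                    "fm_fraction": fm,
                }
            )
    frame = pd.DataFrame(rows)
    path = out / "ratio_fits.csv"
    frame.to_csv(path, index=False)
    return [path]


_STAGES = {
    "fixture": _stage_fixture,
    "readouts": _stage_readouts,
    "tuning": _stage_tuning,
    "gradients": _stage_gradients,
    "sweep": _stage_sweep,
    "sdt": _stage_sdt,
    "ratios": _stage_ratios,
}


def summarize(manifest: RunManifest, output_dir: str | Path | None = None) -> str:
    """Human-readable report of a run; skipped stages are marked, not errors."""
    out = Path(output_dir) if output_dir else None
    lines = [
        f"run {manifest.config_hash} (seed {manifest.seed}), "
        f"{manifest.wall_clock:.1f}s wall clock",
        "",
    ]
    for name, info in manifest.stages.items():
        status = info["status"]
        lines.append(f"[{status}] {name} ({info.get('seconds', 0)}s)")
        if status == "failed":
            lines.append(f"    error: {info['error']}")
        if status != "ok":
            continue
        if out is None:
            continue
        if name == "sweep" and (out / "sweep.csv").exists():
            sweep = pd.read_csv(out / "sweep.csv")
            base = sweep[sweep.beta == 0].groupby("layers")["performance"].mean()
            best = sweep.groupby(["layers", "condition"])["performance"].max().groupby(
                "layers"
            ).mean()
            for layer in base.index:
                lines.append(
                    f"    layer {layer}: baseline {base[layer]:.3f}, "
                    f"best-beta {best[layer]:.3f} "
                    f"(delta {best[layer] - base[layer]:+.3f})"
                )
        if name == "sdt" and (out / "sdt.csv").exists():
            sdt = pd.read_csv(out / "sdt.csv")
            lines.append(
                f"    mean delta criteria {np.mean(sdt.criteria_attn - sdt.criteria_base):+.3f}, "
                f"mean delta d' {np.mean(sdt.dprime_attn - sdt.dprime_base):+.3f}"
            )
        if name == "ratios" and (out / "ratio_fits.csv").exists():
            fits = pd.read_csv(out / "ratio_fits.csv")
            at = fits[fits.applied_layer == fits.recorded_layer]
            lines.append(
                f"    at applied layer: median slope {at.median_slope.mean():+.4f}, "
                f"median intercept-1 {at.median_intercept_minus_1.mean():+.4f}"
            )
    return "\n".join(lines)
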