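"""End-to-end pipeline: data -> normalize -> discretize -> select -> split
-> cascade training -> evaluation, driven by a single nested configuration.

One global seed fans out to per-stage seeds through ``numpy``'s
``SeedSequence`` so any stage can be rerun in isolation reproducibly.
Identical configuration and seed produce byte-identical artifacts.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import cascade as _cascade
from . import evaluation as _evaluation
from . import preprocess as _preprocess
from . import selection as _selection
from . import synthetic as _synthetic
from .data_model import FeatureTable, Schema, load_table, pid_schema
from .errors import ParameterError
from .neural import TrainConfig, hidden_preset

__all__ = ["DEFAULT_CONFIG", "resolve_config", "run_pipeline"]

log = logging.getLogger("diacascade")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "data": {
        "source": "synth",  # synth | csv
        "path": None,
        "schema": None,  # YAML path; None -> PID schema for csv sources
        "missing": "keep",
        "preset": "gaussian",  # gaussian | pid_like
        "n_per_class": 200,
        "separation": 4.0,
        "n_informative": 6,
        "n_noise": 2,
    },
    "select": {"enabled": True, "discard": 2, "smoothing": 1.0},
    "split": {"fraction": 0.8, "stratify": False},
    "net": {"hidden": [50, 25, 5], "preset": None, "activation": "sigmoid"},
    "train": {
        "mode": "scg",
        "max_epochs": 250,
        "goal_mse": 1e-3,
        "ridge": 1e-6,
        "representation": "normalized",  # normalized | discretized
    },
    "evaluate": {"mape_curve": []},
    "eligibility": {"column": None},
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ParameterError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict) and not isinstance(value, dict):
            raise ParameterError(f"configuration key {here} must be a mapping")
        if isinstance(defaults[key], dict):
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def resolve_config(user: dict | None = None, seed: int | None = None) -> dict:
    """Overlay user settings on the defaults, rejecting unknown keys."""
    cfg = _merge(DEFAULT_CONFIG, user or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


def _stage_seed(base: int, stage: int) -> int:
    ss = np.random.SeedSequence(entropy=base, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2**31))


def _load_data(cfg: dict) -> FeatureTable:
    d = cfg["data"]
    if d["source"] == "csv":
        if not d["path"]:
            raise ParameterError("data.path required for csv source")
        schema = Schema.from_yaml(d["schema"]) if d["schema"] else pid_schema()
        return load_table(d["path"], schema, missing=d["missing"])
    if d["source"] == "synth":
        seed = _stage_seed(cfg["seed"], 0)
        if d["preset"] == "gaussian":
            spec = _synthetic.gaussian_spec(
                n_per_class=d["n_per_class"],
                n_informative=d["n_informative"],
                n_noise=d["n_noise"],
                separation=d["separation"],
                seed=seed,
            )
        elif d["preset"] == "pid_like":
            spec = _synthetic.pid_like_spec(n_per_class=d["n_per_class"], seed=seed)
        else:
            raise ParameterError(f"unknown synth preset {d['preset']!r}")
        return _synthetic.generate(spec)
    raise ParameterError(f"unknown data source {d['source']!r}")


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None):
    """Execute every stage in order; returns the final evaluation report.

    When ``out_dir`` is given, writes ``config.yaml`` (the resolved
    configuration), ``model.json``, ``predictions.csv`` and
    ``report.json`` under it.
    """
    cfg = config if config and config.get("_resolved") else resolve_config(config)
    cfg = {k: v for k, v in cfg.items() if k != "_resolved"}
    log.info("resolved configuration: %s", json.dumps(cfg, sort_keys=True))

    table = _load_data(cfg)
    log.info("loaded %d rows x %d attributes", table.n_rows, table.n_attributes)

    normalized = _preprocess.normalize(table)
    disc = _preprocess.discretize(normalized)

    if cfg["select"]["enabled"]:
        report = _selection.strength_matrix(disc, smoothing=cfg["select"]["smoothing"])
        kept = _selection.select_attributes(report, cfg["select"]["discard"])
        log.info("kept attributes: %s (discarded %s)", kept, report.discarded)
    else:
        kept = list(table.attribute_names)

    representation = cfg["train"]["representation"]
    if representation == "normalized":
        working = normalized.select_attributes(kept)
    elif representation == "discretized":
        working = disc.select_attributes(kept).as_feature_table()
    else:
        raise ParameterError(f"unknown representation {representation!r}")

    sp = _preprocess.split(
        working,
        fraction=cfg["split"]["fraction"],
        seed=_stage_seed(cfg["seed"], 1),
        stratify=cfg["split"]["stratify"],
    )

    hidden = (
        hidden_preset(cfg["net"]["preset"])
        if cfg["net"]["preset"]
        else tuple(cfg["net"]["hidden"])
    )
    train_cfg = TrainConfig(
        max_epochs=cfg["train"]["max_epochs"],
        goal_mse=cfg["train"]["goal_mse"],
        seed=_stage_seed(cfg["seed"], 2),
        ridge=cfg["train"]["ridge"],
    )
    model = _cascade.cascade_train(
        sp.train,
        train_cfg,
        hidden=hidden,
        mode=cfg["train"]["mode"],
        hidden_activation=cfg["net"]["activation"],
        eligibility_column=cfg["eligibility"]["column"],
    )

    eligibility = None
    elig_col = cfg["eligibility"]["column"]
    if elig_col is not None:
        eligibility = sp.test.column(elig_col) > 0
    else:
        eligibility = np.ones(sp.test.n_rows, dtype=bool)
    pred, scores = _cascade.cascade_predict_table(
        model, sp.test, eligibility=eligibility, return_scores=True
    )

    report = _evaluation.evaluate(sp.test.labels, pred)
    report.mape = _evaluation.mape(sp.test.labels, pred)
    budgets = cfg["evaluate"]["mape_curve"]
    if budgets:
        report.mape_curve = _evaluation.mape_curve(
            sp.train,
            sp.test,
            budgets,
            cfg=train_cfg,
            hidden=hidden,
            mode=cfg["train"]["mode"],
            eligibility=eligibility,
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        _cascade.save_model(model, out / "model.json")
        _write_predictions(out / "predictions.csv", pred, scores, sp.test.labels)
        (out / "report.json").write_text(
            json.dumps(report.as_dict(), sort_keys=True, indent=1)
        )
        log.info("artifacts written under %s", out)
    return report


def _write_predictions(path: Path, pred, scores, truth) -> None:
    import pandas as pd

    cols = {
        "row": np.arange(len(pred)),
        "true_class": truth,
        "predicted_class": pred,
    }
    names = [
        "stage1_normal",
        "stage1_disease",
        "stage2_normal",
        "stage2_disease",
        "stage3_normal",
        "stage3_disease",
    ]
    for j, name in enumerate(names):
        cols[name] = scores[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)
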