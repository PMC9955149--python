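"""Sequential three-network classifier for diabetes subtypes.

Stage 1 separates normal from type 1, stage 2 normal from type 2 and stage
3 normal from gestational diabetes.  A record flows through the stages in
that fixed order: the first stage that votes "disease" terminates the
cascade with that diagnosis; a record voted normal by every applicable
stage is classified normal.  Because gestational diabetes only occurs in
pregnancy, the third stage is applied only to records flagged eligible.

Each member network is a binary MLP with two outputs, one-hot coded
``[normal, disease]``, trained independently on the two-class subset of the
training table.  Ties between the two output scores resolve to normal, the
conservative choice that passes the record on to the next stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import FeatureTable
from .errors import InputError, ModelFormatError
from .neural import MLPModel, TrainConfig, forward, init_mlp, train_noprop, train_scg

__all__ = [
    "STAGE_CLASSES",
    "STAGE_NAMES",
    "CascadeModel",
    "cascade_train",
    "cascade_predict",
    "cascade_predict_table",
    "save_model",
    "load_model",
    "MODEL_FORMAT_VERSION",
]

#: disease class decided by each stage, in cascade order
STAGE_CLASSES: tuple[int, int, int] = (2, 3, 4)
STAGE_NAMES: tuple[str, str, str] = ("type1", "type2", "gestational")

MODEL_FORMAT_VERSION = 1


@dataclass
class CascadeModel:
    """Ordered triple of binary networks plus the retained attribute list.

    ``nets[k]`` decides ``STAGE_CLASSES[k]``; an untrained stage (no
    training rows for its disease class) is ``None`` and skipped at
    prediction time.
    """

    nets: list[MLPModel | None]
    retained_attributes: list[str]
    stage_order: tuple[str, str, str] = STAGE_NAMES
    eligibility_column: str | None = None

    def __post_init__(self) -> None:
        if len(self.nets) != 3:
            raise InputError("a cascade has exactly three stages")
        width = len(self.retained_attributes)
        for name, net in zip(STAGE_NAMES, self.nets):
            if net is None:
                continue
            if net.n_in != width:
                raise InputError(
                    f"stage {name}: input width {net.n_in} != "
                    f"{width} retained attributes"
                )
            if net.n_out != 2:
                raise InputError(f"stage {name}: member networks need 2 outputs")

    @property
    def input_width(self) -> int:
        return len(self.retained_attributes)


def _stage_seed(base_seed: int, stage: int, attempt: int = 0) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(stage, attempt))
    return int(ss.generate_state(1)[0] % (2**31))


def cascade_train(
    train: FeatureTable,
    cfg: TrainConfig | None = None,
    hidden: tuple[int, ...] = (50, 25, 5),
    mode: str = "scg",
    hidden_activation: str = "sigmoid",
    eligibility_column: str | None = None,
    restarts: int = 5,
) -> CascadeModel:
    """Train the three member networks on two-class subsets.

    Stage ``k`` sees only the rows labelled normal (1) or its disease class
    (``k + 1``), with one-hot ``[normal, disease]`` targets.  All normal
    rows participate in every stage.  A stage whose disease class has no
    rows is left untrained with a warning.  Per-stage seeds are derived
    deterministically from ``cfg.seed``.

    Training a deep sigmoid stack is non-convex and can stall on a plateau,
    so each stage is given up to ``restarts`` seeded re-initializations;
    the first run reaching ``cfg.goal_mse`` wins, otherwise the run with
    the lowest final error is kept.  The whole procedure stays
    deterministic for a fixed ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    if mode not in ("scg", "noprop"):
        raise InputError(f"unknown training mode {mode!r}")
    labels = train.labels
    if not (labels == 1).any():
        raise InputError("training table has no normal (class 1) rows")
    if not np.isin(labels, STAGE_CLASSES).any():
        raise InputError("training table has no disease rows")

    nets: list[MLPModel | None] = []
    for k, disease in enumerate(STAGE_CLASSES):
        rows = np.flatnonzero((labels == 1) | (labels == disease))
        n_disease = int((labels == disease).sum())
        if n_disease == 0:
            warnings.warn(
                f"no class-{disease} rows: stage {STAGE_NAMES[k]} left "
                "untrained and will be skipped at prediction",
                stacklevel=2,
            )
            nets.append(None)
            continue
        X = train.values[rows]
        Y = np.zeros((rows.size, 2))
        Y[labels[rows] == 1, 0] = 1.0  # normal
        Y[labels[rows] == disease, 1] = 1.0  # disease
        trainer = train_scg if mode == "scg" else train_noprop
        best_net = None
        for attempt in range(max(1, restarts)):
            seed = _stage_seed(cfg.seed, k, attempt)
            net = init_mlp(
                [train.n_attributes, *hidden, 2],
                seed=seed,
                hidden_activation=hidden_activation,
            )
            stage_cfg = TrainConfig(
                max_epochs=cfg.max_epochs,
                goal_mse=cfg.goal_mse,
                seed=seed,
                sigma0=cfg.sigma0,
                lambda0=cfg.lambda0,
                patience=cfg.patience,
                ridge=cfg.ridge,
            )
            fitted = trainer(net, X, Y, stage_cfg)
            if best_net is None or fitted.trace[-1] < best_net.trace[-1]:
                best_net = fitted
            if best_net.trace[-1] <= cfg.goal_mse or mode == "noprop":
                break
        nets.append(best_net)
    return CascadeModel(
        nets=nets,
        retained_attributes=list(train.attribute_names),
        eligibility_column=eligibility_column,
    )


def _stage_scores(net: MLPModel, x: np.ndarray) -> np.ndarray:
    return forward(net, x)


def cascade_predict(
    model: CascadeModel, x: np.ndarray, eligible_gestational: bool = True
) -> int:
    """Classify one record; returns a class code in {1, 2, 3, 4}.

    Stages run in order; ``score_disease > score_normal`` terminates with
    the stage's disease class, otherwise the record moves on.  The
    gestational stage only runs when ``eligible_gestational`` is true.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.input_width,):
        raise InputError(
            f"input width mismatch: expected {model.input_width}, got {x.shape}"
        )
    for k, disease in enumerate(STAGE_CLASSES):
        if disease == 4 and not eligible_gestational:
            continue
        net = model.nets[k]
        if net is None:
            continue
        normal_score, disease_score = _stage_scores(net, x)
        if disease_score > normal_score:  # tie resolves to normal
            return disease
    return 1


def cascade_predict_table(
    model: CascadeModel,
    table: FeatureTable,
    eligibility: np.ndarray | None = None,
    return_scores: bool = False,
):
    """Classify every row of a table.

    ``eligibility`` is a boolean vector gating the gestational stage; when
    ``None`` and the model names no eligibility column, every record is
    eligible (a warning notes the unrestricted gate).
    """
    if list(table.attribute_names) != list(model.retained_attributes):
        raise InputError(
            "table attributes do not match the model's retained attributes; "
            f"expected {model.retained_attributes}"
        )
    n = table.n_rows
    if eligibility is None:
        if model.eligibility_column is None:
            warnings.warn(
                "no eligibility rule for the gestational stage; treating "
                "all records as eligible",
                stacklevel=2,
            )
        eligibility = np.ones(n, dtype=bool)
    eligibility = np.asarray(eligibility, dtype=bool)
    if eligibility.shape != (n,):
        raise InputError("eligibility vector must align with table rows")

    scores = np.full((n, 6), np.nan)
    pred = np.ones(n, dtype=int)
    undecided = np.ones(n, dtype=bool)
    for k, disease in enumerate(STAGE_CLASSES):
        net = model.nets[k]
        active = undecided & (eligibility if disease == 4 else True)
        if net is None or not active.any():
            continue
        out = forward(net, table.values[active])
        scores[active, 2 * k : 2 * k + 2] = out
        is_disease = out[:, 1] > out[:, 0]
        idx = np.flatnonzero(active)[is_disease]
        pred[idx] = disease
        undecided[idx] = False
    return (pred, scores) if return_scores else pred


def save_model(model: CascadeModel, path: str | Path) -> None:
    """Write the cascade as a versioned, self-describing JSON archive.

    JSON floats round-trip exactly, so a save/load cycle reproduces the
    weights bit for bit.
    """
    payload = {
        "format": "diacascade-cascade",
        "version": MODEL_FORMAT_VERSION,
        "stage_order": list(model.stage_order),
        "retained_attributes": list(model.retained_attributes),
        "eligibility_column": model.eligibility_column,
        "nets": [net.to_dict() if net is not None else None for net in model.nets],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> CascadeModel:
    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"{path}: not a valid model archive") from exc
    if not isinstance(payload, dict) or payload.get("format") != "diacascade-cascade":
        raise ModelFormatError(f"{path}: not a cascade model archive")
    version = payload.get("version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: model format version {version} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    try:
        nets = [
            MLPModel.from_dict(d) if d is not None else None
            for d in payload["nets"]
        ]
        return CascadeModel(
            nets=nets,
            retained_attributes=list(payload["retained_attributes"]),
            stage_order=tuple(payload["stage_order"]),
            eligibility_column=payload["eligibility_column"],
        )
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"{path}: truncated or corrupt model archive") from exc
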