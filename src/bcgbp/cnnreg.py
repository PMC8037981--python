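"""1-D CNN regression of blood pressure from two-channel BCG phase epochs.

The architecture follows the chair-BCG estimation method exactly: three 1-D
convolution blocks (100/200/300 filters — one, two and three times the
100 Hz sampling rate — with kernels 21/5/5, stride 1, batch normalization
and ReLU after each convolution), max pooling by 2 after the first and
second blocks, global average pooling, and a single dense output unit with
identity activation mapping straight to mmHg.  Training minimizes MSE with
Adam at learning rate 0.001; one network is trained per target (SBP or DBP)
and per session (rest or recovery).  Model selection runs 10-fold
cross-validation over the training split and keeps the fold model with the
lowest validation MSE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .dataset import PhaseEpoch, SplitPlan

__all__ = [
    "ArchitectureSpec",
    "TrainSettings",
    "TrainedRegressor",
    "build_model",
    "shape_report",
    "parameter_count",
    "train_model",
    "predict_bp",
    "epochs_to_arrays",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """The fixed network topology; defaults are the published configuration."""

    input_len: int = 1000
    in_channels: int = 2
    conv_filters: tuple[int, int, int] = (100, 200, 300)
    conv_kernels: tuple[int, int, int] = (21, 5, 5)
    conv_stride: int = 1
    pool_after: tuple[bool, bool, bool] = (True, True, False)
    pool_factor: int = 2
    batch_norm: bool = True
    activation: str = "relu"

    def __post_init__(self) -> None:
        n_pools = sum(self.pool_after)
        if self.input_len % (self.pool_factor**n_pools):
            raise ValueError(
                f"input_len {self.input_len} not divisible by "
                f"pool_factor^{n_pools} = {self.pool_factor**n_pools}"
            )
        if self.conv_stride != 1:
            raise ValueError("only stride 1 is supported")


@dataclass(frozen=True)
class TrainSettings:
    """Optimization settings; loss is MSE and the optimizer Adam."""

    target: str = "sbp"
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target not in ("sbp", "dbp"):
            raise ValueError("target must be 'sbp' or 'dbp'")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainedRegressor:
    """A fitted network plus the CV bookkeeping that selected it."""

    architecture: ArchitectureSpec
    weights: dict[str, np.ndarray]
    target: str
    session: str
    fold_history: list[float]
    selected_fold: int
    train_log: list[dict] = field(default_factory=list)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "architecture.json").write_text(json.dumps(asdict(self.architecture)))
        np.savez(out / "weights.npz", **self.weights)
        meta = {
            "target": self.target,
            "session": self.session,
            "fold_history": self.fold_history,
            "selected_fold": self.selected_fold,
            "train_log": self.train_log,
        }
        (out / "training.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, out_dir: str | Path) -> "TrainedRegressor":
        out = Path(out_dir)
        arch = json.loads((out / "architecture.json").read_text())
        arch["conv_filters"] = tuple(arch["conv_filters"])
        arch["conv_kernels"] = tuple(arch["conv_kernels"])
        arch["pool_after"] = tuple(arch["pool_after"])
        with np.load(out / "weights.npz") as z:
            weights = {k: z[k] for k in z.files}
        meta = json.loads((out / "training.json").read_text())
        return cls(
            architecture=ArchitectureSpec(**arch),
            weights=weights,
            target=meta["target"],
            session=meta["session"],
            fold_history=meta["fold_history"],
            selected_fold=meta["selected_fold"],
            train_log=meta.get("train_log", []),
        )


def build_model(
    spec: ArchitectureSpec = ArchitectureSpec(), rng: np.random.Generator | None = None
) -> tuple[nn.Sequential, list[dict]]:
    """Realize the network and report each layer's output geometry.

    Returns the model and a shape report: one entry per layer with the
    output channel count and sequence length (dense output reported as
    channels=1, length=1).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    layers: list[nn.Layer] = []
    report = [{"layer": "input", "channels": spec.in_channels, "length": spec.input_len}]
    c_in, length = spec.in_channels, spec.input_len
    for i, (c_out, kernel) in enumerate(zip(spec.conv_filters, spec.conv_kernels)):
        layers.append(nn.Conv1D(c_in, c_out, kernel, rng))
        report.append({"layer": f"conv{i + 1}", "channels": c_out, "length": length})
        if spec.batch_norm:
            layers.append(nn.BatchNorm1D(c_out))
        layers.append(nn.ReLU())
        if spec.pool_after[i]:
            layers.append(nn.MaxPool1D(spec.pool_factor))
            length //= spec.pool_factor
            report.append({"layer": f"pool{i + 1}", "channels": c_out, "length": length})
        c_in = c_out
    layers.append(nn.GlobalAvgPool())
    report.append({"layer": "gap", "channels": c_in, "length": 1})
    layers.append(nn.Dense(c_in, 1))
    report.append({"layer": "dense", "channels": 1, "length": 1})
    return nn.Sequential(layers), report


def shape_report(spec: ArchitectureSpec = ArchitectureSpec()) -> list[dict]:
    """The per-layer output-shape report without instantiating weights."""
    _, report = build_model(spec, np.random.default_rng(0))
    return report


def parameter_count(spec: ArchitectureSpec = ArchitectureSpec()) -> int:
    """Trainable parameter total of the realized network."""
    model, _ = build_model(spec, np.random.default_rng(0))
    return model.n_params()


def epochs_to_arrays(
    epochs: list[PhaseEpoch], target: str
) -> tuple[np.ndarray, np.ndarray]:
    """Stack epochs into (n, 2, L) float32 inputs and an (n,) mmHg vector."""
    x = np.stack(
        [np.stack([e.phase_back, e.phase_seat]) for e in epochs]
    ).astype(np.float32)
    y = np.asarray([getattr(e, target) for e in epochs], dtype=np.float32)
    return x, y


def _to_engine(x: np.ndarray) -> np.ndarray:
    """(n, 2, L) channel-first epochs -> engine's channels-last float32."""
    return np.ascontiguousarray(x.transpose(0, 2, 1), dtype=np.float32)


def _fit_one(
    model: nn.Sequential,
    x_tr: np.ndarray,
    y_tr: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    settings: TrainSettings,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], float, list[dict]]:
    """Train one network; early-stop on validation MSE; return best weights."""
    opt = nn.Adam(model, lr=settings.learning_rate)
    # start predictions at the training-target mean so the head only has to
    # learn deviations (the output unit is identity-activated mmHg)
    model.layers[-1].params["b"][:] = np.float32(y_tr.mean())
    n = x_tr.shape[0]
    best_val = np.inf
    best_weights = model.get_weights()
    since_best = 0
    log: list[dict] = []
    for ep in range(settings.max_epochs):
        order = rng.permutation(n)
        tr_loss = 0.0
        for start in range(0, n, settings.batch_size):
            idx = order[start : start + settings.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            pred = model.forward(xb, train=True)[:, 0]
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {ep}, "
                    f"lr={settings.learning_rate}, batch={settings.batch_size}"
                )
            tr_loss += loss * len(idx)
            model.backward((2.0 * err / len(idx))[:, None].astype(np.float32))
            opt.step()
        val_pred = predict_arrays(model, x_val)
        val_mse = float(np.mean((val_pred - y_val) ** 2))
        log.append({"epoch": ep, "train_mse": tr_loss / n, "val_mse": val_mse})
        if val_mse < best_val - 1e-6:
            best_val = val_mse
            best_weights = model.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= settings.early_stop_patience:
                break
    return best_weights, best_val, log


def predict_arrays(model: nn.Sequential, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Inference (batch-norm in running-stats mode) over an (n, L, 2) stack."""
    out = [
        model.forward(x[i : i + batch_size], train=False)[:, 0]
        for i in range(0, x.shape[0], batch_size)
    ]
    return np.concatenate(out)


def train_model(
    epochs: list[PhaseEpoch],
    plan: SplitPlan,
    spec: ArchitectureSpec = ArchitectureSpec(),
    settings: TrainSettings = TrainSettings(),
    refit_full_train: bool = False,
) -> TrainedRegressor:
    """Cross-validated training over the plan's folds.

    For each of the plan's folds, a fresh network is trained on the other
    folds and validated on the held-out one; the fold model with the lowest
    validation MSE is returned as the selected regressor.  With
    ``refit_full_train`` the selected fold only chooses the early-stopping
    validation set and a final network is retrained on the entire training
    split.  Fully deterministic for fixed data, plan and seed.
    """
    if not plan.folds:
        raise ValueError("plan has no CV folds; call make_cv_folds first")
    sessions = {e.session for e in epochs}
    if len(sessions) > 1:
        raise ValueError(f"epochs mix sessions {sorted(sessions)}; train per session")
    session = epochs[0].session
    x, y = epochs_to_arrays(epochs, settings.target)
    if x.shape[2] != spec.input_len or x.shape[1] != spec.in_channels:
        raise ValueError(
            f"epoch geometry {x.shape[1:]} does not match the architecture "
            f"({spec.in_channels}, {spec.input_len})"
        )
    xe = _to_engine(x)
    fold_history: list[float] = []
    logs: list[dict] = []
    best: tuple[float, int, dict[str, np.ndarray]] | None = None
    streams = np.random.SeedSequence(settings.seed).spawn(len(plan.folds))
    for f, val_idx in enumerate(plan.folds):
        train_idx = np.setdiff1d(plan.train, val_idx)
        rng = np.random.default_rng(streams[f])
        model, _ = build_model(spec, rng)
        weights, val_mse, log = _fit_one(
            model, xe[train_idx], y[train_idx], xe[val_idx], y[val_idx], settings, rng
        )
        fold_history.append(val_mse)
        logs.append({"fold": f, "epochs": log})
        if best is None or val_mse < best[0]:
            best = (val_mse, f, weights)
    assert best is not None
    if refit_full_train:
        val_idx = plan.folds[best[1]]
        rng = np.random.default_rng(np.random.SeedSequence(settings.seed).spawn(
            len(plan.folds) + 1)[-1])
        model, _ = build_model(spec, rng)
        weights, val_mse, log = _fit_one(
            model, xe[plan.train], y[plan.train], xe[val_idx], y[val_idx], settings, rng
        )
        logs.append({"fold": "refit_full_train", "epochs": log})
        best = (val_mse, best[1], weights)
    return TrainedRegressor(
        architecture=spec,
        weights=best[2],
        target=settings.target,
        session=session,
        fold_history=fold_history,
        selected_fold=best[1],
        train_log=logs,
    )


def predict_bp(model: TrainedRegressor, epochs: list[PhaseEpoch]) -> np.ndarray:
    """Per-epoch BP estimates (mmHg) from a trained regressor."""
    spec = model.architecture
    for e in epochs:
        if e.n_samples != spec.input_len:
            raise ValueError(
                f"epoch has {e.n_samples} samples, model expects {spec.input_len}"
            )
    net, _ = build_model(spec, np.random.default_rng(0))
    net.set_weights(model.weights)
    x, _ = epochs_to_arrays(epochs, model.target)
    return predict_arrays(net, _to_engine(x)).astype(float)
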