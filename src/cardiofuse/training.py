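"""Composite Huber + concordance loss, optimization schedule, and the
sklearn-style regression estimator.

The loss is ``L = L_Huber(delta=1) + lambda * (1 - CCC)`` with
``lambda = 0.1``: the Huber term gives outlier-robust pointwise accuracy, the
concordance correlation coefficient (CCC) term pushes predictions toward the
identity line (penalizing bias and scale shrinkage, not just decorrelation).
CCC uses population (divide-by-n) moments with an ``eps = 1e-6`` denominator
guard and is clipped to [-1, 1]; in batch-wise training the loss (and its
gradient) is evaluated per batch.

Optimization follows a standard wearable-regression recipe: Adam at 1e-4,
batch 32, up to 1000 epochs, early stopping after 20 epochs without
validation improvement, learning rate halved after 4 stagnant epochs with a
1e-6 floor, and the minimum-validation-loss weights restored at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .network import FusionNetwork, ModelConfig, count_parameters

__all__ = [
    "LossConfig",
    "TrainConfig",
    "huber",
    "huber_grad",
    "ccc",
    "ccc_grad",
    "composite_loss",
    "composite_loss_grad",
    "Adam",
    "PlateauEarlyStop",
    "train",
    "predict_indirect",
    "CardiacOutputRegressor",
    "segments_to_arrays",
]


@dataclass(frozen=True)
class LossConfig:
    delta: float = 1.0   # Huber threshold
    lam: float = 0.1     # weight of the (1 - CCC) term
    eps: float = 1e-6    # CCC denominator guard

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.lam < 0 or self.eps <= 0:
            raise ValueError("require delta > 0, lam >= 0, eps > 0")


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 1e-4
    batch: int = 32
    max_epochs: int = 1000
    early_stop_patience: int = 20
    plateau_patience: int = 4
    plateau_factor: float = 0.5
    lr_min: float = 1e-6
    min_delta: float = 1e-8      # strict-decrease margin for "improvement"
    seed: int = 0
    target: str = "CI"           # {"CI", "CO"}
    standardize_targets: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must be in (0, 1)")
        if self.lr_min >= self.lr0:
            raise ValueError("lr_min must be below lr0")
        if self.target not in ("CI", "CO"):
            raise ValueError("target must be CI or CO")


# ------------------------------------------------------------------- loss

def huber(y, y_hat, delta: float = 1.0) -> float:
    """Mean Huber loss: quadratic within ``delta``, linear beyond."""
    y, y_hat = np.asarray(y, float), np.asarray(y_hat, float)
    if y.size == 0:
        raise ValueError("empty batch")
    e = np.abs(y_hat - y)
    quad = 0.5 * e**2
    lin = delta * e - 0.5 * delta**2
    return float(np.where(e <= delta, quad, lin).mean())


def huber_grad(y, y_hat, delta: float = 1.0) -> np.ndarray:
    """d(mean Huber)/d(y_hat): clip(e, -delta, delta) / n."""
    y, y_hat = np.asarray(y, float), np.asarray(y_hat, float)
    return np.clip(y_hat - y, -delta, delta) / y.size


def _ccc_raw(y, y_hat, eps):
    mx, my = y.mean(), y_hat.mean()
    vx = ((y - mx) ** 2).mean()
    vy = ((y_hat - my) ** 2).mean()
    sxy = ((y - mx) * (y_hat - my)).mean()
    denom = vx + vy + (mx - my) ** 2 + eps
    return 2.0 * sxy / denom, mx, my, sxy, denom


def ccc(y, y_hat, eps: float = 1e-6) -> float:
    """Concordance correlation coefficient with population moments,
    eps-guarded denominator, clipped to [-1, 1]."""
    y, y_hat = np.asarray(y, float), np.asarray(y_hat, float)
    if y.size < 2:
        raise ValueError("CCC needs at least 2 samples")
    c, *_ = _ccc_raw(y, y_hat, eps)
    return float(np.clip(c, -1.0, 1.0))


def ccc_grad(y, y_hat, eps: float = 1e-6) -> np.ndarray:
    """d(CCC)/d(y_hat); zero where the clip to [-1, 1] is active."""
    y, y_hat = np.asarray(y, float), np.asarray(y_hat, float)
    n = y.size
    c, mx, my, sxy, denom = _ccc_raw(y, y_hat, eps)
    if abs(c) > 1.0:  # clipped -> flat
        return np.zeros(n)
    dnum = 2.0 * (y - mx) / n
    dden = 2.0 * (y_hat - mx) / n
    return (dnum * denom - 2.0 * sxy * dden) / denom**2


def composite_loss(y, y_hat, cfg: LossConfig | None = None) -> float:
    """Huber + lam * (1 - CCC)."""
    cfg = cfg or LossConfig()
    return huber(y, y_hat, cfg.delta) + cfg.lam * (1.0 - ccc(y, y_hat, cfg.eps))


def composite_loss_grad(y, y_hat, cfg: LossConfig | None = None) -> np.ndarray:
    cfg = cfg or LossConfig()
    g = huber_grad(y, y_hat, cfg.delta)
    if cfg.lam > 0:
        g = g - cfg.lam * ccc_grad(y, y_hat, cfg.eps)
    return g


# -------------------------------------------------------------- optimizer

class Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + eps)


class PlateauEarlyStop:
    """Validation-loss driven LR plateau decay plus early stopping.

    "Improvement" means a strict decrease of the monitored loss by more than
    ``min_delta``.  After ``plateau_patience`` stagnant epochs the learning
    rate is multiplied by ``plateau_factor`` (floored at ``lr_min``) and the
    plateau counter resets; after ``early_stop_patience`` stagnant epochs
    training stops.  The epoch with the lowest monitored loss is tracked so
    its weights can be restored.
    """

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        self.lr = cfg.lr0
        self.best = np.inf
        self.best_epoch = 0
        self._stall_plateau = 0
        self._stall_stop = 0
        self.epoch = 0

    def step(self, monitored_loss: float) -> dict:
        """Advance one epoch; returns improved/stop flags and the LR to use
        for the *next* epoch."""
        self.epoch += 1
        improved = monitored_loss < self.best - self.cfg.min_delta
        if improved:
            self.best = monitored_loss
            self.best_epoch = self.epoch
            self._stall_plateau = 0
            self._stall_stop = 0
        else:
            self._stall_plateau += 1
            self._stall_stop += 1
            if self._stall_plateau >= self.cfg.plateau_patience:
                self.lr = max(self.lr * self.cfg.plateau_factor, self.cfg.lr_min)
                self._stall_plateau = 0
        stop = self._stall_stop >= self.cfg.early_stop_patience
        return {"improved": improved, "stop": stop, "lr": self.lr}


# --------------------------------------------------------------- training

def train(
    model: FusionNetwork,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
) -> tuple[list, list[dict]]:
    """Mini-batch Adam training with plateau LR decay and early stopping.

    ``X_*`` have shape (n, 2, input_len) — channel 0 ECG, channel 1 PPG.
    The monitored loss is the composite loss on the validation set (full-set
    CCC), or the mean train-batch loss when no validation data is given.
    Returns the best weights (also restored onto ``model``) and the per-epoch
    history (epoch, train_loss, val_loss, lr).
    """
    cfg = cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    if X_train.shape[0] == 0:
        raise ValueError("empty training set")
    has_val = X_val is not None and y_val is not None and len(X_val) > 0
    rng = np.random.default_rng(cfg.seed)
    sched = PlateauEarlyStop(cfg)
    opt = Adam(model.parameters(), lr=cfg.lr0)

    y_train = np.asarray(y_train, float)
    best_weights = model.get_weights()
    history: list[dict] = []
    n = X_train.shape[0]

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        batch_losses = []
        for i in range(0, n, cfg.batch):
            idx = order[i: i + cfg.batch]
            if idx.size < 2:
                continue  # CCC undefined on singleton batches
            xb_e = X_train[idx, 0]
            xb_p = X_train[idx, 1]
            yb = y_train[idx]
            y_hat = model.forward(xb_e, xb_p, training=True, rng=rng)
            if not np.all(np.isfinite(y_hat)):
                raise FloatingPointError(
                    f"non-finite prediction at epoch {epoch}"
                )
            batch_losses.append(composite_loss(yb, y_hat, loss_cfg))
            model.zero_grad()
            model.backward(composite_loss_grad(yb, y_hat, loss_cfg))
            opt.step()
        train_loss = float(np.mean(batch_losses))
        if has_val:
            v_hat = model.predict(X_val[:, 0], X_val[:, 1],
                                  batch_size=cfg.batch)
            monitored = composite_loss(y_val, v_hat, loss_cfg)
            val_loss = monitored
        else:
            monitored, val_loss = train_loss, np.nan
        state = sched.step(monitored)
        if state["improved"]:
            best_weights = model.get_weights()
        history.append(
            {"epoch": epoch, "train_loss": train_loss,
             "val_loss": val_loss, "lr": opt.lr}
        )
        opt.lr = state["lr"]
        if state["stop"]:
            break

    model.set_weights(best_weights)
    return best_weights, history


def predict_indirect(ci_model, X: np.ndarray, bsa: np.ndarray) -> np.ndarray:
    """Indirect CO: predicted CI times patient-specific BSA, per segment."""
    bsa = np.asarray(bsa, float)
    if bsa.size != X.shape[0]:
        raise ValueError("need one BSA per segment")
    if np.any(~np.isfinite(bsa)) or np.any(bsa <= 0):
        raise ValueError("BSA values must be positive and finite")
    ci_hat = np.asarray(ci_model.predict(X), float)
    return ci_hat * bsa


# -------------------------------------------------------------- estimator

class CardiacOutputRegressor(RegressorMixin, BaseEstimator):
    """ECG-PPG fusion regressor with the sklearn estimator API.

    ``X`` has shape (n_segments, 2, input_len): channel 0 the ECG window,
    channel 1 the synchronized PPG window, both at 250 Hz.  ``y`` is the
    reference CI (L/min/m^2) or CO (L/min) per segment.

    Parameters mirror the published architecture/optimization settings; see
    :class:`ModelConfig` and :class:`TrainConfig`.  ``standardize_targets``
    z-scores y with training-set statistics before regression (inverted at
    prediction time) — useful for short training budgets; default off (raw
    physical units).
    """

    def __init__(
        self,
        conv_filters: int = 32,
        kernel: int = 7,
        pool: int = 5,
        se_reduction: int = 8,
        attn_dim: int = 32,
        dense_units: tuple = (64, 32),
        dropout: float = 0.3,
        input_len: int = 15_000,
        delta: float = 1.0,
        lam: float = 0.1,
        eps: float = 1e-6,
        lr0: float = 1e-4,
        batch_size: int = 32,
        max_epochs: int = 1000,
        early_stop_patience: int = 20,
        plateau_patience: int = 4,
        plateau_factor: float = 0.5,
        lr_min: float = 1e-6,
        standardize_targets: bool = False,
        seed: int = 0,
    ):
        self.conv_filters = conv_filters
        self.kernel = kernel
        self.pool = pool
        self.se_reduction = se_reduction
        self.attn_dim = attn_dim
        self.dense_units = dense_units
        self.dropout = dropout
        self.input_len = input_len
        self.delta = delta
        self.lam = lam
        self.eps = eps
        self.lr0 = lr0
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.plateau_patience = plateau_patience
        self.plateau_factor = plateau_factor
        self.lr_min = lr_min
        self.standardize_targets = standardize_targets
        self.seed = seed

    # ------------------------------------------------------------- config
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            conv_filters=self.conv_filters, kernel=self.kernel,
            pool=self.pool, se_reduction=self.se_reduction,
            attn_dim=self.attn_dim, dense_units=tuple(self.dense_units),
            dropout=self.dropout, input_len=self.input_len,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            lr0=self.lr0, batch=self.batch_size, max_epochs=self.max_epochs,
            early_stop_patience=self.early_stop_patience,
            plateau_patience=self.plateau_patience,
            plateau_factor=self.plateau_factor, lr_min=self.lr_min,
            seed=self.seed, standardize_targets=self.standardize_targets,
        )

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1] != 2 or X.shape[2] != self.input_len:
            raise ValueError(
                f"X must have shape (n, 2, {self.input_len}), got {X.shape}"
            )
        return X

    # ---------------------------------------------------------------- api
    def fit(self, X, y, X_val=None, y_val=None):
        X = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if X_val is not None:
            X_val = self._validate_X(X_val)
            y_val = np.asarray(y_val, dtype=float)

        self.y_mean_, self.y_scale_ = 0.0, 1.0
        if self.standardize_targets:
            self.y_mean_ = float(y.mean())
            self.y_scale_ = float(y.std()) or 1.0
        yt = (y - self.y_mean_) / self.y_scale_
        yv = None if y_val is None else (y_val - self.y_mean_) / self.y_scale_

        self.network_ = FusionNetwork(self._model_config(), seed=self.seed)
        self.n_parameters_ = count_parameters(self.network_)
        _, history = train(
            self.network_, X, yt, X_val, yv,
            cfg=self._train_config(),
            loss_cfg=LossConfig(delta=self.delta, lam=self.lam, eps=self.eps),
        )
        self.history_ = history
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "network_"):
            raise AttributeError("estimator is not fitted yet")
        X = self._validate_X(X)
        z = self.network_.predict(X[:, 0], X[:, 1], batch_size=self.batch_size)
        return z * self.y_scale_ + self.y_mean_


def segments_to_arrays(segments, target: str = "CI"):
    """Stack labeled segments into (X, y, patient_ids, bsa) arrays.

    BSA per segment is recovered from the consistent CO/CI label pair.
    """
    if target not in ("CI", "CO"):
        raise ValueError("target must be CI or CO")
    X = np.stack(
        [np.stack([s.ecg, s.ppg]) for s in segments]
    ).astype(np.float32)
    y = np.array(
        [s.ci_ref if target == "CI" else s.co_ref for s in segments], float
    )
    pids = np.array([s.patient_id for s in segments])
    bsa = np.array(
        [s.co_ref / s.ci_ref if (s.co_ref and s.ci_ref) else np.nan
         for s in segments]
    )
    return X, y, pids, bsa
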