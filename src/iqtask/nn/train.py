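"""Training loops for the SR networks and the learned observers.

Both trainers standardize images with the training-set mean/std, run Adam on
mini-batches, and keep the checkpoint with the best validation metric (MSE
for SR, AUC for observers). All shuffling and initialization comes from
explicit generators, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from iqtask.imaging import ImagingEnsemble, redraw_noise
from iqtask.metrics import empirical_auc
from iqtask.nn._engine import Adam, bce_with_logits, mse_loss
from iqtask.nn.models import ResNetObserver, SRCNN
from iqtask.observers import central_crop

__all__ = ["TrainingConfig", "train_sr", "apply_sr", "train_observer"]


@dataclass
class TrainingConfig:
    batch_size: int = 16
    learning_rate: float = 5e-4
    max_epochs: int = 30
    seed: int = 0
    semionline_noise: bool = False
    augment_flips: bool = False
    early_selection: bool = True
    adversarial_weight: float = 0.0
    # train the SR network on the HR-LR residual (identity shortcut); a
    # standard optimization aid for shallow SR networks at small budgets
    residual: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")


def _images(x) -> np.ndarray:
    return np.asarray(x.images if hasattr(x, "images") else x, dtype=np.float32)


def train_sr(
    model: SRCNN,
    lr_train,
    hr_train,
    cfg: TrainingConfig,
    lr_val=None,
    hr_val=None,
    adversarial_grad: Callable[[np.ndarray], np.ndarray] | None = None,
) -> dict:
    """Fit the SR network by minimizing MSE between S(fLR) and fHR.

    ``adversarial_grad`` is an optional hook returning an extra gradient on
    the SR batch (weighted by ``cfg.adversarial_weight``); the default MSE
    path never uses it. Returns a history dict; the model is left holding
    the best-validation checkpoint (or the final one if no validation set).
    """
    x = _images(lr_train)
    y = _images(hr_train)
    if x.shape != y.shape:
        raise ValueError(f"paired ensembles must share shapes, got {x.shape} vs {y.shape}")
    mu = float(x.mean())
    sd = float(x.std()) or 1.0
    model.norm_mu, model.norm_sd = mu, sd
    model.residual = cfg.residual
    xn = (x - mu) / sd
    yn = (y - mu) / sd
    if cfg.residual:
        yn = yn - xn
    has_val = lr_val is not None and hr_val is not None
    if has_val:
        xv = ((_images(lr_val) - mu) / sd)[:, None]
        yv = ((_images(hr_val) - mu) / sd)[:, None]
        if cfg.residual:
            yv = yv - xv
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), cfg.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, None)
    for _ in range(cfg.max_epochs):
        order = rng.permutation(len(xn))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb = xn[idx][:, None]
            pred = model.forward(xb)
            loss, grad = mse_loss(pred, yn[idx][:, None])
            if adversarial_grad is not None and cfg.adversarial_weight > 0:
                grad = grad + cfg.adversarial_weight * adversarial_grad(pred)
            model.backward(grad.astype(np.float32))
            opt.step(model.grads())
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if has_val:
            vloss = _batched_mse(model, xv, yv)
            history["val_loss"].append(vloss)
            if cfg.early_selection and vloss < best[0]:
                best = (vloss, model.state())
    if best[1] is not None:
        model.load_state(best[1])
    model.trained = True
    return history


def _batched_mse(model: SRCNN, xv: np.ndarray, yv: np.ndarray, batch: int = 32) -> float:
    tot, n = 0.0, 0
    for i in range(0, len(xv), batch):
        pred = model.forward(xv[i : i + batch])
        tot += float(np.sum((pred - yv[i : i + batch]).astype(np.float64) ** 2))
        n += pred.size
    return tot / n


def apply_sr(model: SRCNN, ens: ImagingEnsemble, batch_size: int = 32) -> ImagingEnsemble:
    """Super-resolve an ensemble; labels and specs carry over."""
    spec = dict(ens.generation_spec)
    spec["sr_model"] = {
        "spec": model.spec,
        "trained": model.trained,
        "norm": (model.norm_mu, model.norm_sd),
    }
    if not model.trained:
        spec["warning"] = "SR model applied without training"
    return ImagingEnsemble(
        model.predict(ens.images, batch_size=batch_size),
        ens.labels.copy(),
        "SR",
        spec,
    )


def _flip_augment(images: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    stacks = [images, images[:, ::-1], images[:, :, ::-1], images[:, ::-1, ::-1]]
    return np.concatenate(stacks), np.tile(labels, 4)


def train_observer(
    model: ResNetObserver,
    train_ens: ImagingEnsemble,
    val_ens: ImagingEnsemble,
    cfg: TrainingConfig,
    crop: int | None = None,
) -> dict:
    """Fit the observer by minimizing binary cross-entropy on image labels.

    With ``cfg.semionline_noise`` the noise component of every training image
    is re-drawn each epoch from the stored noiseless stack. With
    ``cfg.augment_flips`` the training set is expanded fourfold by flips.
    Returns a history dict; the model holds the best-validation-AUC
    checkpoint.
    """
    labels = train_ens.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    crop = crop if crop is not None else model.spec.input_size
    base = central_crop(train_ens.images, crop)
    mu = float(base.mean())
    sd = float(base.std()) or 1.0
    model.norm_mu, model.norm_sd = mu, sd
    xv = central_crop(val_ens.images, crop)
    vmask0 = val_ens.labels == 0
    rng = np.random.default_rng(cfg.seed)
    noise_rng = np.random.default_rng((cfg.seed, 1))
    opt = Adam(model.params(), cfg.learning_rate)
    history = {"train_loss": [], "val_auc": []}
    best = (-np.inf, None)
    for _ in range(cfg.max_epochs):
        if cfg.semionline_noise:
            imgs = central_crop(redraw_noise(train_ens, noise_rng), crop)
        else:
            imgs = base
        lab = labels
        if cfg.augment_flips:
            imgs, lab = _flip_augment(imgs, lab)
        xn = (imgs - mu) / sd
        order = rng.permutation(len(xn))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb = np.ascontiguousarray(xn[idx][:, None])
            scores = model.forward(xb)
            loss, grad = bce_with_logits(scores, lab[idx])
            model.backward(grad.astype(np.float32), xb.shape)
            opt.step(model.grads())
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        vscores = model.score(xv)
        vauc = empirical_auc((vscores[vmask0], vscores[~vmask0]))
        history["val_auc"].append(vauc)
        if cfg.early_selection and vauc > best[0]:
            best = (vauc, model.state())
    if best[1] is not None:
        model.load_state(best[1])
    model.trained = True
    return history
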