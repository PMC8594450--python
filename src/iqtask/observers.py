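"""Hotelling-family linear observers.

Implements empirical class statistics, the Hotelling observer (HO)
``w = K^{-1} dfbar``, its regularized variant (RHO) built from a truncated
pseudoinverse of the pooled covariance, and the channelized Hotelling
observer (CHO) operating in a 60-dimensional Gabor channel space.

The pooled covariance ``K = (K0 + K1)/2`` is symmetric positive
semidefinite, so its SVD coincides with its eigendecomposition; symmetry is
enforced by averaging with the transpose before decomposing. The truncated
pseudoinverse keeps the P leading modes with ``sigma_P >= lam * sigma_1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Literal, Sequence

import numpy as np

from iqtask.metrics import empirical_auc

__all__ = [
    "CovarianceModel",
    "LinearTemplate",
    "GaborChannelSpec",
    "ChannelMatrix",
    "ScoreSet",
    "central_crop",
    "fit_covariance_model",
    "truncated_pinv",
    "rho_template",
    "ho_template",
    "gabor_function",
    "build_gabor_matrix",
    "cho_template",
    "apply_linear",
    "select_lambda",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID: tuple[float, ...] = (1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4)


def central_crop(images: np.ndarray, size: int | None) -> np.ndarray:
    """Centered crop of a (N, H, W) stack or a single image; None is a no-op.

    For even input sides the window starts at (N - size)//2 (0-based,
    half-open).
    """
    if size is None:
        return np.asarray(images)
    x = np.asarray(images)
    h, w = x.shape[-2:]
    if size > h or size > w:
        raise ValueError(f"crop {size} exceeds image size {(h, w)}")
    r0 = (h - size) // 2
    c0 = (w - size) // 2
    return x[..., r0 : r0 + size, c0 : c0 + size]


def _flatten(images, crop: int | None) -> np.ndarray:
    x = images.images if hasattr(images, "images") else np.asarray(images)
    if x.ndim == 2:
        x = x[None]
    x = central_crop(x, crop)
    return x.reshape(len(x), -1).astype(np.float64)


@dataclass
class CovarianceModel:
    """Class-conditional means and pooled covariance of vectorized images."""

    mean_h0: np.ndarray
    mean_h1: np.ndarray
    cov_h0: np.ndarray
    cov_h1: np.ndarray
    n_samples_per_class: tuple[int, int]
    crop: int | None = None

    @property
    def delta_mean(self) -> np.ndarray:
        return self.mean_h1 - self.mean_h0

    @property
    def pooled_cov(self) -> np.ndarray:
        return 0.5 * (self.cov_h0 + self.cov_h1)

    @cached_property
    def svd(self) -> tuple[np.ndarray, np.ndarray]:
        """(singular_values, singular_vectors) of the symmetrized pooled covariance.

        Values are sorted non-increasing and clipped at zero; for a PSD
        matrix left and right singular vectors coincide with the returned
        eigenvectors (columns).
        """
        k = self.pooled_cov
        k = 0.5 * (k + k.T)
        vals, vecs = np.linalg.eigh(k)
        order = np.argsort(vals)[::-1]
        return np.maximum(vals[order], 0.0), vecs[:, order]

    @property
    def singular_values(self) -> np.ndarray:
        return self.svd[0]

    @property
    def rank(self) -> int:
        s = self.singular_values
        if s.size == 0 or s[0] == 0:
            return 0
        return int(np.sum(s > s[0] * np.finfo(float).eps * len(s)))


@dataclass
class LinearTemplate:
    """An observer weight vector with the metadata that produced it."""

    weights: np.ndarray
    observer_kind: Literal["HO", "RHO", "CHO"]
    lam: float | None = None
    retained_modes: int | None = None
    channel_ref: "ChannelMatrix | None" = None
    crop: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("template weights must be finite")


@dataclass
class ScoreSet:
    """Per-class test-statistic samples of one observer."""

    scores_h0: np.ndarray
    scores_h1: np.ndarray
    observer_id: str = ""
    decision_threshold: float | None = None

    def __post_init__(self) -> None:
        self.scores_h0 = np.asarray(self.scores_h0, dtype=np.float64).ravel()
        self.scores_h1 = np.asarray(self.scores_h1, dtype=np.float64).ravel()


def fit_covariance_model(ens_h0, ens_h1, crop: int | None = None) -> CovarianceModel:
    """Empirical means and covariances per class on (optionally cropped) images.

    Covariances use the 1/(n-1) normalization.
    """
    x0 = _flatten(ens_h0, crop)
    x1 = _flatten(ens_h1, crop)
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("need at least 2 images per class to fit covariances")
    if x0.shape[1] != x1.shape[1]:
        raise ValueError("class image shapes differ")
    m0 = x0.mean(axis=0)
    m1 = x1.mean(axis=0)
    d0 = x0 - m0
    d1 = x1 - m1
    k0 = d0.T @ d0 / (len(x0) - 1)
    k1 = d1.T @ d1 / (len(x1) - 1)
    return CovarianceModel(m0, m1, k0, k1, (len(x0), len(x1)), crop)


def _retained(model: CovarianceModel, lam: float) -> int:
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    s, _ = model.svd
    if s.size == 0 or s[0] <= 0:
        return 0
    floor = s[0] * np.finfo(float).eps * len(s)  # numerically zero modes are never inverted
    return int(np.sum(s >= max(lam * s[0], floor)))


def truncated_pinv(model: CovarianceModel, lam: float) -> np.ndarray:
    """Truncated pseudoinverse keeping modes with sigma_i >= lam * sigma_1."""
    p = _retained(model, lam)
    s, u = model.svd
    if p == 0:
        return np.zeros_like(model.pooled_cov)
    up = u[:, :p]
    return (up / s[:p]) @ up.T


def rho_template(model: CovarianceModel, lam: float) -> LinearTemplate:
    """Regularized Hotelling template ``w = K_lam^+ dfbar``."""
    p = _retained(model, lam)
    s, u = model.svd
    if p == 0:
        w = np.zeros_like(model.delta_mean)
    else:
        up = u[:, :p]
        w = up @ ((up.T @ model.delta_mean) / s[:p])
    return LinearTemplate(w, "RHO", lam=lam, retained_modes=p, crop=model.crop)


def ho_template(model: CovarianceModel) -> LinearTemplate:
    """Hotelling template ``w = K^{-1} dfbar`` (requires invertible K)."""
    w = np.linalg.solve(model.pooled_cov, model.delta_mean)
    t = LinearTemplate(w, "HO", crop=model.crop)
    return t


# ---------------------------------------------------------------------------
# Gabor channels
# ---------------------------------------------------------------------------


def _default_width(nu: float) -> float:
    # 1-octave channel: frequency-domain FWHM = 2*nu/3 = 4 ln2 / (pi w)
    return 6.0 * math.log(2.0) / (math.pi * nu)


@dataclass(frozen=True)
class GaborChannelSpec:
    """Bank of Gabor channels: 6 octave-wide passbands x 5 orientations x 2 phases."""

    center_frequencies: tuple[float, ...] = (3 / 256, 3 / 128, 3 / 64, 3 / 32, 3 / 16, 3 / 8)
    orientations: tuple[float, ...] = (
        0.0,
        2 * math.pi / 5,
        4 * math.pi / 5,
        6 * math.pi / 5,
        8 * math.pi / 5,
    )
    phases: tuple[float, ...] = (0.0, math.pi / 2)
    grid_size: int = 64
    widths: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for nu in self.center_frequencies:
            if nu >= 0.5:
                raise ValueError(f"center frequency {nu} >= Nyquist (0.5 cycles/pixel)")
            if nu <= 0:
                raise ValueError("center frequencies must be positive")
        if self.widths is not None:
            if len(self.widths) != len(self.center_frequencies):
                raise ValueError("one width per passband required")
            if any(w <= 0 for w in self.widths):
                raise ValueError("channel widths must be positive")

    @property
    def resolved_widths(self) -> tuple[float, ...]:
        if self.widths is not None:
            return self.widths
        return tuple(_default_width(nu) for nu in self.center_frequencies)

    @property
    def n_channels(self) -> int:
        return len(self.center_frequencies) * len(self.orientations) * len(self.phases)


def gabor_function(x, y, width: float, nu: float, theta: float, phi: float) -> np.ndarray:
    """Gabor channel profile: Gaussian envelope times an oriented sinusoid."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    envelope = np.exp(-4.0 * math.log(2.0) * (x**2 + y**2) / width**2)
    carrier = np.cos(2.0 * math.pi * nu * (x * math.cos(theta) + y * math.sin(theta)) + phi)
    return envelope * carrier


@dataclass
class ChannelMatrix:
    """Discretized channel bank as a (q, n) matrix acting on vectorized images."""

    matrix: np.ndarray
    spec: GaborChannelSpec | None = None

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def apply(self, images, crop: int | None = None) -> np.ndarray:
        """Channel outputs v = T fhat for a stack of images; returns (N, q)."""
        x = _flatten(images, crop)
        if x.shape[1] != self.matrix.shape[1]:
            raise ValueError(
                f"image length {x.shape[1]} does not match channel matrix width {self.matrix.shape[1]}"
            )
        return x @ self.matrix.T


def build_gabor_matrix(spec: GaborChannelSpec) -> ChannelMatrix:
    """Discretize the Gabor bank on the grid (coordinates centred on the grid)."""
    g = spec.grid_size
    coords = np.arange(g) - (g - 1) / 2.0
    xx = coords[None, :]
    yy = coords[:, None]
    rows = []
    for nu, w in zip(spec.center_frequencies, spec.resolved_widths):
        for theta in spec.orientations:
            for phi in spec.phases:
                rows.append(gabor_function(xx, yy, w, nu, theta, phi).ravel())
    return ChannelMatrix(np.array(rows), spec)


def cho_template(channels: ChannelMatrix, data, crop: int | None = None) -> LinearTemplate:
    """Channelized Hotelling template ``w = Kv^{-1} dvbar``.

    ``data`` is either a fitted :class:`CovarianceModel` (channelized
    analytically) or a pair ``(imgs_h0, imgs_h1)`` of image stacks from
    which the channel-space statistics are estimated directly.
    """
    t = channels.matrix
    if isinstance(data, CovarianceModel):
        kv = t @ data.pooled_cov @ t.T
        dv = t @ data.delta_mean
        crop = data.crop
    else:
        imgs_h0, imgs_h1 = data
        v0 = channels.apply(imgs_h0, crop)
        v1 = channels.apply(imgs_h1, crop)
        if len(v0) < 2 or len(v1) < 2:
            raise ValueError("need at least 2 images per class")
        kv = 0.5 * (np.cov(v0, rowvar=False) + np.cov(v1, rowvar=False))
        dv = v1.mean(axis=0) - v0.mean(axis=0)
    try:
        w = np.linalg.solve(kv, dv)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "channelized covariance is singular; estimate it from more samples"
        ) from err
    return LinearTemplate(w, "CHO", channel_ref=channels, crop=crop)


def apply_linear(
    template: LinearTemplate,
    ens,
    channels: ChannelMatrix | None = None,
    crop: int | None = None,
) -> ScoreSet:
    """Score an ensemble with a linear template: t = w . fhat (or w . T fhat)."""
    channels = channels if channels is not None else template.channel_ref
    crop = crop if crop is not None else template.crop
    if channels is not None:
        feats = channels.apply(ens.images if hasattr(ens, "images") else ens, crop)
    else:
        feats = _flatten(ens, crop)
    if feats.shape[1] != len(template.weights):
        raise ValueError(
            f"feature length {feats.shape[1]} does not match template length {len(template.weights)}"
        )
    scores = feats @ template.weights
    labels = getattr(ens, "labels", None)
    if labels is None:
        raise ValueError("apply_linear needs an ensemble with labels")
    return ScoreSet(scores[labels == 0], scores[labels == 1], observer_id=template.observer_kind)


def select_lambda(
    model: CovarianceModel,
    val_h0,
    val_h1,
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> tuple[float, list[tuple[float, float]]]:
    """Pick the RHO truncation threshold by validation AUC over a grid.

    Returns ``(lam_star, [(lam, auc), ...])``; ties break toward the larger
    lambda (more regularization).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    x0 = _flatten(val_h0, model.crop)
    x1 = _flatten(val_h1, model.crop)
    if len(x0) == 0 or len(x1) == 0:
        raise ValueError("validation ensembles must be non-empty")
    table = []
    best_lam, best_auc = None, -np.inf
    for lam in sorted(grid):
        w = rho_template(model, lam).weights
        auc = empirical_auc((x0 @ w, x1 @ w))
        table.append((lam, auc))
        if auc >= best_auc:  # >= so ties prefer the larger lambda
            best_lam, best_auc = lam, auc
    return best_lam, table
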