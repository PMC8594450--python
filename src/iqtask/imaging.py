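"""Degradation operators, noise model, and HR/LR ensemble assembly.

The low-resolution measurement model differs per task:

* Rayleigh task: ``LR = blur(f, sigma=1.5) + n`` on the same 128x128 grid
  (no resampling), with ``HR = f + n``.
* MC-cluster task: ``LR = up2( down2(blur(f, sigma=1.5)) + n )`` — the blur
  is followed by factor-2 downsampling, noise is added on the LR grid, and a
  bilinear factor-2 upsampling restores the HR grid so LR/SR/HR images are
  directly comparable.

The measurement noise is a centred mixture of a scaled Poisson variate and a
Gaussian: ``n = sigma_p * (P - lam0)/sqrt(lam0) + sigma_g * Z`` with
``P ~ Poisson(lam0)``, ``Z ~ N(0,1)``, IID across pixels, so the per-pixel
noise standard deviation is ``sqrt(sigma_p**2 + sigma_g**2)`` regardless of
the image content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from iqtask.phantoms import (
    CLBParams,
    MCClusterSpec,
    ObjectImage,
    RayleighSignalSpec,
    insert_mc,
    make_rayleigh_signal,
    rotate_crop_cluster,
    sample_clb,
    synth_mc_cluster,
)

__all__ = [
    "DegradationSpec",
    "NoiseSpec",
    "ImagingEnsemble",
    "gaussian_blur",
    "resample",
    "add_mixed_noise",
    "build_task_ensembles",
]


@dataclass(frozen=True)
class DegradationSpec:
    """Blur/resampling chain mapping an HR object to its LR measurement."""

    blur_sigma: float = 1.5
    downsample_factor: int = 1
    upsample_back: bool = False
    task: Literal["rayleigh", "mc"] = "rayleigh"

    def __post_init__(self) -> None:
        if not self.blur_sigma > 0:
            raise ValueError("blur_sigma must be > 0")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")

    @classmethod
    def rayleigh_default(cls) -> "DegradationSpec":
        return cls(1.5, 1, False, "rayleigh")

    @classmethod
    def mc_default(cls) -> "DegradationSpec":
        return cls(1.5, 2, True, "mc")


@dataclass(frozen=True)
class NoiseSpec:
    """Mixed scaled-Poisson plus Gaussian measurement noise.

    ``poisson_rate`` is the internal rate lam0 of the Poisson variate; the
    centred, scaled variate has standard deviation exactly ``poisson_scale``
    for any rate, so lam0 only shapes higher moments.
    """

    poisson_scale: float = 0.013
    gaussian_std: float = 0.35
    poisson_rate: float = 10.0

    def __post_init__(self) -> None:
        if self.poisson_scale < 0 or self.gaussian_std < 0:
            raise ValueError("noise scales must be >= 0")
        if not self.poisson_rate > 0:
            raise ValueError("poisson_rate must be > 0")

    @classmethod
    def rayleigh_default(cls) -> "NoiseSpec":
        return cls(0.013, 0.35)

    @classmethod
    def mc_default(cls) -> "NoiseSpec":
        return cls(0.0001, 0.001)

    @property
    def std(self) -> float:
        return float(np.hypot(self.poisson_scale, self.gaussian_std))


@dataclass
class ImagingEnsemble:
    """A labelled stack of images of one resolution class.

    ``clean`` optionally stores the noiseless image at the grid where noise
    is inserted (HR grid, or the downsampled grid for the MC task) together
    with ``post_noise`` ("none" or "upsample2"), so the noise component can
    be re-drawn later (semionline training).
    """

    images: np.ndarray  # (N, H, W) float32
    labels: np.ndarray  # (N,) int8; 0 = H0, 1 = H1
    resolution_class: Literal["HR", "LR", "SR"]
    generation_spec: dict = field(default_factory=dict)
    clean: np.ndarray | None = None
    post_noise: str = "none"
    noise_spec: NoiseSpec | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.images.ndim != 3:
            raise ValueError("images must be a (N, H, W) stack")
        if len(self.labels) != len(self.images):
            raise ValueError("one label per image required")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    def subset(self, idx) -> "ImagingEnsemble":
        return ImagingEnsemble(
            self.images[idx],
            self.labels[idx],
            self.resolution_class,
            dict(self.generation_spec),
            None if self.clean is None else self.clean[idx],
            self.post_noise,
            self.noise_spec,
        )

    def split(self, n_first: int) -> tuple["ImagingEnsemble", "ImagingEnsemble"]:
        return self.subset(slice(None, n_first)), self.subset(slice(n_first, None))


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, ObjectImage) else np.asarray(img)


def _wrap_like(out: np.ndarray, src) -> ObjectImage | np.ndarray:
    if isinstance(src, ObjectImage):
        return ObjectImage(out, role=src.role, hypothesis=src.hypothesis, seed_provenance=src.seed_provenance)
    return out


def gaussian_blur(img, sigma: float):
    """Convolve with a normalized sampled Gaussian (truncated at 4 sigma, mirror boundary)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    x = _pixels(img)
    if sigma == 0:
        return _wrap_like(x.copy(), img)
    return _wrap_like(ndimage.gaussian_filter(x, sigma, mode="mirror", truncate=4.0), img)


def resample(img, factor: int, direction: Literal["down", "up"]):
    """Decimate by an integer factor, or upsample by bilinear interpolation."""
    x = _pixels(img)
    if factor == 1:
        return _wrap_like(x.copy(), img)
    if direction == "down":
        if x.shape[0] % factor or x.shape[1] % factor:
            raise ValueError(f"image side {x.shape} not divisible by factor {factor}")
        return _wrap_like(np.ascontiguousarray(x[::factor, ::factor]), img)
    if direction == "up":
        out = _sk_resize(
            x,
            (x.shape[0] * factor, x.shape[1] * factor),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        ).astype(x.dtype, copy=False)
        return _wrap_like(out, img)
    raise ValueError("direction must be 'down' or 'up'")


def sample_noise(shape, spec: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw the mixed noise field: zero mean, std sqrt(sigma_p^2 + sigma_g^2)."""
    lam0 = spec.poisson_rate
    n = np.zeros(shape, dtype=np.float64)
    if spec.poisson_scale > 0:
        n += spec.poisson_scale * (rng.poisson(lam0, size=shape) - lam0) / np.sqrt(lam0)
    if spec.gaussian_std > 0:
        n += spec.gaussian_std * rng.standard_normal(shape)
    return n


def add_mixed_noise(img, spec: NoiseSpec, rng: np.random.Generator):
    x = _pixels(img)
    return _wrap_like(x + sample_noise(x.shape, spec, rng), img)


def degrade_clean(obj: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    """Noiseless part of the LR chain: blur, then optional downsampling."""
    out = gaussian_blur(obj, spec.blur_sigma)
    if spec.downsample_factor > 1:
        out = resample(out, spec.downsample_factor, "down")
    return out


def finish_lr(noisy_lr: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    """Post-noise part of the LR chain: optional upsampling back to the HR grid."""
    if spec.upsample_back and spec.downsample_factor > 1:
        return resample(noisy_lr, spec.downsample_factor, "up")
    return noisy_lr


def build_task_ensembles(
    task: Literal["rayleigh", "mc"],
    n_per_class: int,
    rng: np.random.Generator,
    *,
    clb: CLBParams | None = None,
    noise: NoiseSpec | None = None,
    degradation: DegradationSpec | None = None,
    signal_spec: RayleighSignalSpec | None = None,
    signal_lengths: int | list[int] | None = None,
    mc_spec: MCClusterSpec | None = None,
    backgrounds: np.ndarray | None = None,
    keep_clean: bool = False,
    shuffle: bool = True,
) -> tuple[ImagingEnsemble, ImagingEnsemble]:
    """Build paired, class-balanced HR and LR ensembles for one task.

    HR and LR share the same noiseless objects but carry independent noise
    draws. ``backgrounds`` may supply pre-rendered CLB images (2*n_per_class
    of them) to reuse across study levels; otherwise they are drawn here.
    For the Rayleigh task ``signal_lengths`` may be a single L or a list, in
    which case lengths cycle over the list within each class.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    clb = clb or CLBParams()
    if task == "rayleigh":
        noise = noise or NoiseSpec.rayleigh_default()
        degradation = degradation or DegradationSpec.rayleigh_default()
        signal_spec = signal_spec or RayleighSignalSpec()
        if signal_lengths is None:
            signal_lengths = [signal_spec.signal_length]
        elif np.isscalar(signal_lengths):
            signal_lengths = [int(signal_lengths)]
    elif task == "mc":
        noise = noise or NoiseSpec.mc_default()
        degradation = degradation or DegradationSpec.mc_default()
        mc_spec = mc_spec or MCClusterSpec()
    else:
        raise ValueError(f"unknown task {task!r}")

    n_total = 2 * n_per_class
    field = clb.field_size
    if backgrounds is None:
        backgrounds = np.empty((n_total, field, field), dtype=np.float32)
        for i in range(n_total):
            backgrounds[i] = sample_clb(clb, rng)[0].pixels
    else:
        backgrounds = np.asarray(backgrounds, dtype=np.float32)
        if len(backgrounds) != n_total:
            raise ValueError("need 2*n_per_class backgrounds")

    labels = np.repeat(np.array([0, 1], dtype=np.int8), n_per_class)
    objects = np.empty_like(backgrounds)
    if task == "rayleigh":
        # signals are deterministic given (L, hypothesis); cache them
        cache: dict[tuple[str, int], np.ndarray] = {}
        for i in range(n_total):
            hyp = "H0" if labels[i] == 0 else "H1"
            L = int(signal_lengths[i % len(signal_lengths)])
            key = (hyp, L)
            if key not in cache:
                spec_l = RayleighSignalSpec(L, signal_spec.blur_sigma, signal_spec.amplitude)
                cache[key] = make_rayleigh_signal(spec_l, hyp, field).pixels.astype(np.float32)
            objects[i] = backgrounds[i] + cache[key]
    else:
        objects[:n_per_class] = backgrounds[:n_per_class]
        for i in range(n_per_class, n_total):
            smc = synth_mc_cluster(mc_spec, rng)
            crop = rotate_crop_cluster(smc, None, rng, crop_size=field)
            c = rng.uniform(*mc_spec.contrast_range)
            objects[i] = insert_mc(backgrounds[i], crop, c).pixels

    # low-resolution clean chain
    lr_clean0 = degrade_clean(objects[0], degradation)
    lr_clean = np.empty((n_total, *lr_clean0.shape), dtype=np.float32)
    lr_clean[0] = lr_clean0
    for i in range(1, n_total):
        lr_clean[i] = degrade_clean(objects[i], degradation)

    hr_images = (objects + sample_noise(objects.shape, noise, rng)).astype(np.float32)
    lr_noisy = (lr_clean + sample_noise(lr_clean.shape, noise, rng)).astype(np.float32)
    post = "upsample2" if (degradation.upsample_back and degradation.downsample_factor > 1) else "none"
    if post == "upsample2":
        lr_images = np.stack([finish_lr(im, degradation) for im in lr_noisy]).astype(np.float32)
    else:
        lr_images = lr_noisy

    perm = rng.permutation(n_total) if shuffle else np.arange(n_total)
    spec_dict = {
        "task": task,
        "n_per_class": n_per_class,
        "clb": clb,
        "noise": noise,
        "degradation": degradation,
        "signal_spec": signal_spec,
        "signal_lengths": None if task == "mc" else list(signal_lengths),
        "mc_spec": mc_spec,
        "permutation": perm,
    }
    hr = ImagingEnsemble(
        hr_images[perm],
        labels[perm],
        "HR",
        spec_dict,
        objects[perm] if keep_clean else None,
        "none",
        noise,
    )
    lr = ImagingEnsemble(
        lr_images[perm],
        labels[perm],
        "LR",
        dict(spec_dict),
        lr_clean[perm] if keep_clean else None,
        post,
        noise,
    )
    return hr, lr


def redraw_noise(ens: ImagingEnsemble, rng: np.random.Generator) -> np.ndarray:
    """Fresh noisy images from the stored clean stack (semionline training)."""
    if ens.clean is None or ens.noise_spec is None:
        raise ValueError("ensemble was built without keep_clean=True")
    noisy = ens.clean + sample_noise(ens.clean.shape, ens.noise_spec, rng).astype(np.float32)
    if ens.post_noise == "upsample2":
        return np.stack([resample(im, 2, "up") for im in noisy]).astype(np.float32)
    if ens.post_noise != "none":
        raise ValueError(f"unknown post_noise stage {ens.post_noise!r}")
    return noisy.astype(np.float32)
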