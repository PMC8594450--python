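"""Traditional IQ metrics and ROC/AUC statistics.

Ensemble MSE is the grand mean of squared per-pixel differences over all
images; PSNR follows as ``20*log10(peak) - 10*log10(MSE)``. SSIM is the
standard windowed SSIM (11x11 Gaussian window, sigma 1.5, stability
constants ``(0.01*peak)**2`` and ``(0.03*peak)**2``), averaged per image and
then over the ensemble.

The empirical AUC is the Mann-Whitney estimator (ties count 1/2) and its
confidence interval uses DeLong's structural-components variance with a
normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from skimage.metrics import structural_similarity

__all__ = ["IQMetrics", "ROCResult", "iq_metrics", "empirical_auc", "delong_ci"]


@dataclass(frozen=True)
class IQMetrics:
    ensemble_mse: float
    psnr: float
    ssim: float
    peak_value: float
    n_images: int


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    variance: float
    n0: int
    n1: int
    level: float = 0.95
    degenerate: bool = False
    threshold: float | None = None


def _stacks(ref, test) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(ref.images if hasattr(ref, "images") else ref, dtype=np.float64)
    b = np.asarray(test.images if hasattr(test, "images") else test, dtype=np.float64)
    if a.ndim == 2:
        a = a[None]
    if b.ndim == 2:
        b = b[None]
    if a.shape != b.shape:
        raise ValueError(f"ensemble shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def iq_metrics(ref, test, peak: float | str = "auto") -> IQMetrics:
    """MSE/PSNR/SSIM of a test ensemble against an aligned reference ensemble.

    ``peak`` is the PSNR/SSIM dynamic-range reference; ``"auto"`` uses the
    maximum pixel value of the reference ensemble.
    """
    a, b = _stacks(ref, test)
    mse = float(np.mean((a - b) ** 2))
    pk = float(a.max()) if isinstance(peak, str) else float(peak)
    if pk <= 0:
        raise ValueError("peak must be positive")
    psnr = float("inf") if mse == 0 else 20.0 * np.log10(pk) - 10.0 * np.log10(mse)
    ssims = [
        structural_similarity(
            ai,
            bi,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=pk,
            K1=0.01,
            K2=0.03,
        )
        for ai, bi in zip(a, b)
    ]
    return IQMetrics(mse, psnr, float(np.mean(ssims)), pk, len(a))


def _score_pair(scores) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(scores, "scores_h0"):
        s0, s1 = scores.scores_h0, scores.scores_h1
    else:
        s0, s1 = scores
    s0 = np.asarray(s0, dtype=np.float64).ravel()
    s1 = np.asarray(s1, dtype=np.float64).ravel()
    if len(s0) == 0 or len(s1) == 0:
        raise ValueError("both classes must be non-empty")
    if not (np.all(np.isfinite(s0)) and np.all(np.isfinite(s1))):
        raise ValueError("scores must be finite")
    return s0, s1


def empirical_auc(scores) -> float:
    """Mann-Whitney AUC: P(t1 > t0) + 0.5 * P(t1 = t0) over all pairs."""
    s0, s1 = _score_pair(scores)
    n0, n1 = len(s0), len(s1)
    ranks = rankdata(np.concatenate([s0, s1]))
    return float((ranks[n0:].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def delong_ci(scores, level: float = 0.95) -> ROCResult:
    """AUC with DeLong variance and a two-sided normal-approximation CI.

    The structural components are V10[i] = mean_j psi(t1_i, t0_j) and
    V01[j] = mean_i psi(t1_i, t0_j) with psi the tie-corrected Heaviside;
    Var(AUC) = S10/n1 + S01/n0. A degenerate variance (perfect or fully
    reversed separation) collapses the CI to a point and is flagged.
    """
    s0, s1 = _score_pair(scores)
    n0, n1 = len(s0), len(s1)
    if n0 < 2 or n1 < 2:
        raise ValueError("DeLong CI requires at least 2 scores per class")
    # psi matrix computed via midranks, O((n0+n1) log(n0+n1))
    ranks_all = rankdata(np.concatenate([s0, s1]))
    r0, r1 = ranks_all[:n0], ranks_all[n0:]
    auc = float((r1.sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))
    v10 = (r1 - rankdata(s1)) / n0
    v01 = 1.0 - (r0 - rankdata(s0)) / n1
    s10 = v10.var(ddof=1)
    s01 = v01.var(ddof=1)
    var = float(s10 / n1 + s01 / n0)
    if var <= 0:
        return ROCResult(auc, auc, auc, 0.0, n0, n1, level, degenerate=True)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return ROCResult(auc, max(auc - half, 0.0), min(auc + half, 1.0), var, n0, n1, level)
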