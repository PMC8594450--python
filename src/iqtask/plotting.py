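"""Figure helpers for sweep results.

One function per figure family: AUC-versus-level curves with DeLong error
bars per resolution class, and singular-value spectra from the depth sweep.
Figures use a headless-safe backend and are meant for quick inspection, not
publication typography.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_auc_sweep", "plot_spectra", "save_sweep_figures"]

_COLORS = {"HR": "tab:green", "LR": "tab:orange", "SR": "tab:blue"}


def plot_auc_sweep(records: pd.DataFrame, observer: str, ax=None, title: str | None = None):
    """AUC against the sweep level with 95% CI error bars, one line per
    resolution class, for a single observer."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    sub = records[records["observer"] == observer]
    for res, grp in sub.groupby("resolution"):
        grp = grp.sort_values("level")
        yerr = np.vstack([
            grp["auc"] - grp["ci_low"],
            grp["ci_high"] - grp["auc"],
        ])
        ax.errorbar(grp["level"], grp["auc"], yerr=yerr, marker="o", capsize=3,
                    label=res, color=_COLORS.get(res))
    ax.set_xlabel(sub["axis"].iloc[0] if len(sub) else "level")
    ax.set_ylabel("AUC")
    ax.set_title(title or observer)
    ax.legend()
    ax.figure.tight_layout()
    return ax


def plot_spectra(spectra: dict[int, np.ndarray], ax=None, label_prefix: str = "depth "):
    """Singular-value spectra (log scale) of the SR-image covariance per level."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for level in sorted(spectra):
        s = np.asarray(spectra[level])
        ax.semilogy(np.arange(1, len(s) + 1), np.maximum(s, np.finfo(float).tiny),
                    label=f"{label_prefix}{level}")
    ax.set_xlabel("mode index")
    ax.set_ylabel("singular value")
    ax.legend()
    ax.figure.tight_layout()
    return ax


def save_sweep_figures(result, out_dir: str | Path) -> list[Path]:
    """Render the standard figures for a SweepResult; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for observer in result.records["observer"].unique():
        ax = plot_auc_sweep(result.records, observer)
        p = out / f"auc_{result.axis}_{observer.lower()}.png"
        ax.figure.savefig(p, dpi=120)
        plt.close(ax.figure)
        written.append(p)
    if result.spectra:
        ax = plot_spectra(result.spectra)
        p = out / f"spectra_{result.axis}.png"
        ax.figure.savefig(p, dpi=120)
        plt.close(ax.figure)
        written.append(p)
    return written
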