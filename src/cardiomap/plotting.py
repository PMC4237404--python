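"""Matplotlib figures: bull's-eye maps, Bland-Altman and regression plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .compare import BlandAltmanResult, RobustFitResult

__all__ = ["bulls_eye", "bland_altman_plot", "regression_plot", "sweep_plot"]


def bulls_eye(pmap, path=None, *, title: str = "", cmap: str = "turbo",
              smooth_sigma: float = 2.0, size: int = 300):
    """Render a polar map as a bull's-eye (apex at centre, base at rim)."""
    raster, mask = pmap.to_raster(size=size, smooth_sigma=smooth_sigma)
    img = np.where(mask, raster, np.nan)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(img, cmap=cmap, origin="lower")
    ax.set_title(title or pmap.kind)
    ax.set_axis_off()
    fig.colorbar(im, ax=ax, shrink=0.8)
    if path is not None:
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def bland_altman_plot(x, y, result: BlandAltmanResult, path=None, *,
                      xlabel: str = "mean of methods (%)",
                      ylabel: str = "difference (%)"):
    """Paired-difference plot with the mean bias and +/- 2 SD limits."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((x + y) / 2.0, x - y, s=18, alpha=0.8)
    ax.axhline(result.mean_diff, color="black", label=f"mean {result.mean_diff:.2f}")
    for lim in (result.lower_limit, result.upper_limit):
        ax.axhline(lim, color="tab:blue", ls="--")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    if path is not None:
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def regression_plot(x, y, fit: RobustFitResult, path=None, *,
                    xlabel: str = "NOGA area (%)", ylabel: str = "cMRI area (%)"):
    """Scatter with the least-absolute-residual line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=18, alpha=0.8)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, fit.slope * xs + fit.intercept, color="tab:red",
            label=f"y = {fit.slope:.2f} x + {fit.intercept:.2f}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    if path is not None:
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def sweep_plot(sweep, path=None):
    """Correlation-vs-threshold curves of the calibration sweep."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for lev in sweep.levels:
        r = sweep.correlation[lev]
        ax.plot(sweep.thresholds_mV, r, label=f"{lev}% transmurality")
        best = sweep.best_cutoff_mV[lev]
        if np.isfinite(best):
            ax.axvline(best, color="grey", lw=0.5)
    ax.set_xlabel("bipolar threshold (mV)")
    ax.set_ylabel("correlation with cMRI area")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
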