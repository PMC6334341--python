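"""Optional plotting conveniences (residue lines, PSO weights, EJCR)."""

from __future__ import annotations

import numpy as np

from .mwpls import ResidueMap
from .validate import EJCRResult
from .wlssvm import WLSSVMModel


def plot_residue_lines(rmap: ResidueMap, ax=None):
    """SSR vs window-center wavenumber, one line per latent-variable count."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for a in range(rmap.max_lv):
        ax.plot(rmap.center_wavenumbers, rmap.ssr[:, a], lw=0.8, label=f"{a + 1} LV")
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("SSR")
    ax.invert_xaxis()
    ax.legend(fontsize="small")
    return ax


def plot_sample_weights(model: WLSSVMModel, ax=None):
    """Optimized per-sample weights after the PSO search."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.stem(np.arange(1, model.weights.size + 1), model.weights)
    ax.set_xlabel("calibration sample")
    ax.set_ylabel("weight")
    ax.set_ylim(0, 1.05)
    return ax


def plot_ejcr(results: dict[str, EJCRResult], ax=None):
    """Joint confidence ellipses per block with the ideal point (0, 1)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, res in results.items():
        pts = res.boundary()
        ax.plot(pts[:, 0], pts[:, 1], label=name)
    ax.plot(0.0, 1.0, "k*", markersize=12, label="ideal (0, 1)")
    ax.set_xlabel("intercept")
    ax.set_ylabel("slope")
    ax.legend(fontsize="small")
    return ax


def plot_correlation(actual: np.ndarray, predicted: np.ndarray, ax=None):
    """Predicted vs actual with the identity line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(actual, predicted, s=12)
    lims = [min(np.min(actual), np.min(predicted)), max(np.max(actual), np.max(predicted))]
    ax.plot(lims, lims, "k--", lw=0.8)
    ax.set_xlabel("actual")
    ax.set_ylabel("predicted")
    return ax
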