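"""Minimal ROC curve rendering: curve, CI band, pAUC region shading."""

from __future__ import annotations

from typing import Optional, Union

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .curve import PartialRange, ROCCurve
from .intervals import IntervalEstimate
from .smoothing import SmoothROCCurve

__all__ = ["plot_roc"]


def plot_roc(
    curve: Union[ROCCurve, SmoothROCCurve],
    ci_band: Optional[IntervalEstimate] = None,
    prange: Optional[PartialRange] = None,
    ax=None,
    label: Optional[str] = None,
):
    """Plot a ROC curve in specificity/sensitivity axes (sp decreasing).

    Optionally overlays a pointwise CI band (from :func:`ci_shape`) and
    shades the partial-AUC region.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    if isinstance(curve, SmoothROCCurve):
        sp, se = curve.sp_grid, curve.se_values
    else:
        sp, se = curve.specificities, curve.sensitivities
    ax.plot(sp, se, drawstyle="default", label=label)
    ax.plot([0, 1], [1, 0], linestyle=":", color="grey", linewidth=0.8)
    if prange is not None:
        if prange.axis == "specificity":
            ax.axvspan(prange.lo, prange.hi, color="0.9", zorder=0)
        else:
            ax.axhspan(prange.lo, prange.hi, color="0.9", zorder=0)
    if ci_band is not None and ci_band.grid is not None:
        if "fixed specificity" in ci_band.method:
            ax.fill_between(
                ci_band.grid, ci_band.lower, ci_band.upper, alpha=0.3, zorder=1
            )
        else:
            ax.fill_betweenx(
                ci_band.grid, ci_band.lower, ci_band.upper, alpha=0.3, zorder=1
            )
    ax.set_xlim(1.02, -0.02)  # conventional reversed specificity axis
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("Specificity")
    ax.set_ylabel("Sensitivity")
    if label:
        ax.legend(loc="lower right")
    return ax
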