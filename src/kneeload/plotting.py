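"""Matplotlib views of contact traces and added-mass regressions."""

from __future__ import annotations

import numpy as np


def plot_contact_trace(trace, ax=None, label=None):
    """Total, muscle and intersegmental contact force vs. percent stance."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(trace.percent_stance, trace.total, label=label or "total", lw=2)
    ax.plot(trace.percent_stance, trace.muscle_contrib, "--", label="muscle")
    ax.plot(trace.percent_stance, trace.intersegmental, ":", label="intersegmental")
    ax.set_xlabel("stance (%)")
    ax.set_ylabel("compressive tibiofemoral force (BW)")
    ax.legend(frameon=False)
    return ax


def plot_regression(fit, outcomes=None, ax=None):
    """Observed vs. predicted percent changes with the fitted line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    if fit.observed is not None and fit.fitted is not None:
        ax.scatter(fit.fitted, fit.observed, s=18, alpha=0.7)
        lim = [min(0, np.min(fit.fitted)), np.max(fit.fitted) * 1.1 + 1e-9]
        ax.plot(lim, lim, "k--", lw=1)
    coefs = ", ".join(f"{k.replace('m_', '')}={v:.1f}"
                      for k, v in fit.coefficients.items())
    ax.set_title(f"r = {fit.pearson_r:.2f};  {coefs}", fontsize=9)
    ax.set_xlabel("predicted %change")
    ax.set_ylabel("observed %change")
    return ax
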