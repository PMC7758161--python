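"""Fit visualisation: observed vs fitted label enrichment per subset."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_fit", "plot_body_water"]


def plot_fit(results, ax=None):
    """Observed label enrichment and fitted trajectories for one fit."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    model = results.model
    ds = model.dataset
    pred = results.predict()
    ax.plot(pred["day"], 100 * pred["L1"], "-", color="tab:blue",
            label="CD57- fit")
    ax.plot(pred["day"], 100 * pred["L2"], "-", color="tab:red",
            label="CD57+ fit")
    ax.plot(ds.labels["CD57neg"].days, 100 * ds.labels["CD57neg"].enrichment,
            "o", color="tab:blue", label="CD57- data")
    ax.plot(ds.labels["CD57pos"].days, 100 * ds.labels["CD57pos"].enrichment,
            "s", color="tab:red", label="CD57+ data")
    ax.axvline(model.curve.tau, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("day")
    ax.set_ylabel("labeled deoxyadenosine (%)")
    ax.set_title(f"{ds.volunteer_id} {ds.lineage} ({results.variant})")
    ax.legend(fontsize=8)
    return ax


def plot_body_water(fit, series=None, ax=None):
    """Fitted body-water curve U(t), with the saliva data if given."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    t = np.linspace(0, max(126.0, 1.5 * fit.curve.tau), 300)
    ax.plot(t, 100 * fit.curve(t), "-", color="tab:green", label="U(t) fit")
    if series is not None:
        ax.plot(series.days, 100 * series.enrichment, "o",
                color="tab:green", label="saliva")
    ax.axvline(fit.curve.tau, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("day")
    ax.set_ylabel("body-water enrichment (%)")
    ax.legend(fontsize=8)
    return ax
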