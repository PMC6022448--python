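"""Benefit-distribution and calibration plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .evaluate import CalibrationTable  # noqa: E402

__all__ = ["plot_benefit_histogram", "plot_calibration"]


def plot_benefit_histogram(bin_edges, counts, threshold: float = 0.0,
                           ax=None):
    """Histogram of predicted treatment benefit.

    The vertical line marks the treatment threshold: patients to its
    right are multimarker positive.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    widths = np.diff(bin_edges)
    ax.bar(bin_edges[:-1], counts, width=widths, align="edge",
           edgecolor="white", color="#4878a8")
    ax.axvline(threshold, color="firebrick", linestyle="--", linewidth=1)
    ax.set_xlabel("predicted treatment benefit (risk difference)")
    ax.set_ylabel("patients")
    ax.set_title("Distribution of predicted treatment benefit")
    return ax


def plot_calibration(table: CalibrationTable, ax=None):
    """Observed vs predicted group benefits with the identity diagonal.

    Calibration around zero matters most: miscalibration there flips
    treatment decisions.  Groups with an undefined observed benefit are
    omitted.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    frame = table.frame[table.frame["observed_benefit"].notna()]
    x = frame["mean_predicted_benefit"]
    y = frame["observed_benefit"]
    vals = np.abs(np.concatenate([x.to_numpy(), y.to_numpy()]))
    lim = 1.1 * max(0.05, float(vals.max()) if vals.size else 0.0)
    ax.plot([-lim, lim], [-lim, lim], color="grey", linewidth=1,
            label="perfect calibration")
    ax.axvline(0.0, color="firebrick", linestyle="--", linewidth=1)
    ax.axhline(0.0, color="firebrick", linestyle=":", linewidth=0.8)
    ax.scatter(x, y, color="#4878a8", zorder=3)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("mean predicted benefit")
    ax.set_ylabel("observed benefit (control minus treated event rate)")
    ax.set_title("Calibration of predicted treatment benefit")
    ax.legend(loc="upper left", fontsize=8)
    return ax
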