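"""Optional PNG figures: per-chamber box series and distribution histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .popstats import boxplot_stats, histogram

__all__ = ["plot_chamber_series", "plot_distributions"]


def plot_chamber_series(samples_by_time: dict[float, list], out_path) -> None:
    """Quantity / mean diameter / mean IPQ of each chamber over time.

    ``samples_by_time`` maps incubation time (min) to a list of
    SampleSummary; each chamber appears as one point per time, with a box
    (min, quartiles, max, mean) summarizing the spread.
    """
    metrics = [
        ("quantity", "vesicle quantity"),
        ("diameter_mean_um", "mean diameter (um)"),
        ("ipq_mean", "mean IPQ"),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    times = sorted(samples_by_time)
    for ax, (field, label) in zip(axes, metrics):
        series = [[getattr(s, field) for s in samples_by_time[t]] for t in times]
        ax.boxplot(series, tick_labels=[f"{t:g}" for t in times], whis=(0, 100), showmeans=True)
        for i, values in enumerate(series, start=1):
            ax.plot(np.full(len(values), i), values, "o", mfc="none", ms=4, color="tab:blue")
        ax.set_xlabel("incubation time (min)")
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_distributions(records, out_path, diameter_edges=None, ipq_edges=None) -> None:
    """Histograms of one sample's diameter and IPQ distributions."""
    diameter_edges = (
        np.arange(0.0, 52.0, 2.0) if diameter_edges is None else np.asarray(diameter_edges)
    )
    ipq_edges = np.arange(0.5, 1.025, 0.025) if ipq_edges is None else np.asarray(ipq_edges)
    fig, (ax_d, ax_q) = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, field, edges, label in (
        (ax_d, "diameter_um", diameter_edges, "effective diameter (um)"),
        (ax_q, "ipq", ipq_edges, "isoperimetric quotient"),
    ):
        counts = histogram(records, field, edges)
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", edgecolor="black")
        ax.set_xlabel(label)
        ax.set_ylabel("vesicles")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
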