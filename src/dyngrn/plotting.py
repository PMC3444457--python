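"""Minimal figures: GA fitness trace and temporal expression profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ctrnn import FitnessTrace
from .datatypes import ExpressionMatrix


def plot_fitness_trace(trace: FitnessTrace, path: str | None = None):
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(trace.generation, trace.best_fitness)
    ax.set_xlabel("generation")
    ax.set_ylabel("best fitness")
    ax.set_title("GA fitness trace")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_temporal_profiles(
    matrix: ExpressionMatrix, genes: list[str] | None = None, path: str | None = None
):
    means = matrix.mean_by_time()
    if genes is not None:
        means = means.loc[genes]
    fig, ax = plt.subplots(figsize=(5, 3))
    for gene, row in means.iterrows():
        ax.plot(means.columns, row.to_numpy(), alpha=0.6, label=str(gene))
    ax.set_xlabel("time (h)")
    ax.set_ylabel("mean expression")
    if len(means) <= 10:
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
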