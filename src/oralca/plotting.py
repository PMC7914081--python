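"""Figure helpers (population curves, Simpson dynamics, snapshot rasters,
dendrograms).  All functions save to a path and return it; they use the Agg
backend so they are safe in headless runs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram

from .analysis import ClusterResult, PopulationSeries
from .engine import SpeciesArrays, snapshot_rgb
from .lattice import Lattice


def plot_population(pop: PopulationSeries, path, max_species: int = 30):
    fig, ax = plt.subplots(figsize=(8, 4.5))
    order = np.argsort(pop.counts[:, -1])[::-1][:max_species]
    for s in order:
        ax.plot(pop.steps, pop.counts[s], lw=0.9,
                label=f"sp {pop.species_ids[s]}")
    ax.set_xlabel("step")
    ax.set_ylabel("population (cells)")
    if order.size <= 12:
        ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_simpson(steps, values, path, label: str | None = None):
    fig, ax = plt.subplots(figsize=(8, 3.2))
    ax.plot(steps, values, lw=1.2, label=label)
    ax.set_xlabel("step")
    ax.set_ylabel("Simpson alpha (1 - sum p^2)")
    ax.set_ylim(-0.02, 1.0)
    if label:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def save_snapshot_png(lat: Lattice, species: SpeciesArrays, path):
    img = snapshot_rgb(lat, species)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(img, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"step {lat.step_index}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_dendrogram(result: ClusterResult, labels, path):
    fig, ax = plt.subplots(figsize=(7, 4))
    dendrogram(result.linkage_tree, labels=list(labels), ax=ax)
    ax.set_title(
        f"{result.distance_name} + {result.linkage_name} "
        f"(cophenetic r = {result.cophenetic_r:.3f})"
    )
    ax.set_ylabel("merge distance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
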