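"""Community-level analyses of simulator output.

Per-species population series, Simpson (Gini-Simpson) alpha diversity
dynamics, hierarchical clustering of the climax community's species
parameter vectors with cophenetic-correlation model selection, and a
permutation z-score for the spatial aggregation of parameter-similar
species into patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .community import PARAM_BOUNDS, PARAM_ORDER, SpeciesParams
from .exceptions import DegenerateInputError, InsufficientDataError
from .lattice import Lattice

__all__ = [
    "PopulationSeries",
    "ClusterResult",
    "AggregationResult",
    "population_series",
    "simpson_alpha",
    "simpson_series",
    "standardize_vectors",
    "cluster_climax",
    "spatial_aggregation",
    "climax_step",
    "linkage_to_newick",
]


@dataclass
class PopulationSeries:
    """Species-by-step abundance matrix: counts[s, t] is the number of
    occupied sites held by species ``s`` at step ``steps[t]`` (lagged
    individuals count — they occupy positions)."""

    steps: np.ndarray
    counts: np.ndarray
    species_ids: np.ndarray

    def __post_init__(self):
        self.steps = np.asarray(self.steps)
        self.counts = np.asarray(self.counts)
        self.species_ids = np.asarray(self.species_ids)
        if self.counts.shape != (self.species_ids.size, self.steps.size):
            raise ValueError("counts must be (n_species, n_steps)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def occupancy(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def richness(self) -> np.ndarray:
        return (self.counts > 0).sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.counts.T,
                             columns=[f"species_{i}" for i in self.species_ids])
        frame.insert(0, "step", self.steps)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PopulationSeries":
        cols = [c for c in frame.columns if c.startswith("species_")]
        ids = np.array([int(c.split("_", 1)[1]) for c in cols])
        return cls(frame["step"].to_numpy(), frame[cols].to_numpy().T, ids)


def population_series(snapshots: list[Lattice], n_species: int) -> PopulationSeries:
    """Count each species' occupied sites in every snapshot."""
    if not snapshots:
        raise ValueError("no snapshots given")
    shape = snapshots[0].species_id.shape
    for lat in snapshots:
        if lat.species_id.shape != shape:
            raise ValueError("snapshots have inconsistent lattice dimensions")
    steps = np.array([lat.step_index for lat in snapshots])
    counts = np.column_stack([lat.species_counts(n_species) for lat in snapshots])
    return PopulationSeries(steps, counts, np.arange(n_species))


def simpson_alpha(counts: np.ndarray, variant: str = "gini") -> float:
    """Simpson alpha diversity of an abundance vector.

    ``variant="gini"`` (default) returns 1 - sum(p_i^2), in [0, 1), highest
    at even compositions; ``variant="inverse"`` returns 1 / sum(p_i^2).
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("counts sum to zero; diversity undefined")
    p = c / total
    s2 = float((p ** 2).sum())
    if variant == "gini":
        return 1.0 - s2
    if variant == "inverse":
        return 1.0 / s2
    raise ValueError(f"unknown variant {variant!r}")


def simpson_series(pop: PopulationSeries, variant: str = "gini") -> np.ndarray:
    """Simpson alpha at every step (NaN where the lattice is empty)."""
    out = np.full(pop.steps.size, np.nan)
    for t in range(pop.steps.size):
        if pop.counts[:, t].sum() > 0:
            out[t] = simpson_alpha(pop.counts[:, t], variant)
    return out


def standardize_vectors(vectors: np.ndarray) -> np.ndarray:
    """Min-max scale each of the 11 coordinates to [0, 1] using the fixed
    sampling intervals, so probabilities and step counts are commensurable."""
    lo = np.array([PARAM_BOUNDS[k][0] for k in PARAM_ORDER], dtype=float)
    hi = np.array([PARAM_BOUNDS[k][1] for k in PARAM_ORDER], dtype=float)
    return (np.asarray(vectors, dtype=float) - lo) / (hi - lo)


@dataclass
class ClusterResult:
    """One (distance, linkage) candidate: the merge tree, its cophenetic
    correlation against the original pairwise distances, and a flag on the
    max-cophenetic pair."""

    linkage_tree: np.ndarray
    distance_name: str
    linkage_name: str
    cophenetic_r: float
    selected: bool = False


_DEFAULT_DISTANCES = (("minkowski", 1), ("minkowski", 2), ("chebyshev", None))
_DEFAULT_LINKAGES = ("single", "complete", "average", "centroid")

#: linkage methods whose merge heights assume Euclidean geometry
_EUCLIDEAN_ONLY = {"centroid", "median", "ward"}


def cluster_climax(
    vectors: np.ndarray,
    distances=_DEFAULT_DISTANCES,
    linkages=_DEFAULT_LINKAGES,
    *,
    standardize: bool = True,
) -> list[ClusterResult]:
    """Hierarchical clustering of (surviving) species parameter vectors for
    every candidate (distance, linkage) pair, ranked by cophenetic
    correlation.

    Euclidean-geometry linkages (centroid, median, ward) are evaluated only
    with the Minkowski r=2 (Euclidean) distance.  The returned list always
    contains the Minkowski(2)+centroid pair; the entry with maximal
    cophenetic correlation is flagged ``selected``.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise InsufficientDataError(
            f"need >= 3 species vectors to cluster, got {0 if X.ndim != 2 else X.shape[0]}"
        )
    if standardize:
        X = standardize_vectors(X)
    if np.allclose(X, X[0]):
        raise DegenerateInputError("all species vectors are identical")

    results: list[ClusterResult] = []
    for dist_name, r in distances:
        if dist_name == "minkowski":
            y = pdist(X, metric="minkowski", p=r)
            label = f"minkowski({r})"
            euclidean = r == 2
        else:
            y = pdist(X, metric=dist_name)
            label = dist_name
            euclidean = False
        for link_name in linkages:
            if link_name in _EUCLIDEAN_ONLY:
                if not euclidean:
                    continue
                Z = linkage(X, method=link_name)  # recomputes Euclidean internally
            else:
                Z = linkage(y, method=link_name)
            r_coph = float(cophenet(Z, y)[0])
            results.append(ClusterResult(Z, label, link_name, r_coph))
    best = max(range(len(results)), key=lambda i: results[i].cophenetic_r)
    results[best].selected = True
    return results


def cluster_report(results: list[ClusterResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"distance": r.distance_name, "linkage": r.linkage_name,
          "cophenetic_r": r.cophenetic_r, "selected": r.selected}
         for r in results]
    )


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage tree as a Newick string with branch lengths."""
    root = to_tree(Z)

    def walk(node, parent_height):
        length = max(parent_height - node.dist, 0.0) if parent_height is not None else 0.0
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(root, None) + ";"


def climax_step(pop: PopulationSeries, *, window_frac: float = 0.1,
                tol: float = 0.05, min_species: int = 3) -> tuple[int, bool]:
    """Pick the snapshot index holding the climax community.

    The run is at climax when total occupancy varies by less than ``tol``
    (relative) over the trailing ``window_frac`` of steps; the climax
    snapshot is then the final one.  If fewer than ``min_species`` species
    survive there (a reduced-scale run can relax almost to monodominance),
    the latest snapshot with at least ``min_species`` survivors is used
    instead.  Returns ``(index, relaxed)`` where ``relaxed`` flags the
    fallback (or a non-stationary occupancy tail).
    """
    occ = pop.occupancy.astype(float)
    w = max(int(round(len(occ) * window_frac)), 2)
    tail = occ[-w:]
    stationary = tail.mean() > 0 and (tail.max() - tail.min()) / tail.mean() < tol
    idx = len(occ) - 1
    relaxed = not stationary
    if pop.richness[idx] < min_species:
        rich_enough = np.nonzero(pop.richness >= min_species)[0]
        if rich_enough.size == 0:
            raise InsufficientDataError(
                f"no snapshot holds >= {min_species} surviving species"
            )
        idx = int(rich_enough[-1])
        relaxed = True
    return idx, relaxed


@dataclass
class AggregationResult:
    """Observed mean parameter distance between Moore-adjacent occupied
    pairs versus a label-permutation null; negative z means parameter-similar
    species sit next to each other (patches)."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    n_pairs: int
    degenerate: bool = False


def spatial_aggregation(
    lat: Lattice,
    species: list[SpeciesParams],
    n_perm: int = 199,
    rng: np.random.Generator | None = None,
) -> AggregationResult:
    """Permutation z-score of neighbour parameter similarity.

    The statistic is the mean Euclidean distance between the standardized
    parameter vectors of every Moore-adjacent occupied pair (each unordered
    pair once, torus-wrapped).  The null permutes species labels over the
    occupied sites, keeping the occupancy pattern fixed.
    """
    if rng is None:
        rng = np.random.default_rng()
    occ = lat.occupied
    n_occ = int(occ.sum())
    if n_occ < 2:
        raise InsufficientDataError("need >= 2 occupied sites")

    vectors = standardize_vectors(np.array([sp.vector for sp in species]))
    D = squareform(pdist(vectors))

    # each unordered Moore pair once: four directed shifts
    occ_flat_idx = np.full(occ.shape, -1, dtype=np.int64)
    occ_flat_idx[occ] = np.arange(n_occ)
    ia_list, ib_list = [], []
    for di, dj in ((0, 1), (1, 0), (1, 1), (1, -1)):
        nb = np.roll(occ_flat_idx, (-di, -dj), axis=(0, 1))
        both = occ & (nb >= 0)
        ia_list.append(occ_flat_idx[both])
        ib_list.append(nb[both])
    ia = np.concatenate(ia_list)
    ib = np.concatenate(ib_list)
    if ia.size == 0:
        raise InsufficientDataError("no adjacent occupied pairs")

    labels = lat.species_id[occ]
    observed = float(D[labels[ia], labels[ib]].mean())

    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(labels)
        null[k] = D[perm[ia], perm[ib]].mean()
    mu = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd == 0.0:
        return AggregationResult(observed, mu, 0.0, 0.0, ia.size, degenerate=True)
    return AggregationResult(observed, mu, sd, (observed - mu) / sd, ia.size)
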