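"""Monte-Carlo community generation and initial lattice seeding.

A species is a behavioural parameter vector
``[alpha1..3, beta1..3, m, p, d, Lat, n]`` drawn uniformly and independently
from fixed intervals (:data:`PARAM_BOUNDS`), plus an ecological role:

* **collaborators** decompose large organic matter into the shared
  small-molecule pool and enter the lag phase *more* readily the more
  opposite-role (scammer) neighbours surround them (``alpha1 > alpha2 >
  alpha3`` across the high/mid/low neighbour tiers);
* **scammers** consume the shared pool without paying the decomposition cost
  and enter lag *less* readily when surrounded by many collaborators
  (``beta1 < beta2 < beta3``).

The remaining parameters: ``m`` move/proliferation probability, ``p`` death
probability once a lag episode overruns its cap, ``d`` per-step natural death
probability (``d < p``), ``Lat`` mean lag duration in steps, ``n`` the
maximum-lag factor (cap ``Lat*n``).
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .lattice import Lattice

__all__ = [
    "PARAM_BOUNDS",
    "PARAM_ORDER",
    "SpeciesParams",
    "CommunityConfig",
    "sample_community",
    "assign_color",
    "color_scalar",
    "seed_lattice",
    "zero_lag",
    "species_to_frame",
    "species_from_frame",
]

#: Closed sampling intervals for each coordinate of the species vector.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha1": (0.7, 1.0),
    "alpha2": (0.3, 0.7),
    "alpha3": (0.0, 0.3),
    "beta1": (0.0, 0.3),
    "beta2": (0.3, 0.7),
    "beta3": (0.7, 1.0),
    "m": (0.0, 0.2),
    "p": (0.8, 1.0),
    "d": (0.1, 0.3),
    "Lat": (6, 10),
    "n": (1, 3),
}

#: Canonical coordinate order of the 11-vector.
PARAM_ORDER = tuple(PARAM_BOUNDS)

_INT_PARAMS = ("Lat", "n")


@dataclass
class SpeciesParams:
    """One species' behavioural parameter vector, role and display colour."""

    species_id: int
    role: str  # "collaborator" | "scammer"
    alpha1: float
    alpha2: float
    alpha3: float
    beta1: float
    beta2: float
    beta3: float
    m: float
    p: float
    d: float
    Lat: int
    n: int
    color: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def spe(self) -> int:
        """Role flag: 1 = collaborator, 0 = scammer."""
        return 1 if self.role == "collaborator" else 0

    @property
    def vector(self) -> np.ndarray:
        """The 11-vector in :data:`PARAM_ORDER`."""
        return np.array([getattr(self, k) for k in PARAM_ORDER], dtype=float)

    def validate(self) -> None:
        if self.role not in ("collaborator", "scammer"):
            raise ValueError(f"unknown role {self.role!r}")
        for k, (lo, hi) in PARAM_BOUNDS.items():
            v = getattr(self, k)
            if not lo <= v <= hi:
                raise ValueError(f"{k}={v} outside its interval [{lo}, {hi}]")
        if not self.alpha1 > self.alpha2 > self.alpha3:
            raise ValueError("requires alpha1 > alpha2 > alpha3")
        if not self.beta1 < self.beta2 < self.beta3:
            raise ValueError("requires beta1 < beta2 < beta3")
        if not self.d < self.p:
            raise ValueError("requires d < p")
        if int(self.Lat) != self.Lat or int(self.n) != self.n:
            raise ValueError("Lat and n must be integers")


@dataclass
class CommunityConfig:
    """Community-scale simulation configuration.

    N : initial species richness; N_p : collaborator fraction of species;
    M : target initial cells per species (proportionally rescaled when the
    total would exceed ``max_fill`` of the lattice); M_p : collaborator
    fraction of the total initial cells; plus lattice dimensions, step count
    and RNG seed.
    """

    N: int = 20
    N_p: float = 0.5
    M: int = 10_000
    M_p: float = 0.5
    lattice_rows: int = 100
    lattice_cols: int = 100
    steps: int = 1000
    seed: int = 0
    max_fill: float = 0.5
    mll_mode: str = "opposite"
    snapshot_stride: int = 10

    def validate(self) -> None:
        if self.N < 2:
            raise ConfigurationError(f"N must be >= 2, got {self.N}")
        if self.lattice_rows < 8 or self.lattice_cols < 8:
            raise ConfigurationError("lattice dimensions must be >= 8")
        for name in ("N_p", "M_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.max_fill <= 1.0:
            raise ConfigurationError(f"max_fill must be in (0, 1], got {self.max_fill}")
        if self.M < 1:
            raise ConfigurationError(f"M must be >= 1, got {self.M}")
        if self.steps < 1:
            raise ConfigurationError(f"steps must be >= 1, got {self.steps}")
        if self.mll_mode not in ("opposite", "collaborator_sum"):
            raise ConfigurationError(f"unknown mll_mode {self.mll_mode!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "CommunityConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} is not a key: value mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def color_scalar(vector: np.ndarray) -> float:
    """Map a species vector to [0, 1]: Euclidean norm over the norm of the
    interval upper bounds."""
    ub = np.array([PARAM_BOUNDS[k][1] for k in PARAM_ORDER], dtype=float)
    return float(np.linalg.norm(np.asarray(vector, float)) / np.linalg.norm(ub))


def assign_color(sp: SpeciesParams, cmap: str = "viridis") -> tuple[float, float, float]:
    """RGB triple (floats in [0, 1]) from a perceptually uniform colormap of
    the normalized vector magnitude; nearby vectors get nearby colours."""
    import matplotlib

    s = color_scalar(sp.vector)
    r, g, b, _ = matplotlib.colormaps[cmap](s)
    return (float(r), float(g), float(b))


def _sample_one(species_id: int, role: str, rng: np.random.Generator,
                bounds: dict | None = None, max_attempts: int = 100) -> SpeciesParams:
    bounds = bounds or PARAM_BOUNDS

    def draw(k):
        lo, hi = bounds[k]
        if k in _INT_PARAMS:
            return int(rng.integers(int(lo), int(hi) + 1))
        return float(rng.uniform(lo, hi))

    vals = {k: draw(k) for k in PARAM_ORDER}
    # strict orderings hold automatically for disjoint tier intervals; ties at
    # shared endpoints (measure zero) are broken by resampling one coordinate
    for _ in range(max_attempts):
        ok = (vals["alpha1"] > vals["alpha2"] > vals["alpha3"]
              and vals["beta1"] < vals["beta2"] < vals["beta3"]
              and vals["d"] < vals["p"])
        if ok:
            break
        for a, b in (("alpha1", "alpha2"), ("alpha2", "alpha3"),
                     ("beta2", "beta1"), ("beta3", "beta2"), ("p", "d")):
            if not vals[a] > vals[b]:
                vals[b] = draw(b)
    else:
        raise ConfigurationError(
            f"could not satisfy ordering constraints after {max_attempts} resamples"
        )
    sp = SpeciesParams(species_id=species_id, role=role, **vals)
    sp.color = assign_color(sp)
    return sp


def sample_community(cfg: CommunityConfig,
                     rng: np.random.Generator | None = None) -> list[SpeciesParams]:
    """Draw ``cfg.N`` species: ``round(N * N_p)`` collaborators, the rest
    scammers, each coordinate uniform on its interval. Deterministic given
    the generator state (or ``cfg.seed`` when none is passed)."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_collab = int(round(cfg.N * cfg.N_p))
    roles = ["collaborator"] * n_collab + ["scammer"] * (cfg.N - n_collab)
    return [_sample_one(i, role, rng) for i, role in enumerate(roles)]


def _role_counts(species: list[SpeciesParams], total: int, M_p: float) -> np.ndarray:
    """Split ``total`` cells: fraction M_p to collaborators, split equally
    among each role's species (remainders to the lowest ids)."""
    collab_ids = [s.species_id for s in species if s.role == "collaborator"]
    scam_ids = [s.species_id for s in species if s.role == "scammer"]
    n_collab_cells = int(round(total * M_p))
    n_scam_cells = total - n_collab_cells
    if n_collab_cells > 0 and not collab_ids:
        raise ConfigurationError("M_p > 0 but the community has no collaborators")
    if n_scam_cells > 0 and not scam_ids:
        raise ConfigurationError("M_p < 1 but the community has no scammers")
    counts = np.zeros(len(species), dtype=np.int64)
    for ids, cells in ((collab_ids, n_collab_cells), (scam_ids, n_scam_cells)):
        if not ids:
            continue
        base, rem = divmod(cells, len(ids))
        for j, sid in enumerate(sorted(ids)):
            counts[sid] = base + (1 if j < rem else 0)
    return counts


def seed_lattice(species: list[SpeciesParams], cfg: CommunityConfig,
                 rng: np.random.Generator | None = None) -> Lattice:
    """Randomly seed the initial lattice.

    The total request ``N * M`` is proportionally rescaled so occupancy does
    not exceed ``max_fill`` of the lattice; the budget is split so
    collaborator cells make up fraction ``M_p`` of the total, divided equally
    within each role.  Positions are uniform without replacement; every cell
    starts active (not lagged).
    """
    if not species:
        raise ConfigurationError("species list is empty")
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    rows, cols = cfg.lattice_rows, cfg.lattice_cols
    sites = rows * cols
    cap = int(cfg.max_fill * sites)
    total = min(len(species) * cfg.M, cap)
    if total > sites:
        raise ConfigurationError(
            f"requested {total} cells exceed the {sites}-site lattice"
        )
    if total < len(species):
        raise ConfigurationError(
            f"cell budget {total} cannot seed all {len(species)} species "
            f"(raise max_fill, M or the lattice size)"
        )
    counts = _role_counts(species, total, cfg.M_p)
    flat = rng.choice(sites, size=int(counts.sum()), replace=False)
    sid = np.repeat(np.arange(len(species), dtype=np.int32), counts)
    lat = Lattice.empty(rows, cols)
    lat.species_id.ravel()[flat] = sid
    return lat


def zero_lag(species: list[SpeciesParams], epsilon: float = 0.0) -> list[SpeciesParams]:
    """Copies of the species with all lag-entry probabilities forced to
    ``epsilon`` (default 0): the no-delay-response control condition."""
    out = []
    for sp in species:
        out.append(replace(sp, alpha1=epsilon, alpha2=epsilon, alpha3=epsilon,
                           beta1=epsilon, beta2=epsilon, beta3=epsilon))
    return out


def species_to_frame(species: list[SpeciesParams]) -> pd.DataFrame:
    rows = []
    for sp in species:
        row = {"species_id": sp.species_id, "role": sp.role}
        row.update({k: getattr(sp, k) for k in PARAM_ORDER})
        row["color"] = "#%02x%02x%02x" % tuple(int(round(c * 255)) for c in sp.color)
        rows.append(row)
    return pd.DataFrame(rows)


def species_from_frame(frame: pd.DataFrame) -> list[SpeciesParams]:
    out = []
    for _, row in frame.iterrows():
        hexc = str(row["color"]).lstrip("#")
        color = tuple(int(hexc[i:i + 2], 16) / 255.0 for i in (0, 2, 4))
        out.append(SpeciesParams(
            species_id=int(row["species_id"]), role=str(row["role"]),
            **{k: (int(row[k]) if k in _INT_PARAMS else float(row[k]))
               for k in PARAM_ORDER},
            color=color,
        ))
    return out
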