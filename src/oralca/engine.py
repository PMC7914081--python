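"""The cellular automaton: lag-induction, birth/death and move rules.

Each step applies three synchronous phases to the torus lattice, every phase
drawing its decisions from the lattice state at the start of that phase:

1. **Delay-response (lag) rule** — every active occupied cell counts its
   opposite-role Moore neighbours (the MLL statistic) and enters the lag
   phase with the tier probability of its species: collaborators lag more
   readily the more scammers surround them (``alpha1 > alpha2 > alpha3`` for
   MLL 6–8 / 3–5 / 0–2), scammers lag more readily the *fewer* collaborators
   surround them (``beta1 < beta2 < beta3``).  This encodes the
   decomposition-product (public-good) negative feedback without an explicit
   substrate field.
2. **Lag bookkeeping and death** — lag timers advance; a lag episode that
   overruns its cap ``Lat*n`` exposes the cell to death with probability
   ``p`` each step (energy-store depletion); surviving lagged cells recover
   with probability ``1/Lat`` (mean lag ≈ ``Lat`` steps); every occupied
   cell then dies naturally with probability ``d`` (``d < p``).
3. **Move (proliferation) rule** — vacancies, visited in random order, are
   filled by offspring of the occupied, non-lagged cells in the 48-site
   radius-3 shell: each such cell volunteers independently with its species'
   probability ``m``; one volunteer is chosen uniformly; a cell parents at
   most one offspring per step.

Per-step event counts (lag entries, recoveries, overrun and natural deaths,
births) are returned so occupancy bookkeeping can be audited exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._compat import maybe_njit
from .community import SpeciesParams
from .lattice import MOORE_OFFSETS, RADIUS3_OFFSETS, Lattice

__all__ = [
    "SpeciesArrays",
    "StepEvents",
    "mll",
    "mll_grid",
    "lag_tier_probability",
    "apply_lag_rule",
    "update_lag_and_death",
    "apply_move_rule",
    "step",
    "simulate",
    "snapshot_rgb",
]


@dataclass(frozen=True)
class SpeciesArrays:
    """Columnar view of a species table for vectorised rule evaluation."""

    role: np.ndarray       # uint8, 1 = collaborator
    lag_probs: np.ndarray  # (n, 3): tier probabilities for MLL 6-8 / 3-5 / 0-2
    m: np.ndarray
    p: np.ndarray
    d: np.ndarray
    lat: np.ndarray        # int32
    cap: np.ndarray        # int32, Lat * n
    colors: np.ndarray     # (n, 3) floats in [0, 1]

    @classmethod
    def from_species(cls, species: list[SpeciesParams]) -> "SpeciesArrays":
        n = len(species)
        role = np.zeros(n, dtype=np.uint8)
        lag_probs = np.zeros((n, 3))
        m = np.zeros(n)
        p = np.zeros(n)
        d = np.zeros(n)
        lat = np.zeros(n, dtype=np.int32)
        cap = np.zeros(n, dtype=np.int32)
        colors = np.zeros((n, 3))
        for sp in species:
            i = sp.species_id
            role[i] = sp.spe
            if sp.spe == 1:
                lag_probs[i] = (sp.alpha1, sp.alpha2, sp.alpha3)
            else:
                lag_probs[i] = (sp.beta1, sp.beta2, sp.beta3)
            m[i], p[i], d[i] = sp.m, sp.p, sp.d
            lat[i] = int(sp.Lat)
            cap[i] = int(sp.Lat) * int(sp.n)
            colors[i] = sp.color
        return cls(role, lag_probs, m, p, d, lat, cap, colors)


@dataclass
class StepEvents:
    """Exact per-step bookkeeping; occupancy_after = occupancy_before
    - overrun_deaths - natural_deaths + births."""

    step_index: int
    occupancy_before: int
    lag_entries: int
    recoveries: int
    overrun_deaths: int
    natural_deaths: int
    births: int
    occupancy_after: int


def mll(lat: Lattice, species: SpeciesArrays, i: int, j: int,
        mode: str = "opposite") -> int:
    """Neighbourhood statistic of the occupied focal site (i, j).

    ``mode="opposite"`` (default) counts occupied Moore neighbours of the
    role opposite to the focal cell; ``mode="collaborator_sum"`` counts
    collaborator neighbours regardless of the focal role (the literal sum of
    the Spe flags).  Indices wrap on the torus.
    """
    sid = int(lat.species_id[i, j])
    if sid < 0:
        raise ValueError(f"focal site ({i}, {j}) is unoccupied")
    focal_role = int(species.role[sid])
    rows, cols = lat.rows, lat.cols
    count = 0
    for di, dj in MOORE_OFFSETS:
        nsid = int(lat.species_id[(i + di) % rows, (j + dj) % cols])
        if nsid < 0:
            continue
        nrole = int(species.role[nsid])
        if mode == "collaborator_sum":
            count += nrole
        elif nrole != focal_role:
            count += 1
    return count


def mll_grid(lat: Lattice, species: SpeciesArrays,
             mode: str = "opposite") -> np.ndarray:
    """MLL for every site at once (value meaningful only where occupied)."""
    occ = lat.occupied
    role = np.where(occ, species.role[np.where(occ, lat.species_id, 0)], 0)
    occ_i = occ.astype(np.int32)
    collab_i = (occ & (role == 1)).astype(np.int32)
    occ_nb = np.zeros(occ.shape, dtype=np.int32)
    collab_nb = np.zeros(occ.shape, dtype=np.int32)
    for di, dj in MOORE_OFFSETS:
        occ_nb += np.roll(occ_i, (di, dj), axis=(0, 1))
        collab_nb += np.roll(collab_i, (di, dj), axis=(0, 1))
    if mode == "collaborator_sum":
        return collab_nb
    # opposite-role count: scammer neighbours for collaborators and vice versa
    return np.where(role == 1, occ_nb - collab_nb, collab_nb)


def _tier(mll_value: int | np.ndarray) -> int | np.ndarray:
    """Tier index: 0 for MLL 6-8, 1 for 3-5, 2 for 0-2."""
    return np.where(np.asarray(mll_value) >= 6, 0,
                    np.where(np.asarray(mll_value) >= 3, 1, 2))


def lag_tier_probability(sp: SpeciesParams, mll_value: int,
                         role: int | None = None) -> float:
    """Lag-entry probability of a cell of species ``sp`` with the given MLL."""
    if not 0 <= mll_value <= 8:
        raise ValueError(f"MLL must be in [0, 8], got {mll_value}")
    if role is None:
        role = sp.spe
    tier = int(_tier(mll_value))
    if role == 1:
        return (sp.alpha1, sp.alpha2, sp.alpha3)[tier]
    return (sp.beta1, sp.beta2, sp.beta3)[tier]


def apply_lag_rule(lat: Lattice, species: SpeciesArrays,
                   rng: np.random.Generator, mode: str = "opposite") -> int:
    """Synchronous lag entry for all active occupied cells; returns the
    number of cells that entered lag."""
    occ = lat.occupied
    active = occ & (lat.is_lag == 0)
    if not active.any():
        return 0
    mllg = mll_grid(lat, species, mode)
    tier = _tier(mllg)
    sid = np.where(occ, lat.species_id, 0)
    probs = species.lag_probs[sid, tier]
    enter = active & (rng.random(lat.species_id.shape) < probs)
    lat.is_lag[enter] = 1
    lat.lag_timer[enter] = 0
    return int(np.count_nonzero(enter))


def update_lag_and_death(lat: Lattice, species: SpeciesArrays,
                         rng: np.random.Generator) -> tuple[int, int, int]:
    """Advance lag timers, apply overrun death (p), recovery (1/Lat) and
    natural death (d).  Returns (overrun_deaths, recoveries, natural_deaths)."""
    shape = lat.species_id.shape
    occ = lat.occupied
    sid = np.where(occ, lat.species_id, 0)
    lagged = occ & (lat.is_lag == 1)
    lat.lag_timer[lagged] += 1

    overrun = lagged & (lat.lag_timer > species.cap[sid])
    die_overrun = overrun & (rng.random(shape) < species.p[sid])
    n_overrun = int(np.count_nonzero(die_overrun))
    lat.species_id[die_overrun] = -1
    lat.is_lag[die_overrun] = 0
    lat.lag_timer[die_overrun] = 0

    lagged = lagged & ~die_overrun
    recover = lagged & (rng.random(shape) < 1.0 / species.lat[sid])
    n_recover = int(np.count_nonzero(recover))
    lat.is_lag[recover] = 0
    lat.lag_timer[recover] = 0

    occ = lat.occupied
    sid = np.where(occ, lat.species_id, 0)
    die_nat = occ & (rng.random(shape) < species.d[sid])
    n_nat = int(np.count_nonzero(die_nat))
    lat.species_id[die_nat] = -1
    lat.is_lag[die_nat] = 0
    lat.lag_timer[die_nat] = 0
    return n_overrun, n_recover, n_nat


@maybe_njit(cache=False)
def _move_kernel(species_id, is_lag, parented, vac_i, vac_j,
                 off_i, off_j, m_by_species, rand_cand, rand_pick):
    rows, cols = species_id.shape
    births = 0
    ci = np.empty(48, dtype=np.int64)
    cj = np.empty(48, dtype=np.int64)
    for v in range(vac_i.size):
        i0 = vac_i[v]
        j0 = vac_j[v]
        if species_id[i0, j0] >= 0:  # filled earlier this phase
            continue
        n_cand = 0
        for k in range(48):
            ii = (i0 + off_i[k]) % rows
            jj = (j0 + off_j[k]) % cols
            sid = species_id[ii, jj]
            if sid < 0 or is_lag[ii, jj] == 1 or parented[ii, jj] == 1:
                continue
            if rand_cand[v, k] < m_by_species[sid]:
                ci[n_cand] = ii
                cj[n_cand] = jj
                n_cand += 1
        if n_cand == 0:
            continue
        pick = int(rand_pick[v] * n_cand)
        if pick >= n_cand:
            pick = n_cand - 1
        pi = ci[pick]
        pj = cj[pick]
        species_id[i0, j0] = species_id[pi, pj]
        is_lag[i0, j0] = 0
        parented[pi, pj] = 1
        parented[i0, j0] = 1  # newborns do not parent in the same step
        births += 1
    return births


_OFF_I = np.array([o[0] for o in RADIUS3_OFFSETS], dtype=np.int64)
_OFF_J = np.array([o[1] for o in RADIUS3_OFFSETS], dtype=np.int64)


def apply_move_rule(lat: Lattice, species: SpeciesArrays,
                    rng: np.random.Generator) -> int:
    """Fill vacancies by proliferation from the radius-3 shell; returns the
    number of births.  Vacancies are visited in uniformly random order; a
    vacancy filled earlier in the phase is occupied (and its newborn
    ineligible to parent) for later vacancies."""
    vac = np.nonzero(lat.species_id < 0)
    n_vac = vac[0].size
    if n_vac == 0:
        return 0
    order = rng.permutation(n_vac)
    vac_i = vac[0][order].astype(np.int64)
    vac_j = vac[1][order].astype(np.int64)
    rand_cand = rng.random((n_vac, 48))
    rand_pick = rng.random(n_vac)
    parented = np.zeros(lat.species_id.shape, dtype=np.uint8)
    births = _move_kernel(lat.species_id, lat.is_lag, parented,
                          vac_i, vac_j, _OFF_I, _OFF_J,
                          species.m, rand_cand, rand_pick)
    return int(births)


def step(lat: Lattice, species: SpeciesArrays, rng: np.random.Generator,
         mll_mode: str = "opposite") -> StepEvents:
    """Advance the lattice one step (lag rule, lag/death bookkeeping, move
    rule) in place; returns the exact event counts."""
    before = lat.occupancy
    entries = apply_lag_rule(lat, species, rng, mll_mode)
    n_overrun, n_recover, n_nat = update_lag_and_death(lat, species, rng)
    births = apply_move_rule(lat, species, rng)
    lat.step_index += 1
    return StepEvents(
        step_index=lat.step_index,
        occupancy_before=before,
        lag_entries=entries,
        recoveries=n_recover,
        overrun_deaths=n_overrun,
        natural_deaths=n_nat,
        births=births,
        occupancy_after=lat.occupancy,
    )


def simulate(lat: Lattice, species_list: list[SpeciesParams], steps: int,
             rng: np.random.Generator, snapshot_stride: int = 0,
             mll_mode: str = "opposite",
             record_counts: bool = True):
    """Run ``steps`` steps in place.

    Returns ``(events, counts, snapshots)``: the per-step event log as a
    DataFrame, the species-by-step abundance matrix (including step 0) when
    ``record_counts``, and lattice copies every ``snapshot_stride`` steps
    (always including the initial and final states) when the stride is
    positive.
    """
    species = SpeciesArrays.from_species(species_list)
    n_species = len(species_list)
    events = []
    snapshots = [lat.copy()] if snapshot_stride > 0 else []
    counts = [lat.species_counts(n_species)] if record_counts else None
    for s in range(steps):
        ev = step(lat, species, rng, mll_mode)
        events.append(ev)
        if record_counts:
            counts.append(lat.species_counts(n_species))
        if snapshot_stride > 0 and (lat.step_index % snapshot_stride == 0
                                    or s == steps - 1):
            snapshots.append(lat.copy())
    ev_frame = pd.DataFrame([vars(e) for e in events])
    count_mat = np.column_stack(counts) if record_counts else None
    return ev_frame, count_mat, snapshots


def snapshot_rgb(lat: Lattice, species: SpeciesArrays,
                 background: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> np.ndarray:
    """(rows, cols, 3) float RGB raster using species colours; vacant sites
    take the background colour."""
    img = np.empty((lat.rows, lat.cols, 3))
    img[:] = background
    occ = lat.occupied
    img[occ] = species.colors[lat.species_id[occ]]
    return img
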