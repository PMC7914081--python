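"""Torus lattice of cell states.

A site holds at most one microbial individual.  State is stored as parallel
arrays: ``species_id`` (−1 for vacant), ``is_lag`` (1 while dormant) and
``lag_timer`` (steps spent in the current lag episode).  The grid wraps in
both directions (periodic boundary), so every site has exactly 8 Moore
neighbours and 48 radius-3 outer candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Lattice", "CellState", "MOORE_OFFSETS", "RADIUS3_OFFSETS"]

#: The 8 nearest-neighbour displacements.
MOORE_OFFSETS: tuple[tuple[int, int], ...] = tuple(
    (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
)

#: The 48 displacements of the three concentric layers (7x7 block minus centre).
RADIUS3_OFFSETS: tuple[tuple[int, int], ...] = tuple(
    (di, dj) for di in range(-3, 4) for dj in range(-3, 4) if (di, dj) != (0, 0)
)

assert len(MOORE_OFFSETS) == 8 and len(RADIUS3_OFFSETS) == 48


@dataclass(frozen=True)
class CellState:
    """Read-only view of one site: (Pos, Spe, isLag, Lat-timer, Clr)."""

    pos: int
    species_id: int | None
    spe: int | None
    is_lag: int
    lag_timer: int
    clr: tuple[float, float, float] | None


@dataclass
class Lattice:
    species_id: np.ndarray  # int32 (rows, cols), -1 = vacant
    is_lag: np.ndarray      # uint8
    lag_timer: np.ndarray   # int32
    step_index: int = 0

    @classmethod
    def empty(cls, rows: int, cols: int) -> "Lattice":
        return cls(
            species_id=np.full((rows, cols), -1, dtype=np.int32),
            is_lag=np.zeros((rows, cols), dtype=np.uint8),
            lag_timer=np.zeros((rows, cols), dtype=np.int32),
        )

    @property
    def rows(self) -> int:
        return self.species_id.shape[0]

    @property
    def cols(self) -> int:
        return self.species_id.shape[1]

    @property
    def occupied(self) -> np.ndarray:
        return self.species_id >= 0

    @property
    def occupancy(self) -> int:
        return int(np.count_nonzero(self.species_id >= 0))

    def copy(self) -> "Lattice":
        return Lattice(self.species_id.copy(), self.is_lag.copy(),
                       self.lag_timer.copy(), self.step_index)

    def check_consistency(self) -> None:
        vac = self.species_id < 0
        if np.any(self.is_lag[vac]) or np.any(self.lag_timer[vac]):
            raise AssertionError("vacant sites must carry no lag state")
        if np.any(self.lag_timer[self.is_lag == 0] != 0):
            raise AssertionError("active cells must have a zero lag timer")

    def cell(self, i: int, j: int, species=None) -> CellState:
        sid = int(self.species_id[i, j])
        if sid < 0:
            return CellState(0, None, None, 0, 0, None)
        spe = clr = None
        if species is not None:
            spe = species[sid].spe
            clr = species[sid].color
        return CellState(1, sid, spe, int(self.is_lag[i, j]),
                         int(self.lag_timer[i, j]), clr)

    def species_counts(self, n_species: int) -> np.ndarray:
        sid = self.species_id[self.species_id >= 0]
        return np.bincount(sid, minlength=n_species)
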