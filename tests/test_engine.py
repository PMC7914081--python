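"""Cellular-automaton update rules: MLL statistic, lag induction, death and
proliferation, and their bookkeeping."""

import numpy as np
import pytest

from oralca.community import SpeciesParams
from oralca.engine import (
    SpeciesArrays,
    apply_lag_rule,
    apply_move_rule,
    lag_tier_probability,
    mll,
    mll_grid,
    simulate,
    step,
    update_lag_and_death,
)
from oralca.lattice import MOORE_OFFSETS, RADIUS3_OFFSETS, Lattice


def make_species(roles, **overrides):
    """Custom species outside the standard sampling intervals, for rule
    isolation (alpha/beta/m/d/p may be scalars or per-species lists)."""
    out = []
    for i, role in enumerate(roles):
        kw = dict(alpha1=0.9, alpha2=0.5, alpha3=0.1,
                  beta1=0.1, beta2=0.5, beta3=0.9,
                  m=0.1, p=0.9, d=0.2, Lat=6, n=1)
        for key, val in overrides.items():
            kw[key] = val[i] if isinstance(val, (list, tuple)) else val
        out.append(SpeciesParams(species_id=i, role=role, color=(0.5, 0.5, 0.5), **kw))
    return out


def fill_lattice(rows, cols, sid):
    lat = Lattice.empty(rows, cols)
    lat.species_id[:] = sid
    return lat


class TestNeighborhoods:
    def test_moore_and_radius3_set_sizes(self):
        assert len(MOORE_OFFSETS) == 8
        assert len(RADIUS3_OFFSETS) == 48

    def test_mll_against_brute_force_on_torus(self):
        # every site of a random 9x9 lattice, both modes, vs direct modular
        # arithmetic over the 8 neighbour displacements
        rng = np.random.default_rng(5)
        species = make_species(["collaborator", "scammer", "collaborator"])
        arrays = SpeciesArrays.from_species(species)
        lat = Lattice.empty(9, 9)
        lat.species_id[:] = rng.choice([-1, 0, 1, 2], size=(9, 9))
        role_of = {0: 1, 1: 0, 2: 1}
        for mode in ("opposite", "collaborator_sum"):
            grid = mll_grid(lat, arrays, mode)
            for i in range(9):
                for j in range(9):
                    sid = lat.species_id[i, j]
                    if sid < 0:
                        continue
                    expected = 0
                    for di, dj in MOORE_OFFSETS:
                        nsid = lat.species_id[(i + di) % 9, (j + dj) % 9]
                        if nsid < 0:
                            continue
                        if mode == "collaborator_sum":
                            expected += role_of[nsid]
                        elif role_of[nsid] != role_of[sid]:
                            expected += 1
                    assert mll(lat, arrays, i, j, mode) == expected
                    assert grid[i, j] == expected

    def test_mll_extremes(self):
        species = make_species(["collaborator", "scammer"])
        arrays = SpeciesArrays.from_species(species)
        lat = fill_lattice(5, 5, 1)      # all scammers
        lat.species_id[2, 2] = 0         # collaborator focal
        assert mll(lat, arrays, 2, 2) == 8
        lone = Lattice.empty(5, 5)
        lone.species_id[2, 2] = 0
        assert mll(lone, arrays, 2, 2) == 0

    def test_mll_requires_occupied_focal(self):
        arrays = SpeciesArrays.from_species(make_species(["scammer"]))
        with pytest.raises(ValueError):
            mll(Lattice.empty(5, 5), arrays, 0, 0)


class TestTierProbabilities:
    @pytest.mark.parametrize("mll_value,expected", [
        (8, "alpha1"), (7, "alpha1"), (6, "alpha1"),
        (5, "alpha2"), (3, "alpha2"),
        (2, "alpha3"), (0, "alpha3"),
    ])
    def test_collaborator_tiers(self, mll_value, expected):
        sp = make_species(["collaborator"])[0]
        assert lag_tier_probability(sp, mll_value) == getattr(sp, expected)

    def test_scammer_with_many_collaborators_uses_smallest_probability(self):
        sp = make_species(["scammer"])[0]
        assert lag_tier_probability(sp, 8) == sp.beta1
        assert lag_tier_probability(sp, 0) == sp.beta3
        assert sp.beta1 < sp.beta3

    def test_out_of_range_mll_rejected(self):
        sp = make_species(["scammer"])[0]
        with pytest.raises(ValueError):
            lag_tier_probability(sp, 9)

    def test_tier_probability_monotone_in_opposite_neighbours(self):
        collab, scam = make_species(["collaborator", "scammer"])
        pc = [lag_tier_probability(collab, v) for v in range(9)]
        ps = [lag_tier_probability(scam, v) for v in range(9)]
        assert all(a <= b for a, b in zip(pc[:-1], pc[1:]))
        assert all(a >= b for a, b in zip(ps[:-1], ps[1:]))


class TestLagRule:
    def test_zero_probabilities_induce_nothing(self):
        species = make_species(["collaborator", "scammer"],
                               alpha1=0, alpha2=0, alpha3=0,
                               beta1=0, beta2=0, beta3=0)
        lat = fill_lattice(10, 10, np.arange(100).reshape(10, 10) % 2)
        n = apply_lag_rule(lat, SpeciesArrays.from_species(species),
                           np.random.default_rng(0))
        assert n == 0 and not lat.is_lag.any()

    def test_unit_probabilities_induce_every_active_cell(self):
        species = make_species(["collaborator", "scammer"],
                               alpha1=1, alpha2=1, alpha3=1,
                               beta1=1, beta2=1, beta3=1)
        lat = fill_lattice(10, 10, np.arange(100).reshape(10, 10) % 2)
        lat.is_lag[0, 0] = 1  # already lagged: must be skipped, not re-entered
        lat.lag_timer[0, 0] = 3
        n = apply_lag_rule(lat, SpeciesArrays.from_species(species),
                           np.random.default_rng(0))
        assert n == 99
        assert lat.is_lag.all()
        assert lat.lag_timer[0, 0] == 3  # untouched

    def test_entry_fraction_matches_tier_probability(self):
        # 10^4 collaborators, each fully surrounded by non-reactive scammers
        # (MLL = 8 -> alpha1); binomial expectation 0.8 +/- 0.02
        species = make_species(["collaborator", "scammer"],
                               alpha1=0.8, beta1=0, beta2=0, beta3=0)
        lat = fill_lattice(300, 300, 1)
        lat.species_id[::3, ::3] = 0
        n_collab = (lat.species_id == 0).sum()
        assert n_collab == 10_000
        n = apply_lag_rule(lat, SpeciesArrays.from_species(species),
                           np.random.default_rng(123))
        assert n / n_collab == pytest.approx(0.8, abs=0.02)


class TestLagDeath:
    def test_certain_natural_death_empties_the_lattice(self):
        species = make_species(["collaborator"], d=1.0)
        lat = fill_lattice(6, 6, 0)
        update_lag_and_death(lat, SpeciesArrays.from_species(species),
                             np.random.default_rng(0))
        assert lat.occupancy == 0

    def test_no_removal_channels_conserve_occupancy(self):
        species = make_species(["collaborator", "scammer"], d=0.0, p=0.0, m=0.0,
                               alpha1=0, alpha2=0, alpha3=0,
                               beta1=0, beta2=0, beta3=0)
        arrays = SpeciesArrays.from_species(species)
        lat = fill_lattice(10, 10, np.arange(100).reshape(10, 10) % 2)
        rng = np.random.default_rng(1)
        for _ in range(10):
            step(lat, arrays, rng)
        assert lat.occupancy == 100

    def test_overrun_death_starts_beyond_lat_times_n(self):
        # Lat=6, n=1: a lag episode of 6 steps is safe, the 7th exposes the
        # cell to p-death; with p=1 death is certain once timer exceeds 6
        species = make_species(["collaborator"], p=1.0, d=0.0, Lat=6, n=1)
        arrays = SpeciesArrays.from_species(species)

        lat = Lattice.empty(4, 4)
        lat.species_id[1, 1] = 0
        lat.is_lag[1, 1] = 1
        lat.lag_timer[1, 1] = 6  # incremented to 7 > 6 this step
        update_lag_and_death(lat, arrays, np.random.default_rng(0))
        assert lat.occupancy == 0

        lat = Lattice.empty(4, 4)
        lat.species_id[1, 1] = 0
        lat.is_lag[1, 1] = 1
        lat.lag_timer[1, 1] = 3  # within the cap: survives the p-check
        n_overrun, _, _ = update_lag_and_death(lat, arrays, np.random.default_rng(0))
        assert n_overrun == 0 and lat.occupancy == 1


class TestMoveRule:
    def test_zero_move_probability_fills_nothing(self):
        species = make_species(["collaborator"], m=0.0)
        lat = Lattice.empty(10, 10)
        lat.species_id[5, 5] = 0
        births = apply_move_rule(lat, SpeciesArrays.from_species(species),
                                 np.random.default_rng(0))
        assert births == 0 and lat.occupancy == 1

    def test_sole_candidate_with_certain_move_parents_exactly_once(self):
        species = make_species(["collaborator"], m=1.0)
        lat = Lattice.empty(10, 10)
        lat.species_id[5, 5] = 0
        births = apply_move_rule(lat, SpeciesArrays.from_species(species),
                                 np.random.default_rng(3))
        assert births == 1  # one offspring per parent per step
        assert lat.occupancy == 2
        (i0, j0), (i1, j1) = np.argwhere(lat.species_id == 0)
        child = (i1, j1) if (i0, j0) == (5, 5) else (i0, j0)
        assert max(abs(child[0] - 5), abs(child[1] - 5)) <= 3  # radius-3 shell

    def test_lagged_cells_cannot_parent(self):
        species = make_species(["collaborator"], m=1.0)
        lat = Lattice.empty(10, 10)
        lat.species_id[5, 5] = 0
        lat.is_lag[5, 5] = 1
        births = apply_move_rule(lat, SpeciesArrays.from_species(species),
                                 np.random.default_rng(0))
        assert births == 0


class TestStep:
    def test_empty_lattice_stays_empty(self):
        arrays = SpeciesArrays.from_species(make_species(["collaborator"]))
        lat = Lattice.empty(8, 8)
        ev = step(lat, arrays, np.random.default_rng(0))
        assert lat.occupancy == 0 and ev.births == 0
        assert lat.step_index == 1

    def test_all_rules_off_is_identity(self):
        species = make_species(["collaborator", "scammer"],
                               alpha1=0, alpha2=0, alpha3=0,
                               beta1=0, beta2=0, beta3=0,
                               m=0.0, d=0.0, p=0.0)
        arrays = SpeciesArrays.from_species(species)
        lat = fill_lattice(8, 8, np.arange(64).reshape(8, 8) % 2)
        before = lat.species_id.copy()
        step(lat, arrays, np.random.default_rng(0))
        assert np.array_equal(lat.species_id, before)

    def test_equal_seeds_give_bitwise_identical_histories(self):
        rng = np.random.default_rng(8)
        species = make_species(["collaborator"] * 2 + ["scammer"] * 2,
                               m=list(rng.uniform(0.05, 0.2, 4)),
                               d=list(rng.uniform(0.1, 0.3, 4)))
        arrays = SpeciesArrays.from_species(species)
        lats = []
        for _ in range(2):
            lat = Lattice.empty(20, 20)
            lat.species_id[:] = np.random.default_rng(2).choice(
                [-1, 0, 1, 2, 3], size=(20, 20))
            r = np.random.default_rng(99)
            for _ in range(5):
                step(lat, arrays, r)
            lats.append(lat)
        assert np.array_equal(lats[0].species_id, lats[1].species_id)
        assert np.array_equal(lats[0].is_lag, lats[1].is_lag)
        assert np.array_equal(lats[0].lag_timer, lats[1].lag_timer)

    def test_occupancy_bookkeeping_identity_over_a_run(self):
        rng = np.random.default_rng(17)
        species = make_species(
            ["collaborator", "collaborator", "scammer", "scammer", "scammer"],
            m=list(rng.uniform(0.0, 0.2, 5)), d=list(rng.uniform(0.1, 0.3, 5)))
        lat = Lattice.empty(30, 30)
        lat.species_id[:] = np.random.default_rng(4).choice(
            [-1, 0, 1, 2, 3, 4], size=(30, 30))
        events, counts, _ = simulate(lat, species, 50, np.random.default_rng(5))
        assert (events.occupancy_after ==
                events.occupancy_before - events.overrun_deaths
                - events.natural_deaths + events.births).all()
        # the event chain matches the recorded abundance matrix
        assert (counts.sum(axis=0)[1:] == events.occupancy_after.to_numpy()).all()
        lat.check_consistency()
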