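import numpy as np
import pytest

from oralca.community import (
    CommunityConfig,
    sample_community,
    seed_lattice,
    zero_lag,
)
from oralca.engine import simulate


@pytest.fixture(scope="session")
def comparison_experiment():
    """The with/without-delay-responses experiment: 100x100 torus, 20
    species, 1000 steps, 10 seeds, lag-on and lag-off sharing the species
    draw and initial lattice within each seed."""
    runs = []
    for seed in range(10):
        cfg = CommunityConfig(
            N=20, lattice_rows=100, lattice_cols=100, steps=1000, seed=seed
        )
        rng = np.random.default_rng(seed)
        species = sample_community(cfg, rng)
        lat0 = seed_lattice(species, cfg, rng)
        rec = {"seed": seed, "species": species, "initial": lat0.copy()}
        for label, spl in (("on", species), ("off", zero_lag(species))):
            lat = lat0.copy()
            events, counts, snaps = simulate(
                lat, spl, cfg.steps, np.random.default_rng(1000 + seed),
                snapshot_stride=100 if label == "on" else 0,
            )
            rec[label] = {"events": events, "counts": counts, "snapshots": snaps}
        runs.append(rec)
    return runs


@pytest.fixture(scope="session")
def climax_run():
    """A richer community (N=100) on the same lattice for the climax
    cluster analysis: 100x100, 1000 steps, fixed seed."""
    cfg = CommunityConfig(
        N=100, lattice_rows=100, lattice_cols=100, steps=1000, seed=0
    )
    rng = np.random.default_rng(0)
    species = sample_community(cfg, rng)
    lat = seed_lattice(species, cfg, rng)
    events, counts, snaps = simulate(
        lat, species, cfg.steps, np.random.default_rng(100), snapshot_stride=20
    )
    return {"species": species, "events": events, "counts": counts,
            "snapshots": snaps}
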