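import numpy as np
import pandas as pd
import pytest

from dunefly.popgen import GenotypePanel
from dunefly.simulate import PopulationSpec, SimulationConfig


@pytest.fixture
def tiny_events():
    """Hand-written two-pair event log on a 0.25 s lattice."""
    rows = [
        # pair, pop, actor, behavior, start, end
        ("p1", "A", "M", "Orient", 0.0, 5.0),
        ("p1", "A", "M", "Wing-vibrate", 2.0, 5.0),
        ("p1", "A", "M", "Face-off", 6.0, 8.0),
        ("p1", "A", "F", "Standing", 0.0, 4.0),
        ("p1", "A", "F", "Walking", 4.0, 8.0),
        ("p2", "A", "M", "Orient", 0.0, 2.0),
        ("p2", "A", "M", "Orient", 3.0, 4.0),
        ("p2", "A", "F", "Turn", 1.0, 2.5),
    ]
    return pd.DataFrame(
        rows, columns=["pair_id", "population", "actor", "behavior", "start_s", "end_s"]
    )


@pytest.fixture
def small_config():
    """Two small populations, reduced state set, small SNP panel."""
    cfg = SimulationConfig(seed=42)
    cfg.populations = [
        PopulationSpec("A", n_pairs=4, n_genotyped=8, lat=-35.0, lon=150.0),
        PopulationSpec("B", n_pairs=4, n_genotyped=8, lat=-36.5, lon=150.1),
    ]
    cfg.genetics.n_loci = 400
    return cfg


def random_panel(rng, n_pops=3, n_ind=6, n_loci=12, missing=0.0, coords=False):
    """Small random genotype panel for oracle comparisons."""
    g = rng.integers(0, 3, size=(n_pops * n_ind, n_loci)).astype(float)
    if missing:
        g[rng.random(g.shape) < missing] = np.nan
    inds = [f"i{k}" for k in range(g.shape[0])]
    pops = pd.Series(
        [f"P{k // n_ind}" for k in range(g.shape[0])], index=inds
    )
    coord_df = None
    if coords:
        coord_df = pd.DataFrame(
            {
                "lat": -35.0 - 0.3 * np.arange(n_pops),
                "lon": 150.0 + 0.1 * rng.standard_normal(n_pops),
            },
            index=[f"P{k}" for k in range(n_pops)],
        )
    geno = pd.DataFrame(g, index=inds, columns=[f"L{j}" for j in range(n_loci)])
    return GenotypePanel(geno, pops, coord_df)
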