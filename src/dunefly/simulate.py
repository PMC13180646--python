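"""Synthetic courtship-sequence and SNP-panel generation.

The generator emulates the two data streams of the field study:

* **Behavior** — per courting pair, a semi-Markov realization over composite
  behavioral states.  Each population's transition matrix is
  ``P_pop = (1 - eps) * P_base + eps * P_perturb(pop)``, where ``eps`` is the
  divergence knob; state dwell times are gamma-distributed; chains begin at
  bout-start and end after a geometrically distributed number of events.
  Composite states decompose into overlapping per-behavior bout records, the
  event-log dialect the ethogram module consumes.

* **Genetics** — multi-population biallelic SNP panels under the
  Balding–Nichols model: ancestral frequencies uniform on a range, deme
  frequencies Beta-distributed around them with differentiation parameter F
  (scalar per population, or accumulated serially along the habitat to
  create isolation by distance), genotypes binomial, missingness masked at a
  per-locus rate, and per-locus assay metadata (reproducibility, call rate)
  drawn so the standard filters bite realistically.

All randomness flows from a single seed through ``numpy`` SeedSequence
spawning, so identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ethogram import StateSequence
from .popgen import GenotypePanel
from .presets import (
    BOUT_END,
    BOUT_START,
    FULL_STATES,
    FULL_STATE_DECOMPOSITION,
    REDUCED_STATES,
    REDUCED_STATE_DECOMPOSITION,
    parse_state_label,
)


@dataclass
class PopulationSpec:
    name: str
    n_pairs: int = 15
    n_genotyped: int = 15
    lat: float = 0.0
    lon: float = 0.0


@dataclass
class BehaviorConfig:
    """Semi-Markov courtship model parameters.

    Defaults emulate the field recordings: gamma bouts with mean 2 s and a
    geometric event count with mean ~64, giving median interaction lengths
    near 1.5 min with a right-skewed mean.
    """

    preset: str = "reduced"  # "reduced" (12 states) or "full" (41 states)
    duration_shape: float = 2.0
    duration_scale: float = 1.0  # seconds; mean bout = shape * scale
    mean_events: float = 64.0
    min_events: int = 5
    max_events: int = 400
    epsilon: float = 0.0  # divergence knob in [0, 1]
    gradient: float | None = None  # coupled mode: per-population epsilon
    # rises linearly along the population list toward one shared
    # perturbation direction (courtship divergence tracks the habitat axis)
    matrix_seed: int = 20211217  # base/perturbation matrix construction


@dataclass
class GeneticsConfig:
    """Balding–Nichols panel parameters."""

    n_loci: int = 5000
    freq_range: tuple[float, float] = (0.01, 0.5)
    fst: float = 0.2  # scalar F, or see `spatial`
    spatial: str = "island"  # "island" | "serial" (F accumulates along habitat)
    missing_rate: float = 0.03  # mean per-locus missingness before filtering
    low_repro_fraction: float = 0.12  # loci with degraded assay reproducibility


@dataclass
class SimulationConfig:
    seed: int = 0
    populations: list[PopulationSpec] = field(
        default_factory=lambda: [
            PopulationSpec("Greenpatch", 15, 23, -35.1365, 150.72346),
            PopulationSpec("Middle", 15, 10, -36.8915, 149.92931),
            PopulationSpec("Severs", 15, 10, -36.9526, 149.90857),
        ]
    )
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    genetics: GeneticsConfig = field(default_factory=GeneticsConfig)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["populations"] = [PopulationSpec(**p) for p in raw.get("populations", [])]
        if "behavior" in raw:
            raw["behavior"] = BehaviorConfig(**raw["behavior"])
        if "genetics" in raw:
            g = raw["genetics"]
            if "freq_range" in g:
                g["freq_range"] = tuple(g["freq_range"])
            raw["genetics"] = GeneticsConfig(**g)
        return cls(**raw)


def _preset_states(preset: str):
    if preset == "reduced":
        return REDUCED_STATES, REDUCED_STATE_DECOMPOSITION
    if preset == "full":
        return FULL_STATES, FULL_STATE_DECOMPOSITION
    raise ValueError(f"unknown state preset {preset!r}")


def _check_stochastic(P: np.ndarray):
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must be nonnegative and sum to 1")
    if np.abs(np.diag(P)).max() > 1e-12:
        raise ValueError("transition matrix must have a zero diagonal")


def random_transition_matrix(n_states: int, rng, concentration: float = 0.6) -> np.ndarray:
    """Row-stochastic zero-diagonal matrix with Dirichlet rows (sparse-ish)."""
    P = rng.gamma(concentration, 1.0, size=(n_states, n_states))
    np.fill_diagonal(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    return P


def base_transition_matrix(states: list[str], seed: int = 20211217) -> np.ndarray:
    """Deterministic base matrix over non-sentinel states.

    Dirichlet rows with cross-actor transitions upweighted (turn-taking) —
    courting flies tend to answer the partner rather than chain their own
    states.
    """
    rng = np.random.default_rng(seed)
    P = random_transition_matrix(len(states), rng)
    actors = np.array([parse_state_label(s)[0] for s in states])
    cross = actors[:, None] != actors[None, :]
    P = P * np.where(cross, 2.0, 1.0)
    np.fill_diagonal(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    return P


def population_matrices(
    states: list[str],
    pop_names: list[str],
    epsilon: float,
    matrix_seed: int,
    direction: np.ndarray | None = None,
    per_pop_epsilon: dict[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """Per-population matrices ``(1 - e) P_base + e P_perturb``.

    By default each population gets its own random perturbation matrix; a
    shared ``direction`` matrix with per-population magnitudes creates
    coordinated (coupled) divergence along a gradient.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    base = base_transition_matrix(states, matrix_seed)
    rng = np.random.default_rng(np.random.SeedSequence([matrix_seed, 7]))
    out = {}
    for pop in pop_names:
        e = per_pop_epsilon[pop] if per_pop_epsilon is not None else epsilon
        pert = direction if direction is not None else random_transition_matrix(len(states), rng)
        P = (1.0 - e) * base + e * pert
        _check_stochastic(P)
        out[pop] = P
    return out


def _simulate_chain(P: np.ndarray, n_events: int, rng) -> np.ndarray:
    S = P.shape[0]
    cum = np.cumsum(P, axis=1)
    states = np.empty(n_events, dtype=np.intp)
    states[0] = rng.integers(S)
    draws = rng.random(n_events - 1)
    for k in range(1, n_events):
        states[k] = np.searchsorted(cum[states[k - 1]], draws[k - 1], side="right")
    return states


def simulate_behavior(
    config: SimulationConfig,
    return_chains: bool = False,
):
    """Simulate per-pair behavior event logs for every population.

    Returns an event DataFrame (columns pair_id, population, actor,
    behavior, start_s, end_s); with ``return_chains`` also the true composite
    state chains (dict pair_id -> list of labels) for simulator-level tests.
    """
    bc = config.behavior
    states, decomposition = _preset_states(bc.preset)
    chain_states = [s for s in states if s not in (BOUT_START, BOUT_END)]
    per_eps = direction = None
    if bc.gradient is not None:
        n = max(len(config.populations) - 1, 1)
        per_eps = {
            p.name: bc.gradient * i / n for i, p in enumerate(config.populations)
        }
        direction = random_transition_matrix(
            len(chain_states),
            np.random.default_rng(np.random.SeedSequence([bc.matrix_seed, 13])),
        )
    mats = population_matrices(
        chain_states, [p.name for p in config.populations], bc.epsilon,
        bc.matrix_seed, direction=direction, per_pop_epsilon=per_eps,
    )
    root = np.random.SeedSequence([int(config.seed), 1])
    pop_seeds = root.spawn(len(config.populations))

    rows = []
    chains: dict[str, list[str]] = {}
    for pop, pseed in zip(config.populations, pop_seeds):
        P = mats[pop.name]
        _check_stochastic(P)
        pair_seeds = pseed.spawn(pop.n_pairs)
        for k, sseq in enumerate(pair_seeds):
            rng = np.random.default_rng(sseq)
            pair_id = f"{pop.name}_{k + 1:02d}"
            n_events = int(
                np.clip(rng.geometric(1.0 / bc.mean_events), bc.min_events, bc.max_events)
            )
            idx = _simulate_chain(P, n_events, rng)
            durations = rng.gamma(bc.duration_shape, bc.duration_scale, size=n_events)
            t = np.concatenate([[0.0], np.cumsum(durations)])
            labels = [chain_states[i] for i in idx]
            chains[pair_id] = labels
            # decompose composite states into per-behavior bout records,
            # merging a behavior that stays active across adjacent states
            open_bouts: dict[tuple[str, str], float] = {}
            prev: set[tuple[str, str]] = set()
            for step, lab in enumerate(labels + [None]):
                if lab is None:
                    active = set()
                else:
                    actor, behaviors = decomposition[lab]
                    active = {(actor, b) for b in behaviors}
                for key in prev - active:
                    rows.append(
                        (pair_id, pop.name, key[0], key[1], open_bouts.pop(key), t[step])
                    )
                for key in active - prev:
                    open_bouts[key] = t[step]
                prev = active
        # round times to the 60 fps scoring resolution? no — keep exact values
    events = pd.DataFrame(
        rows, columns=["pair_id", "population", "actor", "behavior", "start_s", "end_s"]
    ).sort_values(["pair_id", "start_s", "behavior"], ignore_index=True)
    return (events, chains) if return_chains else events


def simulate_snps(config: SimulationConfig) -> GenotypePanel:
    """Simulate a Balding–Nichols SNP panel with assay metadata.

    Deme allele frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) around the
    ancestral p ("island" mode), or accumulate the same drift serially from
    population to population along the configured order ("serial" mode,
    producing isolation by distance).
    """
    gc = config.genetics
    if not 0.0 < gc.fst < 1.0:
        raise ValueError("fst must lie strictly between 0 and 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    L = gc.n_loci
    lo, hi = gc.freq_range
    p_anc = rng.uniform(lo, hi, size=L)

    def drift(p, F):
        a = np.clip(p * (1.0 - F) / F, 1e-9, None)
        b = np.clip((1.0 - p) * (1.0 - F) / F, 1e-9, None)
        return rng.beta(a, b)

    pop_freqs = {}
    prev = p_anc
    for pop in config.populations:
        if gc.spatial == "island":
            pop_freqs[pop.name] = drift(p_anc, gc.fst)
        elif gc.spatial == "serial":
            prev = drift(prev, gc.fst)
            pop_freqs[pop.name] = prev
        else:
            raise ValueError(f"unknown spatial mode {gc.spatial!r}")

    blocks, inds, pops = [], [], []
    for pop in config.populations:
        f = pop_freqs[pop.name]
        g = rng.binomial(2, f, size=(pop.n_genotyped, L)).astype(float)
        blocks.append(g)
        inds += [f"{pop.name}_g{i + 1:02d}" for i in range(pop.n_genotyped)]
        pops += [pop.name] * pop.n_genotyped
    G = np.vstack(blocks)

    # per-locus missingness, Beta-distributed around the configured mean
    mean = gc.missing_rate
    a, b = 0.8, 0.8 * (1.0 - mean) / max(mean, 1e-9)
    locus_rate = rng.beta(a, b, size=L)
    mask = rng.random(G.shape) < locus_rate[None, :]
    G[mask] = np.nan

    loci = [f"L{i + 1:05d}" for i in range(L)]
    geno = pd.DataFrame(G, index=inds, columns=loci)
    call_rate = 1.0 - np.isnan(G).mean(axis=0)
    low = rng.random(L) < gc.low_repro_fraction
    repro = np.where(low, rng.uniform(0.7, 0.98, size=L), rng.uniform(0.98, 1.0, size=L))
    metadata = pd.DataFrame(
        {"reproducibility": repro, "call_rate": call_rate}, index=pd.Index(loci, name="locus_id")
    )
    coords = pd.DataFrame(
        {"lat": [p.lat for p in config.populations], "lon": [p.lon for p in config.populations]},
        index=[p.name for p in config.populations],
    )
    populations = pd.Series(pops, index=inds, name="population")
    return GenotypePanel(geno, populations, coords, metadata)


# ---------------------------------------------------------------------------
# study-scale configurations

#: The seven sampled beach populations: (name, genotyped flies, lat, lon).
STUDY_SITES = [
    ("Greenpatch", 23, -35.1365, 150.72346),
    ("Wairo", 9, -35.4276, 150.41645),
    ("Haywards", 12, -36.4053, 150.06543),
    ("Beares", 11, -36.4324, 150.07836),
    ("Merimbula", 19, -36.9033, 149.91),
    ("Middle", 10, -36.8915, 149.92931),
    ("Severs", 10, -36.9526, 149.90857),
]

#: The three populations filmed for courtship (15 pairs each).
STUDY_FILMED = ("Greenpatch", "Middle", "Severs")


def study_genetics_config(seed: int) -> SimulationConfig:
    """Field-study-scale SNP campaign: 94 flies across seven beaches,
    38,905 loci before filtering.

    Drift accumulates serially along the coastline (isolation by distance);
    the per-step F, missingness and degraded-assay fraction emulate the
    strong structure and heavy reduced-representation filter attrition of
    panels of this kind.
    """
    cfg = SimulationConfig(seed=seed)
    cfg.populations = [
        PopulationSpec(name, n_pairs=0, n_genotyped=n, lat=lat, lon=lon)
        for name, n, lat, lon in STUDY_SITES
    ]
    cfg.genetics = GeneticsConfig(
        n_loci=38905, fst=0.12, spatial="serial", missing_rate=0.06,
        low_repro_fraction=0.35, freq_range=(0.005, 0.5),
    )
    return cfg


def study_behavior_config(seed: int) -> SimulationConfig:
    """Field-study-scale courtship campaign: 15 filmed pairs in each of the
    three focal populations, full 41-state repertoire, mild divergence
    (displays in this system are largely stable across populations)."""
    cfg = SimulationConfig(seed=seed)
    cfg.populations = [
        PopulationSpec(name, n_pairs=15, n_genotyped=0, lat=lat, lon=lon)
        for name, n, lat, lon in STUDY_SITES
        if name in STUDY_FILMED
    ]
    cfg.behavior = BehaviorConfig(preset="full", epsilon=0.1)
    return cfg


# ---------------------------------------------------------------------------
# file emission (the exact dialects the analysis modules consume)


def write_behavior_csv(events: pd.DataFrame, path):
    events.to_csv(path, index=False)


def write_panel_csv(panel: GenotypePanel, geno_path, popmap_path, metadata_path):
    panel.genotypes.to_csv(geno_path, index_label="individual_id")
    popmap = pd.DataFrame({
        "individual_id": panel.individuals,
        "population": panel.populations.to_numpy(),
    })
    if panel.coords is not None:
        popmap["lat"] = [panel.coords.loc[p, "lat"] for p in popmap["population"]]
        popmap["lon"] = [panel.coords.loc[p, "lon"] for p in popmap["population"]]
    popmap.to_csv(popmap_path, index=False)
    if panel.metadata is not None:
        panel.metadata.to_csv(metadata_path, index_label="locus_id")


def sequences_from_events(events: pd.DataFrame, ethogram=None):
    """Derive per-actor state sequences for every pair in an event log.

    Returns dict pair_id -> {"M": StateSequence, "F": StateSequence}.
    """
    from .ethogram import DEFAULT_ETHOGRAM, derive_state_sequence

    ethogram = ethogram or DEFAULT_ETHOGRAM
    out = {}
    for pid in sorted(events["pair_id"].unique()):
        out[pid] = {
            "M": derive_state_sequence(events, pid, "M", ethogram),
            "F": derive_state_sequence(events, pid, "F", ethogram),
        }
    return out
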