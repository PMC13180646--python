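"""End-to-end orchestration of the courtship/popgen analysis.

Each stage is a plain function over the library modules; the command-line
interface and the numbered analysis drivers are thin wrappers around these.
Every stage returns the paths it wrote plus a manifest entry; a run manifest
(JSON) records inputs, a configuration hash, the seed, software version,
per-stage attrition, timestamps, and a checksum per output file, so reruns
with identical inputs are verifiably identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ethogram import (
    DEFAULT_ETHOGRAM,
    EXTENDED_ETHOGRAM,
    compute_all_metrics,
    load_event_log,
    occurrence_proportions,
    prevalence_filter,
)
from .linkage import courtship_vs_genetic
from .popgen import (
    amova,
    filter_loci,
    genotype_pca,
    heterozygosities,
    kosman_distance,
    mantel_ibd,
    nei_distance,
    pairwise_fst,
    population_specific_fst,
    private_alleles,
    read_dosage_csv,
)
from .simulate import (
    SimulationConfig,
    sequences_from_events,
    simulate_behavior,
    simulate_snps,
    write_behavior_csv,
    write_panel_csv,
)
from .transitions import (
    count_transitions,
    interleave_pair_sequences,
    pairwise_courtship_distances,
    per_individual_matrices,
    permutation_edge_test,
    population_divergence_summary,
)

log = logging.getLogger("dunefly")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _config_hash(config) -> str:
    raw = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(raw.encode()).hexdigest()[:16]


class Manifest:
    """Run manifest: inputs, seed, attrition, and output checksums."""

    def __init__(self, out_dir: Path, seed, config_hash: str):
        self.data = {
            "version": __version__,
            "seed": seed,
            "config_hash": config_hash,
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "stages": {},
            "outputs": {},
        }
        self.out_dir = Path(out_dir)

    def record(self, stage: str, info: dict, outputs: list[Path]):
        self.data["stages"][stage] = info
        for p in outputs:
            self.data["outputs"][str(Path(p).relative_to(self.out_dir))] = _sha256(p)

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        self.data["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        path.write_text(json.dumps(self.data, indent=2, default=str))
        return path


def _ethogram_for(config: SimulationConfig):
    return EXTENDED_ETHOGRAM if config.behavior.preset == "full" else DEFAULT_ETHOGRAM


def stage_simulate(config: SimulationConfig, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events = simulate_behavior(config)
    panel = simulate_snps(config)
    paths = {
        "events": out / "behavior_events.csv",
        "genotypes": out / "genotypes.csv",
        "popmap": out / "popmap.csv",
        "metadata": out / "locus_metadata.csv",
    }
    write_behavior_csv(events, paths["events"])
    write_panel_csv(panel, paths["genotypes"], paths["popmap"], paths["metadata"])
    config.to_json(out / "config.json")
    paths["config"] = out / "config.json"
    log.info(
        "simulated %d behavior events, %d individuals x %d loci",
        len(events), panel.genotypes.shape[0], panel.genotypes.shape[1],
    )
    return {"paths": paths, "events": events, "panel": panel}


def stage_filter(panel, out_dir, repro_min=0.98, callrate_min=0.95, maf_min=0.02):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    filtered, report = filter_loci(panel, repro_min, callrate_min, maf_min)
    for step in report["steps"]:
        log.info(
            "filter %-15s (>= %.3g): removed %d, remaining %d",
            step["filter"], step["threshold"], step["removed"], step["remaining"],
        )
    log.info("residual missing data: %.2f%%", report["missing_pct"])
    path = out / "filter_report.json"
    path.write_text(json.dumps(report, indent=2))
    return {"panel": filtered, "report": report, "paths": {"report": path}}


def stage_popgen(panel, out_dir, n_boot=1000, n_perm=999, mantel_perm=10000, seed=None):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = _seedseq(seed).spawn(3)
    het = heterozygosities(panel)
    betas = population_specific_fst(panel)
    priv = private_alleles(panel)
    summary = het.join(betas).join(priv)
    fst, fst_p = pairwise_fst(panel, n_boot=n_boot, seed=ss[0])
    am = amova(panel, n_perm=n_perm, seed=ss[1])
    nei = nei_distance(panel)
    pca = genotype_pca(panel)
    results = {
        "summary": summary, "pairwise_fst": fst, "pairwise_fst_p": fst_p,
        "amova": am, "nei": nei, "pca": pca,
    }
    if panel.coords is not None and len(panel.pop_names) >= 4:
        results["mantel"] = mantel_ibd(panel, n_perm=mantel_perm, seed=ss[2])
    paths = {}
    paths["summary"] = out / "population_summary.csv"
    summary.to_csv(paths["summary"])
    paths["pairwise_fst"] = out / "pairwise_fst.csv"
    fst.to_csv(paths["pairwise_fst"])
    if fst_p is not None:
        paths["pairwise_fst_p"] = out / "pairwise_fst_pvalues.csv"
        fst_p.to_csv(paths["pairwise_fst_p"])
    paths["nei"] = out / "nei_distance.csv"
    nei.to_csv(paths["nei"])
    paths["pca"] = out / "pca_scores.csv"
    pca.scores.assign(population=panel.populations.to_numpy()).to_csv(paths["pca"])
    amova_flat = {
        **{f"percent_{k}": v for k, v in am["percent"].items()},
        **am["phi"], "p_value": am.get("p_value"),
    }
    paths["amova"] = out / "amova.json"
    Path(paths["amova"]).write_text(json.dumps(amova_flat, indent=2))
    if "mantel" in results:
        paths["mantel"] = out / "mantel.json"
        Path(paths["mantel"]).write_text(json.dumps(
            {k: results["mantel"][k] for k in ("r", "p_value", "n_perm")}, indent=2))
    results["paths"] = paths
    log.info("popgen: global AMOVA Phi_ST=%.4f (p=%s)", am["phi"]["phi_st"], am.get("p_value"))
    return results


def stage_ethogram(events, populations, out_dir, ethogram=DEFAULT_ETHOGRAM,
                   prevalence_threshold=0.5, exclude=("Face-off", "Chasing")):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics = compute_all_metrics(events)
    occ = occurrence_proportions(events, populations, ethogram)
    prevalent = prevalence_filter(occ, prevalence_threshold, exclude=exclude)
    paths = {
        "metrics": out / "courtship_metrics.csv",
        "occurrence": out / "occurrence_proportions.csv",
        "prevalent": out / "prevalent_behaviors.csv",
    }
    metrics.to_csv(paths["metrics"])
    occ.to_csv(paths["occurrence"])
    pd.DataFrame(prevalent, columns=["actor", "behavior"]).to_csv(
        paths["prevalent"], index=False
    )
    log.info("ethogram: %d pairs, %d prevalent behaviors",
             events["pair_id"].nunique(), len(prevalent))
    return {"metrics": metrics, "occurrence": occ, "prevalent": prevalent,
            "paths": paths}


def stage_transitions(events, populations, out_dir, ethogram=DEFAULT_ETHOGRAM,
                      n_perm=1000, alpha=0.05, pseudocount=1.0, seed=None,
                      mode="individual"):
    """Transition matrices, permutation networks per population, KL distances.

    ``mode``: "individual" counts within each actor's own chain (default);
    "pair" interleaves male and female states of a pair into one chain.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    populations = pd.Series(populations)
    seqs = sequences_from_events(events, ethogram)
    state_set = sorted({
        s for pair in seqs.values() for actor_seq in pair.values() for s in actor_seq.states
    })
    per_pair: dict[str, list[list[str]]] = {}
    for pid, pair in seqs.items():
        if mode == "pair":
            per_pair[pid] = [interleave_pair_sequences(pair["M"], pair["F"])]
        else:
            per_pair[pid] = [pair["M"].labels, pair["F"].labels]

    mats = per_individual_matrices(per_pair, states=state_set)
    D = pairwise_courtship_distances(mats, pseudocount=pseudocount)
    summary = population_divergence_summary(D, populations)

    ss = _seedseq(seed).spawn(len(populations.unique()))
    networks = {}
    paths = {}
    for child, pop in zip(ss, sorted(populations.unique())):
        pop_seqs = [s for pid in per_pair if populations[pid] == pop for s in per_pair[pid]]
        net = permutation_edge_test(pop_seqs, states=state_set, n_perm=n_perm,
                                    alpha=alpha, seed=child)
        networks[pop] = net
        paths[f"edges_{pop}"] = out / f"network_edges_{pop}.csv"
        net.edges.to_csv(paths[f"edges_{pop}"], index=False)
        paths[f"graphml_{pop}"] = out / f"network_{pop}.graphml"
        net.write_graphml(paths[f"graphml_{pop}"])
        pop_counts = count_transitions(pop_seqs, states=state_set, scope="population")
        paths[f"counts_{pop}"] = out / f"transition_counts_{pop}.csv"
        pop_counts.to_frame().to_csv(paths[f"counts_{pop}"])
    paths["distances"] = out / "courtship_distances.csv"
    D.to_csv(paths["distances"])
    paths["divergence_summary"] = out / "courtship_divergence_summary.csv"
    summary.to_csv(paths["divergence_summary"], index=False)
    log.info("transitions: %d states, %d individuals", len(state_set), len(mats))
    return {"matrices": mats, "distances": D, "summary": summary,
            "networks": networks, "states": state_set, "paths": paths}


def stage_divergence(courtship_D, courtship_pops, kosman_D, kosman_pops, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, fit = courtship_vs_genetic(courtship_D, courtship_pops, kosman_D, kosman_pops)
    paths = {
        "records": out / "courtship_vs_genetic.csv",
        "fit": out / "courtship_vs_genetic_fit.json",
    }
    records.to_csv(paths["records"], index=False)
    Path(paths["fit"]).write_text(json.dumps(fit, indent=2))
    log.info("divergence link: R^2=%.3f over %d population pairs",
             fit["r_squared"], fit["n_pop_pairs"])
    return {"records": records, "fit": fit, "paths": paths}


def run_pipeline(config: SimulationConfig, out_dir, n_boot=1000, amova_perm=999,
                 edge_perm=1000, mantel_perm=10000) -> dict:
    """Full synthetic pipeline: simulate -> filter -> popgen -> ethogram ->
    transitions -> divergence -> report; writes a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out, config.seed, _config_hash(config))
    seeds = np.random.SeedSequence([int(config.seed), 99]).spawn(3)
    ethogram = _ethogram_for(config)

    sim = stage_simulate(config, out / "data")
    manifest.record("simulate", {"n_events": len(sim["events"])},
                    list(sim["paths"].values()))

    filt = stage_filter(sim["panel"], out / "popgen")
    manifest.record("filter", filt["report"], list(filt["paths"].values()))

    pg = stage_popgen(filt["panel"], out / "popgen", n_boot=n_boot,
                      n_perm=amova_perm, mantel_perm=mantel_perm, seed=seeds[0])
    manifest.record("popgen", {"phi_st": pg["amova"]["phi"]["phi_st"]},
                    list(pg["paths"].values()))

    events = sim["events"]
    populations = events.groupby("pair_id")["population"].first()
    eth = stage_ethogram(events, populations, out / "courtship", ethogram)
    manifest.record("ethogram", {"n_pairs": int(events["pair_id"].nunique())},
                    list(eth["paths"].values()))

    tr = stage_transitions(events, populations, out / "courtship", ethogram,
                           n_perm=edge_perm, seed=seeds[1])
    manifest.record("transitions", {"n_states": len(tr["states"])},
                    list(tr["paths"].values()))

    kos_D, _kos_means = kosman_distance(filt["panel"])
    div = stage_divergence(tr["distances"], populations, kos_D,
                           filt["panel"].populations, out / "courtship")
    manifest.record("divergence", div["fit"], list(div["paths"].values()))

    report = _assemble_report(pg, eth, tr, div, out / "report")
    manifest.record("report", {}, list(report.values()))
    manifest_path = manifest.write()
    return {"simulate": sim, "filter": filt, "popgen": pg, "ethogram": eth,
            "transitions": tr, "divergence": div, "manifest": manifest_path,
            "report": report}


def _assemble_report(pg, eth, tr, div, out_dir) -> dict:
    """Desk-scale analogues of the study's summary tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["table1_like"] = out / "population_genetics_table.csv"
    pg["summary"].to_csv(paths["table1_like"])
    paths["occurrence_like"] = out / "behavior_occurrence_table.csv"
    eth["occurrence"].to_csv(paths["occurrence_like"])
    paths["metric_table"] = out / "courtship_metric_table.csv"
    eth["metrics"].to_csv(paths["metric_table"])
    paths["divergence_like"] = out / "courtship_vs_genetic_table.csv"
    div["records"].to_csv(paths["divergence_like"], index=False)
    return paths
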