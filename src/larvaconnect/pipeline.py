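"""End-to-end orchestration of the toy scenario from a single config.

The pipeline wires the stages together exactly as the desk-scale study
design prescribes: synthetic flow -> scheduled releases and tracking ->
settlement connectivity (optionally accumulated over weekly restarts) ->
walktrap communities; in parallel, genotypes are simulated with one
ancestral cluster per dispersal community (dispersal structure drives the
genetic structure), filtered, imputed, and clustered; finally the two
partitions are compared.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .connectivity import cumulative_network, density_map, settlement_connectivity, source_sink_classify
from .domain import CoastlineSpec, Fjord, build_domain
from .flow import FlowConfig, generate_flow
from .genotypes import PopGenSimConfig, simulate_genotypes
from .netcompare import (
    build_graph,
    partition_agreement,
    site_partition_from_individuals,
    walktrap_communities,
)
from .popgen import FilterConfig, admixture_em, filter_loci, impute_missing, pairwise_fst
from .tracking import Site, SimulationConfig, run_simulation

DAY = np.timedelta64(1, "D")

__all__ = ["weekly_starts", "load_config", "default_toy_config", "run_all"]


def weekly_starts(year: int, n_weeks: int = 14) -> list[np.datetime64]:
    """Weekly simulation start dates: 1 February plus 7-day steps (the
    spawning-season restart schedule; 14 starts end on 2 or 3 May)."""
    first = np.datetime64(f"{year}-02-01", "s")
    return [first + k * 7 * DAY for k in range(n_weeks)]


def default_toy_config() -> dict:
    """A self-contained desk-scale "two bay" scenario: a coastal strip with
    two fjords far apart, two farm sites inside each, tidal + diffusive
    transport that keeps larvae within their bay, and a matching synthetic
    SNP panel whose ancestral clusters follow the dispersal communities."""
    return {
        "seed": 0,
        "domain": {
            "bounds": [-6.0, -5.0, 56.0, 57.2],
            "cell_size": 0.02,
            "coast_lon": -5.5,
            "fjords": [
                [-5.5, -5.3, 56.2, 56.3],
                [-5.5, -5.3, 56.9, 57.0],
            ],
        },
        "flow": {
            "mean_current_speed": 0.0,
            "tidal_amplitude": 0.15,
            "noise_speed": 0.02,
            "diffusivity_D": 5.0,
            "seed": 1,
        },
        "sites": [
            {"id": "Bay1_west", "lon": -5.46, "lat": 56.25, "kind": "farm"},
            {"id": "Bay1_east", "lon": -5.41, "lat": 56.25, "kind": "farm"},
            {"id": "Bay2_west", "lon": -5.46, "lat": 56.95, "kind": "farm"},
            {"id": "Bay2_east", "lon": -5.41, "lat": 56.95, "kind": "farm"},
        ],
        "sim": {
            "release_rate": 2,
            "release_days": 1.0,
            "total_days": 4.0,
            "settle_window_days": 2.0,
            "settle_radius_m": 2000.0,
            "dt_s": 360.0,
            "seed": 2,
        },
        "starts": ["2021-02-01"],
        "genetics": {
            "n_per_pop": 30,
            "n_loci": 300,
            "target_fst": 0.2,
            "missing_rate": 0.05,
            "n_boot": 200,
            "K": None,
            "seed": 3,
        },
    }


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _build_domain(cfg: dict):
    d = cfg["domain"]
    fjords = tuple(Fjord(*f) for f in d.get("fjords", []))
    spec = CoastlineSpec(coast_lon=d.get("coast_lon"), fjords=fjords)
    return build_domain(tuple(d["bounds"]), d["cell_size"], spec)


def run_all(config: dict, outdir, progress=lambda msg: None) -> dict:
    """Execute every stage; write all artefacts plus per-stage manifests
    into ``outdir``; return a summary dict of headline quantities."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))

    # --- physics -----------------------------------------------------
    domain = _build_domain(config)
    sites = [Site(**s) for s in config["sites"]]
    sim_cfg = SimulationConfig(**config.get("sim", {}))
    starts = [np.datetime64(s, "s") for s in config.get("starts", ["2021-02-01"])]
    flow_cfg = FlowConfig(**config.get("flow", {}))

    t0 = min(starts)
    t1 = max(starts) + np.timedelta64(int(sim_cfg.total_days * 86400), "s")
    progress("generating flow field")
    with lio.StageTimer("make-flow", config.get("flow", {}), {"seed": flow_cfg.seed}) as man:
        flow = generate_flow(domain, flow_cfg, t0, t1)
        lio.write_flowfield(flow, outdir / "flow.nc")
        man.outputs = ["flow.nc"]
    man.write(outdir / "manifest_make-flow.json")

    lio.write_sites(sites, outdir / "sites.csv")

    matrices = []
    traj = None
    for k, start in enumerate(starts):
        progress(f"tracking window {k + 1}/{len(starts)}")
        with lio.StageTimer("track", {"start": str(start)}, {"seed": sim_cfg.seed}) as man:
            traj = run_simulation(sites, flow, sim_cfg, sim_start=start)
            name = f"trajectories_w{k}.parquet"
            lio.write_trajectories(traj, outdir / name)
            man.outputs = [name]
        man.write(outdir / f"manifest_track_w{k}.json")
        matrices.append(settlement_connectivity(traj, sites, sim_cfg))

    progress("connectivity")
    C = cumulative_network(matrices)
    lio.write_connectivity(C, outdir / "connectivity.csv")
    lio.write_network_geojson(C, sites, outdir / "network.geojson")
    roles = source_sink_classify(C)
    roles.to_csv(outdir / "site_roles.csv")
    dens = density_map(
        traj, domain,
        (traj.sim_end - np.timedelta64(int(sim_cfg.settle_window_days * 86400), "s"), traj.sim_end),
    )
    lio.write_density(dens, outdir / "density.nc")

    graph = build_graph(C)
    dispersal_part = walktrap_communities(graph)
    lio.write_partition(dispersal_part, outdir / "dispersal_communities.csv")

    # --- genetics: dispersal communities define the ancestral clusters ---
    progress("genetics")
    gen = dict(config.get("genetics", {}))
    n_boot = int(gen.pop("n_boot", 200))
    K_fixed = gen.pop("K", None)
    gen_seed = int(gen.pop("seed", master_seed + 17))
    site_comm = dict(zip(dispersal_part.nodes, dispersal_part.labels))
    n_clusters = dispersal_part.n_communities
    n_sites = len(sites)
    n_per = int(gen.pop("n_per_pop", 30))
    Q_truth = np.zeros((n_sites * n_per, n_clusters))
    for i, s in enumerate(sites):
        Q_truth[i * n_per:(i + 1) * n_per, site_comm[s.id]] = 1.0
    sim_gen_cfg = PopGenSimConfig(
        n_pops=n_sites, n_per_pop=n_per, admixture_Q=Q_truth, seed=gen_seed, **gen
    )
    with lio.StageTimer("simulate-genotypes", {"n_clusters": n_clusters}, {"seed": gen_seed}) as man:
        G = simulate_genotypes(sim_gen_cfg)
        # relabel synthetic pops with the real site ids
        G.samples["site"] = np.repeat([s.id for s in sites], n_per)
        lio.write_vcf(G, outdir / "genotypes.vcf")
        lio.write_sample_metadata(G, outdir / "samples.csv")
        man.outputs = ["genotypes.vcf", "samples.csv"]
    man.write(outdir / "manifest_simulate-genotypes.json")

    G_filt, audit = filter_loci(G, FilterConfig())
    audit.to_csv(outdir / "filter_audit.csv")
    G_imp, _ = impute_missing(G_filt, seed=gen_seed + 1)

    fst = pairwise_fst(G_imp, n_boot=n_boot, seed=gen_seed + 2)
    lio.write_fst(fst, outdir / "fst_matrix.csv", outdir / "fst_pairs.csv")

    K_use = int(K_fixed) if K_fixed else n_clusters
    adm = admixture_em(G_imp, K_use, seed=gen_seed + 3, n_restarts=3)
    lio.write_q_matrix(adm, outdir / "admixture_Q.csv")
    genetic_part = site_partition_from_individuals(
        adm.argmax_labels(), G_imp.samples["site"], [s.id for s in sites]
    )
    lio.write_partition(genetic_part, outdir / "genetic_site_clusters.csv")

    progress("comparison")
    agree = partition_agreement(dispersal_part, genetic_part)
    agree.contingency.to_csv(outdir / "partition_contingency.csv")

    summary = {
        "n_particles": int(traj.n_particles) * len(starts),
        "n_settlement_links": int((C.counts > 0).sum()),
        "n_dispersal_communities": int(dispersal_part.n_communities),
        "n_loci_kept": int(G_filt.n_loci),
        "mean_pairwise_fst": float(np.mean(fst.fst.to_numpy()[np.triu_indices(len(fst.sites), 1)])),
        "admixture_K": K_use,
        "dispersal_vs_genetic_ari": agree.ari,
        "dispersal_vs_genetic_nmi": agree.nmi,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
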