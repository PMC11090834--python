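"""End-to-end orchestration: simulate -> network -> space -> similarity ->
dyadic fit -> genus importance, with a reproducible manifest.

Stage outputs are pure functions of (inputs, config, seed): per-stage
seeds are derived from a single master seed, and the manifest records a
hash of the canonical config together with every produced artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import time
import pandas as pd
import yaml

from . import dyadic, importance as importance_mod, network, similarity, space, synthetic

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

DEFAULT_CONFIG = {
    "seed": 0,
    "world": {},                 # WorldConfig overrides
    "bandwidth": 15.0,
    "min_detections": 10,
    "metric": "jaccard",
    "mcmc": {"chains": 2, "warmup": 300, "draws": 700},
    "run_importance": False,
    "importance_genera": None,
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    with open(path) as fh:
        cfg.update(yaml.safe_load(fh) or {})
    return cfg


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def run_all(config: dict, outdir) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config_hash(cfg), "seed": cfg["seed"],
                "version": __version__, "stages": []}

    def record(stage, t0, **outputs):
        entry = {"stage": stage, "elapsed_s": round(time.time() - t0, 2)}
        entry.update(outputs)
        manifest["stages"].append(entry)
        logger.info("stage %s done in %.1fs", stage, entry["elapsed_s"])

    # simulate -----------------------------------------------------------
    t0 = time.time()
    world_cfg = synthetic.WorldConfig(
        **{**cfg["world"], "seed": _stage_seed(cfg["seed"], "simulate")})
    world = synthetic.simulate_world(world_cfg)
    detections = synthetic.simulate_detections(world)
    counts, meta = synthetic.simulate_microbiota(
        world, world.true_association, world.true_overlap)
    synthetic.write_world(world, detections, counts, meta, out / "inputs")
    record("simulate", t0, outputs=str(out / "inputs"),
           n_detections=len(detections), n_samples=len(meta))

    # network ------------------------------------------------------------
    t0 = time.time()
    filtered = network.filter_detections(detections)
    net = network.build_network(filtered)
    net_path = out / "network.csv"
    net.to_long_dataframe().to_csv(net_path, index=False)
    record("network", t0, outputs=str(net_path), n_edges=int((net.sri > 0).sum() // 2))

    # space --------------------------------------------------------------
    t0 = time.time()
    grid = space.GridSpec(shape=(world_cfg.grid_side, world_cfg.grid_side),
                          cell_size=world_cfg.cell_size)
    uds, excluded = space.estimate_all_uds(
        filtered, grid, cfg["bandwidth"], world.loggers,
        min_detections=cfg["min_detections"])
    ovl_ids, ovl = space.overlap_matrix(uds)
    profiles = {}
    survey = world.habitat_survey()
    for mid, ud in uds.items():
        profiles[mid] = space.habitat_profile(space.core_range(ud), survey)
    hab_ids, hab = space.habitat_similarity_matrix(profiles)
    ovl_path = out / "overlap.csv"
    pd.DataFrame(ovl, index=ovl_ids, columns=ovl_ids).to_csv(ovl_path)
    hab_path = out / "habitat_similarity.csv"
    pd.DataFrame(hab, index=hab_ids, columns=hab_ids).to_csv(hab_path)
    record("space", t0, outputs=f"{ovl_path},{hab_path}",
           n_individuals=len(uds), n_excluded=len(excluded))

    # similarity ---------------------------------------------------------
    t0 = time.time()
    if cfg["metric"] == "bray":
        sim = similarity.bray_curtis_matrix(counts)
    elif cfg["metric"] == "count":
        sim = similarity.shared_count_matrix(counts)
    else:
        sim = similarity.jaccard_matrix(counts)
    sim_path = out / "similarity.csv"
    sim.to_long_dataframe().to_csv(sim_path, index=False)
    record("similarity", t0, outputs=str(sim_path), n_pairs=len(sim.ids) ** 2)

    # dyadic fit ---------------------------------------------------------
    t0 = time.time()
    spec = dyadic.ModelSpec(
        likelihood="poisson" if cfg["metric"] == "count" else "beta",
        mcmc=dyadic.SamplerConfig(**cfg["mcmc"]),
        seed=_stage_seed(cfg["seed"], "fit"))
    dyads = dyadic.build_dyads(meta, sim, net, (ovl_ids, ovl), (hab_ids, hab))
    if not len(dyads):
        raise RuntimeError("stage fit: no dyads could be built")
    dyads_path = out / "dyads.csv"
    dyads.to_csv(dyads_path, index=False)
    fit = dyadic.fit(dyads, spec)
    fit_path = out / "posterior_summary.csv"
    fit.summary.to_csv(fit_path)
    record("fit", t0, outputs=f"{dyads_path},{fit_path}", n_dyads=len(dyads),
           converged=bool(fit.converged))

    # importance (optional) ----------------------------------------------
    if cfg["run_importance"]:
        t0 = time.time()
        ctx = importance_mod.DyadContext(
            counts=counts, genus_map=world.asv_table["genus"], metadata=meta,
            sri=net, overlap=(ovl_ids, ovl), habitat=(hab_ids, hab), spec=spec)
        records, _ = importance_mod.compute_importance(
            ctx, genera=cfg["importance_genera"])
        records = importance_mod.scale_importance(records)
        imp_path = out / "importance.csv"
        records.to_csv(imp_path, index=False)
        record("importance", t0, outputs=str(imp_path), n_records=len(records))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
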