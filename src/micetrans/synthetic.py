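"""Seeded synthetic world: mice, loggers, habitat and route-labelled microbiotas.

The generator produces a population of mice with home-range centres on a
grid of RFID loggers, a smoothed ground-cover raster, nightly detection
streams (including scripted same-logger co-visits for socially tied
pairs), and per-sample ASV count tables in which colonization
probability rises with social association to a seed mouse (social
route), with home-range overlap (spatial route), and is modulated by
habitat for a configurable fraction of ASVs:

    P(mouse i carries ASV a) = 1 - (1 - p0_i) * exp(-beta * driver(i, seed_a))

Phenotypes determine routes: strictly anaerobic non-spore-formers
transmit socially, aerotolerant spore-formers spatially, mixed
phenotypes are assigned a route at random. All randomness flows from one
master seed through named sub-streams, so e.g. changing microbiota
parameters does not perturb the detection stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

COVER_TYPES = ["open_ground", "dogs_mercury", "bluebell", "bramble", "grass",
               "sedge", "nightshade", "wild_garlic", "currant"]

_STREAMS = ("roster", "loggers", "habitat", "asv", "ties", "detections", "microbiota")


@dataclass
class WorldConfig:
    n_mice: int = 40
    grid_side: int = 16
    n_loggers: int = 60
    n_nights: int = 120
    n_asv: int = 300
    n_genera: int = 30
    route_effects: dict = field(default_factory=lambda: {
        "social": 4.0, "spatial": 4.0, "habitat": 1.0})
    baseline_prevalence: float = 0.05
    detection_rate: float = 8.0
    turnover: float = 0.9
    samples_per_mouse: int = 2
    habitat_fraction: float = 0.25
    #: optional list of (aerotolerant, spore_forming) cells cycled across
    #: genera instead of random phenotype draws (for controlled designs)
    phenotype_cells: list = None
    tie_prob: float = 0.12
    joint_visit_rate: float = 3.0
    full_span_fraction: float = 0.7
    cell_size: float = 10.0
    start_date: str = "2019-02-01"
    seed: int = 0

    def __post_init__(self):
        for name in ("baseline_prevalence", "turnover", "habitat_fraction",
                     "tie_prob", "full_span_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_mice", "grid_side", "n_loggers", "n_nights", "n_asv",
                     "n_genera", "samples_per_mouse"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for route, beta in self.route_effects.items():
            if beta < 0:
                raise ValueError(f"route effect {route} must be >= 0")

    @property
    def extent(self) -> float:
        return self.grid_side * self.cell_size


@dataclass
class SyntheticWorld:
    config: WorldConfig
    roster: pd.DataFrame        # id-indexed: sex, age_class, first/last night, centre, scale
    loggers: pd.DataFrame       # id-indexed: x, y
    habitat: np.ndarray         # (grid, grid, n_cover), rows sum to 1
    asv_table: pd.DataFrame     # id-indexed: genus, phenotypes, route, seed_mouse, ...
    true_association: tuple     # (ids, matrix)
    true_overlap: tuple         # (ids, matrix)
    seeds: dict = field(repr=False, default_factory=dict)

    @property
    def mouse_ids(self):
        return list(self.roster.index)

    def genus_phenotypes(self) -> pd.DataFrame:
        """Genus-level phenotype table (aerotolerant, spore_forming, known)."""
        tab = (self.asv_table.groupby("genus")[["aerotolerant", "spore_forming"]]
               .first().astype(int))
        tab["known"] = True
        return tab

    def habitat_survey(self) -> pd.DataFrame:
        """Long-format habitat table: cell_x, cell_y, cover_type, percent."""
        rows = []
        g = self.config.grid_side
        for r in range(g):
            for c in range(g):
                for k, cover in enumerate(COVER_TYPES):
                    rows.append({"cell_x": c, "cell_y": r, "cover_type": cover,
                                 "percent": 100.0 * self.habitat[r, c, k]})
        return pd.DataFrame(rows)


def _streams(seed):
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return dict(zip(_STREAMS, children))


def simulate_world(config: WorldConfig) -> SyntheticWorld:
    """Build the deterministic synthetic world for a config."""
    if config.n_genera > config.n_asv:
        raise ValueError(f"n_genera ({config.n_genera}) > n_asv ({config.n_asv})")
    seeds = _streams(config.seed)

    # roster -------------------------------------------------------------
    rng = np.random.default_rng(seeds["roster"])
    n = config.n_mice
    ids = [f"M{k:03d}" for k in range(n)]
    sex = rng.choice(["F", "M"], size=n)
    age = rng.choice(["adult", "juvenile"], size=n, p=[0.7, 0.3])
    centre = rng.uniform(0, config.extent, size=(n, 2))
    scale = config.cell_size * rng.uniform(1.0, 2.5, size=n)
    full = rng.random(n) < config.full_span_fraction
    first = np.zeros(n, dtype=int)
    last = np.full(n, config.n_nights - 1, dtype=int)
    for i in np.flatnonzero(~full):
        span = int(rng.integers(max(1, config.n_nights // 3), config.n_nights))
        start = int(rng.integers(0, config.n_nights - span + 1))
        first[i], last[i] = start, start + span - 1
    roster = pd.DataFrame({
        "sex": sex, "age_class": age, "first_night": first, "last_night": last,
        "centre_x": centre[:, 0], "centre_y": centre[:, 1], "range_scale": scale,
    }, index=pd.Index(ids, name="individual"))

    # loggers ------------------------------------------------------------
    rng = np.random.default_rng(seeds["loggers"])
    n_cells = config.grid_side ** 2
    cells = rng.choice(n_cells, size=min(config.n_loggers, n_cells), replace=False)
    rows, cols = np.divmod(cells, config.grid_side)
    loggers = pd.DataFrame({
        "x": (cols + 0.5) * config.cell_size,
        "y": (rows + 0.5) * config.cell_size,
    }, index=pd.Index([f"L{k:03d}" for k in range(len(cells))], name="logger"))

    # habitat raster: smoothed Dirichlet fields --------------------------
    rng = np.random.default_rng(seeds["habitat"])
    raw = rng.dirichlet(np.full(len(COVER_TYPES), 0.5),
                        size=(config.grid_side, config.grid_side))
    smooth = np.stack([gaussian_filter(raw[:, :, k], sigma=1.5)
                       for k in range(len(COVER_TYPES))], axis=-1)
    habitat = smooth / smooth.sum(axis=-1, keepdims=True)

    # ASVs: genus structure, phenotypes, routes --------------------------
    rng = np.random.default_rng(seeds["asv"])
    genera = [f"g{k:03d}" for k in range(config.n_genera)]
    if config.phenotype_cells:
        cells = [config.phenotype_cells[k % len(config.phenotype_cells)]
                 for k in range(config.n_genera)]
        aero = np.array([c[0] for c in cells])
        spore = np.array([c[1] for c in cells])
    else:
        aero = rng.integers(0, 2, size=config.n_genera)
        spore = rng.integers(0, 2, size=config.n_genera)
    # every genus gets at least one ASV
    assignment = np.concatenate([
        rng.permutation(config.n_genera),
        rng.integers(0, config.n_genera, size=config.n_asv - config.n_genera)])
    routes = []
    for gi in assignment:
        if aero[gi] == 0 and spore[gi] == 0:
            routes.append("social")
        elif aero[gi] == 1 and spore[gi] == 1:
            routes.append("spatial")
        else:
            routes.append(rng.choice(["social", "spatial"]))
    asv_table = pd.DataFrame({
        "genus": [genera[gi] for gi in assignment],
        "aerotolerant": aero[assignment],
        "spore_forming": spore[assignment],
        "route": routes,
        "seed_mouse": rng.choice(ids, size=config.n_asv),
        "habitat_filtered": rng.random(config.n_asv) < config.habitat_fraction,
        "preferred_cover": rng.choice(COVER_TYPES, size=config.n_asv),
    }, index=pd.Index([f"asv{k:04d}" for k in range(config.n_asv)], name="asv"))

    # ground-truth matrices ----------------------------------------------
    rng = np.random.default_rng(seeds["ties"])
    assoc = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < config.tie_prob:
                assoc[i, j] = assoc[j, i] = rng.beta(2.0, 4.0)
    d2 = ((centre[:, None, :] - centre[None, :, :]) ** 2).sum(-1)
    s2 = scale ** 2
    ssum = s2[:, None] + s2[None, :]
    overlap = (2 * np.outer(scale, scale) / ssum) * np.exp(-d2 / (4 * ssum))
    np.fill_diagonal(overlap, 1.0)

    return SyntheticWorld(config=config, roster=roster, loggers=loggers,
                          habitat=habitat, asv_table=asv_table,
                          true_association=(ids, assoc),
                          true_overlap=(ids, overlap), seeds=seeds)


def _night_times(rng, night_date, size):
    """Timestamps uniform on [16:00, 08:00) of the given night."""
    offs = rng.uniform(0, 16 * 3600, size=size)
    base = pd.Timestamp(night_date) + pd.Timedelta(hours=16)
    return [base + pd.Timedelta(seconds=float(s)) for s in offs]


def simulate_detections(world: SyntheticWorld) -> pd.DataFrame:
    """Nightly Poisson logger visits plus tie-driven same-logger co-visits."""
    cfg = world.config
    rng = np.random.default_rng(world.seeds["detections"])
    start = pd.Timestamp(cfg.start_date)
    lx = world.loggers["x"].to_numpy()
    ly = world.loggers["y"].to_numpy()
    logger_ids = np.array(world.loggers.index)
    recs = []
    if cfg.detection_rate > 0:
        roster = world.roster
        kernels = {}
        for mid, row in roster.iterrows():
            d2 = (lx - row["centre_x"]) ** 2 + (ly - row["centre_y"]) ** 2
            w = np.exp(-0.5 * d2 / row["range_scale"] ** 2)
            kernels[mid] = w / w.sum()
        ids, assoc = world.true_association
        for night in range(cfg.n_nights):
            date = (start + pd.Timedelta(days=night)).date()
            alive = roster[(roster["first_night"] <= night)
                           & (roster["last_night"] >= night)]
            for mid in alive.index:
                k = rng.poisson(cfg.detection_rate)
                if k == 0:
                    continue
                picks = rng.choice(len(logger_ids), size=k, p=kernels[mid])
                for lg, t in zip(logger_ids[picks], _night_times(rng, date, k)):
                    recs.append((mid, lg, t))
            # scripted co-visits for socially tied pairs
            alive_ids = [m for m in alive.index]
            for ai, ma in enumerate(alive_ids):
                ia = ids.index(ma)
                for mb in alive_ids[ai + 1:]:
                    tau = assoc[ia, ids.index(mb)]
                    if tau <= 0:
                        continue
                    k = rng.poisson(cfg.joint_visit_rate * tau)
                    if k == 0:
                        continue
                    joint = kernels[ma] * kernels[mb]
                    if joint.sum() <= 0:
                        continue
                    joint = joint / joint.sum()
                    picks = rng.choice(len(logger_ids), size=k, p=joint)
                    for lg, t in zip(logger_ids[picks], _night_times(rng, date, k)):
                        recs.append((ma, lg, t))
                        recs.append((mb, lg, t + pd.Timedelta(
                            seconds=float(rng.uniform(30, 600)))))
    df = pd.DataFrame(recs, columns=["individual", "logger", "timestamp"])
    return df.sort_values(["timestamp", "individual"],
                          kind="stable").reset_index(drop=True)


def _habitat_multiplier(world: SyntheticWorld) -> pd.DataFrame:
    """Per (mouse, cover type) share of cover at the mouse's centre cell,
    rescaled to mean 1 across mice."""
    cfg = world.config
    rowc = np.clip((world.roster["centre_y"] // cfg.cell_size).astype(int),
                   0, cfg.grid_side - 1)
    colc = np.clip((world.roster["centre_x"] // cfg.cell_size).astype(int),
                   0, cfg.grid_side - 1)
    shares = world.habitat[rowc, colc, :]  # (n_mice, n_cover)
    mult = shares / np.maximum(shares.mean(axis=0, keepdims=True), 1e-12)
    return pd.DataFrame(mult, index=world.roster.index, columns=COVER_TYPES)


def carriage_probabilities(world: SyntheticWorld, association, overlap) -> pd.DataFrame:
    """P(mouse carries ASV) matrix (mice x ASVs) under the colonization model."""
    cfg = world.config
    ids_a, assoc_m = association
    ids_o, ovl_m = overlap
    a_idx = {m: i for i, m in enumerate(ids_a)}
    o_idx = {m: i for i, m in enumerate(ids_o)}
    mice = world.mouse_ids
    for m in mice:
        if m not in a_idx or m not in o_idx:
            raise ValueError(f"mouse {m} missing from driver matrices")
    beta = cfg.route_effects
    mult = _habitat_multiplier(world)
    n_m, n_a = len(mice), len(world.asv_table)
    P = np.empty((n_m, n_a))
    for ai, (asv, row) in enumerate(world.asv_table.iterrows()):
        p0 = np.full(n_m, cfg.baseline_prevalence)
        if row["habitat_filtered"]:
            # beta_hab = 0 switches habitat filtering off; 1 = proportional
            m = mult[row["preferred_cover"]].to_numpy()
            p0 = np.clip(p0 * m ** beta.get("habitat", 1.0), 0.0, 1.0)
        seed = row["seed_mouse"]
        if row["route"] == "social":
            drv = np.array([assoc_m[a_idx[m], a_idx[seed]] for m in mice])
            b = beta.get("social", 0.0)
        else:
            drv = np.array([ovl_m[o_idx[m], o_idx[seed]] for m in mice])
            b = beta.get("spatial", 0.0)
        p = 1 - (1 - p0) * np.exp(-b * drv)
        p[mice.index(seed)] = 1.0
        P[:, ai] = p
    return pd.DataFrame(P, index=mice, columns=world.asv_table.index)


def simulate_microbiota(world: SyntheticWorld, association, overlap):
    """Sample per-occasion presence and sequencing counts.

    Returns (counts, metadata): an integer samples x ASV table and
    sample metadata (individual, date, sex, age class, plate, extraction
    position, read depth).
    """
    cfg = world.config
    rng = np.random.default_rng(world.seeds["microbiota"])
    P = carriage_probabilities(world, association, overlap)
    start = pd.Timestamp(cfg.start_date)
    n_asv = len(world.asv_table)
    sample_rows = []
    count_rows = []
    for mid, mrow in world.roster.iterrows():
        p = P.loc[mid].to_numpy()
        nights = np.linspace(mrow["first_night"], mrow["last_night"],
                             cfg.samples_per_mouse).round().astype(int)
        present = rng.random(n_asv) < p
        for k, night in enumerate(nights):
            if k > 0:
                keep = rng.random(n_asv) < cfg.turnover
                gain = rng.random(n_asv) < cfg.baseline_prevalence
                present = (present & keep) | (~present & gain)
            weights = np.zeros(n_asv)
            npres = int(present.sum())
            if npres:
                weights[present] = rng.lognormal(0.0, 1.0, size=npres)
                props = weights / weights.sum()
            else:
                props = weights
            depth = int(np.round(rng.lognormal(np.log(2e4), 0.4)))
            counts = (rng.multinomial(depth, props) if npres
                      else np.zeros(n_asv, dtype=int))
            sid = f"{mid}_s{k}"
            sample_rows.append({
                "sample": sid, "individual": mid,
                "date": (start + pd.Timedelta(days=int(night))).date().isoformat(),
                "sex": mrow["sex"], "age_class": mrow["age_class"],
                "read_depth": int(counts.sum()),
            })
            count_rows.append(counts)
    counts = pd.DataFrame(np.array(count_rows),
                          index=[r["sample"] for r in sample_rows],
                          columns=world.asv_table.index)
    counts.index.name = "sample"
    meta = pd.DataFrame(sample_rows).set_index("sample")
    order = np.arange(len(meta))
    meta["plate"] = order // 48 + 1
    meta["extraction_row"] = order % 8
    meta["extraction_col"] = (order // 8) % 6
    return counts, meta


def true_habitat_similarity(world: SyntheticWorld) -> tuple:
    """Ground-truth pairwise Bray-Curtis similarity of the habitat
    composition at each mouse's home-range centre cell."""
    from ._metrics import bray_curtis_similarity

    cfg = world.config
    rowc = np.clip((world.roster["centre_y"] // cfg.cell_size).astype(int),
                   0, cfg.grid_side - 1)
    colc = np.clip((world.roster["centre_x"] // cfg.cell_size).astype(int),
                   0, cfg.grid_side - 1)
    shares = world.habitat[rowc, colc, :]
    ids = world.mouse_ids
    n = len(ids)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = bray_curtis_similarity(shares[i], shares[j])
    return ids, m


def write_world(world: SyntheticWorld, detections, counts, meta, outdir):
    """Write the standard text artifacts for a simulated world."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    det = detections.rename(columns={"individual": "tag_id", "logger": "logger_id"})
    det.to_csv(out / "detections.csv", index=False)
    counts.to_csv(out / "counts.tsv", sep="\t")
    meta.to_csv(out / "sample_metadata.tsv", sep="\t")
    pheno = world.genus_phenotypes().reset_index()
    pheno.to_csv(out / "genus_phenotypes.tsv", sep="\t", index=False)
    world.habitat_survey().to_csv(out / "habitat.csv", index=False)
    world.asv_table.to_csv(out / "asv_annotations.tsv", sep="\t")
    ids, assoc = world.true_association
    truth = {
        "config": {k: v for k, v in asdict(world.config).items()},
        "mice": ids,
        "true_association": assoc.tolist(),
        "true_overlap": world.true_overlap[1].tolist(),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return out
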