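"""Synthetic study generator with known ground truth.

Emulates a shelf-to-basin plankton survey: a station grid split into a
shallow shelf and a deep basin, ten nominal sampling depths between the
surface and 1,500 m, two seasons, vertically structured environmental
gradients, and ciliate/phytoplankton communities assembled by Gaussian
niche responses to those gradients plus lognormal noise and zero
inflation.  Every stochastic choice is recorded in a :class:`GroundTruth`
so downstream inference (correlations, variation partitioning, network
edges) can be scored against what was actually simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AbundanceTable,
    EnvFrame,
    SampleFrame,
    TraitFrame,
    ENV_GROUP_MAP,
    FEEDING_HABITS,
)

DEFAULT_DEPTHS = (0, 25, 50, 75, 100, 200, 300, 500, 1000, 1500)

CILIATE_CLASSES = {
    "Oligotrichia": 0.25,
    "Choreotrichia": 0.30,
    "Prostomatea": 0.15,
    "Litostomatea": 0.12,
    "Oligohymenophorea": 0.08,
    "Euplotia": 0.04,
    "Hypotrichia": 0.03,
    "Phyllopharyngea": 0.03,
}

PHYTO_PHYLA = {
    "Bacillariophyta": 0.60,
    "Dinoflagellata": 0.25,
    "Cyanobacteria": 0.10,
    "Haptophyta": 0.05,
}


@dataclass
class EnvParam:
    """Deterministic profile of one environmental variable.

    ``mode='additive'`` variables follow ``surface + depth_coef * (z/1500)**depth_power``
    with additive seasonal offset, coastal term and Gaussian noise.
    ``mode='log'`` (food) variables follow ``surface * exp(-z/decay_scale)``
    with the seasonal offset, coastal term and noise applied on the log scale,
    which keeps them positive and right-skewed.
    """

    surface: float
    depth_coef: float = 0.0
    depth_power: float = 1.0
    mode: str = "additive"
    decay_scale: float = 120.0
    seasonal_offset: float = 0.0  # added in summer
    coast_coef: float = 0.0      # multiplies a [0, 1] coastal index
    noise_sd: float = 0.0


def default_env_params() -> dict[str, EnvParam]:
    """Defaults shaped after the observed gradients: temperature, dissolved
    oxygen and pH fall with depth, inorganic nutrients rise, and the food
    variables (size-fractionated chlorophyll, picoplankton) decay below the
    euphotic zone and are enriched toward the coast."""
    return {
        "Tem": EnvParam(28.0, -22.0, 0.4, seasonal_offset=3.0, noise_sd=0.4),
        "Sal": EnvParam(33.2, 1.3, 0.5, coast_coef=0.3, noise_sd=0.08),
        "pH": EnvParam(8.15, -0.45, 0.7, noise_sd=0.02),
        "DO": EnvParam(7.0, -3.8, 0.5, seasonal_offset=-0.2, noise_sd=0.15),
        "Nox": EnvParam(0.3, 36.0, 0.8, noise_sd=0.5),
        "SRP": EnvParam(0.04, 2.5, 0.9, noise_sd=0.04),
        "Si": EnvParam(2.0, 120.0, 0.85, noise_sd=2.0),
        "MChla": EnvParam(0.30, mode="log", coast_coef=0.8,
                          seasonal_offset=0.15, noise_sd=0.40),
        "NChla": EnvParam(0.50, mode="log", coast_coef=0.5, noise_sd=0.40),
        "PChla": EnvParam(0.40, mode="log", coast_coef=0.3,
                          seasonal_offset=-0.10, noise_sd=0.40),
        "Syn": EnvParam(5e3, mode="log", coast_coef=0.6,
                        seasonal_offset=0.2, noise_sd=0.50),
        "Peuk": EnvParam(2e3, mode="log", coast_coef=0.4, noise_sd=0.50),
        "Pro": EnvParam(8e3, mode="log", coast_coef=-0.6, noise_sd=0.50),
    }


@dataclass
class SimConfig:
    """Configuration of the synthetic survey.

    Defaults mirror the study layout: 31 stations (12 shelf, 19 basin)
    sampled at the ten nominal depths in two seasons, yielding roughly 170
    samples per season once infeasible (station, depth) pairs are dropped.
    """

    n_stations_shelf: int = 12
    n_stations_basin: int = 19
    depth_levels: tuple = DEFAULT_DEPTHS
    seasons: tuple = ("summer", "winter")
    lon_range: tuple = (113.0, 122.0)
    lat_range: tuple = (18.0, 24.5)
    shelf_bottom_range: tuple = (50.0, 180.0)
    basin_bottom_range: tuple = (300.0, 1500.0)

    n_taxa: int = 80
    driver_fractions: dict = field(default_factory=lambda: {
        "env": 0.50, "season": 0.20, "space": 0.10, "none": 0.20})
    noise_sd: float = 0.6           # lognormal noise on log abundance
    zero_inflation_prob: float = 0.25
    season_effect_range: tuple = (1.0, 2.0)   # log-scale multiplier bounds
    log_max_mean: float = np.log(200.0)       # cells/L at the niche optimum
    log_max_sd: float = 0.8
    tolerance_range: tuple = (0.6, 1.6)       # niche breadth, z-score units
    optimum_range: tuple = (-1.8, 1.8)        # niche optimum, z-score units

    n_phyto: int = 40
    n_coupled: int = 10
    coupling: float = 0.8

    env_params: dict = field(default_factory=default_env_params)
    env_noise_scale: float = 1.0
    seed: int = 0


@dataclass
class GroundTruth:
    """What was actually simulated, recorded before noise."""

    taxon_params: pd.DataFrame          # driver type/variable, optimum, tolerance...
    env_effects: pd.DataFrame           # per-variable depth sign and seasonal offset
    coupled_pairs: list                 # (ciliate, phytoplankton) tuples
    expected_log: pd.DataFrame | None = None  # noise-free log expectation

    def to_json(self, path) -> None:
        payload = {
            "taxon_params": self.taxon_params.reset_index().to_dict(orient="records"),
            "env_effects": self.env_effects.reset_index().to_dict(orient="records"),
            "coupled_pairs": [list(p) for p in self.coupled_pairs],
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    # independent stream per stage so stages stay reproducible in isolation
    return np.random.default_rng([int(cfg.seed) % (2**31), stage])


def generate_design(cfg: SimConfig) -> SampleFrame:
    """Station grid and the feasible (station, season, depth) samples.

    Shelf stations occupy the western/coastal side of a rectangular grid
    with bottom depths below 200 m; basin stations get deep bottoms.  Each
    station is sampled at every nominal depth not exceeding its bottom
    depth, in every season.
    """
    if len(cfg.depth_levels) == 0:
        raise ValueError("depth level list must not be empty")
    if cfg.n_stations_shelf < 0 or cfg.n_stations_basin < 0:
        raise ValueError("station counts must be non-negative")
    n = cfg.n_stations_shelf + cfg.n_stations_basin
    if n < 1:
        raise ValueError("need at least one station")
    rng = _rng(cfg, 1)
    # near-rectangular grid over the domain, jittered to avoid exact ties
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    lon = np.linspace(*cfg.lon_range, ncols)
    lat = np.linspace(*cfg.lat_range, nrows)
    gl, gt = np.meshgrid(lon, lat)
    coords = np.column_stack([gl.ravel(), gt.ravel()])[:n]
    coords += rng.normal(0, 0.03, size=coords.shape)
    order = np.argsort(coords[:, 0], kind="stable")  # west -> east
    coords = coords[order]

    bottoms = np.empty(n)
    bottoms[:cfg.n_stations_shelf] = np.linspace(
        *cfg.shelf_bottom_range, max(cfg.n_stations_shelf, 1))[:cfg.n_stations_shelf]
    bottoms[cfg.n_stations_shelf:] = np.linspace(
        *cfg.basin_bottom_range, max(cfg.n_stations_basin, 1))[:cfg.n_stations_basin]

    rows = []
    for i in range(n):
        sid = f"S{i + 1:02d}"
        for season in cfg.seasons:
            for z in cfg.depth_levels:
                if z <= bottoms[i]:
                    rows.append({
                        "sample_id": f"{sid}_{season}_{int(z):04d}",
                        "station_id": sid,
                        "longitude": coords[i, 0],
                        "latitude": coords[i, 1],
                        "season": season,
                        "sample_depth": float(z),
                        "bottom_depth": float(bottoms[i]),
                    })
    frame = pd.DataFrame(rows).set_index("sample_id")
    return SampleFrame(frame)


def _coast_index(frame: SampleFrame) -> np.ndarray:
    """0 offshore .. 1 at the western (coastal) edge."""
    lon = frame.data["longitude"].to_numpy()
    span = lon.max() - lon.min()
    if span == 0:
        return np.zeros(len(lon))
    return (lon.max() - lon) / span


def generate_env(frame: SampleFrame, cfg: SimConfig) -> EnvFrame:
    """Environmental table with vertical gradients, coastal enrichment and
    seasonal offsets; total chlorophyll is the sum of its size fractions."""
    missing = [v for v in ENV_GROUP_MAP if v not in cfg.env_params]
    if missing:
        raise ValueError(f"env gradient params missing for: {missing}")
    rng = _rng(cfg, 2)
    z = frame.data["sample_depth"].to_numpy()
    zd = z / 1500.0
    summer = (frame.data["season"] == "summer").to_numpy().astype(float)
    coast = _coast_index(frame)

    out = {}
    for var, p in cfg.env_params.items():
        noise = rng.normal(0.0, p.noise_sd * cfg.env_noise_scale, size=len(z))
        if p.mode == "additive":
            base = p.surface + p.depth_coef * zd ** p.depth_power
            out[var] = base + p.seasonal_offset * summer + p.coast_coef * coast + noise
        elif p.mode == "log":
            logv = (np.log(p.surface) - z / p.decay_scale
                    + p.seasonal_offset * summer + p.coast_coef * coast + noise)
            out[var] = np.exp(logv)
        else:
            raise ValueError(f"unknown env mode {p.mode!r} for {var}")
    env = pd.DataFrame(out, index=frame.samples)
    env["Chla"] = env[["MChla", "NChla", "PChla"]].sum(axis=1)
    return EnvFrame(env)


def _draw_taxon_params(cfg: SimConfig, rng, taxa, env_vars) -> pd.DataFrame:
    fracs = cfg.driver_fractions
    kinds = list(fracs)
    counts = np.floor(np.array([fracs[k] for k in kinds]) * len(taxa)).astype(int)
    while counts.sum() < len(taxa):
        counts[0] += 1
    driver_type = np.repeat(kinds, counts)[: len(taxa)]
    rng.shuffle(driver_type)

    records = []
    for taxon, kind in zip(taxa, driver_type):
        rec = {
            "driver_type": kind,
            "driver_variable": "",
            "optimum": np.nan,
            "tolerance": np.nan,
            "log_max": rng.normal(cfg.log_max_mean, cfg.log_max_sd),
            "season_pref": "",
            "season_effect": np.nan,
        }
        if kind == "env":
            rec["driver_variable"] = rng.choice(env_vars)
            rec["optimum"] = rng.uniform(*cfg.optimum_range)
            rec["tolerance"] = rng.uniform(*cfg.tolerance_range)
        elif kind == "space":
            rec["driver_variable"] = rng.choice(["longitude", "latitude"])
            rec["optimum"] = rng.uniform(*cfg.optimum_range)
            rec["tolerance"] = rng.uniform(*cfg.tolerance_range)
        elif kind == "season":
            rec["season_pref"] = rng.choice(list(cfg.seasons))
            rec["season_effect"] = rng.uniform(*cfg.season_effect_range)
        elif kind != "none":
            raise ValueError(f"taxon {taxon}: undefined driver type {kind!r}")
        records.append(rec)
    return pd.DataFrame(records, index=pd.Index(taxa, name="taxon"))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _expected_log(params: pd.DataFrame, env: EnvFrame, frame: SampleFrame) -> pd.DataFrame:
    """Noise-free expected log abundance per sample x taxon."""
    zcols = {v: _zscore(env.data[v].to_numpy()) for v in env.data.columns}
    zcols["longitude"] = _zscore(frame.data["longitude"].to_numpy())
    zcols["latitude"] = _zscore(frame.data["latitude"].to_numpy())
    season = frame.data["season"].to_numpy()
    n = len(frame.samples)
    cols = {}
    for taxon, p in params.iterrows():
        if p["driver_type"] in ("env", "space"):
            zv = zcols[p["driver_variable"]]
            cols[taxon] = p["log_max"] - (zv - p["optimum"]) ** 2 / (2 * p["tolerance"] ** 2)
        elif p["driver_type"] == "season":
            boost = np.where(season == p["season_pref"], p["season_effect"], 0.0)
            cols[taxon] = (p["log_max"] - 1.0) + boost
        else:  # none
            cols[taxon] = np.full(n, p["log_max"] - 1.0)
    return pd.DataFrame(cols, index=frame.samples)


def _sample_abundance(expected_log: pd.DataFrame, cfg: SimConfig, rng) -> pd.DataFrame:
    noise = rng.normal(0.0, cfg.noise_sd, size=expected_log.shape)
    abund = np.exp(expected_log.to_numpy() + noise)
    keep = rng.random(size=abund.shape) >= cfg.zero_inflation_prob
    return pd.DataFrame(abund * keep, index=expected_log.index,
                        columns=expected_log.columns)


def _assign_traits(params: pd.DataFrame, expected_log: pd.DataFrame,
                   frame: SampleFrame, rng) -> TraitFrame:
    taxa = params.index
    classes = rng.choice(list(CILIATE_CLASSES), size=len(taxa),
                         p=list(CILIATE_CLASSES.values()))
    feeding = rng.choice(FEEDING_HABITS, size=len(taxa),
                         p=[0.10, 0.15, 0.40, 0.20, 0.15])
    # mixotrophs concentrate among taxa whose expected abundance is
    # weighted toward shallow samples
    depth = frame.data["sample_depth"].to_numpy()
    weights = np.exp(expected_log.to_numpy())
    mean_depth = (weights * depth[:, None]).sum(axis=0) / weights.sum(axis=0)
    terciles = np.quantile(mean_depth, [1 / 3, 2 / 3])
    p_mixo = np.where(mean_depth <= terciles[0], 0.65,
                      np.where(mean_depth <= terciles[1], 0.25, 0.05))
    trophy = np.where(rng.random(len(taxa)) < p_mixo, "mixotrophic", "heterotrophic")
    data = pd.DataFrame({
        "class_subclass": classes,
        "genus": [f"{c[:4]}_g{i % 9 + 1}" for i, c in enumerate(classes)],
        "feeding_habit": feeding,
        "trophy": trophy,
    }, index=taxa)
    return TraitFrame(data)


def generate_community(
    env: EnvFrame, frame: SampleFrame, cfg: SimConfig
) -> tuple[AbundanceTable, TraitFrame, GroundTruth]:
    """Ciliate table assembled by niche responses, plus traits and truth."""
    rng = _rng(cfg, 3)
    taxa = [f"Ciliate_{i + 1:03d}" for i in range(cfg.n_taxa)]
    env_vars = [v for v in ENV_GROUP_MAP]  # Chla excluded: it is a derived sum
    params = _draw_taxon_params(cfg, rng, taxa, env_vars)
    expected = _expected_log(params, env, frame)
    table = AbundanceTable(_sample_abundance(expected, cfg, rng))
    traits = _assign_traits(params, expected, frame, rng)
    env_effects = pd.DataFrame({
        "depth_sign": {v: np.sign(p.depth_coef) if p.mode == "additive" else -1.0
                       for v, p in cfg.env_params.items()},
        "seasonal_offset": {v: p.seasonal_offset for v, p in cfg.env_params.items()},
    })
    env_effects.index.name = "variable"
    truth = GroundTruth(params, env_effects, [], expected)
    return table, traits, truth


def generate_phytoplankton(
    env: EnvFrame, frame: SampleFrame, cfg: SimConfig,
    ciliate_truth: GroundTruth | None = None,
) -> tuple[AbundanceTable, TraitFrame, GroundTruth]:
    """Phytoplankton table, diatom-rich, with a configurable subset of taxa
    coupled to ciliate taxa through a shared noise-free signal so that
    predator-prey edges exist by construction."""
    rng = _rng(cfg, 4)
    taxa = [f"Phyto_{i + 1:03d}" for i in range(cfg.n_phyto)]
    env_vars = [v for v in ENV_GROUP_MAP]
    params = _draw_taxon_params(cfg, rng, taxa, env_vars)
    expected = _expected_log(params, env, frame)

    coupled = []
    if ciliate_truth is not None and cfg.n_coupled > 0 and cfg.coupling > 0:
        cil = ciliate_truth.taxon_params
        candidates = list(cil.index[cil["driver_type"].isin(["env", "space"])])
        k = min(cfg.n_coupled, len(candidates), cfg.n_phyto)
        chosen_c = rng.choice(candidates, size=k, replace=False)
        chosen_p = rng.choice(taxa, size=k, replace=False)
        cil_expected = ciliate_truth.expected_log
        for c, p in zip(chosen_c, chosen_p):
            sig = cil_expected[c].to_numpy()
            own = expected[p].to_numpy()
            # blend on standardized scales, then restore the phyto level;
            # coupled taxa keep at least a one-log-unit signal amplitude
            # (bloom-scale variability, comparable to the niche responses)
            blended = (1 - cfg.coupling) * _zscore(own) + cfg.coupling * _zscore(sig)
            expected[p] = own.mean() + blended * max(own.std(), 1.0)
            coupled.append((c, p))

    table = AbundanceTable(_sample_abundance(expected, cfg, rng))
    phyla = rng.choice(list(PHYTO_PHYLA), size=len(taxa), p=list(PHYTO_PHYLA.values()))
    traits = TraitFrame(pd.DataFrame({"phylum": phyla}, index=pd.Index(taxa, name="taxon")))
    env_effects = pd.DataFrame(index=pd.Index([], name="variable"))
    truth = GroundTruth(params, env_effects, coupled, expected)
    return table, traits, truth


@dataclass
class SimBundle:
    """Everything one synthetic survey produces."""

    frame: SampleFrame
    env: EnvFrame
    community: AbundanceTable
    traits: TraitFrame
    phyto: AbundanceTable
    phyto_traits: TraitFrame
    truth: GroundTruth
    phyto_truth: GroundTruth
    config: SimConfig

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "samples": outdir / "samples.csv",
            "environment": outdir / "environment.csv",
            "community": outdir / "community.csv",
            "traits": outdir / "traits.csv",
            "phytoplankton": outdir / "phytoplankton.csv",
            "phyto_traits": outdir / "phyto_traits.csv",
            "ground_truth": outdir / "ground_truth.json",
        }
        self.frame.data.to_csv(paths["samples"], index_label="sample_id")
        self.env.data.to_csv(paths["environment"], index_label="sample_id")
        self.community.data.to_csv(paths["community"], index_label="sample_id")
        self.traits.data.to_csv(paths["traits"], index_label="taxon")
        self.phyto.data.to_csv(paths["phytoplankton"], index_label="sample_id")
        self.phyto_traits.data.to_csv(paths["phyto_traits"], index_label="taxon")
        self.truth.to_json(paths["ground_truth"])
        return paths


def simulate(cfg: SimConfig | None = None, **overrides) -> SimBundle:
    """Run the full generator: design -> environment -> communities."""
    if cfg is None:
        cfg = SimConfig(**overrides)
    elif overrides:
        cfg = SimConfig(**{**asdict_shallow(cfg), **overrides})
    frame = generate_design(cfg)
    env = generate_env(frame, cfg)
    community, traits, truth = generate_community(env, frame, cfg)
    phyto, phyto_traits, phyto_truth = generate_phytoplankton(env, frame, cfg, truth)
    return SimBundle(frame, env, community, traits, phyto, phyto_traits,
                     truth, phyto_truth, cfg)


def asdict_shallow(cfg: SimConfig) -> dict:
    # dataclasses.asdict would deep-copy EnvParam into dicts; keep objects
    return {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}
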