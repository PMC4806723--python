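"""Seed-reproducible synthetic datasets for the four experimental designs.

The generator emulates a two-species comparison between an invasive desert
annual and a native congener across the four experiments the pipeline
analyses:

1. **Porometry** — instantaneous stomatal conductance on a handful of
   individuals per species at four clock times; each species follows a
   smooth unimodal diurnal template (a sine bump over the daylight window,
   warped so its maximum sits at a configurable peak time) plus Gaussian
   noise clipped at zero.
2. **Sequential harvests** — destructive harvests at fixed ages in two
   contrasting growing seasons ("warm" vs. "cool"); total dry mass grows
   exponentially at a configurable true RGR with multiplicative lognormal
   noise and a plot-level random effect on the log scale; allocation
   (leaf/root fractions, SLA) is per species × year with its own
   multiplicative jitter.
3. **Competition pots** — the six planting combinations (each species alone,
   with four conspecifics, with four heterospecific neighbours); expected
   performance is the species baseline times a neighbour-specific
   suppression factor in (0, 1]; seed counts are negative-binomial,
   biomasses lognormal.
4. **Herbivore exclusion** — paired control/exclusion plots in blocks;
   plot-level summaries are species mean + treatment effect (+ optional
   species-by-treatment interaction) + block random effect + residual.

Every noise parameter set to zero collapses each generated value onto its
stated expectation, giving all downstream estimators an exact
parameter-recovery surface. Identical configs (including seed) produce
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .water_flux import DEFAULT_DAWN, DEFAULT_DUSK, SAMPLING_TIMES

__all__ = [
    "SPECIES",
    "YEARS",
    "SimulationConfig",
    "gen_conductance",
    "gen_harvests",
    "gen_competition",
    "gen_exclusion",
    "write_datasets",
    "read_dataset",
]

SPECIES = ("invasive", "native")
YEARS = ("warm", "cool")

# distinct deterministic RNG stream keys per generator
_STREAM = {"conductance": 1, "harvest": 2, "competition": 3, "exclusion": 4}


def _per_species(d: dict, what: str) -> dict:
    missing = set(SPECIES) - set(d)
    if missing:
        raise ValueError(f"{what}: missing species {sorted(missing)}")
    return d


@dataclass
class SimulationConfig:
    """All "true" effects and noise levels for the four designs.

    Defaults describe the study conditions: the invader loses ~37% less
    water at the leaf level (lower conductance peak), grows faster than the
    native in the warm season with near-parity in the cool season, exerts
    (and tolerates) stronger competition, and herbivore exclusion has no
    effect on either species (no enemy release).
    """

    seed: int = 0

    # --- porometry -------------------------------------------------------
    n_individuals_per_species: int = 5
    #: species -> {"peak": mmol·m⁻²·s⁻¹, "peak_time": hours}
    conductance_peaks: dict = field(
        default_factory=lambda: {
            "invasive": {"peak": 252.0, "peak_time": 12.5},
            "native": {"peak": 400.0, "peak_time": 12.5},
        }
    )
    conductance_noise_sd: float = 30.0
    sampling_times: tuple = SAMPLING_TIMES
    dawn: float = DEFAULT_DAWN
    dusk: float = DEFAULT_DUSK

    # --- sequential harvests --------------------------------------------
    #: species -> year -> intrinsic relative growth rate (day⁻¹)
    rgr_true: dict = field(
        default_factory=lambda: {
            "invasive": {"warm": 0.12, "cool": 0.155},
            "native": {"warm": 0.08, "cool": 0.15},
        }
    )
    #: species -> year -> {"leaf_fraction", "root_fraction", "sla"(cm²·g⁻¹)}
    allocation_true: dict = field(
        default_factory=lambda: {
            "invasive": {
                "warm": {"leaf_fraction": 0.45, "root_fraction": 0.28, "sla": 250.0},
                "cool": {"leaf_fraction": 0.40, "root_fraction": 0.32, "sla": 205.0},
            },
            "native": {
                "warm": {"leaf_fraction": 0.42, "root_fraction": 0.20, "sla": 185.0},
                "cool": {"leaf_fraction": 0.44, "root_fraction": 0.24, "sla": 200.0},
            },
        }
    )
    initial_mass: float = 0.01  # g dry at germination (age 0)
    mass_noise_cv: float = 0.2
    allocation_noise_cv: float = 0.1
    harvest_ages: tuple = (33, 53, 95, 115)  # days after germination
    n_plots: int = 4
    n_plants_per_harvest: int = 6  # per species × year × plot × age
    plot_sd: float = 0.1  # log-scale between-plot sd

    # --- competition pots ------------------------------------------------
    #: focal species -> neighbor identity -> multiplicative suppression in (0,1]
    competition_effects: dict = field(
        default_factory=lambda: {
            # both focals suppressed more by an invasive neighbour; the native
            # focal suppressed more overall; additive on the RII scale, so the
            # focal-by-competitor interaction is null in expectation
            "invasive": {"none": 1.0, "conspecific": 0.449, "heterospecific": 0.667},
            "native": {"none": 1.0, "conspecific": 0.587, "heterospecific": 0.389},
        }
    )
    #: species -> {"seeds", "total_mass"(g), "root_fraction"}
    competition_baselines: dict = field(
        default_factory=lambda: {
            "invasive": {"seeds": 240.0, "total_mass": 1.6, "root_fraction": 0.30},
            "native": {"seeds": 160.0, "total_mass": 1.2, "root_fraction": 0.22},
        }
    )
    n_alone: int = 20
    n_per_neighbor: int = 20
    competition_mass_cv: float = 0.25
    seed_dispersion: float = 8.0  # negative-binomial k; 0 = deterministic counts

    # --- herbivore exclusion --------------------------------------------
    n_blocks: int = 16  # one control + one exclusion plot per block
    #: species -> {"n_individuals", "mean_fruits", "mean_mass"(g)}
    exclusion_species_means: dict = field(
        default_factory=lambda: {
            "invasive": {"n_individuals": 14.0, "mean_fruits": 6.5, "mean_mass": 0.55},
            "native": {"n_individuals": 10.0, "mean_fruits": 4.0, "mean_mass": 0.40},
        }
    )
    exclusion_treatment_effect: dict = field(
        default_factory=lambda: {"n_individuals": 0.0, "mean_fruits": 0.0, "mean_mass": 0.0}
    )
    #: species-by-treatment interaction, added to the native in exclusion plots
    exclusion_interaction_effect: dict = field(
        default_factory=lambda: {"n_individuals": 0.0, "mean_fruits": 0.0, "mean_mass": 0.0}
    )
    exclusion_block_sd: dict = field(
        default_factory=lambda: {"n_individuals": 2.0, "mean_fruits": 0.8, "mean_mass": 0.06}
    )
    exclusion_residual_sd: dict = field(
        default_factory=lambda: {"n_individuals": 2.5, "mean_fruits": 1.0, "mean_mass": 0.08}
    )

    def __post_init__(self) -> None:
        self.sampling_times = tuple(self.sampling_times)
        self.harvest_ages = tuple(self.harvest_ages)
        if self.n_individuals_per_species < 1:
            raise ValueError("n_individuals_per_species must be >= 1")
        if self.n_plots < 1 or self.n_plants_per_harvest < 1:
            raise ValueError("counts must be >= 1")
        if self.n_alone < 1 or self.n_per_neighbor < 1:
            raise ValueError("competition replicate counts must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        for name in (
            "conductance_noise_sd",
            "mass_noise_cv",
            "allocation_noise_cv",
            "plot_sd",
            "competition_mass_cv",
            "seed_dispersion",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.dawn < self.dusk:
            raise ValueError("dawn must precede dusk")
        for sp, pk in _per_species(self.conductance_peaks, "conductance_peaks").items():
            if pk["peak"] < 0:
                raise ValueError(f"{sp}: negative peak conductance")
            if not self.dawn < pk["peak_time"] < self.dusk:
                raise ValueError(f"{sp}: peak time outside the dawn–dusk window")
        if len(self.harvest_ages) == 0:
            raise ValueError("harvest_ages must be non-empty")
        ages = np.asarray(self.harvest_ages, dtype=float)
        if np.any(ages <= 0):
            raise ValueError("harvest ages must be positive")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("harvest ages must be strictly increasing")
        for sp, by_year in _per_species(self.allocation_true, "allocation_true").items():
            for yr, alloc in by_year.items():
                lf, rf = alloc["leaf_fraction"], alloc["root_fraction"]
                if not (0 < lf < 1 and 0 < rf < 1 and lf + rf < 1):
                    raise ValueError(
                        f"{sp}/{yr}: allocation fractions must lie in (0,1) and sum < 1"
                    )
                if alloc["sla"] <= 0:
                    raise ValueError(f"{sp}/{yr}: SLA must be positive")
        for sp, by_nb in _per_species(self.competition_effects, "competition_effects").items():
            for nb, s in by_nb.items():
                if not 0 < s <= 1:
                    raise ValueError(f"{sp}/{nb}: suppression factor must lie in (0, 1]")
        for d in (self.exclusion_block_sd, self.exclusion_residual_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("exclusion sd parameters must be >= 0")

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sampling_times"] = list(self.sampling_times)
        d["harvest_ages"] = list(self.harvest_ages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stream]])


def _diurnal_shape(t: np.ndarray, dawn: float, dusk: float, peak_time: float) -> np.ndarray:
    """Unimodal template in [0,1]: 0 at dawn/dusk, 1 at peak_time.

    A half-sine over the daylight window, time-warped piecewise-linearly so
    the maximum falls at ``peak_time`` rather than the window midpoint.
    """
    t = np.asarray(t, dtype=float)
    u = np.where(
        t <= peak_time,
        0.5 * (t - dawn) / (peak_time - dawn),
        0.5 + 0.5 * (t - peak_time) / (dusk - peak_time),
    )
    return np.sin(np.pi * np.clip(u, 0.0, 1.0))


def gen_conductance(config: SimulationConfig) -> pd.DataFrame:
    """Instantaneous porometry table: one row per individual × clock time.

    ``g_s`` is the species' diurnal template scaled to its peak conductance
    plus Gaussian noise (sd = ``conductance_noise_sd``) clipped at zero.
    """
    rng = config.rng("conductance")
    rows = []
    for sp in SPECIES:
        pk = config.conductance_peaks[sp]
        expected = pk["peak"] * _diurnal_shape(
            np.asarray(config.sampling_times), config.dawn, config.dusk, pk["peak_time"]
        )
        for i in range(config.n_individuals_per_species):
            noise = (
                rng.normal(0.0, config.conductance_noise_sd, size=len(expected))
                if config.conductance_noise_sd > 0
                else np.zeros_like(expected)
            )
            gs = np.maximum(expected + noise, 0.0)
            for t, g in zip(config.sampling_times, gs):
                rows.append(
                    {
                        "individual_id": f"{sp}_{i + 1:02d}",
                        "species": sp,
                        "clock_time": t,
                        "g_s": g,
                    }
                )
    return pd.DataFrame(rows)


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def gen_harvests(config: SimulationConfig) -> pd.DataFrame:
    """Sequential-harvest table: one row per destructively harvested plant.

    Expected total mass at age a is ``initial_mass · exp(rgr_true · a)``;
    noise is mean-one lognormal (cv = ``mass_noise_cv``) times a plot-level
    lognormal effect (log-scale sd = ``plot_sd``, shared by both species in
    a plot). Allocation fractions and SLA get their own mean-one lognormal
    jitter (cv = ``allocation_noise_cv``); jittered fractions are rescaled
    if they would sum past 0.95, so masses always decompose validly.
    """
    rng = config.rng("harvest")
    rows = []
    for yr in YEARS:
        # plots are physical field locations, nested within year
        plot_ids = [f"{yr}_P{p + 1}" for p in range(config.n_plots)]
        plot_eff = (
            rng.normal(0.0, config.plot_sd, size=config.n_plots)
            if config.plot_sd > 0
            else np.zeros(config.n_plots)
        )
        for sp in SPECIES:
            rgr = config.rgr_true[sp][yr]
            alloc = config.allocation_true[sp][yr]
            for p, plot in enumerate(plot_ids):
                for age in config.harvest_ages:
                    n = config.n_plants_per_harvest
                    expected = config.initial_mass * np.exp(rgr * age)
                    total = (
                        expected
                        * np.exp(plot_eff[p])
                        * _lognormal_factor(rng, config.mass_noise_cv, n)
                    )
                    lf = alloc["leaf_fraction"] * _lognormal_factor(
                        rng, config.allocation_noise_cv, n
                    )
                    rf = alloc["root_fraction"] * _lognormal_factor(
                        rng, config.allocation_noise_cv, n
                    )
                    over = lf + rf
                    scale = np.where(over >= 0.95, 0.95 / over, 1.0)
                    lf, rf = lf * scale, rf * scale
                    sla = alloc["sla"] * _lognormal_factor(
                        rng, config.allocation_noise_cv, n
                    )
                    leaf = lf * total
                    root = rf * total
                    for j in range(n):
                        rows.append(
                            {
                                "plant_id": f"{sp}_{yr}_{plot}_a{age}_{j + 1:02d}",
                                "species": sp,
                                "year": yr,
                                "plot": plot,
                                "age": float(age),
                                "total_mass": total[j],
                                "leaf_mass": leaf[j],
                                "root_mass": root[j],
                                "shoot_mass": total[j] - root[j],
                                "leaf_area": sla[j] * leaf[j],
                            }
                        )
    return pd.DataFrame(rows)


def gen_competition(config: SimulationConfig) -> pd.DataFrame:
    """Competition-pot table: the six planting combinations.

    Expected performance = species baseline × suppression factor for the
    neighbour identity. Seed counts are negative-binomial with dispersion
    ``seed_dispersion`` (0 ⇒ deterministic rounded mean); total mass is
    lognormal (cv = ``competition_mass_cv``) and split into root and
    above-ground mass by the species' root fraction.
    """
    rng = config.rng("competition")
    rows = []
    for sp in SPECIES:
        base = config.competition_baselines[sp]
        for nb in ("none", "conspecific", "heterospecific"):
            s = config.competition_effects[sp][nb]
            n = config.n_alone if nb == "none" else config.n_per_neighbor
            mu_seeds = base["seeds"] * s
            mu_total = base["total_mass"] * s
            if config.seed_dispersion > 0:
                k = config.seed_dispersion
                seeds = rng.negative_binomial(k, k / (k + mu_seeds), size=n).astype(float)
            else:
                seeds = np.full(n, np.round(mu_seeds))
            total = mu_total * _lognormal_factor(rng, config.competition_mass_cv, n)
            # root allocation gets its own jitter so the mass partitions are
            # not perfectly collinear across pots
            rf = np.clip(
                base["root_fraction"]
                * _lognormal_factor(rng, config.competition_mass_cv / 2.0, n),
                0.02,
                0.9,
            )
            root = rf * total
            for j in range(n):
                rows.append(
                    {
                        "pot_id": f"{sp}_{nb}_{j + 1:02d}",
                        "focal_species": sp,
                        "neighbor_identity": nb,
                        "seeds": seeds[j],
                        "total_mass": total[j],
                        "above_mass": total[j] - root[j],
                        "root_mass": root[j],
                    }
                )
    return pd.DataFrame(rows)


def gen_exclusion(config: SimulationConfig) -> pd.DataFrame:
    """Herbivore-exclusion table: one row per plot × species.

    Each block holds one control and one exclusion plot. Response =
    species mean + treatment effect (+ interaction, applied to the native
    under exclusion — the enemy-release signature) + block effect +
    residual; individual counts are rounded, all responses clipped at zero.
    """
    rng = config.rng("exclusion")
    responses = ("n_individuals", "mean_fruits", "mean_mass")
    rows = []
    for b in range(config.n_blocks):
        block = f"B{b + 1:02d}"
        block_eff = {
            r: (rng.normal(0.0, sd) if (sd := config.exclusion_block_sd[r]) > 0 else 0.0)
            for r in responses
        }
        for treatment in ("control", "exclusion"):
            plot = f"{block}_{treatment}"
            for sp in SPECIES:
                row = {"block": block, "plot": plot, "treatment": treatment, "species": sp}
                for r in responses:
                    val = config.exclusion_species_means[sp][r] + block_eff[r]
                    if treatment == "exclusion":
                        val += config.exclusion_treatment_effect[r]
                        if sp == "native":
                            val += config.exclusion_interaction_effect[r]
                    sd = config.exclusion_residual_sd[r]
                    if sd > 0:
                        val += rng.normal(0.0, sd)
                    val = max(val, 0.0)
                    row[r] = float(np.round(val)) if r == "n_individuals" else val
                rows.append(row)
    return pd.DataFrame(rows)


_CSV_HEADERS = {
    "conductance": "# stomatal conductance g_s in mmol.m-2.s-1; clock_time in hours since midnight",
    "harvests": "# masses in g dry weight; leaf_area in cm2; age in days after germination",
    "competition": "# seeds: count per focal plant; masses in g dry weight",
    "exclusion": "# n_individuals: count per plot; mean_fruits: fruits per individual; mean_mass in g",
}


def write_datasets(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the four CSVs plus a provenance sidecar; returns the paths.

    Each CSV starts with a ``#`` comment line stating units (readable back
    with ``pandas.read_csv(..., comment='#')``). The sidecar records the
    full config, including the seed, as JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "conductance": gen_conductance(config),
        "harvests": gen_harvests(config),
        "competition": gen_competition(config),
        "exclusion": gen_exclusion(config),
    }
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(_CSV_HEADERS[name] + "\n")
            df.to_csv(fh, index=False)
        paths[name] = path
    sidecar = outdir / "provenance.json"
    sidecar.write_text(json.dumps({"config": config.to_dict()}, indent=2) + "\n")
    paths["provenance"] = sidecar
    return paths


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read one of the generated CSVs (skipping the units comment line)."""
    return pd.read_csv(path, comment="#")
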