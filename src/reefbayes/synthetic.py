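"""Synthetic reef-survey data with known ground truth.

Emulates the structure of multi-institution Hawai‘i reef monitoring data:
a 100 m driver grid (27 correlated drivers in four groups, moku land
divisions, bottom type), survey replicates with gamma-distributed herbivore
biomass driven log-linearly by standardized drivers plus hierarchical
year/moku/dataset effects, a benthic condition log-ratio response with
functional-group main effects and interactions, raw fish records with
occasional extreme schooling counts, and zero-inflated parrotfish data
across management strata.

Every generator is deterministic given its seed, and each output table
draws from its own RNG stream so adding one table does not perturb another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._utils import check_positive_int, spawn_rng

#: The 27 gridded drivers, grouped as fishing / land-based pollution /
#: physical oceanography / habitat.
DRIVER_GROUPS: dict[str, str] = {}
for _g, _names in {
    "fishing": [
        "spear_shore", "spear_boat", "net_shore", "net_boat",
        "line_shore", "line_boat", "aquarium_take", "commercial_trap",
    ],
    "pollution": [
        "urban_runoff", "agricultural_runoff", "sediment",
        "sewage_effluent", "cesspool_effluent", "habitat_modification",
        "golf_course_runoff",
    ],
    "oceanography": [
        "sst_mean", "sst_sd", "chla_mean", "chla_max",
        "wave_mean", "wave_anom_max", "irradiance_mean", "irradiance_sd",
    ],
    "habitat": ["depth", "rugosity", "complexity", "distance_to_shore"],
}.items():
    for _n in _names:
        DRIVER_GROUPS[_n] = _g

DRIVER_NAMES: list[str] = list(DRIVER_GROUPS)
HABITAT_CLASSES = ["reef", "pavement", "boulder", "other"]

#: herbivore-block terms of the benthic log-ratio model
BENTHIC_TERMS = [
    "intercept", "grazer", "scraper", "browser",
    "grazer:scraper", "grazer:browser", "scraper:browser",
    "grazer:scraper:browser",
]


@dataclass
class SyntheticTruth:
    """Ground-truth parameters for the generators.

    beta is on the standardized-driver (log biomass) scale; kappa is the
    gamma shape; the sigma_* are hierarchical effect SDs on the log scale;
    benthic_beta holds the log-ratio model coefficients (herbivore main
    effects and their two-/three-way interactions on log1p biomass);
    hurdle_p / hurdle_mu give presence probability and mean biomass when
    present (g m^-2) per management level.
    """

    beta: dict = field(default_factory=dict)
    intercept: float = 3.0
    kappa: float = 2.0
    sigma_year: float = 0.2
    sigma_moku: float = 0.25
    sigma_dataset: float = 0.15
    benthic_beta: dict = field(default_factory=lambda: {
        "intercept": 0.0, "grazer": 0.30, "scraper": 0.50, "browser": 0.20,
        "grazer:scraper": -0.10, "grazer:browser": -0.08,
        "scraper:browser": -0.06, "grazer:scraper:browser": 0.04,
    })
    sigma_benthic: float = 0.8
    fg_props: tuple = (0.45, 0.30, 0.15)  # grazer, scraper, browser; rest "other"
    hurdle_p: dict = field(default_factory=dict)
    hurdle_mu: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        for name in ("sigma_year", "sigma_moku", "sigma_dataset", "sigma_benthic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for lev, p in self.hurdle_p.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"hurdle_p[{lev!r}] must be in [0, 1], got {p}")
        for lev, m in self.hurdle_mu.items():
            if m <= 0:
                raise ValueError(f"hurdle_mu[{lev!r}] must be > 0, got {m}")
        unknown = set(self.beta) - set(DRIVER_NAMES)
        if unknown:
            raise ValueError(f"beta refers to unknown drivers: {sorted(unknown)}")
        unknown = set(self.benthic_beta) - set(BENTHIC_TERMS)
        if unknown:
            raise ValueError(f"benthic_beta refers to unknown terms: {sorted(unknown)}")

    def beta_vector(self) -> np.ndarray:
        """Coefficients aligned to DRIVER_NAMES (zero where unspecified)."""
        return np.array([self.beta.get(d, 0.0) for d in DRIVER_NAMES])

    def serialize(self) -> dict:
        d = dataclasses.asdict(self)
        d["fg_props"] = list(self.fg_props)
        return d


def make_truth(config: dict | None = None) -> SyntheticTruth:
    """Build a SyntheticTruth from a (possibly partial) parameter map.

    Unspecified entries take the documented defaults; unknown keys or
    invariant violations (kappa <= 0, negative SD, probabilities outside
    [0, 1]) raise ValueError.
    """
    config = dict(config or {})
    valid = {f.name for f in dataclasses.fields(SyntheticTruth)}
    unknown = set(config) - valid
    if unknown:
        raise ValueError(f"unknown truth parameters: {sorted(unknown)}")
    if "fg_props" in config:
        config["fg_props"] = tuple(config["fg_props"])
    return SyntheticTruth(**config)


def save_truth(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth.serialize(), fh, sort_keys=False)


def load_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        return make_truth(yaml.safe_load(fh))


def make_driver_grid(
    n_pixels: int,
    n_moku: int,
    correlation_level: float = 0.3,
    seed: int = 0,
    zero_fishing_frac: float = 0.05,
    hardbottom_frac: float = 0.85,
) -> pd.DataFrame:
    """Generate a 100 m prediction grid with 27 correlated drivers.

    Drivers are drawn from a latent Gaussian with within-group correlation
    ``correlation_level`` (half that across groups) and mapped through
    monotone transforms to native units, so Spearman structure survives.
    Fishing and pollution intensities are non-negative; a
    ``zero_fishing_frac`` fraction of pixels is fully unfished (all fishing
    drivers exactly zero — remote-coast analogue). Moku are contiguous
    pixel blocks, which gives each moku its own driver profile.
    """
    n_pixels = check_positive_int(n_pixels, "n_pixels")
    n_moku = check_positive_int(n_moku, "n_moku")
    if n_pixels < n_moku:
        raise ValueError("n_pixels must be >= n_moku")
    if not 0.0 <= correlation_level <= 1.0:
        raise ValueError("correlation_level must be in [0, 1]")
    rng = spawn_rng(seed, "driver_grid")

    p = len(DRIVER_NAMES)
    groups = np.array([DRIVER_GROUPS[d] for d in DRIVER_NAMES])
    same_group = groups[:, None] == groups[None, :]
    cov = np.where(same_group, correlation_level, 0.5 * correlation_level)
    np.fill_diagonal(cov, 1.0)
    # nearest-PD safeguard for high correlation_level
    w, v = np.linalg.eigh(cov)
    cov = (v * np.clip(w, 1e-6, None)) @ v.T
    z = rng.standard_normal((n_pixels, p)) @ np.linalg.cholesky(cov).T

    grid = pd.DataFrame({"pixel_id": np.arange(n_pixels)})
    grid["longitude"] = -156.0 + 0.001 * np.arange(n_pixels)
    grid["latitude"] = 20.8 + 0.0001 * rng.standard_normal(n_pixels)

    from scipy.stats import norm

    for j, name in enumerate(DRIVER_NAMES):
        g = DRIVER_GROUPS[name]
        if g == "fishing":
            vals = np.exp(0.8 * z[:, j])
        elif g == "pollution":
            vals = np.exp(0.6 * z[:, j])
        elif g == "oceanography":
            vals = 10.0 + 2.0 * z[:, j]
        elif name == "depth":
            vals = 30.0 * norm.cdf(z[:, j])
        else:
            vals = np.exp(0.4 * z[:, j])
        grid[name] = vals

    if zero_fishing_frac > 0:
        unfished = rng.random(n_pixels) < zero_fishing_frac
        fishing_cols = [d for d in DRIVER_NAMES if DRIVER_GROUPS[d] == "fishing"]
        grid.loc[unfished, fishing_cols] = 0.0

    # contiguous moku blocks of near-equal size
    bounds = np.linspace(0, n_pixels, n_moku + 1).astype(int)
    moku = np.empty(n_pixels, dtype=object)
    for k in range(n_moku):
        moku[bounds[k]:bounds[k + 1]] = f"moku_{k + 1:02d}"
    grid["moku_id"] = moku
    grid["hardbottom_flag"] = rng.random(n_pixels) < hardbottom_frac
    grid["habitat_class"] = rng.choice(
        HABITAT_CLASSES, size=n_pixels, p=[0.4, 0.3, 0.15, 0.15]
    )
    return grid


# -- species lookup used to decompose replicate biomass into fish records --
_SPECIES = [
    # code, a (g cm^-b), b, functional group, schooling-prone
    ("SCPS", 0.0135, 3.05, "scraper", False),
    ("CHSP", 0.0210, 2.98, "scraper", False),
    ("ACTR", 0.0288, 2.90, "grazer", True),
    ("ZEFL", 0.0430, 2.81, "grazer", False),
    ("ACNF", 0.0190, 3.02, "grazer", True),
    ("KYSP", 0.0161, 3.02, "browser", True),
    ("NAUN", 0.0235, 2.92, "browser", False),
    ("THDU", 0.0110, 3.05, "other", False),
    ("CHMU", 0.0255, 2.99, "other", False),
]


def species_table() -> pd.DataFrame:
    """Allometric lookup (a, b, functional group) for the synthetic species."""
    return pd.DataFrame(
        _SPECIES, columns=["species_code", "a", "b", "functional_group", "schooling"]
    )


def _sum_to_zero_effects(rng, n_levels, sigma):
    eff = rng.normal(0.0, sigma, size=n_levels) if sigma > 0 else np.zeros(n_levels)
    return eff - eff.mean()


def simulate_surveys(
    grid: pd.DataFrame,
    truth: SyntheticTruth,
    n_replicates: int,
    n_years: int = 5,
    n_datasets: int = 3,
    seed: int = 0,
    school_fraction: float = 0.01,
    school_factor: float = 50.0,
    survey_area: float = 125.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw survey replicates and raw fish records from the generative model.

    Biomass follows y ~ Gamma(shape kappa, mean exp(mu)) with
    mu = intercept + beta·X_std + eps_year + eps_dataset + eps_moku, the
    hierarchical effect vectors centered to exact zero mean. The benthic
    log-ratio is Normal(herbivore-block linear predictor, sigma_benthic)
    on log1p functional-group biomass, and the reported coral / CCA /
    macroalgae covers are consistent with it. Raw fish records decompose
    each replicate's functional-group biomass over the synthetic species
    list; a ``school_fraction`` of records of schooling-prone species gets
    its count multiplied by ``school_factor``.
    """
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    if n_replicates < 0:
        raise ValueError("n_replicates must be >= 0")
    n_years = check_positive_int(n_years, "n_years")
    n_datasets = check_positive_int(n_datasets, "n_datasets")

    rep_cols = [
        "replicate_id", "source_dataset", "latitude", "longitude", "depth",
        "year", "pixel_id", "moku_id", "habitat_class",
        "biomass_total", "biomass_grazer", "biomass_scraper", "biomass_browser",
        "coral", "cca", "macroalgae", "benthic_logratio",
    ]
    fish_cols = ["transect_id", "source_dataset", "species_code", "count",
                 "total_length"]
    if n_replicates == 0:
        return pd.DataFrame(columns=rep_cols), pd.DataFrame(columns=fish_cols)

    rng_assign = spawn_rng(truth.seed + seed, "assign")
    rng_eff = spawn_rng(truth.seed + seed, "effects")
    rng_bio = spawn_rng(truth.seed + seed, "biomass")
    rng_ben = spawn_rng(truth.seed + seed, "benthic")
    rng_fish = spawn_rng(truth.seed + seed, "fish")

    X = grid[DRIVER_NAMES].to_numpy(float)
    mu_d = X.mean(axis=0)
    sd_d = X.std(axis=0, ddof=1)
    sd_d[sd_d == 0] = 1.0
    Xs = (X - mu_d) / sd_d

    pix = rng_assign.integers(0, len(grid), n_replicates)
    years = 2004 + rng_assign.integers(0, n_years, n_replicates)
    datasets = rng_assign.integers(0, n_datasets, n_replicates)

    eff_year = _sum_to_zero_effects(rng_eff, n_years, truth.sigma_year)
    eff_moku = _sum_to_zero_effects(
        rng_eff, grid["moku_id"].nunique(), truth.sigma_moku
    )
    eff_ds = _sum_to_zero_effects(rng_eff, n_datasets, truth.sigma_dataset)
    moku_levels = {m: i for i, m in enumerate(sorted(grid["moku_id"].unique()))}
    moku_of_pix = grid["moku_id"].to_numpy()[pix]
    moku_idx = np.array([moku_levels[m] for m in moku_of_pix])

    mu = (
        truth.intercept
        + Xs[pix] @ truth.beta_vector()
        + eff_year[years - 2004]
        + eff_moku[moku_idx]
        + eff_ds[datasets]
    )
    total = rng_bio.gamma(truth.kappa, np.exp(mu) / truth.kappa)

    props = np.array(truth.fg_props)
    if props.sum() >= 1.0 or np.any(props < 0):
        raise ValueError("fg_props must be non-negative with sum < 1")
    alpha = np.append(props, 1.0 - props.sum()) * 20.0
    shares = rng_bio.dirichlet(alpha, size=n_replicates)
    b_gr, b_sc, b_br = (total * shares[:, k] for k in range(3))

    bb = {t: truth.benthic_beta.get(t, 0.0) for t in BENTHIC_TERMS}
    g, s, b = np.log1p(b_gr), np.log1p(b_sc), np.log1p(b_br)
    lp = (
        bb["intercept"] + bb["grazer"] * g + bb["scraper"] * s + bb["browser"] * b
        + bb["grazer:scraper"] * g * s + bb["grazer:browser"] * g * b
        + bb["scraper:browser"] * s * b + bb["grazer:scraper:browser"] * g * s * b
    )
    logratio = rng_ben.normal(lp, truth.sigma_benthic)
    total_cover = rng_ben.uniform(30.0, 80.0, n_replicates)
    macro = total_cover / (1.0 + np.exp(logratio))
    calc = total_cover - macro
    coral, cca = 0.7 * calc, 0.3 * calc

    reps = pd.DataFrame({
        "replicate_id": np.arange(n_replicates),
        "source_dataset": [f"ds_{d + 1:02d}" for d in datasets],
        "latitude": grid["latitude"].to_numpy()[pix],
        "longitude": grid["longitude"].to_numpy()[pix],
        "depth": grid["depth"].to_numpy()[pix],
        "year": years,
        "pixel_id": grid["pixel_id"].to_numpy()[pix],
        "moku_id": moku_of_pix,
        "habitat_class": grid["habitat_class"].to_numpy()[pix],
        "biomass_total": total,
        "biomass_grazer": b_gr,
        "biomass_scraper": b_sc,
        "biomass_browser": b_br,
        "coral": coral,
        "cca": cca,
        "macroalgae": macro,
        "benthic_logratio": logratio,
    })

    # decompose FG biomass into individual fish records
    spp = species_table()
    by_group = {
        grp: sub.reset_index(drop=True)
        for grp, sub in spp.groupby("functional_group")
    }
    grams = {
        "grazer": b_gr * survey_area,
        "scraper": b_sc * survey_area,
        "browser": b_br * survey_area,
        "other": total * shares[:, 3] * survey_area,
    }
    records = []
    for grp, gvec in grams.items():
        sub = by_group[grp]
        nsp = len(sub)
        split = rng_fish.dirichlet(np.full(nsp, 2.0), size=n_replicates)
        tl = rng_fish.uniform(12.0, 35.0, size=(n_replicates, nsp))
        for k in range(nsp):
            a, bexp = sub.loc[k, "a"], sub.loc[k, "b"]
            w = a * tl[:, k] ** bexp
            count = np.maximum(np.round(gvec * split[:, k] / w), 0.0)
            records.append(pd.DataFrame({
                "transect_id": np.arange(n_replicates),
                "source_dataset": reps["source_dataset"],
                "species_code": sub.loc[k, "species_code"],
                "count": count,
                "total_length": tl[:, k],
            }))
    fish = pd.concat(records, ignore_index=True)
    fish = fish[fish["count"] > 0].reset_index(drop=True)

    prone = set(spp.loc[spp["schooling"], "species_code"])
    is_prone = fish["species_code"].isin(prone).to_numpy()
    spike = is_prone & (rng_fish.random(len(fish)) < school_fraction)
    fish.loc[spike, "count"] *= school_factor

    return reps, fish


def simulate_hurdle_case(
    levels: list[str],
    truth: SyntheticTruth,
    n_per_level: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Zero-inflated biomass observations across management levels.

    Presence ~ Bernoulli(hurdle_p[level]); biomass when present ~
    Gamma(shape kappa, mean hurdle_mu[level]); absent rows have biomass 0.
    """
    n_per_level = check_positive_int(n_per_level, "n_per_level")
    for lev in levels:
        if lev not in truth.hurdle_p or lev not in truth.hurdle_mu:
            raise ValueError(f"level {lev!r} missing hurdle_p/hurdle_mu in truth")
    rng = spawn_rng(truth.seed + seed, "hurdle")
    frames = []
    for lev in levels:
        present = rng.random(n_per_level) < truth.hurdle_p[lev]
        biomass = np.zeros(n_per_level)
        npos = int(present.sum())
        if npos:
            biomass[present] = rng.gamma(
                truth.kappa, truth.hurdle_mu[lev] / truth.kappa, size=npos
            )
        frames.append(pd.DataFrame({
            "management": lev, "present": present.astype(int), "biomass": biomass
        }))
    return pd.concat(frames, ignore_index=True)
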