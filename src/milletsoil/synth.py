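"""Synthetic field-trial and community generator.

Emulates the statistical structure of the two-year fertilization trial so
every downstream stage (indices, diversity, networks, statistics) can be
exercised without the deposited sequence data:

* Soil variables per (treatment, year) are drawn from a normal
  distribution centred on the published group mean with SD = SE * sqrt(n)
  (the published dispersion is a standard error with n = 3), truncated at
  zero for strictly positive quantities.
* Grain yields follow a configurable NPK baseline with per-treatment,
  per-year multipliers; the pig-manure multipliers default to the
  published +4.81 % (2022) and +7.87 % (2023) gains, with cow and sheep
  manure interpolated to preserve the observed PM > SM > CM > NPK order.
* Microbial communities are Dirichlet-multinomial: each treatment has a
  phylum-level concentration profile encoding the reported shifts
  (Proteobacteria elevated under CM; Bacteroidetes and Ascomycota under
  PM; Acidobacteria, Chloroflexi, Basidiomycota and Thaumarchaeota under
  the chemical-fertilizer control), with species simulated within phyla.

Everything is deterministic under (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import table1
from .io import AbundanceTable, SoilSampleTable, TAXON_SEP

#: N application rate shared by all fertilized treatments, kg ha^-1.
N_RATE = 225.0

#: Published pig-manure yield gains over NPK per year.
PM_YIELD_MULTIPLIER = {2022: 1.0481, 2023: 1.0787}


def _default_multipliers() -> dict[int, dict[str, float]]:
    # CM and SM interpolate 1/3 and 2/3 of the PM gain, preserving the
    # reported PM > SM > CM > NPK yield order.
    out: dict[int, dict[str, float]] = {}
    for year, pm in PM_YIELD_MULTIPLIER.items():
        gain = pm - 1.0
        out[year] = {"NPK": 1.0, "CM": 1.0 + gain / 3.0,
                     "SM": 1.0 + 2.0 * gain / 3.0, "PM": pm}
    return out


@dataclass
class TrialConfig:
    """Design of the simulated field trial.

    Defaults reproduce the published design: 4 treatments x 2 years x 3
    replicates, group means/SEs from the published table, NPK yield
    baseline 4200 kg ha^-1 (a typical foxtail-millet yield at 13 %
    moisture), and an unfertilized-control yield at 60 % of NPK — the
    trial had no zero-N plot, so the control needed by agronomic
    efficiency is an explicit assumption.
    """

    treatments: tuple[str, ...] = table1.TREATMENTS
    years: tuple[int, ...] = table1.YEARS
    replicates: int = 3
    means: dict = field(default_factory=lambda: table1.MEANS)
    ses: dict = field(default_factory=lambda: table1.SES)
    yield_baseline: float = 4200.0
    yield_multipliers: dict = field(default_factory=_default_multipliers)
    yield_cv: float = 0.03
    y0_frac: float = 0.6
    n_rate: float = N_RATE

    def validate(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        for var, by_year in self.ses.items():
            for year, vals in by_year.items():
                if any(s < 0 for s in vals):
                    raise ValueError(f"negative SE for {var} in {year}")
        for year, mult in self.yield_multipliers.items():
            if any(m <= 0 for m in mult.values()):
                raise ValueError(f"non-positive yield multiplier in {year}")
        if not 0 < self.y0_frac:
            raise ValueError("y0_frac must be positive")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, lower: float = 0.0) -> np.ndarray:
    """Normal(mean, sd) truncated below at ``lower``."""
    if sd == 0:
        return np.full(size, mean)
    a = (lower - mean) / sd
    tn = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
    return tn.rvs(size=size, random_state=rng)


def generate_soil_dataset(config: TrialConfig, seed: int) -> SoilSampleTable:
    """Draw one replicate-level soil table from the trial design.

    Variable v in group (treatment, year) ~ Normal(mean, SE * sqrt(n)),
    truncated at 0 except for pH (truncated to (0, 14) implicitly by its
    small SE).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    sd_scale = np.sqrt(config.replicates)
    rows = []
    for year in config.years:
        for ti, trt in enumerate(config.treatments):
            draws = {}
            for var in config.means:
                mean = config.means[var][year][ti]
                sd = config.ses[var][year][ti] * sd_scale
                draws[var] = _truncated_normal(rng, mean, sd,
                                               config.replicates)
            for rep in range(config.replicates):
                row = {"treatment": trt, "year": year, "replicate": rep + 1}
                row.update({var: float(draws[var][rep])
                            for var in config.means})
                rows.append(row)
    return SoilSampleTable(pd.DataFrame(rows))


def generate_yields(config: TrialConfig, seed: int) -> pd.DataFrame:
    """Per-plot grain yields (13 % moisture) plus the unfertilized control.

    Returns a frame with columns treatment, year, replicate, yield_kg_ha
    and y0_kg_ha (the assumed unfertilized yield for that year).  In the
    zero-noise limit group means equal baseline x multiplier exactly.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for year in config.years:
        y0 = config.yield_baseline * config.y0_frac
        for trt in config.treatments:
            mult = config.yield_multipliers[year][trt]
            mean = config.yield_baseline * mult
            sd = mean * config.yield_cv
            vals = _truncated_normal(rng, mean, sd, config.replicates)
            for rep, v in enumerate(vals, start=1):
                rows.append({"treatment": trt, "year": year,
                             "replicate": rep, "yield_kg_ha": float(v),
                             "y0_kg_ha": y0})
    return pd.DataFrame(rows)


# --- microbial communities -------------------------------------------------

#: Default phylum pools per kingdom with baseline concentration weights.
DEFAULT_PHYLA = {
    "bacteria": {
        "Proteobacteria": 30.0, "Actinobacteria": 22.0, "Acidobacteria": 14.0,
        "Chloroflexi": 12.0, "Bacteroidetes": 8.0, "Gemmatimonadetes": 6.0,
        "Firmicutes": 5.0, "Verrucomicrobia": 3.0,
    },
    "fungi": {
        "Ascomycota": 55.0, "Basidiomycota": 25.0, "Mortierellomycota": 10.0,
        "Chytridiomycota": 5.0, "Glomeromycota": 3.0, "Zoopagomycota": 2.0,
    },
    "archaea": {
        "Thaumarchaeota": 60.0, "Euryarchaeota": 25.0,
        "Crenarchaeota": 10.0, "Nanoarchaeota": 5.0,
    },
}

#: Multiplicative phylum shifts per treatment, encoding the reported
#: direction of community change under each fertilization regime.
DEFAULT_SHIFTS = {
    "NPK": {"Acidobacteria": 1.5, "Chloroflexi": 1.5, "Basidiomycota": 1.4,
            "Thaumarchaeota": 1.3},
    "CM": {"Proteobacteria": 1.5, "Acidobacteria": 0.75, "Chloroflexi": 0.8},
    "PM": {"Bacteroidetes": 1.6, "Ascomycota": 1.3, "Acidobacteria": 0.75,
           "Chloroflexi": 0.8, "Basidiomycota": 0.8, "Thaumarchaeota": 0.85},
    "SM": {"Proteobacteria": 1.2, "Bacteroidetes": 1.2, "Acidobacteria": 0.8,
           "Chloroflexi": 0.85, "Basidiomycota": 0.9, "Thaumarchaeota": 0.9},
}

DEFAULT_TAXA_PER_KINGDOM = {"bacteria": 60, "fungi": 40, "archaea": 20}


def network_community_config(kingdom: str = "bacteria",
                             **overrides) -> "CommunityConfig":
    """Community configuration for the co-occurrence network stage.

    Correlation-based networks need strong, shared abundance fluctuations
    to be estimable from a few dozen samples, so this profile couples
    species tightly to their phylum (high ``phylum_sigma``) and keeps the
    within-phylum composition stable (high ``concentration``).
    """
    params = dict(kingdom=kingdom, concentration=500.0, phylum_sigma=1.0)
    params.update(overrides)
    return CommunityConfig(**params)


@dataclass
class CommunityConfig:
    """Dirichlet-multinomial community model for one kingdom.

    ``concentration`` scales the Dirichlet vector: large values give
    compositions tightly clustered around the treatment profile (low
    overdispersion), small values give noisy replicates.
    ``phylum_sigma`` is the SD of a per-sample lognormal random effect
    shared by all species of a phylum; it models environmental filtering
    acting at the phylum level and is what makes species of the same
    phylum co-occur (without it Dirichlet components are only weakly
    negatively correlated and co-occurrence networks are empty).
    """

    kingdom: str = "bacteria"
    n_taxa: int = 0  # 0 -> kingdom default
    phyla: dict = None
    shifts: dict = None
    depth: int = 20000
    concentration: float = 200.0
    phylum_sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.phyla is None:
            self.phyla = dict(DEFAULT_PHYLA[self.kingdom])
        if self.shifts is None:
            self.shifts = {t: dict(s) for t, s in DEFAULT_SHIFTS.items()}
        if self.n_taxa == 0:
            self.n_taxa = DEFAULT_TAXA_PER_KINGDOM[self.kingdom]

    def validate(self) -> None:
        if any(w <= 0 for w in self.phyla.values()):
            raise ValueError("phylum concentrations must be positive")
        if self.depth < 1:
            raise ValueError("sequencing depth must be >= 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.phylum_sigma < 0:
            raise ValueError("phylum_sigma must be non-negative")


def _species_layout(config: CommunityConfig,
                    rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
    """Assign species to phyla and fix within-phylum proportions.

    The within-phylum split is drawn once (not per treatment) so treatment
    effects act purely at the phylum level.
    """
    phyla = list(config.phyla)
    n_ph = len(phyla)
    base = config.n_taxa // n_ph
    counts = [base + (1 if i < config.n_taxa % n_ph else 0)
              for i in range(n_ph)]
    labels: list[str] = []
    weights: list[np.ndarray] = []
    for ph, k in zip(phyla, counts):
        k = max(k, 1)
        labels.extend(f"{ph}{TAXON_SEP}sp{j + 1:03d}" for j in range(k))
        # broken-stick style split within the phylum
        w = rng.dirichlet(np.full(k, 2.0))
        weights.append(w)
    return labels, np.concatenate(
        [w * config.phyla[ph] for ph, w in zip(phyla, weights)])


def treatment_profile(config: CommunityConfig, base: np.ndarray,
                      labels: list[str], treatment: str) -> np.ndarray:
    """Dirichlet concentration vector for one treatment."""
    shift = config.shifts.get(treatment, {})
    mult = np.array([shift.get(lbl.split(TAXON_SEP, 1)[0], 1.0)
                     for lbl in labels])
    conc = base * mult
    return conc / conc.sum() * config.concentration


def generate_abundance_dataset(config: CommunityConfig,
                               soil: SoilSampleTable,
                               seed: int) -> AbundanceTable:
    """Simulate a count table over the soil table's samples and return it
    as relative abundances.

    Composition per sample ~ Dirichlet(treatment profile); counts ~
    Multinomial(depth, composition).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    labels, base = _species_layout(config, rng)
    if config.depth < len(labels):
        import warnings
        warnings.warn("sequencing depth below taxon count; columns will be "
                      "sparse", stacklevel=2)
    phylum_idx = np.array([lbl.split(TAXON_SEP, 1)[0] for lbl in labels])
    phyla = list(config.phyla)
    cols = {}
    for key, trt in zip(soil.sample_keys, soil.data["treatment"]):
        conc = treatment_profile(config, base, labels, trt)
        if config.phylum_sigma > 0:
            factors = dict(zip(phyla, rng.lognormal(
                0.0, config.phylum_sigma, len(phyla))))
            conc = conc * np.array([factors[p] for p in phylum_idx])
        comp = rng.dirichlet(conc)
        cols[key] = rng.multinomial(config.depth, comp)
    counts = pd.DataFrame(cols, index=labels)
    return AbundanceTable(config.kingdom, counts.astype(float)).as_relative()
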