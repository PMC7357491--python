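"""Synthetic assay generator calibrated to the published screening study.

Every generator emits the statistical structure the estimators assume —
Gaussian noise on the analysis scale (log1p for halo-type responses, raw
for absorbance/OD/concentration), plate-level random intercepts where the
models expect repeated measures, physical truncation at zero — around
per-strain true means calibrated to the printed results for the three
*Rhizobium* sp. strains B02, L3 and Sp20:

* phosphate-solubilization halo areas of 1.5 / 2.03 / 2.09 cm² at 48 h,
  modulated by the phosphorus source (Ca3PO4 2.39, rock 0.53, FePO4 0.43);
* broth solubilization peaking at 72.6 mg/L for B02 on mannitol + NH4,
  near-zero with yeast extract;
* CAS absorbances 0.861 / 0.884 / 0.594 (siderophore units 86.1 / 88.4 /
  59.4 %);
* crystal-violet biofilm means and SEs per condition (replicate SD taken
  as SE × sqrt(3));
* a 31-substrate EcoPlate utilisation pattern with 17 / 15 / 13 usable
  substrates for L3 / B02 / Sp20 and 13 substrates unusable by all;
* motility and peroxide-sensitivity profiles (L3 the strongest surface
  spreader, B02 the most peroxide resistant).

One PCG64 stream per assay table, seeded from (master seed, CRC32 of the
assay id), so adding an assay never perturbs the draws of another and a
fixed config reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import maut
from .assay_model import AssayTable, write_assay_table
from .errors import ConfigError

STRAINS = ("B02", "L3", "Sp20")

HALO_CONDITIONS = {"Ca3PO4": 2.39, "FePO4": 0.43, "rock_phosphate": 0.53}
BROTH_CONDITIONS = ("Mnn_Ye", "Mnn_NH4", "Glc_NH4", "Suc_NH4", "Frt_NH4")
BIOFILM_CONDITIONS = ("Control_MMS", "Acidic_pH", "Phosphorus_fertilizer",
                      "High_temperature")
H2O2_CONCENTRATIONS_MM = (2.0, 3.0, 5.0, 8.0, 10.0)

#: the 31 EcoPlate sole carbon sources, in plate numbering order
ECO_SUBSTRATES = (
    "alpha-D-lactose",                  # 1
    "beta-methyl-D-glucoside",          # 2
    "D-cellobiose",                     # 3
    "D-galactonic-acid-gamma-lactone",  # 4
    "DL-alpha-glycerol-phosphate",      # 5
    "i-erythritol",                     # 6
    "glucose-1-phosphate",              # 7
    "D-mannitol",                       # 8
    "N-acetyl-D-glucosamine",           # 9
    "D-xylose",                         # 10
    "2-hydroxybenzoic-acid",            # 11
    "4-hydroxybenzoic-acid",            # 12
    "alpha-ketobutyric-acid",           # 13
    "D-galacturonic-acid",              # 14
    "D-glucosaminic-acid",              # 15
    "D-malic-acid",                     # 16
    "gamma-hydroxybutyric-acid",        # 17
    "pyruvic-acid-methyl-ester",        # 18
    "itaconic-acid",                    # 19
    "Tween-40",                         # 20
    "alpha-cyclodextrin",               # 21
    "glycogen",                         # 22
    "phenylethylamine",                 # 23
    "putrescine",                       # 24
    "Tween-80",                         # 25
    "glycyl-L-glutamic-acid",           # 26
    "L-arginine",                       # 27
    "L-asparagine",                     # 28
    "L-phenylalanine",                  # 29
    "L-serine",                         # 30
    "L-threonine",                      # 31
)

#: the 22 substrates carried forward as persistence attributes
FIG5_SUBSTRATES = (
    "alpha-D-lactose", "beta-methyl-D-glucoside", "D-cellobiose",
    "D-galactonic-acid-gamma-lactone", "i-erythritol", "glucose-1-phosphate",
    "D-mannitol", "N-acetyl-D-glucosamine", "D-xylose",
    "4-hydroxybenzoic-acid", "alpha-ketobutyric-acid", "D-galacturonic-acid",
    "D-glucosaminic-acid", "D-malic-acid", "gamma-hydroxybutyric-acid",
    "pyruvic-acid-methyl-ester", "Tween-80", "glycyl-L-glutamic-acid",
    "L-arginine", "L-asparagine", "L-serine", "L-threonine",
)

_USED_BY_ALL = (
    "beta-methyl-D-glucoside", "D-cellobiose", "D-mannitol",
    "N-acetyl-D-glucosamine", "D-xylose", "D-galacturonic-acid",
    "pyruvic-acid-methyl-ester", "L-asparagine", "L-serine",
)
_USED_B02_L3 = ("alpha-D-lactose", "D-galactonic-acid-gamma-lactone",
                "glucose-1-phosphate", "4-hydroxybenzoic-acid", "L-threonine")
_USED_L3_SP20 = ("D-glucosaminic-acid", "D-malic-acid",
                 "glycyl-L-glutamic-acid")
_USED_B02_SP20 = ("L-arginine",)

#: default usability pattern: 15 / 17 / 13 usable substrates, 13 unusable by all
DEFAULT_USABILITY = {
    "B02": frozenset(_USED_BY_ALL + _USED_B02_L3 + _USED_B02_SP20),
    "L3": frozenset(_USED_BY_ALL + _USED_B02_L3 + _USED_L3_SP20),
    "Sp20": frozenset(_USED_BY_ALL + _USED_L3_SP20 + _USED_B02_SP20),
}

#: substrates assimilated fastest by all strains get a higher true slope
_EASY_SUBSTRATES = ("D-mannitol", "N-acetyl-D-glucosamine", "D-xylose",
                    "L-asparagine")


def _default_strain_effects() -> dict:
    return {
        # mean halo areas (cm²) at 48 h, averaged over phosphorus sources
        "halo_nbrip": {"B02": 1.5, "L3": 2.03, "Sp20": 2.09},
        # endpoint soluble phosphate (mg/L) per broth x strain
        "phosphate_broth": {
            "Mnn_Ye": {"B02": 1.5, "L3": 1.2, "Sp20": 1.0},
            "Mnn_NH4": {"B02": 72.6, "L3": 38.0, "Sp20": 32.0},
            "Glc_NH4": {"B02": 65.0, "L3": 18.0, "Sp20": 15.0},
            "Suc_NH4": {"B02": 60.0, "L3": 16.0, "Sp20": 13.0},
            "Frt_NH4": {"B02": 55.0, "L3": 15.0, "Sp20": 12.0},
        },
        # blank-zeroed CAS absorbance at 630 nm
        "cas": {"B02": 0.861, "L3": 0.884, "Sp20": 0.594},
        # swimming halo area (cm²) at 48 h — motile, no real differences
        "swimming": {"B02": 3.5, "L3": 3.6, "Sp20": 3.4},
        # surface spreading: area (cm²) at the 60-h design midpoint and
        # log1p-scale growth per hour
        "surface_spreading": {
            "area_60h": {"B02": 1.5, "L3": 3.2, "Sp20": 1.2},
            "log_slope_per_h": {"B02": 0.006, "L3": 0.012, "Sp20": 0.005},
        },
        # peroxide inhibition halo area (cm²) at the mean concentration;
        # smaller halo = more resistant (B02)
        "ros": {
            "area_mean_conc": {"B02": 0.8, "L3": 3.3, "Sp20": 3.6},
            "log_slope_per_mM": 0.08,
        },
        # crystal violet absorbance (mean, SE) per condition x strain
        "biofilm": {
            "Control_MMS": {"B02": (0.46, 0.03), "L3": (0.53, 0.03),
                            "Sp20": (0.54, 0.04)},
            "Acidic_pH": {"B02": (0.22, 0.01), "L3": (0.21, 0.01),
                          "Sp20": (0.22, 0.02)},
            "Phosphorus_fertilizer": {"B02": (0.22, 0.02), "L3": (0.24, 0.02),
                                      "Sp20": (0.23, 0.02)},
            "High_temperature": {"B02": (0.18, 0.01), "L3": (0.58, 0.02),
                                 "Sp20": (0.42, 0.04)},
        },
        # true OD/h utilisation slope for usable substrates; every well
        # additionally drifts slightly downward (evaporation/settling over
        # the 84-h incubation), so unused wells have a weakly negative
        # true slope rather than an exact zero
        "ecoplate": {
            "slope": {"B02": 0.009, "L3": 0.015, "Sp20": 0.008},
            "easy_multiplier": 1.5,
            "baseline_od": 0.05,
            "drift_od_per_h": -0.0002,
        },
    }


def _default_noise_sd() -> dict:
    return {
        "halo_nbrip": 0.05,          # log1p scale
        "phosphate_broth": 2.0,      # mg/L
        "cas": 0.005,                # absorbance
        "swimming": 0.05,            # log1p scale
        "surface_spreading": 0.06,   # log1p scale
        "ros": 0.05,                 # log1p scale
        "biofilm": None,             # derived from printed SE x sqrt(n)
        "ecoplate": 0.005,           # OD
    }


def _default_timepoints() -> dict:
    return {
        "halo_nbrip": [24.0, 48.0],
        "swimming": [24.0, 48.0],
        "surface_spreading": [24.0, 48.0, 72.0, 96.0],
        # OD read at 12-h intervals to 72 h and once more at 84 h
        "ecoplate": [12.0, 24.0, 36.0, 48.0, 60.0, 72.0, 84.0],
    }


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic screening campaign.

    Defaults reproduce the published study's design: 3 strains, 3
    replicates per experiment, the printed per-strain means where the
    study reports them, and declared dispersion assumptions elsewhere.
    """

    seed: int = 0
    n_strains: int = 3
    n_replicates: int = 3
    strain_effects: dict = field(default_factory=_default_strain_effects)
    noise_sd: dict = field(default_factory=_default_noise_sd)
    plate_sd: float = 0.01
    timepoints_h: dict = field(default_factory=_default_timepoints)
    usability: dict = field(default_factory=lambda: dict(DEFAULT_USABILITY))

    def __post_init__(self):
        if not 1 <= self.n_strains <= len(STRAINS):
            raise ConfigError(f"n_strains must be in 1..{len(STRAINS)}")
        if not isinstance(self.seed, (int, np.integer)) \
                or isinstance(self.seed, bool):
            raise ConfigError("seed must be an integer")
        for k, v in self.noise_sd.items():
            if v is not None and v < 0:
                raise ConfigError(f"noise_sd[{k!r}] must be >= 0")
        if self.plate_sd < 0:
            raise ConfigError("plate_sd must be >= 0")

    @property
    def strains(self) -> tuple:
        return STRAINS[: self.n_strains]

    def rng(self, assay_id: str) -> np.random.Generator:
        """One independent, reproducible stream per assay table."""
        return np.random.default_rng(
            [int(self.seed), zlib.crc32(assay_id.encode("utf-8"))])

    def with_noise(self, level: float) -> "SyntheticConfig":
        """Copy with every noise SD (and the plate SD) set to ``level``."""
        return replace(self, noise_sd={k: level for k in self.noise_sd},
                       plate_sd=level)


def _sd(cfg: SyntheticConfig, assay: str) -> float:
    v = cfg.noise_sd.get(assay, 0.0)
    return 0.0 if v is None else float(v)


# ---------------------------------------------------------------------------
# per-assay generators
# ---------------------------------------------------------------------------

def generate_halo_assay(cfg: SyntheticConfig) -> AssayTable:
    """Phosphate-solubilization halos on NBRIP agar (r1/r2 half-diameters).

    True 48-h areas are the configured per-strain means scaled by the
    phosphorus-source profile (normalised to mean 1, so the across-source
    mean equals the configured strain mean exactly); 24-h halos are 0.55x.
    Noise is Gaussian on the log1p(area) scale and repeated measures of a
    plate share its unit id.
    """
    rng = cfg.rng("halo_nbrip")
    sd = _sd(cfg, "halo_nbrip")
    means = cfg.strain_effects["halo_nbrip"]
    profile = np.array([HALO_CONDITIONS[c] for c in HALO_CONDITIONS])
    weights = dict(zip(HALO_CONDITIONS, profile / profile.mean()))
    rows = []
    for strain in cfg.strains:
        for cond, w in weights.items():
            for rep in range(1, cfg.n_replicates + 1):
                unit = f"halo_{strain}_{cond}_r{rep}"
                for t in cfg.timepoints_h["halo_nbrip"]:
                    mult = 1.0 if t == 48.0 else 0.55
                    mu = np.log1p(means[strain] * w * mult)
                    area = max(float(np.expm1(mu + rng.normal(0.0, sd))), 0.0)
                    r = float(np.sqrt(area))
                    rows.append({"strain": strain, "assay": "halo_nbrip",
                                 "condition": cond, "unit": unit,
                                 "replicate": rep, "time_h": t,
                                 "r1_cm": r, "r2_cm": r})
    return AssayTable(pd.DataFrame(rows), strain_set=cfg.strains)


def generate_broth_solubilization(cfg: SyntheticConfig) -> AssayTable:
    """Endpoint soluble phosphate (mg/L) per broth medium, truncated at 0
    (negative draws are flagged in the ``truncated`` column)."""
    rng = cfg.rng("phosphate_broth")
    sd = _sd(cfg, "phosphate_broth")
    means = cfg.strain_effects["phosphate_broth"]
    rows = []
    for cond in BROTH_CONDITIONS:
        for strain in cfg.strains:
            for rep in range(1, cfg.n_replicates + 1):
                draw = means[cond][strain] + rng.normal(0.0, sd)
                rows.append({"strain": strain, "assay": "phosphate_broth",
                             "condition": cond,
                             "unit": f"broth_{strain}_{cond}_r{rep}",
                             "replicate": rep, "time_h": 24.0,
                             "value": max(float(draw), 0.0),
                             "value_kind": "concentration_mg_per_L",
                             "truncated": bool(draw < 0)})
    return AssayTable(pd.DataFrame(rows), strain_set=cfg.strains)


def generate_cas_assay(cfg: SyntheticConfig) -> AssayTable:
    """Blank-zeroed CAS absorbances at 630 nm (x100 gives percent
    siderophore units: 86.1 / 88.4 / 59.4 at zero noise)."""
    rng = cfg.rng("cas")
    sd = _sd(cfg, "cas")
    means = cfg.strain_effects["cas"]
    rows = []
    for strain in cfg.strains:
        for rep in range(1, cfg.n_replicates + 1):
            draw = means[strain] + rng.normal(0.0, sd)
            rows.append({"strain": strain, "assay": "cas",
                         "condition": "IDM", "unit": f"cas_{strain}_r{rep}",
                         "replicate": rep, "time_h": 0.0,
                         "value": float(np.clip(draw, 0.0, 4.0)),
                         "value_kind": "absorbance"})
    return AssayTable(pd.DataFrame(rows), strain_set=cfg.strains)


def generate_motility_assay(cfg: SyntheticConfig) -> AssayTable:
    """Swimming colony areas (cm²) in semisolid medium at 24/48 h."""
    rng = cfg.rng("swimming")
    sd = _sd(cfg, "swimming")
    means = cfg.strain_effects["swimming"]
    rows = []
    for strain in cfg.strains:
        for rep in range(1, cfg.n_replicates + 1):
            unit = f"swim_{strain}_r{rep}"
            for t in cfg.timepoints_h["swimming"]:
                mult = 1.0 if t == 48.0 else 0.55
                mu = np.log1p(means[strain] * mult)
                area = max(float(np.expm1(mu + rng.normal(0.0, sd))), 0.0)
                rows.append({"strain": strain, "assay": "swimming",
                             "condition": "BM", "unit": unit,
                             "replicate": rep, "time_h": t,
                             "value": area, "value_kind": "area_cm2"})
    return AssayTable(pd.DataFrame(rows), strain_set=cfg.strains)


def generate_spreading_assay(cfg: SyntheticConfig) -> AssayTable:
    """Surface-spreading colony areas over 24–96 h with a plate-level
    random intercept; linear in time on the log1p scale."""
    rng = cfg.rng("surface_spreading")
    sd = _sd(cfg, "surface_spreading")
    eff = cfg.strain_effects["surface_spreading"]
    times = cfg.timepoints_h["surface_spreading"]
    tbar = float(np.mean(times))
    rows = []
    for strain in cfg.strains:
        slope = eff["log_slope_per_h"][strain]
        alpha = np.log1p(eff["area_60h"][strain]) - slope * tbar
        for rep in range(1, cfg.n_replicates + 1):
            unit = f"spread_{strain}_r{rep}"
            u = rng.normal(0.0, cfg.plate_sd)
            for t in times:
                y = alpha + slope * t + u + rng.normal(0.0, sd)
                rows.append({"strain": strain, "assay": "surface_spreading",
                             "condition": "MMS", "unit": unit,
                             "replicate": rep, "time_h": t,
                             "value": max(float(np.expm1(y)), 0.0),
                             "value_kind": "area_cm2"})
    return AssayTable(pd.DataFrame(rows), strain_set=cfg.strains)


def generate_ros_assay(cfg: SyntheticConfig) -> AssayTable:
    """Hydrogen-peroxide growth-inhibition halos at five concentrations;
    the condition field carries the concentration in mM."""
    rng = cfg.rng("ros")
    sd = _sd(cfg, "ros")
    eff = cfg.strain_effects["ros"]
    cbar = float(np.mean(H2O2_CONCENTRATIONS_MM))
    rows = []
    for strain in cfg.strains:
        base = np.log1p(eff["area_mean_conc"][strain])
        for conc in H2O2_CONCENTRATIONS_MM:
            mu = base + eff["log_slope_per_mM"] * (conc - cbar)
            for rep in range(1, cfg.n_replicates + 1):
                y = mu + rng.normal(0.0, sd)
                rows.append({"strain": strain, "assay": "ros",
                             "condition": f"{conc:g}",
                             "unit": f"ros_{strain}_c{conc:g}_r{rep}",
                             "replicate": rep, "time_h": 48.0,
                             "value": max(float(np.expm1(y)), 0.0),
                             "value_kind": "area_cm2"})
    return AssayTable(pd.DataFrame(rows), strain_set=cfg.strains)


def generate_biofilm_assay(cfg: SyntheticConfig) -> AssayTable:
    """Crystal-violet biofilm absorbances per condition; replicate SD is
    the printed SE x sqrt(n_replicates) unless overridden."""
    rng = cfg.rng("biofilm")
    override = cfg.noise_sd.get("biofilm")
    eff = cfg.strain_effects["biofilm"]
    rows = []
    for cond in BIOFILM_CONDITIONS:
        for strain in cfg.strains:
            mean, se = eff[cond][strain]
            sd = float(override) if override is not None \
                else se * np.sqrt(cfg.n_replicates)
            for rep in range(1, cfg.n_replicates + 1):
                draw = mean + rng.normal(0.0, sd)
                rows.append({"strain": strain, "assay": "biofilm",
                             "condition": cond,
                             "unit": f"bf_{strain}_{cond}_r{rep}",
                             "replicate": rep, "time_h": 0.0,
                             "value": float(np.clip(draw, 0.0, 4.0)),
                             "value_kind": "absorbance"})
    return AssayTable(pd.DataFrame(rows), strain_set=cfg.strains)


def generate_ecoplate(cfg: SyntheticConfig, pattern: dict | None = None) -> AssayTable:
    """EcoPlate OD time series: linear in time with the configured true
    slope for usable (strain, substrate) pairs and slope 0 otherwise,
    plate random intercepts, Gaussian noise, truncation to [0, 4]."""
    pattern = {s: frozenset(v) for s, v in (pattern or cfg.usability).items()}
    for strain in cfg.strains:
        unknown = pattern.get(strain, frozenset()) - set(ECO_SUBSTRATES)
        if unknown:
            raise ConfigError(f"unknown substrate(s) in pattern: {sorted(unknown)}")
    rng = cfg.rng("ecoplate")
    sd = _sd(cfg, "ecoplate")
    eff = cfg.strain_effects["ecoplate"]
    times = cfg.timepoints_h["ecoplate"]
    rows = []
    drift = eff.get("drift_od_per_h", 0.0)
    for strain in cfg.strains:
        base_slope = eff["slope"][strain]
        usable = pattern.get(strain, frozenset())
        for rep in range(1, cfg.n_replicates + 1):
            unit = f"eco_{strain}_p{rep}"
            u = rng.normal(0.0, cfg.plate_sd)
            for substrate in ECO_SUBSTRATES:
                slope = drift
                if substrate in usable:
                    slope += base_slope * (eff["easy_multiplier"]
                                           if substrate in _EASY_SUBSTRATES
                                           else 1.0)
                for t in times:
                    od = (eff["baseline_od"] + slope * t + u
                          + rng.normal(0.0, sd))
                    rows.append({"strain": strain, "assay": "ecoplate",
                                 "condition": substrate, "unit": unit,
                                 "replicate": rep, "time_h": t,
                                 "value": float(np.clip(od, 0.0, 4.0)),
                                 "value_kind": "od"})
    return AssayTable(pd.DataFrame(rows), strain_set=cfg.strains)


# ---------------------------------------------------------------------------
# reference MAUT configuration
# ---------------------------------------------------------------------------

#: condition -> attribute id maps shared with the pipeline
HALO_ATTRIBUTES = {"Ca3PO4": "Pca", "FePO4": "Pfe", "rock_phosphate": "Prk"}
BROTH_ATTRIBUTES = {"Mnn_Ye": "PMY", "Mnn_NH4": "PMN", "Glc_NH4": "PGN",
                    "Suc_NH4": "PSN", "Frt_NH4": "PFN"}
BIOFILM_ATTRIBUTES = {"Control_MMS": "BfM", "Acidic_pH": "BfpH",
                      "High_temperature": "BfT",
                      "Phosphorus_fertilizer": "Bfrk"}


def default_attribute_specs() -> list:
    """The 38 declared attributes: 9 plant-growth (8 phosphate +
    siderophore), 4 colonization (2 motility, peroxide resistance,
    control-condition biofilm) and 25 persistence (3 stress biofilms +
    22 carbon sources).  Anchors are declared elicitation choices on each
    measurement scale; peroxide sensitivity is the one decreasing-
    preference attribute (smaller inhibition halo = more resistant)."""
    specs = []
    for attr in HALO_ATTRIBUTES.values():
        specs.append(maut.AttributeSpec(attr, "plant_growth", 0.0, 1.5, 5.0))
    for attr in BROTH_ATTRIBUTES.values():
        specs.append(maut.AttributeSpec(attr, "plant_growth", 0.0, 40.0, 100.0))
    specs.append(maut.AttributeSpec("Sph", "plant_growth", 0.0, 50.0, 100.0))
    specs.append(maut.AttributeSpec("Sw", "colonization", 0.0, 4.0, 8.0))
    specs.append(maut.AttributeSpec("Ss", "colonization", 0.0, 3.0, 8.0))
    specs.append(maut.AttributeSpec("ros", "colonization", 0.0, 3.0, 6.0,
                                    direction="decreasing"))
    specs.append(maut.AttributeSpec("BfM", "colonization", 0.0, 0.5, 1.0))
    for attr in ("BfpH", "BfT", "Bfrk"):
        specs.append(maut.AttributeSpec(attr, "persistence", 0.0, 0.5, 1.0))
    for substrate in FIG5_SUBSTRATES:
        specs.append(maut.AttributeSpec(substrate, "persistence",
                                        0.0, 0.008, 0.02))
    return specs


def default_scenarios() -> list:
    """Three selection scenarios: growth-dominated, growth+colonization,
    and equal criterion weights."""
    return [
        maut.ScenarioWeights("scenario1", {"plant_growth": 0.5,
                                           "colonization": 0.25,
                                           "persistence": 0.25}),
        maut.ScenarioWeights("scenario2", {"plant_growth": 0.4,
                                           "colonization": 0.4,
                                           "persistence": 0.2}),
        maut.ScenarioWeights("scenario3", {"plant_growth": 1 / 3,
                                           "colonization": 1 / 3,
                                           "persistence": 1 / 3}),
    ]


# ---------------------------------------------------------------------------
# full study bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """Every synthetic assay table plus the matching MAUT configuration."""

    config: SyntheticConfig
    tables: dict                   # assay_id -> AssayTable
    attribute_specs: list
    scenarios: list


def generate_full_study(cfg: SyntheticConfig | None = None) -> StudyBundle:
    """One call generating every assay table of the screening campaign
    together with the attribute/scenario config, so the full pipeline can
    run to a ranking with no external input."""
    cfg = cfg or SyntheticConfig()
    tables = {
        "halo_nbrip": generate_halo_assay(cfg),
        "phosphate_broth": generate_broth_solubilization(cfg),
        "cas": generate_cas_assay(cfg),
        "swimming": generate_motility_assay(cfg),
        "surface_spreading": generate_spreading_assay(cfg),
        "ros": generate_ros_assay(cfg),
        "biofilm": generate_biofilm_assay(cfg),
        "ecoplate": generate_ecoplate(cfg),
    }
    return StudyBundle(config=cfg, tables=tables,
                       attribute_specs=default_attribute_specs(),
                       scenarios=default_scenarios())


def write_study(bundle: StudyBundle, outdir) -> dict:
    """Write every table as long CSV plus the MAUT YAML config and a
    manifest recording the seed and SHA-256 of each file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for assay_id, table in bundle.tables.items():
        path = outdir / f"{assay_id}.csv"
        write_assay_table(table, path)
        files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    cfg_path = outdir / "maut_config.yaml"
    maut.dump_maut_config(bundle.attribute_specs, bundle.scenarios, cfg_path)
    files[cfg_path.name] = hashlib.sha256(cfg_path.read_bytes()).hexdigest()
    manifest = {
        "seed": int(bundle.config.seed),
        "n_strains": bundle.config.n_strains,
        "n_replicates": bundle.config.n_replicates,
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_study_tables(indir) -> dict:
    """Re-read the assay CSVs written by :func:`write_study`."""
    from .assay_model import read_assay_table
    indir = Path(indir)
    tables = {}
    for path in sorted(indir.glob("*.csv")):
        tables[path.stem] = read_assay_table(path, layout="long_csv")
    return tables
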