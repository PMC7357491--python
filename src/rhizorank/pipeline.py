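"""End-to-end orchestration: assay tables → performance → scores → ranking.

`estimate_performance` applies, per assay, the model the study design
calls for and extracts the adjusted (estimated marginal) means that become
MAUT performance values:

===================  =====================================================
assay                model and extracted estimand
===================  =====================================================
halo_nbrip           per phosphorus source: LM log1p(area) ~ strain x time,
                     strain means at 48 h, back-transformed (Pca/Pfe/Prk)
phosphate_broth      per medium: LM concentration ~ strain (PMY…PFN)
cas                  mean absorbance per strain x 100 (percent units, Sph)
swimming             LM log1p(area) ~ strain x time, strain means at 48 h
surface_spreading    LMM log1p(area) ~ strain x time_h + (1 | plate),
                     time continuous, strain means at the mean time (Ss)
ros                  LM log1p(area) ~ strain + concentration, strain means
                     at the mean concentration (ros)
biofilm              LM absorbance ~ strain x condition, cell means
                     (BfM/BfpH/BfT/Bfrk) with Tukey letters per cell
ecoplate             per strain x substrate slope of OD on time with
                     plate intercepts, gated to significant positive
                     velocities (one attribute per substrate)
===================  =====================================================

log1p-fitted means are back-transformed with expm1 so the performance
matrix lives on the measurement scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import maut
from .assay_model import AssayTable, halo_area
from .errors import CompletenessError
from .estimation import (ALPHA_DEFAULT, ModelSpec, PerformanceEntry,
                         PerformanceMatrix, build_performance_matrix,
                         degradation_velocities, fit_model, marginal_means,
                         siderophore_percent, tukey_pairwise)
from .synthetic import (BIOFILM_ATTRIBUTES, BROTH_ATTRIBUTES, HALO_ATTRIBUTES,
                        SyntheticConfig, generate_full_study)

REQUIRED_ASSAYS = ("halo_nbrip", "phosphate_broth", "cas", "swimming",
                   "surface_spreading", "ros", "biofilm", "ecoplate")


def _fmt_num(x: float) -> str:
    """Factor-level label for a numeric column (48.0 -> '48')."""
    return f"{float(x):g}"


@dataclass
class EstimationReport:
    """Performance matrix plus the per-assay inference behind it."""

    performance: PerformanceMatrix
    marginal_tables: dict     # label -> marginal means DataFrame
    letters: dict             # label -> compact letter display dict
    velocities: object        # VelocityMatrix for the EcoPlate assay
    alpha: float


def estimate_performance(tables: dict, alpha: float = ALPHA_DEFAULT) -> EstimationReport:
    """Run every assay's model and assemble the performance matrix."""
    missing = [a for a in REQUIRED_ASSAYS if a not in tables]
    if missing:
        raise CompletenessError(f"missing assay table(s): {missing}", missing)

    entries = []
    marginals = {}
    letters = {}

    # --- phosphate solubilization halos (per phosphorus source) ---------
    halo = tables["halo_nbrip"].df.copy()
    halo["area_cm2"] = halo_area(halo["r1_cm"], halo["r2_cm"])
    halo["time_f"] = halo["time_h"].map(_fmt_num)
    for cond, attr in HALO_ATTRIBUTES.items():
        sub = halo[halo["condition"] == cond]
        fit = fit_model(sub, ModelSpec(
            response="area_cm2", fixed_factors=["strain", "time_f"],
            interactions=[("strain", "time_f")], transform="log1p"))
        mm = marginal_means(fit, "strain", at={"time_f": "48"})
        marginals[attr] = mm
        letters[attr] = tukey_pairwise(fit, "strain", alpha,
                                       at={"time_f": "48"}).letters
        entries.append(PerformanceEntry(
            attr, mm["estimate"].to_dict(), "halo_nbrip", "cm2",
            scale="log1p"))

    # --- broth solubilization (per medium) -------------------------------
    broth = tables["phosphate_broth"].df
    for cond, attr in BROTH_ATTRIBUTES.items():
        sub = broth[broth["condition"] == cond]
        fit = fit_model(sub, ModelSpec(response="value",
                                       fixed_factors=["strain"]))
        mm = marginal_means(fit, "strain")
        marginals[attr] = mm
        letters[attr] = tukey_pairwise(fit, "strain", alpha).letters
        entries.append(PerformanceEntry(
            attr, mm["estimate"].to_dict(), "phosphate_broth", "mg_per_L"))

    # --- siderophore units (CAS) -----------------------------------------
    cas = tables["cas"].df
    fit = fit_model(cas, ModelSpec(response="value", fixed_factors=["strain"]))
    mm = marginal_means(fit, "strain")
    marginals["Sph"] = mm
    letters["Sph"] = tukey_pairwise(fit, "strain", alpha).letters
    entries.append(PerformanceEntry(
        "Sph", {s: siderophore_percent(max(v, 0.0))
                for s, v in mm["estimate"].items()},
        "cas", "percent"))

    # --- swimming motility ------------------------------------------------
    swim = tables["swimming"].df.copy()
    swim["time_f"] = swim["time_h"].map(_fmt_num)
    fit = fit_model(swim, ModelSpec(
        response="value", fixed_factors=["strain", "time_f"],
        interactions=[("strain", "time_f")], transform="log1p"))
    mm = marginal_means(fit, "strain", at={"time_f": "48"})
    marginals["Sw"] = mm
    letters["Sw"] = tukey_pairwise(fit, "strain", alpha,
                                   at={"time_f": "48"}).letters
    entries.append(PerformanceEntry("Sw", mm["estimate"].to_dict(),
                                    "swimming", "cm2", scale="log1p"))

    # --- surface spreading (repeated measures per plate) ------------------
    spread = tables["surface_spreading"].df
    fit = fit_model(spread, ModelSpec(
        response="value", fixed_factors=["strain"],
        continuous_covariates=["time_h"],
        interactions=[("strain", "time_h")],
        random_intercept="unit", transform="log1p"))
    mm = marginal_means(fit, "strain")  # at the mean time
    marginals["Ss"] = mm
    letters["Ss"] = tukey_pairwise(fit, "strain", alpha).letters
    entries.append(PerformanceEntry("Ss", mm["estimate"].to_dict(),
                                    "surface_spreading", "cm2",
                                    scale="log1p"))

    # --- peroxide sensitivity ---------------------------------------------
    ros = tables["ros"].df.copy()
    ros["conc_mM"] = ros["condition"].astype(float)
    fit = fit_model(ros, ModelSpec(
        response="value", fixed_factors=["strain"],
        continuous_covariates=["conc_mM"], transform="log1p"))
    mm = marginal_means(fit, "strain")  # at the mean concentration
    marginals["ros"] = mm
    letters["ros"] = tukey_pairwise(fit, "strain", alpha).letters
    entries.append(PerformanceEntry("ros", mm["estimate"].to_dict(),
                                    "ros", "cm2", scale="log1p"))

    # --- biofilm formation (strain x condition cell means) ----------------
    biofilm = tables["biofilm"].df
    fit = fit_model(biofilm, ModelSpec(
        response="value", fixed_factors=["strain", "condition"],
        interactions=[("strain", "condition")]))
    cells = marginal_means(fit, ["strain", "condition"])
    letters["biofilm"] = tukey_pairwise(fit, ["strain", "condition"],
                                        alpha).letters
    marginals["biofilm"] = cells
    for cond, attr in BIOFILM_ATTRIBUTES.items():
        per_strain = {
            level.split(":")[0]: est
            for level, est in cells["estimate"].items()
            if level.split(":")[1] == cond}
        entries.append(PerformanceEntry(attr, per_strain, "biofilm",
                                        "absorbance"))

    # --- carbon-source degradation velocities -----------------------------
    vm = degradation_velocities(tables["ecoplate"], alpha)
    for substrate in vm.velocities.columns:
        entries.append(PerformanceEntry(
            substrate, vm.velocities[substrate].to_dict(),
            "ecoplate", "od_per_h"))

    strains = sorted(tables["cas"].df["strain"].unique())
    perf = build_performance_matrix(entries, strains=strains)
    return EstimationReport(performance=perf, marginal_tables=marginals,
                            letters=letters, velocities=vm, alpha=alpha)


# ---------------------------------------------------------------------------
# scoring and ranking
# ---------------------------------------------------------------------------

@dataclass
class RankReport:
    """Scores, per-scenario rankings and the cross-scenario comparison."""

    scores: maut.ScoreMatrix
    results: list
    comparison: maut.ScenarioComparison

    def ranking_frame(self) -> pd.DataFrame:
        """Long-format ranking table (one row per strain x scenario)."""
        frames = []
        for r in self.results:
            t = r.table.copy()
            t.insert(0, "scenario", r.scenario_id)
            frames.append(t.rename_axis("strain").reset_index())
        return pd.concat(frames, ignore_index=True)


def rank_strains(perf: PerformanceMatrix, specs, scenarios) -> RankReport:
    """Score the declared attributes and rank strains per scenario."""
    spec_list = list(specs)
    perf_sel = perf.select([s.attribute_id for s in spec_list])
    scores = maut.score_matrix(perf_sel, spec_list)
    results = [maut.rank_scenario(scores, sc, spec_list) for sc in scenarios]
    comparison = maut.compare_scenarios(results)
    return RankReport(scores=scores, results=results, comparison=comparison)


def run_full_study(cfg: SyntheticConfig | None = None,
                   alpha: float = ALPHA_DEFAULT):
    """Simulate the whole campaign and rank the strains.

    Returns ``(bundle, estimation_report, rank_report)``.
    """
    bundle = generate_full_study(cfg)
    est = estimate_performance(bundle.tables, alpha=alpha)
    rank = rank_strains(est.performance, bundle.attribute_specs,
                        bundle.scenarios)
    return bundle, est, rank
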