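"""Multiattribute utility scoring and scenario ranking.

Performance values are mapped to 0–1 scores with exponential
single-attribute value functions anchored at elicited minimum, midpoint
and maximum values:

    v(x) = (1 - exp(-(x - v_min) / rho)) / (1 - exp(-(v_max - v_min) / rho))

where the curvature ``rho`` is solved (bisection) so that ``v(v_mid) = 0.5``.
When the midpoint sits exactly halfway between the anchors the function
degenerates to the linear ramp ``(x - v_min) / (v_max - v_min)``; this limit
is represented by ``rho = inf``.  Decreasing-preference attributes (e.g. a
hydrogen-peroxide sensitivity halo, where a smaller halo means a more
resistant strain) evaluate the same function at the reflected value
``v_min + v_max - x``.  Out-of-anchor performance values are clamped, with
the clamp recorded per cell.

Criterion weights (plant growth / colonization / persistence) are
normalised to sum to one and split equally across the attributes of each
criterion; the total score per strain and scenario is the linear weighted
sum of attribute scores, and strains are ranked by descending total.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import CompletenessError, ConfigError, DomainError, IntegrityError

CRITERIA = ("plant_growth", "colonization", "persistence")

#: curvature marker for the linear (midpoint-symmetric) limit
LINEAR = math.inf


@dataclass(frozen=True)
class AttributeSpec:
    """Anchors and preference direction of one attribute's value function."""

    attribute_id: str
    criterion: str
    v_min: float
    v_mid: float
    v_max: float
    direction: str = "increasing"

    def __post_init__(self):
        if self.criterion not in CRITERIA:
            raise ConfigError(f"unknown criterion {self.criterion!r}")
        if self.direction not in ("increasing", "decreasing"):
            raise ConfigError(f"unknown direction {self.direction!r}")
        if not (self.v_min < self.v_max):
            raise DomainError("anchors require v_min < v_max")
        if not (self.v_min < self.v_mid < self.v_max):
            raise DomainError("anchors require v_min < v_mid < v_max")


def solve_curvature(spec: AttributeSpec, tol: float = 1e-10) -> float:
    """Curvature ``rho`` of the exponential value function through
    ``(v_mid, 0.5)``; returns :data:`LINEAR` (``inf``) when the midpoint is
    central within ``tol`` (relative to the anchor range).

    The root is bracketed and bisected on the normalised curvature
    ``c = (v_max - v_min) / rho`` over ``|c|`` in ``[1e-6, 1e6]``.
    """
    rng = spec.v_max - spec.v_min
    u = (spec.v_mid - spec.v_min) / rng
    if spec.direction == "decreasing":
        # the elicited midpoint is reflected with the argument, so solve at
        # the reflected position to keep v(v_mid) = 0.5
        u = 1.0 - u
    if abs(u - 0.5) <= max(tol, 1e-12):
        return LINEAR

    # value of the normalised exponential function at the midpoint, in a
    # form stable for both curvature signs (c = range / rho)
    def vmid(c):
        if c > 0:
            return np.expm1(-u * c) / np.expm1(-c)
        d = -c
        return np.exp((u - 1.0) * d) * np.expm1(-u * d) / np.expm1(-d)

    # v(mid) rises from u (c -> 0) to 1 (c -> +inf) and falls to 0 as
    # c -> -inf, so the root is concave (c > 0) when u < 0.5, convex else.
    lo, hi = 1e-6, 1e6
    sign = 1.0 if u < 0.5 else -1.0
    f = lambda c: vmid(sign * c) - 0.5
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        # root outside the capped |c| range: below the floor the function
        # is indistinguishable from linear; above the ceiling return the
        # maximal curvature of the allowed family
        if (sign > 0) == (flo > 0):
            return LINEAR
        return rng / (sign * hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) <= tol or (hi - lo) <= tol * max(1.0, lo):
            lo = hi = mid
            break
        if flo * fm <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
    c = sign * 0.5 * (lo + hi)
    return rng / c


def savf_score(x, spec: AttributeSpec, rho: float | None = None):
    """Single-attribute value score in [0, 1] for performance ``x``.

    ``x`` may be a scalar or array; it is clamped to the anchor interval
    before evaluation (the documented out-of-range policy).
    """
    if rho is None:
        rho = solve_curvature(spec)
    xv = np.clip(np.asarray(x, dtype=float), spec.v_min, spec.v_max)
    if spec.direction == "decreasing":
        xv = spec.v_min + spec.v_max - xv
    rng = spec.v_max - spec.v_min
    t = (xv - spec.v_min) / rng
    if math.isinf(rho):
        out = t
    else:
        c = rng / rho
        if c > 0:
            out = np.expm1(-t * c) / np.expm1(-c)
        else:
            d = -c
            out = np.exp((t - 1.0) * d) * np.expm1(-t * d) / np.expm1(-d)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class ScoreMatrix:
    """Strain × attribute utility scores in [0, 1], with a per-cell record
    of whether the performance value had to be clamped to the anchors."""

    values: pd.DataFrame
    clamped: pd.DataFrame


def score_matrix(perf, specs) -> ScoreMatrix:
    """Elementwise :func:`savf_score` over a performance matrix.

    ``perf`` is a :class:`~rhizorank.estimation.PerformanceMatrix` (or its
    values frame); every attribute column must have a spec.
    """
    values = perf.values if hasattr(perf, "values") and isinstance(
        getattr(perf, "values"), pd.DataFrame) else pd.DataFrame(perf)
    spec_map = _spec_map(specs)
    missing = [a for a in values.columns if a not in spec_map]
    if missing:
        raise CompletenessError(
            f"no attribute spec for: {missing}", missing)
    scores = pd.DataFrame(index=values.index, dtype=float)
    clamped = pd.DataFrame(index=values.index, dtype=bool)
    for a in values.columns:
        spec = spec_map[a]
        rho = solve_curvature(spec)
        x = values[a].to_numpy(float)
        scores[a] = savf_score(x, spec, rho)
        clamped[a] = (x < spec.v_min) | (x > spec.v_max)
    return ScoreMatrix(values=scores, clamped=clamped)


# ---------------------------------------------------------------------------
# scenarios, weights, aggregation
# ---------------------------------------------------------------------------

@dataclass
class ScenarioWeights:
    """Raw criterion weights defining one selection scenario; normalised to
    sum to one on construction."""

    scenario_id: str
    criterion_weights: dict

    def __post_init__(self):
        w = {c: float(self.criterion_weights.get(c, 0.0)) for c in CRITERIA}
        if any(v < 0 for v in w.values()):
            raise ConfigError("criterion weights must be >= 0")
        total = sum(w.values())
        if total <= 0:
            raise ConfigError("at least one criterion weight must be > 0")
        self.criterion_weights = {c: v / total for c, v in w.items()}


def _spec_map(specs) -> dict:
    if isinstance(specs, dict):
        return specs
    return {s.attribute_id: s for s in specs}


def attribute_weights(scenario: ScenarioWeights, specs) -> dict:
    """Split each normalised criterion weight equally across the criterion's
    attributes; the returned per-attribute weights sum to one."""
    spec_map = _spec_map(specs)
    counts = {c: 0 for c in CRITERIA}
    for s in spec_map.values():
        counts[s.criterion] += 1
    for c, w in scenario.criterion_weights.items():
        if w > 0 and counts[c] == 0:
            raise ConfigError(
                f"criterion {c!r} has weight {w} but no attributes")
    return {a: scenario.criterion_weights[s.criterion] / counts[s.criterion]
            for a, s in spec_map.items()}


@dataclass
class RankingResult:
    """Per-strain totals, per-criterion subtotals and ranks for one scenario."""

    scenario_id: str
    table: pd.DataFrame   # index strain: total, subtotal_<criterion>, rank, tied

    @property
    def ranks(self) -> pd.Series:
        return self.table["rank"]

    def top_strain(self) -> str:
        return self.table["rank"].idxmin()


def total_scores(scores: ScoreMatrix, weights: dict, specs,
                 scenario_id: str = "scenario") -> RankingResult:
    """Linear weighted sum of attribute scores per strain, with
    per-criterion weighted subtotals and a deterministic ranking
    (descending total; ties broken lexicographically by strain id and
    flagged)."""
    values = scores.values
    missing = [a for a in values.columns if a not in weights]
    extra = [a for a in weights if a not in values.columns]
    if missing or extra:
        raise CompletenessError(
            f"weight/score attribute mismatch: missing weights {missing}, "
            f"unmatched weights {extra}", tuple(missing) + tuple(extra))
    wsum = sum(weights.values())
    if abs(wsum - 1.0) > 1e-9:
        raise DomainError(f"attribute weights must sum to 1 (got {wsum!r})")
    spec_map = _spec_map(specs)

    rows = {}
    for crit in CRITERIA:
        attrs = [a for a in values.columns if spec_map[a].criterion == crit]
        w = np.array([weights[a] for a in attrs])
        sub = values[attrs].to_numpy(float) @ w if attrs else \
            np.zeros(len(values))
        rows[f"subtotal_{crit}"] = sub
    table = pd.DataFrame(rows, index=values.index)
    table["total"] = table.sum(axis=1)

    order = sorted(table.index, key=lambda s: (-table.at[s, "total"], str(s)))
    table["rank"] = pd.Series({s: i + 1 for i, s in enumerate(order)})
    totals = table["total"]
    table["tied"] = [
        bool((np.isclose(totals.drop(s), totals[s], rtol=0, atol=1e-12)).any())
        for s in table.index]
    cols = ["total"] + [f"subtotal_{c}" for c in CRITERIA] + ["rank", "tied"]
    return RankingResult(scenario_id=scenario_id, table=table[cols])


def rank_scenario(scores: ScoreMatrix, scenario: ScenarioWeights,
                  specs) -> RankingResult:
    """Convenience: weights + totals for one scenario."""
    w = attribute_weights(scenario, specs)
    return total_scores(scores, w, specs, scenario_id=scenario.scenario_id)


@dataclass
class ScenarioComparison:
    """Totals and ranks side by side across scenarios, with rank reversals."""

    totals: pd.DataFrame      # strains x scenarios
    ranks: pd.DataFrame       # strains x scenarios
    reversals: list           # dicts: scenario_a/b, strain_x/y

    @property
    def has_reversals(self) -> bool:
        return bool(self.reversals)


def compare_scenarios(results) -> ScenarioComparison:
    """Tabulate totals/ranks per scenario and flag pairwise rank reversals
    (a strain pair whose order flips between two scenarios)."""
    results = list(results)
    if not results:
        raise IntegrityError("no scenarios to compare")
    strains = list(results[0].table.index)
    for r in results[1:]:
        if list(r.table.index) != strains:
            raise IntegrityError("scenario results cover different strains")
    totals = pd.DataFrame({r.scenario_id: r.table["total"] for r in results})
    ranks = pd.DataFrame({r.scenario_id: r.table["rank"] for r in results})
    reversals = []
    for ra, rb in itertools.combinations(results, 2):
        for x, y in itertools.combinations(strains, 2):
            da = ra.table.at[x, "rank"] - ra.table.at[y, "rank"]
            db = rb.table.at[x, "rank"] - rb.table.at[y, "rank"]
            if da * db < 0:
                reversals.append({"scenario_a": ra.scenario_id,
                                  "scenario_b": rb.scenario_id,
                                  "strain_x": x, "strain_y": y})
    return ScenarioComparison(totals=totals, ranks=ranks, reversals=reversals)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_maut_config(path):
    """Read attribute specs and scenarios from one YAML file.

    Schema::

        attributes:
          - {id, criterion, direction, min, mid, max}
        scenarios:
          - {id, weights: {plant_growth, colonization, persistence}}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "attributes" not in raw:
        raise ConfigError("config must be a mapping with an 'attributes' list")
    specs = [AttributeSpec(attribute_id=str(a["id"]),
                           criterion=a["criterion"],
                           direction=a.get("direction", "increasing"),
                           v_min=float(a["min"]), v_mid=float(a["mid"]),
                           v_max=float(a["max"]))
             for a in raw["attributes"]]
    ids = [s.attribute_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate attribute ids in config")
    scenarios = [ScenarioWeights(scenario_id=str(s["id"]),
                                 criterion_weights=dict(s["weights"]))
                 for s in raw.get("scenarios", [])]
    return specs, scenarios


def dump_maut_config(specs, scenarios, path) -> None:
    """Write the YAML config consumed by :func:`load_maut_config`."""
    payload = {
        "attributes": [
            {"id": s.attribute_id, "criterion": s.criterion,
             "direction": s.direction, "min": float(s.v_min),
             "mid": float(s.v_mid), "max": float(s.v_max)}
            for s in specs],
        "scenarios": [
            {"id": sc.scenario_id,
             "weights": {c: float(w)
                         for c, w in sc.criterion_weights.items()}}
            for sc in scenarios],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
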