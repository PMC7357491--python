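"""Per-strain performance estimation from raw assay tables.

This module turns long-format assay measurements into the adjusted
performance values that feed the multicriteria ranking:

* :func:`fit_model` — ordinary least squares or a random-intercept linear
  mixed model (REML via statsmodels) from a declarative :class:`ModelSpec`;
* :func:`marginal_means` — estimated (adjusted) marginal means: model
  predictions averaged over a balanced reference grid of the other factors;
* :func:`tukey_pairwise` — all-pairs comparisons with studentized-range
  adjusted p-values and a compact letter display;
* :func:`degradation_velocities` — per strain × substrate OD-vs-time slopes
  with plate-level intercepts, gated to zero unless significantly positive;
* :func:`siderophore_percent` / :func:`capture_contrast` — chrome azurol S
  quantification rules;
* :func:`build_performance_matrix` — assembling the strain × attribute
  performance matrix, back-transforming log1p-scale means with expm1.

Degrees of freedom for mixed models use a residual-df approximation
(observations minus fixed effects minus between-group parameters) rather
than Kenward-Roger; at three replicates per cell the difference is
immaterial for the 0.05 decisions made downstream.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import scipy.linalg
import scipy.stats as st
import statsmodels.formula.api as smf

from .assay_model import AssayTable, log1p_transform
from .errors import (CompletenessError, DesignError, DomainError,
                     SingularDesignError)

ALPHA_DEFAULT = 0.05


# ---------------------------------------------------------------------------
# model specification and fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Declarative description of the linear (mixed) models used here.

    Only the structures the screening pipeline needs are expressible:
    categorical fixed factors with treatment coding (first level
    alphabetically as reference), continuous covariates, factor/covariate
    interactions, at most one random intercept, and an optional log1p
    response transform.
    """

    response: str
    fixed_factors: list = field(default_factory=list)
    continuous_covariates: list = field(default_factory=list)
    interactions: list = field(default_factory=list)
    random_intercept: str | None = None
    transform: str = "none"  # "none" | "log1p"

    def __post_init__(self):
        if self.transform not in ("none", "log1p"):
            raise DesignError(f"unknown transform {self.transform!r}")
        if self.random_intercept in self.fixed_factors:
            raise DesignError("random intercept cannot also be a fixed factor")

    def _term(self, name: str) -> str:
        if name in self.fixed_factors:
            return f'C(Q("{name}"))'
        return f'Q("{name}")'

    def formula(self) -> str:
        terms = [self._term(f) for f in self.fixed_factors]
        terms += [self._term(c) for c in self.continuous_covariates]
        for inter in self.interactions:
            terms.append(":".join(self._term(t) for t in inter))
        rhs = " + ".join(terms) if terms else "1"
        return f'Q("{self.response}") ~ {rhs}'


@dataclass
class FitResult:
    """A fitted LM/LMM reduced to what inference downstream needs."""

    spec: ModelSpec
    params: pd.Series              # fixed-effect coefficients
    cov: pd.DataFrame              # their covariance
    df_resid: float
    sigma2: float
    n_obs: int
    model_type: str                # "ols" | "lmm"
    design_info: object            # patsy design info for prediction
    factor_levels: dict
    covariate_means: dict
    group_var: float | None = None

    @property
    def coefficients(self) -> pd.Series:
        return self.params


def _prepare_frame(table, spec: ModelSpec) -> pd.DataFrame:
    df = table.df if isinstance(table, AssayTable) else table
    cols = ([spec.response] + list(spec.fixed_factors)
            + list(spec.continuous_covariates))
    if spec.random_intercept:
        cols.append(spec.random_intercept)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DesignError(f"column(s) not in table: {', '.join(missing)}")
    df = df[cols].copy().reset_index(drop=True)
    if spec.transform == "log1p":
        df[spec.response] = log1p_transform(df[spec.response].to_numpy())
    for f in spec.fixed_factors:
        df[f] = df[f].astype(str)
    return df


def _check_design(exog: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, r, piv = scipy.linalg.qr(exog, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(exog.shape) * np.finfo(float).eps
        aliased = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [names[j] for j in piv[len(diag):]]
        raise SingularDesignError(
            f"rank-deficient design; aliased term(s): {aliased}", aliased)


def fit_model(table, spec: ModelSpec) -> FitResult:
    """Fit the model described by ``spec`` to ``table``.

    OLS when no random intercept is declared; otherwise a random-intercept
    mixed model fitted by REML.  A mixed fit that fails to converge (e.g.
    zero residual variance in noiseless data) falls back to OLS with a
    warning — the fixed-effect estimates coincide in the balanced designs
    this pipeline produces.
    """
    df = _prepare_frame(table, spec)
    for f in spec.fixed_factors:
        if df[f].nunique() < 2:
            raise DesignError(f"fixed factor {f!r} has < 2 levels")

    formula = spec.formula()
    model = smf.ols(formula, data=df)
    exog = np.asarray(model.exog)
    if df.shape[0] <= exog.shape[1]:
        raise DesignError("more coefficients than observations")
    _check_design(exog, list(model.exog_names))

    factor_levels = {f: sorted(df[f].unique()) for f in spec.fixed_factors}
    cov_means = {c: float(df[c].mean()) for c in spec.continuous_covariates}

    if spec.random_intercept is None:
        res = model.fit()
        return FitResult(
            spec=spec, params=res.params, cov=res.cov_params(),
            df_resid=float(res.df_resid), sigma2=float(res.scale),
            n_obs=int(res.nobs), model_type="ols",
            design_info=model.data.design_info,
            factor_levels=factor_levels, covariate_means=cov_means)

    groups = df[spec.random_intercept].astype(str)
    n_groups = groups.nunique()
    if n_groups < 2:
        raise DesignError("random intercept grouping needs >= 2 units")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mlm = smf.mixedlm(formula, data=df, groups=groups)
            res = mlm.fit(reml=True, method=["lbfgs", "powell"])
        k_fe = len(res.fe_params)
        cov_fe = res.cov_params().iloc[:k_fe, :k_fe]
        ok = (res.converged and np.isfinite(res.fe_params).all()
              and np.isfinite(cov_fe.to_numpy()).all())
    except Exception:
        ok = False
    if not ok:
        warnings.warn("mixed-model fit failed to converge; "
                      "falling back to OLS for the fixed effects")
        res_ols = model.fit()
        return FitResult(
            spec=spec, params=res_ols.params, cov=res_ols.cov_params(),
            df_resid=float(res_ols.df_resid), sigma2=float(res_ols.scale),
            n_obs=int(res_ols.nobs), model_type="lmm",
            design_info=model.data.design_info,
            factor_levels=factor_levels, covariate_means=cov_means,
            group_var=0.0)

    df_resid = max(float(len(df) - k_fe - (n_groups - 1)), 1.0)
    return FitResult(
        spec=spec, params=res.fe_params, cov=cov_fe,
        df_resid=df_resid, sigma2=float(res.scale),
        n_obs=len(df), model_type="lmm",
        design_info=mlm.data.design_info,
        factor_levels=factor_levels, covariate_means=cov_means,
        group_var=float(np.asarray(res.cov_re).ravel()[0]))


# ---------------------------------------------------------------------------
# estimated marginal means and pairwise comparisons
# ---------------------------------------------------------------------------

def _reference_grid(fit: FitResult, at: dict | None) -> pd.DataFrame:
    at = dict(at or {})
    columns, level_sets = [], []
    for f, levels in fit.factor_levels.items():
        columns.append(f)
        if f in at:
            v = str(at.pop(f))
            if v not in levels:
                raise KeyError(f"{v!r} is not a level of factor {f!r}")
            level_sets.append([v])
        else:
            level_sets.append(list(levels))
    grid = pd.DataFrame(list(itertools.product(*level_sets)), columns=columns) \
        if columns else pd.DataFrame(index=[0])
    for c, m in fit.covariate_means.items():
        grid[c] = float(at.pop(c, m))
    if at:
        raise KeyError(f"unknown column(s) in `at`: {sorted(at)}")
    return grid.reset_index(drop=True)


def _level_contrasts(fit: FitResult, factor, at=None):
    """Return (levels, L) with one equal-weight contrast row per level
    (or level combination) of ``factor``, averaging over the remaining
    factors' levels and holding covariates at their data means."""
    factors = [factor] if isinstance(factor, str) else list(factor or [])
    for f in factors:
        if f not in fit.factor_levels:
            raise KeyError(f"factor {f!r} was not in the fitted design")
    grid = _reference_grid(fit, at)
    X = patsy.build_design_matrices([fit.design_info], grid,
                                    return_type="dataframe")[0]
    if not factors:  # grand mean
        return [("(all)",)], X.to_numpy().mean(axis=0, keepdims=True)
    combos = sorted(set(map(tuple, grid[factors].itertuples(index=False))))
    L = np.vstack([
        X.loc[(grid[factors] == pd.Series(dict(zip(factors, combo)))).all(axis=1)]
        .to_numpy().mean(axis=0)
        for combo in combos])
    return combos, L


def _fmt_level(combo) -> str:
    return combo[0] if len(combo) == 1 else ":".join(map(str, combo))


def marginal_means(fit: FitResult, factor=None, at: dict | None = None) -> pd.DataFrame:
    """Estimated marginal means for ``factor`` (a name, a list of names for
    cell combinations, or None for the grand mean).

    ``at`` pins selected factors to a single level or covariates to a fixed
    value (e.g. ``at={"time_h": "48"}`` for the 48-h adjusted means);
    everything else is averaged with equal weight per level.
    Estimates stay on the model (possibly log1p) scale.
    """
    combos, L = _level_contrasts(fit, factor, at)
    beta = fit.params.to_numpy()
    cov = fit.cov.to_numpy()
    est = L @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", L, cov, L), 0.0))
    return pd.DataFrame({
        "level": [_fmt_level(c) for c in combos],
        "estimate": est, "se": se, "df": fit.df_resid,
    }).set_index("level")


@dataclass
class PairwiseComparison:
    """All-pairs Tukey comparisons plus a compact letter display."""

    pairs: pd.DataFrame       # level_a, level_b, difference, se, q, p_adjusted
    letters: dict             # level -> letter string
    alpha: float


def compact_letter_display(levels, significant_pairs) -> dict:
    """Insertion-and-absorption compact letter display.

    Levels sharing a letter are not significantly different.  Deterministic:
    letter columns are ordered by the first level (in input order) they
    contain, ties broken by column size.
    """
    levels = list(levels)
    order = {lv: i for i, lv in enumerate(levels)}
    cols = [frozenset(levels)]
    for a, b in significant_pairs:
        nxt = []
        for col in cols:
            if a in col and b in col:
                nxt.append(col - {a})
                nxt.append(col - {b})
            else:
                nxt.append(col)
        # absorb columns contained in another
        cols = [c for c in set(nxt)
                if c and not any(c < d for d in nxt)]
    cols.sort(key=lambda c: (min(order[lv] for lv in c), -len(c)))
    letters = {lv: "" for lv in levels}
    for i, col in enumerate(cols):
        letter = _letter(i)
        for lv in col:
            letters[lv] += letter
    return {lv: "".join(sorted(s)) for lv, s in letters.items()}


def _letter(i: int) -> str:
    out = ""
    i += 1
    while i:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("A") + rem) + out
    return out


def tukey_pairwise(fit: FitResult, factor, alpha: float = ALPHA_DEFAULT,
                   at: dict | None = None) -> PairwiseComparison:
    """Tukey HSD on the marginal means of ``factor``.

    The studentized-range statistic is ``q = sqrt(2) |diff| / se(diff)``
    with the fit's residual df; p-values are two-sided by construction of
    the range distribution.  With two levels this reduces to the pooled
    two-sample t-test.
    """
    if not 0 < alpha < 1:
        raise DomainError("alpha must lie in (0, 1)")
    combos, L = _level_contrasts(fit, factor, at)
    if len(combos) < 2:
        raise DesignError("Tukey comparisons need >= 2 levels")
    beta = fit.params.to_numpy()
    cov = fit.cov.to_numpy()
    k = len(combos)
    rows, sig = [], []
    names = [_fmt_level(c) for c in combos]
    for i, j in itertools.combinations(range(k), 2):
        l = L[i] - L[j]
        diff = float(l @ beta)
        se = float(np.sqrt(max(l @ cov @ l, 0.0)))
        if se <= 0:
            q = np.inf if abs(diff) > 0 else 0.0
            p = 0.0 if abs(diff) > 0 else 1.0
        else:
            q = abs(diff) / se * np.sqrt(2.0)
            p = float(st.studentized_range.sf(q, k, fit.df_resid))
        p = min(max(p, 0.0), 1.0)
        rows.append({"level_a": names[i], "level_b": names[j],
                     "difference": diff, "se": se, "q": q, "p_adjusted": p})
        if p < alpha:
            sig.append((names[i], names[j]))
    letters = compact_letter_display(names, sig)
    return PairwiseComparison(pairs=pd.DataFrame(rows), letters=letters,
                              alpha=alpha)


# ---------------------------------------------------------------------------
# degradation velocities (carbon-source utilisation kinetics)
# ---------------------------------------------------------------------------

@dataclass
class VelocityMatrix:
    """Strain × substrate degradation velocities (OD/h).

    ``velocities`` holds the gated values (0 where not a significant
    positive slope); ``flags`` records ``significant_slope`` vs
    ``gated_to_zero`` per cell; ``slopes`` keeps the raw estimates with
    standard errors, p-values and confidence limits.
    """

    velocities: pd.DataFrame
    flags: pd.DataFrame
    slopes: pd.DataFrame
    alpha: float


def _within_plate_slope(sub: pd.DataFrame):
    """Slope of OD on time with a free intercept per plate.

    For balanced plate × time layouts this equals the REML fixed-slope
    estimate of the random-intercept model; plate intercepts are profiled
    out by within-plate centering.
    """
    t = sub["time_h"].to_numpy(float)
    y = sub["value"].to_numpy(float)
    units = sub["unit"].to_numpy()
    tc = np.empty_like(t)
    yc = np.empty_like(y)
    n_units = 0
    for u in pd.unique(units):
        m = units == u
        tc[m] = t[m] - t[m].mean()
        yc[m] = y[m] - y[m].mean()
        n_units += 1
    sxx = float(tc @ tc)
    if sxx <= 0:
        raise DesignError("no within-plate time variation")
    slope = float(tc @ yc) / sxx
    resid = yc - slope * tc
    dof = max(len(t) - n_units - 1, 1)
    sigma2 = float(resid @ resid) / dof
    if sigma2 < 1e-24:
        se = 0.0
        p = 1.0 if abs(slope) < 1e-12 else 0.0
    else:
        se = float(np.sqrt(sigma2 / sxx))
        p = float(2 * st.t.sf(abs(slope) / se, dof))
    return slope, se, p, dof


def degradation_velocities(table, alpha: float = ALPHA_DEFAULT) -> VelocityMatrix:
    """Per-(strain, substrate) OD-vs-time slopes, gated to zero unless the
    slope is both statistically significant at ``alpha`` and positive.

    Each cell needs >= 3 distinct time points; repeated measures on the
    same plate are absorbed by plate-level intercepts.
    """
    if not 0 < alpha < 1:
        raise DomainError("alpha must lie in (0, 1)")
    df = table.df if isinstance(table, AssayTable) else table
    rows = []
    for (strain, substrate), sub in df.groupby(["strain", "condition"], sort=True):
        if sub["time_h"].nunique() < 3:
            raise DesignError(
                f"insufficient data for ({strain}, {substrate}): "
                "need >= 3 time points")
        slope, se, p, dof = _within_plate_slope(sub)
        tcrit = st.t.ppf(1 - alpha / 2, dof) if se > 0 else 0.0
        gated = (p >= alpha) or (slope <= 0)
        rows.append({
            "strain": strain, "substrate": substrate, "slope": slope,
            "se": se, "p_value": p, "df": dof,
            "ci_low": slope - tcrit * se, "ci_high": slope + tcrit * se,
            "velocity": 0.0 if gated else slope,
            "flag": "gated_to_zero" if gated else "significant_slope",
        })
    slopes = pd.DataFrame(rows)
    vel = slopes.pivot(index="strain", columns="substrate", values="velocity")
    flags = slopes.pivot(index="strain", columns="substrate", values="flag")
    return VelocityMatrix(velocities=vel, flags=flags, slopes=slopes,
                          alpha=alpha)


# ---------------------------------------------------------------------------
# siderophore quantification (chrome azurol S assay)
# ---------------------------------------------------------------------------

def siderophore_percent(absorbance_630):
    """Percent siderophore units: 100 x the blank-zeroed 630-nm absorbance.

    The literal quantification rule used by the screening protocol (the
    spectrophotometer is zeroed on CAS-treated uninoculated medium, so the
    reading is already the absorbance lost to iron capture).  Values above
    100 are clipped with a warning; see :func:`cas_reference_percent` for
    the conventional reference-normalised formula.
    """
    a = np.asarray(absorbance_630, dtype=float)
    if (a < 0).any():
        raise DomainError("absorbance must be >= 0")
    pct = 100.0 * a
    if (pct > 100).any():
        warnings.warn("siderophore percent > 100 clipped to 100", stacklevel=2)
        pct = np.minimum(pct, 100.0)
    return float(pct) if pct.ndim == 0 else pct


def cas_reference_percent(sample_abs, reference_abs):
    """Conventional CAS siderophore units ``(Ar - As) / Ar * 100``."""
    ar = float(reference_abs)
    if ar <= 0:
        raise DomainError("reference absorbance must be > 0")
    a = np.asarray(sample_abs, dtype=float)
    if (a < 0).any():
        raise DomainError("absorbance must be >= 0")
    pct = (ar - a) / ar * 100.0
    return float(pct) if pct.ndim == 0 else pct


def capture_contrast(percents_group, percent_ref, ndigits: int | None = None):
    """Mean iron-capture percentage of a strain group minus a reference
    strain's percentage (e.g. mean(B02, L3) − Sp20)."""
    group = np.asarray(percents_group, dtype=float)
    if group.size == 0:
        raise DomainError("empty group")
    allv = np.append(group, percent_ref)
    if (allv < 0).any() or (allv > 100).any():
        raise DomainError("capture percentages must lie in [0, 100]")
    diff = float(group.mean() - percent_ref)
    return round(diff, ndigits) if ndigits is not None else diff


# ---------------------------------------------------------------------------
# homoscedasticity check
# ---------------------------------------------------------------------------

def levene_check(table, factor: str, response: str = "value"):
    """Brown–Forsythe (median-centered) Levene test across the levels of
    ``factor``.  Returns ``(statistic, p_value)``."""
    df = table.df if isinstance(table, AssayTable) else table
    groups = [g[response].to_numpy(float) for _, g in df.groupby(factor)]
    if len(groups) < 2:
        raise DesignError("Levene test needs >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise DesignError("Levene test needs >= 2 observations per group")
    stat, p = st.levene(*groups, center="median")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# performance matrix
# ---------------------------------------------------------------------------

@dataclass
class PerformanceEntry:
    """One attribute's per-strain performance values with provenance."""

    attribute_id: str
    per_strain: dict
    source_assay: str
    units: str
    scale: str = "response"   # "response" | "log1p" (back-transformed on add)


@dataclass
class PerformanceMatrix:
    """Strain × attribute performance values plus per-attribute provenance."""

    values: pd.DataFrame        # index strain, columns attributes
    provenance: pd.DataFrame    # index attribute: source_assay, units

    @property
    def strains(self):
        return list(self.values.index)

    @property
    def attributes(self):
        return list(self.values.columns)

    def select(self, attributes) -> "PerformanceMatrix":
        missing = [a for a in attributes if a not in self.values.columns]
        if missing:
            raise CompletenessError(
                f"attribute(s) missing from performance matrix: {missing}",
                missing)
        return PerformanceMatrix(self.values[list(attributes)].copy(),
                                 self.provenance.loc[list(attributes)].copy())

    def to_csv(self, path) -> None:
        self.values.rename_axis("strain").to_csv(path)

    def to_json(self, path) -> None:
        import json
        payload = {
            "strains": self.strains,
            "attributes": [
                {"attribute_id": a,
                 **self.provenance.loc[a].to_dict(),
                 "values": {s: float(self.values.at[s, a])
                            for s in self.strains}}
                for a in self.attributes],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_csv(cls, path) -> "PerformanceMatrix":
        values = pd.read_csv(path, index_col="strain")
        prov = pd.DataFrame({"source_assay": "unknown", "units": "unknown"},
                            index=pd.Index(values.columns, name="attribute"))
        return cls(values, prov)


def build_performance_matrix(entries, strains=None, attributes=None) -> PerformanceMatrix:
    """Assemble a :class:`PerformanceMatrix` from per-attribute entries.

    Entries with ``scale="log1p"`` are back-transformed with ``expm1`` so
    the matrix is on the measurement (response) scale.  Declared strains
    and attributes must be fully populated; missing cells raise a
    :class:`~rhizorank.errors.CompletenessError` listing them.
    """
    entries = list(entries)
    if attributes is None:
        attributes = [e.attribute_id for e in entries]
    by_attr = {e.attribute_id: e for e in entries}
    if strains is None:
        strains = sorted({s for e in entries for s in e.per_strain})
    strains = list(strains)

    missing = []
    data = {}
    prov_rows = []
    for a in attributes:
        e = by_attr.get(a)
        if e is None:
            missing.extend((s, a) for s in strains)
            continue
        col = []
        for s in strains:
            if s not in e.per_strain:
                missing.append((s, a))
                col.append(np.nan)
            else:
                v = float(e.per_strain[s])
                col.append(float(np.expm1(v)) if e.scale == "log1p" else v)
        data[a] = col
        prov_rows.append({"attribute": a, "source_assay": e.source_assay,
                          "units": e.units})
    if missing:
        raise CompletenessError(
            f"missing performance cell(s): {missing[:10]}"
            + ("..." if len(missing) > 10 else ""), missing)
    values = pd.DataFrame(data, index=pd.Index(strains, name="strain"))
    prov = pd.DataFrame(prov_rows).set_index("attribute")
    return PerformanceMatrix(values, prov)
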