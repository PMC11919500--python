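"""Contextual analysis: multilevel selection gradients from fitness models.

The model regresses an individual fitness outcome w on the standardized
individual and group trait deviations simultaneously,

    w_jkl = b0 + b_{w,dPi} dPi_jkl + b_{w,dPg} dPg_jkl + ... + e_jkl,

for individual j in group k in year l, with one analogous individual/group
predictor pair per social trait plus covariates, and random intercepts for
individual identity and year.  Binary outcomes (survival, weaned) use a
binomial GLMM with logit link; litter size uses a Poisson GLMM with log link.
The fixed-effect coefficients on the trait columns are the among-individual
and among-group selection gradients, reported on the link scale as fitted.

Estimation is penalized quasi-likelihood (PQL): iterate a working linear
mixed model (Breslow–Clayton), estimating the two variance components by
REML on the working response at each step.  The two crossed random-intercept
structures make the mixed-model equations separable — the individual block is
diagonal and is eliminated in closed form, leaving a small dense system in
the year effects — so a fit costs O(n) per REML evaluation.  Wald z tests
give fixed-effect p-values; Benjamini–Hochberg FDR adjustment is applied
across the models of the analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .netmetrics import TRAIT_PAIRS
from .records import PredationRecord

#: trait predictor columns, in canonical pair order
PAIR_COLUMNS = tuple(
    (f"dPi_{ind}", f"dPg_{grp}") for ind, grp in TRAIT_PAIRS
)
TRAIT_COLUMNS = tuple(c for pair in PAIR_COLUMNS for c in pair)

COHORTS = ("adult_F", "adult_M", "yearling_F", "yearling_M")

_LOG_S2_MIN, _LOG_S2_MAX = math.log(1e-8), math.log(1e3)


# ---------------------------------------------------------------------------
# Predation index
# ---------------------------------------------------------------------------

def predation_index(records: Iterable[PredationRecord]) -> pd.DataFrame:
    """Predators seen per observation-hour, per colony-year."""
    rows = [
        {
            "colony": r.colony,
            "year": r.year,
            "predation_index": r.predators_seen / r.observation_time,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["colony", "year", "predation_index"])


# ---------------------------------------------------------------------------
# PQL GLMM with crossed random intercepts (individual, year)
# ---------------------------------------------------------------------------

@dataclass
class GLMMFit:
    """Fixed effects and diagnostics of one PQL fit."""

    params: pd.Series
    se: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    vcomp: dict
    converged: bool
    boundary: list[str]
    n_obs: int
    n_individuals: int
    n_years: int
    family: str
    n_iter: int = 0


class _WorkingLMM:
    """REML machinery for z = X beta + Z_u u + Z_v v + e, Var(e) = W^-1.

    u (individual) and v (year) are random intercepts.  Everything is
    expressed through per-level aggregates so that evaluating the REML
    criterion never forms an n x n matrix: the individual block of the
    mixed-model equations is diagonal and eliminated analytically.
    """

    def __init__(self, X, z, w, ind, year, n_ind, n_year):
        self.X, self.z, self.w = X, z, w
        self.ind, self.year = ind, year
        self.n_ind, self.n_year = n_ind, n_year
        p = X.shape[1]
        Xw = X * w[:, None]
        self.t_xx = X.T @ Xw
        self.t_xz = Xw.T @ z
        self.z_wz = float(z @ (w * z))
        self.sum_w_ind = np.zeros(n_ind)
        np.add.at(self.sum_w_ind, ind, w)
        self.sum_w_year = np.zeros(n_year)
        np.add.at(self.sum_w_year, year, w)
        self.C = np.zeros((n_ind, n_year))
        np.add.at(self.C, (ind, year), w)
        self.ZuWX = np.zeros((n_ind, p))
        np.add.at(self.ZuWX, ind, Xw)
        self.ZvWX = np.zeros((n_year, p))
        np.add.at(self.ZvWX, year, Xw)
        self.ZuWz = np.zeros(n_ind)
        np.add.at(self.ZuWz, ind, w * z)
        self.ZvWz = np.zeros(n_year)
        np.add.at(self.ZvWz, year, w * z)
        self.log_w_sum = float(np.sum(np.log(w)))

    def _pieces(self, s2u, s2v):
        d_u = self.sum_w_ind + 1.0 / s2u
        S = np.diag(self.sum_w_year + 1.0 / s2v) - (self.C / d_u[:, None]).T @ self.C
        return d_u, cho_factor(S), S

    def _quad(self, d_u, S_cho, a_u, a_v, b_u, b_v):
        """a' Dtilde^-1 b for stacked (individual, year) blocks."""
        au_d = a_u / d_u[:, None] if a_u.ndim == 2 else a_u / d_u
        term1 = au_d.T @ b_u
        ra = a_v - self.C.T @ (a_u / d_u[:, None] if a_u.ndim == 2 else (a_u / d_u))
        rb = b_v - self.C.T @ (b_u / d_u[:, None] if b_u.ndim == 2 else (b_u / d_u))
        term2 = ra.T @ cho_solve(S_cho, rb)
        return term1 + term2

    def profile(self, s2u, s2v):
        """beta-hat, X'V^-1X, and the REML deviance at given variances."""
        d_u, S_cho, S = self._pieces(s2u, s2v)
        ZuWX2, ZvWX2 = self.ZuWX, self.ZvWX
        xvx = self.t_xx - self._quad(d_u, S_cho, ZuWX2, ZvWX2, ZuWX2, ZvWX2)
        xvz = self.t_xz - self._quad(
            d_u, S_cho, ZuWX2, ZvWX2, self.ZuWz[:, None], self.ZvWz[:, None]
        ).ravel()
        zvz = self.z_wz - float(
            np.squeeze(
                self._quad(
                    d_u, S_cho,
                    self.ZuWz[:, None], self.ZvWz[:, None],
                    self.ZuWz[:, None], self.ZvWz[:, None],
                )
            )
        )
        xvx_cho = cho_factor(xvx)
        beta = cho_solve(xvx_cho, xvz)
        rvr = zvz - float(xvz @ beta)
        logdet_V = (
            -self.log_w_sum
            + self.n_ind * math.log(s2u)
            + self.n_year * math.log(s2v)
            + float(np.sum(np.log(d_u)))
            + 2.0 * float(np.sum(np.log(np.diag(S_cho[0]))))
        )
        logdet_xvx = 2.0 * float(np.sum(np.log(np.diag(xvx_cho[0]))))
        reml = logdet_V + logdet_xvx + rvr
        return beta, xvx, reml, (d_u, S_cho)

    def reml(self, log_s2: np.ndarray) -> float:
        s2u, s2v = np.exp(np.clip(log_s2, _LOG_S2_MIN, _LOG_S2_MAX))
        try:
            return self.profile(s2u, s2v)[2]
        except np.linalg.LinAlgError:
            return np.inf

    def solve(self, s2u, s2v):
        """(beta, u, v, cov_beta) at given variance components."""
        beta, xvx, _, (d_u, S_cho) = self.profile(s2u, s2v)
        r_u = self.ZuWz - self.ZuWX @ beta
        r_v = self.ZvWz - self.ZvWX @ beta
        t_v = cho_solve(S_cho, r_v - self.C.T @ (r_u / d_u))
        t_u = (r_u - self.C @ t_v) / d_u
        cov_beta = np.linalg.inv(xvx)
        return beta, t_u, t_v, cov_beta


_FAMILIES = {
    "binomial": {
        "linkinv": lambda eta: 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30))),
        "weight": lambda mu: np.clip(mu * (1.0 - mu), 1e-10, None),
        "initial": lambda y: np.clip(y, 0.05, 0.95),
        "link": lambda mu: np.log(mu / (1.0 - mu)),
    },
    "poisson": {
        "linkinv": lambda eta: np.exp(np.clip(eta, -30, 30)),
        "weight": lambda mu: np.clip(mu, 1e-10, None),
        "initial": lambda y: np.maximum(y, 0.1),
        "link": np.log,
    },
}


def fit_glmm_pql(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    individual: Sequence,
    year: Sequence,
    family: str = "binomial",
    max_iter: int = 50,
    tol: float = 1e-7,
) -> GLMMFit:
    """Fit a binomial/Poisson GLMM with individual and year random intercepts.

    ``X`` must already contain an intercept column.  Raises on a constant
    response; a variance component estimated at its lower boundary is
    reported in ``boundary`` (the fit is kept, equivalent to dropping the
    component), never silently.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unsupported family {family!r}")
    fam = _FAMILIES[family]
    names = (
        list(X.columns) if isinstance(X, pd.DataFrame)
        else [f"x{i}" for i in range(np.asarray(X).shape[1])]
    )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: outcome is constant")
    ind_codes, ind_levels = pd.factorize(np.asarray(individual))
    year_codes, year_levels = pd.factorize(np.asarray(year))
    n_ind, n_year = len(ind_levels), len(year_levels)

    # GLM start (IRLS without random effects)
    mu = fam["initial"](y)
    eta = fam["link"](mu)
    beta = np.linalg.lstsq(X, eta, rcond=None)[0]
    eta = X @ beta
    for _ in range(25):
        mu = fam["linkinv"](eta)
        w = fam["weight"](mu)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        eta_new = X @ beta_new
        if np.max(np.abs(eta_new - eta)) < 1e-8:
            eta = eta_new
            break
        eta, beta = eta_new, beta_new

    log_s2 = np.array([math.log(0.05), math.log(0.05)])
    converged = False
    lmm = None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = fam["linkinv"](eta)
        w = fam["weight"](mu)
        z = eta + (y - mu) / w
        lmm = _WorkingLMM(X, z, w, ind_codes, year_codes, n_ind, n_year)
        res = optimize.minimize(
            lmm.reml, log_s2, method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 300},
        )
        log_s2 = np.clip(res.x, _LOG_S2_MIN, _LOG_S2_MAX)
        s2u, s2v = np.exp(log_s2)
        beta, u, v, cov_beta = lmm.solve(s2u, s2v)
        eta_new = X @ beta + u[ind_codes] + v[year_codes]
        delta = np.max(np.abs(eta_new - eta))
        eta = eta_new
        if delta < max(tol, 1e-6 * (1 + np.max(np.abs(eta)))):
            converged = True
            break

    boundary = []
    if log_s2[0] <= _LOG_S2_MIN + 1e-6:
        boundary.append("individual")
    if log_s2[1] <= _LOG_S2_MIN + 1e-6:
        boundary.append("year")
    se = np.sqrt(np.diag(cov_beta))
    zval = beta / se
    pval = 2.0 * norm.sf(np.abs(zval))
    idx = pd.Index(names)
    return GLMMFit(
        params=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        zvalues=pd.Series(zval, index=idx),
        pvalues=pd.Series(pval, index=idx),
        vcomp={"individual": float(s2u), "year": float(s2v)},
        converged=converged,
        boundary=boundary,
        n_obs=len(y),
        n_individuals=n_ind,
        n_years=n_year,
        family=family,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Collinearity diagnostics
# ---------------------------------------------------------------------------

def compute_vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1-R²) for each column of ``design``.

    Each predictor is regressed (with intercept) on all the others; perfect
    collinearity yields +inf, not an exception.
    """
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("VIF needs more rows than predictors")
    X = np.column_stack([np.ones(len(design)), np.asarray(design, dtype=float)])
    out = {}
    for j, col in enumerate(design.columns):
        yj = X[:, j + 1]
        others = np.delete(X, j + 1, axis=1)
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot == 0:
            out[col] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def screen_collinearity(
    design: pd.DataFrame,
    threshold: float = 5.0,
    pairs: Sequence[tuple[str, str]] = PAIR_COLUMNS,
) -> tuple[pd.DataFrame, list[tuple[str, str]], pd.Series]:
    """Iteratively drop the analogous trait pair of the worst VIF offender.

    While any trait predictor's VIF exceeds ``threshold``, the offending
    trait's individual AND group columns are removed together (the pair is a
    unit: keeping one level of a collinear trait would misattribute
    selection), then VIFs are recomputed.  Returns the reduced design, the
    removal list in order, and the final VIFs.
    """
    design = design.copy()
    removed: list[tuple[str, str]] = []
    pair_of = {}
    for ind_col, grp_col in pairs:
        pair_of[ind_col] = (ind_col, grp_col)
        pair_of[grp_col] = (ind_col, grp_col)
    while True:
        vifs = compute_vif(design)
        trait_vifs = vifs[[c for c in design.columns if c in pair_of]]
        if trait_vifs.empty or trait_vifs.max() <= threshold:
            return design, removed, vifs
        worst = trait_vifs.idxmax()
        pair = pair_of[worst]
        removed.append(pair)
        design = design.drop(columns=[c for c in pair if c in design.columns])


# ---------------------------------------------------------------------------
# Model specifications and fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One cohort fitness model of the analysis."""

    response: str
    cohort: str  # e.g. "adult_F"
    family: str
    covariates: tuple[str, ...] = ()
    pre_removed_pairs: tuple[tuple[str, str], ...] = ()

    @property
    def name(self) -> str:
        return f"{self.response}:{self.cohort}"


DEGREE_DENSITY_PAIR = PAIR_COLUMNS[0]

#: The eight cohort fitness models: two female reproduction channels, four
#: hibernation-survival cohorts (degree–density pair pre-removed for known
#: collinearity), and two adult summer-survival cohorts.
DEFAULT_MODELS: tuple[ModelSpec, ...] = (
    ModelSpec("weaned", "adult_F", "binomial", ("june_mass",)),
    ModelSpec("n_weaned", "adult_F", "poisson", ("june_mass",)),
    ModelSpec("hibernation_survival", "adult_F", "binomial", ("august_mass",),
              (DEGREE_DENSITY_PAIR,)),
    ModelSpec("hibernation_survival", "adult_M", "binomial", ("august_mass",),
              (DEGREE_DENSITY_PAIR,)),
    ModelSpec("hibernation_survival", "yearling_F", "binomial", ("august_mass",),
              (DEGREE_DENSITY_PAIR,)),
    ModelSpec("hibernation_survival", "yearling_M", "binomial", ("august_mass",),
              (DEGREE_DENSITY_PAIR,)),
    ModelSpec("summer_survival", "adult_F", "binomial",
              ("june_mass", "predation_index")),
    ModelSpec("summer_survival", "adult_M", "binomial",
              ("june_mass", "predation_index")),
)


@dataclass
class SelectionResult:
    """Gradients and diagnostics of one fitted contextual model."""

    spec: ModelSpec
    table: pd.DataFrame  # index = predictor; beta, se, z, p, p_fdr, vif
    converged: bool
    boundary: list[str]
    n_obs: int
    n_individuals: int
    vcomp: dict = field(default_factory=dict)
    removed_pairs: list[tuple[str, str]] = field(default_factory=list)
    n_dropped_rows: int = 0

    def gradient(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "beta"])


def _cohort_mask(data: pd.DataFrame, cohort: str) -> pd.Series:
    age, sex = cohort.rsplit("_", 1)
    return (data["age_class"] == age) & (data["sex"] == sex)


def _zscore_covariate(values: pd.Series) -> pd.Series:
    sd = values.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return values - values.mean()
    return (values - values.mean()) / sd


def fit_contextual_model(
    spec: ModelSpec,
    data: pd.DataFrame,
    vif_threshold: float = 5.0,
) -> SelectionResult:
    """Fit one cohort model and extract its selection gradients.

    Rows: the cohort's individual-years with a non-missing response and
    complete predictors (litter size additionally conditions on a weaned
    litter).  Predictors: the analogous trait pairs (minus any pre-removed
    pairs), globally standardized group size, elevation, and the spec's
    covariates (continuous covariates are z-scored within the model data for
    numerical comparability).  Collinearity is screened before fitting.
    """
    mask = _cohort_mask(data, spec.cohort) & data[spec.response].notna()
    if spec.response == "n_weaned":
        mask &= data["weaned"] == 1
    sub = data.loc[mask].copy()
    if sub.empty:
        raise ValueError(f"{spec.name}: no rows in cohort")

    trait_cols = [
        c
        for pair in PAIR_COLUMNS
        if pair not in spec.pre_removed_pairs
        for c in pair
    ]
    pred_cols = trait_cols + ["group_size_z", "elevation"] + list(spec.covariates)
    design = sub[trait_cols + ["group_size_z"]].astype(float).copy()
    design["elevation"] = (sub["elevation"] == "higher").astype(float)
    for cov in spec.covariates:
        design[cov] = _zscore_covariate(sub[cov].astype(float))
    complete = design.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    design = design.loc[complete]
    sub = sub.loc[complete]
    if sub.empty or sub[spec.response].nunique() < 2:
        raise ValueError(f"{spec.name}: degenerate response")

    screened, removed, vifs = screen_collinearity(
        design, threshold=vif_threshold
    )
    X = screened.copy()
    X.insert(0, "intercept", 1.0)
    fit = fit_glmm_pql(
        sub[spec.response].to_numpy(dtype=float),
        X,
        individual=sub["id"].to_numpy(),
        year=sub["year"].to_numpy(),
        family=spec.family,
    )
    if not fit.converged:
        warnings.warn(f"{spec.name}: PQL did not converge", stacklevel=2)
    table = pd.DataFrame(
        {
            "beta": fit.params,
            "se": fit.se,
            "z": fit.zvalues,
            "p": fit.pvalues,
        }
    )
    table["vif"] = vifs.reindex(table.index)
    table["level"] = [
        "individual" if c.startswith("dPi_")
        else "group" if c.startswith("dPg_")
        else "covariate"
        for c in table.index
    ]
    return SelectionResult(
        spec=spec,
        table=table,
        converged=fit.converged,
        boundary=fit.boundary,
        n_obs=fit.n_obs,
        n_individuals=fit.n_individuals,
        vcomp=fit.vcomp,
        removed_pairs=removed + list(spec.pre_removed_pairs),
        n_dropped_rows=n_dropped,
    )


def run_all_models(
    data: pd.DataFrame,
    models: Sequence[ModelSpec] = DEFAULT_MODELS,
    vif_threshold: float = 5.0,
    fdr_mode: str = "per_predictor",
) -> tuple[list[SelectionResult], dict]:
    """Fit the eight cohort models, apply FDR, and build a run manifest."""
    results: list[SelectionResult] = []
    manifest: dict = {"models": []}
    for spec in models:
        try:
            res = fit_contextual_model(spec, data, vif_threshold)
        except (ValueError, np.linalg.LinAlgError) as exc:
            manifest["models"].append(
                {"model": spec.name, "skipped": str(exc)}
            )
            continue
        results.append(res)
        manifest["models"].append(
            {
                "model": spec.name,
                "family": spec.family,
                "n_obs": res.n_obs,
                "n_individuals": res.n_individuals,
                "converged": res.converged,
                "boundary": res.boundary,
                "removed_pairs": [list(p) for p in res.removed_pairs],
            }
        )
    adjust_fdr(results, mode=fdr_mode)
    return results, manifest


# ---------------------------------------------------------------------------
# Multiple-testing adjustment and summaries
# ---------------------------------------------------------------------------

def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (NaN-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def adjust_fdr(results: Sequence[SelectionResult], mode: str = "per_predictor") -> None:
    """Attach ``p_fdr`` to every model table.

    ``per_predictor`` (default): the family of comparisons for a predictor is
    its p-values across the fitted models (one comparison per model).
    ``whole_table``: a single family over all predictor × model tests.
    Covariate rows are adjusted within their own families the same way.
    """
    if mode not in ("per_predictor", "whole_table"):
        raise ValueError(f"unknown fdr mode {mode!r}")
    for res in results:
        res.table["p_fdr"] = np.nan
    if mode == "whole_table":
        flat = [
            (res, pred) for res in results for pred in res.table.index
        ]
        adj = fdr_adjust([res.table.loc[pred, "p"] for res, pred in flat])
        for (res, pred), a in zip(flat, adj):
            res.table.loc[pred, "p_fdr"] = a
        return
    predictors = {pred for res in results for pred in res.table.index}
    for pred in predictors:
        hits = [res for res in results if pred in res.table.index]
        adj = fdr_adjust([res.table.loc[pred, "p"] for res in hits])
        for res, a in zip(hits, adj):
            res.table.loc[pred, "p_fdr"] = a


def mean_gradient_summary(
    results: Sequence[SelectionResult], converged_only: bool = True
) -> dict:
    """Mean ± s.e. of absolute gradient magnitudes per phenotypic level.

    Pools |beta| of every fitted trait predictor across models (no
    significance filtering), separately for the individual (dPi_*) and group
    (dPg_*) levels.  Non-converged fits are excluded by default — their
    estimates can diverge under quasi-separation and would dominate the
    mean.  s.e. is NA for a single gradient.
    """
    out = {}
    used = [r for r in results if r.converged or not converged_only]
    for level, prefix in (("individual", "dPi_"), ("group", "dPg_")):
        mags = [
            abs(res.table.loc[pred, "beta"])
            for res in used
            for pred in res.table.index
            if pred.startswith(prefix)
        ]
        mags = np.asarray(mags, dtype=float)
        mean = float(np.mean(mags)) if len(mags) else math.nan
        se = (
            float(np.std(mags, ddof=1) / math.sqrt(len(mags)))
            if len(mags) > 1
            else math.nan
        )
        out[f"{level}_mean"] = mean
        out[f"{level}_se"] = se
        out[f"{level}_n"] = int(len(mags))
    return out


def results_frame(results: Sequence[SelectionResult]) -> pd.DataFrame:
    """Long-format results: one row per (model, predictor)."""
    rows = []
    for res in results:
        for pred, row in res.table.iterrows():
            rows.append(
                {
                    "model": res.spec.name,
                    "response": res.spec.response,
                    "cohort": res.spec.cohort,
                    "predictor": pred,
                    "level": row["level"],
                    "beta": row["beta"],
                    "se": row["se"],
                    "z": row["z"],
                    "p": row["p"],
                    "p_fdr": row.get("p_fdr", np.nan),
                    "vif": row["vif"],
                    "n_obs": res.n_obs,
                    "n_individuals": res.n_individuals,
                    "converged": res.converged,
                }
            )
    return pd.DataFrame(rows)
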