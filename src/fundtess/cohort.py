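"""Synthetic cohort generation and the FTD association analysis.

The generator draws a population of elderly subjects whose fundus
tessellated density (FTD) is linearly driven, on the standardized scale,
by six covariates: age, sex, body-mass index, axial length,
parapapillary-atrophy area and subfoveal choroidal thickness (SFCT).
Independent covariates cannot simultaneously reproduce the reported
per-covariate standardized coefficients and a multiple correlation of
R = 0.74, so the covariate correlation matrix is *calibrated*: a
least-squares solve finds a positive-semidefinite correlation structure
that reproduces the multivariate R, the marginal age-FTD correlation,
the per-covariate variance inflation factors, and an axial-length-FTD
marginal correlation strong enough to support the within-myopia
refraction correlation.

Spherical equivalent (SE) is generated from the axial-length latent with
a negative, heavy-left-tailed link (elongation-driven myopization plus a
lognormal high-myopia tail), calibrated against the overall SE moments,
the myopia fraction and the within-myopia SE-FTD correlation.

The analysis half mirrors the epidemiological procedure: univariate
screening of each covariate, a stepwise multivariate model (variance-
inflation pruning followed by backward elimination), and stratified
summaries by age decade, sex and refraction class.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import (CalibrationFailed, CohortTooSmall, ConstantPredictor,
                     EmptyModel, InvalidConfig)

PREDICTORS = ("age", "sex", "bmi", "axial_length", "ppa_area", "sfct")

COHORT_COLUMNS = ("age", "sex", "bmi", "axial_length", "ppa_area", "sfct",
                  "sphere", "cylinder", "se", "ftd")

MYOPIA_CUT = -0.25   # diopters, strict: myopia SE < -0.25, hypermetropia SE > +0.25


@dataclass(frozen=True)
class GeneratorCalibration:
    """Targets the synthetic cohort is calibrated to reproduce.

    ``std_betas`` uses the convention that ``sex`` is an indicator for
    female (FTD is lower in women, hence the negative coefficient).
    ``target_al_r`` is the marginal axial-length-FTD correlation; it is
    not itself a headline statistic but must be this strong for the
    within-myopia SE-FTD correlation to be reachable, because selecting
    the myopic stratum compresses the axial-length range.
    """

    std_betas: tuple[tuple[str, float], ...] = (
        ("age", 0.08), ("sex", -0.11), ("bmi", -0.06),
        ("axial_length", 0.14), ("ppa_area", 0.09), ("sfct", -0.58),
    )
    target_model_R: float = 0.74
    target_age_r: float = 0.33
    target_al_r: float = 0.47
    target_myopia_se_r: float = -0.25
    target_vifs: tuple[tuple[str, float], ...] = (
        ("age", 1.29), ("sex", 1.11), ("bmi", 1.04),
        ("axial_length", 1.35), ("ppa_area", 1.29), ("sfct", 1.35),
    )
    marginal_means_sds: tuple[tuple[str, tuple[float, float]], ...] = (
        ("age", (64.1, 9.7)), ("bmi", (25.3, 3.4)), ("axial_length", (23.22, 1.09)),
        ("ppa_area", (1.5, 1.1)), ("sfct", (254.0, 107.0)),
    )
    ftd_mean: float = 0.14
    ftd_sd: float = 0.08
    female_fraction: float = 0.564
    age_range: tuple[float, float] = (50.0, 93.0)
    se_mean: float = -0.13
    se_sd: float = 1.96
    myopia_fraction: float = 1146 / 3074
    myopia_se_mean: float = -2.16
    hyper_se_mean: float = 0.94

    @property
    def beta_vector(self) -> np.ndarray:
        d = dict(self.std_betas)
        return np.array([d[p] for p in PREDICTORS])

    @property
    def vif_vector(self) -> np.ndarray:
        d = dict(self.target_vifs)
        return np.array([d[p] for p in PREDICTORS])


_SIGMA_CACHE: dict[str, np.ndarray] = {}
_SE_CACHE: dict[str, "SELinkParams"] = {}
_TN_CACHE: dict[tuple, tuple[float, float]] = {}


def _cache_key(cal: GeneratorCalibration) -> str:
    return json.dumps(asdict(cal), sort_keys=True)


# -- correlation-structure calibration -------------------------------------

# weakly-weighted realism prior for correlations the targets leave free
_PRIOR_CORR = {
    (0, 3): 0.05, (0, 4): 0.25, (0, 5): -0.35, (3, 4): 0.30, (3, 5): -0.40,
    (4, 5): -0.25, (0, 1): 0.0, (0, 2): -0.05, (1, 3): -0.15, (1, 5): 0.05,
    (2, 5): 0.10,
}


def calibrate_predictor_corr(cal: GeneratorCalibration | None = None) -> np.ndarray:
    """Solve the 6x6 covariate correlation matrix matching the targets.

    Finds a symmetric, unit-diagonal, positive-semidefinite matrix Sigma
    such that, with beta the standardized coefficients,
    ``beta' Sigma beta`` equals the target R^2 (+-1e-3), each diagonal
    entry of ``Sigma^-1`` (the VIF of that covariate) matches its target
    (+-0.05), and the implied marginal FTD correlations of age
    (``(Sigma beta)_age``, +-0.02) and axial length match their targets.

    Raises
    ------
    CalibrationFailed
        With a residual report, if the tolerances cannot be met.
    """
    cal = cal or GeneratorCalibration()
    key = _cache_key(cal)
    if key in _SIGMA_CACHE:
        return _SIGMA_CACHE[key].copy()

    beta = cal.beta_vector
    vif_t = cal.vif_vector
    r2_t = cal.target_model_R**2
    iu = np.triu_indices(6, 1)

    def mat(x: np.ndarray) -> np.ndarray:
        s = np.eye(6)
        s[iu] = x
        s.T[iu] = x
        return s

    prior = np.zeros((6, 6))
    for (i, j), v in _PRIOR_CORR.items():
        prior[i, j] = v
    prior_v = prior[iu]

    def resid(x: np.ndarray) -> np.ndarray:
        s = mat(x)
        eigs = np.linalg.eigvalsh(s)
        pen = np.minimum(eigs - 1e-6, 0.0) * 100.0
        try:
            vifs = np.diag(np.linalg.inv(s))
        except np.linalg.LinAlgError:
            vifs = np.full(6, 10.0)
        parts = [
            (beta @ s @ beta - r2_t) * 100.0,
            ((s @ beta)[0] - cal.target_age_r) * 50.0,
            ((s @ beta)[3] - cal.target_al_r) * 20.0,
        ]
        parts.extend(((vifs - vif_t) * 20.0).tolist())
        parts.extend(pen.tolist())
        parts.extend(((x - prior_v) * 0.5).tolist())
        return np.array(parts)

    sol = optimize.least_squares(resid, prior_v, bounds=(-0.95, 0.95),
                                 xtol=1e-14, ftol=1e-14, max_nfev=40000)
    sigma = mat(sol.x)

    # project onto the PSD cone if a tiny negative eigenvalue slipped through
    w, v = np.linalg.eigh(sigma)
    if w.min() < -1e-8:
        w = np.clip(w, 0.0, None)
        sigma = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)

    vifs = np.diag(np.linalg.inv(sigma))
    report = {
        "r2_error": float(beta @ sigma @ beta - r2_t),
        "age_r_error": float((sigma @ beta)[0] - cal.target_age_r),
        "vif_errors": {p: float(e) for p, e in zip(PREDICTORS, vifs - vif_t)},
        "min_eigenvalue": float(np.linalg.eigvalsh(sigma).min()),
    }
    if (abs(report["r2_error"]) > 1e-3 or abs(report["age_r_error"]) > 0.02
            or max(abs(e) for e in (vifs - vif_t)) > 0.05):
        raise CalibrationFailed(f"correlation solve outside tolerance: {report}")
    _SIGMA_CACHE[key] = sigma
    return sigma.copy()


# -- refraction link calibration -------------------------------------------

@dataclass(frozen=True)
class SELinkParams:
    """Parameters of the SE | axial-length generative link."""

    intercept: float      # baseline refraction (D)
    log_mu: float         # lognormal myopization: location
    log_sigma: float      # lognormal myopization: scale
    al_mixing: float      # loading of the axial-length latent in the tail
    noise_sd: float       # independent refraction noise (D)
    slope_long: float     # extra linear myopization per SD of long axial length


def _simulate_se(params: np.ndarray, z_al: np.ndarray, w: np.ndarray,
                 eps: np.ndarray) -> np.ndarray:
    a, mug, sg, c, noise, b = params
    c = np.tanh(c)
    g = mug + sg * (c * z_al + np.sqrt(1.0 - c**2) * w)
    se = a - np.exp(g) - b * np.maximum(z_al, 0.0) + noise * eps
    return np.round(se * 4.0) / 4.0   # refractions come in quarter-diopter steps


def calibrate_se_link(cal: GeneratorCalibration | None = None) -> SELinkParams:
    """Calibrate the SE generator against the printed refraction statistics.

    Targets: overall SE mean, myopia prevalence, mean SE of the myopic
    stratum, the within-myopia SE-FTD Pearson correlation, a near-zero
    hyperopic correlation, and (softly) the overall SE spread and the
    hyperopic mean. Deterministic: the internal calibration sample is
    fixed.
    """
    cal = cal or GeneratorCalibration()
    key = _cache_key(cal)
    if key in _SE_CACHE:
        return _SE_CACHE[key]

    sigma = calibrate_predictor_corr(cal)
    beta = cal.beta_vector
    r2 = float(beta @ sigma @ beta)
    rng = np.random.default_rng(987654321)
    n = 120_000
    z = rng.standard_normal((n, 6)) @ np.linalg.cholesky(sigma).T
    ftd_std = z @ beta + rng.standard_normal(n) * np.sqrt(1.0 - r2)
    ftd = np.clip(cal.ftd_mean + cal.ftd_sd * ftd_std, 0.0, 1.0)
    z_al = z[:, 3]
    w = rng.standard_normal(n)
    eps = rng.standard_normal(n)

    def resid(params: np.ndarray) -> np.ndarray:
        se = _simulate_se(params, z_al, w, eps)
        myo = se < MYOPIA_CUT
        hyp = se > -MYOPIA_CUT
        r_myo = np.corrcoef(se[myo], ftd[myo])[0, 1]
        r_hyp = np.corrcoef(se[hyp], ftd[hyp])[0, 1]
        return np.array([
            (se.mean() - cal.se_mean) * 20.0,
            (se.std() - cal.se_sd) * 8.0,
            (myo.mean() - cal.myopia_fraction) * 40.0,
            (se[myo].mean() - cal.myopia_se_mean) * 30.0,
            (r_myo - cal.target_myopia_se_r) * 100.0,
            (se[hyp].mean() - cal.hyper_se_mean) * 5.0,
            (r_hyp - 0.0) * 20.0,
        ])

    best = None
    for start in (np.array([0.9, -0.9, 1.1, np.arctanh(0.9), 0.5, 0.4]),
                  np.array([1.4, 0.1, 0.8, np.arctanh(0.97), 0.2, 0.7])):
        sol = optimize.least_squares(resid, start, xtol=1e-12, ftol=1e-12,
                                     diff_step=1e-4)
        if best is None or sol.cost < best.cost:
            best = sol
    p = best.x
    se = _simulate_se(p, z_al, w, eps)
    myo = se < MYOPIA_CUT
    r_myo = float(np.corrcoef(se[myo], ftd[myo])[0, 1])
    if abs(r_myo - cal.target_myopia_se_r) > 0.03:
        raise CalibrationFailed(
            f"within-myopia SE-FTD correlation {r_myo:.3f} misses "
            f"{cal.target_myopia_se_r} by more than 0.03"
        )
    out = SELinkParams(intercept=float(p[0]), log_mu=float(p[1]),
                       log_sigma=float(p[2]), al_mixing=float(np.tanh(p[3])),
                       noise_sd=float(p[4]), slope_long=float(p[5]))
    _SE_CACHE[key] = out
    return out


# -- marginal transforms ----------------------------------------------------

def _truncnorm_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Underlying (mu, sigma) whose [lo, hi]-truncation has the given moments."""
    key = (mean, sd, lo, hi)
    if key in _TN_CACHE:
        return _TN_CACHE[key]

    def eqs(x):
        mu, log_s = x
        s = np.exp(log_s)
        a, b = (lo - mu) / s, (hi - mu) / s
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(eqs, [mean, np.log(sd)], method="hybr")
    mu, s = float(sol.x[0]), float(np.exp(sol.x[1]))
    _TN_CACHE[key] = (mu, s)
    return mu, s


def _truncnorm_from_latent(z: np.ndarray, mean: float, sd: float,
                           lo: float, hi: float) -> np.ndarray:
    mu, s = _truncnorm_params(mean, sd, lo, hi)
    a, b = (lo - mu) / s, (hi - mu) / s
    u = stats.norm.cdf(z)
    return stats.truncnorm.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, b, loc=mu, scale=s)


# -- cohort generation -------------------------------------------------------

def generate_cohort(n: int, cal: GeneratorCalibration | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Draw a synthetic cohort of ``n`` subjects.

    A latent standard-normal 6-vector per subject carries the calibrated
    correlation structure; latents map to covariate scales through their
    marginal distributions (truncated normals for age, parapapillary
    atrophy and SFCT; a thresholded latent for sex). FTD is the
    standardized linear predictor plus Gaussian residual, rescaled to the
    population mean and SD and clipped to [0, 1]. SE is generated from
    the axial-length latent through the calibrated heavy-tailed link;
    cylinder is drawn small and sphere is set so that
    ``se == sphere + cylinder / 2`` holds exactly.
    """
    cal = cal or GeneratorCalibration()
    if n < 50:
        raise CohortTooSmall("need n >= 50 for meaningful moments")
    sigma = calibrate_predictor_corr(cal)
    se_link = calibrate_se_link(cal)
    beta = cal.beta_vector
    r2 = float(beta @ sigma @ beta)
    marg = dict(cal.marginal_means_sds)

    # De-attenuate the sex row: thresholding a latent shrinks its Pearson
    # correlations by kappa = phi(tau) / sqrt(p (1 - p)).
    p_f = cal.female_fraction
    tau = stats.norm.ppf(1.0 - p_f)  # female iff latent > tau
    kappa = stats.norm.pdf(tau) / np.sqrt(p_f * (1.0 - p_f))
    sigma_lat = sigma.copy()
    sigma_lat[1, :] = sigma[1, :] / kappa
    sigma_lat[:, 1] = sigma[:, 1] / kappa
    sigma_lat[1, 1] = 1.0
    w_eig, v_eig = np.linalg.eigh(sigma_lat)
    if w_eig.min() < 0:
        w_eig = np.clip(w_eig, 1e-10, None)
        sigma_lat = v_eig @ np.diag(w_eig) @ v_eig.T
        d = np.sqrt(np.diag(sigma_lat))
        sigma_lat = sigma_lat / np.outer(d, d)

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 6)) @ np.linalg.cholesky(sigma_lat).T

    age = _truncnorm_from_latent(z[:, 0], *marg["age"], *cal.age_range)
    female = z[:, 1] > tau
    bmi = marg["bmi"][0] + marg["bmi"][1] * z[:, 2]
    axial = marg["axial_length"][0] + marg["axial_length"][1] * z[:, 3]
    ppa = _truncnorm_from_latent(z[:, 4], *marg["ppa_area"], 0.0, np.inf)
    sfct = _truncnorm_from_latent(z[:, 5], *marg["sfct"], 0.0, np.inf)

    obs = np.column_stack([age, female.astype(float), bmi, axial, ppa, sfct])
    x_std = (obs - obs.mean(axis=0)) / obs.std(axis=0)
    eta = x_std @ beta
    ftd_std = eta + rng.standard_normal(n) * np.sqrt(1.0 - r2)
    ftd = np.clip(cal.ftd_mean + cal.ftd_sd * ftd_std, 0.0, 1.0)

    z_al = z[:, 3]
    params = np.array([se_link.intercept, se_link.log_mu, se_link.log_sigma,
                       np.arctanh(se_link.al_mixing), se_link.noise_sd,
                       se_link.slope_long])
    se = _simulate_se(params, z_al, rng.standard_normal(n), rng.standard_normal(n))
    cylinder = -np.round(np.abs(rng.normal(0.0, 0.5, n)) * 4.0) / 4.0
    sphere = se - cylinder / 2.0

    return pd.DataFrame({
        "age": age,
        "sex": np.where(female, "female", "male"),
        "bmi": bmi,
        "axial_length": axial,
        "ppa_area": ppa,
        "sfct": sfct,
        "sphere": sphere,
        "cylinder": cylinder,
        "se": se,
        "ftd": ftd,
    })


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False, columns=list(COHORT_COLUMNS))


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidConfig(f"cohort file missing columns: {sorted(missing)}")
    return df


def _numeric_column(cohort: pd.DataFrame, name: str) -> np.ndarray:
    """Covariate as a numeric vector; sex becomes a female indicator."""
    if name == "sex":
        return (cohort["sex"].astype(str) == "female").to_numpy(float)
    return cohort[name].to_numpy(float)


# -- regression machinery ----------------------------------------------------

@dataclass
class RegressionReport:
    """Per-term coefficients and model-level summary of an OLS fit."""

    terms: pd.DataFrame          # index: predictor; columns: B, beta, ci_low, ci_high, p, vif
    model_r: float
    n: int
    steps: list[str] = field(default_factory=list)


def _ols(y: np.ndarray, x: np.ndarray) -> sm.regression.linear_model.RegressionResultsWrapper:
    return sm.OLS(y, sm.add_constant(x)).fit()


def vif(cohort: pd.DataFrame, predictors: Sequence[str]) -> dict[str, float]:
    """Variance inflation factors 1 / (1 - R_j^2) within the given design."""
    cols = {p: _numeric_column(cohort, p) for p in predictors}
    out = {}
    for p in predictors:
        others = [q for q in predictors if q != p]
        if not others:
            out[p] = 1.0
            continue
        x = np.column_stack([cols[q] for q in others])
        r2 = _ols(cols[p], x).rsquared
        out[p] = float(1.0 / (1.0 - r2))
    return out


def univariate_screen(cohort: pd.DataFrame, outcome: str = "ftd",
                      predictors: Sequence[str] | None = None) -> pd.DataFrame:
    """Simple linear regression of the outcome on each predictor alone.

    Returns one row per predictor with the raw coefficient B, the
    standardized coefficient, the 95% CI of B and the p-value.
    """
    predictors = list(predictors) if predictors is not None else [
        c for c in cohort.columns if c not in (outcome, "sphere", "cylinder")
    ]
    y = cohort[outcome].to_numpy(float)
    rows = []
    for p in predictors:
        x = _numeric_column(cohort, p)
        if np.unique(x).size < 2:
            raise ConstantPredictor(f"predictor {p!r} has no variation")
        fit = _ols(y, x[:, None])
        ci = fit.conf_int()[1]
        rows.append({
            "predictor": p,
            "B": float(fit.params[1]),
            "beta": float(fit.params[1] * x.std() / y.std()),
            "ci_low": float(ci[0]),
            "ci_high": float(ci[1]),
            "p": float(fit.pvalues[1]),
        })
    return pd.DataFrame(rows).set_index("predictor")


def fit_multivariate(cohort: pd.DataFrame, predictors: Sequence[str],
                     outcome: str = "ftd") -> RegressionReport:
    """One OLS fit of the outcome on the given predictors, with VIFs."""
    predictors = list(predictors)
    if not predictors:
        raise EmptyModel("no predictors to fit")
    y = cohort[outcome].to_numpy(float)
    x = np.column_stack([_numeric_column(cohort, p) for p in predictors])
    fit = _ols(y, x)
    vifs = vif(cohort, predictors)
    ci = fit.conf_int()
    terms = pd.DataFrame({
        "B": fit.params[1:],
        "beta": [fit.params[1 + i] * x[:, i].std() / y.std()
                 for i in range(len(predictors))],
        "ci_low": ci[1:, 0],
        "ci_high": ci[1:, 1],
        "p": fit.pvalues[1:],
        "vif": [vifs[p] for p in predictors],
    }, index=pd.Index(predictors, name="predictor"))
    return RegressionReport(terms=terms, model_r=float(np.sqrt(fit.rsquared)),
                            n=len(y))


def multivariate_stepwise(cohort: pd.DataFrame, candidates: Sequence[str],
                          vif_max: float = 3.0, alpha: float = 0.05,
                          outcome: str = "ftd") -> RegressionReport:
    """Stepwise multivariate model: VIF pruning, then backward elimination.

    While any VIF exceeds ``vif_max`` the highest-VIF predictor is
    dropped; then while any p-value exceeds ``alpha`` the least
    significant predictor is dropped. Every removal is logged in
    ``steps``.
    """
    current = list(candidates)
    steps: list[str] = []
    if not current:
        raise EmptyModel("empty candidate set")
    while len(current) > 1:
        vifs = vif(cohort, current)
        worst = max(current, key=lambda p: vifs[p])
        if vifs[worst] <= vif_max:
            break
        current.remove(worst)
        steps.append(f"dropped {worst}: VIF {vifs[worst]:.2f} > {vif_max}")
    while current:
        report = fit_multivariate(cohort, current, outcome=outcome)
        pvals = report.terms["p"]
        worst = pvals.idxmax()
        if pvals[worst] <= alpha:
            report.steps = steps
            return report
        current.remove(worst)
        steps.append(f"dropped {worst}: p {pvals[worst]:.3f} > {alpha}")
    raise EmptyModel("backward elimination removed every candidate")


# -- stratified summaries -----------------------------------------------------

def classify_refraction(se: np.ndarray | pd.Series) -> np.ndarray:
    """Myopia SE < -0.25 D; hypermetropia SE > +0.25 D; else emmetropia."""
    se = np.asarray(se, dtype=float)
    out = np.full(se.shape, "emmetropia", dtype=object)
    out[se < MYOPIA_CUT] = "myopia"
    out[se > -MYOPIA_CUT] = "hypermetropia"
    return out.astype(str)


def stratified_summaries(cohort: pd.DataFrame) -> dict:
    """Age-decade, sex and refraction-class summaries of FTD.

    Returns a dict with: ``age_groups`` (decade bins with mean/SD FTD and
    one-way ANOVA F/p), ``sex`` (per-sex mean/SD with two-sample t), and
    ``refraction`` (per-class n, FTD and SE moments, Pearson r between SE
    and FTD with p). Empty strata appear with n = 0 and missing
    statistics.
    """
    ftd = cohort["ftd"].to_numpy(float)
    age = cohort["age"].to_numpy(float)

    bins = [("50-59", (age >= 50) & (age < 60)),
            ("60-69", (age >= 60) & (age < 70)),
            ("70+", age >= 70)]
    age_rows, groups = [], []
    for label, sel in bins:
        vals = ftd[sel]
        age_rows.append({
            "group": label, "n": int(sel.sum()),
            "ftd_mean": float(vals.mean()) if sel.any() else np.nan,
            "ftd_sd": float(vals.std(ddof=1)) if sel.sum() > 1 else np.nan,
        })
        if sel.any():
            groups.append(vals)
    f_stat, f_p = (stats.f_oneway(*groups) if len(groups) > 1
                   else (np.nan, np.nan))

    sex_rows = []
    sex_vals = {}
    for label in ("male", "female"):
        sel = cohort["sex"].astype(str).to_numpy() == label
        vals = ftd[sel]
        sex_vals[label] = vals
        sex_rows.append({
            "group": label, "n": int(sel.sum()),
            "ftd_mean": float(vals.mean()) if sel.any() else np.nan,
            "ftd_sd": float(vals.std(ddof=1)) if sel.sum() > 1 else np.nan,
        })
    if len(sex_vals["male"]) > 1 and len(sex_vals["female"]) > 1:
        t_stat, t_p = stats.ttest_ind(sex_vals["male"], sex_vals["female"])
    else:
        t_stat, t_p = np.nan, np.nan

    se = cohort["se"].to_numpy(float)
    classes = classify_refraction(se)
    refr_rows = []
    for label in ("emmetropia", "hypermetropia", "myopia"):
        sel = classes == label
        n_c = int(sel.sum())
        row = {"group": label, "n": n_c,
               "ftd_mean": np.nan, "ftd_sd": np.nan,
               "se_mean": np.nan, "se_sd": np.nan, "r": np.nan, "p": np.nan}
        if n_c:
            row["ftd_mean"] = float(ftd[sel].mean())
            row["se_mean"] = float(se[sel].mean())
            if n_c > 1:
                row["ftd_sd"] = float(ftd[sel].std(ddof=1))
                row["se_sd"] = float(se[sel].std(ddof=1))
            if n_c > 2 and np.unique(se[sel]).size > 1:
                r, p = stats.pearsonr(se[sel], ftd[sel])
                row["r"], row["p"] = float(r), float(p)
        refr_rows.append(row)

    return {
        "age_groups": pd.DataFrame(age_rows).set_index("group"),
        "age_anova": {"F": float(f_stat), "p": float(f_p)},
        "sex": pd.DataFrame(sex_rows).set_index("group"),
        "sex_ttest": {"t": float(t_stat), "p": float(t_p)},
        "refraction": pd.DataFrame(refr_rows).set_index("group"),
    }
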