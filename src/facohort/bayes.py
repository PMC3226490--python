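"""MCAR diagnostics and the fully Bayesian joint imputation + health model.

The measured subsample yields observed annual log-FA for a minority of
dwellings; the rest are latent.  The joint model couples

* an exposure submodel  log-FA_d ~ Normal(x_dᵀγ, σ²)  over all dwellings, and
* an outcome submodel   logit P(LRI_i) = z_iᵀθ + β·FA_i  (binary), or its
  three-category multinomial analogue with never-LRI as reference,

where FA_i is the subject's residence-time-weighted level exp(log-FA) in
µg/m³.  A Metropolis-within-Gibbs sampler draws the regression blocks and the
latent log-FA values jointly, so imputation uncertainty propagates into the
posterior of the FA odds ratio.  γ is conjugate-Gibbs; σ, the latent values
and the outcome block use adaptive random-walk Metropolis steps (adaptation
frozen when burn-in ends).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse, stats

from .config import DWELLING_PREDICTORS, OUTCOME_LEVELS, SUBJECT_COVARIATES
from .design import dwelling_design, subject_design
from .errors import FacohortError, SeparationError
from .exposure import annual_means
from .health import iqr_width

logger = logging.getLogger(__name__)

__all__ = [
    "Priors",
    "PosteriorSummary",
    "McarReport",
    "mcar_univariate_tests",
    "mcar_global_test",
    "fit_joint_bayes",
    "convergence_diagnostics",
    "draw_coef_conjugate",
    "BayesResult",
]


# ---------------------------------------------------------------------------
# MCAR diagnostics
# ---------------------------------------------------------------------------

@dataclass
class McarReport:
    """Univariate and global tests of the missing-completely-at-random design."""

    univariate: pd.DataFrame  # predictor, test, statistic, p, p_bonferroni
    global_lrt: float
    global_df: int
    global_p: float

    def to_dict(self) -> dict:
        return {
            "univariate": self.univariate.round(6).to_dict("records"),
            "global": {
                "lrt": round(float(self.global_lrt), 6),
                "df": int(self.global_df),
                "p": round(float(self.global_p), 6),
            },
        }


def _exact_or_chi2(table: np.ndarray, rng_seed: int = 0):
    """χ² independence test, switching to an exact test when an expected cell < 1."""
    expected = stats.contingency.expected_freq(table)
    if (expected >= 1.0).all():
        res = stats.chi2_contingency(table, correction=False)
        return "chi2", float(res.statistic), float(res.pvalue)
    logger.info("MCAR test: expected cell < 1, switching to exact test")
    if table.shape == (2, 2):
        odds, p = stats.fisher_exact(table)
        return "fisher_exact", float(odds), float(p)
    # Monte-Carlo exact test for larger tables: permute labels, compare χ²
    obs_stat = stats.chi2_contingency(table, correction=False).statistic
    rng = np.random.default_rng(rng_seed)
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))
    count = 0
    n_perm = 2000
    for _ in range(n_perm):
        rng.shuffle(cols)
        perm = np.zeros_like(table)
        np.add.at(perm, (rows, cols), 1)
        if stats.chi2_contingency(perm, correction=False).statistic >= obs_stat - 1e-12:
            count += 1
    return "perm_exact", float(obs_stat), float((count + 1) / (n_perm + 1))


def mcar_univariate_tests(dwellings: pd.DataFrame, measured_flags) -> McarReport:
    """Test each FA predictor against measurement status R, Bonferroni-adjusted.

    Categorical predictors use χ² independence tests (exact when sparse);
    continuous predictors use two-sample t tests.  The global likelihood-ratio
    test compares a logistic model of R on all predictors with the
    intercept-only model.
    """
    r = np.asarray(measured_flags, dtype=int)
    if r.min() == r.max():
        raise FacohortError("both measured (R=1) and unmeasured (R=0) groups are required")
    rows = []
    for name in DWELLING_PREDICTORS:
        if name == "window_open_hours":
            x = pd.to_numeric(dwellings[name]).to_numpy(dtype=float)
            a, b = x[r == 1], x[r == 0]
            if np.ptp(x) == 0:
                stat_, p = 0.0, 1.0
            else:
                t = stats.ttest_ind(a, b, equal_var=False)
                stat_, p = float(t.statistic), float(t.pvalue)
            rows.append({"predictor": name, "test": "t", "statistic": stat_, "p": p})
        else:
            tab = pd.crosstab(dwellings[name], r).to_numpy()
            if tab.shape[0] < 2:
                rows.append({"predictor": name, "test": "chi2", "statistic": 0.0, "p": 1.0})
                continue
            test, stat_, p = _exact_or_chi2(tab)
            rows.append({"predictor": name, "test": test, "statistic": stat_, "p": p})
    table = pd.DataFrame(rows)
    m = len(table)
    table["p_bonferroni"] = np.minimum(1.0, table["p"] * m)
    lrt, df, p_global = mcar_global_test(dwellings, measured_flags)
    return McarReport(table, lrt, df, p_global)


def mcar_global_test(dwellings: pd.DataFrame, measured_flags):
    """LRT of logistic R ~ all predictors against the intercept-only model."""
    r = np.asarray(measured_flags, dtype=int)
    X = dwelling_design(dwellings, season_adjust=False)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        logger.info("mcar_global_test: dropping constant column(s) %s", constant)
        X = X.drop(columns=constant)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise FacohortError("design for the global MCAR test is not full rank")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = sm.Logit(r, Xc).fit(disp=0, maxiter=200)
        except Exception as exc:
            raise SeparationError(f"global MCAR logistic fit failed: {exc}") from exc
    if (~np.isfinite(full.bse)).any() or (np.abs(full.params) > 30).any():
        raise SeparationError("separation in the global MCAR model")
    null = sm.Logit(r, np.ones((len(r), 1))).fit(disp=0)
    lrt = 2.0 * (full.llf - null.llf)
    df = Xc.shape[1] - 1
    return float(lrt), int(df), float(stats.chi2.sf(lrt, df))


# ---------------------------------------------------------------------------
# joint Bayesian model
# ---------------------------------------------------------------------------

@dataclass
class Priors:
    """Prior scales: Normal(0, coef_sd²) on coefficients, Half-Normal(0, sigma_sd²) on σ."""

    coef_sd: float = 10.0
    sigma_sd: float = 5.0


@dataclass
class PosteriorSummary:
    name: str
    mean: float
    sd: float
    ci_low: float  # 2.5th percentile
    ci_high: float  # 97.5th percentile
    ess: float
    n_iter: int
    n_burnin: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ess": self.ess,
        }


@dataclass
class BayesResult:
    """Posterior draws, summaries and convergence report of one joint-model run."""

    summaries: dict
    draws: pd.DataFrame  # post-burn-in, one column per parameter
    or_per_iqr: dict  # stratum -> PosteriorSummary of exp(β·IQR)
    iqr_used: float
    convergence: pd.DataFrame
    acceptance: dict
    n_iter: int
    n_burnin: int
    seed: int
    warnings_: list = field(default_factory=list)


def draw_coef_conjugate(X: np.ndarray, f: np.ndarray, sigma: float,
                        prior_sd: float, rng: np.random.Generator) -> np.ndarray:
    """One Gibbs draw of γ | f, σ in the normal linear model with N(0, prior_sd²) prior."""
    p = X.shape[1]
    prec = X.T @ X / sigma**2 + np.eye(p) / prior_sd**2
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, X.T @ f / sigma**2)
    z = rng.standard_normal(p)
    return mean + np.linalg.solve(chol.T, z)


def _color_dwellings(columns_of, n_dwellings, subjects_of):
    """Partition dwelling indices so no two dwellings in a group share a subject."""
    groups: list[list[int]] = []
    group_subjects: list[set] = []
    for d in range(n_dwellings):
        subs = subjects_of[d]
        for g, gs in enumerate(group_subjects):
            if not gs.intersection(subs):
                groups[g].append(d)
                gs.update(subs)
                break
        else:
            groups.append([d])
            group_subjects.append(set(subs))
    return [np.array(g, dtype=int) for g in groups]


class _OutcomeModel:
    """Outcome log-likelihood as a function of (θ-block, subject exposure)."""

    def __init__(self, Z: np.ndarray, y: np.ndarray, kind: str):
        self.Z = Z
        self.y = y
        self.kind = kind
        self.q = Z.shape[1]
        if kind == "binary":
            self.n_par = self.q + 1
            self.strata = ("LRI",)
        else:
            self.n_par = 2 * (self.q + 1)
            self.strata = ("non_wLRI", "wLRI")
            self.y_onehot = np.eye(3)[y]

    def split(self, par):
        if self.kind == "binary":
            return (par[: self.q],), (par[self.q],)
        q = self.q
        return (par[:q], par[q + 1: 2 * q + 1]), (par[q], par[2 * q + 1])

    def loglik_terms(self, par, E):
        """Per-subject log-likelihood contributions."""
        thetas, betas = self.split(par)
        if self.kind == "binary":
            eta = self.Z @ thetas[0] + betas[0] * E
            return self.y * eta - np.logaddexp(0.0, eta)
        eta1 = self.Z @ thetas[0] + betas[0] * E
        eta2 = self.Z @ thetas[1] + betas[1] * E
        etas = np.column_stack([np.zeros_like(eta1), eta1, eta2])
        lse = np.logaddexp.reduce(etas, axis=1)
        return etas[np.arange(len(E)), self.y] - lse

    def loglik(self, par, E):
        return float(self.loglik_terms(par, E).sum())

    def ml_fit(self, E):
        """ML starting values and proposal covariance for the (θ, β) block."""
        X = np.column_stack([self.Z, E])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.kind == "binary":
                res = sm.Logit(self.y, X).fit(disp=0, maxiter=200)
                par = np.asarray(res.params)
                cov = np.asarray(res.cov_params())
            else:
                res = sm.MNLogit(self.y, X).fit(disp=0, maxiter=500)
                par = np.asarray(res.params).T.ravel()  # [θ1, β1, θ2, β2]
                cov = np.asarray(res.cov_params())
        if not np.all(np.isfinite(par)) or not np.all(np.isfinite(cov)):
            raise FacohortError("non-finite ML initial values for the outcome block")
        return par, cov


def fit_joint_bayes(
    subjects: pd.DataFrame,
    dwellings: pd.DataFrame,
    measurements: pd.DataFrame,
    priors: Priors | None = None,
    outcome: str = "binary",
    n_iter: int = 10000,
    n_burnin: int = 1000,
    seed: int = 0,
    min_seasons: int = 3,
    loq_policy: str = "half_loq",
    predictors=DWELLING_PREDICTORS,
    covariates=SUBJECT_COVARIATES,
    season_adjust: bool = True,
    thin: int = 1,
    track_latent: int = 0,
) -> BayesResult:
    """Run the joint imputation + health model by Metropolis-within-Gibbs.

    Returns posterior summaries (mean, SD, 2.5/97.5 percentiles, ESS) for the
    exposure coefficients γ, the residual SD σ, the outcome coefficients θ and
    the FA effect β, plus the per-IQR odds ratio exp(β·IQR) where the IQR is
    taken from the observed annual levels.  Deterministic given ``seed``.
    """
    if priors is None:
        priors = Priors()
    if outcome not in ("binary", "multinomial"):
        raise ValueError("outcome must be 'binary' or 'multinomial'")
    if not 0 <= n_burnin < n_iter:
        raise ValueError("need 0 <= n_burnin < n_iter")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)

    # --- exposure side ----------------------------------------------------
    X_df = dwelling_design(dwellings, predictors, season_adjust=season_adjust)
    X = sm.add_constant(X_df, has_constant="add")
    x_cols = list(X.columns)
    X = X.to_numpy(dtype=float)
    n_d, p = X.shape
    d_index = {d: i for i, d in enumerate(dwellings["dwelling_id"])}

    ann = annual_means(measurements, min_seasons=min_seasons, loq_policy=loq_policy)
    if ann.empty:
        raise FacohortError("measured subsample is empty: no defined annual levels")
    f = np.zeros(n_d)
    observed = np.zeros(n_d, dtype=bool)
    for d, m in zip(ann["dwelling_id"], ann["annual_mean"]):
        i = d_index.get(d)
        if i is None:
            raise FacohortError(f"measurement for unknown dwelling '{d}'")
        f[i] = np.log(m)
        observed[i] = True
    latent = np.flatnonzero(~observed)
    iqr_used = iqr_width(*np.quantile(ann["annual_mean"], [0.25, 0.75]))

    # --- outcome side -----------------------------------------------------
    from .exposure import _parse_history

    y_map = {lv: i for i, lv in enumerate(OUTCOME_LEVELS)}
    if outcome == "binary":
        y = (subjects["outcome"] != "never_LRI").astype(int).to_numpy()
    else:
        y = subjects["outcome"].map(y_map).to_numpy()
    Z = sm.add_constant(subject_design(subjects, covariates), has_constant="add")
    z_cols = list(Z.columns)
    Z = Z.to_numpy(dtype=float)
    n_s = Z.shape[0]

    rows, cols, wts = [], [], []
    subjects_of = [[] for _ in range(n_d)]
    for i, entry in enumerate(subjects["residence_history"]):
        for d, frac in _parse_history(entry):
            j = d_index.get(d)
            if j is None:
                raise FacohortError(f"residence history references unknown dwelling '{d}'")
            rows.append(i)
            cols.append(j)
            wts.append(frac)
            subjects_of[j].append(i)
    W = sparse.csr_matrix((wts, (rows, cols)), shape=(n_s, n_d))
    Wc = W.tocsc()

    model = _OutcomeModel(Z, y, outcome)

    # --- initial values ---------------------------------------------------
    Xo, fo = X[observed], f[observed]
    if observed.sum() <= p:
        raise FacohortError("too few measured dwellings to initialise the exposure block")
    gamma, *_ = np.linalg.lstsq(Xo, fo, rcond=None)
    resid = fo - Xo @ gamma
    sigma = float(max(np.std(resid, ddof=min(p, len(fo) - 1)), 1e-3))
    f[latent] = X[latent] @ gamma
    expf = np.exp(f)
    E = W @ expf

    def _chol_of(cov, dim):
        try:
            return np.linalg.cholesky(cov + 1e-10 * np.eye(dim))
        except np.linalg.LinAlgError:
            return np.diag(np.sqrt(np.diag(cov) + 1e-8))

    par, cov0 = model.ml_fit(E)
    prop_chol = _chol_of(cov0, len(par))
    q = model.q
    beta_idx = [q] if outcome == "binary" else [q, 2 * q + 1]
    beta_scales = {bi: 2.4 * np.sqrt(cov0[bi, bi]) for bi in beta_idx}
    # independence proposal: Laplace approximation, refreshed during burn-in
    IND_INFLATE = 1.4
    ind_center, ind_chol = par.copy(), prop_chol * IND_INFLATE

    def _ind_logq(x):
        z = np.linalg.solve(ind_chol, x - ind_center)
        return -0.5 * float(z @ z)
    ll_terms = model.loglik_terms(par, E)
    ll = float(ll_terms.sum())
    if not np.isfinite(ll):
        raise FacohortError("non-finite posterior density at initial values (outcome block)")

    groups = _color_dwellings(None, n_d, subjects_of)
    latent_groups = [g[~observed[g]] for g in groups]
    latent_groups = [g for g in latent_groups if len(g)]

    XtX = X.T @ X

    # adaptive scales (frozen at end of burn-in); standard RW targets
    s_theta, s_sigma = 2.38 / np.sqrt(len(par)), 0.3
    ACC_THETA, ACC_SIGMA, KAPPA = 0.234, 0.44, 0.05
    acc = {"theta": 0, "sigma": 0, "latent": 0.0, "latent_n": 0}

    precXtX_prior = np.eye(p) / priors.coef_sd**2
    keep = np.arange(n_burnin, n_iter, thin)
    n_keep = len(keep)
    par_names = (
        [f"gamma[{c}]" for c in x_cols]
        + ["sigma"]
        + (
            [f"theta[{c}]" for c in z_cols] + ["beta_fa"]
            if outcome == "binary"
            else [f"theta_non_wLRI[{c}]" for c in z_cols]
            + ["beta_fa_non_wLRI"]
            + [f"theta_wLRI[{c}]" for c in z_cols]
            + ["beta_fa_wLRI"]
        )
    )
    tracked = latent[: max(0, int(track_latent))]
    par_names += [f"latent_logfa[{dwellings['dwelling_id'].iloc[i]}]" for i in tracked]
    trace = np.empty((n_keep, len(par_names)))
    k = 0

    for it in range(n_iter):
        adapt = it < n_burnin

        # γ | f, σ : conjugate Gibbs
        prec = XtX / sigma**2 + precXtX_prior
        cholP = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, X.T @ f / sigma**2)
        gamma = mean + np.linalg.solve(cholP.T, rng.standard_normal(p))
        mu = X @ gamma
        ssr = float(((f - mu) ** 2).sum())

        # σ : random-walk on log σ, proposed jointly with a rescaling of the
        # latent residuals f_l ← μ + (σ'/σ)(f_l − μ).  The latent prior terms
        # cancel against the Jacobian, so the accept ratio involves only the
        # observed dwellings, the Half-Normal prior and the outcome likelihood.
        ls = np.log(sigma)
        ls_new = ls + s_sigma * rng.standard_normal()
        sg_new = np.exp(ls_new)
        c_scale = sg_new / sigma
        ssr_obs = float(((f[observed] - mu[observed]) ** 2).sum())
        n_obs = int(observed.sum())
        f_lat_new = mu[latent] + c_scale * (f[latent] - mu[latent])
        expf_lat_new = np.exp(f_lat_new)
        E_new = E + Wc[:, latent] @ (expf_lat_new - expf[latent])
        ll_new_terms = model.loglik_terms(par, E_new)
        ll_new = float(ll_new_terms.sum())

        def _sigma_logpost(sg, lsg):
            return (-n_obs * lsg - ssr_obs / (2 * sg**2)
                    - sg**2 / (2 * priors.sigma_sd**2) + lsg)

        log_alpha = _sigma_logpost(sg_new, ls_new) - _sigma_logpost(sigma, ls) + ll_new - ll
        accepted = np.log(rng.random()) < log_alpha
        if accepted:
            sigma = sg_new
            f[latent] = f_lat_new
            expf[latent] = expf_lat_new
            E = E_new
            ll_terms = ll_new_terms
            ll = ll_new
            acc["sigma"] += 1
        if adapt:
            s_sigma = float(np.clip(s_sigma * np.exp(KAPPA * (accepted - ACC_SIGMA)),
                                    1e-3, 5.0))

        # latent log-FA values: group-wise independence sampler from the
        # exposure prior N(x'γ, σ); the accept ratio reduces to the outcome
        # likelihood ratio, giving global (non-random-walk) moves
        for g in latent_groups:
            prop = mu[g] + sigma * rng.standard_normal(len(g))
            d_expf = np.exp(prop) - expf[g]
            Wg = Wc[:, g]
            E_new = E + Wg @ d_expf
            ll_new_terms = model.loglik_terms(par, E_new)
            dll_subj = ll_new_terms - ll_terms
            coo = Wg.tocoo()
            dll_dwell = np.zeros(len(g))
            np.add.at(dll_dwell, coo.col, dll_subj[coo.row])
            accept = np.log(rng.random(len(g))) < dll_dwell
            if accept.any():
                ga = g[accept]
                f[ga] = prop[accept]
                new_expf = np.exp(prop[accept])
                dE_acc = Wc[:, ga] @ (new_expf - expf[ga])
                expf[ga] = new_expf
                E = E + dE_acc
                ll_terms = model.loglik_terms(par, E)
            acc["latent"] += float(accept.mean()) if len(g) else 0.0
            acc["latent_n"] += 1
        ll = float(ll_terms.sum())

        # (θ, β) block: a Laplace independence proposal (global moves) followed
        # by a random-walk Metropolis step (local exploration)
        if adapt and it > 0 and it % 50 == 0:
            try:
                ind_center, cov_it = model.ml_fit(E)
                ind_chol = _chol_of(cov_it, len(par)) * IND_INFLATE
            except Exception:  # keep the previous proposal on a failed refit
                pass
        for _ in range(3):  # several cheap global-refresh attempts per sweep
            par_new = ind_center + ind_chol @ rng.standard_normal(len(par))
            ll_new_terms = model.loglik_terms(par_new, E)
            ll_new = float(ll_new_terms.sum())
            dprior = -(par_new @ par_new - par @ par) / (2 * priors.coef_sd**2)
            log_alpha = (ll_new + dprior - ll) - (_ind_logq(par_new) - _ind_logq(par))
            if np.log(rng.random()) < log_alpha:
                par = par_new
                ll_terms = ll_new_terms
                ll = ll_new
                acc["theta_ind"] = acc.get("theta_ind", 0) + 1

        par_new = par + s_theta * (prop_chol @ rng.standard_normal(len(par)))
        ll_new_terms = model.loglik_terms(par_new, E)
        ll_new = float(ll_new_terms.sum())
        dprior = -(par_new @ par_new - par @ par) / (2 * priors.coef_sd**2)
        accepted = np.log(rng.random()) < ll_new - ll + dprior
        if accepted:
            par = par_new
            ll_terms = ll_new_terms
            ll = ll_new
            acc["theta"] += 1
        if adapt:
            s_theta = float(np.clip(s_theta * np.exp(KAPPA * (accepted - ACC_THETA)),
                                    1e-4, 10.0))

        # extra single-coordinate steps on each FA effect β (1-dim, fast mixing)
        for bi in beta_idx:
            par_new = par.copy()
            par_new[bi] += beta_scales[bi] * rng.standard_normal()
            ll_new_terms = model.loglik_terms(par_new, E)
            ll_new = float(ll_new_terms.sum())
            dprior = -(par_new[bi] ** 2 - par[bi] ** 2) / (2 * priors.coef_sd**2)
            if np.log(rng.random()) < ll_new - ll + dprior:
                par = par_new
                ll_terms = ll_new_terms
                ll = ll_new

        if k < n_keep and it == keep[k]:
            trace[k] = np.concatenate([gamma, [sigma], par, f[tracked]])
            k += 1

    draws = pd.DataFrame(trace[:k], columns=par_names)
    conv = convergence_diagnostics(draws)
    warn_list = []
    summaries = {}
    for name in par_names:
        d = draws[name].to_numpy()
        ess = float(conv.loc[name, "ess"])
        summaries[name] = PosteriorSummary(
            name, float(d.mean()), float(d.std(ddof=1)),
            float(np.quantile(d, 0.025)), float(np.quantile(d, 0.975)),
            ess, n_iter, n_burnin, seed,
        )

    or_per_iqr = {}
    beta_cols = (["beta_fa"] if outcome == "binary"
                 else ["beta_fa_non_wLRI", "beta_fa_wLRI"])
    for stratum, col in zip(model.strata, beta_cols):
        ord_ = np.exp(draws[col].to_numpy() * iqr_used)
        or_per_iqr[stratum] = PosteriorSummary(
            f"OR_per_IQR[{stratum}]", float(ord_.mean()), float(ord_.std(ddof=1)),
            float(np.quantile(ord_, 0.025)), float(np.quantile(ord_, 0.975)),
            float(conv.loc[col, "ess"]), n_iter, n_burnin, seed,
        )
        if conv.loc[col, "ess"] < 100:
            warn_list.append(f"ESS < 100 for {col}")
    low_ess = conv.index[conv["ess"] < 100].tolist()
    for name in low_ess:
        msg = f"ESS < 100 for {name}"
        if msg not in warn_list:
            warn_list.append(msg)
    for msg in warn_list:
        logger.warning("fit_joint_bayes: %s", msg)

    acc_rates = {
        "theta": acc["theta"] / n_iter,
        "theta_ind": acc.get("theta_ind", 0) / n_iter,
        "sigma": acc["sigma"] / n_iter,
        "latent": acc["latent"] / max(acc["latent_n"], 1),
    }
    return BayesResult(
        summaries=summaries,
        draws=draws,
        or_per_iqr=or_per_iqr,
        iqr_used=iqr_used,
        convergence=conv,
        acceptance=acc_rates,
        n_iter=n_iter,
        n_burnin=n_burnin,
        seed=seed,
        warnings_=warn_list,
    )


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def _autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = x - x.mean()
    var = float(x @ x)
    if var == 0:
        return np.full(max_lag + 1, np.nan)
    n = len(x)
    acf = np.array([x[: n - k] @ x[k:] / var for k in range(max_lag + 1)])
    return acf


def _geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    n = len(x)
    a, b = x[: int(first * n)], x[int((1 - last) * n):]

    def _spectral_var(seg):
        # batch-means estimate of the long-run variance
        nb = max(int(np.sqrt(len(seg))), 2)
        size = len(seg) // nb
        if size < 1:
            return np.var(seg)
        means = seg[: nb * size].reshape(nb, size).mean(axis=1)
        return size * np.var(means, ddof=1) / 1.0

    va, vb = _spectral_var(a) / len(a), _spectral_var(b) / len(b)
    if va + vb == 0:
        return np.nan
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def convergence_diagnostics(draws, max_lag: int = 50) -> pd.DataFrame:
    """Trace summary per parameter: mean, SD, lag-1 ACF, Geweke z, ESS, flags.

    A parameter is flagged when |Geweke z| > 2, ESS < 100, or the chain is
    degenerate (zero variance).
    """
    import arviz as az

    if isinstance(draws, dict):
        draws = pd.DataFrame(draws)
    if len(draws) < 2:
        raise ValueError("need at least 2 retained draws")
    rows = []
    for name in draws.columns:
        x = draws[name].to_numpy(dtype=float)
        degenerate = float(np.ptp(x)) == 0.0
        if degenerate:
            rows.append(
                {"parameter": name, "mean": float(x.mean()), "sd": 0.0,
                 "lag1_acf": np.nan, "geweke_z": np.nan, "ess": 0.0,
                 "flagged": True, "degenerate": True}
            )
            continue
        acf = _autocorr(x, min(max_lag, len(x) - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = float(az.ess(np.asarray(x)))
        gz = _geweke_z(x)
        flagged = bool((np.isfinite(gz) and abs(gz) > 2) or ess < 100)
        rows.append(
            {"parameter": name, "mean": float(x.mean()), "sd": float(x.std(ddof=1)),
             "lag1_acf": float(acf[1]) if len(acf) > 1 else np.nan,
             "geweke_z": gz, "ess": ess, "flagged": flagged, "degenerate": False}
        )
    return pd.DataFrame(rows).set_index("parameter")
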