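"""ML and FIML estimation for covariance-structure models.

Complete-data ML minimizes the discrepancy

    F(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

and reports chi2 = (n - 1) * F_min.  FIML maximizes the casewise Gaussian
log-likelihood over missingness patterns with a saturated mean structure
(one free mean per observed variable; since both the model and the
saturated reference carry the same p means, the degrees of freedom equal
the complete-data count).  The FIML chi2 is the likelihood ratio against
the saturated model, whose MLE is obtained by EM.

Standard errors come from the inverse numerical Hessian of the
(n-1)/2-scaled discrepancy (ML) or of the negative log-likelihood (FIML);
critical ratios are referred to the standard normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.tools.numdiff import approx_hess3

from .model import SemModel
from .indices import fit_indices

__all__ = ["SemFit", "fit_ml", "fit_fiml", "standardize", "em_mvn"]

_LOG2PI = np.log(2.0 * np.pi)
_VAR_FLOOR = 1e-8


@dataclass
class SemFit:
    """Fitted model: estimates, inference, standardized solution, fit indices."""

    model: SemModel
    estimates: dict[str, float]
    se: dict[str, float]
    cr: dict[str, float]
    p_two_sided: dict[str, float]
    standardized: dict[str, float]
    smc: dict[str, float]
    chi_square: float
    df: int
    p_chi: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    loglik: float
    n: int
    converged: bool
    estimator: str
    theta: np.ndarray = field(repr=False, default=None)
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"SEM fit ({self.estimator.upper()}), n = {self.n}, converged = {self.converged}",
            f"chi2({self.df}) = {self.chi_square:.3f}, p = {self.p_chi:.3f}, "
            f"RMSEA = {self.rmsea:.3f} [{self.rmsea_ci90[0]:.3f}, {self.rmsea_ci90[1]:.3f}]",
            f"{'parameter':<28}{'est':>10}{'se':>10}{'cr':>8}{'p':>8}{'std':>8}",
        ]
        for name in self.estimates:
            se = self.se.get(name, np.nan)
            cr = self.cr.get(name, np.nan)
            p = self.p_two_sided.get(name, np.nan)
            std = self.standardized.get(name, np.nan)
            lines.append(
                f"{name:<28}{self.estimates[name]:>10.4f}{se:>10.4f}{cr:>8.2f}{p:>8.3f}{std:>8.3f}"
            )
        if self.smc:
            lines.append("SMC: " + ", ".join(f"{v}={r:.3f}" for v, r in self.smc.items()))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "n": self.n,
            "converged": self.converged,
            "estimates": self.estimates,
            "se": self.se,
            "cr": self.cr,
            "p_two_sided": self.p_two_sided,
            "standardized": self.standardized,
            "smc": self.smc,
            "chi_square": self.chi_square,
            "df": self.df,
            "p_chi": self.p_chi,
            "rmsea": self.rmsea,
            "rmsea_ci90": list(self.rmsea_ci90),
            "loglik": self.loglik,
            "warnings": self.warnings,
        }


# ---------------------------------------------------------------------------
# shared helpers


def _align_cov(model: SemModel, sample_cov) -> np.ndarray:
    if isinstance(sample_cov, pd.DataFrame):
        missing = [v for v in model.observed_vars if v not in sample_cov.columns]
        if missing:
            raise ValueError(f"sample covariance lacks variables: {missing}")
        return sample_cov.loc[model.observed_vars, model.observed_vars].to_numpy(dtype=float)
    S = np.asarray(sample_cov, dtype=float)
    if S.shape != (len(model.observed_vars),) * 2:
        raise ValueError(
            f"sample covariance shape {S.shape} does not match "
            f"{len(model.observed_vars)} observed variables"
        )
    return S


def _start_vector(model: SemModel, sample_cov: pd.DataFrame) -> np.ndarray:
    """Deterministic data-informed start values.

    Latents are proxied by the anchor indicator behind their fixed loading;
    free paths start at the crude regression slope between the anchors of
    source and target (falling back to 0.5), variances at half the sample
    (or anchor) variance, covariances at 0.
    """
    observed = set(model.observed_vars)

    def anchor(v: str, depth: int = 0) -> str | None:
        """Observed proxy variable for v (itself if observed)."""
        if v in observed:
            return v
        if depth < 3:
            for src, tgt, fx, _ in model.paths:
                if src == v and fx is not None and abs(fx) > 0:
                    a = anchor(tgt, depth + 1)
                    if a is not None:
                        return a
        return None

    def svar(v: str | None) -> float:
        if v is not None and v in sample_cov.columns:
            x = float(sample_cov.loc[v, v])
            if np.isfinite(x) and x > 0:
                return x
        return 2.0

    theta = []
    for p in model.free_parameters:
        if p.matrix == "A":
            if p.start is not None:
                theta.append(p.start)
                continue
            src = model.variables[p.col]
            tgt = model.variables[p.row]
            a_s, a_t = anchor(src), anchor(tgt)
            if (
                a_s is not None
                and a_t is not None
                and a_s in sample_cov.columns
                and a_t in sample_cov.columns
            ):
                v_s = svar(a_s)
                c = float(sample_cov.loc[a_t, a_s])
                theta.append(c / v_s if np.isfinite(c) and v_s > 0 else 0.5)
            else:
                theta.append(0.5)
        elif p.row == p.col:
            theta.append(0.5 * svar(anchor(model.variables[p.row])))
        else:
            theta.append(0.0)
    return np.array(theta, dtype=float)


def _bounds(model: SemModel) -> list[tuple[float | None, float | None]]:
    out = []
    for p in model.free_parameters:
        if p.matrix == "S" and p.row == p.col:
            out.append((_VAR_FLOOR, None))
        else:
            out.append((None, None))
    return out


def _safe_sigma(Sigma: np.ndarray) -> tuple[np.ndarray, float]:
    """Ridge retreat: shift a non-PD implied covariance back to PD, with penalty."""
    try:
        linalg.cho_factor(Sigma, check_finite=False)
        return Sigma, 0.0
    except (linalg.LinAlgError, ValueError):
        ev = np.linalg.eigvalsh(Sigma)
        ridge = abs(min(ev.min(), 0.0)) + 1e-8 * max(np.trace(Sigma) / Sigma.shape[0], 1.0)
        return Sigma + ridge * np.eye(Sigma.shape[0]), ridge


def standardize(model: SemModel, theta: np.ndarray) -> tuple[dict[str, float], dict[str, float]]:
    """Standardized solution and squared multiple correlations.

    Path coefficients are rescaled by model-implied SDs
    (beta_std = beta * sd(source)/sd(target)); residual covariances are
    reported as residual correlations; SMC(v) = 1 - resid_var(v)/implied_var(v).
    """
    C = model.total_covariance(theta)
    d = np.diag(C).copy()
    if np.any(d <= 0):
        bad = [model.variables[i] for i in np.where(d <= 0)[0]]
        raise ValueError(f"zero or negative implied variance for {bad}")
    sd = np.sqrt(d)
    _, S = model.matrices(theta)
    endo = set(model.endogenous)
    std: dict[str, float] = {}
    smc: dict[str, float] = {}
    vals = model.param_dict(theta)
    for p in model.parameters:
        v = vals[p.name]
        if p.matrix == "A":
            std[p.name] = v * sd[p.col] / sd[p.row]
        elif p.row == p.col:
            std[p.name] = v / C[p.row, p.row]
        else:
            a, b = model.variables[p.row], model.variables[p.col]
            if a in endo and b in endo:
                denom = np.sqrt(S[p.row, p.row] * S[p.col, p.col])
            else:
                denom = sd[p.row] * sd[p.col]
            std[p.name] = v / denom if denom > 0 else np.nan
    for v in model.endogenous:
        i = model.var_index[v]
        smc[v] = float(1.0 - S[i, i] / C[i, i])
    return std, smc


def _inference(
    hess_fn, theta: np.ndarray, names: list[str], warn: list[str]
) -> tuple[dict, dict, dict]:
    se = dict.fromkeys(names, np.nan)
    try:
        H = approx_hess3(theta, hess_fn)
        cov = np.linalg.inv(H)
        dg = np.diag(cov)
        for i, name in enumerate(names):
            se[name] = float(np.sqrt(dg[i])) if dg[i] > 0 else np.nan
        if np.any(dg <= 0):
            warn.append("Hessian not positive definite; some SEs missing")
    except np.linalg.LinAlgError:
        warn.append("Hessian singular; SEs missing")
    cr = {}
    for k, v in zip(names, theta):
        s = se.get(k, np.nan)
        cr[k] = float(v / s) if (np.isfinite(s) and s > 0) else np.nan
    p = {k: float(2.0 * stats.norm.sf(abs(c))) if np.isfinite(c) else np.nan for k, c in cr.items()}
    return se, cr, p


def _finalize(
    model: SemModel,
    theta: np.ndarray,
    chi_square: float,
    df: int,
    loglik: float,
    n: int,
    converged: bool,
    estimator: str,
    hess_fn,
    extra_names: list[str] = (),
    extra_theta: np.ndarray = None,
    compute_se: bool = True,
    warn: list[str] | None = None,
) -> SemFit:
    warn = warn if warn is not None else []
    q_theta = theta if extra_theta is None else np.concatenate([theta, extra_theta])
    names = model.free_names + list(extra_names)
    estimates = model.param_dict(theta)
    for name, v in zip(extra_names, extra_theta if extra_theta is not None else []):
        estimates[name] = float(v)
    if compute_se:
        se, cr, p = _inference(hess_fn, q_theta, names, warn)
    else:
        se = {}
        cr = {}
        p = {}
    if df == 0:
        if chi_square > 1e-4:
            warn.append(f"saturated model did not reach F = 0 (chi2 = {chi_square:.2e})")
        p_chi, rmsea, ci = 1.0, 0.0, (0.0, 0.0)
    else:
        p_chi, rmsea, ci = fit_indices(chi_square, df, n)
    try:
        std, smc = standardize(model, theta)
    except ValueError as err:
        warn.append(str(err))
        std, smc = {}, {}
    return SemFit(
        model=model,
        estimates=estimates,
        se=se,
        cr=cr,
        p_two_sided=p,
        standardized=std,
        smc=smc,
        chi_square=float(chi_square),
        df=int(df),
        p_chi=float(p_chi),
        rmsea=float(rmsea),
        rmsea_ci90=ci,
        loglik=float(loglik),
        n=int(n),
        converged=bool(converged),
        estimator=estimator,
        theta=q_theta,
        warnings=warn,
    )


# ---------------------------------------------------------------------------
# complete-data ML


def fit_ml(model: SemModel, sample_cov, n: int, compute_se: bool = True) -> SemFit:
    """Fit by complete-data maximum likelihood on a sample covariance matrix."""
    S = _align_cov(model, sample_cov)
    p = S.shape[0]
    if n <= p:
        raise ValueError(f"n = {n} must exceed the number of observed variables ({p})")
    ev = np.linalg.eigvalsh(S)
    if ev.min() <= 0:
        raise ValueError("sample covariance is not positive definite")
    sign, logdetS = np.linalg.slogdet(S)
    df = p * (p + 1) // 2 - model.n_free
    if df < 0:
        raise ValueError(f"model has more free parameters ({model.n_free}) than moments ({p * (p + 1) // 2})")

    def F(theta: np.ndarray) -> float:
        Sigma, ridge = _safe_sigma(model.implied_covariance(theta))
        c = linalg.cho_factor(Sigma, check_finite=False)
        logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
        tr = np.trace(linalg.cho_solve(c, S, check_finite=False))
        return logdet + tr - logdetS - p + 1e3 * ridge

    Sdf = pd.DataFrame(S, index=model.observed_vars, columns=model.observed_vars)
    theta0 = _start_vector(model, Sdf)
    res = optimize.minimize(
        F, theta0, method="L-BFGS-B", bounds=_bounds(model),
        options={"maxiter": 5000, "maxfun": 100000, "ftol": 1e-14, "gtol": 1e-10},
    )
    warn: list[str] = []
    if not res.success:
        res2 = optimize.minimize(
            F, res.x, method="Nelder-Mead",
            options={"maxiter": 5000, "fatol": 1e-12, "xatol": 1e-10},
        )
        if res2.fun <= res.fun:
            res = res2
    converged = bool(res.success)
    if not converged:
        warn.append(f"optimizer did not converge: {res.message}")
    theta = np.asarray(res.x, dtype=float)
    F_min = max(0.0, float(F(theta)))
    chi_square = (n - 1) * F_min
    Sigma, _ = _safe_sigma(model.implied_covariance(theta))
    St = (n - 1) / n * S
    c = linalg.cho_factor(Sigma, check_finite=False)
    loglik = -0.5 * n * (
        p * _LOG2PI
        + 2.0 * np.sum(np.log(np.diag(c[0])))
        + np.trace(linalg.cho_solve(c, St, check_finite=False))
    )
    return _finalize(
        model, theta, chi_square, df, loglik, n, converged, "ml",
        hess_fn=lambda t: 0.5 * (n - 1) * F(t),
        compute_se=compute_se, warn=warn,
    )


# ---------------------------------------------------------------------------
# FIML


def _patterns(X: np.ndarray):
    """Group rows by missingness pattern; precompute count, mean and scatter."""
    obs = ~np.isnan(X)
    keys, inverse = np.unique(obs, axis=0, return_inverse=True)
    out = []
    for k in range(keys.shape[0]):
        idx = np.where(keys[k])[0]
        if idx.size == 0:
            continue
        rows = X[inverse == k][:, idx]
        nk = rows.shape[0]
        mean = rows.mean(axis=0)
        centered = rows - mean
        scatter = centered.T @ centered
        out.append((idx, nk, mean, scatter))
    return out


def _pattern_loglik(patterns, mu: np.ndarray, Sigma: np.ndarray) -> float:
    ll = 0.0
    for idx, nk, mean, scatter in patterns:
        sub = Sigma[np.ix_(idx, idx)]
        c = linalg.cho_factor(sub, check_finite=False)
        logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
        d = mean - mu[idx]
        quad = np.trace(linalg.cho_solve(c, scatter, check_finite=False)) + nk * d @ linalg.cho_solve(c, d, check_finite=False)
        ll += -0.5 * (nk * (idx.size * _LOG2PI + logdet) + quad)
    return float(ll)


def em_mvn(
    X: np.ndarray, max_iter: int = 500, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian MLE (mu, Sigma, loglik) under ignorable missingness, by EM."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    mu = np.nanmean(X, axis=0)
    var = np.nanvar(X, axis=0)
    Sigma = np.diag(np.maximum(var, 1e-8))
    obs = ~np.isnan(X)
    keys, inverse = np.unique(obs, axis=0, return_inverse=True)
    groups = [(np.where(k)[0], np.where(~k)[0], np.where(inverse == i)[0]) for i, k in enumerate(keys)]
    patterns = _patterns(X)
    ll_old = -np.inf
    for _ in range(max_iter):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        for o, m, rows in groups:
            if o.size == 0:
                continue
            Xo = X[rows][:, o]
            if m.size == 0:
                T1[o] += Xo.sum(axis=0)
                T2[np.ix_(o, o)] += Xo.T @ Xo
                continue
            Soo = Sigma[np.ix_(o, o)]
            Smo = Sigma[np.ix_(m, o)]
            c = linalg.cho_factor(Soo, check_finite=False)
            B = linalg.cho_solve(c, Smo.T, check_finite=False).T  # Smo Soo^-1
            Xm = mu[m] + (Xo - mu[o]) @ B.T
            Cm = Sigma[np.ix_(m, m)] - B @ Smo.T
            T1[o] += Xo.sum(axis=0)
            T1[m] += Xm.sum(axis=0)
            T2[np.ix_(o, o)] += Xo.T @ Xo
            T2[np.ix_(o, m)] += Xo.T @ Xm
            T2[np.ix_(m, o)] += Xm.T @ Xo
            T2[np.ix_(m, m)] += Xm.T @ Xm + Xm.shape[0] * Cm
        mu = T1 / n
        Sigma = T2 / n - np.outer(mu, mu)
        Sigma = (Sigma + Sigma.T) / 2.0
        ll = _pattern_loglik(patterns, mu, Sigma)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            break
        ll_old = ll
    return mu, Sigma, ll


def fit_fiml(model: SemModel, data: pd.DataFrame, compute_se: bool = True) -> SemFit:
    """Full-information ML on casewise data with missing values.

    Each case contributes the Gaussian log-density of its observed
    sub-vector; the mean structure is saturated (one free mean per observed
    variable).  chi2 is the likelihood ratio against the EM-fitted
    saturated model.
    """
    missing_cols = [v for v in model.observed_vars if v not in data.columns]
    if missing_cols:
        raise ValueError(f"data lacks variables: {missing_cols}")
    X = data[model.observed_vars].to_numpy(dtype=float)
    n0 = X.shape[0]
    keep = ~np.all(np.isnan(X), axis=1)
    warn: list[str] = []
    if not keep.all():
        warn.append(f"dropped {int((~keep).sum())} case(s) with no observed variables")
        X = X[keep]
    n, p = X.shape
    n_obs_per_var = (~np.isnan(X)).sum(axis=0)
    thin = [model.observed_vars[j] for j in np.where(n_obs_per_var < 2)[0]]
    if thin:
        raise ValueError(f"variables observed for fewer than 2 cases: {thin}")

    patterns = _patterns(X)
    q = model.n_free
    df = p * (p + 1) // 2 - q
    if df < 0:
        raise ValueError(f"model has more free parameters ({q}) than covariance moments")

    def negll(full: np.ndarray) -> float:
        theta, mu = full[:q], full[q:]
        Sigma, ridge = _safe_sigma(model.implied_covariance(theta))
        try:
            ll = _pattern_loglik(patterns, mu, Sigma)
        except (linalg.LinAlgError, ValueError):
            return 1e12
        return -ll + 1e3 * n * ridge

    pairwise = pd.DataFrame(X, columns=model.observed_vars).cov()
    theta0 = _start_vector(model, pairwise)
    mu0 = np.nanmean(X, axis=0)
    full0 = np.concatenate([theta0, mu0])
    bounds = _bounds(model) + [(None, None)] * p
    res = optimize.minimize(
        negll, full0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 5000, "maxfun": 200000, "ftol": 1e-13, "gtol": 1e-7},
    )
    converged = bool(res.success)
    if not converged:
        warn.append(f"optimizer did not converge: {res.message}")
    theta = np.asarray(res.x[:q], dtype=float)
    mu_hat = np.asarray(res.x[q:], dtype=float)
    ll_model = -float(negll(res.x))

    mu_s, Sigma_s, ll_sat = em_mvn(X)
    chi_square = max(0.0, 2.0 * (ll_sat - ll_model))

    mean_names = [f"mean({v})" for v in model.observed_vars]
    return _finalize(
        model, theta, chi_square, df, ll_model, n, converged, "fiml",
        hess_fn=negll,
        extra_names=mean_names, extra_theta=mu_hat,
        compute_se=compute_se, warn=warn,
    )
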