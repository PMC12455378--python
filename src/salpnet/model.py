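"""Nested random-effects logistic regression and variance decomposition.

The analysis model is a patient-level logistic regression of the
opportunistic-salpingectomy (OS) outcome on the peer-exposure quartile and
screened covariates, with a random intercept for the operating surgeon
nested inside a random intercept for the surgeon's patient-sharing network:

    logit P(y_ij = 1) = x_ij' beta + u_j + v_k(j)
    u_j ~ N(0, sigma2_surgeon),  v_k ~ N(0, sigma2_network)

Because each surgeon belongs to exactly one network, the penalized-
likelihood Hessian is block "arrowhead" per network (a diagonal surgeon
block bordered by a single network row), so the inner Newton mode-finding,
the log-determinant, and the linear solves are all O(n) and fully
vectorized across networks.  Two marginal-likelihood approximations are
available on top of that machinery:

``laplace``
    classic Laplace approximation at the joint random-effect mode (what
    lme4's ``glmer`` does for multiple grouping factors);
``agq`` (default)
    nested adaptive Gauss-Hermite quadrature, the multilevel-logistic
    estimator popularized by Stata's ``melogit``/GLLAMM.  Conditional on
    the network intercept the surgeons are independent, so the integral
    factorizes into stacked one-dimensional quadratures: an inner
    surgeon-level rule centered at each surgeon's conditional mode and an
    outer network-level rule centered at the Laplace mode with the Schur-
    complement curvature.  AGQ removes the downward small-cluster bias
    that the Laplace approximation shows in variance components with
    binary outcomes.

Variance decomposition follows the latent-threshold convention: the
patient-level residual variance on the logistic scale is fixed at pi^2/3,
and the surgeon and network shares are their fitted variance components
over the total sigma2_network + sigma2_surgeon + pi^2/3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, stats
from scipy.special import expit, logsumexp

__all__ = [
    "ModelSpec",
    "FitResult",
    "VarianceDecomposition",
    "ScreenResult",
    "univariate_screen",
    "build_design",
    "fit_nested_logistic",
    "fit_null_model",
    "variance_decomposition",
    "density_interaction_fit",
]

#: Latent-scale residual variance of the standard logistic distribution.
LOGISTIC_RESIDUAL_VARIANCE = np.pi**2 / 3.0

# Reference level per covariate; dummies are created against these.
REFERENCE_LEVELS = {
    "quartile": "Q1",
    "age_band": "18-29",
    "mode_of_delivery": "vaginal",
    "bmi_class": "<25",
    "smoking": False,
    "elixhauser_class": "0",
    "region": "Midwest",
    "sdi_class": "<25",
    "metro": False,
    "year": 2020,
}

CATEGORICAL_COVARIATES = [
    "age_band",
    "mode_of_delivery",
    "bmi_class",
    "smoking",
    "elixhauser_class",
    "region",
    "sdi_class",
    "metro",
    "year",
]
COUNT_COVARIATES = ["surgeon_volume"]


@dataclass
class ModelSpec:
    """Fixed-effect layout for the nested logistic model.

    ``fixed_effects`` lists covariate column names; the peer-exposure
    quartile is always included and need not be listed.  ``interaction``
    adds a network-density main effect and quartile x density terms.
    """

    fixed_effects: list[str] = field(default_factory=list)
    include_quartile: bool = True
    interaction: bool = False


@dataclass
class ScreenResult:
    covariate: str
    test: str
    statistic: float
    p_value: float
    retained: bool
    note: str = ""


@dataclass
class FitResult:
    """Fitted nested logistic model.

    ``params`` has one row per fixed-effect term with columns
    ``term, estimate, se, odds_ratio, ci_low, ci_high, p_value``.
    """

    params: pd.DataFrame
    sigma2_surgeon: float
    sigma2_network: float
    log_likelihood: float
    converged: bool
    n_patients: int
    n_surgeons: int
    n_networks: int
    boundary_surgeon: bool = False
    boundary_network: bool = False
    vcov: np.ndarray | None = None
    diagnostics: str = ""

    def coef(self, term: str) -> float:
        row = self.params.loc[self.params["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["estimate"].iloc[0])

    def se(self, term: str) -> float:
        row = self.params.loc[self.params["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["se"].iloc[0])


@dataclass
class VarianceDecomposition:
    proportion_patient: float
    proportion_surgeon: float
    proportion_network: float
    ci_patient: tuple[float, float] | None = None
    ci_surgeon: tuple[float, float] | None = None
    ci_network: tuple[float, float] | None = None

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for level, share, ci in [
            ("patient", self.proportion_patient, self.ci_patient),
            ("surgeon", self.proportion_surgeon, self.ci_surgeon),
            ("network", self.proportion_network, self.ci_network),
        ]:
            rows.append(
                {
                    "level": level,
                    "proportion": share,
                    "ci_low": ci[0] if ci else np.nan,
                    "ci_high": ci[1] if ci else np.nan,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Univariate screening
# ---------------------------------------------------------------------------


def univariate_screen(
    dataset: pd.DataFrame,
    covariates: list[str] | None = None,
    alpha: float = 0.2,
    outcome: str = "os_flag",
) -> tuple[list[str], list[ScreenResult]]:
    """Screen covariates one at a time against the binary outcome.

    Categorical covariates use the chi-square test of independence;
    count-valued covariates (surgeon volume) use the Wilcoxon rank-sum
    test between outcome groups.  Covariates with P < ``alpha`` are
    retained.  The quartile exposure is never screened out: it is the
    exposure of interest and enters every model unconditionally.
    """
    if covariates is None:
        covariates = [
            c
            for c in CATEGORICAL_COVARIATES + COUNT_COVARIATES
            if c in dataset.columns
        ]
    y = dataset[outcome].astype(bool)
    results: list[ScreenResult] = []
    retained: list[str] = []
    for cov in covariates:
        x = dataset[cov]
        if x.nunique(dropna=True) < 2:
            results.append(
                ScreenResult(cov, "skipped", np.nan, np.nan, False, "single level")
            )
            warnings.warn(f"covariate {cov!r} has a single observed level; skipped")
            continue
        if cov in COUNT_COVARIATES or pd.api.types.is_float_dtype(x):
            a = x[y].to_numpy(dtype=float)
            b = x[~y].to_numpy(dtype=float)
            stat, p = stats.ranksums(a, b)
            test = "ranksum"
        else:
            table = pd.crosstab(x, y)
            stat, p, _, _ = stats.chi2_contingency(table)
            test = "chi2"
        keep = bool(p < alpha)
        results.append(ScreenResult(cov, test, float(stat), float(p), keep))
        if keep:
            retained.append(cov)
    return retained, results


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def build_design(
    dataset: pd.DataFrame,
    spec: ModelSpec,
    densities: pd.Series | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Expand the analysis table into (X, term names, y, surgeon, network).

    Dummy coding is against the fixed reference levels (first-listed level
    of each characteristic; Q1 for the exposure).  Surgeon and network ids
    are factorized to dense indices with surgeon→network consistency
    checked.
    """
    df = dataset.reset_index(drop=True)
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]

    def add_categorical(cov: str) -> None:
        ref = REFERENCE_LEVELS.get(cov)
        levels = [lv for lv in _ordered_levels(df[cov]) if lv != ref]
        if ref is not None and ref not in set(_ordered_levels(df[cov])):
            # reference absent in data: use first observed level as reference
            levels = _ordered_levels(df[cov])[1:]
        for lv in levels:
            cols.append((df[cov] == lv).to_numpy(dtype=float))
            names.append(f"{cov}[{lv}]")

    if spec.include_quartile:
        add_categorical("quartile")
    for cov in spec.fixed_effects:
        if cov == "quartile":
            continue
        if cov in COUNT_COVARIATES:
            cols.append(df[cov].to_numpy(dtype=float))
            names.append(cov)
        else:
            add_categorical(cov)

    if spec.interaction:
        if densities is None:
            raise ValueError("interaction model requires per-network densities")
        dens = df["network_id"].map(densities).to_numpy(dtype=float)
        if not np.all(np.isfinite(dens)):
            raise ValueError("density missing for some rows; drop them first")
        if np.ptp(dens) < 1e-12:
            raise ValueError("network density is constant; interaction inestimable")
        cols.append(dens)
        names.append("network_density")
        for lv in ("Q2", "Q3", "Q4"):
            cols.append((df["quartile"] == lv).to_numpy(dtype=float) * dens)
            names.append(f"quartile[{lv}]:network_density")

    X = np.column_stack(cols)
    y = df["os_flag"].to_numpy(dtype=float)
    surgeon, _ = pd.factorize(df["surgeon_id"], sort=True)
    network_of_row, _ = pd.factorize(df["network_id"], sort=True)
    # surgeon -> network map; a surgeon must sit in exactly one network
    mapping = pd.DataFrame({"s": surgeon, "k": network_of_row}).drop_duplicates()
    if mapping["s"].duplicated().any():
        raise ValueError("a surgeon appears in more than one network")
    return X, names, y, surgeon, network_of_row


def _ordered_levels(series: pd.Series) -> list:
    vals = series.dropna().unique().tolist()
    try:
        return sorted(vals)
    except TypeError:
        return sorted(vals, key=str)


# ---------------------------------------------------------------------------
# Laplace machinery
# ---------------------------------------------------------------------------


class _LaplaceWorkspace:
    """Precomputed index structure plus warm-started random-effect modes."""

    def __init__(self, X, y, surgeon, network_of_row):
        self.X = X
        self.y = y
        self.surgeon = surgeon
        self.n_s = int(surgeon.max()) + 1
        # network of each surgeon (consistent by construction)
        net_of_s = np.full(self.n_s, -1, dtype=int)
        net_of_s[surgeon] = network_of_row
        self.net_of_s = net_of_s
        self.n_k = int(network_of_row.max()) + 1
        self.network_of_row = network_of_row
        self.u = np.zeros(self.n_s)
        self.v = np.zeros(self.n_k)

    def penalized_loglik(self, eta_fix, u, v, s2s, s2n):
        eta = eta_fix + u[self.surgeon] + v[self.network_of_row]
        ll = np.sum(self.y * eta - np.logaddexp(0.0, eta))
        pen = 0.5 * np.sum(u**2) / s2s + 0.5 * np.sum(v**2) / s2n
        return ll - pen

    def find_mode(self, eta_fix, s2s, s2n, max_iter=100, tol=1e-10):
        """Newton iteration for the joint (u, v) mode; arrowhead solves."""
        u = self.u.copy()
        v = self.v.copy()
        surgeon, net_row, net_s = self.surgeon, self.network_of_row, self.net_of_s
        y = self.y
        f = self.penalized_loglik(eta_fix, u, v, s2s, s2n)
        for _ in range(max_iter):
            eta = eta_fix + u[surgeon] + v[net_row]
            p = expit(eta)
            r = y - p
            w = p * (1.0 - p)
            g_u = np.bincount(surgeon, weights=r, minlength=self.n_s) - u / s2s
            g_v = np.bincount(net_row, weights=r, minlength=self.n_k) - v / s2n
            b = np.bincount(surgeon, weights=w, minlength=self.n_s)
            A = b + 1.0 / s2s
            c = np.bincount(net_row, weights=w, minlength=self.n_k) + 1.0 / s2n
            # Schur complement of the surgeon block, per network
            schur = c - np.bincount(net_s, weights=b**2 / A, minlength=self.n_k)
            rhs_v = g_v - np.bincount(net_s, weights=b * g_u / A, minlength=self.n_k)
            dv = rhs_v / schur
            du = (g_u - b * dv[net_s]) / A
            gnorm = max(np.abs(g_u).max(initial=0.0), np.abs(g_v).max(initial=0.0))
            if gnorm < 1e-9:
                break
            step = 1.0
            for _ in range(30):
                f_new = self.penalized_loglik(
                    eta_fix, u + step * du, v + step * dv, s2s, s2n
                )
                if f_new >= f - 1e-12:
                    break
                step *= 0.5
            u = u + step * du
            v = v + step * dv
            if f_new - f < tol and gnorm < 1e-6:
                f = f_new
                break
            f = f_new
        self.u, self.v = u, v
        return u, v

    def marginal_loglik(self, beta, s2s, s2n):
        eta_fix = self.X @ beta
        u, v = self.find_mode(eta_fix, s2s, s2n)
        eta = eta_fix + u[self.surgeon] + v[self.network_of_row]
        p = expit(eta)
        w = p * (1.0 - p)
        b = np.bincount(self.surgeon, weights=w, minlength=self.n_s)
        A = b + 1.0 / s2s
        c = np.bincount(self.network_of_row, weights=w, minlength=self.n_k) + 1.0 / s2n
        schur = c - np.bincount(self.net_of_s, weights=b**2 / A, minlength=self.n_k)
        logdet = np.sum(np.log(A)) + np.sum(np.log(schur))
        ll_data = np.sum(self.y * eta - np.logaddexp(0.0, eta))
        pen = 0.5 * np.sum(u**2) / s2s + 0.5 * np.sum(v**2) / s2n
        prior_norm = 0.5 * self.n_s * np.log(s2s) + 0.5 * self.n_k * np.log(s2n)
        return ll_data - pen - prior_norm - 0.5 * logdet

    def agq_loglik(self, beta, s2s, s2n, n_points=7, inner_newton=3):
        """Nested adaptive Gauss-Hermite marginal log-likelihood.

        Outer rule integrates the network intercept v_k (centered at the
        joint Laplace mode, scaled by the arrowhead Schur complement);
        inner rule integrates each surgeon intercept conditional on the
        outer node (re-centered by a few vectorized Newton steps).
        """
        surg, net_row, net_s = self.surgeon, self.network_of_row, self.net_of_s
        y, n_s, n_k = self.y, self.n_s, self.n_k
        eta_fix = self.X @ beta
        u0, v0 = self.find_mode(eta_fix, s2s, s2n)
        eta = eta_fix + u0[surg] + v0[net_row]
        p = expit(eta)
        w = p * (1.0 - p)
        b = np.bincount(surg, weights=w, minlength=n_s)
        A = b + 1.0 / s2s
        c = np.bincount(net_row, weights=w, minlength=n_k) + 1.0 / s2n
        schur = c - np.bincount(net_s, weights=b**2 / A, minlength=n_k)
        t, om = hermegauss(n_points)  # weight function exp(-x^2/2)
        log_om = np.log(om)
        sd_v = 1.0 / np.sqrt(schur)
        log_nodes = np.empty((n_points, n_k))
        for qi in range(n_points):
            v = v0 + sd_v * t[qi]
            u = u0.copy()
            for _ in range(inner_newton):
                eta = eta_fix + u[surg] + v[net_row]
                pp = expit(eta)
                g = np.bincount(surg, weights=y - pp, minlength=n_s) - u / s2s
                lam = (
                    np.bincount(surg, weights=pp * (1 - pp), minlength=n_s)
                    + 1.0 / s2s
                )
                u = u + g / lam
            sd_u = 1.0 / np.sqrt(lam)
            inner = np.empty((n_points, n_s))
            for qj in range(n_points):
                uq = u + sd_u * t[qj]
                eta = eta_fix + uq[surg] + v[net_row]
                ll_i = y * eta - np.logaddexp(0.0, eta)
                h = (
                    np.bincount(surg, weights=ll_i, minlength=n_s)
                    - uq**2 / (2.0 * s2s)
                )
                inner[qj] = log_om[qj] + t[qj] ** 2 / 2.0 + h
            log_g = (
                np.log(sd_u)
                + logsumexp(inner, axis=0)
                - 0.5 * np.log(2.0 * np.pi * s2s)
            )
            hv = np.bincount(net_s, weights=log_g, minlength=n_k) - v**2 / (
                2.0 * s2n
            )
            log_nodes[qi] = log_om[qi] + t[qi] ** 2 / 2.0 + hv
        log_Lk = (
            np.log(sd_v)
            + logsumexp(log_nodes, axis=0)
            - 0.5 * np.log(2.0 * np.pi * s2n)
        )
        return float(np.sum(log_Lk))


_LOG_S2_MIN, _LOG_S2_MAX = np.log(1e-8), np.log(1e4)


def _fit_laplace(
    X: np.ndarray,
    names: list[str],
    y: np.ndarray,
    surgeon: np.ndarray,
    network_of_row: np.ndarray,
    start_s2: tuple[float, float] = (0.2, 0.2),
    method: str = "agq",
    agq_points: int = 7,
) -> FitResult:
    if method not in ("laplace", "agq"):
        raise ValueError(f"unknown method {method!r}")
    n, p = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; model is degenerate")
    ws = _LaplaceWorkspace(X, y, surgeon, network_of_row)
    if ws.n_k < 2:
        raise ValueError("fewer than 2 networks; network variance inestimable")

    # plain logistic start for beta
    beta0 = np.zeros(p)
    for _ in range(25):
        mu = expit(X @ beta0)
        W = mu * (1 - mu) + 1e-9
        z = X.T @ (y - mu)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, z)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, z, rcond=None)[0]
        beta0 = beta0 + step
        if np.abs(step).max() < 1e-10:
            break

    def negll_laplace(theta):
        beta = theta[:p]
        s2s = np.exp(min(theta[p], _LOG_S2_MAX))
        s2n = np.exp(min(theta[p + 1], _LOG_S2_MAX))
        return -ws.marginal_loglik(beta, s2s, s2n)

    def negll_agq(theta):
        beta = theta[:p]
        s2s = np.exp(min(theta[p], _LOG_S2_MAX))
        s2n = np.exp(min(theta[p + 1], _LOG_S2_MAX))
        return -ws.agq_loglik(beta, s2s, s2n, n_points=agq_points)

    x0 = np.concatenate([beta0, np.log(np.asarray(start_s2))])
    bounds = [(None, None)] * p + [(_LOG_S2_MIN, _LOG_S2_MAX)] * 2
    # Laplace pass first: cheap, and the AGQ refinement then starts at
    # (nearly) the right optimum.
    res = optimize.minimize(
        negll_laplace,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
    )
    negll = negll_laplace
    if method == "agq":
        negll = negll_agq
        res = optimize.minimize(
            negll_agq,
            res.x,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-11, "gtol": 1e-6},
        )
    theta = res.x
    beta = theta[:p]
    s2s, s2n = float(np.exp(theta[p])), float(np.exp(theta[p + 1]))
    converged = bool(res.success)

    # observed-information SEs on (beta, log s2s, log s2n) by central differences
    vcov, se = _numeric_vcov(negll, theta)
    se_beta = se[:p]

    z = beta / se_beta
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    params = pd.DataFrame(
        {
            "term": names,
            "estimate": beta,
            "se": se_beta,
            "odds_ratio": np.exp(beta),
            "ci_low": np.exp(beta - 1.96 * se_beta),
            "ci_high": np.exp(beta + 1.96 * se_beta),
            "p_value": pvals,
        }
    )
    return FitResult(
        params=params,
        sigma2_surgeon=s2s,
        sigma2_network=s2n,
        log_likelihood=-float(res.fun),
        converged=converged,
        n_patients=n,
        n_surgeons=ws.n_s,
        n_networks=ws.n_k,
        boundary_surgeon=bool(theta[p] <= _LOG_S2_MIN + 1e-6),
        boundary_network=bool(theta[p + 1] <= _LOG_S2_MIN + 1e-6),
        vcov=vcov,
        diagnostics="" if converged else str(res.message),
    )


def _numeric_vcov(negll, theta, h=1e-4):
    """Central-difference Hessian of the negative log-likelihood, inverted."""
    k = len(theta)
    H = np.zeros((k, k))
    f0 = negll(theta)
    steps = np.maximum(h, h * np.abs(theta))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        H[i, i] = (negll(theta + ei) - 2 * f0 + negll(theta - ei)) / steps[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = steps[j]
            fpp = negll(theta + ei + ej)
            fpm = negll(theta + ei - ej)
            fmp = negll(theta - ei + ej)
            fmm = negll(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    try:
        vcov = np.linalg.inv(H)
        diag = np.diag(vcov).copy()
        bad = diag <= 0
        diag[bad] = np.nan
        return vcov, np.sqrt(diag)
    except np.linalg.LinAlgError:
        return None, np.full(k, np.nan)


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------


def fit_nested_logistic(
    dataset: pd.DataFrame,
    spec: ModelSpec | None = None,
    densities: pd.Series | None = None,
    method: str = "agq",
    agq_points: int = 7,
) -> FitResult:
    """Fit the nested random-intercept logistic model on an analysis table.

    ``dataset`` needs columns ``os_flag``, ``quartile``, ``surgeon_id``,
    ``network_id`` plus any covariates named in ``spec.fixed_effects``.
    """
    spec = spec or ModelSpec()
    X, names, y, surgeon, network_of_row = build_design(dataset, spec, densities)
    return _fit_laplace(
        X, names, y, surgeon, network_of_row, method=method, agq_points=agq_points
    )


def fit_null_model(
    dataset: pd.DataFrame, method: str = "agq", agq_points: int = 7
) -> FitResult:
    """Intercept + nested random effects only (for variance decomposition)."""
    df = dataset.reset_index(drop=True)
    X = np.ones((len(df), 1))
    y = df["os_flag"].to_numpy(dtype=float)
    surgeon, _ = pd.factorize(df["surgeon_id"], sort=True)
    network_of_row, _ = pd.factorize(df["network_id"], sort=True)
    mapping = pd.DataFrame({"s": surgeon, "k": network_of_row}).drop_duplicates()
    if mapping["s"].duplicated().any():
        raise ValueError("a surgeon appears in more than one network")
    if len(np.unique(network_of_row)) < 2:
        raise ValueError("single network in data; network variance inestimable")
    return _fit_laplace(
        X,
        ["intercept"],
        y,
        surgeon,
        network_of_row,
        method=method,
        agq_points=agq_points,
    )


def decompose(s2s: float, s2n: float) -> tuple[float, float, float]:
    """Latent-scale variance shares (patient, surgeon, network)."""
    total = s2s + s2n + LOGISTIC_RESIDUAL_VARIANCE
    return (
        LOGISTIC_RESIDUAL_VARIANCE / total,
        s2s / total,
        s2n / total,
    )


def variance_decomposition(
    null_fit: FitResult,
    dataset: pd.DataFrame | None = None,
    n_boot: int = 200,
    seed: int = 0,
    boot_method: str = "laplace",
) -> VarianceDecomposition:
    """Partition latent-scale outcome variance across the three levels.

    The point decomposition is the closed form from the fitted variance
    components.  If ``dataset`` is given, percentile confidence intervals
    are computed by parametric bootstrap: simulate outcomes from the fitted
    null model on the observed grouping structure, refit, and decompose.
    Bootstrap refits default to the fast Laplace path; the interval width
    is insensitive to the small Laplace-vs-quadrature offset.
    """
    if not null_fit.converged:
        raise ValueError("null model did not converge; decomposition blocked")
    p_pat, p_sur, p_net = decompose(null_fit.sigma2_surgeon, null_fit.sigma2_network)
    ci_p = ci_s = ci_n = None
    if dataset is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        df = dataset.reset_index(drop=True)
        surgeon, _ = pd.factorize(df["surgeon_id"], sort=True)
        network_of_row, _ = pd.factorize(df["network_id"], sort=True)
        n_s = surgeon.max() + 1
        n_k = network_of_row.max() + 1
        net_of_s = np.full(n_s, -1, dtype=int)
        net_of_s[surgeon] = network_of_row
        beta0 = null_fit.coef("intercept")
        draws = []
        failures = 0
        for _ in range(n_boot):
            u = rng.normal(0, np.sqrt(null_fit.sigma2_surgeon), n_s)
            v = rng.normal(0, np.sqrt(null_fit.sigma2_network), n_k)
            eta = beta0 + u[surgeon] + v[network_of_row]
            yb = rng.random(len(df)) < 1.0 / (1.0 + np.exp(-eta))
            if yb.all() or not yb.any():
                failures += 1
                continue
            try:
                fb = _fit_laplace(
                    np.ones((len(df), 1)),
                    ["intercept"],
                    yb.astype(float),
                    surgeon,
                    network_of_row,
                    start_s2=(
                        max(null_fit.sigma2_surgeon, 1e-3),
                        max(null_fit.sigma2_network, 1e-3),
                    ),
                    method=boot_method,
                )
            except (ValueError, np.linalg.LinAlgError):
                failures += 1
                continue
            draws.append(decompose(fb.sigma2_surgeon, fb.sigma2_network))
        if failures:
            warnings.warn(f"{failures} bootstrap replicates failed; intervals use the rest")
        if len(draws) >= 10:
            arr = np.array(draws)
            lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
            ci_p, ci_s, ci_n = (
                (float(lo[0]), float(hi[0])),
                (float(lo[1]), float(hi[1])),
                (float(lo[2]), float(hi[2])),
            )
    return VarianceDecomposition(
        proportion_patient=p_pat,
        proportion_surgeon=p_sur,
        proportion_network=p_net,
        ci_patient=ci_p,
        ci_surgeon=ci_s,
        ci_network=ci_n,
    )


def density_interaction_fit(
    dataset: pd.DataFrame,
    spec: ModelSpec | None = None,
    densities: pd.Series | None = None,
    method: str = "agq",
) -> tuple[FitResult, float, float]:
    """Main model plus network-density main effect and quartile x density.

    Returns the fit together with the joint Wald chi-square statistic and
    P value over the three interaction coefficients.
    """
    if densities is None:
        raise ValueError("per-network densities are required")
    spec = spec or ModelSpec()
    spec = ModelSpec(
        fixed_effects=list(spec.fixed_effects),
        include_quartile=True,
        interaction=True,
    )
    df = dataset.reset_index(drop=True)
    have = df["network_id"].map(densities).notna()
    dropped = int((~have).sum())
    if dropped:
        warnings.warn(f"{dropped} rows dropped: no density for their network")
        df = df.loc[have].reset_index(drop=True)
    fit = fit_nested_logistic(df, spec, densities, method=method)
    idx = [
        i
        for i, t in enumerate(fit.params["term"])
        if t.endswith(":network_density")
    ]
    if len(idx) != 3 or fit.vcov is None:
        raise ValueError("interaction terms missing or covariance unavailable")
    b = fit.params["estimate"].to_numpy()[idx]
    V = fit.vcov[np.ix_(idx, idx)]
    if not np.all(np.isfinite(V)) or np.linalg.cond(V) > 1e10:
        raise ValueError(
            "interaction covariance ill-conditioned; density variation too small"
        )
    eigs = np.linalg.eigvalsh(V)
    if eigs.min() <= 0:
        raise ValueError("interaction covariance not positive definite")
    stat = float(b @ np.linalg.solve(V, b))
    if stat > 1e4:
        raise ValueError(
            "interaction Wald statistic numerically degenerate "
            "(too few networks / too little density variation)"
        )
    p = float(stats.chi2.sf(stat, df=3))
    return fit, stat, p
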