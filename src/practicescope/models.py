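"""Inferential layer: correlations, Bayesian mixed model, latent change model.

Three analyses connect anxiety, practice behavior and performance quality:

* **Correlation matrices** between anxiety measures (self-report and
  cardiac) and practice descriptors, with two-tailed p-values from the
  t-distribution on n-2 df.

* **Bayesian mixed-effects learning model.**  Quality scores at baseline
  (time = 0) and acquisition (time = minutes practiced) are regressed on
  time, a standardized anxiety measure and their interaction, with
  correlated random intercepts and time slopes per performer.  Random
  effects are integrated out analytically, and the marginal posterior of
  the eight remaining parameters is sampled with an affine-invariant
  ensemble sampler.  An effect is 'meaningful' when its central 95%
  credible interval excludes zero.

* **Latent change score (LCS) model.**  Six observed variables — quality
  scores and pre/post-performance anxiety at two occasions — are expressed
  through baseline components and unit-loading change factors
  (x2 = x1 + Dx).  Free means and the free covariance matrix of the six
  components are estimated by maximum likelihood, minimizing
  F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p; chi2 = (n-1) F_ML, with
  CFI/TLI/RFI against the independence baseline and SRMR on standardized
  residuals.  Change-score correlations get delta-method standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

import emcee

# ---------------------------------------------------------------------------
# correlations and simple group comparison


@dataclass(frozen=True)
class CorrelationReport:
    pairs: pd.DataFrame  # columns: var_x, var_y, r, df, p, significant

    def matrix(self) -> pd.DataFrame:
        return self.pairs.pivot(index="var_x", columns="var_y", values="r")


def correlation_matrix(
    table: pd.DataFrame, x_vars: Sequence[str], y_vars: Sequence[str]
) -> CorrelationReport:
    """Pearson correlations for every (x, y) pair with complete-case n.

    p-values are two-tailed from the t distribution with n-2 df; pairs with
    a zero-variance member are flagged undefined (NaN r and p).
    """
    rows = []
    for x in x_vars:
        for y in y_vars:
            sub = table[[x, y]].dropna()
            n = len(sub)
            if n < 4:
                raise ValueError(f"need >= 4 complete rows for ({x}, {y})")
            xv, yv = sub[x].to_numpy(float), sub[y].to_numpy(float)
            if np.std(xv) == 0 or np.std(yv) == 0:
                rows.append(dict(var_x=x, var_y=y, r=np.nan, df=n - 2, p=np.nan,
                                 significant=False))
                continue
            r, p = stats.pearsonr(xv, yv)
            rows.append(dict(var_x=x, var_y=y, r=float(r), df=n - 2, p=float(p),
                             significant=bool(p < 0.05)))
    return CorrelationReport(pd.DataFrame(rows))


@dataclass(frozen=True)
class GroupDifference:
    statistic: float
    df: float
    p: float
    group_means: dict


def group_difference(values: Sequence[float], group_labels: Sequence) -> GroupDifference:
    """Welch two-sample t-test for a two-group comparison."""
    values = np.asarray(values, float)
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(groups)}")
    a, b = (values[labels == g] for g in groups)
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupDifference(
        statistic=float(res.statistic), df=float(res.df), p=float(res.pvalue),
        group_means={str(g): float(v.mean()) for g, v in zip(groups, (a, b))},
    )


# ---------------------------------------------------------------------------
# Bayesian mixed-effects learning model

FIXED_EFFECTS = ("intercept", "time", "anxiety", "time:anxiety")
VARIANCE_PARAMS = ("sd_intercept", "sd_time", "cor_intercept_time", "sd_residual")


@dataclass(frozen=True)
class MixedModelSpec:
    n_walkers: int = 24
    n_steps: int = 1500
    n_burn: int = 500
    prior_beta_scale: float = 2.5  # times SD(y)
    prior_sd_scale: float = 1.0  # times SD(y), half-normal
    rhat_threshold: float = 1.05
    ess_threshold: float = 400.0


@dataclass
class MixedModelFit:
    summary: pd.DataFrame  # parameter, estimate, ci_low, ci_high
    r2_conditional: tuple[float, float, float]  # estimate, ci_low, ci_high
    r2_marginal: tuple[float, float, float]
    meaningful: dict  # fixed effect -> CI excludes 0
    diagnostics: dict  # max_rhat, min_ess
    converged: bool
    draws: np.ndarray | None = None  # (n_draws, 8) on the natural scale

    def estimate(self, parameter: str) -> float:
        row = self.summary.set_index("parameter").loc[parameter]
        return float(row["estimate"])

    def ci(self, parameter: str) -> tuple[float, float]:
        row = self.summary.set_index("parameter").loc[parameter]
        return float(row["ci_low"]), float(row["ci_high"])


def _two_row_blocks(long_table: pd.DataFrame, anxiety_var: str):
    """Arrange the long table as per-performer (t, y, a) pairs."""
    g = long_table.sort_values(["id", "time"])
    counts = g.groupby("id").size()
    if not (counts == 2).all():
        raise ValueError("expected exactly two rows (baseline, acquisition) per performer")
    t = g["time"].to_numpy(float).reshape(-1, 2)
    y = g["score"].to_numpy(float).reshape(-1, 2)
    a = g[anxiety_var].to_numpy(float).reshape(-1, 2)[:, 0]
    a = (a - a.mean()) / a.std(ddof=1)  # standardized across participants
    return t, y, a


def _log_posterior(theta: np.ndarray, t: np.ndarray, y: np.ndarray, a: np.ndarray,
                   sy: float, spec: MixedModelSpec) -> np.ndarray:
    """Marginal log-posterior, vectorized over an ensemble of walkers.

    ``theta`` has shape (W, 8): four fixed effects, log random-intercept SD,
    log random-slope SD, atanh random-effect correlation, log residual SD.
    Random effects are integrated out analytically (2x2 marginal covariance
    per performer).
    """
    theta = np.atleast_2d(theta)
    beta = theta[:, :4]
    tau0, tau1 = np.exp(theta[:, 4]), np.exp(theta[:, 5])
    sigma = np.exp(theta[:, 7])
    rho = np.tanh(theta[:, 6])

    # walker-parameter columns (W, 1) against performer rows (1, N)
    b0, b1, b2, b3 = (beta[:, i][:, None] for i in range(4))
    c = (rho * tau0 * tau1)[:, None]
    t0sq, t1sq, ssq = (tau0**2)[:, None], (tau1**2)[:, None], (sigma**2)[:, None]
    t1_, t2_ = t[None, :, 0], t[None, :, 1]
    a_ = a[None, :]
    r1 = y[None, :, 0] - (b0 + b1 * t1_ + b2 * a_ + b3 * t1_ * a_)
    r2 = y[None, :, 1] - (b0 + b1 * t2_ + b2 * a_ + b3 * t2_ * a_)
    v11 = t0sq + 2 * c * t1_ + t1sq * t1_**2 + ssq
    v22 = t0sq + 2 * c * t2_ + t1sq * t2_**2 + ssq
    v12 = t0sq + c * (t1_ + t2_) + t1sq * t1_ * t2_
    det = v11 * v22 - v12**2
    bad = np.any(det <= 0, axis=1) | (np.maximum(np.maximum(tau0, tau1), sigma) > 1e3 * sy)
    det = np.where(det <= 0, 1.0, det)
    quad = (v22 * r1**2 - 2 * v12 * r1 * r2 + v11 * r2**2) / det
    loglik = -0.5 * np.sum(np.log(det) + quad, axis=1) - t.size / 2 * np.log(2 * np.pi)

    bscale = spec.prior_beta_scale * sy
    sscale = spec.prior_sd_scale * sy
    logprior = (
        -0.5 * np.sum((beta / bscale) ** 2, axis=1)
        - 0.5 * ((tau0 / sscale) ** 2 + (tau1 / sscale) ** 2 + (sigma / sscale) ** 2)
        # log-Jacobians: exp for the SDs, tanh for the correlation
        + theta[:, 4] + theta[:, 5] + theta[:, 7]
        + np.log1p(-rho**2 + 1e-300)
    )
    out = loglik + logprior
    out[bad] = -np.inf
    return out


def fit_mixed_model(
    long_table: pd.DataFrame,
    anxiety_var: str,
    spec: MixedModelSpec | None = None,
    seed: int = 0,
) -> MixedModelFit:
    """Sample the posterior of the learning model for one anxiety measure.

    ``long_table`` needs columns ``id, time, score`` and the anxiety
    variable (constant within performer); baseline rows have time = 0.
    Returns posterior means with central 95% credible intervals, variance
    components, conditional/marginal R-squared and sampler diagnostics.
    """
    spec = spec or MixedModelSpec()
    t, y, a = _two_row_blocks(long_table, anxiety_var)
    sy = float(y.std(ddof=1))
    if sy == 0:
        # degenerate input: constant criterion determines the fit exactly
        names = list(FIXED_EFFECTS) + list(VARIANCE_PARAMS)
        est = np.zeros(len(names))
        est[0] = float(y.mean())
        summary = pd.DataFrame(dict(parameter=names, estimate=est,
                                    ci_low=est, ci_high=est))
        return MixedModelFit(
            summary=summary, r2_conditional=(0.0, 0.0, 0.0),
            r2_marginal=(0.0, 0.0, 0.0),
            meaningful={n: n == "intercept" and est[0] != 0 for n in FIXED_EFFECTS},
            diagnostics=dict(max_rhat=1.0, min_ess=np.inf), converged=True,
            draws=None,
        )

    rng = np.random.RandomState(seed)
    ndim = 8
    X = np.column_stack([np.ones(t.size), t.ravel(),
                         np.repeat(a, 2), (t * a[:, None]).ravel()])
    beta0, *_ = np.linalg.lstsq(X, y.ravel(), rcond=None)
    start = np.concatenate([beta0, np.log([0.5 * sy, 0.05 * sy]), [0.0], [np.log(0.7 * sy)]])
    p0 = start + 0.05 * rng.normal(size=(spec.n_walkers, ndim))

    sampler = emcee.EnsembleSampler(
        spec.n_walkers, ndim, _log_posterior, args=(t, y, a, sy, spec),
        vectorize=True,
    )
    sampler.random_state = np.random.RandomState(seed + 1).get_state()
    sampler.run_mcmc(p0, spec.n_steps, progress=False)
    chain = sampler.get_chain(discard=spec.n_burn)  # (steps, walkers, ndim)

    nat = chain.copy()
    nat[..., 4] = np.exp(chain[..., 4])
    nat[..., 5] = np.exp(chain[..., 5])
    nat[..., 6] = np.tanh(chain[..., 6])
    nat[..., 7] = np.exp(chain[..., 7])
    draws = nat.reshape(-1, ndim)

    names = list(FIXED_EFFECTS) + list(VARIANCE_PARAMS)
    est = draws.mean(axis=0)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    summary = pd.DataFrame(dict(parameter=names, estimate=est, ci_low=lo, ci_high=hi))

    # variance-decomposition R2 per draw
    tt = t.ravel()
    Xd = np.column_stack([np.ones(tt.size), tt, np.repeat(a, 2), tt * np.repeat(a, 2)])
    var_f = np.var(Xd @ draws[:, :4].T, axis=0, ddof=0)
    tau0, tau1, rho, sig = draws[:, 4], draws[:, 5], draws[:, 6], draws[:, 7]
    var_r = (tau0**2 + 2 * rho * tau0 * tau1 * tt.mean() + tau1**2 * np.mean(tt**2))
    r2c = (var_f + var_r) / (var_f + var_r + sig**2)
    r2m = var_f / (var_f + var_r + sig**2)

    def _summ(x: np.ndarray) -> tuple[float, float, float]:
        return float(x.mean()), *map(float, np.percentile(x, [2.5, 97.5]))

    # split-chain convergence diagnostics over walkers
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.convert_to_dataset(np.moveaxis(chain, 1, 0))
        rhat = az.rhat(idata).to_array().to_numpy()
        ess = az.ess(idata).to_array().to_numpy()
    max_rhat = float(np.nanmax(rhat))
    min_ess = float(np.nanmin(ess))

    meaningful = {
        n: bool(lo[i] > 0 or hi[i] < 0) for i, n in enumerate(FIXED_EFFECTS)
    }
    return MixedModelFit(
        summary=summary,
        r2_conditional=_summ(r2c),
        r2_marginal=_summ(r2m),
        meaningful=meaningful,
        diagnostics=dict(max_rhat=max_rhat, min_ess=min_ess),
        converged=bool(max_rhat < spec.rhat_threshold and min_ess > spec.ess_threshold),
        draws=draws,
    )


# ---------------------------------------------------------------------------
# latent change score model

COMPONENTS = ("perf1", "vasa1", "vasa2", "dperf", "dvasa_pre", "dvasa_post")
OBSERVED = ("perf1", "perf2", "vasa1", "vasa3", "vasa2", "vasa4")

# observed = _T @ components: perf2 = perf1 + dperf, vasa3 = vasa1 + dvasa_pre,
# vasa4 = vasa2 + dvasa_post (unit loadings, unit autoregression)
_T = np.array(
    [
        [1, 0, 0, 0, 0, 0],  # perf1
        [1, 0, 0, 1, 0, 0],  # perf2
        [0, 1, 0, 0, 0, 0],  # vasa1
        [0, 1, 0, 0, 1, 0],  # vasa3
        [0, 0, 1, 0, 0, 0],  # vasa2
        [0, 0, 1, 0, 0, 1],  # vasa4
    ],
    dtype=float,
)
_T_INV = np.linalg.inv(_T)


@dataclass(frozen=True)
class LcsSpec:
    """Which component covariances are constrained to zero.

    The default single constraint cov(perf1, dvasa_pre) = 0 leaves one
    over-identifying degree of freedom.
    """

    zero_constraints: tuple[tuple[str, str], ...] = (("perf1", "dvasa_pre"),)
    observed_columns: tuple[str, ...] = OBSERVED

    def free_index_pairs(self) -> list[tuple[int, int]]:
        fixed = set()
        for a, b in self.zero_constraints:
            i, j = COMPONENTS.index(a), COMPONENTS.index(b)
            if i == j:
                raise ValueError("cannot constrain a variance to zero")
            fixed.add((min(i, j), max(i, j)))
        return [
            (i, j)
            for i in range(6)
            for j in range(i, 6)
            if (i, j) not in fixed
        ]


@dataclass
class LcsFit:
    theta: np.ndarray  # component covariance matrix (6x6)
    means: np.ndarray  # component means
    chi2: float
    df: int
    p: float
    cfi: float
    tli: float
    rfi: float
    srmr: float
    correlations: pd.DataFrame  # pair, r, se, z, p
    n: int
    converged: bool = True

    def correlation(self, a: str, b: str) -> float:
        i, j = COMPONENTS.index(a), COMPONENTS.index(b)
        return float(self.theta[i, j] / np.sqrt(self.theta[i, i] * self.theta[j, j]))


def _fml(theta_mat: np.ndarray, S: np.ndarray, logdet_s: float) -> float:
    sigma = _T @ theta_mat @ _T.T
    min_eig = float(np.linalg.eigvalsh(sigma)[0])
    if min_eig <= 1e-10:
        # smooth penalty steers the optimizer back into the PD cone
        return 1e6 * (1.0 - min(min_eig, 0.0))
    L = np.linalg.cholesky(sigma)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    inv = np.linalg.inv(sigma)
    return logdet + float(np.trace(S @ inv)) - logdet_s - S.shape[0]


def _fml_and_grad(
    x: np.ndarray, pairs: list[tuple[int, int]], S: np.ndarray, logdet_s: float
) -> tuple[float, np.ndarray]:
    """F_ML and its analytic gradient w.r.t. the free covariance entries.

    dF/dTheta_ij = [T' (Sigma^-1 - Sigma^-1 S Sigma^-1) T]_ij, doubled for
    off-diagonal entries (symmetric parameterization).
    """
    theta_mat = _unpack(x, pairs)
    sigma = _T @ theta_mat @ _T.T
    min_eig = float(np.linalg.eigvalsh(sigma)[0])
    if min_eig <= 1e-10:
        # penalty region: push the smallest eigenvalue back up
        vals, vecs = np.linalg.eigh(sigma)
        v = vecs[:, 0]
        g_sigma = -1e6 * np.outer(v, v) if vals[0] < 0 else np.zeros((6, 6))
        G = _T.T @ g_sigma @ _T
        grad = np.array([G[i, j] * (1.0 if i == j else 2.0) for i, j in pairs])
        return 1e6 * (1.0 - min(min_eig, 0.0)), grad
    inv = np.linalg.inv(sigma)
    sign, logdet = np.linalg.slogdet(sigma)
    f = logdet + float(np.trace(S @ inv)) - logdet_s - S.shape[0]
    G = _T.T @ (inv - inv @ S @ inv) @ _T
    grad = np.array([G[i, j] * (1.0 if i == j else 2.0) for i, j in pairs])
    return f, grad


def _pack(theta_mat: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
    return np.array([theta_mat[i, j] for i, j in pairs])


def _unpack(x: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
    m = np.zeros((6, 6))
    for v, (i, j) in zip(x, pairs):
        m[i, j] = m[j, i] = v
    return m


def fit_lcs(
    wide_table: pd.DataFrame,
    spec: LcsSpec | None = None,
    correlation_pairs: Sequence[tuple[str, str]] = (
        ("dvasa_pre", "dvasa_post"),
        ("dperf", "dvasa_post"),
        ("vasa1", "vasa2"),
        ("perf1", "vasa2"),
        ("perf1", "dvasa_post"),
    ),
) -> LcsFit:
    """Fit the latent change score model by maximum likelihood.

    ``wide_table`` must contain the six observed columns of the spec
    (default ``perf1, perf2, vasa1, vasa3, vasa2, vasa4``).  With an empty
    constraint set the model is just-identified and fits perfectly; each
    zero constraint adds one degree of freedom.
    """
    spec = spec or LcsSpec()
    cols = list(spec.observed_columns)
    data = wide_table[cols].dropna().to_numpy(float)
    n = len(data)
    if n < 20:
        raise ValueError("need at least 20 complete rows")
    S = np.cov(data, rowvar=False, ddof=1)
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance matrix is not positive definite")

    pairs = spec.free_index_pairs()
    theta0 = _T_INV @ S @ _T_INV.T
    for a, b in spec.zero_constraints:
        i, j = COMPONENTS.index(a), COMPONENTS.index(b)
        theta0[i, j] = theta0[j, i] = 0.0

    converged = True
    if len(pairs) == 21:  # saturated: exact solution, F_ML = 0
        theta_hat = _T_INV @ S @ _T_INV.T
        fmin = 0.0
    else:
        def objective(x: np.ndarray):
            return _fml_and_grad(x, pairs, S, logdet_s)

        x0 = _pack(theta0, pairs)
        res = optimize.minimize(objective, x0, jac=True, method="BFGS",
                                options=dict(maxiter=2000, gtol=1e-9))
        grad_norm = float(np.linalg.norm(res.jac))
        if not (res.success or grad_norm < 1e-6) and res.fun > 1e-8:
            for start in (res.x, x0):
                res2 = optimize.minimize(
                    lambda x: objective(x)[0], start, method="Nelder-Mead",
                    options=dict(maxiter=10000, fatol=1e-12, xatol=1e-10))
                if res2.fun < res.fun:
                    res = res2
        converged = bool(np.isfinite(res.fun))
        theta_hat = _unpack(res.x, pairs)
        fmin = max(float(res.fun), 0.0)

    chi2 = (n - 1) * fmin
    df = 21 - len(pairs)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    sigma_hat = _T @ theta_hat @ _T.T
    chi2_0 = (n - 1) * (float(np.sum(np.log(np.diag(S)))) - logdet_s)
    df_0 = 15
    cfi, tli, rfi, srmr = fit_indices(chi2, df, chi2_0, df_0, S, sigma_hat)

    means = _T_INV @ data.mean(axis=0)

    # delta-method SEs for derived correlations
    acov = None
    if df > 0:
        x_hat = _pack(theta_hat, pairs)
        H = _numeric_hessian(lambda x: _fml(_unpack(x, pairs), S, logdet_s), x_hat)
        try:
            acov = 2.0 / (n - 1) * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            acov = None
    else:
        # saturated: asymptotic covariance of covariance-matrix elements
        x_hat = _pack(theta_hat, pairs)
        H = _numeric_hessian(lambda x: _fml(_unpack(x, pairs), S, logdet_s), x_hat)
        acov = 2.0 / (n - 1) * np.linalg.pinv(H)

    rows = []
    pair_index = {pq: k for k, pq in enumerate(pairs)}
    for a, b in correlation_pairs:
        i, j = COMPONENTS.index(a), COMPONENTS.index(b)
        key = (min(i, j), max(i, j))
        cij, vi, vj = theta_hat[i, j], theta_hat[i, i], theta_hat[j, j]
        r = cij / np.sqrt(vi * vj)
        se = z = pv = np.nan
        if acov is not None and key in pair_index:
            grad = np.zeros(len(pairs))
            grad[pair_index[key]] = 1.0 / np.sqrt(vi * vj)
            grad[pair_index[(i, i)]] = -cij / (2 * vi**1.5 * np.sqrt(vj))
            grad[pair_index[(j, j)]] = -cij / (2 * vj**1.5 * np.sqrt(vi))
            var_r = float(grad @ acov @ grad)
            if var_r > 0:
                se = float(np.sqrt(var_r))
                z = float(r / se)
                pv = float(2 * stats.norm.sf(abs(z)))
        rows.append(dict(component_a=a, component_b=b, r=float(r), se=se, z=z, p=pv))

    return LcsFit(
        theta=theta_hat, means=means, chi2=float(chi2), df=df, p=p,
        cfi=cfi, tli=tli, rfi=rfi, srmr=srmr,
        correlations=pd.DataFrame(rows), n=n, converged=converged,
    )


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
    return H


def fit_indices(
    chi2_m: float, df_m: int, chi2_0: float, df_0: int,
    S: np.ndarray, Sigma: np.ndarray,
) -> tuple[float, float, float, float]:
    """Incremental fit indices and SRMR.

    CFI caps the numerator at zero so a model with chi2 <= df scores 1;
    TLI and RFI are undefined (NaN) for a just-identified model (df = 0);
    TLI is capped at 1.  SRMR is the RMS of correlation-metric residuals
    over the p(p+1)/2 unique moments.
    """
    if df_0 <= df_m:
        raise ValueError("baseline model must have more df than the target model")
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_0 - df_0, chi2_m - df_m, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    if df_m > 0:
        ratio0 = chi2_0 / df_0
        tli = min((ratio0 - chi2_m / df_m) / (ratio0 - 1.0), 1.0)
        rfi = 1.0 - (chi2_m / df_m) / ratio0
    else:
        tli = rfi = np.nan
    d = np.sqrt(np.diag(S))
    resid = (S - Sigma) / np.outer(d, d)
    iu = np.triu_indices_from(resid)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    return float(cfi), float(tli), float(rfi), srmr
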