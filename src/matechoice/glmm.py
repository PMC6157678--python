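"""Logistic mixed model with crossed random intercepts.

Fits logit(P(y=1)) = X beta + Z u, u ~ N(0, diag(sigma_k^2)) with one
variance component per grouping factor (e.g. year, mating site, male
identity), by maximum likelihood under the Laplace approximation:

* inner loop -- Newton iteration on the penalized Bernoulli
  log-likelihood over the random effects u for fixed (beta, sigma);
* outer loop -- quasi-Newton (L-BFGS-B) jointly over the fixed effects
  and the log standard deviations of the Laplace log-likelihood

    l(beta, theta) = sum_i [y_i eta_i - log(1 + e^{eta_i})]
                     - u' Sigma^{-1} u / 2
                     - log det(I + Sigma Z' W Z) / 2

  evaluated at the conditional mode u(beta, theta), with
  W = diag(p(1-p)).

This matches the default Laplace scheme of the standard mixed-model
packages (objective and estimates agree with lme4::glmer to numerical
precision). Fixed-effect standard errors come from the beta block of
the inverse finite-difference Hessian of the Laplace objective over
(beta, log sd) jointly, so they carry the uncertainty in the variance
parameters; when a variance sits on the boundary (or the Hessian is not
invertible) the conditional Schur complement
X'WX - X'WZ (Z'WZ + Sigma^{-1})^{-1} Z'WX is used instead. Inference is
Wald: z = estimate/SE with two-sided normal p-values.

The fit is deterministic: beta and u start at zero and every free
random-effect SD starts at 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from matechoice.errors import InsufficientDataError

_LOG_SD_BOUNDS = (-6.0, 3.0)
_START_SD = 0.5


@dataclass
class GlmmFit:
    """Result of a logistic mixed-model fit.

    ``fixed_effects`` has columns term/estimate/std_error/z_value/
    p_value; ``random_variances`` maps factor name to the estimated
    intercept variance.
    """

    fixed_effects: pd.DataFrame
    random_variances: dict[str, float]
    loglik: float
    converged: bool
    n_rows: int
    n_groups: dict[str, int]
    messages: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.fixed_effects.set_index("term").loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.fixed_effects.set_index("term").loc[term, "p_value"])


def _loglik_bernoulli(y: np.ndarray, eta: np.ndarray) -> float:
    # y*eta - log(1+e^eta), stable via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _solve_u(
    y: np.ndarray,
    Z: np.ndarray,
    offset: np.ndarray,
    pen_u: np.ndarray,
    u0: np.ndarray,
    max_iter: int = 80,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton (with step halving) for the conditional mode of u.

    Maximizes sum[y eta - log(1+e^eta)] - u' diag(pen_u) u / 2 with
    eta = offset + Z u. Returns (u, W at the mode, converged).
    """

    def pll(u):
        eta = offset + Z @ u
        return _loglik_bernoulli(y, eta) - 0.5 * float(u @ (pen_u * u))

    u = u0.copy()
    f = pll(u)
    ok = False
    for _ in range(max_iter):
        eta = offset + Z @ u
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        grad = Z.T @ (y - mu) - pen_u * u
        if np.max(np.abs(grad)) < tol:
            ok = True
            break
        H = (Z.T * w) @ Z
        H[np.diag_indices_from(H)] += pen_u
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            cand = u + t * step
            fc = pll(cand)
            if fc >= f - 1e-13:
                break
            t *= 0.5
        else:
            break
        if abs(fc - f) < tol * (abs(f) + 1.0):
            u, f = cand, fc
            ok = True
            break
        u, f = cand, fc
    eta = offset + Z @ u
    mu = special.expit(eta)
    w = mu * (1.0 - mu)
    return u, w, ok


def _hessian_se(
    negll, x_opt: np.ndarray, p: int, interior_sds: list[int], h: float = 1e-3
) -> np.ndarray | None:
    """Central-difference Hessian of the Laplace objective over beta and
    the interior variance parameters; returns the beta-block SEs, or
    None when the Hessian is unusable."""
    idx = list(range(p)) + [p + i for i in interior_sds]
    d = len(idx)
    H = np.zeros((d, d))
    try:
        for a in range(d):
            for b in range(a, d):
                ea = np.zeros_like(x_opt)
                eb = np.zeros_like(x_opt)
                ea[idx[a]] = h
                eb[idx[b]] = h
                v = (
                    negll(x_opt + ea + eb)
                    - negll(x_opt + ea - eb)
                    - negll(x_opt - ea + eb)
                    + negll(x_opt - ea - eb)
                ) / (4 * h * h)
                H[a, b] = H[b, a] = v
        cov = np.linalg.inv(H)
    except (np.linalg.LinAlgError, FloatingPointError):
        return None
    diag = np.diag(cov)[:p]
    if np.any(~np.isfinite(diag)) or np.any(diag <= 0):
        return None
    return np.sqrt(diag)


def _build_z(
    groups: dict[str, np.ndarray], n: int
) -> tuple[np.ndarray, list[str], np.ndarray, dict[str, int]]:
    """Dense indicator matrix for all factors, plus per-column factor
    index and per-factor level counts."""
    cols = []
    factor_of_col: list[int] = []
    n_groups = {}
    names = list(groups)
    for fi, name in enumerate(names):
        codes, levels = pd.factorize(np.asarray(groups[name]))
        q_f = len(levels)
        n_groups[name] = q_f
        zf = np.zeros((n, q_f))
        zf[np.arange(n), codes] = 1.0
        cols.append(zf)
        factor_of_col.extend([fi] * q_f)
    Z = np.concatenate(cols, axis=1) if cols else np.zeros((n, 0))
    return Z, names, np.asarray(factor_of_col, dtype=int), n_groups


def fit_logistic_mixed(
    y: np.ndarray,
    X: np.ndarray,
    terms: list[str],
    groups: dict[str, np.ndarray] | None = None,
    fix_sds: dict[str, float] | None = None,
) -> GlmmFit:
    """Fit the logistic mixed model.

    Parameters
    ----------
    y, X
        Response (0/1) and fixed-effect design (including an intercept
        column if wanted); ``terms`` names the columns of X.
    groups
        Mapping factor name -> per-row level labels; each factor gets an
        independent random-intercept variance. ``None``/empty gives
        ordinary logistic regression.
    fix_sds
        Factor name -> SD held fixed instead of estimated. An SD of 0
        removes the factor (useful for model-reduction checks).

    Non-convergence is reported on the returned fit (``converged`` /
    ``messages``), not raised.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if len(terms) != p:
        raise ValueError("terms must name every column of X")
    if len(np.unique(y)) < 2:
        raise InsufficientDataError("response has fewer than 2 distinct values")
    groups = dict(groups or {})
    fix_sds = dict(fix_sds or {})
    messages: list[str] = []

    dropped_groups = {k: 0 for k, v in fix_sds.items() if v == 0.0 and k in groups}
    for k in dropped_groups:
        groups.pop(k)
        messages.append(f"random factor {k!r} fixed at SD 0 (dropped)")
    for name, g in groups.items():
        if len(pd.unique(np.asarray(g))) < 2:
            raise InsufficientDataError(
                f"random factor {name!r} has fewer than 2 levels"
            )

    Z, factor_names, factor_of_col, n_groups = _build_z(groups, n)
    q = Z.shape[1]
    free = [f for f in factor_names if f not in fix_sds]
    free_pos = {f: i for i, f in enumerate(free)}

    state = {"u": np.zeros(q), "inner_ok": True}

    def unpack(params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta = params[:p]
        sds = np.empty(len(factor_names))
        for j, f in enumerate(factor_names):
            sds[j] = fix_sds[f] if f in fix_sds else np.exp(params[p + free_pos[f]])
        return beta, sds

    def negll(params: np.ndarray) -> float:
        beta, sds = unpack(params)
        offset = X @ beta
        if q:
            pen_u = 1.0 / np.maximum(sds[factor_of_col] ** 2, 1e-12)
            u, w, ok = _solve_u(y, Z, offset, pen_u, state["u"])
            state["u"] = u
            state["inner_ok"] = ok
            eta = offset + Z @ u
            ll = _loglik_bernoulli(y, eta) - 0.5 * float(u @ (pen_u * u))
            M = (Z.T * w) @ Z
            M[np.diag_indices_from(M)] += pen_u
            sign, logdet = np.linalg.slogdet(M)
            if sign <= 0:
                return np.inf
            ll -= 0.5 * (logdet + float(np.sum(np.log(sds[factor_of_col] ** 2))))
        else:
            ll = _loglik_bernoulli(y, offset)
        return -ll

    x0 = np.concatenate([np.zeros(p), np.full(len(free), np.log(_START_SD))])
    bounds = [(None, None)] * p + [_LOG_SD_BOUNDS] * len(free)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            negll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "maxfun": 20000, "ftol": 1e-12, "gtol": 1e-7},
        )
    outer_ok = bool(res.success)
    if not outer_ok:
        messages.append(f"outer optimizer: {res.message}")
    negll_opt = negll(res.x)  # refresh state at the optimum
    beta, sds = unpack(res.x)
    if not state["inner_ok"]:
        outer_ok = False
        messages.append("inner Newton for random effects did not converge")

    u = state["u"]
    eta = X @ beta + (Z @ u if q else 0.0)
    mu = special.expit(eta)
    w = mu * (1.0 - mu)

    if np.max(np.abs(eta)) > 30 or np.max(np.abs(beta)) > 15:
        messages.append(
            "possible complete separation: extreme linear predictor or coefficient"
        )

    # Wald SEs: beta block of the inverse Hessian of the Laplace
    # objective over (beta, free log-sds). Variance parameters at the
    # lower bound are excluded (one-sided curvature there).
    interior = [
        i for i in range(len(free))
        if res.x[p + i] > _LOG_SD_BOUNDS[0] + 0.1
    ]
    se = _hessian_se(negll, res.x, p, interior)
    if se is None:
        # conditional (fixed-theta) fallback: Schur complement
        XtWX = (X.T * w) @ X
        if q:
            pen_u = 1.0 / np.maximum(sds[factor_of_col] ** 2, 1e-12)
            M = (Z.T * w) @ Z
            M[np.diag_indices_from(M)] += pen_u
            XtWZ = (X.T * w) @ Z
            info = XtWX - XtWZ @ np.linalg.solve(M, XtWZ.T)
        else:
            info = XtWX
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            messages.append("standard errors from conditional information")
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
            messages.append(
                "singular information matrix; standard errors unavailable"
            )
    inv_ok = bool(np.all(np.isfinite(se)) and np.all(se > 0))
    if not inv_ok:
        messages.append("non-positive or undefined standard error")

    z = np.divide(beta, se, out=np.full(p, np.nan), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "term": terms,
            "estimate": beta,
            "std_error": se,
            "z_value": z,
            "p_value": pvals,
        }
    )
    variances = {f: float(sds[j] ** 2) for j, f in enumerate(factor_names)}
    variances.update({k: 0.0 for k in dropped_groups})
    n_groups_all = dict(n_groups)
    n_groups_all.update(dropped_groups)
    return GlmmFit(
        fixed_effects=table,
        random_variances=variances,
        loglik=-float(negll_opt),
        converged=outer_ok and inv_ok,
        n_rows=n,
        n_groups=n_groups_all,
        messages=messages,
    )
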