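"""Bernoulli GLMM with two crossed random intercepts, fitted by Laplace approximation.

The model for attempt *i* of individual ``ind(i)`` in season ``yr(i)`` is

.. math::

    y_i \\sim \\mathrm{Bernoulli}(p_i), \\qquad
    \\mathrm{logit}(p_i) = x_i^\\top \\beta + u_{ind(i)} + v_{yr(i)},

with :math:`u \\sim N(0, \\sigma^2_{ind} I)` and
:math:`v \\sim N(0, \\sigma^2_{yr} I)` crossed (every individual can occur in
many seasons and vice versa).  The marginal likelihood integrates over
``(u, v)`` jointly; because the factors are crossed the integral does not
factorise, and we approximate it by Laplace's method at the conditional mode
(one quadrature point), the standard approach for binomial mixed models of
this size.

Estimation is a nested optimisation, mirroring the penalised iteratively
reweighted least squares (PIRLS) scheme of mainstream mixed-model software:

* inner loop: for fixed variance components, Newton/IRLS on the *joint*
  penalised log-likelihood in ``(beta, u, v)``.  The normal equations are
  solved exactly by eliminating the (diagonal-dominant) individual block,
  so cost per iteration is linear in observations and individuals.
* outer loop: bounded quasi-Newton (L-BFGS-B) on
  ``(log sigma_ind, log sigma_yr)`` of the profiled Laplace log-likelihood,
  with deterministic restarts from perturbed starting points on failure.

Variance components that collapse to the boundary are reported as 0 (and a
flag set) but still count one AIC parameter each, so
``k = n_fixed + n_variance_components`` regardless of boundary estimates --
a convention that matters when comparing models by dAIC and therefore
stated prominently here.

:func:`loglik_oracle` provides an exact (dense Gauss--Hermite) evaluation of
the marginal log-likelihood for small problems, used to validate the
Laplace approximation; it is never part of the fitting path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, log_expit

__all__ = [
    "GlmmFit",
    "SeparationError",
    "fit_glmm",
    "loglik_laplace",
    "loglik_oracle",
    "aic",
    "delta_aic",
    "predict_fixed",
]

_SEP_LIMIT = 15.0  # |beta| beyond this on the logit scale => separation
_BOUNDARY_S2 = 1e-4  # variance estimates below this are reported as 0


class SeparationError(RuntimeError):
    """Raised when the fixed-effect estimates diverge (complete separation)."""


class ConvergenceError(RuntimeError):
    """Raised when the optimiser fails after all restarts."""


@dataclass
class GlmmFit:
    """A fitted Bernoulli mixed model.

    Attributes
    ----------
    beta, se : arrays of fixed-effect estimates and standard errors (logit scale).
    terms : column names of the design matrix.
    sigma2_ind, sigma2_year : variance components (0 at the boundary).
    loglik : Laplace-approximate marginal log-likelihood.
    aic : -2 loglik + 2 k with k = len(beta) + number of estimated variances.
    vcov : fixed-effect covariance (from the joint observed information).
    """

    beta: np.ndarray
    se: np.ndarray
    terms: list
    sigma2_ind: float
    sigma2_year: float
    loglik: float
    aic: float
    k: int
    n_obs: int
    converged: bool
    vcov: np.ndarray
    boundary_ind: bool = False
    boundary_year: bool = False
    u: np.ndarray | None = None
    v: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def summary_frame(self):
        import pandas as pd

        z = np.divide(self.beta, self.se, out=np.full_like(self.beta, np.nan), where=self.se > 0)
        return pd.DataFrame({"term": self.terms, "estimate": self.beta, "se": self.se, "z": z})


def _check_inputs(y, X, ind, year):
    y = np.ascontiguousarray(y, dtype=float)
    X = np.ascontiguousarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with one row per observation")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary")
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")
    ind = np.ascontiguousarray(ind)
    year = np.ascontiguousarray(year)
    if len(ind) != len(y) or len(year) != len(y):
        raise ValueError("grouping vectors must align with y")
    _, ind_idx = np.unique(ind, return_inverse=True)
    _, yr_idx = np.unique(year, return_inverse=True)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return y, X, ind_idx.astype(np.intp), yr_idx.astype(np.intp)


def _bernoulli_loglik(y, eta):
    # log p(y|eta) computed stably via log_expit
    return float(np.sum(y * log_expit(eta) + (1.0 - y) * log_expit(-eta)))


def _cross_weights(ind, yr, w, n_i, n_y):
    """C[i, j] = sum of w over observations with individual i in year j (dense n_i x n_y)."""
    return np.bincount(ind * n_y + yr, weights=w, minlength=n_i * n_y).reshape(n_i, n_y)


def _pirls(y, X, ind, yr, s2i, s2y, beta, u, v, max_iter=80, tol=1e-10, fixed_beta=False):
    """Newton (penalised IRLS) on the joint penalised log-likelihood.

    Returns the joint mode and the pieces needed for the Laplace correction.
    With ``fixed_beta=True`` only the random effects are updated (used when
    evaluating the Laplace likelihood at user-supplied beta).
    """
    n, p = X.shape
    n_i = int(ind.max()) + 1 if s2i > 0 else 0
    n_y = int(yr.max()) + 1 if s2y > 0 else 0
    if s2i <= 0:
        u = np.zeros(0)
    elif u is None or len(u) != n_i:
        u = np.zeros(n_i)
    if s2y <= 0:
        v = np.zeros(0)
    elif v is None or len(v) != n_y:
        v = np.zeros(n_y)

    def penalised(eta, u, v):
        pen = 0.0
        if s2i > 0:
            pen += 0.5 * u @ u / s2i
        if s2y > 0:
            pen += 0.5 * v @ v / s2y
        return _bernoulli_loglik(y, eta) - pen

    eta = X @ beta
    if s2i > 0:
        eta = eta + u[ind]
    if s2y > 0:
        eta = eta + v[yr]
    obj = penalised(eta, u, v)

    for _ in range(max_iter):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        # weighted penalised least squares in (beta, u, v); eliminate the
        # (diagonal) individual block first.  With fixed_beta the fixed part
        # is moved to the offset and only (u, v) are solved for.
        if fixed_beta:
            z_eff = z - X @ beta
            n_free = 0
        else:
            z_eff = z
            n_free = p
        wz = w * z_eff
        if s2i > 0:
            a = np.bincount(ind, weights=w, minlength=n_i) + 1.0 / s2i
            r_u = np.bincount(ind, weights=wz, minlength=n_i)
        if not fixed_beta:
            XtWX = X.T @ (X * w[:, None])
            XtWz = X.T @ wz
            if s2i > 0:
                XtWZi = np.stack(
                    [np.bincount(ind, weights=w * X[:, j], minlength=n_i) for j in range(p)]
                )  # p x n_i
        if s2y > 0:
            d_y = np.bincount(yr, weights=w, minlength=n_y) + 1.0 / s2y
            r_y = np.bincount(yr, weights=wz, minlength=n_y)
            if s2i > 0:
                C = _cross_weights(ind, yr, w, n_i, n_y)

        dim = n_free + (n_y if s2y > 0 else 0)
        if dim > 0:
            M = np.zeros((dim, dim))
            r = np.zeros(dim)
            if not fixed_beta:
                M[:p, :p] = XtWX
                r[:p] = XtWz
                if s2i > 0:
                    M[:p, :p] -= (XtWZi / a) @ XtWZi.T
                    r[:p] -= XtWZi @ (r_u / a)
            off = n_free
            if s2y > 0:
                M[off:, off:] = np.diag(d_y)
                r[off:] = r_y
                if s2i > 0:
                    M[off:, off:] -= (C / a[:, None]).T @ C
                    r[off:] -= C.T @ (r_u / a)
                if not fixed_beta:
                    XtWZy = np.stack(
                        [np.bincount(yr, weights=w * X[:, j], minlength=n_y) for j in range(p)]
                    )
                    cross = XtWZy
                    if s2i > 0:
                        cross = cross - (XtWZi / a) @ C
                    M[:p, off:] = cross
                    M[off:, :p] = cross.T
            sol = np.linalg.solve(M, r)
            beta_new = sol[:p] if not fixed_beta else beta
            v_new = sol[n_free:] if s2y > 0 else v
        else:
            beta_new, v_new = beta, v
        if s2i > 0:
            resid = r_u.copy()
            if not fixed_beta:
                resid -= XtWZi.T @ beta_new
            if s2y > 0:
                resid -= C @ v_new
            u_new = resid / a
        else:
            u_new = u

        # step-halving line search on the penalised objective
        step = 1.0
        for _ in range(30):
            b_try = beta + step * (beta_new - beta)
            u_try = u + step * (u_new - u) if s2i > 0 else u
            v_try = v + step * (v_new - v) if s2y > 0 else v
            eta_try = X @ b_try
            if s2i > 0:
                eta_try = eta_try + u_try[ind]
            if s2y > 0:
                eta_try = eta_try + v_try[yr]
            obj_try = penalised(eta_try, u_try, v_try)
            if obj_try >= obj - 1e-12:
                break
            step *= 0.5
        improved = obj_try - obj
        beta, u, v, eta, obj = b_try, u_try, v_try, eta_try, obj_try
        if abs(improved) < tol * (1.0 + abs(obj)):
            break

    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    return beta, u, v, eta, w, obj


def _laplace_logdet(ind, yr, w, s2i, s2y):
    """log det of the random-effects block Z'WZ + Sigma^{-1} (Schur on the individual block)."""
    if s2i <= 0 and s2y <= 0:
        return 0.0
    if s2i > 0:
        n_i = int(ind.max()) + 1
        a = np.bincount(ind, weights=w, minlength=n_i) + 1.0 / s2i
        ld = float(np.sum(np.log(a)))
    else:
        ld = 0.0
    if s2y > 0:
        n_y = int(yr.max()) + 1
        d_y = np.bincount(yr, weights=w, minlength=n_y) + 1.0 / s2y
        if s2i > 0:
            C = _cross_weights(ind, yr, w, n_i, n_y)
            S = np.diag(d_y) - (C / a[:, None]).T @ C
            sign, ld_y = np.linalg.slogdet(S)
            if sign <= 0:
                raise np.linalg.LinAlgError("random-effect information not positive definite")
            ld += float(ld_y)
        else:
            ld += float(np.sum(np.log(d_y)))
    return ld


def _laplace_from_mode(y, eta, u, v, w, ind, yr, s2i, s2y):
    ll = _bernoulli_loglik(y, eta)
    if s2i > 0:
        ll -= 0.5 * (u @ u / s2i + len(u) * np.log(s2i))
    if s2y > 0:
        ll -= 0.5 * (v @ v / s2y + len(v) * np.log(s2y))
    ll -= 0.5 * _laplace_logdet(ind, yr, w, s2i, s2y)
    return ll


def loglik_laplace(y, X, beta, sigma2_ind, sigma2_year, ind, year):
    """Laplace marginal log-likelihood at fixed (beta, variance components).

    Maximises the joint penalised log-likelihood over the random effects only
    and applies the Laplace determinant correction.  Mainly used to compare
    against :func:`loglik_oracle`.
    """
    y, X, ind, yr = _check_inputs(y, X, ind, year)
    beta = np.asarray(beta, dtype=float)
    _, u, v, eta, w, _ = _pirls(
        y, X, ind, yr, sigma2_ind, sigma2_year, beta, None, None, fixed_beta=True
    )
    return _laplace_from_mode(y, eta, u, v, w, ind, yr, sigma2_ind, sigma2_year)


def fit_glmm(
    y,
    X,
    ind,
    year,
    terms=None,
    fix_sigma2: tuple | None = None,
    theta0=(np.log(0.5), np.log(0.5)),
    maxiter: int = 200,
) -> GlmmFit:
    """Fit the crossed-intercepts Bernoulli GLMM by Laplace approximation.

    Parameters
    ----------
    y, X : response vector and full-column-rank fixed-effects design.
    ind, year : grouping labels (any hashable values) for the two crossed
        random intercepts.
    terms : optional column names for reporting.
    fix_sigma2 : optionally pin ``(sigma2_ind, sigma2_year)`` instead of
        estimating them; an entry of 0 removes that random effect exactly
        (the ``(0, 0)`` limit is ordinary logistic regression).  Fixed
        components do not count towards the AIC parameter count.
    theta0 : starting values for ``(log sigma_ind, log sigma_year)``.

    Raises
    ------
    SeparationError
        If any fixed effect diverges beyond +/-15 on the logit scale.
    ValueError
        Rank-deficient design, misaligned inputs, non-binary response.
    """
    y, X, ind_idx, yr_idx = _check_inputs(y, X, ind, year)
    n, p = X.shape
    if terms is None:
        terms = [f"x{j}" for j in range(p)]
    terms = list(terms)

    state = {"beta": np.zeros(p), "u": None, "v": None}

    def profile_neg_loglik(theta):
        s2i = float(np.exp(2.0 * theta[0]))
        s2y = float(np.exp(2.0 * theta[1]))
        beta, u, v, eta, w, _ = _pirls(
            y, X, ind_idx, yr_idx, s2i, s2y, state["beta"].copy(), state["u"], state["v"]
        )
        state.update(beta=beta, u=u.copy() if len(u) else None, v=v.copy() if len(v) else None)
        return -_laplace_from_mode(y, eta, u, v, w, ind_idx, yr_idx, s2i, s2y)

    if fix_sigma2 is not None:
        s2i, s2y = float(fix_sigma2[0]), float(fix_sigma2[1])
        n_var = 0
        converged = True
    else:
        bounds = [(-6.0, 2.5), (-6.0, 2.5)]
        starts = [np.asarray(theta0, float)]
        for d in ((0.7, -0.7), (-1.5, 0.5), (1.0, 1.0)):
            starts.append(np.clip(np.asarray(theta0, float) + d, -6.0, 2.5))
        res = None
        converged = False
        for th0 in starts:
            r = minimize(
                profile_neg_loglik,
                th0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
            )
            if res is None or r.fun < res.fun - 1e-9:
                res = r
            if r.success:
                res = r if r.fun <= res.fun + 1e-9 else res
                converged = True
                break
        s2i = float(np.exp(2.0 * res.x[0]))
        s2y = float(np.exp(2.0 * res.x[1]))
        n_var = 2

    boundary_ind = s2i < _BOUNDARY_S2 and (fix_sigma2 is None)
    boundary_year = s2y < _BOUNDARY_S2 and (fix_sigma2 is None)

    beta, u, v, eta, w, _ = _pirls(
        y, X, ind_idx, yr_idx, s2i, s2y, state["beta"].copy(), state["u"], state["v"],
        tol=1e-12,
    )
    if np.max(np.abs(beta)) > _SEP_LIMIT:
        raise SeparationError(
            "fixed-effect estimate beyond +/-15 logits; data are (quasi-)separated"
        )
    ll = _laplace_from_mode(y, eta, u, v, w, ind_idx, yr_idx, s2i, s2y)

    vcov = _beta_vcov(X, w, ind_idx, yr_idx, s2i, s2y)
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))

    k = p + n_var
    fit = GlmmFit(
        beta=beta,
        se=se,
        terms=terms,
        sigma2_ind=0.0 if boundary_ind else s2i,
        sigma2_year=0.0 if boundary_year else s2y,
        loglik=float(ll),
        aic=float(-2.0 * ll + 2.0 * k),
        k=k,
        n_obs=n,
        converged=bool(converged),
        vcov=vcov,
        boundary_ind=boundary_ind,
        boundary_year=boundary_year,
        u=u if len(u) else None,
        v=v if len(v) else None,
    )
    return fit


def _beta_vcov(X, w, ind, yr, s2i, s2y):
    """Fixed-effect covariance: inverse Schur complement of the random block
    in the joint observed information at the mode."""
    n, p = X.shape
    Xw = X * w[:, None]
    I_bb = X.T @ Xw
    if s2i <= 0 and s2y <= 0:
        return np.linalg.inv(I_bb)
    n_i = int(ind.max()) + 1
    n_y = int(yr.max()) + 1
    corr = np.zeros((p, p))
    if s2i > 0:
        a = np.bincount(ind, weights=w, minlength=n_i) + 1.0 / s2i
        XtWZi = np.stack([np.bincount(ind, weights=w * X[:, j], minlength=n_i) for j in range(p)])
    if s2y > 0:
        d_y = np.bincount(yr, weights=w, minlength=n_y) + 1.0 / s2y
        XtWZy = np.stack([np.bincount(yr, weights=w * X[:, j], minlength=n_y) for j in range(p)])
    if s2i > 0 and s2y > 0:
        C = _cross_weights(ind, yr, w, n_i, n_y)
        S = np.diag(d_y) - (C / a[:, None]).T @ C
        G = XtWZy - (XtWZi / a) @ C  # p x n_y, cross after eliminating u
        corr = (XtWZi / a) @ XtWZi.T + G @ np.linalg.solve(S, G.T)
    elif s2i > 0:
        corr = (XtWZi / a) @ XtWZi.T
    else:
        corr = (XtWZy / d_y) @ XtWZy.T
    return np.linalg.inv(I_bb - corr)


def aic(fit: GlmmFit) -> float:
    """AIC = -2 loglik + 2 k (k counts fixed effects plus estimated variances)."""
    return fit.aic


def delta_aic(model_a: GlmmFit, model_b: GlmmFit) -> float:
    """AIC(a) - AIC(b); both fits must be on the same response vector."""
    if model_a.n_obs != model_b.n_obs:
        raise ValueError("models were fitted to different numbers of observations")
    return model_a.aic - model_b.aic


def predict_fixed(fit: GlmmFit, X_new):
    """Fixed-effects-only predictions on the probability scale with delta-method SEs.

    Random effects are set to zero (population-typical prediction), matching
    the convention used for plotting average age trajectories.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(fit.beta):
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns; model has {len(fit.beta)} coefficients"
        )
    eta = X_new @ fit.beta
    p = expit(eta)
    var_eta = np.einsum("ij,jk,ik->i", X_new, fit.vcov, X_new)
    se = p * (1.0 - p) * np.sqrt(np.clip(var_eta, 0.0, None))
    return p, se


# ---------------------------------------------------------------------------
# exact quadrature oracle


def loglik_oracle(y, X, beta, sigma2_ind, sigma2_year, ind, year, order: int = 25,
                  max_year_levels: int = 5):
    """Exact marginal log-likelihood by dense Gauss--Hermite quadrature.

    Conditional on the year effects the individuals are independent, so the
    crossed integral is evaluated as a product Gauss--Hermite grid over the
    year levels with a one-dimensional quadrature per individual inside.
    Cost is ``order**n_year * n_ind * order``; the number of *year* levels is
    the binding limit (<= ``max_year_levels``), individuals scale linearly.

    Deterministic given ``order``.  Test/validation oracle only.
    """
    y, X, ind, yr = _check_inputs(y, X, ind, year)
    beta = np.asarray(beta, dtype=float)
    base = X @ beta
    n_i = int(ind.max()) + 1
    n_y = int(yr.max()) + 1

    nodes, weights = hermgauss(order)
    logw = np.log(weights) - 0.5 * np.log(np.pi)

    si = np.sqrt(max(sigma2_ind, 0.0))
    sy = np.sqrt(max(sigma2_year, 0.0))
    u_nodes = np.sqrt(2.0) * si * nodes  # N(0, s2i) change of variables

    if sigma2_year <= 0:
        # years drop out: independent 1-D integrals per individual
        if sigma2_ind <= 0:
            return _bernoulli_loglik(y, base)
        total = 0.0
        for i in range(n_i):
            m = ind == i
            ll_k = np.array(
                [
                    np.sum(y[m] * log_expit(base[m] + u) + (1 - y[m]) * log_expit(-(base[m] + u)))
                    for u in u_nodes
                ]
            )
            total += _logsumexp(logw + ll_k)
        return float(total)

    if n_y > max_year_levels:
        raise ValueError(
            f"{n_y} year levels exceed max_year_levels={max_year_levels}: "
            "the product quadrature grid would be too large"
        )
    v_nodes = np.sqrt(2.0) * sy * nodes

    grid_shape = (order,) * n_y
    # per-individual conditional log-likelihood on the joint year grid:
    # for each u-node k, S_i[k] has shape grid_shape, built by broadcasting each
    # observation's (order,) year-node profile along its year's axis.
    total = 0.0
    n_u = len(u_nodes) if sigma2_ind > 0 else 1
    u_vals = u_nodes if sigma2_ind > 0 else np.zeros(1)
    for i in range(n_i):
        m = np.flatnonzero(ind == i)
        Li_log = np.full((n_u,) + grid_shape, 0.0)
        for t in m:
            # (n_u, order): log p(y_t | base + u_k + v_m)
            eta_km = base[t] + u_vals[:, None] + v_nodes[None, :]
            lp = y[t] * log_expit(eta_km) + (1 - y[t]) * log_expit(-eta_km)
            shape = [n_u] + [1] * n_y
            shape[1 + yr[t]] = order
            Li_log = Li_log + lp.reshape(shape)
        if sigma2_ind > 0:
            # integrate u by logsumexp over axis 0 with weights
            Li_log = Li_log + logw.reshape([n_u] + [1] * n_y)
            Li = _logsumexp_axis0(Li_log)
        else:
            Li = Li_log[0]
        total = total + Li  # accumulate log over individuals on the grid
    # integrate the year grid: sum over all axes with product weights
    wgrid = logw
    for _ in range(n_y - 1):
        wgrid = np.add.outer(wgrid, logw)
    return float(_logsumexp((total + wgrid).ravel()))


def _logsumexp(a):
    amax = np.max(a)
    return float(amax + np.log(np.sum(np.exp(a - amax))))


def _logsumexp_axis0(a):
    amax = np.max(a, axis=0)
    return amax + np.log(np.sum(np.exp(a - amax[None]), axis=0))
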