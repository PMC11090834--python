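"""Hamiltonian Monte Carlo for multi-membership generalized linear mixed models.

A small, self-contained HMC engine (jittered-length leapfrog trajectories,
dual-averaging step-size adaptation, diagonal mass-matrix estimation in a
warmup window, divergence detection) plus log-posterior/gradient
implementations for the three likelihoods used here:

* beta (logit link, mean-precision parameterization),
* poisson (log link),
* gaussian (identity link, optionally with a correlated random effect
  defined through a Cholesky factor, e.g. a phylogenetic correlation).

Random intercepts are non-centred: ``effect = sigma * z`` with
``z ~ N(0, 1)``, which keeps the geometry manageable for short chains.

Priors (weakly informative, documented defaults):
intercept and group SDs ~ student-t(3, 0, 2.5) (SDs half-t), slopes
~ normal(0, 5), beta precision phi ~ gamma(0.01, 0.01), gaussian residual
SD ~ half-t(3, 0, 2.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from ._kernels import HAVE_NUMBA, beta_loglik, beta_mm2_logp_grad, poisson_loglik

logger = logging.getLogger(__name__)

_T_SCALE = 2.5        # student-t scale for intercept / SDs
_SLOPE_SD = 5.0       # normal prior sd for slopes
_PHI_A = 0.01         # gamma prior on beta precision
_PHI_B = 0.01


@dataclass
class Group:
    """One multi-membership random-intercept block.

    ``idx_a``/``idx_b`` index the effect vector for the two members of
    each row (``idx_b`` may be None for single-membership). ``chol`` is
    an optional Cholesky factor of a correlation structure among levels.

    ``center`` subtracts the mean effect before it enters the linear
    predictor, letting the intercept absorb it. The mean of a
    multi-membership intercept vector is only weakly identified (it is
    confounded with the intercept), and that ridge is what forces very
    deep NUTS trees in off-the-shelf samplers; centring removes it at
    the cost of a sum-to-zero constraint that leaves slope inference
    unchanged.
    """

    name: str
    n_levels: int
    idx_a: np.ndarray
    idx_b: np.ndarray = None
    chol: np.ndarray = None
    center: bool = True


class GLMM:
    """Log posterior and gradient for a mixed model on a packed vector.

    Parameter layout: [beta (p), z_g1, z_g2, ..., log_sigma_g (G), aux]
    where aux is log(phi) for the beta likelihood and log(sigma_e) for
    the gaussian one.
    """

    def __init__(self, y, X, groups, likelihood="beta", term_names=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.groups = list(groups)
        if likelihood not in ("beta", "poisson", "gaussian"):
            raise ValueError(f"unknown likelihood {likelihood!r}")
        if likelihood == "beta" and ((self.y <= 0).any() or (self.y >= 1).any()):
            raise ValueError("beta likelihood needs responses strictly inside (0, 1)")
        self.likelihood = likelihood
        self.n, self.p = self.X.shape
        self.term_names = list(term_names) if term_names else [
            f"b{k}" for k in range(self.p)]
        # slices into the packed parameter vector
        pos = self.p
        self._z_slices = []
        for g in self.groups:
            self._z_slices.append(slice(pos, pos + g.n_levels))
            pos += g.n_levels
        self._sigma_slice = slice(pos, pos + len(self.groups))
        pos += len(self.groups)
        self._aux = pos if likelihood != "poisson" else None
        self.dim = pos + (1 if self._aux is not None else 0)
        if likelihood == "poisson" and (self.y < 0).any():
            raise ValueError("poisson likelihood needs non-negative responses")
        # constants reused by every likelihood evaluation
        if likelihood == "beta":
            self._log_y = np.log(self.y)
            self._log_1my = np.log1p(-self.y)
        elif likelihood == "poisson":
            self._lgam_y1 = float(gammaln(self.y + 1).sum())
        # fused kernel for the common dyadic structure (two plain centred
        # multi-membership blocks under a beta likelihood)
        self._fast = (HAVE_NUMBA and likelihood == "beta" and len(self.groups) == 2
                      and all(g.chol is None and g.center and g.idx_b is not None
                              for g in self.groups))

    # -- naming ---------------------------------------------------------
    def param_names(self):
        names = list(self.term_names)
        for g in self.groups:
            names += [f"z_{g.name}[{i}]" for i in range(g.n_levels)]
        names += [f"sd_{g.name}" for g in self.groups]
        if self.likelihood == "beta":
            names.append("phi")
        elif self.likelihood == "gaussian":
            names.append("sigma")
        return names

    def initial_point(self):
        theta = np.zeros(self.dim)
        if self.likelihood == "beta":
            m = np.clip(self.y.mean(), 1e-3, 1 - 1e-3)
            theta[0] = np.log(m / (1 - m))
            theta[self._aux] = np.log(10.0)
        elif self.likelihood == "poisson":
            theta[0] = np.log(self.y.mean() + 0.5)
        else:
            theta[0] = self.y.mean()
            theta[self._aux] = np.log(self.y.std() + 1e-3)
        theta[self._sigma_slice] = np.log(0.5)
        return theta

    # -- transformed draws ----------------------------------------------
    def constrain(self, draws: np.ndarray) -> dict:
        """Map packed draws (..., dim) to named constrained parameters."""
        out = {name: draws[..., k] for k, name in enumerate(self.term_names)}
        sig = np.exp(draws[..., self._sigma_slice])
        for gi, g in enumerate(self.groups):
            out[f"sd_{g.name}"] = sig[..., gi]
        if self.likelihood == "beta":
            out["phi"] = np.exp(draws[..., self._aux])
        elif self.likelihood == "gaussian":
            out["sigma"] = np.exp(draws[..., self._aux])
        return out

    # -- log posterior ---------------------------------------------------
    def _eta(self, theta):
        eta = self.X @ theta[:self.p]
        sigmas = np.exp(theta[self._sigma_slice])
        us = []
        for g, zsl, sigma in zip(self.groups, self._z_slices, sigmas):
            z = theta[zsl]
            eff = g.chol @ z if g.chol is not None else z
            if g.center:
                eff = eff - eff.mean()
            u = eff[g.idx_a]
            if g.idx_b is not None:
                u = u + eff[g.idx_b]
            us.append(u)
            eta = eta + sigma * u
        return eta, sigmas, us

    def logp_grad(self, theta):
        if self._fast:
            g0, g1 = self.groups
            return beta_mm2_logp_grad(
                theta, self.X, self._log_y, self._log_1my,
                g0.idx_a, g0.idx_b, g1.idx_a, g1.idx_b,
                g0.n_levels, g1.n_levels,
                3 * _T_SCALE ** 2, _SLOPE_SD ** 2, _PHI_A, _PHI_B)
        y, X = self.y, self.X
        beta = theta[:self.p]
        eta, sigmas, us = self._eta(theta)
        grad = np.zeros_like(theta)

        # likelihood and d logp / d eta
        if self.likelihood == "beta":
            phi = np.exp(np.clip(theta[self._aux], -30.0, 30.0))
            ll, g_eta, dphi = beta_loglik(eta, self._log_y, self._log_1my, phi)
            # gamma(a, b) prior on phi plus log-jacobian
            lp_aux = (_PHI_A * theta[self._aux] - _PHI_B * phi)
            grad[self._aux] = dphi * phi + _PHI_A - _PHI_B * phi
        elif self.likelihood == "poisson":
            ll, g_eta = poisson_loglik(eta, y)
            ll -= self._lgam_y1
            lp_aux = 0.0
        else:
            sigma_e = np.exp(theta[self._aux])
            resid = y - eta
            ll = -self.n * np.log(sigma_e) - 0.5 * np.sum(resid ** 2) / sigma_e ** 2
            g_eta = resid / sigma_e ** 2
            # half-t(3, 0, 2.5) on sigma_e plus log-jacobian
            lp_aux = (-2.0 * np.log1p(sigma_e ** 2 / (3 * _T_SCALE ** 2))
                      + theta[self._aux])
            grad[self._aux] = (-self.n + np.sum(resid ** 2) / sigma_e ** 2
                               - 4 * sigma_e ** 2 / (3 * _T_SCALE ** 2 + sigma_e ** 2) + 1.0)

        # fixed effects: student-t(3) intercept, normal(0, 5) slopes
        grad[:self.p] = X.T @ g_eta
        b0 = beta[0]
        lp_beta = -2.0 * np.log1p(b0 ** 2 / (3 * _T_SCALE ** 2))
        grad[0] += -4 * b0 / (3 * _T_SCALE ** 2 + b0 ** 2)
        if self.p > 1:
            lp_beta += -0.5 * np.sum(beta[1:] ** 2) / _SLOPE_SD ** 2
            grad[1:self.p] += -beta[1:] / _SLOPE_SD ** 2

        # random effects
        lp_re = 0.0
        for gi, (g, zsl, sigma, u) in enumerate(
                zip(self.groups, self._z_slices, sigmas, us)):
            z = theta[zsl]
            lp_re += -0.5 * np.sum(z ** 2)
            s = np.bincount(g.idx_a, weights=g_eta, minlength=g.n_levels)
            if g.idx_b is not None:
                s += np.bincount(g.idx_b, weights=g_eta, minlength=g.n_levels)
            if g.center:
                s = s - s.sum() / g.n_levels
            if g.chol is not None:
                grad[zsl] = sigma * (g.chol.T @ s) - z
            else:
                grad[zsl] = sigma * s - z
            # half-t(3, 0, 2.5) prior on sigma with log-jacobian
            lp_re += -2.0 * np.log1p(sigma ** 2 / (3 * _T_SCALE ** 2)) + np.log(sigma)
            grad[self._sigma_slice][gi] = (
                sigma * np.dot(g_eta, u)
                - 4 * sigma ** 2 / (3 * _T_SCALE ** 2 + sigma ** 2) + 1.0)

        lp = ll + lp_beta + lp_re + lp_aux
        return lp, grad

    # -- interweaved SD update -------------------------------------------
    def interweave(self, theta, rng):
        """Sufficient-parameterization Gibbs update of the group SDs.

        Holding the effects u = sigma * z fixed (likelihood unchanged),
        the conditional of each sigma given u involves only the normal
        density of u and the half-t prior; one slice-sampling update
        there, followed by z <- u / sigma', walks the sigma-z funnel
        that fixed-length HMC traverses slowly. Mutates theta in place.
        """
        for gi, (g, zsl) in enumerate(zip(self.groups, self._z_slices)):
            k = self._sigma_slice.start + gi
            ls = theta[k]
            sigma = np.exp(ls)
            z = theta[zsl]
            q = sigma ** 2 * float(z @ z)
            n = g.n_levels

            def logf(ls_new):
                s2 = np.exp(2 * ls_new)
                return (-n * ls_new - 0.5 * q / s2
                        - 2.0 * np.log1p(s2 / (3 * _T_SCALE ** 2)) + ls_new)

            ls_new = _slice_sample(logf, ls, rng, w=0.5)
            theta[k] = ls_new
            theta[zsl] = z * np.exp(ls - ls_new)


class MarginalGaussianRegression:
    """Gaussian regression with one correlated random effect, marginalized.

    y ~ N(X beta, sigma_b^2 C + sigma_e^2 I). The random effect is
    integrated out analytically via the eigendecomposition C = Q L Q^T,
    in whose basis the covariance is diagonal. The sampler then works on
    [beta, log sigma_b, log sigma_e] only, which removes the
    one-effect-per-observation funnel entirely (exact same posterior for
    the reported parameters as the latent formulation).

    Priors match GLMM: student-t(3, 0, 2.5) intercept, normal(0, 5)
    slopes, half-t(3, 0, 2.5) on both scales.
    """

    likelihood = "gaussian_marginal"

    def __init__(self, y, X, C=None, term_names=None, group_name="genus"):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.group_name = group_name
        if C is None:
            C = np.eye(self.n)
        lam, Q = np.linalg.eigh(np.asarray(C, dtype=float))
        self.lam = np.maximum(lam, 0.0)
        self.Qt_y = Q.T @ self.y
        self.Qt_X = Q.T @ self.X
        self.term_names = list(term_names) if term_names else [
            f"b{k}" for k in range(self.p)]
        self.dim = self.p + 2
        self._sb = self.p
        self._se = self.p + 1

    def param_names(self):
        return self.term_names + [f"sd_{self.group_name}", "sigma"]

    def initial_point(self):
        theta = np.zeros(self.dim)
        theta[0] = self.y.mean()
        s = max(self.y.std() / np.sqrt(2), 1e-3)
        theta[self._sb] = np.log(s)
        theta[self._se] = np.log(s)
        return theta

    def constrain(self, draws):
        out = {name: draws[..., k] for k, name in enumerate(self.term_names)}
        out[f"sd_{self.group_name}"] = np.exp(draws[..., self._sb])
        out["sigma"] = np.exp(draws[..., self._se])
        return out

    def logp_grad(self, theta):
        beta = theta[:self.p]
        if not np.all(np.isfinite(theta)) or np.abs(theta[self.p:]).max() > 25:
            return -np.inf, np.zeros_like(theta)
        sb2 = np.exp(2 * theta[self._sb])
        se2 = np.exp(2 * theta[self._se])
        d = sb2 * self.lam + se2
        r = self.Qt_y - self.Qt_X @ beta
        inv_d = 1.0 / d
        ll = -0.5 * float(np.sum(np.log(d)) + np.sum(r ** 2 * inv_d))
        grad = np.zeros_like(theta)
        grad[:self.p] = self.Qt_X.T @ (r * inv_d)
        common = r ** 2 * inv_d ** 2 - inv_d
        grad[self._sb] = sb2 * float(np.sum(self.lam * common))
        grad[self._se] = se2 * float(np.sum(common))
        # priors
        b0 = beta[0]
        lp = ll - 2.0 * np.log1p(b0 ** 2 / (3 * _T_SCALE ** 2))
        grad[0] += -4 * b0 / (3 * _T_SCALE ** 2 + b0 ** 2)
        if self.p > 1:
            lp += -0.5 * float(np.sum(beta[1:] ** 2)) / _SLOPE_SD ** 2
            grad[1:self.p] += -beta[1:] / _SLOPE_SD ** 2
        for k, s2 in ((self._sb, sb2), (self._se, se2)):
            lp += -2.0 * np.log1p(s2 / (3 * _T_SCALE ** 2)) + 0.5 * np.log(s2)
            grad[k] += -4 * s2 / (3 * _T_SCALE ** 2 + s2) + 1.0
        return lp, grad


def _slice_sample(logf, x0, rng, w=1.0, max_steps=20):
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    y = logf(x0) + np.log(rng.random())
    lo = x0 - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if logf(lo) <= y:
            break
        lo -= w
    for _ in range(max_steps):
        if logf(hi) <= y:
            break
        hi += w
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logf(x1) > y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


# ---------------------------------------------------------------------------
# HMC engine
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    chains: int = 2
    warmup: int = 300
    draws: int = 700
    target_accept: float = 0.8
    max_leapfrog: int = 24
    metric: str = "dense"  # "dense" or "diag" mass matrix
    divergence_threshold: float = 1000.0
    jitter: float = 0.5  # init jitter sd around the model's initial point


@dataclass
class SampleResult:
    draws: np.ndarray       # (chains, draws, dim), unconstrained
    divergences: int
    accept_rate: float
    step_sizes: list = field(default_factory=list)


class _Metric:
    """Euclidean metric: diagonal or dense inverse mass (posterior covariance)."""

    def __init__(self, dim):
        self.diag = np.ones(dim)
        self.cov = None
        self._chol = None

    def set_diag(self, var):
        self.diag = var
        self.cov = None
        self._chol = None

    def set_dense(self, cov):
        self.cov = cov
        self._chol = np.linalg.cholesky(cov)
        self.diag = None

    def velocity(self, r):
        if self.cov is None:
            return self.diag * r
        return self.cov @ r

    def sample_momentum(self, rng, dim):
        xi = rng.standard_normal(dim)
        if self.cov is None:
            return xi / np.sqrt(self.diag)
        # r ~ N(0, cov^-1) via r = L^-T xi with cov = L L^T
        from scipy.linalg import solve_triangular
        return solve_triangular(self._chol.T, xi, lower=False)

    def kinetic(self, r):
        return 0.5 * float(r @ self.velocity(r))


def _leapfrog(logp_grad, theta, r, eps, metric, n_steps):
    lp, grad = logp_grad(theta)
    for _ in range(n_steps):
        r = r + 0.5 * eps * grad
        theta = theta + eps * metric.velocity(r)
        lp, grad = logp_grad(theta)
        r = r + 0.5 * eps * grad
    return theta, r, lp, grad


def _find_epsilon(logp_grad, theta, metric, rng):
    eps = 0.1
    lp0, _ = logp_grad(theta)
    r0 = metric.sample_momentum(rng, theta.size)
    h0 = lp0 - metric.kinetic(r0)
    _, r1, lp1, _ = _leapfrog(logp_grad, theta, r0, eps, metric, 1)
    h1 = lp1 - metric.kinetic(r1)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        _, r1, lp1, _ = _leapfrog(logp_grad, theta, r0, eps, metric, 1)
        h1 = lp1 - metric.kinetic(r1)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return max(eps, 1e-8)


def find_mode(logp_grad, theta0, free=None, fixed_var=0.25):
    """Conditional posterior mode and Laplace covariance.

    Optimizes only the ``free`` coordinates (all when None), holding the
    rest at their ``theta0`` values. In the non-centred parameterization
    the joint mode runs up the funnel in the group-SD coordinates (large
    sigma, shrunken z), so those are held fixed and assigned
    ``fixed_var`` in the returned covariance instead of a Hessian-based
    value; the warmup windows refine them from actual draws.
    """
    from scipy.optimize import minimize

    dim = theta0.size
    if free is None:
        free = np.ones(dim, dtype=bool)
    idx = np.flatnonzero(free)
    base = theta0.copy()

    def neg(x):
        t = base.copy()
        t[idx] = x
        lp, g = logp_grad(t)
        return -lp, -g[idx]

    res = minimize(neg, theta0[idx], jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    mode = base.copy()
    mode[idx] = res.x

    # central-difference Hessian of the free block from the gradient
    h = 1e-4
    k = idx.size
    H = np.empty((k, k))
    for col, i in enumerate(idx):
        e = np.zeros(dim)
        e[i] = h
        _, gp = logp_grad(mode + e)
        _, gm = logp_grad(mode - e)
        H[:, col] = -(gp[idx] - gm[idx]) / (2 * h)
    H = 0.5 * (H + H.T)
    H[~np.isfinite(H)] = 0.0
    try:
        vals, vecs = np.linalg.eigh(H)
    except np.linalg.LinAlgError:
        vals, vecs = np.ones(k), np.eye(k)
    floor = max(vals.max() * 1e-8, 1e-8)
    vals = np.maximum(vals, floor)
    block = (vecs / vals) @ vecs.T
    cov = np.eye(dim) * fixed_var
    cov[np.ix_(idx, idx)] = block
    return mode, cov


def _run_chain(logp_grad, init, cfg: SamplerConfig, rng, interweave=None,
               init_cov=None, sub_idx=None):
    """One HMC chain, optionally restricted to the ``sub_idx`` coordinates.

    Coordinates outside ``sub_idx`` are left to the ``interweave``
    callback (HMC-within-Gibbs): group SDs have funnel-shaped
    conditionals that fixed-length trajectories traverse poorly, so they
    are updated by exact 1-D slice moves between trajectories while HMC
    handles the well-conditioned remainder.
    """
    theta_full = init.copy()
    if sub_idx is None:
        sub_idx = np.arange(init.size)
    dim = sub_idx.size

    def lpg(x):
        theta_full[sub_idx] = x
        lp, g = logp_grad(theta_full)
        return lp, g[sub_idx]

    theta = theta_full[sub_idx].copy()
    metric = _Metric(dim)
    if init_cov is not None:
        if cfg.metric == "dense":
            metric.set_dense(init_cov)
        else:
            metric.set_diag(np.diag(init_cov).copy())
    warmup, draws = cfg.warmup, cfg.draws

    # windowed adaptation boundaries
    w1 = max(1, int(0.15 * warmup))
    w2 = max(w1 + 1, int(0.75 * warmup))

    eps = _find_epsilon(lpg, theta, metric, rng)
    mu = np.log(10 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_iter = 0

    window = np.empty((w2 - w1, dim))
    var_n = 0

    out = np.empty((draws, init.size))
    divergences = 0
    accepts = []
    lp_cur, _ = lpg(theta)

    for it in range(warmup + draws):
        in_warmup = it < warmup
        r0 = metric.sample_momentum(rng, dim)
        h0 = lp_cur - metric.kinetic(r0)
        n_steps = int(rng.integers(max(1, cfg.max_leapfrog // 2),
                                   cfg.max_leapfrog + 1))
        theta_new, r_new, lp_new, _ = _leapfrog(lpg, theta, r0, eps,
                                                metric, n_steps)
        h_new = lp_new - metric.kinetic(r_new)
        delta_h = h_new - h0
        if not np.isfinite(delta_h):
            delta_h = -np.inf
        divergent = (-delta_h) > cfg.divergence_threshold
        alpha = min(1.0, np.exp(min(delta_h, 0.0)))
        if (not divergent) and rng.random() < alpha:
            theta = theta_new
        theta_full[sub_idx] = theta
        if interweave is not None:
            interweave(theta_full, rng)
            theta = theta_full[sub_idx].copy()
        lp_cur, _ = lpg(theta)
        if in_warmup:
            # dual averaging on the acceptance statistic
            da_iter += 1
            h_bar = ((1 - 1 / (da_iter + t0)) * h_bar
                     + (cfg.target_accept - alpha) / (da_iter + t0))
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            w = da_iter ** -kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if w1 <= it < w2:
                window[var_n] = theta
                var_n += 1
            if it == w2 - 1 and var_n > 10:
                samples = window[:var_n]
                var = samples.var(axis=0)
                shrink = var_n / (var_n + 5.0)
                reg_var = shrink * np.maximum(var, 1e-10) + (1 - shrink) * 1e-3
                if cfg.metric == "dense":
                    cov = np.cov(samples.T)
                    w_d = var_n / (var_n + dim + 5.0)
                    prior_cov = init_cov if init_cov is not None else np.diag(reg_var)
                    cov = w_d * cov + (1 - w_d) * prior_cov
                    cov[np.diag_indices(dim)] += 1e-8
                    metric.set_dense(cov)
                else:
                    metric.set_diag(reg_var)
                eps = _find_epsilon(lpg, theta, metric, rng)
                mu = np.log(10 * eps)
                log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
            if it == warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            if divergent:
                divergences += 1
            accepts.append(alpha)
            theta_full[sub_idx] = theta
            out[it - warmup] = theta_full
    return out, divergences, float(np.mean(accepts)) if accepts else 0.0, eps


def sample(model: GLMM, cfg: SamplerConfig = None, seed=0) -> SampleResult:
    """Run ``cfg.chains`` independent HMC chains on the model posterior."""
    cfg = cfg or SamplerConfig()
    seq = np.random.SeedSequence(seed)
    chain_seeds = seq.spawn(cfg.chains)
    free = np.ones(model.dim, dtype=bool)
    theta0 = model.initial_point()
    interweave = getattr(model, "interweave", None)
    if interweave is not None:
        # group SDs are Gibbs-updated, not part of the HMC block
        free[model._sigma_slice] = False
        theta0[model._sigma_slice] = np.log(0.3)
    mode, cov = find_mode(model.logp_grad, theta0, free=free)
    sub_idx = np.flatnonzero(free)
    cov_sub = cov[np.ix_(sub_idx, sub_idx)]
    scale = np.sqrt(np.diag(cov))
    all_draws = np.empty((cfg.chains, cfg.draws, model.dim))
    total_div = 0
    acc = []
    steps = []
    for c in range(cfg.chains):
        rng = np.random.default_rng(chain_seeds[c])
        init = mode + cfg.jitter * scale * rng.standard_normal(model.dim)
        draws, div, a, eps = _run_chain(model.logp_grad, init, cfg, rng,
                                        interweave=interweave,
                                        init_cov=cov_sub, sub_idx=sub_idx)
        all_draws[c] = draws
        total_div += div
        acc.append(a)
        steps.append(eps)
    logger.info("HMC: %d chains x %d draws, accept %.2f, %d divergences",
                cfg.chains, cfg.draws, float(np.mean(acc)), total_div)
    return SampleResult(all_draws, total_div, float(np.mean(acc)), steps)
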