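"""MCMC samplers for the multilevel circadian models.

Two samplers, both operating on a fixed-effect design matrix ``X`` plus two
crossed-to-nested random-intercept structures (mouse, and study-block within
mouse):

* :func:`gibbs_gaussian` -- fully conjugate Gibbs sampler for the Gaussian
  model on the square-root scale:
  ``y = X b + u[mouse] + v[mouse-block] + e``.
* :func:`mwg_beta` -- adaptive Metropolis-within-Gibbs for the beta model
  with logit link and constant precision phi:
  ``y ~ Beta(mu*phi, (1-mu)*phi), logit(mu) = X b + u[mouse] + v[mouse-block]``.

Priors are weakly informative: ``b ~ N(0, 100^2)``, variance components
``~ InvGamma(1e-3, 1e-3)``, ``log(phi) ~ N(3, 10^2)``.  Chains are
initialised with over-dispersed jitter; convergence is summarised by the
maximum split-R-hat over the fixed-effect coefficients (arviz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import expit, gammaln

import arviz as az

PRIOR_BETA_SD = 100.0
PRIOR_IG_A = 1e-3
PRIOR_IG_B = 1e-3


@dataclass
class SamplerSettings:
    """Chain layout. Defaults follow the reference analysis: 3 chains of
    10,000 iterations, the first half discarded as burn-in and the remainder
    thinned by keeping every 4th draw (3,750 retained draws in total)."""

    chains: int = 3
    iterations: int = 10_000
    burn_in: Optional[int] = None  # default: iterations // 2
    thin: int = 4

    @property
    def n_burn(self) -> int:
        return self.iterations // 2 if self.burn_in is None else self.burn_in

    @property
    def n_draws(self) -> int:
        return self.chains * ((self.iterations - self.n_burn) // self.thin)


#: reduced preset for desk-scale runs and the test-suite
REDUCED = SamplerSettings(chains=2, iterations=2_000)
#: tiny preset for smoke tests
TINY = SamplerSettings(chains=1, iterations=400)
FULL = SamplerSettings()


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws, concatenated across chains."""

    beta: np.ndarray           # (n_draws, p)
    sigma2: np.ndarray         # residual variance (gaussian) -- (n_draws,)
    phi: np.ndarray            # beta-family precision -- (n_draws,)
    sigma2_mouse: np.ndarray
    sigma2_cell: np.ndarray
    chains: int = 1
    rhat_max: float = np.nan

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]


def _rhat_max(chain_draws: List[np.ndarray]) -> float:
    """Max split-R-hat across coefficients (NaN for a single short chain)."""
    arr = np.stack(chain_draws)  # (chain, draw, p)
    if arr.shape[0] < 2:
        return np.nan
    r = az.rhat(az.convert_to_dataset(arr))
    return float(np.nanmax(r.to_array().values))


def gibbs_gaussian(
    y: np.ndarray,
    X: np.ndarray,
    mouse_idx: np.ndarray,
    cell_idx: np.ndarray,
    settings: SamplerSettings = REDUCED,
    seed: int = 0,
) -> PosteriorDraws:
    """Conjugate Gibbs sampler for the Gaussian mixed model."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    M = int(mouse_idx.max()) + 1
    C = int(cell_idx.max()) + 1
    XtX = X.T @ X
    n_m = np.bincount(mouse_idx, minlength=M).astype(float)
    n_c = np.bincount(cell_idx, minlength=C).astype(float)

    keep = []
    chain_betas = []
    s2_keep, s2m_keep, s2c_keep = [], [], []
    for chain in range(settings.chains):
        rng = np.random.default_rng((seed, chain))
        # over-dispersed start around a ridge fit
        beta = np.linalg.solve(XtX + np.eye(p), X.T @ y)
        beta = beta + rng.normal(0, 0.05 + 0.05 * chain, p)
        u = np.zeros(M)
        v = np.zeros(C)
        s2, s2m, s2c = float(np.var(y)) or 1.0, 0.01, 0.01
        this_chain = []
        for it in range(settings.iterations):
            # fixed effects
            r = y - u[mouse_idx] - v[cell_idx]
            A = XtX / s2 + np.eye(p) / PRIOR_BETA_SD**2
            L = cholesky(A, lower=True)
            mean = cho_solve((L, True), X.T @ r / s2)
            beta = mean + solve_triangular(L.T, rng.standard_normal(p), lower=False)
            resid_f = y - X @ beta
            # mouse intercepts
            prec_u = n_m / s2 + 1.0 / s2m
            mean_u = np.bincount(mouse_idx, weights=resid_f - v[cell_idx], minlength=M) / s2 / prec_u
            u = mean_u + rng.standard_normal(M) / np.sqrt(prec_u)
            # mouse-block intercepts
            prec_v = n_c / s2 + 1.0 / s2c
            mean_v = np.bincount(cell_idx, weights=resid_f - u[mouse_idx], minlength=C) / s2 / prec_v
            v = mean_v + rng.standard_normal(C) / np.sqrt(prec_v)
            # variances
            resid = resid_f - u[mouse_idx] - v[cell_idx]
            s2 = 1.0 / rng.gamma(PRIOR_IG_A + n / 2, 1.0 / (PRIOR_IG_B + resid @ resid / 2))
            s2m = 1.0 / rng.gamma(PRIOR_IG_A + M / 2, 1.0 / (PRIOR_IG_B + u @ u / 2))
            s2c = 1.0 / rng.gamma(PRIOR_IG_A + C / 2, 1.0 / (PRIOR_IG_B + v @ v / 2))
            if it >= settings.n_burn and (it - settings.n_burn) % settings.thin == 0:
                this_chain.append(beta.copy())
                s2_keep.append(s2)
                s2m_keep.append(s2m)
                s2c_keep.append(s2c)
        chain_betas.append(np.array(this_chain))
        keep.extend(this_chain)
    return PosteriorDraws(
        beta=np.array(keep),
        sigma2=np.array(s2_keep),
        phi=np.full(len(keep), np.nan),
        sigma2_mouse=np.array(s2m_keep),
        sigma2_cell=np.array(s2c_keep),
        chains=settings.chains,
        rhat_max=_rhat_max(chain_betas),
    )


def _beta_loglik_rows(y_terms, eta, phi):
    """Per-row Beta log-likelihood given the linear predictor."""
    ly, l1y = y_terms
    mu = expit(eta)
    a = mu * phi
    b = (1.0 - mu) * phi
    return (a - 1.0) * ly + (b - 1.0) * l1y - (gammaln(a) + gammaln(b) - gammaln(phi))


def mwg_beta(
    y: np.ndarray,
    X: np.ndarray,
    mouse_idx: np.ndarray,
    cell_idx: np.ndarray,
    param_blocks: Sequence[Tuple[np.ndarray, np.ndarray]],
    settings: SamplerSettings = REDUCED,
    seed: int = 0,
    cov_move: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> PosteriorDraws:
    """Adaptive Metropolis-within-Gibbs for the beta mixed model.

    ``param_blocks`` lists (column indices, row indices) pairs partitioning
    the fixed-effect columns into update blocks together with the data rows
    they touch (for the cell-means circadian design each group-by-block cell
    is one such block; a global covariate column touches all rows).

    ``cov_move`` is an optional likelihood-invariant direction
    ``(s_beta, s_u)`` in (fixed effects, mouse intercepts) along which the
    linear predictor is constant; the sampler takes an exact Gaussian-prior
    Gibbs step along it each iteration.  It is used when a covariate is
    collinear with the spline span (the acclimation-profile covariate).
    """
    y = np.asarray(y, float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("beta responses must lie strictly in (0, 1); nudge first")
    X = np.asarray(X, float)
    n, p = X.shape
    M = int(mouse_idx.max()) + 1
    C = int(cell_idx.max()) + 1
    y_terms = (np.log(y), np.log1p(-y))
    mouse_of_cell = np.zeros(C, dtype=int)
    mouse_of_cell[cell_idx] = mouse_idx

    # initial values from an empirical-logit ridge fit
    e = np.log(y / (1 - y))
    beta0 = np.linalg.solve(X.T @ X + 1e-6 * np.eye(p), X.T @ e)
    mu0 = expit(X @ beta0)
    resid0 = y - mu0
    phi0 = float(np.clip(np.mean(mu0 * (1 - mu0)) / max(np.var(resid0), 1e-6) - 1.0, 5.0, 500.0))

    # blockwise proposal covariances from working-weight Fisher approximations
    prop_chol = []
    for cols, rows in param_blocks:
        Xb = X[np.ix_(rows, cols)]
        w = phi0 * mu0[rows] * (1 - mu0[rows])
        F = Xb.T @ (Xb * w[:, None]) + 1e-6 * np.eye(len(cols))
        prop_chol.append(cholesky(np.linalg.inv(F), lower=True))

    keep_beta, keep_phi, keep_s2m, keep_s2c = [], [], [], []
    chain_betas = []
    for chain in range(settings.chains):
        rng = np.random.default_rng((seed, chain, 7))
        beta = beta0 + rng.normal(0, 0.02 + 0.02 * chain, p)
        u = np.zeros(M)
        v = np.zeros(C)
        logphi = np.log(phi0) + rng.normal(0, 0.1)
        s2m, s2c = 0.05, 0.05
        eta = X @ beta
        ll = _beta_loglik_rows(y_terms, eta, np.exp(logphi))
        log_scales = np.zeros(len(param_blocks))
        sd_u, sd_v, sd_phi = 0.1, 0.1, 0.05
        this_chain = []
        for it in range(settings.iterations):
            phi = np.exp(logphi)
            adapt = it < settings.n_burn
            gamma_t = 1.0 / np.sqrt(1 + it) if adapt else 0.0
            # fixed-effect blocks
            for j, (cols, rows) in enumerate(param_blocks):
                z = rng.standard_normal(len(cols))
                step = np.exp(log_scales[j]) * (prop_chol[j] @ z)
                eta_new = eta[rows] + X[np.ix_(rows, cols)] @ step
                ll_new = _beta_loglik_rows((y_terms[0][rows], y_terms[1][rows]), eta_new, phi)
                dprior = -0.5 * ((beta[cols] + step) @ (beta[cols] + step) - beta[cols] @ beta[cols]) / PRIOR_BETA_SD**2
                log_a = ll_new.sum() - ll[rows].sum() + dprior
                acc = min(1.0, np.exp(min(log_a, 0.0)))
                if rng.random() < acc:
                    beta[cols] += step
                    eta[rows] = eta_new
                    ll[rows] = ll_new
                log_scales[j] += gamma_t * (acc - 0.25)
            # mouse intercepts (independent accept/reject per mouse)
            du = rng.normal(0, sd_u, M)
            eta_new = eta + du[mouse_idx]
            ll_new = _beta_loglik_rows(y_terms, eta_new, phi)
            d_m = np.bincount(mouse_idx, weights=ll_new - ll, minlength=M)
            d_m += -0.5 * ((u + du) ** 2 - u**2) / s2m
            acc_m = rng.random(M) < np.exp(np.minimum(d_m, 0.0))
            if acc_m.any():
                u = np.where(acc_m, u + du, u)
                rows_acc = acc_m[mouse_idx]
                eta = np.where(rows_acc, eta_new, eta)
                ll = np.where(rows_acc, ll_new, ll)
            sd_u *= np.exp(gamma_t * (acc_m.mean() - 0.35))
            # mouse-block intercepts
            dv = rng.normal(0, sd_v, C)
            eta_new = eta + dv[cell_idx]
            ll_new = _beta_loglik_rows(y_terms, eta_new, phi)
            d_c = np.bincount(cell_idx, weights=ll_new - ll, minlength=C)
            d_c += -0.5 * ((v + dv) ** 2 - v**2) / s2c
            acc_c = rng.random(C) < np.exp(np.minimum(d_c, 0.0))
            if acc_c.any():
                v = np.where(acc_c, v + dv, v)
                rows_acc = acc_c[cell_idx]
                eta = np.where(rows_acc, eta_new, eta)
                ll = np.where(rows_acc, ll_new, ll)
            sd_v *= np.exp(gamma_t * (acc_c.mean() - 0.35))
            # interweaving recentring moves: shift mass between a cell-means
            # intercept and the random intercepts it rides on (likelihood
            # invariant, exact Gaussian conditionals) -- removes the ridge
            # that defeats random-walk updates
            for j, (cols, rows) in enumerate(param_blocks):
                if len(cols) == 1:
                    continue  # global covariate block has no own intercept
                cset = np.unique(cell_idx[rows])
                prec = cset.size / s2c + 1.0 / PRIOR_BETA_SD**2
                mean = (v[cset].sum() / s2c - beta[cols[0]] / PRIOR_BETA_SD**2) / prec
                delta = mean + rng.standard_normal() / np.sqrt(prec)
                beta[cols[0]] += delta
                v[cset] -= delta
            # ... between each mouse's intercept and its block-cell intercepts
            n_cells_per_mouse = np.bincount(mouse_of_cell, minlength=M).astype(float)
            prec_m = 1.0 / s2m + n_cells_per_mouse / s2c
            sum_v = np.bincount(mouse_of_cell, weights=v, minlength=M)
            mean_m = (sum_v / s2c - u / s2m) / prec_m
            delta_m = mean_m + rng.standard_normal(M) / np.sqrt(prec_m)
            u = u + delta_m
            v = v - delta_m[mouse_of_cell]
            # ... and between the global level (all cell intercepts) and the
            # mouse-intercept mean
            icols = np.array([cols[0] for cols, _ in param_blocks if len(cols) > 1])
            prec_g = icols.size / PRIOR_BETA_SD**2 + M / s2m
            mean_g = (u.sum() / s2m - beta[icols].sum() / PRIOR_BETA_SD**2) / prec_g
            delta_g = mean_g + rng.standard_normal() / np.sqrt(prec_g)
            beta[icols] += delta_g
            u = u - delta_g
            # exact step along a supplied likelihood-invariant direction
            if cov_move is not None:
                sb, su = cov_move
                prec_c = sb @ sb / PRIOR_BETA_SD**2 + (su @ su) / s2m
                mean_c = -(beta @ sb / PRIOR_BETA_SD**2 + (u @ su) / s2m) / prec_c
                dc = mean_c + rng.standard_normal() / np.sqrt(prec_c)
                beta = beta + dc * sb
                u = u + dc * su
            # precision
            lp_new = logphi + rng.normal(0, sd_phi)
            ll_new = _beta_loglik_rows(y_terms, eta, np.exp(lp_new))
            log_a = ll_new.sum() - ll.sum() - 0.5 * ((lp_new - 3) ** 2 - (logphi - 3) ** 2) / 100.0
            acc = min(1.0, np.exp(min(log_a, 0.0)))
            if rng.random() < acc:
                logphi = lp_new
                ll = ll_new
            sd_phi *= np.exp(gamma_t * (acc - 0.44))
            # variance components (conjugate)
            s2m = 1.0 / rng.gamma(PRIOR_IG_A + M / 2, 1.0 / (PRIOR_IG_B + u @ u / 2))
            s2c = 1.0 / rng.gamma(PRIOR_IG_A + C / 2, 1.0 / (PRIOR_IG_B + v @ v / 2))
            if it >= settings.n_burn and (it - settings.n_burn) % settings.thin == 0:
                this_chain.append(beta.copy())
                keep_phi.append(np.exp(logphi))
                keep_s2m.append(s2m)
                keep_s2c.append(s2c)
        chain_betas.append(np.array(this_chain))
        keep_beta.extend(this_chain)
    return PosteriorDraws(
        beta=np.array(keep_beta),
        sigma2=np.full(len(keep_beta), np.nan),
        phi=np.array(keep_phi),
        sigma2_mouse=np.array(keep_s2m),
        sigma2_cell=np.array(keep_s2c),
        chains=settings.chains,
        rhat_max=_rhat_max(chain_betas),
    )
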