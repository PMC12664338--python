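"""Bayesian estimation of the DSEM by Metropolis-within-Gibbs sampling.

The update sweep per iteration:

1. person dynamics (phi_sb,i, beta_sb,i) and (phi_pa,i, beta_pa,i) by
   conjugate Gaussian regression of deviations on lagged deviations,
   Metropolis-corrected to target the person-mean-marginalized
   conditional (see below);
2. person means (mu_sb,i, mu_pa,i) jointly by conjugate bivariate
   Gaussian (the within equations are linear in the means), preceded by
   a collapsed draw of the mean-block regression coefficients with the
   person means integrated out;
3. log innovation variances (log_psi_sb,i, log_psi_pa,i) by adaptive
   random-walk Metropolis, step tuned toward 30-50% acceptance during
   burn-in and frozen afterwards;
4. latent deviations of missing days from their Gaussian full
   conditionals (alternating day parity so adjacent missing days are
   never updated simultaneously);
5. between level: regression coefficients (gamma0, gamma1) by conjugate
   Gaussian regression, random-effect variances tau by conjugate
   inverse-gamma, the (mu_sb, mu_pa) residual covariance by conjugate
   inverse-Wishart.

Each person's first within state carries the person-specific stationary
distribution (diffuse N(0, s0 I) fallback when a draw is non-stationary).
This term identifies the latent means in short panels — under a purely
conditional likelihood an offset in mu_i can be traded against phi_i -> 1
almost for free. The same trade-off makes plain single-site Gibbs mix
poorly at T = 7: mu_i and phi_i sit on a curved ridge. The sampler
therefore collapses the person means wherever they couple strongly:

* the dynamics update proposes from the conjugate (transition-likelihood)
  full conditional given the current means and accepts under the target
  with the person's bivariate mean integrated out analytically
  (independence Metropolis-Hastings on the collapsed conditional), after
  which the means are redrawn — jointly a valid blocked draw of
  (dynamics, means);
* the mean-block fixed effects (gamma for mu_sb, mu_pa) are drawn from
  their Gaussian conditional with all person means integrated out, then
  the person means from their exact bivariate full conditionals.

Stationarity is not enforced on person-effect draws. Priors are diffuse:
N(0, 1e6) on regression coefficients (1e8 for the min/day-scaled mean
intercepts); flat-on-SD priors on the scalar random-effect variances and
the Jeffreys prior on the person-mean covariance block (both conjugate;
inverse-gamma / inverse-Wishart variants are available through
FitConfig). The heavy-tailed IG(0.001, 0.001) family is avoided by
default because with few days per person it inflates the random-effect
spread, which leaks into the mean/autoregression trade-off.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import EFFECTS, FitConfig, PanelDataset, PosteriorDraws

_I2 = np.eye(2)
_LOG2PI = float(np.log(2.0 * np.pi))

# indices into the effect vector
_MU, _PHI, _BETA, _LAM = slice(0, 2), slice(2, 4), slice(4, 6), slice(6, 8)


def _sample_mvn_prec(prec: np.ndarray, b: np.ndarray, rng) -> np.ndarray:
    """Sample N(prec^-1 b, prec^-1) for batched 2x2 precisions.

    prec: (..., 2, 2), b: (..., 2). Uses the closed-form 2x2 inverse and
    Cholesky factor, so the whole batch is one set of array ops.
    """
    a = prec[..., 0, 0]
    c = prec[..., 0, 1]
    d = prec[..., 1, 1]
    det = a * d - c * c
    cov00 = d / det
    cov01 = -c / det
    cov11 = a / det
    mean0 = cov00 * b[..., 0] + cov01 * b[..., 1]
    mean1 = cov01 * b[..., 0] + cov11 * b[..., 1]
    l00 = np.sqrt(cov00)
    l10 = cov01 / l00
    l11 = np.sqrt(np.maximum(cov11 - l10 * l10, 1e-300))
    z = rng.standard_normal(b.shape)
    out = np.empty_like(b)
    out[..., 0] = mean0 + l00 * z[..., 0]
    out[..., 1] = mean1 + l10 * z[..., 0] + l11 * z[..., 1]
    return out


def _sample_invwishart2(scale: np.ndarray, df: float, rng) -> np.ndarray:
    """Inverse-Wishart(scale, df) draw for a 2x2 scale matrix (Bartlett)."""
    scale_inv = np.linalg.inv(scale)
    l = np.linalg.cholesky(scale_inv)
    bart = np.zeros((2, 2))
    bart[0, 0] = np.sqrt(rng.chisquare(df))
    bart[1, 1] = np.sqrt(rng.chisquare(df - 1))
    bart[1, 0] = rng.standard_normal()
    w = l @ bart
    wishart = w @ w.T
    return np.linalg.inv(wishart)


try:  # compiled kernel for the per-sweep hot spot; numpy fallback below
    from numba import njit as _njit

    @_njit(cache=False)
    def _initial_moments_nb(a, psi, s0):  # pragma: no cover - jitted
        n = a.shape[0]
        v_inv = np.empty((n, 2, 2))
        logdet = np.empty(n)
        stable = np.empty(n, np.bool_)
        for i in range(n):
            a11, a12 = a[i, 0, 0], a[i, 0, 1]
            a21, a22 = a[i, 1, 0], a[i, 1, 1]
            tr = a11 + a22
            det_a = a11 * a22 - a12 * a21
            disc = tr * tr - 4.0 * det_a
            if disc >= 0.0:
                rho = 0.5 * (abs(tr) + np.sqrt(disc))
            else:
                rho = np.sqrt(max(det_a, 0.0))
            ok = False
            v11 = s0
            v12 = 0.0
            v22 = s0
            if rho < 1.0:
                m11, m12, m13 = 1 - a11 * a11, -2 * a11 * a12, -a12 * a12
                m21, m22 = -a11 * a21, 1 - (a11 * a22 + a12 * a21)
                m23 = -a12 * a22
                m31, m32, m33 = -a21 * a21, -2 * a21 * a22, 1 - a22 * a22
                det_m = (
                    m11 * (m22 * m33 - m23 * m32)
                    - m12 * (m21 * m33 - m23 * m31)
                    + m13 * (m21 * m32 - m22 * m31)
                )
                if det_m != 0.0:
                    p1, p2 = psi[i, 0], psi[i, 1]
                    c11 = (
                        p1 * (m22 * m33 - m23 * m32)
                        + p2 * (m12 * m23 - m13 * m22)
                    ) / det_m
                    c12 = (
                        -p1 * (m21 * m33 - m23 * m31)
                        - p2 * (m11 * m23 - m13 * m21)
                    ) / det_m
                    c22 = (
                        p1 * (m21 * m32 - m22 * m31)
                        + p2 * (m11 * m22 - m12 * m21)
                    ) / det_m
                    d = c11 * c22 - c12 * c12
                    if np.isfinite(d) and d > 0.0 and np.isfinite(c11):
                        v11, v12, v22 = c11, c12, c22
                        ok = True
            det = v11 * v22 - v12 * v12
            v_inv[i, 0, 0] = v22 / det
            v_inv[i, 1, 1] = v11 / det
            v_inv[i, 0, 1] = -v12 / det
            v_inv[i, 1, 0] = -v12 / det
            logdet[i] = np.log(det)
            stable[i] = ok
        return v_inv, logdet, stable

except ImportError:  # pragma: no cover
    _initial_moments_nb = None


def _initial_moments(a: np.ndarray, psi: np.ndarray, s0: float):
    """Batched inverse and log-determinant of the initial-state covariance.

    Stationary covariance V = A V A' + diag(psi) where the lag matrix is
    stable, the diffuse fallback s0 I elsewhere.

    Returns (v_inv (N,2,2), logdet (N,), stable (N,)).
    """
    if _initial_moments_nb is not None:
        return _initial_moments_nb(
            np.ascontiguousarray(a), np.ascontiguousarray(psi), float(s0)
        )
    n = a.shape[0]
    a11, a12 = a[:, 0, 0], a[:, 0, 1]
    a21, a22 = a[:, 1, 0], a[:, 1, 1]
    # closed-form spectral radius of a real 2x2 matrix
    tr = a11 + a22
    det_a = a11 * a22 - a12 * a21
    disc = tr * tr - 4.0 * det_a
    with np.errstate(invalid="ignore"):
        rho = np.where(
            disc >= 0,
            0.5 * (np.abs(tr) + np.sqrt(np.maximum(disc, 0.0))),
            np.sqrt(np.maximum(det_a, 0.0)),
        )
    stable = rho < 1.0

    # symmetric Lyapunov reduction: 3 unknowns (v11, v12, v22) solved by
    # Cramer's rule on the 3x3 system (I - M) v = (psi1, 0, psi2)
    m11, m12, m13 = 1 - a11 * a11, -2 * a11 * a12, -a12 * a12
    m21, m22, m23 = -a11 * a21, 1 - (a11 * a22 + a12 * a21), -a12 * a22
    m31, m32, m33 = -a21 * a21, -2 * a21 * a22, 1 - a22 * a22
    det_m = (
        m11 * (m22 * m33 - m23 * m32)
        - m12 * (m21 * m33 - m23 * m31)
        + m13 * (m21 * m32 - m22 * m31)
    )
    p1, p2 = psi[..., 0], psi[..., 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        v11 = (
            p1 * (m22 * m33 - m23 * m32) - 0.0 + p2 * (m12 * m23 - m13 * m22)
        ) / det_m
        v12 = (
            -p1 * (m21 * m33 - m23 * m31) + p2 * -(m11 * m23 - m13 * m21)
        ) / det_m
        v22 = (
            p1 * (m21 * m32 - m22 * m31) + p2 * (m11 * m22 - m12 * m21)
        ) / det_m
    bad = ~stable | ~np.isfinite(v11) | ~np.isfinite(v12) | ~np.isfinite(v22)
    v11 = np.where(bad, s0, v11)
    v12 = np.where(bad, 0.0, v12)
    v22 = np.where(bad, s0, v22)
    det = v11 * v22 - v12 * v12
    v_inv = np.empty((n, 2, 2))
    v_inv[:, 0, 0] = v22 / det
    v_inv[:, 1, 1] = v11 / det
    v_inv[:, 0, 1] = v_inv[:, 1, 0] = -v12 / det
    return v_inv, np.log(det), stable & ~bad


def _initial_logpdf(
    a: np.ndarray, psi: np.ndarray, w0: np.ndarray, s0: float
) -> np.ndarray:
    """Log density of the first states under the initial-state law, (N,)."""
    v_inv, logdet, _ = _initial_moments(a, psi, s0)
    quad = np.einsum("nj,njk,nk->n", w0, v_inv, w0)
    return -0.5 * (2 * _LOG2PI + logdet + quad)


def _build_lag(u: np.ndarray) -> np.ndarray:
    a = np.empty((u.shape[0], 2, 2))
    a[:, 0, 0] = u[:, 2]
    a[:, 0, 1] = u[:, 4]
    a[:, 1, 0] = u[:, 5]
    a[:, 1, 1] = u[:, 3]
    return a


class _ChainState:
    """Mutable state of one chain, vectorized over persons."""

    def __init__(self, y, obs, c, config: FitConfig, rng):
        self.y = y
        self.obs = obs
        self.o = obs.astype(float)
        self.c = c
        self.cfg = config
        self.rng = rng
        n, t_len, _ = y.shape
        self.n, self.t_len = n, t_len

        y_filled = np.where(obs[..., None], y, 0.0)
        counts = np.maximum(obs.sum(axis=1), 1)[:, None]
        mu0 = y_filled.sum(axis=1) / counts
        self.u = np.zeros((n, 8))
        self.u[:, :2] = mu0
        dev = np.where(obs[..., None], y - mu0[:, None, :], np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-NaN slices fall back below
            var0 = np.nanvar(dev, axis=1)
        var0 = np.where(np.isfinite(var0) & (var0 > 1e-6), var0, 1.0)
        self.u[:, 6:8] = np.log(var0)

        self.w = np.where(obs[..., None], y - mu0[:, None, :], 0.0)
        self.y_filled = y_filled

        # between-level state
        self.gamma = np.zeros((8, 2))
        self.gamma[:, 0] = self.u.mean(axis=0)
        self.tau = np.maximum(self.u.var(axis=0), [100.0, 100.0] + [0.05] * 6)
        self.sigma_mu = np.array(
            [[self.tau[0], 0.0], [0.0, self.tau[1]]]
        )

        self.step = np.full((n, 2), config.step_init)
        self.acc = np.zeros((n, 2))
        self.acc_total = np.zeros((n, 2))
        self.n_after_burn = 0

        # missing-day bookkeeping, split by day parity so adjacent missing
        # days are never refreshed in the same vectorized block
        miss = np.argwhere(~obs)
        self.missing_index = miss
        self.miss_groups = [
            (miss[miss[:, 1] % 2 == p, 0], miss[miss[:, 1] % 2 == p, 1])
            for p in (0, 1)
            if (miss[:, 1] % 2 == p).any()
        ]

        self.x_between = np.column_stack([np.ones(n), c])

    # -- priors ---------------------------------------------------------

    def _prior_mean(self, idx: np.ndarray | slice) -> np.ndarray:
        """(N, k) between-level means of selected effects."""
        g = self.gamma[idx]
        return g[:, 0][None, :] + np.outer(self.c, g[:, 1])

    # -- sweep steps ----------------------------------------------------

    @property
    def _stationary_init(self) -> bool:
        return self.cfg.initial == "stationary"

    def _mu_terms(self, a: np.ndarray, psi: np.ndarray):
        """Likelihood of the data as a quadratic in the person means.

        Accumulates, for the current states and a candidate set of lag
        matrices/innovation variances, the terms of
        -2 log L(mu) = mu' prec mu - 2 b' mu + squad (+ logdetv), where the
        initial-state density contributes through V (stationary or diffuse).

        Returns (prec (N,2,2), b (N,2), squad (N,), logdetv (N,)).
        """
        psi_inv = 1.0 / psi
        o = self.o
        v = np.where(self.obs[..., None], self.y_filled, self.w)
        d = v[:, 1:] - np.einsum("njk,ntk->ntj", a, v[:, :-1])
        ct = (
            o[:, 1:, None, None] * _I2[None, None]
            - o[:, :-1, None, None] * a[:, None, :, :]
        )
        prec = np.einsum("ntaj,na,ntak->njk", ct, psi_inv, ct)
        b = np.einsum("ntaj,na,nta->nj", ct, psi_inv, d)
        squad = np.einsum("nta,na,nta->n", d, psi_inv, d)
        s0 = self.cfg.initial_state_var
        if self._stationary_init:
            v_inv, logdetv, _ = _initial_moments(a, psi, s0)
        else:
            v_inv = np.broadcast_to(_I2 / s0, (self.n, 2, 2))
            logdetv = np.full(self.n, 2.0 * np.log(s0))
        o0 = o[:, 0]
        y0 = self.y_filled[:, 0]
        first = np.where(o0[:, None] > 0, y0, self.w[:, 0])
        prec = prec + o0[:, None, None] * v_inv
        b = b + o0[:, None] * np.einsum("njk,nk->nj", v_inv, y0)
        squad = squad + np.einsum("nj,njk,nk->n", first, v_inv, first)
        return prec, b, squad, logdetv

    def _collapsed_loglik(self, a: np.ndarray, psi: np.ndarray) -> np.ndarray:
        """Log likelihood with the person means integrated out, (N,).

        Marginalizes mu_i over its between-level Gaussian prior; additive
        constants that do not depend on the dynamics are dropped.
        """
        prec, b, squad, logdetv = self._mu_terms(a, psi)
        sig_inv = np.linalg.inv(self.sigma_mu)
        m0 = self._prior_mean(_MU)
        pt = prec + sig_inv[None]
        bt = b + m0 @ sig_inv
        det = pt[:, 0, 0] * pt[:, 1, 1] - pt[:, 0, 1] * pt[:, 1, 0]
        z0 = (pt[:, 1, 1] * bt[:, 0] - pt[:, 0, 1] * bt[:, 1]) / det
        z1 = (pt[:, 0, 0] * bt[:, 1] - pt[:, 1, 0] * bt[:, 0]) / det
        quad = bt[:, 0] * z0 + bt[:, 1] * z1
        return -0.5 * (logdetv + np.log(det) + squad - quad)

    def update_dynamics(self):
        """Update (phi_j,i, beta_j,i) for both equations.

        Proposes from the conjugate full conditional of the transition
        likelihood given the current person means and accepts under the
        conditional with the means integrated out (independence MH on the
        collapsed target); the means are redrawn right after in the sweep.
        """
        w = self.w
        lag_own = w[:, :-1, :]  # (N, T-1, 2): column j is own-lag for eq j
        psi = np.exp(self.u[:, 6:8])
        psi_inv = 1.0 / psi
        s0 = self.cfg.initial_state_var
        w0 = w[:, 0, :]
        a_cur = _build_lag(self.u)
        logm_cur = (
            self._collapsed_loglik(a_cur, psi) if self.cfg.random_effects else None
        )
        for j in (0, 1):
            x = np.stack([lag_own[:, :, j], lag_own[:, :, 1 - j]], axis=2)
            r = w[:, 1:, j]
            xtx = np.einsum("nta,ntb->nab", x, x)
            xtr = np.einsum("nta,nt->na", x, r)
            phi_idx, beta_idx = 2 + j, 4 + j
            if self.cfg.random_effects:
                prior_var = np.array([self.tau[phi_idx], self.tau[beta_idx]])
                m0 = np.stack(
                    [
                        self._prior_mean([phi_idx])[:, 0],
                        self._prior_mean([beta_idx])[:, 0],
                    ],
                    axis=1,
                )
                prec_g = xtx * psi_inv[:, j, None, None]
                prec_g[:, 0, 0] += 1.0 / prior_var[0]
                prec_g[:, 1, 1] += 1.0 / prior_var[1]
                b_g = xtr * psi_inv[:, j, None] + m0 / prior_var[None, :]
                theta_prop = _sample_mvn_prec(prec_g, b_g, self.rng)
                theta_cur = self.u[:, [phi_idx, beta_idx]]
                a_prop = a_cur.copy()
                a_prop[:, j, j] = theta_prop[:, 0]
                a_prop[:, j, 1 - j] = theta_prop[:, 1]
                logm_prop = self._collapsed_loglik(a_prop, psi)

                def quad_g(th):
                    return -0.5 * np.einsum(
                        "nj,njk,nk->n", th, prec_g, th
                    ) + np.einsum("nj,nj->n", b_g, th)

                def logprior(th):
                    return -0.5 * (
                        (th[:, 0] - m0[:, 0]) ** 2 / prior_var[0]
                        + (th[:, 1] - m0[:, 1]) ** 2 / prior_var[1]
                    )

                log_alpha = (
                    logm_prop
                    - logm_cur
                    + logprior(theta_prop)
                    - logprior(theta_cur)
                    + quad_g(theta_cur)
                    - quad_g(theta_prop)
                )
                accept = np.log(self.rng.random(self.n)) < log_alpha
                self.u[accept, phi_idx] = theta_prop[accept, 0]
                self.u[accept, beta_idx] = theta_prop[accept, 1]
                a_cur[accept] = a_prop[accept]
                logm_cur = np.where(accept, logm_prop, logm_cur)
            else:
                # pooled dynamics: conjugate proposal, initial-density MH
                v0 = self.cfg.gamma_prior_var
                prec = (xtx * psi_inv[:, j, None, None]).sum(axis=0) + _I2 / v0
                b = (xtr * psi_inv[:, j, None]).sum(axis=0)
                theta = np.broadcast_to(
                    _sample_mvn_prec(prec[None], b[None], self.rng), (self.n, 2)
                )
                if self._stationary_init:
                    a_prop = a_cur.copy()
                    a_prop[:, j, j] = theta[:, 0]
                    a_prop[:, j, 1 - j] = theta[:, 1]
                    log_ratio = (
                        _initial_logpdf(a_prop, psi, w0, s0)
                        - _initial_logpdf(a_cur, psi, w0, s0)
                    ).sum()
                    ok = np.log(self.rng.random()) < log_ratio
                else:
                    ok = True
                if ok:
                    self.u[:, phi_idx] = theta[:, 0]
                    self.u[:, beta_idx] = theta[:, 1]
                    a_cur = _build_lag(self.u)
                self.gamma[phi_idx, 0] = self.u[0, phi_idx]
                self.gamma[beta_idx, 0] = self.u[0, beta_idx]

    def update_means(self):
        """Collapsed gamma-mu draw, then exact bivariate draws of the means.

        With the dynamics fixed everything is jointly Gaussian in the
        mean-block regression coefficients and the person means, so the
        coefficients are drawn from their conditional with the person
        means integrated out, then each person's (mu_sb, mu_pa) from its
        full conditional.
        """
        a = _build_lag(self.u)
        psi = np.exp(self.u[:, 6:8])
        prec, b, _, _ = self._mu_terms(a, psi)
        if self.cfg.random_effects:
            sig_inv = np.linalg.inv(self.sigma_mu)
            pt = prec + sig_inv[None]
            det = pt[:, 0, 0] * pt[:, 1, 1] - pt[:, 0, 1] * pt[:, 1, 0]
            pt_inv = np.empty_like(pt)
            pt_inv[:, 0, 0] = pt[:, 1, 1] / det
            pt_inv[:, 1, 1] = pt[:, 0, 0] / det
            pt_inv[:, 0, 1] = pt_inv[:, 1, 0] = -pt[:, 0, 1] / det
            # evidence of each mu_i as a quadratic in its prior mean:
            # m_i ~ N(mu_hat_i, Sigma + P_i^-1) with mu_hat = P^-1 b
            # (this form stays PSD where the Woodbury complement cancels)
            det_p = prec[:, 0, 0] * prec[:, 1, 1] - prec[:, 0, 1] * prec[:, 1, 0]
            p_inv = np.empty_like(prec)
            p_inv[:, 0, 0] = prec[:, 1, 1] / det_p
            p_inv[:, 1, 1] = prec[:, 0, 0] / det_p
            p_inv[:, 0, 1] = p_inv[:, 1, 0] = -prec[:, 0, 1] / det_p
            q = np.linalg.inv(self.sigma_mu[None] + p_inv)
            mu_hat = np.einsum("njk,nk->nj", p_inv, b)
            r = np.einsum("njk,nk->nj", q, mu_hat)
            x = self.x_between
            prec4 = np.einsum("nlk,na,nb->lakb", q, x, x).reshape(4, 4)
            prec4 = prec4 + np.diag(
                [
                    1.0 / self.cfg.mu_intercept_prior_var,
                    1.0 / self.cfg.gamma_prior_var,
                ]
                * 2
            )
            b4 = np.einsum("na,nl->al", x, r).flatten(order="F")
            chol = np.linalg.cholesky(prec4)
            theta = np.linalg.solve(prec4, b4) + np.linalg.solve(
                chol.T, self.rng.standard_normal(4)
            )
            bmat = theta.reshape(2, 2, order="F")
            self.gamma[0] = bmat[:, 0]
            self.gamma[1] = bmat[:, 1]
            m0 = x @ bmat
            mu = _sample_mvn_prec(pt, b + m0 @ sig_inv, self.rng)
        else:
            v_mu0 = self.cfg.mu_intercept_prior_var
            prec_pool = prec.sum(axis=0) + _I2 / v_mu0
            b_pool = b.sum(axis=0)
            mu1 = _sample_mvn_prec(prec_pool[None], b_pool[None], self.rng)[0]
            self.gamma[0, 0], self.gamma[1, 0] = mu1
            mu = np.broadcast_to(mu1[None], (self.n, 2)).copy()
        self.u[:, 0:2] = mu
        self.w = np.where(
            self.obs[..., None], self.y_filled - mu[:, None, :], self.w
        )

    def update_logvars(self, adapting: bool):
        """Adaptive random-walk Metropolis on the log innovation variances."""
        a = _build_lag(self.u)
        resid = self.w[:, 1:] - np.einsum("njk,ntk->ntj", a, self.w[:, :-1])
        sse = (resid**2).sum(axis=1)  # (N, 2)
        nt = self.t_len - 1
        s0 = self.cfg.initial_state_var
        w0 = self.w[:, 0, :]

        def init_term(lam_mat):
            if not self._stationary_init:
                return 0.0
            return _initial_logpdf(a, np.exp(lam_mat), w0, s0)

        accept_mat = np.zeros((self.n, 2), dtype=bool)
        if self.cfg.random_effects:
            m0 = self._prior_mean(_LAM)
            tau = self.tau[6:8]
            for k in (0, 1):
                lam = self.u[:, 6:8].copy()
                prop = lam.copy()
                prop[:, k] += self.step[:, k] * self.rng.standard_normal(self.n)
                logr = (
                    -0.5 * (nt * prop[:, k] + sse[:, k] * np.exp(-prop[:, k]))
                    + 0.5 * (nt * lam[:, k] + sse[:, k] * np.exp(-lam[:, k]))
                    - 0.5 * (prop[:, k] - m0[:, k]) ** 2 / tau[k]
                    + 0.5 * (lam[:, k] - m0[:, k]) ** 2 / tau[k]
                )
                logr = logr + init_term(prop) - init_term(lam)
                acc = np.log(self.rng.random(self.n)) < logr
                self.u[acc, 6 + k] = prop[acc, k]
                accept_mat[:, k] = acc
        else:
            v0 = self.cfg.gamma_prior_var
            nt_pool = self.n * nt
            sse_pool = sse.sum(axis=0)
            for k in (0, 1):
                lam = self.u[:, 6:8].copy()
                prop = lam.copy()
                prop[:, k] += self.step[0, k] * self.rng.standard_normal()
                logr = (
                    -0.5 * (nt_pool * prop[0, k] + sse_pool[k] * np.exp(-prop[0, k]))
                    + 0.5 * (nt_pool * lam[0, k] + sse_pool[k] * np.exp(-lam[0, k]))
                    - 0.5 * prop[0, k] ** 2 / v0
                    + 0.5 * lam[0, k] ** 2 / v0
                )
                init_delta = init_term(prop) - init_term(lam)
                if np.ndim(init_delta):
                    logr = logr + init_delta.sum()
                if np.log(self.rng.random()) < logr:
                    self.u[:, 6 + k] = prop[:, k]
                    self.gamma[6 + k, 0] = prop[0, k]
                    accept_mat[:, k] = True
        self.acc += accept_mat
        self.acc_total += accept_mat
        if adapting:
            self._maybe_adapt()

    _adapt_counter = 0

    def _maybe_adapt(self):
        self._adapt_counter += 1
        if self._adapt_counter % self.cfg.adapt_interval:
            return
        rate = self.acc / self.cfg.adapt_interval
        lo, hi = self.cfg.target_accept
        self.step = np.where(rate > hi, self.step * np.exp(0.2), self.step)
        self.step = np.where(rate < lo, self.step * np.exp(-0.2), self.step)
        self.acc[:] = 0.0

    def update_missing(self):
        """Gibbs refresh of latent deviations on missing days."""
        if not self.miss_groups:
            return
        a = _build_lag(self.u)
        psi_inv = np.exp(-self.u[:, 6:8])
        s0 = self.cfg.initial_state_var
        if self._stationary_init:
            v_inv_all, _, _ = _initial_moments(a, 1.0 / psi_inv, s0)
        else:
            v_inv_all = np.broadcast_to(_I2 / s0, (self.n, 2, 2))
        for ii, tt in self.miss_groups:
            ai = a[ii]  # (M, 2, 2)
            pinv = psi_inv[ii]  # (M, 2)
            prec = np.zeros((ii.size, 2, 2))
            b = np.zeros((ii.size, 2))
            has_prev = tt >= 1
            w_prev = self.w[ii, np.maximum(tt - 1, 0)]
            mean_in = np.einsum("mjk,mk->mj", ai, w_prev)
            hp = has_prev.astype(float)
            prec[:, 0, 0] += hp * pinv[:, 0]
            prec[:, 1, 1] += hp * pinv[:, 1]
            prec += (1.0 - hp)[:, None, None] * v_inv_all[ii]
            b += hp[:, None] * pinv * mean_in
            has_next = tt <= self.t_len - 2
            if has_next.any():
                w_next = self.w[ii, np.minimum(tt + 1, self.t_len - 1)]
                hn = has_next.astype(float)
                apa = np.einsum("maj,ma,mak->mjk", ai, pinv, ai)
                prec += hn[:, None, None] * apa
                b += hn[:, None] * np.einsum("maj,ma,ma->mj", ai, pinv, w_next)
            self.w[ii, tt] = _sample_mvn_prec(prec, b, self.rng)

    def _dyn_likelihood(self, j: int):
        """Per-person Gaussian transition likelihood for (phi_j, beta_j).

        Returns precision L_i (N,2,2) and linear term h_i (N,2) of
        -2 log L(theta_i) = theta' L theta - 2 h' theta + const, given the
        current states and innovation variances.
        """
        w = self.w
        x = np.stack([w[:, :-1, j], w[:, :-1, 1 - j]], axis=2)
        r = w[:, 1:, j]
        psi_inv = np.exp(-self.u[:, 6 + j])
        l_mat = np.einsum("nta,ntb->nab", x, x) * psi_inv[:, None, None]
        h = np.einsum("nta,nt->na", x, r) * psi_inv[:, None]
        return l_mat, h

    def _init_logpdf_rows(self, theta: np.ndarray, j: int) -> np.ndarray:
        """Initial-state log density with equation j's row set to theta."""
        a = _build_lag(self.u)
        a[:, j, j] = theta[:, 0]
        a[:, j, 1 - j] = theta[:, 1]
        return _initial_logpdf(
            a, np.exp(self.u[:, 6:8]), self.w[:, 0, :], self.cfg.initial_state_var
        )

    def update_dynamics_hierarchy(self):
        """Interweaving moves breaking the tau -> 0 funnel of the dynamics.

        For each equation: (a) a collapsed draw of the four regression
        coefficients with the person effects integrated out of the
        transition likelihood, followed by a redraw of the person effects;
        (b) a rescaling draw of each random-effect SD in the non-centered
        parameterization (standardized residuals held fixed). Both are
        exact Gibbs blocks of the transition-only model and are accepted
        with the ratio of initial-state densities.
        """
        if not (self.cfg.random_effects and self._stationary_init):
            return
        rng = self.rng
        x = self.x_between
        v0 = self.cfg.gamma_prior_var
        for j in (0, 1):
            phi_idx, beta_idx = 2 + j, 4 + j
            l_mat, h = self._dyn_likelihood(j)
            det_l = l_mat[:, 0, 0] * l_mat[:, 1, 1] - l_mat[:, 0, 1] * l_mat[:, 1, 0]
            det_l = np.maximum(det_l, 1e-300)
            l_inv = np.empty_like(l_mat)
            l_inv[:, 0, 0] = l_mat[:, 1, 1] / det_l
            l_inv[:, 1, 1] = l_mat[:, 0, 0] / det_l
            l_inv[:, 0, 1] = l_inv[:, 1, 0] = -l_mat[:, 0, 1] / det_l
            theta_hat = np.einsum("njk,nk->nj", l_inv, h)
            d_mat = np.diag([self.tau[phi_idx], self.tau[beta_idx]])

            # (a) gamma move, person effects collapsed
            q = np.linalg.inv(d_mat[None] + l_inv)
            r_vec = np.einsum("njk,nk->nj", q, theta_hat)
            prec4 = np.einsum("nlk,na,nb->lakb", q, x, x).reshape(4, 4)
            prec4 = prec4 + np.eye(4) / v0
            b4 = np.einsum("na,nl->al", x, r_vec).flatten(order="F")
            chol = np.linalg.cholesky(prec4)
            gamma_prop = np.linalg.solve(prec4, b4) + np.linalg.solve(
                chol.T, rng.standard_normal(4)
            )
            gmat = gamma_prop.reshape(2, 2, order="F")  # rows: int/slope
            m_prop = x @ gmat
            d_inv = np.diag(1.0 / np.maximum(np.diag(d_mat), 1e-300))
            post_prec = l_mat + d_inv[None]
            theta_prop = _sample_mvn_prec(
                post_prec, h + m_prop @ d_inv, rng
            )
            theta_cur = self.u[:, [phi_idx, beta_idx]]
            log_ratio = (
                self._init_logpdf_rows(theta_prop, j)
                - self._init_logpdf_rows(theta_cur, j)
            ).sum()
            if np.log(rng.random()) < log_ratio:
                self.gamma[phi_idx] = gmat[:, 0]
                self.gamma[beta_idx] = gmat[:, 1]
                self.u[:, phi_idx] = theta_prop[:, 0]
                self.u[:, beta_idx] = theta_prop[:, 1]

            # (b) SD rescaling in the non-centered parameterization
            for k, idx in ((0, phi_idx), (1, beta_idx)):
                m_i = self._prior_mean([idx])[:, 0]
                s_cur = np.sqrt(self.tau[idx])
                if s_cur <= 0:
                    continue
                e = (self.u[:, idx] - m_i) / s_cur
                # transition likelihood of u = m + s e is quadratic in s
                other = self.u[:, beta_idx if k == 0 else phi_idx]
                lkk = l_mat[:, k, k]
                lko = l_mat[:, k, 1 - k]
                # h_eff: linear coefficient for u_k with the other fixed
                h_eff = h[:, k] - lko * other
                a2 = float((lkk * e * e).sum())
                a1 = float((e * (h_eff - lkk * m_i)).sum())
                if a2 <= 0:
                    continue
                s_prop = a1 / a2 + rng.standard_normal() / np.sqrt(a2)
                u_prop = m_i + s_prop * e
                theta_cur = self.u[:, [phi_idx, beta_idx]]
                theta_prop = theta_cur.copy()
                theta_prop[:, k] = u_prop
                log_ratio = (
                    self._init_logpdf_rows(theta_prop, j)
                    - self._init_logpdf_rows(theta_cur, j)
                ).sum()
                if np.log(rng.random()) < log_ratio:
                    self.u[:, idx] = u_prop
                    self.tau[idx] = s_prop * s_prop

    def update_mu_cov_collapsed(self):
        """MH update of the person-mean covariance with the means collapsed.

        The conjugate inverse-Wishart draw conditions on the current means;
        when the chain sits in a high-persistence basin those are
        over-shrunk and the covariance cannot grow. Here the evidence
        p(data_i | Sigma) = N(mu_hat_i; m_i, Sigma + P_i^-1) is used
        directly (P_i, mu_hat_i from the Gaussian mean likelihood), with a
        random walk on (log tau_sb, log tau_pa, atanh rho) under the
        Jeffreys prior, after which all means are redrawn exactly.
        """
        if not (self.cfg.random_effects and self.cfg.mu_cov_prior == "jeffreys"):
            return
        rng = self.rng
        a = _build_lag(self.u)
        psi = np.exp(self.u[:, 6:8])
        prec, b, _, _ = self._mu_terms(a, psi)
        det_p = prec[:, 0, 0] * prec[:, 1, 1] - prec[:, 0, 1] * prec[:, 1, 0]
        c_mat = np.empty_like(prec)  # P^-1
        c_mat[:, 0, 0] = prec[:, 1, 1] / det_p
        c_mat[:, 1, 1] = prec[:, 0, 0] / det_p
        c_mat[:, 0, 1] = c_mat[:, 1, 0] = -prec[:, 0, 1] / det_p
        mu_hat = np.einsum("njk,nk->nj", c_mat, b)
        m0 = self._prior_mean(_MU)
        r = mu_hat - m0

        def log_target(sig):
            s = sig[None] + c_mat
            det = s[:, 0, 0] * s[:, 1, 1] - s[:, 0, 1] * s[:, 1, 0]
            quad = (
                s[:, 1, 1] * r[:, 0] ** 2
                - 2 * s[:, 0, 1] * r[:, 0] * r[:, 1]
                + s[:, 0, 0] * r[:, 1] ** 2
            ) / det
            ev = -0.5 * (np.log(det) + quad).sum()
            t1, t2 = sig[0, 0], sig[1, 1]
            rho2 = sig[0, 1] ** 2 / (t1 * t2)
            # Jeffreys prior |Sigma|^{-3/2} plus the (log, log, atanh)
            # parameterization Jacobian tau1 tau2 (1-rho^2) sqrt(tau1 tau2)
            log_prior = -1.5 * (np.log(t1) + np.log(t2) + np.log1p(-rho2))
            log_jac = 1.5 * (np.log(t1) + np.log(t2)) + np.log1p(-rho2)
            return ev + log_prior + log_jac

        sig = self.sigma_mu
        for _ in range(2):
            t1, t2 = sig[0, 0], sig[1, 1]
            rho = sig[0, 1] / np.sqrt(t1 * t2)
            coords = np.array([np.log(t1), np.log(t2), np.arctanh(np.clip(rho, -0.999, 0.999))])
            prop = coords + 0.25 * rng.standard_normal(3)
            t1p, t2p = np.exp(prop[0]), np.exp(prop[1])
            rhop = np.tanh(prop[2])
            sig_prop = np.array(
                [[t1p, rhop * np.sqrt(t1p * t2p)], [rhop * np.sqrt(t1p * t2p), t2p]]
            )
            if np.log(rng.random()) < log_target(sig_prop) - log_target(sig):
                sig = sig_prop
        if sig is not self.sigma_mu:
            self.sigma_mu = sig
            self.tau[0], self.tau[1] = sig[0, 0], sig[1, 1]
            # exact redraw of the means under the new covariance
            sig_inv = np.linalg.inv(sig)
            pt = prec + sig_inv[None]
            mu = _sample_mvn_prec(pt, b + m0 @ sig_inv, rng)
            self.u[:, 0:2] = mu
            self.w = np.where(
                self.obs[..., None], self.y_filled - mu[:, None, :], self.w
            )

    def update_logvar_hierarchy(self):
        """Interweaving moves for the log-variance random effects.

        The transition likelihood is not Gaussian in lambda, so these are
        plain Metropolis moves in the non-centered parameterization:
        a common shift of all person log variances together with their
        intercept, the same along the predictor direction with the slope,
        and a rescaling of the random-effect SD with the standardized
        residuals held fixed. Each is accepted under the exact target
        (transition + initial-state + prior terms).
        """
        if not (self.cfg.random_effects and self._stationary_init):
            return
        rng = self.rng
        a = _build_lag(self.u)
        resid = self.w[:, 1:] - np.einsum("njk,ntk->ntj", a, self.w[:, :-1])
        sse = (resid**2).sum(axis=1)  # (N, 2)
        nt = self.t_len - 1
        s0 = self.cfg.initial_state_var
        w0 = self.w[:, 0, :]
        v0 = self.cfg.gamma_prior_var

        def within(lam_mat):
            return -0.5 * (nt * lam_mat + sse * np.exp(-lam_mat)).sum(axis=0)

        for j in (0, 1):
            lam_idx = 6 + j
            for mode in ("shift0", "shift1", "scale"):
                lam = self.u[:, 6:8].copy()
                g0, g1 = self.gamma[lam_idx]
                tau = self.tau[lam_idx]
                extra = 0.0
                if mode == "shift0":
                    delta = 0.2 * rng.standard_normal()
                    lam_prop = lam.copy()
                    lam_prop[:, j] += delta
                    d_prior = -0.5 * ((g0 + delta) ** 2 - g0**2) / v0
                    new_state = ("gamma0", g0 + delta, None)
                elif mode == "shift1":
                    scale_c = max(float(np.std(self.c)), 1e-6)
                    delta = 0.2 * rng.standard_normal() / scale_c
                    lam_prop = lam.copy()
                    lam_prop[:, j] += delta * self.c
                    d_prior = -0.5 * ((g1 + delta) ** 2 - g1**2) / v0
                    new_state = ("gamma1", g1 + delta, None)
                else:
                    s_cur = np.sqrt(tau)
                    if s_cur <= 0:
                        continue
                    m_i = self._prior_mean([lam_idx])[:, 0]
                    e = (lam[:, j] - m_i) / s_cur
                    s_prop = s_cur * np.exp(0.4 * rng.standard_normal())
                    lam_prop = lam.copy()
                    lam_prop[:, j] = m_i + s_prop * e
                    d_prior = 0.0
                    extra = np.log(s_prop / s_cur)  # log-normal proposal ratio
                    new_state = ("tau", s_prop * s_prop, None)
                d_within = within(lam_prop)[j] - within(lam)[j]
                d_init = (
                    _initial_logpdf(a, np.exp(lam_prop), w0, s0)
                    - _initial_logpdf(a, np.exp(lam), w0, s0)
                ).sum()
                if np.log(rng.random()) < d_within + d_init + d_prior + extra:
                    self.u[:, lam_idx] = lam_prop[:, j]
                    kind, value, _ = new_state
                    if kind == "gamma0":
                        self.gamma[lam_idx, 0] = value
                    elif kind == "gamma1":
                        self.gamma[lam_idx, 1] = value
                    else:
                        self.tau[lam_idx] = value

    def update_persistence_ridge(self):
        """Joint MH shift along the persistence/variance ridge.

        For each series, proposes a common shift of all person
        autoregressions (and of their fixed effect) with the per-person
        log innovation variance adjusted to hold the implied marginal
        variance psi/(1-phi^2) fixed. The map is a translation in every
        coordinate (unit Jacobian), so the acceptance ratio is the exact
        target ratio. This walks the population-level trade-off between
        persistence and innovation variance that coordinate-wise updates
        cross only slowly at T = 7.
        """
        if not (self.cfg.random_effects and self._stationary_init):
            return
        rng = self.rng

        def logv(phi):
            return np.log(np.maximum(1e-3, 1.0 - np.clip(phi, -0.9995, 0.9995) ** 2))

        for j, step in ((0, 0.1), (1, 0.1), (0, 0.3), (1, 0.3)):
            phi_idx, lam_idx = 2 + j, 6 + j
            phi = self.u[:, phi_idx]
            lam = self.u[:, lam_idx]
            delta = step * rng.standard_normal()
            phi_p = phi + delta
            shift = logv(phi_p) - logv(phi)
            lam_p = lam + shift

            w = self.w
            lag_own = w[:, :-1, j]
            a_cur = _build_lag(self.u)
            resid_cur = w[:, 1:, j] - np.einsum(
                "ntk,nk->nt", w[:, :-1, :], a_cur[:, j, :]
            )
            resid_prop = resid_cur - delta * lag_own
            nt = self.t_len - 1
            sse_cur = (resid_cur**2).sum(axis=1)
            sse_prop = (resid_prop**2).sum(axis=1)
            d_within = -0.5 * (
                (nt * lam_p + sse_prop * np.exp(-lam_p))
                - (nt * lam + sse_cur * np.exp(-lam))
            ).sum()

            psi_cur = np.exp(self.u[:, 6:8])
            psi_prop = psi_cur.copy()
            psi_prop[:, j] = np.exp(lam_p)
            a_prop = a_cur.copy()
            a_prop[:, j, j] = phi_p
            s0 = self.cfg.initial_state_var
            w0 = self.w[:, 0, :]
            d_init = (
                _initial_logpdf(a_prop, psi_prop, w0, s0)
                - _initial_logpdf(a_cur, psi_cur, w0, s0)
            ).sum()

            # between level: phi residuals unchanged (gamma0 shifts along);
            # lambda residuals change by the centered shifts
            mean_shift = shift.mean()
            r_lam = lam - self._prior_mean([lam_idx])[:, 0]
            r_lam_p = r_lam + shift - mean_shift
            d_between = -0.5 * ((r_lam_p**2).sum() - (r_lam**2).sum()) / self.tau[lam_idx]

            g_phi, g_lam = self.gamma[phi_idx, 0], self.gamma[lam_idx, 0]
            d_prior = -0.5 * (
                ((g_phi + delta) ** 2 - g_phi**2)
                + ((g_lam + mean_shift) ** 2 - g_lam**2)
            ) / self.cfg.gamma_prior_var

            if np.log(rng.random()) < d_within + d_init + d_between + d_prior:
                self.u[:, phi_idx] = phi_p
                self.u[:, lam_idx] = lam_p
                self.gamma[phi_idx, 0] += delta
                self.gamma[lam_idx, 0] += mean_shift

    def update_between(self):
        """Conjugate updates of gamma, tau and the mean-block covariance."""
        if not self.cfg.random_effects:
            return
        rng = self.rng
        x = self.x_between
        xtx = x.T @ x
        v0 = self.cfg.gamma_prior_var
        # independent effects
        for j in range(2, 8):
            uj = self.u[:, j]
            prec = xtx / self.tau[j] + _I2 / v0
            b = x.T @ uj / self.tau[j]
            g = _sample_mvn_prec(prec[None], b[None], rng)[0]
            self.gamma[j] = g
            resid = uj - x @ g
            if self.cfg.tau_prior == "uniform_sd":
                shape = 0.5 * (self.n - 1)
                rate = 0.5 * float(resid @ resid) + 1e-12
            else:  # inverse_gamma
                shape = self.cfg.tau_prior_shape + 0.5 * self.n
                rate = self.cfg.tau_prior_rate + 0.5 * float(resid @ resid)
            self.tau[j] = rate / rng.gamma(shape, 1.0)
        # correlated mean block: the regression coefficients were drawn in
        # update_means (collapsed); here only the residual covariance moves
        bmat = np.stack([self.gamma[0], self.gamma[1]], axis=-1)
        resid = self.u[:, 0:2] - x @ bmat
        if self.cfg.mu_cov_prior == "jeffreys":
            scale = resid.T @ resid + 1e-8 * np.eye(2)
            df = float(self.n)
        else:  # inverse_wishart, IW(I, p+1)
            scale = np.eye(2) + resid.T @ resid
            df = 3.0 + self.n
        self.sigma_mu = _sample_invwishart2(scale, df, rng)
        self.tau[0] = self.sigma_mu[0, 0]
        self.tau[1] = self.sigma_mu[1, 1]

    # -- outputs --------------------------------------------------------

    def deviance(self) -> float:
        """Conditional deviance: -2 log p(observed days t>=2 | effects, states)."""
        a = _build_lag(self.u)
        psi = np.exp(self.u[:, 6:8])
        pred = self.u[:, None, 0:2] + np.einsum("njk,ntk->ntj", a, self.w[:, :-1])
        resid = self.y_filled[:, 1:] - pred
        ll = -0.5 * (_LOG2PI + np.log(psi[:, None, :]) + resid**2 / psi[:, None, :])
        mask = self.obs[:, 1:, None]
        return float(-2.0 * (ll * mask).sum())

    def check_finite(self, iteration: int):
        if not (np.isfinite(self.u).all() and np.isfinite(self.gamma).all()):
            raise FloatingPointError(
                f"NaN in sweep at iteration {iteration}; "
                f"gamma={self.gamma!r}, tau={self.tau!r}"
            )


def deviance_at(
    u: np.ndarray, w: np.ndarray, y: np.ndarray, obs: np.ndarray
) -> float:
    """Conditional deviance at an arbitrary configuration (for DIC)."""
    a = _build_lag(u)
    psi = np.exp(u[:, 6:8])
    y_filled = np.where(obs[..., None], y, 0.0)
    pred = u[:, None, 0:2] + np.einsum("njk,ntk->ntj", a, w[:, :-1])
    resid = y_filled[:, 1:] - pred
    ll = -0.5 * (_LOG2PI + np.log(psi[:, None, :]) + resid**2 / psi[:, None, :])
    return float(-2.0 * (ll * obs[:, 1:, None]).sum())


def fit(panel: PanelDataset, config: FitConfig) -> PosteriorDraws:
    """Run the Metropolis-within-Gibbs sampler on a panel.

    Returns thinned post-burn-in draws from ``config.n_chains`` independent
    chains (seeded by spawning from ``config.seed``; the same seed and
    config reproduce the draws exactly).
    """
    y, obs, pred = panel.to_arrays()
    c = pred - pred.mean()
    n, t_len, _ = y.shape
    if config.random_effects and n < 2:
        raise ValueError("need >= 2 persons for the hierarchical model")
    if (obs.sum(axis=1) >= 2).sum() == 0:
        raise ValueError(
            "identifiability: no person has >= 2 observed days"
        )

    n_burn, n_keep = config.n_burn, config.n_keep
    chains = []
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    n_miss = int((~obs).sum())
    missing_index = np.argwhere(~obs)

    for chain_seed in seeds:
        rng = np.random.default_rng(chain_seed)
        state = _ChainState(y, obs, c, config, rng)
        keep = {
            "gamma0": np.empty((n_keep, 8)),
            "gamma1": np.empty((n_keep, 8)),
            "tau": np.empty((n_keep, 8)),
            "sigma_mu": np.empty(n_keep),
            "person": np.empty((n_keep, n, 8)),
            "states": np.empty((n_keep, n_miss, 2)),
            "deviance": np.empty(n_keep),
        }
        k = 0
        for it in range(config.iterations):
            adapting = it < n_burn
            state.update_dynamics()
            state.update_means()
            state.update_logvars(adapting)
            state.update_missing()
            state.update_between()
            state.update_dynamics_hierarchy()
            state.update_logvar_hierarchy()
            state.update_persistence_ridge()
            state.update_mu_cov_collapsed()
            if it >= n_burn:
                state.n_after_burn += 1
                if (it - n_burn) % config.thin == config.thin - 1 and k < n_keep:
                    keep["gamma0"][k] = state.gamma[:, 0]
                    keep["gamma1"][k] = state.gamma[:, 1]
                    keep["tau"][k] = state.tau
                    keep["sigma_mu"][k] = state.sigma_mu[0, 1]
                    keep["person"][k] = state.u
                    if n_miss:
                        keep["states"][k] = state.w[~obs]
                    keep["deviance"][k] = state.deviance()
                    k += 1
            if it % 500 == 499:
                state.check_finite(it)
        for key in keep:
            keep[key] = keep[key][:k]
        keep["accept"] = state.acc_total / config.iterations
        chains.append(keep)

    k_min = min(ch["gamma0"].shape[0] for ch in chains)
    stack = lambda key: np.stack([ch[key][:k_min] for ch in chains])
    return PosteriorDraws(
        gamma0=stack("gamma0"),
        gamma1=stack("gamma1"),
        tau=stack("tau"),
        sigma_mu=stack("sigma_mu"),
        person=stack("person"),
        states=stack("states"),
        missing_index=missing_index,
        deviance=stack("deviance"),
        accept_rate=np.stack([ch["accept"] for ch in chains]),
        seed=config.seed,
        config=config,
        person_ids=panel.person_ids,
    )


def psr(draws: PosteriorDraws) -> dict[str, float]:
    """Potential scale reduction per fixed effect.

    Defined as sqrt((W + B) / W) with W the mean within-chain variance and
    B the variance of the chain means, so two identical chains give exactly
    1. A single chain is split in half with a warning.
    """
    out = {}
    for name, mat in draws.fixed_effects().items():
        if mat.shape[0] < 2:
            warnings.warn("single chain: PSR computed on split halves", stacklevel=2)
            half = mat.shape[1] // 2
            mat = np.stack([mat[0, :half], mat[0, half : 2 * half]])
        w = mat.var(axis=1, ddof=1).mean()
        b = mat.mean(axis=1).var(ddof=1)
        out[name] = float(np.sqrt((w + b) / w)) if w > 0 else (1.0 if b == 0 else np.inf)
    return out


def dic(draws: PosteriorDraws, panel: PanelDataset) -> tuple[float, float]:
    """Conditional DIC and effective parameter count pD.

    D(theta) is the conditional deviance given person effects and latent
    states; DIC = Dbar + pD with pD = Dbar - D(theta_hat), theta_hat the
    posterior mean of person effects and states.
    """
    if draws.n_draws == 0:
        raise ValueError("empty draws")
    y, obs, _ = panel.to_arrays()
    dbar = float(draws.deviance.mean())
    u_hat = draws.person.mean(axis=(0, 1))
    w_hat = np.where(obs[..., None], y - u_hat[:, None, 0:2], 0.0)
    if draws.missing_index.size:
        states_hat = draws.states.mean(axis=(0, 1))
        w_hat[draws.missing_index[:, 0], draws.missing_index[:, 1]] = states_hat
    d_hat = deviance_at(u_hat, w_hat, y, obs)
    pd_val = dbar - d_hat
    return dbar + pd_val, pd_val


__all__ = ["fit", "psr", "dic", "deviance_at", "FitConfig", "PosteriorDraws", "EFFECTS"]
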