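"""Generative and likelihood core of the bivariate multilevel VAR(1) DSEM.

Observed minutes decompose into a latent person mean and a within-person
deviation, SB_it = mu_sb,i + w_sb,it and PA_it = mu_pa,i + w_pa,it. The
deviations follow a person-specific first-order vector autoregression

    w_sb,t = phi_sb,i w_sb,t-1 + beta_sb,i w_pa,t-1 + zeta_sb,t
    w_pa,t = phi_pa,i w_pa,t-1 + beta_pa,i w_sb,t-1 + zeta_pa,t

with independent Gaussian innovations of variances psi = exp(log_psi).
beta_sb is the coefficient *in the SB equation* (previous-day PA -> next-day
SB). All eight person effects are random at the between level, regressed on
a grand-mean-centered person predictor; their residuals are independent
except for the (mu_sb, mu_pa) pair, which carries one covariance.
"""

from __future__ import annotations

import numpy as np

from .types import EFFECTS, DsemParams, PanelDataset, PersonEffects

_LOG2PI = float(np.log(2.0 * np.pi))


def lag_matrix(effects: np.ndarray) -> np.ndarray:
    """Build person lag matrices A_i = [[phi_sb, beta_sb], [beta_pa, phi_pa]].

    ``effects`` is (..., 8) in :data:`actdsem.types.EFFECTS` order; returns
    (..., 2, 2).
    """
    effects = np.asarray(effects, dtype=float)
    a = np.empty(effects.shape[:-1] + (2, 2))
    a[..., 0, 0] = effects[..., 2]
    a[..., 0, 1] = effects[..., 4]
    a[..., 1, 0] = effects[..., 5]
    a[..., 1, 1] = effects[..., 3]
    return a


def within_equations(
    u: np.ndarray, w_prev: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional mean and (diagonal) covariance of (w_sb,t, w_pa,t).

    Parameters
    ----------
    u
        Person effects, shape (..., 8).
    w_prev
        Previous-day deviations, shape (..., 2).
    """
    u = np.asarray(u, dtype=float)
    w_prev = np.asarray(w_prev, dtype=float)
    if not (np.isfinite(u).all() and np.isfinite(w_prev).all()):
        raise ValueError("non-finite inputs to within_equations")
    a = lag_matrix(u)
    mean = np.einsum("...jk,...k->...j", a, w_prev)
    psi = np.exp(u[..., 6:8])
    cov = np.zeros(u.shape[:-1] + (2, 2))
    cov[..., 0, 0] = psi[..., 0]
    cov[..., 1, 1] = psi[..., 1]
    return mean, cov


def between_equations(
    params: DsemParams, centered_p: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and covariance of the person effects u_i given P_i.

    Returns
    -------
    mean : (N, 8) array gamma0 + gamma1 * (P_i - Pbar).
    cov : (8, 8) covariance, diagonal tau except the (mu_sb, mu_pa) block.
    """
    centered_p = np.atleast_1d(np.asarray(centered_p, dtype=float))
    if not np.isfinite(centered_p).all():
        raise ValueError("non-finite predictor values")
    mean = params.gamma0[None, :] + np.outer(centered_p, params.gamma1)
    cov = np.diag(params.tau.copy())
    cov[0, 1] = cov[1, 0] = params.sigma_mu
    if np.linalg.eigvalsh(cov[:2, :2]).min() < -1e-12:
        raise ValueError("(mu_sb, mu_pa) covariance block not PSD")
    return mean, cov


def spectral_radius(a: np.ndarray) -> np.ndarray:
    """Spectral radius of (..., 2, 2) lag matrices."""
    eig = np.linalg.eigvals(np.asarray(a, dtype=float))
    return np.abs(eig).max(axis=-1)


def stationary_covariance(a: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Stationary covariance V of the within process, batched.

    Solves the discrete Lyapunov equation V = A V A' + diag(psi) through the
    vectorized form (I4 - A (x) A) vec(V) = vec(Psi), which batches over
    leading axes (draws x persons) in one call.

    Parameters
    ----------
    a
        Lag matrices, shape (..., 2, 2); spectral radius must be < 1.
    psi
        Innovation variances (psi_sb, psi_pa), shape (..., 2).

    Raises
    ------
    ValueError
        If any system is non-stationary (use :func:`spectral_radius` to
        screen and report such draws as undefined instead).
    """
    a = np.asarray(a, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if (spectral_radius(a) >= 1.0).any():
        raise ValueError("non-stationary dynamics: spectral radius >= 1")
    kron = np.einsum("...ij,...kl->...ikjl", a, a).reshape(a.shape[:-2] + (4, 4))
    eye = np.eye(4)
    rhs = np.zeros(a.shape[:-2] + (4,))
    rhs[..., 0] = psi[..., 0]
    rhs[..., 3] = psi[..., 1]
    vec_v = np.linalg.solve(eye - kron, rhs[..., None])[..., 0]
    return vec_v.reshape(a.shape[:-2] + (2, 2))


def _gauss_logpdf(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    return -0.5 * (_LOG2PI + np.log(var) + (x - mean) ** 2 / var)


def _mvn_logpdf2(x: np.ndarray, cov: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError("covariance not positive definite")
    quad = float(x @ np.linalg.solve(cov, x))
    return -0.5 * (2 * _LOG2PI + logdet + quad)


def joint_log_density(
    params: DsemParams,
    effects: PersonEffects,
    states: np.ndarray,
    obs: np.ndarray,
    centered_p: np.ndarray,
    initial: str = "stationary",
    diffuse_var: float = 1e6,
) -> float:
    """Log density of the full hierarchical model at one configuration.

    Parameters
    ----------
    effects
        Person effects u_i, (N, 8).
    states
        Complete within-deviation paths w_it, (N, T, 2): observed-day
        deviations plus sampled values for missing days.
    obs
        (N, T) observation mask (used only for error reporting; the joint
        density treats missing-day states as latent variables).
    centered_p
        Centered predictor values, (N,).
    initial
        "stationary" gives t=1 the person-specific stationary distribution
        (diffuse fallback for non-stationary draws); "diffuse" uses a fixed
        N(0, diffuse_var I) initial — the convention the sampler targets.

    Returns the sum of within-level transition densities (t >= 2), the
    initial-state density, and the between-level density of u_i given P_i.
    """
    u = effects.values
    w = np.asarray(states, dtype=float)
    n, t_len, _ = w.shape
    if u.shape[0] != n or obs.shape != (n, t_len):
        raise ValueError("inconsistent dimensions")

    a = lag_matrix(u)
    psi = np.exp(u[:, 6:8])

    total = 0.0
    # within transitions
    if t_len >= 2:
        pred = np.einsum("njk,ntk->ntj", a, w[:, :-1, :])
        resid = w[:, 1:, :] - pred
        ll = _gauss_logpdf(resid, 0.0, psi[:, None, :])
        if not np.isfinite(ll).all():
            i, t, _ = np.argwhere(~np.isfinite(ll))[0]
            raise ValueError(f"non-finite within density for person {i}, day {t + 2}")
        total += float(ll.sum())
    # initial state
    if initial == "stationary":
        rho = spectral_radius(a)
        for i in range(n):
            if rho[i] < 1.0:
                v = stationary_covariance(a[i], psi[i])
            else:
                v = np.eye(2) * diffuse_var
            total += _mvn_logpdf2(w[i, 0], v)
    elif initial == "diffuse":
        total += float(_gauss_logpdf(w[:, 0, :], 0.0, diffuse_var).sum())
    else:
        raise ValueError(f"unknown initial convention {initial!r}")
    # between level
    mean_u, cov_u = between_equations(params, centered_p)
    resid_u = u - mean_u
    # mu block (2x2 with covariance), remaining effects independent
    mu_cov = cov_u[:2, :2]
    for i in range(n):
        total += _mvn_logpdf2(resid_u[i, :2], mu_cov)
    tau_rest = params.tau[2:]
    if (tau_rest <= 0).any():
        raise ValueError("zero between-level variance in joint density")
    ll_rest = _gauss_logpdf(resid_u[:, 2:], 0.0, tau_rest[None, :])
    total += float(ll_rest.sum())
    if not np.isfinite(total):
        raise ValueError("non-finite joint log density")
    return total


def panel_arrays(panel: PanelDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convenience: (y, obs, centered predictor) arrays of a panel."""
    y, obs, pred = panel.to_arrays()
    return y, obs, pred - pred.mean()


__all__ = [
    "EFFECTS",
    "lag_matrix",
    "within_equations",
    "between_equations",
    "spectral_radius",
    "stationary_covariance",
    "joint_log_density",
    "panel_arrays",
]
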