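"""Shared containers for the accelerometer → panel → DSEM pipeline.

The pipeline moves through three representations: epoch-level count streams
(:class:`EpochSeries`), per-day wear/SB/PA summaries (:class:`DayRecord`),
and the person × day panel with a person-level symptom predictor
(:class:`PanelDataset`) that the dynamic structural equation model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical ordering of the eight person-level random effects.
#: mu_* are latent person means (min/d), phi_* autoregressive slopes,
#: beta_* cross-lagged slopes, log_psi_* log innovation variances.
EFFECTS: tuple[str, ...] = (
    "mu_sb",
    "mu_pa",
    "phi_sb",
    "phi_pa",
    "beta_sb",
    "beta_pa",
    "log_psi_sb",
    "log_psi_pa",
)

#: Names of the person-level predictor columns carried through the panel.
PREDICTOR_COLUMNS: tuple[str, ...] = ("pain", "fatigue", "wellbeing")


class MinuteLabel(IntEnum):
    """Intensity label of one wear-protocol minute."""

    NONWEAR = 0
    SB = 1
    PA = 2


@dataclass(frozen=True)
class EpochSeries:
    """One person's equally spaced vertical-axis activity-count stream.

    Parameters
    ----------
    person_id
        Participant identifier.
    epoch_length_s
        Epoch duration in seconds; 10 (raw export) or 60 (collapsed).
    start_time
        Timestamp of the first epoch.
    counts
        Non-negative integer counts, one per epoch.
    """

    person_id: str
    epoch_length_s: int
    start_time: pd.Timestamp
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if counts.size and counts.min() < 0:
            raise ValueError("activity counts must be non-negative")
        if 60 % self.epoch_length_s != 0:
            raise ValueError("epoch_length_s must divide 60")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "start_time", pd.Timestamp(self.start_time))

    @property
    def n_epochs(self) -> int:
        return int(self.counts.size)

    def times(self) -> pd.DatetimeIndex:
        """Timestamps of every epoch."""
        step = pd.Timedelta(seconds=self.epoch_length_s)
        return pd.date_range(self.start_time, periods=self.n_epochs, freq=step)


@dataclass(frozen=True)
class DayRecord:
    """Wear-protocol summary of one person-day."""

    person_id: str
    date: pd.Timestamp
    is_weekend: bool
    wear_min: int
    sb_min: int
    pa_min: int
    valid_day: bool

    def __post_init__(self) -> None:
        if self.wear_min != self.sb_min + self.pa_min:
            raise ValueError("wear_min must equal sb_min + pa_min")
        if not 0 <= self.wear_min <= 1440:
            raise ValueError("wear_min outside [0, 1440]")


@dataclass(frozen=True)
class ParticipantValidity:
    """Inclusion decision for one participant under the wear protocol."""

    person_id: str
    n_valid_days: int
    n_valid_weekend_days: int
    included: bool

    @property
    def has_valid_weekend_day(self) -> bool:
        return self.n_valid_weekend_days >= 1


@dataclass
class PanelDataset:
    """Person × day panel of SB/PA minutes with a person-level predictor.

    ``data`` is a long DataFrame with columns person_id, day_index, date,
    is_weekend, wear_min, sb_min, pa_min, valid_day plus one column per
    predictor; sb_min/pa_min are NaN on missing (invalid or absent) days.
    ``predictor`` names the active between-person moderator column.
    """

    data: pd.DataFrame
    predictor: str = "pain"

    def __post_init__(self) -> None:
        required = {"person_id", "day_index", "sb_min", "pa_min"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        dup = self.data.duplicated(subset=["person_id", "day_index"])
        if dup.any():
            row = self.data[dup].iloc[0]
            raise ValueError(
                f"duplicate (person_id, day_index): ({row['person_id']}, {row['day_index']})"
            )
        if self.predictor not in self.data.columns:
            raise ValueError(f"predictor column {self.predictor!r} not in panel")
        p = self.data.groupby("person_id", sort=False)[self.predictor].nunique(dropna=False)
        if (p > 1).any():
            raise ValueError("predictor must be constant within person")

    # -- shape -----------------------------------------------------------

    @property
    def person_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["person_id"]))

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def n_days(self) -> int:
        return int(self.data["day_index"].max())

    def select_predictor(self, name: str) -> "PanelDataset":
        """Return a view of the panel with a different active predictor."""
        return PanelDataset(data=self.data, predictor=name)

    # -- model-facing arrays --------------------------------------------

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Wide arrays for the sampler.

        Returns
        -------
        y : (N, T, 2) float array of (SB, PA) minutes, NaN where missing.
        obs : (N, T) boolean observation mask.
        pred : (N,) raw predictor values.
        """
        ids = self.person_ids
        n, t = len(ids), self.n_days
        y = np.full((n, t, 2), np.nan)
        pred = np.full(n, np.nan)
        index = {pid: k for k, pid in enumerate(ids)}
        for _, row in self.data.iterrows():
            i = index[row["person_id"]]
            d = int(row["day_index"]) - 1
            y[i, d, 0] = row["sb_min"]
            y[i, d, 1] = row["pa_min"]
            pred[i] = row[self.predictor]
        obs = ~np.isnan(y).any(axis=2)
        if np.isnan(pred).any():
            raise ValueError("every person needs a predictor value")
        return y, obs, pred

    def centered_predictor(self) -> np.ndarray:
        """Grand-mean-centered predictor, one value per person."""
        _, _, pred = self.to_arrays()
        return pred - pred.mean()


@dataclass(frozen=True)
class DsemParams:
    """Population-level parameters of the DSEM.

    For each of the eight random effects u (ordered as :data:`EFFECTS`):
    ``gamma0[u]`` is the between-level intercept, ``gamma1[u]`` the slope on
    the centered predictor, and ``tau[u]`` the residual variance of the
    random effect. ``sigma_mu`` is the residual covariance between the two
    person means (the only off-diagonal the model carries).
    """

    gamma0: np.ndarray  # (8,)
    gamma1: np.ndarray  # (8,)
    tau: np.ndarray  # (8,) residual variances, >= 0
    sigma_mu: float  # cov(mu_sb, mu_pa) residuals

    def __post_init__(self) -> None:
        for name in ("gamma0", "gamma1", "tau"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (8,):
                raise ValueError(f"{name} must have shape (8,)")
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite values in {name}")
            object.__setattr__(self, name, arr)
        if (self.tau < 0).any():
            raise ValueError("random-effect variances must be >= 0")
        block = self.mu_cov()
        if np.linalg.eigvalsh(block).min() < -1e-12:
            raise ValueError("(mu_sb, mu_pa) covariance block not PSD")

    def mu_cov(self) -> np.ndarray:
        """2x2 covariance of the (mu_sb, mu_pa) random-effect residuals."""
        return np.array(
            [[self.tau[0], self.sigma_mu], [self.sigma_mu, self.tau[1]]]
        )


@dataclass(frozen=True)
class PersonEffects:
    """Realized random effects for N persons: array of shape (N, 8)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 8:
            raise ValueError("values must have shape (N, 8)")
        object.__setattr__(self, "values", values)

    def __getitem__(self, effect: str) -> np.ndarray:
        return self.values[:, EFFECTS.index(effect)]

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    def lag_matrix(self) -> np.ndarray:
        """(N, 2, 2) array of person lag matrices [[phi_sb, beta_sb], [beta_pa, phi_pa]]."""
        a = np.empty((self.n_persons, 2, 2))
        a[:, 0, 0] = self["phi_sb"]
        a[:, 0, 1] = self["beta_sb"]
        a[:, 1, 0] = self["beta_pa"]
        a[:, 1, 1] = self["phi_pa"]
        return a

    def innovation_cov(self) -> np.ndarray:
        """(N, 2, 2) diagonal innovation covariances diag(psi_sb, psi_pa)."""
        psi = np.exp(self.values[:, 6:8])
        out = np.zeros((self.n_persons, 2, 2))
        out[:, 0, 0] = psi[:, 0]
        out[:, 1, 1] = psi[:, 1]
        return out


@dataclass(frozen=True)
class FitConfig:
    """MCMC settings for :func:`actdsem.fit.fit`.

    Defaults mirror the analysis protocol: 50,000 iterations thinned by 10,
    first half discarded as burn-in, two chains, diffuse priors.
    """

    iterations: int = 50_000
    thin: int = 10
    n_chains: int = 2
    burn_in_fraction: float = 0.5
    seed: int = 0
    psr_threshold: float = 1.1
    # diffuse-prior settings. Scalar random-effect variances use a flat
    # prior on the SD scale by default ("uniform_sd"); "inverse_gamma"
    # switches to IG(tau_prior_shape, tau_prior_rate). The person-mean
    # covariance block uses the Jeffreys prior by default; the
    # "inverse_wishart" alternative is IW(identity, p+1).
    gamma_prior_var: float = 1e6
    mu_intercept_prior_var: float = 1e8
    tau_prior: str = "uniform_sd"
    tau_prior_shape: float = 0.001
    tau_prior_rate: float = 0.001
    mu_cov_prior: str = "jeffreys"
    # first-state law: "stationary" (person-specific, diffuse fallback for
    # non-stationary draws) or "diffuse" (fixed N(0, initial_state_var I))
    initial: str = "stationary"
    initial_state_var: float = 1e6
    # adaptive Metropolis controls for the log-variance effects
    step_init: float = 0.5
    target_accept: tuple[float, float] = (0.3, 0.5)
    adapt_interval: int = 50
    # hierarchical structure switch: False ties person effects to the
    # between-level mean (tau -> 0), for single-cluster oracle checks
    random_effects: bool = True

    def __post_init__(self) -> None:
        if not self.iterations >= self.thin >= 1:
            raise ValueError("need iterations >= thin >= 1")
        if not 0 < self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in (0, 1)")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_burn(self) -> int:
        return int(self.iterations * self.burn_in_fraction)

    @property
    def n_keep(self) -> int:
        return (self.iterations - self.n_burn) // self.thin


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in MCMC draws.

    Arrays are indexed (chain, draw, ...). ``person`` holds the person-level
    random effects in :data:`EFFECTS` order; ``states`` the imputed latent
    deviations for missing days (chain, draw, n_missing, 2) aligned with
    ``missing_index`` (person row, day) pairs.
    """

    gamma0: np.ndarray  # (C, D, 8)
    gamma1: np.ndarray  # (C, D, 8)
    tau: np.ndarray  # (C, D, 8); mu entries are the sigma-block diagonals
    sigma_mu: np.ndarray  # (C, D)
    person: np.ndarray  # (C, D, N, 8)
    states: np.ndarray  # (C, D, M, 2)
    missing_index: np.ndarray  # (M, 2) int
    deviance: np.ndarray  # (C, D)
    accept_rate: np.ndarray  # (C, N or 1, 2)
    seed: int = 0
    config: FitConfig | None = None
    person_ids: Sequence[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.gamma0.shape[0]

    @property
    def n_draws(self) -> int:
        return self.gamma0.shape[1]

    def fixed_effect_names(self) -> list[str]:
        return [e for e in EFFECTS] + [f"{e}_on_p" for e in EFFECTS]

    def fixed_effects(self) -> dict[str, np.ndarray]:
        """Per-chain draw matrices of the 16 fixed effects, name -> (C, D)."""
        out: dict[str, np.ndarray] = {}
        for j, e in enumerate(EFFECTS):
            out[e] = self.gamma0[:, :, j]
        for j, e in enumerate(EFFECTS):
            out[f"{e}_on_p"] = self.gamma1[:, :, j]
        return out

    def stacked(self, name: str) -> np.ndarray:
        """All chains pooled for one fixed effect or variance component."""
        if name == "sigma_mu":
            return self.sigma_mu.reshape(-1)
        if name.startswith("tau_"):
            return self.tau[:, :, EFFECTS.index(name[4:])].reshape(-1)
        return self.fixed_effects()[name].reshape(-1)
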