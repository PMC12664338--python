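"""Synthetic data: epoch-level count streams and DSEM-generated panels.

Two generators stand in for the study's raw data. The epoch simulator
emits 10 s vertical-axis count streams with known per-minute wear ground
truth, for exercising the preprocessing chain. The panel simulator draws
person effects from the between-person model, iterates the within-person
VAR(1), and emits SB/PA minutes per day, so sampler recovery can be checked
against known truth.

Default panel truth emulates the study conditions: 41 persons x 7 days,
fixed effects loosely matched to the reported estimates (person means near
460/245 min/d, weak positive autoregression, negligible cross-lags, log
innovation variances near 9.1/8.1), sizeable between-person heterogeneity,
and a negatively correlated (mu_sb, mu_pa) pair. Simulated minutes are
real-valued Gaussian draws and are deliberately not truncated to [0, 1440]:
the fitted model is Gaussian and truncation would bias recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import lag_matrix, spectral_radius, stationary_covariance
from .types import EFFECTS, DsemParams, PanelDataset, PersonEffects

EPOCHS_PER_MINUTE = 6  # 10 s epochs


def study_truth() -> DsemParams:
    """Default generative truth at study scale.

    Fixed effects sit near the reported posterior medians; predictor slopes
    are zero (no moderation was detected); random-effect variances and the
    person-mean covariance are set to the reported variance estimates.
    """
    gamma0 = np.array([460.0, 245.0, 0.18, 0.05, -0.01, -0.02, 9.10, 8.12])
    gamma1 = np.zeros(8)
    tau = np.array([13600.0, 10400.0, 0.06, 0.06, 0.20, 0.01, 0.20, 1.00])
    sigma_mu = -0.56 * np.sqrt(tau[0] * tau[1])
    return DsemParams(gamma0=gamma0, gamma1=gamma1, tau=tau, sigma_mu=sigma_mu)


# ---------------------------------------------------------------------------
# epoch streams


@dataclass(frozen=True)
class EpochSimSpec:
    """Plan for one person's simulated epoch stream.

    wear_bouts[d] lists (start_min, end_min, level_cpm) half-open minute
    intervals of day d during which the device is worn at a mean intensity
    of level_cpm; nonwear_bouts[d] lists (start_min, end_min) intervals
    forced to zero. Minutes covered by no bout are non-wear (zero counts).
    """

    n_days: int
    wear_bouts: list[list[tuple[int, int, float]]]
    nonwear_bouts: list[list[tuple[int, int]]] = field(default_factory=list)
    noise_model: str = "poisson"
    seed: int = 0
    person_id: str = "sim"
    start_date: str = "2022-03-07"  # a Monday

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if len(self.wear_bouts) != self.n_days:
            raise ValueError("wear_bouts must have one list per day")
        nonwear = self.nonwear_bouts or [[] for _ in range(self.n_days)]
        if len(nonwear) != self.n_days:
            raise ValueError("nonwear_bouts must have one list per day")
        object.__setattr__(self, "nonwear_bouts", nonwear)
        if self.noise_model not in ("poisson", "constant"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        for d in range(self.n_days):
            intervals = [(s, e) for s, e, *_ in self.wear_bouts[d]] + list(
                nonwear[d]
            )
            for s, e in intervals:
                if not (0 <= s < e <= 1440):
                    raise ValueError(
                        f"day {d}: interval ({s}, {e}) outside [0, 1440)"
                    )
            for lv in (lvl for _, _, lvl in self.wear_bouts[d]):
                if lv < 0:
                    raise ValueError(f"day {d}: negative bout level")
            for k, (s1, e1) in enumerate(intervals):
                for s2, e2 in intervals[k + 1 :]:
                    if s1 < e2 and s2 < e1:
                        raise ValueError(
                            f"day {d}: overlapping bouts ({s1}, {e1}) and ({s2}, {e2})"
                        )


def simulate_epoch_stream(spec: EpochSimSpec):
    """Simulate a 10 s count stream plus ground-truth per-minute wear labels.

    Counts within a wear bout of level L cpm are Poisson(L / 6) per 10 s
    epoch ("poisson") or the constant L / 6 rounded ("constant"). Non-wear
    minutes are exactly zero.

    Returns
    -------
    series : EpochSeries (epoch_length_s=10, six epochs per minute)
    wear_truth : (n_days * 1440,) boolean ground-truth wear labels
    """
    from .types import EpochSeries  # local to avoid cycle in type hints

    rng = np.random.default_rng(spec.seed)
    n_min = spec.n_days * 1440
    level = np.zeros(n_min)
    wear_truth = np.zeros(n_min, dtype=bool)
    for d in range(spec.n_days):
        base = d * 1440
        for s, e, lvl in spec.wear_bouts[d]:
            level[base + s : base + e] = lvl
            wear_truth[base + s : base + e] = True
    per_epoch = np.repeat(level / EPOCHS_PER_MINUTE, EPOCHS_PER_MINUTE)
    if spec.noise_model == "poisson":
        counts = rng.poisson(per_epoch)
    else:
        counts = np.rint(per_epoch).astype(np.int64)
    counts[np.repeat(~wear_truth, EPOCHS_PER_MINUTE)] = 0
    series = EpochSeries(
        person_id=spec.person_id,
        epoch_length_s=10,
        start_time=pd.Timestamp(spec.start_date),
        counts=counts.astype(np.int64),
    )
    return series, wear_truth


# ---------------------------------------------------------------------------
# panels


@dataclass(frozen=True)
class PanelSimSpec:
    """Plan for a simulated person x day panel.

    predictor_dist is the (mean, SD) of the person-level symptom score on
    the 0-10 numeric rating scale; draws are clipped into [0, 10].
    """

    n_persons: int = 41
    t_days: int = 7
    truth: DsemParams = field(default_factory=study_truth)
    predictor_dist: tuple[float, float] = (1.9, 2.4)
    missing_day_prob: float = 0.0
    seed: int = 0
    predictor_name: str = "pain"
    start_date: str = "2022-03-07"

    def __post_init__(self) -> None:
        if self.n_persons < 2:
            raise ValueError("n_persons must be >= 2")
        if self.t_days < 2:
            raise ValueError("t_days must be >= 2")
        if not 0 <= self.missing_day_prob < 1:
            raise ValueError("missing_day_prob must be in [0, 1)")


def simulate_panel(spec: PanelSimSpec) -> tuple[PanelDataset, PersonEffects]:
    """Draw a panel from the generative DSEM.

    Per person: draw the predictor, draw random effects from the between
    model (rejecting non-stationary lag matrices, so every person has a
    well-defined stationary distribution), draw the initial deviation from
    that stationary distribution, iterate the within equations, and emit
    SB/PA = person mean + deviation. Days are masked missing independently
    with ``missing_day_prob``.

    Returns the panel and the realized person effects (for recovery tests).
    The number of stationarity rejections is stored on the returned panel
    as ``panel.data.attrs["n_stationarity_rejections"]``.
    """
    truth = spec.truth
    rng = np.random.default_rng(spec.seed)
    n, t_len = spec.n_persons, spec.t_days

    p_raw = np.clip(
        rng.normal(spec.predictor_dist[0], spec.predictor_dist[1], size=n), 0.0, 10.0
    )
    centered = p_raw - p_raw.mean()

    mean_u = truth.gamma0[None, :] + np.outer(centered, truth.gamma1)
    sd_rest = np.sqrt(truth.tau[2:])
    mu_chol = np.linalg.cholesky(truth.mu_cov() + 1e-12 * np.eye(2))

    u = np.empty((n, 8))
    n_reject = 0
    for i in range(n):
        while True:
            ui = np.empty(8)
            ui[:2] = mean_u[i, :2] + mu_chol @ rng.standard_normal(2)
            ui[2:] = mean_u[i, 2:] + sd_rest * rng.standard_normal(6)
            if spectral_radius(lag_matrix(ui)) < 1.0:
                u[i] = ui
                break
            n_reject += 1
    effects = PersonEffects(values=u)

    a = effects.lag_matrix()
    psi = np.exp(u[:, 6:8])
    w = np.empty((n, t_len, 2))
    for i in range(n):
        v = stationary_covariance(a[i], psi[i])
        w[i, 0] = np.linalg.cholesky(v + 1e-12 * np.eye(2)) @ rng.standard_normal(2)
    innov_sd = np.sqrt(psi)
    for t in range(1, t_len):
        shocks = innov_sd * rng.standard_normal((n, 2))
        w[:, t] = np.einsum("njk,nk->nj", a, w[:, t - 1]) + shocks

    y = u[:, None, :2] + w
    observed = rng.random((n, t_len)) >= spec.missing_day_prob

    start = pd.Timestamp(spec.start_date)
    rows = []
    for i in range(n):
        pid = f"p{i + 1:03d}"
        for t in range(t_len):
            date = start + pd.Timedelta(days=t)
            ok = observed[i, t]
            rows.append(
                {
                    "person_id": pid,
                    "day_index": t + 1,
                    "date": date,
                    "is_weekend": date.dayofweek >= 5,
                    "wear_min": y[i, t].sum() if ok else np.nan,
                    "sb_min": y[i, t, 0] if ok else np.nan,
                    "pa_min": y[i, t, 1] if ok else np.nan,
                    "valid_day": bool(ok),
                    spec.predictor_name: p_raw[i],
                }
            )
    data = pd.DataFrame(rows)
    for col in ("pain", "fatigue", "wellbeing"):
        if col not in data.columns:
            data[col] = np.nan
    data.attrs["n_stationarity_rejections"] = n_reject
    panel = PanelDataset(data=data, predictor=spec.predictor_name)
    return panel, effects


__all__ = [
    "EpochSimSpec",
    "PanelSimSpec",
    "simulate_epoch_stream",
    "simulate_panel",
    "study_truth",
    "EFFECTS",
]
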