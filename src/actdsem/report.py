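"""Posterior reporting: summaries, standardization, descriptives.

Standardization follows the model-implied convention: within-person
moments come from each person's stationary covariance (Lyapunov solution),
not from sample moments of a handful of noisy days. For a stationary draw
of person i,

    std phi_u,i   = phi_u,i                      (same stationary SD on
                                                  both sides of the lag)
    std beta_sb,i = beta_sb,i sqrt(V_pa / V_sb)
    std beta_pa,i = beta_pa,i sqrt(V_sb / V_pa)
    std zeta_u,i  = psi_u,i / V_u                (innovation share)
    R2_u,i        = 1 - std zeta_u,i

averaged across persons per draw; non-stationary person-draws are excluded
from that draw's average and the exclusion rate is reported. Between-level
effects are standardized as gamma1 SD(P) / SD(u) with SD(u)^2 =
gamma1^2 Var(P) + tau_u, and the person-mean covariance as the residual
correlation sigma_mu / sqrt(tau_musb tau_mupa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import spectral_radius, stationary_covariance
from .types import EFFECTS, PanelDataset, PosteriorDraws


@dataclass(frozen=True)
class ParamSummary:
    """Posterior summary of one reported parameter."""

    name: str
    median: float
    mean: float
    ci_low: float
    ci_high: float
    p_onetailed: float
    significant: bool

    def as_dict(self) -> dict:
        return {
            "parameter": self.name,
            "estimate": self.median,
            "mean": self.mean,
            "ci_2.5": self.ci_low,
            "ci_97.5": self.ci_high,
            "p": self.p_onetailed,
            "significant": self.significant,
        }


def summarize_posterior(values: np.ndarray, name: str = "") -> ParamSummary:
    """Median, 95% equal-tail interval, one-tailed p, significance flag.

    One-tailed p is min(share of draws below 0, share above 0); the flag is
    set when the 95% interval excludes zero.
    """
    values = np.asarray(values, dtype=float).reshape(-1)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need >= 2 draws to summarize")
    lo, hi = np.percentile(values, [2.5, 97.5])
    p = min(float((values < 0).mean()), float((values > 0).mean()))
    return ParamSummary(
        name=name,
        median=float(np.median(values)),
        mean=float(values.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        p_onetailed=p,
        significant=not (lo <= 0.0 <= hi),
    )


# ---------------------------------------------------------------------------
# standardization


_WITHIN_NAMES = (
    "phi_sb",
    "phi_pa",
    "beta_sb",
    "beta_pa",
    "zeta_sb",
    "zeta_pa",
    "r2_sb",
    "r2_pa",
)


@dataclass
class WithinStandardized:
    """Standardized within-person block, averaged across clusters."""

    summaries: dict[str, ParamSummary]
    person_means: pd.DataFrame  # posterior-mean standardized coefs per person
    coefficient_ranges: dict[str, tuple[float, float]]
    antipersistence_share: dict[str, float]  # share of persons with phi < 0
    exclusion_rate: float  # non-stationary person-draws excluded


def _person_standardized(person_draws: np.ndarray):
    """Per-draw, per-person standardized quantities.

    person_draws: (S, N, 8) in EFFECTS order. Returns dict name -> (S, N)
    with NaN where the draw is non-stationary, plus the stable mask.
    """
    s, n, _ = person_draws.shape
    a = np.empty((s, n, 2, 2))
    a[..., 0, 0] = person_draws[..., 2]
    a[..., 0, 1] = person_draws[..., 4]
    a[..., 1, 0] = person_draws[..., 5]
    a[..., 1, 1] = person_draws[..., 3]
    psi = np.exp(person_draws[..., 6:8])
    stable = spectral_radius(a) < 1.0

    v = np.full((s, n, 2, 2), np.nan)
    if stable.any():
        v[stable] = stationary_covariance(a[stable], psi[stable])
    v_sb, v_pa = v[..., 0, 0], v[..., 1, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = {
            "phi_sb": np.where(stable, person_draws[..., 2], np.nan),
            "phi_pa": np.where(stable, person_draws[..., 3], np.nan),
            "beta_sb": person_draws[..., 4] * np.sqrt(v_pa / v_sb),
            "beta_pa": person_draws[..., 5] * np.sqrt(v_sb / v_pa),
            "zeta_sb": psi[..., 0] / v_sb,
            "zeta_pa": psi[..., 1] / v_pa,
        }
        out["r2_sb"] = 1.0 - out["zeta_sb"]
        out["r2_pa"] = 1.0 - out["zeta_pa"]
    return out, stable


def standardize_within(
    draws: PosteriorDraws, panel: PanelDataset | None = None
) -> WithinStandardized:
    """Standardized within-person estimates averaged across clusters."""
    person = draws.person.reshape(-1, *draws.person.shape[2:])  # (S, N, 8)
    per, stable = _person_standardized(person)
    exclusion_rate = 1.0 - float(stable.mean())

    summaries = {}
    for name in _WITHIN_NAMES:
        per_draw_avg = np.nanmean(per[name], axis=1)  # average across clusters
        summaries[name] = summarize_posterior(per_draw_avg, name)

    person_means = pd.DataFrame(
        {name: np.nanmean(per[name], axis=0) for name in _WITHIN_NAMES[:4]},
        index=list(draws.person_ids) or range(person.shape[1]),
    )
    ranges = {
        name: (float(person_means[name].min()), float(person_means[name].max()))
        for name in _WITHIN_NAMES[:4]
    }
    anti = {
        "sb": float((person_means["phi_sb"] < 0).mean()),
        "pa": float((person_means["phi_pa"] < 0).mean()),
    }
    return WithinStandardized(
        summaries=summaries,
        person_means=person_means,
        coefficient_ranges=ranges,
        antipersistence_share=anti,
        exclusion_rate=exclusion_rate,
    )


@dataclass
class BetweenStandardized:
    """Standardized between-person block: ON-predictor effects, covariance, R2."""

    on_predictor: dict[str, ParamSummary]  # per effect
    sigma_mu_std: ParamSummary
    r2_between: dict[str, ParamSummary]  # keys "sb", "pa" (person means)


def standardize_between(
    draws: PosteriorDraws, panel: PanelDataset
) -> BetweenStandardized:
    """Standardized predictor effects on each random effect."""
    c = panel.centered_predictor()
    var_p = float(np.var(c, ddof=1))
    if var_p <= 0:
        raise ValueError("predictor variance is zero; cannot standardize")

    g1 = draws.gamma1.reshape(-1, 8)
    tau = draws.tau.reshape(-1, 8)
    sd_u2 = g1**2 * var_p + tau
    std = g1 * np.sqrt(var_p) / np.sqrt(sd_u2)
    r2 = g1**2 * var_p / sd_u2

    on_pred = {
        e: summarize_posterior(std[:, j], f"{e}_on_p") for j, e in enumerate(EFFECTS)
    }
    sig = draws.sigma_mu.reshape(-1)
    sig_std = sig / np.sqrt(tau[:, 0] * tau[:, 1])
    r2_between = {
        "sb": summarize_posterior(r2[:, 0], "r2_between_sb"),
        "pa": summarize_posterior(r2[:, 1], "r2_between_pa"),
    }
    return BetweenStandardized(
        on_predictor=on_pred,
        sigma_mu_std=summarize_posterior(sig_std, "sigma_mu_std"),
        r2_between=r2_between,
    )


# ---------------------------------------------------------------------------
# descriptives


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman correlation (average ranks for ties) with two-sided p.

    The p-value uses the t approximation on r sqrt((n-2)/(1-r^2)).
    """
    r, p = stats.spearmanr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def descriptives(panel: PanelDataset, min_persons_corr: int = 3) -> pd.DataFrame:
    """Day-wise descriptives of wear/SB/PA minutes with SB-PA correlation.

    One row per day index: across-person mean and SD of wear, SB and PA
    minutes on valid days, the SB share of wear time (both as the mean of
    person-level ratios and as the ratio of means), and the Spearman
    correlation between SB and PA across persons with its two-sided
    p-value (t approximation, average ranks for ties). Correlations need
    at least ``min_persons_corr`` persons and non-constant vectors;
    otherwise they are emitted as NaN.
    """
    rows = []
    for day, grp in panel.data.groupby("day_index", sort=True):
        valid = grp.dropna(subset=["sb_min", "pa_min"])
        row: dict = {"day_index": int(day), "n": len(valid)}
        if len(valid) == 0:
            rows.append(row)
            continue
        for col in ("wear_min", "sb_min", "pa_min"):
            row[f"{col}_mean"] = float(valid[col].mean())
            row[f"{col}_sd"] = float(valid[col].std(ddof=1)) if len(valid) > 1 else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = valid["sb_min"] / valid["wear_min"]
        row["sb_share_mean_ratio"] = float(ratios.mean())
        row["sb_share_ratio_of_means"] = float(
            valid["sb_min"].mean() / valid["wear_min"].mean()
        )
        sb = valid["sb_min"].to_numpy(float)
        pa = valid["pa_min"].to_numpy(float)
        if len(valid) >= min_persons_corr and np.ptp(sb) > 0 and np.ptp(pa) > 0:
            r, p = spearman_with_p(sb, pa)
            row["spearman_r"] = r
            row["spearman_p"] = p
        else:
            row["spearman_r"] = np.nan
            row["spearman_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# assembled reporting table


def make_summary_table(draws: PosteriorDraws, panel: PanelDataset) -> pd.DataFrame:
    """Full reporting table: unstandardized fixed effects, random-effect
    variances, standardized within (averaged across clusters) and between
    blocks, and R-squared."""
    from .fit import dic as _dic  # local import keeps module deps one-way

    rows: list[dict] = []

    def add(block: str, summary: ParamSummary):
        d = summary.as_dict()
        d["block"] = block
        rows.append(d)

    for j, e in enumerate(EFFECTS):
        add("fixed", summarize_posterior(draws.gamma0[:, :, j], e))
    for j, e in enumerate(EFFECTS):
        add("fixed", summarize_posterior(draws.gamma1[:, :, j], f"{e}_on_p_unstd"))
    for j, e in enumerate(EFFECTS):
        add("random_variance", summarize_posterior(draws.tau[:, :, j], f"tau_{e}"))
    add("random_variance", summarize_posterior(draws.sigma_mu, "sigma_mu"))

    within = standardize_within(draws, panel)
    for name in ("phi_sb", "phi_pa", "beta_sb", "beta_pa", "zeta_sb", "zeta_pa"):
        add("std_within", within.summaries[name])
    between = standardize_between(draws, panel)
    for e in EFFECTS:
        add("std_between", between.on_predictor[e])
    add("std_between", between.sigma_mu_std)
    add("r2", within.summaries["r2_sb"])
    add("r2", within.summaries["r2_pa"])
    add("r2", between.r2_between["sb"])
    add("r2", between.r2_between["pa"])

    table = pd.DataFrame(rows)
    dic_val, pd_val = _dic(draws, panel)
    table.attrs["dic"] = dic_val
    table.attrs["pd"] = pd_val
    table.attrs["within_exclusion_rate"] = within.exclusion_rate
    table.attrs["antipersistence_share"] = within.antipersistence_share
    table.attrs["coefficient_ranges"] = within.coefficient_ranges
    cols = ["block", "parameter", "estimate", "mean", "ci_2.5", "ci_97.5", "p", "significant"]
    return table[cols]


__all__ = [
    "ParamSummary",
    "WithinStandardized",
    "BetweenStandardized",
    "summarize_posterior",
    "spearman_with_p",
    "standardize_within",
    "standardize_between",
    "descriptives",
    "make_summary_table",
]
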