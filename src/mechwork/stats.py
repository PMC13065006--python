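"""Pooled correlations, agreement analysis and sensitivity utilities.

Per-player Pearson correlations between peak sprint velocity (% of the
player's maximum) and cumulative positive mechanical work are pooled
across players on the Fisher-z scale with a random-effects model:
per-player sampling variance ``1 / (n_i - 3)``, between-player variance
``tau^2`` estimated by the DerSimonian-Laird moment estimator (truncated
at zero), inverse-variance weights ``1 / (1/(n_i-3) + tau^2)``, and the
95% interval of the pooled z back-transformed through ``tanh``.

Repeated-measures Bland-Altman agreement decomposes the proxy-reference
differences into within- and between-subject variance components via
one-way random-effects ANOVA; the limits of agreement are
``bias +/- 1.96 * sqrt(sd_within^2 + sd_between^2)``, appropriate when
the true quantity genuinely varies between repeated trials.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _st

from .segmentation import PlayerSeries

__all__ = [
    "PlayerCorrelation",
    "PooledCorrelation",
    "AgreementResult",
    "player_correlation",
    "pooled_correlation",
    "magnitude_label",
    "rm_bland_altman",
    "min_detectable_r",
]

_Z95 = float(_st.norm.ppf(0.975))


@dataclass(frozen=True)
class PlayerCorrelation:
    """One player's Pearson coefficient and the cycle count behind it."""

    player_id: str
    r: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"|r| must be <= 1, got {self.r}")
        if self.n < 3:
            raise ValueError(f"player {self.player_id!r}: n={self.n} < 3 cycles")


@dataclass(frozen=True)
class PooledCorrelation:
    r_pooled: float
    ci_low: float
    ci_high: float
    tau2: float  # between-player variance on the Fisher-z scale
    n_players: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.r_pooled <= self.ci_high:
            raise ValueError("confidence interval must bracket the pooled r")
        if self.tau2 < 0:
            raise ValueError(f"tau2 must be non-negative, got {self.tau2}")


@dataclass(frozen=True)
class AgreementResult:
    """Repeated-measures Bland-Altman bias and limits of agreement (J/kg)."""

    bias: float
    loa_halfwidth: float
    sd_within: float
    sd_between: float

    def __post_init__(self) -> None:
        expected = _Z95 * float(np.hypot(self.sd_within, self.sd_between))
        if abs(self.loa_halfwidth - expected) > 1e-9:
            raise ValueError("loa_halfwidth must equal 1.96 * sqrt(sw^2 + sb^2)")


def player_correlation(
    series: PlayerSeries,
    work_variant: str = "total",
) -> PlayerCorrelation:
    """Pearson r of peak velocity (%max) against cumulative positive work."""
    if series.n_cycles < 3:
        raise ValueError(
            f"player {series.player_id!r}: need at least 3 cycles, got {series.n_cycles}"
        )
    pct = np.array([rec.peak_velocity_pct for rec in series.records])
    work = np.array(
        [rec.cumulative_work[work_variant] for rec in series.records], dtype=float
    )
    if np.any(np.isnan(work)):
        raise ValueError(
            f"player {series.player_id!r}: work variant {work_variant!r} absent"
        )
    if np.ptp(pct) == 0 or np.ptp(work) == 0:
        raise ValueError(
            f"player {series.player_id!r}: zero variance in "
            f"{'velocity' if np.ptp(pct) == 0 else 'work'}; correlation undefined"
        )
    r = float(_st.pearsonr(pct, work).statistic)
    return PlayerCorrelation(player_id=series.player_id, r=r, n=series.n_cycles)


def pooled_correlation(
    correlations: Sequence[PlayerCorrelation],
) -> PooledCorrelation:
    """Random-effects pooled Pearson correlation with a 95% CI.

    A single player's correlation is returned with its own Fisher-z
    interval; two or more are pooled with DerSimonian-Laird weights.
    """
    if not correlations:
        raise ValueError("no correlations to pool")
    for corr in correlations:
        if corr.n <= 3:
            raise ValueError(
                f"player {corr.player_id!r} has n={corr.n} <= 3; the Fisher-z "
                "weight 1/(n-3) is undefined"
            )
    z = np.array([np.arctanh(c.r) for c in correlations])
    v = np.array([1.0 / (c.n - 3) for c in correlations])
    k = z.size
    if k == 1:
        half = _Z95 * np.sqrt(v[0])
        return PooledCorrelation(
            r_pooled=float(np.tanh(z[0])),
            ci_low=float(np.tanh(z[0] - half)),
            ci_high=float(np.tanh(z[0] + half)),
            tau2=0.0,
            n_players=1,
        )
    w = 1.0 / v
    z_fixed = np.sum(w * z) / np.sum(w)
    q = float(np.sum(w * (z - z_fixed) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom)
    w_star = 1.0 / (v + tau2)
    z_pooled = float(np.sum(w_star * z) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    return PooledCorrelation(
        r_pooled=float(np.tanh(z_pooled)),
        ci_low=float(np.tanh(z_pooled - _Z95 * se)),
        ci_high=float(np.tanh(z_pooled + _Z95 * se)),
        tau2=float(tau2),
        n_players=k,
    )


def magnitude_label(r: float) -> str:
    """Magnitude of a correlation: thresholds 0.5 / 0.7 / 0.9 on |r|.

    Values strictly above a threshold earn the label; boundary values
    fall to the smaller category.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    magnitude = abs(r)
    if magnitude > 0.9:
        return "extremely large"
    if magnitude > 0.7:
        return "very large"
    if magnitude > 0.5:
        return "large"
    return "trivial-to-moderate"


def rm_bland_altman(
    paired: Mapping[str, Sequence[tuple[float, float]]],
) -> AgreementResult:
    """Repeated-measures Bland-Altman agreement of proxy vs reference work.

    ``paired`` maps subject id to that subject's trial-level
    ``(reference, proxy)`` pairs.  Differences are ``proxy - reference``;
    their variance is split into between- and within-subject components
    by one-way random-effects ANOVA (unbalanced designs use the standard
    average-group-size correction for the between component).
    """
    groups = [np.array([p - r for r, p in pairs], dtype=float)
              for pairs in paired.values() if len(pairs) > 0]
    if len(groups) < 2:
        raise ValueError("need differences from at least 2 subjects")
    counts = np.array([g.size for g in groups], dtype=float)
    total_n = counts.sum()
    k = len(groups)
    all_d = np.concatenate(groups)
    bias = float(all_d.mean())
    group_means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(counts * (group_means - bias) ** 2))
    ss_within = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, group_means)))
    if total_n - k <= 0:
        raise ValueError("no within-subject degrees of freedom")
    ms_within = ss_within / (total_n - k)
    ms_between = ss_between / (k - 1)
    n0 = (total_n - np.sum(counts**2) / total_n) / (k - 1)
    sd_within = float(np.sqrt(ms_within))
    sd_between = float(np.sqrt(max(0.0, (ms_between - ms_within) / n0)))
    total_sd = float(np.hypot(sd_within, sd_between))
    return AgreementResult(
        bias=bias,
        loa_halfwidth=_Z95 * total_sd,
        sd_within=sd_within,
        sd_between=sd_between,
    )


def min_detectable_r(n: int, alpha: float = 0.05, power: float = 0.8) -> float:
    """Smallest correlation detectable by a two-sided Fisher-z test.

    Solves ``atanh(r) * sqrt(n - 3) = z_{1-alpha/2} + z_power``; the
    closed form of the bisection stated in the contract.
    """
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    z_alpha = float(_st.norm.ppf(1 - alpha / 2))
    z_power = float(_st.norm.ppf(power))
    return float(np.tanh((z_alpha + z_power) / np.sqrt(n - 3)))
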