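"""Synthetic observers: a generative model of audiovisual threshold modulation.

Each observer has a baseline log10 contrast threshold drawn from the
population distribution, and a sound-driven modulation of that threshold
that is Gaussian-tuned over the 5 salience *bins* (not dB), peaking at an
observer-specific optimal salience s*. The in-phase (IP) and out-of-phase
(OP) sounds carry separate amplitudes; the effect direction is +1
(enhancement: sound lowers the threshold) or -1 (suppression). Trial
outcomes are Bernoulli draws from the Weibull 2AFC psychometric function
whose scale parameter is the observer's condition-specific true threshold;
reaction times are log-normal.

This module provides ground truth for recovery and calibration tests of the
analysis pipeline; it does not simulate eye movements, fatigue, or learning.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .design import DesignConfig


@dataclass
class ObserverParams:
    """Generative truth for one synthetic participant."""

    participant_id: str
    baseline_log10_threshold: float  # log10 of % contrast
    weibull_shape: float  # beta > 0
    lapse: float  # in [0, 0.05]
    optimal_salience_index: int  # s* in 1..5
    effect_direction: int  # +1 enhancement, -1 suppression
    ip_amplitude: float  # A_IP >= 0, log10-threshold units
    op_amplitude: float  # A_OP, log10-threshold units
    tuning_width_bins: float  # sigma_s > 0
    rt_location_ms: float = 500.0  # log-normal median
    rt_scale: float = 0.25  # log-normal sigma

    def __post_init__(self) -> None:
        if not 1 <= self.optimal_salience_index <= 5:
            raise ValueError("optimal_salience_index must be in 1..5")
        if self.effect_direction not in (-1, 1):
            raise ValueError("effect_direction must be +1 or -1")
        if self.weibull_shape <= 0 or self.tuning_width_bins <= 0:
            raise ValueError("shape and tuning width must be positive")
        if not 0 <= self.lapse <= 0.05:
            raise ValueError("lapse must be in [0, 0.05]")
        if self.ip_amplitude < 0:
            raise ValueError("ip_amplitude must be >= 0")


@dataclass
class SimCohortConfig:
    """Cohort-level generative settings, defaulting to the study conditions."""

    n_participants: int = 20
    baseline_mean_log10: float = -0.352
    baseline_sd_log10: float = 0.188
    p_enhancement: float = 0.5
    ip_amplitude_mean: float = 0.135
    ip_amplitude_sd: float = 0.0
    op_amplitude_mean: float = 0.0
    tuning_width_bins: float = 1.0
    lapse: float = 0.02
    weibull_shape: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.baseline_sd_log10 < 0 or self.ip_amplitude_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.p_enhancement <= 1:
            raise ValueError("p_enhancement must be in [0, 1]")


def sample_observers(config: SimCohortConfig) -> list[ObserverParams]:
    """Draw a reproducible cohort of observers from the population model."""
    rng = np.random.default_rng(config.seed)
    observers = []
    for i in range(config.n_participants):
        baseline = rng.normal(config.baseline_mean_log10, config.baseline_sd_log10)
        s_star = int(rng.integers(1, 6))
        direction = 1 if rng.random() < config.p_enhancement else -1
        a_ip = max(0.0, rng.normal(config.ip_amplitude_mean, config.ip_amplitude_sd))
        observers.append(
            ObserverParams(
                participant_id=f"S{i + 1:03d}",
                baseline_log10_threshold=float(baseline),
                weibull_shape=config.weibull_shape,
                lapse=config.lapse,
                optimal_salience_index=s_star,
                effect_direction=direction,
                ip_amplitude=float(a_ip),
                op_amplitude=config.op_amplitude_mean,
                tuning_width_bins=config.tuning_width_bins,
            )
        )
    return observers


def true_threshold(
    observer: ObserverParams, condition: str, salience_index: int | None = None
) -> float:
    """True Weibull scale (% contrast) for one condition cell.

    log10 thr(BL) = baseline; for IP/OP at salience bin s,
    log10 thr = baseline - direction * A * exp(-(s - s*)^2 / (2 sigma_s^2)).
    A positive-direction (enhancement) observer therefore has a *lower*
    threshold with the IP sound, maximally so at s = s*.
    """
    if condition == "BL":
        return float(10.0 ** observer.baseline_log10_threshold)
    if condition not in ("IP", "OP"):
        raise ValueError(f"unknown condition {condition!r}")
    if salience_index is None or not 1 <= salience_index <= 5:
        raise ValueError("salience_index must be in 1..5 for IP/OP")
    amp = observer.ip_amplitude if condition == "IP" else observer.op_amplitude
    gain = np.exp(
        -((salience_index - observer.optimal_salience_index) ** 2)
        / (2.0 * observer.tuning_width_bins**2)
    )
    log_thr = (
        observer.baseline_log10_threshold
        - observer.effect_direction * amp * gain
    )
    return float(10.0**log_thr)


def simulate_trials(
    design: pd.DataFrame,
    observer: ObserverParams,
    seed: int,
    design_config: DesignConfig | None = None,
) -> pd.DataFrame:
    """Fill a planned trial table with Bernoulli outcomes and log-normal RTs.

    Each trial is correct with probability weibull_p(contrast; alpha =
    true_threshold(condition, salience), beta, gamma = 0.5, lapse).
    """
    cfg = design_config or DesignConfig()
    sal_to_index = {s: i + 1 for i, s in enumerate(cfg.salience_levels_db)}
    df = design.copy()
    df["participant_id"] = observer.participant_id

    contrasts = df["max_contrast_pct"].to_numpy(float)
    if np.any(contrasts <= 0):
        raise ValueError("contrast must be positive")
    alphas = np.empty(len(df))
    for i, (cond, sal) in enumerate(
        zip(df["condition"].to_numpy(), df["salience_db"].to_numpy())
    ):
        s_idx = None if pd.isna(sal) else sal_to_index[float(sal)]
        alphas[i] = true_threshold(observer, cond, s_idx)
    # vectorised weibull_p with per-trial alpha
    F = 1.0 - np.exp(-((contrasts / alphas) ** observer.weibull_shape))
    p = 0.5 + (0.5 - observer.lapse) * F
    rng = np.random.default_rng(seed)
    df["correct"] = (rng.random(len(df)) < p).astype(int)
    df["rt_ms"] = np.exp(
        rng.normal(np.log(observer.rt_location_ms), observer.rt_scale, len(df))
    )
    return df


def simulate_cohort(
    config: SimCohortConfig, design_config: DesignConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trials, truth) tables.

    Every participant runs the same factorial design with an independent
    seeded trial order and independent outcome noise, all derived from
    ``config.seed``.
    """
    from .design import build_design

    cfg = design_config or DesignConfig()
    observers = sample_observers(config)
    rng = np.random.default_rng(config.seed + 1)
    frames = []
    for obs in observers:
        order_seed, outcome_seed = rng.integers(0, 2**31 - 1, size=2)
        plan = build_design(cfg, int(order_seed), participant_id=obs.participant_id)
        frames.append(simulate_trials(plan, obs, int(outcome_seed), cfg))
    trials = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame([asdict(o) for o in observers])
    return trials, truth
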