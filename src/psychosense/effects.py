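"""Difference measures, exclusions, observer grouping, and optimal-salience alignment.

For every participant we fit one psychometric function per auditory
condition cell (BL, and IP/OP at each of the 5 saliences) and derive three
difference measures per salience, on log10 scale for thresholds and raw
scale for slopes:

    BL-IP(s) = log10 thr_BL - log10 thr_IP(s)   (positive = IP benefit)
    OP-BL(s) = log10 thr_OP(s) - log10 thr_BL
    OP-IP(s) = log10 thr_OP(s) - log10 thr_IP(s)

which satisfy BL-IP + OP-BL = OP-IP identically at every salience.

The optimal salience of an observer is the bin where BL-IP is maximal; the
alignment re-indexes all three comparisons to {optimal, +/-1, +/-2} bins,
averaging when two source bins exist. Because the optimal bin is chosen as
an argmax of a noisy estimate, the aligned value at the optimal bin is
upward-biased under the null (max-statistic selection bias); see
``pipeline.selection_bias_experiment`` for the diagnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignConfig
from .psychometric import fit_psychometric

logger = logging.getLogger(__name__)

COMPARISONS = ("BL-IP", "OP-BL", "OP-IP")
BIN_LABELS = ("optimal", "pm1", "pm2")


@dataclass
class ExclusionReport:
    """One removed participant: which criterion fired and how far out."""

    participant_id: str
    criterion: str  # "baseline" or "mid_salience_blip"
    value: float
    group_mean: float
    group_sd: float
    z: float


def fit_all_cells(trials: pd.DataFrame, config: DesignConfig | None = None) -> pd.DataFrame:
    """Fit a Weibull per participant x condition x salience cell.

    Returns a tidy table of PsychFit fields; salience_db is NaN for BL.
    """
    cfg = config or DesignConfig()
    rows = []
    key = ["participant_id", "condition", "salience_db"]
    grouped = trials.groupby(key, dropna=False, sort=True)
    for (pid, cond, sal), cell in grouped:
        counts = (
            cell.groupby("max_contrast_pct")["correct"]
            .agg(["sum", "count"])
            .reset_index()
        )
        fit = fit_psychometric(
            counts["max_contrast_pct"], counts["sum"], counts["count"]
        )
        rows.append(
            {
                "participant_id": pid,
                "condition": cond,
                "salience_db": sal,
                "alpha": fit.alpha,
                "beta": fit.beta,
                "lapse": fit.lapse,
                "threshold75": fit.threshold75,
                "slope": fit.slope_at_threshold,
                "loglik": fit.loglik,
                "converged": fit.converged,
                "n_trials": fit.n_trials,
            }
        )
    return pd.DataFrame(rows)


def _fits_wide(fits: pd.DataFrame, value: str, cfg: DesignConfig):
    """Per-participant BL value and {IP,OP} x salience values; errors on gaps."""
    out = {}
    for pid, sub in fits.groupby("participant_id"):
        bl = sub[sub.condition == "BL"]
        if len(bl) != 1:
            raise ValueError(f"{pid}: expected exactly one BL fit, got {len(bl)}")
        per_cond = {}
        for cond in ("IP", "OP"):
            vals = {}
            for s in cfg.salience_levels_db:
                row = sub[(sub.condition == cond) & (np.isclose(sub.salience_db, s))]
                if len(row) != 1:
                    raise ValueError(f"{pid}: missing fit for {cond} at {s} dB")
                vals[s] = float(row[value].iloc[0])
            per_cond[cond] = vals
        out[pid] = (float(bl[value].iloc[0]), per_cond)
    return out


def threshold_differences(
    fits: pd.DataFrame, config: DesignConfig | None = None
) -> pd.DataFrame:
    """Log10-threshold difference measures per participant x comparison x salience.

    Also carries each participant's log10 BL threshold (used by the
    exclusion rule and the baseline-vs-effect correlation).
    """
    cfg = config or DesignConfig()
    wide = _fits_wide(fits, "threshold75", cfg)
    rows = []
    for pid, (thr_bl, per_cond) in wide.items():
        log_bl = np.log10(thr_bl)
        for s in cfg.salience_levels_db:
            log_ip = np.log10(per_cond["IP"][s])
            log_op = np.log10(per_cond["OP"][s])
            blip = log_bl - log_ip
            opbl = log_op - log_bl
            rows.append(
                {
                    "participant_id": pid,
                    "salience_db": s,
                    "log10_bl_threshold": log_bl,
                    "BL-IP": blip,
                    "OP-BL": opbl,
                    # sum form keeps the three-way identity exact in floats
                    "OP-IP": blip + opbl,
                }
            )
    return pd.DataFrame(rows)


def slope_differences(
    fits: pd.DataFrame, config: DesignConfig | None = None
) -> pd.DataFrame:
    """Raw slope differences, oriented like the threshold measures.

    Orientation mirrors the threshold convention: BL-IP = slope_BL -
    slope_IP, OP-BL = slope_OP - slope_BL, OP-IP = slope_OP - slope_IP.
    """
    cfg = config or DesignConfig()
    wide = _fits_wide(fits, "slope", cfg)
    rows = []
    for pid, (sl_bl, per_cond) in wide.items():
        for s in cfg.salience_levels_db:
            sl_ip = per_cond["IP"][s]
            sl_op = per_cond["OP"][s]
            blip = sl_bl - sl_ip
            opbl = sl_op - sl_bl
            rows.append(
                {
                    "participant_id": pid,
                    "salience_db": s,
                    "BL-IP": blip,
                    "OP-BL": opbl,
                    "OP-IP": blip + opbl,
                }
            )
    return pd.DataFrame(rows)


def rt_trim_and_mean(rts) -> float:
    """Mean RT after removing trials slower than mean + 2 SD.

    The rule is one-sided: only slow outliers are removed, per participant x
    condition x salience cell. With fewer than 2 RTs or zero spread nothing
    can be trimmed.
    """
    rts = np.asarray(rts, dtype=float)
    rts = rts[np.isfinite(rts)]
    if len(rts) < 2:
        raise ValueError("need >= 2 reaction times")
    cut = rts.mean() + 2.0 * rts.std(ddof=1)
    kept = rts[rts <= cut]
    return float(kept.mean())


def rt_differences(
    trials: pd.DataFrame, config: DesignConfig | None = None
) -> pd.DataFrame:
    """Trimmed-mean RT differences per comparison x salience (ms)."""
    cfg = config or DesignConfig()
    rows = []
    for pid, sub in trials.groupby("participant_id"):
        bl_rt = rt_trim_and_mean(sub[sub.condition == "BL"]["rt_ms"])
        for s in cfg.salience_levels_db:
            cell = {
                cond: rt_trim_and_mean(
                    sub[(sub.condition == cond) & (np.isclose(sub.salience_db, s))]["rt_ms"]
                )
                for cond in ("IP", "OP")
            }
            blip = bl_rt - cell["IP"]
            opbl = cell["OP"] - bl_rt
            rows.append(
                {
                    "participant_id": pid,
                    "salience_db": s,
                    "BL-IP": blip,
                    "OP-BL": opbl,
                    "OP-IP": blip + opbl,
                }
            )
    return pd.DataFrame(rows)


def exclude_participants(
    effects: pd.DataFrame, grouping_salience_db: float = 39.5
) -> tuple[pd.DataFrame, list[ExclusionReport]]:
    """Two-step outlier exclusion on cohort statistics.

    Step 1 removes participants whose log10 baseline threshold lies more
    than 2 SD from the cohort mean (mean/SD computed on the input cohort).
    Step 2 recomputes mean/SD of the mid-salience BL-IP difference on the
    survivors and removes participants more than 2 SD out. Returns the kept
    effects table and a report of each removal with its z-score.
    """
    pids = effects["participant_id"].unique()
    if len(pids) < 3:
        raise ValueError("need >= 3 participants for exclusion statistics")
    reports: list[ExclusionReport] = []

    base = effects.groupby("participant_id")["log10_bl_threshold"].first()
    mean, sd = base.mean(), base.std(ddof=1)
    step1_removed = base.index[np.abs(base - mean) > 2.0 * sd]
    for pid in step1_removed:
        reports.append(
            ExclusionReport(
                pid, "baseline", float(base[pid]), float(mean), float(sd),
                float((base[pid] - mean) / sd),
            )
        )
    kept = effects[~effects["participant_id"].isin(step1_removed)]

    mid = kept[np.isclose(kept["salience_db"], grouping_salience_db)]
    if mid.empty:
        raise ValueError(f"grouping salience {grouping_salience_db} dB not in table")
    blip = mid.set_index("participant_id")["BL-IP"]
    mean2, sd2 = blip.mean(), blip.std(ddof=1)
    step2_removed = blip.index[np.abs(blip - mean2) > 2.0 * sd2]
    for pid in step2_removed:
        reports.append(
            ExclusionReport(
                pid, "mid_salience_blip", float(blip[pid]), float(mean2),
                float(sd2), float((blip[pid] - mean2) / sd2),
            )
        )
    kept = kept[~kept["participant_id"].isin(step2_removed)]
    return kept.reset_index(drop=True), reports


def classify_groups(
    effects: pd.DataFrame, grouping_salience_db: float = 39.5
) -> pd.Series:
    """Enhancement/suppression grouping by the sign of mid-salience BL-IP.

    Positive BL-IP at the grouping salience (the in-phase sound lowered the
    threshold) -> "enhancement"; negative -> "suppression". An exact zero is
    classed as enhancement with a warning.
    """
    mid = effects[np.isclose(effects["salience_db"], grouping_salience_db)]
    if mid.empty:
        raise ValueError(f"grouping salience {grouping_salience_db} dB not in table")
    blip = mid.set_index("participant_id")["BL-IP"]
    if (blip == 0).any():
        warnings.warn(
            f"exact-zero BL-IP at grouping salience for "
            f"{list(blip.index[blip == 0])}; classed as enhancement",
            RuntimeWarning,
            stacklevel=2,
        )
    return blip.apply(lambda v: "enhancement" if v >= 0 else "suppression")


def align_to_optimal(
    effects: pd.DataFrame, config: DesignConfig | None = None
) -> pd.DataFrame:
    """Re-index each observer's difference measures to the optimal salience.

    The optimal bin is the argmax over the 5 BL-IP values (ties break to
    the lowest salience index, with a warning); the same index anchors the
    OP-BL and OP-IP alignments. Bin +/-k is the mean over existing source
    bins at distance k from the optimum, so every bin is nonempty for any
    optimal index in 1..5.
    """
    cfg = config or DesignConfig()
    order = list(cfg.salience_levels_db)
    rows = []
    for pid, sub in effects.groupby("participant_id"):
        sub = sub.set_index("salience_db").loc[order]
        blip = sub["BL-IP"].to_numpy()
        opt = int(np.argmax(blip))  # np.argmax takes first max: lowest index
        if np.sum(blip == blip.max()) > 1:
            warnings.warn(
                f"{pid}: tied BL-IP maximum; optimal bin set to lowest salience",
                RuntimeWarning,
                stacklevel=2,
            )
        row = {
            "participant_id": pid,
            "optimal_salience_index": opt + 1,
            "optimal_salience_db": order[opt],
        }
        for comp in COMPARISONS:
            vals = sub[comp].to_numpy()
            for dist, label in zip((0, 1, 2), BIN_LABELS):
                idx = [i for i in range(5) if abs(i - opt) == dist]
                row[f"{comp}_{label}"] = float(np.mean(vals[idx]))
        rows.append(row)
    return pd.DataFrame(rows)


def aligned_matrix(aligned: pd.DataFrame, comparison: str) -> np.ndarray:
    """Participants x 3 matrix (optimal, +/-1, +/-2) for one comparison."""
    cols = [f"{comparison}_{label}" for label in BIN_LABELS]
    return aligned[cols].to_numpy(float)
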