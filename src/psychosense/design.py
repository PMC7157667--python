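"""Experimental design: condition enumeration, contrast-range adaptation, trial I/O.

The experiment measures visual contrast thresholds in a 2AFC task under 11
auditory conditions — a silent baseline (BL) plus a sound whose amplitude
modulation is in-phase (IP) or out-of-phase (OP) with the visual contrast
modulation, each at 5 maximum sound levels (auditory saliences). Each
condition is tested at 5 maximum visual contrasts drawn from a 7-entry menu;
the 5-entry window is adapted per participant from a short practice block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("BL", "IP", "OP")

#: Columns of the canonical tidy trial table.
TRIAL_COLUMNS = [
    "participant_id",
    "block",
    "trial_index",
    "condition",
    "salience_db",
    "max_contrast_pct",
    "correct",
    "rt_ms",
]

_RANGE_SLICES = {"hard": slice(0, 5), "medium": slice(1, 6), "easy": slice(2, 7)}


class DesignError(ValueError):
    """Raised when a design configuration cannot be realised."""


class ValidationError(ValueError):
    """Raised when a trial table violates the design invariants."""


@dataclass
class DesignConfig:
    """Parameters defining the factorial design.

    Contrasts are percent Michelson contrast (0.16 means 0.16%); saliences
    are maximum sound levels in dB.
    """

    salience_levels_db: tuple[float, ...] = (31.5, 35.5, 39.5, 47.5, 55.0)
    contrast_menu_pct: tuple[float, ...] = (0.08, 0.16, 0.31, 0.63, 1.25, 2.5, 5.0)
    contrast_range: str = "medium"
    trials_per_cell: int = 20
    block_size: int = 110
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        if self.contrast_range not in _RANGE_SLICES:
            raise DesignError(f"unknown contrast_range {self.contrast_range!r}")
        if len(self.contrast_menu_pct) != 7:
            raise DesignError("contrast menu must list 7 values")
        if any(c <= 0 for c in self.contrast_menu_pct):
            raise DesignError("contrasts must be positive")
        if self.trials_per_cell < 1:
            raise DesignError("trials_per_cell must be >= 1")

    @property
    def active_contrasts(self) -> tuple[float, ...]:
        """The 5 consecutive menu contrasts selected by ``contrast_range``."""
        return tuple(self.contrast_menu_pct[_RANGE_SLICES[self.contrast_range]])

    @property
    def auditory_conditions(self) -> list[tuple[str, float | None]]:
        """All (condition, salience) pairs: BL plus IP/OP x each salience."""
        out: list[tuple[str, float | None]] = [("BL", None)]
        for cond in ("IP", "OP"):
            out.extend((cond, s) for s in self.salience_levels_db)
        return out

    @property
    def n_cells(self) -> int:
        return len(self.auditory_conditions) * len(self.active_contrasts)

    @property
    def n_trials(self) -> int:
        return self.n_cells * self.trials_per_cell

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrialRecord:
    """One 2AFC trial outcome (or planned trial, before outcomes exist)."""

    participant_id: str
    block: int
    trial_index: int
    condition: str
    salience_db: float | None
    max_contrast_pct: float
    correct: bool | None = None
    rt_ms: float | None = None


def build_design(
    config: DesignConfig, seed: int, participant_id: str = "P01"
) -> pd.DataFrame:
    """Enumerate and block-randomise every trial of the main experiment.

    Each (auditory condition x contrast) cell appears ``trials_per_cell``
    times overall; within every block each cell repeats exactly
    ``block_size / n_cells`` times (2 with defaults), in an order shuffled
    by ``seed``. Returns a planned trial table (``correct``/``rt_ms`` NaN).
    """
    cells = [
        (cond, sal, c)
        for cond, sal in config.auditory_conditions
        for c in config.active_contrasts
    ]
    n_cells = len(cells)
    if config.block_size % n_cells:
        raise DesignError(
            f"block_size {config.block_size} not divisible by {n_cells} cells"
        )
    repeats_per_block = config.block_size // n_cells
    if config.trials_per_cell % repeats_per_block:
        raise DesignError(
            f"trials_per_cell {config.trials_per_cell} not divisible into "
            f"blocks of {repeats_per_block} repeats"
        )
    n_blocks = config.trials_per_cell // repeats_per_block

    rng = np.random.default_rng(seed)
    rows = []
    trial_index = 0
    for block in range(1, n_blocks + 1):
        block_cells = cells * repeats_per_block
        order = rng.permutation(len(block_cells))
        for i in order:
            cond, sal, contrast = block_cells[i]
            trial_index += 1
            rows.append((participant_id, block, trial_index, cond, sal, contrast))
    df = pd.DataFrame(
        rows,
        columns=TRIAL_COLUMNS[:6],
    )
    df["correct"] = np.nan
    df["rt_ms"] = np.nan
    return df


def build_practice_design(
    config: DesignConfig, participant_id: str = "P01"
) -> pd.DataFrame:
    """30 silent practice trials: 10 each at the lowest, middle and highest
    contrast of the default (medium) range."""
    medium = tuple(config.contrast_menu_pct[_RANGE_SLICES["medium"]])
    picks = (medium[0], medium[2], medium[4])
    rows = []
    idx = 0
    for contrast in picks:
        for _ in range(10):
            idx += 1
            rows.append((participant_id, 1, idx, "BL", None, contrast))
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS[:6])
    df["correct"] = np.nan
    df["rt_ms"] = np.nan
    return df


def select_contrast_range(practice: pd.DataFrame) -> str:
    """Adapt the contrast window from practice performance.

    The window is shifted one step harder if the lowest practice contrast is
    already too easy (accuracy > 0.65, i.e. clearly above the 50% target),
    one step easier if the highest is too hard (accuracy < 0.85, below the
    90-100% target), and left at medium otherwise. If both fire, harder
    wins: an unconstrained floor is more damaging to threshold estimation.
    """
    if practice.empty:
        raise ValidationError("practice table is empty")
    acc = practice.groupby("max_contrast_pct")["correct"].mean()
    if len(acc) < 3:
        raise ValidationError(
            f"practice must cover 3 contrasts, found {len(acc)}"
        )
    if acc.isna().any():
        raise ValidationError("practice table has trials without outcomes")
    lowest, highest = acc.index.min(), acc.index.max()
    if acc[lowest] > 0.65:
        return "hard"
    if acc[highest] < 0.85:
        return "easy"
    return "medium"


def _validate_frame(df: pd.DataFrame, menu: tuple[float, ...] | None) -> None:
    for i, row in enumerate(df.itertuples(index=False)):
        if row.condition not in CONDITIONS:
            raise ValidationError(
                f"row {i + 1}: unknown condition {row.condition!r}"
            )
        has_sal = pd.notna(row.salience_db)
        if row.condition == "BL" and has_sal:
            raise ValidationError(f"row {i + 1}: BL trial carries a salience")
        if row.condition != "BL" and not has_sal:
            raise ValidationError(
                f"row {i + 1}: {row.condition} trial missing salience"
            )
        if menu is not None and not any(
            np.isclose(row.max_contrast_pct, m) for m in menu
        ):
            raise ValidationError(
                f"row {i + 1}: contrast {row.max_contrast_pct} not in menu"
            )


def read_trials(path, config: DesignConfig | None = None) -> pd.DataFrame:
    """Read and validate a tidy trial CSV.

    Validation errors name the offending row (1-based, excluding header).
    An empty file yields an empty table with a logged warning.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    if df.empty:
        logger.warning("trial file %s is empty", path)
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    menu = config.contrast_menu_pct if config is not None else None
    _validate_frame(df, menu)
    return df[TRIAL_COLUMNS]


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table as CSV; absent values serialise as empty fields."""
    df.to_csv(path, index=False, columns=[c for c in TRIAL_COLUMNS if c in df.columns])


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records], columns=TRIAL_COLUMNS)
    return df


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TrialRecord(
                participant_id=str(row.participant_id),
                block=int(row.block),
                trial_index=int(row.trial_index),
                condition=row.condition,
                salience_db=None if pd.isna(row.salience_db) else float(row.salience_db),
                max_contrast_pct=float(row.max_contrast_pct),
                correct=None if pd.isna(row.correct) else bool(row.correct),
                rt_ms=None if pd.isna(row.rt_ms) else float(row.rt_ms),
            )
        )
    return out
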