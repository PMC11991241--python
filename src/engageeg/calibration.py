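"""Per-player game-difficulty calibration from in-game metrics.

The stunt-plane game logs three per-level counts: rings collected (TC),
rings missed (TM) and obstacle hits (OH). Each metric is min-max
normalised across the ten levels and combined into a weighted
Performance Index

    PI = a_tc * TC' - a_tm * TM' - a_oh * OH'

where the adjusted weights derive from raw importance weights 5/5/2
(collected and missed items matter equally; obstacle hits measure
dexterity and matter less). Collected items reward performance; misses
and hits penalise it. The PI column is itself min-max normalised to a
0-100 scale (%PI'); the level scoring 100 is the player's *optimal*
difficulty, level 1 is *easy*, and *hard* sits four levels above
optimal (capped at the top level).

Two weight modes are provided. ``paper-rounded-4dp`` uses the adjusted
weights rounded to four decimals (0.4167 / 0.4167 / 0.1666), which is
what the published worked example is computed with; ``exact-fraction``
uses the exact fractions 5/12, 5/12, 2/12 for principled use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GameMetricsRecord",
    "WeightScheme",
    "LevelCalibration",
    "min_max_normalize",
    "performance_index",
    "calibrate_levels",
    "example_session_metrics",
]


@dataclass(frozen=True)
class GameMetricsRecord:
    """Raw in-game counts for one difficulty level of one player."""

    level: int
    tc: int  # rings collected
    tm: int  # rings missed
    oh: int  # obstacle hits

    def __post_init__(self) -> None:
        if self.tc < 0 or self.tm < 0 or self.oh < 0:
            raise ValidationError(
                f"level {self.level}: in-game counts must be >= 0, "
                f"got TC={self.tc} TM={self.tm} OH={self.oh}"
            )


@dataclass(frozen=True)
class WeightScheme:
    """Raw and adjusted metric weights for the Performance Index.

    ``rounding_mode`` selects between the published 4-decimal adjusted
    weights (``a_tc``/``a_tm``/``a_oh``, defaulting to the printed
    0.4167 / 0.4167 / 0.1666 — note 2/12 was truncated, not rounded,
    in the original datasheet, so these cannot be derived by uniform
    rounding) and exact fractions of the raw weights. The datasheet's
    worked example reproduces bit-for-bit only in paper-rounded mode.
    When supplying non-default raw weights in paper-rounded mode, pass
    matching 4-decimal ``a_*`` values as well.
    """

    w_tc: float = 5.0
    w_tm: float = 5.0
    w_oh: float = 2.0
    a_tc: float = 0.4167
    a_tm: float = 0.4167
    a_oh: float = 0.1666
    rounding_mode: str = "paper-rounded-4dp"

    _MODES = ("paper-rounded-4dp", "exact-fraction")

    def __post_init__(self) -> None:
        if min(self.w_tc, self.w_tm, self.w_oh) <= 0:
            raise ConfigurationError("raw weights must be positive")
        if self.rounding_mode not in self._MODES:
            raise ConfigurationError(
                f"rounding_mode must be one of {self._MODES}, got {self.rounding_mode!r}"
            )
        if self.rounding_mode == "paper-rounded-4dp":
            # adjusted weights must be the raw ratios to 4-decimal precision
            total = self.w_tc + self.w_tm + self.w_oh
            for name, a, w in (
                ("a_tc", self.a_tc, self.w_tc),
                ("a_tm", self.a_tm, self.w_tm),
                ("a_oh", self.a_oh, self.w_oh),
            ):
                if abs(a - w / total) > 1e-4:
                    raise ConfigurationError(
                        f"{name}={a} inconsistent with raw ratio {w / total:.6f}"
                    )

    @property
    def adjusted(self) -> tuple[float, float, float]:
        """Adjusted weights (a_tc, a_tm, a_oh) normalised by the weight sum."""
        if self.rounding_mode == "exact-fraction":
            total = self.w_tc + self.w_tm + self.w_oh
            return (self.w_tc / total, self.w_tm / total, self.w_oh / total)
        return (self.a_tc, self.a_tm, self.a_oh)

    @property
    def adjusted_fractions(self) -> tuple[Fraction, Fraction, Fraction]:
        """Exact adjusted weights as fractions (independent of rounding mode)."""
        total = Fraction(self.w_tc + self.w_tm + self.w_oh)
        return (
            Fraction(self.w_tc) / total,
            Fraction(self.w_tm) / total,
            Fraction(self.w_oh) / total,
        )


def min_max_normalize(x: float, lo: float, hi: float) -> float:
    """Map ``x`` in [lo, hi] onto [0, 1]; a degenerate range maps to 0.

    The degenerate convention keeps a single constant metric from
    poisoning the Performance Index with NaNs.
    """
    if not (lo <= x <= hi):
        raise ValidationError(f"x={x} outside [{lo}, {hi}]")
    if hi == lo:
        return 0.0
    return (x - lo) / (hi - lo)


def performance_index(
    tc_n: float, tm_n: float, oh_n: float, w: WeightScheme | None = None
) -> float:
    """Weighted Performance Index from min-max normalised metrics.

    Bounded in [-(a_tm + a_oh), a_tc]: the best possible level collects
    everything (TC' = 1) while missing and hitting nothing.
    """
    w = w or WeightScheme()
    for name, v in (("tc_n", tc_n), ("tm_n", tm_n), ("oh_n", oh_n)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name}={v} outside [0, 1]")
    a_tc, a_tm, a_oh = w.adjusted
    return a_tc * tc_n - a_tm * tm_n - a_oh * oh_n


@dataclass(frozen=True)
class LevelCalibration:
    """Calibration table plus the derived easy/optimal/hard assignment.

    ``table`` has one row per level with columns
    level, tc, tm, oh, tc_n, tm_n, oh_n, pi, pct_pi.
    """

    table: pd.DataFrame
    easy_level: int
    optimal_level: int
    hard_level: int
    hard_capped: bool = False
    weights: WeightScheme = field(default_factory=WeightScheme)

    @property
    def assigned_levels(self) -> dict[str, int]:
        return {
            "easy": self.easy_level,
            "optimal": self.optimal_level,
            "hard": self.hard_level,
        }

    def pi(self, level: int) -> float:
        return float(self.table.set_index("level").loc[level, "pi"])

    def pct_pi(self, level: int) -> float:
        return float(self.table.set_index("level").loc[level, "pct_pi"])


def _as_records(records: Iterable) -> list[GameMetricsRecord]:
    out = []
    for r in records:
        if isinstance(r, GameMetricsRecord):
            out.append(r)
        else:  # tolerate (level, tc, tm, oh) tuples and dicts
            if isinstance(r, dict):
                out.append(GameMetricsRecord(r["level"], r["tc"], r["tm"], r["oh"]))
            else:
                out.append(GameMetricsRecord(*r))
    return out


def calibrate_levels(
    records: Sequence[GameMetricsRecord] | pd.DataFrame,
    w: WeightScheme | None = None,
    max_level: int = 10,
) -> LevelCalibration:
    """Normalise metrics across levels, compute PI and %PI', assign levels.

    The optimal level is the argmax of %PI' (ties broken toward the
    lowest level, the most conservative difficulty); the hard level is
    optimal + 4, capped at ``max_level`` with a warning; easy is level 1.
    """
    w = w or WeightScheme()
    if isinstance(records, pd.DataFrame):
        cols = {c.lower(): c for c in records.columns}
        records = [
            GameMetricsRecord(
                int(row[cols["level"]]),
                int(row[cols["tc"]]),
                int(row[cols["tm"]]),
                int(row[cols["oh"]]),
            )
            for _, row in records.iterrows()
        ]
    records = _as_records(records)
    if len(records) < 2:
        raise ValidationError("calibration needs at least 2 levels")
    levels = [r.level for r in records]
    if len(set(levels)) != len(levels):
        raise ValidationError(f"duplicate levels in metrics table: {sorted(levels)}")

    tc = np.array([r.tc for r in records], dtype=float)
    tm = np.array([r.tm for r in records], dtype=float)
    oh = np.array([r.oh for r in records], dtype=float)
    if np.ptp(tc) == 0 and np.ptp(tm) == 0 and np.ptp(oh) == 0:
        raise DegenerateInputError(
            "all three metrics are constant across levels; no level is distinguishable"
        )

    tc_n = np.array([min_max_normalize(v, tc.min(), tc.max()) for v in tc])
    tm_n = np.array([min_max_normalize(v, tm.min(), tm.max()) for v in tm])
    oh_n = np.array([min_max_normalize(v, oh.min(), oh.max()) for v in oh])
    pi = np.array(
        [performance_index(a, b, c, w) for a, b, c in zip(tc_n, tm_n, oh_n)]
    )
    pct_pi = 100.0 * np.array(
        [min_max_normalize(v, pi.min(), pi.max()) for v in pi]
    )

    table = pd.DataFrame(
        {
            "level": levels,
            "tc": tc.astype(int),
            "tm": tm.astype(int),
            "oh": oh.astype(int),
            "tc_n": tc_n,
            "tm_n": tm_n,
            "oh_n": oh_n,
            "pi": pi,
            "pct_pi": pct_pi,
        }
    ).sort_values("level", ignore_index=True)

    # argmax of pct_pi, lowest level on ties
    best = table.loc[table["pct_pi"] == table["pct_pi"].max(), "level"].min()
    optimal = int(best)
    hard = optimal + 4
    capped = hard > max_level
    if capped:
        warnings.warn(
            f"hard level {hard} exceeds max level {max_level}; capping",
            stacklevel=2,
        )
        logger.warning("hard level capped at %d (optimal=%d)", max_level, optimal)
        hard = max_level
    return LevelCalibration(
        table=table,
        easy_level=1,
        optimal_level=optimal,
        hard_level=hard,
        hard_capped=capped,
        weights=w,
    )


# Published per-level datasheet for one player of the stunt-plane game
# (raw counts only; normalised columns are recomputed by calibrate_levels).
_EXAMPLE_ROWS = [
    (1, 29, 0, 3),
    (2, 54, 6, 3),
    (3, 76, 10, 8),
    (4, 91, 27, 11),
    (5, 98, 44, 20),
    (6, 115, 57, 21),
    (7, 115, 89, 31),
    (8, 111, 119, 34),
    (9, 128, 139, 42),
    (10, 131, 161, 57),
]


def example_session_metrics() -> pd.DataFrame:
    """The published worked-example datasheet (levels 1-10, TC/TM/OH counts).

    Calibrating this table with default weights yields optimal level 4,
    hard level 8 and easy level 1.
    """
    return pd.DataFrame(_EXAMPLE_ROWS, columns=["level", "tc", "tm", "oh"])
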