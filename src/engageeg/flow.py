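"""Flow-state-scale scoring and high/low engagement labeling.

The flow state scale for occupational tasks is a 14-item Likert
questionnaire, each item rated 0 (strongly disagree) to 7 (strongly
agree), filled in after each 2-minute gameplay session. The *rated
score* is the raw sum divided by 14, so it lives on the same 0-7 scale
as the items. Sessions scoring >= 4.5 are labeled *high* engagement and
sessions below 4.5 *low* — except that scores at the scale's undecided
midpoint (4, within a configurable band) are labeled *neutral* and
excluded from classifier training downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

N_ITEMS = 14
HIGH_THRESHOLD = 4.5
#: Default neutral band: the undecided midpoint 4 within +/- 0.25.
DEFAULT_NEUTRAL_BAND: tuple[float, float] = (3.75, 4.25)

__all__ = [
    "FlowScaleResponse",
    "EngagementLabel",
    "rated_score",
    "score_and_label",
    "label_table",
    "retained_subjects",
    "N_ITEMS",
    "HIGH_THRESHOLD",
    "DEFAULT_NEUTRAL_BAND",
]


@dataclass(frozen=True)
class FlowScaleResponse:
    """One questionnaire response: 14 integer items in 0..7."""

    items: tuple[int, ...]
    subject_id: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        items = tuple(int(v) for v in self.items)
        object.__setattr__(self, "items", items)
        if len(items) != N_ITEMS:
            raise ValidationError(
                f"expected {N_ITEMS} items, got {len(items)}"
            )
        bad = [v for v in items if not (0 <= v <= 7)]
        if bad:
            raise ValidationError(f"items outside [0, 7]: {bad}")


@dataclass(frozen=True)
class EngagementLabel:
    """Rated score plus its high/low/neutral label."""

    rated_score: float
    label: str
    subject_id: str = ""
    session: str = ""


def rated_score(r: FlowScaleResponse | Sequence[int]) -> float:
    """Raw item sum divided by 14; a value on the 0-7 item scale."""
    if not isinstance(r, FlowScaleResponse):
        r = FlowScaleResponse(tuple(r))
    return sum(r.items) / N_ITEMS


def score_and_label(
    r: FlowScaleResponse | Sequence[int],
    neutral_band: tuple[float, float] | None = DEFAULT_NEUTRAL_BAND,
) -> EngagementLabel:
    """Label a response high (score >= 4.5), low (< 4.5) or neutral.

    ``neutral_band`` is a closed score interval (default [3.75, 4.25])
    capturing undecided responses; pass ``None`` to disable the band and
    force a binary label.
    """
    if not isinstance(r, FlowScaleResponse):
        r = FlowScaleResponse(tuple(r))
    score = rated_score(r)
    if neutral_band is not None and neutral_band[0] <= score <= neutral_band[1]:
        label = "neutral"
    elif score >= HIGH_THRESHOLD:
        label = "high"
    else:
        label = "low"
    return EngagementLabel(
        rated_score=score, label=label, subject_id=r.subject_id, session=r.session
    )


def label_table(
    responses: Iterable[FlowScaleResponse],
    neutral_band: tuple[float, float] | None = DEFAULT_NEUTRAL_BAND,
) -> pd.DataFrame:
    """Score a batch of responses into a (subject_id, session, rated_score, label) table."""
    rows = []
    for r in responses:
        lab = score_and_label(r, neutral_band=neutral_band)
        rows.append(
            {
                "subject_id": lab.subject_id,
                "session": lab.session,
                "rated_score": lab.rated_score,
                "label": lab.label,
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "session", "rated_score", "label"])


def retained_subjects(labels: pd.DataFrame, mode: str = "per-participant") -> list[str]:
    """Subjects usable for within-subject classification.

    After neutral sessions are removed, a subject is retained only when
    their remaining sessions carry *both* a high and a low label —
    otherwise binary classification of their epochs is undefined.
    ``mode`` ``per-participant`` drops the whole subject (default);
    ``per-session`` merely drops neutral sessions, which happens in
    either mode.
    """
    if mode not in ("per-participant", "per-session"):
        raise ValidationError(f"unknown exclusion mode {mode!r}")
    kept: list[str] = []
    for sid, grp in labels.groupby("subject_id", sort=True):
        present = set(grp.loc[grp["label"] != "neutral", "label"])
        if mode == "per-participant":
            keep = {"high", "low"} <= present
        else:  # per-session: keep any subject with usable sessions left
            keep = bool(present)
        if keep:
            kept.append(str(sid))
    n_drop = labels["subject_id"].nunique() - len(kept)
    if n_drop:
        logger.info("excluded %d subject(s) without both engagement classes", n_drop)
    return kept
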