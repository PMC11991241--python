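"""Nonparametric group statistics across the three game difficulty levels.

The analysis plan is: screen each condition with the Shapiro-Wilk test
(reported, but the pipeline proceeds nonparametrically regardless,
since at least one condition is typically non-normal), compare the
easy/optimal/hard conditions with a Friedman test of related samples
(tie-corrected, with mean ranks), and follow up with SPSS-style Dunn
pairwise comparisons of mean ranks under a Bonferroni correction.

The Friedman statistic with tie correction is

    chi2 = n * (k - 1) * (S - C) / (Sr - C)

with S = sum_j (R_j - n(k+1)/2)^2 / n expressed via rank sums; here we
use the equivalent standard form based on squared rank sums divided by
the tie-correction factor. Dunn's z for conditions i, j is

    z = (Rbar_i - Rbar_j) / sqrt(k (k + 1) / (6 n))

with two-sided normal p-values multiplied by the number of pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .exceptions import ValidationError

ALPHA = 0.05

__all__ = [
    "FriedmanResult",
    "PairwiseComparison",
    "friedman_test",
    "posthoc_pairwise",
    "normality_screen",
    "ALPHA",
]


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    p: float
    mean_ranks: tuple[float, ...]
    n: int
    k: int
    condition_names: tuple[str, ...] = ()

    def summary(self) -> str:
        names = self.condition_names or tuple(
            f"cond{j + 1}" for j in range(self.k)
        )
        ranks = ", ".join(
            f"{nm}={r:.2f}" for nm, r in zip(names, self.mean_ranks)
        )
        return (
            f"Friedman chi2({self.df}, N = {self.n}) = {self.chi2:.2f}, "
            f"p = {self.p:.3f}; mean ranks: {ranks}"
        )


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    z: float
    p_raw: float
    p_adjusted: float


def friedman_test(
    scores: np.ndarray, condition_names: Sequence[str] | None = None
) -> FriedmanResult:
    """Tie-corrected Friedman test on a subjects x conditions matrix."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValidationError("scores must be a 2-D subjects x conditions matrix")
    n, k = scores.shape
    if n < 2 or k < 2:
        raise ValidationError(f"need >=2 subjects and >=2 conditions, got {n}x{k}")
    if not np.isfinite(scores).all():
        raise ValidationError("scores contain missing or non-finite cells")
    names = tuple(condition_names) if condition_names else tuple(
        f"cond{j + 1}" for j in range(k)
    )
    if len(names) != k:
        raise ValidationError("condition_names length mismatch")

    ranks = np.apply_along_axis(sstats.rankdata, 1, scores)  # average ranks on ties
    rank_sums = ranks.sum(axis=0)
    mean_ranks = rank_sums / n

    # tie correction: for each subject, sum of (t^3 - t) over tied groups
    tie_term = 0.0
    for row in scores:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))

    if correction <= 0:  # every row fully tied: no information
        chi2 = 0.0
    else:
        raw = (12.0 / (n * k * (k + 1))) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
        chi2 = max(raw / correction, 0.0)
    df = k - 1
    p = float(sstats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return FriedmanResult(
        chi2=float(chi2),
        df=df,
        p=p,
        mean_ranks=tuple(float(r) for r in mean_ranks),
        n=n,
        k=k,
        condition_names=names,
    )


def posthoc_pairwise(result: FriedmanResult) -> list[PairwiseComparison]:
    """Dunn rank comparisons with Bonferroni adjustment over all pairs."""
    k, n = result.k, result.n
    names = result.condition_names or tuple(f"cond{j + 1}" for j in range(k))
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    m = k * (k - 1) // 2
    out = []
    for i, j in combinations(range(k), 2):
        z = (result.mean_ranks[i] - result.mean_ranks[j]) / se
        p_raw = float(2.0 * sstats.norm.sf(abs(z)))
        out.append(
            PairwiseComparison(
                pair=(names[i], names[j]),
                z=float(z),
                p_raw=p_raw,
                p_adjusted=min(1.0, m * p_raw),
            )
        )
    return out


def normality_screen(
    conditions: dict[str, np.ndarray] | Sequence[np.ndarray],
) -> dict[str, tuple[float, float]]:
    """Shapiro-Wilk W and p per condition (reporting only; the group
    comparison is nonparametric either way)."""
    if not isinstance(conditions, dict):
        conditions = {f"cond{j + 1}": v for j, v in enumerate(conditions)}
    out = {}
    for name, values in conditions.items():
        values = np.asarray(values, dtype=float)
        if not (3 <= values.size <= 5000):
            raise ValidationError(
                f"{name}: Shapiro-Wilk defined for 3 <= n <= 5000, got n={values.size}"
            )
        w, p = sstats.shapiro(values)
        out[name] = (float(w), float(p))
    return out
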