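"""Effort-risk scoring: expert weights applied to per-diagnosis averages.

The score mirrors how the expert panel framed total consumer effort:
each factor owns a fixed percentage of the total (the six percentages
sum to 100), and a diagnosis's score is the weighted sum of its factor
averages,

    score(d) = sum_f (w_f / 100) * mean_f(d)

so a weight acts like a coefficient on the average number of times a
consumer with that diagnosis experienced the factor in the analysis
window.  Scores are unitless; they order diagnoses by the
administrative effort their consumers put into finding and paying for
care.  Totals are always computed from unrounded components; half-up
two-decimal rounding is a display convention only.
"""

from __future__ import annotations

import logging

import pandas as pd

from .claims_io import FACTORS, EffortWeights
from .factor_aggregation import FACTOR_COUNT_COLUMNS
from .errors import InsufficientDataError, ParameterError

logger = logging.getLogger(__name__)

MEAN_COLUMNS = [f"mean_{f}" for f in FACTORS]
COMPONENT_COLUMNS = [f"component_{f}" for f in FACTORS]

__all__ = [
    "MEAN_COLUMNS",
    "COMPONENT_COLUMNS",
    "component_scores",
    "effort_risk_score",
    "rank_diagnoses",
    "factor_correlations",
]


def _check_means(averages: pd.DataFrame) -> None:
    missing = [c for c in MEAN_COLUMNS if c not in averages.columns]
    if missing:
        raise ParameterError(f"averages frame missing column(s): {missing}")
    for col in MEAN_COLUMNS:
        if (averages[col] < 0).any():
            raise ParameterError(f"negative factor mean in column {col!r}")


def component_scores(
    averages: pd.DataFrame, weights: EffortWeights
) -> pd.DataFrame:
    """Per-factor score components, (weight/100) x mean, full precision.

    Returns a frame with one ``component_<factor>`` column per factor,
    aligned row-for-row with ``averages``.
    """
    _check_means(averages)
    comp = pd.DataFrame(index=averages.index)
    for factor in FACTORS:
        comp[f"component_{factor}"] = averages[f"mean_{factor}"] * weights.fraction(
            factor
        )
    return comp


def effort_risk_score(
    averages: pd.DataFrame, weights: EffortWeights
) -> pd.DataFrame:
    """Score every diagnosis row of a per-diagnosis averages frame.

    Output carries the identifying columns of the input (``code`` and/or
    a ``diagnosis`` label, plus ``n_households`` when present), the six
    factor means, the six components and their sum ``total``.
    """
    comp = component_scores(averages, weights)
    carry = [c for c in ("code", "diagnosis", "n_households") if c in averages.columns]
    if not carry:
        raise ParameterError(
            "averages frame needs a 'code' or 'diagnosis' identifier column"
        )
    out = pd.concat([averages[carry + MEAN_COLUMNS], comp], axis=1)
    out["total"] = comp[COMPONENT_COLUMNS].sum(axis=1)
    return out


def rank_diagnoses(
    scores: pd.DataFrame, top_n: int | None = None
) -> pd.DataFrame:
    """Order scored diagnoses by descending unrounded total.

    Ties are broken by ascending code (or label when no code column
    exists); ``top_n`` truncates to the highest-effort diagnoses.
    """
    if top_n is not None and top_n <= 0:
        raise ParameterError(f"top_n must be a positive integer, got {top_n!r}")
    key = "code" if "code" in scores.columns else "diagnosis"
    ranked = scores.sort_values(
        ["total", key], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_n is not None:
        ranked = ranked.head(top_n)
    return ranked


def factor_correlations(
    counts: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise correlations of the six factor counts across households.

    ``counts`` is the household factor-counts frame.  Returns a 6x6
    symmetric frame labeled with the canonical factor names, unit
    diagonal.  ``method`` may be any correlation pandas supports
    ("pearson" default, "spearman" for rank correlation).  A factor
    with zero variance across households yields undefined (NaN)
    off-diagonal cells and a warning.
    """
    if len(counts) < 3:
        raise InsufficientDataError(
            f"need at least 3 households for factor correlations, got {len(counts)}"
        )
    data = counts[list(FACTOR_COUNT_COLUMNS.values())].copy()
    data.columns = list(FACTORS)
    constant = [f for f in FACTORS if data[f].nunique() <= 1]
    if constant:
        logger.warning(
            "factor(s) with zero variance, correlations undefined: %s", constant
        )
    corr = data.corr(method=method)
    for f in FACTORS:  # self-correlation is 1 by convention, even degenerate
        corr.loc[f, f] = 1.0
    return corr
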