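"""Diagnosis-code scoping by cumulative occurrence coverage.

Large claims extracts concentrate most diagnosis occurrences in a small
set of codes; the analysis restricts itself to the most frequent codes
that jointly cover a target fraction (default 80%) of all occurrences.
An *occurrence* is one code on one claim line, so a claim carrying k
codes contributes k occurrences and repeats across a patient's claims
all count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParameterError

DEFAULT_COVERAGE = 0.80

__all__ = [
    "DEFAULT_COVERAGE",
    "ScopedCodes",
    "count_diagnoses",
    "select_top_coverage",
    "read_scoped_codes",
    "write_scoped_codes",
]


@dataclass(frozen=True)
class ScopedCodes:
    """Codes retained by the coverage rule, plus the coverage achieved.

    ``codes`` preserves descending-frequency order; ``achieved_coverage``
    is the cumulative occurrence share of the retained prefix, reported
    at full precision (it is >= the requested threshold, not equal).
    """

    codes: tuple[str, ...]
    achieved_coverage: float

    def __contains__(self, code: str) -> bool:
        return code in set(self.codes)

    def __len__(self) -> int:
        return len(self.codes)


def count_diagnoses(claims: pd.DataFrame) -> pd.DataFrame:
    """Tally diagnosis occurrences across all claim lines.

    Returns a frame with columns ``code``, ``count`` and ``share``
    (fraction of total occurrences), sorted by descending count with
    ties broken by ascending code string.
    """
    if claims.empty:
        raise EmptyInputError("cannot count diagnoses of an empty claims table")
    codes = claims["diagnosis_codes"].explode()
    counts = codes.value_counts()
    freq = (
        counts.rename_axis("code")
        .reset_index(name="count")
        .sort_values(["count", "code"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    freq["share"] = freq["count"] / freq["count"].sum()
    return freq


def select_top_coverage(
    freq: pd.DataFrame, threshold: float = DEFAULT_COVERAGE
) -> ScopedCodes:
    """Shortest descending-frequency prefix with cumulative share >= threshold.

    ``freq`` is the output of :func:`count_diagnoses`.  The prefix rule
    includes codes in frequency order until the cumulative share first
    reaches the threshold; ties in counts are already broken
    lexicographically by the counting step, so selection is
    deterministic.
    """
    if not 0.0 < threshold <= 1.0:
        raise ParameterError(
            f"coverage threshold must be in (0, 1], got {threshold!r}"
        )
    if freq.empty:
        raise EmptyInputError("empty diagnosis frequency table")
    cum = freq["share"].cumsum()
    # float cumsum can land a hair under the exact rational share; snap
    # within 1e-12 so threshold 1.0 never over-selects past the table
    n_keep = int(np.searchsorted(cum.to_numpy(), threshold - 1e-12) + 1)
    n_keep = min(n_keep, len(freq))
    return ScopedCodes(
        codes=tuple(freq["code"].iloc[:n_keep]),
        achieved_coverage=float(cum.iloc[n_keep - 1]),
    )


def write_scoped_codes(scoped: ScopedCodes, path: str | Path) -> None:
    """One code per line; a trailing comment records achieved coverage."""
    lines = list(scoped.codes) + [f"# coverage={scoped.achieved_coverage!r}"]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_scoped_codes(path: str | Path) -> ScopedCodes:
    codes: list[str] = []
    coverage = float("nan")
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("# coverage="):
            coverage = float(line.split("=", 1)[1])
        elif not line.startswith("#"):
            codes.append(line)
    return ScopedCodes(codes=tuple(codes), achieved_coverage=coverage)
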