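"""Household-level factor counting and per-diagnosis averaging.

The unit of observation is the *consumer*, defined as all members of a
household covered under one plan: every factor is counted at household
level over the full analysis window.  Because contact-center inquiries
cannot be tied to a diagnosis, a household's whole-year factor counts
are attributed in full to every diagnosis code the household carries —
there is no per-diagnosis apportionment of calls, denials or visits.

The six factors, per household:

* members with claims — distinct member_ids appearing on its claims
* out-of-network     — claim lines flagged ``out_of_network``
* adjustments        — claim lines flagged ``adjusted``
* denials            — claim lines flagged ``denied``
* calls              — phone contact events
* web/mobile         — web plus mobile contact events

A claim flagged both denied and adjusted increments both counts: the two
are distinct effort events (a denial may subsequently qualify for an
adjustment).
"""

from __future__ import annotations

import logging

import pandas as pd

from .claims_io import FACTORS
from .diagnosis_scope import ScopedCodes
from .errors import EmptyInputError

logger = logging.getLogger(__name__)

#: canonical factor name -> column of the household counts frame
FACTOR_COUNT_COLUMNS = {
    "household": "n_members_with_claims",
    "out_of_network": "n_out_of_network",
    "adjustments": "n_adjustments",
    "denials": "n_denials",
    "calls": "n_phone",
    "web_mobile": "n_web_mobile",
}

COUNTS_COLUMNS = ["household_id", *FACTOR_COUNT_COLUMNS.values()]

#: per-diagnosis averages frame layout
AVERAGES_COLUMNS = (
    ["code", "n_households"]
    + [f"mean_{f}" for f in FACTORS]
    + [f"median_{f}" for f in FACTORS]
)


def household_factor_counts(
    claims: pd.DataFrame, contacts: pd.DataFrame
) -> pd.DataFrame:
    """Whole-year factor counts per household.

    Households appearing only in contacts (never in claims) are retained
    with zero members-with-claims and a warning, so inquiry volume is
    never silently dropped.
    """
    if claims.empty:
        raise EmptyInputError("cannot aggregate an empty claims table")
    by_hh = claims.groupby("household_id", sort=True)
    counts = pd.DataFrame(
        {
            "n_members_with_claims": by_hh["member_id"].nunique(),
            "n_out_of_network": by_hh["out_of_network"].sum(),
            "n_adjustments": by_hh["adjusted"].sum(),
            "n_denials": by_hh["denied"].sum(),
        }
    )
    if len(contacts):
        channel_tab = (
            contacts.groupby(["household_id", "channel"]).size().unstack(fill_value=0)
        )
        phone = channel_tab.get("phone", 0)
        web_mobile = channel_tab.get("web", 0) + channel_tab.get("mobile", 0)
        counts["n_phone"] = phone
        counts["n_web_mobile"] = web_mobile
        orphans = channel_tab.index.difference(counts.index)
        if len(orphans):
            logger.warning(
                "%d household(s) have contacts but no claims: %s",
                len(orphans),
                list(orphans[:5]),
            )
            extra = pd.DataFrame(
                0,
                index=orphans,
                columns=[c for c in counts.columns if c not in ("n_phone", "n_web_mobile")],
            )
            extra["n_phone"] = channel_tab.loc[orphans].get("phone", 0)
            extra["n_web_mobile"] = channel_tab.loc[orphans].get(
                "web", 0
            ) + channel_tab.loc[orphans].get("mobile", 0)
            counts = pd.concat([counts, extra])
    else:
        counts["n_phone"] = 0
        counts["n_web_mobile"] = 0
    counts = counts.fillna(0).astype(int).sort_index()
    out = counts.rename_axis("household_id").reset_index()
    return out[COUNTS_COLUMNS]


def household_diagnosis_index(claims: pd.DataFrame) -> dict[str, set[str]]:
    """Map each diagnosis code to the set of households carrying it.

    A household is listed under every code appearing on any of its
    claim lines; repeats collapse (set semantics).
    """
    exploded = claims[["household_id", "diagnosis_codes"]].explode("diagnosis_codes")
    index: dict[str, set[str]] = {}
    for code, group in exploded.groupby("diagnosis_codes", sort=True):
        index[code] = set(group["household_id"])
    return index


def per_diagnosis_averages(
    counts: pd.DataFrame,
    index: dict[str, set[str]],
    scoped: ScopedCodes,
) -> pd.DataFrame:
    """Mean and median of each factor over each scoped code's households.

    A household's whole-year counts contribute in full to every code it
    carries.  Scoped codes absent from the index are excluded with a
    warning.  Output is sorted by ascending code.
    """
    missing = [c for c in scoped.codes if c not in index]
    if missing:
        logger.warning(
            "%d scoped code(s) have no claims and are excluded: %s",
            len(missing),
            missing[:5],
        )
    kept = [c for c in scoped.codes if c in index]
    if not kept:
        raise EmptyInputError("no scoped code has any claims")
    pairs = pd.DataFrame(
        [(code, hh) for code in kept for hh in index[code]],
        columns=["code", "household_id"],
    )
    merged = pairs.merge(counts, on="household_id", how="left", validate="m:1")
    if merged[list(FACTOR_COUNT_COLUMNS.values())].isna().any().any():
        raise EmptyInputError(
            "household(s) in the diagnosis index are missing from the counts table"
        )
    grouped = merged.groupby("code", sort=True)
    out = pd.DataFrame({"n_households": grouped.size()})
    for factor, col in FACTOR_COUNT_COLUMNS.items():
        out[f"mean_{factor}"] = grouped[col].mean()
        out[f"median_{factor}"] = grouped[col].median()
    out = out.rename_axis("code").reset_index()
    return out[AVERAGES_COLUMNS]


def read_averages(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in AVERAGES_COLUMNS if c not in frame.columns]
    if missing:
        raise EmptyInputError(f"averages table missing column(s): {missing}")
    return frame[AVERAGES_COLUMNS]


def write_averages(averages: pd.DataFrame, path) -> None:
    averages[AVERAGES_COLUMNS].to_csv(path, sep="\t", index=False)
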