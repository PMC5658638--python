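"""Synthetic 12-month claims and contact-center extracts with known truth.

No claims dataset of the kind this analysis targets can be deposited
(it is protected health information), so every downstream stage is
exercised on simulated data whose per-diagnosis factor structure is
known exactly.  The generator emulates one plan-year of a payer's
extract:

* households have 1 + Poisson(mu - 1) members; every member incurs at
  least one claim, so members-with-claims equals household size;
* each household carries a set of diagnosis codes: 1 + Poisson(lam - 1)
  draws from a Zipf-like prevalence distribution over the vocabulary
  (rank-r code has probability proportional to r**-s), duplicates
  collapsed — so a modest head of the vocabulary accounts for most
  diagnosis occurrences, as in real extracts;
* each household-code pair emits one clean "encounter" claim line (the
  diagnosis has to appear on a claim to exist in the data) plus
  independent Poisson numbers of out-of-network, adjusted and denied
  claim lines, and Poisson numbers of phone and web/mobile inquiries,
  at per-code configured yearly rates;
* inquiries are recorded with the household only — like real contact
  data they cannot be attributed to a diagnosis.

Because the analysis attributes a household's whole-year counts to
every code the household carries, the true per-code mean of an event
factor f is not the configured rate alone but

    true_mean_f(c) = rate_f(c) + sum_{c' != c} P(c' in S | c in S) * rate_f(c')

where S is the household's code set.  The inclusion probabilities have
a closed form under the (1 + Poisson)-with-dedup draw:

    P(c not in S)            = (1 - p_c) * exp(-(lam - 1) * p_c)
    P(c, c' both not in S)   = (1 - p_c - p_c') * exp(-(lam - 1) * (p_c + p_c'))

and inclusion-exclusion gives the conditional.  :func:`expected_scores`
uses these exact means, so parameter-recovery tests need no Monte-Carlo
reference.  The true household-size factor is ``household_size_mean``
for every code (size is drawn before codes and independently of them).
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .claims_io import FACTORS, EffortWeights, validate_claims, validate_contacts
from .errors import ParameterError

logger = logging.getLogger(__name__)

#: the five event factors with per-code yearly rates (household size is
#: governed globally by ``household_size_mean``)
EVENT_FACTORS = ("out_of_network", "adjustments", "denials", "calls", "web_mobile")

_WINDOW_START = dt.date(2014, 1, 1)  # analysis window: one plan year
_WINDOW_DAYS = 365

__all__ = [
    "EVENT_FACTORS",
    "SimConfig",
    "GroundTruth",
    "code_labels",
    "default_rate_table",
    "simulate",
    "expected_scores",
]


def code_labels(n_codes: int) -> list[str]:
    """Synthetic diagnosis-code vocabulary: D001, D002, ...

    Labels are opaque to every computation; lexicographic order equals
    rank order, which makes tie-breaks easy to reason about in tests.
    """
    width = max(3, len(str(n_codes)))
    return [f"D{i + 1:0{width}d}" for i in range(n_codes)]


def default_rate_table(n_codes: int, seed: int = 20140101) -> pd.DataFrame:
    """Per-code yearly event rates spanning realistic magnitudes.

    Rates are drawn once from uniform ranges chosen so that, after
    whole-household attribution, per-diagnosis averages land in the
    ranges seen in payer extracts (denials the largest, adjustments the
    smallest).  The table is deterministic for a given (n_codes, seed)
    and is part of the configuration, not of the simulation randomness.
    """
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {
            "out_of_network": rng.uniform(0.2, 5.0, n_codes),
            "adjustments": rng.uniform(0.05, 0.8, n_codes),
            "denials": rng.uniform(0.5, 8.0, n_codes),
            "calls": rng.uniform(0.1, 1.2, n_codes),
            "web_mobile": rng.uniform(0.2, 2.0, n_codes),
        },
        index=pd.Index(code_labels(n_codes), name="code"),
    )
    return table.round(4)


@dataclass
class SimConfig:
    """Conditions of one simulated plan-year.

    Parameters
    ----------
    n_households
        Number of households (consumers) in the extract.
    seed
        Seed for all simulation randomness.
    n_codes
        Size of the diagnosis vocabulary.
    zipf_exponent
        Prevalence skew: rank-r code drawn with probability ~ r**-s.
    household_size_mean
        Mean household size; sizes are 1 + Poisson(mean - 1).
    diagnoses_per_household_mean
        Mean number of code draws per household (1 + Poisson(mean - 1),
        before duplicate collapse).
    factor_rate_table
        Per-code yearly mean counts for the five event factors; defaults
        to :func:`default_rate_table`.
    household_frailty_sd
        Optional lognormal sigma of a shared per-household rate
        multiplier (mean 1).  Default 0 (off): factors are independent
        given the code set, matching the panel's view that effort on
        one factor does not imply effort on another; switch it on to
        exercise the correlation stage.
    """

    n_households: int
    seed: int = 0
    n_codes: int = 150
    zipf_exponent: float = 1.0
    household_size_mean: float = 2.5
    diagnoses_per_household_mean: float = 2.0
    factor_rate_table: pd.DataFrame | None = field(default=None, repr=False)
    household_frailty_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_households < 1:
            raise ParameterError("n_households must be >= 1")
        if self.n_codes < 1:
            raise ParameterError("n_codes must be >= 1")
        if self.zipf_exponent <= 0:
            raise ParameterError("zipf_exponent must be > 0")
        if self.household_size_mean < 1:
            raise ParameterError("household_size_mean must be >= 1")
        if self.diagnoses_per_household_mean < 1:
            raise ParameterError("diagnoses_per_household_mean must be >= 1")
        if self.household_frailty_sd < 0:
            raise ParameterError("household_frailty_sd must be >= 0")
        if self.factor_rate_table is None:
            self.factor_rate_table = default_rate_table(self.n_codes)
        missing = [f for f in EVENT_FACTORS if f not in self.factor_rate_table]
        if missing:
            raise ParameterError(f"factor_rate_table missing column(s): {missing}")
        if len(self.factor_rate_table) != self.n_codes:
            raise ParameterError(
                "factor_rate_table must have one row per diagnosis code"
            )
        if (self.factor_rate_table[list(EVENT_FACTORS)] < 0).any().any():
            raise ParameterError("factor rates must be non-negative")
        if not (self.factor_rate_table[list(EVENT_FACTORS)] > 0).any().any():
            logger.warning(
                "all factor rates are zero: the extract will contain encounter "
                "claim lines but no effort events at all"
            )

    @property
    def codes(self) -> list[str]:
        return list(self.factor_rate_table.index)

    def code_probabilities(self) -> np.ndarray:
        ranks = np.arange(1, self.n_codes + 1, dtype=float)
        p = ranks ** (-self.zipf_exponent)
        return p / p.sum()


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-code factor means (and, with weights, effort scores).

    ``table`` has one row per code with ``true_mean_<factor>`` for the
    six factors and, after :meth:`with_scores`, a ``true_score`` column
    equal to the weighted sum of the true means — the same formula the
    scoring stage applies to estimated means.
    """

    table: pd.DataFrame

    def with_scores(self, weights: EffortWeights) -> "GroundTruth":
        out = self.table.copy()
        out["true_score"] = sum(
            out[f"true_mean_{f}"] * weights.fraction(f) for f in FACTORS
        )
        return GroundTruth(out)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.table.to_dict(orient="list"), indent=1) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(pd.DataFrame(data))


def _true_event_means(config: SimConfig) -> pd.DataFrame:
    """Closed-form whole-household-attributed means for the event factors."""
    p = config.code_probabilities()
    lam = config.diagnoses_per_household_mean
    p_out = (1.0 - p) * np.exp(-(lam - 1.0) * p)  # P(code not in S)
    p_in = 1.0 - p_out
    psum = p[:, None] + p[None, :]
    both_out = np.clip(1.0 - psum, 0.0, None) * np.exp(-(lam - 1.0) * psum)
    both_in = 1.0 - p_out[:, None] - p_out[None, :] + both_out
    with np.errstate(invalid="ignore"):
        q = both_in / p_in[:, None]  # q[c, c'] = P(c' in S | c in S)
    np.fill_diagonal(q, 1.0)
    rates = config.factor_rate_table[list(EVENT_FACTORS)].to_numpy()
    means = q @ rates
    return pd.DataFrame(
        means, columns=list(EVENT_FACTORS), index=config.factor_rate_table.index
    )


def expected_scores(config: SimConfig, weights: EffortWeights | None = None) -> GroundTruth:
    """Exact per-code true factor means (and scores, when weights given)."""
    event_means = _true_event_means(config)
    table = pd.DataFrame({"code": config.codes})
    table["true_mean_household"] = config.household_size_mean
    for f in EVENT_FACTORS:
        table[f"true_mean_{f}"] = event_means[f].to_numpy()
    truth = GroundTruth(table)
    if weights is not None:
        truth = truth.with_scores(weights)
    return truth


def simulate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one plan-year extract: (claims, contacts, ground truth).

    Fully reproducible: the same config (including its seed) yields
    identical tables.  Returns validated canonical frames.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_households
    codes = np.asarray(config.codes)

    sizes = 1 + rng.poisson(config.household_size_mean - 1.0, n)
    n_draws = 1 + rng.poisson(config.diagnoses_per_household_mean - 1.0, n)
    drawn = rng.choice(
        config.n_codes, size=int(n_draws.sum()), p=config.code_probabilities()
    )
    pair_df = pd.DataFrame(
        {"hh": np.repeat(np.arange(n), n_draws), "code_idx": drawn}
    ).drop_duplicates(ignore_index=True)
    hh = pair_df["hh"].to_numpy()
    code_idx = pair_df["code_idx"].to_numpy()
    n_pairs = len(pair_df)

    rates = config.factor_rate_table[list(EVENT_FACTORS)].to_numpy()[code_idx]
    if config.household_frailty_sd > 0:
        sd = config.household_frailty_sd
        frailty = rng.lognormal(-0.5 * sd * sd, sd, n)  # mean 1
        rates = rates * frailty[hh, None]
    event_counts = rng.poisson(rates)  # (n_pairs, 5)

    # --- claim lines -------------------------------------------------
    # one clean encounter line per pair, cycled over members so every
    # member of every household appears on at least one claim
    pairs_per_hh = np.bincount(hh, minlength=n)
    enc_within = _within_group_arange(hh, n)
    enc_member = enc_within % sizes[hh]
    enc_hh, enc_code, enc_flags = hh, code_idx, np.zeros((n_pairs, 3), dtype=bool)

    # wellness lines for members of large households not reached by the
    # encounter cycle; they carry the household's first code
    extra = np.maximum(sizes - pairs_per_hh, 0)
    first_pair = np.full(n, -1)
    first_seen = pd.Series(np.arange(n_pairs)).groupby(hh).min()
    first_pair[first_seen.index] = first_seen.to_numpy()
    well_hh = np.repeat(np.arange(n), extra)
    well_member = _within_group_arange(well_hh, n) + np.repeat(pairs_per_hh, extra)
    well_code = code_idx[first_pair[well_hh]]
    well_flags = np.zeros((len(well_hh), 3), dtype=bool)

    # one line per event, flag set by factor (a denied claim and the
    # adjustment it later needs are distinct effort events, hence
    # distinct lines; counts per factor are exactly the drawn counts)
    flag_cols = ("out_of_network", "adjustments", "denials")
    ev_hh_parts, ev_code_parts, ev_flag_parts = [], [], []
    for j, _factor in enumerate(flag_cols):
        cnt = event_counts[:, j]
        m = int(cnt.sum())
        flags = np.zeros((m, 3), dtype=bool)
        flags[:, j] = True
        ev_hh_parts.append(np.repeat(hh, cnt))
        ev_code_parts.append(np.repeat(code_idx, cnt))
        ev_flag_parts.append(flags)
    ev_hh = np.concatenate([enc_hh, well_hh, *ev_hh_parts])
    ev_code = np.concatenate([enc_code, well_code, *ev_code_parts])
    ev_flags = np.concatenate([enc_flags, well_flags, *ev_flag_parts])
    ev_member = np.concatenate(
        [enc_member, well_member, rng.integers(0, sizes[np.concatenate(ev_hh_parts)])]
        if len(ev_hh_parts) and sum(len(a) for a in ev_hh_parts)
        else [enc_member, well_member]
    )

    n_claims = len(ev_hh)
    order = np.lexsort((ev_code, ev_hh))
    ev_hh, ev_code, ev_member, ev_flags = (
        ev_hh[order], ev_code[order], ev_member[order], ev_flags[order],
    )
    dates = _random_dates(rng, n_claims)
    claims = pd.DataFrame(
        {
            "claim_id": [f"C{i + 1:08d}" for i in range(n_claims)],
            "household_id": _hh_ids(ev_hh),
            "member_id": [f"H{h + 1:06d}-M{m + 1}" for h, m in zip(ev_hh, ev_member)],
            "service_date": dates,
            "diagnosis_codes": [(c,) for c in codes[ev_code]],
            "out_of_network": ev_flags[:, 0],
            "denied": ev_flags[:, 2],
            "adjusted": ev_flags[:, 1],
        }
    )

    # --- contact events ----------------------------------------------
    n_calls = event_counts[:, 3]
    n_wm = event_counts[:, 4]
    call_hh = np.repeat(hh, n_calls)
    wm_hh = np.repeat(hh, n_wm)
    wm_channel = rng.choice(["web", "mobile"], size=len(wm_hh))
    ct_hh = np.concatenate([call_hh, wm_hh])
    ct_channel = np.concatenate([np.repeat("phone", len(call_hh)), wm_channel])
    ct_order = np.argsort(ct_hh, kind="stable")
    ct_hh, ct_channel = ct_hh[ct_order], ct_channel[ct_order]
    contacts = pd.DataFrame(
        {
            "household_id": _hh_ids(ct_hh),
            "channel": ct_channel,
            "event_date": _random_dates(rng, len(ct_hh)),
        }
    )

    truth = expected_scores(config)
    return validate_claims(claims), validate_contacts(contacts), truth


def _within_group_arange(group: np.ndarray, n_groups: int) -> np.ndarray:
    """0,1,2,... within each run of a sorted group vector."""
    counts = np.bincount(group, minlength=n_groups)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    return np.arange(len(group)) - np.repeat(starts, counts)


def _hh_ids(hh_idx: np.ndarray) -> list[str]:
    return [f"H{h + 1:06d}" for h in hh_idx]


def _random_dates(rng: np.random.Generator, n: int) -> list[dt.date]:
    offsets = rng.integers(0, _WINDOW_DAYS, n)
    return [_WINDOW_START + dt.timedelta(days=int(d)) for d in offsets]
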