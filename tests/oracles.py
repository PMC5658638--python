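"""Brute-force reference implementations used to check the pipeline.

Everything here rescans the raw tables from scratch with plain Python
loops and the statistics module — deliberately independent of the
pandas implementations under test.
"""

import random
import statistics
from collections import Counter

from effortrisk.claims_io import ClaimRecord, ContactEvent, claims_to_frame, contacts_to_frame


def oracle_count_diagnoses(claims_frame):
    """(code, count) list: one occurrence per code per claim line,
    descending count, ties by ascending code."""
    counter = Counter()
    for codes in claims_frame["diagnosis_codes"]:
        for code in codes:
            counter[code] += 1
    return sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))


def oracle_select_prefix(counts, threshold):
    """First descending-frequency prefix whose cumulative share reaches
    the threshold, by scanning every prefix."""
    total = sum(c for _, c in counts)
    for k in range(1, len(counts) + 1):
        share = sum(c for _, c in counts[:k]) / total
        if share >= threshold - 1e-12:
            return [code for code, _ in counts[:k]], share
    return [code for code, _ in counts], 1.0


def oracle_per_diagnosis_averages(claims_frame, contacts_frame, codes):
    """For each code, rescan all claims and contacts per household.

    Returns {code: {"n": ..., "mean_<factor>": ..., "median_<factor>": ...}}
    with the same whole-household attribution the pipeline uses.
    """
    claims = list(claims_frame.itertuples(index=False))
    contacts = list(contacts_frame.itertuples(index=False))
    out = {}
    for code in codes:
        households = sorted({c.household_id for c in claims if code in c.diagnosis_codes})
        if not households:
            continue
        per_factor = {f: [] for f in
                      ("household", "out_of_network", "adjustments",
                       "denials", "calls", "web_mobile")}
        for hh in households:
            mine = [c for c in claims if c.household_id == hh]
            my_contacts = [e for e in contacts if e.household_id == hh]
            per_factor["household"].append(len({c.member_id for c in mine}))
            per_factor["out_of_network"].append(sum(c.out_of_network for c in mine))
            per_factor["adjustments"].append(sum(c.adjusted for c in mine))
            per_factor["denials"].append(sum(c.denied for c in mine))
            per_factor["calls"].append(sum(e.channel == "phone" for e in my_contacts))
            per_factor["web_mobile"].append(
                sum(e.channel in ("web", "mobile") for e in my_contacts)
            )
        entry = {"n": len(households)}
        for f, vals in per_factor.items():
            entry[f"mean_{f}"] = statistics.mean(vals)
            entry[f"median_{f}"] = statistics.median(vals)
        out[code] = entry
    return out


def random_toy_tables(seed, max_households=50):
    """A small random claims+contacts pair for oracle comparisons."""
    import datetime as dt

    rng = random.Random(seed)
    n_hh = rng.randint(1, max_households)
    codes = [f"X{i}" for i in range(rng.randint(1, 8))]
    claims, contacts = [], []
    cid = 0
    for h in range(n_hh):
        hh = f"H{h}"
        for m in range(rng.randint(1, 3)):
            for _ in range(rng.randint(1, 4)):
                cid += 1
                k = rng.randint(1, min(3, len(codes)))
                claims.append(
                    ClaimRecord(
                        claim_id=f"c{cid}",
                        household_id=hh,
                        member_id=f"{hh}-M{m}",
                        service_date=dt.date(2014, 1, 1) + dt.timedelta(rng.randint(0, 364)),
                        diagnosis_codes=tuple(rng.sample(codes, k)),
                        out_of_network=rng.random() < 0.3,
                        denied=rng.random() < 0.4,
                        adjusted=rng.random() < 0.2,
                    )
                )
        for _ in range(rng.randint(0, 5)):
            contacts.append(
                ContactEvent(hh, rng.choice(["phone", "web", "mobile"]),
                             dt.date(2014, 6, 1))
            )
    return claims_to_frame(claims), contacts_to_frame(contacts)
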