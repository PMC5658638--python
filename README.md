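# effortrisk

Expert-weighted **consumer effort-risk scoring** of health-insurance
claims, by diagnosis.

Health-plan members spend real administrative work — "effort" — finding
and paying for care: calling the payer's contact center, disputing
denied claims, chasing claim adjustments, discovering that a provider
was out of network. This package implements a descriptive method for
quantifying that effort from a payer's own data and ranking diagnoses
by it, so that payer information systems can be designed around the
consumers who work hardest. It is aimed at health-services researchers
and payer analytics teams with access to a claims extract and a
contact-center log.

## The method

The unit of analysis is the *consumer*: all members of a household
covered under one plan, represented by the caretaker who bears the
administrative burden. Over a 12-month window, six countable **effort
factors** are tallied per household:

| factor | counted as | weight $w_f$ (%) |
|---|---|---|
| phone calls | phone contact events | 40 |
| claim denials | claim lines with payment denied | 25 |
| web / mobile inquiries | web + mobile contact events | 15 |
| out-of-network visits | claim lines flagged out-of-network | 8 |
| claim adjustments | claim lines needing reprocessing | 7 |
| household size | distinct members with claims | 5 |

The weights are expert-elicited percentages of total effort (they sum
to 100) and are consumed as configuration, not code constants. The
analysis is restricted to the most frequent diagnosis codes — the
shortest descending-frequency prefix covering ≥ 80% of all diagnosis
occurrences, one occurrence per code per claim line. Because contacts
cannot be attributed to a diagnosis, a household's whole-year counts
are attributed in full to every code the household carries. For each
retained diagnosis $d$ the per-household mean $\bar{x}_f(d)$ of each
factor is computed over the households carrying $d$, and the
**effort-risk score** is the weighted sum

$$\mathrm{score}(d) \;=\; \sum_{f} \frac{w_f}{100}\,\bar{x}_f(d).$$

Scores are unitless and rank diagnoses by consumer effort; totals are
computed at full precision and rendered half-up to two decimals.

Because real claims extracts are protected health information, the
package includes a seeded synthetic generator (`effortrisk.simulate`)
that emulates a plan-year extract — Zipf-skewed code prevalence,
Poisson households and event counts — with *exact closed-form ground
truth* for every per-diagnosis factor mean and score, so the whole
pipeline is testable end to end without any data access.

## Worked example

Scoring the published factor averages for dislocation of the knee
under the expert-panel weights:

```python
import pandas as pd
from effortrisk import EffortWeights, effort_risk_score

weights = EffortWeights(calls_pct=40, denials_pct=25, web_mobile_pct=15,
                        out_of_network_pct=8, adjustments_pct=7, household_pct=5)
averages = pd.DataFrame([{
    "diagnosis": "Dislocation of the knee",
    "mean_household": 2.14, "mean_out_of_network": 4.48,
    "mean_adjustments": 0.57, "mean_denials": 7.11,
    "mean_calls": 0.65, "mean_web_mobile": 1.72,
}])
scored = effort_risk_score(averages, weights)

from effortrisk.rounding import format_fixed
row = scored.iloc[0]
for f in ("household", "out_of_network", "adjustments", "denials", "calls", "web_mobile"):
    print(f"{f:15s} mean {row[f'mean_{f}']:5.2f}  component {format_fixed(row[f'component_{f}'])}")
print("total effort-risk:", format_fixed(row["total"]))
```

prints, per factor, `(weight/100) × mean`:

```
household       mean  2.14  component 0.11
out_of_network  mean  4.48  component 0.36
adjustments     mean  0.57  component 0.04
denials         mean  7.11  component 1.78
calls           mean  0.65  component 0.26
web_mobile      mean  1.72  component 0.26
total effort-risk: 2.80
```

A total of 2.80 means this diagnosis's consumers average, e.g., 7.11
denied claims and 0.65 calls a year, combined on the common 0–100%
weight scale; only its *rank* against other diagnoses is meaningful.

The same pipeline end to end on synthetic data, from the shell:

```
$ effort run --simulate-households 2000 --seed 7 \
        --weights weights.json --out-dir out/
INFO effortrisk.pipeline: simulate: 35463 claims, 7052 contacts
INFO effortrisk.pipeline: scope: 45 of 150 codes retained, coverage 0.8026
35463 claims, 45 scoped codes (coverage 0.8026); report in out/

$ head -4 out/report.tsv
diagnosis  avg_household_size  avg_out_of_network  avg_adjustments  avg_denials  avg_phone  avg_web_mobile  total_effort_risk
D019       2.51                8.49                0.71             16.69        2.51       3.11            6.50
D027       2.73                6.58                0.58             13.50        2.69       4.15            5.78
D040       2.38                6.46                0.92             14.00        2.54       3.23            5.70
```

Each stage (`effort simulate | scope | aggregate | score`) can also be
run on its own; stages communicate only through the documented CSV/TSV
formats.

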