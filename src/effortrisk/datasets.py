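"""Published reference inputs for the effort-risk method.

A peer-reviewed study of one large US payer's 2014 claims (about 60
million claims, 292 million diagnosis occurrences) elicited the six
factor weights from a 12-member expert panel and reported per-diagnosis
factor averages and effort-risk totals for the 25 highest-effort
diagnoses.  Those printed tables are shipped here as inputs: the
weights are the default scoring configuration, and the averages table
is the worked example / regression fixture for the scoring stage.

The underlying claims data are protected health information and are not
(and cannot be) distributed; only these published summary tables are.
"""

from __future__ import annotations

import pandas as pd

from .claims_io import EffortWeights

__all__ = [
    "expert_panel_weights",
    "published_factor_averages",
    "published_totals",
]


def expert_panel_weights() -> EffortWeights:
    """The expert-elicited factor weights (percent of total effort)."""
    return EffortWeights(
        calls_pct=40.0,
        denials_pct=25.0,
        web_mobile_pct=15.0,
        out_of_network_pct=8.0,
        adjustments_pct=7.0,
        household_pct=5.0,
    )


# diagnosis label -> (household, out_of_network, adjustments, denials,
#                     calls, web_mobile, printed total)
_PUBLISHED_ROWS: dict[str, tuple[float, ...]] = {
    "Chronic kidney disease": (1.61, 7.10, 1.38, 15.87, 0.57, 1.13, 5.11),
    "Drug dependence": (2.18, 11.62, 0.97, 8.61, 0.95, 1.79, 3.91),
    "Heart failure": (1.39, 3.64, 0.77, 12.61, 0.41, 0.55, 3.82),
    "Complic medical care nec/nos": (1.61, 0.74, 0.28, 11.89, 0.69, 1.17, 3.58),
    "Sprain of the knee and leg": (2.32, 5.46, 0.60, 8.27, 0.81, 1.72, 3.25),
    "Chr airway obstruct nec": (1.41, 2.45, 0.46, 10.38, 0.35, 0.85, 3.16),
    "Malig neo female breast": (1.74, 3.40, 0.97, 7.89, 0.85, 2.47, 3.11),
    "Intervertebral disc dis": (1.91, 5.17, 0.64, 8.00, 0.74, 1.41, 3.06),
    "Somatic dysfunction": (2.18, 6.17, 0.52, 7.69, 0.56, 1.74, 3.05),
    "Dis of muscle or lig or fascia": (2.00, 5.33, 0.47, 7.49, 0.63, 1.48, 2.91),
    "Other cervical spice dis": (1.96, 5.04, 0.52, 7.14, 0.68, 1.68, 2.85),
    "Periph enthesopathies": (1.95, 4.27, 0.52, 7.22, 0.67, 1.78, 2.82),
    "Dislocation of the knee": (2.14, 4.48, 0.57, 7.11, 0.65, 1.72, 2.80),
    "Osteoarthrosis etal": (1.59, 3.33, 0.66, 7.20, 0.74, 1.64, 2.73),
    "Cardiac dysrhythmias": (1.56, 2.34, 0.50, 8.03, 0.51, 1.20, 2.69),
    "Nurit or metab or devel symp": (2.40, 3.97, 0.72, 6.28, 0.75, 1.53, 2.59),
    "Malign neopl prostrate": (1.69, 2.52, 0.71, 7.04, 0.60, 1.56, 2.57),
    "Back disorder nec and nos": (1.87, 4.04, 0.47, 6.23, 0.60, 1.54, 2.48),
    "Radius and ulna fracture": (2.51, 3.41, 0.61, 5.98, 0.71, 1.56, 2.45),
    "Oth-ill def morbid or mortl": (1.55, 2.15, 0.33, 6.80, 0.62, 1.41, 2.43),
    "Joint disorder nec and nos": (1.96, 3.64, 0.46, 5.88, 0.69, 1.42, 2.38),
    "Oth dis synov or tend or bursa": (1.82, 3.37, 0.52, 5.88, 0.61, 1.55, 2.34),
    "Normal pregnancy": (2.19, 2.45, 0.59, 5.16, 1.06, 1.84, 2.34),
    "Oth chr ischemic hrt dis": (1.56, 1.97, 0.53, 6.43, 0.48, 1.26, 2.26),
    "Sprain of the back nec or nos": (1.84, 4.02, 0.37, 5.39, 0.54, 1.10, 2.17),
}


def published_factor_averages() -> pd.DataFrame:
    """Per-diagnosis factor averages for the 25 highest-effort diagnoses.

    Columns follow the package's averages layout (``diagnosis`` label
    plus ``mean_<factor>``), so the frame feeds straight into
    ``effort_scoring.effort_risk_score``.  Values are as printed, i.e.
    rounded to two decimals at the source.
    """
    rows = [
        {
            "diagnosis": label,
            "mean_household": v[0],
            "mean_out_of_network": v[1],
            "mean_adjustments": v[2],
            "mean_denials": v[3],
            "mean_calls": v[4],
            "mean_web_mobile": v[5],
        }
        for label, v in _PUBLISHED_ROWS.items()
    ]
    return pd.DataFrame(rows)


def published_totals() -> pd.Series:
    """Printed total effort-risk score per diagnosis label.

    Totals were computed at the source from unrounded averages, so a
    recomputation from the two-decimal printed averages can differ by
    up to 0.01 for some rows.
    """
    return pd.Series(
        {label: v[6] for label, v in _PUBLISHED_ROWS.items()}, name="total"
    )
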