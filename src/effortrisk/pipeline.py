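"""End-to-end orchestration: (simulate |) scope -> aggregate -> score -> report.

Stages communicate only through the documented file formats, so any
stage can be run, inspected and tested on its own; :func:`run_pipeline`
is exactly the composition of the individually invokable stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import claims_io, diagnosis_scope, effort_scoring, factor_aggregation
from .claims_io import EffortWeights
from .errors import ConfigError, EffortRiskError, PipelineStageError
from .synthetic_claims import SimConfig, simulate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One pipeline run: either real input paths or a simulation, not both."""

    out_dir: str | Path
    claims_path: str | Path | None = None
    contacts_path: str | Path | None = None
    weights_path: str | Path | None = None
    sim: SimConfig | None = None
    coverage: float = diagnosis_scope.DEFAULT_COVERAGE
    top_n: int | None = 25
    weights: EffortWeights | None = None

    def __post_init__(self) -> None:
        have_real = self.claims_path is not None or self.contacts_path is not None
        if have_real and self.sim is not None:
            raise ConfigError(
                "provide either real input paths or simulation settings, not both"
            )
        if not have_real and self.sim is None:
            raise ConfigError("provide claims/contacts paths or simulation settings")
        if have_real and (self.claims_path is None or self.contacts_path is None):
            raise ConfigError("real inputs need both --claims and --contacts")
        if self.weights is None and self.weights_path is None:
            raise ConfigError("provide a weights config (path or EffortWeights)")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except EffortRiskError as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages, write every artifact, return a run summary.

    Artifacts written under ``out_dir``: claims.csv / contacts.csv /
    truth.json (simulated runs only), scoped_codes.txt, averages.tsv,
    report.tsv, summary.json.  Deterministic given the inputs (and the
    simulation seed).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.sim is not None:
        claims, contacts, truth = _stage("simulate")(simulate)(config.sim)
        claims_io.write_claims(claims, out_dir / "claims.csv")
        claims_io.write_contacts(contacts, out_dir / "contacts.csv")
        truth.to_json(out_dir / "truth.json")
        logger.info("simulate: %d claims, %d contacts", len(claims), len(contacts))
    else:
        claims = _stage("read_claims")(claims_io.read_claims)(config.claims_path)
        contacts = _stage("read_contacts")(claims_io.read_contacts)(
            config.contacts_path
        )
    weights = (
        config.weights
        if config.weights is not None
        else _stage("read_weights")(claims_io.read_weights)(config.weights_path)
    )

    freq = _stage("scope")(diagnosis_scope.count_diagnoses)(claims)
    scoped = _stage("scope")(diagnosis_scope.select_top_coverage)(
        freq, config.coverage
    )
    diagnosis_scope.write_scoped_codes(scoped, out_dir / "scoped_codes.txt")
    logger.info(
        "scope: %d of %d codes retained, coverage %.4f",
        len(scoped), len(freq), scoped.achieved_coverage,
    )

    counts = _stage("aggregate")(factor_aggregation.household_factor_counts)(
        claims, contacts
    )
    index = _stage("aggregate")(factor_aggregation.household_diagnosis_index)(claims)
    averages = _stage("aggregate")(factor_aggregation.per_diagnosis_averages)(
        counts, index, scoped
    )
    factor_aggregation.write_averages(averages, out_dir / "averages.tsv")

    scores = _stage("score")(effort_scoring.effort_risk_score)(averages, weights)
    ranked = _stage("score")(effort_scoring.rank_diagnoses)(scores, config.top_n)
    report = ranked.rename(columns={"code": "diagnosis"}) if "diagnosis" not in ranked else ranked
    claims_io.write_report(report, out_dir / "report.tsv")

    summary = {
        "n_claims": int(len(claims)),
        "n_contacts": int(len(contacts)),
        "n_households": int(claims["household_id"].nunique()),
        "n_diagnosis_occurrences": int(freq["count"].sum()),
        "n_codes_total": int(len(freq)),
        "n_codes_scoped": int(len(scoped)),
        "achieved_coverage": float(scoped.achieved_coverage),
        "n_diagnoses_scored": int(len(scores)),
        "top_diagnoses": [
            {"code": str(row[0]), "total": float(row[1])}
            for row in ranked[[("code" if "code" in ranked else "diagnosis"), "total"]]
            .head(5)
            .itertuples(index=False)
        ],
        "artifacts": sorted(p.name for p in out_dir.iterdir() if p.is_file()),
    }
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=1) + "\n", encoding="utf-8"
    )
    return summary
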