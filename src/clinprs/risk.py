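"""Risk-threshold calibration and the end-to-end single-sample assay.

A published per-SD odds ratio OR_sd is converted into a threshold on the
standardized adjusted score: tau = ln(target OR) / ln(OR_sd). Under the
assumption that OR_sd captures the PRS-disease relationship, the odds of
disease at a standardized score of tau are target-OR-fold those at the
median score. A score strictly above tau is called high polygenic risk;
anything else is average risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from . import ancestry, engine, io
from .types import DiseaseConfig, QCFailure, SampleGenotypes, ScoreResult


@dataclass(frozen=True)
class RiskThreshold:
    disease: str
    or_sd: float
    target_or: float
    tau: float


def tau_threshold(config: DiseaseConfig) -> RiskThreshold:
    """tau = ln(target_or) / ln(or_sd); undefined (error) for or_sd <= 1."""
    if not config.or_sd > 1:
        raise ValueError(
            f"{config.disease}: or_sd must be > 1 for a positive threshold, "
            f"got {config.or_sd}"
        )
    tau = math.log(config.target_or) / math.log(config.or_sd)
    return RiskThreshold(disease=config.disease, or_sd=config.or_sd,
                         target_or=config.target_or, tau=tau)


def classify(result: ScoreResult, threshold: RiskThreshold) -> ScoreResult:
    """Categorize: high iff the standardized adjusted score is strictly
    above tau, else average (a score exactly at tau is average risk)."""
    if threshold.disease != result.disease:
        raise ValueError(
            f"threshold disease {threshold.disease!r} does not match result "
            f"disease {result.disease!r}"
        )
    category = "high" if result.prs_std_adj > threshold.tau else "average"
    return ScoreResult(sample_id=result.sample_id, disease=result.disease,
                       prs_raw=result.prs_raw, prs_pred=result.prs_pred,
                       prs_adj=result.prs_adj, prs_std_adj=result.prs_std_adj,
                       category=category)


def _diseases_for_sex(configs: Sequence[DiseaseConfig], sex: str):
    if sex not in ("male", "female", "unspecified"):
        raise ValueError(f"sex must be male/female/unspecified, got {sex!r}")
    for c in configs:
        if c.sex is None or c.sex == sex:
            yield c


def run_assay(genotypes: SampleGenotypes,
              weight_tables: Mapping[str, object],
              bundle_dir: str | Path,
              configs: Sequence[DiseaseConfig],
              sex: str = "unspecified",
              findings: Sequence = (),
              call_rate_threshold: float = 0.985,
              ambiguous_policy: str = "drop",
              out: str | Path | None = None,
              drop_log: str | Path | None = None) -> dict:
    """Score one sample end to end and assemble the report.

    The sample must pass the overall call-rate gate (strictly greater than
    ``call_rate_threshold``; failure raises :class:`QCFailure` carrying the
    rate). Sex-specific diseases are scored only when the sample's reported
    sex matches their configuration. Secondary findings, if supplied, are
    attached to the report in their own section.
    """
    qc = engine.check_call_rate(genotypes, call_rate_threshold)
    if not qc.passed:
        raise QCFailure(
            f"sample {genotypes.sample_id} failed QC: call rate "
            f"{qc.call_rate:.4f} not above {qc.threshold:.4f}",
            call_rate=qc.call_rate,
        )
    ref, models = io.read_reference_bundle(bundle_dir)
    pcs = ancestry.project_sample(genotypes, ref)

    results: list[ScoreResult] = []
    thresholds: dict[str, RiskThreshold] = {}
    all_loci = []
    for config in _diseases_for_sex(configs, sex):
        disease = config.disease
        if disease not in weight_tables:
            raise ValueError(f"no weight table supplied for disease {disease!r}")
        if disease not in models:
            raise ValueError(f"reference bundle has no model for {disease!r}")
        loci = engine.harmonize(weight_tables[disease], genotypes,
                                ambiguous_policy=ambiguous_policy)
        all_loci.extend(loci)
        raw = engine.compute_raw_prs(loci, genotypes.sample_id, disease)
        scored = ancestry.adjust_and_standardize(raw, pcs, models[disease])
        threshold = tau_threshold(config)
        thresholds[disease] = threshold
        results.append(classify(scored, threshold))

    if drop_log is not None:
        engine.write_drop_log(all_loci, drop_log)
    call_rates = {genotypes.sample_id: qc.call_rate}
    if out is not None:
        return io.write_report(results, findings, out, thresholds=thresholds,
                               call_rates=call_rates)
    return io.build_report(results, findings, thresholds=thresholds,
                           call_rates=call_rates)
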