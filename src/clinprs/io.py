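"""Readers and writers for on-disk artifacts.

Covers PGS-Catalog-style scoring files, VCF genotypes/dosages, the
tab-separated reference-panel bundle, YAML disease configuration, the
published replication contingency table shipped as package data, and the
JSON assay report. All tabular artifacts are plain tab-separated text so
they are diffable and language-neutral.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .types import (
    AdjustmentModel,
    BundleError,
    DiseaseConfig,
    GenotypeCall,
    PCAReference,
    SampleGenotypes,
    ScoreResult,
    WeightRecord,
    WeightTable,
)

logger = logging.getLogger(__name__)

# Column aliases accepted for scoring files. PGS Catalog headers first.
_WEIGHT_COLUMNS = {
    "chrom": ["chr_name", "chrom", "chromosome", "chr"],
    "pos": ["chr_position", "pos", "position"],
    "effect_allele": ["effect_allele"],
    "other_allele": ["other_allele", "reference_allele", "ref_allele"],
    "weight": ["effect_weight", "weight", "beta"],
}

#: Fixed limitations block attached to every report (clinical layout is out
#: of scope; this is the informational floor every report carries).
LIMITATIONS_TEXT = (
    "Polygenic risk scores estimate relative, not absolute, disease risk from "
    "common variants only. Published weights derive predominantly from "
    "European-ancestry cohorts; despite adjustment for population structure, "
    "score accuracy may be reduced in individuals of other or admixed "
    "ancestry. An average-risk result does not rule out disease, and results "
    "do not account for family history, monogenic variants or non-genetic "
    "risk factors. Results should be interpreted by a qualified clinician in "
    "the full clinical context."
)


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    resolved = {}
    lower = {c.lower(): c for c in columns}
    for canonical, aliases in _WEIGHT_COLUMNS.items():
        for alias in aliases:
            if alias in lower:
                resolved[canonical] = lower[alias]
                break
        else:
            raise ValueError(
                f"scoring file is missing a recognizable {canonical!r} column "
                f"(accepted: {aliases}); found columns {list(columns)}"
            )
    return resolved


def read_weight_table(path: str | Path, dialect: str = "pgs_catalog",
                      prs_id: str | None = None) -> WeightTable:
    """Parse a tab-separated scoring file into a :class:`WeightTable`.

    ``dialect`` is ``pgs_catalog`` (``#``-prefixed metadata header, PGS
    Catalog column names) or ``generic_tsv`` (plain header); both accept the
    same column aliases, so the dialect mainly documents intent. Rows that
    fail validation are rejected with their row index; duplicate
    (chrom, pos, effect_allele) keys are an error. A header-only file yields
    an empty table with a warning.
    """
    path = Path(path)
    if dialect not in ("pgs_catalog", "generic_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if prs_id is None:
        prs_id = path.stem
        # PGS Catalog metadata block can carry the score id.
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if "pgs_id" in line and "=" in line:
                    prs_id = line.split("=", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = _resolve_columns(df.columns)
    if len(df) == 0:
        warnings.warn(f"scoring file {path} has a header but no rows")
        return WeightTable(prs_id=prs_id, records=[])
    records = []
    for i, row in df.iterrows():
        try:
            pos = int(row[cols["pos"]])
            weight = float(row[cols["weight"]])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} row {i}: {exc}") from exc
        try:
            records.append(
                WeightRecord(
                    chrom=str(row[cols["chrom"]]),
                    pos=pos,
                    effect_allele=str(row[cols["effect_allele"]]).upper(),
                    other_allele=str(row[cols["other_allele"]]).upper(),
                    weight=weight,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {i}: {exc}") from exc
    return WeightTable(prs_id=prs_id, records=records)


def write_weight_table(table: WeightTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "weight": r.weight,
            }
            for r in table.records
        ],
        columns=["chrom", "pos", "effect_allele", "other_allele", "weight"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_genotypes(path: str | Path, samples: Sequence[str] | None = None,
                   prefer_dosage: bool = True) -> list[SampleGenotypes]:
    """Read per-sample genotype calls from a VCF (plain or bgzipped).

    Dosage is the imputed ``DS`` field when present and ``prefer_dosage`` is
    set, otherwise the ALT-allele count from ``GT``. Missing genotypes are
    masked, never imputed. Requires biallelic records (split multi-allelics
    upstream); anything else is rejected.
    """
    vcf = VCF(str(path), gts012=True)
    available = list(vcf.samples)
    if samples is not None:
        missing = set(samples) - set(available)
        if missing:
            raise ValueError(f"samples not present in {path}: {sorted(missing)}")
        vcf = VCF(str(path), gts012=True, samples=list(samples))
    sample_ids = list(vcf.samples)
    calls: list[dict] = [dict() for _ in sample_ids]
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"non-biallelic record at {v.CHROM}:{v.POS} "
                f"(ALT={v.ALT}); normalize/split upstream"
            )
        ref, alt = v.REF, v.ALT[0]
        gt = v.gt_types  # gts012: 0/1/2 = ALT count, 3 = missing
        ds = v.format("DS") if prefer_dosage else None
        for i in range(len(sample_ids)):
            dosage: float | None = None
            if ds is not None:
                d = float(ds[i][0]) if ds.ndim == 2 else float(ds[i])
                if np.isfinite(d) and 0.0 <= d <= 2.0:
                    dosage = d
            if dosage is None and gt[i] != 3:
                dosage = float(gt[i])
            calls[i][(v.CHROM, v.POS)] = GenotypeCall(ref=ref, alt=alt, dosage=dosage)
    return [
        SampleGenotypes(sample_id=s, calls=c) for s, c in zip(sample_ids, calls)
    ]


# ---------------------------------------------------------------------------
# Reference bundle: one concern per file, plain TSV + a JSON manifest.

_BUNDLE_FILES = ("manifest.json", "loadings.tsv", "eigenvalues.tsv",
                 "afreq.tsv", "coords.tsv", "models.tsv")
_KEY_COLS = ["chrom", "pos", "ref", "alt"]


def write_reference_bundle(ref: PCAReference,
                           models: Mapping[str, AdjustmentModel],
                           directory: str | Path) -> None:
    """Write a reference bundle (loadings, eigenvalues, frequencies,
    reference coordinates, per-disease models, manifest) to ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    k = ref.k
    pc_cols = [f"PC{i + 1}" for i in range(k)]
    keys = pd.DataFrame(ref.variant_keys, columns=_KEY_COLS)

    loadings = pd.concat(
        [keys, pd.DataFrame(ref.loadings, columns=pc_cols)], axis=1
    )
    loadings.to_csv(d / "loadings.tsv", sep="\t", index=False, float_format="%.17g")

    pd.DataFrame({"pc": pc_cols, "eigenvalue": ref.eigenvalues}).to_csv(
        d / "eigenvalues.tsv", sep="\t", index=False, float_format="%.17g"
    )
    afreq = keys.copy()
    afreq["alt_freq"] = ref.allele_frequencies
    afreq.to_csv(d / "afreq.tsv", sep="\t", index=False, float_format="%.17g")

    coords = pd.concat(
        [pd.DataFrame({"sample": ref.ref_samples}),
         pd.DataFrame(ref.ref_coordinates, columns=pc_cols)],
        axis=1,
    )
    coords.to_csv(d / "coords.tsv", sep="\t", index=False, float_format="%.17g")

    rows = []
    for m in models.values():
        row = {"disease": m.disease, "intercept": m.intercept}
        for i, b in enumerate(m.beta):
            row[f"beta{i + 1}"] = b
        row["ref_mean_adj"] = m.ref_mean_adj
        row["ref_sd_adj"] = m.ref_sd_adj
        rows.append(row)
    pd.DataFrame(
        rows,
        columns=["disease", "intercept", "beta1", "beta2", "beta3", "beta4",
                 "ref_mean_adj", "ref_sd_adj"],
    ).to_csv(d / "models.tsv", sep="\t", index=False, float_format="%.17g")

    manifest = {
        "format": "clinprs-reference-bundle-v1",
        "n_variants": len(ref.variant_keys),
        "k": k,
        "n_ref_samples": len(ref.ref_samples),
        "n_models": len(models),
        "scaling_mode": ref.scaling_mode,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_reference_bundle(
    directory: str | Path,
) -> tuple[PCAReference, dict[str, AdjustmentModel]]:
    """Read and cross-validate a bundle written by :func:`write_reference_bundle`."""
    d = Path(directory)
    for name in _BUNDLE_FILES:
        if not (d / name).exists():
            raise BundleError(f"reference bundle {d} is missing {name}")
    manifest = json.loads((d / "manifest.json").read_text())
    loadings = pd.read_csv(d / "loadings.tsv", sep="\t", float_precision="round_trip")
    eigen = pd.read_csv(d / "eigenvalues.tsv", sep="\t", float_precision="round_trip")
    afreq = pd.read_csv(d / "afreq.tsv", sep="\t", float_precision="round_trip")
    coords = pd.read_csv(d / "coords.tsv", sep="\t", float_precision="round_trip")
    models_df = pd.read_csv(d / "models.tsv", sep="\t", float_precision="round_trip")

    pc_cols = [c for c in loadings.columns if c.startswith("PC")]
    k = len(pc_cols)
    if k != manifest.get("k"):
        raise BundleError(f"manifest k={manifest.get('k')} but loadings carry {k} PCs")
    lkeys = [tuple(r) for r in loadings[_KEY_COLS].itertuples(index=False)]
    fkeys = [tuple(r) for r in afreq[_KEY_COLS].itertuples(index=False)]
    if lkeys != fkeys:
        raise BundleError(
            "loadings and allele frequencies do not cover identical variant sets"
        )
    if len(lkeys) != manifest.get("n_variants"):
        raise BundleError("manifest variant count disagrees with loadings.tsv")
    if len(eigen) != k:
        raise BundleError("eigenvalue count disagrees with loading PC columns")

    beta_cols = [c for c in models_df.columns if c.startswith("beta")]
    if len(beta_cols) != 4:
        raise BundleError(
            f"adjustment models carry {len(beta_cols)} PC coefficients; the "
            "assay contract requires exactly 4 (PRS_raw ~ PC1 + PC2 + PC3 + PC4)"
        )
    models = {}
    for row in models_df.itertuples(index=False):
        m = AdjustmentModel(
            disease=row.disease,
            intercept=float(row.intercept),
            beta=tuple(float(getattr(row, c)) for c in beta_cols),
            ref_mean_adj=float(row.ref_mean_adj),
            ref_sd_adj=float(row.ref_sd_adj),
        )
        models[m.disease] = m
    if len(models) != manifest.get("n_models"):
        raise BundleError("manifest model count disagrees with models.tsv")

    variant_keys = [(str(c), int(p), str(r), str(a)) for c, p, r, a in lkeys]
    ref = PCAReference(
        variant_keys=variant_keys,
        allele_frequencies=afreq["alt_freq"].to_numpy(),
        loadings=loadings[pc_cols].to_numpy(),
        eigenvalues=eigen["eigenvalue"].to_numpy(),
        ref_coordinates=coords[pc_cols].to_numpy(),
        ref_samples=coords["sample"].astype(str).tolist(),
        scaling_mode=manifest.get("scaling_mode", "sqrt_eig_x2"),
    )
    return ref, models


def read_disease_configs(path: str | Path) -> list[DiseaseConfig]:
    """Load per-disease assay configuration from YAML.

    Expected layout::

        diseases:
          - {disease: BrCa, or_sd: 1.57, target_or: 2, sex: female}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["diseases"] if isinstance(doc, dict) else doc
    configs = []
    for e in entries:
        configs.append(
            DiseaseConfig(
                disease=str(e["disease"]),
                or_sd=float(e["or_sd"]),
                target_or=float(e.get("target_or", 2.0)),
                sex=e.get("sex"),
            )
        )
    return configs


def write_disease_configs(configs: Iterable[DiseaseConfig], path: str | Path) -> None:
    doc = {"diseases": [
        {k: v for k, v in dataclasses.asdict(c).items() if v is not None}
        for c in configs
    ]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def build_report(results: Sequence[ScoreResult], findings: Sequence,
                 thresholds: Mapping[str, object] | None = None,
                 call_rates: Mapping[str, float] | None = None) -> dict:
    """Assemble the JSON-serializable report document.

    PRS results and monogenic secondary findings are reported in separate
    sections, without comment on any interaction between them. Any PRS not
    categorized as high risk is described as conferring average risk, which
    classification already guarantees (category is always high/average).
    """
    samples: dict[str, dict] = {}
    for r in results:
        if r.category is None:
            raise ValueError(
                f"unclassified ScoreResult for {r.sample_id}/{r.disease}"
            )
        entry = {
            "category": r.category,
            "prs_std_adj": r.prs_std_adj,
        }
        if thresholds is not None and r.disease in thresholds:
            t = thresholds[r.disease]
            entry["tau"] = t.tau
            entry["or_sd"] = t.or_sd
            entry["target_or"] = t.target_or
        samples.setdefault(r.sample_id, {"prs": {}})["prs"][r.disease] = entry
    if call_rates:
        for sid, rate in call_rates.items():
            if sid in samples:
                samples[sid]["call_rate"] = rate
    return {
        "schema": "clinprs-report-v1",
        "samples": samples,
        "secondary_findings": [
            dataclasses.asdict(f) if dataclasses.is_dataclass(f) else dict(f)
            for f in findings
        ],
        "limitations": LIMITATIONS_TEXT,
    }


def write_report(results: Sequence[ScoreResult], findings: Sequence,
                 path: str | Path, thresholds: Mapping[str, object] | None = None,
                 call_rates: Mapping[str, float] | None = None) -> dict:
    """Write the assay report as JSON and return the document."""
    doc = build_report(results, findings, thresholds=thresholds,
                       call_rates=call_rates)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
    return doc


def load_published_replication_table() -> pd.DataFrame:
    """Published 2x2 counts (high-risk PRS x disease) from a 36,423-participant
    biobank replication of six PRS, overall and by reported race, together
    with the odds ratios and 95% CIs as printed in the source publication.

    Columns: disease, group, a (high-risk cases), b (high-risk controls),
    c (other cases), d (other controls), or_printed, ci_low_printed,
    ci_high_printed (the latter three as printed strings; ``NA``/``NaN``
    mark the degenerate zero-cell entry).
    """
    with resources.files("clinprs.data").joinpath(
        "replication_table.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"or_printed": str,
                                                "ci_low_printed": str,
                                                "ci_high_printed": str})
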