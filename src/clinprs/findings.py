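"""Rule-based screening of annotated variants for actionable monogenic findings.

A variant in the secondary-findings gene panel is flagged if any of four
criteria hold: (1) previously classified pathogenic/likely pathogenic by the
reporting laboratory; (2) ClinVar pathogenic/likely pathogenic with
MAF < 0.1%; (3) an HGMD disease-causing mutation with MAF < 0.03%; (4) a
loss-of-function variant (nonsense, frameshift, canonical splice-site,
start-loss) with MAF < 0.1% in a gene where loss of function is an
established disease mechanism. Absence from frequency databases (unknown
MAF) is treated as evidence of rarity and passes the MAF gates by default.

Output variants are candidates for expert review (formal classification and
orthogonal confirmation are human steps outside this package).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

#: Consequences counted as loss of function.
LOF_CONSEQUENCES = frozenset(
    {"nonsense", "frameshift", "canonical_splice", "start_lost"}
)

RULE_LAB_KNOWN = "lab_known"
RULE_CLINVAR_PLP = "clinvar_plp"
RULE_HGMD_DM = "hgmd_dm"
RULE_LOF = "lof"


@dataclass(frozen=True)
class AnnotatedVariant:
    """One externally annotated variant (annotation engines are upstream)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    maf: float | None  # None = unknown (absent from frequency databases)
    clinvar: str = "none"  # P, LP, VUS, LB, B, none
    hgmd_dm: bool = False
    lab_known_plp: bool = False

    def __post_init__(self) -> None:
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"MAF {self.maf} outside [0, 1]")


@dataclass
class FilterRules:
    """Gene panel (gene -> LoF-mechanism flag) and MAF gates.

    Defaults follow the published screening thresholds: 0.1% for ClinVar
    P/LP and loss-of-function variants, 0.03% for HGMD disease-causing
    mutations; all gates are strict ``<`` comparisons.
    """

    gene_panel: dict[str, bool]
    maf_clinvar: float = 0.001
    maf_hgmd: float = 0.0003
    maf_lof: float = 0.001
    unknown_maf_passes: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_clinvar", "maf_hgmd", "maf_lof"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass(frozen=True)
class SecondaryFinding:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    rules_triggered: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rules_triggered:
            raise ValueError("a finding must have at least one triggered rule")


def load_default_gene_panel() -> dict[str, bool]:
    """The 59-gene ACMG SF v2.0 screening panel with per-gene
    LoF-mechanism flags, shipped as editable package config."""
    with resources.files("clinprs.data").joinpath("acmg_sf_v2_genes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return {row.gene: bool(row.lof_mechanism) for row in df.itertuples(index=False)}


def default_rules() -> FilterRules:
    return FilterRules(gene_panel=load_default_gene_panel())


def _maf_passes(maf: float | None, threshold: float, rules: FilterRules) -> bool:
    if maf is None:
        return rules.unknown_maf_passes
    return maf < threshold


def filter_variants(variants: Sequence[AnnotatedVariant],
                    rules: FilterRules) -> list[SecondaryFinding]:
    """Apply the four screening criteria; all triggered rules are recorded."""
    if not rules.gene_panel:
        raise ValueError("gene panel is empty")
    findings = []
    for v in variants:
        if v.gene not in rules.gene_panel:
            continue
        triggered = []
        if v.lab_known_plp:
            triggered.append(RULE_LAB_KNOWN)
        if v.clinvar in ("P", "LP") and _maf_passes(v.maf, rules.maf_clinvar, rules):
            triggered.append(RULE_CLINVAR_PLP)
        if v.hgmd_dm and _maf_passes(v.maf, rules.maf_hgmd, rules):
            triggered.append(RULE_HGMD_DM)
        if (
            v.consequence in LOF_CONSEQUENCES
            and rules.gene_panel[v.gene]
            and _maf_passes(v.maf, rules.maf_lof, rules)
        ):
            triggered.append(RULE_LOF)
        if triggered:
            findings.append(
                SecondaryFinding(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                                 gene=v.gene, rules_triggered=tuple(triggered))
            )
    return findings


def read_annotated_variants(path: str | Path) -> list[AnnotatedVariant]:
    """Read a tab-separated annotated-variant table.

    Columns: chrom, pos, ref, alt, gene, consequence, maf (empty = unknown),
    clinvar, hgmd_dm (0/1), lab_known_plp (0/1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        maf = None if pd.isna(row.maf) else float(row.maf)
        out.append(
            AnnotatedVariant(
                chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref),
                alt=str(row.alt), gene=str(row.gene),
                consequence=str(row.consequence), maf=maf,
                clinvar=str(row.clinvar) if not pd.isna(row.clinvar) else "none",
                hgmd_dm=bool(row.hgmd_dm), lab_known_plp=bool(row.lab_known_plp),
            )
        )
    return out


def write_findings(findings: Sequence[SecondaryFinding], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\trules_triggered\n")
        for f in findings:
            fh.write(f"{f.chrom}\t{f.pos}\t{f.ref}\t{f.alt}\t{f.gene}\t"
                     f"{','.join(f.rules_triggered)}\n")
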