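"""Allele harmonization, QC and raw PRS computation.

The raw PRS is the product of the count of effect (risk) alleles and the
effect-allele weight at each locus, summed across available loci. Missing
genotypes contribute nothing (no mean imputation), so single-sample batches
are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .types import (
    DosageMatrix,
    RawScore,
    SampleGenotypes,
    VariantKey,
    WeightTable,
)

#: Strand-ambiguous (palindromic) allele pairs: indistinguishable between
#: strands without frequency information, which this engine does not use.
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

STATUS_MATCHED = "matched"
STATUS_FLIPPED = "flipped"
STATUS_DROPPED_AMBIGUOUS = "dropped_ambiguous"
STATUS_DROPPED_MISSING = "dropped_missing"


@dataclass(frozen=True)
class HarmonizedLocus:
    """One weight-table locus after matching against observed alleles.

    ``dosage_transform`` maps the stored ALT dosage to an effect-allele
    dosage: ``identity`` (effect allele is ALT) or ``complement`` (effect
    allele is REF; effect dosage = 2 - ALT dosage). Dropped loci contribute
    0 to the score and carry a drop reason.
    """

    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    weight: float
    dosage_transform: str | None  # "identity" | "complement" | None if dropped
    status: str
    reason: str | None = None
    alt_dosage: float | None = None  # observed ALT dosage; None if missing/dropped

    @property
    def effect_dosage(self) -> float | None:
        if self.alt_dosage is None or self.dosage_transform is None:
            return None
        if self.dosage_transform == "identity":
            return self.alt_dosage
        return 2.0 - self.alt_dosage

    @property
    def usable(self) -> bool:
        return (
            self.status in (STATUS_MATCHED, STATUS_FLIPPED)
            and self.alt_dosage is not None
        )


def _match_alleles(effect: str, other: str, ref: str, alt: str) -> str | None:
    """Return the dosage transform for this orientation, or None if the
    weight-table alleles do not correspond to the observed REF/ALT pair."""
    if effect == alt and other == ref:
        return "identity"
    if effect == ref and other == alt:
        return "complement"
    return None


def harmonize(weights: WeightTable, genotypes: SampleGenotypes,
              ambiguous_policy: str = "drop") -> list[HarmonizedLocus]:
    """Match each weight-table locus to the sample's observed alleles.

    Strand-ambiguous A/T and C/G pairs are dropped under the default
    ``drop`` policy (array strand is unverifiable without frequencies) or
    matched normally under ``keep``. Loci absent from the genotypes, or with
    alleles that match neither orientation, are dropped with a reason.
    Degradation is logged in the returned loci, never fatal.
    """
    if ambiguous_policy not in ("drop", "keep"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    out = []
    for rec in weights:
        base = dict(chrom=rec.chrom, pos=rec.pos, effect_allele=rec.effect_allele,
                    other_allele=rec.other_allele, weight=rec.weight)
        if (
            ambiguous_policy == "drop"
            and (rec.effect_allele, rec.other_allele) in _PALINDROMIC
        ):
            out.append(HarmonizedLocus(**base, dosage_transform=None,
                                       status=STATUS_DROPPED_AMBIGUOUS,
                                       reason="strand-ambiguous palindromic pair"))
            continue
        call = genotypes.get(rec.chrom, rec.pos)
        if call is None:
            out.append(HarmonizedLocus(**base, dosage_transform=None,
                                       status=STATUS_DROPPED_MISSING,
                                       reason="variant absent from genotypes"))
            continue
        transform = _match_alleles(rec.effect_allele, rec.other_allele,
                                   call.ref, call.alt)
        if transform is None:
            out.append(HarmonizedLocus(**base, dosage_transform=None,
                                       status=STATUS_DROPPED_MISSING,
                                       reason=f"allele mismatch "
                                              f"({call.ref}/{call.alt} observed)"))
            continue
        status = STATUS_MATCHED if transform == "identity" else STATUS_FLIPPED
        out.append(HarmonizedLocus(**base, dosage_transform=transform,
                                   status=status, alt_dosage=call.dosage))
    return out


def compute_raw_prs(loci: Sequence[HarmonizedLocus], sample_id: str,
                    disease: str) -> RawScore:
    """Sum weight x effect-allele dosage over usable loci.

    Loci with a missing genotype contribute nothing and are not counted in
    ``n_loci_used``. Zero usable loci is an error naming the disease.
    """
    used = [l for l in loci if l.usable]
    if not used:
        raise ValueError(f"no usable loci to score disease {disease!r}")
    prs = float(sum(l.weight * l.effect_dosage for l in used))
    return RawScore(sample_id=sample_id, disease=disease, prs_raw=prs,
                    n_loci_used=len(used), n_loci_total=len(loci))


@dataclass(frozen=True)
class CallRateCheck:
    passed: bool
    call_rate: float
    threshold: float


def check_call_rate(genotypes: SampleGenotypes,
                    threshold: float = 0.985) -> CallRateCheck:
    """QC gate: pass iff the overall call rate is strictly greater than the
    threshold (default 98.5%)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    rate = genotypes.call_rate
    return CallRateCheck(passed=rate > threshold, call_rate=rate,
                         threshold=threshold)


def write_drop_log(loci: Sequence[HarmonizedLocus], path: str | Path) -> None:
    """Tab-separated log of every dropped locus: variant key and reason."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\teffect_allele\tother_allele\tstatus\treason\n")
        for l in loci:
            if l.status in (STATUS_DROPPED_AMBIGUOUS, STATUS_DROPPED_MISSING):
                fh.write(f"{l.chrom}\t{l.pos}\t{l.effect_allele}\t"
                         f"{l.other_allele}\t{l.status}\t{l.reason}\n")


# ---------------------------------------------------------------------------
# Cohort-mode scoring (vectorized over a DosageMatrix).

def harmonize_panel(weights: WeightTable, variants: Sequence[VariantKey],
                    ambiguous_policy: str = "drop"
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match a weight table against a cohort variant panel.

    Returns ``(indices, w, flip)``: column indices into the panel, the
    per-locus weights, and a boolean flag marking complement-transformed
    loci (effect allele = REF).
    """
    if ambiguous_policy not in ("drop", "keep"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    by_pos: dict[tuple[str, int], list[int]] = {}
    for j, (chrom, pos, _, _) in enumerate(variants):
        by_pos.setdefault((chrom, pos), []).append(j)
    idx, w, flip = [], [], []
    for rec in weights:
        if (
            ambiguous_policy == "drop"
            and (rec.effect_allele, rec.other_allele) in _PALINDROMIC
        ):
            continue
        for j in by_pos.get((rec.chrom, rec.pos), []):
            _, _, ref, alt = variants[j]
            transform = _match_alleles(rec.effect_allele, rec.other_allele, ref, alt)
            if transform is not None:
                idx.append(j)
                w.append(rec.weight)
                flip.append(transform == "complement")
                break
    return np.asarray(idx, dtype=int), np.asarray(w, dtype=float), np.asarray(
        flip, dtype=bool
    )


def compute_raw_prs_cohort(weights: WeightTable, dm: DosageMatrix,
                           ambiguous_policy: str = "drop") -> np.ndarray:
    """Raw PRS for every sample in a cohort dosage matrix.

    Missing dosages contribute nothing, matching the per-sample path.
    """
    idx, w, flip = harmonize_panel(weights, dm.variants, ambiguous_policy)
    if idx.size == 0:
        raise ValueError(
            f"no usable loci to score weight table {weights.prs_id!r}"
        )
    d = dm.dosages[:, idx]
    eff = np.where(flip[None, :], 2.0 - d, d)
    return np.nansum(eff * w[None, :], axis=1)
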