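"""Core in-memory containers shared across the pipeline.

A variant is identified everywhere by the key ``(chrom, pos, ref, alt)``
with a 1-based VCF position; genome builds are assumed consistent between
all inputs (single-build contract, no liftover).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: (chrom, pos, ref, alt) with 1-based position.
VariantKey = tuple[str, int, str, str]


class QCFailure(Exception):
    """A sample failed quality control (e.g. overall call rate too low)."""

    def __init__(self, message: str, call_rate: float | None = None):
        super().__init__(message)
        self.call_rate = call_rate


class BundleError(ValueError):
    """A reference bundle is missing files or internally inconsistent."""


@dataclass(frozen=True)
class WeightRecord:
    """One scored locus: per-copy weight of the effect allele (log-odds scale)."""

    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    weight: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"effect and other allele identical at {self.chrom}:{self.pos}"
            )
        if not math.isfinite(self.weight):
            raise ValueError(f"non-finite weight at {self.chrom}:{self.pos}")


@dataclass
class WeightTable:
    """An ordered scoring file for one disease PRS."""

    prs_id: str
    records: list[WeightRecord]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int, str], int] = {}
        for i, r in enumerate(self.records):
            key = (r.chrom, r.pos, r.effect_allele)
            if key in seen:
                raise ValueError(
                    f"duplicate variant key {key} at rows {seen[key]} and {i} "
                    f"in weight table {self.prs_id!r}"
                )
            seen[key] = i

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class GenotypeCall:
    """Observed alleles and ALT-allele dosage at one site; dosage None = missing."""

    ref: str
    alt: str
    dosage: float | None

    def __post_init__(self) -> None:
        if self.dosage is not None and not (0.0 <= self.dosage <= 2.0):
            raise ValueError(f"dosage {self.dosage} outside [0, 2]")


@dataclass
class SampleGenotypes:
    """All genotype calls for one sample, keyed by (chrom, pos).

    Biallelic sites only (multi-allelic records must be split/normalized
    upstream). ``call_rate`` is the fraction of sites with a non-missing
    genotype; masked (missing) sites are never imputed here.
    """

    sample_id: str
    calls: dict[tuple[str, int], GenotypeCall]

    @property
    def call_rate(self) -> float:
        if not self.calls:
            return 0.0
        n_called = sum(1 for c in self.calls.values() if c.dosage is not None)
        return n_called / len(self.calls)

    @property
    def n_missing(self) -> int:
        return sum(1 for c in self.calls.values() if c.dosage is None)

    def get(self, chrom: str, pos: int) -> GenotypeCall | None:
        return self.calls.get((chrom, pos))


@dataclass
class DosageMatrix:
    """Effect-agnostic ALT-allele dosages for a cohort, NaN marking missingness."""

    samples: list[str]
    variants: list[VariantKey]
    dosages: np.ndarray  # shape (n_samples, n_variants), float, NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(
                self.dosages, initial=0.0
            ) > 2:
                raise ValueError("dosages outside [0, 2]")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def sample_genotypes(self, sample: str) -> SampleGenotypes:
        """Extract one sample as a :class:`SampleGenotypes` view."""
        i = self.samples.index(sample)
        calls = {}
        for j, (chrom, pos, ref, alt) in enumerate(self.variants):
            d = self.dosages[i, j]
            calls[(chrom, pos)] = GenotypeCall(ref, alt, None if np.isnan(d) else float(d))
        return SampleGenotypes(sample_id=sample, calls=calls)


@dataclass(frozen=True)
class DiseaseConfig:
    """Per-disease assay configuration.

    ``or_sd`` is the published odds ratio per standard deviation of the
    standardized adjusted PRS; ``target_or`` the odds ratio defining high
    risk (default 2). ``sex`` restricts scoring to samples of that reported
    sex (``None`` = scored for everyone).
    """

    disease: str
    or_sd: float
    target_or: float = 2.0
    sex: str | None = None

    def __post_init__(self) -> None:
        if not self.or_sd > 1:
            raise ValueError(f"{self.disease}: or_sd must be > 1, got {self.or_sd}")
        if not self.target_or > 1:
            raise ValueError(
                f"{self.disease}: target_or must be > 1, got {self.target_or}"
            )
        if self.sex not in (None, "male", "female"):
            raise ValueError(f"{self.disease}: sex must be male/female/None")


@dataclass
class PCAReference:
    """Reference-panel principal components for projecting new samples.

    ``loadings`` are projection-ready per-allele weights: a new sample's raw
    projection is the dot product of its variance-standardized dosages with
    these columns, and the published scaling recipe (multiply by the square
    root of the eigenvalue, then by 2) recovers reference-scale coordinates.
    """

    variant_keys: list[VariantKey]
    allele_frequencies: np.ndarray  # effect(ALT)-allele frequency per variant
    loadings: np.ndarray  # (n_variants, k)
    eigenvalues: np.ndarray  # (k,) descending
    ref_coordinates: np.ndarray  # (n_ref_samples, k)
    ref_samples: list[str]
    scaling_mode: str = "sqrt_eig_x2"

    def __post_init__(self) -> None:
        self.allele_frequencies = np.asarray(self.allele_frequencies, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.ref_coordinates = np.asarray(self.ref_coordinates, dtype=float)
        k = self.loadings.shape[1]
        if k < 4:
            raise ValueError(f"reference must carry at least 4 PCs, got {k}")
        if len(self.eigenvalues) != k:
            raise ValueError("eigenvalue count does not match loading columns")
        if np.any(self.eigenvalues <= 0):
            raise ValueError("eigenvalues must be positive")
        if np.any(np.diff(self.eigenvalues) > 0):
            raise ValueError("eigenvalues must be sorted descending")
        if len(self.variant_keys) != self.loadings.shape[0] or len(
            self.variant_keys
        ) != len(self.allele_frequencies):
            raise ValueError("loadings and frequencies must cover identical variants")

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


@dataclass(frozen=True)
class PCCoordinates:
    """First-four principal-component coordinates of one sample (reference scale)."""

    sample_id: str
    pc: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.pc) != 4 or not all(math.isfinite(x) for x in self.pc):
            raise ValueError("pc must be 4 finite floats")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.pc, dtype=float)


@dataclass(frozen=True)
class AdjustmentModel:
    """Per-disease linear model raw PRS ~ PC1..PC4 fitted in reference controls,
    plus the reference mean/SD of the adjusted (residual) PRS used for
    standardization."""

    disease: str
    intercept: float
    beta: tuple[float, float, float, float]
    ref_mean_adj: float
    ref_sd_adj: float

    def __post_init__(self) -> None:
        if len(self.beta) != 4:
            raise ValueError(
                f"{self.disease}: adjustment model must have exactly 4 PC "
                f"coefficients, got {len(self.beta)}"
            )
        if not self.ref_sd_adj > 0:
            raise ValueError(f"{self.disease}: ref_sd_adj must be > 0")

    def predict(self, pcs: np.ndarray) -> float | np.ndarray:
        pcs = np.asarray(pcs, dtype=float)
        return self.intercept + pcs @ np.asarray(self.beta)


@dataclass(frozen=True)
class RawScore:
    """Unadjusted raw PRS for one sample and disease."""

    sample_id: str
    disease: str
    prs_raw: float
    n_loci_used: int
    n_loci_total: int

    def __post_init__(self) -> None:
        if self.n_loci_used > self.n_loci_total:
            raise ValueError("n_loci_used exceeds n_loci_total")
        if not math.isfinite(self.prs_raw):
            raise ValueError("prs_raw must be finite")


@dataclass(frozen=True)
class ScoreResult:
    """Full scoring result for one sample and disease.

    ``prs_adj = prs_raw - prs_pred`` and
    ``prs_std_adj = (prs_adj - ref_mean_adj) / ref_sd_adj``.
    ``category`` is None until classification.
    """

    sample_id: str
    disease: str
    prs_raw: float
    prs_pred: float
    prs_adj: float
    prs_std_adj: float
    category: str | None = None

    def __post_init__(self) -> None:
        if not math.isclose(self.prs_adj, self.prs_raw - self.prs_pred,
                            rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("prs_adj must equal prs_raw - prs_pred")
        if self.category not in (None, "high", "average"):
            raise ValueError(f"invalid category {self.category!r}")
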