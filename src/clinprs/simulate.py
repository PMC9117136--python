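"""Seedable multi-subpopulation cohort generator.

Genotypes follow the Balding-Nichols model: each variant draws an ancestral
allele frequency p ~ Uniform(range); each subpopulation then draws its own
frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), so F acts as the divergence
(Fst) between subpopulations; genotypes are Binomial(2, p_sub). Effect
weights are N(0, weights_scale^2) with the effect allele assigned at random
to REF or ALT, which exercises allele harmonization downstream. Disease
status is generated from a logistic model whose log-odds is linear in the
standardized adjusted PRS, with slope ln(OR_sd) and an intercept solved so
the cohort prevalence matches its target.

No linkage disequilibrium, admixture gradients or imputation-error model:
subpopulation structure enters only through allele-frequency divergence.

Randomness comes from one seed partitioned into named substreams (variants,
frequencies, genotypes, weights, disease), so e.g. changing the variant
count does not perturb the disease labels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import integrate, optimize
from scipy import stats as sps
from scipy.special import expit

from . import ancestry, engine, io
from .types import (
    AdjustmentModel,
    DiseaseConfig,
    DosageMatrix,
    PCAReference,
    WeightRecord,
    WeightTable,
)

# Ordered, strand-unambiguous REF/ALT pairs (palindromic A/T and C/G excluded
# so that every simulated locus is scoreable under the default drop policy).
_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults give two subpopulations with moderate divergence (F = 0.05),
    a 500-variant score with per-allele weights of SD 0.1, a per-SD odds
    ratio of 1.3 and a 15% disease prevalence; see the methods note for
    the calibration rationale behind the OR/prevalence pairing.
    """

    n_per_subpop: tuple[int, ...] = (1000, 1000)
    n_variants: int = 500
    fst: float = 0.05
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    weights_scale: float = 0.1
    or_sd_true: float = 1.3
    prevalence_target: float = 0.15
    #: Systematic risk-allele frequency shift applied to every subpopulation
    #: after the first (confounded scenario: groups differ in risk-allele
    #: frequency but not in true effect, so raw PRS distributions separate
    #: for structural reasons only).
    risk_freq_shift: float = 0.0
    disease: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 1:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if not 0 < self.prevalence_target < 1:
            raise ValueError("prevalence_target must be in (0, 1)")
        if self.or_sd_true <= 0:
            raise ValueError("or_sd_true must be positive")


def _rng(seed: int, stage: str) -> np.random.Generator:
    key = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _draw_variants(spec: CohortSpec) -> list:
    rng_var = _rng(spec.seed, "variants")
    pair_idx = rng_var.integers(0, len(_ALLELE_PAIRS), size=spec.n_variants)
    return [
        ("1", 10_001 + 100 * j, *_ALLELE_PAIRS[pair_idx[j]])
        for j in range(spec.n_variants)
    ]


def simulate_genotypes(spec: CohortSpec,
                       alt_freq_shift: np.ndarray | None = None
                       ) -> tuple[DosageMatrix, np.ndarray]:
    """Draw a genotype panel; returns the dosage matrix and the per-sample
    subpopulation index.

    ``alt_freq_shift``, when given, is a per-variant ALT-frequency offset
    added to every subpopulation after the first (the confounded scenario).
    """
    m = spec.n_variants
    pops = len(spec.n_per_subpop)
    lo, hi = spec.ancestral_freq_range
    p_anc = _rng(spec.seed, "frequencies").uniform(lo, hi, size=m)

    rng_sub = _rng(spec.seed, "subpop-frequencies")
    if spec.fst > 0:
        a = p_anc * (1 - spec.fst) / spec.fst
        b = (1 - p_anc) * (1 - spec.fst) / spec.fst
        p_sub = rng_sub.beta(a, b, size=(pops, m))
    else:
        p_sub = np.tile(p_anc, (pops, 1))
    if alt_freq_shift is not None:
        p_sub[1:] = np.clip(p_sub[1:] + alt_freq_shift[None, :], 0.01, 0.99)

    rng_geno = _rng(spec.seed, "genotypes")
    blocks = [
        rng_geno.binomial(2, p_sub[k], size=(n_k, m)).astype(float)
        for k, n_k in enumerate(spec.n_per_subpop)
    ]
    dosages = np.vstack(blocks)
    subpop = np.repeat(np.arange(pops), spec.n_per_subpop)

    variants = _draw_variants(spec)
    samples = [f"S{i:05d}" for i in range(dosages.shape[0])]
    return DosageMatrix(samples=samples, variants=variants, dosages=dosages), subpop


def simulate_weights(spec: CohortSpec, variants: list) -> WeightTable:
    """Per-allele weights N(0, weights_scale^2); effect allele randomly
    REF or ALT."""
    rng = _rng(spec.seed, "weights")
    w = rng.normal(0.0, spec.weights_scale, size=len(variants))
    effect_is_alt = rng.random(len(variants)) < 0.5
    records = []
    for j, (chrom, pos, ref, alt) in enumerate(variants):
        eff, oth = (alt, ref) if effect_is_alt[j] else (ref, alt)
        records.append(WeightRecord(chrom=chrom, pos=pos, effect_allele=eff,
                                    other_allele=oth, weight=float(w[j])))
    return WeightTable(prs_id=f"SIM-{spec.disease}", records=records)


def simulate_disease(prs_std: np.ndarray, or_sd_true: float,
                     prevalence_target: float, seed: int) -> np.ndarray:
    """Draw 0/1 disease labels with P(case) = logistic(b0 + ln(OR_sd) * z),
    b0 solved numerically so the expected prevalence hits the target."""
    if or_sd_true <= 0:
        raise ValueError("or_sd_true must be positive")
    if not 0 < prevalence_target < 1:
        raise ValueError(
            f"unattainable prevalence target {prevalence_target}; must be in (0, 1)"
        )
    z = np.asarray(prs_std, dtype=float)
    slope = np.log(or_sd_true)

    def mean_risk(b0: float) -> float:
        return float(np.mean(expit(b0 + slope * z))) - prevalence_target

    b0 = optimize.brentq(mean_risk, -40.0, 40.0)
    p = expit(b0 + slope * z)
    rng = _rng(seed, "disease")
    return (rng.random(z.shape[0]) < p).astype(int)


def expected_dichotomous_or(or_sd: float, prevalence: float,
                            target_or: float = 2.0) -> float:
    """Theoretical odds ratio comparing samples above vs below the tau
    threshold, under z ~ N(0,1) and a logistic disease model with per-SD
    odds ratio ``or_sd``.

    This quantity exceeds ``target_or`` for any or_sd > 1 and approaches it
    only as or_sd -> 1; it guides the choice of simulation conditions for
    threshold-calibration checks.
    """
    b = np.log(or_sd)
    tau = np.log(target_or) / b

    def solve_b0() -> float:
        f = lambda b0: integrate.quad(
            lambda z: sps.norm.pdf(z) * expit(b0 + b * z), -8, 8
        )[0] - prevalence
        return optimize.brentq(f, -30, 30)

    b0 = solve_b0()
    p = lambda z: expit(b0 + b * z)
    phi = sps.norm.pdf
    a_ = integrate.quad(lambda z: phi(z) * p(z), tau, 8)[0]
    b_ = integrate.quad(lambda z: phi(z) * (1 - p(z)), tau, 8)[0]
    c_ = integrate.quad(lambda z: phi(z) * p(z), -8, tau)[0]
    d_ = integrate.quad(lambda z: phi(z) * (1 - p(z)), -8, tau)[0]
    return (a_ * d_) / (b_ * c_)


@dataclass
class SyntheticCohort:
    """A fully realized synthetic study: genotypes, weights, labels, the
    reference artifacts built from the panel itself, and truth scores."""

    spec: CohortSpec
    dosages: DosageMatrix
    subpop: np.ndarray
    weights: WeightTable
    prs_raw: np.ndarray
    pca: PCAReference
    prs_std_true: np.ndarray  # standardized residual used to generate labels
    labels: np.ndarray
    model: AdjustmentModel  # control-fitted, as the assay prescribes
    prs_std_adj: np.ndarray  # assay-side standardized adjusted score

    @property
    def config(self) -> DiseaseConfig:
        return DiseaseConfig(disease=self.spec.disease,
                             or_sd=self.spec.or_sd_true, target_or=2.0)


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort and run the reference-side pipeline on it.

    Disease labels are generated from the standardized residual of an
    all-sample fit (the generator's truth); the assay-side adjustment model
    is then re-fitted in controls only, exactly as prescribed for the
    reference cohort.
    """
    variants = _draw_variants(spec)
    weights = simulate_weights(spec, variants)
    shift = None
    if spec.risk_freq_shift != 0.0:
        # Shift each ALT frequency toward the risk direction: the ALT-scale
        # weight is +w when the effect allele is ALT, -w when it is REF.
        w_alt = np.array([
            r.weight if r.effect_allele == alt else -r.weight
            for r, (_, _, _, alt) in zip(weights.records, variants)
        ])
        shift = spec.risk_freq_shift * np.sign(w_alt)
    dm, subpop = simulate_genotypes(spec, alt_freq_shift=shift)
    prs_raw = engine.compute_raw_prs_cohort(weights, dm)
    pca = ancestry.fit_reference_pca(dm, k=4)
    coords = pca.ref_coordinates[:, :4]

    all_mask = np.ones(len(prs_raw), dtype=bool)
    truth_model = ancestry.fit_adjustment_model(prs_raw, coords, all_mask,
                                                disease=spec.disease)
    _, prs_std_true = ancestry.adjust_cohort(prs_raw, coords, truth_model)

    labels = simulate_disease(prs_std_true, spec.or_sd_true,
                              spec.prevalence_target, spec.seed)
    controls = labels == 0
    model = ancestry.fit_adjustment_model(prs_raw, coords, controls,
                                          disease=spec.disease)
    _, prs_std_adj = ancestry.adjust_cohort(prs_raw, coords, model)
    return SyntheticCohort(spec=spec, dosages=dm, subpop=subpop,
                           weights=weights, prs_raw=prs_raw, pca=pca,
                           prs_std_true=prs_std_true, labels=labels,
                           model=model, prs_std_adj=prs_std_adj)


def write_vcf(dm: DosageMatrix, path: str | Path,
              missing_mask: np.ndarray | None = None) -> None:
    """Write the cohort as a VCF 4.2 text file with GT and DS fields.

    Deterministic byte-for-byte for a given dosage matrix.
    """
    mask = dm.missing_mask if missing_mask is None else missing_mask
    contigs = sorted({v[0] for v in dm.variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated ALT allele dosage">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dm.samples) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, (chrom, pos, ref, alt) in enumerate(dm.variants):
            fields = [chrom, str(pos), f"var{j}", ref, alt, ".", "PASS", ".",
                      "GT:DS"]
            for i in range(len(dm.samples)):
                if mask[i, j]:
                    fields.append("./.:.")
                else:
                    d = dm.dosages[i, j]
                    gt = gt_map[int(round(d))]
                    fields.append(f"{gt}:{d:g}")
            fh.write("\t".join(fields) + "\n")


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Emit the full on-disk study: VCF, weight TSV, truth TSV, disease
    config, and the reference bundle built from the simulated panel."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": d / "genotypes.vcf",
        "weights": d / f"weights_{cohort.spec.disease}.tsv",
        "truth": d / "truth.tsv",
        "config": d / "diseases.yaml",
        "bundle": d / "bundle",
    }
    write_vcf(cohort.dosages, paths["vcf"])
    io.write_weight_table(cohort.weights, paths["weights"])
    with open(paths["truth"], "w") as fh:
        fh.write("sample\tsubpop\tlabel\tprs_raw\tprs_std_true\tprs_std_adj\n")
        for i, s in enumerate(cohort.dosages.samples):
            fh.write(f"{s}\t{cohort.subpop[i]}\t{cohort.labels[i]}\t"
                     f"{cohort.prs_raw[i]!r}\t{cohort.prs_std_true[i]!r}\t"
                     f"{cohort.prs_std_adj[i]!r}\n")
    io.write_disease_configs([cohort.config], paths["config"])
    io.write_reference_bundle(cohort.pca, {cohort.spec.disease: cohort.model},
                              paths["bundle"])
    return paths
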