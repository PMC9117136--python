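"""Population-structure reference construction and PRS adjustment.

Systematic allele-frequency differences among ancestral groups shift PRS
distributions even when per-allele effects are identical across groups. The
remedy implemented here: principal components are computed once on a large
reference panel; for each disease an ordinary least squares model
``PRS_raw ~ PC1 + PC2 + PC3 + PC4`` is fitted in reference controls; any
sample's adjusted score is the residual ``PRS_raw - PRS_pred``, standardized
by the mean and SD of the adjusted score across the whole reference panel.

A prospectively genotyped individual cannot be re-decomposed with the
reference, so it is *projected*: its variance-standardized dosages (using
reference allele frequencies, missing variants skipped, never
mean-imputed) are multiplied by stored per-allele loadings, and the raw
projection is rescaled by sqrt(eigenvalue) x 2 to the reference coordinate
scale. The bundle stores loadings pre-scaled so that this literal recipe
reproduces a held-in reference sample's coordinates exactly.
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm

from .types import (
    AdjustmentModel,
    DosageMatrix,
    PCAReference,
    PCCoordinates,
    RawScore,
    SampleGenotypes,
    ScoreResult,
)


def _standardize(dosages: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Variance-standardize ALT dosages under Hardy-Weinberg: (d - 2p)/sqrt(2p(1-p))."""
    return (dosages - 2.0 * freqs) / np.sqrt(2.0 * freqs * (1.0 - freqs))


def fit_reference_pca(dm: DosageMatrix, k: int = 4) -> PCAReference:
    """Decompose a reference panel into principal components.

    Variants with zero variance (monomorphic or constant) are excluded.
    Missing reference dosages are mean-filled for the decomposition only.
    The sign of each PC is fixed deterministically (largest-|loading|
    entry positive) so bundles are reproducible across runs.
    """
    n, m = dm.dosages.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples to fit {k} PCs, got {n}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        freqs = np.nanmean(dm.dosages, axis=0) / 2.0
        variances = np.nanvar(dm.dosages, axis=0)
    keep = np.isfinite(freqs) & (freqs > 0) & (freqs < 1) & (variances > 0)
    if not np.any(keep):
        raise ValueError("no polymorphic variants with non-zero variance")
    freqs = freqs[keep]
    X = _standardize(dm.dosages[:, keep], freqs)
    X = np.where(np.isnan(X), 0.0, X)  # mean-fill for the decomposition only
    # Center columns exactly (mean dosage fill leaves means ~0 already).
    X -= X.mean(axis=0)

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    if k > rank:
        raise ValueError(f"requested {k} PCs but matrix rank is {rank}")
    U, S, V = U[:, :k], S[:k], Vt[:k].T

    # Deterministic sign: largest-magnitude loading positive per PC.
    for j in range(k):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]

    eigenvalues = S**2
    coords = U * S  # reference-scale coordinates
    # Pre-scaled projection loadings: raw projection x sqrt(eig) x 2 == x . V
    loadings = V / (2.0 * np.sqrt(eigenvalues))

    kept_keys = [key for key, flag in zip(dm.variants, keep) if flag]
    return PCAReference(
        variant_keys=kept_keys,
        allele_frequencies=freqs,
        loadings=loadings,
        eigenvalues=eigenvalues,
        ref_coordinates=coords,
        ref_samples=list(dm.samples),
        scaling_mode="sqrt_eig_x2",
    )


def project_sample(genotypes: SampleGenotypes, ref: PCAReference,
                   min_coverage: float = 0.5,
                   warn_coverage: float = 0.9) -> PCCoordinates:
    """Place a new sample into the reference PC space.

    Each reference variant found in the sample contributes its
    variance-standardized dosage (reference allele frequencies) times the
    stored per-allele loading; missing variants are skipped, never
    mean-imputed. The raw projection is rescaled by sqrt(eigenvalue) x 2
    per PC (``scaling_mode="sqrt_eig_x2"``) to the reference convention.
    """
    m = len(ref.variant_keys)
    x = np.zeros(m)
    used = 0
    for j, (chrom, pos, vref, valt) in enumerate(ref.variant_keys):
        call = genotypes.get(chrom, pos)
        if call is None or call.dosage is None:
            continue
        if call.ref != vref or call.alt != valt:
            continue
        p = ref.allele_frequencies[j]
        x[j] = (call.dosage - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
        used += 1
    coverage = used / m if m else 0.0
    if coverage < min_coverage:
        raise ValueError(
            f"sample {genotypes.sample_id}: only {coverage:.1%} of reference "
            f"variants usable (floor {min_coverage:.0%})"
        )
    if coverage < warn_coverage:
        warnings.warn(
            f"sample {genotypes.sample_id}: projection coverage {coverage:.1%} "
            f"below {warn_coverage:.0%}; coordinates may be attenuated"
        )
    raw = x @ ref.loadings  # (k,)
    if ref.scaling_mode == "sqrt_eig_x2":
        scaled = raw * np.sqrt(ref.eigenvalues) * 2.0
    elif ref.scaling_mode == "none":
        scaled = raw
    else:
        raise ValueError(f"unknown scaling_mode {ref.scaling_mode!r}")
    return PCCoordinates(sample_id=genotypes.sample_id,
                         pc=tuple(float(v) for v in scaled[:4]))


def fit_adjustment_model(prs_raw: np.ndarray, pcs: np.ndarray,
                         control_mask: np.ndarray, disease: str,
                         standardize_on: str = "all") -> AdjustmentModel:
    """Fit ``PRS_raw ~ PC1 + PC2 + PC3 + PC4`` by OLS in controls only.

    The reference mean/SD of the adjusted (residual) score — used later for
    standardization — are computed over all reference samples by default
    (``standardize_on="all"``), or over controls only
    (``standardize_on="controls"``).
    """
    prs_raw = np.asarray(prs_raw, dtype=float)
    pcs = np.asarray(pcs, dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    if pcs.shape[1] < 4:
        raise ValueError("need at least 4 PC columns")
    pcs = pcs[:, :4]
    n_controls = int(control_mask.sum())
    if n_controls < 6:
        raise ValueError(
            f"{disease}: need at least 6 controls to fit 5 parameters, "
            f"got {n_controls}"
        )
    # PCs that are identically zero in controls carry no information; their
    # coefficients are pinned to 0 rather than left to the solver.
    active = np.any(pcs[control_mask] != 0, axis=0)
    X = sm.add_constant(pcs[control_mask][:, active], has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"{disease}: control design matrix is rank deficient")
    fit = sm.OLS(prs_raw[control_mask], X).fit()
    intercept = float(fit.params[0])
    beta_active = iter(float(b) for b in fit.params[1:])
    beta = tuple(next(beta_active) if a else 0.0 for a in active)

    pred_all = intercept + pcs @ np.asarray(beta)
    adj_all = prs_raw - pred_all
    pool = adj_all if standardize_on == "all" else adj_all[control_mask]
    if standardize_on not in ("all", "controls"):
        raise ValueError(f"unknown standardize_on {standardize_on!r}")
    ref_mean = float(np.mean(pool))
    ref_sd = float(np.std(pool, ddof=1))
    if not ref_sd > 0:
        raise ValueError(f"{disease}: adjusted PRS has zero variance")
    return AdjustmentModel(disease=disease, intercept=intercept, beta=beta,
                           ref_mean_adj=ref_mean, ref_sd_adj=ref_sd)


def adjust_and_standardize(raw: RawScore, pcs: PCCoordinates,
                           model: AdjustmentModel) -> ScoreResult:
    """Residualize and standardize one raw score (category left unset)."""
    if model.disease != raw.disease:
        raise ValueError(
            f"model disease {model.disease!r} does not match raw score "
            f"disease {raw.disease!r}"
        )
    pred = float(model.predict(pcs.as_array()))
    adj = raw.prs_raw - pred
    std = (adj - model.ref_mean_adj) / model.ref_sd_adj
    return ScoreResult(sample_id=raw.sample_id, disease=raw.disease,
                       prs_raw=raw.prs_raw, prs_pred=pred, prs_adj=adj,
                       prs_std_adj=std)


def adjust_cohort(prs_raw: np.ndarray, pcs: np.ndarray,
                  model: AdjustmentModel) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized residualization: returns (prs_adj, prs_std_adj) arrays."""
    prs_raw = np.asarray(prs_raw, dtype=float)
    pred = model.predict(np.asarray(pcs, dtype=float)[:, :4])
    adj = prs_raw - pred
    return adj, (adj - model.ref_mean_adj) / model.ref_sd_adj
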