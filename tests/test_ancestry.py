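"""Reference PCA, sample projection, control-fitted adjustment models."""

import numpy as np
import pytest

from clinprs import ancestry, simulate
from clinprs.types import (
    AdjustmentModel,
    DosageMatrix,
    GenotypeCall,
    PCCoordinates,
    RawScore,
    SampleGenotypes,
)


def _panel_sample(ref, dosages):
    """SampleGenotypes carrying the given ALT dosages at the reference variants."""
    calls = {
        (c, p): GenotypeCall(r, a, d)
        for (c, p, r, a), d in zip(ref.variant_keys, dosages)
    }
    return SampleGenotypes(sample_id="probe", calls=calls)


class TestFitReferencePca:
    def test_pc1_separates_two_subpopulations(self, cohort):
        pc1 = cohort.pca.ref_coordinates[:, 0]
        g0, g1 = pc1[cohort.subpop == 0], pc1[cohort.subpop == 1]
        gap = abs(g0.mean() - g1.mean())
        within = max(g0.std(), g1.std())
        assert gap > within

    def test_identical_samples_rejected(self):
        dm = DosageMatrix(samples=[f"S{i}" for i in range(10)],
                          variants=[("1", 100 * (j + 1), "A", "G")
                                    for j in range(5)],
                          dosages=np.ones((10, 5)))
        with pytest.raises(ValueError, match="zero variance|polymorphic"):
            ancestry.fit_reference_pca(dm, k=4)

    def test_reference_coordinates_centered(self, cohort):
        means = cohort.pca.ref_coordinates.mean(axis=0)
        assert np.all(np.abs(means) < 1e-9)

    def test_eigenvalues_descending_positive(self, cohort):
        ev = cohort.pca.eigenvalues
        assert np.all(ev > 0)
        assert np.all(np.diff(ev) <= 0)

    def test_k_exceeding_rank_rejected(self, rng):
        base = rng.integers(0, 3, size=(3, 6)).astype(float)
        dm = DosageMatrix(samples=[f"s{i}" for i in range(6)],
                          variants=[("1", 100 * (j + 1), "A", "G")
                                    for j in range(6)],
                          dosages=np.vstack([base, base]))  # rank <= 2 centered
        with pytest.raises(ValueError, match="rank"):
            ancestry.fit_reference_pca(dm, k=4)


class TestProjectSample:
    def test_mean_genotype_sample_lands_at_origin(self, cohort):
        ref = cohort.pca
        probe = _panel_sample(ref, 2.0 * ref.allele_frequencies)
        pc = ancestry.project_sample(probe, ref)
        assert np.allclose(pc.as_array(), 0.0, atol=1e-9)

    def test_held_in_sample_reprojects_to_stored_coordinates(self, cohort):
        ref = cohort.pca
        for i in (0, 123, 777):
            sg = cohort.dosages.sample_genotypes(cohort.dosages.samples[i])
            pc = ancestry.project_sample(sg, ref)
            np.testing.assert_allclose(pc.as_array(), ref.ref_coordinates[i, :4],
                                       rtol=1e-6, atol=1e-9)

    def test_duplicated_sample_identical_coordinates(self, cohort):
        sg = cohort.dosages.sample_genotypes(cohort.dosages.samples[5])
        a = ancestry.project_sample(sg, cohort.pca).as_array()
        b = ancestry.project_sample(sg, cohort.pca).as_array()
        np.testing.assert_array_equal(a, b)

    def test_coverage_floor_enforced(self, cohort):
        ref = cohort.pca
        keep = len(ref.variant_keys) // 4  # 25% coverage < 50% floor
        dos = 2.0 * ref.allele_frequencies
        calls = {
            (c, p): GenotypeCall(r, a, d)
            for (c, p, r, a), d in list(zip(ref.variant_keys, dos))[:keep]
        }
        probe = SampleGenotypes(sample_id="sparse", calls=calls)
        with pytest.raises(ValueError, match="floor"):
            ancestry.project_sample(probe, ref)

    def test_low_coverage_warns(self, cohort):
        ref = cohort.pca
        m = len(ref.variant_keys)
        keep = int(0.7 * m)
        dos = 2.0 * ref.allele_frequencies
        calls = {
            (c, p): GenotypeCall(r, a, d)
            for (c, p, r, a), d in list(zip(ref.variant_keys, dos))[:keep]
        }
        with pytest.warns(UserWarning, match="coverage"):
            ancestry.project_sample(SampleGenotypes("lowcov", calls), ref)

    def test_leave_one_out_projection_close_to_held_in(self):
        """A sample excluded from the decomposition then projected lands
        near its held-in coordinate (within 0.1 * sqrt(eigenvalue) per PC)
        on a structured panel of n >= 500."""
        spec = simulate.CohortSpec(
            n_per_subpop=(120,) * 5, n_variants=300, fst=0.15, seed=21
        )
        dm, _ = simulate.simulate_genotypes(spec)
        full = ancestry.fit_reference_pca(dm, k=4)
        tol = 0.1 * np.sqrt(full.eigenvalues[:4])
        for i in (0, 150, 299, 450, 599):
            loo = DosageMatrix(
                samples=dm.samples[:i] + dm.samples[i + 1:],
                variants=dm.variants,
                dosages=np.delete(dm.dosages, i, axis=0),
            )
            ref_loo = ancestry.fit_reference_pca(loo, k=4)
            sg = dm.sample_genotypes(dm.samples[i])
            pc = ancestry.project_sample(sg, ref_loo).as_array()
            assert np.all(np.abs(pc - full.ref_coordinates[i, :4]) < tol)


class TestFitAdjustmentModel:
    def test_all_zero_pcs_reduce_to_control_mean(self, rng):
        prs = rng.normal(size=40)
        pcs = np.zeros((40, 4))
        mask = np.zeros(40, dtype=bool)
        mask[:25] = True
        m = ancestry.fit_adjustment_model(prs, pcs, mask, "CAD")
        assert m.intercept == pytest.approx(prs[:25].mean())
        assert m.beta == (0.0, 0.0, 0.0, 0.0)

    def test_noiseless_linear_score_recovered_exactly(self, rng):
        pcs = rng.normal(size=(60, 4))
        prs = 3.0 + 2.0 * pcs[:, 0] - 1.0 * pcs[:, 1]
        mask = np.ones(60, dtype=bool)
        m = ancestry.fit_adjustment_model(prs, pcs, mask, "CAD")
        np.testing.assert_allclose(
            [m.intercept, *m.beta], [3.0, 2.0, -1.0, 0.0, 0.0], atol=1e-8
        )

    def test_matches_normal_equations_oracle(self, rng):
        prs = rng.normal(size=50)
        pcs = rng.normal(size=(50, 4))
        mask = rng.random(50) < 0.7
        m = ancestry.fit_adjustment_model(prs, pcs, mask, "T2D")
        X = np.column_stack([np.ones(mask.sum()), pcs[mask]])
        coef = np.linalg.solve(X.T @ X, X.T @ prs[mask])  # independent oracle
        np.testing.assert_allclose([m.intercept, *m.beta], coef, atol=1e-8)

    def test_too_few_controls_rejected(self, rng):
        prs = rng.normal(size=20)
        pcs = rng.normal(size=(20, 4))
        mask = np.zeros(20, dtype=bool)
        mask[:5] = True
        with pytest.raises(ValueError, match="controls"):
            ancestry.fit_adjustment_model(prs, pcs, mask, "AFib")

    def test_rank_deficient_design_rejected(self, rng):
        pcs = rng.normal(size=(30, 4))
        pcs[:, 1] = 2.0 * pcs[:, 0]  # collinear
        with pytest.raises(ValueError, match="rank deficient"):
            ancestry.fit_adjustment_model(rng.normal(size=30), pcs,
                                          np.ones(30, dtype=bool), "CAD")


class TestAdjustAndStandardize:
    MODEL = AdjustmentModel("CAD", intercept=1.0, beta=(0.5, -0.25, 0.0, 0.0),
                            ref_mean_adj=0.2, ref_sd_adj=2.0)

    def test_algebra(self):
        raw = RawScore("S1", "CAD", prs_raw=3.0, n_loci_used=5, n_loci_total=5)
        pcs = PCCoordinates("S1", (2.0, 4.0, 1.0, -1.0))
        res = ancestry.adjust_and_standardize(raw, pcs, self.MODEL)
        assert res.prs_pred == pytest.approx(1.0 + 1.0 - 1.0)  # 1 + 0.5*2 - 0.25*4
        assert res.prs_adj == pytest.approx(2.0)
        assert res.prs_std_adj == pytest.approx((2.0 - 0.2) / 2.0)

    def test_raw_equals_pred_gives_shifted_zero(self):
        raw = RawScore("S1", "CAD", prs_raw=1.0, n_loci_used=1, n_loci_total=1)
        pcs = PCCoordinates("S1", (0.0, 0.0, 0.0, 0.0))
        res = ancestry.adjust_and_standardize(raw, pcs, self.MODEL)
        assert res.prs_adj == 0.0
        assert res.prs_std_adj == pytest.approx(-0.2 / 2.0)

    def test_zero_beta_identity_model(self):
        m = AdjustmentModel("CAD", intercept=1.5, beta=(0, 0, 0, 0),
                            ref_mean_adj=0.0, ref_sd_adj=1.0)
        raw = RawScore("S1", "CAD", prs_raw=4.0, n_loci_used=1, n_loci_total=1)
        res = ancestry.adjust_and_standardize(
            raw, PCCoordinates("S1", (9.0, 9.0, 9.0, 9.0)), m)
        assert res.prs_std_adj == pytest.approx(4.0 - 1.5)

    def test_disease_mismatch_rejected(self):
        raw = RawScore("S1", "T2D", prs_raw=1.0, n_loci_used=1, n_loci_total=1)
        with pytest.raises(ValueError, match="disease"):
            ancestry.adjust_and_standardize(
                raw, PCCoordinates("S1", (0, 0, 0, 0)), self.MODEL)


class TestCohortProperties:
    def test_residuals_orthogonal_to_pcs_in_controls(self, cohort):
        controls = cohort.labels == 0
        adj = cohort.prs_raw - cohort.model.predict(
            cohort.pca.ref_coordinates[:, :4]
        )
        assert abs(adj[controls].mean()) < 1e-10
        for j in range(4):
            r = np.corrcoef(adj[controls],
                            cohort.pca.ref_coordinates[controls, j])[0, 1]
            assert abs(r) < 1e-10

    def test_standardized_adjusted_score_mean0_sd1(self, cohort):
        z = cohort.prs_std_adj
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1.0) < 1e-12

    def test_structure_removal_realigns_distributions(self):
        """Confounded scenario: subpopulations differ in risk-allele
        frequency but not in effect; adjustment shrinks the standardized
        mean difference between groups by at least 80%."""
        spec = simulate.CohortSpec(n_per_subpop=(500, 500), n_variants=300,
                                   fst=0.05, risk_freq_shift=0.05, seed=31)
        c = simulate.simulate_cohort(spec)

        def smd(x):
            a, b = x[c.subpop == 0], x[c.subpop == 1]
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            return abs(a.mean() - b.mean()) / pooled

        raw_std = (c.prs_raw - c.prs_raw.mean()) / c.prs_raw.std(ddof=1)
        smd_raw, smd_adj = smd(raw_std), smd(c.prs_std_adj)
        assert smd_raw > 1.0  # structure separates the raw distributions
        assert smd_adj <= 0.2 * smd_raw
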