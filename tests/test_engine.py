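"""Allele harmonization, raw PRS computation and call-rate QC."""

import numpy as np
import pytest

from clinprs import engine
from clinprs.types import (
    DosageMatrix,
    GenotypeCall,
    SampleGenotypes,
    WeightRecord,
    WeightTable,
)


def _sample(calls, sample_id="S1"):
    return SampleGenotypes(sample_id=sample_id, calls={
        (chrom, pos): GenotypeCall(ref, alt, dosage)
        for chrom, pos, ref, alt, dosage in calls
    })


def _weights(rows, prs_id="toy"):
    return WeightTable(prs_id=prs_id, records=[
        WeightRecord(chrom=c, pos=p, effect_allele=e, other_allele=o, weight=w)
        for c, p, e, o, w in rows
    ])


class TestHarmonize:
    def test_effect_equals_alt_is_identity(self):
        loci = engine.harmonize(_weights([("1", 100, "G", "A", 0.2)]),
                                _sample([("1", 100, "A", "G", 1.0)]))
        assert loci[0].status == "matched"
        assert loci[0].effect_dosage == 1.0

    def test_effect_equals_ref_complements_dosage(self):
        loci = engine.harmonize(_weights([("1", 100, "A", "G", 0.2)]),
                                _sample([("1", 100, "A", "G", 0.5)]))
        assert loci[0].status == "flipped"
        assert loci[0].effect_dosage == pytest.approx(1.5)

    def test_five_variant_toy_with_palindromic_site(self):
        # Hand enumeration: 4 strand-safe loci match (2 identity, 2
        # complement); the single A/T locus is dropped under the default
        # policy and scored under keep.
        wt = _weights([
            ("1", 100, "G", "A", 0.1),   # identity
            ("1", 200, "C", "T", 0.2),   # complement (effect = REF)
            ("1", 300, "T", "A", 0.3),   # palindromic
            ("1", 400, "T", "C", -0.4),  # identity
            ("1", 500, "G", "A", 0.5),   # complement
        ])
        sample = _sample([
            ("1", 100, "A", "G", 2.0),
            ("1", 200, "C", "T", 1.0),
            ("1", 300, "A", "T", 2.0),
            ("1", 400, "C", "T", 0.0),
            ("1", 500, "G", "A", 1.0),
        ])
        loci = engine.harmonize(wt, sample, ambiguous_policy="drop")
        statuses = [l.status for l in loci]
        assert statuses == ["matched", "flipped", "dropped_ambiguous",
                            "matched", "flipped"]
        assert sum(l.usable for l in loci) == 4

        kept = engine.harmonize(wt, sample, ambiguous_policy="keep")
        assert kept[2].status == "matched"
        assert kept[2].effect_dosage == 2.0

    def test_absent_and_mismatched_loci_dropped_with_reason(self):
        wt = _weights([("1", 100, "A", "G", 0.1), ("1", 200, "C", "A", 0.2)])
        sample = _sample([("1", 200, "G", "T", 1.0)])
        loci = engine.harmonize(wt, sample)
        assert loci[0].status == "dropped_missing"
        assert "absent" in loci[0].reason
        assert loci[1].status == "dropped_missing"
        assert "mismatch" in loci[1].reason

    def test_dropped_accounting_matches_drop_log(self, tmp_path):
        wt = _weights([
            ("1", 100, "G", "A", 0.1),
            ("1", 200, "A", "T", 0.2),   # palindromic -> dropped
            ("1", 300, "C", "T", 0.3),   # absent -> dropped
        ])
        sample = _sample([("1", 100, "A", "G", 1.0)])
        loci = engine.harmonize(wt, sample)
        raw = engine.compute_raw_prs(loci, "S1", "CAD")
        log = tmp_path / "drops.tsv"
        engine.write_drop_log(loci, log)
        n_dropped = len(log.read_text().splitlines()) - 1
        assert raw.n_loci_total - raw.n_loci_used == n_dropped == 2


class TestComputeRawPrs:
    def test_hand_sum(self):
        # dosages (0, 1, 2) x weights (0.2, -0.3, 0.1) -> -0.1
        wt = _weights([("1", 100, "G", "A", 0.2), ("1", 200, "T", "C", -0.3),
                       ("1", 300, "G", "A", 0.1)])
        sample = _sample([("1", 100, "A", "G", 0.0), ("1", 200, "C", "T", 1.0),
                          ("1", 300, "A", "G", 2.0)])
        raw = engine.compute_raw_prs(engine.harmonize(wt, sample), "S1", "CAD")
        assert raw.prs_raw == pytest.approx(-0.1)
        assert (raw.n_loci_used, raw.n_loci_total) == (3, 3)

    def test_zero_weights_give_zero_score(self):
        wt = _weights([("1", 100, "G", "A", 0.0), ("1", 200, "T", "C", 0.0)])
        sample = _sample([("1", 100, "A", "G", 2.0), ("1", 200, "C", "T", 1.0)])
        raw = engine.compute_raw_prs(engine.harmonize(wt, sample), "S1", "CAD")
        assert raw.prs_raw == 0.0

    def test_missing_locus_contributes_nothing(self):
        wt = _weights([("1", 100, "G", "A", 0.2), ("1", 200, "T", "C", -0.3),
                       ("1", 300, "G", "A", 0.1)])
        sample = _sample([("1", 100, "A", "G", 1.0),
                          ("1", 200, "C", "T", None),  # genotype missing
                          ("1", 300, "A", "G", 2.0)])
        raw = engine.compute_raw_prs(engine.harmonize(wt, sample), "S1", "CAD")
        assert raw.prs_raw == pytest.approx(0.2 + 0.2)
        assert raw.n_loci_used == 2

    def test_zero_usable_loci_names_disease(self):
        wt = _weights([("1", 100, "G", "A", 0.2)])
        sample = _sample([("2", 500, "A", "G", 1.0)])
        with pytest.raises(ValueError, match="T2D"):
            engine.compute_raw_prs(engine.harmonize(wt, sample), "S1", "T2D")

    def test_permutation_invariance(self, rng):
        rows = [("1", 100 * (j + 1), "G", "A", float(rng.normal()))
                for j in range(20)]
        calls = [("1", 100 * (j + 1), "A", "G", float(rng.integers(0, 3)))
                 for j in range(20)]
        sample = _sample(calls)
        base = engine.compute_raw_prs(
            engine.harmonize(_weights(rows), sample), "S1", "X").prs_raw
        for _ in range(5):
            perm = [rows[i] for i in rng.permutation(len(rows))]
            shuffled = engine.compute_raw_prs(
                engine.harmonize(_weights(perm), sample), "S1", "X").prs_raw
            assert shuffled == pytest.approx(base, rel=1e-12)

    def test_ref_alt_relabel_with_complement_is_consistent(self, rng):
        """Swapping REF/ALT labels (and re-expressing dosage on the new ALT)
        leaves the effect-allele score unchanged; checked against a
        brute-force oracle that rebuilds the sum from scratch."""
        for _ in range(10):
            m = int(rng.integers(3, 15))
            rows, calls, swapped = [], [], []
            expected = 0.0
            for j in range(m):
                pos = 100 * (j + 1)
                w = float(rng.normal())
                d = float(rng.integers(0, 3))
                effect_is_alt = bool(rng.random() < 0.5)
                eff, oth = ("G", "A") if effect_is_alt else ("A", "G")
                rows.append(("1", pos, eff, oth, w))
                calls.append(("1", pos, "A", "G", d))
                swapped.append(("1", pos, "G", "A", 2.0 - d))
                expected += w * (d if effect_is_alt else 2.0 - d)  # oracle
            s1 = engine.compute_raw_prs(
                engine.harmonize(_weights(rows), _sample(calls)), "S", "X")
            s2 = engine.compute_raw_prs(
                engine.harmonize(_weights(rows), _sample(swapped)), "S", "X")
            assert s1.prs_raw == pytest.approx(expected, abs=1e-12)
            assert s2.prs_raw == pytest.approx(expected, abs=1e-12)


class TestCallRate:
    def test_full_call_rate_passes(self):
        g = _sample([("1", 100, "A", "G", 1.0)])
        assert engine.check_call_rate(g, 0.985).passed

    def test_exactly_at_threshold_fails(self):
        # 197/200 called = 0.985 exactly; the gate requires strictly greater.
        calls = [("1", 100 * (j + 1), "A", "G", 1.0 if j < 197 else None)
                 for j in range(200)]
        check = engine.check_call_rate(_sample(calls), 0.985)
        assert check.call_rate == pytest.approx(0.985)
        assert not check.passed

    def test_low_call_rate_fails(self):
        calls = [("1", 100 * (j + 1), "A", "G", 1.0 if j < 97 else None)
                 for j in range(100)]
        assert not engine.check_call_rate(_sample(calls), 0.985).passed

    def test_invalid_threshold(self):
        g = _sample([("1", 100, "A", "G", 1.0)])
        with pytest.raises(ValueError):
            engine.check_call_rate(g, 0.0)


def test_cohort_mode_matches_per_sample_scoring(rng):
    from clinprs import simulate
    spec = simulate.CohortSpec(n_per_subpop=(15, 15), n_variants=40, seed=7)
    variants = simulate._draw_variants(spec)
    weights = simulate.simulate_weights(spec, variants)
    dm, _ = simulate.simulate_genotypes(spec)
    cohort_scores = engine.compute_raw_prs_cohort(weights, dm)
    for i in (0, 7, 29):
        sg = dm.sample_genotypes(dm.samples[i])
        raw = engine.compute_raw_prs(engine.harmonize(weights, sg),
                                     sg.sample_id, "SIM")
        assert raw.prs_raw == pytest.approx(cohort_scores[i], rel=1e-12)
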