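"""Allele frequencies, LD pruning, allele-sharing distances, classical MDS,
and supervised ancestry estimation."""

from __future__ import annotations

import numpy as np
import pytest

from admixrisk.genio import MISSING, GenotypeMatrix, VariantRecord
from admixrisk.popgen import (
    AncestryFractions,
    DistanceMatrix,
    ReferenceFrequencies,
    allele_frequencies,
    allele_frequency_records,
    allele_sharing_distance,
    estimate_ancestry_supervised,
    ld_prune,
    project_mds,
)
from admixrisk.simulate import (
    PopulationProfile,
    SimulationConfig,
    draw_admixed_genotypes,
    draw_ancestral_frequencies,
)


def _gm(dosages, pops=None):
    d = np.asarray(dosages, dtype=np.int16)
    variants = [
        VariantRecord(f"v{j}", "1", 100 + j, "A", "G") for j in range(d.shape[1])
    ]
    return GenotypeMatrix(
        [f"s{i}" for i in range(d.shape[0])], variants, d, pops
    )


class TestAlleleFrequencies:
    def test_hand_counts(self):
        gm = _gm([[2], [1], [0]])
        df = allele_frequencies(gm, by_population=False)
        assert df.risk_allele_count.tolist() == [3]
        assert df.nonrisk_allele_count.tolist() == [3]
        assert df.risk_allele_freq.tolist() == [0.5]

    def test_missing_excluded_from_both_counts(self):
        gm = _gm([[2], [MISSING], [0]])
        df = allele_frequencies(gm, by_population=False)
        assert df.risk_allele_count.tolist() == [2]
        assert df.nonrisk_allele_count.tolist() == [2]
        assert df.risk_allele_freq.tolist() == [0.5]

    def test_all_homozygous_risk(self):
        gm = _gm([[2], [2]])
        df = allele_frequencies(gm, by_population=False)
        assert df.risk_allele_freq.tolist() == [1.0]

    def test_zero_call_snp_flagged_undefined(self, caplog):
        gm = _gm([[MISSING, 1], [MISSING, 2]])
        with caplog.at_level("WARNING"):
            df = allele_frequencies(gm, by_population=False)
        assert df.defined.tolist() == [False, True]
        assert np.isnan(df.risk_allele_freq[0])

    def test_count_conservation(self, effect_study):
        df = allele_frequencies(effect_study.genotypes)
        called = df.risk_allele_count + df.nonrisk_allele_count
        assert (called % 2 == 0).all()
        total_calls = int(
            (effect_study.genotypes.dosages != MISSING).sum()
        )
        assert int(called.sum()) == 2 * total_calls

    def test_record_properties(self):
        recs = allele_frequency_records(_gm([[2], [1], [0]]), "all")
        assert recs[0].ra == 0.5 and recs[0].nra == 0.5
        assert abs(recs[0].ra + recs[0].nra - 1.0) < 1e-12


class TestLdPrune:
    def test_duplicate_column_pruned(self, rng):
        base = rng.integers(0, 3, size=(100, 1))
        gm = _gm(np.hstack([base, base, rng.integers(0, 3, size=(100, 3))]))
        kept = ld_prune(gm, r2_threshold=0.8)
        assert "v0" in kept and "v1" not in kept

    def test_independent_snps_mostly_retained(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.9, size=1000)
        d = rng.binomial(2, p[None, :], size=(500, 1000))
        kept = ld_prune(_gm(d), r2_threshold=0.8)
        assert len(kept) >= 990

    def test_window_of_one_never_prunes(self, rng):
        base = rng.integers(0, 3, size=(50, 1))
        gm = _gm(np.hstack([base, base]))
        kept = ld_prune(gm, r2_threshold=0.5, window_snps=1)
        assert len(kept) == 2

    def test_monomorphic_retained_with_log(self, caplog, rng):
        d = rng.integers(0, 3, size=(60, 3))
        d[:, 1] = 2
        with caplog.at_level("WARNING"):
            kept = ld_prune(_gm(d), r2_threshold=0.5)
        assert "v1" in kept
        assert "monomorphic" in caplog.text

    def test_original_order_preserved(self, rng):
        d = rng.integers(0, 3, size=(80, 20))
        kept = ld_prune(_gm(d), r2_threshold=0.9)
        assert kept == sorted(kept, key=lambda s: int(s[1:]))


class TestAlleleSharingDistance:
    def test_identical_samples_distance_zero(self, rng):
        row = rng.integers(0, 3, size=(1, 30))
        dm = allele_sharing_distance(_gm(np.vstack([row, row])))
        assert dm.values[0, 1] == 0.0

    def test_opposite_homozygotes_single_locus(self):
        dm = allele_sharing_distance(_gm([[0], [2]]))
        assert dm.values[0, 1] == 1.0

    def test_hand_computed_two_loci(self):
        # s = (0 + 1)/2 over loci -> distance 0.5
        dm = allele_sharing_distance(_gm([[0, 1], [2, 1]]))
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_missing_loci_skipped_pairwise(self):
        dm = allele_sharing_distance(_gm([[0, 1, MISSING], [2, MISSING, 0]]))
        # only locus 0 jointly called -> distance 1
        assert dm.values[0, 1] == 1.0

    def test_bounds_symmetry_zero_diagonal(self, effect_study):
        gm = effect_study.genotypes.subset_samples(range(40))
        dm = allele_sharing_distance(gm)
        v = dm.values
        assert (v >= 0).all() and (v <= 1).all()
        assert np.array_equal(v, v.T)
        assert np.all(np.diag(v) == 0)

    def test_sample_order_invariance(self, effect_study, rng):
        gm = effect_study.genotypes.subset_samples(range(25))
        dm = allele_sharing_distance(gm)
        perm = rng.permutation(25)
        dm_p = allele_sharing_distance(gm.subset_samples(perm))
        np.testing.assert_allclose(
            dm_p.values, dm.values[np.ix_(perm, perm)], atol=1e-12
        )

    def test_zero_joint_loci_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            allele_sharing_distance(_gm([[0, MISSING], [MISSING, 1]]))


class TestProjectMds:
    def test_all_zero_distances_give_zero_coordinates(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        with pytest.warns(UserWarning, match="non-positive eigenvalue"):
            coords = project_mds(dm, n_dims=2)
        assert np.allclose(coords, 0.0)

    def test_collinear_points_recovered(self):
        x = np.array([0.0, 1.0, 2.5, 4.0, 7.0, 11.0])
        d = np.abs(x[:, None] - x[None, :]) / x.max()
        dm = DistanceMatrix([f"p{i}" for i in range(x.size)], d)
        coords = project_mds(dm, n_dims=2)
        r = np.corrcoef(coords[:, 0], x)[0, 1]
        assert abs(r) > 0.999

    def test_two_populations_separate(self):
        """MDS on allele-sharing distances separates differentiated cohorts."""
        from sklearn.metrics import silhouette_score

        cfg = SimulationConfig(
            n_snps=800,
            n_risk_snps=10,
            seed=42,
            missing_rate=0.0,
            fst_per_pop=(0.2, 0.2, 0.2),
            pop_profiles=(
                PopulationProfile("p0", 40, (1e4, 1e-4, 1e-4)),
                PopulationProfile("p1", 40, (1e-4, 1e4, 1e-4)),
            ),
        )
        freqs = draw_ancestral_frequencies(cfg)
        gm, _ = draw_admixed_genotypes(cfg, freqs)
        coords = project_mds(allele_sharing_distance(gm), n_dims=2)
        labels = [0] * 40 + [1] * 40
        assert silhouette_score(coords, labels) > 0.5

    def test_non_symmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.2], [0.3, 0.0]]))


class TestSupervisedAncestry:
    def _study(self, profiles, n_snps, seed=9, fst=(0.1, 0.1, 0.1)):
        cfg = SimulationConfig(
            n_snps=n_snps,
            n_risk_snps=1,
            risk_shift_delta=0.0,
            seed=seed,
            missing_rate=0.0,
            fst_per_pop=fst,
            pop_profiles=profiles,
        )
        freqs = draw_ancestral_frequencies(cfg)
        gm, truth = draw_admixed_genotypes(cfg, freqs)
        ref = ReferenceFrequencies(
            cfg.ancestry_labels, gm.variant_ids, freqs
        )
        return gm, truth, ref

    def test_pure_individual_recovered(self):
        gm, _, ref = self._study(
            (PopulationProfile("pure1", 5, (1e-4, 1e4, 1e-4)),), n_snps=5000
        )
        frac = estimate_ancestry_supervised(gm, ref)
        assert (frac.fractions[:, 1] >= 0.95).all()

    def test_half_admixture_recovered(self):
        gm, _, ref = self._study(
            (PopulationProfile("half", 6, (1e4, 1e4, 1e-4)),), n_snps=10_000
        )
        frac = estimate_ancestry_supervised(gm, ref)
        assert np.abs(frac.fractions[:, 0] - 0.5).max() < 0.05

    def test_log_likelihood_never_decreases(self):
        gm, _, ref = self._study(
            (PopulationProfile("mix", 20, (3.0, 3.0, 3.0)),), n_snps=1000
        )
        frac = estimate_ancestry_supervised(gm, ref)
        diffs = np.diff(frac.log_likelihood_path)
        assert (diffs >= -1e-7).all()

    def test_identical_references_return_uniform_with_warning(self, rng):
        d = rng.integers(0, 3, size=(4, 50))
        gm = _gm(d)
        p = rng.uniform(0.2, 0.8, size=50)
        ref = ReferenceFrequencies(
            ("X", "Y", "Z"), gm.variant_ids, np.vstack([p, p, p])
        )
        with pytest.warns(UserWarning, match="non-identifiable"):
            frac = estimate_ancestry_supervised(gm, ref)
        assert np.allclose(frac.fractions, 1.0 / 3.0)

    def test_no_shared_snps_is_error(self, rng):
        gm = _gm(rng.integers(0, 3, size=(2, 10)))
        ref = ReferenceFrequencies(
            ("A", "B"), ["other1", "other2"], np.full((2, 2), 0.5)
        )
        with pytest.raises(ValueError, match="no SNPs shared"):
            estimate_ancestry_supervised(gm, ref)

    def test_missing_loci_skipped(self):
        gm, truth, ref = self._study(
            (PopulationProfile("mix", 10, (5.0, 5.0, 5.0)),), n_snps=2000
        )
        d = gm.dosages.copy()
        rng = np.random.default_rng(0)
        d[rng.random(d.shape) < 0.1] = MISSING
        gm2 = GenotypeMatrix(gm.samples, gm.variants, d)
        frac = estimate_ancestry_supervised(gm2, ref)
        rmse = np.sqrt(
            np.mean((frac.fractions - truth.ancestry_fractions) ** 2)
        )
        assert rmse < 0.06

    def test_fractions_on_simplex(self, effect_study):
        gm = effect_study.genotypes.subset_samples(range(20))
        cfg = effect_study.config
        ref = ReferenceFrequencies(
            cfg.ancestry_labels,
            [v.id for v in gm.variants[: cfg.n_snps]],
            effect_study.truth.ancestral_freqs,
        )
        frac = estimate_ancestry_supervised(gm, ref, tol=1e-5)
        assert np.allclose(frac.fractions.sum(axis=1), 1.0, atol=1e-9)
        assert (frac.fractions >= 0).all()
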