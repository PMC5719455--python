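"""Log odds ratios, meta-analysis, and the polygenic risk score, each
checked against independent arithmetic oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixrisk.genio import MISSING, GenotypeMatrix, VariantRecord
from admixrisk.popgen import AlleleFrequencyRecord
from admixrisk.riskstats import (
    MetaResult,
    ORResult,
    meta_analyze,
    or_table,
    polygenic_risk_score,
    snp_log_or,
)


def _rec(risk, nonrisk, pop="A", rsid="rs1"):
    return AlleleFrequencyRecord(pop, rsid, risk, nonrisk)


def _oracle_or(a, b, c, d):
    """Independent 2×2-table arithmetic: log OR, Woolf SE, 1.96 CI."""
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return log_or, se, log_or - 1.96 * se, log_or + 1.96 * se, corrected


class TestSnpLogOr:
    def test_worked_example(self):
        """Counts (60,40) vs (40,60): OR = 2.25."""
        r = snp_log_or(_rec(60, 40), _rec(40, 60, pop="B"))
        assert r.log_or == pytest.approx(math.log(2.25), abs=1e-12)
        assert r.se == pytest.approx(
            math.sqrt(1 / 60 + 1 / 40 + 1 / 40 + 1 / 60), abs=1e-12
        )
        assert r.ci_low == pytest.approx(0.2451, abs=1e-4)
        assert r.ci_high == pytest.approx(1.3767, abs=1e-4)
        assert r.significant and not r.corrected

    def test_equal_frequencies_null(self):
        r = snp_log_or(_rec(30, 70), _rec(30, 70, pop="B"))
        assert r.log_or == 0.0
        assert not r.significant

    def test_swap_antisymmetry_exact(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            a, b, c, d = rng.integers(0, 500, size=4)
            if a + b == 0 or c + d == 0:
                continue
            fwd = snp_log_or(_rec(int(a), int(b)), _rec(int(c), int(d), pop="B"))
            rev = snp_log_or(_rec(int(c), int(d), pop="B"), _rec(int(a), int(b)))
            assert rev.log_or == -fwd.log_or  # bitwise exact
            assert rev.se == fwd.se

    def test_matches_oracle_to_1e12(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(0, 400, size=4))
            if a + b == 0 or c + d == 0:
                continue
            r = snp_log_or(_rec(a, b), _rec(c, d, pop="B"))
            lo, se, cl, ch, corr = _oracle_or(a, b, c, d)
            assert r.log_or == pytest.approx(lo, abs=1e-12)
            assert r.se == pytest.approx(se, abs=1e-12)
            assert r.ci_low == pytest.approx(cl, abs=1e-12)
            assert r.ci_high == pytest.approx(ch, abs=1e-12)
            assert r.corrected == corr

    @given(
        a=st.integers(0, 300), b=st.integers(0, 300),
        c=st.integers(0, 300), d=st.integers(0, 300),
    )
    @settings(max_examples=200, derandomize=True)
    def test_correction_iff_zero_cell_and_finite(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        r = snp_log_or(_rec(a, b), _rec(c, d, pop="B"))
        assert r.corrected == (0 in (a, b, c, d))
        assert math.isfinite(r.log_or) and math.isfinite(r.se)
        assert r.ci_low <= r.log_or <= r.ci_high
        assert r.significant == (r.ci_low > 0 or r.ci_high < 0)

    def test_mismatched_rsids_rejected(self):
        with pytest.raises(ValueError, match="different SNPs"):
            snp_log_or(_rec(1, 1, rsid="rs1"), _rec(1, 1, rsid="rs2"))

    def test_undefined_record_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            snp_log_or(_rec(0, 0), _rec(1, 1, pop="B"))


def _or_result(y, se, rsid="rs"):
    return ORResult(rsid, y, se, y - 1.96 * se, y + 1.96 * se,
                    significant=False, corrected=False)


def _oracle_meta(ys, ses, model):
    """Plain-loop inverse-variance / DerSimonian–Laird re-implementation."""
    w = [1.0 / s**2 for s in ses]
    pooled_f = sum(wi * yi for wi, yi in zip(w, ys)) / sum(w)
    q = sum(wi * (yi - pooled_f) ** 2 for wi, yi in zip(w, ys))
    tau2 = 0.0
    if model == "random":
        denom = sum(w) - sum(wi**2 for wi in w) / sum(w)
        tau2 = max(0.0, (q - (len(ys) - 1)) / denom)
        w = [1.0 / (s**2 + tau2) for s in ses]
    pooled = sum(wi * yi for wi, yi in zip(w, ys)) / sum(w)
    se = 1.0 / math.sqrt(sum(w))
    return pooled, se, tau2, q


class TestMetaAnalyze:
    def test_equal_se_is_arithmetic_mean(self):
        res = meta_analyze([_or_result(0.2, 0.1), _or_result(0.4, 0.1)])
        assert res.pooled_log_or == pytest.approx(0.3, abs=1e-12)

    def test_homogeneous_inputs_truncate_tau2_to_zero(self):
        """Q <= k-1 forces tau2 = 0, so random equals fixed."""
        ors = [_or_result(0.30, 0.2), _or_result(0.31, 0.2), _or_result(0.29, 0.2)]
        fixed = meta_analyze(ors, "fixed")
        random = meta_analyze(ors, "random")
        assert random.tau2 == 0.0
        assert random.pooled_log_or == pytest.approx(fixed.pooled_log_or, abs=1e-15)
        assert random.se == pytest.approx(fixed.se, abs=1e-15)

    @pytest.mark.parametrize("model", ["fixed", "random"])
    def test_matches_independent_oracle(self, model, rng):
        for _ in range(10):
            k = int(rng.integers(3, 30))
            ys = rng.normal(0.2, 0.5, size=k)
            ses = rng.uniform(0.05, 0.6, size=k)
            res = meta_analyze(
                [_or_result(y, s) for y, s in zip(ys, ses)], model
            )
            pooled, se, tau2, q = _oracle_meta(list(ys), list(ses), model)
            assert res.pooled_log_or == pytest.approx(pooled, abs=1e-12)
            assert res.se == pytest.approx(se, abs=1e-12)
            assert res.tau2 == pytest.approx(tau2, abs=1e-12)
            assert res.q == pytest.approx(q, abs=1e-10)

    def test_matches_statsmodels_cross_check(self, rng):
        from statsmodels.stats.meta_analysis import combine_effects

        ys = rng.normal(0.3, 0.4, size=12)
        var = rng.uniform(0.01, 0.2, size=12)
        ors = [_or_result(y, math.sqrt(v)) for y, v in zip(ys, var)]
        sm = combine_effects(ys, var, method_re="dl")
        fixed = meta_analyze(ors, "fixed")
        random = meta_analyze(ors, "random")
        assert fixed.pooled_log_or == pytest.approx(sm.mean_effect_fe, rel=1e-10)
        assert random.pooled_log_or == pytest.approx(sm.mean_effect_re, rel=1e-10)
        assert random.tau2 == pytest.approx(sm.tau2, rel=1e-10)

    def test_pooled_within_input_range(self, rng):
        ys = rng.normal(0, 1, size=20)
        ses = rng.uniform(0.1, 1.0, size=20)
        for model in ("fixed", "random"):
            res = meta_analyze([_or_result(y, s) for y, s in zip(ys, ses)], model)
            assert ys.min() <= res.pooled_log_or <= ys.max()

    def test_random_se_at_least_fixed_se(self, rng):
        ys = rng.normal(0, 1.5, size=15)
        ses = rng.uniform(0.1, 0.3, size=15)
        ors = [_or_result(y, s) for y, s in zip(ys, ses)]
        assert meta_analyze(ors, "random").se >= meta_analyze(ors, "fixed").se

    def test_fewer_than_two_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            meta_analyze([_or_result(0.2, 0.1)])


def _aligned_gm(dosages):
    d = np.asarray(dosages, dtype=np.int16)
    variants = [
        VariantRecord(f"v{j}", "1", 100 + j, "A", "G") for j in range(d.shape[1])
    ]
    return GenotypeMatrix([f"s{i}" for i in range(d.shape[0])], variants, d)


class TestPolygenicRiskScore:
    def test_worked_example(self):
        prs = polygenic_risk_score(_aligned_gm([[2, 1, 0]]))
        assert prs.scores[0] == pytest.approx(0.5)
        assert prs.n_called_alleles[0] == 6

    def test_all_homozygous_risk_is_one(self):
        prs = polygenic_risk_score(_aligned_gm([[2, 2, 2]]))
        assert prs.scores[0] == 1.0

    def test_missing_snp_shrinks_denominator(self):
        prs = polygenic_risk_score(_aligned_gm([[2, MISSING, 0]]))
        assert prs.scores[0] == pytest.approx(0.5)
        assert prs.n_called_alleles[0] == 4

    def test_zero_called_snps_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            prs = polygenic_risk_score(_aligned_gm([[MISSING, MISSING]]))
        assert np.isnan(prs.scores[0])
        assert not prs.defined[0]

    def test_scores_bounded(self, effect_study):
        from admixrisk.genio import align_risk_alleles

        aligned = align_risk_alleles(
            effect_study.genotypes, effect_study.risk_set
        )
        prs = polygenic_risk_score(aligned)
        ok = prs.defined
        assert (prs.scores[ok] >= 0).all() and (prs.scores[ok] <= 1).all()

    def test_duplicate_snp_pulls_scores_toward_its_dosage(self, rng):
        d = rng.integers(0, 3, size=(30, 10)).astype(np.int16)
        base = polygenic_risk_score(_aligned_gm(d)).scores
        dup = np.hstack([d, d[:, :1]])
        moved = polygenic_risk_score(_aligned_gm(dup)).scores
        target = d[:, 0] / 2.0
        assert (np.abs(moved - target) <= np.abs(base - target) + 1e-12).all()


class TestOrTableEndToEnd:
    def test_direction_recovery_under_risk_shift(self, effect_study):
        """A +0.15 shift toward the ancestry that dominates cohort A yields a
        significantly positive pooled log OR (A vs B)."""
        from admixrisk.genio import align_risk_alleles

        aligned = align_risk_alleles(
            effect_study.genotypes, effect_study.risk_set
        )
        ors = or_table(aligned, "choco_like", "antioquia_like")
        assert len(ors) == 165
        res = meta_analyze(ors, "fixed")
        assert res.pooled_log_or > 0
        assert res.p_value < 0.01

    def test_skips_undefined_snps(self, caplog):
        d = np.array([[1, MISSING], [2, MISSING], [0, 1], [1, 2]], dtype=np.int16)
        variants = [VariantRecord(f"v{j}", "1", 100 + j, "A", "G") for j in range(2)]
        gm = GenotypeMatrix(
            ["a", "b", "c", "d"], variants, d, ["P", "P", "Q", "Q"]
        )
        with caplog.at_level("WARNING"):
            ors = or_table(gm, "P", "Q")
        assert [r.rsid for r in ors] == ["v0"]
        assert "skipped" in caplog.text
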