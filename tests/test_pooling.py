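"""Per-study effects, Mantel-Haenszel and DerSimonian-Laird pooling."""

import math

import numpy as np
import pytest

import f13meta as fm
from f13meta.genetic_models import ContingencyTable, GeneticModel
from f13meta.pooling import DL_RANDOM, MH_FIXED, inverse_variance_fixed


def table(a, b, c, d, study_id="t", corrected=False):
    return ContingencyTable(study_id, a, b, c, d, corrected=corrected)


class TestStudyEffect:
    def test_log_or_and_woolf_se(self):
        e = fm.study_effect(table(56, 44, 35, 72))
        assert e.or_ == pytest.approx(2.618, abs=5e-4)
        assert e.log_or == pytest.approx(0.9623, abs=5e-4)
        assert e.se == pytest.approx(0.2882, abs=5e-4)
        assert e.ci_low < e.or_ < e.ci_high

    def test_unit_table_is_null(self):
        e = fm.study_effect(table(1, 1, 1, 1))
        assert e.or_ == 1.0 and e.log_or == 0.0

    def test_corrected_cells_used_directly(self):
        e = fm.study_effect(table(0.5, 10.5, 5.5, 20.5, corrected=True))
        assert e.or_ == pytest.approx(0.1775, abs=5e-4)

    def test_zero_cell_without_correction_rejected(self):
        with pytest.raises(ValueError, match="zero cell"):
            fm.study_effect(ContingencyTable("z", 0, 10, 5, 20))


class TestMantelHaenszel:
    def test_single_table_equals_crude_or(self):
        t = table(56, 44, 35, 72)
        res = fm.pool_fixed_mh([t])
        assert res.pooled_or == pytest.approx((56 * 72) / (44 * 35), rel=1e-12)
        assert res.k == 1

    def test_identical_tables_pool_to_common_or(self):
        t = table(30, 20, 25, 40)
        res = fm.pool_fixed_mh([t] * 5)
        assert res.pooled_or == pytest.approx((30 * 40) / (20 * 25), rel=1e-12)

    def test_matches_direct_formula_on_stroke_tables(self, is_set):
        """Oracle: evaluate sum(ad/n)/sum(bc/n) by hand over the 6 tables."""
        tables, _ = fm.derive_all(is_set, GeneticModel.DOMINANT)
        num = sum(t.a * t.d / (t.a + t.b + t.c + t.d) for t in tables)
        den = sum(t.b * t.c / (t.a + t.b + t.c + t.d) for t in tables)
        res = fm.pool_fixed_mh(tables)
        assert res.pooled_or == pytest.approx(num / den, rel=1e-12)

    def test_weights_normalised(self, mi_set):
        tables, _ = fm.derive_all(mi_set, GeneticModel.DOMINANT)
        res = fm.pool_fixed_mh(tables)
        assert sum(w for _, w in res.weights) == pytest.approx(100.0, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(fm.InsufficientStudiesError):
            fm.pool_fixed_mh([])


class TestDerSimonianLaird:
    def test_mi_dominant_reference_values(self, mi_set):
        """Frozen reference: independent random-effects computation of the
        13-study dominant pool (R metafor, DL estimator)."""
        tables, _ = fm.derive_all(mi_set, GeneticModel.DOMINANT)
        res = fm.pool_random_dl(tables)
        assert res.pooled_or == pytest.approx(0.7945, abs=5e-4)
        assert res.ci_low == pytest.approx(0.6391, abs=5e-4)
        assert res.ci_high == pytest.approx(0.9877, abs=5e-4)
        assert res.p == pytest.approx(0.0383, abs=5e-4)
        assert res.het.i2 == pytest.approx(63.8, abs=0.05)

    def test_mi_heterozygous_reference_values(self, mi_set):
        tables, _ = fm.derive_all(mi_set, GeneticModel.HETEROZYGOUS)
        res = fm.pool_random_dl(tables)
        assert res.k == 12
        assert res.pooled_or == pytest.approx(0.7723, abs=5e-4)
        assert res.ci_low == pytest.approx(0.6095, abs=5e-4)
        assert res.ci_high == pytest.approx(0.9786, abs=5e-4)

    def test_single_study_identity(self):
        t = table(30, 20, 25, 40)
        res = fm.pool_random_dl([t])
        e = fm.study_effect(t)
        assert res.pooled_or == pytest.approx(e.or_, rel=1e-12)
        assert res.het.q == 0.0 and res.het.tau2 == 0.0

    def test_homogeneous_studies_reduce_to_fixed_iv(self):
        tables = [table(30, 20, 25, 40)] * 4
        res = fm.pool_random_dl(tables)
        effects = [fm.study_effect(t) for t in tables]
        y_fixed, se_fixed = inverse_variance_fixed(effects)
        assert res.het.q == pytest.approx(0.0, abs=1e-12)
        assert res.het.tau2 == 0.0
        assert math.log(res.pooled_or) == pytest.approx(y_fixed, abs=1e-12)

    def test_dl_equals_iv_fixed_when_tau2_zero(self):
        """Whenever Q <= k-1 the DL weights collapse to inverse-variance."""
        tables = [table(300, 200, 250, 400, "a"),
                  table(302, 198, 250, 400, "b"),
                  table(298, 202, 251, 399, "c")]
        res = fm.pool_random_dl(tables)
        assert res.het.q < res.het.df
        assert res.het.tau2 == 0.0
        effects = [fm.study_effect(t) for t in tables]
        y_fixed, se_fixed = inverse_variance_fixed(effects)
        assert math.log(res.pooled_or) == pytest.approx(y_fixed, rel=1e-12)
        assert (math.log(res.ci_high) - math.log(res.pooled_or)) / 1.959963984540054 \
            == pytest.approx(se_fixed, rel=1e-12)

    @pytest.mark.parametrize("model", list(GeneticModel))
    def test_estimate_within_study_range(self, mi_set, model):
        tables, _ = fm.derive_all(mi_set, model)
        res = fm.pool_random_dl(tables)
        logs = [fm.study_effect(t).log_or for t in tables]
        assert min(logs) <= math.log(res.pooled_or) <= max(logs)


class TestSymmetry:
    @pytest.mark.parametrize("method", [MH_FIXED, DL_RANDOM])
    @pytest.mark.parametrize("model", [GeneticModel.DOMINANT, GeneticModel.ALLELIC])
    def test_case_control_swap_inverts_pooled_or(self, mi_set, method, model):
        tables, _ = fm.derive_all(mi_set, model)
        fwd = fm.pool(tables, method)
        rev = fm.pool([t.swapped() for t in tables], method)
        assert rev.pooled_or == pytest.approx(1.0 / fwd.pooled_or, rel=1e-9)
        assert rev.z == pytest.approx(-fwd.z, rel=1e-6, abs=1e-9)
        assert rev.ci_low == pytest.approx(1.0 / fwd.ci_high, rel=1e-9)


class TestHeterogeneity:
    def test_q_matches_direct_summation(self, is_set):
        tables, _ = fm.derive_all(is_set, GeneticModel.DOMINANT)
        effects = [fm.study_effect(t) for t in tables]
        het = fm.heterogeneity(effects)
        w = np.array([1 / e.se**2 for e in effects])
        y = np.array([e.log_or for e in effects])
        y_hat = (w * y).sum() / w.sum()
        assert het.q == pytest.approx(float((w * (y - y_hat) ** 2).sum()), rel=1e-12)
        assert het.df == 5

    def test_identical_effects_no_heterogeneity(self):
        effects = [fm.EffectEstimate(f"s{i}", 0.4, 0.2) for i in range(4)]
        het = fm.heterogeneity(effects)
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.i2 == 0.0 and het.tau2 == 0.0

    def test_i2_floored_when_q_below_df(self):
        effects = [fm.EffectEstimate("a", 0.40, 0.3),
                   fm.EffectEstimate("b", 0.41, 0.3),
                   fm.EffectEstimate("c", 0.40, 0.3)]
        het = fm.heterogeneity(effects)
        assert het.q < het.df
        assert het.i2 == 0.0 and het.tau2 == 0.0

    def test_requires_two_studies(self):
        with pytest.raises(fm.InsufficientStudiesError):
            fm.heterogeneity([fm.EffectEstimate("a", 0.1, 0.2)])


class TestSelectMethod:
    @pytest.mark.parametrize("i2,expected", [
        (0.0, MH_FIXED), (49.9, MH_FIXED), (50.0, DL_RANDOM), (75.0, DL_RANDOM),
    ])
    def test_threshold_inclusive_at_fifty(self, i2, expected):
        het = fm.HeterogeneityStats(q=1, df=1, i2=i2, tau2=0, p_q=0.5)
        assert fm.select_method(het) == expected

    def test_threshold_configurable(self):
        het = fm.HeterogeneityStats(q=1, df=1, i2=30.0, tau2=0, p_q=0.5)
        assert fm.select_method(het, i2_threshold=25.0) == DL_RANDOM
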