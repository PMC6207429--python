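"""Activity-ratio fits, feature-matching criteria, per-image measures, bootstrap."""

import numpy as np
import pytest

from fsgm_attn import analysis as an
from fsgm_attn import stimuli as st
from fsgm_attn import tuning as tn
from fsgm_attn.attention import AttentionConfig, build_attention_field


def synthetic_record(ratios, orientations=None):
    """Build an ActivityRatioRecord from a (K, n_att, n_stim) ratio tensor."""
    ratios = np.asarray(ratios, dtype=float)
    orientations = orientations or list(range(ratios.shape[1]))
    return an.ActivityRatioRecord(
        orientations=list(orientations),
        ratios={1: ratios},
        valid={1: np.ones_like(ratios, dtype=bool)},
        n_excluded={1: 0},
        applied_layers=(1,),
        beta=0.5,
        mode="multiplicative",
    )


def table_for(f_rows, orientations):
    return tn.TuningTable(conditions=list(orientations), values={1: np.asarray(f_rows)})


class TestLeastSquares:
    def test_ols_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        x = np.arange(5.0)
        design = np.c_[x, np.ones(5)]
        for _ in range(1000):
            y = rng.standard_normal(5) * rng.uniform(0.1, 10)
            slope, intercept = an.ols_line(x, y)
            expect, *_ = np.linalg.lstsq(design, y, rcond=None)
            assert abs(slope - expect[0]) < 1e-10
            assert abs(intercept - expect[1]) < 1e-10


class TestRatioFit:
    def test_all_ratios_one_gives_flat_unit_line(self):
        oris = list(range(0, 180, 20))
        rec = synthetic_record(np.ones((2, 9, 9)), oris)
        table = table_for(np.tile(np.linspace(1, -1, 9), (2, 1)), oris)
        fit = an.fsgm_ratio_fit(rec, table, 1)
        np.testing.assert_allclose(fit.slope, 0.0, atol=1e-12)
        np.testing.assert_allclose(fit.intercept, 1.0, atol=1e-12)

    def test_hand_example_from_linear_gain(self):
        # ratios 1 + 0.5*f with f = (0.8,...,-0.8): collapsed points
        # (1.4, 1.25, 1.05, 0.85, 0.65) -> slope -0.19, intercept 1.42
        oris = list(range(0, 180, 20))
        f = np.array([0.8, 0.6, 0.4, 0.2, 0.0, -0.2, -0.4, -0.6, -0.8])
        diag = 1 + 0.5 * f
        ratios = np.broadcast_to(diag, (9, 9)).copy()[None, :, :]
        # place the attended==stimulus ratios on the diagonal
        tensor = np.ones((1, 9, 9))
        tensor[0, np.arange(9), np.arange(9)] = diag
        rec = synthetic_record(tensor, oris)
        table = table_for(f[None, :], oris)
        fit = an.fsgm_ratio_fit(rec, table, 1)
        assert fit.slope[0] == pytest.approx(-0.19, abs=1e-12)
        assert fit.intercept[0] == pytest.approx(1.42, abs=1e-12)

    def test_pair_permutation_leaves_fit_unchanged(self):
        oris = list(range(0, 180, 20))
        rng = np.random.default_rng(1)
        f = np.sort(rng.standard_normal(9))[::-1]
        diag = rng.uniform(0.5, 1.5, size=9)
        tensor = np.ones((1, 9, 9))
        tensor[0, np.arange(9), np.arange(9)] = diag
        rec = synthetic_record(tensor, oris)
        fit1 = an.fsgm_ratio_fit(rec, table_for(f[None, :], oris), 1)
        # swap tuning of a preference pair (positions 1 and 2 in the order):
        # their ratios swap position in the ordering, but the pair mean is
        # unchanged, so the fit must be identical
        order = np.argsort(-f)
        f2 = f.copy()
        f2[order[1]], f2[order[2]] = f[order[2]], f[order[1]]
        tensor2 = np.ones((1, 9, 9))
        d2 = diag.copy()
        d2[order[1]], d2[order[2]] = diag[order[2]], diag[order[1]]
        tensor2[0, np.arange(9), np.arange(9)] = d2
        fit2 = an.fsgm_ratio_fit(synthetic_record(tensor2, oris), table_for(f[None, :], oris), 1)
        assert fit1.slope[0] == pytest.approx(fit2.slope[0], rel=1e-12)
        assert fit1.intercept[0] == pytest.approx(fit2.intercept[0], rel=1e-12)

    def test_wrong_orientation_count_rejected(self):
        rec = synthetic_record(np.ones((1, 5, 5)))
        table = table_for(np.zeros((1, 5)), list(range(5)))
        with pytest.raises(ValueError):
            an.fsgm_ratio_fit(rec, table, 1)


class TestFeatureMatching:
    def _table(self):
        # map 0: prefers orientation 0, anti-prefers orientation 160
        f = np.linspace(1, -1, 9)[None, :]
        return table_for(f, list(range(0, 180, 20)))

    def test_equal_ratios_never_feature_matching(self):
        rec = synthetic_record(np.ones((1, 9, 9)), list(range(0, 180, 20)))
        assert an.feature_matching_fraction(rec, self._table(), 1) == 0.0

    def test_constructed_fm_map_detected(self):
        tensor = np.ones((1, 9, 9))
        tensor[0, 0, 0] = 1.3   # attend pref, pref present
        tensor[0, 0, 8] = 1.1   # attend pref, anti present
        tensor[0, 8, 8] = 1.2   # attend anti, anti present
        tensor[0, 8, 0] = 0.9   # attend anti, pref present
        rec = synthetic_record(tensor, list(range(0, 180, 20)))
        assert an.feature_matching_fraction(rec, self._table(), 1) == 1.0

    def test_pure_fsgm_map_not_flagged_fm(self):
        # FSGM: ratio depends only on the attended orientation, not stimulus
        tensor = np.ones((1, 9, 9))
        tensor[0, 0, :] = 1.3  # attending preferred boosts everywhere
        tensor[0, 8, :] = 0.8  # attending anti-preferred suppresses everywhere
        rec = synthetic_record(tensor, list(range(0, 180, 20)))
        assert an.feature_matching_fraction(rec, self._table(), 1) == 0.0


class TestClosedFormOnFixture:
    """Multiplicative tuning attention recorded at the applied layer."""

    def test_ratio_equals_one_plus_beta_f(self, model, tuning_table):
        layer = 4
        beta = 0.5
        cfg = AttentionConfig(
            source="tuning", layers=(layer,), beta=beta,
            attended_condition=st.ORIENTATIONS[0],
        )
        rec = an.record_activity_ratios(model, tuning_table, cfg)
        diag, ok = rec.diagonal(layer)
        f = tuning_table.values[layer]
        expect = 1 + beta * f
        np.testing.assert_allclose(diag[ok], expect[ok], rtol=1e-6)

    def test_zero_beta_gives_unit_ratios(self, model, tuning_table):
        # beta=0 template is promoted to the protocol default, so build the
        # field explicitly with an epsilon-free zero strength
        cfg = AttentionConfig(
            source="tuning", layers=(5,), beta=1e-300,
            attended_condition=st.ORIENTATIONS[0],
        )
        rec = an.record_activity_ratios(model, tuning_table, cfg)
        diag, ok = rec.diagonal(5)
        np.testing.assert_allclose(diag[ok], 1.0, rtol=1e-9)

    def test_per_image_slope_equals_beta(self, model, tuning_table, test_arrays):
        layer = 5
        beta = 0.45
        ori = st.ORIENTATIONS[2]
        x, pos = test_arrays[ori]
        images = x[pos][:10]
        cfg = AttentionConfig(
            source="tuning", layers=(layer,), beta=beta, attended_condition=ori
        )
        field = build_attention_field(cfg, tuning_table, model)
        f_col = tuning_table.column(ori)[layer]
        slopes = an.per_image_fsgm_slope(
            model, images, field, f_col, tuning_table.dead[layer], layer
        )
        good = np.isfinite(slopes)
        assert good.any()
        np.testing.assert_allclose(slopes[good], beta, rtol=1e-6)


class TestVectorAngle:
    def test_no_attention_difference_is_zero(self, model, tuning_table, test_arrays):
        ori = st.ORIENTATIONS[1]
        x, pos = test_arrays[ori]
        cfg = AttentionConfig(
            source="tuning", layers=(5,), beta=0.45, attended_condition=ori
        )
        field = build_attention_field(cfg, tuning_table, model)
        # same field with zero strength: cosines must be identical
        zero_field = build_attention_field(
            AttentionConfig(source="tuning", layers=(5,), beta=0.0,
                            attended_condition=ori),
            tuning_table, model,
        )
        m0 = an.vector_angle_measure(model, x, ori, x[pos], zero_field, 5)
        assert m0.difference == pytest.approx(0.0, abs=1e-12)
        m1 = an.vector_angle_measure(model, x, ori, x[pos], field, 5)
        assert -1 <= m1.median_cos_with <= 1
        assert -1 <= m1.median_cos_without <= 1
        assert m1.retained_variance >= 0.90


class TestBootstrap:
    def test_identical_measure_correlates_perfectly(self):
        rng = np.random.default_rng(0)
        perf = rng.standard_normal(50)
        pairs = np.c_[perf, perf]
        out = an.correlate_and_bootstrap(pairs, pairs, n_boot=20, seed=1)
        assert out.correlation_a == pytest.approx(1.0)
        assert out.correlation_b == pytest.approx(1.0)

    def test_permuted_pairs_decorrelate(self):
        rng = np.random.default_rng(2)
        perf = rng.standard_normal(200)
        measure = perf + 0.1 * rng.standard_normal(200)
        good = np.c_[measure, perf]
        permuted = np.c_[rng.permutation(measure), perf]
        out = an.correlate_and_bootstrap(good, permuted, n_boot=100, seed=3)
        assert out.correlation_a > 0.9
        assert abs(out.correlation_b) < 0.2
        assert out.ci_b[0] < 0.15 and out.ci_b[1] > -0.15
        assert out.p_value < 0.01

    def test_same_seed_reproduces_everything_exactly(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((30, 2))
        b = rng.standard_normal((30, 2))
        o1 = an.correlate_and_bootstrap(a, b, n_boot=100, seed=7)
        o2 = an.correlate_and_bootstrap(a, b, n_boot=100, seed=7)
        np.testing.assert_array_equal(o1.boot_a, o2.boot_a)
        np.testing.assert_array_equal(o1.boot_b, o2.boot_b)
        assert o1.p_value == o2.p_value
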