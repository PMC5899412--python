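import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulonfit import (
    AnnealingConfig,
    CandidateNetwork,
    ClassificationConfig,
    ConstantSynthesisParams,
    ErrorMarginSpec,
    ExpressionSet,
    Label,
    RegulationParams,
    RegularizationSpec,
    anneal_fit,
    apply_overrides,
    classify_no_change,
    error_margin,
    evaluate_edges,
    fit_constant_synthesis,
    fit_quality,
    integrate_constant_synthesis,
    integrate_model,
)
from regulonfit.fitting import FitSettings
from regulonfit.io import empty_result_table
from regulonfit.smoothing import DenseGrid


class TestErrorMargin:
    @pytest.mark.parametrize(
        "z,spec,expected",
        [
            (1.0, (0.1, 0.05, 0.1), 0.15),
            (0.1, (0.1, 0.05, 0.1), 0.1),  # minimal floor binds
            (0.0, (0.0, 0.2, 0.5), 0.2),
        ],
    )
    def test_tabulated_values(self, z, spec, expected):
        margin = ErrorMarginSpec(*spec)
        assert error_margin(z, margin) == pytest.approx(expected)

    def test_all_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            ErrorMarginSpec(0.0, 0.0, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0, max_value=100),
        st.floats(min_value=0, max_value=5),
        st.floats(min_value=0, max_value=5),
        st.floats(min_value=0.01, max_value=5),
    )
    def test_monotone_in_each_component(self, z, e_min, e_abs, e_rel):
        base = error_margin(z, ErrorMarginSpec(e_min, e_abs, e_rel))
        for bumped in (
            ErrorMarginSpec(e_min + 1, e_abs, e_rel),
            ErrorMarginSpec(e_min, e_abs + 1, e_rel),
            ErrorMarginSpec(e_min, e_abs, e_rel + 1),
        ):
            assert error_margin(z, bumped) >= base


class TestFitQuality:
    MARGIN = ErrorMarginSpec(0.1, 0.0, 0.1)

    def test_identity_is_one(self):
        z = np.array([1.0, 2.0, 3.0])
        assert fit_quality(z, z, self.MARGIN) == 1.0

    def test_three_of_four_inside(self):
        meas = np.array([1.0, 1.0, 1.0, 1.0])
        pred = np.array([1.0, 1.0, 1.0, 2.0])
        assert fit_quality(pred, meas, self.MARGIN) == 0.75

    def test_everywhere_outside_is_zero(self):
        meas = np.ones(10)
        pred = meas + 10 * error_margin(meas, self.MARGIN)
        assert fit_quality(pred, meas, self.MARGIN) == 0.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_quality(np.ones(3), np.ones(4), self.MARGIN)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0, max_value=2))
    def test_widening_margin_never_decreases_quality(self, extra):
        rng = np.random.default_rng(0)
        meas = rng.random(30) * 2
        pred = meas + rng.normal(0, 0.3, 30)
        narrow = fit_quality(pred, meas, ErrorMarginSpec(0.05, 0.0, 0.1))
        wide = fit_quality(pred, meas, ErrorMarginSpec(0.05 + extra, extra, 0.1))
        assert wide >= narrow


class TestClassifyNoChange:
    MARGIN = ErrorMarginSpec(0.1, 0.0, 0.1)

    def test_constant_profile(self):
        assert classify_no_change(np.full(50, 3.0), self.MARGIN)

    def test_ramp_is_change(self):
        assert not classify_no_change(np.linspace(0, 10, 50), self.MARGIN)

    def test_boundary_is_inclusive(self):
        # profile sits exactly at mean +/- the margin at every point;
        # the margin (0.25, exactly representable) avoids float fuzz
        margin = ErrorMarginSpec(0.25, 0.0, 0.0)
        profile = np.array([2.25, 1.75] * 10)
        assert profile.mean() == 2.0
        assert classify_no_change(profile, margin)
        assert not classify_no_change(profile * 1.02, margin)


class TestConstantSynthesisFit:
    CONFIG = AnnealingConfig(restarts=32, iterations=400, seed=0)

    def test_recovers_noise_free_trajectory(self):
        dense = DenseGrid(0.0, 12.0, 130)
        truth = ConstantSynthesisParams(2.0, 0.5)
        target = integrate_constant_synthesis(truth, 1.0, dense)
        cls = ClassificationConfig(0.8, ErrorMarginSpec(0.05, 0.0, 0.1))
        fit = fit_constant_synthesis(target, dense, cls, self.CONFIG)
        assert fit.fit_quality == 1.0
        assert fit.label is Label.CONSTANT_SYNTHESIS
        assert fit.params.steady_state == pytest.approx(4.0, rel=0.05)

    def test_monotone_saturating_profile_accepted(self):
        dense = DenseGrid(0.0, 12.0, 130)
        target = 3.0 - 2.5 * np.exp(-0.4 * dense.times)
        cls = ClassificationConfig(0.8, ErrorMarginSpec(0.05, 0.0, 0.1))
        fit = fit_constant_synthesis(target, dense, cls, self.CONFIG)
        assert fit.label is Label.CONSTANT_SYNTHESIS

    def test_two_reversals_rejected(self):
        # rise, fall, second rise: monotone solutions cannot track this
        dense = DenseGrid(0.0, 12.0, 130)
        target = 1.5 + np.sin(dense.times)
        cls = ClassificationConfig(0.8, ErrorMarginSpec(0.05, 0.0, 0.1))
        fit = fit_constant_synthesis(target, dense, cls, self.CONFIG)
        assert fit.fit_quality < 0.8
        assert fit.label is not Label.CONSTANT_SYNTHESIS


def _simulated_pair(seed, dense):
    """Target driven by a pulse regulator with known parameters."""
    rng = np.random.default_rng(seed)
    y = 0.1 + (dense.times / 3) * np.exp(1 - dense.times / 3)
    k1 = rng.uniform(1, 2)
    k2 = rng.uniform(0.2, 0.7)
    w = rng.uniform(2, 5)
    b = -w * rng.uniform(0.3, 0.8)
    params = RegulationParams(k1, k2, b, [w])
    target = integrate_model(params, y[None, :], 0.2, dense)
    return y, target, params


class TestAnnealFit:
    DENSE = DenseGrid(0.0, 12.0, 130)
    CONFIG = AnnealingConfig(restarts=32, iterations=400, seed=0)

    def _classification(self, target):
        margin = ErrorMarginSpec(0.01 * float(np.max(target)), 0.0, 0.1)
        return ClassificationConfig(0.8, margin)

    def test_recovers_simulated_target_profile(self):
        y, target, _ = _simulated_pair(5, self.DENSE)
        spec = RegularizationSpec(c=13.0)
        fit = anneal_fit(
            target, y[None, :], self.DENSE, spec, self.CONFIG,
            self._classification(target),
        )
        assert fit.label is Label.GOOD_FIT
        assert fit.fit_quality >= 0.95

    def test_same_seed_bit_identical(self):
        y, target, _ = _simulated_pair(6, self.DENSE)
        spec = RegularizationSpec(c=13.0)
        cls = self._classification(target)
        a = anneal_fit(target, y[None, :], self.DENSE, spec, self.CONFIG, cls)
        b = anneal_fit(target, y[None, :], self.DENSE, spec, self.CONFIG, cls)
        assert a.params == b.params
        np.testing.assert_array_equal(a.predicted, b.predicted)
        assert a.fit_quality == b.fit_quality

    def test_true_regulator_beats_unrelated_profile(self):
        # across 20 simulated targets, the generating regulator fits at
        # least as well as an independent random profile in >= 80% of cases
        spec = RegularizationSpec(c=13.0)
        rng = np.random.default_rng(999)
        unrelated = 0.4 + 0.6 * rng.random(self.DENSE.resolution)
        wins = 0
        n = 20
        for seed in range(1, n + 1):
            y, target, _ = _simulated_pair(seed, self.DENSE)
            cls = self._classification(target)
            with_true = anneal_fit(
                target, y[None, :], self.DENSE, spec, self.CONFIG, cls
            )
            with_null = anneal_fit(
                target, unrelated[None, :], self.DENSE, spec, self.CONFIG, cls
            )
            if with_true.fit_quality >= with_null.fit_quality:
                wins += 1
        assert wins >= 0.8 * n

    def test_zero_regulators_rejected(self):
        y, target, _ = _simulated_pair(7, self.DENSE)
        with pytest.raises(ValueError, match="constant-synthesis"):
            anneal_fit(
                target, np.empty((0, self.DENSE.resolution)), self.DENSE,
                RegularizationSpec(), self.CONFIG, self._classification(target),
            )

    def test_best_objective_non_increasing_in_restarts(self):
        # prefix property: per-restart streams are independent, so adding
        # restarts can only improve (or keep) the best objective
        y, target, _ = _simulated_pair(8, self.DENSE)
        spec = RegularizationSpec(c=13.0)
        cls = self._classification(target)
        residuals = []
        for restarts in (4, 8, 16):
            cfg = AnnealingConfig(
                restarts=restarts, iterations=200, seed=3, polish=False
            )
            fit = anneal_fit(target, y[None, :], self.DENSE, spec, cfg, cls)
            obj = fit.residual_ss + fit.regularization_term
            residuals.append(obj)
        assert residuals[0] >= residuals[1] >= residuals[2]


class TestEvaluateEdges:
    def _dataset(self):
        from regulonfit import FixtureSpec, make_fixture

        spec = FixtureSpec(n_targets=2, n_constant=1, n_const_synth=1, seed=4)
        return make_fixture(spec)

    def test_three_way_classification(self, quick_settings):
        ds, net, truth = self._dataset()
        table = evaluate_edges(ds, net, quick_settings)
        by_target = table.set_index("target")["label"]
        assert by_target["const0"] == "NO_CHANGE"
        assert by_target["csyn0"] == "CONSTANT_SYNTHESIS"
        assert by_target["tgt00"] in ("GOOD_FIT", "NO_FIT")

    def test_empty_network_empty_table(self, quick_settings):
        ds, _, _ = self._dataset()
        table = evaluate_edges(ds, CandidateNetwork([]), quick_settings)
        assert len(table) == 0

    def test_constant_regulator_excluded(self, quick_settings):
        ds, _, _ = self._dataset()
        net = CandidateNetwork([("const0", "tgt00")])
        table = evaluate_edges(ds, net, quick_settings)
        assert table.iloc[0]["label"] == "NO_CHANGE"
        assert "regulator" in table.iloc[0]["note"]

    def test_unknown_gene_rejected(self, quick_settings):
        ds, _, _ = self._dataset()
        with pytest.raises(KeyError, match="ghost"):
            evaluate_edges(ds, CandidateNetwork([("reg", "ghost")]), quick_settings)


class TestApplyOverrides:
    def _table(self):
        t = empty_result_table()
        t.loc[0] = dict(
            regulator="r", target="t", label="GOOD_FIT", fit_quality=0.9,
            residual_ss=0.1, regularization=0.0, k1=1.0, k2=0.5, b=0.0,
            w="1", note="", provenance="auto",
        )
        return t

    def test_flip_one_label(self):
        overrides = pd.DataFrame(
            [{"regulator": "r", "target": "t", "new_label": "NO_FIT"}]
        )
        out = apply_overrides(self._table(), overrides)
        assert out.iloc[0]["label"] == "NO_FIT"
        assert out.iloc[0]["provenance"] == "manual"

    def test_empty_overrides_identity(self):
        out = apply_overrides(self._table(), pd.DataFrame(columns=["regulator", "target", "new_label"]))
        pd.testing.assert_frame_equal(out, self._table())

    def test_unknown_edge_rejected(self):
        overrides = pd.DataFrame(
            [{"regulator": "r", "target": "ghost", "new_label": "NO_FIT"}]
        )
        with pytest.raises(ValueError, match="ghost"):
            apply_overrides(self._table(), overrides)
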