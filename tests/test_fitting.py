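import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grfkit.dataio import DegenerateInputError, GeneTimeSeries, Kind
from grfkit.fitting import (FitConfig, data_collapse_residual, fast_config,
                            fit_grf, score, select_best_form,
                            select_best_inputs)
from grfkit.grf_models import GRFForm, GRFSpec
from grfkit.protein_proxy import Propagator
from tests.conftest import LAM_TRUE, proxy_target

# deliberately tiny annealing budget: these tests exercise contracts,
# not optimization quality (that is covered by the acceptance suite)
TINY = FitConfig(n_restarts=1, chain_length=10, cooling=0.5,
                 t_floor_ratio=1e-2, polish=False, seed=0)


class TestScore:
    def test_perfect_fit_is_zero(self):
        d = np.array([1.0, 2.0, 3.0, 2.0])
        assert score(d, d) == 0.0

    def test_constant_mean_model_is_one(self):
        d = np.array([1.0, 2.0, 3.0, 2.0])
        assert score(d, np.full(4, d.mean())) == pytest.approx(1.0)

    def test_two_point_hand_arithmetic(self):
        # numerator mean((0-1)^2,(2-1)^2)=1, denominator mean(1,1)=1
        assert score(np.array([0.0, 2.0]), np.array([1.0, 1.0])) \
            == pytest.approx(1.0)

    def test_constant_observed_rejected(self):
        with pytest.raises(DegenerateInputError):
            score(np.array([2.0, 2.0]), np.array([1.0, 2.0]))

    @settings(derandomize=True, max_examples=30)
    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    def test_invariant_under_common_affine_rescale(self, a, b):
        rng = np.random.default_rng(0)
        d = rng.random(20)
        m = d + 0.1 * rng.standard_normal(20)
        assert score(a * d + b, a * m + b) == pytest.approx(score(d, m), rel=1e-9)


class TestFitGrf:
    def test_seeded_determinism(self, tf_mrna, act_target):
        target, _ = act_target
        cfg = FitConfig(n_restarts=2, chain_length=30, seed=7, polish=False)
        r1 = fit_grf(target, [tf_mrna], GRFForm.ACT, cfg, fixed_lam=(LAM_TRUE,))
        r2 = fit_grf(target, [tf_mrna], GRFForm.ACT, cfg, fixed_lam=(LAM_TRUE,))
        assert r1 == r2

    def test_noise_free_recovery_single_restart(self, tf_mrna, act_target):
        """With lam pinned to truth, even one annealing restart plus polish
        lands on the generating parameters."""
        target, true = act_target
        cfg = FitConfig(n_restarts=1, seed=3)
        fit = fit_grf(target, [tf_mrna], GRFForm.ACT, cfg, fixed_lam=(LAM_TRUE,))
        assert fit.score < 1e-6
        assert fit.spec.K[0] == pytest.approx(true.K[0], rel=0.02)
        assert fit.spec.n[0] == pytest.approx(true.n[0], rel=0.02)

    def test_best_of_restarts_never_worse(self, tf_mrna, act_target):
        target, _ = act_target
        few = fit_grf(target, [tf_mrna], GRFForm.ACT,
                      FitConfig(n_restarts=1, chain_length=20, polish=False,
                                seed=5), fixed_lam=(LAM_TRUE,))
        more = fit_grf(target, [tf_mrna], GRFForm.ACT,
                       FitConfig(n_restarts=3, chain_length=20, polish=False,
                                 seed=5), fixed_lam=(LAM_TRUE,))
        assert more.score <= few.score

    def test_score_never_beats_constant_model_bound(self, tf_mrna, grid):
        """The constant model (alpha ~ 0, b = mean) is in the search space,
        so the best fit cannot be worse than score 1 (+ small slack)."""
        rng = np.random.default_rng(2)
        noise = GeneTimeSeries("N", Kind.synthesis_rate,
                               rng.random(42) + 0.5, grid)
        fit = fit_grf(noise, [tf_mrna], GRFForm.ACT,
                      FitConfig(n_restarts=2, seed=1), fixed_lam=(LAM_TRUE,))
        assert fit.score <= 1.0 + 1e-6

    def test_arity_mismatch_rejected(self, tf_mrna, act_target):
        with pytest.raises(ValueError, match="inputs"):
            fit_grf(act_target[0], [tf_mrna], GRFForm.AND, TINY)
        with pytest.raises(ValueError, match="inputs"):
            fit_grf(act_target[0], [], GRFForm.ACT, TINY)

    def test_degenerate_target_rejected(self, tf_mrna, grid):
        flat = GeneTimeSeries("F", Kind.synthesis_rate, np.ones(42), grid)
        with pytest.raises(DegenerateInputError):
            fit_grf(flat, [tf_mrna], GRFForm.ACT, TINY)


class TestSelectBestForm:
    def test_repressor_data_prefers_rep(self, tf_mrna, tf_protein, grid):
        spec = GRFSpec(GRFForm.REP, b=0.2, alpha=1.5, K=(1.0,), n=(3.0,),
                       inputs=("TF",))
        target = proxy_target("T_REP", spec, [tf_protein], grid,
                              noise_sigma=0.05, seed=4)
        best = select_best_form(target, [tf_mrna],
                                fast_config(seed=0), fixed_lam=(LAM_TRUE,))
        assert best.spec.form == GRFForm.REP

    def test_arity2_evaluates_all_ten_forms(self, tf_mrna, tf_protein, grid):
        spec = GRFSpec(GRFForm.AND, b=0.1, alpha=1.0, K=(1.0, 1.0), n=(2.0, 2.0),
                       inputs=("TF", "TF2"))
        tf2 = GeneTimeSeries("TF2", Kind.mrna_level,
                             1 + 0.5 * np.cos(2 * np.pi * grid.times / 60.0),
                             grid)
        p2 = Propagator(tf2, lam_min=LAM_TRUE).values(LAM_TRUE)
        target = proxy_target("T2", spec, [tf_protein, p2], grid)
        best, results = select_best_form(target, [tf_mrna, tf2], TINY,
                                         fixed_lam=(LAM_TRUE, LAM_TRUE),
                                         return_all=True)
        assert len(results) == 10
        assert best.score == min(r.score for r in results)

    def test_exact_tie_prefers_fewer_parameters(self):
        """Constant data fitted by 1- and 2-input menus: every form reaches
        score ~identical; parsimony must pick a 1-input form."""
        from grfkit.fitting import _better, FitResult
        s1 = GRFSpec(GRFForm.REP, b=1.0, alpha=0.0, K=(1.0,), n=(1.0,),
                     inputs=("A",))
        s2 = GRFSpec(GRFForm.AND, b=1.0, alpha=0.0, K=(1.0, 1.0), n=(1.0, 1.0),
                     inputs=("A", "B"))
        r1 = FitResult("T", ("A",), s1, (0.1,), 0.5)
        r2 = FitResult("T", ("A", "B"), s2, (0.1, 0.1), 0.5)
        assert _better(r1, r2) and not _better(r2, r1)


class TestSelectBestInputs:
    def _inputs(self, grid, k):
        rng = np.random.default_rng(9)
        out = []
        for i in range(k):
            v = 1 + 0.6 * np.sin(2 * np.pi * grid.times / 60.0 + 1.1 * i) \
                + 0.05 * rng.standard_normal(42)
            out.append(GeneTimeSeries(f"I{i}", Kind.mrna_level, np.abs(v), grid))
        return out

    def test_three_candidates_give_six_input_sets(self, grid):
        inputs = self._inputs(grid, 3)
        p0 = Propagator(inputs[0], lam_min=LAM_TRUE).values(LAM_TRUE)
        spec = GRFSpec(GRFForm.ACT, b=0.1, alpha=1.0, K=(1.0,), n=(2.0,),
                       inputs=("I0",))
        target = proxy_target("T", spec, [p0], grid)
        _, ranked = select_best_inputs(target, inputs, TINY,
                                       fixed_lam={m.gene: LAM_TRUE for m in inputs})
        assert len(ranked) == 6  # C(3,1) + C(3,2)
        assert [r.score for r in ranked] == sorted(r.score for r in ranked)

    def test_two_candidates_give_three_input_sets(self, grid):
        inputs = self._inputs(grid, 2)
        p0 = Propagator(inputs[0], lam_min=LAM_TRUE).values(LAM_TRUE)
        spec = GRFSpec(GRFForm.ACT, b=0.1, alpha=1.0, K=(1.0,), n=(2.0,),
                       inputs=("I0",))
        target = proxy_target("T", spec, [p0], grid)
        _, ranked = select_best_inputs(target, inputs, TINY,
                                       fixed_lam={m.gene: LAM_TRUE for m in inputs})
        assert len(ranked) == 3

    def test_true_pair_beats_decoy(self, grid):
        """Target built from inputs {I0, I1}; decoy I2 must not win."""
        inputs = self._inputs(grid, 3)
        p0 = Propagator(inputs[0], lam_min=LAM_TRUE).values(LAM_TRUE)
        p1 = Propagator(inputs[1], lam_min=LAM_TRUE).values(LAM_TRUE)
        spec = GRFSpec(GRFForm.AND, b=0.1, alpha=2.0, K=(1.0, 1.0), n=(3.0, 3.0),
                       inputs=("I0", "I1"))
        target = proxy_target("T", spec, [p0, p1], grid, noise_sigma=0.02, seed=1)
        best, _ = select_best_inputs(target, inputs, fast_config(seed=0),
                                     fixed_lam={m.gene: LAM_TRUE for m in inputs})
        assert set(best.inputs) == {"I0", "I1"}

    def test_needs_two_candidates(self, grid, tf_mrna, act_target):
        with pytest.raises(ValueError):
            select_best_inputs(act_target[0], [tf_mrna], TINY)


class TestDataCollapse:
    def test_residual_minimized_near_true_lam(self, tf_mrna, act_target):
        """Plotting s against p collapses to a curve only at the right
        protein timescale; the smoothness residual dips there."""
        target, _ = act_target
        lam_grid = np.geomspace(LAM_TRUE / 8, LAM_TRUE * 8, 17)
        res = data_collapse_residual(target, tf_mrna, lam_grid)
        best = lam_grid[int(np.argmin(res))]
        assert abs(math.log(best / LAM_TRUE)) < math.log(2.0)
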