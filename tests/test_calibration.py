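import copy

import numpy as np
import pytest

from baymix.calibration import (
    ParameterSpec,
    build_parameter_specs,
    calibrate,
    objective_catch_fit,
    objective_hake,
    objective_nephrops_accessibility,
    objective_sole_accessibility,
)
from baymix.synthetic import PRESETS, generate_config


def _cells(values, quarter=1, group="gillnetters", fraction="landings", year=2010):
    return {(c, (year, quarter), group, fraction): v for c, v in enumerate(values)}


class TestHakeObjective:
    w = {(q, "gillnetters", f): 1.0 for q in (1, 2, 3, 4) for f in ("landings", "discards")}

    def test_identical_cells_score_zero(self):
        cells = _cells([5.0, 7.0])
        assert objective_hake(cells, dict(cells), self.w, self.w) == 0.0

    def test_two_cell_toy_example(self):
        sim = _cells([1.0, 2.0])
        obs = _cells([0.0, 0.0])
        assert objective_hake(sim, obs, self.w, composition=False) == pytest.approx(5.0)

    def test_doubling_weights_doubles_score(self):
        sim, obs = _cells([1.0, 2.0]), _cells([0.0, 1.0])
        w2 = {k: 2.0 for k in self.w}
        s1 = objective_hake(sim, obs, self.w, composition=False)
        s2 = objective_hake(sim, obs, w2, composition=False)
        assert s2 == pytest.approx(2 * s1)

    def test_missing_weight_key_named(self):
        sim = {(0, (2010, 1), "longliners", "landings"): 1.0}
        with pytest.raises(KeyError, match="longliners"):
            objective_hake(sim, {}, self.w, composition=False)

    def test_composition_term_is_scale_free(self):
        """The composition part compares proportions, so rescaling the whole
        simulated distribution leaves it unchanged."""
        obs = _cells([10.0, 30.0])
        sim = _cells([20.0, 60.0])
        score = objective_hake(sim, obs, {k: 0.0 for k in self.w}, self.w)
        assert score == pytest.approx(0.0)


class TestOtherObjectives:
    def test_sole_f_residuals(self):
        assert objective_sole_accessibility(
            np.array([[0.5, 0.3]]), np.array([[0.4, 0.4]])
        ) == pytest.approx(0.02)

    def test_sole_shape_mismatch(self):
        with pytest.raises(ValueError):
            objective_sole_accessibility(np.ones((1, 2)), np.ones((1, 3)))

    def test_nephrops_single_cell(self):
        sim, obs = np.zeros((4, 3)), np.zeros((4, 3))
        sim[1, 2] = 3.0
        assert objective_nephrops_accessibility(sim, obs) == 9.0

    def test_all_zero_quarter_changes_nothing(self):
        sim, obs = np.ones((4, 3)), np.ones((4, 3))
        base = objective_nephrops_accessibility(sim, obs)
        sim5 = np.vstack([sim, np.zeros((1, 3))])
        obs5 = np.vstack([obs, np.zeros((1, 3))])
        assert objective_nephrops_accessibility(sim5, obs5) == base == 0.0

    def test_catch_fit_cell_off_by_ten(self):
        sim = {("m", (2010, 1)): 15.0}
        obs = {("m", (2010, 1)): 5.0}
        assert objective_catch_fit(sim, obs, "metier_quarter") == pytest.approx(100.0)

    def test_catch_fit_order_invariant(self):
        sim = {("a", (2010, 1)): 1.0, ("b", (2010, 2)): 2.0}
        obs = {("b", (2010, 2)): 0.0, ("a", (2010, 1)): 0.0}
        assert objective_catch_fit(sim, obs, "metier_quarter") == pytest.approx(5.0)

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError):
            objective_catch_fit({}, {}, "by_vessel")


class TestParameterLayout:
    def test_full_scale_parameter_counts(self):
        """Full-scale layouts: 4 hake accessibility scalars (one per quarter,
        shared across lengths), one sole accessibility per age (7), one
        Norway lobster accessibility per sex x length class (56), and
        20 hake target factors (5 métier groups x 4 quarters)."""
        cfg = generate_config(0, PRESETS["paperlike"])
        specs = {s.name: s for s in build_parameter_specs(cfg)}
        assert specs["accessibility:hake"].n == 4
        assert specs["accessibility:sole"].n == 7
        assert specs["accessibility:nephrops"].n == 56
        assert specs["targetfactor:hake"].n == 20
        assert specs["targetfactor:nephrops"].n == 2

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            ParameterSpec("accessibility:hake", [1], [(1.0, 0.5)], np.array([0.7]))
        with pytest.raises(ValueError):
            ParameterSpec("accessibility:hake", [1, 2], [(0, 1)], np.array([0.5]))


class TestCalibrationMachinery:
    def test_truth_is_a_fixed_point(self, tiny_truth, tiny_obs):
        """Starting the optimiser at the synthetic truth, the objective is
        already (numerically) zero and estimates stay put."""
        specs = build_parameter_specs(tiny_truth)
        spec = [s for s in specs if s.name == "accessibility:sole"][0]
        truth_x = tiny_truth.stocks["sole"].accessibility.copy()
        spec.x0 = truth_x
        cal, res = calibrate(tiny_truth, tiny_obs, specs=[spec], maxfev=80)
        assert res.objectives["accessibility:sole"][0] == pytest.approx(0.0, abs=1e-12)
        est = cal.stocks["sole"].accessibility
        assert np.allclose(est, truth_x, rtol=1e-3)

    def test_single_set_recovery_within_bounds(self, tiny_truth, tiny_obs, calibration_start):
        spec = [s for s in build_parameter_specs(calibration_start)
                if s.name == "accessibility:sole"][0]
        cal, res = calibrate(calibration_start, tiny_obs, specs=[spec])
        est = cal.stocks["sole"].accessibility
        truth = tiny_truth.stocks["sole"].accessibility
        assert np.all(est >= 0) and np.all(est <= 2.0)  # bounds respected
        assert np.allclose(est, truth, rtol=0.05)
        traj = res.objectives["accessibility:sole"]
        assert traj[-1] <= traj[0]  # objective non-increasing

    def test_objective_decomposability(self):
        """Total score is the sum of per-cell contributions."""
        sim = _cells([1.0, 2.0, 3.0])
        obs = _cells([0.0, 0.0, 0.0])
        w = TestHakeObjective.w
        total = objective_hake(sim, obs, w, composition=False)
        parts = sum(
            objective_hake({k: v}, {k: 0.0}, w, composition=False)
            for k, v in sim.items()
        )
        assert total == pytest.approx(parts)

    def test_caller_config_not_mutated(self, tiny_truth, tiny_obs):
        before = copy.deepcopy(tiny_truth.stocks["sole"].accessibility)
        spec = [s for s in build_parameter_specs(tiny_truth)
                if s.name == "accessibility:sole"][0]
        calibrate(tiny_truth, tiny_obs, specs=[spec], maxfev=20)
        assert np.array_equal(tiny_truth.stocks["sole"].accessibility, before)
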