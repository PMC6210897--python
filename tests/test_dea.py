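import numpy as np
import pytest
from _oracles import (random_instance, sbm_score_oracle, simplex_grid,
                      super_score_oracle)

from effidiff import (DMUSet, SolveOptions, consistently_efficient,
                      count_efficient, evaluate_panel, score_dmu, solve_sbm,
                      solve_super_sbm)
from effidiff.panel_io import PanelValidationError
from effidiff.synthetic import GroupSpec, SyntheticSpec, generate_dmu_panel


class TestClosedForms:
    """2-DMU instances where the fractional optimum is known by hand."""

    def test_dominated_unit_sbm(self, two_dmu):
        res = solve_sbm(two_dmu, 1)
        assert res.score == pytest.approx(0.5, abs=1e-9)
        assert res.slacks_in[0] == pytest.approx(1.0, abs=1e-8)
        assert res.slacks_out[0] == pytest.approx(0.0, abs=1e-8)
        assert res.lambdas[0] == pytest.approx(1.0, abs=1e-8)

    def test_single_peer_super(self, two_dmu):
        res = solve_super_sbm(two_dmu, 0)
        assert res.score == pytest.approx(2.0, abs=1e-9)
        xbar, ybar = res.projection
        assert xbar[0] == pytest.approx(2.0, abs=1e-8)
        assert ybar[0] == pytest.approx(1.0, abs=1e-8)

    def test_two_stage_protocol(self, two_dmu):
        a = score_dmu(two_dmu, 0)
        b = score_dmu(two_dmu, 1)
        assert (a.value, a.stage) == (pytest.approx(2.0, abs=1e-9), "super")
        assert (b.value, b.stage) == (pytest.approx(0.5, abs=1e-9), "sbm")

    def test_closed_forms_agree_with_grid_oracle(self, two_dmu):
        assert sbm_score_oracle(two_dmu.X, two_dmu.Y, 1) == pytest.approx(
            0.5, abs=1e-5)
        assert super_score_oracle(two_dmu.X, two_dmu.Y, 0) == pytest.approx(
            2.0, abs=1e-5)


class TestDegenerateReferences:
    def test_twin_units_are_sbm_efficient(self):
        d = DMUSet(X=np.array([[2.0, 3.0], [2.0, 3.0]]),
                   Y=np.array([[1.5], [1.5]]))
        for k in (0, 1):
            res = solve_sbm(d, k)
            assert res.score == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(res.slacks_in, 0, atol=1e-8)
            assert np.allclose(res.slacks_out, 0, atol=1e-8)

    def test_twin_super_score_is_one(self):
        d = DMUSet(X=np.array([[2.0], [2.0], [5.0]]),
                   Y=np.array([[1.0], [1.0], [1.0]]))
        assert solve_super_sbm(d, 0).score == pytest.approx(1.0, abs=1e-9)

    def test_identical_triplet_all_super_one(self):
        d = DMUSet(X=np.full((3, 2), 2.0), Y=np.full((3, 1), 1.0))
        for k in range(3):
            es = score_dmu(d, k)
            assert es.stage == "super"
            assert es.value == pytest.approx(1.0, abs=1e-9)

    def test_strictly_dominated_unit_is_inefficient(self):
        rng = np.random.default_rng(3)
        X = rng.lognormal(0, 0.4, size=(4, 2))
        Y = rng.lognormal(0, 0.4, size=(4, 2))
        X = np.vstack([X, X[0] * 1.5])  # more input, less output than unit 0
        Y = np.vstack([Y, Y[0] * 0.5])
        es = score_dmu(DMUSet(X=X, Y=Y), 4)
        assert es.stage == "sbm" and es.value < 1.0

    def test_super_needs_two_units(self):
        d = DMUSet(X=np.array([[1.0]]), Y=np.array([[1.0]]))
        with pytest.raises(PanelValidationError):
            solve_super_sbm(d, 0)


class TestInvariants:
    def test_units_invariance(self):
        """SBM scores are invariant to rescaling any indicator column."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            X, Y = random_instance(rng)
            d = DMUSet(X=X, Y=Y)
            cx = rng.uniform(0.1, 10, size=X.shape[1])
            cy = rng.uniform(0.1, 10, size=Y.shape[1])
            d2 = DMUSet(X=X * cx, Y=Y * cy)
            for k in range(d.n):
                assert score_dmu(d2, k).value == pytest.approx(
                    score_dmu(d, k).value, abs=1e-9)

    def test_adding_dominated_unit_preserves_scores(self):
        rng = np.random.default_rng(12)
        X, Y = random_instance(rng)
        base = DMUSet(X=X, Y=Y)
        ref = [solve_sbm(base, k).score for k in range(base.n)]
        Xa = np.vstack([X, X.max(axis=0) * 2.0])
        Ya = np.vstack([Y, Y.min(axis=0) * 0.5])
        grown = DMUSet(X=Xa, Y=Ya)
        for rts in ("vrs", "crs"):
            opts = SolveOptions(returns_to_scale=rts)
            ref_rts = [solve_sbm(base, k, opts).score for k in range(base.n)]
            new = [solve_sbm(grown, k, opts).score for k in range(base.n)]
            np.testing.assert_allclose(new, ref_rts, atol=1e-8)
        del ref

    def test_slack_identities_reconstruct_unit(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            X, Y = random_instance(rng)
            d = DMUSet(X=X, Y=Y)
            for k in range(d.n):
                r = solve_sbm(d, k)
                np.testing.assert_allclose(
                    X[k], r.lambdas @ X + r.slacks_in, atol=1e-7)
                np.testing.assert_allclose(
                    Y[k], r.lambdas @ Y - r.slacks_out, atol=1e-7)

    def test_two_stage_consistency(self):
        rng = np.random.default_rng(14)
        for _ in range(8):
            X, Y = random_instance(rng)
            d = DMUSet(X=X, Y=Y)
            for k in range(d.n):
                es = score_dmu(d, k)
                if es.value < 1.0 - 1e-9:
                    assert es.stage == "sbm"
                if es.value > 1.0 + 1e-9:
                    assert es.stage == "super"

    def test_sbm_scores_match_grid_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            X, Y = random_instance(rng)
            d = DMUSet(X=X, Y=Y)
            for k in range(d.n):
                lp = solve_sbm(d, k).score
                assert lp == pytest.approx(
                    sbm_score_oracle(X, Y, k), abs=1e-4)

    def test_super_scores_match_grid_oracle(self):
        rng = np.random.default_rng(16)
        checked = 0
        while checked < 6:
            X, Y = random_instance(rng, n_max=4)
            d = DMUSet(X=X, Y=Y)
            for k in range(d.n):
                if solve_sbm(d, k).score >= 1 - 1e-6:
                    lp = solve_super_sbm(d, k).score
                    assert lp == pytest.approx(
                        super_score_oracle(X, Y, k), abs=1e-4)
                    checked += 1


@pytest.fixture(scope="module")
def synth_panel():
    spec = SyntheticSpec(groups=[GroupSpec("g", 10, 0.8, 0.1)], years=2,
                         n_inputs=2, n_outputs=1, noise_sd=0.05, seed=0)
    return generate_dmu_panel(spec)[0]


class TestPanelEvaluation:
    def test_scores_shape_and_stage_invariants(self, synth_panel):
        eff = evaluate_panel(synth_panel)
        assert eff.scores.shape == (10, 2)
        for i in range(10):
            for t in range(2):
                v, st = eff.scores[i, t], eff.status[i, t]
                assert st in ("sbm", "super")
                if st == "sbm":
                    assert v <= 1 + 1e-9
                else:
                    assert v >= 1 - 1e-9

    def test_output_degradation_lowers_score(self, synth_panel):
        """Halving one unit's outputs in year 2 only cannot raise its
        year-2 score above its year-1 score (all else unchanged)."""
        panel = synth_panel
        base = evaluate_panel(panel)
        Y = panel.Y.copy()
        Y[1, 0] *= 0.5
        worse = type(panel)(unit_ids=panel.unit_ids, years=panel.years,
                            input_names=panel.input_names,
                            output_names=panel.output_names,
                            X=panel.X, Y=Y)
        eff = evaluate_panel(worse)
        assert eff.scores[0, 1] <= eff.scores[0, 0] + 1e-9
        assert eff.scores[0, 1] <= base.scores[0, 1] + 1e-9

    def test_column_rescaling_leaves_panel_scores(self, synth_panel):
        panel = synth_panel
        scaled = type(panel)(unit_ids=panel.unit_ids, years=panel.years,
                             input_names=panel.input_names,
                             output_names=panel.output_names,
                             X=panel.X * np.array([3.0, 0.2]),
                             Y=panel.Y * 40.0)
        np.testing.assert_allclose(evaluate_panel(scaled).scores,
                                   evaluate_panel(panel).scores, atol=1e-9)


class TestEfficientCounts:
    def test_fixture_counts(self, table1):
        assert count_efficient(table1, 2008)[0] == 12
        assert count_efficient(table1, 2016)[0] == 10

    def test_fixture_intersection(self, table1):
        assert consistently_efficient(table1) == [
            "Chongqing", "Guangdong", "Hainan", "Jiangsu", "Ningxia",
            "Shanghai"]

    def test_threshold_is_respected(self, table1):
        n_all, units = count_efficient(table1, 2008, threshold=0.0)
        assert n_all == 30
        assert "Tianjin" in units


def test_simplex_grid_covers_vertices():
    g = simplex_grid(3, 4)
    assert g.shape == (15, 3)
    np.testing.assert_allclose(g.sum(axis=1), 1.0)
    for v in np.eye(3):
        assert (np.abs(g - v).sum(axis=1) < 1e-12).any()
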