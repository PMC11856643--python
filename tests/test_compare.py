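import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdmcompare import (difficulty_agreement, make_taxonomy_qmatrix, paired_mad_test,
                        rank_agreement, regression_robustness, run_full_comparison,
                        simulate_additive, simulate_conjunctive, steiger_z)
from cdmcompare.compare import select_top_components
from cdmcompare.lltm import LLTM


class TestPairedMADTest:
    def test_identical_vectors_are_null(self):
        a = pd.Series([0.03, 0.05, 0.04], index=list("abc"))
        res = paired_mad_test(a, a)
        assert (res.t, res.d, res.p) == (0.0, 0.0, 1.0)

    def test_hand_arithmetic(self):
        res = paired_mad_test(np.array([0.01, 0.02, 0.03]), np.zeros(3))
        assert res.t == pytest.approx(3.464, abs=1e-3)
        assert res.d == pytest.approx(2.0, abs=1e-9)
        assert res.df == 2

    def test_constant_nonzero_difference_reported_as_infinite(self):
        res = paired_mad_test(np.array([0.1, 0.1, 0.1]), np.zeros(3))
        assert np.isinf(res.t) and res.t > 0
        assert res.p == 0.0

    @given(seed=st.integers(0, 10_000))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(8), rng.random(8)
        fwd, rev = paired_mad_test(a, b), paired_mad_test(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.d == pytest.approx(-rev.d)
        assert fwd.p == pytest.approx(rev.p)

    def test_unmatched_items_rejected(self):
        a = pd.Series([1.0, 2, 3], index=list("abc"))
        b = pd.Series([1.0, 2, 3], index=list("abd"))
        with pytest.raises(ValueError, match="matched"):
            paired_mad_test(a, b)


class TestDifficultyAgreement:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = difficulty_agreement(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            difficulty_agreement(np.ones(6), np.arange(6.0))

    def test_fisher_interval_covers_true_correlation(self):
        """~95% coverage of the Fisher-z CI at n=18, population r=0.7."""
        rng = np.random.default_rng(1234)
        rho = 0.7
        cover = 0
        reps = 1000
        for _ in range(reps):
            x = rng.standard_normal(18)
            y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal(18)
            res = difficulty_agreement(x, y)
            cover += res.ci_low <= rho <= res.ci_high
        assert 0.92 <= cover / reps <= 0.98


class TestSteigerZ:
    def test_equal_correlations_give_zero(self):
        res = steiger_z(0.5, 0.5, 0.3, 50)
        assert res.z == 0.0
        assert res.p == 1.0

    def test_matches_independent_formula_implementation(self):
        def reference(ra, rb, rab, n):
            # independently coded from the published dependent-correlation test
            za, zb = np.arctanh(ra), np.arctanh(rb)
            rm = (ra + rb) / 2
            psi = rab * (1 - 2 * rm ** 2) - 0.5 * rm ** 2 * (1 - 2 * rm ** 2 - rab ** 2)
            s = psi / (1 - rm ** 2) ** 2
            return (za - zb) * np.sqrt((n - 3) / (2 - 2 * s))

        res = steiger_z(0.6, 0.4, 0.5, 103)
        assert res.z == pytest.approx(reference(0.6, 0.4, 0.5, 103), abs=1e-6)

    @given(ra=st.floats(-0.9, 0.9), rb=st.floats(-0.9, 0.9), rab=st.floats(-0.5, 0.5))
    def test_antisymmetric_in_the_two_correlations(self, ra, rb, rab):
        fwd = steiger_z(ra, rb, rab, 40)
        rev = steiger_z(rb, ra, rab, 40)
        assert fwd.z == pytest.approx(-rev.z, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="Fisher"):
            steiger_z(1.0, 0.5, 0.3, 50)
        with pytest.raises(ValueError, match="n must"):
            steiger_z(0.5, 0.4, 0.3, 5)


class TestRankAgreement:
    def test_identical_and_reversed_rankings(self):
        a = np.array([3.0, 1.0, 2.0, 5.0])
        assert rank_agreement(a, a) == pytest.approx(1.0)
        assert rank_agreement(a, -a) == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rank_agreement(np.ones(5), np.arange(5.0))


class TestRegressionRobustness:
    def _setup(self, seed=0):
        q = make_taxonomy_qmatrix(20, rng_seed=seed)
        selected = ["CQ", "SS", "DP", "VOS"]
        return q, selected

    def test_additive_truth_yields_no_interaction_gain(self):
        q, selected = self._setup()
        eta = np.linspace(-0.8, 0.8, 9)
        sigma = q.weights @ eta
        res = regression_robustness(sigma, q, selected)
        assert res.delta_r2 < 0.25
        assert res.p > 0.05

    def test_planted_interaction_matches_brute_force_r2(self):
        q, selected = self._setup(seed=4)
        qf = q.to_frame().astype(float)
        y = (0.5 * qf["CQ"] + 0.8 * qf["DP"] + 1.2 * qf["CQ"] * qf["DP"]).to_numpy()
        y = y + np.linspace(-0.01, 0.01, len(y))       # break exact collinearity
        res = regression_robustness(y, q, selected)

        def brute_r2(cols):
            x = np.column_stack([np.ones(len(y))] + cols)
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ beta
            return 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

        main_cols = [qf[c].to_numpy() for c in selected]
        inter_cols = [qf[a].to_numpy() * qf[b].to_numpy()
                      for a, b in [(r, p) for r in ("CQ", "SS") for p in ("DP", "VOS")]]
        kept = [c for name, c in zip(
            [f"{r}x{p}" for r in ("CQ", "SS") for p in ("DP", "VOS")], inter_cols)
            if name in res.interactions]
        expected_delta = brute_r2(main_cols + kept) - brute_r2(main_cols)
        assert res.delta_r2 == pytest.approx(expected_delta, abs=1e-10)

    def test_missing_component_rejected(self):
        q, _ = self._setup()
        with pytest.raises(ValueError, match="not in Q-matrix"):
            regression_robustness(np.zeros(q.n_items), q, ["NOPE"])


class TestFullComparison:
    def test_additive_truth_ranks_lltm_first(self, q18):
        fit = simulate_additive(q18, n_persons=600, rng_seed=20250901)
        cv = simulate_additive(q18, n_persons=600, rng_seed=20250903)
        report = run_full_comparison(fit.responses, cv.responses, q18)
        lltm_row = report.row("LLTM", "rasch")
        lsdm_row = report.row("LSDM", "rasch")
        assert lltm_row.mean_mad < lsdm_row.mean_mad
        assert lltm_row.predictive.r > lsdm_row.predictive.r

    def test_conjunctive_truth_ranks_lsdm_at_or_above_lltm(self):
        q = make_taxonomy_qmatrix(18, rng_seed=20250902)
        fit = simulate_conjunctive(q, n_persons=600, rng_seed=20250902)
        cv = simulate_conjunctive(q, n_persons=600, rng_seed=20250903)
        report = run_full_comparison(fit.responses, cv.responses, q)
        assert report.row("LSDM", "rasch").mean_mad <= report.row("LLTM", "rasch").mean_mad

    def test_cross_validation_r_inside_fisher_interval_of_fit_r(self, q18):
        """Disjoint samples of one generating process: the cross-validation r
        falls inside the Fisher CI of the in-sample r in most replicates.

        The generating world lets the taxonomy explain most but not all of
        item difficulty (slopes near 1, difficulties additive plus an
        item-specific deviation), so the structural correlation is away from
        the degenerate r=1 boundary where the Fisher interval collapses.
        """
        import numpy as np

        from cdmcompare import simulate_2pl

        rng = np.random.default_rng(7)
        eta = rng.uniform(-0.6, 0.6, 9)
        b = q18.weights @ eta + rng.normal(0, 0.35, 18)
        b -= b.mean()
        a = rng.uniform(0.8, 1.2, 18)
        hits = 0
        for rep in range(10):
            fit = simulate_2pl(a, b, n_persons=600, rng_seed=3000 + 2 * rep,
                               item_ids=list(q18.items))
            cv = simulate_2pl(a, b, n_persons=600, rng_seed=3001 + 2 * rep,
                              item_ids=list(q18.items))
            report = run_full_comparison(fit.responses, cv.responses, q18,
                                         screen_items=False)
            row = report.row("LLTM", "rasch")
            hits += row.predictive.ci_low <= row.cross_validation.r <= row.predictive.ci_high
        assert hits >= 8

    def test_report_serializes_and_renders(self, q18):
        fit = simulate_additive(q18, n_persons=400, rng_seed=71)
        cv = simulate_additive(q18, n_persons=400, rng_seed=72)
        report = run_full_comparison(fit.responses, cv.responses, q18)
        d = report.to_dict()
        assert {r["model"] for r in d["rows"]} == {"LLTM", "LSDM"}
        assert "lltm_vs_lsdm_rasch_fit" in d["steiger_tests"]
        text = report.render_text()
        assert "Predictive r" in text and "LLTM" in text

    def test_top_component_selection_uses_both_kinds(self, additive_data, q18):
        lltm = LLTM().fit(additive_data.responses, q18)
        top = select_top_components(lltm, n_per_kind=2)
        kinds = {q18.taxonomy.kind_of(c) for c in top}
        assert len(top) == 4 and len(kinds) == 2
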