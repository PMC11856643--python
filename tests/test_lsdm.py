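import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from cdmcompare import (LSDM, AttributeCurveParams, RaschCML, ThetaGrid,
                        implied_item_difficulty, mad_diagnostics, mad_label)
from cdmcompare.containers import ICCTable
from cdmcompare.lltm import LLTM
from cdmcompare.lsdm import MADReport, attribute_curve_summary
from cdmcompare.taxonomy import QMatrix


def _conjunctive_icc(q, grid, curves):
    comp = curves.probs(grid.points)
    probs = np.exp(q.weights @ np.log(comp))
    return ICCTable(items=list(q.items), grid=grid, probs=probs, provenance="rasch"), comp


class TestSolve:
    def test_identity_q_returns_log_iccs_exactly(self, identity_taxonomy, grid):
        b = np.linspace(-1.5, 1.5, 9)
        probs = expit(grid.points[None, :] - b[:, None])
        source = ICCTable(items=list(identity_taxonomy.items), grid=grid,
                          probs=probs, provenance="rasch")
        fit = LSDM().fit(source, identity_taxonomy)
        assert np.allclose(fit.attribute_logprobs_, np.log(probs), atol=1e-10)
        assert np.all(fit.residual_norms_ < 1e-10)

    def test_consistent_three_item_system(self, two_component_taxonomy):
        q = QMatrix(items=["i1", "i2", "i3"], taxonomy=two_component_taxonomy,
                    weights=np.array([[1, 0], [0, 1], [1, 1]]))
        g = ThetaGrid(np.array([0.0]))
        source = ICCTable(items=q.items, grid=g,
                          probs=np.array([[0.8], [0.5], [0.4]]), provenance="rasch")
        fit = LSDM().fit(source, q)
        assert fit.attribute_logprobs_[0, 0] == pytest.approx(np.log(0.8), abs=1e-10)
        assert fit.attribute_logprobs_[1, 0] == pytest.approx(np.log(0.5), abs=1e-10)
        assert fit.residual_norms_[0] == pytest.approx(0.0, abs=1e-10)

    def test_exact_recovery_of_conjunctive_construction(self, q18, grid):
        curves = AttributeCurveParams(difficulty=np.linspace(-2, 1, 9),
                                      discrimination=np.linspace(0.7, 1.6, 9))
        source, comp = _conjunctive_icc(q18, grid, curves)
        fit = LSDM().fit(source, q18)
        assert fit.residual_norms_.max() < 1e-6
        assert fit.mad_.per_item.max() < 1e-6
        assert np.abs(np.exp(fit.attribute_logprobs_) - comp).max() < 1e-6

    def test_constrained_probabilities_never_exceed_one(self, rasch_fit, q18, grid):
        fit = LSDM(constrained=True).fit(rasch_fit.icc_table(grid), q18)
        assert np.all(fit.attribute_logprobs_ <= 1e-12)
        assert fit.reconstructed_.probs.max() <= 1.0

    def test_unconstrained_mode_reports_clipped_cells(self, two_component_taxonomy):
        q = QMatrix(items=["i1", "i2"], taxonomy=two_component_taxonomy,
                    weights=np.array([[1, 0], [1, 1]]))
        g = ThetaGrid(np.array([0.0]))
        # exact solution: x1 = ln 0.5, x2 = ln 0.8 - ln 0.5 > 0 (prob > 1)
        source = ICCTable(items=q.items, grid=g,
                          probs=np.array([[0.5], [0.8]]), provenance="rasch")
        fit = LSDM(constrained=False).fit(source, q)
        assert fit.n_clipped_ == 1
        assert fit.reconstructed_.probs.max() < 1.0

    def test_all_zero_component_column_rejected(self, q18, rasch_fit, grid):
        w = q18.weights.copy()
        w[:, 4] = 0
        w[w.sum(axis=1) == 0, 0] = 1
        q_dead = QMatrix(items=list(q18.items), taxonomy=q18.taxonomy, weights=w)
        with pytest.raises(ValueError, match="SS"):
            LSDM().fit(rasch_fit.icc_table(grid), q_dead)


class TestMAD:
    def test_identical_tables_give_zero_good(self, rasch_fit, grid):
        t = rasch_fit.icc_table(grid)
        rep = mad_diagnostics(t, t)
        assert rep.mean == 0.0
        assert (rep.labels == "good").all()

    def test_constant_gap_is_satisfactory(self, grid):
        base = expit(grid.points[None, :] - np.array([[0.0]]))
        a = ICCTable(items=["i1"], grid=grid, probs=np.clip(base, 1e-6, 1 - 1e-6),
                     provenance="rasch")
        shifted = np.clip(base - 0.08, 1e-6, 1 - 1e-6)
        # keep the gap exactly 0.08 inside the clip range
        mask = (base > 0.09) & (base < 0.99)
        b = ICCTable(items=["i1"], grid=ThetaGrid(grid.points[mask[0]]),
                     probs=base[:, mask[0]] - 0.08, provenance="lsdm-reconstructed")
        a_sub = ICCTable(items=["i1"], grid=b.grid, probs=base[:, mask[0]],
                         provenance="rasch")
        rep = mad_diagnostics(a_sub, b)
        assert rep.per_item["i1"] == pytest.approx(0.08)
        assert rep.labels["i1"] == "satisfactory"

    def test_grid_mismatch_rejected(self, rasch_fit, grid):
        t = rasch_fit.icc_table(grid)
        other = rasch_fit.icc_table(ThetaGrid.make(-3, 3, 61))
        with pytest.raises(ValueError, match="grids differ"):
            mad_diagnostics(t, other)

    @given(perm_seed=st.integers(0, 10_000))
    def test_mad_invariant_to_item_and_grid_order(self, rasch_fit, grid, perm_seed):
        t = rasch_fit.icc_table(grid)
        noisy = ICCTable(items=t.items, grid=grid,
                         probs=np.clip(t.probs + 0.01, 1e-6, 1 - 1e-6),
                         provenance="lsdm-reconstructed")
        base = mad_diagnostics(t, noisy).per_item
        rng = np.random.default_rng(perm_seed)
        items_perm = rng.permutation(len(t.items))
        grid_perm = np.argsort(grid.points)    # grid must stay increasing; permute items only
        t2 = ICCTable(items=[t.items[i] for i in items_perm], grid=grid,
                      probs=t.probs[items_perm][:, grid_perm], provenance="rasch")
        n2 = ICCTable(items=t2.items, grid=grid, probs=noisy.probs[items_perm][:, grid_perm],
                      provenance="lsdm-reconstructed")
        permuted = mad_diagnostics(t2, n2).per_item
        assert np.allclose(permuted.sort_index(), base.sort_index())

    def test_label_thresholds(self):
        assert mad_label(0.049999) == "good"
        assert mad_label(0.05) == "satisfactory"
        assert mad_label(0.099999) == "satisfactory"
        assert mad_label(0.10) == "poor"
        with pytest.raises(ValueError):
            MADReport(per_item=pd.Series([-0.01], index=["i1"]))


class TestImpliedDifficulty:
    def test_logistic_row_crosses_at_its_location(self, grid):
        b = 0.73
        probs = expit(grid.points[None, :] - b)
        t = ICCTable(items=["i1"], grid=grid, probs=probs, provenance="lsdm-reconstructed")
        out = implied_item_difficulty(t)
        spacing = grid.points[1] - grid.points[0]
        assert abs(out.loc["i1", "difficulty"] - b) < spacing / 10
        assert not out.loc["i1", "extrapolated"]

    def test_linear_interpolation_arithmetic(self):
        g = ThetaGrid(np.array([-1.0, 0.0, 1.0]))
        t = ICCTable(items=["i1"], grid=g, probs=np.array([[0.30, 0.45, 0.60]]),
                     provenance="lsdm-reconstructed")
        out = implied_item_difficulty(t)
        assert out.loc["i1", "difficulty"] == pytest.approx((0.50 - 0.45) / 0.15)

    def test_row_below_half_flagged_at_upper_bound(self, grid):
        probs = np.full((1, len(grid)), 0.2)
        t = ICCTable(items=["i1"], grid=grid, probs=probs, provenance="lsdm-reconstructed")
        out = implied_item_difficulty(t)
        assert out.loc["i1", "extrapolated"]
        assert out.loc["i1", "difficulty"] == grid.points[-1]


class TestAttributeSummary:
    def test_exact_logistic_curve_recovered(self, identity_taxonomy, grid):
        b = np.linspace(-1.5, 1.5, 9)
        b[0] = 1.0
        probs = expit(grid.points[None, :] - b[:, None])
        source = ICCTable(items=list(identity_taxonomy.items), grid=grid,
                          probs=probs, provenance="rasch")
        fit = LSDM().fit(source, identity_taxonomy)
        summary = attribute_curve_summary(fit).table
        first = summary.iloc[0]
        assert first["difficulty"] == pytest.approx(1.0, abs=1e-6)
        assert first["discrimination"] == pytest.approx(1.0, abs=1e-6)
        assert first["r2"] == pytest.approx(1.0, abs=1e-9)

    def test_flat_mastered_component_is_degenerate(self, two_component_taxonomy):
        g = ThetaGrid.make(-4, 4, 31)
        q = QMatrix(items=["i1", "i2"], taxonomy=two_component_taxonomy,
                    weights=np.array([[1, 1], [1, 2]]))
        curves = AttributeCurveParams(difficulty=np.zeros(2), discrimination=np.ones(2),
                                      pinned=np.array([np.nan, 0.99]))
        source, _ = _conjunctive_icc(q, g, curves)
        fit = LSDM().fit(source, q)
        row = attribute_curve_summary(fit).table.loc["D1"]
        assert row["unfit"] or row["extrapolated"] or abs(row["discrimination"]) < 0.1


class TestModelDiscriminationDirection:
    def test_lsdm_worse_than_lltm_on_additive_truth(self, additive_data, q18, grid):
        rasch = RaschCML().fit(additive_data.responses)
        source = rasch.icc_table(grid)
        lsdm_mad = LSDM().fit(source, q18).mad_.mean
        lltm_mad = mad_diagnostics(source, LLTM().fit(additive_data.responses,
                                                      q18).icc_table(grid)).mean
        assert lsdm_mad >= lltm_mad
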