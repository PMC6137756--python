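"""The grid search itself: TMGR/TMPR, per-cell LPs, knockout extraction,
cell scoring and the final design selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gridprod as gp
from gridprod.errors import ConfigurationError, GridProdError
from gridprod.grid_search import GridCell


class TestTheoreticalMaxima:
    def test_toy_tmgr(self, toy):
        assert gp.compute_tmgr(toy) == pytest.approx(10.0, abs=1e-6)

    def test_toy_tmpr(self, toy):
        assert gp.compute_tmpr(toy) == pytest.approx(8.0, abs=1e-6)

    def test_tmgr_zero_when_sources_closed(self, toy):
        starved = gp.apply_knockouts(toy, {"R1", "R2"})
        assert gp.compute_tmgr(starved) == pytest.approx(0.0, abs=1e-9)

    def test_tmpr_zero_when_routes_cut(self, toy):
        cut = gp.apply_knockouts(toy, {"R4", "R5"})
        assert gp.compute_tmpr(cut) == pytest.approx(0.0, abs=1e-9)

    def test_tmpr_zero_when_target_clamped(self, toy):
        toy.require_reaction("R6").upper_bound = 0.0
        assert gp.compute_tmpr(toy) == pytest.approx(0.0, abs=1e-9)

    def test_tmpr_relaxes_biomass_lower_bound(self, toy):
        # force a growth demand the production optimum would violate
        toy.require_reaction("R7").lower_bound = 9.0
        assert gp.compute_tmpr(toy) == pytest.approx(8.0, abs=1e-6)
        assert toy.require_reaction("R7").lower_bound == 9.0  # restored


@settings(max_examples=50, deadline=None)
@given(tmgr=st.floats(0.1, 100), tmpr=st.floats(0.1, 100),
       p_inv=st.integers(1, 40))
def test_grid_cells_tile_the_rectangle_exactly(tmgr, tmpr, p_inv):
    cells = [GridCell.from_indices(i, j, tmgr, tmpr, p_inv)
             for i in range(p_inv) for j in range(p_inv)]
    assert cells[0].gr_lower == 0 and cells[0].pr_lower == 0
    assert cells[-1].gr_upper == pytest.approx(tmgr, rel=1e-12)
    assert cells[-1].pr_upper == pytest.approx(tmpr, rel=1e-12)
    for c in cells:
        assert c.gr_lower <= c.gr_upper and c.pr_lower <= c.pr_upper
        assert c.gr_upper - c.gr_lower == pytest.approx(tmgr / p_inv, rel=1e-9)


class TestFirstLp:
    def test_point_below_constant_source_is_infeasible(self, toy):
        cell = GridCell(0, 0, gr_lower=0, gr_upper=0, pr_lower=3, pr_upper=3)
        assert gp.first_lp(toy, "R6", cell).status == "infeasible"

    def test_parsimonious_solution_drops_side_routes(self, toy):
        cell = GridCell(0, 0, gr_lower=2, gr_upper=2, pr_lower=3, pr_upper=3)
        out = gp.first_lp(toy, "R6", cell)
        assert out.optimal
        for rid, val in {"R1": 0, "R2": 5, "R3": 2, "R4": 3, "R5": 0,
                         "R6": 3, "R7": 2, "R8": 0}.items():
            assert out.flux[rid] == pytest.approx(val, abs=1e-6), rid

    def test_cell_above_tmpr_is_infeasible(self, toy):
        cell = GridCell(0, 0, gr_lower=0, gr_upper=1, pr_lower=9, pr_upper=10)
        assert gp.first_lp(toy, "R6", cell).status == "infeasible"


class TestExtractKnockouts:
    def test_zero_flux_internal_reactions(self, toy):
        cell = GridCell(0, 0, 2, 2, 4, 4)
        flux = gp.first_lp(toy, "R6", cell).flux
        assert gp.extract_knockouts(flux, toy, gp.GridConfig()) == {"R5", "R8"}

    def test_all_active_gives_empty_set(self, toy):
        flux = gp.FluxDistribution(
            values={rid: 1.0 for rid in toy.reaction_ids}, objective_value=8.0)
        assert gp.extract_knockouts(flux, toy, gp.GridConfig()) == frozenset()

    def test_infinite_threshold_takes_all_unprotected(self, toy):
        flux = gp.FluxDistribution(
            values={rid: 1.0 for rid in toy.reaction_ids}, objective_value=8.0)
        config = gp.GridConfig(zero_tol=float("inf"))
        assert gp.extract_knockouts(flux, toy, config) == {"R3", "R4", "R5", "R8"}

    def test_exchange_protection_switch(self, toy):
        flux = gp.FluxDistribution(
            values={rid: 0.0 for rid in toy.reaction_ids}, objective_value=0.0)
        unprotected = gp.extract_knockouts(
            flux, toy, gp.GridConfig(protect_exchanges=False))
        # biomass and target stay protected even then
        assert unprotected == {"R1", "R2", "R3", "R4", "R5", "R8"}


class TestSecondLp:
    def test_r3_knockout_couples_production(self, toy, toy_med):
        sec = gp.second_lp(toy, {"R3"}, toy_med)
        assert sec.gr == pytest.approx(1.0, abs=1e-6)
        assert sec.pr == pytest.approx(4.0, abs=1e-6)
        assert sec.stored_pr == pytest.approx(4.0, abs=1e-6)

    def test_no_knockout_gives_full_growth_no_production(self, toy, toy_med):
        sec = gp.second_lp(toy, set(), toy_med)
        assert sec.gr == pytest.approx(10.0, abs=1e-6)
        assert sec.stored_pr == pytest.approx(0.0, abs=1e-6)

    def test_growth_below_minimum_is_gated_to_zero(self, toy, toy_med):
        sec = gp.second_lp(toy, {"R3", "R8"}, toy_med)
        assert sec.gr == pytest.approx(0.0, abs=1e-6)
        assert sec.stored_pr == 0.0

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_second_growth_at_least_first_growth(self, seed, toy_med):
        """Knocking out only the first LP's own zero-flux reactions keeps
        that flux feasible, so maximal growth cannot drop below it."""
        model = gp.random_network(3, 9, seed=seed)
        grid = gp.GridConfig(p_inv=3)
        tmgr, tmpr = gp.compute_tmgr(model), gp.compute_tmpr(model)
        if tmpr <= 0:
            pytest.skip("target not producible in this draw")
        for i in range(3):
            for j in range(3):
                cell = GridCell.from_indices(i, j, tmgr, tmpr, 3)
                first = gp.first_lp(model, model.target_id, cell)
                if not first.optimal:
                    continue
                kos = gp.extract_knockouts(first.flux, model, grid)
                sec = gp.second_lp(model, kos, toy_med)
                assert sec.status == "optimal"
                assert sec.gr >= first.flux[model.biomass_id] - 1e-6


class TestRunGridprod:
    def test_toy_grid_has_no_positive_cell(self, toy, toy_med):
        """On the toy network the parsimonious flux always routes growth
        through R3, so no cell's knockout set removes it and every stored
        score is 0 — the documented sharp case the exhaustive oracle beats."""
        res = gp.run_gridprod(toy, grid=gp.GridConfig(p_inv=5), medium=toy_med)
        assert res.tmgr == pytest.approx(10.0, abs=1e-6)
        assert res.tmpr == pytest.approx(8.0, abs=1e-6)
        assert np.all(res.pr_matrix == 0.0)
        # in particular the whole GR >= 2 band, as in the worked example
        assert np.all(res.pr_matrix[1:, :] == 0.0)

    def test_single_cell_grid_spans_rectangle(self, toy, toy_med):
        res = gp.run_gridprod(toy, grid=gp.GridConfig(p_inv=1), medium=toy_med)
        assert res.pr_matrix.shape == (1, 1)
        cell = res.cells[0].cell
        assert (cell.gr_lower, cell.gr_upper) == (0.0, pytest.approx(10.0))
        assert (cell.pr_lower, cell.pr_upper) == (0.0, pytest.approx(8.0))

    def test_matrix_invariant_to_cell_order(self, toy_med):
        model = gp.random_network(3, 9, seed=4)
        grid = gp.GridConfig(p_inv=4)
        forward = gp.run_gridprod(model, grid=grid, medium=toy_med)
        order = [(i, j) for i in range(4) for j in range(4)][::-1]
        backward = gp.run_gridprod(model, grid=grid, medium=toy_med,
                                   cell_order=order)
        np.testing.assert_allclose(forward.pr_matrix, backward.pr_matrix,
                                   atol=1e-9)
        assert forward.best_cell == backward.best_cell
        assert forward.knockouts == backward.knockouts

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_stored_scores_within_tmpr(self, seed):
        model = gp.random_network(3, 9, seed=seed)
        res = gp.run_gridprod(model, grid=gp.GridConfig(p_inv=4))
        assert np.all(res.pr_matrix >= 0.0)
        assert np.all(res.pr_matrix <= res.tmpr + 1e-6)
        assert res.pr == pytest.approx(res.pr_matrix.max(), abs=1e-9)
        assert res.reactions_used == len(model.reactions) - len(res.knockouts)

    def test_errors_when_nothing_to_grid(self, toy, toy_med):
        toy.require_reaction("R6").upper_bound = 0.0
        with pytest.raises(GridProdError):
            gp.run_gridprod(toy, grid=gp.GridConfig(p_inv=2), medium=toy_med)

    def test_requires_target(self, toy):
        toy.target_id = None
        with pytest.raises(ConfigurationError):
            gp.run_gridprod(toy)

    @pytest.mark.parametrize("seed", range(1, 9))
    def test_never_beats_exhaustive_oracle(self, seed):
        model = gp.random_network(3, 9, seed=seed)
        res = gp.run_gridprod(model, grid=gp.GridConfig(p_inv=5))
        oracle = gp.brute_force_design(model)
        assert res.pr <= oracle.pr + 1e-6

    def test_refinement_trend_on_fixed_ensemble(self):
        """Finer grids should not hurt on average (the saturation-at-25
        behaviour seen on genome-scale screens, at desk scale)."""
        coarse, fine = [], []
        for seed in range(1, 7):
            model = gp.random_network(3, 11, seed=seed)
            coarse.append(gp.run_gridprod(model, grid=gp.GridConfig(p_inv=2)).pr)
            fine.append(gp.run_gridprod(model, grid=gp.GridConfig(p_inv=25)).pr)
        assert np.mean(fine) >= np.mean(coarse) - 1e-9


class TestIsProducible:
    def _result(self, lo, hi):
        return gp.GridProdResult(best_cell=(0, 0), knockouts=frozenset(),
                                 gr=1.0, pr=lo, pr_fva_min=lo, pr_fva_max=hi,
                                 reactions_used=8,
                                 pr_matrix=np.zeros((1, 1)), tmgr=10.0,
                                 tmpr=8.0)

    @pytest.mark.parametrize("value,expected", [(0.0, False), (4.0, True),
                                                (1e-6, False), (1e-5, True)])
    def test_cutoff(self, value, expected):
        res = self._result(value, value)
        assert gp.is_producible(res, "fva_min") is expected

    def test_criteria_are_independent(self):
        res = self._result(0.0, 4.0)
        assert not gp.is_producible(res, "fva_min")
        assert gp.is_producible(res, "fva_max")


def test_grid_config_validation():
    with pytest.raises(ConfigurationError):
        gp.GridConfig(p_inv=0)
    with pytest.raises(ConfigurationError):
        gp.GridConfig(zero_tol=0)
    with pytest.raises(ConfigurationError):
        gp.GridConfig(criterion="median")
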