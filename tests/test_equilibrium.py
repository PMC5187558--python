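import math

import numpy as np
import pytest

from cvmlat import (
    BRANCH_2D,
    BranchError,
    SingularityError,
    ThermoParams,
    equilibrium_1d,
    equilibrium_2d_numeric,
    equilibrium_2d_z3,
    equilibrium_curve,
    minimize_free_energy,
    reduced_free_energy_1d,
    reduced_free_energy_2d,
    symmetric_fractions,
)


def feasible_gradient(z1, z3, h, dims):
    """Central-difference gradient of the reduced free energy in the
    symmetric (z1, z3) chart — independent of the solver's own gradient."""
    params = ThermoParams.from_h(h)
    fe = reduced_free_energy_1d if dims == 1 else reduced_free_energy_2d

    def g(a, b):
        return fe(symmetric_fractions(a, b), params).g_reduced

    d = 1e-7
    return np.array(
        [
            (g(z1 + d, z3) - g(z1 - d, z3)) / (2 * d),
            (g(z1, z3 + d) - g(z1, z3 - d)) / (2 * d),
        ]
    )


class TestClosedForm1D:
    def test_no_interaction_point(self):
        sol = equilibrium_1d(1.0)
        assert sol.z1 == sol.z3 == 0.125
        assert sol.y2 == 0.25
        assert sol.s == 1.0
        assert sol.fractions.x1 == 0.5

    def test_strong_ferromagnetic_point(self):
        sol = equilibrium_1d(3.0)
        assert sol.z1 == pytest.approx(0.405, abs=5e-4)
        assert sol.z3 == pytest.approx(0.005, abs=5e-4)

    def test_symmetry_of_solution(self):
        sol = equilibrium_1d(1.7)
        z = sol.fractions.z
        y = sol.fractions.y
        assert z[0] == z[5] and z[1] == z[4] and z[2] == z[3]
        assert y[0] == y[2]
        assert sum(sol.fractions.aggregated_z()) == pytest.approx(1.0, abs=1e-15)

    def test_antiferromagnetic_limit(self):
        sol = equilibrium_1d(1e-4)
        assert sol.z3 == pytest.approx(0.5, abs=1e-3)
        assert sol.z1 < 1e-10
        assert sol.y2 == pytest.approx(0.5, abs=1e-3)

    def test_ferromagnetic_limit(self):
        sol = equilibrium_1d(1e4)
        assert sol.z1 == pytest.approx(0.5, abs=1e-3)
        assert sol.z3 < 1e-10
        assert sol.y2 > 0.0  # unlike pairs never vanish in a mixed system

    def test_nonpositive_h_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_1d(-0.5)

    @pytest.mark.parametrize("h", [0.5, 1.0, 2.0, 3.0])
    def test_closed_form_is_stationary(self, h):
        sol = equilibrium_1d(h)
        grad = feasible_gradient(sol.z1, sol.z3, h, dims=1)
        assert np.abs(grad).max() < 1e-6  # central differences at step 1e-7

    @pytest.mark.parametrize("h", [0.5, 1.0, 2.0, 3.0])
    def test_stationarity_system_has_single_multiplier(self, h):
        # with lambda = 0 the six stationarity relations share one scalar q
        sol = equilibrium_1d(h)
        z1, z2, z3 = sol.fractions.z[:3]
        y1, y2, _ = sol.fractions.y
        qs = [
            y1 / z1,
            math.sqrt(y1 * y2) / (h * z2),
            y2 / (h * h * z3),
            y2 / (h * h * z3),
            math.sqrt(y2 * y1) / (h * z2),
            y1 / z1,
        ]
        assert max(qs) - min(qs) < 1e-10 * max(qs)


class TestNumericMinimiser:
    @pytest.mark.parametrize("h", np.linspace(0.3, 3.0, 10).round(3).tolist())
    def test_1d_minimum_matches_closed_form(self, h):
        num = minimize_free_energy(h, dims=1)
        ref = equilibrium_1d(h)
        assert num.z1 == pytest.approx(ref.z1, abs=1e-6)
        assert num.z3 == pytest.approx(ref.z3, abs=1e-6)
        assert num.g_reduced == pytest.approx(ref.g_reduced, abs=1e-9)

    @pytest.mark.parametrize("h", [0.6, 0.85, 1.0, 1.2, 1.5, 1.7])
    def test_2d_minimum_matches_analytic_z3(self, h):
        sol = equilibrium_2d_numeric(h, tol=1e-6)
        assert sol.z3 == pytest.approx(equilibrium_2d_z3(h), abs=1e-8)
        assert sol.flags["matches_closed_form"]

    def test_2d_swap_symmetry_of_minimum(self):
        sol = equilibrium_2d_numeric(1.2)
        swapped = sol.fractions.swap_states()
        params = ThermoParams.from_h(1.2)
        g_orig = reduced_free_energy_2d(sol.fractions, params).g_reduced
        g_swap = reduced_free_energy_2d(swapped, params).g_reduced
        assert g_swap == pytest.approx(g_orig, abs=1e-13)


class TestAnalytic2D:
    def test_no_interaction_point(self):
        assert equilibrium_2d_z3(1.0) == pytest.approx(0.125, abs=1e-15)

    def test_branch_endpoints(self):
        lo, hi = BRANCH_2D
        assert equilibrium_2d_z3(hi) == pytest.approx(0.0, abs=1e-12)
        assert equilibrium_2d_z3(lo) == pytest.approx(0.5, abs=1e-12)

    def test_intermediate_value(self):
        assert equilibrium_2d_z3(1.2) == pytest.approx(0.0855, abs=5e-5)

    def test_out_of_branch_rejected(self):
        with pytest.raises(BranchError):
            equilibrium_2d_z3(2.0)

    def test_singularity_guard(self):
        pole = math.sqrt(3 - 2 * math.sqrt(2))
        with pytest.raises(SingularityError):
            equilibrium_2d_z3(pole + 1e-9)


class TestCurve:
    def test_1d_grid_contains_equilibrium_row(self):
        table = equilibrium_curve(0.5, 1.5, 3, dims=1)
        row = table[table.h == 1.0].iloc[0]
        assert row.z1 == row.z3 == 0.125

    def test_1d_monotonicity(self):
        table = equilibrium_curve(0.2, 3.0, 40, dims=1)
        assert (np.diff(table.z3) < 0).all()
        assert (np.diff(table.z1) > 0).all()

    def test_2d_matches_analytic_pointwise(self):
        table = equilibrium_curve(0.6, 1.7, 12, dims=2)
        assert (table["flags"] == "ok").all()
        for _, row in table.iterrows():
            assert row.z3 == pytest.approx(equilibrium_2d_z3(row.h), abs=1e-8)

    def test_2d_out_of_branch_rows_flagged_not_dropped(self):
        table = equilibrium_curve(0.3, 2.2, 8, dims=2)
        assert len(table) == 8
        assert (table["flags"] == "out_of_branch").any()
        assert table.loc[table["flags"] != "ok", "z3"].isna().all()

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_curve(2.0, 1.0, 5)
        with pytest.raises(ValueError):
            equilibrium_curve(0.5, 1.5, 1)
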