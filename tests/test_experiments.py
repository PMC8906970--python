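import numpy as np
import pytest

from wanscfd.exact import ExactSolutionParams
from wanscfd.experiments import (
    CONVERGENCE_REFERENCE_ROWS,
    compare_schemes,
    convergence_order,
    error_table,
    fixture_parameters,
    named_scheme,
    ranked_summary,
    stability_dichotomy_experiment,
    steady_spatial_order_study,
    sweep_profiles,
    truncate_two_decimals,
)
from wanscfd.solver import solve
from wanscfd.stencils import GridSpec


class TestConvergenceOrder:
    def test_formula_basics(self):
        assert convergence_order(4.0e-3, 1.0e-3) == pytest.approx(2.0)
        assert convergence_order(7e-4, 7e-4) == 0.0
        with pytest.raises(ValueError):
            convergence_order(0.0, 1e-3)

    def test_reference_rows_close_under_truncation(self):
        # the printed order column is the formula's value truncated, not
        # rounded, to two decimals — all five rows must close
        for _xi, eM, e2M, printed in CONVERGENCE_REFERENCE_ROWS:
            assert truncate_two_decimals(convergence_order(eM, e2M)) == pytest.approx(printed)

    def test_truncation_not_rounding(self):
        assert truncate_two_decimals(1.849) == 1.84
        assert truncate_two_decimals(-0.126) == -0.12


class TestFixtures:
    @pytest.mark.parametrize("name", ["table2", "table3", "table4", "table5", "table6",
                                      "fig2", "fig3", "fig5", "fig7"])
    def test_known_fixtures_complete(self, name):
        fx = fixture_parameters(name)
        assert fx["grid"].l == 5.0 and fx["grid"].N == 50
        assert 0.0 < fx["alpha"] <= 1.0
        assert fx["params"].Pr > 0

    def test_table2_caption_values(self):
        fx = fixture_parameters("table2")
        p = fx["params"]
        assert (p.phi, p.Pr, p.Gr, p.K_perm, p.M_mag, p.gamma) == (0.01, 25.0, 0.0, 1.0, 0.5, 1.0)
        assert fx["alpha"] == 0.8 and fx["omega"] == 0.0 and fx["t_eval"] == 0.9
        assert all(abs(round(x / 0.1) * 0.1 - x) < 1e-9 for x in fx["probes"])

    def test_unknown_fixture_rejected(self):
        with pytest.raises(KeyError):
            fixture_parameters("table9")


class TestErrorTable:
    def test_reference_against_itself_is_zero(self, neutral_params):
        fx = fixture_parameters("table2")
        grid = GridSpec(l=5.0, N=50, T=0.9, Z=9)
        history = solve(neutral_params, grid, named_scheme("WASCFD"), alpha=1.0)
        ref = ExactSolutionParams.from_physical(neutral_params)
        rep = error_table(history, ref, [2.0, 3.0], 0.9)
        rep_same = error_table(history, ref, [2.0, 3.0], 0.9)
        assert np.array_equal(rep.errors, rep_same.errors)
        assert rep.max_error == rep.errors.max() >= 0.0

    def test_probe_must_be_grid_node(self, neutral_params):
        grid = GridSpec(l=5.0, N=50, T=0.9, Z=9)
        history = solve(neutral_params, grid, named_scheme("WASCFD"), alpha=1.0)
        ref = ExactSolutionParams.from_physical(neutral_params)
        with pytest.raises(ValueError, match="grid node"):
            error_table(history, ref, [2.05], 0.9)
        with pytest.raises(ValueError, match="time level"):
            error_table(history, ref, [2.0], 0.85)

    def test_shared_dirichlet_probe_error_negligible(self, neutral_params):
        # on a domain long enough for the far field to have died out, the
        # numerical value at xi = l is exactly the Dirichlet zero and the
        # exact solution is vanishingly small, so the probe error is ~0
        grid = GridSpec(l=12.0, N=48, T=0.9, Z=9)
        history = solve(neutral_params, grid, named_scheme("WASCFD"), alpha=1.0)
        ref = ExactSolutionParams.from_physical(neutral_params)
        rep = error_table(history, ref, [12.0], 0.9)
        assert history.u[-1, -1] == 0.0
        assert rep.errors[0] < 1e-9


class TestCompareSchemes:
    def test_identical_scheme_twice_identical_reports(self):
        fx = fixture_parameters("table2")
        fx = {**fx, "grid": GridSpec(l=5.0, N=25, T=0.9, Z=18), "probes": [2.0, 2.8, 3.6]}
        scheme = named_scheme("WASCFD", omega=0.0)
        reports = compare_schemes(fx, {"a": scheme, "b": scheme})
        assert np.array_equal(reports["a"].errors, reports["b"].errors)
        summary = ranked_summary(reports)
        assert list(summary.columns) == ["scheme", "max_error"]
        assert summary["max_error"].is_monotonic_increasing


class TestSteadySpatialOrder:
    def test_compact_order_near_four(self):
        e1, e2, order = steady_spatial_order_study(stencil_order=4, N_coarse=10, Z=200)
        assert e1 > e2 > 0.0
        assert order > 3.5  # coarse quick check; the full study runs in acceptance


class TestStabilityDichotomy:
    def test_lattice_agreement_and_coverage(self):
        records = stability_dichotomy_experiment(seed=99, dts=(0.0005, 0.08), Z=100,
                                                 omegas=(0.0, 1.0))
        verdicts = {r["scan_stable"] for r in records}
        assert verdicts == {True, False}  # spans both regimes
        assert all(r["agree"] for r in records)


class TestSweeps:
    def test_velocity_decreases_with_casson_parameter(self):
        # larger gamma weakens the effective diffusivity (1 + 1/gamma), so
        # wall momentum penetrates less far
        fx = fixture_parameters("fig6")
        fx = {**fx, "grid": GridSpec(l=5.0, N=25, T=0.6, Z=30)}
        curves = sweep_profiles(fx, "gamma", [0.5, 1.0, 2.0],
                                scheme=named_scheme("WASCFD", 0.0))
        mid = 5
        values = [curves[v][1][mid] for v in (0.5, 1.0, 2.0)]
        assert values[0] > values[1] > values[2]

    def test_velocity_decreases_with_magnetic_parameter(self):
        # the Lorentz drag M*phi2 opposes the motion
        fx = fixture_parameters("fig5")
        fx = {**fx, "grid": GridSpec(l=5.0, N=25, T=0.6, Z=30)}
        curves = sweep_profiles(fx, "M_mag", [0.5, 4.0],
                                scheme=named_scheme("WASCFD", 0.0))
        near_wall = 2
        assert curves[0.5][1][near_wall] > curves[4.0][1][near_wall]

    def test_velocity_rises_with_volume_fraction_in_impulsive_regime(self):
        # in the boundary-driven Gr = 0 regime, raising phi raises the
        # effective momentum diffusivity A and spreads the wall momentum
        # farther, so u at fixed xi increases with phi
        fx = fixture_parameters("fig3")
        fx = {**fx, "grid": GridSpec(l=5.0, N=25, T=1.0, Z=30)}
        curves = sweep_profiles(fx, "phi", [0.0, 0.2, 0.4],
                                scheme=named_scheme("WASCFD", 0.0))
        mid = 7
        values = [curves[v][1][mid] for v in (0.0, 0.2, 0.4)]
        assert values[0] < values[1] < values[2]

    def test_profile_plot_written(self, tmp_path):
        fx = fixture_parameters("fig3")
        fx = {**fx, "grid": GridSpec(l=5.0, N=20, T=1.0, Z=15)}
        from wanscfd.experiments import profile_plots

        out = profile_plots(fx, "phi", [0.0, 0.2], tmp_path / "fig3.png")
        assert out.exists() and out.stat().st_size > 0
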