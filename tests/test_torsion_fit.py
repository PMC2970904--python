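"""Boltzmann-weighted least-squares torsion fitting."""

import numpy as np
import pytest

from ildnfit.scan_grid import make_chi1_chi2_grid, make_chi1_grid, ScanTable
from ildnfit.synthetic_data import BackgroundSpec, SyntheticScanSpec, synth_scan
from ildnfit.torsion_fit import (
    FitSpec,
    beta_to_temperature,
    boltzmann_weights,
    fit_torsion,
    select_dihedral_definition,
    subtract_torsion,
    temperature_to_beta,
)
from ildnfit.torsion_model import CosineSeries, TorsionDefinition, evaluate_torsion, ildn_parameters


class TestBoltzmannWeights:
    def test_beta_zero_gives_uniform_weights(self, rng):
        energies = rng.normal(size=17)
        np.testing.assert_allclose(boltzmann_weights(energies, 0.0), np.full(17, 1 / 17))

    def test_hand_computed_two_point_case(self):
        # exp(0) : exp(-ln 2) = 1 : 1/2 -> weights 2/3, 1/3
        weights = boltzmann_weights([0.0, np.log(2.0)], beta=1.0)
        np.testing.assert_allclose(weights, [2 / 3, 1 / 3], atol=1e-12)

    def test_equal_energies_give_uniform_weights(self):
        np.testing.assert_allclose(boltzmann_weights([5.0] * 4, 1.0), np.full(4, 0.25))

    def test_shift_invariance(self, rng):
        energies = rng.normal(size=9)
        np.testing.assert_allclose(
            boltzmann_weights(energies, 1.0), boltzmann_weights(energies + 300.0, 1.0)
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_weights([], 1.0)


class TestBetaTemperature:
    def test_unit_beta_is_about_500K(self):
        assert beta_to_temperature(1.0) == pytest.approx(500.0, abs=5.0)

    def test_room_temperature_is_about_1p7(self):
        assert temperature_to_beta(298.0) == pytest.approx(1.7, abs=0.02)

    def test_inverse_pair(self):
        assert beta_to_temperature(temperature_to_beta(341.0)) == pytest.approx(341.0)


def _exact_scan(generators, grid, background=None, offset=0.0, seed=0, sigma=0.0):
    spec = SyntheticScanSpec(
        generators=generators,
        background=background if background is not None else BackgroundSpec(),
        noise_sigma=sigma,
        offset=offset,
        seed=seed,
    )
    return synth_scan(grid, spec)


class TestFitTorsion:
    def test_zero_noise_recovery_of_published_series(self, ildn_entry):
        residue, angle, series, _ = ildn_entry
        if angle == "chi1" and residue in ("ILE", "LEU"):
            grid = make_chi1_grid(step=15.0)
        else:
            grid = make_chi1_chi2_grid(step=30.0)
        scan = _exact_scan({angle: series}, grid)
        mults = {angle: series.multiplicities}
        result = fit_torsion(scan, FitSpec(mults, beta=1.0))
        np.testing.assert_allclose(
            result.series[angle].force_constants, series.force_constants, atol=1e-8
        )

    def test_null_signal_gives_all_zeros(self):
        grid = make_chi1_grid(step=15.0)
        scan = grid.with_energies(
            E_qm=BackgroundSpec()(grid.points["chi1"]),
            E_mm_base=BackgroundSpec()(grid.points["chi1"]),
        )
        result = fit_torsion(scan, FitSpec({"chi1": [1, 2, 3]}))
        np.testing.assert_allclose(result.chi1.force_constants, 0.0, atol=1e-10)
        assert result.k0 == pytest.approx(0.0, abs=1e-10)
        assert result.weighted_residual == pytest.approx(0.0, abs=1e-20)

    def test_uniform_energy_shift_absorbed_by_offset(self):
        series, _ = ildn_parameters("ILE", "chi1")
        grid = make_chi1_grid(step=15.0)
        base = _exact_scan({"chi1": series}, grid)
        shifted_df = base.points.copy()
        shifted_df["E_qm"] += 10.0
        shifted = ScanTable(shifted_df)
        spec = FitSpec({"chi1": (1, 2)})
        r0 = fit_torsion(base, spec)
        r1 = fit_torsion(shifted, spec)
        np.testing.assert_allclose(r1.chi1.force_constants, r0.chi1.force_constants, atol=1e-8)
        assert r1.k0 - r0.k0 == pytest.approx(10.0, abs=1e-8)

    def test_beta_zero_matches_normal_equations_oracle(self, rng):
        # independent oracle: unweighted normal equations on a 10-point scan
        chi1 = np.linspace(-180.0, 170.0, 10)
        import pandas as pd

        df = pd.DataFrame({"chi1": chi1, "phi": -135.0, "psi": 135.0})
        E_qm = rng.normal(size=10)
        scan = ScanTable(df).with_energies(E_qm=E_qm, E_mm_base=np.zeros(10))
        mults = (1, 2, 3)
        result = fit_torsion(scan, FitSpec({"chi1": mults}, beta=0.0))

        X = np.column_stack(
            [1.0 + np.cos(m * np.deg2rad(chi1)) for m in mults] + [np.ones(10)]
        )
        oracle = np.linalg.solve(X.T @ X, X.T @ E_qm)
        np.testing.assert_allclose(result.chi1.force_constants, oracle[:3], atol=1e-9)
        assert result.k0 == pytest.approx(oracle[3], abs=1e-9)

    def test_solution_is_locally_optimal(self, rng):
        series, _ = ildn_parameters("LEU", "chi1")
        grid = make_chi1_grid(step=15.0)
        scan = _exact_scan({"chi1": series}, grid, sigma=0.3, seed=11)
        spec = FitSpec({"chi1": (1, 2, 3)})
        result = fit_torsion(scan, spec)

        from ildnfit.torsion_fit import boltzmann_weights as bw

        weights = bw(scan.points["E_qm"].to_numpy(), spec.beta)
        target = (scan.points["E_qm"] - scan.points["E_mm_base"]).to_numpy()
        theta = np.deg2rad(scan.points["chi1"].to_numpy())

        def objective(ks, k0):
            model = sum(k * (1 + np.cos(m * theta)) for m, k in zip((1, 2, 3), ks)) + k0
            return np.sum(weights * (model - target) ** 2)

        best = objective(result.chi1.force_constants, result.k0)
        for _ in range(25):
            perturbed = np.array(result.chi1.force_constants) + rng.normal(0, 0.01, 3)
            assert objective(perturbed, result.k0 + rng.normal(0, 0.01)) >= best

    def test_symmetric_chi2_data_zeroes_odd_multiplicities(self):
        # Asp-like: generator and background both even under chi2 -> chi2+180
        chi2_series = CosineSeries([(2, -0.443), (4, -0.138), (6, -0.013)])
        chi1_series, _ = ildn_parameters("ASP", "chi1")
        grid = make_chi1_chi2_grid(step=30.0)  # full grid so odd terms are determinable
        scan = _exact_scan(
            {"chi1": chi1_series, "chi2": chi2_series},
            grid,
            background=BackgroundSpec.chi2_symmetric(),
        )
        result = fit_torsion(
            scan, FitSpec({"chi1": range(1, 7), "chi2": range(1, 7)}, beta=1.0)
        )
        fitted = dict(result.series["chi2"].terms)
        for m in (1, 3, 5):
            assert abs(fitted[m]) < 1e-8
        for m, expected in ((2, -0.443), (4, -0.138), (6, -0.013)):
            assert fitted[m] == pytest.approx(expected, abs=1e-8)

    def test_recovery_error_shrinks_with_noise(self):
        series, _ = ildn_parameters("ASN", "chi1")
        grid = make_chi1_grid(step=15.0)
        errors = []
        for sigma in (0.4, 0.1, 0.01):
            scan = _exact_scan({"chi1": series}, grid, sigma=sigma, seed=5)
            result = fit_torsion(scan, FitSpec({"chi1": series.multiplicities}))
            errors.append(
                np.max(np.abs(np.subtract(result.chi1.force_constants, series.force_constants)))
            )
        assert errors[0] > errors[1] > errors[2]

    def test_result_invariant_to_row_order(self, rng):
        series, _ = ildn_parameters("ILE", "chi1")
        grid = make_chi1_grid(step=15.0)
        scan = _exact_scan({"chi1": series}, grid, sigma=0.2, seed=3)
        shuffled = ScanTable(
            scan.points.sample(frac=1.0, random_state=4).reset_index(drop=True)
        )
        spec = FitSpec({"chi1": (1, 2)})
        r0, r1 = fit_torsion(scan, spec), fit_torsion(shuffled, spec)
        np.testing.assert_allclose(r1.chi1.force_constants, r0.chi1.force_constants, atol=1e-10)

    def test_rank_deficiency_names_degenerate_columns(self):
        import pandas as pd

        # 3 distinct points cannot determine 3 constants + offset
        df = pd.DataFrame({"chi1": [0.0, 60.0, 120.0], "phi": -135.0, "psi": 135.0})
        scan = ScanTable(df).with_energies(E_qm=[0.0, 1.0, 2.0], E_mm_base=[0.0, 0.0, 0.0])
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            fit_torsion(scan, FitSpec({"chi1": (1, 2, 3)}))

    def test_subtract_torsion_restores_base_convention(self):
        old = CosineSeries([(3, 1.4)])
        new, _ = ildn_parameters("LEU", "chi1")
        grid = make_chi1_grid(step=15.0)
        scan = _exact_scan({"chi1": new}, grid)
        # contaminate the base energy with an old torsion, then subtract it
        df = scan.points.copy()
        df["E_mm_base"] += evaluate_torsion(old, df["chi1"].to_numpy())
        df["E_qm"] += evaluate_torsion(old, df["chi1"].to_numpy())
        cleaned = subtract_torsion(ScanTable(df), {"chi1": old})
        np.testing.assert_allclose(
            cleaned.points["E_mm_base"], scan.points["E_mm_base"], atol=1e-12
        )


class TestDefinitionSelection:
    def _candidates(self, offset=120.0):
        """Two chi1 relabelings offset by the local geometry; data generated
        on the first."""
        series, _ = ildn_parameters("ILE", "chi1")
        grid_n = make_chi1_grid(step=15.0)
        scan_n = _exact_scan({"chi1": series}, grid_n)
        df_c = scan_n.points.copy()
        df_c["chi1"] = (df_c["chi1"] + offset + 180.0) % 360.0 - 180.0
        scan_c = ScanTable(df_c)
        d_n = TorsionDefinition("ILE", "chi1", ("N", "CA", "CB", "CG2"))
        d_c = TorsionDefinition("ILE", "chi1", ("C", "CA", "CB", "CG2"))
        return [(d_n, scan_n), (d_c, scan_c)]

    def test_generating_definition_selected(self):
        candidates = self._candidates()
        result = select_dihedral_definition(candidates, FitSpec({"chi1": (1, 2)}))
        assert result.definition.atoms[0] == "N"
        assert result.weighted_residual == pytest.approx(0.0, abs=1e-16)

    def test_tie_broken_by_first_listed(self):
        candidates = self._candidates()
        duplicated = [candidates[0], (TorsionDefinition("ILE", "chi1",
                     ("C", "CA", "CB", "CG2")), candidates[0][1])]
        result = select_dihedral_definition(duplicated, FitSpec({"chi1": (1, 2)}))
        assert result.definition.atoms[0] == "N"

    def test_single_candidate_returned(self):
        candidates = self._candidates()[:1]
        result = select_dihedral_definition(candidates, FitSpec({"chi1": (1, 2)}))
        assert result.definition is candidates[0][0]

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_dihedral_definition([], FitSpec({"chi1": (1, 2)}))
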