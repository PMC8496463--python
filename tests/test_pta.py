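"""Partial triadic analysis: stack construction, the three PTA steps, and
equivalence with a literal brute-force implementation."""
import numpy as np
import pandas as pd
import pytest

import specphyto as sp
from specphyto.pta import KTableStack, compromise, interstructure, pta

from .conftest import make_detrended_long
from .oracle_pta import pta_brute


def stack_from_arrays(tables, wavelengths=None):
    tables = np.asarray(tables, dtype=float)
    k, n, p = tables.shape
    return KTableStack(
        wavelengths=list(wavelengths or range(k)),
        stations=[f"S{i}" for i in range(n)],
        parameters=[f"p{j}" for j in range(p)],
        values=tables,
        scaling=pd.DataFrame({"mean": np.zeros(p), "scale": np.ones(p)},
                             index=[f"p{j}" for j in range(p)]))


class TestBuildStack:
    def test_incomplete_station_dropped(self):
        rng = np.random.default_rng(0)
        long = make_detrended_long(rng, stations=5, wavelengths=(440, 590))
        long = long[~((long.station == "S2") & (long.wavelength == 590))]
        stack = sp.build_stack(long, parameters=("p1", "p2"))
        assert "S2" not in stack.stations
        assert stack.dropped_stations == ["S2"]
        assert stack.values.shape == (2, 4, 2)

    def test_global_standardisation_and_round_trip(self):
        rng = np.random.default_rng(1)
        long = make_detrended_long(rng, stations=6, wavelengths=(440, 480, 540))
        stack = sp.build_stack(long, parameters=("p1", "p2"))
        stacked = stack.values.reshape(-1, 2)
        assert np.allclose(stacked.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(stacked.std(axis=0), 1.0, atol=1e-12)
        # Unscale restores the raw values.
        raw = stack.unscale()
        wide = long.pivot_table(index="station",
                                columns=["wavelength", "parameter"],
                                values="detrended")
        for i, wl in enumerate(stack.wavelengths):
            expected = wide[wl][["p1", "p2"]].loc[stack.stations].to_numpy()
            assert np.allclose(raw[i], expected, atol=1e-12)

    def test_already_standardised_input(self):
        rng = np.random.default_rng(2)
        long = make_detrended_long(rng, stations=50, wavelengths=(440, 480))
        pre = sp.build_stack(long, parameters=("p1", "p2"))
        # Feed the standardised values back in: scaling must be ~(0, 1).
        rows = []
        for i, wl in enumerate(pre.wavelengths):
            for r, st in enumerate(pre.stations):
                for j, par in enumerate(pre.parameters):
                    rows.append((st, wl, par, pre.values[i, r, j]))
        long2 = pd.DataFrame(rows, columns=["station", "wavelength",
                                            "parameter", "detrended"])
        stack2 = sp.build_stack(long2, parameters=("p1", "p2"))
        assert np.allclose(stack2.scaling["mean"], 0.0, atol=1e-12)
        assert np.allclose(stack2.scaling["scale"], 1.0, atol=1e-12)

    def test_zero_variance_column_rejected(self):
        rng = np.random.default_rng(3)
        long = make_detrended_long(rng, stations=4, wavelengths=(440, 480))
        long.loc[long.parameter == "p2", "detrended"] = 1.0
        with pytest.raises(sp.ValidationError, match="p2"):
            sp.build_stack(long, parameters=("p1", "p2"))

    def test_range_scaling_option(self):
        rng = np.random.default_rng(4)
        long = make_detrended_long(rng, stations=5, wavelengths=(440, 480))
        stack = sp.build_stack(long, parameters=("p1", "p2"), scale="range")
        stacked = stack.values.reshape(-1, 2)
        assert np.allclose(stacked.max(axis=0) - stacked.min(axis=0), 1.0)


class TestInterstructure:
    def test_identical_tables_limit(self):
        x = np.random.default_rng(5).normal(size=(6, 3))
        stack = stack_from_arrays([x] * 5)
        rv, eig, pct, weights, cos2 = interstructure(stack)
        assert np.allclose(rv, 1.0)
        assert np.allclose(weights, 1 / np.sqrt(5))
        assert weights[0] == pytest.approx(0.4472, abs=5e-5)
        assert np.allclose(cos2, 1.0)

    def test_rv_self_is_one_and_psd(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            stack = stack_from_arrays(rng.normal(size=(3, 4, 3)))
            rv, *_ = interstructure(stack)
            assert np.allclose(np.diag(rv), 1.0)
            assert np.linalg.eigvalsh(rv).min() > -1e-10
            assert np.all((rv > 0) & (rv <= 1 + 1e-12))

    def test_pct_inertia_sums_to_100(self):
        rng = np.random.default_rng(7)
        stack = stack_from_arrays(rng.normal(size=(4, 5, 3)))
        _, _, pct, _, _ = interstructure(stack)
        assert pct.sum() == pytest.approx(100.0, abs=1e-9)


class TestCompromise:
    def test_identical_tables_match_single_table_pca_profile(self):
        x = np.random.default_rng(8).normal(size=(6, 3))
        stack = stack_from_arrays([x] * 3)
        _, eig, pct, *_ = compromise(stack, np.ones(3))
        single = np.sort(np.linalg.eigvalsh(x.T @ x))[::-1]
        assert np.allclose(eig, single, atol=1e-9)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(9)
        stack = stack_from_arrays(rng.normal(size=(3, 5, 4)))
        w = np.abs(rng.normal(size=3)) + 0.1
        _, _, pct1, *_ = compromise(stack, w)
        _, _, pct2, *_ = compromise(stack, 13.7 * w)
        assert np.allclose(pct1, pct2, atol=1e-12)

    def test_rank_one_tables_give_single_axis(self):
        u = np.array([1.0, -2.0, 0.5])[:, None]
        v = np.array([0.3, 1.2])[None, :]
        stack = stack_from_arrays([u @ v, 2.0 * u @ v])
        _, eig, pct, *_ = compromise(stack, np.ones(2))
        assert pct[0] == pytest.approx(100.0, abs=1e-9)


class TestIntrastructureAndFull:
    def test_identical_tables_zero_polygon_areas(self):
        x = np.random.default_rng(10).normal(size=(5, 3))
        result = pta(stack_from_arrays([x] * 5, wavelengths=[440, 480, 540, 590, 625]))
        areas = result.polygon_areas()
        assert np.allclose(areas, 0.0, atol=1e-12)
        first = result.table_row_coords[440]
        for wl in (480, 540, 590, 625):
            assert np.allclose(result.table_row_coords[wl], first, atol=1e-12)

    def test_perturbing_one_table_moves_only_it(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(5, 3))
        base = [x.copy() for _ in range(3)]
        pert = [x.copy() for _ in range(3)]
        pert[1][0, 0] += 0.5
        res_a = pta(stack_from_arrays(base))
        res_b = pta(stack_from_arrays(pert))
        # Projections are X_k V; with V from each run, table 0 and 2 share X.
        assert not np.allclose(res_a.table_row_coords[1],
                               res_b.table_row_coords[1], atol=1e-6)
        assert np.allclose(
            res_b.table_row_coords[0], res_b.table_row_coords[2], atol=1e-12)

    def test_weighted_average_of_projections_is_compromise(self):
        rng = np.random.default_rng(12)
        stack = stack_from_arrays(rng.normal(size=(4, 6, 3)))
        res = pta(stack)
        alphas = res.weights / res.weights.sum()
        avg_rows = sum(a * res.table_row_coords[wl].to_numpy()
                       for a, wl in zip(alphas, stack.wavelengths))
        assert np.allclose(avg_rows, res.row_coords.to_numpy(), atol=1e-9)
        avg_vars = sum(a * res.table_variable_coords[wl].to_numpy()
                       for a, wl in zip(alphas, stack.wavelengths))
        assert np.allclose(avg_vars, res.variable_coords.to_numpy(), atol=1e-9)


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_k2_tiny_stacks_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tables = rng.normal(size=(2, 3, 2))
        res = pta(stack_from_arrays(tables))
        ref = pta_brute(list(tables))
        assert np.allclose(res.rv, ref["rv"], atol=1e-9)
        assert np.allclose(res.inter_eigenvalues, ref["inter_eigenvalues"],
                           atol=1e-9)
        assert np.allclose(res.weights, ref["weights"], atol=1e-9)
        assert np.allclose(res.cos2, ref["cos2"], atol=1e-9)
        assert np.allclose(res.compromise.to_numpy(), ref["compromise"],
                           atol=1e-9)
        assert np.allclose(res.comp_eigenvalues, ref["comp_eigenvalues"],
                           atol=1e-9)
        assert np.allclose(res.comp_pct_inertia, ref["comp_pct"], atol=1e-9)
        assert np.allclose(res.variable_coords.to_numpy(),
                           ref["variable_coords"], atol=1e-9)
        assert np.allclose(res.row_coords.to_numpy(), ref["row_coords"],
                           atol=1e-9)
        for i, wl in enumerate(range(2)):
            assert np.allclose(res.table_row_coords[wl].to_numpy(),
                               ref["table_rows"][i], atol=1e-9)
            assert np.allclose(res.table_variable_coords[wl].to_numpy(),
                               ref["table_vars"][i], atol=1e-9)
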