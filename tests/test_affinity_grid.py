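"""Affinity ladder construction and mutation-kernel probabilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from abdyn import (
    ConfigurationError,
    bin_mass,
    build_grid,
    build_kernel,
    initial_composition,
    mutation_split,
)


class TestBuildGrid:
    def test_default_ladder(self, grid):
        assert grid.n == 9
        np.testing.assert_allclose(
            grid.log10_kd, [-5, -6, -7, -8, -9, -10, -11, -12, -13]
        )
        # central class sits at the distribution mean with k2 = 1e-9
        assert grid[5].log10_kd == pytest.approx(-9.0)
        assert grid[5].k2 == pytest.approx(1e-9)
        # ascending binding strength = ascending k2
        assert np.all(np.diff(grid.k2) > 0)

    def test_log10_kd_consistent_with_rates(self, grid):
        for c in grid.classes:
            assert c.log10_kd == pytest.approx(
                np.log10(c.k_minus2 / c.k2), abs=1e-12
            )

    def test_degenerate_single_class(self):
        g = build_grid(n=1, k2_weakest=1e-9, k2_strongest=1e-9)
        assert g.n == 1
        assert g[1].log10_kd == pytest.approx(-9.0)

    def test_non_decade_spacing_rejected(self):
        with pytest.raises(ConfigurationError):
            build_grid(n=9, k2_weakest=1e-13, k2_strongest=2e-5)

    def test_bad_n_rejected(self):
        with pytest.raises(ValueError):
            build_grid(n=0)


class TestBinMass:
    @pytest.mark.parametrize(
        "i, expected",
        [
            (5, 0.3829),   # central bin
            (4, 0.2417),   # one step off center
            (6, 0.2417),
            (3, 0.0606),   # two steps: Phi(2.5) - Phi(1.5)
            (1, 0.0002),   # four steps
        ],
    )
    def test_printed_masses(self, grid, i, expected):
        assert bin_mass(grid, i) == pytest.approx(expected, abs=5e-5)

    def test_matches_quadrature(self, grid):
        # CDF differences vs numerical integration of the density
        for i in range(1, 10):
            lo = grid[i].log10_kd - 0.5
            exact, _ = quad(norm(loc=grid.mu, scale=grid.sigma).pdf, lo, lo + 1)
            assert bin_mass(grid, i) == pytest.approx(exact, abs=1e-9)

    def test_index_out_of_range(self, grid):
        with pytest.raises(IndexError):
            bin_mass(grid, 0)
        with pytest.raises(IndexError):
            bin_mass(grid, 10)


class TestMutationSplit:
    def test_worked_example_class6(self, grid):
        pw, ps, pst = mutation_split(grid, 6)
        assert pw == pytest.approx(0.6915, abs=1e-4)
        assert ps == pytest.approx(0.2417, abs=1e-4)
        assert pst == pytest.approx(0.0668, abs=1e-4)

    def test_central_class_symmetric(self, grid):
        pw, ps, pst = mutation_split(grid, 5)
        assert pw == pytest.approx(norm.cdf(-0.5))
        assert ps == pytest.approx(norm.cdf(0.5) - norm.cdf(-0.5))
        assert pw == pytest.approx(pst)

    def test_weak_edge_absorbs_tail(self, grid):
        pw, ps, pst = mutation_split(grid, 1)
        assert pw == 0.0
        # stay = on-grid bin mass plus the off-grid tail
        assert ps == pytest.approx(0.00023, abs=2e-5)
        assert pst == pytest.approx(0.99977, abs=2e-5)

    def test_strong_edge_mirrors_weak_edge(self, grid):
        assert mutation_split(grid, 9)[::-1] == pytest.approx(
            mutation_split(grid, 1)
        )


class TestKernel:
    def test_worked_row(self, grid, kernel):
        assert kernel.row(6) == pytest.approx((0.6915, 0.2417, 0.0668),
                                              abs=1e-4)

    def test_rows_sum_to_one(self, kernel):
        np.testing.assert_allclose(
            kernel.p_weaker + kernel.p_stay + kernel.p_stronger, 1.0,
            atol=1e-12,
        )

    def test_mirror_symmetry_about_center(self, kernel):
        # row 4 is row 6 with weaker/stronger swapped, etc.
        for i in range(1, 10):
            pw, ps, pst = kernel.row(i)
            mw, ms, mst = kernel.row(10 - i)
            assert (pw, ps, pst) == pytest.approx((mst, ms, mw), abs=1e-12)

    def test_mutations_drift_toward_moderate_affinity(self, kernel):
        # weak side of the mean: stronger-binding moves dominate; vice versa
        for i in range(1, 5):
            pw, _, pst = kernel.row(i)
            assert pst > pw
        for i in range(6, 10):
            pw, _, pst = kernel.row(i)
            assert pw > pst

    @given(
        n=st.integers(min_value=1, max_value=15),
        mu=st.floats(min_value=-12, max_value=-6),
        sigma=st.floats(min_value=0.3, max_value=3),
    )
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_rows_sum_to_one_any_grid(self, n, mu, sigma):
        k_minus2 = 1e-18
        k2_weak = 1e-13
        g = build_grid(n=n, k2_weakest=k2_weak,
                       k2_strongest=k2_weak * 10.0 ** (n - 1),
                       k_minus2=k_minus2, mu=mu, sigma=sigma)
        k = build_kernel(g)
        np.testing.assert_allclose(
            k.p_weaker + k.p_stay + k.p_stronger, 1.0, atol=1e-12
        )
        assert k.p_weaker[0] == 0.0
        assert k.p_stronger[-1] == 0.0

    def test_csv_dump_schema(self, grid, kernel):
        text = kernel.to_csv(grid)
        header = text.splitlines()[0].split(",")
        assert header == ["class_index", "log10_kd", "k2", "k_minus2",
                          "p_weaker", "p_stay", "p_stronger"]
        assert len(text.splitlines()) == 10


class TestInitialComposition:
    def test_printed_fractions(self, grid):
        y = initial_composition(grid, 1e6)
        assert y[4] == pytest.approx(0.3829e6, abs=50)
        assert y[2] == pytest.approx(0.0606e6, abs=50)
        assert y[0] == pytest.approx(0.0002e6, abs=50)

    def test_zero_total(self, grid):
        assert np.all(initial_composition(grid, 0.0) == 0.0)

    def test_fractions_sum_below_one(self, grid):
        frac = initial_composition(grid, 1.0).sum()
        # tails beyond +-4.5 sigma are excluded
        assert frac == pytest.approx(2 * norm.cdf(4.5) - 1, abs=1e-12)
        assert frac < 1.0

    def test_negative_total_rejected(self, grid):
        with pytest.raises(ValueError):
            initial_composition(grid, -1.0)
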