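"""Informativeness curves: closed forms, normalisation, profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

import phyloinform as pf
from phyloinform.informativeness import default_grid


class TestRho:
    def test_zero_rate_carries_no_signal(self):
        for v in ("original", "modified"):
            assert pf.rho(0.0, 10.0, v) == 0.0

    def test_original_formula_value(self):
        assert pf.rho(0.05, 5.0, "original") == pytest.approx(
            16 * 0.05**2 * 5 * np.exp(-1), rel=1e-12
        )
        assert pf.rho(0.05, 5.0, "original") == pytest.approx(0.073576, abs=1e-6)

    @pytest.mark.parametrize("lam", [0.003, 0.02, 0.4])
    def test_modified_peak_height_is_rate_free(self, lam):
        t_star = pf.peak_time(lam)
        assert pf.rho(lam, t_star, "modified") == pytest.approx(
            np.exp(-1) / 4, rel=1e-12
        )
        assert pf.rho(lam, t_star, "modified") == pytest.approx(
            0.091970, abs=1e-6
        )

    def test_original_peak_height_grows_with_rate(self):
        lams = [0.001, 0.01, 0.1]
        heights = [pf.rho(l, pf.peak_time(l), "original") for l in lams]
        assert heights[0] < heights[1] < heights[2]
        for lam, h in zip(lams, heights):
            assert h == pytest.approx(4 * lam / np.e, rel=1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            pf.rho(0.01, 0.0)

    @pytest.mark.parametrize("lam", [0.001, 0.01, 0.1])
    def test_original_variant_has_unit_integral(self, lam):
        total, err = quad(lambda t: pf.rho(lam, t, "original"), 0, np.inf)
        assert abs(total - 1.0) < 1e-6


class TestPeakAndCrossing:
    def test_peak_examples(self):
        assert pf.peak_time(0.025) == pytest.approx(10.0)
        assert pf.peak_time(0.005) == pytest.approx(50.0)

    def test_peak_matches_grid_argmax(self):
        lam = 0.0123
        grid = np.linspace(1e-3, 100, 20001)
        step = grid[1] - grid[0]
        numeric = grid[np.argmax(pf.rho(lam, grid, "modified"))]
        assert abs(numeric - pf.peak_time(lam)) <= step

    def test_peak_undefined_at_zero(self):
        with pytest.raises(ValueError):
            pf.peak_time(0.0)

    def test_crossing_closed_form_vs_rootfinder(self):
        ls, lf = 0.01, 0.04
        tx = pf.crossing_time(ls, lf)
        assert tx == pytest.approx(np.log(4) / 0.12, rel=1e-12)
        root = brentq(
            lambda t: pf.rho(ls, t, "modified") - pf.rho(lf, t, "modified"),
            1.0,
            100.0,
        )
        assert tx == pytest.approx(root, rel=1e-9)

    def test_slow_exceeds_fast_beyond_crossing(self):
        ls, lf = 0.01, 0.04
        tx = pf.crossing_time(ls, lf)
        assert pf.rho(ls, 2 * tx, "modified") > pf.rho(lf, 2 * tx, "modified")
        assert pf.rho(ls, 0.5 * tx, "modified") < pf.rho(lf, 0.5 * tx, "modified")

    def test_crossing_continuity_limit(self):
        ls = 0.02
        lf = ls * 1.001
        assert pf.crossing_time(ls, lf) == pytest.approx(
            pf.peak_time(ls), rel=2e-3
        )

    def test_modified_curves_cross_exactly_once(self):
        ls, lf = 0.004, 0.09
        t = np.linspace(1e-4, 500, 200000)
        diff = pf.rho(ls, t, "modified") - pf.rho(lf, t, "modified")
        signs = np.sign(diff[np.abs(diff) > 1e-300])
        flips = int((np.diff(signs) != 0).sum())
        assert flips == 1

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            pf.crossing_time(0.04, 0.01)


def _table(lams, partitions):
    n = len(lams)
    return pf.SiteRateTable(
        pd.DataFrame(
            {
                "site": np.arange(1, n + 1),
                "partition": partitions,
                "lambda": lams,
                "loglik": 0.0,
                "boundary": False,
            }
        )
    )


class TestProfile:
    def test_additivity_identical_sites(self):
        lam = 0.01
        table = _table([lam] * 10, ["p"] * 10)
        scheme = pf.PartitionScheme({"p": np.arange(1, 11)}, width=10)
        pi = pf.profile(table, scheme, t_max=100.0, grid_points=64)
        single = pf.rho(lam, pi.grid, "modified")
        np.testing.assert_allclose(pi.values("p", "modified"), 10 * single)

    def test_concatenation_is_sum_of_partitions(self):
        rng = np.random.default_rng(0)
        lams = rng.uniform(0, 0.05, 30)
        table = _table(lams, ["a"] * 10 + ["b"] * 20)
        split = pf.PartitionScheme(
            {"a": np.arange(1, 11), "b": np.arange(11, 31)}, width=30
        )
        whole = pf.PartitionScheme({"all": np.arange(1, 31)}, width=30)
        pi_split = pf.profile(table, split, t_max=80.0, grid_points=32)
        pi_whole = pf.profile(table, whole, t_max=80.0, grid_points=32)
        np.testing.assert_allclose(
            pi_whole.values("all", "modified"),
            pi_split.values("a", "modified") + pi_split.values("b", "modified"),
            atol=1e-12,
        )

    def test_average_modified_is_per_base(self):
        """Same per-site rate spectrum, lengths 100 vs 500: identical
        average-modified curves, modified curves differing 5-fold."""
        rng = np.random.default_rng(1)
        base = rng.gamma(2.0, 0.005, 100)
        lams = np.concatenate([base, np.tile(base, 5)])
        table = _table(lams, ["short"] * 100 + ["long"] * 500)
        scheme = pf.PartitionScheme(
            {"short": np.arange(1, 101), "long": np.arange(101, 601)},
            width=600,
        )
        pi = pf.profile(table, scheme, t_max=60.0, grid_points=16)
        np.testing.assert_allclose(
            pi.values("short", "average_modified"),
            pi.values("long", "average_modified"),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            pi.values("long", "modified"),
            5 * pi.values("short", "modified"),
            atol=1e-12,
        )

    def test_missing_rate_raises_listing_sites(self):
        table = _table([0.01] * 5, ["p"] * 5)
        scheme = pf.PartitionScheme({"p": np.arange(1, 11)}, width=10)
        with pytest.raises(KeyError, match="no rate for sites"):
            pf.profile(table, scheme, t_max=50.0)

    def test_default_grid_spans_0_T(self):
        g = default_grid(110.0, 512)
        assert len(g) == 512 and g[0] > 0 and g[-1] == pytest.approx(110.0)

    def test_fixture_nuclear_thirds_beat_mito_thirds_beyond_25ma(
        self, bench_bundle, bench_rates
    ):
        """Per aligned base, nuclear third positions out-inform the
        saturating mitochondrial third positions at deep timescales."""
        b = bench_bundle
        pi = pf.profile(
            bench_rates, b.scheme, t_max=110.0, grid_points=110,
            variants=("average_modified",),
        )
        mask = pi.grid > 25.0
        nuc3 = ["CAD_pos3", "Wnt_pos3", "H3_pos3"]
        mito3 = ["COI_3p_pos3", "COI_5p_pos3", "COII_pos3"]
        for n in nuc3:
            vn = pi.values(n, "average_modified")[mask]
            for m in mito3:
                vm = pi.values(m, "average_modified")[mask]
                assert np.all(vn > vm)
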