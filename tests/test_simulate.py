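"""Synthetic-data generator: trees, alignments, missingness, fixture."""

import numpy as np
import pytest
from scipy.linalg import expm

import phyloinform as pf
from phyloinform.simulate import FRAGMENTS, RATE_CLASSES
from phyloinform.substmodel import (
    build_hky_rate_matrix,
    hky_spectral,
    stationary_mismatch,
    transition_matrices,
)

from conftest import SUITE_SEED


class TestSubstModel:
    def test_spectral_matches_matrix_exponential(self):
        kappa, freqs = 4.0, (0.3, 0.2, 0.2, 0.3)
        Q = build_hky_rate_matrix(kappa, freqs)
        spec = hky_spectral(kappa, freqs)
        for d in (0.01, 0.3, 2.5):
            np.testing.assert_allclose(
                transition_matrices(np.array([d]), spec)[0],
                expm(Q * d),
                atol=1e-10,
            )

    def test_unit_mean_rate(self):
        Q = build_hky_rate_matrix(2.0, (0.1, 0.2, 0.3, 0.4))
        freqs = np.array([0.1, 0.2, 0.3, 0.4])
        assert -np.dot(freqs, np.diag(Q)) == pytest.approx(1.0)

    def test_jc_ceiling(self):
        assert stationary_mismatch((0.25,) * 4) == pytest.approx(0.75)


class TestSimulateTree:
    def test_two_tips_single_cherry(self):
        t = pf.simulate_tree(2, 100.0, seed=3)
        assert t.n_tips == 2
        a, b = t.tip_labels
        assert t.patristic_distance(a, b) == pytest.approx(200.0)
        assert t.root_age == pytest.approx(100.0)

    def test_forty_tips_ultrametric(self):
        t = pf.simulate_tree(40, 110.0, seed=1)
        assert t.n_tips == 40
        assert t.is_ultrametric(1e-9)
        assert t.root_age == pytest.approx(110.0)

    def test_same_seed_identical_newick(self):
        a = pf.simulate_tree(25, 80.0, seed=9)
        b = pf.simulate_tree(25, 80.0, seed=9)
        assert a.to_newick() == b.to_newick()

    def test_no_zero_length_terminal_branches(self):
        t = pf.simulate_tree(30, 100.0, seed=4)
        assert all(t.blen[i] > 0 for i in t.tip_ids)


class TestSimulateAlignment:
    def test_zero_rate_gives_constant_columns(self):
        tree = pf.simulate_tree(12, 60.0, seed=2)
        bundle = pf.simulate_alignment(
            tree, [pf.SimPartitionSpec("z", 50, 0.0)], seed=5
        )
        chars = bundle.matrix.chars
        assert all(len(set(chars[:, j])) == 1 for j in range(50))

    def test_jc_two_taxon_mismatch_fraction(self):
        """Observed mismatches within 3 binomial SEs of
        (3/4)(1 - exp(-4d/3)) at the simulated distance."""
        tree = pf.simulate_tree(2, 50.0, seed=6)
        lam = 0.004  # d = 2 * 50 * lam = 0.4 between the two tips
        n = 2000
        bundle = pf.simulate_alignment(
            tree, [pf.SimPartitionSpec("jc", n, lam)], seed=8
        )
        a, b = bundle.matrix.chars
        observed = np.mean(a != b)
        d = 2 * 50.0 * lam
        expected = 0.75 * (1 - np.exp(-4 * d / 3))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) <= 3 * se

    def test_hky_transition_bias(self):
        """kappa = 4 must produce more transitions than transversions on
        a shallow tree (per-pair counts, A<->G and C<->T vs the rest)."""
        tree = pf.simulate_tree(2, 20.0, seed=10)
        spec = pf.SimPartitionSpec(
            "hky", 4000, 0.002, model="HKY", kappa=4.0
        )
        bundle = pf.simulate_alignment(tree, [spec], seed=12)
        a, b = bundle.matrix.codes()
        diff = a != b
        purines = {0, 2}
        transitions = sum(
            1
            for x, y in zip(a[diff], b[diff])
            if ({x, y} <= purines) or ({x, y} <= {1, 3})
        )
        transversions = int(diff.sum()) - transitions
        assert transitions > transversions

    def test_true_rates_recorded_per_site(self):
        tree = pf.simulate_tree(5, 40.0, seed=1)
        specs = [
            pf.SimPartitionSpec("a", 30, 0.01, gamma_shape=2.0),
            pf.SimPartitionSpec("b", 20, 0.001),
        ]
        bundle = pf.simulate_alignment(tree, specs, seed=14)
        frame = bundle.rates.frame
        assert len(frame) == 50
        assert (frame.loc[frame["partition"] == "b", "lambda"] == 0.001).all()


class TestInjectMissing:
    def _bundle(self):
        tree = pf.simulate_tree(10, 50.0, seed=3)
        specs = [pf.SimPartitionSpec(f"g{i}", 40, 0.005) for i in range(4)]
        return pf.simulate_alignment(tree, specs, seed=4)

    def test_rate_zero_is_identity(self):
        b = self._bundle()
        out = pf.inject_missing(b.matrix, b.scheme, 0.0, seed=5)
        assert (out.chars == b.matrix.chars).all()

    def test_rate_one_wipes_everything(self):
        b = self._bundle()
        out = pf.inject_missing(b.matrix, b.scheme, 1.0, seed=5)
        assert (out.chars == "?").all()

    def test_realized_fraction_near_target(self):
        tree = pf.simulate_tree(40, 50.0, seed=6)
        specs = [pf.SimPartitionSpec(f"g{i}", 30, 0.005) for i in range(8)]
        b = pf.simulate_alignment(tree, specs, seed=7)
        out = pf.inject_missing(b.matrix, b.scheme, 0.11, seed=8)
        wiped = 0
        for name, cols0 in b.scheme.items0():
            wiped += int((out.chars[:, cols0] == "?").all(axis=1).sum())
        n_cells = 40 * 8
        rate = wiped / n_cells
        se = np.sqrt(0.11 * 0.89 / n_cells)
        assert abs(rate - 0.11) <= 3 * se


class TestBenchmarkFixture:
    def test_total_width_matches_fragment_lengths(self, bench_bundle):
        total = sum(length for length, _, _ in FRAGMENTS.values())
        assert total == 6095
        assert bench_bundle.matrix.n_sites == 6095

    def test_partition_structure(self, bench_bundle):
        names = bench_bundle.scheme.names
        assert "16S" in names and "28S" in names
        assert "CAD_pos1" in names and "COI_3p_pos3" in names
        assert len(names) == 6 * 3 + 2
        assert bench_bundle.scheme.length("CAD_pos1") == 670
        assert bench_bundle.scheme.length("CAD_pos3") == 669

    def test_same_seed_byte_identical_fasta(self, tmp_path):
        import filecmp

        a = pf.aciliini_fixture(SUITE_SEED)
        b = pf.aciliini_fixture(SUITE_SEED)
        pa, pb = tmp_path / "a", tmp_path / "b"
        pf.write_bundle(a, pa)
        pf.write_bundle(b, pb)
        assert filecmp.cmp(pa / "alignment.fasta", pb / "alignment.fasta", shallow=False)
        assert filecmp.cmp(pa / "tree.nwk", pb / "tree.nwk", shallow=False)

    def test_rate_regime_ordering(self, bench_bundle):
        rates = bench_bundle.config["partition_mean_rate"]
        mito3 = min(rates[n] for n in ("COI_3p_pos3", "COI_5p_pos3", "COII_pos3"))
        nuc3 = max(rates[n] for n in ("CAD_pos3", "Wnt_pos3", "H3_pos3"))
        assert mito3 > nuc3 > rates["16S"] > rates["CAD_pos1"]

    def test_saturation_regimes(self, bench_bundle):
        """Mitochondrial third positions exceed 2 expected root-to-tip
        substitutions (saturated); first/second stay below 0.2."""
        T = bench_bundle.tree.root_age
        assert RATE_CLASSES["mito_pos3"] * T > 2
        assert RATE_CLASSES["mito_pos12"] * T < 0.2
        assert RATE_CLASSES["nuclear_pos12"] * T < 0.2

    def test_rank_recovery_across_rate_classes(self, bench_bundle, bench_rates):
        """Estimated per-class mean rates preserve the true ordering."""
        from scipy import stats

        true_rates = bench_bundle.config["partition_mean_rate"]
        classes = {}
        for name, r in true_rates.items():
            classes.setdefault(r, []).append(name)
        frame = bench_rates.frame
        truth, est = [], []
        for r, names in classes.items():
            truth.append(r)
            est.append(frame.loc[frame["partition"].isin(names), "lambda"].mean())
        assert len(truth) == 8
        rho = stats.spearmanr(truth, est).statistic
        assert rho == pytest.approx(1.0)

    def test_pi_class_ordering_true_vs_estimated(self, bench_bundle, bench_rates):
        """At 15/35/50 Ma the four most informative rate classes come out
        in the same order whether modified-PI profiles are built from
        true or from estimated rates. (The ordering among the remaining
        near-zero curves - heavily saturated vs ultra-slow classes at
        deep times - is within noise and not expected to be stable.)"""
        b = bench_bundle
        grid = np.array([15.0, 35.0, 50.0])
        pi_true = pf.profile(b.rates, b.scheme, grid=grid, variants=("modified",))
        pi_est = pf.profile(bench_rates, b.scheme, grid=grid, variants=("modified",))
        classes = {}
        for name, r in b.config["partition_mean_rate"].items():
            classes.setdefault(r, []).append(name)
        keys = sorted(classes)
        for k in range(len(grid)):
            agg_true, agg_est = [], []
            for r in keys:
                names = classes[r]
                agg_true.append(sum(pi_true.values(n, "modified")[k] for n in names))
                agg_est.append(sum(pi_est.values(n, "modified")[k] for n in names))
            top_true = list(np.argsort(agg_true)[::-1][:4])
            top_est = list(np.argsort(agg_est)[::-1][:4])
            assert top_true == top_est

    def test_bundle_directory_contents(self, tmp_path, bench_bundle):
        paths = pf.write_bundle(bench_bundle, tmp_path / "fix")
        for key in ("alignment", "tree", "partitions", "true_rates", "config"):
            assert (key in paths) and __import__("os").path.exists(paths[key])
        again = pf.read_fasta(paths["alignment"])
        assert again.n_sites == 6095
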