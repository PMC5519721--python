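"""Selection statistics against brute-force oracles and sign conventions."""

import numpy as np
import pytest

from sre_selscan import selection, simulate
from sre_selscan.types import HaplotypePanel


def wc_fst_oracle(n1, x1, n2, x2):
    """Independent transcription of the Weir-Cockerham (1984) two-population
    haploid-count estimator, written directly from the variance components."""
    p1, p2 = x1 / n1, x2 / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = 0.0
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a / (a + b + c)


def ehh_oracle(H, core, allele, direction):
    """O(n^2 m) pairwise-comparison EHH with trapezoid integration points."""
    carriers = np.flatnonzero(H[:, core] == allele)
    n = len(carriers)
    vals, js = [1.0], [core]
    j = core
    while True:
        j += direction
        if j < 0 or j >= H.shape[1]:
            break
        same = 0
        lo, hi = sorted((core, j))
        for a in range(n):
            for b in range(a + 1, n):
                if np.array_equal(H[carriers[a], lo : hi + 1], H[carriers[b], lo : hi + 1]):
                    same += 1
        vals.append(2 * same / (n * (n - 1)))
        js.append(j)
        if vals[-1] < 0.05:
            break
    return np.array(js), np.array(vals)


class TestWcFst:
    def test_reciprocal_fixation(self):
        assert selection.wc_fst(100, 100, 100, 0) == pytest.approx(1.0)

    def test_identical_counts_nonpositive(self):
        assert selection.wc_fst(50, 20, 50, 20) <= 0

    def test_monomorphic_undefined(self):
        assert np.isnan(selection.wc_fst(50, 0, 50, 0))
        assert np.isnan(selection.wc_fst(1, 0, 50, 10))

    def test_against_independent_oracle(self, rng):
        assert selection.wc_fst(20, 15, 20, 5) == pytest.approx(
            wc_fst_oracle(20, 15, 20, 5), abs=1e-12
        )
        for _ in range(100):
            n1, n2 = rng.integers(4, 200, size=2)
            x1 = rng.integers(0, n1 + 1)
            x2 = rng.integers(0, n2 + 1)
            if x1 + x2 == 0 or x1 + x2 == n1 + n2:
                continue
            assert selection.wc_fst(n1, x1, n2, x2) == pytest.approx(
                wc_fst_oracle(n1, x1, n2, x2), abs=1e-10
            )

    def test_range_invariant(self, rng):
        vals = []
        for _ in range(500):
            n1, n2 = rng.integers(4, 50, size=2)
            x1 = rng.integers(0, n1 + 1)
            x2 = rng.integers(0, n2 + 1)
            v = selection.wc_fst(n1, x1, n2, x2)
            if np.isfinite(v):
                vals.append(v)
        assert min(vals) >= -0.5 and max(vals) <= 1.0

    def test_population_swap_symmetric(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(4, 100, size=2)
            x1, x2 = rng.integers(1, n1), rng.integers(1, n2)
            assert selection.wc_fst(n1, x1, n2, x2) == pytest.approx(
                selection.wc_fst(n2, x2, n1, x1), abs=1e-12
            )


class TestDaf:
    def _panel(self, col):
        H = np.array(col, dtype=np.int8).reshape(-1, 1)
        return HaplotypePanel("P", H, np.array([100]), np.array([1e-4]))

    def test_ancestral_ref(self):
        p = self._panel([1] * 30 + [0] * 70)
        assert selection.derived_allele_freq(p, 0, ancestral_is_ref=True) == pytest.approx(0.30)

    def test_ancestral_alt_complement(self):
        p = self._panel([1] * 30 + [0] * 70)
        assert selection.derived_allele_freq(p, 0, ancestral_is_ref=False) == pytest.approx(0.70)


class TestEhh:
    def test_identical_carriers_unit_curve(self):
        H = np.zeros((6, 50), dtype=np.int8)
        H[:3, 25] = 1
        panel = HaplotypePanel("P", H, np.arange(1, 51) * 100, np.arange(50) * 1e-4)
        curve = selection.ehh_curve(panel, 25, 1, +1)
        assert np.all(curve.ehh == 1.0) and curve.truncated

    def test_immediate_split_drops_to_zero(self):
        H = np.zeros((4, 5), dtype=np.int8)
        H[:2, 2] = 1
        H[0, 3] = 1  # two carriers differ at the next site
        panel = HaplotypePanel("P", H, np.arange(1, 6), np.arange(5) * 1e-6)
        curve = selection.ehh_curve(panel, 2, 1, +1)
        assert curve.ehh[1] == 0.0

    def test_lt2_carriers_undefined(self):
        H = np.zeros((4, 5), dtype=np.int8)
        H[0, 2] = 1
        panel = HaplotypePanel("P", H, np.arange(1, 6), np.arange(5) * 1e-6)
        assert selection.ehh_curve(panel, 2, 1, +1) is None

    def test_non_increasing_and_matches_pairwise_oracle(self, rng):
        for _ in range(50):
            H = (rng.random((8, 30)) < 0.5).astype(np.int8)
            core = 15
            allele = int(H[0, core])
            panel = HaplotypePanel("P", H, np.arange(1, 31) * 50, np.arange(30) * 5e-5)
            for direction in (+1, -1):
                curve = selection.ehh_curve(panel, core, allele, direction)
                assert np.all(np.diff(curve.ehh) <= 1e-12)
                js, vals = ehh_oracle(H, core, allele, direction)
                assert np.allclose(curve.ehh, vals, atol=1e-12)


class TestIhs:
    def test_mirror_symmetry_gives_zero(self):
        """Ancestral and derived carrier sets with identical internal
        haplotype structure integrate identically."""
        block = np.array([[0, 1, 0, 1, 0], [0, 1, 1, 1, 0], [1, 0, 0, 0, 1], [1, 0, 1, 0, 1]], dtype=np.int8)
        H = np.hstack([block[:, :2], np.array([[0], [0], [1], [1]], dtype=np.int8), block[:, 2:]])
        panel = HaplotypePanel("P", H, np.arange(1, 7) * 100, np.arange(6) * 1e-4)
        val, why = selection.ihs(panel, 2, ancestral_is_ref=True)
        assert why == "" and val == pytest.approx(0.0, abs=1e-12)

    def test_sweep_on_derived_is_negative(self, rng):
        panels, _, _ = simulate.simulate_panels(600, 0.1, 80, rng)
        P = panels["P1"]
        core = 300
        if not 0 < P.alt_count()[core] < 80:
            pytest.skip("core monomorphic under this seed")
        swept = simulate.plant_sweep(P, core, 1, 0.9, rng, 100)
        val, why = selection.ihs(swept, core, ancestral_is_ref=True)
        assert why == "" and val < 0

    def test_integrals_match_quadrature_oracle(self, rng):
        for _ in range(20):
            H = (rng.random((12, 40)) < 0.5).astype(np.int8)
            panel = HaplotypePanel("P", H, np.arange(1, 41) * 50, np.arange(40) * 5e-5)
            core = 20
            allele = int(H[0, core])
            out = selection.ehh_integral(panel, core, allele)
            left = selection.ehh_curve(panel, core, allele, -1)
            right = selection.ehh_curve(panel, core, allele, +1)
            oracle = np.trapezoid(left.ehh, left.distances) + np.trapezoid(
                right.ehh, right.distances
            )
            assert out[0] == pytest.approx(oracle, abs=1e-12)


class TestXpEhh:
    def test_identical_panels_zero(self, rng):
        panels, _, _ = simulate.simulate_panels(200, 0.1, 30, rng)
        P = panels["P1"]
        val, why = selection.xp_ehh(P, P, 100)
        assert why == "" and val == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric_under_swap_and_fst_unchanged(self, rng):
        panels, _, _ = simulate.simulate_panels(200, 0.2, 30, rng)
        P1, P2 = panels["P1"], panels["P2"]
        v12, _ = selection.xp_ehh(P1, P2, 100)
        v21, _ = selection.xp_ehh(P2, P1, 100)
        assert v12 == pytest.approx(-v21, abs=1e-12)
        n = np.full(200, 30)
        f12 = selection.wc_fst(n, P1.alt_count(), n, P2.alt_count())
        f21 = selection.wc_fst(n, P2.alt_count(), n, P1.alt_count())
        assert np.allclose(f12, f21, atol=1e-12, equal_nan=True)

    def test_sweep_in_p1_positive(self, rng):
        panels, _, _ = simulate.simulate_panels(600, 0.05, 80, rng)
        P1, P2 = panels["P1"], panels["P2"]
        core = 300
        if not 0 < P1.alt_count()[core] < 80:
            pytest.skip("core monomorphic under this seed")
        P1s = simulate.plant_sweep(P1, core, 1, 0.9, rng, 100)
        val, why = selection.xp_ehh(P1s, P2, core, 1)
        assert why == "" and val > 0


class TestStandardize:
    def test_per_bin_mean_zero_var_one(self, rng):
        raw = rng.standard_normal(2000) * 3 + 1
        daf = rng.random(2000)
        z = selection.standardize_scores(raw, daf, bin_width=0.05)
        idx = np.floor(daf / 0.05).astype(int)
        for b in np.unique(idx):
            sel = idx == b
            if np.isfinite(z[sel]).all() and sel.sum() >= 20:
                assert abs(z[sel].mean()) < 1e-12
                assert abs(z[sel].var() - 1.0) < 1e-12

    def test_global_bin_equals_zscore(self, rng):
        raw = rng.standard_normal(500) * 2 + 5
        z = selection.standardize_scores(raw)
        assert np.allclose(z, (raw - raw.mean()) / raw.std(), atol=1e-12)

    def test_outlier_threshold_two(self, rng):
        raw = rng.standard_normal(5000)
        z = selection.standardize_scores(raw)
        assert 0.01 < np.mean(np.abs(z) >= 2) < 0.10

    def test_sparse_bins_merged(self, rng):
        raw = rng.standard_normal(30)
        bv = np.concatenate([np.zeros(25), np.full(5, 0.9)])  # sparse top bin
        z = selection.standardize_scores(raw, bv, bin_width=0.05, min_per_bin=20)
        assert np.isfinite(z).all()
        assert abs(z.mean()) < 1e-12  # single merged bin in the extreme case

    def test_nan_propagates(self):
        z = selection.standardize_scores(np.array([1.0, np.nan, 3.0, 5.0]))
        assert np.isnan(z[1]) and np.isfinite(z[[0, 2, 3]]).all()


class TestXpclr:
    def test_single_snp_zero_shift_grid_gives_zero(self, rng):
        panels, _, _ = simulate.simulate_panels(1, 0.1, 20, rng, spacing_bp=1000)
        drift = selection.DriftModel(omega=0.1, window_snps=1, s_grid=(0.0,))
        wins = selection.xpclr_windows(panels["P1"], panels["P2"], drift)
        assert wins["clr"].abs().max() == 0.0

    def test_nonnegative(self, rng):
        panels, _, _ = simulate.simulate_panels(500, 0.1, 40, rng)
        om = selection.calibrate_omega(panels["P1"], panels["P2"])
        wins = selection.xpclr_windows(panels["P1"], panels["P2"], selection.DriftModel(omega=om))
        assert (wins["clr"] >= -1e-9).all()

    def test_sweep_windows_exceed_null(self, rng):
        """Planted sweeps separate from the neutral CLR distribution
        (rank-sum check on a reduced problem; the 20-seed detection-rate
        version runs in the acceptance suite)."""
        panels, _, _ = simulate.simulate_panels(1000, 0.05, 80, rng)
        P1, P2 = panels["P1"], panels["P2"]
        om = selection.calibrate_omega(P1, P2)
        drift = selection.DriftModel(omega=om, grid_step=5)
        null = selection.xpclr_windows(P1, P2, drift)["clr"]
        core = 500
        # sweep the majority allele so the carrier class dominates the panel
        allele = 1 if P1.alt_count()[core] >= 40 else 0
        P1s = simulate.plant_sweep(P1, core, allele, 0.8, rng, 100)
        swept = selection.xpclr_per_variant(selection.xpclr_windows(P1s, P2, drift), 1000)
        assert swept[core] > np.quantile(null, 0.99)


class TestCalibrateOmega:
    def test_identical_panels_at_floor(self, rng):
        panels, _, _ = simulate.simulate_panels(2000, 0.1, 50, rng)
        P = panels["P1"]
        assert selection.calibrate_omega(P, P) == pytest.approx(1e-6)

    def test_known_divergence_recovered(self):
        panels, _, _ = simulate.simulate_panels(20000, 0.15, 100, 77)
        om = selection.calibrate_omega(panels["P1"], panels["P2"])
        target = 2 * 0.15 / (1 - 0.15)
        assert abs(om - target) / target < 0.20

    def test_doubling_divergence_roughly_doubles_omega(self):
        oms = []
        for c in (0.05, 0.10):
            panels, _, _ = simulate.simulate_panels(20000, c, 100, 88)
            oms.append(selection.calibrate_omega(panels["P1"], panels["P2"]))
        assert 1.6 < oms[1] / oms[0] < 2.5


class TestComposite:
    def test_zero_weights_give_unit_likelihood(self, rng):
        x = rng.random(100)
        out = selection.composite_likelihood(x, x, x, alpha=0, beta=0, gamma=0)
        assert np.allclose(out, 0.0)

    def test_single_component_preserves_density_ranking(self, rng):
        fst = rng.random(500)
        out = selection.composite_likelihood(fst, rng.random(500), rng.random(500), 1, 0, 0)
        edges, dens = selection._hist_density(fst)
        f = selection._density_lookup(edges, dens, fst)
        assert np.allclose(out, np.log(f), atol=1e-12)  # identical ranking

    def test_matches_direct_histogram_product(self, rng):
        fst, xpe, xpc = rng.random(300), rng.standard_normal(300), rng.random(300) * 5
        out = selection.composite_likelihood(fst, xpe, xpc)
        direct = np.zeros(300)
        for v in (fst, xpe, xpc):
            e, d = selection._hist_density(v)
            direct += np.log(selection._density_lookup(e, d, v))
        assert np.allclose(out, direct, atol=1e-12)
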