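"""Odds ratios, CMH de-confounding, matched nulls, rank/KS comparisons."""

import itertools

import numpy as np
import pytest
from scipy import stats

from sre_selscan import enrichment, simulate
from sre_selscan.types import ConfigurationError


class TestLdExtent:
    def test_no_neighbours_zero(self, rng):
        panels, _, _ = simulate.simulate_panels(10, 0.1, 20, rng, spacing_bp=10**6)
        assert enrichment.ld_extent(panels["P1"], 5, window_bp=1000) == 0.0

    def test_duplicate_site_contributes_one(self, rng):
        from sre_selscan.types import HaplotypePanel

        H = (rng.random((40, 5)) < 0.5).astype(np.int8)
        H[:20, 2] = 1  # guarantee the focal site is polymorphic
        H[20:, 2] = 0
        pos = np.arange(1, 6) * 100
        P = HaplotypePanel("P1", H, pos, pos / 1e6)
        H_dup = np.hstack([H, H[:, [2]]])
        pos_dup = np.append(pos, pos[-1] + 10)
        dup_panel = HaplotypePanel("P1", H_dup, pos_dup, pos_dup / 1e6)
        base = enrichment.ld_extent(P, 2, 10**6)
        dup = enrichment.ld_extent(dup_panel, 2, 10**6)
        assert dup == pytest.approx(base + 1.0, abs=1e-9)

    def test_monomorphic_focal_undefined(self, rng):
        panels, _, _ = simulate.simulate_panels(10, 0.1, 20, rng)
        P = panels["P1"]
        P.haplotypes[:, 4] = 0
        assert np.isnan(enrichment.ld_extent(P, 4))

    def test_matches_bruteforce_r2(self, rng):
        for _ in range(20):
            panels, _, _ = simulate.simulate_panels(60, 0.2, 30, rng)
            P = panels["P1"]
            j = int(rng.integers(0, 60))
            H = P.haplotypes.astype(float)
            if H[:, j].std() == 0:
                continue
            acc = 0.0
            for k in range(60):
                if k == j or abs(int(P.positions[k]) - int(P.positions[j])) > 20000:
                    continue
                if H[:, k].std() == 0:
                    continue
                acc += np.corrcoef(H[:, j], H[:, k])[0, 1] ** 2
            assert enrichment.ld_extent(P, j, 20000) == pytest.approx(acc, abs=1e-10)


class TestOddsRatio:
    def test_balanced_table_unity(self):
        res = enrichment.odds_ratio_2x2(30, 70, 30, 70)
        assert res.oddsratio == pytest.approx(1.0)

    def test_direct_evaluation(self):
        res = enrichment.odds_ratio_2x2(30, 70, 10, 90)
        assert res.oddsratio == pytest.approx(27 / 7)
        assert 0 < res.pvalue <= 1

    def test_zero_cell_corrected(self):
        res = enrichment.odds_ratio_2x2(0, 50, 10, 40)
        assert res.corrected and np.isfinite(res.oddsratio)

    def test_probability_form_equals_ad_over_bc(self, rng):
        """Eq-style OR from conditional probabilities equals ad/bc."""
        for _ in range(50):
            a, b, c, d = rng.integers(1, 100, size=4)
            pfs = a / (a + b)
            pfc = c / (c + d)
            direct = (pfs / (1 - pfs)) / (pfc / (1 - pfc))
            assert enrichment.odds_ratio_2x2(a, b, c, d).oddsratio == pytest.approx(direct)

    def test_bin_table_counts_partition_universe(self, rng):
        fst = rng.random(1000)
        in_set = rng.random(1000) < 0.3
        table = enrichment.fst_bin_table(fst, in_set)
        bins = table[~table["lo"].isna()]
        assert bins["n_set"].sum() == in_set.sum()
        assert bins["n_comp"].sum() == (~in_set).sum()

    def test_negative_fst_clipped_into_first_bin(self):
        table = enrichment.fst_bin_table(np.array([-0.2, 0.05]), np.array([True, False]))
        first = table.iloc[0]
        assert first["n_set"] == 1 and first["n_comp"] == 1


class TestConditionalOddsRatio:
    def test_whole_range_equals_unconditional(self, rng):
        fst = rng.random(2000)
        in_set = rng.random(2000) < 0.3
        full = enrichment.odds_ratio(enrichment.fst_bin_table(fst, in_set), "fst>0.7")
        cond = enrichment.conditional_odds_ratio(fst, in_set, "fst>0.7", np.ones(2000, bool))
        assert cond.oddsratio == pytest.approx(full.oddsratio)

    def test_recovers_generating_stratum_ors(self, rng):
        """A mixture built with different ORs per DAF stratum returns each
        stratum's own OR within sampling error."""
        rows = []
        for stratum, or_true in ((0, 1.0), (1, 3.0)):
            n = 60000
            in_set = rng.random(n) < 0.5
            base = 0.1
            odds = np.where(in_set, or_true * base / (1 - base), base / (1 - base))
            high = rng.random(n) < odds / (1 + odds)
            rows.append((np.full(n, stratum), in_set, high))
        strat = np.concatenate([r[0] for r in rows])
        in_set = np.concatenate([r[1] for r in rows])
        fst = np.where(np.concatenate([r[2] for r in rows]), 0.9, 0.1)
        for stratum, or_true in ((0, 1.0), (1, 3.0)):
            res = enrichment.conditional_odds_ratio(fst, in_set, "fst>0.7", strat == stratum)
            assert res.oddsratio == pytest.approx(or_true, rel=0.1)

    def test_degenerate_stratum_errors(self, rng):
        fst = rng.random(100)
        in_set = np.ones(100, bool)
        with pytest.raises(ConfigurationError):
            enrichment.conditional_odds_ratio(fst, in_set, "fst>0.7", np.ones(100, bool))


class TestCMH:
    def test_homogeneous_strata(self):
        tables = [(20, 80, 10, 90)] * 4  # OR = 2.25 in every stratum
        res = enrichment.cmh_common_or(tables)
        assert res.common_or == pytest.approx(2.25, rel=1e-9)

    def test_single_stratum_equals_its_or(self):
        res = enrichment.cmh_common_or([(30, 70, 10, 90)])
        assert res.common_or == pytest.approx(27 / 7)

    def test_matches_direct_mantel_haenszel_formula(self, rng):
        tables = [tuple(int(x) for x in rng.integers(5, 100, size=4)) for _ in range(6)]
        res = enrichment.cmh_common_or(tables)
        num = sum(a * d / (a + b + c + d) for a, b, c, d in tables)
        den = sum(b * c / (a + b + c + d) for a, b, c, d in tables)
        assert res.common_or == pytest.approx(num / den, rel=1e-12)

    def test_confounded_fixture_deflates_crude_or(self, rng):
        """B-value confounding (Simpson-type): the pooled OR is inflated
        while the common OR recovers the generating within-stratum OR."""
        tables = simulate.confounded_strata(rng, stratum_or=1.2)
        res = enrichment.cmh_common_or(tables)
        assert res.crude_or > res.common_or
        assert abs(np.log(res.common_or)) < abs(np.log(res.crude_or))
        assert res.common_or == pytest.approx(1.2, rel=0.05)

    def test_degenerate_strata_dropped(self):
        res = enrichment.cmh_common_or([(30, 70, 10, 90), (0, 0, 5, 5)])
        assert res.n_strata_dropped == 1 and res.n_strata_used == 1
        with pytest.raises(ConfigurationError):
            enrichment.cmh_common_or([(0, 0, 5, 5)])


class TestMatchedNull:
    def test_engineered_extreme_target(self, rng):
        n = 400
        values = np.zeros(n)
        is_target = np.zeros(n, bool)
        is_target[:20] = True
        values[:20] = 1.0  # target exceeds every possible null set
        keys = np.zeros(n, int)
        p, _, obs = enrichment.matched_null_pvalue(values, is_target, keys, rng, n_sets=99)
        assert p == pytest.approx(1 / 100)
        assert obs == 20

    def test_deterministic_under_seed(self, rng):
        n = 300
        values = np.random.default_rng(1).random(n)
        is_target = np.zeros(n, bool)
        is_target[:30] = True
        keys = np.random.default_rng(2).integers(0, 5, size=n)
        p1, _, _ = enrichment.matched_null_pvalue(
            values, is_target, keys, np.random.default_rng(7), n_sets=200
        )
        p2, _, _ = enrichment.matched_null_pvalue(
            values, is_target, keys, np.random.default_rng(7), n_sets=200
        )
        assert p1 == p2

    def test_empty_cell_errors(self, rng):
        values = np.zeros(10)
        is_target = np.array([True] + [False] * 9)
        keys = np.array([99] + [0] * 9)  # no pool candidate shares the target's cell
        with pytest.raises(ConfigurationError, match="99"):
            enrichment.matched_null_pvalue(values, is_target, keys, rng)

    def test_null_sets_match_composition(self, rng):
        """Every null draw has exactly the target's per-bin composition."""
        n = 500
        keys = rng.integers(0, 4, size=n)
        is_target = np.zeros(n, bool)
        is_target[rng.choice(n, 50, replace=False)] = True
        values = keys.astype(float)  # value identifies the bin
        _, nulls, obs = enrichment.matched_null_pvalue(
            values, is_target, keys, rng, statistic=np.sum, n_sets=50
        )
        assert np.allclose(nulls, obs)  # bin sums forced equal by matching


class TestMatchBins:
    def test_ld_intervals(self):
        import pandas as pd

        feats = pd.DataFrame({"ld": [10.0, 60.0, 100.0, 120.0, 200.0]})
        keys = enrichment.assign_match_bins(feats)
        assert [k[0] for k in keys] == [0, 1, 2, 3, 4]

    def test_matched_draw_shares_all_bins(self, rng):
        import pandas as pd

        feats = pd.DataFrame(
            {
                # coarse features so every matching cell is well populated
                "bvalue": rng.choice([200.0, 700.0], 400),
                "daf": rng.choice([0.12, 0.62], 400),
                "ld": rng.choice([20.0, 120.0], 400),
            }
        )
        keys = enrichment.assign_match_bins(feats)
        is_target = np.zeros(400, bool)
        is_target[:40] = True
        vals = np.arange(400, dtype=float)
        # matching cannot fail silently: compositions agree exactly
        _, nulls, _ = enrichment.matched_null_pvalue(
            (keys.factorize()[0]).astype(float), is_target, keys, rng,
            statistic=np.sum, n_sets=20,
        )
        target_sum = float((keys.factorize()[0])[is_target].sum())
        assert np.allclose(nulls, target_sum)


class TestRankCompare:
    def test_identical_samples(self):
        u, p = enrichment.rank_compare([1.0, 1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_exact_small_sample(self):
        u, p = enrichment.rank_compare([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_exact_matches_enumeration_oracle(self, rng):
        """Exact two-sided p equals exhaustive enumeration over all
        C(n1+n2, n1) group assignments of the pooled values."""
        for _ in range(10):
            a = rng.random(4)
            b = rng.random(3)
            _, p = enrichment.rank_compare(a, b)
            pooled = np.concatenate([a, b])
            ranks = stats.rankdata(pooled)
            n1 = len(a)

            def ustat(idx):
                r1 = ranks[list(idx)].sum()
                u1 = r1 - n1 * (n1 + 1) / 2
                return min(u1, len(a) * len(b) - u1)

            obs = ustat(range(n1))
            total, extreme = 0, 0
            for idx in itertools.combinations(range(len(pooled)), n1):
                total += 1
                if ustat(idx) <= obs:
                    extreme += 1
            assert p == pytest.approx(extreme / total, abs=1e-8)

    def test_asymptotic_close_to_exact_on_moderate_n(self, rng):
        a = rng.random(30)
        b = rng.random(25) + 0.2
        _, p_asym = enrichment.rank_compare(a, b)
        p_ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert p_asym == pytest.approx(p_ref, abs=5e-3)


class TestKS:
    def test_identical_samples_statistic_zero(self, rng):
        x = rng.random(100)
        stat, _ = enrichment.distribution_compare_ks(x, x)
        assert stat == 0.0

    def test_enriched_low_pvalues_detected(self):
        x = np.random.default_rng(3).random(10000) ** 2
        _, p = enrichment.distribution_compare_ks(x)
        assert p < 1e-10

    def test_qq_table_monotone(self, rng):
        qq = enrichment.qq_table(rng.random(100))
        assert (np.diff(qq["expected_neglog10"]) <= 0).all()
        assert (np.diff(qq["observed_neglog10"]) <= 1e-12).all()
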