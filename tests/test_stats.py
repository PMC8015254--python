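"""Statistics: OLS oracle equivalence, BH, permutation nulls, threshold
search, gene/specimen calls, staging, voxel-level maps."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sstats

from embryomorph.errors import DegenerateDataError, DesignError, ParameterError
from embryomorph.phantom import (
    LineEffect,
    default_phantom_spec,
    simulate_cohort_tables,
    truth_to_organ_table,
)
from embryomorph.stats import (
    bh_fdr,
    build_null_distributions,
    fit_linear_model,
    gene_level_calls,
    organ_bh_calls,
    organ_table_wide,
    permutation_threshold_search,
    specimen_level_calls,
    staging_report,
    voxel_level_stats,
)


def brute_force_bh(p):
    """Direct step-up enumeration of BH q-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def brute_force_threshold(nulls, alts, start=0.05, target=0.05):
    """Exhaustive scan over all candidate thresholds (pooled p-values)."""
    cands = sorted({p for p in list(nulls) + list(alts) if p <= start}, reverse=True)
    for c in cands:
        fa = np.mean(np.asarray(alts) <= c)
        fn = np.mean(np.asarray(nulls) <= c)
        if fa > 0 and fn / fa < target:
            return c
    return None


def make_table(seed=0, wt_n=50, lines=(), substage=(0.9, 1.1)):
    spec = default_phantom_spec()
    specimens, truth = simulate_cohort_tables(spec, wt_n, substage, list(lines), seed)
    return truth_to_organ_table(specimens, truth)


class TestLinearFit:
    def test_matches_normal_equations_and_statsmodels(self, rng):
        n = 12
        group = (np.arange(n) % 2).astype(float)
        wev = rng.uniform(20, 40, n)
        y = 0.3 * group + 0.01 * wev + rng.normal(0, 0.1, n)
        fit = fit_linear_model(y, group, wev)
        X = np.column_stack([np.ones(n), group, wev])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-10)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, atol=1e-10)
        np.testing.assert_allclose(fit.p_values, ref.pvalues, atol=1e-10)
        assert fit.dof == n - 3

    def test_exact_fit_is_degenerate_with_zero_group_effect(self):
        n = 10
        wev = np.linspace(20, 40, n)
        group = np.zeros(n)
        group[5:] = 1.0
        y = 2.0 + 0.1 * wev  # exactly linear in WEV, groups identical
        fit = fit_linear_model(y, group, wev)
        assert fit.degenerate
        assert abs(fit.coefficients[fit.term("genotype")]) < 1e-10
        assert fit.p_values[fit.term("genotype")] == 1.0

    def test_omitting_wev_exposes_confounding(self):
        """Relabelling the largest specimens as mutant: the genotype p-value
        without the WEV covariate is (spuriously) far smaller than with it,
        consistently across seeds."""
        wins, min_p = 0, 1.0
        for seed in range(5):
            table = make_table(seed=40 + seed, wt_n=60)
            wide, meta = organ_table_wide(table)
            wev = meta["wev_mm3"].to_numpy()
            group = (wev > np.quantile(wev, 0.85)).astype(float)
            y = wide[2].to_numpy()  # allometric exponent > 1 organ
            p_with = fit_linear_model(y, group, wev).p_values[1]
            p_without = fit_linear_model(y, group, include_wev=False).p_values[1]
            wins += int(p_without < p_with)
            min_p = min(min_p, p_without)
        assert wins >= 4
        assert min_p < 0.01

    def test_rank_deficiency_rejected(self):
        with pytest.raises(DesignError):
            fit_linear_model(np.arange(8.0), np.ones(8), np.ones(8))


class TestBH:
    def test_single_and_tied_pvalues(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(5):
            p = rng.uniform(0, 1, 10)
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(0, 1, 30)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_fdr([0.5, 1.2])


class TestNullDistributions:
    def test_fixed_seed_reproducible(self):
        table = make_table(seed=1)
        a = build_null_distributions(table, [2, 4], n_perms=50, seed=7)
        b = build_null_distributions(table, [2, 4], n_perms=50, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_size_allocation_matches_proportions(self):
        table = make_table(seed=1)
        nulls = build_null_distributions(table, [3, 3, 4, 4], n_perms=100, seed=0)
        assert nulls.attrs["line_sizes"] == [3, 3, 4, 4]
        # degenerate size distribution: every synthetic line has size 2
        nulls2 = build_null_distributions(table, [2, 2], n_perms=20, seed=0)
        assert nulls2.shape == (20, 8)

    def test_null_pvalues_uniform_under_exchangeability(self):
        """On exactly exchangeable Gaussian baselines (correctly specified
        model) the synthetic-line null p-values are uniform."""
        rng = np.random.default_rng(44)
        n = 200  # large pool: synthetic lines barely overlap, p-values ~iid
        wev = rng.uniform(25, 40, n)
        rows = []
        for i in range(n):
            for lab in (1, 2, 3):
                rows.append(
                    {
                        "specimen": f"wt{i}", "line": "baseline", "genotype": "wt",
                        "sex": "M", "label": lab, "volume_mm3": np.nan,
                        "wev_mm3": wev[i],
                        "normalized_volume": rng.normal(0.02, 0.002),
                        "wev_zscore": 0.0,
                    }
                )
        table = pd.DataFrame(rows)
        nulls = build_null_distributions(table, [4], n_perms=1000, seed=3)
        crit = 1.63 / math.sqrt(1000)  # 1% critical value
        for organ in nulls.columns:
            d = sstats.kstest(nulls[organ], "uniform").statistic
            assert d < crit

    def test_unique_guard_warns_below_500(self, caplog):
        table = make_table(seed=1, wt_n=8)
        with caplog.at_level(logging.WARNING):
            build_null_distributions(table, [3], n_perms=10, seed=0)
        assert "unique" in caplog.text  # C(8,3)=56 < 500

    def test_impossible_size_rejected(self):
        table = make_table(seed=1, wt_n=4)
        with pytest.raises(DesignError):
            build_null_distributions(table, [4], n_perms=10, seed=0)


class TestThresholdSearch:
    def test_well_separated_alternatives_pick_largest_alt(self):
        nulls = pd.DataFrame({"o": [0.01, 0.02, 0.03, 0.04]})
        alts = pd.DataFrame({"o": [0.0005, 0.002]})
        out = permutation_threshold_search(nulls, alts)
        assert out.loc[0, "threshold"] == pytest.approx(0.002)

    def test_exchangeable_lists_give_no_threshold(self):
        same = pd.DataFrame({"o": [0.001, 0.01, 0.03, 0.2, 0.7]})
        out = permutation_threshold_search(same, same.copy())
        assert np.isnan(out.loc[0, "threshold"])

    def test_tiny_lists_match_exhaustive_scan(self):
        nulls = pd.DataFrame({"o": [0.2, 0.5, 0.9, 0.04]})
        alts = pd.DataFrame({"o": [0.0005, 0.01, 0.3]})
        out = permutation_threshold_search(nulls, alts)
        expect = brute_force_threshold(nulls["o"], alts["o"])
        assert out.loc[0, "threshold"] == pytest.approx(expect)

    def test_random_inputs_match_exhaustive_scan(self, rng):
        for _ in range(20):
            nulls = rng.uniform(0, 1, rng.integers(5, 50))
            alts = rng.uniform(0, 0.5, rng.integers(2, 10))
            out = permutation_threshold_search(
                pd.DataFrame({"o": nulls}), pd.DataFrame({"o": alts})
            )
            expect = brute_force_threshold(nulls, alts)
            got = out.loc[0, "threshold"]
            if expect is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect)
            if np.isfinite(got):
                assert got <= 0.05

    def test_literal_ratio_direction_available(self):
        nulls = pd.DataFrame({"o": [0.2, 0.5, 0.9, 0.04]})
        alts = pd.DataFrame({"o": [0.0005, 0.01, 0.3]})
        lit = permutation_threshold_search(nulls, alts, literal_ratio=True)
        # alt/null ratio is never < 0.05 here, so no threshold
        assert np.isnan(lit.loc[0, "threshold"])


class TestCalls:
    def test_injected_reduction_called_smaller(self):
        eff = LineEffect("hyp", {4: 0.5}, {4: 1.0}, expressivity_sd=0.1)
        hits = 0
        for seed in range(6):
            table = make_table(seed=100 + seed, lines=[(eff, 4)])
            calls, thr, _ = gene_level_calls(table, n_perms=400, seed=seed)
            row = calls[(calls["label"] == 4)].iloc[0]
            hits += int(row["significant"] and row["direction"] == "smaller")
        assert hits >= 5

    def test_significant_calls_respect_thresholds(self):
        eff = LineEffect("hyp", {4: 0.5}, {4: 1.0})
        table = make_table(seed=3, lines=[(eff, 4)])
        calls, thr, _ = gene_level_calls(table, n_perms=300, seed=1)
        sig = calls[calls["significant"]]
        t = thr.set_index("label")["threshold"]
        assert (sig["p"].to_numpy() < t.loc[sig["label"]].to_numpy()).all()
        assert np.nanmax(thr["threshold"].to_numpy()) <= 0.05

    def test_empty_mutant_set_gives_empty_tables(self):
        table = make_table(seed=2)
        calls, thr, dists = gene_level_calls(table)
        assert calls.empty and thr.empty and dists is None

    def test_partial_penetrance_separates_affected_specimens(self):
        """With 50% penetrance, specimen-level calls should hit the affected
        specimens far more often than the unaffected ones."""
        spec = default_phantom_spec()
        affected_hits, unaffected_hits, n_aff, n_unaff = 0, 0, 0, 0
        for seed in range(8):
            eff = LineEffect("pp", {4: 0.4}, {4: 0.5})
            specimens, truth = simulate_cohort_tables(
                spec, 40, (0.9, 1.1), [(eff, 6)], 300 + seed
            )
            table = truth_to_organ_table(specimens, truth)
            affected = set(
                truth.loc[
                    (truth["label"] == 4) & (truth["effect_applied"] != 1.0),
                    "specimen",
                ]
            )
            calls, _, _ = specimen_level_calls(table, n_perms=300, seed=seed)
            organ4 = calls[calls["label"] == 4]
            for _, row in organ4.iterrows():
                if row["unit"] in affected:
                    n_aff += 1
                    affected_hits += int(row["significant"])
                else:
                    n_unaff += 1
                    unaffected_hits += int(row["significant"])
        assert n_aff > 0 and n_unaff > 0
        assert affected_hits / n_aff > unaffected_hits / max(n_unaff, 1) + 0.3

    def test_power_does_not_drop_with_more_baselines(self):
        """Enlarging the baseline set (10 → 49) does not decrease detection
        power for a fixed injected effect."""
        eff = LineEffect("hyp", {4: 0.7}, {4: 1.0})
        power = {}
        for wt_n in (10, 49):
            hits = 0
            for seed in range(10):
                table = make_table(seed=500 + seed, wt_n=wt_n, lines=[(eff, 3)])
                calls, _, _ = gene_level_calls(table, n_perms=300, seed=seed)
                hits += int(calls[calls["label"] == 4]["significant"].iloc[0])
            power[wt_n] = hits / 10
        assert power[49] >= power[10] - 0.1


class TestSexAndBHFallback:
    def test_sex_contrast_finds_only_gonad_analogue(self):
        table = make_table(seed=9, wt_n=60)
        res = organ_bh_calls(table, group_col="sex", test_value="F")
        sig = set(res.loc[res["significant"], "label"])
        assert 7 in sig  # the dimorphic organ
        assert res.set_index("label").loc[7, "coef"] < 0  # females smaller
        assert len(sig - {7}) <= 1  # at most one stray label


class TestStaging:
    def test_allometric_organs_show_wev_effect(self):
        table = make_table(seed=11, wt_n=50)
        wt = table[table["genotype"] == "wt"]
        rep = staging_report(wt).set_index("label")
        # strong allometric organ (a=1.3): significant, proportionally larger
        assert rep.loc[2, "significant"] and rep.loc[2, "wev_coef"] > 0
        # sub-isometric organ trends in the opposite direction
        assert rep.loc[3, "wev_coef"] < 0

    def test_isometric_organ_rarely_significant(self):
        hits = 0
        for seed in range(10):
            wt = make_table(seed=700 + seed, wt_n=50)
            rep = staging_report(wt).set_index("label")
            hits += int(rep.loc[6, "significant"])  # exponent exactly 1
        assert hits <= 1

    def test_insufficient_baselines_rejected(self):
        wt = make_table(seed=0, wt_n=2)
        with pytest.raises(DesignError):
            staging_report(wt)

    def test_constant_wev_rejected(self):
        wt = make_table(seed=0, wt_n=6)
        wt["wev_mm3"] = 1.0
        wt["normalized_volume"] = wt["volume_mm3"]
        with pytest.raises(DegenerateDataError):
            staging_report(wt)


class TestVoxelStats:
    def _stack(self, rng, n=20, shape=(10, 10, 10), effect=0.0, region=None):
        stack = rng.normal(1.0, 0.05, size=(n, *shape))
        group = np.zeros(n)
        group[n // 2 :] = 1.0
        if effect and region is not None:
            stack[(group == 1)[:, None, None, None] & region[None]] += effect
        return stack, group

    def test_global_null_controls_voxel_fdr(self):
        rng = np.random.default_rng(0)
        shape = (10, 10, 10)
        mask = np.ones(shape, dtype=bool)
        fracs = []
        for _ in range(10):
            stack, group = self._stack(rng)
            wev = rng.uniform(20, 40, len(group))
            res = voxel_level_stats(stack, group, wev, mask)
            fracs.append(res.n_significant / mask.sum())
        assert np.mean(fracs) <= 0.05

    def test_injected_expansion_recovered(self):
        rng = np.random.default_rng(1)
        shape = (12, 12, 12)
        region = np.zeros(shape, dtype=bool)
        region[3:8, 3:8, 3:8] = True
        stack, group = self._stack(rng, n=20, shape=shape, effect=0.3, region=region)
        wev = rng.uniform(20, 40, len(group))
        res = voxel_level_stats(stack, group, wev, np.ones(shape, dtype=bool))
        sig = res.thresholded_t != 0
        assert (sig & region).sum() / region.sum() >= 0.5
        assert np.nanmin(res.q[~np.isnan(res.q)]) >= 0  # q defined on mask
        assert np.all(res.q[res.mask] >= res.p[res.mask] - 1e-12)

    def test_empty_mask_rejected(self, rng):
        stack = rng.normal(size=(5, 4, 4, 4))
        with pytest.raises(DegenerateDataError):
            voxel_level_stats(
                stack, np.array([0, 0, 0, 1, 1.0]), None,
                np.zeros((4, 4, 4), dtype=bool), include_wev=False,
            )
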