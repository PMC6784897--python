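"""Enrichment cascade, permutation test, rank statistics, correlations."""

import math

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_fisher, exhaustive_perm_p, rank_with_ties
from metacomm import enrichment
from metacomm.enrichment import PermutationSpec


def groups_series(n_inc, n_dec, n_nei):
    labels = (["Increase"] * n_inc + ["Decrease"] * n_dec
              + ["Neither"] * n_nei)
    return pd.Series(labels, index=[f"g{i}" for i in range(len(labels))])


class TestPrefilter:
    def test_carriers_only_in_neither_removed(self):
        gr = groups_series(2, 2, 2)
        fm = pd.DataFrame({"f": [0, 0, 0, 0, 1, 1]}, index=gr.index)
        assert enrichment.prefilter_categories(fm.astype(bool), gr) == []

    def test_one_carrier_per_side_kept(self):
        gr = groups_series(2, 2, 2)
        fm = pd.DataFrame({"f": [1, 0, 1, 0, 0, 0]}, index=gr.index)
        assert enrichment.prefilter_categories(fm.astype(bool), gr) == ["f"]

    def test_empty_matrix(self):
        gr = groups_series(1, 1, 1)
        fm = pd.DataFrame(index=gr.index)
        assert enrichment.prefilter_categories(fm, gr) == []


class TestFisherExact:
    def test_degenerate_2x2_hand_enumeration(self):
        p = enrichment.fisher_exact_2xc(np.array([2, 0]), np.array([2, 2]))
        assert p == pytest.approx(1 / 3)

    def test_identical_columns_give_p_one(self):
        p = enrichment.fisher_exact_2xc(np.array([2, 2, 2]),
                                        np.array([4, 4, 4]))
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_brute_force_for_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(1, 5, size=3)
        while sizes.sum() > 12:
            sizes = rng.integers(1, 5, size=3)
        carriers = np.array([rng.integers(0, n + 1) for n in sizes])
        p = enrichment.fisher_exact_2xc(carriers, sizes)
        assert p == pytest.approx(brute_force_fisher(list(carriers),
                                                     list(sizes)), abs=1e-12)

    def test_matches_scipy_on_2x2(self):
        from scipy.stats import fisher_exact

        carriers, sizes = np.array([8, 2]), np.array([12, 10])
        p = enrichment.fisher_exact_2xc(carriers, sizes)
        table = [[8, 2], [12 - 8, 10 - 2]]
        assert p == pytest.approx(fisher_exact(table)[1], rel=1e-9)

    def test_total_above_cap_rejected(self):
        with pytest.raises(ValueError, match="Monte-Carlo"):
            enrichment.fisher_exact_2xc(
                np.array([10, 10]), np.array([4000, 4000]))


class TestPermutationPosthoc:
    def test_constant_presence_guard_returns_one(self):
        gr = groups_series(2, 2, 2)
        pres = pd.Series(True, index=gr.index)
        assert enrichment.permutation_posthoc(pres, gr) == 1.0

    def test_perfect_separation_four_genomes(self):
        gr = groups_series(2, 2, 0)
        pres = pd.Series([1, 1, 0, 0], index=gr.index).astype(bool)
        p = enrichment.permutation_posthoc(
            pres, gr, PermutationSpec(n_perm=2000, seed=0))
        # T_obs = 1 is maximal; nothing strictly exceeds it
        assert p == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_inc, n_dec, n_nei = 3, 3, 4
        gr = groups_series(n_inc, n_dec, n_nei)
        x = rng.random(10) < 0.4
        if x.all() or not x.any():
            x[0] = ~x[0]
        pres = pd.Series(x, index=gr.index)
        p_exact = exhaustive_perm_p(x.astype(float), n_inc, n_dec)
        n_perm = 4000
        p_mc = enrichment.permutation_posthoc(
            pres, gr, PermutationSpec(n_perm=n_perm, seed=seed + 100))
        se = np.sqrt(max(p_exact * (1 - p_exact), 1e-6) / n_perm)
        assert abs(p_mc - p_exact) <= 3 * se + 1e-3

    def test_seed_reproducibility_and_modes(self):
        gr = groups_series(5, 5, 10)
        rng = np.random.default_rng(1)
        pres = pd.Series(rng.random(20) < 0.5, index=gr.index)
        spec = PermutationSpec(n_perm=500, seed=9)
        assert enrichment.permutation_posthoc(pres, gr, spec) == \
            enrichment.permutation_posthoc(pres, gr, spec)
        indep = PermutationSpec(n_perm=500, seed=9, draw_mode="independent")
        assert 0 <= enrichment.permutation_posthoc(pres, gr, indep) <= 1

    def test_oversized_groups_rejected(self):
        gr = pd.Series(["Increase", "Decrease"], index=["a", "b"])
        pres = pd.Series([True, False], index=["a", "b"])
        # fine at the boundary (n_inc + n_dec == n_tot)
        enrichment.permutation_posthoc(pres, gr,
                                       PermutationSpec(n_perm=10, seed=0))


class TestCascade:
    def _planted(self, seed=0, mult=6.0):
        rng = np.random.default_rng(seed)
        gr = groups_series(60, 60, 80)
        base = 0.25
        odds = base / (1 - base) * mult
        lifted = odds / (1 + odds)
        rates = np.where(gr == "Increase", lifted, base)
        fm = pd.DataFrame(
            {
                "planted": rng.random(200) < rates,
                "null_a": rng.random(200) < 0.3,
                "null_b": rng.random(200) < 0.15,
            },
            index=gr.index,
        )
        return fm, gr

    def test_planted_category_is_significant(self):
        fm, gr = self._planted()
        res = enrichment.enrichment_cascade(
            fm, gr, PermutationSpec(n_perm=5000, seed=1))
        assert bool(res.table.loc["planted", "significant"])
        assert res.table.loc["planted", "enriched_group"] == "Increase"

    def test_gate_blocks_posthoc(self):
        fm, gr = self._planted()
        res = enrichment.enrichment_cascade(
            fm, gr, PermutationSpec(n_perm=1000, seed=1))
        gated_out = res.table["fisher_fdr"] > 0.1
        assert res.table.loc[gated_out, "perm_p"].isna().all()
        assert not res.table.loc[gated_out, "significant"].any()

    def test_never_significant_without_gate(self):
        fm, gr = self._planted(seed=3, mult=1.0)
        res = enrichment.enrichment_cascade(
            fm, gr, PermutationSpec(n_perm=1000, seed=2))
        sig = res.table["significant"]
        assert (res.table.loc[sig, "fisher_fdr"] <= 0.1).all()
        assert (res.table.loc[sig, "perm_fdr"] <= 0.05).all()


class TestDiversityContrast:
    def test_identical_groups_are_null(self):
        gr = groups_series(5, 5, 5)
        vals = pd.DataFrame({"m": list(range(5)) * 3}, index=gr.index,
                            dtype=float)
        res = enrichment.diversity_contrast(vals, gr)
        assert res.loc["m", "kw_p"] > 0.5
        assert not res.loc["m", "significant"]

    def test_constant_metric_returns_h_zero(self):
        gr = groups_series(4, 4, 4)
        vals = pd.DataFrame({"m": [3.0] * 12}, index=gr.index)
        res = enrichment.diversity_contrast(vals, gr)
        assert res.loc["m", "kw_H"] == 0.0
        assert res.loc["m", "kw_p"] == 1.0

    def test_complete_separation_exact_rank_sum_p(self):
        """Fully separated Increase and Decrease (n = 10 vs 10) give the
        minimal exact two-sided rank-sum p = 2 / C(20, 10)."""
        gr = groups_series(10, 10, 10)
        vals = pd.DataFrame(
            {"m": list(range(100, 110)) + list(range(10))
             + list(range(50, 60))},
            index=gr.index, dtype=float,
        )
        res = enrichment.diversity_contrast(vals, gr)
        assert res.loc["m", "kw_fdr"] <= 0.1
        assert res.loc["m", "wilcoxon_p"] == \
            pytest.approx(2 / math.comb(20, 10))

    def test_monotone_transform_invariance(self):
        gr = groups_series(6, 6, 6)
        rng = np.random.default_rng(7)
        vals = pd.DataFrame({"m": rng.random(18) * 10}, index=gr.index)
        a = enrichment.diversity_contrast(vals, gr)
        b = enrichment.diversity_contrast(np.exp(vals / 3), gr)
        assert a["kw_p"].equals(b["kw_p"])
        assert a["wilcoxon_p"].equals(b["wilcoxon_p"])


class TestSpearman:
    def test_monotone_pair_is_one(self):
        fm = pd.DataFrame({"a": [1, 2, 3, 5], "b": [2, 4, 9, 11]})
        rho, _, _ = enrichment.cooccurrence_spearman(fm)
        assert rho.loc["a", "b"] == pytest.approx(1.0)

    def test_reversed_vector_is_minus_one(self):
        fm = pd.DataFrame({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]})
        rho, _, _ = enrichment.cooccurrence_spearman(fm)
        assert rho.loc["a", "b"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_rank_pearson_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        fm = pd.DataFrame(rng.integers(0, 4, size=(8, 3)),
                          columns=["a", "b", "c"])
        if fm.std().min() == 0:
            fm.iloc[0] += 1
        rho, _, _ = enrichment.cooccurrence_spearman(fm)
        ra = rank_with_ties(fm["a"])
        rb = rank_with_ties(fm["b"])
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert rho.loc["a", "b"] == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_masked(self):
        fm = pd.DataFrame({"a": [1, 2, 3, 4], "b": [5, 5, 5, 5]})
        rho, fdr, mask = enrichment.cooccurrence_spearman(fm)
        assert np.isnan(rho.loc["a", "b"])
        assert not mask.loc["a", "b"]

    def test_too_few_genomes_rejected(self):
        with pytest.raises(ValueError):
            enrichment.cooccurrence_spearman(pd.DataFrame({"a": [1, 2]}))


class TestProteomics:
    def test_sparse_functions_dropped(self):
        spectra = pd.DataFrame(
            [[3, 3, 3, 3, 3, 0], [1, 1, 1, 1, 0, 0]],
            index=["kept", "dropped"],
        )
        out = enrichment.proteomics_summary(spectra)
        assert list(out.index) == ["kept"]

    def test_uniform_counts_share_rank(self):
        spectra = pd.DataFrame(np.full((3, 6), 4.0),
                               index=["f1", "f2", "f3"])
        out = enrichment.proteomics_summary(spectra)
        assert np.allclose(out["mean_rank"], 2.0)  # average of ranks 1..3

    def test_rank_one_is_most_abundant(self):
        spectra = pd.DataFrame(
            [[50, 60, 70, 80, 90], [5, 6, 7, 8, 9], [20, 21, 22, 23, 24]],
            index=["big", "small", "mid"],
        )
        out = enrichment.proteomics_summary(spectra)
        assert out.loc["big", "mean_rank"] == 1.0
        assert list(out.index) == ["big", "mid", "small"]

    def test_hypergeometric_hand_value(self):
        p = enrichment.ko_overrepresentation(4, 5, 4, 10)
        assert p == pytest.approx(6 / 252)

    def test_invalid_universe_rejected(self):
        with pytest.raises(ValueError):
            enrichment.ko_overrepresentation(1, 11, 5, 10)
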