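"""NB-GLM engine: size factors, BH, LRT, depth slopes, Wald contrasts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from metacomm import diffabund, synthetic


class TestSizeFactors:
    def test_doubled_sample_has_double_factor(self):
        rng = np.random.default_rng(0)
        a = rng.integers(5, 100, size=30).astype(float)
        counts = pd.DataFrame({"A": a, "B": 2 * a, "C": a})
        s = diffabund.size_factors(counts)
        assert s["B"] / s["A"] == pytest.approx(2.0)

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"A": [3, 7, 9], "B": [3, 7, 9]})
        assert np.allclose(diffabund.size_factors(counts), 1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 50, size=(20, 4)),
                              columns=list("ABCD"))
        s = diffabund.size_factors(counts)
        s_perm = diffabund.size_factors(counts[["C", "A", "D", "B"]])
        assert np.allclose(s[["C", "A", "D", "B"]], s_perm)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 200, size=(50, 6)))
        s = diffabund.size_factors(counts)
        assert np.exp(np.mean(np.log(s))) == pytest.approx(1.0)

    def test_sparse_table_needs_explicit_fallback(self):
        counts = pd.DataFrame({"A": [0, 5], "B": [5, 0]})
        with pytest.raises(ValueError, match="pseudo_reference"):
            diffabund.size_factors(counts)
        s = diffabund.size_factors(counts, pseudo_reference=True)
        assert (s > 0).all()


class TestBhFdr:
    def test_stepup_hand_example(self):
        q = diffabund.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_and_degenerate_vectors(self):
        assert diffabund.bh_fdr([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(diffabund.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_nan_passthrough_and_reduced_m(self):
        q = diffabund.bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # m = 2, not 3: q = (0.02, 0.04)
        assert q[0] == pytest.approx(0.02)
        assert q[2] == pytest.approx(0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diffabund.bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_statsmodels_and_is_monotone(self, pvals):
        q = diffabund.bh_fdr(pvals)
        q_ref = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(q, q_ref)
        order = np.argsort(pvals)
        assert (np.diff(np.array(q)[order]) >= -1e-12).all()
        assert (q >= np.asarray(pvals) - 1e-12).all()


def _null_community(n_sg, seed):
    params = synthetic.CommunitySimParams(
        n_sg=n_sg, frac_depth_responsive=0.0, frac_treat_responsive=0.0,
        seed=seed,
    )
    return synthetic.simulate_community(params)


class TestNbLrt:
    def test_all_zero_feature_gets_nan_p(self, small_community):
        tables, design = (small_community["tables"],
                          small_community["design"])
        counts = tables["read_counts"].iloc[:5].copy()
        counts.iloc[0] = 0
        res = diffabund.nb_lrt(counts, design)
        assert np.isnan(res.table.iloc[0]["p"])
        assert res.table.iloc[1:]["p"].notna().all()

    def test_statistic_nonnegative_and_df_matches(self, small_community):
        tables, design = (small_community["tables"],
                          small_community["design"])
        res = diffabund.nb_lrt(tables["read_counts"].iloc[:8], design)
        ok = res.table.dropna(subset=["statistic"])
        assert (ok["statistic"] >= 0).all()
        # depth has 3 levels: the full design adds 2 columns
        assert len(res.design_full) - len(res.design_reduced) == 2

    def test_poisson_limit_equals_deviance_difference(self, small_community):
        """At dispersion -> 0 the NB LRT statistic is the Poisson deviance
        difference between reduced and full fits."""
        tables, design = (small_community["tables"],
                          small_community["design"])
        design = design.set_index("sample_id").loc[
            tables["read_counts"].columns].reset_index()
        y = tables["read_counts"].iloc[3].to_numpy(dtype=float)
        X_full, _ = diffabund.design_matrix(
            design, ["replicate", "time_point", "treat_control", "depth"])
        X_red, _ = diffabund.design_matrix(
            design, ["replicate", "time_point", "treat_control"])
        offset = np.zeros(len(y))
        ll_full = diffabund._nb_llf(y, X_full, offset, 0.0).llf
        ll_red = diffabund._nb_llf(y, X_red, offset, 0.0).llf
        stat = 2 * (ll_full - ll_red)
        dev_full = sm.GLM(y, X_full, family=sm.families.Poisson(),
                          offset=offset).fit().deviance
        dev_red = sm.GLM(y, X_red, family=sm.families.Poisson(),
                         offset=offset).fit().deviance
        assert stat == pytest.approx(dev_red - dev_full, rel=1e-6)

    def test_non_nested_designs_rejected(self, small_community):
        tables, design = (small_community["tables"],
                          small_community["design"])
        with pytest.raises(ValueError):
            diffabund.nb_lrt(
                tables["read_counts"].iloc[:2], design,
                full_terms=["replicate", "depth"],
                reduced_terms=["time_point"],
            )


class TestDepthDirection:
    def _norm(self, rows, design):
        cols = design["sample_id"]
        return pd.DataFrame(rows, columns=cols)

    def test_doubling_with_depth_is_increase(self, small_community):
        design = small_community["design"]
        depth = design.set_index("sample_id")["depth_cm"]
        vals = 2.0 ** ((depth.to_numpy() - 15) / 10)
        norm = self._norm([vals * 10], design)
        res = diffabund.depth_direction(norm, depth)
        assert res.iloc[0]["direction"] == "Increase"
        assert res.iloc[0]["slope"] > 0

    def test_constant_counts_are_neither(self, small_community):
        design = small_community["design"]
        depth = design.set_index("sample_id")["depth_cm"]
        norm = self._norm([np.full(len(design), 7.0)], design)
        res = diffabund.depth_direction(norm, depth)
        assert res.iloc[0]["slope"] == pytest.approx(0.0)
        assert res.iloc[0]["direction"] == "Neither"

    def test_requires_three_depths(self, small_community):
        design = small_community["design"]
        two = design[design["depth"] != "20-30"]
        depth = two.set_index("sample_id")["depth_cm"]
        norm = pd.DataFrame([np.ones(len(two))], columns=two["sample_id"])
        with pytest.raises(ValueError):
            diffabund.depth_direction(norm, depth)

    def test_planted_signs_recovered(self, small_community):
        tables, design = (small_community["tables"],
                          small_community["design"])
        truth = small_community["truth"]
        res = diffabund.depth_response_groups(
            tables["read_counts"], tables["normalized_coverage"], design)
        inc = set(res.index[res["direction"] == "Increase"])
        dec = set(res.index[res["direction"] == "Decrease"])
        # no sign flips between planted and recovered responders
        assert not inc & set(truth["depth_decrease"])
        assert not dec & set(truth["depth_increase"])
        planted = set(truth["depth_increase"]) | set(truth["depth_decrease"])
        recovered = (inc | dec) & planted
        assert len(recovered) >= 0.8 * len(planted)


class TestTreatmentContrast:
    def test_label_swap_flips_sign(self, small_community):
        tables, design = (small_community["tables"],
                          small_community["design"])
        counts = tables["read_counts"].iloc[:4]
        res = diffabund.treatment_contrast(counts, design, "20cm")
        swapped = design.copy()
        swap = {"treatment": "control", "control": "treatment"}
        swapped["treat_control"] = swapped["treat_control"].map(swap)
        swapped["factor"] = (
            swapped["treat_control"]
            + swapped["depth"].str.split("-").str[1] + "cm"
        )
        res_sw = diffabund.treatment_contrast(counts, swapped, "20cm")
        assert np.allclose(res.table["log_fc"], -res_sw.table["log_fc"],
                           atol=1e-5)

    def test_absent_level_rejected(self, small_community):
        tables, design = (small_community["tables"],
                          small_community["design"])
        with pytest.raises(ValueError):
            diffabund.treatment_contrast(
                tables["read_counts"].iloc[:2], design, "99cm")

    def test_direction_partition(self, small_community):
        tables, design = (small_community["tables"],
                          small_community["design"])
        res = diffabund.treatment_contrast(
            tables["read_counts"].iloc[:12], design, "40cm")
        t = res.table
        sig = t["fdr"] <= 0.05
        assert set(t.loc[sig, "direction"]) <= {"Increase", "Decrease"}
        assert (t.loc[~sig, "direction"] == "Neither").all()
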