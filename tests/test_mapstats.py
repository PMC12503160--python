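import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import oracles
from conftest import flat_atlas
from groovemap.mapstats import (
    fdr_threshold,
    one_sample_t_map,
    paired_t_map,
    rm_anova_map,
    split_entropy,
    split_familiarity,
    summarize_regions,
)


def _const_maps(values, shape=(4, 4)):
    return [np.full(shape, float(v)) for v in values]


class TestOneSampleT:
    def test_closed_form_example(self):
        """Subject values (1, 2, 3) give t = 2 / (1/sqrt(3)) ~ 3.4641, df 2."""
        atlas = flat_atlas((4, 4))
        smap = one_sample_t_map(_const_maps([1, 2, 3]), atlas, q=0.05)
        assert smap.stat[0, 0] == pytest.approx(3.4641016, abs=1e-6)
        assert smap.df == (2.0,)

    def test_all_zero_maps_null(self):
        atlas = flat_atlas((4, 4))
        smap = one_sample_t_map(_const_maps([0, 0, 0, 0]), atlas)
        assert (smap.stat[atlas.mask] == 0).all()
        assert (smap.p[atlas.mask] == 1).all()
        assert smap.n_sig == 0 and smap.n_flagged == 0

    def test_zero_variance_nonzero_mean_sentinel(self):
        atlas = flat_atlas((2, 2))
        smap = one_sample_t_map(_const_maps([1, 1, 1], (2, 2)), atlas)
        assert np.isposinf(smap.stat[atlas.mask]).all()
        assert (smap.p[atlas.mask] == 0).all()
        assert smap.n_flagged == 4

    def test_subject_order_invariance(self, rng):
        atlas = flat_atlas((3, 3))
        maps = [rng.normal(size=(3, 3)) for _ in range(6)]
        a = one_sample_t_map(maps, atlas)
        b = one_sample_t_map(maps[::-1], atlas)
        assert np.allclose(a.stat[atlas.mask], b.stat[atlas.mask])

    def test_matches_scipy_oracle(self, rng):
        atlas = flat_atlas((4, 4))
        maps = [rng.normal(size=(4, 4)) for _ in range(5)]
        smap = one_sample_t_map(maps, atlas)
        data = np.stack(maps)
        t_ref, p_ref = stats.ttest_1samp(data, 0.0, axis=0)
        assert np.allclose(smap.stat, t_ref, rtol=1e-12)
        assert np.allclose(smap.p, p_ref, rtol=1e-10)


class TestPairedT:
    def test_identical_collections_zero(self, rng):
        atlas = flat_atlas((3, 3))
        maps = [rng.random((3, 3)) for _ in range(4)]
        smap = paired_t_map(maps, maps, atlas)
        assert (smap.stat[atlas.mask] == 0).all()

    def test_antisymmetry_under_swap(self, rng):
        atlas = flat_atlas((3, 3))
        a = [rng.normal(size=(3, 3)) for _ in range(5)]
        b = [rng.normal(size=(3, 3)) for _ in range(5)]
        ab = paired_t_map(a, b, atlas)
        ba = paired_t_map(b, a, atlas)
        assert np.allclose(ab.stat[atlas.mask], -ba.stat[atlas.mask])
        assert np.array_equal(ab.sig, ba.sig)

    def test_constant_differences_flagged(self):
        atlas = flat_atlas((2, 2))
        a = _const_maps([2, 3, 4, 5], (2, 2))
        b = _const_maps([1, 2, 3, 4], (2, 2))
        smap = paired_t_map(a, b, atlas)
        assert np.isposinf(smap.stat[atlas.mask]).all()
        assert smap.n_flagged == 4

    def test_subject_mismatch_rejected(self, rng):
        atlas = flat_atlas((2, 2))
        maps = [rng.random((2, 2)) for _ in range(3)]
        with pytest.raises(ValueError, match="match"):
            paired_t_map(maps, maps, atlas,
                         subjects_a=["p1", "p2", "p3"], subjects_b=["p1", "p3", "p2"])


class TestRmAnova:
    def test_constant_cells_give_null_maps(self):
        atlas = flat_atlas((2, 2))
        cell_maps = {
            (s, a, b): np.full((2, 2), 0.4)
            for s in range(4)
            for a in ("m", "p")
            for b in ("f", "j", "r")
        }
        res = rm_anova_map(cell_maps, {"comp": ["m", "p"], "genre": ["f", "j", "r"]}, atlas)
        for smap in res.values():
            assert (smap.stat[atlas.mask] == 0).all()
            assert smap.n_sig == 0

    def test_toy_table_matches_brute_force_and_pingouin(self):
        """Single pixel, n=4, 2x3 design: F values equal an independent
        sums-of-squares computation and pingouin's rm_anova."""
        data = np.array(
            [
                [[2.0, 3.0, 4.0], [1.0, 2.0, 2.0]],
                [[3.0, 4.0, 5.0], [2.0, 3.0, 3.0]],
                [[2.5, 3.0, 3.5], [1.5, 2.0, 2.5]],
                [[3.0, 5.0, 4.0], [2.0, 4.0, 3.0]],
            ]
        )  # [n=4, a=2, b=3]
        atlas = flat_atlas((1, 1))
        cell_maps = {
            (s, a, b): np.full((1, 1), data[s, i, j])
            for s in range(4)
            for i, a in enumerate(["m", "p"])
            for j, b in enumerate(["f", "j", "r"])
        }
        res = rm_anova_map(cell_maps, {"comp": ["m", "p"], "genre": ["f", "j", "r"]}, atlas)
        ref = oracles.rm_anova_2way(data)
        for key, name in [("comp", "A"), ("genre", "B"), ("comp:genre", "A:B")]:
            F_ref, df1, df2 = ref[name]
            assert res[key].stat[0, 0] == pytest.approx(F_ref, rel=1e-12)
            assert res[key].df == (float(df1), float(df2))

        pg = pytest.importorskip("pingouin")
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(4), 6),
                "comp": np.tile(np.repeat(["m", "p"], 3), 4),
                "genre": np.tile(["f", "j", "r"], 8),
                "y": data.reshape(-1),
            }
        )
        tab = pg.rm_anova(data=long, dv="y", within=["comp", "genre"],
                          subject="subject", detailed=True)
        for key, source in [("comp", "comp"), ("genre", "genre"),
                            ("comp:genre", "comp * genre")]:
            F_pg = float(tab.loc[tab["Source"] == source, "F"].iloc[0])
            assert res[key].stat[0, 0] == pytest.approx(F_pg, rel=1e-9)

    def test_one_factor_variant_matches_f_oneway_structure(self, rng):
        """One-factor RM F equals the two-factor oracle with a dummy factor."""
        atlas = flat_atlas((2, 2))
        n, a = 5, 3
        vals = rng.normal(size=(n, a, 4))
        cell_maps = {
            (s, lev): vals[s, i].reshape(2, 2)
            for s in range(n)
            for i, lev in enumerate(["lo", "mid", "hi"])
        }
        res = rm_anova_map(cell_maps, {"entropy": ["lo", "mid", "hi"]}, atlas)
        for px in range(4):
            ref = oracles.rm_anova_2way(vals[:, :, px][:, :, None])  # b=1
            assert res["entropy"].stat.reshape(-1)[px] == pytest.approx(
                ref["A"][0], rel=1e-10
            )

    def test_missing_cell_named_in_error(self):
        atlas = flat_atlas((2, 2))
        cell_maps = {
            (s, a): np.zeros((2, 2)) for s in range(3) for a in ("x", "y")
        }
        del cell_maps[(1, "y")]
        with pytest.raises(ValueError, match=r"\(1, 'y'\)"):
            rm_anova_map(cell_maps, {"f": ["x", "y"]}, atlas)


class TestFdr:
    def test_hand_worked_examples(self):
        rej, crit = fdr_threshold(np.array([0.01, 0.02, 0.03, 0.04]), 0.05)
        assert rej.all() and crit == 0.04
        rej, crit = fdr_threshold(np.ones(10), 0.05)
        assert not rej.any() and crit == 0.0
        rej, crit = fdr_threshold(np.array([0.04]), 0.05)
        assert rej.all() and crit == 0.04
        rej, crit = fdr_threshold(np.empty(0), 0.05)
        assert rej.size == 0

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40),
           st.floats(min_value=0.01, max_value=0.2))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_brute_force_and_statsmodels(self, ps, q):
        p = np.array(ps)
        rej, crit = fdr_threshold(p, q)
        ref_rej, ref_crit = oracles.bh_reject(list(p), q)
        assert rej.tolist() == ref_rej
        assert crit == pytest.approx(ref_crit)
        sm_rej = multipletests(p, alpha=q, method="fdr_bh")[0]
        assert rej.tolist() == sm_rej.tolist()

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_rejections_monotone_in_q(self, ps):
        p = np.array(ps)
        prev = np.zeros(len(ps), dtype=bool)
        for q in (0.01, 0.05, 0.10, 0.25):
            rej, _ = fdr_threshold(p, q)
            assert (prev <= rej).all()
            prev = rej


class TestSplits:
    def test_median_split_hand_example(self):
        labels = split_familiarity(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert labels.tolist() == ["low", "low", "high", "high"]

    def test_all_tied_means_warn_all_low(self):
        with pytest.warns(UserWarning, match="tied"):
            labels = split_familiarity(pd.Series([2.0] * 5))
        assert (labels == "low").all()

    def test_twelve_distinct_means_split_evenly(self, rng):
        labels = split_familiarity(pd.Series(rng.permutation(12).astype(float)))
        assert (labels == "low").sum() == 6 and (labels == "high").sum() == 6

    def test_tertiles_balanced_for_twelve(self, rng):
        labels = split_entropy(pd.Series(rng.permutation(12).astype(float)))
        assert labels.value_counts().to_dict() == {"low": 4, "medium": 4, "high": 4}

    def test_three_values_one_per_bin(self):
        labels = split_entropy(pd.Series([0.1, 0.2, 0.3], index=list("abc")))
        assert labels.tolist() == ["low", "medium", "high"]

    def test_remainder_goes_to_middle_and_matches_sort_oracle(self, rng):
        vals = pd.Series(rng.random(100))
        labels = split_entropy(vals)
        order = np.argsort(vals.to_numpy(), kind="stable")
        assert set(order[:33]) == set(np.flatnonzero((labels == "low").to_numpy()))
        assert set(order[-33:]) == set(np.flatnonzero((labels == "high").to_numpy()))
        assert (labels == "medium").sum() == 34

    def test_too_few_stimuli_rejected(self):
        with pytest.raises(ValueError):
            split_familiarity(pd.Series([1.0]))
        with pytest.raises(ValueError):
            split_entropy(pd.Series([0.1, 0.2]))


class TestRegionSummary:
    def test_empty_sig_all_zero(self, small_atlas):
        smap = one_sample_t_map(
            [np.zeros(small_atlas.dims) for _ in range(3)], small_atlas
        )
        table = summarize_regions(smap, small_atlas)
        assert (table["n_sig"] == 0).all()

    def test_head_only_significance(self, small_atlas):
        head = small_atlas.region_mask("head")
        maps = [np.where(head, 0.5 + 0.01 * i, 0.0) for i in range(6)]
        smap = one_sample_t_map(maps, small_atlas)
        table = summarize_regions(smap, small_atlas).set_index("region")
        assert table.loc["head", "frac_sig"] == 1.0
        others = table.drop("head")
        assert (others["n_sig"] == 0).all()

    def test_planted_regions_rank_first(self, small_atlas, rng):
        arms = small_atlas.region_mask("arms")
        legs = small_atlas.region_mask("legs")
        signal = arms | legs
        maps = [
            np.where(signal, 1.0, 0.0) + rng.normal(0, 0.05, small_atlas.dims)
            for _ in range(8)
        ]
        maps = [np.where(small_atlas.mask, m, 0.0) for m in maps]
        smap = one_sample_t_map(maps, small_atlas, q=0.001)
        table = summarize_regions(smap, small_atlas)
        assert set(table.head(2)["region"]) == {"arms", "legs"}
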