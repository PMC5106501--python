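import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliamorph import (
    InputError,
    compare_groups,
    ddct_fold,
    kendall_tau_b,
    kruskal_dunn,
    ks_normality,
    mann_whitney,
)


def _mw_enumeration_oracle(x, y):
    """Brute-force two-sided Mann-Whitney p by relabelling raw values."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_of(a, b):
        return sum(
            (ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b
        )

    mu = n1 * len(y) / 2.0
    u_obs = u_of(x, y)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_of(a, b) - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return u_obs, hits / total


class TestMannWhitney:
    def test_separated_pairs_exact(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 6), min_size=2, max_size=5),
        st.lists(st.integers(0, 6), min_size=2, max_size=5),
    )
    def test_exact_branch_matches_enumeration(self, x, y):
        u, p = mann_whitney(x, y)
        u_ref, p_ref = _mw_enumeration_oracle(x, y)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref)

    def test_identical_groups_maximal_p(self):
        _, p = mann_whitney([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_asymptotic_branch_reasonable(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(2, 1, 30)
        _, p = mann_whitney(x, y)
        assert p < 1e-6


class TestKruskalDunn:
    def test_two_groups_reduces_to_mann_whitney(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(1, 1, 12)
        _, p_kw, _ = kruskal_dunn({"a": x, "b": y})
        _, p_mw = mann_whitney(x, y)
        # chi-square KW with 2 groups equals the two-sided normal MW test
        # without continuity correction; allow the cc difference
        assert p_kw == pytest.approx(p_mw, abs=0.02)

    def test_adjusted_p_bounded(self, rng):
        groups = {g: rng.normal(i, 1, 10) for i, g in enumerate("abc")}
        _, _, pairwise = kruskal_dunn(groups, adjust="bonferroni")
        _, _, raw = kruskal_dunn(groups, adjust="none")
        assert (pairwise["p_adj"] >= raw["p_adj"] - 1e-12).all()
        assert (pairwise["p_adj"] <= 1.0).all()

    def test_holm_between_none_and_bonferroni(self, rng):
        groups = {g: rng.normal(i / 2, 1, 8) for i, g in enumerate("abcd")}
        _, _, bon = kruskal_dunn(groups, adjust="bonferroni")
        _, _, holm = kruskal_dunn(groups, adjust="holm")
        _, _, raw = kruskal_dunn(groups, adjust="none")
        assert (holm["p_adj"] <= bon["p_adj"] + 1e-12).all()
        assert (holm["p_adj"] >= raw["p_adj"] - 1e-12).all()


class TestKendallTauB:
    def test_monotone_pairs(self):
        tau, _ = kendall_tau_b([1, 2, 3, 4], [10, 20, 30, 40])
        assert tau == 1.0
        tau, _ = kendall_tau_b([1, 2, 3, 4], [40, 30, 20, 10])
        assert tau == -1.0

    def test_single_swap(self):
        tau, p = kendall_tau_b([1, 2, 3, 4], [1, 3, 2, 4])
        assert tau == pytest.approx(4 / 6)
        assert p == pytest.approx(1 / 3)

    def test_matches_scipy_with_ties(self, rng):
        from scipy.stats import kendalltau

        x = rng.integers(0, 4, 7).astype(float)
        y = rng.integers(0, 4, 7).astype(float)
        if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        tau, _ = kendall_tau_b(x, y)
        assert tau == pytest.approx(kendalltau(x, y, variant="b").statistic)

    def test_all_tied_undefined(self):
        with pytest.raises(InputError):
            kendall_tau_b([1, 1, 1], [2, 3, 4])

    def test_large_n_uses_normal_approximation(self, rng):
        x = np.arange(50.0)
        y = x + rng.normal(0, 5, 50)
        tau, p = kendall_tau_b(x, y)
        assert 0.5 < tau <= 1.0
        assert p < 1e-6


class TestKsNormality:
    def test_too_small_sample_rejected(self):
        with pytest.raises(InputError):
            ks_normality([1.0, 2.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            ks_normality([3.0, 3.0, 3.0, 3.0])

    def test_bimodal_sample_rejected_strongly(self, rng):
        x = np.concatenate([rng.normal(-3, 0.3, 100), rng.normal(3, 0.3, 100)])
        assert ks_normality(x, rng=rng) < 0.01

    def test_null_p_roughly_uniform(self, rng):
        ps = [ks_normality(rng.normal(size=25), n_boot=400, rng=rng) for _ in range(150)]
        # type-I calibration at the 10% level
        assert np.mean(np.array(ps) < 0.10) == pytest.approx(0.10, abs=0.06)


class TestCompareGroups:
    def test_small_group_rejected(self):
        with pytest.raises(InputError):
            compare_groups({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})

    def test_forced_nonparametric_two_groups(self):
        res = compare_groups({"a": [1, 2, 5], "b": [3, 4, 6]}, force="nonparametric")
        assert res.method == "mann_whitney"
        assert res.pairwise is None

    def test_normal_data_takes_parametric_branch(self, rng):
        g = {k: rng.normal(i, 1, 20) for i, k in enumerate("ab")}
        res = compare_groups(g, rng=np.random.default_rng(1))
        assert res.method == "t_test"

    def test_skewed_data_takes_nonparametric_branch(self, rng):
        g = {k: np.exp(rng.normal(0, 1.2, 60)) for k in "ab"}
        res = compare_groups(g, rng=np.random.default_rng(1))
        assert res.method == "mann_whitney"

    def test_three_groups_produce_pairwise_table(self, rng):
        g = {k: rng.normal(i, 1, 12) for i, k in enumerate("abc")}
        res = compare_groups(g, rng=np.random.default_rng(1))
        assert res.method in ("anova_tukey", "kruskal_dunn")
        assert len(res.pairwise) == 3

    def test_dataframe_input_with_variable_filter(self, rng):
        df = pd.DataFrame(
            {
                "group": ["a"] * 5 + ["b"] * 5,
                "variable": ["load"] * 10,
                "value": rng.normal(size=10),
            }
        )
        res = compare_groups(df, variable="load", force="nonparametric")
        assert res.method == "mann_whitney"


def test_plot_groups_renders_axes(rng):
    import matplotlib

    matplotlib.use("Agg")
    from gliamorph import plot_groups

    g = {"a": rng.normal(size=8), "b": rng.normal(1, 1, 8)}
    res = compare_groups(g, force="nonparametric")
    ax = plot_groups(g, variable="loading", comparison=res)
    assert len(ax.get_xticklabels()) == 2
    assert "p =" in ax.get_title()


class TestDdctFold:
    @pytest.fixture
    def records(self):
        return pd.DataFrame(
            {
                "sample_id": list(range(6)),
                "group": ["Braak0"] * 3 + ["BraakV_VI"] * 3,
                "Ct_target": [20.0, 21.0, 22.0, 19.0, 18.5, 20.0],
                "Ct_housekeeper": [15.0] * 6,
            }
        )

    def test_reference_mean_gives_fold_one(self, records):
        out = ddct_fold(records, "Braak0")
        ref_mean_dct = out.loc[out.group == "Braak0", "delta_Ct"].mean()
        row = out.iloc[1]  # delta_Ct == 6 == reference mean
        assert row["delta_Ct"] == ref_mean_dct
        assert row["fold"] == pytest.approx(1.0)

    def test_fold_halves_and_quadruples(self, records):
        out = ddct_fold(records, "Braak0")
        assert np.allclose(out["fold"], 2.0 ** (-out["delta_delta_Ct"]))
        # ddCt = +1 -> fold 0.5; ddCt = -2 -> fold 4
        assert 2.0 ** (-1.0) == 0.5 and 2.0 ** (2.0) == 4.0

    def test_reference_geometric_mean_is_exactly_one(self, records):
        out = ddct_fold(records, "Braak0")
        ref = out.loc[out.group == "Braak0", "fold"]
        assert np.exp(np.log(ref).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_missing_reference_group_rejected(self, records):
        with pytest.raises(InputError):
            ddct_fold(records, "Braak9000")

    def test_missing_housekeeper_rejected(self, records):
        records.loc[0, "Ct_housekeeper"] = np.nan
        with pytest.raises(InputError):
            ddct_fold(records, "Braak0")

    def test_per_gene_referencing(self, records):
        records["gene"] = ["CD68", "CD68", "CD68", "CD68", "CD68", "CD68"]
        out = ddct_fold(records, "Braak0")
        assert "fold" in out.columns
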