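import numpy as np
import pandas as pd
import pytest

from refstab import (
    RQMatrix,
    bestkeeper_stability,
    delta_ct_stability,
    genorm_m_values,
    genorm_pairwise_variation,
    genorm_rank,
    normfinder_stability,
)
from refstab.errors import DomainError, InsufficientDataError
from refstab.stability import rank_ascending

from conftest import make_ct, make_rq
import oracles


def _random_rq(rng, n_genes=5, n_samples=6):
    vals = {f"g{i}": np.power(2.0, rng.normal(0, 1, n_samples)) for i in range(n_genes)}
    vals = {g: v / v.max() for g, v in vals.items()}
    return make_rq({g: list(v) for g, v in vals.items()})


class TestGenormM:
    def test_hand_computed_three_genes(self, rq_abc):
        m = genorm_m_values(rq_abc)
        assert m["A"] == pytest.approx(np.sqrt(2) / 2, abs=1e-10)
        assert m["B"] == pytest.approx(np.sqrt(2) / 2, abs=1e-10)
        assert m["C"] == pytest.approx(np.sqrt(2), abs=1e-10)

    def test_proportional_genes_have_zero_m(self):
        rq = make_rq({"A": [1, 0.3, 0.7], "B": [0.5, 0.15, 0.35]})
        m = genorm_m_values(rq)
        assert np.allclose(m, 0.0, atol=1e-12)

    def test_matches_brute_force(self, rng):
        rq = _random_rq(rng)
        m = genorm_m_values(rq)
        brute = oracles.genorm_m_brute(
            {g: dict(rq.values.loc[g]) for g in rq.values.index}
        )
        for g in rq.values.index:
            assert m[g] == pytest.approx(brute[g], abs=1e-10)

    def test_two_gene_m_equals_pairwise_sd(self):
        rq = make_rq({"A": [1, 0.5, 0.7], "B": [1, 0.25, 0.9]})
        m = genorm_m_values(rq)
        v_ab = np.std(np.log2(rq.values.loc["A"] / rq.values.loc["B"]), ddof=1)
        assert m["A"] == pytest.approx(v_ab, abs=1e-12)
        assert m["B"] == pytest.approx(v_ab, abs=1e-12)

    def test_nonpositive_rq_rejected(self):
        with pytest.raises(DomainError):
            make_rq({"A": [1, -0.5], "B": [1, 0.5]})

    def test_single_sample_insufficient(self):
        rq = make_rq({"A": [1.0], "B": [1.0]})
        with pytest.raises(InsufficientDataError):
            genorm_m_values(rq)


class TestGenormRank:
    def test_three_gene_elimination_and_finalist_ranks(self, rq_abc):
        res = genorm_rank(rq_abc)
        assert res.extras["elimination_order"] == ["C"]
        assert res.ranks.to_dict() == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_finalists_can_be_ordered_instead(self, rq_abc):
        res = genorm_rank(rq_abc, finalists_rank_one=False)
        assert sorted(res.ranks) == [1.0, 2.0, 3.0]

    def test_noisy_gene_eliminated_first(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            base = rng.normal(0, 1, 8)
            vals = {f"g{i}": np.power(2.0, base) for i in range(3)}
            vals["noisy"] = np.power(2.0, base + rng.normal(0, 1.0, 8))
            rq = make_rq({g: list(v / v.max()) for g, v in vals.items()})
            if genorm_rank(rq).extras["elimination_order"][0] == "noisy":
                hits += 1
        assert hits >= 95

    def test_identical_profiles_tie_break_deterministic(self):
        rq = make_rq({g: [1, 0.5, 0.25] for g in ["A", "B", "C", "D"]})
        res = genorm_rank(rq)
        # all M tie at 0; lexicographically greatest eliminated first
        assert res.extras["elimination_order"] == ["D", "C"]
        assert res.extras["finalists"] == ["A", "B"]


class TestPairwiseVariation:
    def test_identical_top_genes_give_zero_v(self):
        rq = make_rq({g: [1, 0.5, 0.25] for g in ["A", "B", "C"]})
        v = genorm_pairwise_variation(rq, ["A", "B", "C"])
        assert v["V2/3"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_v23(self, rq_abc):
        v = genorm_pairwise_variation(rq_abc, ["A", "B", "C"])
        brute = oracles.genorm_v_brute(
            {g: dict(rq_abc.values.loc[g]) for g in "ABC"}, ["A", "B", "C"]
        )
        assert v["V2/3"] == pytest.approx(brute[2], abs=1e-10)
        assert v["V2/3"] == pytest.approx(0.4714, abs=5e-5)

    def test_coregulated_extra_gene_leaves_v_unchanged(self, rng):
        rq = _random_rq(rng, n_genes=3)
        v3 = genorm_pairwise_variation(rq, list(rq.values.index))
        # a 4th gene proportional to gene 0 changes NF ratios beyond n=3 only
        vals = {g: list(rq.values.loc[g]) for g in rq.values.index}
        vals["g3"] = list(rq.values.loc["g0"] * 0.5)
        rq4 = make_rq(vals)
        v4 = genorm_pairwise_variation(rq4, ["g0", "g1", "g2", "g3"])
        assert v4["V2/3"] == pytest.approx(v3["V2/3"], abs=1e-12)


class TestNormFinder:
    def test_perfectly_additive_matrix_is_zero(self):
        y = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["A", "B"])
        res = normfinder_stability(y)
        assert np.allclose(res.values, 0.0, atol=1e-12)

    def test_gene_tracking_sample_mean_is_zero(self, rng):
        # a gene equal to the mean profile of the others also equals the
        # column means of the full matrix, so its residuals vanish exactly
        y = pd.DataFrame(rng.normal(0, 1, (4, 6)), index=list("ABCD"))
        y.loc["E"] = y.mean(axis=0)
        res = normfinder_stability(y)
        assert res.values["E"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        y = pd.DataFrame(rng.normal(20, 2, (5, 7)), index=[f"g{i}" for i in range(5)])
        res = normfinder_stability(y)
        brute = oracles.normfinder_brute({g: dict(y.loc[g]) for g in y.index})
        for g in y.index:
            assert res.values[g] == pytest.approx(brute[g], abs=1e-10)

    def test_noisy_gene_has_largest_stability(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sample_effect = rng.normal(0, 1, 10)
            y = pd.DataFrame(
                [sample_effect + rng.normal(0, 0.2, 10) for _ in range(5)],
                index=[f"g{i}" for i in range(5)],
            )
            y.loc["noisy"] = sample_effect + rng.normal(0, 1.0, 10)
            if normfinder_stability(y).values.idxmax() == "noisy":
                hits += 1
        assert hits >= 95

    def test_bias_corrected_orders_like_plain(self, rng):
        y = pd.DataFrame(rng.normal(0, 1, (6, 8)), index=[f"g{i}" for i in range(6)])
        plain = normfinder_stability(y)
        corr = normfinder_stability(y, bias_corrected=True)
        assert corr.extras["bias_corrected"]
        # the corrected variance is an increasing affine map of the plain one,
        # so the ranking is unchanged
        pd.testing.assert_series_equal(corr.ranks, plain.ranks)
        # direct recomputation of the unbiased estimator
        k, n = y.shape
        z = plain.values**2
        s_total = z.sum() * k / (k - 1)
        expect = np.sqrt(np.maximum((z - s_total / k**2) * k / (k - 2), 0.0))
        assert np.allclose(corr.values, expect, atol=1e-12)

    def test_grouped_mode_flags_inter_group_shift(self, rng):
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=[f"s{i}" for i in range(8)])
        y = pd.DataFrame(
            rng.normal(0, 0.1, (4, 8)),
            index=[f"g{i}" for i in range(4)],
            columns=groups.index,
        )
        y.loc["shifted"] = np.r_[rng.normal(0, 0.1, 4), rng.normal(3, 0.1, 4)]
        res = normfinder_stability(y, groups=groups)
        assert res.extras["mode"] == "grouped-simplified"
        assert res.values.idxmax() == "shifted"

    def test_incomplete_matrix_rejected(self):
        y = pd.DataFrame([[1.0, np.nan], [3.0, 4.0]], index=["A", "B"])
        with pytest.raises(DomainError):
            normfinder_stability(y)


class TestBestKeeper:
    def test_hand_computed_descriptives(self):
        ct = make_ct({"g": {"s1": 20.0, "s2": 21.0, "s3": 22.0},
                      "h": {"s1": 25.0, "s2": 25.0, "s3": 25.0}})
        res = bestkeeper_stability(ct)
        row = res.extras["table"].loc["g"]
        assert row["mean_ct"] == pytest.approx(21.0)
        assert row["sd"] == pytest.approx(1.0, abs=1e-12)
        assert row["mad"] == pytest.approx(2.0 / 3.0, abs=1e-10)
        assert row["cv_pct"] == pytest.approx(100.0 / 21.0, abs=1e-10)

    def test_constant_gene_is_rank_one(self):
        ct = make_ct({"g": {"s1": 20.0, "s2": 22.0}, "h": {"s1": 25.0, "s2": 25.0}})
        res = bestkeeper_stability(ct)
        assert res.ranks["h"] == 1.0
        assert res.values["h"] == 0.0

    def test_degenerate_all_constant_index(self):
        ct = make_ct({"g": {"s1": 20.0, "s2": 20.0}, "h": {"s1": 20.0, "s2": 20.0}})
        res = bestkeeper_stability(ct)
        assert np.allclose(res.extras["index"], 20.0)
        assert set(res.extras["constant_input"]) == {"g", "h"}
        assert res.extras["table"]["r_vs_index"].isna().all()
        assert (res.ranks == 1.5).all()  # tied SDs still ranked

    def test_matches_brute_force_sd(self, rng):
        vals = {f"g{i}": {f"s{j}": 20 + rng.uniform(0, 5) for j in range(6)} for i in range(4)}
        res = bestkeeper_stability(make_ct(vals))
        brute = oracles.bestkeeper_sd_brute(vals)
        for g in vals:
            assert res.values[g] == pytest.approx(brute[g], abs=1e-10)


class TestDeltaCt:
    def test_hand_computed_three_genes(self):
        ct = make_ct({"g1": {"s1": 20.0, "s2": 20.0},
                      "g2": {"s1": 22.0, "s2": 22.0},
                      "g3": {"s1": 25.0, "s2": 26.0}})
        res = delta_ct_stability(ct)
        assert res.values["g1"] == pytest.approx(np.sqrt(2) / 4, abs=1e-4)
        assert res.values["g2"] == pytest.approx(np.sqrt(2) / 4, abs=1e-4)
        assert res.values["g3"] == pytest.approx(np.sqrt(2) / 2, abs=1e-4)

    def test_per_sample_shift_invariance(self, rng):
        vals = {f"g{i}": {f"s{j}": 20 + rng.uniform(0, 3) for j in range(5)} for i in range(4)}
        res1 = delta_ct_stability(make_ct(vals))
        shifted = {g: {s: v + (2.5 if s == "s2" else 0.0) for s, v in d.items()}
                   for g, d in vals.items()}
        res2 = delta_ct_stability(make_ct(shifted))
        pd.testing.assert_series_equal(res1.values, res2.values)

    def test_matches_brute_force(self, rng):
        vals = {f"g{i}": {f"s{j}": 20 + rng.uniform(0, 5) for j in range(6)} for i in range(4)}
        res = delta_ct_stability(make_ct(vals))
        brute = oracles.delta_ct_brute(vals)
        for g in vals:
            assert res.values[g] == pytest.approx(brute[g], abs=1e-10)


class TestCrossMethod:
    def test_gene_permutation_invariance(self, rng):
        vals = {f"g{i}": {f"s{j}": 20 + rng.uniform(0, 4) for j in range(6)} for i in range(5)}
        ct = make_ct(vals)
        perm = make_ct(dict(reversed(list(vals.items()))))
        for fn in (bestkeeper_stability, delta_ct_stability):
            a, b = fn(ct).values.sort_index(), fn(perm).values.sort_index()
            pd.testing.assert_series_equal(a, b)
        rq = make_rq({g: [d[f"s{j}"] for j in range(6)] for g, d in vals.items()})
        rq_perm = make_rq({g: [vals[g][f"s{j}"] for j in range(6)]
                           for g in reversed(list(vals))})
        pd.testing.assert_series_equal(
            genorm_m_values(rq).sort_index(), genorm_m_values(rq_perm).sort_index()
        )

    def test_delta_ct_and_genorm_agree_at_perfect_efficiency(self, rng):
        """Both are mean pairwise delta-Ct SDs on log2 scale when base = 2."""
        cts = {f"g{i}": {f"s{j}": 20 + rng.uniform(0, 4) for j in range(8)} for i in range(5)}
        dct = delta_ct_stability(make_ct(cts))
        rq_vals = {}
        for g, d in cts.items():
            arr = np.array([d[f"s{j}"] for j in range(8)])
            rq_vals[g] = list(np.power(2.0, arr.min() - arr))
        m = genorm_m_values(make_rq(rq_vals))
        pd.testing.assert_series_equal(
            rank_ascending(dct.values).sort_index(),
            rank_ascending(m).sort_index(),
            check_names=False,
        )
        # identical statistics, not merely identical ranks
        assert np.allclose(dct.values.sort_index(), m.sort_index(), atol=1e-10)

    def test_injected_noise_raises_median_stability_all_methods(self):
        """Adding i.i.d. Ct noise to one gene raises its median stability."""
        base_stab, noisy_stab = {m: [] for m in range(4)}, {m: [] for m in range(4)}
        for seed in range(100):
            rng = np.random.default_rng(seed)
            shared = rng.normal(0, 1, 6)
            cts = {f"g{i}": dict(zip([f"s{j}" for j in range(6)],
                                     22 + shared + rng.normal(0, 0.3, 6)))
                   for i in range(4)}
            noisy = {g: dict(d) for g, d in cts.items()}
            noisy["g0"] = {s: v + rng.normal(0, 1.0) for s, v in cts["g0"].items()}
            for mi, fn in enumerate([delta_ct_stability, bestkeeper_stability]):
                base_stab[mi].append(fn(make_ct(cts)).values["g0"])
                noisy_stab[mi].append(fn(make_ct(noisy)).values["g0"])

            def to_rq(d):
                out = {}
                for g, dd in d.items():
                    arr = np.array([dd[f"s{j}"] for j in range(6)])
                    out[g] = list(np.power(2.0, arr.min() - arr))
                return make_rq(out)

            base_stab[2].append(genorm_m_values(to_rq(cts))["g0"])
            noisy_stab[2].append(genorm_m_values(to_rq(noisy))["g0"])
            base_stab[3].append(normfinder_stability(to_rq(cts).log2()).values["g0"])
            noisy_stab[3].append(normfinder_stability(to_rq(noisy).log2()).values["g0"])
        for mi in range(4):
            assert np.median(noisy_stab[mi]) > np.median(base_stab[mi])
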