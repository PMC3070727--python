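import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from orthocorr import (
    AnalysisConfig,
    adjusted_residuals,
    classify_pairs,
    concordance_percentage,
    consensus_gene_test,
    detection_rate_curves,
    generate_null_labels,
    gsea_null,
    gsea_running_score,
    hypergeom_band,
    proportion_concordance_test,
    ranked_overlap_curve,
)
from orthocorr.stats import ContingencyResult

from conftest import identity_map, make_de_table


# ---------------------------------------------------------------------------
# enumeration oracles
# ---------------------------------------------------------------------------


def hypergeom_pmf_oracle(M, K, n):
    """Hypergeometric pmf by direct combinatorial enumeration."""
    lo = max(0, n - (M - K))
    hi = min(n, K)
    pmf = {}
    denom = math.comb(M, n)
    for x in range(lo, hi + 1):
        pmf[x] = math.comb(K, x) * math.comb(M - K, n - x) / denom
    return pmf


def band_oracle(M, K, n, level=0.95):
    """Equal-tail band from the enumerated pmf."""
    pmf = hypergeom_pmf_oracle(M, K, n)
    xs = sorted(pmf)
    alpha = (1 - level) / 2
    cum = 0.0
    lo = xs[-1]
    for x in xs:
        cum += pmf[x]
        if cum > alpha + 1e-12:
            lo = x
            break
    cum = 0.0
    hi = xs[0]
    for x in reversed(xs):
        cum += pmf[x]
        if cum > alpha + 1e-12:
            hi = x
            break
    return lo, hi


def es_brute(ranking, S):
    """Running-sum enrichment score computed step by step."""
    S = set(S)
    M, s = len(ranking), len(S)
    run, mx, mn = 0.0, 0.0, 0.0
    for g in ranking:
        run += 1.0 / s if g in S else -1.0 / (M - s)
        mx, mn = max(mx, run), min(mn, run)
    return mx if mx >= -mn - 1e-12 else mn


class TestConcordancePercentage:
    @pytest.mark.parametrize(
        "n1,n2,expected",
        [(26, 2, 92.9), (0, 10, 0.0), (56, 72, 43.8), (25, 3, 89.3), (23, 5, 82.1)],
    )
    def test_worked_values(self, n1, n2, expected):
        up, down = concordance_percentage(n1, n2)
        assert up == expected
        assert up + down == pytest.approx(100.0, abs=0.11)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            concordance_percentage(0, 0)


class TestHypergeomBand:
    def test_matches_enumeration(self):
        assert hypergeom_band(20, 10, 6) == band_oracle(20, 10, 6)

    def test_edge_cases(self):
        assert hypergeom_band(10, 5, 0) == (0, 0)
        assert hypergeom_band(10, 0, 4) == (0, 0)
        assert hypergeom_band(10, 10, 4) == (4, 4)

    def test_random_instances_vs_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(150):
            M = int(rng.integers(1, 31))
            K = int(rng.integers(0, M + 1))
            n = int(rng.integers(0, M + 1))
            assert hypergeom_band(M, K, n) == band_oracle(M, K, n), (M, K, n)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            hypergeom_band(10, 11, 5)


class TestProportionConcordance:
    def test_small_instance_matches_enumeration(self):
        # population of 10 mapped mouse transcripts, 5 increased; the human
        # set maps to 4 of them, 3 increased
        human = make_de_table([1.0] * 4, prefix="H")
        lfc = np.array([1, 1, 1, -1, 1, 1, -1, -1, -1, -1], dtype=float)
        mouse = make_de_table(lfc, prefix="M")
        omap = identity_map(
            [f"H{i}" for i in range(10)], [f"M{i}" for i in range(10)]
        )
        res = proportion_concordance_test(
            [f"H{i}" for i in range(4)], omap, mouse, set_label="toy"
        )
        assert (res.n, res.n1, res.n2) == (4, 3, 1)
        assert res.band == band_oracle(10, 5, 4)
        pmf = hypergeom_pmf_oracle(10, 5, 4)
        assert res.p == pytest.approx(sum(v for x, v in pmf.items() if x >= 3))

    def test_all_increased_population(self):
        mouse = make_de_table(np.ones(6), prefix="M")
        omap = identity_map([f"H{i}" for i in range(6)], [f"M{i}" for i in range(6)])
        res = proportion_concordance_test(["H0", "H1"], omap, mouse)
        assert res.n1 == res.n == 2
        assert res.band == (2, 2)
        assert res.p == pytest.approx(1.0)

    def test_empty_mapping_rejected(self):
        mouse = make_de_table(np.ones(3), prefix="M")
        omap = identity_map(["H0"], ["M0"])
        with pytest.raises(ValueError):
            proportion_concordance_test(["H_absent"], omap, mouse)


class TestRankedOverlap:
    def test_identity_rankings_hug_maximum(self):
        lfc = np.linspace(3, -3, 40)
        human = make_de_table(lfc, prefix="H")
        mouse = make_de_table(lfc, prefix="M")
        omap = identity_map([f"H{i}" for i in range(40)], [f"M{i}" for i in range(40)])
        cfg = AnalysisConfig(rank_max=30)
        curve = ranked_overlap_curve(human, mouse, omap, "up", cfg)
        np.testing.assert_array_equal(curve.overlap, curve.ranks)

    def test_band_matches_enumeration_tiny_universe(self):
        rng = np.random.default_rng(10)
        human = make_de_table(rng.normal(size=8), prefix="H")
        mouse = make_de_table(rng.normal(size=8), prefix="M")
        omap = identity_map([f"H{i}" for i in range(8)], [f"M{i}" for i in range(8)])
        cfg = AnalysisConfig(rank_max=3)
        curve = ranked_overlap_curve(human, mouse, omap, "up", cfg, grid=[3])
        lo, hi = band_oracle(8, int(curve.mapped_size[0]), 3)
        assert (curve.band_lo[0], curve.band_hi[0]) == (lo, hi)

    def test_overlap_bounds_and_monotonicity(self, dataset, de_tables):
        human, mouse = de_tables
        cfg = AnalysisConfig(rank_max=2000)
        curve = ranked_overlap_curve(human, mouse, dataset.orthologs, "up", cfg)
        assert (curve.overlap <= np.minimum(curve.mapped_size, curve.ranks)).all()
        assert (np.diff(curve.overlap) >= 0).all()

    def test_rank_max_validation(self):
        human = make_de_table(np.arange(5.0), prefix="H")
        mouse = make_de_table(np.arange(5.0), prefix="M")
        omap = identity_map([f"H{i}" for i in range(5)], [f"M{i}" for i in range(5)])
        with pytest.raises(ValueError, match="rank_max"):
            ranked_overlap_curve(
                human, mouse, omap, "up", AnalysisConfig(rank_max=50)
            )


class TestContingency:
    def test_all_up_up(self):
        labels = pd.Series(
            ["up"] * 4, index=[f"H{i}" for i in range(4)]
        )
        mlabels = pd.Series(["up"] * 4, index=[f"M{i}" for i in range(4)])
        omap = identity_map(list(labels.index), list(mlabels.index))
        res = classify_pairs(labels, mlabels, omap)
        assert res.counts.loc["up", "up"] == 4
        assert res.total == 4

    def test_nine_cell_fixture(self):
        hl, ml = [], []
        for h in ("up", "down", "ns"):
            for m in ("up", "down", "ns"):
                hl.append(h)
                ml.append(m)
        human_labels = pd.Series(hl, index=[f"H{i}" for i in range(9)])
        mouse_labels = pd.Series(ml, index=[f"M{i}" for i in range(9)])
        omap = identity_map(list(human_labels.index), list(mouse_labels.index))
        res = classify_pairs(human_labels, mouse_labels, omap)
        assert (res.counts.to_numpy() == 1).all()

    def test_missing_label_rejected(self):
        human_labels = pd.Series(["up"], index=["H0"])
        mouse_labels = pd.Series([], dtype=object)
        omap = identity_map(["H0"], ["M0"])
        with pytest.raises(ValueError, match="missing label"):
            classify_pairs(human_labels, mouse_labels, omap)


class TestAdjustedResiduals:
    def _contingency(self, arr):
        df = pd.DataFrame(
            np.asarray(arr, dtype=float),
            index=["up", "down", "ns"][: len(arr)],
            columns=["up", "down", "ns"][: len(arr[0])],
        )
        return ContingencyResult(counts=df.reindex(index=["up", "down", "ns"],
                                                   columns=["up", "down", "ns"],
                                                   fill_value=0))

    def test_independent_table_gives_zero(self):
        row = np.array([10, 20, 30])
        col = np.array([6, 14, 40])
        O = np.outer(row, col) / 60.0
        c = self._contingency(O * 10)  # scale keeps exact proportionality
        resid, flags = adjusted_residuals(c)
        np.testing.assert_allclose(resid.to_numpy(), 0.0, atol=1e-10)
        assert not flags.to_numpy().any()

    def test_two_by_two_hand_formula(self):
        # embed a 2x2 table (10, 20; 30, 40) and evaluate the formula by hand
        O = np.array([[10.0, 20.0], [30.0, 40.0]])
        T = O.sum()
        R, C = O.sum(axis=1), O.sum(axis=0)
        E = np.outer(R, C) / T
        hand = (O - E) / np.sqrt(
            E * (1 - R[:, None] / T) * (1 - C[None, :] / T)
        )
        counts = pd.DataFrame(O, index=["up", "down"], columns=["up", "down"])
        c = ContingencyResult(
            counts=counts.reindex(index=["up", "down", "ns"],
                                  columns=["up", "down", "ns"], fill_value=0)
        )
        # margins with an empty ns row/col are degenerate; drop to 2x2
        with pytest.raises(ValueError):
            adjusted_residuals(c)
        # direct 2x2 computation through the same formula path
        c2 = ContingencyResult.__new__(ContingencyResult)
        c2.counts = counts
        resid, _ = adjusted_residuals(c2)
        np.testing.assert_allclose(resid.to_numpy(), hand, atol=1e-12)

    def test_two_by_two_residuals_equal_magnitude(self):
        # algebraic identity: all four adjusted residuals of a 2x2 table
        # share one magnitude with alternating signs
        counts = pd.DataFrame(
            [[37.0, 12.0], [25.0, 44.0]], index=["up", "down"], columns=["up", "down"]
        )
        c = ContingencyResult.__new__(ContingencyResult)
        c.counts = counts
        resid, _ = adjusted_residuals(c)
        r = resid.to_numpy()
        assert abs(r[0, 0]) == pytest.approx(abs(r[0, 1]), abs=1e-10)
        assert abs(r[0, 0]) == pytest.approx(abs(r[1, 0]), abs=1e-10)
        assert r[0, 0] == pytest.approx(-r[0, 1], abs=1e-10)
        assert r[0, 0] == pytest.approx(r[1, 1], abs=1e-10)


class TestDetectionRate:
    def _setup(self, n=300, seed=11):
        rng = np.random.default_rng(seed)
        human = make_de_table(rng.normal(size=n), prefix="H")
        mouse_lfc = rng.normal(size=n)
        mouse_p = rng.uniform(size=n)
        mouse = make_de_table(mouse_lfc, p=mouse_p, prefix="M")
        omap = identity_map([f"H{i}" for i in range(n)], [f"M{i}" for i in range(n)])
        return human, mouse, omap

    def test_extremal_foreground_attains_maximum_area(self):
        human, mouse, omap = self._setup()
        lfc = np.linspace(3, -3, 300)
        human2 = make_de_table(lfc, prefix="H")
        # mouse foreground exactly the top-50 human orthologs, significant
        mouse_p = np.where(np.arange(300) < 50, 0.001, 0.9)
        mouse2 = make_de_table(lfc, p=mouse_p, prefix="M")
        res = detection_rate_curves(human2, mouse2, omap, "up", AnalysisConfig(foreground_size=50))
        # maximal area by direct construction: fg curve reaches 1 at rank 50
        n = 300
        fg_curve = np.minimum(np.arange(1, n + 1) / 50, 1.0)
        bg_set = np.arange(300) >= 50
        order = np.arange(300)
        bg_curve = np.cumsum(bg_set[order]) / bg_set.sum()
        max_area = np.mean(fg_curve - bg_curve)
        assert res.area == pytest.approx(max_area, abs=1e-9)

    def test_null_area_near_zero(self):
        rng = np.random.default_rng(12)
        n = 5000
        human = make_de_table(rng.normal(size=n), prefix="H")
        mouse = make_de_table(
            rng.normal(size=n), p=rng.uniform(size=n), prefix="M"
        )
        omap = identity_map([f"H{i}" for i in range(n)], [f"M{i}" for i in range(n)])
        res = detection_rate_curves(human, mouse, omap, "up")
        assert abs(res.area) < 0.02

    def test_curves_monotone_and_normalized(self):
        human, mouse, omap = self._setup()
        res = detection_rate_curves(human, mouse, omap, "up", AnalysisConfig(foreground_size=30))
        assert res.foreground_curve[-1] == pytest.approx(1.0)
        assert (np.diff(res.foreground_curve) >= 0).all()
        assert (np.diff(res.background_curve) >= 0).all()

    def test_small_foreground_rejected(self):
        human, mouse, omap = self._setup(n=30)
        cfg = AnalysisConfig(foreground_size=200, mouse_alpha=0.001)
        with pytest.raises(ValueError, match="foreground"):
            detection_rate_curves(human, mouse, omap, "up", cfg)


class TestGsea:
    def test_extremal_placements(self):
        ranking = [f"g{i}" for i in range(10)]
        assert gsea_running_score(ranking, ranking[:3]).es == pytest.approx(1.0)
        assert gsea_running_score(ranking, ranking[-3:]).es == pytest.approx(-1.0)

    def test_exhaustive_brute_force_c12_3(self):
        ranking = [f"g{i}" for i in range(12)]
        for S in combinations(ranking, 3):
            es = gsea_running_score(ranking, S).es
            assert es == pytest.approx(es_brute(ranking, S), abs=1e-9), S

    def test_running_score_endpoints(self):
        ranking = [f"g{i}" for i in range(20)]
        res = gsea_running_score(ranking, ranking[5:10])
        assert res.running[-1] == pytest.approx(0.0, abs=1e-12)
        assert abs(res.running).max() == pytest.approx(abs(res.es))

    def test_miss_block_permutation_invariance(self):
        ranking = [f"g{i}" for i in range(15)]
        S = {"g2", "g7", "g11"}
        base = gsea_running_score(ranking, S).es
        # permute misses between consecutive hits
        shuffled = ranking[:3] + ["g5", "g4", "g6", "g3"] + ranking[7:]
        assert gsea_running_score(shuffled, S).es == pytest.approx(base)

    def test_invalid_sets(self):
        ranking = ["a", "b", "c"]
        with pytest.raises(ValueError):
            gsea_running_score(ranking, [])
        with pytest.raises(ValueError):
            gsea_running_score(ranking, ranking)

    def test_null_extremal_p_bound_and_determinism(self):
        ranking = [f"g{i}" for i in range(200)]
        res = gsea_running_score(ranking, ranking[:20])
        null1 = gsea_null(res, n_perm=1000, seed=7)
        null2 = gsea_null(res, n_perm=1000, seed=7)
        assert null1.p == pytest.approx(1.0 / 1001.0)
        assert null1.p == null2.p
        np.testing.assert_array_equal(null1.null_es, null2.null_es)


class TestConsensus:
    @staticmethod
    def _labels(sig_idx, G, name="m"):
        lab = np.array(["ns"] * G, dtype=object)
        lab[list(sig_idx)] = "up"
        return pd.Series(lab, index=[f"g{i}" for i in range(G)])

    def test_null_mean_matches_closed_form(self):
        G = 100
        labels = {
            "m1": self._labels(range(50), G),
            "m2": self._labels(range(50, 100), G),
        }
        res = consensus_gene_test(
            labels, mappable=[f"g{i}" for i in range(G)], n_sim=20000, seed=13
        )
        # E[|A ∩ B|] = m1*m2/G = 25; MC s.e. = sd/sqrt(n)
        mean = res.null_sample.mean()
        se = res.null_sample.std(ddof=1) / np.sqrt(len(res.null_sample))
        assert abs(mean - 25.0) < 3 * se + 1e-9

    def test_zero_observed_p_near_one(self):
        G = 60
        labels = {
            "m1": self._labels(range(10), G),
            "m2": self._labels(range(50, 60), G),
        }
        res = consensus_gene_test(labels, mappable=[], n_sim=2000, seed=14)
        assert res.observed == 0
        assert res.p > 0.95

    def test_planted_consensus_significant(self):
        G = 2000
        rng = np.random.default_rng(15)
        planted = list(range(30))
        labels = {}
        for k in range(6):
            extra = rng.choice(np.arange(30, G), size=170, replace=False)
            labels[f"m{k}"] = self._labels(planted + list(extra), G)
        res = consensus_gene_test(
            labels, mappable=[f"g{i}" for i in range(G)], n_sim=10000, seed=16
        )
        assert res.observed >= 30
        assert res.p <= 0.001

    def test_chain_equals_direct_subset_simulation(self):
        # exactness of the hypergeometric chain against literal subset draws
        G, m = 30, (12, 9, 7)
        rng = np.random.default_rng(17)
        direct = []
        for _ in range(40000):
            sets = [set(rng.choice(G, size=mk, replace=False)) for mk in m]
            direct.append(len(set.intersection(*sets)))
        direct = np.array(direct)
        labels = {
            f"m{k}": self._labels(range(mk), G) for k, mk in enumerate(m)
        }
        res = consensus_gene_test(
            labels, mappable=[f"g{i}" for i in range(G)], n_sim=40000, seed=18
        )
        assert res.null_sample.mean() == pytest.approx(direct.mean(), abs=0.02)
        assert res.null_sample.var() == pytest.approx(direct.var(), rel=0.1)


class TestNullLabels:
    def test_degenerate_margins(self):
        df = generate_null_labels(5, (1, 0, 0), (1, 0, 0), seed=1)
        assert (df["human_label"] == "up").all()
        assert (df["mouse_label"] == "up").all()

    def test_determinism(self):
        a = generate_null_labels(100, (0.3, 0.3, 0.4), (0.2, 0.5, 0.3), seed=2)
        b = generate_null_labels(100, (0.3, 0.3, 0.4), (0.2, 0.5, 0.3), seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_margins(self):
        with pytest.raises(ValueError):
            generate_null_labels(10, (0.5, 0.5, 0.5), (1, 0, 0), seed=3)

    def test_independence_calibration(self):
        from scipy.stats import chi2_contingency

        margins = (0.2, 0.3, 0.5)
        n_reject = 0
        runs = 300
        for i in range(runs):
            df = generate_null_labels(2000, margins, margins, seed=100 + i)
            tab = pd.crosstab(df["human_label"], df["mouse_label"])
            _, p, _, _ = chi2_contingency(tab)
            n_reject += p < 0.05
        assert n_reject / runs <= 0.06 + 2.5 * np.sqrt(0.05 * 0.95 / runs)
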