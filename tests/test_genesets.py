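import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from orthocorr import (
    GeneSet,
    GeneSetCollection,
    SyntheticConfig,
    classify_de,
    concordance_percentage,
    concordant_discordant_subsets,
    differential_expression,
    generate_dataset,
    overrepresentation_test,
    signature_set_score,
    term_correspondence,
)

from conftest import identity_map, make_de_table


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) for X ~ Hypergeom(N, K, n), by combinatorial enumeration."""
    denom = math.comb(N, n)
    hi = min(n, K)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x) / denom for x in range(k, hi + 1)
    )


def collection(*sets):
    coll = GeneSetCollection()
    for sid, members in sets:
        coll.add(GeneSet(sid, sid, list(members)))
    return coll


class TestOverrepresentation:
    def test_term_equal_to_de_set(self):
        background = [f"g{i}" for i in range(100)]
        de = background[:10]
        coll = collection(("T", de))
        res = overrepresentation_test(de, coll, background, min_size=1)
        assert res[0].p == pytest.approx(hypergeom_tail_oracle(10, 100, 10, 10))

    def test_disjoint_term_maximal_p(self):
        background = [f"g{i}" for i in range(50)]
        coll = collection(("T", background[40:]))
        res = overrepresentation_test(background[:10], coll, background, min_size=0)
        assert res[0].p == pytest.approx(1.0)

    def test_random_instances_match_enumeration(self):
        rng = np.random.default_rng(20)
        for _ in range(50):
            N = int(rng.integers(5, 31))
            background = [f"g{i}" for i in range(N)]
            n_de = int(rng.integers(1, N + 1))
            de = list(rng.choice(background, size=n_de, replace=False))
            K = int(rng.integers(1, N + 1))
            term = list(rng.choice(background, size=K, replace=False))
            res = overrepresentation_test(de, collection(("T", term)), background, min_size=0)
            k = len(set(term) & set(de))
            assert res[0].p == pytest.approx(
                hypergeom_tail_oracle(k, N, K, n_de), abs=1e-12
            )

    def test_conditional_discounts_child_signal(self):
        background = [f"g{i}" for i in range(200)]
        child = background[:20]
        parent = background[:40]  # child's genes plus 20 unenriched ones
        de = background[:20]  # exactly the child
        coll = collection(("child", child), ("parent", parent))
        relation = {"parent": ["child"]}
        uncond = overrepresentation_test(de, coll, background, min_size=0)
        cond = overrepresentation_test(
            de, coll, background, conditional=True, relation=relation, min_size=0
        )
        p_uncond = {r.term_id: r.p for r in uncond}
        p_cond = {r.term_id: r.p for r in cond}
        assert p_cond["child"] == pytest.approx(p_uncond["child"])
        assert p_cond["parent"] > 100 * p_uncond["parent"]

    def test_min_size_filter(self):
        background = [f"g{i}" for i in range(50)]
        coll = collection(("T", background[:4]))
        assert overrepresentation_test(background[:4], coll, background, min_size=10) == []
        assert len(overrepresentation_test(background[:4], coll, background, min_size=3)) == 1

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            overrepresentation_test(["a"], collection(("T", ["a"])), [])


class TestTermCorrespondence:
    def test_epidermis_style_counts(self):
        # 26 human transcripts mapping to 28 mouse transcripts, 26 increased
        human_ids = [f"H{i}" for i in range(26)]
        mouse_ids = [f"M{i}" for i in range(28)]
        pairs = {"human_transcript": [], "mouse_transcript": []}
        for i in range(26):
            pairs["human_transcript"].append(human_ids[i])
            pairs["mouse_transcript"].append(mouse_ids[i])
        # two extra mouse partners for the first two human transcripts
        pairs["human_transcript"] += [human_ids[0], human_ids[1]]
        pairs["mouse_transcript"] += [mouse_ids[26], mouse_ids[27]]
        omap = identity_map(["x"])  # placeholder replaced below
        omap.pairs = pd.DataFrame(
            {
                "human_transcript": pairs["human_transcript"],
                "human_gene": "G",
                "mouse_transcript": pairs["mouse_transcript"],
                "mouse_gene": "g",
            }
        )
        lfc = np.concatenate([np.abs(np.random.default_rng(0).normal(1, 0.3, 26)),
                              [-0.5, -0.7]])
        mouse = make_de_table(lfc, prefix="X").rename(
            index=dict(zip([f"X{i}" for i in range(28)], mouse_ids))
        )
        tc = term_correspondence("epidermis", human_ids, omap, mouse)
        assert (tc.n_human, tc.n_mouse) == (26, 28)
        n1 = 26
        assert concordance_percentage(n1, 2)[0] == 92.9

    def test_zero_variance_degenerate(self):
        mouse = make_de_table(np.ones(5), prefix="M")
        omap = identity_map([f"H{i}" for i in range(5)], [f"M{i}" for i in range(5)])
        tc = term_correspondence("t", [f"H{i}" for i in range(5)], omap, mouse)
        assert tc.degenerate
        assert tc.mean_mouse_log2fc == pytest.approx(1.0)

    def test_matches_textbook_t_oracle(self):
        rng = np.random.default_rng(21)
        vals = rng.normal(0.5, 1.0, size=20)
        mouse = make_de_table(vals, prefix="M")
        omap = identity_map([f"H{i}" for i in range(20)], [f"M{i}" for i in range(20)])
        tc = term_correspondence("t", [f"H{i}" for i in range(20)], omap, mouse)
        mean = vals.mean()
        t_oracle = mean / (vals.std(ddof=1) / np.sqrt(20))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), 19)
        assert tc.t_stat == pytest.approx(t_oracle, abs=1e-10)
        assert tc.p == pytest.approx(p_oracle, abs=1e-10)

    def test_duplicate_human_members_count_mouse_once(self):
        omap = identity_map(["H0"], ["M0"])
        omap.pairs = pd.concat(
            [
                omap.pairs,
                pd.DataFrame(
                    {
                        "human_transcript": ["H1"],
                        "human_gene": ["G"],
                        "mouse_transcript": ["M0"],
                        "mouse_gene": ["g"],
                    }
                ),
            ],
            ignore_index=True,
        )
        mouse = make_de_table([2.0]).rename(index={"T0": "M0"})
        tc = term_correspondence("t", ["H0", "H1"], omap, mouse)
        assert tc.n_mouse == 1
        assert tc.mean_mouse_log2fc == pytest.approx(2.0)


class TestSubsets:
    def test_eight_pair_fixture(self):
        cats = [("up", "up"), ("down", "down"), ("up", "down"), ("down", "up")]
        hl, ml = [], []
        for h, m in cats:
            hl += [h, h]
            ml += [m, m]
        human_labels = pd.Series(hl, index=[f"H{i}" for i in range(8)])
        mouse_labels = pd.Series(ml, index=[f"M{i}" for i in range(8)])
        omap = identity_map(list(human_labels.index), list(mouse_labels.index))
        subsets = concordant_discordant_subsets(human_labels, mouse_labels, omap)
        assert all(len(s) == 2 for s in subsets.values())

    def test_disjoint_partition(self, dataset, de_tables):
        human, mouse = de_tables
        hl = classify_de(human, "human_broad")
        ml = classify_de(mouse, "mouse")
        subsets = concordant_discordant_subsets(hl, ml, dataset.orthologs)
        seen = set()
        for s in subsets.values():
            keys = set(zip(s["human_transcript"], s["mouse_transcript"]))
            assert not (keys & seen)
            seen |= keys
        assert len(seen) <= dataset.orthologs.n_pairs

    def test_high_rho_concordance_dominates(self):
        ds = generate_dataset(SyntheticConfig(seed=22, rho=0.9, spikes={}))
        human = differential_expression(ds.human)
        mouse = differential_expression(ds.mouse)
        hl = classify_de(human, "human_broad")
        ml = classify_de(mouse, "mouse")
        subsets = concordant_discordant_subsets(hl, ml, ds.orthologs)
        concordant = len(subsets["up_up"]) + len(subsets["down_down"])
        discordant = len(subsets["up_down"]) + len(subsets["down_up"])
        assert concordant > 3 * max(discordant, 1)


class TestSignatureScore:
    def test_zero_fold_changes(self):
        table = make_de_table(np.zeros(10))
        gs = GeneSet("S", "s", list(table.index[:5]))
        score = signature_set_score(gs, table)
        assert score.mean_log2fc == 0.0
        assert score.degenerate  # zero variance

    def test_mean_is_arithmetic_mean(self):
        rng = np.random.default_rng(23)
        table = make_de_table(rng.normal(size=30))
        members = list(table.index[:12])
        gs = GeneSet("S", "s", members)
        score = signature_set_score(gs, table)
        assert score.mean_log2fc == pytest.approx(
            table.loc[members, "log2fc"].mean()
        )
        assert score.n_present == 12

    def test_planted_shift_power(self):
        rng = np.random.default_rng(24)
        detected = 0
        for _ in range(100):
            lfc = rng.normal(0, 1, size=500)
            lfc[:50] += 0.8
            table = make_de_table(lfc)
            gs = GeneSet("S", "s", list(table.index[:50]))
            if signature_set_score(gs, table).p < 0.01:
                detected += 1
        assert detected >= 95

    def test_missing_members_flagged(self):
        table = make_de_table([1.0, 2.0])
        gs = GeneSet("S", "s", ["T0", "absent1", "absent2"])
        score = signature_set_score(gs, table)
        assert score.n_present == 1
        assert score.degenerate
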