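"""Rarefaction, alpha diversity, KS, NJ trees, Faith's PD, paired stats, ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from denoise_impact.diversity import (
    alpha_diversity,
    build_nj_tree,
    faith_pd,
    ks_two_sample,
    paired_t,
    pooled_evenness,
    rank_abundance,
    rank_shift,
    rarefy,
    two_way_anova,
)
from denoise_impact.otu import DistanceMatrix
from oracles import ks_statistic


class TestRarefy:
    def test_row_at_depth_unchanged(self):
        tab = pd.DataFrame({"o1": [60], "o2": [40]}, index=["s1"])
        out = rarefy(tab, depth=100, seed=0)
        assert out.table.loc["s1"].tolist() == [60, 40]

    def test_sample_below_depth_excluded(self):
        tab = pd.DataFrame({"o1": [2999]}, index=["s1"])
        out = rarefy(tab, depth=3000, seed=0)
        assert out.excluded_samples == ["s1"]
        assert len(out.table) == 0

    def test_rows_sum_exactly_to_depth(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(rng.integers(0, 50, (5, 30)), index=[f"s{i}" for i in range(5)])
        out = rarefy(tab, depth=200, seed=3)
        assert (out.table.sum(axis=1) == 200).all()

    def test_hypergeometric_mean_recovered_over_seeds(self):
        """E[rarefied count] = D * n / N for an OTU with n of N reads."""
        n, rest, depth = 40, 160, 50
        tab = pd.DataFrame({"o1": [n], "o2": [rest]}, index=["s1"])
        draws = [rarefy(tab, depth=depth, seed=s).table.loc["s1", "o1"] for s in range(1000)]
        expected = depth * n / (n + rest)
        se = np.sqrt(1000) * 2.5  # loose multiple of the binomial sd
        assert abs(sum(draws) - 1000 * expected) < se * 3

    def test_determinism(self):
        tab = pd.DataFrame({"o1": [50], "o2": [70]}, index=["s1"])
        a = rarefy(tab, depth=60, seed=9).table
        b = rarefy(tab, depth=60, seed=9).table
        assert a.equals(b)


class TestAlpha:
    def test_uniform_counts_maximize_evenness(self):
        tab = pd.DataFrame({f"o{i}": [25] for i in range(4)}, index=["s1"])
        a = alpha_diversity(tab).loc["s1"]
        assert a["shannon"] == pytest.approx(np.log(4))
        assert a["evenness"] == pytest.approx(1.0)
        assert a["richness"] == 4

    def test_single_otu_has_zero_shannon_and_undefined_evenness(self):
        tab = pd.DataFrame({"o1": [10]}, index=["s1"])
        a = alpha_diversity(tab).loc["s1"]
        assert a["shannon"] == 0.0
        assert np.isnan(a["evenness"])

    def test_chao1_formula_bias_corrected_and_classical(self):
        # S=5, n1=2 singletons, n2=1 doubleton
        tab = pd.DataFrame({"a": [1], "b": [1], "c": [2], "d": [5], "e": [9]}, index=["s1"])
        assert alpha_diversity(tab).loc["s1", "chao1"] == pytest.approx(5 + 2 * 1 / (2 * 2))
        assert alpha_diversity(tab, bias_corrected_chao=False).loc["s1", "chao1"] == pytest.approx(7.0)

    def test_matches_skbio_reference(self):
        """Cross-check Shannon and Chao1 against the established library."""
        from skbio.diversity.alpha import chao1, shannon

        rng = np.random.default_rng(4)
        counts = rng.integers(0, 30, 20)
        counts[0] = 1
        tab = pd.DataFrame([counts], index=["s1"])
        a = alpha_diversity(tab).loc["s1"]
        nz = counts[counts > 0]
        assert a["shannon"] == pytest.approx(shannon(nz, base=np.e))
        assert a["chao1"] == pytest.approx(chao1(counts, bias_corrected=True))

    def test_all_zero_sample_is_explicit_failure(self):
        with pytest.raises(ValueError):
            alpha_diversity(pd.DataFrame({"o1": [0]}, index=["s1"]))

    def test_pooled_evenness(self):
        tab = pd.DataFrame({"o1": [10, 10], "o2": [10, 10]}, index=["s1", "s2"])
        h, e, s = pooled_evenness(tab)
        assert (h, e, s) == (pytest.approx(np.log(2)), pytest.approx(1.0), 2)


class TestKS:
    def test_identical_inputs_give_zero(self):
        assert ks_two_sample([5, 3, 1], [5, 3, 1]).d == 0.0

    def test_disjoint_supports_give_one(self):
        res = ks_two_sample([1, 2, 3], [10, 20, 30])
        assert res.d == pytest.approx(1.0)

    def test_matches_brute_force_ecdf_scan(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.integers(1, 100, 20)
            y = rng.integers(1, 100, 20)
            assert ks_two_sample(x, y).d == pytest.approx(ks_statistic(x, y))

    def test_invariant_under_common_monotone_rescaling(self):
        rng = np.random.default_rng(8)
        x, y = rng.integers(1, 500, 30), rng.integers(1, 500, 25)
        assert ks_two_sample(x, y).d == pytest.approx(ks_two_sample(np.log(x), np.log(y)).d)

    def test_rank_abundance_sorted_desc(self):
        ra = rank_abundance([3, 0, 9, 1])
        assert ra.tolist() == [9, 3, 1]


class TestNeighborJoining:
    def test_two_taxa_edge_length(self):
        dm = DistanceMatrix(ids=["a", "b"], data=np.array([[0, 0.1], [0.1, 0]]))
        tree = build_nj_tree(dm)
        assert sum(t.length for t in tree.tips()) == pytest.approx(0.1)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        tree = build_nj_tree(DistanceMatrix(ids=list("abc"), data=d))
        bl = {t.name: t.length for t in tree.tips()}
        assert bl["a"] == pytest.approx(0.05)
        assert bl["b"] == pytest.approx(0.15)
        assert bl["c"] == pytest.approx(0.25)

    def test_exact_recovery_of_additive_five_taxon_matrix(self):
        # distances generated from a known tree are recovered exactly
        ids = list("abcde")
        d = np.array(
            [
                [0, 3, 7, 5, 6],
                [3, 0, 8, 6, 7],
                [7, 8, 0, 4, 9],
                [5, 6, 4, 0, 7],
                [6, 7, 9, 7, 0],
            ],
            dtype=float,
        )
        tree = build_nj_tree(DistanceMatrix(ids=ids, data=d))
        tips = {t.name: t for t in tree.tips()}
        for x, y in itertools.combinations(ids, 2):
            assert tips[x].distance(tips[y]) == pytest.approx(d[ids.index(x), ids.index(y)])

    def test_matches_skbio_nj_topology(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj

        rng = np.random.default_rng(3)
        d = np.triu(rng.uniform(0.05, 0.5, (6, 6)), 1)
        d = d + d.T
        ids = [f"t{i}" for i in range(6)]
        ours = build_nj_tree(DistanceMatrix(ids=ids, data=d))
        ref = nj(SkbioDM(d, ids))
        assert ours.compare_rfd(ref) == 0.0

    def test_single_taxon_is_error(self):
        with pytest.raises(ValueError):
            build_nj_tree(DistanceMatrix(ids=["a"], data=np.zeros((1, 1))))


class TestFaithPD:
    def tree(self):
        from skbio import TreeNode

        return TreeNode.read(["((l1:1,l2:2):0.5,l3:3,l4:4);"])

    def test_all_leaves_gives_total_branch_length(self):
        t = self.tree()
        total = sum(n.length for n in t.traverse() if n.length)
        assert faith_pd(t, ["l1", "l2", "l3", "l4"]) == pytest.approx(total)

    def test_star_subset_spans_path(self):
        from skbio import TreeNode

        star = TreeNode.read(["(a:1,b:2,c:3);"])
        assert faith_pd(star, ["a", "b"]) == pytest.approx(3.0)

    def test_single_taxon_zero_under_unrooted_convention(self):
        assert faith_pd(self.tree(), ["l3"]) == 0.0

    def test_unknown_taxon_is_explicit_failure(self):
        with pytest.raises(ValueError):
            faith_pd(self.tree(), ["ghost"])

    def test_matches_skbio_on_leaves_spanning_the_root(self):
        from skbio import TreeNode
        from skbio.diversity.alpha import faith_pd as skbio_faith

        t = TreeNode.read(["((l1:1,l2:2):0.5,(l3:3,l4:4):0.7);"])
        # skbio's rooted convention and the unrooted spanning subtree agree
        # whenever the selected leaves bracket the root
        ours = faith_pd(t, ["l1", "l4"])
        theirs = skbio_faith([1, 0, 0, 1], taxa=["l1", "l2", "l3", "l4"], tree=t)
        assert ours == pytest.approx(theirs)


class TestPairedStats:
    def test_constant_shift_is_degenerate(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_hand_five_pair_dataset(self):
        a = np.array([3.1, 2.8, 3.6, 3.3, 2.9])
        b = np.array([2.9, 2.9, 3.1, 3.0, 2.8])
        t, p = paired_t(a, b)
        diff = a - b
        t_ref = diff.mean() / (diff.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(t_ref)
        assert 0 < p < 1

    def test_rank_shift_identity_and_reversal(self):
        vals = {f"s{i}": float(i) for i in range(5)}
        table, rho = rank_shift(vals, vals)
        assert (table.delta == 0).all()
        assert rho == pytest.approx(1.0)
        rev = {f"s{i}": float(-i) for i in range(5)}
        _, rho_rev = rank_shift(vals, rev)
        assert rho_rev == pytest.approx(-1.0)

    def test_rank_shift_crafted_six_sample_case(self):
        a = {"s1": 10, "s2": 9, "s3": 8, "s4": 7, "s5": 6, "s6": 5}
        b = {"s1": 10, "s2": 5, "s3": 8, "s4": 7, "s5": 6, "s6": 9}
        table, _ = rank_shift(a, b)
        assert table.loc["s2", "delta"] == 4  # dropped from rank 2 to rank 6
        assert table.loc["s6", "delta"] == -4
        assert table.loc["s1", "delta"] == 0


class TestAnova:
    def balanced(self, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for a in (1, 32):
            for b in ("h1", "h2"):
                for _ in range(3):
                    y = 1.0 * (a == 32) + 2.0 * (b == "h2") + rng.normal(0, noise)
                    rows.append({"shannon": y, "plant_richness": a, "host_species": b})
        return pd.DataFrame(rows)

    def test_additive_zero_noise_has_zero_interaction(self):
        table = two_way_anova(self.balanced()).table
        assert table.loc["plant_richness:host_species", "sum_sq"] == pytest.approx(0.0, abs=1e-18)
        assert table.loc["plant_richness", "sum_sq"] == pytest.approx(3.0)  # 12 * (0.5)^2
        assert table.loc["host_species", "sum_sq"] == pytest.approx(12.0)

    def test_balanced_type3_equals_cell_mean_decomposition(self):
        df = self.balanced(noise=0.3, seed=5)
        table = two_way_anova(df).table
        # balanced design: Type III SS equal classical factor SS
        ym = df.shannon.mean()
        ss_a = sum(
            6 * (df[df.plant_richness == a].shannon.mean() - ym) ** 2 for a in (1, 32)
        )
        assert table.loc["plant_richness", "sum_sq"] == pytest.approx(ss_a)
        # DFs additive up to the corrected total
        assert table.loc["Corrected Total", "df"] == table["df"].iloc[:4].sum()

    def test_constant_response_is_flagged(self):
        df = self.balanced()
        df["shannon"] = 1.0
        out = two_way_anova(df)
        assert out.warnings

    def test_single_level_factor_is_error(self):
        df = self.balanced()
        df["host_species"] = "h1"
        with pytest.raises(ValueError):
            two_way_anova(df)

    def test_empty_cell_is_named_in_error(self):
        df = self.balanced()
        df = df[~((df.plant_richness == 1) & (df.host_species == "h2"))]
        with pytest.raises(ValueError, match="empty cells"):
            two_way_anova(df)
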