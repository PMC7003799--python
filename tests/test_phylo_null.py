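"""Nearest-taxon statistics, their null models, and the classification rules."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from interactome import phylo_null as pn
from interactome import synthetic as syn

from _brute import (
    beta_mntd as brute_beta_mntd,
    beta_mntd_weighted as brute_beta_mntd_w,
    mntd as brute_mntd,
    mntd_weighted as brute_mntd_w,
    patristic,
)
from conftest import tree_from_newick


def table_from_sets(sets: dict[str, list[str]], all_taxa: list[str]) -> pd.DataFrame:
    rows = {
        s: [1 if t in taxa else 0 for t in all_taxa] for s, taxa in sets.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=all_taxa)


class TestPatristicMatrix:
    def test_two_tip(self):
        dm = pn.patristic_matrix(tree_from_newick("(A:1.25,B:0.5);"))
        assert dm["A", "B"] == pytest.approx(1.75)

    def test_balanced_ultrametric_cherries(self):
        # depth 3, cherry nodes at depth 2 -> cherry mates 2*(3-2) = 2
        tree = tree_from_newick("((A:1,B:1):2,(C:1,D:1):2);")
        dm = pn.patristic_matrix(tree)
        assert dm["A", "B"] == pytest.approx(2.0)
        assert dm["C", "D"] == pytest.approx(2.0)
        assert dm["A", "C"] == pytest.approx(6.0)

    def test_matches_root_path_algebra(self):
        tree = syn.simulate_tree(10, seed=6)
        dm = pn.patristic_matrix(tree)
        for a in dm.ids:
            for b in dm.ids:
                if a < b:
                    assert dm[a, b] == pytest.approx(
                        patristic(tree, a, b), abs=1e-12
                    )


class TestMntd:
    def test_two_taxa_equals_their_distance(self):
        tree = tree_from_newick("(A:1,(B:0.5,C:0.5):1);")
        dm = pn.patristic_matrix(tree)
        assert pn.mntd(["A", "B"], dm) == pytest.approx(dm["A", "B"])

    def test_star_tree_unit_lengths_gives_two(self):
        tree = tree_from_newick("(A:1,B:1,C:1,D:1,E:1);")
        dm = pn.patristic_matrix(tree)
        for taxa in (["A", "B"], ["A", "C", "E"], list("ABCDE")):
            assert pn.mntd(taxa, dm) == pytest.approx(2.0)

    def test_matches_double_loop_oracle(self, rng):
        tree = syn.simulate_tree(15, seed=2)
        dm = pn.patristic_matrix(tree)
        tips = list(dm.ids)
        for _ in range(10):
            taxa = list(rng.choice(tips, size=6, replace=False))
            assert pn.mntd(taxa, dm) == pytest.approx(
                brute_mntd(taxa, lambda a, b: dm[a, b]), abs=1e-12
            )
            abund = {t: float(rng.integers(1, 9)) for t in taxa}
            assert pn.mntd(pd.Series(abund), dm, abundance_weighted=True) == (
                pytest.approx(brute_mntd_w(abund, lambda a, b: dm[a, b]), abs=1e-12)
            )

    def test_fewer_than_two_taxa_rejected(self):
        dm = pn.patristic_matrix(tree_from_newick("(A:1,B:1);"))
        with pytest.raises(ValueError):
            pn.mntd(["A"], dm)


class TestAlphaNti:
    def test_full_tree_community_is_undefined(self):
        tree = syn.simulate_tree(12, seed=4)
        tips = sorted(t.name for t in tree.tips())
        table = table_from_sets({"all": tips, "all2": tips}, tips)
        res = pn.alpha_nti(table, tree, n_null=49, seed=0)
        for ens in res.ensembles.values():
            assert np.isnan(ens.index)
            assert ens.undefined_reason == "zero null variance"

    def test_closest_pair_is_strongly_clustered(self):
        tree = syn.simulate_tree(50, seed=2)
        dm = pn.patristic_matrix(tree)
        off = np.where(np.eye(50, dtype=bool), np.inf, dm.data)
        i, j = np.unravel_index(np.argmin(off), off.shape)
        pair = [dm.ids[i], dm.ids[j]]
        table = table_from_sets({"s": pair}, sorted(dm.ids))
        res = pn.alpha_nti(table, tree, n_null=999, seed=1)
        # for a two-taxon community the null is the pairwise-distance
        # distribution itself, so the index tends to (mean - min)/sd
        iu = np.triu_indices(50, 1)
        v = dm.data[iu]
        expected = (v.mean() - v.min()) / v.std(ddof=1)
        assert expected > 2  # fixture premise: observed is the distribution's minimum
        assert res.ensembles["s"].index > 2
        assert res.ensembles["s"].index == pytest.approx(expected, rel=0.2)

    def test_scale_invariance_of_index(self):
        tree = syn.simulate_tree(30, seed=5)
        scaled = tree.copy()
        for node in scaled.traverse(include_self=False):
            node.length = (node.length or 0.0) * 7.5
        tips = sorted(t.name for t in tree.tips())
        rng = np.random.default_rng(3)
        sets = {f"s{i}": list(rng.choice(tips, 8, replace=False)) for i in range(3)}
        table = table_from_sets(sets, tips)
        a = pn.alpha_nti(table, tree, n_null=99, seed=7)
        b = pn.alpha_nti(table, scaled, n_null=99, seed=7)
        assert np.allclose(a.indices, b.indices)

    def test_bit_reproducible(self):
        tree = syn.simulate_tree(40, seed=1)
        tips = sorted(t.name for t in tree.tips())
        rng = np.random.default_rng(4)
        table = table_from_sets(
            {f"s{i}": list(rng.choice(tips, 10, replace=False)) for i in range(4)}, tips
        )
        a = pn.alpha_nti(table, tree, n_null=99, seed=42)
        b = pn.alpha_nti(table, tree, n_null=99, seed=42)
        assert a.summary().equals(b.summary())

    def test_unweighted_index_ignores_abundance_values(self):
        tree = syn.simulate_tree(25, seed=2)
        tips = sorted(t.name for t in tree.tips())
        members = tips[:7]
        t1 = table_from_sets({"s": members}, tips)
        t2 = t1.copy()
        t2.loc["s", members] = [5, 1, 9, 2, 2, 7, 1]
        a = pn.alpha_nti(t1, tree, n_null=99, seed=3)
        b = pn.alpha_nti(t2, tree, n_null=99, seed=3)
        assert a.ensembles["s"].index == b.ensembles["s"].index


class TestBetaMntd:
    def test_identical_samples_give_zero(self):
        tree = syn.simulate_tree(10, seed=3)
        tips = sorted(t.name for t in tree.tips())
        table = table_from_sets({"a": tips[:5], "b": tips[:5]}, tips)
        assert pn.beta_mntd(table, tree)["a", "b"] == pytest.approx(0.0)

    def test_singleton_samples_give_their_distance(self):
        tree = syn.simulate_tree(10, seed=3)
        dm = pn.patristic_matrix(tree)
        tips = sorted(dm.ids)
        table = table_from_sets({"a": [tips[0]], "b": [tips[4]]}, tips)
        assert pn.beta_mntd(table, tree)["a", "b"] == pytest.approx(
            dm[tips[0], tips[4]]
        )

    def test_matches_double_loop_oracle(self, rng):
        tree = syn.simulate_tree(14, seed=8)
        dm = pn.patristic_matrix(tree)
        tips = sorted(dm.ids)
        sets = {f"s{i}": list(rng.choice(tips, 5, replace=False)) for i in range(3)}
        table = table_from_sets(sets, tips)
        out = pn.beta_mntd(table, dm)
        for a in sets:
            for b in sets:
                if a < b:
                    assert out[a, b] == pytest.approx(
                        brute_beta_mntd(sets[a], sets[b], lambda x, y: dm[x, y]),
                        abs=1e-12,
                    )
        # abundance-weighted variant against its own oracle
        wtable = table * 0
        for s, taxa in sets.items():
            for t in taxa:
                wtable.loc[s, t] = float(rng.integers(1, 9))
        wout = pn.beta_mntd(wtable, dm, abundance_weighted=True)
        for a in sets:
            for b in sets:
                if a < b:
                    expected = brute_beta_mntd_w(
                        wtable.loc[a][wtable.loc[a] > 0].to_dict(),
                        wtable.loc[b][wtable.loc[b] > 0].to_dict(),
                        lambda x, y: dm[x, y],
                    )
                    assert wout[a, b] == pytest.approx(expected, abs=1e-12)


class TestBetaNti:
    def test_same_clade_pair_is_negative(self):
        tree = syn.simulate_tree(100, seed=12)
        dm = pn.patristic_matrix(tree)
        # two disjoint halves of the same tight 20-tip neighbourhood: every
        # nearest relative sits within the clade, far closer than a random
        # relabelling allows
        order = np.argsort(dm.data[0])
        clade = [dm.ids[i] for i in order[:20]]
        sets = {"a": clade[0::2], "b": clade[1::2]}
        table = table_from_sets(sets, sorted(dm.ids))
        res = pn.beta_nti(table, tree, n_null=999, seed=2)
        assert res.index.loc["a", "b"] < -2

    def test_distant_clades_pair_is_positive(self):
        tree = syn.simulate_tree(100, seed=12)
        dm = pn.patristic_matrix(tree)
        far = np.unravel_index(np.argmax(dm.data), dm.data.shape)
        a_anchor, b_anchor = far
        a_clade = [dm.ids[i] for i in np.argsort(dm.data[a_anchor])[:10]]
        b_clade = [dm.ids[i] for i in np.argsort(dm.data[b_anchor])[:10]]
        table = table_from_sets(
            {"a": a_clade, "b": b_clade}, sorted(dm.ids)
        )
        res = pn.beta_nti(table, tree, n_null=999, seed=2)
        assert res.index.loc["a", "b"] > 2

    def test_degenerate_all_tip_samples_flagged_undefined(self):
        tree = syn.simulate_tree(10, seed=1)
        tips = sorted(t.name for t in tree.tips())
        table = table_from_sets({"a": tips, "b": tips}, tips)
        res = pn.beta_nti(table, tree, n_null=49, seed=0)
        assert bool(res.undefined.loc["a", "b"])
        assert np.isnan(res.index.loc["a", "b"])

    def test_bit_reproducible(self):
        tree = syn.simulate_tree(30, seed=3)
        tips = sorted(t.name for t in tree.tips())
        rng = np.random.default_rng(5)
        table = table_from_sets(
            {f"s{i}": list(rng.choice(tips, 8, replace=False)) for i in range(4)}, tips
        )
        a = pn.beta_nti(table, tree, n_null=99, seed=11)
        b = pn.beta_nti(table, tree, n_null=99, seed=11)
        pd.testing.assert_frame_equal(a.index, b.index)


class TestIndexTTest:
    def test_identical_vectors_give_zero_t(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = pn.index_t_test(v, v)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_shift_is_detected(self, rng):
        a = rng.normal(5, 1, 30)
        b = rng.normal(0, 1, 300)
        _, p = pn.index_t_test(a, b)
        assert p < 1e-3

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            pn.index_t_test([1.0], [0.0, 1.0])


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (4.64, "clustered"),
            (0.0, "random"),
            (-2.0, "random"),
            (2.0, "random"),
            (-2.5, "overdispersed"),
            (float("nan"), "undefined"),
        ],
    )
    def test_within_community_rules(self, value, expected):
        assert pn.classify_structure(value) == expected

    def test_between_community_sign_convention(self):
        assert pn.classify_structure(-3.58, between=True) == "clustered"
        assert pn.classify_structure(3.0, between=True) == "overdispersed"


R_ORACLE = r"""
suppressMessages(library(picante))
args <- commandArgs(trailingOnly=TRUE)
tr <- read.tree(args[1])
comm <- as.matrix(read.table(args[2], header=TRUE, row.names=1, sep="\t",
                             check.names=FALSE))
d <- cophenetic(tr)
m_u <- mntd(comm, d, abundance.weighted=FALSE)
m_w <- mntd(comm, d, abundance.weighted=TRUE)
b_u <- as.matrix(comdistnt(comm, d, abundance.weighted=FALSE))
b_w <- as.matrix(comdistnt(comm, d, abundance.weighted=TRUE))
write.table(data.frame(mntd_u=m_u, mntd_w=m_w), args[3], sep="\t")
write.table(b_u, args[4], sep="\t")
write.table(b_w, args[5], sep="\t")
"""


class TestPicanteCrossCheck:
    def test_mntd_and_beta_mntd_match_picante(self, tmp_path, rng):
        """Independent oracle: the reference R implementation of the same
        statistics (picante mntd / comdistnt) on a small fixture."""
        tree = syn.simulate_tree(12, seed=17)
        tips = sorted(t.name for t in tree.tips())
        counts = rng.integers(0, 6, size=(3, 12))
        counts[:, 0] += 1
        table = pd.DataFrame(counts, index=["s1", "s2", "s3"], columns=tips)
        tree.write(str(tmp_path / "tree.nwk"))
        table.to_csv(tmp_path / "comm.tsv", sep="\t")
        script = tmp_path / "oracle.R"
        script.write_text(R_ORACLE)
        subprocess.run(
            [
                "Rscript", "--vanilla", str(script),
                str(tmp_path / "tree.nwk"), str(tmp_path / "comm.tsv"),
                str(tmp_path / "mntd.tsv"), str(tmp_path / "bmntd_u.tsv"),
                str(tmp_path / "bmntd_w.tsv"),
            ],
            check=True, capture_output=True,
        )
        r_mntd = pd.read_csv(tmp_path / "mntd.tsv", sep="\t")
        r_bu = pd.read_csv(tmp_path / "bmntd_u.tsv", sep="\t")
        r_bw = pd.read_csv(tmp_path / "bmntd_w.tsv", sep="\t")
        dm = pn.patristic_matrix(tree)
        ours_u = pn.beta_mntd(table, dm)
        ours_w = pn.beta_mntd(table, dm, abundance_weighted=True)
        for i, s in enumerate(table.index):
            present = table.columns[table.loc[s] > 0]
            assert pn.mntd(list(present), dm) == pytest.approx(
                r_mntd["mntd_u"].iloc[i], abs=1e-8
            )
            assert pn.mntd(table.loc[s], dm, abundance_weighted=True) == (
                pytest.approx(r_mntd["mntd_w"].iloc[i], abs=1e-8)
            )
        order = list(table.index)
        for a in order:
            for b in order:
                if a < b:
                    i = order.index(a)
                    assert ours_u[a, b] == pytest.approx(r_bu.loc[r_bu.index[i], b], abs=1e-8)
                    assert ours_w[a, b] == pytest.approx(r_bw.loc[r_bw.index[i], b], abs=1e-8)
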