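"""Tree operations: NJ consistency, monophyly, concordance factors,
Colless imbalance with an enumeration oracle."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from admixdelim.treekit import (
    colless,
    gene_concordance,
    is_monophyletic,
    nj_tree,
    p_distance_genotypes,
    read_tree,
    site_concordance,
    terminal_gcf,
    terminal_gcf_table,
)
from admixdelim.containers import GenotypeMatrix, LocusAlignment


# ---------------------------------------------------------------------------
# neighbor joining


class TestNJ:
    def test_additive_four_taxon_matrix_recovered_exactly(self):
        labels = list("ABCD")
        d = pd.DataFrame(
            [[0, 0.2, 0.6, 0.6], [0.2, 0, 0.6, 0.6],
             [0.6, 0.6, 0, 0.2], [0.6, 0.6, 0.2, 0]],
            index=labels, columns=labels,
        )
        tree = nj_tree(d)
        assert is_monophyletic(tree, ["A", "B"], rooted=False)
        assert is_monophyletic(tree, ["C", "D"], rooted=False)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["A"], taxa["B"]) == pytest.approx(0.2)
        assert pdm.distance(taxa["A"], taxa["C"]) == pytest.approx(0.6)

    def test_three_taxa_star(self):
        d = pd.DataFrame(
            [[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]],
            index=list("abc"), columns=list("abc"),
        )
        tree = nj_tree(d)
        assert len(tree.leaf_nodes()) == 3
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["a"], taxa["b"]) == pytest.approx(0.3)

    def test_fewer_than_three_taxa_rejected(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(d)

    @pytest.mark.parametrize("seed", range(5))
    def test_tree_metric_reproduced(self, seed):
        """NJ on distances from a random tree recovers that tree."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 16))
        # random binary tree by sequential joining, random positive lengths
        frags = [f"t{i:02d}:{rng.uniform(0.05, 1.0):.4f}" for i in range(n)]
        while len(frags) > 2:
            i, j = sorted(rng.choice(len(frags), size=2, replace=False))
            merged = f"({frags[i]},{frags[j]}):{rng.uniform(0.05, 1.0):.4f}"
            frags[j:j + 1] = []
            frags[i] = merged
        newick = f"({frags[0]},{frags[1]});"
        source = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            rooting="force-unrooted",
        )
        pdm = source.phylogenetic_distance_matrix()
        names = [t.label for t in source.taxon_namespace]
        mat = pd.DataFrame(
            [[pdm.distance(a, b) for b in source.taxon_namespace]
             for a in source.taxon_namespace],
            index=names, columns=names,
        )
        rebuilt = nj_tree(mat)
        b1 = source.as_string(schema="newick")
        # compare unrooted topologies via symmetric difference
        ns2 = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=b1, schema="newick", taxon_namespace=ns2,
                               rooting="force-unrooted")
        t2 = dendropy.Tree.get(
            data=rebuilt.as_string(schema="newick"), schema="newick",
            taxon_namespace=ns2, rooting="force-unrooted",
        )
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_mosaic_individual_attaches_between_clades(self):
        # two diverged clades + one 50/50 mosaic: the mosaic joins the
        # internal path, rootward of both within-clade crowns
        rng = np.random.default_rng(3)
        n_sites = 400
        a = rng.binomial(2, 0.05, size=(4, n_sites))
        b = rng.binomial(2, 0.95, size=(4, n_sites))
        half = np.concatenate(
            [b[0, : n_sites // 2], a[0, n_sites // 2:]]
        )[None, :]
        g = np.vstack([a, b, half]).astype(np.int8)
        names = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)] + ["mosaic"]
        gm = GenotypeMatrix(specimens=names, genotypes=g)
        tree = nj_tree(p_distance_genotypes(gm))
        assert is_monophyletic(tree, [f"a{i}" for i in range(4)], rooted=False)
        assert is_monophyletic(tree, [f"b{i}" for i in range(4)], rooted=False)

    def test_all_missing_pair_raises_with_names(self):
        g = np.array([[0, -1], [-1, 0], [1, 1]], dtype=np.int8)
        gm = GenotypeMatrix(specimens=["u", "v", "w"], genotypes=g)
        with pytest.raises(ValueError, match="u.*v"):
            p_distance_genotypes(gm)


# ---------------------------------------------------------------------------
# monophyly


class TestMonophyly:
    def test_full_set_and_singleton_trivially_true(self):
        tree = read_tree("(((a1,a2),b1),b2);")
        assert is_monophyletic(tree, ["a1", "a2", "b1", "b2"])
        assert is_monophyletic(tree, ["b1"])

    def test_caterpillar_b_set(self):
        # rooted: {b1, b2} is no clade of the caterpillar. Unrooted, the
        # 4-taxon caterpillar collapses to ((a1,a2),(b1,b2)), whose single
        # internal edge does isolate {b1, b2}.
        tree = read_tree("(((a1,a2),b1),b2);")
        assert not is_monophyletic(tree, ["b1", "b2"], rooted=True)
        assert is_monophyletic(tree, ["b1", "b2"], rooted=False)
        # a 5-taxon caterpillar keeps the distinction in both readings
        tree5 = read_tree("((((a1,a2),b1),b2),b3);")
        assert not is_monophyletic(tree5, ["b1", "b2"], rooted=True)
        assert not is_monophyletic(tree5, ["b1", "b2"], rooted=False)

    def test_unrooted_bipartition_found(self):
        tree = read_tree("((a1,a2),(b1,b2));", rooted=False)
        assert is_monophyletic(tree, ["b1", "b2"], rooted=False)

    def test_unknown_label_rejected(self):
        tree = read_tree("((a,b),c);")
        with pytest.raises(KeyError, match="zz"):
            is_monophyletic(tree, ["zz"])


# ---------------------------------------------------------------------------
# concordance factors


class TestGeneConcordance:
    def test_identical_gene_trees_give_100_everywhere(self):
        sp = read_tree("(((a,b),(c,d)),(e,f));")
        gts = [sp.as_string(schema="newick")] * 5
        for bs in gene_concordance(sp, gts):
            assert bs.gcf == pytest.approx(100.0)

    def test_worked_example_two_thirds(self):
        sp = read_tree("((A,B),(C,D));")
        gts = ["((A,B),(C,D));", "((A,C),(B,D));", "((A,B),(C,D));"]
        (bs,) = gene_concordance(sp, gts)
        assert bs.gcf == pytest.approx(100 * 2 / 3)
        assert (bs.concordant, bs.decisive) == (2, 3)

    def test_missing_taxon_excluded_from_denominator(self):
        sp = read_tree("((A,B),(C,D));")
        gts = ["((A,B),(C,D));", "((A,B),C);"]
        (bs,) = gene_concordance(sp, gts)
        assert bs.decisive == 1

    def test_input_order_invariance(self):
        sp = read_tree("(((a,b),c),(d,e));")
        gts = ["(((a,b),c),(d,e));", "(((a,c),b),(d,e));", "((a,b),(c,(d,e)));"]
        fwd = {frozenset(b.bipartition): b.gcf for b in gene_concordance(sp, gts)}
        rev = {
            frozenset(b.bipartition): b.gcf
            for b in gene_concordance(sp, list(reversed(gts)))
        }
        assert fwd == rev

    def test_no_gene_trees_rejected(self):
        sp = read_tree("((a,b),(c,d));")
        with pytest.raises(ValueError, match="no gene trees"):
            gene_concordance(sp, [])

    def test_gcf_within_bounds(self, coalescent_dataset):
        ds = coalescent_dataset
        from admixdelim.treekit import p_distance_alignments

        tree = nj_tree(p_distance_alignments(ds.alignments))
        haplotype_trees = [read_tree(t, rooted=False) for t in ds.gene_trees]
        # collapse haplotype tips to specimen tips for comparability
        for t in haplotype_trees:
            for leaf in t.leaf_node_iter():
                leaf.taxon.label = leaf.taxon.label.rsplit("/", 1)[0]
        # keep one tip per specimen
        pruned = []
        for t in haplotype_trees:
            seen = set()
            remove = []
            for leaf in t.leaf_node_iter():
                if leaf.taxon.label in seen:
                    remove.append(leaf.taxon)
                else:
                    seen.add(leaf.taxon.label)
            t.prune_taxa(remove)
            pruned.append(t)
        for bs in gene_concordance(tree, pruned):
            if not bs.undefined:
                assert 0.0 <= bs.gcf <= 100.0
                assert bs.decisive >= bs.concordant


def _diagnostic_alignment(n_conc, n_d1, n_d2, taxa=("A", "B", "C", "D")):
    """Build a 4-specimen alignment with the given quartet site counts."""
    sites = (
        [("A", "A", "C", "C")] * n_conc
        + [("A", "C", "A", "C")] * n_d1
        + [("A", "C", "C", "A")] * n_d2
    )
    seqs = ["".join(s[i] for s in sites) for i in range(4)]
    names = [f"{t}/{p}" for t in taxa for p in (1, 2)]
    seqs2 = []
    for t_idx in range(4):
        seqs2.extend([seqs[t_idx], seqs[t_idx]])
    return LocusAlignment(locus_id="L1", names=names, sequences=seqs2)


class TestSiteConcordance:
    def test_perfectly_diagnostic_sites_give_100(self):
        sp = read_tree("((A,B),(C,D));")
        aln = _diagnostic_alignment(30, 0, 0)
        (bs,) = site_concordance(sp, [aln], n_quartets=10, seed=1)
        assert bs.scf == pytest.approx(100.0)

    def test_symmetric_support_gives_one_third(self):
        sp = read_tree("((A,B),(C,D));")
        aln = _diagnostic_alignment(10, 10, 10)
        (bs,) = site_concordance(sp, [aln], n_quartets=10, seed=2)
        assert bs.scf == pytest.approx(100 / 3, abs=1e-9)

    def test_zero_decisive_sites_flagged_undefined(self):
        sp = read_tree("((A,B),(C,D));")
        aln = _diagnostic_alignment(0, 0, 0)
        # pad with invariant sites so the alignment is non-empty
        names = [f"{t}/{p}" for t in "ABCD" for p in (1, 2)]
        aln = LocusAlignment(locus_id="L1", names=names, sequences=["AAAA"] * 8)
        (bs,) = site_concordance(sp, [aln], n_quartets=5, seed=3)
        assert bs.undefined

    def test_deterministic_under_seed(self, coalescent_dataset):
        ds = coalescent_dataset
        sp = read_tree(
            "(((X1_i0,X1_i1),(X2_i0,X2_i1)),((Y1_i0,Y1_i1),(Y2_i0,Y2_i1)));"
        )
        r1 = site_concordance(sp, ds.alignments, n_quartets=20, seed=5)
        r2 = site_concordance(sp, ds.alignments, n_quartets=20, seed=5)
        assert [b.scf for b in r1] == [b.scf for b in r2]

    def test_scf_stable_across_seeds(self, coalescent_dataset):
        ds = coalescent_dataset
        sp = read_tree(
            "(((X1_i0,X1_i1),(X2_i0,X2_i1)),((Y1_i0,Y1_i1),(Y2_i0,Y2_i1)));"
        )
        per_seed = []
        for seed in range(10):
            res = site_concordance(sp, ds.alignments, n_quartets=100, seed=seed)
            per_seed.append([b.scf for b in res if b.scf is not None])
        arr = np.array(per_seed)
        assert (arr.std(axis=0) < 2.0).all()


class TestTerminalGcf:
    def test_cherry_specimens_share_value(self):
        sp = read_tree("(((a,b),c),(d,e));")
        gts = ["(((a,b),c),(d,e));"] * 3 + ["(((a,c),b),(d,e));"]
        table = terminal_gcf_table(sp, gts)
        assert table["a"] == table["b"]
        assert table["a"] == pytest.approx(75.0)

    def test_branch_in_all_gene_trees_gives_100(self):
        sp = read_tree("(((a,b),c),(d,e));")
        gts = ["(((a,b),c),(d,e));"] * 4
        assert terminal_gcf(sp, gts, "a") == pytest.approx(100.0)

    def test_three_taxon_tree_is_undefined(self):
        sp = read_tree("((a,b),c);")
        gts = ["((a,b),c);"]
        table = terminal_gcf_table(sp, gts)
        assert table["c"] is None


# ---------------------------------------------------------------------------
# Colless imbalance


def _all_rooted_topologies(labels):
    """Enumerate all rooted binary topologies as nested tuples."""
    if len(labels) == 1:
        yield labels[0]
        return
    first = labels[0]
    rest = labels[1:]
    for size in range(1, len(rest) + 1):
        for combo in itertools.combinations(rest, size - 0):
            pass
    # standard recursion: split on which subset joins the first label
    for mask in range(1, 2 ** len(rest) - 0):
        left = [first] + [rest[i] for i in range(len(rest)) if mask & (1 << i)]
        right = [rest[i] for i in range(len(rest)) if not mask & (1 << i)]
        if not right:
            continue
        for lt in _all_rooted_topologies(left):
            for rt in _all_rooted_topologies(right):
                yield (lt, rt)


def _colless_recursive(topology):
    """Independent oracle: recursive (tips, I) computation on tuples."""
    if isinstance(topology, str):
        return 1, 0
    ln, li = _colless_recursive(topology[0])
    rn, ri = _colless_recursive(topology[1])
    return ln + rn, li + ri + abs(ln - rn)


def _to_newick(topology):
    if isinstance(topology, str):
        return topology
    return f"({_to_newick(topology[0])},{_to_newick(topology[1])})"


class TestColless:
    def test_balanced_four_tip_tree_is_zero(self):
        stat = colless(read_tree("((a,b),(c,d));"))
        assert stat.colless_i == 0
        assert stat.i_pda == 0.0

    def test_caterpillar_four_tips(self):
        stat = colless(read_tree("(((a,b),c),d);"))
        assert stat.colless_i == 2 + 1 + 0
        assert stat.i_pda == pytest.approx(3 / 8)

    def test_max_normalization_option(self):
        stat = colless(read_tree("(((a,b),c),d);"), normalization="max")
        assert stat.i_pda == pytest.approx(3 / 3)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_matches_enumeration_oracle(self, n):
        labels = [f"t{i}" for i in range(n)]
        seen = set()
        for topo in _all_rooted_topologies(labels):
            newick = _to_newick(topo) + ";"
            if newick in seen:
                continue
            seen.add(newick)
            tips, expected = _colless_recursive(topo)
            stat = colless(read_tree(newick))
            assert stat.colless_i == expected
            assert stat.n_tips == tips == n
            assert 0 <= stat.colless_i <= (n - 1) * (n - 2) / 2

    def test_polytomy_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            colless(read_tree("(a,b,c,d);"))

    def test_tiny_tree_excluded(self):
        stat = colless(read_tree("(a,b);"))
        assert stat.excluded
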