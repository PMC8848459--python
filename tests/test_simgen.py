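"""Generator correctness: moment identities, coalescent calibration,
sequence evolution closed forms, mito capture, determinism."""

import numpy as np
import pandas as pd
import pytest

from admixdelim.simgen import (
    AdmixtureEvent,
    HybridSpec,
    PopulationModel,
    SimConfig,
    evolve_sequences,
    genotypes_from_alignments,
    make_mito_capture_locus,
    simulate_allele_frequencies,
    simulate_dataset,
    simulate_gene_trees,
    simulate_genotypes,
)
from admixdelim.treekit import (
    is_monophyletic,
    nj_tree,
    p_distance_alignments,
    read_tree,
)


class TestAlleleFrequencies:
    def test_degenerate_ancestral_frequency_propagates(self):
        model = PopulationModel(["a", "b"], drift={"a": 0.3, "b": 0.3})
        freqs = simulate_allele_frequencies(
            model, 50, seed=1, ancestral_range=(0.0, 0.0)
        )
        assert (freqs.to_numpy() == 0.0).all()

    def test_weak_drift_limit_collapses_to_ancestral(self):
        model = PopulationModel(["a"], drift={"a": 1e-4})
        freqs = simulate_allele_frequencies(
            model, 100_000, seed=2, ancestral_range=(0.5, 0.5)
        )
        assert freqs.to_numpy().var() < 1e-4

    def test_balding_nichols_variance_identity(self):
        # Var(p_k) = F p (1-p) = 0.2 * 0.25 = 0.05
        model = PopulationModel(["a"], drift={"a": 0.2})
        freqs = simulate_allele_frequencies(
            model, 100_000, seed=3, ancestral_range=(0.5, 0.5)
        )
        var = freqs.to_numpy().var()
        assert var == pytest.approx(0.05, rel=0.05)

    def test_degenerate_drift_rejected(self):
        with pytest.raises(ValueError, match="strictly in"):
            PopulationModel(["a"], drift={"a": 0.0})
        with pytest.raises(ValueError, match="strictly in"):
            PopulationModel(["a"], drift={"a": 1.0})

    def test_admixture_mixture_frequencies(self):
        model = PopulationModel(
            ["d", "r"],
            drift={"d": 0.2, "r": 0.2},
            admixture=[AdmixtureEvent(0.0, "d", "r", 1.0)],
        )
        freqs = simulate_allele_frequencies(model, 200, seed=4)
        np.testing.assert_allclose(freqs.loc["r"], freqs.loc["d"])

    def test_outgroup_fixed_ancestral(self):
        model = PopulationModel(["a", "out"], drift={"a": 0.2, "out": 0.2})
        freqs = simulate_allele_frequencies(model, 100, seed=5, outgroup="out")
        assert (freqs.loc["out"] == 0.0).all()


class TestGenotypes:
    def _one_hot_q(self, pops, reps=2):
        rows, names = [], []
        for k, p in enumerate(pops):
            for i in range(reps):
                q = np.zeros(len(pops))
                q[k] = 1.0
                rows.append(q)
                names.append(f"{p}{i}")
        return pd.DataFrame(rows, index=names, columns=pops)

    def test_fixed_frequencies_give_fixed_genotypes(self):
        q = self._one_hot_q(["a", "b"])
        ones = pd.DataFrame(np.ones((2, 30)), index=["a", "b"])
        zeros = pd.DataFrame(np.zeros((2, 30)), index=["a", "b"])
        g1 = simulate_genotypes(ones, q, SimConfig(seed=1, n_loci=3))
        g0 = simulate_genotypes(zeros, q, SimConfig(seed=1, n_loci=3))
        assert (g1.genotypes == 2).all()
        assert (g0.genotypes == 0).all()

    def test_heterozygous_mean_at_diagnostic_site(self):
        # q = (0.5, 0.5) with p = (1, 0): mean genotype = 2 * 0.5 = 1
        freqs = pd.DataFrame([[1.0], [0.0]], index=["a", "b"])
        q = pd.DataFrame(
            np.full((10_000, 2), 0.5), index=[f"h{i}" for i in range(10_000)],
            columns=["a", "b"],
        )
        gm = simulate_genotypes(freqs, q, SimConfig(seed=2, n_loci=1))
        assert gm.genotypes.mean() == pytest.approx(1.0, abs=0.02)

    def test_dimension_mismatch_rejected(self):
        freqs = pd.DataFrame(np.full((3, 5), 0.5), index=["a", "b", "c"])
        q = pd.DataFrame([[0.5, 0.5]], index=["x"], columns=["a", "b"])
        with pytest.raises(ValueError, match="ancestry columns"):
            simulate_genotypes(freqs, q, SimConfig(seed=1))


class TestGeneTrees:
    def test_single_population_mean_tmrca_is_one(self):
        model = PopulationModel(["p"], tree="(p:5)root;")
        trees = simulate_gene_trees(model, {"p": ["a"]}, 2000, seed=1)
        tmrca = []
        for newick in trees:
            t = read_tree(newick)
            tmrca.append(max(l.distance_from_root() for l in t.leaf_node_iter()))
        assert np.mean(tmrca) == pytest.approx(1.0, abs=0.05)

    def test_deep_split_gives_reciprocal_monophyly(self):
        model = PopulationModel(["x", "y"], tree="((x:10,y:10)anc:1)root;")
        trees = simulate_gene_trees(
            model, {"x": ["x0", "x1"], "y": ["y0", "y1"]}, 300, seed=2
        )
        mono = 0
        for newick in trees:
            t = read_tree(newick)
            x_tips = [f"x{i}/{p}" for i in range(2) for p in (1, 2)]
            y_tips = [f"y{i}/{p}" for i in range(2) for p in (1, 2)]
            if is_monophyletic(t, x_tips) and is_monophyletic(t, y_tips):
                mono += 1
        assert mono / 300 > 0.99

    def test_pulse_routing_probability(self):
        model = PopulationModel(
            ["d", "r", "o"],
            tree="(((d:5,r:5)dr:5,o:10)anc:1)root;",
            admixture=[AdmixtureEvent(0.5, "o", "r", 0.3)],
        )
        trees = simulate_gene_trees(
            model, {"d": ["d0"], "r": ["r0"], "o": ["o0"]}, 2000, seed=3,
            haploid=True,
        )
        moved = 0
        for newick in trees:
            t = read_tree(newick)
            leaf = next(
                l for l in t.leaf_node_iter() if l.taxon.label == "r0/1"
            )
            others = {
                x.taxon.label[0] for x in leaf.parent_node.leaf_iter()
            } - {"r"}
            if others == {"o"}:
                moved += 1
        assert moved / 2000 == pytest.approx(0.30, abs=0.03)

    def test_unknown_population_in_samples(self):
        model = PopulationModel(["x"], tree="(x:5)root;")
        with pytest.raises(KeyError, match="unknown"):
            simulate_gene_trees(model, {"zz": ["a"]}, 1, seed=1)

    def test_event_time_outside_branch_rejected(self):
        with pytest.raises(ValueError, match="existence"):
            PopulationModel(
                ["x", "y"],
                tree="((x:2,y:2)anc:1)root;",
                admixture=[AdmixtureEvent(3.0, "x", "y", 0.1)],
            )


class TestSequences:
    def test_zero_rate_gives_identical_sequences(self):
        aln = evolve_sequences("(x:1,y:2);", 300, rate=0.0, seed=1)
        assert aln.sequences[0] == aln.sequences[1]

    def test_jc_expected_pairwise_difference(self):
        # d = 0.1 total: expected diff (3/4)(1 - exp(-4d/3))
        aln = evolve_sequences("(x:0.05,y:0.05);", 100_000, rate=1.0, seed=2)
        a, b = (np.frombuffer(s.encode(), dtype="S1") for s in aln.sequences)
        observed = float(np.mean(a != b))
        expected = 0.75 * (1.0 - np.exp(-4.0 * 0.1 / 3.0))
        se = np.sqrt(expected * (1 - expected) / 100_000)
        assert abs(observed - expected) < 2 * se

    def test_saturation_limit(self):
        aln = evolve_sequences("(x:500,y:500);", 50_000, rate=1.0, seed=3)
        a, b = (np.frombuffer(s.encode(), dtype="S1") for s in aln.sequences)
        assert float(np.mean(a != b)) == pytest.approx(0.75, abs=0.01)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            evolve_sequences("(x:1,y:1);", 0, rate=0.1, seed=1)


class TestDataset:
    def test_fixed_seed_byte_identical(self):
        model = PopulationModel(["x", "y"], tree="((x:3,y:3)anc:1)root;")
        cfg = SimConfig(
            n_loci=4, locus_length=200, samples_per_population=2, seed=42,
            site_missingness=0.05, ambiguity_rate=0.01,
        )
        d1 = simulate_dataset(model, cfg)
        d2 = simulate_dataset(model, cfg)
        assert d1.gene_trees == d2.gene_trees
        for a1, a2 in zip(d1.alignments, d2.alignments):
            assert a1.sequences == a2.sequences
        np.testing.assert_array_equal(d1.genotypes.genotypes, d2.genotypes.genotypes)

    def test_genotypes_recomputable_from_alignments(self, coalescent_dataset):
        ds = coalescent_dataset
        redo = genotypes_from_alignments(ds.alignments, list(ds.q_true.index))
        np.testing.assert_array_equal(ds.genotypes.genotypes, redo.genotypes)

    def test_q_true_rows_sum_to_one(self, coalescent_dataset):
        np.testing.assert_allclose(
            coalescent_dataset.q_true.sum(axis=1).to_numpy(), 1.0
        )

    def test_f1_hybrid_haplotypes_split_between_parents(self):
        model = PopulationModel(["x", "y"], tree="((x:10,y:10)anc:1)root;")
        hyb = HybridSpec("hyb", ("x", "y"), (0.5, 0.5), generation="F1")
        cfg = SimConfig(
            n_loci=10, locus_length=200, samples_per_population=2, seed=5,
            hybrids=[hyb],
        )
        ds = simulate_dataset(model, cfg)
        assert ds.q_true.loc["hyb", "x"] == 0.5
        # at every locus one haplotype coalesces inside each parent clade
        x_tips = {f"x_i{i}/{p}" for i in range(2) for p in (1, 2)}
        for newick in ds.gene_trees:
            t = read_tree(newick)
            leaf = next(
                l for l in t.leaf_node_iter() if l.taxon.label == "hyb/1"
            )
            assert leaf is not None


@pytest.fixture(scope="module")
def mito_dataset():
    nwk = "(((X:4,Y:4):4,out:8):1)root;"
    model = PopulationModel(["X", "Y", "out"], tree=nwk)
    cfg = SimConfig(
        n_loci=3, locus_length=300, samples_per_population=3, seed=9,
        mito_capture=True,
    )
    return simulate_dataset(model, cfg)


class TestMitoCapture:

    def test_no_carriers_returns_dataset_unchanged(self, mito_dataset):
        assert make_mito_capture_locus(mito_dataset, [], "Y") is mito_dataset

    def test_carriers_cluster_inside_donor_clade(self, mito_dataset):
        carriers = ["X_i0", "X_i1"]
        captured = make_mito_capture_locus(mito_dataset, carriers, "Y")
        mito = next(a for a in captured.alignments if a.locus_id == "mito")
        tree = nj_tree(p_distance_alignments([mito]))
        donors = [f"Y_i{i}" for i in range(3)]
        assert is_monophyletic(tree, donors + carriers, rooted=False)
        # partial capture splits X across two clusters
        assert not is_monophyletic(
            tree, [f"X_i{i}" for i in range(3)], rooted=False
        )

    def test_nuclear_loci_untouched(self, mito_dataset):
        captured = make_mito_capture_locus(mito_dataset, ["X_i0"], "Y")
        for before, after in zip(
            mito_dataset.alignments, captured.alignments
        ):
            if before.locus_id != "mito":
                assert before.sequences == after.sequences

    def test_unknown_carrier_rejected(self, mito_dataset):
        with pytest.raises(KeyError, match="carriers"):
            make_mito_capture_locus(mito_dataset, ["nope"], "Y")


@pytest.mark.parametrize("n_pops,t_split", [(3, 4.0)])
def test_mean_pairwise_coalescence_matches_msprime(n_pops, t_split):
    """Cross-check against an independent coalescent implementation."""
    msprime = pytest.importorskip("msprime")
    nwk = f"(((a:{t_split},b:{t_split})ab:{t_split},c:{2*t_split})anc:1)root;"
    model = PopulationModel(["a", "b", "c"], tree=nwk)
    n_loci = 600
    trees = simulate_gene_trees(
        model, {"a": ["a0"], "b": ["b0"], "c": ["c0"]}, n_loci, seed=1,
        haploid=True,
    )
    ours = {"ab": [], "ac": []}
    for newick in trees:
        t = read_tree(newick)
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        ours["ab"].append(pdm.distance(taxa["a0/1"], taxa["b0/1"]) / 2.0)
        ours["ac"].append(pdm.distance(taxa["a0/1"], taxa["c0/1"]) / 2.0)

    # msprime with matching demography; with ploidy 1 the pair-coalescence
    # rate is 1/N, so N=1 reproduces the pairwise-rate-1 scale
    demography = msprime.Demography()
    for pop in ("a", "b", "c", "ab", "anc"):
        demography.add_population(name=pop, initial_size=1.0)
    demography.add_population_split(time=t_split, derived=["a", "b"], ancestral="ab")
    demography.add_population_split(
        time=2 * t_split, derived=["ab", "c"], ancestral="anc"
    )
    theirs = {"ab": [], "ac": []}
    reps = msprime.sim_ancestry(
        samples={"a": 1, "b": 1, "c": 1},
        demography=demography,
        ploidy=1,
        num_replicates=n_loci,
        random_seed=10,
    )
    for ts in reps:
        tr = ts.first()
        theirs["ab"].append(tr.tmrca(0, 1))
        theirs["ac"].append(tr.tmrca(0, 2))
    for key in ("ab", "ac"):
        a, b = np.array(ours[key]), np.array(theirs[key])
        se = np.sqrt(a.var() / len(a) + b.var() / len(b))
        assert abs(a.mean() - b.mean()) < 3 * se
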