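"""Prebuilt synthetic experiments for the downstream statistics.

These scenario builders wire the generator tiers into the standard
experimental designs used to validate the pipeline: a many-candidate
hybridization experiment for the distortion statistics, and a null
(no-gene-flow) community for calibration of the site-pattern tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from ..treekit import nj_tree, p_distance_genotypes, read_tree, root_with_outgroup
from .coalescent import simulate_gene_trees
from .dataset import simulate_dataset
from .model import HybridSpec, PopulationModel, SimConfig


def paired_candidates_model(
    n_candidates: int = 24,
    pair_depth: float = 2.5,
    sublineage_depth: float = 1.0,
    step: float = 0.8,
    outgroup_depth: float = 18.0,
) -> PopulationModel:
    """Sister-pair community with within-candidate structure.

    Each candidate consists of two sublineages (``Pka`` and ``Pkb``,
    diverged at ``sublineage_depth``) — the phylogeographic structure
    real candidates carry. Candidates come in sister pairs whose crowns
    sit at ``pair_depth``; pairs are joined ladder-wise at increasing
    depths, plus a deep outgroup for rooting and polarization.
    """
    if n_candidates % 2:
        raise ValueError("n_candidates must be even (sister pairs)")

    def cand(k: int) -> str:
        stem = pair_depth - sublineage_depth
        return (
            f"(P{k:02d}a:{sublineage_depth},P{k:02d}b:{sublineage_depth})"
            f"P{k:02d}x:{stem}"
        )

    pairs = []
    for k in range(n_candidates // 2):
        pairs.append(
            (f"({cand(2 * k)},{cand(2 * k + 1)})pair{k:02d}", pair_depth)
        )
    frag, age = pairs[0]
    for k in range(1, len(pairs)):
        new_age = pair_depth + step * k
        sub, sub_age = pairs[k]
        frag = (
            f"({frag}:{new_age - age},{sub}:{new_age - sub_age})join{k:02d}"
        )
        age = new_age
    newick = f"(({frag}:{outgroup_depth - age},out:{outgroup_depth})anc:1)root;"
    pops = [
        f"P{i:02d}{s}" for i in range(n_candidates) for s in "ab"
    ] + ["out"]
    return PopulationModel(pops, tree=newick)


@dataclass
class DistortionExperiment:
    """One realization of the hybridization-distortion experiment."""

    tree: dendropy.Tree  # rooted concatenated NJ tree (specimen tips)
    gene_trees: list[dendropy.Tree]  # specimen-tip gene trees
    q_true: pd.DataFrame
    candidate_of: pd.Series  # specimen -> candidate
    hybrid_of: pd.Series  # specimen -> bool (constructed hybrid)
    outgroup_specimens: list[str]


def distortion_experiment(
    seed: int,
    n_candidates: int = 24,
    per_candidate: int = 14,
    hybrid_fraction: float = 0.30,
    n_loci: int = 90,
    locus_length: int = 500,
    mutation_rate: float = 0.01,
) -> DistortionExperiment:
    """Simulate a community where half the candidates harbor hybrids.

    Odd-numbered candidates receive ``hybrid_fraction`` of their members
    as admixed individuals with the even-numbered sister candidate as the
    secondary parent. Hybrid classes are mixed (an F1, then backcross-like
    individuals with clinal ancestry fractions), so admixed specimens
    carry different ancestry ratios and arrange into ladder-like grades
    rather than a tight hybrid clade — the configuration that distorts
    concatenated trees. The concatenated tree is rebuilt by neighbor
    joining from the simulated genotypes and rooted on the outgroup; the
    true per-locus gene trees are collapsed to specimen tips (one
    haplotype per specimen, phase chosen per locus) for concordance
    statistics.
    """
    model = paired_candidates_model(n_candidates)
    rng = np.random.default_rng(seed)
    hybrids = []
    n_hyb = int(round(hybrid_fraction * per_candidate))
    for k in range(0, n_candidates, 2):
        recipient, donor = f"P{k + 1:02d}a", f"P{k:02d}a"
        # ancestry fractions spread evenly from F1 toward near-pure: a
        # ladder of admixture classes (F1, backcross, clinal tail), the
        # configuration that drags specimens into graded positions
        spread = np.linspace(0.5, 0.9, n_hyb) if n_hyb > 1 else [0.5]
        for j in range(n_hyb):
            frac = float(spread[j]) + float(rng.uniform(-0.02, 0.02))
            gen = "F1" if j == 0 else ("BC1" if abs(frac - 0.75) < 0.07 else "clinal")
            if j == 0:
                frac, gen = 0.5, "F1"
            hybrids.append(
                HybridSpec(
                    individual=f"P{k + 1:02d}_i{j}",
                    parents=(recipient, donor),
                    fractions=(frac, 1.0 - frac),
                    generation=gen,
                )
            )
    # most specimens from sublineage a, a sparse pair from sublineage b —
    # sparsely sampled sublineages give pure specimens deep, well-supported
    # terminal placements
    samples: dict[str, list[str]] = {}
    for i in range(n_candidates):
        names = [f"P{i:02d}_i{j}" for j in range(per_candidate)]
        samples[f"P{i:02d}a"] = names[:-2]
        samples[f"P{i:02d}b"] = names[-2:]
    samples["out"] = ["out_i0", "out_i1"]
    cfg = SimConfig(
        n_loci=n_loci,
        locus_length=locus_length,
        mutation_rate=mutation_rate,
        samples_per_population=per_candidate,
        hybrids=hybrids,
        seed=seed,
    )
    ds = simulate_dataset(model, cfg, samples=samples)

    distances = p_distance_genotypes(ds.genotypes)
    tree = root_with_outgroup(nj_tree(distances), "out_i0")

    specimen_trees = []
    for newick in ds.gene_trees:
        gt = read_tree(newick, rooted=False)
        keep_phase = {
            spec: int(rng.integers(1, 3)) for spec in ds.q_true.index
        }
        drop = []
        for leaf in gt.leaf_node_iter():
            spec, phase = leaf.taxon.label.rsplit("/", 1)
            if int(phase) == keep_phase.get(spec, 1):
                leaf.taxon.label = spec
            else:
                drop.append(leaf.taxon)
        gt.prune_taxa(drop)
        gt.purge_taxon_namespace()
        specimen_trees.append(gt)

    candidate_of = pd.Series(
        {s: s.rsplit("_", 1)[0] for s in ds.q_true.index if not s.startswith("out")}
    )
    hybrid_names = {h.individual for h in hybrids}
    hybrid_of = pd.Series(
        {s: s in hybrid_names for s in candidate_of.index}
    )
    # candidate-level ancestry: pool the sublineage columns per candidate
    cand_of_pop = {
        pop: (pop if pop == "out" else pop[:-1]) for pop in ds.q_true.columns
    }
    q_cand = ds.q_true.T.groupby(cand_of_pop).sum().T
    return DistortionExperiment(
        tree=tree,
        gene_trees=specimen_trees,
        q_true=q_cand,
        candidate_of=candidate_of,
        hybrid_of=hybrid_of,
        outgroup_specimens=["out_i0", "out_i1"],
    )
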