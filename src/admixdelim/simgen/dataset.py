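"""End-to-end assembly of synthetic datasets (coalescent tier).

``simulate_dataset`` wires the pieces together: gene trees from the
multispecies coalescent, Jukes–Cantor sequences per locus, optional
degradation (missing bases, ambiguities), genotype calling, the true
ancestry matrix, and a population map shaped like the study's specimen
table. ``make_mito_capture_locus`` then emulates mitochondrial capture by
replanting donor haplotypes into the designated maternal locus of carrier
specimens.
"""

from __future__ import annotations

import copy
from typing import Optional

import numpy as np
import pandas as pd

from .coalescent import simulate_gene_trees
from .model import PopulationModel, SimConfig, SyntheticDataset
from .sequences import degrade_alignment, evolve_sequences, genotypes_from_alignments

MITO_LOCUS_ID = "mito"


def study_scale_model(
    drift: float = 0.2,
    admixture=None,
    ghosts=None,
) -> PopulationModel:
    """Default demography: 12 populations in 3 clades plus an outgroup.

    A quarter-scale analogue of the study system: three clades of four
    populations each, within-clade crowns at 3 coalescent units, clades
    joined at 6 and 10, and a deeply diverged outgroup at 16 units that
    downstream site-pattern code can use for polarization.
    """
    def clade(prefix: str) -> str:
        a, b, c, d = (f"{prefix}{i}" for i in range(1, 5))
        return (
            f"(({a}:1,{b}:1){prefix}_12:2,({c}:1,{d}:1){prefix}_34:2){prefix}_anc"
        )

    newick = (
        f"(({clade('A')}:3,{clade('B')}:3)AB_anc:4,"
        f"{clade('C')}:7)ABC_anc:6,out:16"
    )
    newick = f"({newick})root;"
    pops = [f"{c}{i}" for c in "ABC" for i in range(1, 5)] + ["out"]
    return PopulationModel(
        populations=pops,
        tree=newick,
        drift={p: drift for p in pops},
        admixture=admixture,
        ghosts=ghosts,
    )


def default_samples(
    model: PopulationModel, config: SimConfig
) -> dict[str, list[str]]:
    return {
        pop: [f"{pop}_i{j}" for j in range(config.samples_per_population)]
        for pop in model.sampled_populations()
    }


def true_ancestry(
    model: PopulationModel,
    samples: dict[str, list[str]],
    config: SimConfig,
) -> pd.DataFrame:
    """Ground-truth Q matrix: one-hot for pure individuals, the target
    fractions for declared hybrids. Columns are the sampled populations."""
    pops = model.sampled_populations()
    hybrid_by_name = {h.individual: h for h in config.hybrids}
    rows, names = [], []
    for pop in pops:
        for spec in samples.get(pop, []):
            q = np.zeros(len(pops))
            hyb = hybrid_by_name.get(spec)
            if hyb is None:
                q[pops.index(pop)] = 1.0
            else:
                for parent, frac in zip(hyb.parents, hyb.fractions):
                    if parent not in pops:
                        raise ValueError(
                            f"hybrid parent {parent!r} is not a sampled population"
                        )
                    q[pops.index(parent)] += frac
            rows.append(q)
            names.append(spec)
    return pd.DataFrame(rows, index=names, columns=pops)


def simulate_dataset(
    model: PopulationModel,
    config: SimConfig,
    samples: Optional[dict[str, list[str]]] = None,
) -> SyntheticDataset:
    """Simulate a complete phased dataset with ground truth.

    Byte-identical for a fixed ``config.seed``. Declared hybrid
    individuals that do not already appear in ``samples`` are attached to
    their first parent population.
    """
    if samples is None:
        samples = default_samples(model, config)
    samples = {pop: list(specs) for pop, specs in samples.items()}
    present = {s for specs in samples.values() for s in specs}
    for hyb in config.hybrids:
        if hyb.individual not in present:
            samples.setdefault(hyb.parents[0], []).append(hyb.individual)

    root = np.random.default_rng(config.seed)
    tree_seed = int(root.integers(2**31))
    mito_seed = int(root.integers(2**31))
    seq_seeds = root.integers(2**31, size=config.n_loci + 1)
    degrade_rng = np.random.default_rng(int(root.integers(2**31)))

    gene_trees = simulate_gene_trees(
        model, samples, config.n_loci, tree_seed, hybrids=config.hybrids
    )
    alignments = []
    for i, newick in enumerate(gene_trees):
        aln = evolve_sequences(
            newick,
            config.locus_length,
            config.mutation_rate,
            int(seq_seeds[i]),
            locus_id=f"L{i:04d}",
        )
        alignments.append(aln)

    mito_trees: list[str] = []
    if config.mito_capture:
        mito_trees = simulate_gene_trees(
            model, samples, 1, mito_seed, hybrids=config.hybrids, haploid=True
        )
        mito = evolve_sequences(
            mito_trees[0],
            config.locus_length,
            config.mutation_rate,
            int(seq_seeds[-1]),
            locus_id=MITO_LOCUS_ID,
        )
        # haploid maternal locus: represent as two identical haplotypes
        names, seqs = [], []
        for name, seq in zip(mito.names, mito.sequences):
            spec = name.rsplit("/", 1)[0]
            names.extend([f"{spec}/1", f"{spec}/2"])
            seqs.extend([seq, seq])
        mito.names, mito.sequences = names, seqs
        alignments.append(mito)

    if config.site_missingness or config.ambiguity_rate:
        alignments = [
            degrade_alignment(
                aln, config.site_missingness, config.ambiguity_rate, degrade_rng
            )
            for aln in alignments
        ]

    q_true = true_ancestry(model, samples, config)
    genotypes = genotypes_from_alignments(alignments, list(q_true.index))
    population_map = _population_map(model, samples, config)
    provenance = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "model_newick": model.newick,
        "n_loci": config.n_loci,
        "mito_locus": MITO_LOCUS_ID if config.mito_capture else None,
    }
    return SyntheticDataset(
        alignments=alignments,
        genotypes=genotypes,
        gene_trees=gene_trees + mito_trees,
        q_true=q_true,
        population_map=population_map,
        provenance=provenance,
    )


def _population_map(model, samples, config) -> pd.DataFrame:
    hybrid_by_name = {h.individual: h for h in config.hybrids}
    rows = []
    for pop in model.sampled_populations():
        for spec in samples.get(pop, []):
            rows.append(
                {
                    "specimen": spec,
                    "population": pop,
                    "clade": pop[0] if pop != "out" else "out",
                    "candidate": pop,
                    "lineage": "-",
                    "geo_distinct": True,
                    "hybrid_spec": hybrid_by_name.get(spec) is not None,
                }
            )
    return pd.DataFrame(rows)


def make_mito_capture_locus(
    dataset: SyntheticDataset,
    carrier_individuals: list[str],
    donor_population: str,
) -> SyntheticDataset:
    """Replace carriers' maternal-locus haplotypes with donor haplotypes.

    Carriers' mitochondrial sequences become copies of haplotypes drawn
    round-robin from non-carrier members of ``donor_population``, so the
    carriers cluster inside the donor clade on the maternal locus while
    all nuclear loci are untouched. Returns a new dataset; the input is
    not modified.
    """
    if not carrier_individuals:
        return dataset
    mito_id = dataset.provenance.get("mito_locus")
    if mito_id is None:
        raise ValueError("dataset has no maternally inherited locus")
    popmap = dataset.population_map
    known = set(popmap["specimen"])
    unknown = [c for c in carrier_individuals if c not in known]
    if unknown:
        raise KeyError(f"carriers not in dataset: {unknown}")
    donors = popmap.loc[
        (popmap["population"] == donor_population)
        & ~popmap["specimen"].isin(carrier_individuals),
        "specimen",
    ].tolist()
    if not donors:
        raise ValueError(f"no donor specimens in population {donor_population!r}")

    new = copy.deepcopy(dataset)
    mito = next(a for a in new.alignments if a.locus_id == mito_id)
    index = {name: i for i, name in enumerate(mito.names)}
    for k, carrier in enumerate(carrier_individuals):
        donor_seq = mito.sequences[index[f"{donors[k % len(donors)]}/1"]]
        for phase in (1, 2):
            mito.sequences[index[f"{carrier}/{phase}"]] = donor_seq
    new.genotypes = genotypes_from_alignments(
        new.alignments, list(new.q_true.index)
    )
    new.provenance = dict(new.provenance)
    new.provenance["mito_capture"] = {
        "carriers": list(carrier_individuals),
        "donor": donor_population,
    }
    return new
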