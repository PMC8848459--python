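"""Sequence evolution on gene trees and assembly into phased loci.

Sequences evolve under Jukes–Cantor: along a branch of expected length
``d`` substitutions/site, each site changes with probability
``(3/4)(1 - exp(-4 d / 3))`` to one of the three other bases uniformly.
Composing branches reproduces the exact JC transition probabilities, so
the closed-form expected pairwise difference between two tips separated
by path length ``d`` is ``(3/4)(1 - exp(-4 d / 3))``.
"""

from __future__ import annotations

from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from ..containers import MISSING, GenotypeMatrix, LocusAlignment, split_haplotype_name

_BASES = np.array(["A", "C", "G", "T"])
#: ambiguity codes used when injecting uncertain base calls
_AMBIG = np.array(["R", "Y", "S", "W", "K", "M"])


def evolve_sequences(
    gene_tree: str | dendropy.Tree,
    length: int,
    rate: float,
    seed: int,
    locus_id: str = "locus",
) -> LocusAlignment:
    """Evolve a phased alignment along ``gene_tree`` under Jukes–Cantor.

    ``rate`` converts the tree's branch lengths (coalescent units) into
    expected substitutions per site. The root sequence is uniform over
    A/C/G/T. Deterministic for a fixed seed.
    """
    if length < 1:
        raise ValueError("alignment length must be positive")
    if isinstance(gene_tree, str):
        tree = dendropy.Tree.get(
            data=gene_tree, schema="newick",
            preserve_underscores=True, rooting="force-rooted"
        )
    else:
        tree = gene_tree
    rng = np.random.default_rng(seed)
    root = tree.seed_node
    root._seq = rng.integers(0, 4, size=length, dtype=np.int8)
    names: list[str] = []
    seqs: list[str] = []
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        d = max(rate * (node.edge.length or 0.0), 0.0)
        p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
        seq = node.parent_node._seq.copy()
        hit = rng.random(length) < p_change
        n_hit = int(hit.sum())
        if n_hit:
            # jump uniformly to one of the 3 other bases
            seq[hit] = (seq[hit] + rng.integers(1, 4, size=n_hit)) % 4
        node._seq = seq
        if node.is_leaf():
            names.append(node.taxon.label)
            seqs.append("".join(_BASES[seq]))
    order = np.argsort(names, kind="stable")
    return LocusAlignment(
        locus_id=locus_id,
        names=[names[i] for i in order],
        sequences=[seqs[i] for i in order],
    )


def degrade_alignment(
    aln: LocusAlignment,
    site_missingness: float,
    ambiguity_rate: float,
    rng: np.random.Generator,
    individual_missingness: Optional[dict[str, float]] = None,
) -> LocusAlignment:
    """Inject missing bases and IUPAC ambiguities at the given rates.

    ``individual_missingness`` optionally adds a per-specimen missingness
    rate on top of the global per-site rate (the "degraded specimen"
    mode used to emulate poorly preserved material).
    """
    chars = aln.to_array()
    n, L = chars.shape
    per_row = np.full(n, site_missingness)
    if individual_missingness:
        for i, name in enumerate(aln.names):
            spec = split_haplotype_name(name)[0]
            per_row[i] = min(1.0, per_row[i] + individual_missingness.get(spec, 0.0))
    miss = rng.random((n, L)) < per_row[:, None]
    chars[miss] = "-"
    if ambiguity_rate > 0:
        amb = (rng.random((n, L)) < ambiguity_rate) & ~miss
        k = int(amb.sum())
        if k:
            chars[amb] = _AMBIG[rng.integers(0, len(_AMBIG), size=k)]
    return LocusAlignment(
        locus_id=aln.locus_id,
        names=list(aln.names),
        sequences=["".join(row) for row in chars],
    )


def genotypes_from_alignments(
    alignments: list[LocusAlignment],
    specimens: Optional[list[str]] = None,
) -> GenotypeMatrix:
    """Call a genotype matrix from phased alignments.

    Every biallelic variable site (two distinct unambiguous bases among
    the called haplotypes) becomes one column; the genotype is the count
    of the minor allele on the specimen's two haplotypes, missing if
    either haplotype is uncalled at that position. This is the raw call;
    the QC module applies the filtering rules.
    """
    if specimens is None:
        seen: dict[str, None] = {}
        for aln in alignments:
            for s in aln.specimens():
                seen.setdefault(s, None)
        specimens = list(seen)
    blocks: list[np.ndarray] = []
    metas: list[pd.DataFrame] = []
    for aln in alignments:
        chars = aln.to_array()
        # encode A/C/G/T as 0..3, anything else (gap, N, ambiguity) as -1
        code = np.full(chars.shape, -1, dtype=np.int8)
        for b, base in enumerate("ACGT"):
            code[chars == base] = b
        counts = np.stack(
            [(code == b).sum(axis=0) for b in range(4)], axis=0
        )  # 4 x L
        biallelic = (counts > 0).sum(axis=0) == 2
        if not biallelic.any():
            continue
        cols = np.flatnonzero(biallelic)
        sub = counts[:, cols]  # 4 x m
        # major (ref) and minor (alt) allele; ties break toward the
        # alphabetically earlier base for determinism
        order = np.argsort(-sub + np.arange(4)[:, None] * 1e-9, axis=0, kind="stable")
        ref_code, alt_code = order[0], order[1]
        hap_of: dict[str, dict[int, int]] = {}
        for i, name in enumerate(aln.names):
            spec, phase = split_haplotype_name(name)
            hap_of.setdefault(spec, {})[phase] = i
        geno = np.full((len(specimens), len(cols)), MISSING, dtype=np.int8)
        for k, spec in enumerate(specimens):
            phases = hap_of.get(spec)
            if not phases or 1 not in phases or 2 not in phases:
                continue
            a = code[phases[1], cols]
            b = code[phases[2], cols]
            ok = (a >= 0) & (b >= 0)
            g = (a == alt_code).astype(np.int8) + (b == alt_code).astype(np.int8)
            geno[k, ok] = g[ok]
        blocks.append(geno)
        metas.append(
            pd.DataFrame(
                {
                    "locus": aln.locus_id,
                    "pos": cols,
                    "ref": _BASES[ref_code],
                    "alt": _BASES[alt_code],
                }
            )
        )
    if blocks:
        geno = np.concatenate(blocks, axis=1)
        rows_meta = pd.concat(metas, ignore_index=True)
    else:
        geno = np.zeros((len(specimens), 0), dtype=np.int8)
        rows_meta = pd.DataFrame({"locus": [], "pos": [], "ref": [], "alt": []})
    return GenotypeMatrix(
        specimens=list(specimens),
        genotypes=geno,
        sites=rows_meta,
    )
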