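"""Tree building, monophyly, concordance factors and imbalance.

The primary analysis path ingests externally estimated trees (Newick);
the neighbor-joining builder here is an internal stand-in so the whole
pipeline can run self-contained. All downstream statistics are agnostic
to how the tree was inferred.

Concordance factors follow the standard definitions: for an internal
branch, the gene concordance factor (gCF) is the percentage of *decisive*
gene trees (those with at least one taxon in each of the four subtrees
adjacent to the branch) that contain the branch's bipartition restricted
to their taxa; the site concordance factor (sCF) is the mean, over
sampled quartets around the branch, of the percentage of decisive
(quartet-informative) alignment sites supporting the branch's quartet
topology. A branch with no decisive gene trees or sites is flagged
undefined rather than reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, LocusAlignment, split_haplotype_name


# ---------------------------------------------------------------------------
# Newick I/O helpers


def read_tree(source: str, rooted: bool = True) -> dendropy.Tree:
    """Parse a Newick string (or ``@path``) into a tree."""
    kwargs = {"rooting": "force-rooted" if rooted else "force-unrooted"}
    if "(" in source:
        return dendropy.Tree.get(data=source, schema="newick", preserve_underscores=True, **kwargs)
    return dendropy.Tree.get(path=source, schema="newick", preserve_underscores=True, **kwargs)


def read_trees(source: str | Iterable[str], rooted: bool = True) -> list[dendropy.Tree]:
    if isinstance(source, str):
        with open(source) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
    else:
        lines = [s for s in source if s.strip()]
    return [read_tree(ln, rooted=rooted) for ln in lines]


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# distances and neighbor joining


def p_distance_genotypes(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise p-distance between specimens with pairwise deletion.

    ``d(i, j)`` is the mean absolute allele-count difference over sites
    called in both specimens, divided by 2 (so identical genotypes give
    0 and opposite homozygotes give 1).
    """
    g = gm.genotypes.astype(np.float32)
    called = (gm.genotypes >= 0).astype(np.float32)
    g = np.where(called > 0, g, 0.0)
    n = gm.n_specimens
    shared = called @ called.T
    # sum over shared sites of |g_i - g_j| via expansion on genotype classes
    diff = np.zeros((n, n), dtype=np.float64)
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            ia = ((gm.genotypes == a).astype(np.float32))
            ib = ((gm.genotypes == b).astype(np.float32))
            diff += abs(a - b) * (ia @ ib.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = diff / (2.0 * shared)
    if np.isnan(d[np.triu_indices(n, 1)]).any():
        i, j = np.argwhere(np.isnan(d) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(
            f"no shared called sites between {gm.specimens[i]!r} "
            f"and {gm.specimens[j]!r}"
        )
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=gm.specimens, columns=gm.specimens)


def p_distance_alignments(
    alignments: Sequence[LocusAlignment],
    specimens: Optional[list[str]] = None,
    chunk: int = 20000,
) -> pd.DataFrame:
    """Mean pairwise mismatch between specimens over concatenated loci.

    Each specimen is summarized per site by its haplotype allele
    frequencies; the expected mismatch probability between two specimens
    at a site is ``1 - sum_b f_i(b) f_j(b)``, averaged over sites where
    both have at least one called haplotype (pairwise deletion).
    """
    if specimens is None:
        seen: dict[str, None] = {}
        for aln in alignments:
            for s in aln.specimens():
                seen.setdefault(s, None)
        specimens = list(seen)
    n = len(specimens)
    match = np.zeros((n, n))
    shared = np.zeros((n, n))
    for aln in alignments:
        chars = aln.to_array()
        code = np.full(chars.shape, -1, dtype=np.int8)
        for b, base in enumerate("ACGT"):
            code[chars == base] = b
        rows_of: dict[str, list[int]] = {}
        for i, name in enumerate(aln.names):
            rows_of.setdefault(split_haplotype_name(name)[0], []).append(i)
        L = aln.length
        for start in range(0, L, chunk):
            sl = slice(start, min(start + chunk, L))
            width = sl.stop - sl.start
            freq = np.zeros((n, width, 4), dtype=np.float32)
            called = np.zeros((n, width), dtype=np.float32)
            for k, spec in enumerate(specimens):
                rows = rows_of.get(spec, [])
                if not rows:
                    continue
                sub = code[rows, sl]
                cnt = np.stack([(sub == b).sum(axis=0) for b in range(4)], axis=1)
                tot = cnt.sum(axis=1)
                ok = tot > 0
                freq[k, ok] = cnt[ok] / tot[ok, None]
                called[k] = ok
            flat = freq.reshape(n, width * 4)
            match += (flat @ flat.T).astype(np.float64)
            shared += (called @ called.T).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - match / shared
    bad = np.isnan(d) & ~np.eye(n, dtype=bool)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"no shared called sites between {specimens[i]!r} and {specimens[j]!r}"
        )
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=specimens, columns=specimens)


def nj_tree(distances: pd.DataFrame) -> dendropy.Tree:
    """Saitou–Nei neighbor joining on a distance matrix.

    Ties in the Q criterion break deterministically toward the pair
    earliest in taxon-label order. Negative branch lengths are clamped to
    0 with the deficit transferred to the adjacent branch so path lengths
    are preserved. Exact on additive matrices. The result is unrooted
    (trifurcating seed node).
    """
    labels = list(distances.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    order = np.argsort(labels, kind="stable")
    labels = [labels[i] for i in order]
    d = distances.to_numpy(dtype=float)[np.ix_(order, order)]
    if not np.isfinite(d).all():
        raise ValueError("distances must be finite")

    nodes: list[str] = [f"{lbl}" for lbl in labels]  # newick fragments
    active = list(range(len(labels)))
    D = d.copy()

    while len(active) > 3:
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        m = len(idx)
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)
        a, b = divmod(flat, m)
        if a > b:
            a, b = b, a
        i, j = idx[a], idx[b]
        dij = D[i, j]
        li = dij / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        merged = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        new_d = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_d])
        D = np.hstack([D, np.append(new_d, 0.0)[:, None]])
        nodes.append(merged)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    li = (D[i, j] + D[i, k] - D[j, k]) / 2.0
    lj = (D[i, j] + D[j, k] - D[i, k]) / 2.0
    lk = (D[i, k] + D[j, k] - D[i, j]) / 2.0
    li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
    newick = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g},{nodes[k]}:{lk:.10g});"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True, rooting="force-unrooted")


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    elif lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


# ---------------------------------------------------------------------------
# monophyly


def is_monophyletic(
    tree: dendropy.Tree, label_set: Iterable[str], rooted: bool = True
) -> bool:
    """Does ``label_set`` form a clade (rooted) or a bipartition (unrooted)?"""
    want = frozenset(label_set)
    have = frozenset(leaf_labels(tree))
    unknown = want - have
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    if want == have or len(want) == 1:
        return True
    if rooted:
        for node in tree.preorder_internal_node_iter():
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            if below == want:
                return True
        return False
    return want in _bipartition_sides(tree) or (have - want) in _bipartition_sides(tree)


def _bipartition_sides(tree: dendropy.Tree) -> set[frozenset]:
    """Both sides of every non-trivial bipartition of the (unrooted) tree."""
    all_taxa = frozenset(leaf_labels(tree))
    sides: set[frozenset] = set()
    for node in tree.preorder_internal_node_iter():
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        other = all_taxa - below
        if len(below) >= 2 and len(other) >= 2:
            sides.add(below)
            sides.add(other)
    return sides


# ---------------------------------------------------------------------------
# concordance factors


@dataclass
class BranchSupport:
    """Support record for one internal branch (identified by bipartition)."""

    bipartition: frozenset
    gcf: Optional[float] = None
    scf: Optional[float] = None
    concordant: int = 0
    decisive: int = 0
    undefined: bool = False


@dataclass
class _BranchContext:
    bipartition: frozenset  # leaves below the branch
    clades: tuple[frozenset, frozenset, frozenset, frozenset]  # A, B, C, D


def _branch_contexts(tree: dendropy.Tree) -> list[_BranchContext]:
    """Internal branches with their four adjacent subtree leaf sets.

    A and B are the two subtrees below the branch, C and D the two on the
    far side (in the unrooted sense; a degree-2 root is suppressed).
    """
    work = tree.clone(depth=1)
    if len(work.seed_node.child_nodes()) == 2:
        work.collapse_basal_bifurcation()
    all_taxa = frozenset(l.taxon.label for l in work.leaf_node_iter())
    below: dict[int, frozenset] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.child_nodes())
            )
    contexts = []
    for node in work.preorder_internal_node_iter():
        if node is work.seed_node:
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError("concordance factors require a binary tree")
        a, b = (below[id(c)] for c in children)
        parent = node.parent_node
        siblings = [c for c in parent.child_nodes() if c is not node]
        if parent is work.seed_node:
            if len(siblings) != 2:
                raise ValueError("unexpected root degree")
            c_set, d_set = (below[id(s)] for s in siblings)
        else:
            c_set = below[id(siblings[0])]
            d_set = all_taxa - a - b - c_set
        if not c_set or not d_set:
            continue
        contexts.append(
            _BranchContext(bipartition=a | b, clades=(a, b, c_set, d_set))
        )
    return contexts


def gene_concordance(
    species_tree: dendropy.Tree, gene_trees: Sequence[dendropy.Tree | str]
) -> list[BranchSupport]:
    """Gene concordance factor for every internal branch.

    Gene trees may omit taxa; a gene tree is decisive for a branch only
    if it contains at least one taxon from each of the branch's four
    adjacent subtrees, and concordant if, restricted to its own taxa, it
    contains the branch's bipartition.
    """
    if not gene_trees:
        raise ValueError("no gene trees supplied")
    parsed = [
        read_tree(t, rooted=False) if isinstance(t, str) else t for t in gene_trees
    ]
    gene_info = []
    for gt in parsed:
        taxa = frozenset(leaf_labels(gt))
        gene_info.append((taxa, _bipartition_sides(gt)))
    supports = []
    for ctx in _branch_contexts(species_tree):
        a, b, c, d = ctx.clades
        concordant = decisive = 0
        for taxa, sides in gene_info:
            if not (taxa & a and taxa & b and taxa & c and taxa & d):
                continue
            decisive += 1
            target = frozenset(ctx.bipartition & taxa)
            if target in sides or (taxa - target) in sides:
                concordant += 1
        supports.append(
            BranchSupport(
                bipartition=ctx.bipartition,
                gcf=100.0 * concordant / decisive if decisive else None,
                concordant=concordant,
                decisive=decisive,
                undefined=decisive == 0,
            )
        )
    return supports


def _specimen_sequences(
    alignments: Sequence[LocusAlignment], taxa: Iterable[str]
) -> dict[str, np.ndarray]:
    """Concatenated first-haplotype sequence per specimen, coded 0..3/-1."""
    taxa = list(taxa)
    chunks: dict[str, list[np.ndarray]] = {t: [] for t in taxa}
    for aln in alignments:
        code = np.full((aln.n_haplotypes, aln.length), -1, dtype=np.int8)
        chars = aln.to_array()
        for b, base in enumerate("ACGT"):
            code[chars == base] = b
        row_of = {}
        for i, name in enumerate(aln.names):
            spec, phase = split_haplotype_name(name)
            if phase == 1:
                row_of[spec] = i
        for t in taxa:
            if t in row_of:
                chunks[t].append(code[row_of[t]])
            else:
                chunks[t].append(np.full(aln.length, -1, dtype=np.int8))
    return {t: np.concatenate(chunks[t]) for t in taxa}


def site_concordance(
    species_tree: dendropy.Tree,
    alignments: Sequence[LocusAlignment],
    n_quartets: int = 100,
    seed: int = 0,
) -> list[BranchSupport]:
    """Quartet-sampled site concordance factor per internal branch.

    For each branch, up to ``n_quartets`` quartets are sampled with one
    taxon from each adjacent subtree; a site is decisive for a quartet
    when all four taxa are called, exactly two alleles occur, and the
    split is 2+2. sCF is the mean over quartets (with at least one
    decisive site) of the percentage of decisive sites matching the
    branch's quartet. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    taxa = leaf_labels(species_tree)
    seqs = _specimen_sequences(alignments, taxa)
    supports = []
    for ctx in _branch_contexts(species_tree):
        a, b, c, d = (sorted(s) for s in ctx.clades)
        ratios = []
        for _ in range(n_quartets):
            qa = seqs[a[rng.integers(len(a))]]
            qb = seqs[b[rng.integers(len(b))]]
            qc = seqs[c[rng.integers(len(c))]]
            qd = seqs[d[rng.integers(len(d))]]
            called = (qa >= 0) & (qb >= 0) & (qc >= 0) & (qd >= 0)
            if not called.any():
                continue
            sa, sb, sc, sd = (s[called] for s in (qa, qb, qc, qd))
            conc = (sa == sb) & (sc == sd) & (sa != sc)
            d1 = (sa == sc) & (sb == sd) & (sa != sb)
            d2 = (sa == sd) & (sb == sc) & (sa != sb)
            decisive = conc | d1 | d2
            n_dec = int(decisive.sum())
            if n_dec:
                ratios.append(100.0 * conc.sum() / n_dec)
        supports.append(
            BranchSupport(
                bipartition=ctx.bipartition,
                scf=float(np.mean(ratios)) if ratios else None,
                decisive=len(ratios),
                undefined=not ratios,
            )
        )
    return supports


def terminal_gcf(
    tree: dendropy.Tree,
    gene_trees: Sequence[dendropy.Tree | str],
    specimen: str,
) -> Optional[float]:
    """gCF of the internal branch immediately ancestral to a terminal.

    Sister specimens in a cherry share the cherry's subtending branch and
    therefore report identical values. Returns None (undefined) when the
    terminal hangs directly off the unrooted "root" trifurcation.
    """
    return terminal_gcf_table(tree, gene_trees)[specimen]


def terminal_gcf_table(
    tree: dendropy.Tree, gene_trees: Sequence[dendropy.Tree | str]
) -> pd.Series:
    """Terminal gCF for every specimen in one pass (see terminal_gcf)."""
    supports: dict[frozenset, BranchSupport] = {}
    all_taxa = frozenset(leaf_labels(tree))
    for bs in gene_concordance(tree, gene_trees):
        # an unrooted bipartition can surface as either side
        supports[bs.bipartition] = bs
        supports[all_taxa - bs.bipartition] = bs
    values: dict[str, Optional[float]] = {}
    for leaf in tree.leaf_node_iter():
        parent = leaf.parent_node
        if parent is None or parent is tree.seed_node:
            values[leaf.taxon.label] = None
            continue
        below = frozenset(l.taxon.label for l in parent.leaf_iter())
        bs = supports.get(below)
        values[leaf.taxon.label] = None if bs is None or bs.undefined else bs.gcf
    return pd.Series(values)


# ---------------------------------------------------------------------------
# imbalance


@dataclass
class ImbalanceStat:
    clade_id: str
    n_tips: int
    colless_i: int
    i_pda: float
    excluded: bool = False  # clades with < 3 tips carry no signal


def colless(
    tree: dendropy.Tree,
    clade_id: str = "",
    normalization: str = "pda",
) -> ImbalanceStat:
    """Colless imbalance of a rooted binary tree.

    ``I`` sums ``|L - R|`` over all internal nodes (cherries contribute
    0). The default normalization divides by ``n**1.5``, the scaling of
    the expected imbalance under the proportional-to-distinguishable-
    arrangements (PDA) null model; ``normalization="max"`` divides by the
    caterpillar maximum ``(n - 1)(n - 2) / 2`` instead.
    """
    n = len(tree.leaf_nodes())
    if n < 3:
        return ImbalanceStat(clade_id, n, 0, 0.0, excluded=True)
    total = 0
    for node in tree.preorder_internal_node_iter():
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError(
                "Colless imbalance requires a rooted binary tree "
                "(resolve polytomies first)"
            )
        l, r = (len(c.leaf_nodes()) for c in children)
        total += abs(l - r)
    if normalization == "pda":
        norm = total / n**1.5
    elif normalization == "max":
        norm = total / ((n - 1) * (n - 2) / 2.0)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return ImbalanceStat(clade_id, n, total, norm)


def resolve_polytomies(tree: dendropy.Tree, seed: int = 0) -> dendropy.Tree:
    """Randomly (but reproducibly) resolve polytomies. Off by default in
    every caller; provided for trees from consensus methods."""
    work = tree.clone(depth=1)
    rng = np.random.default_rng(seed)
    work.resolve_polytomies(rng=_RngShim(rng))
    return work


class _RngShim:
    """Adapter giving dendropy the ``sample``/``shuffle`` calls it expects."""

    def __init__(self, rng: np.random.Generator) -> None:
        self._rng = rng

    def sample(self, population, k):
        idx = self._rng.choice(len(population), size=k, replace=False)
        return [population[i] for i in idx]

    def shuffle(self, x):
        self._rng.shuffle(x)

    def randint(self, a, b):
        return int(self._rng.integers(a, b + 1))


def root_with_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Rooted copy with ``outgroup`` as the sister of everything else."""
    work = tree.clone(depth=1)
    leaf = next(
        (l for l in work.leaf_node_iter() if l.taxon.label == outgroup), None
    )
    if leaf is None:
        raise KeyError(f"outgroup {outgroup!r} not in tree")
    length = leaf.edge.length or 0.0
    work.reroot_at_edge(leaf.edge, length1=length / 2, length2=length / 2)
    work.is_rooted = True
    return work


def extract_subtree(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Tree:
    """Pruned copy containing only ``labels`` (rooted at their MRCA)."""
    keep = set(labels)
    sub = tree.extract_tree_with_taxa_labels(keep)
    sub.purge_taxon_namespace()
    return sub
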