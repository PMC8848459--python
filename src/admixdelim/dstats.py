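"""Excess-allele-sharing statistics: D, f4-ratio and f-branch.

All statistics work on population-sample derived-allele frequencies
polarized against a designated outgroup, with loci as linkage blocks for
delete-one block-jackknife standard errors.

For an ordered quartet (P1, P2, P3, O) with derived frequencies
``p1, p2, p3, p4`` per site:

* ``ABBA = sum (1-p1) p2 p3 (1-p4)`` and ``BABA = sum p1 (1-p2) p3 (1-p4)``;
  Patterson's ``D = (ABBA - BABA) / (ABBA + BABA)``.
* the f4-ratio admixture fraction for donor C into recipient B is
  ``f = S(A, B, Ca, O) / S(A, Cb, Ca, O)`` where ``S`` is the summed
  ABBA-BABA difference and C's called haplotypes are split per site into
  random halves Ca/Cb (removing the same-sample squared-frequency bias).
* the f-branch statistic maps excess sharing onto a rooted species tree:
  ``f_b(C) = median over A in sister(b) of min over B in desc(b) of
  f(A, B, C, O)`` for donors C outside b's subtree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .treekit import leaf_labels


# ---------------------------------------------------------------------------
# allele-frequency table


@dataclass
class AlleleFrequencyTable:
    """Per-population derived-allele counts at polarized biallelic sites."""

    populations: list[str]
    derived: np.ndarray  # populations x sites, derived-allele counts
    called: np.ndarray  # populations x sites, called haplotype counts
    blocks: np.ndarray  # site -> block id
    outgroup: str
    polarized: bool = True

    def freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.called > 0, self.derived / self.called, np.nan)

    def index(self, pop: str) -> int:
        try:
            return self.populations.index(pop)
        except ValueError:
            raise KeyError(f"population {pop!r} not in table") from None


def allele_freqs(
    gm: GenotypeMatrix,
    population_map: pd.Series | dict[str, str],
    outgroup: str,
    max_outgroup_maf: float = 0.10,
) -> AlleleFrequencyTable:
    """Polarized per-population derived-allele frequencies.

    The outgroup's major allele is taken as ancestral; sites are dropped
    when the outgroup has no called haplotypes, when its minor-allele
    frequency exceeds ``max_outgroup_maf`` (too polymorphic to polarize),
    or when no ingroup variation remains. Blocks follow the site->locus
    provenance.
    """
    if not isinstance(population_map, pd.Series):
        population_map = pd.Series(population_map)
    pops = sorted(population_map.unique())
    if outgroup not in pops:
        raise KeyError(f"outgroup {outgroup!r} absent from population map")
    rows_of = {
        pop: [gm.specimens.index(s) for s in population_map.index[population_map == pop]]
        for pop in pops
    }
    g = gm.genotypes
    n_pops, n_sites = len(pops), gm.n_sites
    alt = np.zeros((n_pops, n_sites))
    called = np.zeros((n_pops, n_sites))
    for i, pop in enumerate(pops):
        sub = g[rows_of[pop]]
        ok = sub >= 0
        alt[i] = np.where(ok, sub, 0).sum(axis=0)
        called[i] = 2.0 * ok.sum(axis=0)
    for i, pop in enumerate(pops):
        if called[i].sum() == 0:
            raise ValueError(f"population {pop!r} has zero called haplotypes")

    og = pops.index(outgroup)
    with np.errstate(invalid="ignore", divide="ignore"):
        og_freq = np.where(called[og] > 0, alt[og] / called[og], np.nan)
    keep = called[og] > 0
    flip = keep & (og_freq > 0.5)
    derived = alt.copy()
    derived[:, flip] = called[:, flip] - alt[:, flip]
    with np.errstate(invalid="ignore", divide="ignore"):
        og_derived = np.where(called[og] > 0, derived[og] / called[og], np.nan)
    keep &= ~(og_derived > max_outgroup_maf)

    ingroup = [i for i in range(n_pops) if i != og]
    with np.errstate(invalid="ignore", divide="ignore"):
        f_in = np.where(called[ingroup] > 0, derived[ingroup] / called[ingroup], np.nan)
    any_seg = (np.nanmax(f_in, axis=0) > 0) & (np.nanmin(f_in, axis=0) < 1)
    keep &= np.where(np.isnan(any_seg), False, any_seg)

    idx = np.flatnonzero(keep)
    return AlleleFrequencyTable(
        populations=pops,
        derived=derived[:, idx],
        called=called[:, idx],
        blocks=gm.site_blocks()[idx],
        outgroup=outgroup,
    )


# ---------------------------------------------------------------------------
# jackknife


def jackknife_se(loo_values: np.ndarray) -> float:
    """Delete-one block-jackknife standard error from leave-one-out values."""
    loo = np.asarray(loo_values, dtype=float)
    m = loo.size
    if m < 2:
        raise ValueError("jackknife requires at least 2 blocks")
    return float(np.sqrt((m - 1) / m * np.sum((loo - loo.mean()) ** 2)))


def jackknife(theta: float, loo_values: np.ndarray) -> tuple[float, float, float]:
    """(SE, Z, two-sided p) for a blocked statistic.

    Degenerate (identical) leave-one-out values give SE = 0 and p = nan,
    flagged to the caller by the nan rather than a spurious 0.
    """
    se = jackknife_se(loo_values)
    if se == 0.0:
        return 0.0, np.inf if theta != 0 else 0.0, np.nan
    z = theta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return se, float(z), float(p)


# ---------------------------------------------------------------------------
# Patterson's D


@dataclass
class DResult:
    trio: tuple[str, str, str]
    outgroup: str
    d: float
    se: float
    z: float
    p: float
    abba: float
    baba: float
    n_blocks: int
    swapped: bool = False  # P1/P2 swapped to make D >= 0
    undefined: bool = False


def patterson_d(
    freqs: AlleleFrequencyTable,
    trio: tuple[str, str, str],
    outgroup: Optional[str] = None,
) -> DResult:
    """ABBA-BABA test with block-jackknife significance.

    P1 and P2 are oriented so the reported D is nonnegative (the original
    orientation is recorded via ``swapped``). Sites where any of the four
    populations has no called haplotype are skipped.
    """
    outgroup = outgroup or freqs.outgroup
    p = freqs.freq()
    i1, i2, i3, i4 = (freqs.index(x) for x in (*trio, outgroup))
    ok = ~np.isnan(p[[i1, i2, i3, i4]]).any(axis=0)
    p1, p2, p3, p4 = (p[i][ok] for i in (i1, i2, i3, i4))
    blocks = freqs.blocks[ok]
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)

    n_blocks_total = int(freqs.blocks.max()) + 1 if freqs.blocks.size else 0
    if n_blocks_total < 2:
        raise ValueError("need at least 2 blocks for the jackknife")
    sum_a = np.bincount(blocks, weights=abba, minlength=n_blocks_total)
    sum_b = np.bincount(blocks, weights=baba, minlength=n_blocks_total)
    tot_a, tot_b = sum_a.sum(), sum_b.sum()
    if tot_a + tot_b == 0:
        return DResult(trio, outgroup, np.nan, np.nan, np.nan, np.nan, 0.0, 0.0,
                       n_blocks_total, undefined=True)
    d = (tot_a - tot_b) / (tot_a + tot_b)
    swapped = d < 0
    if swapped:
        trio = (trio[1], trio[0], trio[2])
        sum_a, sum_b = sum_b, sum_a
        tot_a, tot_b = tot_b, tot_a
        d = -d
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (tot_a - sum_a - (tot_b - sum_b)) / (tot_a - sum_a + tot_b - sum_b)
    loo = loo[~np.isnan(loo)]
    se, z, pval = jackknife(d, loo)
    return DResult(
        trio=trio,
        outgroup=outgroup,
        d=float(d),
        se=se,
        z=z,
        p=pval,
        abba=float(tot_a),
        baba=float(tot_b),
        n_blocks=n_blocks_total,
        swapped=bool(swapped),
    )


def d_statistic_raw(
    freqs: AlleleFrequencyTable, trio: tuple[str, str, str]
) -> float:
    """Unoriented D (P1/P2 as given); exact antisymmetry under swap."""
    p = freqs.freq()
    i1, i2, i3, i4 = (freqs.index(x) for x in (*trio, freqs.outgroup))
    ok = ~np.isnan(p[[i1, i2, i3, i4]]).any(axis=0)
    p1, p2, p3, p4 = (p[i][ok] for i in (i1, i2, i3, i4))
    abba = ((1 - p1) * p2 * p3 * (1 - p4)).sum()
    baba = (p1 * (1 - p2) * p3 * (1 - p4)).sum()
    if abba + baba == 0:
        return np.nan
    return float((abba - baba) / (abba + baba))


# ---------------------------------------------------------------------------
# f4-ratio


@dataclass
class F4Result:
    quartet: tuple[str, str, str, str]  # A, B, C, O
    f_raw: float
    f: float  # clamped to [0, 1]
    numerator: float
    denominator: float
    block_num: np.ndarray = field(repr=False, default=None)
    block_den: np.ndarray = field(repr=False, default=None)
    undefined: bool = False


def f4_ratio(
    freqs: AlleleFrequencyTable,
    A: str,
    B: str,
    C: str,
    O: Optional[str] = None,
    seed: int = 0,
) -> F4Result:
    """Admixture fraction of donor C in recipient B via the f4-ratio.

    C's called haplotypes are split per site into two random halves Ca
    and Cb (seeded hypergeometric draw on the counts); the estimate is
    ``sum (pB - pA) pCa (1 - pO) / sum (pCb - pA) pCa (1 - pO)``. Sites
    where C has fewer than 2 called haplotypes are skipped. A
    non-positive denominator flags the result undefined.
    """
    O = O or freqs.outgroup
    rng = np.random.default_rng(seed)
    f = freqs.freq()
    ia, ib, ic, io = (freqs.index(x) for x in (A, B, C, O))
    nc = freqs.called[ic]
    dc = freqs.derived[ic]
    ok = (
        ~np.isnan(f[[ia, ib, io]]).any(axis=0)
        & (nc >= 2)
    )
    pa, pb, po = f[ia][ok], f[ib][ok], f[io][ok]
    n = nc[ok].astype(int)
    d = dc[ok].astype(int)
    na = n // 2
    nb = n - na
    ha = rng.hypergeometric(d, n - d, na)
    hb = d - ha
    pca = ha / na
    pcb = hb / nb
    blocks = freqs.blocks[ok]

    num = (pb - pa) * pca * (1 - po)
    den = (pcb - pa) * pca * (1 - po)
    n_blocks_total = int(freqs.blocks.max()) + 1 if freqs.blocks.size else 0
    block_num = np.bincount(blocks, weights=num, minlength=n_blocks_total)
    block_den = np.bincount(blocks, weights=den, minlength=n_blocks_total)
    tot_num, tot_den = block_num.sum(), block_den.sum()
    if tot_den <= 0:
        return F4Result((A, B, C, O), np.nan, np.nan, tot_num, tot_den,
                        block_num, block_den, undefined=True)
    f_raw = tot_num / tot_den
    return F4Result(
        quartet=(A, B, C, O),
        f_raw=float(f_raw),
        f=float(np.clip(f_raw, 0.0, 1.0)),
        numerator=float(tot_num),
        denominator=float(tot_den),
        block_num=block_num,
        block_den=block_den,
    )


# ---------------------------------------------------------------------------
# f-branch


@dataclass
class FBranchMatrix:
    """Branch x donor matrix of f-branch values with significance.

    ``values`` holds the clamped f_b estimates (NaN where structurally
    undefined, i.e. the donor sits inside the recipient clade);
    ``pvals`` the jackknife p-values; ``display`` the mask at the
    configured threshold (value > threshold and p < 0.05). ``branches``
    maps each row label to its descendant tip set.
    """

    values: pd.DataFrame
    pvals: pd.DataFrame
    display: pd.DataFrame
    branches: dict[str, frozenset]
    threshold: float


def _branch_rows(tree: dendropy.Tree, outgroup: str) -> list[tuple[str, frozenset, frozenset]]:
    """(label, descendant tips, sister tips) per branch, ladderized order."""
    work = tree.clone(depth=1)
    tips = set(leaf_labels(work))
    if outgroup in tips:
        work.prune_taxa_with_labels([outgroup])
        work.purge_taxon_namespace()
    work.ladderize()
    rows = []
    for node in work.preorder_node_iter():
        if node is work.seed_node or node.parent_node is None:
            continue
        desc = frozenset(l.taxon.label for l in node.leaf_iter())
        siblings = [c for c in node.parent_node.child_nodes() if c is not node]
        sister = frozenset(
            l.taxon.label for s in siblings for l in s.leaf_iter()
        )
        if not sister:
            continue
        label = (
            next(iter(desc))
            if len(desc) == 1
            else "+".join(sorted(desc))
        )
        rows.append((label, desc, sister))
    return rows


def f_branch(
    species_tree: dendropy.Tree,
    freqs: AlleleFrequencyTable,
    threshold: float = 0.20,
    seed: int = 0,
    trio_results: Optional[dict] = None,
) -> FBranchMatrix:
    """Map excess allele sharing onto branches of a rooted species tree.

    For each branch b (terminal and internal) and each candidate donor C
    outside b's subtree, ``f_b(C)`` is the median over A in sister(b) of
    the minimum over B in desc(b) of the f4-ratio f(A, B, C, O), with
    negative medians clamped to 0. Cells with donors inside the
    recipient clade are structurally undefined (NaN). Significance is a
    delete-one block jackknife of the full median-min statistic.
    Precomputed ``trio_results`` (keyed by (A, B, C)) are reused.
    """
    outgroup = freqs.outgroup
    tree_tips = set(leaf_labels(species_tree)) - {outgroup}
    table_pops = set(freqs.populations) - {outgroup}
    missing = tree_tips - table_pops
    if missing:
        raise KeyError(f"tree tips absent from frequency table: {sorted(missing)}")
    donors = sorted(tree_tips)
    rows = _branch_rows(species_tree, outgroup)
    cache: dict = dict(trio_results or {})

    def trio(a: str, b: str, c: str) -> F4Result:
        key = (a, b, c)
        if key not in cache:
            cache[key] = f4_ratio(freqs, a, b, c, outgroup, seed=seed)
        return cache[key]

    n_blocks = None
    values = pd.DataFrame(np.nan, index=[r[0] for r in rows], columns=donors)
    pvals = pd.DataFrame(np.nan, index=[r[0] for r in rows], columns=donors)
    for label, desc, sister in rows:
        for c in donors:
            if c in desc:
                continue  # structurally masked
            a_stats, a_loo = [], []
            for a in sorted(sister):
                if a == c:
                    continue
                b_vals, b_loo = [], []
                for b in sorted(desc):
                    if b == c:
                        continue
                    res = trio(a, b, c)
                    if res.undefined:
                        continue
                    b_vals.append(res.f_raw)
                    n_blocks = res.block_num.size
                    tot_n = res.block_num.sum()
                    tot_d = res.block_den.sum()
                    with np.errstate(invalid="ignore", divide="ignore"):
                        loo = (tot_n - res.block_num) / (tot_d - res.block_den)
                    b_loo.append(loo)
                if not b_vals:
                    continue
                pick = int(np.argmin(b_vals))
                a_stats.append(b_vals[pick])
                a_loo.append(np.min(np.vstack(b_loo), axis=0))
            if not a_stats:
                continue
            stat = float(np.median(a_stats))
            loo_stats = np.median(np.vstack(a_loo), axis=0)
            loo_stats = loo_stats[np.isfinite(loo_stats)]
            if loo_stats.size >= 2:
                _, _, pv = jackknife(stat, loo_stats)
            else:
                pv = np.nan
            values.loc[label, c] = max(stat, 0.0)
            pvals.loc[label, c] = pv
    display = (values > threshold) & (pvals < 0.05)
    return FBranchMatrix(
        values=values,
        pvals=pvals,
        display=display,
        branches={label: desc for label, desc, _ in rows},
        threshold=threshold,
    )


def fbranch_row_correlation(matrix: FBranchMatrix) -> pd.DataFrame:
    """Pairwise correlation of f-branch rows.

    A deep branch-to-branch event tends to leave correlated signal across
    the rows of related recipients; this report helps spot that pattern.
    It is an observation aid, not a test.
    """
    filled = matrix.values.fillna(0.0)
    return filled.T.corr()
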