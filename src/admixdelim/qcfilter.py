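"""Data-trimming and SNP-extraction rules.

The rules are applied with strict threshold semantics, exactly as they
are usually quoted for target-capture QC:

* haplotypes (alleles) with **>80%** missing data or **>5%** ambiguities
  are removed from alignments;
* specimens with **>50%** missing genotype calls are dropped from SNP
  matrices (they remain available for tree analyses);
* SNPs are kept only when biallelic, with **<20%** missing data among the
  clade members being analysed, and not singletons (minor allele seen on
  exactly one haplotype).

Ambiguity codes count toward "ambiguities"; gaps and Ns count toward
"missing". Multi-allelic sites are dropped rather than split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import (
    MISSING,
    GenotypeMatrix,
    LocusAlignment,
    split_haplotype_name,
)


@dataclass
class FilterReport:
    """Per-rule accounting of what a filter removed.

    ``counts[rule] = (dropped, retained)``; for every rule the two add up
    to the number of items the rule saw.
    """

    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    dropped_ids: dict[str, list[str]] = field(default_factory=dict)

    def record(self, rule: str, dropped: list[str], retained: int) -> None:
        self.counts[rule] = (len(dropped), retained)
        self.dropped_ids[rule] = list(dropped)

    def to_dict(self) -> dict:
        return {
            "counts": {k: list(v) for k, v in self.counts.items()},
            "dropped": self.dropped_ids,
        }


def trim_alleles(
    aln: LocusAlignment,
    max_missing: float = 0.80,
    max_ambig: float = 0.05,
) -> tuple[LocusAlignment, FilterReport]:
    """Remove haplotypes with >``max_missing`` missing or >``max_ambig``
    ambiguous bases (strict inequalities; a haplotype at exactly the
    threshold is retained). Survivor order is preserved."""
    if not 0.0 <= max_missing <= 1.0 or not 0.0 <= max_ambig <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")
    if aln.n_haplotypes == 0:
        raise ValueError(f"locus {aln.locus_id}: empty alignment")
    keep, dropped = [], []
    for i, name in enumerate(aln.names):
        if aln.missing_fraction(i) > max_missing or aln.ambiguity_fraction(i) > max_ambig:
            dropped.append(name)
        else:
            keep.append(i)
    report = FilterReport()
    report.record("allele_trim", dropped, len(keep))
    return aln.subset(keep), report


def drop_individuals(
    gm: GenotypeMatrix, max_missing: float = 0.50
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop specimens whose genotype missingness exceeds ``max_missing``
    (strictly). Raises if nothing would remain."""
    frac = gm.specimen_missingness()
    keep = [s for s, f in zip(gm.specimens, frac) if f <= max_missing]
    dropped = [s for s, f in zip(gm.specimens, frac) if f > max_missing]
    if not keep:
        raise ValueError(
            f"all {gm.n_specimens} specimens exceed {max_missing:.0%} missing data"
        )
    report = FilterReport()
    report.record("individual_missingness", dropped, len(keep))
    return gm.subset_specimens(keep), report


def extract_snps(
    alignments: list[LocusAlignment],
    clade_members: list[str],
    max_site_missing: float = 0.20,
    drop_singletons: bool = True,
    singleton_on_genotypes: bool = False,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Extract a clade-specific biallelic SNP matrix from phased loci.

    Site filters, applied among ``clade_members`` only:

    * invariant and multi-allelic sites removed;
    * sites with missingness ``>= max_site_missing`` removed (the kept
      sites have strictly less than the threshold);
    * singletons removed: minor allele observed on exactly one haplotype
      (or, with ``singleton_on_genotypes``, in exactly one specimen).

    Provenance (locus, position, alleles) is kept per retained site. An
    input with no variable sites yields an empty matrix, not an error.
    """
    if not clade_members:
        raise ValueError("clade_members must be non-empty")
    member_set = set(clade_members)
    report = FilterReport()
    kept_cols: list[np.ndarray] = []
    metas = {"locus": [], "pos": [], "ref": [], "alt": []}
    n_invariant = n_multi = n_missing = n_singleton = 0

    for aln in alignments:
        hap_rows: dict[str, dict[int, int]] = {}
        member_rows = []
        for i, name in enumerate(aln.names):
            spec, phase = split_haplotype_name(name)
            if spec in member_set:
                hap_rows.setdefault(spec, {})[phase] = i
                member_rows.append(i)
        if not member_rows:
            continue
        chars = aln.to_array()[member_rows]
        code = np.full(chars.shape, -1, dtype=np.int8)
        for b, base in enumerate("ACGT"):
            code[chars == base] = b
        counts = np.stack([(code == b).sum(axis=0) for b in range(4)])
        n_alleles = (counts > 0).sum(axis=0)
        missing_frac = (code < 0).mean(axis=0)

        for j in range(aln.length):
            if n_alleles[j] < 2:
                n_invariant += 1
                continue
            if n_alleles[j] > 2:
                n_multi += 1
                continue
            if missing_frac[j] >= max_site_missing:
                n_missing += 1
                continue
            col = counts[:, j]
            alleles = np.flatnonzero(col)
            maj, mino = alleles[np.argsort(col[alleles])[::-1]]
            if col[maj] == col[mino]:  # tie: alphabetically earlier = major
                maj, mino = sorted(alleles)
            if drop_singletons:
                if singleton_on_genotypes:
                    carriers = {
                        split_haplotype_name(aln.names[member_rows[r]])[0]
                        for r in np.flatnonzero(code[:, j] == mino)
                    }
                    is_singleton = len(carriers) == 1 and col[mino] <= 2
                else:
                    is_singleton = col[mino] == 1
                if is_singleton:
                    n_singleton += 1
                    continue
            geno = np.full(len(clade_members), MISSING, dtype=np.int8)
            for k, spec in enumerate(clade_members):
                phases = hap_rows.get(spec)
                if not phases or 1 not in phases or 2 not in phases:
                    continue
                a = aln.sequences[phases[1]][j]
                b = aln.sequences[phases[2]][j]
                bases = "ACGT"
                if a not in bases or b not in bases:
                    continue
                geno[k] = int(bases.index(a) == mino) + int(bases.index(b) == mino)
            kept_cols.append(geno)
            metas["locus"].append(aln.locus_id)
            metas["pos"].append(j)
            metas["ref"].append("ACGT"[maj])
            metas["alt"].append("ACGT"[mino])

    report.counts["invariant"] = (n_invariant, len(kept_cols))
    report.counts["multiallelic"] = (n_multi, len(kept_cols))
    report.counts["site_missingness"] = (n_missing, len(kept_cols))
    report.counts["singleton"] = (n_singleton, len(kept_cols))

    if kept_cols:
        geno = np.stack(kept_cols, axis=1)
    else:
        geno = np.zeros((len(clade_members), 0), dtype=np.int8)
    gm = GenotypeMatrix(
        specimens=list(clade_members),
        genotypes=geno,
        sites=pd.DataFrame(metas),
    )
    return gm, report


def pca_genotypes(
    gm: GenotypeMatrix, n_axes: int = 2, scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the SNP matrix for cluster visualization.

    Missing entries are imputed with the per-site mean; genotypes are
    centered (and optionally scaled to unit variance). Returns the score
    table (specimens x axes) and the explained-variance fractions. If
    ``n_axes`` exceeds the matrix rank the result is truncated.
    """
    if gm.n_specimens < 2 or gm.n_sites < 1:
        raise ValueError("PCA requires at least 2 specimens and 1 site")
    x = gm.genotypes.astype(float)
    mask = gm.missing_mask()
    with np.errstate(invalid="ignore"):
        means = np.nanmean(np.where(mask, np.nan, x), axis=0)
    means = np.nan_to_num(means, nan=0.0)
    x = np.where(mask, means[None, :], x)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = x / sd
    max_rank = min(gm.n_specimens - 1, gm.n_sites)
    k = min(n_axes, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    table = pd.DataFrame(
        scores,
        index=gm.specimens,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return table, pca.explained_variance_ratio_
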