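"""Core in-memory containers shared across the toolkit.

Two objects move between nearly every stage of the pipeline:

* :class:`LocusAlignment` — a phased multiple-sequence alignment for one
  nuclear (or mitochondrial) locus, with two haplotype rows per diploid
  specimen (``<specimen>/1`` and ``<specimen>/2``).
* :class:`GenotypeMatrix` — a specimens x biallelic-sites matrix of
  minor/derived-allele counts in {0, 1, 2}, with -1 marking missing calls
  and per-site provenance (locus, position, alleles) retained so that
  sites can always be traced back to the alignment they came from and
  grouped into linkage blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: bases treated as "missing" in alignments (gap / undetermined)
MISSING_CHARS = frozenset("-?Nn.")
#: IUPAC ambiguity codes (heterozygous or uncertain base calls)
AMBIGUITY_CHARS = frozenset("RYSWKMBDHVryswkmbdhv")
_ACGT = frozenset("ACGTacgt")


def haplotype_name(specimen: str, phase: int) -> str:
    """Canonical haplotype label, e.g. ``("sp1", 1) -> "sp1/1"``."""
    return f"{specimen}/{phase}"


def split_haplotype_name(name: str) -> tuple[str, int]:
    specimen, _, phase = name.rpartition("/")
    if not specimen:
        raise ValueError(f"haplotype name {name!r} lacks a '/<phase>' suffix")
    return specimen, int(phase)


@dataclass
class LocusAlignment:
    """Phased alignment for a single locus.

    Attributes
    ----------
    locus_id:
        Identifier of the locus (used for site provenance and blocking).
    names:
        Haplotype labels, ``<specimen>/<phase>``; order is meaningful.
    sequences:
        Upper-case sequence strings, one per haplotype, equal lengths.
    """

    locus_id: str
    names: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(
                f"locus {self.locus_id}: unequal sequence lengths {sorted(lengths)}"
            )
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_haplotypes(self) -> int:
        return len(self.names)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def specimens(self) -> list[str]:
        """Unique specimen ids, preserving first-appearance order."""
        seen: dict[str, None] = {}
        for name in self.names:
            seen.setdefault(split_haplotype_name(name)[0], None)
        return list(seen)

    def to_array(self) -> np.ndarray:
        """Alignment as a (haplotypes, sites) array of single characters."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype="S1"
        ).reshape(self.n_haplotypes, self.length).astype("U1")

    def missing_fraction(self, i: int) -> float:
        seq = self.sequences[i]
        if not seq:
            return 0.0
        return sum(c in MISSING_CHARS for c in seq) / len(seq)

    def ambiguity_fraction(self, i: int) -> float:
        seq = self.sequences[i]
        if not seq:
            return 0.0
        return sum(c in AMBIGUITY_CHARS for c in seq) / len(seq)

    def subset(self, keep: list[int]) -> "LocusAlignment":
        return LocusAlignment(
            locus_id=self.locus_id,
            names=[self.names[i] for i in keep],
            sequences=[self.sequences[i] for i in keep],
        )


@dataclass
class GenotypeMatrix:
    """Specimens x sites matrix of allele counts with site provenance.

    ``genotypes[i, j]`` is the number of copies of the alternate allele
    carried by specimen ``i`` at site ``j`` (0, 1, 2), or ``MISSING``.
    ``sites`` carries one row per column with at least the columns
    ``locus``, ``pos``, ``ref`` and ``alt``.
    """

    specimens: list[str]
    genotypes: np.ndarray
    sites: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D")
        if self.genotypes.shape[0] != len(self.specimens):
            raise ValueError("row count does not match specimen list")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values must be in {0, 1, 2, missing}")
        if len(self.sites) == 0:
            self.sites = pd.DataFrame(
                {
                    "locus": ["locus0"] * self.n_sites,
                    "pos": np.arange(self.n_sites),
                    "ref": ["A"] * self.n_sites,
                    "alt": ["T"] * self.n_sites,
                }
            )
        if len(self.sites) != self.n_sites:
            raise ValueError("site table does not match genotype columns")

    @property
    def n_specimens(self) -> int:
        return len(self.specimens)

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def specimen_missingness(self) -> np.ndarray:
        """Fraction of missing calls per specimen."""
        if self.n_sites == 0:
            return np.zeros(self.n_specimens)
        return self.missing_mask().mean(axis=1)

    def site_missingness(self) -> np.ndarray:
        """Fraction of missing calls per site."""
        if self.n_specimens == 0:
            return np.zeros(self.n_sites)
        return self.missing_mask().mean(axis=0)

    def subset_specimens(self, keep: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.specimens)}
        unknown = [s for s in keep if s not in index]
        if unknown:
            raise KeyError(f"unknown specimens: {unknown}")
        rows = [index[s] for s in keep]
        return GenotypeMatrix(
            specimens=list(keep),
            genotypes=self.genotypes[rows],
            sites=self.sites.reset_index(drop=True).copy(),
        )

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            specimens=list(self.specimens),
            genotypes=self.genotypes[:, keep],
            sites=self.sites.iloc[keep].reset_index(drop=True),
        )

    def site_blocks(self) -> np.ndarray:
        """Integer block id per site (one block per locus, in order)."""
        loci = self.sites["locus"].to_numpy()
        _, inverse = np.unique(loci, return_inverse=True)
        return inverse
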