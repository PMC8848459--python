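"""Readers and writers for the on-disk dataset layout.

A simulated (or real) dataset directory holds per-locus phased FASTA
files, a diploid VCF, one Newick gene tree per line, a specimen table
(CSV) and a YAML provenance record.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..containers import MISSING, GenotypeMatrix, LocusAlignment
from .model import SyntheticDataset


def write_fasta(aln: LocusAlignment, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in zip(aln.names, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike, locus_id: str | None = None) -> LocusAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    return LocusAlignment(
        locus_id=locus_id or Path(path).stem,
        names=[r.id for r in records],
        sequences=[str(r.seq) for r in records],
    )


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write the genotype matrix as minimal diploid VCF v4.2 (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for locus in dict.fromkeys(gm.sites["locus"]):
            fh.write(f"##contig=<ID={locus}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.specimens)
            + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, site in gm.sites.iterrows():
            calls = "\t".join(
                gt_strings[int(g)] for g in gm.genotypes[:, j]
            )
            fh.write(
                f"{site['locus']}\t{int(site['pos']) + 1}\t.\t{site['ref']}\t"
                f"{site['alt']}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a diploid VCF back into a genotype matrix (via pysam).

    Only the GT field is used; biallelic records only. ALT allele counts
    are reported, matching :func:`write_vcf`.
    """
    import pandas as pd
    import pysam

    rows, meta = [], {"locus": [], "pos": [], "ref": [], "alt": []}
    with pysam.VariantFile(str(path)) as vcf:
        specimens = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            genos = []
            for s in specimens:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    genos.append(MISSING)
                else:
                    genos.append(sum(int(a) for a in gt))
            rows.append(genos)
            meta["locus"].append(rec.chrom)
            meta["pos"].append(rec.pos - 1)
            meta["ref"].append(rec.ref)
            meta["alt"].append(rec.alts[0])
    geno = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(specimens), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        specimens=specimens, genotypes=geno, sites=pd.DataFrame(meta)
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | os.PathLike) -> None:
    """Write alignments, VCF, gene trees, population map and provenance."""
    out = Path(out_dir)
    (out / "loci").mkdir(parents=True, exist_ok=True)
    for aln in dataset.alignments:
        write_fasta(aln, out / "loci" / f"{aln.locus_id}.fasta")
    write_vcf(dataset.genotypes, out / "genotypes.vcf")
    with open(out / "gene_trees.nwk", "w") as fh:
        for newick in dataset.gene_trees:
            fh.write(newick.rstrip() + "\n")
    dataset.q_true.rename_axis("specimen").to_csv(out / "q_true.csv")
    dataset.population_map.to_csv(out / "population_map.csv", index=False)
    with open(out / "provenance.yaml", "w") as fh:
        yaml.safe_dump(dataset.provenance, fh, sort_keys=True)
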