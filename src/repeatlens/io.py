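"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA goes through Biopython; the minimal SNP VCF through pysam.  Record IDs
for allele FASTA follow ``sample|allele1`` / ``sample|allele2``; mixed
heterozygote amplicons are one IUPAC record per sample.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif_core import AlleleStructure, DiploidGenotype, format_nomenclature

#: rs identifiers of the five flanking SNPs, in plus-strand order around the
#: repeat locus (SNP1, SNP2, [repeat], SNP3, SNP4, SNP5).
SNP_IDS = ("rs11150824", "rs2289534", "rs3829612", "rs10782008", "rs12943620")


def write_fasta(records: Iterable[tuple[str, str]], path: str) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        path,
        "fasta",
    )


def read_fasta(path: str) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]


def write_genotype_table(genotypes: Sequence[DiploidGenotype], path: str) -> None:
    rows = []
    for g in genotypes:
        row = {
            "sample": g.sample_id,
            "allele1": format_nomenclature(g.allele1),
            "allele2": format_nomenclature(g.allele2),
        }
        if g.snp_genotypes is not None:
            for rsid, gt in zip(SNP_IDS, g.snp_genotypes):
                row[rsid] = f"{gt[0]}/{gt[1]}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genotype_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_snp_vcf(genotypes: Sequence[DiploidGenotype], path: str) -> None:
    """Minimal single-contig VCF with GT-only genotypes for the 5 SNPs.

    SNP alleles are coded 0/1 internally; REF/ALT are written as placeholder
    A/G since the panel is purely biallelic-by-code.
    """
    header = pysam.VariantHeader()
    header.add_line('##contig=<ID=chr17,length=83257441>')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for g in genotypes:
        header.add_sample(g.sample_id)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for i, rsid in enumerate(SNP_IDS):
            rec = vcf.new_record(
                contig="chr17", start=80_000_000 + 100_000 * i, stop=80_000_000 + 100_000 * i + 1,
                alleles=("A", "G"), id=rsid,
            )
            for g in genotypes:
                gt = g.snp_genotypes[i] if g.snp_genotypes is not None else (None, None)
                rec.samples[g.sample_id]["GT"] = tuple(gt)
                rec.samples[g.sample_id].phased = False
            vcf.write(rec)


def read_snp_vcf(path: str) -> pd.DataFrame:
    """Read GT codes keyed by rs ID; returns samples x SNP DataFrame of
    (code, code) tuples with None for missing."""
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        data: dict[str, list] = {s: [] for s in samples}
        rsids = []
        for rec in vcf:
            rsids.append(rec.id)
            for s in samples:
                gt = rec.samples[s]["GT"]
                data[s].append(None if gt is None or None in gt else tuple(gt))
    return pd.DataFrame(data, index=rsids).T


def write_plate_tsv(wells: pd.DataFrame, path: str) -> None:
    wells.to_csv(path, sep="\t", index=False)


def read_plate_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
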