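"""Readers and writers for the standard interchange formats.

FASTA via Biopython, allele-observation and SNP tables as TSV, annotation as
GFF3, candidate variants as VCF (pysam).  The VCF layout used here carries the
GATK-style site annotations in INFO (QD, MQ, FS, SOR, DP) plus per-accession
DNA/RNA depths (DNADP_*, RNADP_*), and one genotype column per dataset named
``<accession>.<dataset>`` (e.g. ``accA.dna``), so a reference SNP build is
fully reconstructable from a single file.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variants import CandidateSNP, ReferenceSNPSet, VariantAnnotations


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, os.fspath(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(os.fspath(path), "fasta")
    }


def write_observations(observations: pd.DataFrame, path) -> None:
    observations.to_csv(path, sep="\t", index=False)


def read_observations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_snp_table(snp_table: pd.DataFrame, path) -> None:
    snp_table.to_csv(path, sep="\t", index=False)


def read_snp_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_reference_snps(ref: ReferenceSNPSet, path) -> None:
    ref.to_frame().to_csv(path, sep="\t", index=False)


def read_reference_snps(path) -> ReferenceSNPSet:
    return ReferenceSNPSet.from_frame(pd.read_csv(path, sep="\t"))


def write_gff3(annotation: pd.DataFrame, path) -> None:
    """Transcript annotation as GFF3 (mRNA + five_prime_UTR/CDS/
    three_prime_UTR features, 1-based closed coordinates)."""
    feature_types = {
        "utr5": "five_prime_UTR",
        "cds": "CDS",
        "utr3": "three_prime_UTR",
    }
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            start = min(row.utr5_start, row.cds_start, row.utr3_start)
            end = max(row.utr5_end, row.cds_end, row.utr3_end)
            fh.write(
                f"{row.contig}\tgraftmobile\tmRNA\t{start}\t{end}\t.\t"
                f"{row.strand}\t.\tID={row.transcript}\n"
            )
            for region, ftype in feature_types.items():
                fh.write(
                    f"{row.contig}\tgraftmobile\t{ftype}\t"
                    f"{getattr(row, f'{region}_start')}\t"
                    f"{getattr(row, f'{region}_end')}\t.\t{row.strand}\t.\t"
                    f"Parent={row.transcript}\n"
                )


def read_gff3(path) -> pd.DataFrame:
    """Read annotation written by :func:`write_gff3` back into the flat
    per-transcript table."""
    region_of = {
        "five_prime_UTR": "utr5",
        "CDS": "cds",
        "three_prime_UTR": "utr3",
    }
    rows: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            contig, _, ftype, start, end, _, strand, _, attrs = (
                line.rstrip("\n").split("\t")
            )
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "mRNA":
                rows[attr_map["ID"]] = {
                    "transcript": attr_map["ID"],
                    "contig": contig,
                    "strand": strand,
                }
            elif ftype in region_of:
                region = region_of[ftype]
                rec = rows[attr_map["Parent"]]
                rec[f"{region}_start"] = int(start)
                rec[f"{region}_end"] = int(end)
    return pd.DataFrame(list(rows.values()))


def write_candidate_vcf(
    candidates: Iterable[CandidateSNP],
    contig_lengths: Mapping[str, int],
    path,
) -> None:
    """Candidate SNPs as a plain-text VCF with site annotations in INFO and
    per-dataset genotype columns."""
    import pysam

    candidates = list(candidates)
    accessions: list[str] = []
    datasets: list[tuple[str, str]] = []
    for v in candidates:
        for acc, calls in v.per_accession_alleles.items():
            if acc not in accessions:
                accessions.append(acc)
            for ds in calls:
                if (acc, ds) not in datasets:
                    datasets.append((acc, ds))

    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=length)
    for key, vtype, desc in [
        ("QD", "Float", "Quality by depth"),
        ("MQ", "Float", "RMS mapping quality"),
        ("FS", "Float", "Fisher strand bias (phred)"),
        ("SOR", "Float", "Strand odds ratio"),
        ("DP", "Integer", "Total read depth"),
    ]:
        header.info.add(key, number=1, type=vtype, description=desc)
    for acc in accessions:
        header.info.add(
            f"DNADP_{acc}", number=1, type="Integer",
            description=f"DNA depth in {acc}",
        )
        header.info.add(
            f"RNADP_{acc}", number=1, type="Integer",
            description=f"RNA depth in {acc}",
        )
    header.info.add(
        "TRANSCRIPT", number=1, type="String", description="Source transcript"
    )
    header.formats.add("GT", number=1, type="String", description="Genotype")
    sample_names = [f"{acc}.{ds}" for acc, ds in datasets]
    for name in sample_names:
        header.add_sample(name)

    with pysam.VariantFile(os.fspath(path), "w", header=header) as vcf:
        for v in candidates:
            rec = vcf.new_record(
                contig=v.contig,
                start=v.pos - 1,
                stop=v.pos,
                alleles=(v.ref_allele, v.alt_allele),
            )
            a = v.annotations
            rec.info["QD"] = float(a.qd)
            rec.info["MQ"] = float(a.mq)
            rec.info["FS"] = float(a.fs)
            rec.info["SOR"] = float(a.sor)
            rec.info["DP"] = int(a.dp)
            for acc in accessions:
                rec.info[f"DNADP_{acc}"] = int(v.dna_depth.get(acc, 0))
                rec.info[f"RNADP_{acc}"] = int(v.rna_depth.get(acc, 0))
            if v.transcript:
                rec.info["TRANSCRIPT"] = v.transcript
            alleles = (v.ref_allele, v.alt_allele)
            for (acc, ds), name in zip(datasets, sample_names):
                call = v.per_accession_alleles.get(acc, {}).get(ds)
                if call in alleles:
                    idx = alleles.index(call)
                    rec.samples[name]["GT"] = (idx, idx)
                elif call is not None and len(call) == 2:
                    # heterozygous shorthand, e.g. "GT"
                    rec.samples[name]["GT"] = (0, 1)
                else:
                    rec.samples[name]["GT"] = (None,)
            vcf.write(rec)


def read_candidate_vcf(path) -> list[CandidateSNP]:
    """Read candidate SNPs from a VCF produced by
    :func:`write_candidate_vcf` (or any VCF carrying the same INFO keys)."""
    import pysam

    out: list[CandidateSNP] = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        sample_names = list(vcf.header.samples)
        accessions = sorted({name.split(".", 1)[0] for name in sample_names})
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                continue  # non-biallelic records are dropped at read time
            alleles = (rec.ref, rec.alts[0])
            per_acc: dict[str, dict[str, str]] = {acc: {} for acc in accessions}
            for name in sample_names:
                acc, ds = name.split(".", 1)
                gt = rec.samples[name].get("GT")
                if gt is None or any(g is None for g in gt):
                    call = "N"
                elif len(set(gt)) > 1:
                    call = "".join(sorted(alleles[g] for g in gt))
                else:
                    call = alleles[gt[0]]
                per_acc[acc][ds] = call
            info = rec.info
            out.append(
                CandidateSNP(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    annotations=VariantAnnotations(
                        qd=float(info["QD"]),
                        mq=float(info["MQ"]),
                        fs=float(info["FS"]),
                        sor=float(info["SOR"]),
                        dp=int(info["DP"]),
                    ),
                    per_accession_alleles=per_acc,
                    dna_depth={
                        acc: int(info.get(f"DNADP_{acc}", 0)) for acc in accessions
                    },
                    rna_depth={
                        acc: int(info.get(f"RNADP_{acc}", 0)) for acc in accessions
                    },
                    transcript=info.get("TRANSCRIPT"),
                )
            )
    return out
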