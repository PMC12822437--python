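"""Accession-specific reference SNP construction.

Candidate variants (GATK-style annotations) are passed through a fixed filter
ladder — hard filtering on site annotations, depth support in both DNA- and
RNA-level data for both accessions, genotype consistency across datasets, and
exclusion of organellar contigs — and the survivors become the diagnostic
reference SNP set used to assign sequencing reads to their accession of
origin.  Each rejected variant is attributed to the first stage that failed,
so stage counts always sum back to the input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

_VALID_BASES = frozenset("ACGT")

#: Hard-filter thresholds: a record failing ANY clause is removed.
HARD_FILTER_THRESHOLDS = {
    "qd_min": 2.0,
    "mq_min": 40.0,
    "fs_max": 60.0,
    "sor_max": 3.0,
    "dp_min": 10,
}

FILTER_STAGES = ("hard_filter", "support", "consistency", "organelle", "pass")


@dataclass(frozen=True)
class VariantAnnotations:
    """Site-level quality annotations (GATK INFO semantics).

    qd: quality by depth; mq: RMS mapping quality; fs: Fisher strand-bias
    (phred); sor: strand odds ratio; dp: total read depth.
    """

    qd: float
    mq: float
    fs: float
    sor: float
    dp: int

    def __post_init__(self) -> None:
        for name in ("qd", "mq", "fs", "sor", "dp"):
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"missing annotation {name!r}")
            if not math.isfinite(float(value)):
                raise ValueError(f"annotation {name!r} is not finite: {value!r}")
        if self.dp < 0:
            raise ValueError(f"DP must be >= 0, got {self.dp}")


@dataclass
class CandidateSNP:
    """A biallelic candidate variant between the two accessions.

    per_accession_alleles maps accession -> {dataset-id -> observed allele};
    a heterozygous or ambiguous call is any value that is not a single
    A/C/G/T.  dna_depth / rna_depth map accession -> coverage in the genomic
    and transcriptomic data.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    annotations: VariantAnnotations
    per_accession_alleles: Mapping[str, Mapping[str, str]]
    dna_depth: Mapping[str, int]
    rna_depth: Mapping[str, int]
    transcript: str | None = None

    def __post_init__(self) -> None:
        if self.ref_allele not in _VALID_BASES or self.alt_allele not in _VALID_BASES:
            raise ValueError(
                f"alleles must be single A/C/G/T bases, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class ReferenceSNPSet:
    """Diagnostic SNPs keyed by (contig, pos) -> (allele_a, allele_b)."""

    entries: dict[tuple[str, int], tuple[str, str]] = field(default_factory=dict)
    transcripts: dict[tuple[str, int], str | None] = field(default_factory=dict)

    def add(
        self,
        contig: str,
        pos: int,
        allele_a: str,
        allele_b: str,
        transcript: str | None = None,
    ) -> None:
        key = (contig, pos)
        if allele_a == allele_b:
            raise ValueError(f"alleles at {key} must differ")
        if key in self.entries and self.entries[key] != (allele_a, allele_b):
            raise ValueError(
                f"conflicting alleles at {key}: "
                f"{self.entries[key]} vs {(allele_a, allele_b)}"
            )
        self.entries[key] = (allele_a, allele_b)
        self.transcripts[key] = transcript

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.entries

    def alleles(self, contig: str, pos: int) -> tuple[str, str]:
        return self.entries[(contig, pos)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "contig": contig,
                "pos": pos,
                "allele_a": a,
                "allele_b": b,
                "transcript": self.transcripts.get((contig, pos)),
            }
            for (contig, pos), (a, b) in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows, columns=["contig", "pos", "allele_a", "allele_b", "transcript"]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReferenceSNPSet":
        out = cls()
        for row in frame.itertuples(index=False):
            transcript = getattr(row, "transcript", None)
            out.add(row.contig, int(row.pos), row.allele_a, row.allele_b, transcript)
        return out


def hard_filter_variant(
    v: CandidateSNP, thresholds: Mapping[str, float] = HARD_FILTER_THRESHOLDS
) -> bool:
    """True iff the variant survives hard filtering.

    Fails iff QD < 2.0 or MQ < 40.0 or FS > 60.0 or SOR > 3.0 or DP < 10
    (at the default thresholds).  A missing annotation raises rather than
    silently passing; VariantAnnotations enforces this at construction.
    """
    a = v.annotations
    return not (
        a.qd < thresholds["qd_min"]
        or a.mq < thresholds["mq_min"]
        or a.fs > thresholds["fs_max"]
        or a.sor > thresholds["sor_max"]
        or a.dp < thresholds["dp_min"]
    )


def support_filter(v: CandidateSNP, min_depth: int = 10) -> bool:
    """True iff the site is covered by >= min_depth reads in both the DNA and
    the RNA data of both accessions."""
    depths = list(v.dna_depth.values()) + list(v.rna_depth.values())
    if any(d < 0 for d in depths):
        raise ValueError(f"negative depth at {(v.contig, v.pos)}")
    return all(d >= min_depth for d in depths)


def _single_allele(calls: Mapping[str, str]) -> str | None:
    """The one allele reported by all datasets of an accession, or None if
    calls disagree, are heterozygous, or are not clean single bases."""
    alleles = set(calls.values())
    if len(alleles) != 1:
        return None
    allele = alleles.pop()
    if not isinstance(allele, str) or len(allele) != 1 or allele not in _VALID_BASES:
        return None
    return allele


def genotype_consistency(v: CandidateSNP) -> bool:
    """True iff each accession reports one homozygous allele across all of
    its datasets and the two accessions' alleles differ."""
    per_acc = [
        _single_allele(calls) for calls in v.per_accession_alleles.values()
    ]
    if len(per_acc) != 2 or any(a is None for a in per_acc):
        return False
    return per_acc[0] != per_acc[1]


@dataclass
class FilterReport:
    """Per-stage removal counts; input = passed + sum(removed)."""

    n_input: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {s: 0 for s in FILTER_STAGES[:-1]}
    )
    n_passed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": s, "removed": n} for s, n in self.removed.items()]
        rows.append({"stage": "pass", "removed": self.n_passed})
        return pd.DataFrame(rows)


def first_failing_stage(
    v: CandidateSNP,
    organelle_contigs: Iterable[str],
    min_depth: int = 10,
    thresholds: Mapping[str, float] = HARD_FILTER_THRESHOLDS,
) -> str:
    """Stage at which a candidate is removed, or 'pass'.

    Fixed order: hard filter -> depth support -> genotype consistency ->
    organelle exclusion."""
    if not hard_filter_variant(v, thresholds):
        return "hard_filter"
    if not support_filter(v, min_depth):
        return "support"
    if not genotype_consistency(v):
        return "consistency"
    if v.contig in set(organelle_contigs):
        return "organelle"
    return "pass"


def build_reference_snps(
    candidates: Iterable[CandidateSNP],
    organelle_contigs: Iterable[str] = (),
    min_depth: int = 10,
    thresholds: Mapping[str, float] = HARD_FILTER_THRESHOLDS,
) -> tuple[ReferenceSNPSet, FilterReport]:
    """Apply the filter ladder and assemble the diagnostic SNP set.

    The retained alleles are (accession-A allele, accession-B allele) in the
    order the accessions appear in ``per_accession_alleles``.  Duplicate
    (contig, pos) keys with conflicting alleles raise.
    """
    organelle = set(organelle_contigs)
    ref = ReferenceSNPSet()
    report = FilterReport()
    for v in candidates:
        report.n_input += 1
        stage = first_failing_stage(v, organelle, min_depth, thresholds)
        if stage != "pass":
            report.removed[stage] += 1
            continue
        accs = list(v.per_accession_alleles)
        allele_a = _single_allele(v.per_accession_alleles[accs[0]])
        allele_b = _single_allele(v.per_accession_alleles[accs[1]])
        assert allele_a is not None and allele_b is not None
        ref.add(v.contig, v.pos, allele_a, allele_b, v.transcript)
        report.n_passed += 1
    return ref, report


def candidates_from_truth(
    truth,
    dna_depth: int = 30,
    rna_depth: int = 30,
    annotations: VariantAnnotations | None = None,
) -> list[CandidateSNP]:
    """Clean CandidateSNPs for every SNP in a synthetic truth object
    (organellar sites included, so organelle exclusion is exercised)."""
    if annotations is None:
        annotations = VariantAnnotations(qd=25.0, mq=60.0, fs=1.0, sor=1.0, dp=60)
    acc_a, acc_b = truth.accessions
    out = []
    for row in truth.snp_table.itertuples(index=False):
        out.append(
            CandidateSNP(
                contig=row.contig,
                pos=int(row.pos),
                ref_allele=row.allele_a,
                alt_allele=row.allele_b,
                annotations=annotations,
                per_accession_alleles={
                    acc_a: {"dna": row.allele_a, "rna": row.allele_a},
                    acc_b: {"dna": row.allele_b, "rna": row.allele_b},
                },
                dna_depth={acc_a: dna_depth, acc_b: dna_depth},
                rna_depth={acc_a: rna_depth, acc_b: rna_depth},
                transcript=row.transcript,
            )
        )
    return out
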