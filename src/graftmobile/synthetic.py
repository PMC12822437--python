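"""Synthetic heterograft experiments with known ground truth.

Everything downstream of read alignment in the mobile-mRNA pipeline consumes
per-SNP allele counts, so the generators here emit allele-observation tables
directly (one row per SNP site per sample) rather than reads.  The simulated
design mirrors a reciprocal hypocotyl-grafting experiment between two
polymorphic accessions: scion/rootstock genotype combinations, shoot and root
tissues, four phosphate regimes, and replicated sequencing with a uniform
per-base error model.  Companion generators produce TRAP-seq (ribosome
immunoprecipitation) tables and targeted DMS mutational-profiling counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The four phosphate regimes of the grafting design: 7 d full Pi (control),
#: 3 d and 7 d of Pi starvation, and 7 d starvation + 2 d resupply.
CONDITIONS: tuple[str, ...] = ("FP7D", "NP3D", "NP7D", "NP7DRP2D")

#: Conditions grouped by effective Pi status.  Mobility seen only under
#: deficiency is "Pi starvation induced" (PSI); only under sufficiency,
#: "Pi starvation decreased" (PSD).
PI_SUFFICIENT: frozenset[str] = frozenset({"FP7D", "NP7DRP2D"})
PI_DEFICIENT: frozenset[str] = frozenset({"NP3D", "NP7D"})

DIRECTIONS: tuple[str, str] = ("shoot_to_root", "root_to_shoot")

TISSUES: tuple[str, str] = ("shoot", "root")

_BASES = np.array(["A", "C", "G", "T"])

#: Direction a foreign transcript must have travelled to appear in a tissue.
DIRECTION_OF_TISSUE: dict[str, str] = {
    "root": "shoot_to_root",
    "shoot": "root_to_shoot",
}


@dataclass(frozen=True)
class GraftSample:
    """One grafted sample: genotypes of the two graft partners, treatment
    condition and which tissue was harvested."""

    scion_genotype: str
    rootstock_genotype: str
    condition: str
    tissue: str

    @property
    def is_heterograft(self) -> bool:
        return self.scion_genotype != self.rootstock_genotype

    @property
    def tissue_genotype(self) -> str:
        """Genotype locally encoded by the harvested tissue."""
        return (
            self.rootstock_genotype if self.tissue == "root" else self.scion_genotype
        )

    @property
    def donor_genotype(self) -> str:
        """Genotype of the graft partner, i.e. of any foreign transcript."""
        return (
            self.scion_genotype if self.tissue == "root" else self.rootstock_genotype
        )

    @property
    def label(self) -> str:
        return (
            f"r{self.rootstock_genotype}-s{self.scion_genotype}"
            f"_{self.condition}_{self.tissue}"
        )


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated accession pair.

    genomes
        accession -> contig -> sequence.
    annotation
        One row per transcript: contig, strand and 1-based closed intervals
        for the 5'UTR, CDS and 3'UTR in genomic coordinates.
    snp_table
        Biallelic diagnostic SNPs: contig, pos, allele_a, allele_b,
        transcript.
    mobile_truth
        transcript x condition x direction -> expected foreign-read fraction
        at each covered SNP in the recipient tissue.
    translated_truth
        mobile transcript -> whether its foreign copies are ribosome bound in
        the recipient tissue.
    expression_truth
        transcript x tissue x condition -> relative mean expression.
    """

    accessions: tuple[str, str]
    genomes: dict[str, dict[str, str]]
    annotation: pd.DataFrame
    snp_table: pd.DataFrame
    organelle_contigs: set[str]
    mobile_truth: pd.DataFrame
    translated_truth: dict[str, bool]
    expression_truth: pd.DataFrame
    seed: int = 0

    @property
    def nuclear_snp_table(self) -> pd.DataFrame:
        return self.snp_table[~self.snp_table["contig"].isin(self.organelle_contigs)]

    def mobile_transcripts(self, direction: str | None = None) -> set[str]:
        mt = self.mobile_truth
        if direction is not None:
            mt = mt[mt["direction"] == direction]
        return set(mt["transcript"])


def _split_regions(length: int, rng: np.random.Generator) -> tuple[int, int]:
    """Lengths of the 5'UTR and 3'UTR for a transcript of ``length`` nt."""
    utr5 = max(30, int(round(length * rng.uniform(0.08, 0.20))))
    utr3 = max(40, int(round(length * rng.uniform(0.12, 0.25))))
    # CDS keeps at least a third of the transcript
    while utr5 + utr3 > 2 * length // 3:
        utr5 = max(30, utr5 // 2)
        utr3 = max(40, utr3 // 2)
    return utr5, utr3


def generate_accession_pair(
    seed: int,
    n_transcripts: int,
    snp_density: float = 0.01,
    organelle_fraction: float = 0.04,
    mean_length: int = 1000,
    mobile_fraction: float = 0.15,
    mobile_rate: float = 0.05,
    translated_fraction: float = 0.5,
    accessions: tuple[str, str] = ("accA", "accB"),
) -> SyntheticTruth:
    """Simulate two accessions differing at biallelic SNPs.

    Each transcript occupies its own contig; a configurable fraction of
    contigs is flagged as organellar (their SNPs must be excluded when
    building the diagnostic reference set).  A subset of nuclear,
    SNP-bearing transcripts is labelled mobile: each is assigned a travel
    direction, a set of conditions under which it moves (Pi-starvation
    induced, Pi-starvation decreased, or constitutive) and a per-read
    transfer rate.

    SNP count per transcript is Binomial(length, snp_density); output is
    deterministic given ``seed``.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    if not 0 <= snp_density < 0.2:
        raise ValueError(f"snp_density must be in [0, 0.2), got {snp_density}")
    if not 0 <= mobile_rate < 1:
        raise ValueError("mobile_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    acc_a, acc_b = accessions

    n_organelle = int(round(organelle_fraction * n_transcripts))
    genome_a: dict[str, str] = {}
    genome_b: dict[str, str] = {}
    ann_rows = []
    snp_rows = []
    organelle_contigs: set[str] = set()

    for i in range(n_transcripts):
        organelle = i < n_organelle
        contig = f"org{i:04d}" if organelle else f"chr_t{i:04d}"
        transcript = f"T{i:04d}"
        if organelle:
            organelle_contigs.add(contig)
        length = max(300, int(rng.exponential(mean_length - 300)) + 300)
        seq_a = rng.choice(_BASES, size=length)

        # place SNPs
        is_snp = rng.random(length) < snp_density
        seq_b = seq_a.copy()
        for pos0 in np.flatnonzero(is_snp):
            ref = seq_a[pos0]
            alt = rng.choice(_BASES[_BASES != ref])
            seq_b[pos0] = alt
            snp_rows.append(
                {
                    "contig": contig,
                    "pos": int(pos0) + 1,
                    "allele_a": str(ref),
                    "allele_b": str(alt),
                    "transcript": transcript,
                }
            )

        utr5, utr3 = _split_regions(length, rng)
        strand = "+" if rng.random() < 0.8 else "-"
        if strand == "+":
            u5 = (1, utr5)
            cds = (utr5 + 1, length - utr3)
            u3 = (length - utr3 + 1, length)
        else:
            # transcript 5'->3' runs right to left on the contig
            u5 = (length - utr5 + 1, length)
            cds = (utr3 + 1, length - utr5)
            u3 = (1, utr3)
        ann_rows.append(
            {
                "transcript": transcript,
                "contig": contig,
                "strand": strand,
                "length": length,
                "utr5_start": u5[0],
                "utr5_end": u5[1],
                "cds_start": cds[0],
                "cds_end": cds[1],
                "utr3_start": u3[0],
                "utr3_end": u3[1],
            }
        )
        genome_a[contig] = "".join(seq_a)
        genome_b[contig] = "".join(seq_b)

    annotation = pd.DataFrame(ann_rows)
    snp_table = pd.DataFrame(
        snp_rows, columns=["contig", "pos", "allele_a", "allele_b", "transcript"]
    )

    # mobile transcripts: nuclear, >=1 SNP
    nuclear = annotation[~annotation["contig"].isin(organelle_contigs)]
    with_snp = set(snp_table.loc[
        ~snp_table["contig"].isin(organelle_contigs), "transcript"
    ])
    eligible = [t for t in nuclear["transcript"] if t in with_snp]
    n_mobile = min(len(eligible), int(round(mobile_fraction * n_transcripts)))
    mobile_ids = list(rng.choice(eligible, size=n_mobile, replace=False))

    mobile_rows = []
    translated_truth: dict[str, bool] = {}
    for t in mobile_ids:
        direction = DIRECTIONS[int(rng.integers(2))]
        kind = rng.choice(["psi", "psd", "common"], p=[0.35, 0.35, 0.30])
        if kind == "psi":
            conds = sorted(PI_DEFICIENT)
        elif kind == "psd":
            conds = sorted(PI_SUFFICIENT)
        else:
            conds = list(CONDITIONS)
        for c in conds:
            mobile_rows.append(
                {
                    "transcript": t,
                    "condition": c,
                    "direction": direction,
                    "rate": float(mobile_rate),
                }
            )
        translated_truth[t] = bool(rng.random() < translated_fraction)
    mobile_truth = pd.DataFrame(
        mobile_rows, columns=["transcript", "condition", "direction", "rate"]
    )

    expr_rows = []
    base_expr = rng.lognormal(mean=0.0, sigma=0.6, size=n_transcripts)
    for (_, row), e in zip(annotation.iterrows(), base_expr):
        for tissue in TISSUES:
            for cond in CONDITIONS:
                expr_rows.append(
                    {
                        "transcript": row["transcript"],
                        "tissue": tissue,
                        "condition": cond,
                        "mean_expression": float(e),
                    }
                )
    expression_truth = pd.DataFrame(expr_rows)

    return SyntheticTruth(
        accessions=(acc_a, acc_b),
        genomes={acc_a: genome_a, acc_b: genome_b},
        annotation=annotation,
        snp_table=snp_table,
        organelle_contigs=organelle_contigs,
        mobile_truth=mobile_truth,
        translated_truth=translated_truth,
        expression_truth=expression_truth,
        seed=seed,
    )


def reciprocal_design(
    accessions: tuple[str, str],
    conditions: Sequence[str] = CONDITIONS,
    include_homografts: bool = True,
) -> list[GraftSample]:
    """Standard design: one heterograft (A rootstock / B scion) plus the two
    homograft controls, both tissues, every condition."""
    acc_a, acc_b = accessions
    pairs = [(acc_b, acc_a)]  # scion, rootstock
    if include_homografts:
        pairs += [(acc_a, acc_a), (acc_b, acc_b)]
    return [
        GraftSample(scion, rootstock, cond, tissue)
        for scion, rootstock in pairs
        for cond in conditions
        for tissue in TISSUES
    ]


def generate_graft_experiment(
    truth: SyntheticTruth,
    design: Iterable[GraftSample | tuple[str, str, str, str]],
    depth: float = 50.0,
    error_rate: float = 0.002,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample allele-observation tables over the truth's SNP sites.

    At every SNP site in every sample the emitted row carries
    ``(n_local, n_foreign, n_other)`` with ``n_local + n_foreign + n_other``
    equal to the site depth.  Foreign-allele reads at non-mobile transcripts
    arise only from sequencing error (uniform substitution to the three
    non-template bases, so a fraction error_rate/3 of local reads is miscalled
    as the diagnostic foreign allele); transcripts in ``mobile_truth`` draw
    genuinely foreign reads at their truth rate, only in the listed
    conditions and only in the tissue matching the travel direction of a
    heterograft.
    """
    if not 0 <= error_rate < 0.05:
        raise ValueError(f"error_rate must be in [0, 0.05), got {error_rate}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    samples = [
        s if isinstance(s, GraftSample) else GraftSample(*s) for s in design
    ]
    known = set(truth.accessions)
    for s in samples:
        if s.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {s.condition!r}")
        if s.scion_genotype not in known or s.rootstock_genotype not in known:
            raise ValueError(f"unknown genotype in design entry {s}")

    rng = np.random.default_rng(seed)
    snps = truth.snp_table
    n_sites = len(snps)
    # expected foreign fraction per site, per (condition, tissue) of a
    # heterograft sample
    rate_lookup: dict[tuple[str, str], np.ndarray] = {}
    for cond in CONDITIONS:
        for tissue in TISSUES:
            direction = DIRECTION_OF_TISSUE[tissue]
            sub = truth.mobile_truth
            sub = sub[(sub["condition"] == cond) & (sub["direction"] == direction)]
            per_transcript = dict(zip(sub["transcript"], sub["rate"]))
            rate_lookup[(cond, tissue)] = snps["transcript"].map(
                lambda t: per_transcript.get(t, 0.0)
            ).to_numpy(dtype=float)

    frames = []
    for s in samples:
        p_mob = (
            rate_lookup[(s.condition, s.tissue)]
            if s.is_heterograft
            else np.zeros(n_sites)
        )
        for rep in range(1, replicates + 1):
            n_total = rng.poisson(depth, size=n_sites)
            # observed-base probabilities under the substitution model
            p_foreign = p_mob * (1 - error_rate) + (1 - p_mob) * error_rate / 3.0
            p_other = np.full(n_sites, 2.0 * error_rate / 3.0)
            n_foreign = rng.binomial(n_total, p_foreign)
            rest = n_total - n_foreign
            with np.errstate(invalid="ignore"):
                p_other_given_rest = np.where(
                    1.0 - p_foreign > 0, p_other / (1.0 - p_foreign), 0.0
                )
            n_other = rng.binomial(rest, p_other_given_rest)
            n_local = rest - n_other
            frames.append(
                pd.DataFrame(
                    {
                        "sample": f"{s.label}_rep{rep}",
                        "scion_genotype": s.scion_genotype,
                        "rootstock_genotype": s.rootstock_genotype,
                        "condition": s.condition,
                        "tissue": s.tissue,
                        "genotype": s.tissue_genotype,
                        "replicate": rep,
                        "contig": snps["contig"].to_numpy(),
                        "pos": snps["pos"].to_numpy(),
                        "transcript": snps["transcript"].to_numpy(),
                        "n_local": n_local,
                        "n_foreign": n_foreign,
                        "n_other": n_other,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def generate_trap_experiment(
    truth: SyntheticTruth,
    observations: pd.DataFrame,
    capture_efficiency: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Ribosome-IP (TRAP) allele observations derived from RNA observations.

    Counts are binomially thinned at ``capture_efficiency``.  Foreign reads
    of mobile transcripts whose truth label says "not translated in the
    recipient tissue" are absent from the IP entirely (they never co-purify
    with tagged ribosomes).
    """
    if not 0 < capture_efficiency <= 1:
        raise ValueError(
            f"capture_efficiency must be in (0, 1], got {capture_efficiency}"
        )
    rng = np.random.default_rng(seed)
    ip = observations.copy()
    untranslated = {
        t for t, ok in truth.translated_truth.items() if not ok
    }

    def thin(col: np.ndarray) -> np.ndarray:
        if capture_efficiency == 1.0:
            return col.copy()
        return rng.binomial(col, capture_efficiency)

    ip["n_local"] = thin(ip["n_local"].to_numpy())
    ip["n_foreign"] = thin(ip["n_foreign"].to_numpy())
    ip["n_other"] = thin(ip["n_other"].to_numpy())
    ip.loc[ip["transcript"].isin(untranslated), "n_foreign"] = 0
    ip["sample"] = ip["sample"] + "_IP"
    return ip


def generate_dms_experiment(
    structure: str,
    sequence: str,
    depth: int = 2000,
    rate_unpaired: float = 0.05,
    rate_paired: float = 0.005,
    seed: int = 0,
    background_rate: float = 0.0005,
) -> pd.DataFrame:
    """Per-position (mismatch, depth) counts for one DMS-treated amplicon.

    DMS methylates unpaired adenosines and cytosines, which read out as
    mismatches during reverse transcription.  A and C positions draw
    mismatches at ``rate_unpaired`` or ``rate_paired`` according to the
    dot-bracket ``structure``; G and U/T positions see only the background
    error rate.
    """
    if len(structure) != len(sequence):
        raise ValueError(
            f"structure length {len(structure)} != sequence length {len(sequence)}"
        )
    if not rate_unpaired > rate_paired:
        raise ValueError("rate_unpaired must exceed rate_paired")
    rng = np.random.default_rng(seed)
    seq = sequence.upper().replace("T", "U")
    rows = []
    for i, (base, sym) in enumerate(zip(seq, structure), start=1):
        paired = sym != "."
        if base in "AC":
            rate = rate_paired if paired else rate_unpaired
        else:
            rate = background_rate
        rows.append(
            {
                "pos": i,
                "base": base,
                "paired": paired,
                "depth": depth,
                "mismatch": int(rng.binomial(depth, rate)),
            }
        )
    return pd.DataFrame(rows)


def generate_count_matrix(
    truth: SyntheticTruth,
    tissue: str,
    conditions: Sequence[str] = CONDITIONS,
    replicates: int = 3,
    library_size: float = 2e6,
    dispersion: float = 0.1,
    seed: int = 0,
    de_transcripts: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Gene x sample count matrix from the truth's expression means.

    Counts are negative-binomial around library-scaled means; entries in
    ``de_transcripts`` (transcript -> fold change) are scaled in every
    condition other than the first (treated vs control layout).
    """
    rng = np.random.default_rng(seed)
    transcripts = truth.annotation["transcript"].to_numpy()
    expr = (
        truth.expression_truth.query("tissue == @tissue")
        .drop_duplicates("transcript")
        .set_index("transcript")["mean_expression"]
        .reindex(transcripts)
        .to_numpy()
    )
    mean_counts = expr / expr.sum() * library_size
    data = {}
    control = conditions[0]
    for cond in conditions:
        mu = mean_counts.copy()
        if de_transcripts and cond != control:
            for t, fc in de_transcripts.items():
                mu[transcripts == t] *= fc
        for rep in range(1, replicates + 1):
            # NB via gamma-Poisson
            shape = 1.0 / dispersion
            lam = rng.gamma(shape, mu / shape)
            data[f"{tissue}_{cond}_rep{rep}"] = rng.poisson(lam)
    return pd.DataFrame(data, index=pd.Index(transcripts, name="transcript"))
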