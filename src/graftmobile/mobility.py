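"""Mobile-transcript identification from heterograft allele observations.

A transcript is called mobile in a graft tissue when reads carrying the graft
partner's diagnostic allele are seen above what sequencing error explains.
Error is controlled site by site with a beta-binomial Bayes factor contrasting
the heterograft against matched homograft counts: under the null a single
error rate generates the foreign-allele reads of both, under the alternative
the heterograft has its own (mobile) rate.  Sites with log10 BF above the
threshold are "informative"; foreign reads over informative sites feed a
replicate-level detection rule (> min_reads foreign reads in >= min_replicates
replicates), per-million mobile abundance, the mobile index (recipient mobile
abundance over donor local abundance) and condition-specificity
classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln
from scipy.stats import hypergeom

from .synthetic import CONDITIONS, DIRECTION_OF_TISSUE, PI_DEFICIENT, PI_SUFFICIENT
from .variants import ReferenceSNPSet

LN10 = math.log(10.0)

CATEGORIES = ("PSI-specific", "PSD-specific", "common", "other")


@dataclass(frozen=True)
class AlleleCount:
    """Foreign-allele reads over total reads at one diagnostic site."""

    site: tuple[str, int]
    n_foreign: int
    n_total: int
    n_other: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_foreign <= self.n_total:
            raise ValueError(
                f"need 0 <= n_foreign <= n_total at {self.site}: "
                f"{self.n_foreign}/{self.n_total}"
            )


@dataclass(frozen=True)
class BayesFactorResult:
    site: tuple[str, int]
    log10_bf: float
    defined: bool
    het: tuple[int, int]
    homo: tuple[int, int]
    prior_error: tuple[float, float]
    prior_mobile: tuple[float, float]


@dataclass
class TranscriptEvidence:
    """Foreign-SNP-read counts per biological replicate for one transcript in
    one condition/direction."""

    transcript: str
    direction: str
    condition: str
    replicate_counts: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.replicate_counts) < 1:
            raise ValueError("at least one replicate required")
        if any(c < 0 for c in self.replicate_counts.values()):
            raise ValueError("replicate counts must be >= 0")


def site_allele_counts(
    pileups: Mapping[tuple[str, int], Mapping[str, int]],
    ref_snps: ReferenceSNPSet,
    self_genotype_allele: Mapping[tuple[str, int], str] | str,
) -> tuple[list[AlleleCount], int]:
    """Count foreign-allele reads from per-site base pileups.

    ``self_genotype_allele`` names which of the two diagnostic alleles is
    local to the tissue: either "a"/"b" (applies to all sites) or a per-site
    map to "a"/"b".  Bases matching neither diagnostic allele go to n_other
    and never count as foreign.  Sites absent from the reference set are
    skipped; their number is returned alongside the counts.
    """
    out: list[AlleleCount] = []
    skipped = 0
    for site, pileup in pileups.items():
        if site not in ref_snps:
            skipped += 1
            continue
        allele_a, allele_b = ref_snps.alleles(*site)
        which = (
            self_genotype_allele
            if isinstance(self_genotype_allele, str)
            else self_genotype_allele[site]
        )
        if which not in ("a", "b"):
            raise ValueError("self genotype must be 'a' or 'b'")
        local = allele_a if which == "a" else allele_b
        foreign = allele_b if which == "a" else allele_a
        n_total = int(sum(pileup.values()))
        n_foreign = int(pileup.get(foreign, 0))
        n_local = int(pileup.get(local, 0))
        out.append(
            AlleleCount(
                site=site,
                n_foreign=n_foreign,
                n_total=n_total,
                n_other=n_total - n_foreign - n_local,
            )
        )
    return out, skipped


def _log_betabinom_marginal(k, n, a: float, b: float):
    """log integral of Binomial(k | n, theta) over theta ~ Beta(a, b),
    dropping the binomial coefficient (it cancels in the Bayes factor)."""
    return betaln(a + k, b + n - k) - betaln(a, b)


def log10_bayes_factor(
    het: AlleleCount | tuple[int, int],
    homo: AlleleCount | tuple[int, int],
    prior_error: tuple[float, float] = (1.0, 1.0),
    prior_mobile: tuple[float, float] = (1.0, 1.0),
) -> BayesFactorResult:
    """Beta-binomial Bayes factor for genuine foreign reads at one site.

    M1: the homograft foreign-read count is generated by an error rate
    theta_err ~ Beta(prior_error) and the heterograft count by an independent
    rate theta_mob ~ Beta(prior_mobile).  M0: both are generated by a single
    shared theta_err.  Marginal likelihoods are exact beta-binomial integrals;
    the result is log10(m1/m0).  A heterograft with zero coverage is flagged
    non-informative.
    """
    kh, nh = (het.n_foreign, het.n_total) if isinstance(het, AlleleCount) else het
    km, nm = (homo.n_foreign, homo.n_total) if isinstance(homo, AlleleCount) else homo
    site = het.site if isinstance(het, AlleleCount) else ("", 0)
    if nh == 0:
        return BayesFactorResult(
            site, float("nan"), False, (kh, nh), (km, nm), prior_error, prior_mobile
        )
    a0, b0 = prior_error
    a1, b1 = prior_mobile
    log_m1 = _log_betabinom_marginal(km, nm, a0, b0) + _log_betabinom_marginal(
        kh, nh, a1, b1
    )
    log_m0 = _log_betabinom_marginal(kh + km, nh + nm, a0, b0)
    return BayesFactorResult(
        site,
        float((log_m1 - log_m0) / LN10),
        True,
        (kh, nh),
        (km, nm),
        prior_error,
        prior_mobile,
    )


def _log10_bf_array(
    kh: np.ndarray,
    nh: np.ndarray,
    km: np.ndarray,
    nm: np.ndarray,
    prior_error: tuple[float, float] = (1.0, 1.0),
    prior_mobile: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Vectorized log10 Bayes factor; NaN where the heterograft has no
    coverage."""
    a0, b0 = prior_error
    a1, b1 = prior_mobile
    log_m1 = _log_betabinom_marginal(km, nm, a0, b0) + _log_betabinom_marginal(
        kh, nh, a1, b1
    )
    log_m0 = _log_betabinom_marginal(kh + km, nh + nm, a0, b0)
    out = (log_m1 - log_m0) / LN10
    return np.where(nh > 0, out, np.nan)


def informative_sites(
    bf_results: Iterable[BayesFactorResult], threshold: float = 1.0
) -> set[tuple[str, int]]:
    """Sites with log10 BF strictly above the threshold (default 1.0); a site
    at exactly the threshold is excluded."""
    return {
        r.site for r in bf_results if r.defined and r.log10_bf > threshold
    }


def call_mobile(
    evidence: TranscriptEvidence, min_reads: int = 3, min_replicates: int = 2
) -> bool:
    """Detection rule: the transcript is mobile iff the number of replicates
    with strictly more than ``min_reads`` foreign SNP-covering reads is at
    least ``min_replicates``."""
    n_supported = sum(
        1 for c in evidence.replicate_counts.values() if c > min_reads
    )
    return n_supported >= min_replicates


def mobile_abundance(
    replicate_counts: Sequence[float],
    library_sizes: Sequence[float] | float,
    per: float = 1e6,
) -> float:
    """Mean over replicates of foreign reads scaled per ``per`` SNP-covering
    library reads."""
    counts = np.asarray(replicate_counts, dtype=float)
    libs = np.broadcast_to(
        np.asarray(library_sizes, dtype=float), counts.shape
    )
    if np.any(libs <= 0):
        raise ValueError("library sizes must be positive")
    return float(np.mean(counts / libs * per))


def mobile_index(
    recipient_mobile_abundance_mean: float, donor_local_abundance_mean: float
) -> float:
    """Transport efficiency: mean mobile abundance in the recipient tissue
    divided by mean local abundance in the donor tissue."""
    if donor_local_abundance_mean <= 0:
        raise ValueError("mobile index undefined: donor local abundance is zero")
    if recipient_mobile_abundance_mean < 0:
        raise ValueError("abundance must be >= 0")
    return recipient_mobile_abundance_mean / donor_local_abundance_mean


def classify_condition_specificity(detected_conditions: Iterable[str]) -> str:
    """Partition a detection pattern over the four Pi regimes.

    PSI-specific: detected only under Pi deficiency (NP3D/NP7D);
    PSD-specific: detected only under effective Pi sufficiency
    (FP7D/NP7DRP2D); common: detected in at least one condition of each
    group; other: detected nowhere.
    """
    detected = set(detected_conditions)
    unknown = detected - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown conditions: {sorted(unknown)}")
    in_deficient = bool(detected & PI_DEFICIENT)
    in_sufficient = bool(detected & PI_SUFFICIENT)
    if in_deficient and not in_sufficient:
        return "PSI-specific"
    if in_sufficient and not in_deficient:
        return "PSD-specific"
    if in_deficient and in_sufficient:
        return "common"
    return "other"


def phr_dependence(
    wildtype_calls: set[str], mutant_calls: set[str]
) -> tuple[set[str], float]:
    """Mobile transcripts lost in a PSR-signaling mutant graft.

    Returns (dependent set = wild-type calls absent from the mutant,
    fraction of wild-type calls retained in the mutant)."""
    if not wildtype_calls:
        raise ValueError("wild-type call set is empty; retained fraction undefined")
    dependent = set(wildtype_calls) - set(mutant_calls)
    retained = len(set(wildtype_calls) & set(mutant_calls)) / len(wildtype_calls)
    return dependent, retained


def hypergeometric_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail hypergeometric p-value for the overlap of two gene sets
    drawn from a common universe: P(X >= |A & B|)."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("both sets must be subsets of the universe")
    overlap = len(a & b)
    return float(hypergeom.sf(overlap - 1, len(u), len(a), len(b)))


@dataclass
class MobileScreenResult:
    """Output of the end-to-end screen.

    calls: one row per transcript x direction x condition with detection,
    abundance and mobile index.  mobile: one row per detected transcript x
    direction with its condition set and category.  bf_table: per-site Bayes
    factors per (condition, tissue).
    """

    calls: pd.DataFrame
    mobile: pd.DataFrame
    bf_table: pd.DataFrame
    n_sites_tested: int
    n_sites_informative: int
    params: dict = field(default_factory=dict)

    def mobile_set(self, direction: str | None = None) -> set[str]:
        m = self.mobile
        if direction is not None:
            m = m[m["direction"] == direction]
        return set(m["transcript"])

    def detected_conditions(self, transcript: str, direction: str) -> set[str]:
        sub = self.calls[
            (self.calls["transcript"] == transcript)
            & (self.calls["direction"] == direction)
            & self.calls["detected"]
        ]
        return set(sub["condition"])


def identify_mobile_transcripts(
    observations: pd.DataFrame,
    bf_threshold: float = 1.0,
    min_reads: int = 3,
    min_replicates: int = 2,
    prior_error: tuple[float, float] = (1.0, 1.0),
    prior_mobile: tuple[float, float] = (1.0, 1.0),
) -> MobileScreenResult:
    """Run the full screen on an allele-observation table.

    ``observations`` must contain heterograft and homograft samples in the
    schema produced by :func:`graftmobile.synthetic.generate_graft_experiment`
    (columns: sample, scion_genotype, rootstock_genotype, condition, tissue,
    replicate, contig, pos, transcript, n_local, n_foreign, n_other).

    Steps: (1) pool homograft foreign/total counts per site as the error
    reference; (2) per tissue, pool heterograft counts per site across all
    conditions and replicates and compute the beta-binomial log10 Bayes
    factor — informative-site selection is a dataset-level reference step, so
    pooling maximizes its depth; (3) keep sites with log10 BF > bf_threshold;
    (4) per transcript, condition and replicate, sum foreign reads over the
    tissue's informative sites and apply the detection rule; (5) compute
    per-million mobile abundance, donor local abundance and the mobile index.
    """
    obs = observations.copy()
    obs["n_total"] = obs["n_local"] + obs["n_foreign"] + obs["n_other"]
    het = obs[obs["scion_genotype"] != obs["rootstock_genotype"]]
    homo = obs[obs["scion_genotype"] == obs["rootstock_genotype"]]
    if het.empty:
        raise ValueError("no heterograft samples in observations")

    homo_site = (
        homo.groupby(["contig", "pos"])[["n_foreign", "n_total"]]
        .sum()
        .rename(columns={"n_foreign": "k_homo", "n_total": "n_homo"})
    )

    lib_sizes = obs.groupby("sample")["n_total"].sum()

    # dataset-level informative-site gate: per tissue, pooled across all
    # heterograft conditions and replicates
    bf_frames = []
    informative_by_tissue: dict[str, pd.DataFrame] = {}
    n_informative_total = 0
    n_tested_total = 0
    for tissue, group in het.groupby("tissue"):
        pooled = (
            group.groupby(["contig", "pos", "transcript"])[["n_foreign", "n_total"]]
            .sum()
            .reset_index()
            .rename(columns={"n_foreign": "k_het", "n_total": "n_het"})
        )
        pooled = pooled.join(homo_site, on=["contig", "pos"])
        pooled[["k_homo", "n_homo"]] = (
            pooled[["k_homo", "n_homo"]].fillna(0).astype(int)
        )
        pooled["log10_bf"] = _log10_bf_array(
            pooled["k_het"].to_numpy(),
            pooled["n_het"].to_numpy(),
            pooled["k_homo"].to_numpy(),
            pooled["n_homo"].to_numpy(),
            prior_error,
            prior_mobile,
        )
        pooled["informative"] = pooled["log10_bf"] > bf_threshold
        pooled.insert(0, "tissue", tissue)
        bf_frames.append(pooled)
        n_tested_total += int((pooled["n_het"] > 0).sum())
        n_informative_total += int(pooled["informative"].sum())
        informative_by_tissue[tissue] = pooled.loc[
            pooled["informative"], ["contig", "pos"]
        ]

    call_rows = []
    for (condition, tissue), group in het.groupby(["condition", "tissue"]):
        direction = DIRECTION_OF_TISSUE[tissue]
        informative = informative_by_tissue[tissue]
        inf_group = group.merge(informative, on=["contig", "pos"])

        # donor tissue of the same heterograft/condition: local reads at the
        # same informative sites
        donor_tissue = "shoot" if tissue == "root" else "root"
        donor = het[
            (het["condition"] == condition) & (het["tissue"] == donor_tissue)
        ].merge(informative, on=["contig", "pos"])

        replicates = sorted(group["replicate"].unique())
        rec_lib = {
            r: float(
                lib_sizes.get(group.loc[group["replicate"] == r, "sample"].iloc[0], 0)
            )
            for r in replicates
        }
        donor_lib = {}
        for r in sorted(donor["replicate"].unique()):
            donor_lib[r] = float(
                lib_sizes.get(donor.loc[donor["replicate"] == r, "sample"].iloc[0], 0)
            )

        foreign = (
            inf_group.groupby(["transcript", "replicate"])["n_foreign"]
            .sum()
            .unstack(fill_value=0)
            .reindex(columns=replicates, fill_value=0)
        )
        donor_local = (
            donor.groupby(["transcript", "replicate"])["n_local"]
            .sum()
            .unstack(fill_value=0)
        )

        for transcript in sorted(set(group["transcript"])):
            counts = (
                foreign.loc[transcript]
                if transcript in foreign.index
                else pd.Series(0, index=replicates)
            )
            n_detected = int((counts > min_reads).sum())
            detected = n_detected >= min_replicates
            abund = (
                mobile_abundance(
                    counts.to_numpy(),
                    [rec_lib[r] for r in counts.index],
                )
                if rec_lib and all(rec_lib[r] > 0 for r in counts.index)
                else float("nan")
            )
            if transcript in donor_local.index and donor_lib:
                dl = donor_local.loc[transcript]
                donor_abund = mobile_abundance(
                    dl.to_numpy(), [donor_lib[r] for r in dl.index]
                )
            else:
                donor_abund = float("nan")
            mi = (
                abund / donor_abund
                if donor_abund and donor_abund > 0 and not math.isnan(abund)
                else float("nan")
            )
            call_rows.append(
                {
                    "transcript": transcript,
                    "direction": direction,
                    "condition": condition,
                    "tissue": tissue,
                    "foreign_reads_total": int(counts.sum()),
                    "n_replicates_detected": n_detected,
                    "detected": detected,
                    "mobile_abundance": abund,
                    "donor_local_abundance": donor_abund,
                    "mobile_index": mi,
                }
            )

    calls = pd.DataFrame(call_rows)
    bf_table = pd.concat(bf_frames, ignore_index=True)

    mobile_rows = []
    if not calls.empty:
        for (transcript, direction), sub in calls.groupby(["transcript", "direction"]):
            detected_conditions = set(sub.loc[sub["detected"], "condition"])
            if not detected_conditions:
                continue
            mobile_rows.append(
                {
                    "transcript": transcript,
                    "direction": direction,
                    "detected_conditions": ",".join(
                        c for c in CONDITIONS if c in detected_conditions
                    ),
                    "category": classify_condition_specificity(detected_conditions),
                }
            )
    mobile = pd.DataFrame(
        mobile_rows,
        columns=["transcript", "direction", "detected_conditions", "category"],
    )

    return MobileScreenResult(
        calls=calls,
        mobile=mobile,
        bf_table=bf_table,
        n_sites_tested=n_tested_total,
        n_sites_informative=n_informative_total,
        params={
            "bf_threshold": bf_threshold,
            "min_reads": min_reads,
            "min_replicates": min_replicates,
            "prior_error": prior_error,
            "prior_mobile": prior_mobile,
        },
    )
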