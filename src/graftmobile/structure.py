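"""Region-wise RNA secondary-structure statistics.

For each transcript region (5'UTR, CDS, 3'UTR) the minimum free energy (MFE,
ΔG <= 0) of the predicted secondary structure is computed and normalized by
length to −ΔG/nt, the per-nucleotide folding strength: a lower −ΔG/nt means a
less structured region.  Two folding backends are provided: the production
backend delegates to a nearest-neighbor thermodynamic model at 37 °C
(ViennaRNA bindings, required only to reproduce published kcal/mol values),
and a built-in dynamic-programming backend with weighted base pairs, a
stacking bonus and a minimum hairpin loop of three — exactly checkable against
exhaustive structure enumeration on short sequences.  Group contrasts use the
two-sample Kolmogorov–Smirnov D statistic and the two-sided rank-sum test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import gc_fraction
from scipy import stats

#: Pair weights of the built-in backend (score units; dG = -score).
PAIR_SCORES: dict[frozenset, float] = {
    frozenset(("G", "C")): 3.0,
    frozenset(("A", "U")): 2.0,
    frozenset(("G", "U")): 1.0,
}
STACK_BONUS = 1.0
MIN_HAIRPIN = 3  # minimum unpaired nucleotides enclosed by a pair

_RNA_ALPHABET = frozenset("ACGU")


@dataclass
class RegionSet:
    """The three regions of one transcript, in transcript orientation.
    Absent regions are None and are excluded from region statistics."""

    transcript: str
    utr5: str | None = None
    cds: str | None = None
    utr3: str | None = None

    def get(self, region: str) -> str | None:
        return {"utr5": self.utr5, "cds": self.cds, "utr3": self.utr3}[region]


@dataclass(frozen=True)
class StructureStats:
    """MFE statistics for one region: dG (kcal/mol, <= 0), its
    length-normalized negation, GC fraction and length."""

    transcript: str
    region: str
    dg: float
    neg_dg_per_nt: float
    gc: float
    length: int


@dataclass
class GroupComparison:
    """Two-sample comparison of a structure statistic.

    d is the Kolmogorov–Smirnov statistic (maximal ECDF separation),
    ks_p and wilcoxon_p the KS and two-sided rank-sum p-values.
    """

    d: float
    ks_p: float
    wilcoxon_p: float
    n_a: int
    n_b: int
    ecdf_a: pd.DataFrame | None = None
    ecdf_b: pd.DataFrame | None = None


def pair_score(x: str, y: str) -> float:
    """Score of a base pair, 0 if the bases cannot pair."""
    return PAIR_SCORES.get(frozenset((x, y)), 0.0)


def _normalize_rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    return s


def _mfe_test_backend(seq: str) -> float:
    """Weighted base-pair maximization with a stacking bonus.

    Maximizes sum of pair scores plus STACK_BONUS per directly stacked pair
    (pairs (i,j) and (i+1,j-1) both formed), over all pseudoknot-free
    structures with hairpin loops of at least MIN_HAIRPIN unpaired bases.
    Returns dG = -(best score); 0.0 when no pair is admissible.
    """
    n = len(seq)
    NEG = float("-inf")
    # S[i][j]: best score on i..j; Sp[i][j]: best score with i paired to j
    S = [[0.0] * n for _ in range(n)]
    Sp = [[NEG] * n for _ in range(n)]
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            w = pair_score(seq[i], seq[j])
            if w > 0:
                inner = S[i + 1][j - 1] if j - 1 >= i + 1 else 0.0
                best_inner = inner
                if Sp[i + 1][j - 1] != NEG:
                    best_inner = max(best_inner, Sp[i + 1][j - 1] + STACK_BONUS)
                Sp[i][j] = w + best_inner
            best = S[i][j - 1]
            for k in range(i, j - MIN_HAIRPIN):
                if Sp[k][j] != NEG:
                    left = S[i][k - 1] if k - 1 >= i else 0.0
                    best = max(best, left + Sp[k][j])
            S[i][j] = best
    return -S[0][n - 1] if n > 0 else 0.0


def _mfe_nearest_neighbor(seq: str) -> float:
    """Nearest-neighbor thermodynamic MFE at 37 °C (ViennaRNA bindings)."""
    try:
        import RNA  # type: ignore
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "the nearest-neighbor backend requires the ViennaRNA python "
            "bindings; use backend='test' otherwise"
        ) from exc
    _, dg = RNA.fold(seq)
    return float(dg)


BACKENDS = {"test": _mfe_test_backend, "nn": _mfe_nearest_neighbor}


def mfe_fold(seq: str, backend: str = "test") -> float:
    """Minimum free energy of the predicted secondary structure of ``seq``.

    T is treated as U and case is ignored.  backend='nn' gives kcal/mol under
    the nearest-neighbor model; backend='test' gives the built-in
    base-pair-maximization energy (exactly reproducible and oracle-testable).
    """
    s = _normalize_rna(seq)
    if len(s) < 1:
        raise ValueError("sequence must have length >= 1")
    try:
        fn = BACKENDS[backend]
    except KeyError:
        raise ValueError(f"unknown backend {backend!r}; use 'test' or 'nn'")
    return fn(s)


def neg_dg_per_nt(dg: float, length: int) -> float:
    """Length-normalized folding strength −ΔG/nt."""
    if length <= 0:
        raise ValueError("length must be positive")
    return -dg / length


def gc_content(seq: str) -> float:
    """GC fraction in [0, 1], case-insensitive, T and U equivalent."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    return float(gc_fraction(seq, ambiguous="ignore"))


def _extract_interval(contig_seq: str, start: int, end: int, strand: str) -> str:
    """1-based closed genomic interval, reverse-complemented on minus."""
    if start < 1 or end > len(contig_seq) or start > end:
        raise ValueError(
            f"interval [{start}, {end}] outside contig bounds 1..{len(contig_seq)}"
        )
    sub = contig_seq[start - 1 : end]
    if strand == "-":
        return str(Seq(sub).reverse_complement())
    return sub


def extract_regions(
    annotation: pd.DataFrame, sequences: Mapping[str, str]
) -> dict[str, RegionSet]:
    """Region sequences in transcript orientation for every annotated
    transcript.

    ``annotation`` uses 1-based closed intervals (columns utr5_start/utr5_end,
    cds_start/cds_end, utr3_start/utr3_end; NaN marks an absent region);
    ``sequences`` maps contig -> genomic sequence.
    """
    out: dict[str, RegionSet] = {}
    for row in annotation.itertuples(index=False):
        contig_seq = sequences[row.contig]
        regions: dict[str, str | None] = {}
        for region in ("utr5", "cds", "utr3"):
            start = getattr(row, f"{region}_start", None)
            end = getattr(row, f"{region}_end", None)
            if start is None or end is None or pd.isna(start) or pd.isna(end):
                regions[region] = None
            else:
                regions[region] = _extract_interval(
                    contig_seq, int(start), int(end), row.strand
                )
        out[row.transcript] = RegionSet(transcript=row.transcript, **regions)
    return out


def region_structure_stats(
    regions: Mapping[str, RegionSet], region: str, backend: str = "test"
) -> pd.DataFrame:
    """Fold one region of every transcript and tabulate dG, −ΔG/nt, GC and
    length; transcripts lacking the region are omitted."""
    rows = []
    for transcript, rs in regions.items():
        seq = rs.get(region)
        if not seq:
            continue
        dg = mfe_fold(seq, backend=backend)
        rows.append(
            {
                "transcript": transcript,
                "region": region,
                "dg": dg,
                "neg_dg_per_nt": neg_dg_per_nt(dg, len(seq)),
                "gc": gc_content(seq),
                "length": len(seq),
            }
        )
    return pd.DataFrame(
        rows, columns=["transcript", "region", "dg", "neg_dg_per_nt", "gc", "length"]
    )


def _ecdf(values: np.ndarray) -> pd.DataFrame:
    x = np.sort(values)
    return pd.DataFrame({"x": x, "F": np.arange(1, len(x) + 1) / len(x)})


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], ecdf: bool = True
) -> GroupComparison:
    """KS D / p and two-sided rank-sum p for two samples of a statistic,
    with ECDF tables for cumulative-distribution plots."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ks = stats.ks_2samp(a, b)
    try:
        mw = stats.mannwhitneyu(a, b, alternative="two-sided")
        wilcoxon_p = float(mw.pvalue)
    except ValueError:  # all values identical
        wilcoxon_p = 1.0
    return GroupComparison(
        d=float(ks.statistic),
        ks_p=float(ks.pvalue),
        wilcoxon_p=wilcoxon_p,
        n_a=len(a),
        n_b=len(b),
        ecdf_a=_ecdf(a) if ecdf else None,
        ecdf_b=_ecdf(b) if ecdf else None,
    )


def quartile_partition(
    values: Mapping[str, float], query_set: Iterable[str]
) -> tuple[dict[str, str], pd.DataFrame]:
    """Stratify ids into bottom 25% / middle 50% / top 25% by value.

    Quartile boundaries fall at rank ceil(n/4) from each end; ties are broken
    by stable id order so labels are deterministic.  Returns the id -> stratum
    labels and, per stratum, the count of ``query_set`` members with an
    upper-tail hypergeometric enrichment p-value.
    """
    ids = list(values)
    n = len(ids)
    if n < 4:
        raise ValueError("need at least 4 values to form quartiles")
    query = set(query_set)
    unknown = query - set(ids)
    if unknown:
        raise ValueError(f"query ids not in values: {sorted(unknown)[:5]}")
    ordered = sorted(ids, key=lambda i: (values[i], i))
    k = math.ceil(n / 4)
    labels: dict[str, str] = {}
    for rank, i in enumerate(ordered):
        if rank < k:
            labels[i] = "bottom25"
        elif rank >= n - k:
            labels[i] = "top25"
        else:
            labels[i] = "middle50"
    rows = []
    for stratum in ("bottom25", "middle50", "top25"):
        members = [i for i in ordered if labels[i] == stratum]
        overlap = len(query & set(members))
        p = float(stats.hypergeom.sf(overlap - 1, n, len(query), len(members)))
        rows.append(
            {
                "stratum": stratum,
                "size": len(members),
                "query_count": overlap,
                "enrichment_p": p,
            }
        )
    return labels, pd.DataFrame(rows)
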