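"""Targeted DMS mutational-profiling (DMS-MaPseq) reactivities.

Dimethyl sulfate methylates unpaired adenosines and cytosines; during reverse
transcription these adducts read out as mismatches.  Raw reactivity at an A or
C is therefore mismatch count over sequencing depth, with mismatches within a
few nucleotides of an indel discarded as alignment artifacts.  Replicates with
a pathological profile (almost all A/C silent but a few extreme positions, a
signature of PCR jackpotting at low input) are excluded; surviving replicates
are averaged position-wise, then the averaged profile is normalized by the
median of its top 5% of rates and winsorized at 1.0 — averaging strictly
precedes normalization.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NO_DATA = -999.0  # constraint-file sentinel for non-A/C or no-data positions

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class AlignedRead:
    """Minimal aligned read: 1-based start on the amplicon, CIGAR, and the
    read sequence (query bases, soft-clips excluded from the amplicon)."""

    start: int
    cigar: str
    seq: str


@dataclass
class DmsProfile:
    """Per-position mismatch/depth and reactivity for one amplicon.

    ``table`` columns: pos (1-based), base, depth, mismatch, raw (NaN at
    non-A/C or low-depth positions) and, once normalized, normalized.
    """

    amplicon: str
    table: pd.DataFrame

    @property
    def raw(self) -> pd.Series:
        return self.table.set_index("pos")["raw"]


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if not ops or "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def mutation_profile(
    aligned_reads: Iterable[AlignedRead],
    amplicon_ref: str,
    indel_mask_nt: int = 3,
) -> pd.DataFrame:
    """Per-position (mismatch, depth) over an amplicon.

    Depth counts reads whose alignment covers the position (match states).
    A mismatch is counted only if no indel of the same read lies within
    ``indel_mask_nt`` of the position (reference coordinates); masked
    mismatches still contribute depth.  Reads extending beyond the amplicon
    raise.
    """
    length = len(amplicon_ref)
    depth = np.zeros(length, dtype=int)
    mismatch = np.zeros(length, dtype=int)
    for read in aligned_reads:
        ops = _parse_cigar(read.cigar)
        ref_pos = read.start - 1  # 0-based
        query_pos = 0
        if read.start < 1:
            raise ValueError(f"read starts before the amplicon: {read}")
        covered: list[tuple[int, str]] = []  # (ref index, query base)
        indel_positions: list[int] = []
        for n, op in ops:
            if op in ("M", "=", "X"):
                for k in range(n):
                    covered.append((ref_pos + k, read.seq[query_pos + k]))
                ref_pos += n
                query_pos += n
            elif op == "I":
                # anchor the insertion at the preceding reference base
                indel_positions.append(ref_pos - 1)
                query_pos += n
            elif op == "D" or op == "N":
                indel_positions.extend(range(ref_pos, ref_pos + n))
                ref_pos += n
            elif op == "S":
                query_pos += n
            elif op in ("H", "P"):
                continue
            else:  # pragma: no cover
                raise ValueError(f"unsupported CIGAR op {op!r}")
        if ref_pos > length:
            raise ValueError(
                f"read extends beyond the amplicon (end {ref_pos} > {length})"
            )
        for idx, base in covered:
            depth[idx] += 1
            if base.upper() != amplicon_ref[idx].upper():
                near_indel = any(
                    abs(idx - ip) <= indel_mask_nt for ip in indel_positions
                )
                if not near_indel:
                    mismatch[idx] += 1
    return pd.DataFrame(
        {
            "pos": np.arange(1, length + 1),
            "base": list(amplicon_ref.upper().replace("T", "U")),
            "depth": depth,
            "mismatch": mismatch,
        }
    )


def raw_reactivity(profile: pd.DataFrame, min_depth: int = 500) -> pd.DataFrame:
    """Raw DMS reactivity = mismatch/depth at A and C positions.

    Non-A/C positions and positions below ``min_depth`` get NaN (no data).
    The default depth floor suits targeted amplicon sequencing.
    """
    table = profile.copy()
    is_ac = table["base"].isin(["A", "C"])
    has_depth = table["depth"] >= min_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = table["mismatch"] / table["depth"]
    table["raw"] = rate.where(is_ac & has_depth)
    return table


def replicate_qc(
    raw_rates: Sequence[float] | pd.Series,
    low_rate: float = 0.005,
    low_frac: float = 0.90,
    high_rate: float = 0.05,
) -> bool:
    """True iff the replicate's A/C reactivity profile looks sound.

    Fails on the jackpot pathology — a fraction above ``low_frac`` of A/C
    positions essentially silent (< low_rate) while at least one position
    spikes to >= high_rate — and on the degenerate all-zero profile.
    """
    rates = pd.Series(raw_rates, dtype=float).dropna()
    if rates.empty or float(rates.max()) == 0.0:
        return False
    frac_low = float((rates < low_rate).mean())
    if frac_low > low_frac and float(rates.max()) >= high_rate:
        return False
    return True


def average_replicates(profiles: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Position-wise arithmetic mean of raw reactivities over replicates.

    Positions missing (NaN) in some replicates average over the replicates
    with data; ``n_replicates`` records how many contributed per position.
    """
    if len(profiles) < 1:
        raise ValueError("need at least one replicate")
    base = profiles[0][["pos", "base"]].copy()
    raws = pd.concat(
        [p.set_index("pos")["raw"] for p in profiles], axis=1
    )
    base["raw"] = raws.mean(axis=1, skipna=True).to_numpy()
    base["n_replicates"] = raws.notna().sum(axis=1).to_numpy()
    return base


def normalize_reactivity(raw_rates: Sequence[float] | pd.Series) -> pd.Series:
    """Scale reactivities by the median of the highest 5% of rates and
    winsorize values above 1.0 down to 1.0.

    The top slice holds ceil(0.05 * n) positions (n = positions with data);
    an even slice takes the midpoint median.  All-zero input raises (the
    normalizer would be zero).
    """
    rates = pd.Series(raw_rates, dtype=float)
    observed = rates.dropna()
    if observed.empty or float(observed.max()) <= 0:
        raise ValueError("cannot normalize: no positive reactivity")
    n_top = math.ceil(0.05 * len(observed))
    top = observed.sort_values(ascending=False).iloc[:n_top]
    normalizer = float(top.median())
    if normalizer <= 0:
        raise ValueError("normalizer is zero")
    return (rates / normalizer).clip(upper=1.0)


def export_constraints(
    normalized: Mapping[int, float] | pd.Series, path
) -> None:
    """Write a SHAPE-style two-column constraint file (1-based position,
    reactivity; -999 marks non-A/C or no-data positions)."""
    series = pd.Series(dict(normalized)).sort_index()
    with open(path, "w") as fh:
        for pos, value in series.items():
            out = NO_DATA if pd.isna(value) else float(value)
            fh.write(f"{int(pos)}\t{out:.4f}\n")


def read_constraints(path) -> pd.Series:
    """Read a SHAPE-style constraint file back; -999 becomes NaN."""
    table = pd.read_csv(path, sep="\t", header=None, names=["pos", "value"])
    values = table.set_index("pos")["value"]
    return values.where(values != NO_DATA)


def structure_agreement(
    normalized: Mapping[int, float] | pd.Series,
    reference_structure: str,
    sequence: str,
) -> float:
    """AUC of normalized reactivity separating unpaired from paired A/C.

    ``reference_structure`` is dot-bracket over ``sequence`` (1-based
    positions in ``normalized``).  1.0 means reactivity perfectly ranks
    unpaired above paired positions; 0.5 is chance.
    """
    from sklearn.metrics import roc_auc_score

    if len(reference_structure) != len(sequence):
        raise ValueError("structure and sequence lengths differ")
    series = pd.Series(dict(normalized))
    seq = sequence.upper().replace("T", "U")
    y, score = [], []
    for pos, value in series.items():
        base = seq[int(pos) - 1]
        if base not in "AC" or pd.isna(value):
            continue
        y.append(0 if reference_structure[int(pos) - 1] != "." else 1)
        score.append(float(value))
    if len(set(y)) < 2:
        raise ValueError("need both paired and unpaired A/C positions")
    return float(roc_auc_score(y, score))
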