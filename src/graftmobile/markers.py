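"""In-silico CAPS/dCAPS genotype verification.

Grafted tissues are genotyped by amplifying a short region spanning an
accession-diagnostic SNP and digesting the product with a restriction enzyme
whose site is present in one accession's allele only: the fragment-length
pattern on a gel identifies the genotype.  This module simulates the assay —
primer annealing with a mismatch tolerance (a 3'-terminal mismatch abolishes
priming), virtual digestion, and pattern matching against expected fragment
multisets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

#: Built-in enzymes as (recognition sequence, cut offset after the offset-th
#: base of the site on the given strand).
BUILTIN_ENZYMES: dict[str, tuple[str, int]] = {
    "RsaI": ("GTAC", 2),
    "BamHI": ("GGATCC", 1),
}


@dataclass(frozen=True)
class Amplicon:
    """A virtual PCR product: its sequence and the 1-based closed primer
    span on the template."""

    sequence: str
    template_id: str
    fwd_start: int
    rev_end: int

    def __post_init__(self) -> None:
        if len(self.sequence) != self.rev_end - self.fwd_start + 1:
            raise ValueError("amplicon length inconsistent with primer span")

    def __len__(self) -> int:
        return len(self.sequence)


class AmpliconError(ValueError):
    """No unique amplicon: zero hits or multiple equally good products."""

    def __init__(self, message: str, candidates: Sequence[tuple[int, int]] = ()):
        super().__init__(message)
        self.candidates = list(candidates)


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _primer_sites(
    template: str, probe: str, max_mismatch: int, three_prime_index: int
) -> list[tuple[int, int]]:
    """0-based start positions where ``probe`` anneals within tolerance.

    ``three_prime_index`` is the index within the probe that corresponds to
    the primer's 3' terminus; a mismatch there abolishes priming regardless
    of the tolerance.  Returns (start, n_mismatches) tuples.
    """
    hits = []
    w = len(probe)
    for start in range(0, len(template) - w + 1):
        window = template[start : start + w]
        if window[three_prime_index] != probe[three_prime_index]:
            continue
        mm = _mismatches(window, probe)
        if mm <= max_mismatch:
            hits.append((start, mm))
    return hits


def insilico_pcr(
    template: str,
    fwd: str,
    rev: str,
    max_mismatch: int = 1,
    template_id: str = "template",
) -> Amplicon:
    """Virtual PCR: the unique best product of a primer pair on a template.

    The forward primer anneals to the plus strand; the reverse primer anneals
    to the minus strand, i.e. its reverse complement is matched on the plus
    strand downstream of the forward site.  The amplicon spans
    primer-to-primer inclusive.  Raises :class:`AmpliconError` when no
    orientation-consistent product exists or several products tie at the
    minimal total mismatch count.
    """
    template = template.upper()
    fwd = fwd.upper()
    rev = rev.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 nt")
    fwd_hits = _primer_sites(template, fwd, max_mismatch, len(fwd) - 1)
    rev_rc = str(Seq(rev).reverse_complement())
    # reverse primer's 3' end maps to the FIRST base of its plus-strand match
    rev_hits = _primer_sites(template, rev_rc, max_mismatch, 0)

    candidates: list[tuple[int, int, int]] = []  # (fwd_start, rev_end, mm)
    for f_start, f_mm in fwd_hits:
        for r_start, r_mm in rev_hits:
            r_end = r_start + len(rev_rc) - 1
            if r_start > f_start + len(fwd) - 1:
                candidates.append((f_start, r_end, f_mm + r_mm))
    if not candidates:
        raise AmpliconError(
            "no amplicon: primers do not anneal in productive orientation"
        )
    best_mm = min(c[2] for c in candidates)
    best = [(f, r) for f, r, mm in candidates if mm == best_mm]
    if len(best) > 1:
        raise AmpliconError(
            f"{len(best)} equally good amplicons at {best_mm} mismatches",
            candidates=[(f + 1, r + 1) for f, r in best],
        )
    f_start, r_end = best[0]
    return Amplicon(
        sequence=template[f_start : r_end + 1],
        template_id=template_id,
        fwd_start=f_start + 1,
        rev_end=r_end + 1,
    )


def restriction_digest(
    seq: str, recognition: str, cut_offset: int
) -> list[int]:
    """Fragment lengths after complete digestion, ordered along the sequence.

    The duplex is cut after ``cut_offset`` bases of each recognition-site
    occurrence; for non-palindromic sites the reverse-complement orientation
    is scanned too (cut placed symmetrically).  Fragment lengths always sum
    to the input length.
    """
    s = seq.upper()
    rec = recognition.upper()
    if not 0 <= cut_offset <= len(rec):
        raise ValueError("cut offset must lie within the recognition site")
    cuts: set[int] = set()
    for probe, offset in {
        rec: cut_offset,
        str(Seq(rec).reverse_complement()): len(rec) - cut_offset,
    }.items():
        start = s.find(probe)
        while start != -1:
            cut = start + offset
            if 0 < cut < len(s):
                cuts.add(cut)
            start = s.find(probe, start + 1)
    bounds = [0, *sorted(cuts), len(s)]
    return [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]


def genotype_call(
    fragments: Sequence[int],
    expected_patterns: Mapping[str, Sequence[int]],
    tolerance: int = 2,
) -> str:
    """Match an observed fragment-length pattern to a genotype.

    A pattern matches when the sorted fragment multisets have equal size and
    agree pairwise within ``tolerance`` bp (gel resolution).  Returns the
    genotype label, or "ambiguous" when zero or several patterns match.
    """
    observed = sorted(fragments)
    matches = []
    for genotype, expected in expected_patterns.items():
        exp = sorted(expected)
        if len(exp) == len(observed) and all(
            abs(o - e) <= tolerance for o, e in zip(observed, exp)
        ):
            matches.append(genotype)
    return matches[0] if len(matches) == 1 else "ambiguous"


def caps_assay(
    template: str,
    fwd: str,
    rev: str,
    enzyme: str | tuple[str, int],
    expected_patterns: Mapping[str, Sequence[int]],
    max_mismatch: int = 1,
    tolerance: int = 2,
    template_id: str = "template",
) -> tuple[Amplicon, list[int], str]:
    """Full assay: amplify, digest, call the genotype."""
    recognition, offset = (
        BUILTIN_ENZYMES[enzyme] if isinstance(enzyme, str) else enzyme
    )
    amplicon = insilico_pcr(
        template, fwd, rev, max_mismatch=max_mismatch, template_id=template_id
    )
    fragments = restriction_digest(amplicon.sequence, recognition, offset)
    call = genotype_call(fragments, expected_patterns, tolerance=tolerance)
    return amplicon, fragments, call
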