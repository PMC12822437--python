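"""Translation status of mobile transcripts from TRAP-seq evidence.

TRAP-seq (translating ribosome affinity purification) recovers transcripts
co-purifying with tagged ribosomes.  A mobile transcript whose foreign-allele
reads are found in the ribosome IP of the recipient tissue is considered
translated there; one detected in total RNA but absent from the IP is
untranslated.  The IP data pass through the same informative-site and
detection thresholds as the RNA-seq screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .mobility import MobileScreenResult, identify_mobile_transcripts


@dataclass(frozen=True)
class TranslationRecord:
    """Translational state of one transcript in one tissue/condition."""

    transcript: str
    trap_abundance: float
    rna_abundance: float
    tissue: str = ""
    condition: str = ""

    @property
    def te(self) -> float:
        return translational_efficiency(self.trap_abundance, self.rna_abundance)

    @property
    def translated(self) -> bool:
        return self.trap_abundance > 0


def screen_trap(
    trap_observations: pd.DataFrame,
    bf_threshold: float = 1.0,
    min_reads: int = 3,
    min_replicates: int = 2,
    **kwargs,
) -> MobileScreenResult:
    """Run the mobile screen on TRAP IP allele observations with the same
    thresholds used for the RNA-seq screen."""
    return identify_mobile_transcripts(
        trap_observations,
        bf_threshold=bf_threshold,
        min_reads=min_reads,
        min_replicates=min_replicates,
        **kwargs,
    )


def call_translated_mobile(
    mobile_calls: Iterable[str], trap_detected: Iterable[str]
) -> tuple[set[str], set[str]]:
    """Partition mobile transcripts by ribosome association.

    translated = mobile transcripts also detected in the TRAP IP;
    untranslated = the rest.  The two sets are disjoint and their union is
    the input mobile set.
    """
    mobile = set(mobile_calls)
    trap = set(trap_detected)
    translated = mobile & trap
    return translated, mobile - translated


def translational_efficiency(trap_abundance: float, rna_abundance: float) -> float:
    """TE = TRAP-seq abundance / RNA-seq abundance, on identically
    normalized scales."""
    if trap_abundance < 0 or rna_abundance < 0:
        raise ValueError("abundances must be >= 0")
    if rna_abundance == 0:
        raise ValueError("TE undefined: RNA abundance is zero")
    return trap_abundance / rna_abundance


def te_contrast(te_treatment: float, te_control: float) -> float:
    """log2(TE_treatment / TE_control); positive means higher translational
    efficiency under the treatment."""
    if te_control <= 0:
        raise ValueError("contrast undefined: control TE is zero")
    if te_treatment < 0:
        raise ValueError("TE must be >= 0")
    if te_treatment == 0:
        return float("-inf")
    return math.log2(te_treatment / te_control)
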