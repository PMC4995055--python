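"""Codon extraction, start/stop classification and RSCU.

The genetic code defaults to the invertebrate mitochondrial code
(NCBI translation table 5: ATA = Met, TGA = Trp, AGA/AGG = Ser), the code
used by insect mitogenomes.  Mitochondrial CDS frequently end on an
incomplete stop codon — a trailing T or TA at the annotation boundary that
is completed to TAA by post-transcriptional polyadenylation — so stop
classification and codon extraction both understand 3k+1 / 3k+2 length CDS.

RSCU (relative synonymous codon usage) of a codon is its observed count
divided by the mean count over its synonymous family; 1 means unbiased use,
and values over a family sum to the family size.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Data import CodonTable

__all__ = [
    "CodonProfile",
    "StartStopCall",
    "StopClassificationError",
    "classify_start_stop",
    "extract_codons",
    "count_codons",
    "rscu",
    "top_codons",
    "synonymous_families",
    "sense_codons",
    "stop_codons",
    "translate_codon",
]

BASES = "TCAG"
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]


class StopClassificationError(ValueError):
    """CDS of complete codon length whose final codon is not a stop."""


@lru_cache(maxsize=None)
def _table(code_table: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[code_table]


def stop_codons(code_table: int = 5) -> frozenset[str]:
    return frozenset(_table(code_table).stop_codons)


def sense_codons(code_table: int = 5) -> list[str]:
    stops = stop_codons(code_table)
    return [c for c in ALL_CODONS if c not in stops]


def translate_codon(codon: str, code_table: int = 5) -> str:
    """Amino acid (one letter) of a sense codon; '*' for a stop."""
    codon = codon.upper()
    if codon in stop_codons(code_table):
        return "*"
    return _table(code_table).forward_table[codon]


@lru_cache(maxsize=None)
def synonymous_families(code_table: int = 5) -> dict[str, tuple[str, ...]]:
    """Map amino acid -> tuple of its sense codons under the code table."""
    fams: dict[str, list[str]] = {}
    for c in sense_codons(code_table):
        fams.setdefault(translate_codon(c, code_table), []).append(c)
    return {aa: tuple(cs) for aa, cs in fams.items()}


@dataclass(frozen=True)
class StartStopCall:
    start_codon: str
    stop_codon: str       # "TAA", "TAG", "T" or "TA"
    complete: bool


def classify_start_stop(cds: str, code_table: int = 5) -> StartStopCall:
    """Classify the start and stop of a CDS given 5'→3' on its coding strand.

    Length mod 3 == 1 with a trailing T → incomplete stop "T"; mod 3 == 2
    with trailing "TA" → incomplete stop "TA"; otherwise the final codon
    must be a stop under the code table.
    """
    cds = cds.upper()
    if len(cds) < 6:
        raise ValueError("CDS too short to carry a start and a stop")
    start = cds[:3]
    r = len(cds) % 3
    if r == 1:
        if cds[-1] == "T":
            return StartStopCall(start, "T", complete=False)
        raise StopClassificationError(
            f"CDS length mod 3 == 1 but trailing base is {cds[-1]!r}, not T"
        )
    if r == 2:
        if cds[-2:] == "TA":
            return StartStopCall(start, "TA", complete=False)
        raise StopClassificationError(
            f"CDS length mod 3 == 2 but tail is {cds[-2:]!r}, not TA"
        )
    last = cds[-3:]
    if last not in stop_codons(code_table):
        raise StopClassificationError(
            f"final codon {last} is not a stop under code table {code_table}"
        )
    return StartStopCall(start, last, complete=True)


def extract_codons(cds: str, code_table: int = 5) -> list[str]:
    """Split a CDS into sense codons for usage statistics.

    An incomplete stop tail (1–2 nt) is trimmed first; a complete terminal
    stop codon is excluded.  An internal stop raises a warning naming the
    codon index but is kept (annotation edge cases should be visible, not
    fatal).
    """
    cds = cds.upper()
    r = len(cds) % 3
    incomplete_tail = r and cds[-r:] in ("T", "TA")
    if r:
        cds = cds[:-r]
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    stops = stop_codons(code_table)
    if codons and codons[-1] in stops:
        codons = codons[:-1]
    elif not incomplete_tail:
        warnings.warn("CDS has no terminal stop codon (complete or incomplete)",
                      stacklevel=2)
    for i, c in enumerate(codons):
        if c in stops:
            warnings.warn(f"internal stop codon {c} at codon {i + 1}", stacklevel=2)
    return codons


@dataclass
class CodonProfile:
    """Codon counts plus RSCU under a fixed genetic code."""

    counts: dict[str, int]
    code_table: int = 5
    rscu: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rscu:
            self.rscu = rscu(self.counts, self.code_table)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())


def count_codons(cds_list: Iterable[str], code_table: int = 5) -> CodonProfile:
    """Pool codon counts over a set of CDS (stops trimmed/excluded)."""
    counts: dict[str, int] = {}
    for cds in cds_list:
        for c in extract_codons(cds, code_table):
            if set(c) <= set("ACGT"):
                counts[c] = counts.get(c, 0) + 1
    return CodonProfile(counts=counts, code_table=code_table)


def rscu(counts: Mapping[str, int], code_table: int = 5) -> dict[str, float]:
    """RSCU(c) = count(c) / mean count over c's synonymous family.

    Stop codons are excluded; a family with no observed codon gets RSCU 0
    for all of its members (not NaN), which keeps downstream tables stable.
    """
    out: dict[str, float] = {}
    for aa, fam in synonymous_families(code_table).items():
        total = sum(counts.get(c, 0) for c in fam)
        if total == 0:
            for c in fam:
                out[c] = 0.0
        else:
            mean = total / len(fam)
            for c in fam:
                out[c] = counts.get(c, 0) / mean
    return out


def top_codons(counts: Mapping[str, int], k: Optional[int] = None) -> list[str]:
    """Codons ranked by count descending, ties broken lexicographically."""
    if not counts:
        raise ValueError("empty codon counts")
    ranked = sorted(counts, key=lambda c: (-counts[c], c))
    return ranked if k is None else ranked[:k]
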