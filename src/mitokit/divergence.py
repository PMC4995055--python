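"""Nei–Gojobori (NG86) Ka/Ks estimation with Jukes–Cantor correction.

Synonymous (S) and nonsynonymous (N) site counts are computed per codon by
enumerating the three single-nucleotide mutations at each position;
mutations into stop codons are excluded from the denominator.  Observed
differences between a codon pair are averaged over all minimal mutational
paths with uniform weights, excluding paths that pass through a stop codon
(renormalizing over the remaining paths).  Proportions pS = Sd/S and
pN = Nd/N are corrected with the Jukes–Cantor formula
d = −(3/4)·ln(1 − (4/3)·p), undefined for p ≥ 3/4.

Ka/Ks > 1 indicates positive selection on a protein-coding gene, < 1
purifying selection; panels average the defined pairwise estimates over all
unordered species pairs of a per-gene alignment set.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations
from typing import Mapping, Optional

from .codon_usage import stop_codons, translate_codon

__all__ = [
    "SubstitutionEstimates",
    "PanelEstimates",
    "count_sites",
    "count_differences",
    "ng86",
    "pergene_panel",
    "classify_selection",
    "trim_to_codons",
]

_BASES = "ACGT"


@lru_cache(maxsize=None)
def count_sites(codon: str, code_table: int = 5) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    At each of the three positions, the fraction of single-nucleotide
    mutations that are synonymous is computed over the mutations that do
    not create a stop codon; the synonymous fractions sum to ``s_sites``
    and ``n_sites = 3 - s_sites``.
    """
    codon = codon.upper()
    stops = stop_codons(code_table)
    if codon in stops:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = translate_codon(codon, code_table)
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in stops:
                continue
            valid += 1
            if translate_codon(mut, code_table) == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def count_differences(c1: str, c2: str, code_table: int = 5) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts between two sense
    codons over all minimal mutational paths (uniform weights).

    Paths passing through a stop codon are excluded and the average is
    renormalized over the remaining paths; if every path is blocked (rare),
    all paths are used.  Always ``sd + nd = hamming(c1, c2)``.
    """
    c1, c2 = c1.upper(), c2.upper()
    stops = stop_codons(code_table)
    if c1 in stops or c2 in stops:
        raise ValueError("stop codons are not comparable")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    blocked_paths: list[tuple[float, float]] = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in stops:
                blocked = True
            step_syn = (nxt not in stops and cur not in stops and
                        translate_codon(nxt, code_table) == translate_codon(cur, code_table))
            if step_syn:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked_paths if blocked else paths).append((sd, nd))
    use = paths if paths else blocked_paths
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def _jc(p: float) -> Optional[float]:
    """Jukes–Cantor multiple-hit correction; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


@dataclass
class SubstitutionEstimates:
    """NG86 quantities for one pairwise codon alignment."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: Optional[float]
    pN: Optional[float]
    Ks: Optional[float]
    Ka: Optional[float]
    ratio: Optional[float]
    n_codons: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        rd = lambda x: None if x is None else round(x, 6)
        return {"S": rd(self.S), "N": rd(self.N), "Sd": rd(self.Sd), "Nd": rd(self.Nd),
                "pS": rd(self.pS), "pN": rd(self.pN), "Ks": rd(self.Ks),
                "Ka": rd(self.Ka), "ratio": rd(self.ratio),
                "n_codons": self.n_codons, "flags": list(self.flags)}


def _codon_pairs(seq1: str, seq2: str, code_table: int):
    if len(seq1) != len(seq2):
        raise ValueError(f"alignment lengths differ: {len(seq1)} vs {len(seq2)}")
    if len(seq1) % 3:
        raise ValueError("alignment length is not a multiple of 3")
    stops = stop_codons(code_table)
    for i in range(0, len(seq1), 3):
        a, b = seq1[i:i + 3].upper(), seq2[i:i + 3].upper()
        if not (set(a) <= set(_BASES) and set(b) <= set(_BASES)):
            continue  # gapped/ambiguous column: dropped
        if a in stops or b in stops:
            continue
        yield a, b


def ng86(seq1: str, seq2: str, code_table: int = 5) -> SubstitutionEstimates:
    """NG86 estimates for a gap-free in-frame pairwise codon alignment.

    S and N are averaged over the two sequences; codon columns containing
    gaps, ambiguity codes or stop codons are dropped.
    """
    S1 = N1 = S2 = N2 = Sd = Nd = 0.0
    n = 0
    for a, b in _codon_pairs(seq1, seq2, code_table):
        s1, n1 = count_sites(a, code_table)
        s2, n2 = count_sites(b, code_table)
        S1 += s1; N1 += n1; S2 += s2; N2 += n2
        sd, nd = count_differences(a, b, code_table)
        Sd += sd; Nd += nd
        n += 1
    S = (S1 + S2) / 2.0
    N = (N1 + N2) / 2.0
    flags: list[str] = []
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    if S <= 0:
        flags.append("no-synonymous-sites")
    Ks = _jc(pS) if pS is not None else None
    Ka = _jc(pN) if pN is not None else None
    if pS is not None and pS >= 0.75:
        flags.append("Ks-saturated")
    if pN is not None and pN >= 0.75:
        flags.append("Ka-saturated")
    ratio: Optional[float] = None
    if Ka is not None and Ks is not None:
        if Ks > 0:
            ratio = Ka / Ks
        elif Ka == 0:
            flags.append("zero-over-zero")
        else:
            flags.append("Ks-zero")
    else:
        flags.append("ratio-undefined")
    return SubstitutionEstimates(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
                                 Ks=Ks, Ka=Ka, ratio=ratio, n_codons=n, flags=flags)


def trim_to_codons(seq: str, code_table: int = 5) -> str:
    """Codon-aware trimming for panel input: drop an incomplete stop tail
    and a complete terminal stop codon."""
    seq = seq.upper()
    r = len(seq) % 3
    if r:
        seq = seq[:-r]
    if len(seq) >= 3 and seq[-3:] in stop_codons(code_table):
        seq = seq[:-3]
    return seq


@dataclass
class PanelEstimates:
    """Unweighted pairwise means for one gene across a species panel."""

    gene: str
    n_species: int
    n_pairs: int
    n_undefined: int
    mean_ka: Optional[float]
    mean_ks: Optional[float]
    mean_ratio: Optional[float]
    pairwise: dict[tuple[str, str], SubstitutionEstimates] = field(default_factory=dict)

    def to_dict(self) -> dict:
        rd = lambda x: None if x is None else round(x, 6)
        return {"gene": self.gene, "n_species": self.n_species,
                "n_pairs": self.n_pairs, "n_undefined": self.n_undefined,
                "mean_ka": rd(self.mean_ka), "mean_ks": rd(self.mean_ks),
                "mean_ratio": rd(self.mean_ratio)}


def pergene_panel(gene_name: str, cds_by_species: Mapping[str, str],
                  code_table: int = 5) -> PanelEstimates:
    """NG86 over all unordered species pairs of one gene; means are
    unweighted over pairs with a defined Ka/Ks (undefined pairs counted)."""
    if len(cds_by_species) < 2:
        raise ValueError(f"gene {gene_name!r}: need at least two species")
    trimmed = {sp: trim_to_codons(s, code_table) for sp, s in cds_by_species.items()}
    lengths = {len(s) for s in trimmed.values()}
    if len(lengths) != 1:
        raise ValueError(
            f"gene {gene_name!r}: unequal CDS lengths after codon-aware "
            f"trimming ({sorted(lengths)}); inputs must be aligned"
        )
    pairwise: dict[tuple[str, str], SubstitutionEstimates] = {}
    ratios, kas, kss = [], [], []
    n_undef = 0
    for sp1, sp2 in combinations(sorted(trimmed), 2):
        est = ng86(trimmed[sp1], trimmed[sp2], code_table)
        pairwise[(sp1, sp2)] = est
        if est.Ka is not None:
            kas.append(est.Ka)
        if est.Ks is not None:
            kss.append(est.Ks)
        if est.ratio is not None:
            ratios.append(est.ratio)
        else:
            n_undef += 1
    mean = lambda xs: sum(xs) / len(xs) if xs else None
    return PanelEstimates(
        gene=gene_name, n_species=len(trimmed), n_pairs=len(pairwise),
        n_undefined=n_undef, mean_ka=mean(kas), mean_ks=mean(kss),
        mean_ratio=mean(ratios), pairwise=pairwise,
    )


def classify_selection(ratio: Optional[float]) -> str:
    """Selection regime from a Ka/Ks value: >1 positive, <1 purifying,
    ==1 neutral, None/flagged undefined."""
    if ratio is None:
        return "undefined"
    if ratio > 1:
        return "positive"
    if ratio < 1:
        return "purifying"
    return "neutral"
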