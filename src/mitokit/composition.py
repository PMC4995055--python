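"""Base composition and strand-asymmetry (skew) statistics.

AT skew = (A − T) / (A + T) and GC skew = (G − C) / (G + C), computed on the
strand as given.  Skews are antisymmetric under reverse complement, which is
what makes them useful as strand-asymmetry diagnostics for mitogenomes.

Ambiguity codes are excluded from every denominator and reported separately
as ``n_ambiguous``.  Reporting convention follows mitogenome papers:
percentages to 1 decimal, skews to 3 decimals; internal values keep full
precision.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .genome_model import MitoAnnotation

__all__ = [
    "CompositionStats",
    "base_composition",
    "skews_from_percentages",
    "codon_position_composition",
    "table_column_stats",
    "ColumnStats",
]


@dataclass
class CompositionStats:
    counts: dict[str, int]
    n_ambiguous: int
    fractions: dict[str, float]
    at_content: float           # percent
    at_skew: Optional[float]    # None when A+T = 0
    gc_skew: Optional[float]    # None when G+C = 0

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "n_ambiguous": self.n_ambiguous,
            "fractions": {b: round(f, 6) for b, f in self.fractions.items()},
            "at_content": round(self.at_content, 1),
            "at_skew": None if self.at_skew is None else round(self.at_skew, 3),
            "gc_skew": None if self.gc_skew is None else round(self.gc_skew, 3),
        }


def base_composition(seq: str) -> CompositionStats:
    """Count A/T/G/C in a sequence; anything else counts as ambiguous."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    counts = {b: s.count(b) for b in "ATGC"}
    n = sum(counts.values())
    n_amb = len(s) - n
    if n == 0:
        raise ValueError("sequence contains no unambiguous bases")
    fractions = {b: c / n for b, c in counts.items()}
    a, t, g, c = counts["A"], counts["T"], counts["G"], counts["C"]
    at_skew = (a - t) / (a + t) if a + t else None
    gc_skew = (g - c) / (g + c) if g + c else None
    return CompositionStats(
        counts=counts,
        n_ambiguous=n_amb,
        fractions=fractions,
        at_content=100.0 * (a + t) / n,
        at_skew=at_skew,
        gc_skew=gc_skew,
    )


def skews_from_percentages(a: float, t: float, g: float, c: float,
                           ndigits: int = 3) -> tuple[Optional[float], Optional[float]]:
    """Apply the skew formulas to printed base percentages.

    Returns ``(at_skew, gc_skew)`` rounded to ``ndigits`` (reporting
    precision); a zero denominator yields ``None`` for that skew.
    """
    if min(a, t, g, c) < 0:
        raise ValueError("percentages must be non-negative")
    at_skew = (a - t) / (a + t) if a + t else None
    gc_skew = (g - c) / (g + c) if g + c else None
    rd = lambda x: None if x is None else round(x, ndigits)
    return rd(at_skew), rd(gc_skew)


def codon_position_composition(
    cds_list: Sequence[str],
    names: Optional[Sequence[str]] = None,
) -> tuple[CompositionStats, CompositionStats, CompositionStats]:
    """Pooled base composition at codon positions 1, 2 and 3.

    Each CDS must be in frame and a multiple of 3 (trim incomplete stop
    tails first); a violating entry is reported by name/index.
    """
    pools = ["", "", ""]
    for i, cds in enumerate(cds_list):
        if len(cds) % 3 != 0:
            label = names[i] if names is not None else f"#{i}"
            raise ValueError(
                f"CDS {label} has length {len(cds)}, not a multiple of 3 "
                "(trim incomplete stop tails first)"
            )
        for p in range(3):
            pools[p] += cds[p::3]
    if not any(pools):
        raise ValueError("no codons supplied")
    return tuple(base_composition(p) for p in pools)  # type: ignore[return-value]


@dataclass
class ColumnStats:
    column: str
    n: int
    min: float
    max: float
    mean: float
    argmin: str
    argmax: str

    def to_dict(self) -> dict:
        return {"column": self.column, "n": self.n,
                "min": self.min, "max": self.max, "mean": round(self.mean, 1),
                "argmin": self.argmin, "argmax": self.argmax}


_COLUMN_GETTERS = {
    "AT_percent": lambda f: f.declared_at,
    "Size": lambda f: f.declared_size,
    "IGN": lambda f: f.declared_ign,
}


def table_column_stats(ann: MitoAnnotation, column: str,
                       categories: Optional[Iterable[str]] = None) -> ColumnStats:
    """Unweighted min/max/mean of a declared table column over a category
    subset (e.g. the average A+T content of the tRNA genes)."""
    if column not in _COLUMN_GETTERS:
        raise ValueError(f"unknown column {column!r}; one of {sorted(_COLUMN_GETTERS)}")
    get = _COLUMN_GETTERS[column]
    cats = set(categories) if categories is not None else None
    vals: list[tuple[float, str]] = []
    for f in ann.features:
        if cats is not None and f.category not in cats:
            continue
        v = get(f)
        if v is not None:
            vals.append((float(v), f.name))
    if not vals:
        raise ValueError(f"no populated {column!r} values in subset {cats}")
    vmin = min(vals, key=lambda x: x[0])
    vmax = max(vals, key=lambda x: x[0])
    return ColumnStats(
        column=column, n=len(vals),
        min=vmin[0], max=vmax[0],
        mean=sum(v for v, _ in vals) / len(vals),
        argmin=vmin[1], argmax=vmax[1],
    )
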