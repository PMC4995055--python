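"""Structural dissection of mitochondrial control regions (D-loop-like).

Insect control regions are built from a small vocabulary of elements:
tandem-repeat arrays (adjacent approximate copies of a unit), inverted
repeats folding into stem-loops, homopolymer runs (poly-T stretches
implicated in replication initiation), and segments whose G+C content is
elevated relative to the AT-rich genome.  This module detects each element
class and tiles a control-region sequence into a non-overlapping ordered
segment report.

The tandem-repeat finder is a deliberately simple seed-and-extend detector:
it seeds candidate periods by exact k-mer self-matches and extends copy by
copy with banded edit-distance alignment (via edlib), scoring each copy by
identity to the first full copy.  It is not a reimplementation of any
external repeat-finding program's scoring; divergences are documented in
the methods note.

All reported coordinates are 1-based inclusive.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import edlib

from .composition import CompositionStats, base_composition

__all__ = [
    "TandemRepeatHit",
    "HairpinHit",
    "Segment",
    "CRReport",
    "find_tandem_repeats",
    "find_hairpins",
    "find_homopolymers",
    "partition_cr",
]

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


# ---------------------------------------------------------------------------
# tandem repeats


@dataclass
class TandemRepeatHit:
    """One tandem-repeat array: ``copies`` approximate copies of a
    ``period``-bp unit starting at 1-based ``start``."""

    start: int
    period: int
    copies: float
    consensus: str
    per_copy_identity: list[float]
    total_span: int

    @property
    def end(self) -> int:
        return self.start + self.total_span - 1

    def to_dict(self) -> dict:
        return {"start": self.start, "end": self.end, "period": self.period,
                "copies": round(self.copies, 2), "consensus": self.consensus,
                "per_copy_identity": [round(x, 3) for x in self.per_copy_identity],
                "total_span": self.total_span}


def _align_copy(unit: str, window: str) -> tuple[int, int]:
    """Align ``unit`` against a prefix of ``window``; return (edit distance,
    consumed window length).  SHW mode leaves the window suffix free."""
    if not window:
        return len(unit), 0
    res = edlib.align(unit, window, mode="SHW", task="distance")
    end = res["locations"][0][1]
    if end is None:
        return len(unit), 0
    return res["editDistance"], end + 1


def _extend_array(seq: str, i: int, p: int, min_identity: float,
                  max_indels_per_copy: int) -> Optional[dict]:
    """Grow a tandem array rightward from a seed copy at ``i`` (0-based)."""
    n = len(seq)
    unit = seq[i:i + p]
    idents = [1.0]
    pos = i + p
    while pos + p // 2 <= n:
        window = seq[pos:pos + p + max_indels_per_copy]
        d, consumed = _align_copy(unit, window)
        identity = 1.0 - d / p
        if identity < min_identity or consumed == 0:
            break
        idents.append(identity)
        pos += consumed
    n_full = len(idents)
    if n_full < 2:
        return None
    # fractional last copy: exact-matching prefix of the unit
    frac = 0
    tail = seq[pos:pos + p]
    for k in range(min(len(tail), p)):
        if tail[k] == unit[k]:
            frac += 1
        else:
            break
    copies = n_full + (frac / p if frac >= 3 else 0)
    span = (pos + (frac if frac >= 3 else 0)) - i
    return {"start": i, "period": p, "copies": copies, "unit": unit,
            "idents": idents, "span": span}


def find_tandem_repeats(seq: str, period_range: tuple[int, int] = (2, 150),
                        min_copies: int = 2, min_identity: float = 0.8,
                        max_indels_per_copy: int = 8,
                        seed_k: int = 8) -> list[TandemRepeatHit]:
    """Detect tandem-repeat arrays by k-mer self-match seeding and per-copy
    banded alignment.

    A position ``i`` seeds period ``p`` when the leading k-mer of
    ``seq[i:]`` recurs at ``i + p``; the array is then extended copy by
    copy, each copy accepted while its identity to the first copy is at
    least ``min_identity`` with at most ``max_indels_per_copy`` indels
    (accommodating internally deleted copies).  Overlapping candidates are
    resolved leftmost-longest (ties to the smaller period).  Single-base
    units are skipped — homopolymer runs are a separate element class.
    """
    seq = seq.upper()
    n = len(seq)
    pmin, pmax = period_range
    if pmin < 2:
        raise ValueError("minimum period must be >= 2")
    if pmax >= n:
        raise ValueError(f"maximum period {pmax} must be < sequence length {n}")
    if not (0.5 < min_identity <= 1.0):
        raise ValueError("min_identity must lie in (0.5, 1]")
    candidates: list[dict] = []
    for p in range(pmin, pmax + 1):
        k = min(seed_k, p)
        for i in range(0, n - 2 * p + 1):
            if seq[i:i + k] != seq[i + p:i + p + k]:
                continue
            unit = seq[i:i + p]
            if len(set(unit)) == 1:
                continue
            arr = _extend_array(seq, i, p, min_identity, max_indels_per_copy)
            if arr is not None and len(arr["idents"]) >= min_copies:
                candidates.append(arr)
    # longest-first resolution (ties: leftmost, then smaller period): a
    # long array must not be truncated by a short overlapping candidate
    candidates.sort(key=lambda a: (-a["span"], a["start"], a["period"]))
    hits: list[TandemRepeatHit] = []
    occupied: list[tuple[int, int]] = []
    for arr in candidates:
        s, e = arr["start"], arr["start"] + arr["span"]
        if any(s < oe and os_ < e for os_, oe in occupied):
            continue
        occupied.append((s, e))
        hits.append(TandemRepeatHit(
            start=s + 1, period=arr["period"], copies=arr["copies"],
            consensus=arr["unit"], per_copy_identity=arr["idents"],
            total_span=arr["span"],
        ))
    hits.sort(key=lambda h: h.start)
    return hits


# ---------------------------------------------------------------------------
# hairpins (inverted repeats)


@dataclass
class HairpinHit:
    """A stem-loop: two reverse-complementary arms around a loop.

    All coordinates 1-based inclusive; ``span = 2 * stem + loop``.
    """

    arm1_start: int
    arm1_end: int
    loop_len: int
    arm2_start: int
    arm2_end: int
    stem_len: int
    mismatches: int

    @property
    def span(self) -> int:
        return 2 * self.stem_len + self.loop_len

    @property
    def start(self) -> int:
        return self.arm1_start

    @property
    def end(self) -> int:
        return self.arm2_end

    def to_dict(self) -> dict:
        return {"arm1": [self.arm1_start, self.arm1_end],
                "loop_len": self.loop_len,
                "arm2": [self.arm2_start, self.arm2_end],
                "stem_len": self.stem_len, "mismatches": self.mismatches,
                "span": self.span}


def _pairs(x: str, y: str, allow_gu: bool) -> bool:
    if (x, y) in _WC:
        return True
    return allow_gu and (x, y) in _GU


def find_hairpins(seq: str, min_stem: int = 4,
                  loop_range: tuple[int, int] = (3, 30),
                  max_mismatches: int = 0,
                  allow_gu: bool = True) -> list[HairpinHit]:
    """Scan for maximal stem-loops (inverted repeats).

    A hit is a stem of ``s >= min_stem`` pairs around a loop of length in
    ``loop_range``, with at most ``max_mismatches`` interior mismatches;
    both the innermost and the outermost pair must pair (G·U counts as a
    pair when ``allow_gu``).  Hits are maximal: the outer flanking pair
    does not pair, and the stem cannot grow inward without shrinking the
    loop below its minimum.  Sorted by stem length descending.
    """
    if min_stem < 4:
        raise ValueError("min_stem must be >= 4")
    seq = seq.upper()
    n = len(seq)
    lmin, lmax = loop_range
    hits: list[HairpinHit] = []
    for p in range(n - 1):
        for l in range(lmin, lmax + 1):
            q = p + l + 1
            if q >= n:
                break
            if not _pairs(seq[p], seq[q], allow_gu):
                continue
            # innermost pair must not be extendable inward within loop bounds
            if l - 2 >= lmin and _pairs(seq[p + 1], seq[q - 1], allow_gu):
                continue
            # walk outward, emitting maximal prefixes that end on a pair
            mism = 0
            s = 1
            emit_at: list[tuple[int, int]] = []  # (stem_len, mismatches)
            while True:
                a, b = p - s, q + s
                outside = a < 0 or b >= n
                ok = (not outside) and _pairs(seq[a], seq[b], allow_gu)
                if not ok and (outside or True):
                    emit_at.append((s, mism))
                if outside:
                    break
                if ok:
                    s += 1
                else:
                    mism += 1
                    if mism > max_mismatches:
                        break
                    s += 1
            seen = set()
            for stem, m in emit_at:
                # trim trailing mismatches: stems must end on a pair
                while stem > 1 and not _pairs(seq[p - stem + 1], seq[q + stem - 1], allow_gu):
                    stem -= 1
                    m -= 1
                if stem < min_stem or (stem, m) in seen:
                    continue
                seen.add((stem, m))
                hits.append(HairpinHit(
                    arm1_start=p - stem + 2, arm1_end=p + 1,
                    loop_len=l,
                    arm2_start=q + 1, arm2_end=q + stem,
                    stem_len=stem, mismatches=m,
                ))
    hits.sort(key=lambda h: (-h.stem_len, h.arm1_start, h.loop_len))
    return hits


def hairpins_outside_repeats(hairpins: Sequence[HairpinHit],
                             repeats: Sequence[TandemRepeatHit]
                             ) -> list[HairpinHit]:
    """Drop hairpins overlapping a tandem-repeat array.

    Repeat arrays routinely contain incidental self-complementary matches
    between copies; for element classification the repeat annotation takes
    precedence and such hairpins are discarded up front.
    """
    spans = [(r.start, r.end) for r in repeats]
    return [h for h in hairpins
            if not any(h.start <= e and s <= h.end for s, e in spans)]


# ---------------------------------------------------------------------------
# homopolymers


def find_homopolymers(seq: str, base: str, min_run: int = 2) -> list[tuple[int, int]]:
    """Maximal runs of ``base`` with length >= min_run, as 1-based
    (start, length) pairs."""
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    seq = seq.upper()
    base = base.upper()
    out: list[tuple[int, int]] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            if j - i >= min_run:
                out.append((i + 1, j - i))
            i = j
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# partition


@dataclass
class Segment:
    start: int   # 1-based inclusive
    end: int
    cls: str     # gc-elevated | poly-T | stem-loop | repeat-array | spacer
    composition: Optional[CompositionStats] = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_dict(self) -> dict:
        return {"start": self.start, "end": self.end, "class": self.cls,
                "length": self.length,
                "composition": None if self.composition is None
                else self.composition.to_dict()}


@dataclass
class CRReport:
    length: int
    segments: list[Segment]

    def classes(self) -> list[str]:
        return [s.cls for s in self.segments]

    def to_dict(self) -> dict:
        return {"length": self.length,
                "segments": [s.to_dict() for s in self.segments]}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


_PRECEDENCE = ("repeat-array", "stem-loop", "poly-T")


def partition_cr(seq: str,
                 repeats: Sequence[TandemRepeatHit] = (),
                 hairpins: Sequence[HairpinHit] = (),
                 homopolymers: Sequence[tuple[int, int]] = (),
                 gc_window: int = 50,
                 gc_threshold: float = 0.35) -> CRReport:
    """Tile a control-region sequence into ordered, non-overlapping
    segments.

    Detector hits claim their intervals with precedence repeat-array >
    stem-loop > poly-T (within a class, leftmost-longest wins); remaining
    intervals are classified ``gc-elevated`` when their windowed mean G+C
    fraction exceeds ``gc_threshold``, else ``spacer``.
    """
    n = len(seq)
    claims: list[tuple[int, int, str]] = []  # 0-based half-open

    def claim(s: int, e: int, cls: str) -> None:
        s, e = max(0, s), min(n, e)
        if e <= s:
            return
        if any(s < ce and cs < e for cs, ce, _ in claims):
            return
        claims.append((s, e, cls))

    by_class = {
        "repeat-array": sorted(((h.start - 1, h.start - 1 + h.total_span)
                                for h in repeats), key=lambda x: (x[0], x[0] - x[1])),
        "stem-loop": sorted(((h.arm1_start - 1, h.arm2_end) for h in hairpins),
                            key=lambda x: (x[0], x[0] - x[1])),
        "poly-T": sorted(((s - 1, s - 1 + ln) for s, ln in homopolymers),
                         key=lambda x: (x[0], x[0] - x[1])),
    }
    for cls in _PRECEDENCE:
        for s, e in by_class[cls]:
            claim(s, e, cls)
    claims.sort()
    # verify invariant before filling gaps
    for (s1, e1, _), (s2, e2, _) in zip(claims, claims[1:]):
        if s2 < e1:
            raise RuntimeError("internal error: overlapping claims after precedence")

    segments: list[Segment] = []

    def add_gap(s: int, e: int) -> None:
        if e <= s:
            return
        sub = seq[s:e]
        if len(sub) <= gc_window:
            gc = 1.0 - base_composition(sub).at_content / 100.0
        else:
            vals = [1.0 - base_composition(sub[i:i + gc_window]).at_content / 100.0
                    for i in range(0, len(sub) - gc_window + 1)]
            gc = sum(vals) / len(vals)
        cls = "gc-elevated" if gc > gc_threshold else "spacer"
        segments.append(Segment(s + 1, e, cls, base_composition(sub)))

    cursor = 0
    for s, e, cls in claims:
        add_gap(cursor, s)
        segments.append(Segment(s + 1, e, cls, base_composition(seq[s:e])))
        cursor = e
    add_gap(cursor, n)

    total = sum(sg.length for sg in segments)
    if total != n:
        raise RuntimeError(f"internal error: segments cover {total} of {n} bp")
    return CRReport(length=n, segments=segments)
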