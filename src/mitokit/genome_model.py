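"""Annotated circular mitogenomes and coordinate-derived annotation analytics.

The central object is :class:`MitoAnnotation`, the in-memory form of a
mitogenome feature table: an ordered list of :class:`GeneFeature` rows
(1-based inclusive coordinates, GenBank convention) plus the genome length
and topology.  Everything a feature table implies — gene sizes, intergenic
spacers and overlaps, strand census — is derived here.

Insect mitogenome tables conventionally carry both *declared* values (what
the annotators printed) and values recomputable from the coordinates.  The
two can disagree in published tables; this module keeps both and reports
mismatches via :func:`validate_declared` rather than silently correcting
either side.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneFeature",
    "MitoAnnotation",
    "AdjacencyReport",
    "StrandCensus",
    "FeatureTableError",
    "GenBankError",
    "read_feature_table",
    "write_feature_table",
    "read_genbank",
    "feature_length",
    "junction",
    "summarize_junctions",
    "strand_census",
    "extract_sequence",
    "validate_declared",
]

Strand = Literal["forward", "reverse"]
Category = Literal["PCG", "tRNA", "rRNA", "CR"]

TABLE_COLUMNS = ["Gene", "Start", "End", "Size", "Direction", "IGN", "Codons", "AT_percent"]


class FeatureTableError(ValueError):
    """Raised on malformed feature-table input."""


class GenBankError(ValueError):
    """Raised on unusable GenBank records."""


def categorize(name: str) -> Category:
    """Feature category from the gene symbol (trn* / rrn* / CR / else PCG)."""
    if name.startswith("trn"):
        return "tRNA"
    if name.startswith("rrn"):
        return "rRNA"
    if name.upper() in ("CR", "D-LOOP", "D_LOOP", "CONTROL_REGION"):
        return "CR"
    return "PCG"


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature with circular 1-based inclusive coordinates.

    ``end < start`` is legal only for a feature spanning the origin of a
    circular molecule.  ``declared_*`` fields hold table-printed values that
    may disagree with the coordinates; they are never reconciled silently.
    """

    name: str
    start: int
    end: int
    strand: Strand = "forward"
    anticodon_or_codons: Optional[str] = None
    declared_size: Optional[int] = None
    declared_ign: Optional[int] = None
    declared_at: Optional[float] = None

    @property
    def category(self) -> Category:
        return categorize(self.name)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise FeatureTableError(
                f"feature {self.name!r}: coordinates must be >= 1 "
                f"(got {self.start}..{self.end})"
            )
        if self.strand not in ("forward", "reverse"):
            raise FeatureTableError(f"feature {self.name!r}: bad strand {self.strand!r}")


@dataclass
class MitoAnnotation:
    """Ordered feature list plus genome length and topology."""

    genome_length: int
    topology: Literal["circular", "linear"] = "circular"
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.features:
            if f.start > self.genome_length or f.end > self.genome_length:
                raise FeatureTableError(
                    f"feature {f.name!r} exceeds genome length {self.genome_length}"
                )

    def genes(self) -> list[GeneFeature]:
        """Features excluding the control region."""
        return [f for f in self.features if f.category != "CR"]

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


def feature_length(f: GeneFeature, genome_length: int,
                   topology: str = "circular") -> int:
    """Length in bp of a feature, handling origin-spanning features.

    ``end >= start`` gives ``end - start + 1``; a wraparound feature
    (``end < start``) is only meaningful on a circular molecule and has
    length ``(L - start + 1) + end``.
    """
    if f.end >= f.start:
        return f.end - f.start + 1
    if topology != "circular":
        raise FeatureTableError(
            f"feature {f.name!r} wraps the origin but topology is {topology!r}"
        )
    return (genome_length - f.start + 1) + f.end


def junction(prev: GeneFeature, nxt: GeneFeature, genome_length: int,
             wrap: bool = False) -> int:
    """Signed spacer between two adjacent features (negative = overlap).

    For the ordinary in-table pair the spacer is ``next.start - prev.end - 1``.
    For the wrap pair of a circular annotation (last feature back to the
    first) it is ``(L - prev.end) + (next.start - 1)``.
    """
    if wrap:
        return (genome_length - prev.end) + (nxt.start - 1)
    return nxt.start - prev.end - 1


@dataclass
class AdjacencyReport:
    """Sign partition of the per-junction spacer list.

    Positive spacers are intergenic nucleotides (IGN); negative spacers are
    gene overlaps.  ``spacers`` keeps the full list as
    ``(prev_name, next_name, signed_bp)`` in junction order.
    """

    spacers: list[tuple[str, str, int]]
    total_overlap_bp: int
    n_overlap_pairs: int
    total_ign_bp: int
    n_ign_pairs: int
    longest_overlap: Optional[tuple[int, tuple[str, str]]]
    longest_ign: Optional[tuple[int, tuple[str, str]]]
    source: str = "coordinates"

    def to_dict(self) -> dict:
        d = {
            "source": self.source,
            "spacers": [list(s) for s in self.spacers],
            "total_overlap_bp": self.total_overlap_bp,
            "n_overlap_pairs": self.n_overlap_pairs,
            "total_ign_bp": self.total_ign_bp,
            "n_ign_pairs": self.n_ign_pairs,
            "longest_overlap": None if self.longest_overlap is None
            else {"bp": self.longest_overlap[0], "pair": list(self.longest_overlap[1])},
            "longest_ign": None if self.longest_ign is None
            else {"bp": self.longest_ign[0], "pair": list(self.longest_ign[1])},
        }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _spacer_list(ann: MitoAnnotation, source: str) -> list[tuple[str, str, int]]:
    feats = ann.features
    if len(feats) < 2:
        raise FeatureTableError("need at least two features to evaluate junctions")
    out: list[tuple[str, str, int]] = []
    if source == "coordinates":
        for prev, nxt in zip(feats, feats[1:]):
            out.append((prev.name, nxt.name, junction(prev, nxt, ann.genome_length)))
        if ann.topology == "circular":
            out.append((feats[-1].name, feats[0].name,
                        junction(feats[-1], feats[0], ann.genome_length, wrap=True)))
    elif source == "declared":
        if all(f.declared_ign is None for f in feats):
            raise FeatureTableError("declared junction source requested but IGN column absent")
        n = len(feats)
        last = n if ann.topology == "circular" else n - 1
        for i in range(last):
            prev, nxt = feats[i], feats[(i + 1) % n]
            if prev.declared_ign is not None:
                out.append((prev.name, nxt.name, prev.declared_ign))
    else:
        raise ValueError(f"unknown junction source {source!r}")
    return out


def summarize_junctions(ann: MitoAnnotation,
                        source: str = "coordinates") -> AdjacencyReport:
    """Sign-partition the spacer list of adjacent features, in table order.

    ``source="coordinates"`` recomputes every junction from coordinates
    (including the wrap junction when circular); ``source="declared"`` uses
    the table-printed IGN values, skipping rows where the cell is blank.
    """
    spacers = _spacer_list(ann, source)
    overlaps = [s for s in spacers if s[2] < 0]
    igns = [s for s in spacers if s[2] > 0]
    longest_overlap = None
    if overlaps:
        a, b, v = min(overlaps, key=lambda s: s[2])
        longest_overlap = (-v, (a, b))
    longest_ign = None
    if igns:
        a, b, v = max(igns, key=lambda s: s[2])
        longest_ign = (v, (a, b))
    return AdjacencyReport(
        spacers=spacers,
        total_overlap_bp=sum(-s[2] for s in overlaps),
        n_overlap_pairs=len(overlaps),
        total_ign_bp=sum(s[2] for s in igns),
        n_ign_pairs=len(igns),
        longest_overlap=longest_overlap,
        longest_ign=longest_ign,
        source=source,
    )


@dataclass
class StrandCensus:
    n_forward: int
    n_reverse: int
    by_category: dict[str, int]
    by_strand_category: dict[tuple[str, str], int]

    def to_dict(self) -> dict:
        return {
            "n_forward": self.n_forward,
            "n_reverse": self.n_reverse,
            "by_category": dict(self.by_category),
            "by_strand_category": {f"{s}:{c}": n
                                   for (s, c), n in self.by_strand_category.items()},
        }


def strand_census(ann: MitoAnnotation) -> StrandCensus:
    """Count features per strand and per category; CR is excluded from the
    strand counts (a control region has no coding strand)."""
    by_cat: dict[str, int] = {}
    by_sc: dict[tuple[str, str], int] = {}
    n_fwd = n_rev = 0
    for f in ann.features:
        by_cat[f.category] = by_cat.get(f.category, 0) + 1
        if f.category == "CR":
            continue
        key = (f.strand, f.category)
        by_sc[key] = by_sc.get(key, 0) + 1
        if f.strand == "forward":
            n_fwd += 1
        else:
            n_rev += 1
    return StrandCensus(n_fwd, n_rev, by_cat, by_sc)


def extract_sequence(genome: str, f: GeneFeature,
                     topology: str = "circular") -> str:
    """Slice a feature's sequence; reverse-strand features are returned
    reverse-complemented (i.e. 5'→3' on the coding strand)."""
    L = len(genome)
    if f.start > L or f.end > L:
        raise FeatureTableError(
            f"feature {f.name!r} ({f.start}..{f.end}) exceeds genome of {L} bp"
        )
    if f.end >= f.start:
        s = genome[f.start - 1:f.end]
    else:
        if topology != "circular":
            raise FeatureTableError(
                f"feature {f.name!r} wraps the origin of a linear molecule"
            )
        s = genome[f.start - 1:] + genome[:f.end]
    if f.strand == "reverse":
        s = str(Seq(s).reverse_complement())
    return s


# ---------------------------------------------------------------------------
# feature-table I/O


def _parse_int(cell, row: int, col: str) -> Optional[int]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return None
    try:
        return int(str(cell).strip())
    except ValueError:
        raise FeatureTableError(f"row {row}: malformed integer in column {col}: {cell!r}")


def read_feature_table(path: str | Path) -> MitoAnnotation:
    """Read a TSV feature table (Gene/Start/End/Size/Direction/IGN/Codons/
    AT_percent) into a :class:`MitoAnnotation`, preserving row order.

    An optional leading comment line ``#genome_length=N\ttopology=circular``
    fixes the molecule size; otherwise the maximum coordinate is used.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FeatureTableError(f"{path}: empty feature table")
    genome_length = None
    topology = "circular"
    lines = text.splitlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        for tok in line[1:].replace("\t", " ").split():
            if tok.startswith("genome_length="):
                genome_length = int(tok.split("=", 1)[1])
            elif tok.startswith("topology="):
                topology = tok.split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in ("Gene", "Start", "End", "Direction") if c not in df.columns]
    if missing:
        raise FeatureTableError(f"{path}: missing required columns {missing}")
    feats: list[GeneFeature] = []
    for i, row in df.iterrows():
        rowno = i + 2 + body_start
        name = str(row["Gene"]).strip()
        start = _parse_int(row["Start"], rowno, "Start")
        end = _parse_int(row["End"], rowno, "End")
        if start is None or end is None:
            raise FeatureTableError(f"row {rowno} ({name}): missing Start/End coordinate")
        direction = row.get("Direction")
        if direction is None or (isinstance(direction, float) and pd.isna(direction)) \
                or str(direction).strip() == "":
            strand: Strand = "forward"  # directionless rows (e.g. CR)
        else:
            d = str(direction).strip().lower()
            if d not in ("forward", "reverse"):
                raise FeatureTableError(f"row {rowno} ({name}): unknown Direction {direction!r}")
            strand = d  # type: ignore[assignment]
        codons = row.get("Codons")
        if codons is not None and not (isinstance(codons, float) and pd.isna(codons)):
            codons = str(codons).strip() or None
        else:
            codons = None
        at = row.get("AT_percent")
        at_val = None
        if at is not None and not (isinstance(at, float) and pd.isna(at)) and str(at).strip():
            at_val = float(at)
        feats.append(GeneFeature(
            name=name, start=start, end=end, strand=strand,
            anticodon_or_codons=codons,
            declared_size=_parse_int(row.get("Size"), rowno, "Size"),
            declared_ign=_parse_int(row.get("IGN"), rowno, "IGN"),
            declared_at=at_val,
        ))
    if genome_length is None:
        genome_length = max(max(f.start, f.end) for f in feats)
    return MitoAnnotation(genome_length=genome_length, topology=topology, features=feats)


def write_feature_table(ann: MitoAnnotation, path: str | Path,
                        genome: Optional[str] = None) -> None:
    """Write the annotation back to TSV in the standard column layout.

    With a genome sequence, Size/IGN/AT_percent are recomputed from the
    coordinates and sequence; otherwise declared values are echoed.
    """
    from .composition import base_composition  # local import to avoid a cycle

    rows = []
    feats = ann.features
    n = len(feats)
    for i, f in enumerate(feats):
        if genome is not None:
            size = feature_length(f, ann.genome_length, ann.topology)
            at = round(base_composition(extract_sequence(genome, f, ann.topology)).at_content, 1)
            if i < n - 1:
                ign = junction(f, feats[i + 1], ann.genome_length)
            elif ann.topology == "circular":
                ign = junction(f, feats[0], ann.genome_length, wrap=True)
            else:
                ign = None
        else:
            size, ign, at = f.declared_size, f.declared_ign, f.declared_at
        rows.append({
            "Gene": f.name, "Start": f.start, "End": f.end,
            "Size": "" if size is None else size,
            "Direction": "" if f.category == "CR" else f.strand.capitalize(),
            "IGN": "" if ign is None else ign,
            "Codons": f.anticodon_or_codons or "",
            "AT_percent": "" if at is None else at,
        })
    header = f"#genome_length={ann.genome_length}\ttopology={ann.topology}\n"
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GenBank I/O


def _genbank_feature_name(feat) -> Optional[str]:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return None


def read_genbank(path: str | Path) -> tuple[str, MitoAnnotation]:
    """Read a GenBank flat file into ``(sequence, MitoAnnotation)``.

    Feature types CDS/tRNA/rRNA are kept (plain ``gene`` records that pair
    with them are skipped); ``D-loop``/``misc_feature`` become the "CR"
    feature.  A two-part join spanning the origin of a circular record is
    merged into a single wraparound feature; any other multi-interval
    feature is rejected.
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper()
    if not seq:
        raise GenBankError(f"{path}: record has no sequence")
    topology = record.annotations.get("topology", "linear")
    L = len(seq)
    feats: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "D-loop", "misc_feature"):
            continue
        name = _genbank_feature_name(feat)
        if feat.type in ("D-loop", "misc_feature"):
            name = "CR"
        if name is None:
            raise GenBankError(f"{path}: unnamed {feat.type} feature")
        loc = feat.location
        parts = list(loc.parts)
        if len(parts) == 1:
            start = int(loc.start) + 1
            end = int(loc.end)
        elif len(parts) == 2 and topology == "circular" and \
                int(parts[0].end) == L and int(parts[1].start) == 0:
            start = int(parts[0].start) + 1
            end = int(parts[1].end)
        else:
            raise GenBankError(
                f"{path}: unsupported multi-interval feature {name!r} ({loc})"
            )
        strand: Strand = "reverse" if loc.strand == -1 else "forward"
        feats.append(GeneFeature(name=name, start=start, end=end, strand=strand,
                                 anticodon_or_codons=str(
                                     feat.qualifiers.get("anticodon", [None])[0]
                                 ) if "anticodon" in feat.qualifiers else None))
    return seq, MitoAnnotation(genome_length=L, topology=topology, features=feats)


# ---------------------------------------------------------------------------
# declared-vs-computed validation


@dataclass(frozen=True)
class Mismatch:
    kind: str          # "size" | "ign"
    feature: str
    declared: int
    computed: int

    def to_dict(self) -> dict:
        return {"kind": self.kind, "feature": self.feature,
                "declared": self.declared, "computed": self.computed}


def validate_declared(ann: MitoAnnotation) -> list[Mismatch]:
    """Compare declared Size/IGN against coordinate-derived values.

    Published tables are not always internally consistent; every mismatch is
    reported, none is corrected.
    """
    out: list[Mismatch] = []
    feats = ann.features
    n = len(feats)
    for i, f in enumerate(feats):
        if f.declared_size is not None:
            comp = feature_length(f, ann.genome_length, ann.topology)
            if comp != f.declared_size:
                out.append(Mismatch("size", f.name, f.declared_size, comp))
        if f.declared_ign is not None:
            if i < n - 1:
                comp = junction(f, feats[i + 1], ann.genome_length)
            elif ann.topology == "circular":
                comp = junction(f, feats[0], ann.genome_length, wrap=True)
            else:
                continue
            if comp != f.declared_ign:
                out.append(Mismatch("ign", f.name, f.declared_ign, comp))
    return out
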