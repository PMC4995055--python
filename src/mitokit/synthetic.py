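"""Synthetic mitogenome generator: ground truth for every pipeline stage.

The generator builds a fully specified circular mitogenome — sequence,
annotation and GenBank record — from a :class:`GenomeSpec`.  The default
spec emulates a whitefly-like molecule: 36 genes (13 protein-coding, 21
tRNA, 2 rRNA) on two strands in the rearranged whitefly order, AT-rich
composition (A/T/G/C = 0.310/0.398/0.168/0.124 on the coding strand), ATN
starts, complete and incomplete stops, and a ~920 bp control region built
to a five-part structural plan (GC-elevated segment, 69 bp poly-T, 44 bp
hairpin, two 128 bp tandem copies, an intervening spacer, and three 38 bp
copies of which the third carries a 6 bp internal deletion).

Composition targets apply to the coding strand of each gene; reverse-strand
genes are planted as reverse complements, which produces the strand
asymmetry characteristic of real mitogenomes.  Everything is deterministic
under a fixed seed.

``evolve_cds`` provides event-count ground truth for Ka/Ks recovery tests:
proposed single-nucleotide changes are accepted with relative probability 1
(synonymous) or omega (nonsynonymous), stop-creating proposals rejected.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .codon_usage import sense_codons, stop_codons
from .gene_order import GeneOrder
from .genome_model import GeneFeature, MitoAnnotation, write_feature_table

__all__ = [
    "GeneSpec",
    "CRPlan",
    "GenomeSpec",
    "SyntheticGenome",
    "default_spec",
    "generate_mitogenome",
    "evolve_cds",
    "scramble_order",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")
_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "T"), ("T", "G")}


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GeneSpec:
    name: str
    length: int
    strand: str = "forward"          # on the genome (J) strand
    start_codon: Optional[str] = None  # PCGs only
    stop: Optional[str] = None         # "TAA"/"TAG" or incomplete "T"/"TA"
    anticodon: Optional[str] = None


@dataclass(frozen=True)
class CRPlan:
    """Element plan for the control region, in order."""

    gc_region_len: int = 293
    gc_region_gc: float = 0.39
    polyt_len: int = 69
    hairpin_stem: int = 16
    hairpin_loop: int = 12
    pad_after_hairpin: int = 19
    long_repeat_period: int = 128
    long_repeat_copies: int = 2
    spacer_len: int = 94
    short_repeat_period: int = 38
    short_repeat_copies: int = 3
    short_repeat_deletion: int = 6     # internal deletion in the last copy
    tail_pad: int = 37

    @property
    def length(self) -> int:
        return (self.gc_region_len + self.polyt_len
                + 2 * self.hairpin_stem + self.hairpin_loop
                + self.pad_after_hairpin
                + self.long_repeat_period * self.long_repeat_copies
                + self.spacer_len
                + self.short_repeat_period * self.short_repeat_copies
                - self.short_repeat_deletion
                + self.tail_pad)


@dataclass(frozen=True)
class GenomeSpec:
    """Full recipe for one synthetic mitogenome (seed mandatory)."""

    genes: tuple[GeneSpec, ...]
    composition: dict[str, float]
    seed: int
    code_table: int = 5
    cr_plan: CRPlan = field(default_factory=CRPlan)
    name: str = "synthetic-mitogenome"

    def __post_init__(self) -> None:
        if abs(sum(self.composition.values()) - 1.0) > 1e-9:
            raise ValueError("composition fractions must sum to 1")
        for g in self.genes:
            if g.length <= 0:
                raise ValueError(f"gene {g.name}: non-positive length")


# the default whitefly-like plan: gene list, strands, sizes, starts/stops
# and anticodons mirroring the packaged annotation table (zero spacers).
_DEFAULT_GENES: tuple[GeneSpec, ...] = (
    GeneSpec("cox1", 1539, "forward", "ATG", "TAA"),
    GeneSpec("trnL1", 64, "forward", anticodon="TAA"),
    GeneSpec("cox2", 664, "forward", "ATT", "T"),
    GeneSpec("trnK", 70, "forward", anticodon="CTT"),
    GeneSpec("trnD", 62, "forward", anticodon="GTC"),
    GeneSpec("atp8", 147, "forward", "ATA", "TAA"),
    GeneSpec("atp6", 645, "forward", "ATA", "TAG"),
    GeneSpec("trnE", 67, "forward", anticodon="TTC"),
    GeneSpec("trnF", 63, "reverse", anticodon="GAA"),
    GeneSpec("nad5", 1675, "reverse", "ATA", "T"),
    GeneSpec("trnH", 61, "reverse", anticodon="GTG"),
    GeneSpec("nad4", 1281, "reverse", "ATG", "TAG"),
    GeneSpec("nad4l", 297, "reverse", "ATG", "TAA"),
    GeneSpec("trnT", 62, "forward", anticodon="TGT"),
    GeneSpec("trnP", 61, "reverse", anticodon="TGG"),
    GeneSpec("nad6", 441, "forward", "ATA", "TAA"),
    GeneSpec("cytb", 1134, "forward", "ATG", "TAA"),
    GeneSpec("trnS2", 57, "forward", anticodon="GCT"),
    GeneSpec("nad1", 921, "reverse", "ATA", "TAA"),
    GeneSpec("trnL2", 63, "reverse", anticodon="TAG"),
    GeneSpec("rrnL", 1278, "reverse"),
    GeneSpec("rrnS", 771, "reverse"),
    GeneSpec("trnN", 66, "forward", anticodon="GTT"),
    GeneSpec("trnQ", 71, "reverse", anticodon="TTG"),
    GeneSpec("trnV", 64, "reverse", anticodon="TAC"),
    GeneSpec("trnR", 65, "reverse", anticodon="TCG"),
    GeneSpec("trnA", 62, "reverse", anticodon="TGC"),
    GeneSpec("nad3", 353, "forward", "ATT", "TA"),
    GeneSpec("trnG", 63, "forward", anticodon="TCC"),
    GeneSpec("cox3", 786, "forward", "ATG", "TAA"),
    GeneSpec("CR", 920),
    GeneSpec("trnI", 66, "forward", anticodon="GAT"),
    GeneSpec("trnM", 68, "forward", anticodon="CAT"),
    GeneSpec("nad2", 975, "forward", "ATA", "TAA"),
    GeneSpec("trnW", 63, "forward", anticodon="TCA"),
    GeneSpec("trnY", 62, "reverse", anticodon="GCA"),
    GeneSpec("trnC", 63, "reverse", anticodon="GTA"),
)

DEFAULT_COMPOSITION = {"A": 0.310, "T": 0.398, "G": 0.168, "C": 0.124}


def default_spec(seed: int, composition: Optional[dict[str, float]] = None,
                 all_forward: bool = False) -> GenomeSpec:
    """The default whitefly-like genome spec (~15.2 kb, 36 genes + CR)."""
    genes = _DEFAULT_GENES
    if all_forward:
        genes = tuple(replace(g, strand="forward") for g in genes)
    return GenomeSpec(genes=genes,
                      composition=dict(composition or DEFAULT_COMPOSITION),
                      seed=seed)


def _sample_bases(rng: np.random.Generator, n: int,
                  composition: dict[str, float]) -> str:
    probs = [composition[b] for b in _BASES]
    return "".join(rng.choice(list(_BASES), size=n, p=probs)) if n else ""


def _exact_bases(rng: np.random.Generator, n: int,
                 composition: dict[str, float]) -> str:
    """A random permutation with *exact* base counts (largest-remainder
    rounding), so segment-level composition targets hold for every seed."""
    if n == 0:
        return ""
    quotas = {b: composition[b] * n for b in _BASES}
    counts = {b: int(q) for b, q in quotas.items()}
    short = n - sum(counts.values())
    for b in sorted(_BASES, key=lambda b: quotas[b] - counts[b], reverse=True)[:short]:
        counts[b] += 1
    pool = "".join(b * counts[b] for b in _BASES)
    return "".join(rng.permutation(list(pool)))


def _sense_codon_dist(composition_key: tuple, code_table: int):
    """Distribution over sense codons whose *marginal* base composition
    equals the target.

    Naive i.i.d. base sampling with stop rejection under-represents A
    (stops are A-rich), skewing whole-genome composition; a fixed-point
    adjustment of the per-position base weights removes that bias.
    """
    p = dict(composition_key)
    q = dict(p)
    codons = sense_codons(code_table)
    w = None
    for _ in range(500):
        w = np.array([q[c[0]] * q[c[1]] * q[c[2]] for c in codons])
        w = w / w.sum()
        m = {b: 0.0 for b in _BASES}
        for wi, c in zip(w, codons):
            for ch in c:
                m[ch] += wi / 3.0
        if max(abs(m[b] - p[b]) for b in _BASES) < 1e-12:
            break
        q = {b: q[b] * p[b] / m[b] for b in _BASES}
        tot = sum(q.values())
        q = {b: v / tot for b, v in q.items()}
    return codons, w


_DIST_CACHE: dict = {}


def _sample_codons(rng: np.random.Generator, n: int,
                   composition: dict[str, float], code_table: int) -> list[str]:
    key = (tuple(sorted(composition.items())), code_table)
    if key not in _DIST_CACHE:
        _DIST_CACHE[key] = _sense_codon_dist(key[0], code_table)
    codons, w = _DIST_CACHE[key]
    return list(rng.choice(codons, size=n, p=w)) if n else []


def _build_cds(rng: np.random.Generator, g: GeneSpec,
               composition: dict[str, float], code_table: int) -> str:
    if g.start_codon is None or g.stop is None:
        raise ValueError(f"gene {g.name}: PCG needs start and stop")
    tail = g.stop if g.stop in ("T", "TA") else ""
    body_len = g.length - 3 - len(tail) - (0 if tail else 3)
    if body_len < 0 or body_len % 3:
        raise ValueError(
            f"gene {g.name}: length {g.length} incompatible with stop {g.stop!r}"
        )
    codons = _sample_codons(rng, body_len // 3, composition, code_table)
    return g.start_codon + "".join(codons) + (tail if tail else g.stop)


def _build_cr(rng: np.random.Generator, plan: CRPlan,
              composition: dict[str, float]) -> str:
    """Assemble the control region to the element plan.

    The GC-elevated segment and the AT-rich fillers use exact-count base
    sampling so their composition classes are recovered for every seed;
    repeat units, hairpin arms and loop are i.i.d. at genome composition.
    """
    at = {b: composition[b] for b in _BASES}
    # deliberately AT-poor-in-GC filler (intervening spacers and pads)
    low_gc = {"A": 0.45, "T": 0.45, "G": 0.05, "C": 0.05}
    gc = plan.gc_region_gc
    g_frac = composition["G"] / (composition["G"] + composition["C"])
    a_frac = composition["A"] / (composition["A"] + composition["T"])
    gc_comp = {"G": gc * g_frac, "C": gc * (1 - g_frac),
               "A": (1 - gc) * a_frac, "T": (1 - gc) * (1 - a_frac)}
    # GC-elevated segment must not end in T (the poly-T run would extend left)
    while True:
        gc_region = _exact_bases(rng, plan.gc_region_len, gc_comp)
        if gc_region[-1] != "T":
            break
    parts = [gc_region]
    parts.append("T" * plan.polyt_len)
    # hairpin: arm1 + loop + revcomp(arm1).  Constraints keep the planted
    # elements exactly recoverable for any seed: arm1 must not start with T
    # (poly-T run length), the loop ends must not pair (no inward stem
    # growth), and the first pad base must not pair with the last poly-T
    # base (no outward stem growth across the hairpin boundary).
    while True:
        arm1 = _sample_bases(rng, plan.hairpin_stem, at)
        if arm1[0] in "ACG" and len(set(arm1)) > 1:
            break
    while True:
        loop = _sample_bases(rng, plan.hairpin_loop, at)
        if (loop[0], loop[-1]) not in (_WC_PAIRS | _GU_PAIRS):
            break
    parts.append(arm1 + loop + _revcomp(arm1))
    while True:
        pad = _exact_bases(rng, plan.pad_after_hairpin, low_gc)
        if ("T", pad[0]) not in (_WC_PAIRS | _GU_PAIRS):
            break
    parts.append(pad)
    long_unit = _sample_bases(rng, plan.long_repeat_period, at)
    parts.append(long_unit * plan.long_repeat_copies)
    parts.append(_exact_bases(rng, plan.spacer_len, low_gc))
    short_unit = _sample_bases(rng, plan.short_repeat_period, at)
    p = plan.short_repeat_period
    dele = plan.short_repeat_deletion
    cut = p // 2
    last_copy = short_unit[:cut] + short_unit[cut + dele:]
    parts.append(short_unit * (plan.short_repeat_copies - 1) + last_copy)
    parts.append(_exact_bases(rng, plan.tail_pad, low_gc))
    cr = "".join(parts)
    assert len(cr) == plan.length
    return cr


@dataclass
class SyntheticGenome:
    """One generated mitogenome bundle."""

    spec: GenomeSpec
    sequence: str
    annotation: MitoAnnotation
    record: SeqRecord

    def write_bundle(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fasta",
            "genbank": outdir / "genome.gb",
            "table": outdir / "features.tsv",
        }
        SeqIO.write([self.record], str(paths["fasta"]), "fasta")
        SeqIO.write([self.record], str(paths["genbank"]), "genbank")
        write_feature_table(self.annotation, paths["table"], genome=self.sequence)
        return paths


def generate_mitogenome(spec: GenomeSpec) -> SyntheticGenome:
    """Build the circular genome sequence, annotation and GenBank record.

    Genes are laid head-to-tail in spec order (zero spacers); each gene is
    generated 5'→3' on its coding strand at the spec's composition and
    planted as-is (forward) or reverse-complemented (reverse).  PCGs are
    valid ORFs under the code table with the planted start/stop, including
    incomplete stops.  The same seed always yields the same bytes.
    """
    if spec.cr_plan.length != next(
            (g.length for g in spec.genes if g.name == "CR"),
            spec.cr_plan.length):
        raise ValueError(
            f"CR plan length {spec.cr_plan.length} does not match the CR "
            f"gene length in the spec"
        )
    rng = np.random.default_rng(spec.seed)
    chunks: list[str] = []
    features: list[GeneFeature] = []
    pos = 1
    for g in spec.genes:
        if g.name == "CR":
            coding = _build_cr(rng, spec.cr_plan, spec.composition)
        elif g.start_codon is not None:
            coding = _build_cds(rng, g, spec.composition, spec.code_table)
        else:
            coding = _sample_bases(rng, g.length, spec.composition)
        assert len(coding) == g.length
        chunks.append(coding if g.strand == "forward" else _revcomp(coding))
        if g.start_codon is not None:
            label = f"{g.start_codon}, {g.stop if len(g.stop) == 3 else g.stop + '-' * (3 - len(g.stop))}"
        else:
            label = g.anticodon
        features.append(GeneFeature(
            name=g.name, start=pos, end=pos + g.length - 1,
            strand=g.strand if g.name != "CR" else "forward",
            anticodon_or_codons=label,
        ))
        pos += g.length
    sequence = "".join(chunks)
    ann = MitoAnnotation(genome_length=len(sequence), topology="circular",
                         features=features)
    # declared columns mirror the computed values (a consistent table)
    from .composition import base_composition
    from .genome_model import extract_sequence, feature_length, junction
    declared = []
    n = len(features)
    for i, f in enumerate(features):
        nxt = features[(i + 1) % n]
        declared.append(replace(
            f,
            declared_size=feature_length(f, ann.genome_length),
            declared_ign=junction(f, nxt, ann.genome_length, wrap=(i == n - 1)),
            declared_at=round(base_composition(
                extract_sequence(sequence, f)).at_content, 1),
        ))
    ann = MitoAnnotation(genome_length=len(sequence), topology="circular",
                         features=declared)
    record = _to_record(spec, sequence, ann)
    return SyntheticGenome(spec=spec, sequence=sequence, annotation=ann,
                           record=record)


def _to_record(spec: GenomeSpec, sequence: str, ann: MitoAnnotation) -> SeqRecord:
    record = SeqRecord(Seq(sequence), id="SYNMT01", name="SYNMT01",
                       description=spec.name)
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular"
    for f in ann.features:
        loc = FeatureLocation(f.start - 1, f.end,
                              strand=-1 if f.strand == "reverse" else 1)
        if f.category == "PCG":
            ftype, quals = "CDS", {"gene": [f.name],
                                   "transl_table": [str(spec.code_table)]}
        elif f.category == "tRNA":
            ftype, quals = "tRNA", {"gene": [f.name]}
            if f.anticodon_or_codons:
                quals["anticodon"] = [f.anticodon_or_codons]
        elif f.category == "rRNA":
            ftype, quals = "rRNA", {"gene": [f.name]}
        else:
            ftype, quals = "misc_feature", {"note": ["control region"]}
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    return record


# ---------------------------------------------------------------------------
# CDS evolution (Ka/Ks ground truth)


def evolve_cds(cds: str, omega: float, expected_subs_per_codon: float,
               seed: int, code_table: int = 5) -> tuple[str, dict[str, int]]:
    """Evolve a stop-free in-frame CDS under a relative-rate process.

    Substitutions are proposed position by position (uniform position,
    uniform non-stop alternative base at that position) and accepted with
    relative probability 1 when synonymous and ``omega`` when
    nonsynonymous; accepted events accumulate until
    ``round(expected_subs_per_codon * n_codons)`` substitutions have been
    realized.  Returns the derived CDS and the realized event counts.
    """
    from .codon_usage import translate_codon

    if omega < 0:
        raise ValueError("omega must be >= 0")
    if len(cds) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    cds = cds.upper()
    stops = stop_codons(code_table)
    n_codons = len(cds) // 3
    target = round(expected_subs_per_codon * n_codons)
    seq = list(cds)
    rng = np.random.default_rng(seed)
    counts = {"synonymous": 0, "nonsynonymous": 0}
    guard = 0
    max_proposals = max(1000, 200 * target) if target else 0
    while sum(counts.values()) < target:
        guard += 1
        if guard > max_proposals:
            raise RuntimeError("substitution process failed to reach target "
                               "(omega too small for the requested count?)")
        pos = int(rng.integers(len(seq)))
        ci = pos - pos % 3
        codon = "".join(seq[ci:ci + 3])
        alts = []
        for b in _BASES:
            if b == seq[pos]:
                continue
            mut = codon[:pos - ci] + b + codon[pos - ci + 1:]
            if mut not in stops:
                alts.append((b, mut))
        if not alts:
            continue
        b, mut = alts[int(rng.integers(len(alts)))]
        syn = translate_codon(mut, code_table) == translate_codon(codon, code_table)
        # relative acceptance 1 (syn) : omega (nonsyn), rescaled so the
        # larger of the two is certain (omega may exceed 1)
        accept_p = (1.0 if syn else omega) / max(1.0, omega)
        if rng.random() < accept_p:
            seq[pos] = b
            counts["synonymous" if syn else "nonsynonymous"] += 1
    return "".join(seq), counts


# ---------------------------------------------------------------------------
# gene-order scrambling (rearrangement ground truth)


def scramble_order(order: GeneOrder, n_inversions: int = 0,
                   n_translocations: int = 0, seed: int = 0
                   ) -> tuple[GeneOrder, list[dict]]:
    """Apply random segment inversions and translocations to a signed
    circular gene order, logging every event."""
    if n_inversions < 0 or n_translocations < 0:
        raise ValueError("event counts must be >= 0")
    rng = np.random.default_rng(seed)
    genes = list(order.genes)
    log: list[dict] = []
    events = ["inversion"] * n_inversions + ["translocation"] * n_translocations
    for ev in events:
        n = len(genes)
        i = int(rng.integers(n))
        ln = int(rng.integers(1, max(2, n // 2)))
        j = min(i + ln, n)
        seg = genes[i:j]
        if ev == "inversion":
            genes[i:j] = [(g, -s) for g, s in reversed(seg)]
            log.append({"event": "inversion", "at": i,
                        "genes": [g for g, _ in seg]})
        else:
            rest = genes[:i] + genes[j:]
            k = int(rng.integers(len(rest) + 1))
            genes = rest[:k] + seg + rest[k:]
            log.append({"event": "translocation", "from": i, "to": k,
                        "genes": [g for g, _ in seg]})
    return GeneOrder(tuple(genes), name=order.name), log


# ---------------------------------------------------------------------------
# config-file loading


def spec_from_config(path: str | Path, seed: Optional[int] = None) -> GenomeSpec:
    """Build a GenomeSpec from a YAML key-value config.

    Recognized keys: ``seed`` (int, overridable by the argument),
    ``composition`` (map A/T/G/C → fraction), ``all_forward`` (bool).
    Anything omitted falls back to the default whitefly-like spec.
    """
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if seed is None:
        seed = int(cfg.get("seed", 0))
    return default_spec(seed=seed,
                        composition=cfg.get("composition"),
                        all_forward=bool(cfg.get("all_forward", False)))
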