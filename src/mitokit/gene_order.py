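"""Signed circular gene orders, breakpoint distances and rearrangement reports.

A mitogenome's gene order is modelled as a signed circular permutation:
gene symbols with an orientation sign, no distinguished start, and no
distinguished strand (reading the circle backwards with all signs flipped
is the same molecule).  The breakpoint distance between two orders on a
common gene set is the number of gene adjacencies — unordered pairs of gene
*extremities* (head/tail) — present in one order but not the other; it is a
standard proxy for the number of rearrangement events.

``describe_events`` decomposes a query order into maximal runs that are
consecutive in a reference order (in either direction) and labels each run
as in-place / inverted / translocated, which is how rearrangements such as
a reversed-and-moved gene cluster are described in comparative mitogenomics.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .genome_model import MitoAnnotation

__all__ = [
    "GeneOrder",
    "Block",
    "RearrangementReport",
    "extract_order",
    "restrict_to_common",
    "breakpoint_distance",
    "adjacency_set",
    "describe_events",
    "distance_matrix",
    "nj_tree",
    "parse_order",
    "read_orders",
    "write_orders",
    "load_reference_order",
]


@dataclass(frozen=True)
class GeneOrder:
    """Ordered signed gene symbols on a circular molecule."""

    genes: tuple[tuple[str, int], ...]   # (symbol, +1/-1)
    name: str = ""

    def __post_init__(self) -> None:
        symbols = [g for g, _ in self.genes]
        if len(symbols) != len(set(symbols)):
            dup = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate gene symbols in order: {dup}")
        for _, s in self.genes:
            if s not in (1, -1):
                raise ValueError(f"sign must be +1/-1, got {s}")

    @property
    def alphabet(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __str__(self) -> str:
        body = " ".join(("+" if s > 0 else "-") + g for g, s in self.genes)
        return f"{self.name or 'order'}: {body}"


def parse_order(line: str) -> GeneOrder:
    """Parse one ``name: ±gene1 ±gene2 ...`` line."""
    if ":" in line:
        name, _, body = line.partition(":")
    else:
        name, body = "", line
    genes = []
    for tok in body.split():
        m = re.fullmatch(r"([+-]?)([\w().'-]+)", tok)
        if not m:
            raise ValueError(f"bad gene token {tok!r}")
        sign = -1 if m.group(1) == "-" else 1
        genes.append((m.group(2), sign))
    if not genes:
        raise ValueError(f"empty gene order line: {line!r}")
    return GeneOrder(genes=tuple(genes), name=name.strip())


def read_orders(path: str | Path) -> dict[str, GeneOrder]:
    """Read a gene-order text file (one genome per line, # comments)."""
    out: dict[str, GeneOrder] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        order = parse_order(line)
        key = order.name or f"genome{len(out) + 1}"
        out[key] = order
    if not out:
        raise ValueError(f"{path}: no gene orders found")
    return out


def write_orders(orders: Mapping[str, GeneOrder], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, order in orders.items():
            body = " ".join(("+" if s > 0 else "-") + g for g, s in order.genes)
            fh.write(f"{name}: {body}\n")


def load_reference_order(name: str = "ancestral-insect") -> GeneOrder:
    """Load a named packaged reference order (or any gene-order file path).

    The shipped ``ancestral-insect`` reference is the canonical ancestral
    insect (Drosophila yakuba type) order, the standard comparison point
    for insect mitogenome rearrangements; any one-line text file in the
    same format may be supplied instead.
    """
    if name == "ancestral-insect":
        with resources.files("mitokit.data").joinpath("ancestral_insect.txt").open() as fh:
            text = fh.read()
        for line in text.splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                return parse_order(line)
        raise ValueError("packaged reference order file is empty")
    return next(iter(read_orders(name).values()))


def extract_order(ann: MitoAnnotation, include_cr: bool = False) -> GeneOrder:
    """Gene order of an annotation in its listing order; the control region
    is excluded by default (it is not a gene)."""
    genes = []
    for f in ann.features:
        if f.category == "CR" and not include_cr:
            continue
        genes.append((f.name, 1 if f.strand == "forward" else -1))
    return GeneOrder(genes=tuple(genes))


def restrict_to_common(a: GeneOrder, b: GeneOrder
                       ) -> tuple[GeneOrder, GeneOrder, dict[str, list[str]]]:
    """Restrict both orders to their shared gene set, preserving relative
    order; removed symbols are reported per side."""
    common = a.alphabet & b.alphabet
    if not common:
        raise ValueError("gene orders share no symbols")
    ra = GeneOrder(tuple(g for g in a.genes if g[0] in common), name=a.name)
    rb = GeneOrder(tuple(g for g in b.genes if g[0] in common), name=b.name)
    removed = {
        "a": sorted(a.alphabet - common),
        "b": sorted(b.alphabet - common),
    }
    return ra, rb, removed


def _extremity(gene: str, sign: int, side: str) -> tuple[str, str]:
    # side "left"/"right" in reading direction; head = 3' end of a +gene
    if side == "right":
        return (gene, "h") if sign > 0 else (gene, "t")
    return (gene, "t") if sign > 0 else (gene, "h")


def adjacency_set(order: GeneOrder) -> frozenset[frozenset[tuple[str, str]]]:
    """Set of circular adjacencies as unordered extremity pairs.

    Invariant under rotation and under whole-molecule reversal with sign
    flip (the same circle read from the other strand).
    """
    n = len(order.genes)
    adj = set()
    for i in range(n):
        g1, s1 = order.genes[i]
        g2, s2 = order.genes[(i + 1) % n]
        adj.add(frozenset({_extremity(g1, s1, "right"), _extremity(g2, s2, "left")}))
    return frozenset(adj)


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of adjacencies of ``a`` absent from ``b`` (symmetric on a
    common alphabet; apply :func:`restrict_to_common` first)."""
    if a.alphabet != b.alphabet:
        raise ValueError("gene orders are on different alphabets; restrict first")
    return len(adjacency_set(a) - adjacency_set(b))


@dataclass(frozen=True)
class Block:
    genes: tuple[str, ...]
    inverted: bool
    translocated: bool

    @property
    def status(self) -> str:
        if self.inverted and self.translocated:
            return "inverted+translocated"
        if self.inverted:
            return "inverted"
        if self.translocated:
            return "translocated"
        return "in-place"


@dataclass
class RearrangementReport:
    query: str
    reference: str
    missing_in_query: list[str]
    missing_in_reference: list[str]
    n_shared_adjacencies: int
    n_breakpoints: int
    blocks: list[Block]

    def to_dict(self) -> dict:
        return {
            "query": self.query, "reference": self.reference,
            "missing_in_query": list(self.missing_in_query),
            "missing_in_reference": list(self.missing_in_reference),
            "n_shared_adjacencies": self.n_shared_adjacencies,
            "n_breakpoints": self.n_breakpoints,
            "blocks": [{"genes": list(b.genes), "status": b.status} for b in self.blocks],
        }


def _common_runs(query: GeneOrder, reference: GeneOrder) -> list[Block]:
    """Greedy maximal-run decomposition of the query against the reference.

    A run is a maximal stretch of query genes occupying consecutive
    reference positions, walked forward or backward.  Orientation is
    "inverted" for a backward walk (multi-gene runs) or a sign flip
    (single-gene runs); a run is "translocated" when its unsigned
    neighbours in the query differ from its neighbours in the reference.
    """
    n = len(reference.genes)
    pos = {g: i for i, (g, _) in enumerate(reference.genes)}
    rsign = {g: s for g, s in reference.genes}
    q = query.genes
    m = len(q)

    def step(a: tuple[str, int], b: tuple[str, int]) -> Optional[int]:
        """Direction of a compatible step from gene a to gene b, or None.

        Compatible steps: forward with unflipped signs (+1), backward with
        flipped signs (a proper inversion, -1), or backward with unflipped
        signs (order reversal without strand change, -1).  The sign
        relationship (query sign x reference sign) must agree between the
        two genes.
        """
        (ga, sa), (gb, sb) = a, b
        rel_a, rel_b = sa * rsign[ga], sb * rsign[gb]
        if rel_a != rel_b:
            return None
        if pos[gb] == (pos[ga] + 1) % n and rel_a == 1:
            return 1
        if pos[gb] == (pos[ga] - 1) % n:
            return -1
        return None

    runs: list[tuple[int, int, int]] = []  # (start_idx, length, direction)
    i = 0
    while i < m:
        j = i
        direction = 0
        while j + 1 < m:
            d = step(q[j], q[j + 1])
            if d is None or (direction and d != direction):
                break
            direction = d
            j += 1
        runs.append((i, j - i + 1, direction))
        i = j + 1
    # merge a wrap run (last run continuing into the first) for circularity
    if len(runs) > 1:
        (i0, l0, d0), (i1, l1, d1) = runs[0], runs[-1]
        d = step(q[-1], q[0])
        if d is not None and (d0 in (0, d)) and (d1 in (0, d)):
            runs = runs[1:-1] + [(i1, l1 + l0, d)]

    blocks: list[Block] = []
    for start, length, direction in runs:
        genes = tuple(q[(start + k) % m][0] for k in range(length))
        if length == 1:
            g, s = q[start]
            inverted = s != rsign[g]
        else:
            inverted = direction == -1
        # unsigned neighbour comparison (circular)
        q_prev = q[(start - 1) % m][0]
        q_next = q[(start + length) % m][0]
        first, last = genes[0], genes[-1]
        if direction == -1:
            ref_before = reference.genes[(pos[first] + 1) % n][0]
            ref_after = reference.genes[(pos[last] - 1) % n][0]
        else:
            ref_before = reference.genes[(pos[first] - 1) % n][0]
            ref_after = reference.genes[(pos[last] + 1) % n][0]
        translocated = {q_prev, q_next} != {ref_before, ref_after}
        if length == m:  # whole order is one run
            translocated = False
        blocks.append(Block(genes=genes, inverted=inverted, translocated=translocated))
    return blocks


def describe_events(query: GeneOrder, reference: GeneOrder) -> RearrangementReport:
    """Compare a query gene order against a reference: missing genes,
    breakpoint/shared-adjacency counts, and labelled rearranged blocks."""
    rq, rr, removed = restrict_to_common(query, reference)
    shared = adjacency_set(rq) & adjacency_set(rr)
    n_adj = len(rq)
    blocks = _common_runs(rq, rr)
    return RearrangementReport(
        query=query.name or "query",
        reference=reference.name or "reference",
        missing_in_query=removed["b"],
        missing_in_reference=removed["a"],
        n_shared_adjacencies=len(shared),
        n_breakpoints=n_adj - len(shared),
        blocks=blocks,
    )


def distance_matrix(orders: Mapping[str, GeneOrder]) -> pd.DataFrame:
    """Pairwise breakpoint distances (each pair restricted to its common
    gene set) as a symmetric DataFrame with zero diagonal."""
    names = list(orders)
    df = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a, b in combinations(names, 2):
        ra, rb, _ = restrict_to_common(orders[a], orders[b])
        d = breakpoint_distance(ra, rb)
        df.loc[a, b] = df.loc[b, a] = d
    return df


def nj_tree(dm: pd.DataFrame) -> str:
    """Neighbor-joining tree from a distance matrix, as a Newick string.

    Negative branch lengths are clamped to zero.  This is an explicit
    distance-tree stand-in for rearrangement-based tree search: it orders
    taxa by breakpoint distance, it does not infer ancestral gene orders.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(dm) < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    sk = DistanceMatrix(dm.values.astype(float), ids=list(dm.index))
    tree = nj(sk, neg_as_zero=True)
    return str(tree).strip()
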