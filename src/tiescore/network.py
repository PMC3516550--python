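"""Cross-group PPI network between two locus-linked gene groups.

Given an interactome and the (filtered) gene groups linked to the two trait
loci, the cross-group network keeps exactly the edges joining a group-1 gene
with a group-2 gene.  Genes linked to both loci belong to both groups, so an
edge between two such genes also qualifies as a cross-group edge.  The
counting statistics mirror the field convention: the cross-interaction
frequency is 100 * edges / (|group1| * |group2|), with group sizes being the
interactome-present counts and genes shared by both groups counted in each —
the denominator deliberately double-counts shared-gene pairs for fidelity to
how these tables are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .model import PpiNetwork

logger = logging.getLogger("tiescore")


@dataclass
class CrossGroupNetwork:
    """Cross edges between two locus groups, with per-gene degrees."""

    group1: frozenset
    group2: frozenset
    edges: frozenset  # of sorted (a, b) tuples, one endpoint in each group

    @property
    def both_set(self) -> frozenset:
        return self.group1 & self.group2

    @property
    def nodes(self) -> set:
        return {g for e in self.edges for g in e}

    @property
    def degree(self) -> dict:
        deg = {g: 0 for g in self.group1 | self.group2}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def neighbors(self, gene: str) -> set:
        gene = str(gene)
        return {b if a == gene else a for a, b in self.edges if gene in (a, b)}


def build_cross_network(
    ppi: PpiNetwork, group1: Iterable[str], group2: Iterable[str]
) -> CrossGroupNetwork:
    """Restrict groups to interactome genes and keep only cross-group edges."""
    present = ppi.nodes
    g1 = frozenset(str(g) for g in group1) & present
    g2 = frozenset(str(g) for g in group2) & present
    if not g1 or not g2:
        logger.warning(
            "empty restricted group (|group1|=%d, |group2|=%d): cross network empty",
            len(g1),
            len(g2),
        )
        return CrossGroupNetwork(group1=g1, group2=g2, edges=frozenset())
    edges = frozenset(
        e
        for e in ppi.edges
        if (e[0] in g1 and e[1] in g2) or (e[0] in g2 and e[1] in g1)
    )
    return CrossGroupNetwork(group1=g1, group2=g2, edges=edges)


@dataclass
class CrossFrequency:
    """Cross-interaction counting statistics (one table row)."""

    n_edges: int
    n_group1: int
    n_group2: int
    percent: float  # 100 * edges / (|g1| * |g2|); NaN if a group is empty


def cross_frequency_from_counts(
    n_group1: int, n_group2: int, n_edges: int
) -> CrossFrequency:
    """Frequency of observing a cross-group interaction, as a percentage."""
    if n_group1 <= 0 or n_group2 <= 0:
        logger.warning("empty group: cross-interaction frequency undefined")
        pct = float("nan")
    else:
        pct = 100.0 * n_edges / (n_group1 * n_group2)
    return CrossFrequency(
        n_edges=int(n_edges),
        n_group1=int(n_group1),
        n_group2=int(n_group2),
        percent=pct,
    )


def cross_frequency(network: CrossGroupNetwork) -> CrossFrequency:
    return cross_frequency_from_counts(
        len(network.group1), len(network.group2), len(network.edges)
    )


def format_frequency(freq: CrossFrequency) -> str:
    """Two-significant-digit percentage string, e.g. ``0.73%`` or ``1.4%``."""
    if freq.percent != freq.percent:  # NaN
        return "NA"
    return f"{freq.percent:.2g}%"


def write_sif(network: CrossGroupNetwork, path) -> None:
    """Cytoscape SIF export of the cross-group edges."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\tpp\t{b}\n")


def write_node_attributes(network: CrossGroupNetwork, path) -> None:
    """Node attribute TSV: group color (green/red/yellow) per gene."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    both = network.both_set
    with open(path, "w") as fh:
        fh.write("gene\tgroup\tcolor\n")
        for g in sorted(network.group1 | network.group2):
            if g in both:
                group, color = "both", "yellow"
            elif g in network.group1:
                group, color = "locus1", "green"
            else:
                group, color = "locus2", "red"
            fh.write(f"{g}\t{group}\t{color}\n")
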