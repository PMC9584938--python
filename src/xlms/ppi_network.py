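"""Protein-level interaction networks from inter-protein cross-links.

Each unique inter-link is residue-level evidence for a protein-protein
interaction; collapsing residue pairs per protein pair gives a network whose
edges carry a support count (number of distinct residue pairs).  On top of
the graph this module computes overlap with a reference edge list (e.g. a
STRING export), compartment summaries of the partners of an anchor set,
per-protein cross-link site-frequency profiles (percent of sites per
20-residue bin), and interaction-hotspot calls: confined stretches of
<100 residues that concentrate most of a protein's hetero-interaction sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .xl_tables import CrossLinkPair

logger = logging.getLogger(__name__)

__all__ = [
    "COMPARTMENTS",
    "XlNetwork",
    "SiteFrequencyProfile",
    "HotspotCall",
    "build_network",
    "compare_reference",
    "compartment_summary",
    "site_frequency",
    "detect_hotspots",
    "write_network_tsv",
    "write_graphml",
]

#: Subcellular compartment codes: cytoplasm, cytoskeleton, nucleus,
#: endoplasmic reticulum, Golgi apparatus, plasma membrane, lysosome,
#: others, not known.
COMPARTMENTS = ("CY", "CK", "NC", "ER", "GA", "PM", "LS", "OT", "NK")


@dataclass
class XlNetwork:
    """Protein-level interaction graph derived from inter-links.

    Nodes are accessions (optionally labelled with a compartment); edges are
    unordered accession pairs with ``support`` = number of distinct residue
    pairs.  Self-edges never occur: intra/self links are not interactions
    between two proteins.
    """

    graph: nx.Graph
    n_residue_pairs: int = 0

    @property
    def n_proteins(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_interactions(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[frozenset[str]]:
        return [frozenset(e) for e in self.graph.edges]

    def annotate(self, compartments: Mapping[str, str]) -> None:
        for node in self.graph.nodes:
            self.graph.nodes[node]["compartment"] = compartments.get(node, "NK")


@dataclass
class SiteFrequencyProfile:
    """Percent of a protein's cross-linked sites per residue bin."""

    accession: str
    bin_width: int
    bins: list[tuple[int, float]]  # (start residue, percent)
    n_sites: int


@dataclass
class HotspotCall:
    """A confined residue window concentrating hetero-interaction sites."""

    accession: str
    window: tuple[int, int]
    fraction: float
    n_sites_inside: int
    n_sites_total: int


def build_network(pairs: Iterable[CrossLinkPair]) -> XlNetwork:
    """Build the protein-level graph from inter-links.

    Edge multiplicity (several residue pairs for one protein pair) collapses
    to one edge with a ``support`` count; the residue-pair total is kept on
    the network so both granularities are reportable.  Proteins seen only in
    intra/self links do not enter the graph.
    """
    g = nx.Graph()
    n_residue_pairs = 0
    for pair in pairs:
        if pair.link_class != "inter":
            continue
        a, b = pair.accessions
        n_residue_pairs += 1
        if g.has_edge(a, b):
            g[a][b]["support"] += 1
        else:
            g.add_edge(a, b, support=1)
    return XlNetwork(g, n_residue_pairs)


def compare_reference(
    net: XlNetwork, reference_edges: Iterable[tuple[str, str] | frozenset[str]]
) -> tuple[float, list[frozenset[str]], list[frozenset[str]]]:
    """Fraction of the network's edges present in a reference edge list.

    Matching is order-insensitive.  Returns (fraction, matched, unmatched).
    """
    reference = {frozenset(e) for e in reference_edges}
    if not reference:
        raise ValueError("reference edge list is empty")
    matched, unmatched = [], []
    for edge in net.edges():
        (matched if edge in reference else unmatched).append(edge)
    total = len(matched) + len(unmatched)
    return (len(matched) / total if total else 0.0), matched, unmatched


def compartment_summary(
    net: XlNetwork,
    annotations: Mapping[str, str],
    anchors: set[str],
) -> dict[str, int]:
    """Count partner proteins per compartment for edges touching an anchor set.

    Each distinct non-anchor partner is counted once, in its annotated
    compartment; unannotated partners count as NK.
    """
    partners: set[str] = set()
    for a, b in net.graph.edges:
        if a in anchors and b not in anchors:
            partners.add(b)
        elif b in anchors and a not in anchors:
            partners.add(a)
    counts = {c: 0 for c in COMPARTMENTS}
    for p in partners:
        comp = annotations.get(p, "NK")
        if comp not in counts:
            comp = "NK"
        counts[comp] += 1
    return counts


def site_frequency(
    pairs: Iterable[CrossLinkPair],
    accession: str,
    protein_length: int,
    bin_width: int = 20,
) -> SiteFrequencyProfile:
    """Histogram of a protein's cross-linked sites in bins of ``bin_width`` residues.

    Every side of every unique pair involving the protein contributes one
    site; percents are normalized to the protein's site total so they sum to
    100 whenever at least one site exists.  Bins tile [1, protein_length].
    """
    if protein_length < 1:
        raise ValueError("protein length must be >= 1")
    n_bins = (protein_length + bin_width - 1) // bin_width
    counts = [0] * n_bins
    total = 0
    for pair in pairs:
        for acc, site in (pair.site_u, pair.site_v):
            if acc != accession:
                continue
            if site > protein_length:
                raise ValueError(
                    f"pair {pair.key}: site {site} beyond protein length {protein_length}"
                )
            counts[(site - 1) // bin_width] += 1
            total += 1
    bins = [
        (i * bin_width + 1, (100.0 * c / total) if total else 0.0)
        for i, c in enumerate(counts)
    ]
    return SiteFrequencyProfile(accession, bin_width, bins, total)


def detect_hotspots(
    pairs: Iterable[CrossLinkPair],
    accession: str,
    exclude_partners: set[str] | None = None,
    window: int = 100,
    threshold: float = 0.75,
) -> list[HotspotCall]:
    """Find confined windows concentrating a protein's hetero-interaction sites.

    Only sites from inter-links to proteins outside ``exclude_partners`` (plus
    the protein itself) are considered -- e.g. FLOT1/FLOT2 mutual links are
    excluded when asking where the flotillins bind *other* proteins.  All
    windows of at most ``window`` residues holding a fraction of sites >=
    ``threshold`` are enumerated; nested and overlapping candidates are merged
    per overlap group and the best call (highest fraction, then widest) is
    reported for each.  Output is independent of input order.
    """
    exclude = set(exclude_partners or ()) | {accession}
    sites: list[int] = []
    for pair in pairs:
        if pair.link_class != "inter":
            continue
        for (acc, site), (other_acc, _) in ((pair.site_u, pair.site_v), (pair.site_v, pair.site_u)):
            if acc == accession and other_acc not in exclude:
                sites.append(site)
    if not sites:
        return []
    sites.sort()
    n = len(sites)

    candidates: list[tuple[int, int, int]] = []  # (start_site, end_site, inside)
    j = 0
    for i in range(n):
        j = max(j, i)
        while j + 1 < n and sites[j + 1] - sites[i] + 1 <= window:
            j += 1
        inside = j - i + 1
        if inside / n >= threshold:
            candidates.append((sites[i], sites[j], inside))
    if not candidates:
        return []

    # merge overlap groups, keep the best candidate of each
    candidates.sort()
    calls: list[HotspotCall] = []
    group = [candidates[0]]
    group_end = candidates[0][1]
    for cand in candidates[1:]:
        if cand[0] <= group_end:
            group.append(cand)
            group_end = max(group_end, cand[1])
        else:
            calls.append(_best_call(group, accession, n))
            group = [cand]
            group_end = cand[1]
    calls.append(_best_call(group, accession, n))
    return calls


def _best_call(group: list[tuple[int, int, int]], accession: str, n: int) -> HotspotCall:
    best = max(group, key=lambda c: (c[2], c[1] - c[0]))
    return HotspotCall(accession, (best[0], best[1]), best[2] / n, best[2], n)


# ---------------------------------------------------------------------------
# Export


def write_network_tsv(net: XlNetwork, nodes_path: str | Path, edges_path: str | Path) -> None:
    nodes = [
        {"accession": node, "compartment": data.get("compartment", "")}
        for node, data in net.graph.nodes(data=True)
    ]
    edges = [
        {"protein_a": a, "protein_b": b, "support": data["support"]}
        for a, b, data in net.graph.edges(data=True)
    ]
    pd.DataFrame(nodes, columns=["accession", "compartment"]).to_csv(nodes_path, sep="\t", index=False)
    pd.DataFrame(edges, columns=["protein_a", "protein_b", "support"]).to_csv(edges_path, sep="\t", index=False)


def write_graphml(net: XlNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))
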