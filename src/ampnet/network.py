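"""Thresholded phi networks per sample group and cross-group node classification.

A co-occurrence network has an edge between two SVs when their phi
proportionality falls strictly below the marker-specific threshold (0.12 for
eukaryotes, 0.08 for prokaryotes). SVs carrying at least one edge are the
node SVs (nSVs). Across the four field x crop group networks, nodes are
classified as core (top fraction by degree within a network), common (present
in all four networks), or crop-/field-specific (present in both networks of
one level and absent from both networks of the other).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import networkx as nx
import pandas as pd

from .composition import PhiMatrix
from .io_tables import CROPS, FIELDS, NA_SENTINEL, TaxonomyTable


@dataclass
class CoNetwork:
    """One group's thresholded phi network with size-ordered clusters."""

    group: tuple[str, str]  # (field, crop)
    graph: nx.Graph
    threshold: float
    components: list[list[str]] = dc_field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_conetwork(
    phi: PhiMatrix | pd.DataFrame, threshold: float, group: tuple[str, str]
) -> CoNetwork:
    """Edges where phi < threshold (strict); isolated SVs are not nodes.

    Connected components ("clusters") are ordered by size descending, ties
    broken by the smallest member id, so "cluster 1" is the largest.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    vals = phi.values if isinstance(phi, PhiMatrix) else phi
    ids = list(vals.index)
    arr = vals.to_numpy()
    g = nx.Graph()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            v = arr[i, j]
            if not math.isnan(v) and v < threshold:
                g.add_edge(ids[i], ids[j], phi=float(v))
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return CoNetwork(group=tuple(group), graph=g, threshold=threshold, components=comps)


def classify_core_nsvs(net: CoNetwork, top_fraction: float) -> set[str]:
    """Top-degree nodes: k = ceil(fraction x node count), boundary ties included."""
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    degs = net.degrees
    if not degs:
        return set()
    k = math.ceil(top_fraction * len(degs))
    kth_degree = sorted(degs.values(), reverse=True)[k - 1]
    return {n for n, d in degs.items() if d >= kth_degree}


@dataclass
class NetworkComparison:
    """Ledger of core / common / crop- and field-specific nSVs."""

    core: dict[tuple[str, str], set[str]]
    common: set[str]
    crop_specific: dict[str, set[str]]
    field_specific: dict[str, set[str]]
    core_fraction: float


def compare_networks(
    nets: dict[tuple[str, str], CoNetwork], core_fraction: float = 0.10
) -> NetworkComparison:
    """Classify nodes across the four field x crop group networks.

    common = intersection of all four node sets; a crop-specific nSV is
    present in *both* networks of that crop and absent from *both* networks
    of the other crop (and analogously for fields).
    """
    expected = {(f, c) for f in FIELDS for c in CROPS}
    if set(nets) != expected:
        raise ValueError(
            f"need exactly the four group networks {sorted(expected)}, got {sorted(nets)}"
        )
    nodes = {g: nets[g].nodes for g in nets}
    common = set.intersection(*nodes.values())
    crop_specific = {}
    for crop in CROPS:
        other = [c for c in CROPS if c != crop][0]
        present = nodes[(FIELDS[0], crop)] & nodes[(FIELDS[1], crop)]
        absent = nodes[(FIELDS[0], other)] | nodes[(FIELDS[1], other)]
        crop_specific[crop] = present - absent
    field_specific = {}
    for field in FIELDS:
        other = [f for f in FIELDS if f != field][0]
        present = nodes[(field, CROPS[0])] & nodes[(field, CROPS[1])]
        absent = nodes[(other, CROPS[0])] | nodes[(other, CROPS[1])]
        field_specific[field] = present - absent
    core = {g: classify_core_nsvs(nets[g], core_fraction) for g in nets}
    return NetworkComparison(core, common, crop_specific, field_specific, core_fraction)


def node_taxon_summary(net: CoNetwork, tax: TaxonomyTable) -> dict[str, float]:
    """Fraction of nSVs per phylum (unassigned nodes under "NA"); sums to 1."""
    nodes = sorted(net.nodes)
    if not nodes:
        return {}
    phyla = tax.rank_of(nodes, "phylum")
    counts = phyla.value_counts()
    return {str(p): float(c) / len(nodes) for p, c in counts.items()}


# ---------------------------------------------------------------------------
# exports

def write_graphml(net: CoNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))


def write_edge_list(net: CoNetwork, path: str | Path) -> None:
    rows = [(a, b, d["phi"]) for a, b, d in sorted(net.graph.edges(data=True))]
    pd.DataFrame(rows, columns=["sv_a", "sv_b", "phi"]).to_csv(path, sep="\t", index=False)


def build_node_ledger(
    nets: dict[tuple[str, str], CoNetwork],
    comparison: NetworkComparison,
    tax: TaxonomyTable | None = None,
) -> pd.DataFrame:
    """Tidy per-(group, nSV) ledger: degree, cluster id, core/common/specific flags."""
    rows = []
    for g in sorted(nets):
        net = nets[g]
        cluster_of = {}
        for ci, comp in enumerate(net.components, start=1):
            for n in comp:
                cluster_of[n] = ci
        degs = net.degrees
        for n in sorted(net.nodes):
            phylum = (
                tax.rank_of([n], "phylum").iloc[0] if tax is not None else NA_SENTINEL
            )
            rows.append({
                "sv_id": n,
                "field": g[0],
                "crop": g[1],
                "degree": degs[n],
                "cluster": cluster_of[n],
                "core": n in comparison.core[g],
                "common": n in comparison.common,
                "crop_specific": next(
                    (c for c, s in comparison.crop_specific.items() if n in s), ""
                ),
                "field_specific": next(
                    (f for f, s in comparison.field_specific.items() if n in s), ""
                ),
                "phylum": phylum,
            })
    return pd.DataFrame(rows)
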