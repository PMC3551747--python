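"""TCS-style parsimony networks of ribotypes.

Haplotypes are joined in increasing order of mutational-step distance, in
the manner of a minimum-spanning network: at each distance level d, every
pair of haplotypes lying in different components (as of the start of that
level) is connected, so equally parsimonious alternative connections are all
retained (reticulation).  A d-step connection is expanded into a path through
d−1 inferred intermediate haplotypes — unsampled ribotypes drawn as empty
nodes.  Their sequences are left abstract, because the order of mutations
along a multi-step path is not identifiable.  Pairs farther apart than the
connection limit remain in separate subnetworks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .core_io import SequenceRecord
from .diversity import distance_matrix, p_distance

__all__ = [
    "HaplotypeNetwork",
    "mutational_steps",
    "build_network",
    "overlay_categories",
    "write_edge_list",
    "write_node_table",
]


def mutational_steps(a: SequenceRecord, b: SequenceRecord) -> int:
    """Raw count of differing comparable sites between two haplotypes."""
    return p_distance(a, b).differences


@dataclass(frozen=True)
class HaplotypeNetwork:
    """A haplotype graph whose every edge is a single mutational step.

    Sampled nodes carry ``frequency`` (observation count) and optionally an
    ``overlay`` of category proportions; inferred intermediates have
    ``kind="inferred"`` and frequency 0.
    """

    graph: nx.Graph
    max_connection_steps: int

    @property
    def sampled_nodes(self) -> tuple[str, ...]:
        return tuple(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == "sampled"
        )

    @property
    def inferred_nodes(self) -> tuple[str, ...]:
        return tuple(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == "inferred"
        )

    def sampled_components(self) -> list[frozenset[str]]:
        """Connected subnetworks, reported by their sampled members."""
        sampled = set(self.sampled_nodes)
        return sorted(
            (frozenset(comp & sampled) for comp in nx.connected_components(self.graph)),
            key=lambda c: sorted(c),
        )


def build_network(
    seqs: Sequence[SequenceRecord],
    frequencies: Mapping[str, int] | None = None,
    max_connection_steps: int = 20,
) -> HaplotypeNetwork:
    """Build the parsimony network of a set of equal-length haplotypes."""
    if not seqs:
        raise ValueError("no haplotypes")
    if max_connection_steps < 1:
        raise ValueError("max_connection_steps must be ≥ 1")
    freqs = dict(frequencies or {})
    graph = nx.Graph()
    for s in seqs:
        graph.add_node(s.id, kind="sampled", frequency=int(freqs.get(s.id, 1)))

    dm = distance_matrix(seqs)
    steps = dm.differences
    labels = dm.labels
    n = len(labels)

    pairs_at: dict[int, list[tuple[str, str]]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            pairs_at.setdefault(int(steps[i, j]), []).append((labels[i], labels[j]))

    next_inferred = 0
    for d in sorted(pairs_at):
        if d == 0 or d > max_connection_steps:
            continue
        # freeze membership at the start of the level: all equally short
        # cross-component connections are added (reticulation allowed)
        component_of: dict[str, int] = {}
        for k, comp in enumerate(nx.connected_components(graph)):
            for node in comp:
                component_of[node] = k
        for a, b in sorted(pairs_at[d]):
            if component_of[a] == component_of[b]:
                continue
            path = [a]
            for _ in range(d - 1):
                next_inferred += 1
                name = f"inferred_{next_inferred}"
                graph.add_node(name, kind="inferred", frequency=0)
                path.append(name)
            path.append(b)
            for u, v in zip(path, path[1:]):
                graph.add_edge(u, v, steps=1)
    return HaplotypeNetwork(graph=graph, max_connection_steps=max_connection_steps)


def overlay_categories(
    network: HaplotypeNetwork,
    observations: pd.DataFrame,
    category_column: str = "category",
) -> HaplotypeNetwork:
    """Attach per-node category proportions (e.g. sample period or host).

    ``observations`` needs columns ``ribotype`` and ``category_column``, one
    row per labeled observation (or a ``count`` column).  Observations of
    ribotypes absent from the network are excluded with a warning.  Each
    sampled node gains ``overlay`` (proportions summing to 1) and its
    frequency is set to the total labeled observation count.
    """
    required = {"ribotype", category_column}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations table lacks columns {sorted(missing)}")
    obs = observations.copy()
    if "count" not in obs.columns:
        obs["count"] = 1

    graph = network.graph.copy()
    sampled = {n for n, d in graph.nodes(data=True) if d["kind"] == "sampled"}
    unknown = sorted(set(obs["ribotype"]) - sampled)
    if unknown:
        warnings.warn(
            f"observations for ribotypes absent from the network excluded: {unknown}",
            stacklevel=2,
        )
        obs = obs[obs["ribotype"].isin(sampled)]

    totals = obs.groupby("ribotype")["count"].sum()
    by_cat = obs.groupby(["ribotype", category_column])["count"].sum()
    for node in sampled & set(totals.index):
        total = float(totals.loc[node])
        overlay = {
            cat: float(cnt) / total for (rt, cat), cnt in by_cat.items() if rt == node
        }
        graph.nodes[node]["overlay"] = overlay
        graph.nodes[node]["frequency"] = int(total)
    return HaplotypeNetwork(
        graph=graph, max_connection_steps=network.max_connection_steps
    )


def write_edge_list(network: HaplotypeNetwork, path) -> None:
    """Write the expanded single-step edges as tab-delimited text."""
    with open(path, "w") as handle:
        handle.write("node_a\tnode_b\tsteps\n")
        for u, v, data in sorted(network.graph.edges(data=True)):
            handle.write(f"{u}\t{v}\t{data.get('steps', 1)}\n")


def write_node_table(network: HaplotypeNetwork, path) -> None:
    """Write node attributes (kind, frequency, overlay proportions) as TSV."""
    rows = []
    for node, data in sorted(network.graph.nodes(data=True)):
        overlay = data.get("overlay", {})
        rows.append(
            {
                "node": node,
                "kind": data["kind"],
                "frequency": data["frequency"],
                "overlay": ";".join(f"{c}={p:.4f}" for c, p in sorted(overlay.items())),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
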