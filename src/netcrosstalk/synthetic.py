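"""Synthetic test beds for validating crosstalk statistics.

Real validation data for this kind of analysis — a genome-scale
functional-association network plus curated pathway collections — is
large and external.  These generators emulate the relevant structure so
every statistical property is testable from code alone:

* Barabási–Albert scale-free networks as background (biological
  interaction networks are heavy-tailed);
* random degree-matched groups: gene groups that mimic a template's
  size and degree composition but carry no biological signal, the
  negative control for null calibration;
* planted modules: groups with artificially boosted internal
  connectivity, the positive control with known ground truth;
* balanced random group splits, for inter-crosstalk recovery between
  halves of a connected module.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import GeneGroup, GroupSet, Network, connectivity_bin

__all__ = [
    "PlantedModuleSpec",
    "barabasi_albert",
    "random_degree_matched_group",
    "plant_modules",
    "split_group",
]


def _node_name(i: int, width: int) -> str:
    return f"g{i:0{width}d}"


def barabasi_albert(n: int, m: int, seed: int) -> Network:
    """Preferential-attachment scale-free network with string node ids.

    Growth starts from an m-node seed clique (for m >= 2), then each new
    node attaches to m existing nodes with probability proportional to
    degree, giving m(n - m) + C(m, 2) links.  For m = 1 the seed is a
    single node and the result is a tree with n - 1 links.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if n <= m:
        raise ValueError(f"need n > m, got n={n}, m={m}")
    if m == 1:
        g = nx.barabasi_albert_graph(n, m, seed=seed)
    else:
        g = nx.barabasi_albert_graph(
            n, m, seed=seed, initial_graph=nx.complete_graph(m)
        )
    width = len(str(n - 1))
    return Network(
        (_node_name(u, width), _node_name(v, width)) for u, v in g.edges()
    )


def random_degree_matched_group(
    net: Network, template: GeneGroup, rng: np.random.Generator
) -> GeneGroup:
    """Replace each template member by a random node of similar degree.

    Each member is swapped for a uniformly chosen node from the same
    connectivity bin, excluding all template members and nodes already
    chosen, so the output is disjoint from the template, has no
    duplicates, and preserves the template's bin multiset exactly.
    """
    deg = net.degree
    missing = sorted(template.members - set(deg))
    if missing:
        raise ValueError(f"template members absent from network: {missing}")
    by_bin: dict[int, list[str]] = {}
    for u in net.sorted_nodes():
        by_bin.setdefault(connectivity_bin(deg[u]), []).append(u)
    chosen: set[str] = set()
    forbidden = template.members
    for u in sorted(template.members):
        b = connectivity_bin(deg[u])
        candidates = [v for v in by_bin.get(b, []) if v not in forbidden and v not in chosen]
        if not candidates:
            raise ValueError(
                f"connectivity bin {b} exhausted: no replacement left for {u!r}"
            )
        chosen.add(candidates[int(rng.integers(len(candidates)))])
    return GeneGroup(template.name, frozenset(chosen))


@dataclass(frozen=True)
class PlantedModuleSpec:
    """Parameters of a planted-module positive-control network."""

    n_background_nodes: int = 3000
    ba_links_per_node: int = 3
    n_modules: int = 20
    module_size: int = 30
    intra_link_boost: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size < 3:
            raise ValueError("module_size must be >= 3")
        if self.n_modules * self.module_size > self.n_background_nodes:
            raise ValueError("modules do not fit disjointly into the background")


def plant_modules(spec: PlantedModuleSpec) -> tuple[Network, GroupSet]:
    """Scale-free background with disjoint modules of boosted connectivity.

    Picks ``n_modules`` disjoint random node sets of ``module_size`` and
    adds ``intra_link_boost`` new links inside each, between previously
    unlinked member pairs.  Boosted links never duplicate existing links
    or form self-links, so the result satisfies all network invariants.
    """
    base = barabasi_albert(spec.n_background_nodes, spec.ba_links_per_node, spec.seed)
    rng = np.random.default_rng((spec.seed, 1))
    nodes = base.sorted_nodes()
    perm = rng.permutation(len(nodes))
    edges = set(base.links)
    groups = []
    width = len(str(spec.n_modules - 1))
    for k in range(spec.n_modules):
        members = sorted(
            nodes[perm[i]]
            for i in range(k * spec.module_size, (k + 1) * spec.module_size)
        )
        pairs = [
            (members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
        free = [pq for pq in pairs if pq not in edges]
        if len(free) < spec.intra_link_boost:
            raise ValueError(
                f"module {k}: only {len(free)} unlinked pairs available, "
                f"cannot plant {spec.intra_link_boost} links"
            )
        pick = rng.permutation(len(free))[: spec.intra_link_boost]
        for i in pick:
            edges.add(free[int(i)])
        groups.append(GeneGroup(f"module{k:0{width}d}", frozenset(members)))
    return Network(edges), GroupSet(groups)


def split_group(
    g: GeneGroup, rng: np.random.Generator
) -> tuple[GeneGroup, GeneGroup]:
    """Random balanced split into disjoint halves (sizes ceil/floor of n/2)."""
    if len(g.members) < 4:
        raise ValueError(f"group {g.name!r} too small to split (need >= 4 members)")
    members = sorted(g.members)
    perm = rng.permutation(len(members))
    half = (len(members) + 1) // 2
    first = frozenset(members[i] for i in perm[:half])
    second = frozenset(members[i] for i in perm[half:])
    return (
        GeneGroup(f"{g.name}_A", first),
        GeneGroup(f"{g.name}_B", second),
    )
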