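"""Undirected gene-network data model, file I/O, and topology diagnostics.

The network is a simple undirected graph over opaque string gene
identifiers: no self-links, no duplicate links, and every node carries at
least one link (isolated nodes cannot arise from an edge list).  Edge
weights (confidence scores) are used only to filter links at load time;
the in-memory network is unweighted.

Topology diagnostics compare a randomized network against the original:

* assortativity — Pearson correlation of endpoint degrees over all links
  (each link contributes both orientations);
* s-metric — sum over links of the product of endpoint degrees;
* link identity fraction — share of original links retained.

Degree classes for "similar connectivity" use the natural-log binning
B(d) = round(ln(d) + 1), with round-half-away-from-zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "GeneGroup",
    "GroupSet",
    "NetworkParseError",
    "read_network",
    "write_network",
    "read_groups",
    "write_groups_gmt",
    "connectivity_bin",
    "assortativity",
    "s_metric",
    "link_identity_fraction",
]


class NetworkParseError(ValueError):
    """Raised for malformed network or group files."""


def _ordered(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


class Network:
    """Simple undirected graph over string gene identifiers.

    Parameters
    ----------
    edges:
        Iterable of node pairs.  Duplicate pairs (in either orientation)
        collapse to a single link.  Self-pairs raise ``ValueError`` —
        callers that tolerate self-links in input (file readers) must drop
        them before construction.
    """

    __slots__ = ("_adj", "_links")

    def __init__(self, edges: Iterable[tuple[str, str]]):
        adj: dict[str, set[str]] = {}
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-link {u!r}-{v!r} is not allowed")
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        self._adj = adj
        self._links: Optional[frozenset[tuple[str, str]]] = None

    # -- basic accessors -------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    @property
    def adj(self) -> dict[str, set[str]]:
        """Adjacency map node -> set of neighbors (treat as read-only)."""
        return self._adj

    @property
    def links(self) -> frozenset[tuple[str, str]]:
        """The link set as lexicographically ordered node pairs."""
        if self._links is None:
            self._links = frozenset(
                (u, v) for u, nbrs in self._adj.items() for v in nbrs if u < v
            )
        return self._links

    @property
    def degree(self) -> dict[str, int]:
        return {u: len(nbrs) for u, nbrs in self._adj.items()}

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_links(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def neighbors(self, u: str) -> set[str]:
        return self._adj[u]

    def has_link(self, u: str, v: str) -> bool:
        nbrs = self._adj.get(u)
        return nbrs is not None and v in nbrs

    def sorted_nodes(self) -> list[str]:
        return sorted(self._adj)

    def sorted_links(self) -> list[tuple[str, str]]:
        return sorted(self.links)

    def __contains__(self, u: str) -> bool:
        return u in self._adj

    def __iter__(self) -> Iterator[str]:
        return iter(self._adj)

    def __len__(self) -> int:
        return len(self._adj)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.links == other.links

    def __hash__(self) -> int:
        return hash(self.links)

    def __repr__(self) -> str:
        return f"Network(n_nodes={self.n_nodes}, n_links={self.n_links})"


@dataclass(frozen=True)
class GeneGroup:
    """A named set of gene identifiers (an experimental set, module, or pathway)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("group name must be non-empty")
        if not isinstance(self.members, frozenset):
            object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def restrict_to(self, nodes: set[str] | Network) -> "GeneGroup":
        """Group with membership intersected with a node universe."""
        universe = nodes.nodes if isinstance(nodes, Network) else nodes
        return GeneGroup(self.name, self.members & frozenset(universe))


@dataclass
class GroupSet:
    """An ordered collection of uniquely named gene groups.

    Groups may share members; only names must be unique.
    """

    groups: list[GeneGroup] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate group names: {dupes}")

    def __iter__(self) -> Iterator[GeneGroup]:
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def __getitem__(self, name: str) -> GeneGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.groups:
            out |= g.members
        return frozenset(out)


# -- degree binning ------------------------------------------------------


def connectivity_bin(d: int) -> int:
    """Log-scale degree class B(d) = round(ln(d) + 1).

    Rounding is half-away-from-zero (ties at .5 round up; for integer d
    the argument is never exactly half-integral in practice, but the
    convention is fixed to avoid platform-dependent banker's rounding).
    """
    if d < 1:
        raise ValueError(f"degree must be >= 1, got {d}")
    return int(math.floor(math.log(d) + 1.5))


# -- topology diagnostics ------------------------------------------------


def assortativity(net: Network) -> Optional[float]:
    """Degree assortativity: Pearson r of endpoint degrees over links.

    Each link contributes both orientations (deg u, deg v) and
    (deg v, deg u).  Returns ``None`` when undefined: fewer than two
    links, or zero endpoint-degree variance (regular graphs).
    """
    links = net.sorted_links()
    if len(links) < 2:
        return None
    deg = net.degree
    du = np.array([deg[u] for u, _ in links], dtype=float)
    dv = np.array([deg[v] for _, v in links], dtype=float)
    x = np.concatenate([du, dv])
    y = np.concatenate([dv, du])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def s_metric(net: Network) -> int:
    """Sum over links of the product of endpoint degrees."""
    deg = net.degree
    return sum(deg[u] * deg[v] for u, v in net.links)


def link_identity_fraction(original: Network, randomized: Network) -> float:
    """Fraction of original links retained in the randomized network."""
    if original.nodes != randomized.nodes:
        raise ValueError("networks must share the same node set")
    n = original.n_links
    if n == 0:
        raise ValueError("original network has no links")
    return len(original.links & randomized.links) / n


# -- file I/O ------------------------------------------------------------


def read_network(path, cutoff: Optional[float] = None) -> Network:
    """Read a whitespace/tab-delimited edge list.

    Columns: gene1, gene2[, score].  Lines starting with '#' and blank
    lines are skipped.  When ``cutoff`` is given, rows carrying a score
    below it are excluded; rows without a score column are always kept.
    Duplicate rows (either orientation) collapse to one link and
    self-link rows are dropped with a warning.
    """
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise NetworkParseError(
                    f"{path}: line {lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            u, v = parts[0], parts[1]
            if len(parts) == 3:
                try:
                    score = float(parts[2])
                except ValueError as exc:
                    raise NetworkParseError(
                        f"{path}: line {lineno}: non-numeric score {parts[2]!r}"
                    ) from exc
                if cutoff is not None and score < cutoff:
                    continue
            if u == v:
                logger.warning("%s: line %d: dropping self-link %r", path, lineno, u)
                continue
            edges.append((u, v))
    if not edges:
        raise NetworkParseError(f"{path}: no links remain after filtering")
    return Network(edges)


def write_network(net: Network, path) -> None:
    """Write the link set as a two-column TSV (sorted, reproducible)."""
    with open(path, "w") as fh:
        for u, v in net.sorted_links():
            fh.write(f"{u}\t{v}\n")


def read_groups(path, fmt: str = "auto") -> GroupSet:
    """Read gene groups from GMT or two-column membership TSV.

    GMT: per line ``name<TAB>description<TAB>member...``.
    Membership TSV: per line ``group_id<TAB>gene`` (whitespace also
    accepted); groups ordered by first appearance.
    ``fmt`` is one of ``auto`` (detect: all data rows with exactly two
    columns -> membership, otherwise GMT), ``gmt`` or ``tsv``.
    """
    if fmt not in ("auto", "gmt", "tsv"):
        raise ValueError(f"unknown group file format {fmt!r}")
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            rows.append((lineno, parts))
    if not rows:
        raise NetworkParseError(f"{path}: no groups found")
    if fmt == "auto":
        fmt = "tsv" if all(len(p) == 2 for _, p in rows) else "gmt"
    groups: list[GeneGroup] = []
    if fmt == "tsv":
        order: dict[str, list[str]] = {}
        for lineno, parts in rows:
            if len(parts) != 2:
                raise NetworkParseError(
                    f"{path}: line {lineno}: membership rows need 2 columns"
                )
            order.setdefault(parts[0], []).append(parts[1])
        groups = [GeneGroup(name, frozenset(members)) for name, members in order.items()]
    else:
        for lineno, parts in rows:
            if len(parts) < 3:
                raise NetworkParseError(
                    f"{path}: line {lineno}: GMT rows need name, description, members"
                )
            groups.append(GeneGroup(parts[0], frozenset(parts[2:])))
    return GroupSet(groups)


def write_groups_gmt(groups: GroupSet, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for g in groups:
            fh.write("\t".join([g.name, description, *sorted(g.members)]) + "\n")
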