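"""Degree-preserving network randomization null models.

Four algorithms generate randomized network instances that exactly
preserve the degree sequence of the input and differ in how much
second-order topology (degree–degree mixing) they conserve:

LP (link permutation)
    Repeated random link swaps: links {a,b},{c,d} sharing no node are
    rewired to {a,c},{b,d} or {a,d},{b,c} (chosen uniformly) provided
    neither new link exists.  Swapping continues until every original
    link has been swapped away or a bounded number of consecutive
    proposals fail.

NP (node permutation)
    Node labels are shuffled uniformly within log-degree connectivity
    bins B(d) = round(ln d + 1); the unlabeled topology is untouched, so
    assortativity and the s-metric are preserved exactly.

LA (link assignment)
    Configuration-model rebuild: all links are removed and stubs (node
    slots, one per unit of degree) are re-matched uniformly at random,
    rejecting self-links and duplicates.  Nodes that cannot recover
    their original degree are completed by a swap-based degree repair.

LA+S (link assignment + second-order conservation)
    As LA, but each node may only be re-wired to nodes falling in the
    same connectivity bins as its original neighbors, so each node keeps
    (approximately) its original neighbor-degree-bin multiset.  The
    degree repair, when needed, relaxes the bin constraint for the
    residual links only: the degree sequence is the hard constraint,
    second-order structure the soft one.

All algorithms are deterministic functions of (network, method, seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import (
    Network,
    assortativity,
    connectivity_bin,
    link_identity_fraction,
    s_metric,
)

__all__ = [
    "METHODS",
    "RandomizerSpec",
    "RandomizationError",
    "randomize",
    "randomize_lp",
    "randomize_np",
    "randomize_la",
    "randomize_las",
    "fix_residual_degrees",
    "topology_report",
]

METHODS = ("LP", "NP", "LA", "LA+S")

_MAX_MATCH_ROUNDS = 30  # re-shuffle rounds for stub matching before repair
_REPAIR_PROBES = 500  # random link probes per repair move


class RandomizationError(RuntimeError):
    """Raised when a randomizer cannot restore the target degree sequence."""


class _StallError(RuntimeError):
    pass


@dataclass(frozen=True)
class RandomizerSpec:
    """Configuration of one randomization run.

    ``max_attempt_factor`` bounds LP effort (consecutive failed swap
    proposals allowed = factor x |links|); ``stall_retries`` bounds how
    often the link-assignment methods restart with a fresh stream when
    the degree repair stalls.
    """

    method: str = "LA+S"
    rng_seed: int = 0
    max_attempt_factor: int = 100
    stall_retries: int = 10

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")


def randomize(net: Network, spec: RandomizerSpec) -> Network:
    """Dispatch to the configured randomization algorithm."""
    fn = {
        "LP": randomize_lp,
        "NP": randomize_np,
        "LA": randomize_la,
        "LA+S": randomize_las,
    }[spec.method]
    return fn(net, spec)


# ---------------------------------------------------------------------
# LP — link permutation (degree-preserving double-edge swaps)
# ---------------------------------------------------------------------


def randomize_lp(net: Network, spec: RandomizerSpec) -> Network:
    rng = random.Random(spec.rng_seed)
    link_list = net.sorted_links()
    n = len(link_list)
    if n < 2:
        return Network(link_list)
    link_set = set(link_list)
    unswapped = set(link_list)  # original links still present
    max_fail = spec.max_attempt_factor * n
    fails = 0
    randrange = rng.randrange
    coin = rng.random
    while unswapped and fails < max_fail:
        i = randrange(n)
        j = randrange(n)
        if i == j:
            fails += 1
            continue
        a, b = link_list[i]
        c, d = link_list[j]
        if coin() < 0.5:  # both legal rewirings equally likely
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            fails += 1
            continue
        new1 = (a, c) if a < c else (c, a)
        new2 = (b, d) if b < d else (d, b)
        if new1 in link_set or new2 in link_set:
            fails += 1
            continue
        old1, old2 = link_list[i], link_list[j]
        link_set.remove(old1)
        link_set.remove(old2)
        unswapped.discard(old1)
        unswapped.discard(old2)
        link_set.add(new1)
        link_set.add(new2)
        link_list[i] = new1
        link_list[j] = new2
        fails = 0
    return Network(link_set)


# ---------------------------------------------------------------------
# NP — node permutation within connectivity bins
# ---------------------------------------------------------------------


def randomize_np(net: Network, spec: RandomizerSpec) -> Network:
    rng = np.random.default_rng(spec.rng_seed)
    deg = net.degree
    by_bin: dict[int, list[str]] = {}
    for u in net.sorted_nodes():
        by_bin.setdefault(connectivity_bin(deg[u]), []).append(u)
    mapping: dict[str, str] = {}
    for b in sorted(by_bin):
        members = by_bin[b]
        perm = rng.permutation(len(members))
        for i, u in enumerate(members):
            mapping[u] = members[perm[i]]
    return Network((mapping[u], mapping[v]) for u, v in net.links)


# ---------------------------------------------------------------------
# LA / LA+S — configuration-model link assignment
# ---------------------------------------------------------------------


def _match_stubs(stubs: list[int], link_set: set, rng) -> list[int]:
    """Uniform stub matching with rejection; returns unmatched stubs.

    Stubs are node indices repeated once per unit of residual degree.
    Accepted pairs enter ``link_set``; pairs forming self-links or
    duplicates are returned to the pool and re-shuffled, until matched
    or no further progress is made.
    """
    remaining = stubs
    for _ in range(_MAX_MATCH_ROUNDS):
        if len(remaining) < 2:
            break
        order = rng.permutation(len(remaining))
        shuffled = [remaining[i] for i in order]
        leftover: list[int] = []
        it = iter(shuffled)
        for u, v in zip(it, it):
            if u == v:
                leftover.append(u)
                leftover.append(v)
                continue
            key = (u, v) if u < v else (v, u)
            if key in link_set:
                leftover.append(u)
                leftover.append(v)
                continue
            link_set.add(key)
        if len(shuffled) % 2:
            leftover.append(shuffled[-1])
        if len(leftover) == len(remaining):
            break
        remaining = leftover
    return remaining


def _residual_counts(leftover: list[int]) -> dict[int, int]:
    res: dict[int, int] = {}
    for u in leftover:
        res[u] = res.get(u, 0) + 1
    return res


def _repair_degrees(link_set: set, residual: dict[int, int], rng) -> None:
    """Swap-based degree repair (in place).

    For each pair of degree-deficient stubs (u, v): add {u,v} directly if
    absent; otherwise find an existing link {x,y} disjoint from {u,v}
    with {u,x} and {v,y} both absent, replace it by {u,x} and {v,y}.
    Raises ``_StallError`` when no fixing move can be found.
    """
    stubs = [n for n, r in sorted(residual.items()) for _ in range(r)]
    if not stubs:
        return
    if len(stubs) % 2:
        raise ValueError("total residual degree must be even")
    order = rng.permutation(len(stubs))
    stubs = [stubs[i] for i in order]
    link_list = list(link_set)
    pos = {l: i for i, l in enumerate(link_list)}

    def _add(a, b):
        key = (a, b) if a < b else (b, a)
        link_set.add(key)
        pos[key] = len(link_list)
        link_list.append(key)

    def _remove(key):
        i = pos.pop(key)
        last = link_list.pop()
        if last != key:
            link_list[i] = last
            pos[last] = i
        link_set.remove(key)

    while stubs:
        u = stubs.pop()
        v = stubs.pop()
        key = (u, v) if u < v else (v, u)
        if u != v and key not in link_set:
            _add(u, v)
            continue
        placed = False
        for _ in range(_REPAIR_PROBES):
            if not link_list:
                break
            xy = link_list[int(rng.integers(len(link_list)))]
            for x, y in (xy, xy[::-1]):
                if x == u or x == v or y == u or y == v:
                    continue
                ux = (u, x) if u < x else (x, u)
                vy = (v, y) if v < y else (y, v)
                if ux in link_set or vy in link_set:
                    continue
                _remove(xy)
                _add(u, x)
                _add(v, y)
                placed = True
                break
            if placed:
                break
        if not placed:
            raise _StallError(f"cannot repair residual degree at stubs {u}, {v}")


def _la_links(net: Network, rng, second_order: bool):
    """One link-assignment attempt; returns (index link set, residual, nodes)."""
    nodes = net.sorted_nodes()
    index = {u: i for i, u in enumerate(nodes)}
    adj = net.adj
    degs = [len(adj[u]) for u in nodes]
    link_set: set[tuple[int, int]] = set()

    if not second_order:
        stubs = [i for i, d in enumerate(degs) for _ in range(d)]
        leftover = _match_stubs(stubs, link_set, rng)
    else:
        bins = [connectivity_bin(d) for d in degs]
        classes: dict[tuple[int, int], list[int]] = {}
        for u_name, v_name in net.sorted_links():
            u, v = index[u_name], index[v_name]
            classes.setdefault((bins[u], bins[v]), []).append(u)
            classes.setdefault((bins[v], bins[u]), []).append(v)
        leftover = []
        for x, y in sorted(classes):
            if x > y:
                continue  # handled with its mirror class
            if x == y:
                leftover.extend(_match_stubs(classes[(x, x)], link_set, rng))
            else:
                leftover.extend(
                    _match_bipartite(classes[(x, y)], classes[(y, x)], link_set, rng)
                )
    return link_set, _residual_counts(leftover), nodes


def _match_bipartite(a_stubs: list[int], b_stubs: list[int], link_set: set, rng):
    """Pair stubs across two mirrored bin classes; returns unmatched stubs."""
    a, b = a_stubs, b_stubs
    for _ in range(_MAX_MATCH_ROUNDS):
        if not a or not b:
            break
        a = [a[i] for i in rng.permutation(len(a))]
        b = [b[i] for i in rng.permutation(len(b))]
        la: list[int] = []
        lb: list[int] = []
        for u, v in zip(a, b):
            if u == v:
                la.append(u)
                lb.append(v)
                continue
            key = (u, v) if u < v else (v, u)
            if key in link_set:
                la.append(u)
                lb.append(v)
                continue
            link_set.add(key)
        la.extend(a[min(len(a), len(b)):])
        lb.extend(b[min(len(a), len(b)):])
        if len(la) + len(lb) == len(a) + len(b):
            break
        a, b = la, lb
    return [*a, *b] if (a or b) else []


def _randomize_assignment(net: Network, spec: RandomizerSpec, second_order: bool):
    last_residual: dict[int, int] = {}
    nodes: list[str] = []
    for attempt in range(spec.stall_retries + 1):
        rng = np.random.default_rng((spec.rng_seed, attempt))
        link_set, residual, nodes = _la_links(net, rng, second_order)
        try:
            _repair_degrees(link_set, residual, rng)
        except _StallError:
            last_residual = residual
            continue
        return Network((nodes[i], nodes[j]) for i, j in link_set)
    bad = sorted(nodes[i] for i in last_residual)
    raise RandomizationError(
        f"degree repair stalled after {spec.stall_retries} retries; "
        f"unresolved residual degrees at nodes {bad}"
    )


def randomize_la(net: Network, spec: RandomizerSpec) -> Network:
    return _randomize_assignment(net, spec, second_order=False)


def randomize_las(net: Network, spec: RandomizerSpec) -> Network:
    return _randomize_assignment(net, spec, second_order=True)


def fix_residual_degrees(
    partial: Network, target_degree: dict[str, int], spec: RandomizerSpec
) -> Network:
    """Complete a partial network to an exact target degree map.

    Nodes named in ``target_degree`` but absent from ``partial`` are
    treated as currently isolated.  Preconditions: no node exceeds its
    target degree and the total residual degree is even.
    """
    nodes = sorted(set(target_degree) | partial.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    adj = partial.adj
    residual: dict[int, int] = {}
    for u in nodes:
        cur = len(adj.get(u, ()))
        tgt = target_degree.get(u, cur)
        if cur > tgt:
            raise ValueError(f"node {u!r} exceeds its target degree ({cur} > {tgt})")
        if cur < tgt:
            residual[index[u]] = tgt - cur
    if sum(residual.values()) % 2:
        raise ValueError("total residual degree must be even")
    link_set = {(index[u], index[v]) for u, v in partial.links}
    for attempt in range(spec.stall_retries + 1):
        rng = np.random.default_rng((spec.rng_seed, attempt))
        working = set(link_set)
        try:
            _repair_degrees(working, dict(residual), rng)
        except _StallError:
            continue
        return Network((nodes[i], nodes[j]) for i, j in working)
    bad = sorted(nodes[i] for i in residual)
    raise RandomizationError(
        f"could not complete degrees after {spec.stall_retries} retries; "
        f"deficient nodes {bad}"
    )


# ---------------------------------------------------------------------
# Topology conservation report
# ---------------------------------------------------------------------


def topology_report(
    net: Network,
    methods=METHODS,
    iterations: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean ± sd of topology conservation metrics per randomization method.

    Columns: percent link identity with the original, assortativity of
    the randomized instances, and s-metric ratio randomized/original.
    """
    s0 = s_metric(net)
    rows = []
    for method in methods:
        ident, assort, ratio = [], [], []
        for i in range(iterations):
            rnd = randomize(net, RandomizerSpec(method=method, rng_seed=seed + i))
            ident.append(100.0 * link_identity_fraction(net, rnd))
            a = assortativity(rnd)
            assort.append(np.nan if a is None else a)
            ratio.append(s_metric(rnd) / s0 if s0 else np.nan)
        rows.append(
            {
                "method": method,
                "percent_identity_mean": float(np.mean(ident)),
                "percent_identity_sd": float(np.std(ident, ddof=1)) if iterations > 1 else 0.0,
                "assortativity_mean": float(np.nanmean(assort)) if not np.all(np.isnan(assort)) else np.nan,
                "assortativity_sd": float(np.nanstd(assort, ddof=1)) if iterations > 1 and not np.all(np.isnan(assort)) else 0.0,
                "s_metric_ratio_mean": float(np.mean(ratio)),
                "s_metric_ratio_sd": float(np.std(ratio, ddof=1)) if iterations > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
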