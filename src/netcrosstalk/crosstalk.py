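"""Crosstalk enrichment screening between and within gene groups.

For each group pair the observed number of network links is compared to
a null distribution built by counting the same links in N randomized
network instances (see :mod:`netcrosstalk.randomize`).  The z-score
(observed minus null mean, over the null standard deviation) is
transformed into a one-sided enrichment p-value, adjusted by
Benjamini–Hochberg across the result family, and gated by the reduced
chi-squared normality diagnostic.  Inter- and intra-group results form
separate FDR families when a single group collection is screened; in
two-collection mode all (cross) results form one family.

Overlapping groups require a convention for links touching shared
genes.  Two counting modes exist for inter-group links:

* ``either`` (default): a link is not tallied if *either* endpoint lies
  in the intersection of the two groups;
* ``both``: a link is not tallied only if *both* endpoints lie in the
  intersection.

Intra-group links are always tallied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .network import GeneGroup, GroupSet, Network
from .randomize import RandomizerSpec, randomize
from .stats import bh_fdr, p_from_z, reduced_chi_squared, z_score

logger = logging.getLogger(__name__)

__all__ = [
    "COUNTING_MODES",
    "RunConfig",
    "NullTally",
    "CrosstalkResult",
    "count_inter_links",
    "count_intra_links",
    "build_null",
    "crosstalk_screen",
    "write_results",
]

COUNTING_MODES = ("either", "both")

#: Null means below this are tagged low-expectation (normality fragile).
LOW_EXPECTATION = 5.0


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a crosstalk screen."""

    method: str = "LA+S"
    n_randomizations: int = 100
    counting_mode: str = "either"
    seed: int = 0
    fdr_alpha: float = 0.05
    chi2_max: float = 1.0
    min_group_size_in_network: int = 1
    chi2_dof: str = "randomizations"
    max_attempt_factor: int = 100
    stall_retries: int = 10

    def __post_init__(self) -> None:
        if self.n_randomizations < 2:
            raise ValueError("need at least 2 randomizations")
        if self.counting_mode not in COUNTING_MODES:
            raise ValueError(f"counting_mode must be one of {COUNTING_MODES}")

    def randomizer_spec(self, iteration: int) -> RandomizerSpec:
        # per-iteration stream: seed + iteration index
        return RandomizerSpec(
            method=self.method,
            rng_seed=self.seed + iteration,
            max_attempt_factor=self.max_attempt_factor,
            stall_retries=self.stall_retries,
        )


@dataclass
class NullTally:
    """Link counts for one group pair across N randomized instances."""

    pair: tuple[str, str]
    counts: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def sd(self) -> float:
        return float(np.std(self.counts, ddof=1))


@dataclass
class CrosstalkResult:
    group1: str
    group2: str
    kind: str  # "inter" | "intra"
    n_obs: int
    n_exp: float
    sd: float
    z: Optional[float]
    p: Optional[float]
    fdr: Optional[float] = None
    chi2_reduced: Optional[float] = None
    significant: bool = False
    low_expectation: bool = False

    @property
    def direction(self) -> str:
        if self.z is None or self.z == 0:
            return "none"
        return "enrichment" if self.z > 0 else "depletion"


# ---------------------------------------------------------------------
# link counting
# ---------------------------------------------------------------------


def _tally_inter(adj, a: frozenset, b: frozenset, shared: frozenset, mode: str) -> int:
    either = mode == "either"
    count = 0
    # iterate the smaller group; every qualifying link has an endpoint in it
    small, other = (a, b) if len(a) <= len(b) else (b, a)
    for u in small:
        nbrs = adj.get(u)
        if not nbrs:
            continue
        u_in_other = u in other
        for v in nbrs:
            if v not in other:
                continue
            # count each link once even when both endpoints qualify both ways
            if u_in_other and v in small and u > v:
                continue
            if either:
                if u in shared or v in shared:
                    continue
            else:
                if u in shared and v in shared:
                    continue
            count += 1
    return count


def _tally_intra(adj, a: frozenset) -> int:
    count = 0
    for u in a:
        nbrs = adj.get(u)
        if not nbrs:
            continue
        for v in nbrs:
            if v in a and u < v:
                count += 1
    return count


def count_inter_links(
    net: Network, a: GeneGroup, b: GeneGroup, mode: str = "either"
) -> int:
    """Links between groups a and b under the given counting mode."""
    if a.name == b.name:
        raise ValueError("inter-group counting requires two distinct groups")
    if mode not in COUNTING_MODES:
        raise ValueError(f"counting mode must be one of {COUNTING_MODES}")
    return _tally_inter(net.adj, a.members, b.members, a.members & b.members, mode)


def count_intra_links(net: Network, a: GeneGroup) -> int:
    """Links with both endpoints inside group a."""
    return _tally_intra(net.adj, a.members)


# ---------------------------------------------------------------------
# null distributions
# ---------------------------------------------------------------------


def build_null(
    net: Network,
    pairs: Sequence[tuple[GeneGroup, GeneGroup]],
    cfg: RunConfig,
) -> dict[tuple[str, str], NullTally]:
    """Tally every pair's link count in each of N randomized instances.

    Intra-group tallies are requested by passing the same group twice
    (pair key (g, g)).  One set of N randomized networks is shared by
    all pairs.
    """
    n = cfg.n_randomizations
    keys = []
    specs = []  # (members_a, members_b, shared, intra?)
    for a, b in pairs:
        if a.name == b.name:
            keys.append((a.name, a.name))
            specs.append((a.members, None, None))
        else:
            keys.append((a.name, b.name))
            specs.append((a.members, b.members, a.members & b.members))
    counts = np.zeros((len(pairs), n), dtype=np.int64)
    for i in range(n):
        rnd = randomize(net, cfg.randomizer_spec(i))
        adj = rnd.adj
        for j, (ma, mb, shared) in enumerate(specs):
            if mb is None:
                counts[j, i] = _tally_intra(adj, ma)
            else:
                counts[j, i] = _tally_inter(adj, ma, mb, shared, cfg.counting_mode)
    return {key: NullTally(pair=key, counts=counts[j]) for j, key in enumerate(keys)}


# ---------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------


def _filter_groups(groups: GroupSet, net: Network, min_size: int) -> GroupSet:
    kept = []
    nodes = net.nodes
    for g in groups:
        in_net = g.members & frozenset(nodes)
        dropped = len(g.members) - len(in_net)
        if dropped:
            logger.warning(
                "group %s: %d member(s) absent from the network", g.name, dropped
            )
        if len(in_net) < min_size:
            logger.warning(
                "dropping group %s: %d network member(s) < minimum %d",
                g.name,
                len(in_net),
                min_size,
            )
            continue
        kept.append(GeneGroup(g.name, in_net))
    return GroupSet(kept)


def _apply_family_fdr(results: list[CrosstalkResult], cfg: RunConfig) -> None:
    """BH adjustment in place; sd = 0 results are excluded from the family."""
    testable = [r for r in results if r.p is not None]
    if not testable:
        return
    adj = bh_fdr([r.p for r in testable])
    for r, q in zip(testable, adj):
        r.fdr = float(q)
        r.significant = (
            r.fdr < cfg.fdr_alpha
            and r.chi2_reduced is not None
            and r.chi2_reduced <= cfg.chi2_max
            and r.z is not None
            and r.z > 0
        )


def crosstalk_screen(
    net: Network,
    groups_a: GroupSet,
    groups_b: Optional[GroupSet] = None,
    cfg: RunConfig = RunConfig(),
) -> list[CrosstalkResult]:
    """Full crosstalk screen.

    With one group collection: one intra result per group plus one inter
    result per unordered group pair, BH-adjusted as two separate
    families.  With two collections: one inter result per cross pair
    (A x B), one FDR family.

    A result is flagged significant when FDR < alpha, reduced
    chi-squared <= chi2_max, and z > 0.
    """
    ga = _filter_groups(groups_a, net, cfg.min_group_size_in_network)
    if len(ga) == 0:
        raise ValueError("no groups left in first collection after filtering")
    if groups_b is not None:
        gb = _filter_groups(groups_b, net, cfg.min_group_size_in_network)
        if len(gb) == 0:
            raise ValueError("no groups left in second collection after filtering")
        pairs = [(a, b) for a in ga for b in gb]
    else:
        gl = list(ga)
        pairs = [(g, g) for g in gl]
        pairs += [(gl[i], gl[j]) for i in range(len(gl)) for j in range(i + 1, len(gl))]

    null = build_null(net, pairs, cfg)
    results: list[CrosstalkResult] = []
    for a, b in pairs:
        intra = a.name == b.name
        key = (a.name, b.name)
        tally = null[key]
        if intra:
            n_obs = count_intra_links(net, a)
        else:
            n_obs = count_inter_links(net, a, b, cfg.counting_mode)
        mean, sd = tally.mean, tally.sd
        z = z_score(n_obs, mean, sd)
        p = None if z is None else p_from_z(z)
        chi2 = reduced_chi_squared(tally.counts, dof=cfg.chi2_dof)
        results.append(
            CrosstalkResult(
                group1=a.name,
                group2=b.name,
                kind="intra" if intra else "inter",
                n_obs=n_obs,
                n_exp=mean,
                sd=sd,
                z=z,
                p=p,
                chi2_reduced=chi2,
                low_expectation=mean < LOW_EXPECTATION,
            )
        )
        if z is None:
            logger.warning(
                "pair (%s, %s): degenerate null (sd = 0), z/p undefined", a.name, b.name
            )
    # separate FDR families for intra and inter (one family in A x B mode)
    if groups_b is None:
        _apply_family_fdr([r for r in results if r.kind == "intra"], cfg)
        _apply_family_fdr([r for r in results if r.kind == "inter"], cfg)
    else:
        _apply_family_fdr(results, cfg)
    return results


# ---------------------------------------------------------------------
# output
# ---------------------------------------------------------------------

_COLUMNS = (
    "group1",
    "group2",
    "type",
    "n_obs",
    "n_exp",
    "sd",
    "z",
    "p",
    "fdr",
    "chi2_reduced",
    "significant",
)


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, bool):
        return str(x)
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_results(results: Sequence[CrosstalkResult], path, header_lines=()) -> None:
    """Write the screen as a fixed-column TSV, floats at 6 significant digits."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    _fmt(v)
                    for v in (
                        r.group1,
                        r.group2,
                        r.kind,
                        r.n_obs,
                        r.n_exp,
                        r.sd,
                        r.z,
                        r.p,
                        r.fdr,
                        r.chi2_reduced,
                        r.significant,
                    )
                )
                + "\n"
            )
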