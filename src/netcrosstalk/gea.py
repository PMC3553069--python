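"""Hypergeometric gene-set enrichment analysis (GEA) baseline.

The classical annotation approach that crosstalk analysis is compared
against: for a signature of n genes and a pathway of m genes drawn from
a universe of N genes, the overlap k is scored with the hypergeometric
upper tail

    p = P(X >= k) = sum_{j >= k} C(m, j) C(N - m, n - j) / C(N, n)

and BH-adjusted across all signature x pathway pairs.  GEA sees only
shared gene membership — a pathway densely wired to a signature in the
network but sharing few genes with it is invisible here, which is
exactly the gap crosstalk analysis fills.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy.stats import hypergeom

from .network import GroupSet
from .stats import bh_fdr

__all__ = ["OverlapTest", "hypergeom_overlap_p", "gea_screen", "shared_universe"]


@dataclass
class OverlapTest:
    signature: str
    pathway: str
    universe_size: int
    pathway_size: int
    signature_size: int
    overlap: int
    p: float
    fdr: Optional[float] = None
    significant: bool = False


def hypergeom_overlap_p(N: int, m: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric overlap probability P(X >= k)."""
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError("require 0 <= m, n <= N")
    if not (0 <= k <= min(m, n)):
        raise ValueError("require 0 <= k <= min(m, n)")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, m, n))


def shared_universe(signatures: GroupSet, pathways: GroupSet) -> frozenset[str]:
    """Genes present in both collections — the default test universe."""
    return signatures.all_members() & pathways.all_members()


def gea_screen(
    signatures: GroupSet,
    pathways: GroupSet,
    universe: frozenset[str],
    fdr_alpha: float = 0.05,
) -> list[OverlapTest]:
    """One hypergeometric test per signature x pathway pair, one BH family.

    Memberships are intersected with the universe before counting.
    """
    if not universe:
        raise ValueError("empty gene universe")
    N = len(universe)
    results: list[OverlapTest] = []
    sig_sets = [(s.name, s.members & universe) for s in signatures]
    path_sets = [(p.name, p.members & universe) for p in pathways]
    for s_name, s_members in sig_sets:
        for p_name, p_members in path_sets:
            m = len(p_members)
            n = len(s_members)
            k = len(s_members & p_members)
            results.append(
                OverlapTest(
                    signature=s_name,
                    pathway=p_name,
                    universe_size=N,
                    pathway_size=m,
                    signature_size=n,
                    overlap=k,
                    p=hypergeom_overlap_p(N, m, n, k),
                )
            )
    adjusted = bh_fdr([r.p for r in results])
    for r, q in zip(results, adjusted):
        r.fdr = float(q)
        r.significant = r.fdr < fdr_alpha
    return results


def write_gea_results(results, path) -> None:
    columns = ("signature", "pathway", "N", "m", "n", "k", "p", "fdr", "significant")
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.signature,
                        r.pathway,
                        str(r.universe_size),
                        str(r.pathway_size),
                        str(r.signature_size),
                        str(r.overlap),
                        f"{r.p:.6g}",
                        f"{r.fdr:.6g}",
                        str(r.significant),
                    ]
                )
                + "\n"
            )
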