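"""Validation experiments on synthetic test beds.

These functions bundle the generators (:mod:`netcrosstalk.synthetic`)
with the crosstalk screen into the standard validation battery:

* second-order topology preservation under node permutation;
* planted-module recovery (false-negative positive control) for all
  four randomization methods;
* split-module inter-crosstalk recovery;
* null calibration on random degree-matched group pairs (p-value bias
  ratio, z-score moments, and the normality-diagnostic pass rate).

Every experiment is a deterministic function of its seed.
"""

from __future__ import annotations

import numpy as np

from .crosstalk import RunConfig, crosstalk_screen
from .network import GeneGroup, GroupSet, assortativity, s_metric
from .randomize import METHODS, RandomizerSpec, randomize_np
from .synthetic import (
    PlantedModuleSpec,
    barabasi_albert,
    plant_modules,
    random_degree_matched_group,
    split_group,
)

__all__ = [
    "np_topology_preservation",
    "planted_module_bed",
    "planted_module_recovery",
    "split_recovery",
    "null_calibration",
]


def np_topology_preservation(seed: int, n: int = 2000, m: int = 3) -> dict:
    """s-metric ratio and assortativity change under node permutation."""
    net = barabasi_albert(n, m, seed=seed)
    rnd = randomize_np(net, RandomizerSpec(method="NP", rng_seed=seed + 1))
    a0, a1 = assortativity(net), assortativity(rnd)
    return {
        "s_metric_ratio": s_metric(rnd) / s_metric(net),
        "assortativity_original": a0,
        "assortativity_randomized": a1,
        "assortativity_abs_diff": abs(a1 - a0),
    }


def planted_module_bed(
    seed: int,
    n_background: int = 3000,
    m: int = 3,
    n_modules: int = 20,
    module_size: int = 30,
    boost: int = 40,
):
    """The shared positive-control network and its planted modules."""
    spec = PlantedModuleSpec(
        n_background_nodes=n_background,
        ba_links_per_node=m,
        n_modules=n_modules,
        module_size=module_size,
        intra_link_boost=boost,
        seed=seed,
    )
    return plant_modules(spec)


def planted_module_recovery(
    net,
    modules: GroupSet,
    seed: int,
    methods=METHODS,
    n_randomizations: int = 100,
) -> dict[str, float]:
    """Percent of planted modules with significant intra-crosstalk, per method."""
    out: dict[str, float] = {}
    for k, method in enumerate(methods):
        cfg = RunConfig(
            method=method,
            n_randomizations=n_randomizations,
            seed=seed * 1000 + 200 * k,
        )
        res = crosstalk_screen(net, modules, None, cfg)
        intra = [r for r in res if r.kind == "intra"]
        out[method] = 100.0 * sum(r.significant for r in intra) / len(intra)
    return out


def split_recovery(
    net,
    modules: GroupSet,
    seed: int,
    methods=METHODS,
    n_randomizations: int = 100,
) -> dict[str, float]:
    """Percent of modules whose random halves show significant inter-crosstalk.

    Each module is split into balanced halves; the first halves are
    screened against the second halves (one FDR family over all cross
    pairs) and a module counts as recovered when its own half-pair is
    significant.
    """
    rng = np.random.default_rng((seed, 17))
    firsts, seconds = [], []
    for g in modules:
        a, b = split_group(g, rng)
        firsts.append(a)
        seconds.append(b)
    ga, gb = GroupSet(firsts), GroupSet(seconds)
    out: dict[str, float] = {}
    for k, method in enumerate(methods):
        cfg = RunConfig(
            method=method,
            n_randomizations=n_randomizations,
            seed=seed * 1000 + 200 * k + 100,
        )
        res = crosstalk_screen(net, ga, gb, cfg)
        diagonal = [r for r in res if r.group1[:-2] == r.group2[:-2]]
        out[method] = 100.0 * sum(r.significant for r in diagonal) / len(diagonal)
    return out


def null_calibration(
    seed: int,
    n_groups: int = 66,
    size_range: tuple[int, int] = (20, 60),
    method: str = "LA+S",
    n_randomizations: int = 150,
    n_background: int = 3000,
    m: int = 3,
) -> dict:
    """Null p-value / z-score calibration on degree-matched random groups.

    Random node-set templates (sizes uniform in ``size_range``) are
    replaced by degree-bin-matched instances carrying no signal; all
    inter pairs are screened.  Reported:

    * ``bias_ratio`` — count of p < 0.05 over the mean count in the 19
      equally sized bins at p >= 0.05, among chi2-passing pairs (an
      unbiased distribution gives 1);
    * ``z_mean`` / ``z_sd`` — moments of the null z-scores;
    * ``chi2_pass_pct_exp_gt5`` — percent of pairs with expected links
      above 5 passing reduced chi-squared <= 1.
    """
    net = barabasi_albert(n_background, m, seed=seed)
    rng = np.random.default_rng((seed, 23))
    nodes = net.sorted_nodes()
    groups = []
    for i in range(n_groups):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        pick = rng.choice(len(nodes), size=size, replace=False)
        template = GeneGroup(f"t{i:03d}", frozenset(nodes[j] for j in pick))
        inst = random_degree_matched_group(net, template, rng)
        groups.append(GeneGroup(f"rg{i:03d}", inst.members))
    cfg = RunConfig(
        method=method, n_randomizations=n_randomizations, seed=seed * 1000 + 900
    )
    res = crosstalk_screen(net, GroupSet(groups), None, cfg)
    inter = [r for r in res if r.kind == "inter"]
    ok = [
        r
        for r in inter
        if r.p is not None and r.chi2_reduced is not None and r.chi2_reduced <= 1.0
    ]
    p = np.array([r.p for r in ok])
    z = np.array([r.z for r in ok])
    n_low = int(np.sum(p < 0.05))
    bin_counts = [
        int(np.sum((p >= lo) & (p < lo + 0.05))) for lo in np.arange(0.05, 0.999, 0.05)
    ]
    big = [r for r in inter if r.n_exp > 5.0]
    return {
        "n_pairs": len(inter),
        "n_chi2_passing": len(ok),
        "bias_ratio": n_low / np.mean(bin_counts),
        "frac_p_below_05": n_low / len(p),
        "z_mean": float(z.mean()),
        "z_sd": float(z.std(ddof=1)),
        "n_exp_gt5": len(big),
        "chi2_pass_pct_exp_gt5": 100.0
        * sum(r.chi2_reduced is not None and r.chi2_reduced <= 1.0 for r in big)
        / max(len(big), 1),
    }
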