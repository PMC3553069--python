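"""Link counting, null distributions, and the crosstalk screen."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netcrosstalk import (
    Network,
    NullTally,
    RunConfig,
    build_null,
    count_inter_links,
    count_intra_links,
    crosstalk_screen,
    write_results,
)
from netcrosstalk.network import GeneGroup, GroupSet
from netcrosstalk.synthetic import PlantedModuleSpec, plant_modules

from conftest import random_simple_network


def grp(name, *members):
    return GeneGroup(name, frozenset(members))


class TestCountInterLinks:
    def test_disjoint_groups_one_link(self):
        net = Network([("x", "y")])
        a, b = grp("a", "x"), grp("b", "y")
        assert count_inter_links(net, a, b, "either") == 1
        assert count_inter_links(net, a, b, "both") == 1

    def test_overlap_exclusion_rules(self):
        net = Network([("x", "y"), ("x", "z")])
        a, b = grp("a", "x", "z"), grp("b", "y", "z")
        # {x,z} touches z in the intersection: skipped under either-exclusion
        assert count_inter_links(net, a, b, "either") == 1
        assert count_inter_links(net, a, b, "both") == 2

    def test_identical_membership_counts_nothing(self):
        net = Network([("z", "w")])
        a, b = grp("a", "z", "w"), grp("b", "z", "w")
        assert count_inter_links(net, a, b, "either") == 0
        assert count_inter_links(net, a, b, "both") == 0

    def test_same_name_rejected(self):
        net = Network([("x", "y")])
        with pytest.raises(ValueError):
            count_inter_links(net, grp("a", "x"), grp("a", "y"))

    def test_absent_members_count_zero(self):
        net = Network([("x", "y")])
        assert count_inter_links(net, grp("a", "q"), grp("b", "r")) == 0


class TestCountIntraLinks:
    def test_triangle_all_nodes(self, triangle):
        assert count_intra_links(triangle, grp("g", "a", "b", "c")) == 3

    def test_single_node(self, triangle):
        assert count_intra_links(triangle, grp("g", "a")) == 0

    def test_two_unlinked_nodes(self, star4):
        assert count_intra_links(star4, grp("g", "l1", "l2")) == 0


def _brute_force_inter(net, a, b, mode):
    """Independent oracle: iterate all links, apply the skip rule directly."""
    shared = a.members & b.members
    count = 0
    for u, v in net.links:
        qualifies = (u in a.members and v in b.members) or (
            u in b.members and v in a.members
        )
        if not qualifies:
            continue
        if mode == "either" and (u in shared or v in shared):
            continue
        if mode == "both" and (u in shared and v in shared):
            continue
        count += 1
    return count


class TestCountingModeProperties:
    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_monotonicity_and_oracle_agreement(self, seed):
        """either-exclusion <= both-exclusion <= no-exclusion, and both
        implemented modes agree with a brute-force link scan."""
        rng = np.random.default_rng(seed)
        net = random_simple_network(rng, n_nodes=15, p=0.25)
        nodes = net.sorted_nodes()
        a = grp("a", *(nodes[i] for i in rng.choice(len(nodes), 6, replace=False)))
        b = grp("b", *(nodes[i] for i in rng.choice(len(nodes), 6, replace=False)))
        either = count_inter_links(net, a, b, "either")
        both = count_inter_links(net, a, b, "both")
        assert either == _brute_force_inter(net, a, b, "either")
        assert both == _brute_force_inter(net, a, b, "both")
        no_excl = _brute_force_inter(net, a, b, "none")
        assert either <= both <= no_excl

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_disjoint_groups_agree_across_modes(self, seed):
        rng = np.random.default_rng(seed)
        net = random_simple_network(rng, n_nodes=15, p=0.25)
        nodes = net.sorted_nodes()
        pick = rng.choice(len(nodes), 10, replace=False)
        a = grp("a", *(nodes[i] for i in pick[:5]))
        b = grp("b", *(nodes[i] for i in pick[5:]))
        assert count_inter_links(net, a, b, "either") == count_inter_links(
            net, a, b, "both"
        )


class TestNullTally:
    def test_moments_recomputable(self):
        t = NullTally(pair=("a", "b"), counts=np.array([1, 2, 3, 4]))
        assert t.mean == pytest.approx(2.5)
        assert t.sd == pytest.approx(np.std([1, 2, 3, 4], ddof=1))

    def test_constant_counts_zero_sd(self):
        t = NullTally(pair=("a", "a"), counts=np.array([3, 3]))
        assert t.mean == 3 and t.sd == 0


class TestBuildNull:
    def test_np_on_topology_forced_network_gives_constant_counts(self, triangle):
        # every NP relabeling of the triangle is the triangle itself
        g = grp("g", "a", "b")
        cfg = RunConfig(method="NP", n_randomizations=5, seed=0)
        null = build_null(triangle, [(g, g)], cfg)
        tally = null[("g", "g")]
        assert tally.sd == 0
        assert np.all(tally.counts == tally.counts[0])

    def test_la_on_unique_realization_counts_constant(self, triangle):
        g = grp("g", "a", "b", "c")
        cfg = RunConfig(method="LA", n_randomizations=4, seed=1)
        null = build_null(triangle, [(g, g)], cfg)
        assert np.all(null[("g", "g")].counts == 3)

    def test_one_network_set_shared_by_all_pairs(self, cycle4):
        g1, g2, g3 = grp("g1", "a", "b"), grp("g2", "c", "d"), grp("g3", "a", "c")
        cfg = RunConfig(method="LP", n_randomizations=6, seed=3)
        null = build_null(cycle4, [(g1, g2), (g1, g3), (g2, g2)], cfg)
        assert set(null) == {("g1", "g2"), ("g1", "g3"), ("g2", "g2")}
        assert all(len(t.counts) == 6 for t in null.values())


class TestCrosstalkScreen:
    def test_single_set_combinatorics(self):
        rng = np.random.default_rng(0)
        net = random_simple_network(rng, n_nodes=20, p=0.3)
        nodes = net.sorted_nodes()
        groups = GroupSet(
            [grp(f"g{i}", *nodes[4 * i : 4 * i + 4]) for i in range(4)]
        )
        cfg = RunConfig(method="NP", n_randomizations=10, seed=0)
        res = crosstalk_screen(net, groups, None, cfg)
        assert sum(r.kind == "intra" for r in res) == 4
        assert sum(r.kind == "inter" for r in res) == 6

    def test_two_set_combinatorics(self):
        rng = np.random.default_rng(1)
        net = random_simple_network(rng, n_nodes=20, p=0.3)
        nodes = net.sorted_nodes()
        ga = GroupSet([grp("a1", *nodes[:4]), grp("a2", *nodes[4:8])])
        gb = GroupSet([grp("b1", *nodes[8:12]), grp("b2", *nodes[12:16]), grp("b3", *nodes[16:20])])
        res = crosstalk_screen(net, ga, gb, RunConfig(method="NP", n_randomizations=10, seed=0))
        assert len(res) == 6
        assert all(r.kind == "inter" for r in res)

    def test_degenerate_null_flagged_and_excluded_from_fdr(self, triangle):
        groups = GroupSet([grp("g1", "a", "b"), grp("g2", "b", "c")])
        cfg = RunConfig(method="NP", n_randomizations=5, seed=0)
        res = crosstalk_screen(triangle, groups, None, cfg)
        assert all(r.sd == 0 for r in res)
        assert all(r.z is None and r.p is None and r.fdr is None for r in res)
        assert not any(r.significant for r in res)

    def test_fdr_at_least_p_and_sign_consistency(self):
        rng = np.random.default_rng(4)
        net = random_simple_network(rng, n_nodes=30, p=0.25)
        nodes = net.sorted_nodes()
        groups = GroupSet(
            [grp(f"g{i}", *(nodes[j] for j in rng.choice(30, 8, replace=False))) for i in range(5)]
        )
        res = crosstalk_screen(net, groups, None, RunConfig(method="LP", n_randomizations=30, seed=2))
        for r in res:
            if r.p is not None:
                assert r.fdr >= r.p - 1e-12
            if r.z is not None and r.sd > 0:
                assert np.sign(r.z) == np.sign(r.n_obs - r.n_exp) or r.z == 0

    def test_small_groups_dropped_with_min_size(self):
        net = Network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")])
        groups = GroupSet([grp("big", "a", "b", "c"), grp("tiny", "d", "zz_absent")])
        cfg = RunConfig(method="NP", n_randomizations=5, seed=0, min_group_size_in_network=2)
        res = crosstalk_screen(net, groups, None, cfg)
        names = {r.group1 for r in res} | {r.group2 for r in res}
        assert names == {"big"}

    def test_all_groups_filtered_out_errors(self, triangle):
        groups = GroupSet([grp("g", "absent1", "absent2")])
        with pytest.raises(ValueError):
            crosstalk_screen(triangle, groups, None, RunConfig(method="NP", n_randomizations=5))

    def test_planted_module_detected(self):
        """A dense planted module in a sparse background must come out
        enriched (z > 0) and significant at FDR < 0.05."""
        spec = PlantedModuleSpec(
            n_background_nodes=600,
            ba_links_per_node=3,
            n_modules=4,
            module_size=15,
            intra_link_boost=25,
            seed=5,
        )
        net, groups = plant_modules(spec)
        cfg = RunConfig(method="LA+S", n_randomizations=60, seed=9)
        res = crosstalk_screen(net, groups, None, cfg)
        intra = [r for r in res if r.kind == "intra"]
        assert len(intra) == 4
        for r in intra:
            assert r.z is not None and r.z > 0
            assert r.significant

    def test_determinism(self):
        rng = np.random.default_rng(6)
        net = random_simple_network(rng, n_nodes=25, p=0.2)
        nodes = net.sorted_nodes()
        groups = GroupSet([grp("g1", *nodes[:6]), grp("g2", *nodes[6:12])])
        cfg = RunConfig(method="LA+S", n_randomizations=20, seed=13)
        r1 = crosstalk_screen(net, groups, None, cfg)
        r2 = crosstalk_screen(net, groups, None, cfg)
        assert [(a.group1, a.group2, a.n_obs, a.n_exp, a.sd, a.z, a.p, a.fdr) for a in r1] == [
            (a.group1, a.group2, a.n_obs, a.n_exp, a.sd, a.z, a.p, a.fdr) for a in r2
        ]


class TestWriteResults:
    def test_tsv_layout(self, tmp_path, triangle):
        groups = GroupSet([grp("g1", "a", "b"), grp("g2", "b", "c")])
        res = crosstalk_screen(
            triangle, groups, None, RunConfig(method="NP", n_randomizations=5, seed=0)
        )
        out = tmp_path / "res.tsv"
        write_results(res, out, header_lines=["method=NP"])
        lines = out.read_text().splitlines()
        assert lines[0] == "# method=NP"
        assert lines[1].split("\t") == [
            "group1", "group2", "type", "n_obs", "n_exp", "sd",
            "z", "p", "fdr", "chi2_reduced", "significant",
        ]
        # degenerate nulls render as NA
        assert "NA" in lines[2]
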