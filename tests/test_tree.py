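"""Parsimony tree construction: forced topologies, exhaustive-search oracle,
tip-replay invariant, subclade detection and homoplasy scanning."""

import itertools

import numpy as np
import pytest

from mitophylo.simulate import SimConfig, simulate_clade
from mitophylo.tree import (
    CladePhylogeny,
    PhyloNode,
    _refine_reversions,
    build_tree,
    detect_subclades,
    homoplasy_scan,
    write_edge_table,
    write_newick,
)
from mitophylo.variants import MtVariant, SiteMask, VariantProfile, parse_variant


def prof(sid, tokens):
    return VariantProfile.from_tokens(sid, tokens)


NO_MASK = SiteMask()


# ---------------------------------------------------------------------------
# Exhaustive parsimony oracle (small instances only)


def all_rooted_binary(leaves):
    """Yield every rooted binary leaf-labelled topology as nested tuples."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]

    def insertions(tree, leaf):
        yield (tree, leaf)  # new root above everything
        if isinstance(tree, tuple):
            l, r = tree
            for sub in insertions(l, leaf):
                yield (sub, r)
            for sub in insertions(r, leaf):
                yield (l, sub)

    trees = [first]
    for leaf in rest:
        trees = [t2 for t in trees for t2 in insertions(t, leaf)]
    yield from trees


def fitch_score(tree, states, root_state=0):
    """Minimum changes on a rooted tree for one binary character, with the
    root fixed to the ancestral state."""
    changes = 0

    def sets(t):
        nonlocal changes
        if not isinstance(t, tuple):
            return {states[t]}
        a, b = sets(t[0]), sets(t[1])
        if a & b:
            return a & b
        changes += 1
        return a | b

    top = sets(tree)
    if root_state not in top:
        changes += 1
    return changes


def exhaustive_parsimony(profiles):
    """Minimum total mutations over all rooted binary topologies."""
    sites = sorted({v for p in profiles for v in p.variants})
    ids = [p.sample_id for p in profiles]
    carry = {p.sample_id: p.variants for p in profiles}
    best = None
    for topo in all_rooted_binary(ids):
        total = 0
        for s in sites:
            states = {i: (1 if s in carry[i] else 0) for i in ids}
            total += fitch_score(topo, states)
        best = total if best is None else min(best, total)
    return best


def random_perfect_instance(rng, n_tips, n_sites):
    """Tip profiles generated by dropping each site on one edge of a random
    binary genealogy (homoplasy-free by construction)."""
    ids = list(range(n_tips))
    topos = list(all_rooted_binary(ids))
    topo = topos[rng.integers(0, len(topos))]
    nodes = []

    def collect(t):
        nodes.append(t)
        if isinstance(t, tuple):
            collect(t[0])
            collect(t[1])

    collect(topo)
    carriers = {i: set() for i in ids}

    def tips_below(t):
        return [t] if not isinstance(t, tuple) else tips_below(t[0]) + tips_below(t[1])

    for s in range(n_sites):
        edge = nodes[rng.integers(0, len(nodes))]
        for tip in tips_below(edge):
            carriers[tip].add(s)
    return [
        prof(f"s{i}", " ".join(str(1000 + 7 * s) for s in sorted(carriers[i])))
        for i in ids
    ]


# ---------------------------------------------------------------------------


class TestBuildTree:
    def test_identical_profiles_single_cluster(self):
        profiles = [prof(f"s{i}", "1000 2000") for i in range(4)]
        t = build_tree(profiles)
        assert t.total_mutations() == 2
        (cluster,) = t.root.children
        assert {v.position for v in cluster.edge_mutations} == {1000, 2000}
        assert len(cluster.children) == 4

    def test_forced_split(self):
        t = build_tree([prof("x", "1000 2000 3000"), prof("y", "1000 2000 4000")])
        assert t.total_mutations() == 4
        (shared,) = t.root.children
        assert {v.position for v in shared.edge_mutations} == {1000, 2000}
        leaf_edges = sorted(
            {v.position for v in c.edge_mutations} for c in shared.children
        )
        assert leaf_edges == [{3000}, {4000}]

    def test_single_profile(self):
        t = build_tree([prof("only", "1000 16129")])
        assert t.total_mutations() == 2
        assert [n.name for n in t.tips()] == ["only"]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_tree([prof("a", "1000"), prof("a", "2000")])

    def test_mixed_references_rejected(self):
        a = VariantProfile.from_tokens("a", "73", reference="rCRS")
        b = VariantProfile.from_tokens("b", "73", reference="RSRS")
        with pytest.raises(ValueError, match="reference"):
            build_tree([a, b])

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_search_on_perfect_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        profiles = random_perfect_instance(rng, n, int(rng.integers(2, 11)))
        t = build_tree(profiles, mask=NO_MASK)
        assert t.total_mutations() == exhaustive_parsimony(profiles)

    @pytest.mark.parametrize("seed", range(6))
    def test_tip_replay_on_random_clades(self, seed):
        res = simulate_clade(SimConfig(12, seed=900 + seed, tmrca_years=10000.0))
        t = build_tree(res.profiles, mask=NO_MASK)
        by_id = {p.sample_id: p for p in res.profiles}
        for tip in t.tips():
            assert t.replay(tip) == by_id[tip.name].variants

    def test_duplicate_haplotype_changes_nothing(self):
        res = simulate_clade(SimConfig(8, seed=321, tmrca_years=9000.0))
        t1 = build_tree(res.profiles, mask=NO_MASK)
        clone = VariantProfile(
            "clone_of_first", res.profiles[0].variants
        )
        t2 = build_tree(res.profiles + [clone], mask=NO_MASK)
        assert t2.total_mutations() == t1.total_mutations()
        # the clone attaches as a zero-length tip next to its original
        clone_tip = next(n for n in t2.tips() if n.name == "clone_of_first")
        assert clone_tip.edge_mutations == []

    def test_mutation_count_lower_bound(self):
        for seed in range(4):
            res = simulate_clade(SimConfig(10, seed=40 + seed, tmrca_years=12000.0))
            t = build_tree(res.profiles, mask=NO_MASK)
            distinct = len({v for p in res.profiles for v in p.variants})
            assert t.total_mutations() >= distinct


class TestSubcladesAndHomoplasy:
    def test_star_tree_has_no_subclades(self):
        profiles = [prof(f"s{i}", str(1000 * (i + 1))) for i in range(4)]
        t = build_tree(profiles)
        assert detect_subclades(t, 2) == []

    def test_min_tips_validation(self):
        t = build_tree([prof("a", "1000")])
        with pytest.raises(ValueError):
            detect_subclades(t, 1)

    def test_two_profile_subclade(self):
        t = build_tree([prof("x", "1000 2000 3000"), prof("y", "1000 2000 4000")])
        [(node, muts)] = detect_subclades(t, 2)
        assert {v.position for v in muts} == {1000, 2000}
        assert len(node.tips()) == 2

    def test_recovers_planted_partitions(self):
        rng = np.random.default_rng(3)
        profiles = random_perfect_instance(rng, 6, 9)
        t = build_tree(profiles, mask=NO_MASK)
        truth_parts = set()
        for v in {v for p in profiles for v in p.variants}:
            part = frozenset(p.sample_id for p in profiles if v in p.variants)
            if 2 <= len(part) < len(profiles):
                truth_parts.add(part)
        found = {
            frozenset(tip.name for tip in node.tips())
            for node, _ in detect_subclades(t, 2)
        }
        assert truth_parts <= found

    def test_homoplasy_free_tree_is_clean(self):
        rng = np.random.default_rng(8)
        profiles = random_perfect_instance(rng, 5, 7)
        t = build_tree(profiles, mask=NO_MASK)
        assert homoplasy_scan(t) == []

    def test_three_independent_hits_reported(self):
        # position 185 recurring on three separate branches
        profiles = [
            prof("a", "1000 2000 185"),
            prof("b", "1000 2000"),
            prof("c", "3000 4000 185"),
            prof("d", "3000 4000"),
            prof("e", "5000 185"),
            prof("f", "5000"),
        ]
        t = build_tree(profiles)
        reports = {r.position: r.occurrences for r in homoplasy_scan(t)}
        assert reports == {185: 3}

    def test_planted_recurrent_counts(self):
        res = simulate_clade(SimConfig(25, seed=5150, tmrca_years=16000.0))
        t = build_tree(res.profiles, mask=NO_MASK)
        # every reported recurrence is genuinely multi-edge in the built tree
        for rep in homoplasy_scan(t):
            edges = sum(
                1
                for n in t.walk()
                if any(v.position == rep.position for v in n.edge_mutations)
            )
            assert edges == rep.occurrences >= 2


class TestReversions:
    def test_refinement_pulls_shared_variant_up(self):
        # hand-built: three of four children carry 500 on their stems
        root = PhyloNode()
        mid = root.add_child(PhyloNode())
        mid.edge_mutations = [MtVariant(100)]
        for i, has in enumerate([True, True, True, False]):
            tip = mid.add_child(PhyloNode(f"s{i}"))
            tip.edge_mutations = [MtVariant(500)] if has else [MtVariant(700)]
        before = sum(len(n.edge_mutations) for n in root.walk())
        _refine_reversions(root)
        after = sum(len(n.edge_mutations) for n in root.walk())
        assert after == before - 1
        assert MtVariant(500) in mid.edge_mutations
        t = CladePhylogeny(root)
        # replay still reproduces each tip's haplotype
        tips = {n.name: t.replay(n) for n in t.tips()}
        assert {v.position for v in tips["s0"]} == {100, 500}
        assert {v.position for v in tips["s3"]} == {100, 700}

    def test_reversion_rendered_with_at(self):
        root = PhyloNode()
        mid = root.add_child(PhyloNode())
        mid.edge_mutations = [MtVariant(100)]
        for i in range(4):
            tip = mid.add_child(PhyloNode(f"s{i}"))
            tip.edge_mutations = [MtVariant(500)] if i < 3 else []
        _refine_reversions(root)
        tokens = [v.render() for n in root.walk() for v in n.edge_mutations]
        assert "500@" in tokens


class TestOutputs:
    def test_newick_and_edge_table(self, tmp_path):
        t = build_tree([prof("x", "1000 2000 3000"), prof("y", "1000 2000 4000")])
        nwk = write_newick(t, tmp_path / "t.nwk")
        assert nwk.endswith(";") and "x" in nwk and "[&muts=" in nwk
        import dendropy

        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == {"x", "y"}
        df = write_edge_table(t, tmp_path / "t.tsv")
        assert set(df.columns) == {"parent", "child", "name", "label", "mutations"}
        assert (tmp_path / "t.tsv").exists()
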