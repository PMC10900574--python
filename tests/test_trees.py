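"""Tree model, Newick I/O, clade sets, distances and canonical topologies."""

import itertools

import numpy as np
import pytest

from phylodisc.trees import (
    NewickParseError,
    Tree,
    TreeError,
    canonical_topology,
    clades,
    enumerate_rooted_topologies,
    matching_cluster_distance,
    parse_newick,
    restrict,
    rf_cluster_distance,
    root_with_outgroup,
    write_newick,
)

from conftest import random_tree


class TestNewick:
    def test_parse_readback(self):
        t = parse_newick("((A:1,B:1):0.5,C:1.5);")
        assert t.tip_labels == {"A", "B", "C"}
        internal = [n for n in t.preorder() if not n.is_tip and n.parent is not None]
        assert internal[0].length == 0.5

    def test_lengths_optional(self):
        t = parse_newick("((A,B),C);")
        assert all(n.length is None for n in t.preorder())
        assert canonical_topology(t) == "((A,B),C)"

    @pytest.mark.parametrize(
        "bad", ["((A,B,C);", "(A,B));", "(A,B)", "((A:x,B),C);", "", "((A,B),A);"]
    )
    def test_malformed_or_invalid(self, bad):
        with pytest.raises((NewickParseError, TreeError)):
            parse_newick(bad)

    def test_parse_error_reports_position(self):
        with pytest.raises(NewickParseError) as exc:
            parse_newick("((A,B,C);")
        assert exc.value.pos == 8

    def test_annotations_roundtrip(self):
        t = parse_newick("((A:1[&theta=0.01],B:1):0.5[&theta=0.02,tau=0.5],C:1.5);")
        tips = {n.label: n for n in t.tips()}
        assert tips["A"].annotations == {"theta": 0.01}
        inner = [n for n in t.preorder() if not n.is_tip and n.parent is not None][0]
        assert inner.annotations == {"theta": 0.02, "tau": 0.5}
        out = write_newick(t, annotations=True)
        again = parse_newick(out)
        assert [n.annotations for n in again.preorder()] == [
            n.annotations for n in t.preorder()
        ]

    def test_roundtrip_random_trees(self, rng):
        """parse(write(t)) preserves topology and lengths on 200 random trees."""
        for _ in range(200):
            n = int(rng.integers(3, 12))
            t = random_tree([f"t{i}" for i in range(n)], rng)
            again = parse_newick(write_newick(t))
            assert canonical_topology(again) == canonical_topology(t)
            d1, d2 = t.depths(), again.depths()
            for k in d1:
                assert d2[k] == pytest.approx(d1[k], rel=1e-9)


class TestClades:
    def test_examples(self):
        assert clades(parse_newick("(((A,B),C),D);")) == {
            frozenset("AB"),
            frozenset("ABC"),
        }
        assert clades(parse_newick("((A,B),(C,D));")) == {
            frozenset("AB"),
            frozenset("CD"),
        }
        assert clades(parse_newick("(A,B,C,D);")) == frozenset()

    def test_count_binary(self, rng):
        for n in (4, 6, 9):
            t = random_tree([f"t{i}" for i in range(n)], rng)
            assert len(clades(t)) == n - 2


class TestDistances:
    def test_worked_pair(self):
        t1 = parse_newick("(((A,B),C),D);")
        t2 = parse_newick("((A,B),(C,D));")
        assert rf_cluster_distance(t1, t2) == 2
        assert matching_cluster_distance(t1, t2) == 3

    def test_identity_and_symmetry(self, rng):
        for _ in range(100):
            labels = [f"t{i}" for i in range(int(rng.integers(4, 8)))]
            t1, t2 = random_tree(labels, rng), random_tree(labels, rng)
            assert rf_cluster_distance(t1, t1) == 0
            assert matching_cluster_distance(t1, t1) == 0
            assert rf_cluster_distance(t1, t2) == rf_cluster_distance(t2, t1)
            assert matching_cluster_distance(t1, t2) == matching_cluster_distance(t2, t1)
            assert rf_cluster_distance(t1, t2) <= 2 * (len(labels) - 2)
            same = canonical_topology(t1) == canonical_topology(t2)
            assert (rf_cluster_distance(t1, t2) == 0) == same
            assert (matching_cluster_distance(t1, t2) == 0) == same

    def test_tipset_mismatch(self):
        with pytest.raises(TreeError):
            rf_cluster_distance(parse_newick("((A,B),C);"), parse_newick("((A,B),D);"))

    def test_matching_equals_bruteforce(self, rng):
        """Exact assignment equals minimum over all cluster permutations."""
        for _ in range(40):
            labels = [f"t{i}" for i in range(6)]
            t1, t2 = random_tree(labels, rng), random_tree(labels, rng)
            c1 = sorted(clades(t1), key=sorted)
            c2 = sorted(clades(t2), key=sorted)
            k = max(len(c1), len(c2))
            c1 += [frozenset()] * (k - len(c1))
            c2 += [frozenset()] * (k - len(c2))
            brute = min(
                sum(len(a ^ b) for a, b in zip(c1, perm))
                for perm in itertools.permutations(c2)
            )
            assert matching_cluster_distance(t1, t2) == brute

    def test_triangle_inequality(self, rng):
        for _ in range(30):
            labels = [f"t{i}" for i in range(6)]
            ts = [random_tree(labels, rng) for _ in range(3)]
            d01 = matching_cluster_distance(ts[0], ts[1])
            d12 = matching_cluster_distance(ts[1], ts[2])
            d02 = matching_cluster_distance(ts[0], ts[2])
            assert d02 <= d01 + d12

    def test_against_dendropy_rf(self, rng):
        """Unrooted RF from dendropy relates to our rooted-cluster count on
        matched rootings (independent I/O cross-check)."""
        import dendropy

        for _ in range(20):
            labels = [f"t{i}" for i in range(7)]
            t1, t2 = random_tree(labels, rng), random_tree(labels, rng)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=t1.newick(), schema="newick", taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.newick(), schema="newick", taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            unrooted_rf = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            ours = rf_cluster_distance(t1, t2)
            # rooted clusters refine unrooted splits: counts differ by at most 2
            assert abs(ours - unrooted_rf) <= 2


class TestRestrict:
    def test_examples(self):
        t = parse_newick("(((A:1,B:1):0.5,C:1.5):0.5,D:2);")
        r = restrict(t, {"A", "C", "D"})
        assert canonical_topology(r) == "((A,C),D)"
        assert r.depths()["A"] == pytest.approx(2.0)
        full = restrict(t, t.tip_labels)
        assert canonical_topology(full) == canonical_topology(t)

    def test_unknown_label(self):
        with pytest.raises(TreeError):
            restrict(parse_newick("((A,B),C);"), {"A", "Z"})

    def test_matches_quartet_oracle(self, rng):
        """Restriction to 4 tips agrees with a path-contraction oracle based
        on pairwise path lengths (4-point condition)."""
        for _ in range(20):
            labels = [f"t{i}" for i in range(8)]
            t = random_tree(labels, rng)
            depths = t.depths()
            # pairwise distances from LCA depths
            node_depth = {}
            stack = [(t.root, 0.0)]
            while stack:
                n, d = stack.pop()
                node_depth[id(n)] = d
                for c in n.children:
                    stack.append((c, d + (c.length or 0.0)))

            def pathlen(a, b):
                ta, tb = t.find_tip(a), t.find_tip(b)
                anc = set()
                x = ta
                while x is not None:
                    anc.add(id(x))
                    x = x.parent
                y = tb
                while id(y) not in anc:
                    y = y.parent
                return depths[a] + depths[b] - 2 * node_depth[id(y)]

            for quad in itertools.combinations(labels, 4):
                sub = restrict(t, quad)
                a, b, c, d = quad
                sums = {
                    frozenset(((a, b), (c, d))): pathlen(a, b) + pathlen(c, d),
                    frozenset(((a, c), (b, d))): pathlen(a, c) + pathlen(b, d),
                    frozenset(((a, d), (b, c))): pathlen(a, d) + pathlen(b, c),
                }
                # the unrooted split of the restricted tree (any 2-tip
                # cluster) must achieve the minimum pairing sum
                two = [c for c in clades(sub) if len(c) == 2]
                if not two:
                    continue
                cluster = two[0]
                pair = tuple(sorted(cluster))
                rest = tuple(sorted(set(quad) - cluster))
                key = frozenset((pair, rest))
                best = min(sums.values())
                assert sums[key] == pytest.approx(best)


class TestCanonical:
    def test_child_order_invariance(self):
        assert canonical_topology(parse_newick("((B,A),C);")) == canonical_topology(
            parse_newick("((A,B),C);")
        )

    def test_topology_counts_four_tips(self):
        trees = enumerate_rooted_topologies(list("ABCD"))
        rooted = {canonical_topology(t) for t in trees}
        unrooted = {canonical_topology(t, rooted=False) for t in trees}
        assert len(rooted) == 15
        assert len(unrooted) == 3

    def test_unrooted_invariant_to_rooting(self, rng):
        for _ in range(20):
            labels = [f"t{i}" for i in range(6)]
            t = random_tree(labels, rng)
            rerooted = root_with_outgroup(t, "t3")
            assert canonical_topology(t, rooted=False) == canonical_topology(
                rerooted, rooted=False
            )


class TestReroot:
    def test_outgroup_becomes_root_child(self):
        t = parse_newick("((A:1,B:1):0.5,(C:1,(D:0.5,E:0.5):0.5):0.5);")
        r = root_with_outgroup(t, "D")
        assert {c.label for c in r.root.children if c.is_tip} == {"D"}
        # tip-to-tip path length D..E preserved (0.5 + 0.5 in the original)
        assert r.depths()["D"] + r.depths()["E"] == pytest.approx(1.0)
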