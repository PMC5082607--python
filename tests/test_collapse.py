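"""Collapse to group nodes with meta-edges; exact restoration on expand."""

from collections import Counter

import numpy as np
import pytest

from netannotate import (AnnotationManager, AnnotationSet, CloudOptions,
                         Cluster, LabelOptions, Network, collapse,
                         collapse_all, expand, expand_all)

from helpers import (expected_meta_edges, random_attributed_network,
                     random_partition)


def simple_net(edges, nodes=None):
    net = Network()
    for n in nodes or sorted({x for e in edges for x in e}):
        net.add_node(n, attrs={"desc": f"text {n}"}, position=(1.0, 2.0))
    for u, v in edges:
        net.add_edge(u, v)
    return net


def cluster_of(members, cid="C", label="label"):
    return Cluster(id=cid, members=set(members), label=label)


def meta_edges(net):
    return [e for e in net.edges if e.attrs.get("is_meta")]


class TestCollapse:
    def test_boundary_edge_becomes_counted_meta_edge(self):
        net = simple_net([("a", "b"), ("a", "e")])
        _, record = collapse(net, cluster_of({"a", "b"}))
        assert net.nodes == {"group:C", "e"}
        (meta,) = meta_edges(net)
        assert meta.endpoints() == {"group:C", "e"}
        assert meta.attrs["count"] == 1

    def test_no_external_edges_gives_isolated_group_node(self):
        net = simple_net([("a", "b")])
        collapse(net, cluster_of({"a", "b"}))
        assert net.nodes == {"group:C"}
        assert net.edges == []

    def test_shared_external_neighbor_deduplicated_with_count(self):
        net = simple_net([("a", "b"), ("a", "e"), ("b", "e")])
        collapse(net, cluster_of({"a", "b"}))
        (meta,) = meta_edges(net)
        assert meta.attrs["count"] == 2

    def test_group_node_named_by_label_at_centroid(self):
        net = Network()
        net.add_node("a", position=(0.0, 0.0))
        net.add_node("b", position=(10.0, 20.0))
        collapse(net, cluster_of({"a", "b"}, label="dna repair"))
        assert net.get_attr("group:C", "name") == "dna repair"
        assert net.positions["group:C"] == (5.0, 10.0)

    def test_double_collapse_rejected(self):
        net = simple_net([("a", "b")])
        cluster = cluster_of({"a", "b"})
        collapse(net, cluster)
        with pytest.raises(ValueError, match="already collapsed"):
            collapse(net, cluster)

    def test_adjacent_collapsed_clusters_share_one_meta_edge(self):
        net = simple_net([("a1", "a2"), ("b1", "b2"),
                          ("a1", "b1"), ("a2", "b2"), ("a2", "b1")])
        ca, cb = cluster_of({"a1", "a2"}, "A"), cluster_of({"b1", "b2"}, "B")
        collapse(net, ca)
        collapse(net, cb)
        (meta,) = meta_edges(net)
        assert meta.endpoints() == {"group:A", "group:B"}
        assert meta.attrs["count"] == 3


class TestExpand:
    def test_roundtrip_identity(self):
        net = simple_net([("a", "b"), ("a", "e"), ("e", "f")])
        before = net.copy()
        cluster = cluster_of({"a", "b"})
        _, record = collapse(net, cluster)
        expand(net, record, cluster)
        assert net.structurally_equal(before)
        assert cluster.collapsed is False

    def test_expand_twice_rejected(self):
        net = simple_net([("a", "b")])
        _, record = collapse(net, cluster_of({"a", "b"}))
        expand(net, record)
        with pytest.raises(ValueError, match="not present"):
            expand(net, record)

    @pytest.mark.parametrize("expand_order", [(1, 0), (0, 1)])
    def test_two_cluster_expand_in_either_order(self, expand_order):
        net = simple_net([("a1", "a2"), ("b1", "b2"), ("a1", "b1"),
                          ("a1", "e"), ("b2", "e")])
        before = net.copy()
        clusters = [cluster_of({"a1", "a2"}, "A"), cluster_of({"b1", "b2"}, "B")]
        records = [collapse(net, c)[1] for c in clusters]
        for i in expand_order:
            expand(net, records[i], clusters[i])
        assert net.structurally_equal(before)


class TestCollapseAll:
    @staticmethod
    def annotation_set(partition):
        return AnnotationSet(name="s", clusters=[
            Cluster(id=cid, members=set(m), label=f"cluster {cid}")
            for cid, m in partition.clusters.items()
        ])

    def test_node_count_after_collapse_all(self):
        rng = np.random.default_rng(0)
        net = random_attributed_network(rng)
        part = random_partition(rng, net)
        aset = self.annotation_set(part)
        n_before = len(net.nodes)
        hidden = sum(len(m) for m in part.clusters.values())
        collapse_all(net, aset)
        assert len(net.nodes) == n_before - hidden + len(part.clusters)
        assert all(c.collapsed for c in aset.clusters)

    def test_zero_clusters_is_identity(self):
        net = simple_net([("a", "b")])
        before = net.copy()
        collapse_all(net, AnnotationSet(name="s"))
        assert net.structurally_equal(before)

    @pytest.mark.parametrize("seed", range(8))
    def test_roundtrip_and_meta_edge_oracle(self, seed):
        """collapse_all/expand_all restore everything; meta-edge endpoints and
        counts match a brute-force boundary-edge scan of the original graph."""
        rng = np.random.default_rng(seed)
        net = random_attributed_network(rng)
        part = random_partition(rng, net)
        before = net.copy()
        aset = self.annotation_set(part)
        collapse_all(net, aset)

        observed = Counter()
        for e in net.edges:
            if e.attrs.get("is_meta"):
                observed[e.endpoints()] += e.attrs["count"]
        expected = expected_meta_edges(before, part)
        expected = Counter({frozenset(k): v for k, v in expected.items()})
        assert observed == expected
        # exactly one meta-edge per adjacent pair
        endpoint_pairs = [e.endpoints() for e in net.edges if e.attrs.get("is_meta")]
        assert len(endpoint_pairs) == len(set(endpoint_pairs))

        expand_all(net, aset)
        assert net.structurally_equal(before)
        assert net.positions == before.positions
        assert aset.collapse_records == {}

    def test_unclustered_nodes_untouched(self):
        net = simple_net([("a", "b"), ("u", "a")])
        aset = self.annotation_set(
            type("P", (), {"clusters": {"C": {"a", "b"}}})())
        collapse_all(net, aset)
        assert "u" in net.nodes
        assert net.get_attr("u", "desc") == "text u"


class TestManagerIntegration:
    def test_collapsed_annotations_suppressed_then_restored(self):
        net = Network()
        for i, n in enumerate(("a", "b", "c")):
            net.add_node(n, attrs={"desc": "dna repair"}, position=(float(i), 0.0))
        net.add_edge("a", "b")
        mgr = AnnotationManager(net)
        from netannotate import Partition
        aset = mgr.create_annotation_set(
            Partition(clusters={"C": {"a", "b"}}, unclustered={"c"}),
            CloudOptions(attributes=("desc",)), LabelOptions(), name="s")
        collapse_all(net, aset)
        assert aset.cluster("C").collapsed
        with pytest.raises(ValueError, match="expand"):
            mgr.set_active(None)
        expand_all(net, aset)
        mgr.set_active(None)
        assert mgr.active is None
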