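"""Annotation sets: creation, switching, edits, shape/label geometry."""

import math

import numpy as np
import pytest

from netannotate import (AnnotationManager, CloudOptions, Cluster,
                         DisplayOptions, LabelOptions, Network, Partition,
                         cluster_geometry)


@pytest.fixture
def themed_net():
    net = Network()
    texts = {
        "a1": "dna repair", "a2": "dna repair", "a3": "dna damage repair",
        "b1": "cell cycle", "b2": "cell cycle", "b3": "cell cycle arrest",
        "u1": "background noise",
    }
    for i, (node, text) in enumerate(sorted(texts.items())):
        net.add_node(node, attrs={"desc": text}, position=(10.0 * i, 5.0 * i))
    net.add_edge("a1", "a2")
    net.add_edge("b1", "b2")
    return net


@pytest.fixture
def partition():
    return Partition(clusters={"A": {"a1", "a2", "a3"}, "B": {"b1", "b2", "b3"}},
                     unclustered={"u1"})


@pytest.fixture
def manager(themed_net, partition):
    mgr = AnnotationManager(themed_net)
    mgr.create_annotation_set(partition, CloudOptions(attributes=("desc",)),
                              LabelOptions(), name="set1")
    return mgr


class TestCreateAnnotationSet:
    def test_two_labeled_clusters(self, manager):
        aset = manager.sets["set1"]
        labels = {c.id: c.label for c in aset.clusters}
        assert "repair" in labels["A"] or "dna" in labels["A"]
        assert "cell" in labels["B"] or "cycle" in labels["B"]

    def test_empty_partition_is_valid(self, themed_net):
        mgr = AnnotationManager(themed_net)
        aset = mgr.create_annotation_set(
            Partition(unclustered=set(themed_net.nodes)),
            CloudOptions(attributes=("desc",)), LabelOptions(), name="empty")
        assert aset.clusters == []

    def test_multiple_independent_sets(self, manager, partition):
        second = manager.create_annotation_set(
            partition, CloudOptions(attributes=("desc",)),
            LabelOptions(max_words=1), name="set2")
        assert set(manager.sets) == {"set1", "set2"}
        assert all(len(c.label.split()) <= 1 for c in second.clusters)

    def test_duplicate_name_rejected(self, manager, partition):
        with pytest.raises(ValueError, match="already exists"):
            manager.create_annotation_set(
                partition, CloudOptions(attributes=("desc",)),
                LabelOptions(), name="set1")

    def test_reproducible_labels(self, themed_net, partition):
        results = []
        for _ in range(2):
            mgr = AnnotationManager(themed_net)
            aset = mgr.create_annotation_set(
                partition, CloudOptions(attributes=("desc",)),
                LabelOptions(), name="x")
            results.append([(c.id, c.label) for c in aset.clusters])
        assert results[0] == results[1]


class TestSetActive:
    def test_switch_between_sets(self, manager, partition):
        manager.create_annotation_set(partition, CloudOptions(attributes=("desc",)),
                                      LabelOptions(), name="set2")
        manager.set_active("set2")
        assert manager.active.name == "set2"

    def test_collapsed_cluster_blocks_switch(self, manager):
        manager.sets["set1"].clusters[0].collapsed = True
        with pytest.raises(ValueError, match="expand"):
            manager.set_active(None)

    def test_clearing_active_set(self, manager):
        manager.set_active(None)
        assert manager.active is None

    def test_unknown_name_rejected(self, manager):
        with pytest.raises(KeyError):
            manager.set_active("nope")


class TestClusterEdits:
    def test_merge_unions_members_and_relabels(self, manager):
        aset = manager.sets["set1"]
        merged = manager.merge_clusters(aset, ["A", "B"])
        assert merged.members == {"a1", "a2", "a3", "b1", "b2", "b3"}
        assert len(aset.clusters) == 1
        assert merged.label != ""

    def test_merge_same_cluster_twice_rejected(self, manager):
        with pytest.raises(ValueError, match="duplicate"):
            manager.merge_clusters(manager.sets["set1"], ["A", "A"])

    def test_merge_needs_two_clusters(self, manager):
        with pytest.raises(ValueError, match="at least two"):
            manager.merge_clusters(manager.sets["set1"], ["A"])

    def test_selection_moves_overlap_out_of_old_cluster(self, manager):
        aset = manager.sets["set1"]
        new = manager.create_cluster_from_selection(aset, {"a1", "u1"})
        assert new.members == {"a1", "u1"}
        assert aset.cluster("A").members == {"a2", "a3"}
        aset.validate_disjoint()

    def test_selection_equal_to_existing_cluster(self, manager):
        aset = manager.sets["set1"]
        new = manager.create_cluster_from_selection(aset, {"a1", "a2", "a3"})
        assert new.members == {"a1", "a2", "a3"}
        ids = [c.id for c in aset.clusters]
        assert "A" not in ids  # emptied original dropped
        aset.validate_disjoint()

    def test_empty_selection_rejected(self, manager):
        with pytest.raises(ValueError, match="empty"):
            manager.create_cluster_from_selection(manager.sets["set1"], set())

    def test_manual_relabel_is_verbatim(self, manager):
        cluster = manager.relabel(manager.sets["set1"], "A", "cell cycle")
        assert cluster.label == "cell cycle"

    def test_recompute_after_shrinking_word_budget(self, manager):
        aset = manager.sets["set1"]
        aset.label_options = LabelOptions(max_words=1)
        cluster = manager.relabel(aset, "A", None)
        assert len(cluster.label.split()) == 1

    def test_manual_empty_label_allowed(self, manager):
        assert manager.relabel(manager.sets["set1"], "A", "").label == ""

    def test_unknown_cluster_id_rejected(self, manager):
        with pytest.raises(KeyError):
            manager.relabel(manager.sets["set1"], "Z", "x")

    @pytest.mark.parametrize("seed", range(3))
    def test_random_edit_sequences_keep_disjointness(self, manager, seed):
        rng = np.random.default_rng(seed)
        aset = manager.sets["set1"]
        nodes = sorted(manager.net.nodes)
        for _ in range(15):
            ids = [c.id for c in aset.clusters]
            if len(ids) >= 2 and rng.random() < 0.3:
                picks = rng.choice(len(ids), 2, replace=False)
                manager.merge_clusters(aset, [ids[i] for i in picks])
            else:
                k = int(rng.integers(1, 4))
                manager.create_cluster_from_selection(
                    aset, set(rng.choice(nodes, k, replace=False)))
            aset.validate_disjoint()


class TestGeometry:
    def test_single_point_padded_box(self):
        net = Network()
        net.add_node("a", position=(0.0, 0.0))
        cluster = Cluster(id=1, members={"a"}, label="x")
        shape, label = cluster_geometry(net, cluster, DisplayOptions())
        assert (shape.x, shape.y, shape.w, shape.h) == (-10, -10, 20, 20)
        assert (label.anchor_x, label.anchor_y) == (0, -10)

    def test_two_member_box(self):
        net = Network()
        net.add_node("a", position=(0.0, 0.0))
        net.add_node("b", position=(100.0, 40.0))
        cluster = Cluster(id=1, members={"a", "b"}, label="x")
        shape, _ = cluster_geometry(net, cluster, DisplayOptions())
        assert (shape.x, shape.y, shape.w, shape.h) == (-10, -10, 120, 60)

    def test_geometry_follows_moved_node(self):
        net = Network()
        net.add_node("a", position=(0.0, 0.0))
        cluster = Cluster(id=1, members={"a"}, label="x")
        before, _ = cluster_geometry(net, cluster, DisplayOptions())
        net.positions["a"] = (50.0, 0.0)
        after, _ = cluster_geometry(net, cluster, DisplayOptions())
        assert after.x == before.x + 50

    def test_missing_coordinates_block_geometry_not_labels(self):
        net = Network()
        net.add_node("a")
        cluster = Cluster(id=1, members={"a"}, label="still labeled")
        with pytest.raises(ValueError, match="coordinates"):
            cluster_geometry(net, cluster, DisplayOptions())
        assert cluster.label == "still labeled"

    def test_font_scaling_grows_with_log_member_count(self):
        net = Network()
        for i in range(10):
            net.add_node(f"n{i}", position=(float(i), 0.0))
        cluster = Cluster(id=1, members=set(net.nodes), label="x")
        display = DisplayOptions(base_font=16.0, font_scaling=True)
        _, label = cluster_geometry(net, cluster, display)
        assert label.font_size == pytest.approx(16.0 * (1 + math.log10(10)))
        display_off = DisplayOptions(base_font=16.0, font_scaling=False)
        _, label_off = cluster_geometry(net, cluster, display_off)
        assert label_off.font_size == 16.0

    def test_members_lie_inside_shape(self):
        rng = np.random.default_rng(4)
        net = Network()
        for i in range(8):
            net.add_node(f"n{i}", position=tuple(rng.normal(0, 30, 2)))
        cluster = Cluster(id=1, members=set(net.nodes), label="x")
        shape, _ = cluster_geometry(net, cluster, DisplayOptions())
        for m in cluster.members:
            x, y = net.positions[m]
            assert shape.x <= x <= shape.x + shape.w
            assert shape.y <= y <= shape.y + shape.h
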