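import numpy as np
import pandas as pd
import pytest

from fermgenomics.cloud_network import (
    build_clouds,
    build_network,
    build_ph_cloud,
    enrichment,
    export_network,
    import_network,
    partition_by_signature,
)
from fermgenomics.errors import ConfigError, ValidationError


def de_table(rows):
    """rows: gene -> (ratio, q)"""
    return pd.DataFrame(
        {"ratio": [v[0] for v in rows.values()], "q": [v[1] for v in rows.values()]},
        index=list(rows),
    )


class TestBuildClouds:
    def test_threshold_fixtures(self):
        de = de_table(
            {
                "strong_up": (2.0, 0.01),
                "weak_fold": (1.2, 0.01),
                "not_significant": (3.0, 0.2),
                "strong_down": (0.4, 0.02),
            }
        )
        clouds = build_clouds({"T": de})
        cloud = clouds["T"]
        assert set(cloud.up.index) == {"strong_up"}
        assert set(cloud.down.index) == {"strong_down"}
        assert "weak_fold" not in cloud.genes
        assert "not_significant" not in cloud.genes

    def test_fold_threshold_is_symmetric(self):
        de = de_table({"down2x": (0.5, 0.01), "down1p2": (1 / 1.2, 0.01)})
        cloud = build_clouds({"f": de})["f"]
        assert set(cloud.down.index) == {"down2x"}

    def test_fold_min_below_one_rejected(self):
        with pytest.raises(ConfigError):
            build_clouds({"f": de_table({"g": (2.0, 0.01)})}, fold_min=0.9)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_relaxing_thresholds_never_shrinks_clouds(self, seed):
        rng = np.random.default_rng(seed)
        de = de_table(
            {f"g{i}": (float(2 ** rng.normal(0, 1)), float(rng.uniform())) for i in range(200)}
        )
        tight = build_clouds({"f": de}, q_max=0.05, fold_min=2.0)["f"].genes
        loose = build_clouds({"f": de}, q_max=0.10, fold_min=1.5)["f"].genes
        assert tight <= loose


class TestPartition:
    def make_clouds(self):
        # g1,g2 respond to T only; g3 to both T and pH; g4 to pH only; g5 to pH
        de_t = de_table(
            {"g1": (2.0, 0.01), "g2": (0.4, 0.01), "g3": (2.5, 0.01),
             "g4": (1.0, 0.9), "g5": (1.0, 0.9)}
        )
        de_ph = de_table(
            {"g1": (1.0, 0.9), "g2": (1.0, 0.9), "g3": (2.0, 0.01),
             "g4": (3.0, 0.01), "g5": (0.3, 0.01)}
        )
        return build_clouds({"T": de_t, "pH": de_ph})

    def test_hand_fixture_group_sizes(self):
        groups = partition_by_signature(self.make_clouds())
        sizes = sorted(len(g) for g in groups.values())
        assert sizes == [1, 2, 2]
        assert groups[frozenset({"T", "pH"})] == ["g3"]
        assert groups[frozenset({"T"})] == ["g1", "g2"]

    def test_groups_partition_cloud_members(self):
        clouds = self.make_clouds()
        groups = partition_by_signature(clouds)
        members = [g for genes in groups.values() for g in genes]
        assert sorted(members) == sorted(set().union(*(c.genes for c in clouds.values())))
        assert len(members) == len(set(members))

    def test_single_cloud_gene_is_singleton_group(self):
        groups = partition_by_signature(self.make_clouds())
        assert frozenset({"pH"}) in groups


class TestNetworkExport:
    def make_network(self):
        return build_network(self.make_clouds())

    make_clouds = TestPartition.make_clouds

    def test_sif_round_trip(self, tmp_path):
        net = self.make_network()
        path = tmp_path / "net.sif"
        export_network(net, "SIF", path)
        again = import_network("SIF", path)
        assert set(again.nodes) == set(net.nodes)
        assert set(again.edges) == set(net.edges)
        for u, v, data in net.edges(data=True):
            assert again.edges[u, v]["direction"] == data["direction"]

    def test_graphml_round_trip_preserves_attributes(self, tmp_path):
        net = self.make_network()
        path = tmp_path / "net.graphml"
        export_network(net, "GraphML", path)
        again = import_network("GraphML", path)
        assert set(again.nodes) == set(net.nodes)
        assert set(again.edges) == set(net.edges)
        for u, v, data in net.edges(data=True):
            assert again.edges[u, v]["direction"] == data["direction"]

    def test_every_gene_node_has_an_edge(self):
        net = self.make_network()
        for node, data in net.nodes(data=True):
            if data.get("kind") == "gene":
                assert net.degree(node) >= 1

    def test_empty_network_rejected(self, tmp_path):
        import networkx as nx

        with pytest.raises(ValidationError, match="no edges"):
            export_network(nx.DiGraph(), "SIF", tmp_path / "x.sif")

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="format"):
            export_network(self.make_network(), "DOT", tmp_path / "x.dot")


class TestPhCollapse:
    def test_direction_from_widest_contrast(self):
        pairs = {
            "pH_5.2_vs_5.8": de_table({"g1": (2.0, 0.01), "g2": (1.0, 0.9)}),
            "pH_5.2_vs_6.4": de_table({"g1": (0.4, 0.2), "g2": (1.0, 0.9)}),
            "pH_5.8_vs_6.4": de_table({"g1": (1.0, 0.9), "g2": (1.0, 0.9)}),
        }
        cloud = build_ph_cloud(pairs)
        # g1 qualifies via the 5.2-vs-5.8 contrast but its direction comes
        # from the extreme 5.2-vs-6.4 ratio (0.4 -> down)
        assert set(cloud.down.index) == {"g1"}
        assert cloud.up.empty


class TestEnrichment:
    def test_closed_form_small_case(self):
        universe = [f"g{i}" for i in range(10)]
        classes = {g: ("in" if i < 5 else "out") for i, g in enumerate(universe)}
        table = enrichment({"g0", "g1", "g2"}, classes, universe)
        row = table.set_index("class").loc["in"]
        assert row["p"] == pytest.approx(10 / 120)  # C(5,3)/C(10,3)

    def test_zero_overlap_is_certain(self):
        universe = [f"g{i}" for i in range(10)]
        classes = {g: "c" for g in universe[:4]}
        table = enrichment(set(universe[4:7]), classes, universe)
        assert table.iloc[0]["p"] == pytest.approx(1.0)

    def test_full_draw_is_certain(self):
        universe = [f"g{i}" for i in range(8)]
        classes = {g: ("a" if i < 3 else "b") for i, g in enumerate(universe)}
        table = enrichment(set(universe), classes, universe)
        assert np.allclose(table["p"], 1.0)

    def test_geneset_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="universe"):
            enrichment({"alien"}, {"g1": "c"}, {"g1"})

    def test_matches_monte_carlo_resampling(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(30)]
        class_members = set(universe[:8])
        classes = {g: "c" for g in class_members}
        geneset = set(rng.choice(universe, size=10, replace=False))
        k = len(geneset & class_members)
        table = enrichment(geneset, classes, universe)
        p_exact = float(table.iloc[0]["p"])
        draws = 4000
        hits = sum(
            len(set(rng.choice(universe, size=10, replace=False)) & class_members) >= k
            for _ in range(draws)
        )
        p_mc = hits / draws
        se = np.sqrt(p_exact * (1 - p_exact) / draws)
        assert abs(p_mc - p_exact) <= 3 * se + 1e-9
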