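import numpy as np
import pandas as pd
import pytest

from inflamnet import network as net
from inflamnet.modules import ModuleDefinition


def make_interactions(rows):
    return pd.DataFrame(rows, columns=["gene1", "gene2", "confidence", "source"])


def interface_bruteforce(edges, module_of):
    """Double loop over the raw edge list: a gene is an interface gene iff it
    touches an edge whose endpoints live in different modules."""
    counts = {}
    for a, b in edges:
        if module_of[a] != module_of[b]:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
    return counts


class TestLoadInteractions:
    def test_strict_confidence_threshold(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text(
            "protein1\tprotein2\tcombined_score\nA\tB\t900\nA\tC\t901\n"
        )
        table = net.load_interactions([p])
        assert list(zip(table["gene1"], table["gene2"])) == [("A", "C")]

    def test_duplicate_pair_keeps_max(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\t910\nB\tA\t950\n")
        table = net.load_interactions([p])
        assert len(table) == 1
        assert table.iloc[0]["confidence"] == 950

    def test_unscored_pairs_get_confidence_1000(self, tmp_path):
        p = tmp_path / "pairs.txt"
        p.write_text("A\tB\nC\tD\n")
        table = net.load_interactions([p])
        assert (table["confidence"] == 1000).all()
        assert len(table) == 2

    def test_self_loops_dropped(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tA\t999\nA\tB\t999\n")
        table = net.load_interactions([p])
        assert len(table) == 1

    def test_malformed_line_reports_position(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\t950\nA\tB\tC\tD\n")
        with pytest.raises(ValueError, match=":2"):
            net.load_interactions([p])


@pytest.fixture()
def toy_setup():
    """4-gene toy: modules A = {A1, A2}, B = {B1, B2}; expression engineered
    so r(A1,B1) ~ 0.5, r(A1,A2) ~ 0.9, r(A2,B2) ~ 0.1."""
    rng = np.random.default_rng(42)
    n = 2000
    z1, z2, z3 = rng.normal(size=(3, n))

    def mix(rho, z, other):
        return rho * z + np.sqrt(1 - rho**2) * other

    a1 = z1
    a2 = mix(0.9, z1, z2)
    b1 = mix(0.5, z1, rng.normal(size=n))
    b2 = mix(0.1, a2 / a2.std(), rng.normal(size=n))
    expr = pd.DataFrame(
        [a1, a2, b1, b2],
        index=["A1", "A2", "B1", "B2"],
        columns=[f"S{i}" for i in range(n)],
    )
    interactions = make_interactions(
        [
            ("A1", "B1", 950, "t"),
            ("A1", "A2", 950, "t"),
            ("A2", "B2", 950, "t"),
        ]
    )
    mod_a = ModuleDefinition("modA", [], ["A1", "A2"])
    mod_b = ModuleDefinition("modB", [], ["B1", "B2"])
    return interactions, mod_a, mod_b, expr


class TestBuildNPNetwork:
    def test_toy_edge_filtering(self, toy_setup):
        interactions, mod_a, mod_b, expr = toy_setup
        g = net.build_np_network(interactions, mod_a, mod_b, expr, r_threshold=0.22)
        kept = {tuple(sorted(e)) for e in g.edges}
        assert kept == {("A1", "B1"), ("A1", "A2")}
        assert g.edges["A1", "B1"]["scope"] == "cross"
        assert g.edges["A1", "A2"]["scope"] == "intra"

    def test_identical_vectors_positive_edge(self):
        expr = pd.DataFrame(
            [[1.0, 2, 3, 4], [1.0, 2, 3, 4]],
            index=["A1", "B1"],
            columns=["S1", "S2", "S3", "S4"],
        )
        interactions = make_interactions([("A1", "B1", 950, "t")])
        g = net.build_np_network(
            interactions,
            ModuleDefinition("a", [], ["A1"]),
            ModuleDefinition("b", [], ["B1"]),
            expr,
        )
        assert g.edges["A1", "B1"]["sign"] == "positive"
        assert g.edges["A1", "B1"]["r"] == pytest.approx(1.0)

    def test_exact_threshold_excluded(self):
        # construct two vectors with r exactly 0.22
        x = np.array([1.0, -1.0, 1.0, -1.0])
        r = 0.22
        y = r * x + np.sqrt(1 - r**2) * np.array([1.0, 1.0, -1.0, -1.0])
        expr = pd.DataFrame([x, y], index=["A1", "B1"], columns=list("WXYZ"))
        interactions = make_interactions([("A1", "B1", 950, "t")])
        g = net.build_np_network(
            interactions,
            ModuleDefinition("a", [], ["A1"]),
            ModuleDefinition("b", [], ["B1"]),
            expr,
            r_threshold=0.22,
        )
        assert g.number_of_edges() == 0

    def test_negative_correlation_sign(self):
        expr = pd.DataFrame(
            [[1.0, 2, 3, 4], [4.0, 3, 2, 1]],
            index=["A1", "B1"],
            columns=["S1", "S2", "S3", "S4"],
        )
        interactions = make_interactions([("A1", "B1", 950, "t")])
        g = net.build_np_network(
            interactions,
            ModuleDefinition("a", [], ["A1"]),
            ModuleDefinition("b", [], ["B1"]),
            expr,
        )
        assert g.edges["A1", "B1"]["sign"] == "negative"

    def test_overlapping_modules_rejected(self, toy_setup):
        interactions, mod_a, _, expr = toy_setup
        bad = ModuleDefinition("b", [], ["A1", "B1"])
        with pytest.raises(ValueError, match="disjoint"):
            net.build_np_network(interactions, mod_a, bad, expr)

    def test_module_swap_symmetry(self, toy_setup):
        interactions, mod_a, mod_b, expr = toy_setup
        g1 = net.build_np_network(interactions, mod_a, mod_b, expr)
        g2 = net.build_np_network(interactions, mod_b, mod_a, expr)
        i1a, i1b = net.extract_interface_genes(g1)
        i2a, i2b = net.extract_interface_genes(g2)
        pd.testing.assert_frame_equal(i1a, i2b)
        pd.testing.assert_frame_equal(i1b, i2a)

    def test_threshold_monotonicity(self, toy_setup):
        interactions, mod_a, mod_b, expr = toy_setup
        edges_prev = None
        for r_thr in (0.05, 0.22, 0.5, 0.95):
            g = net.build_np_network(
                interactions, mod_a, mod_b, expr, r_threshold=r_thr
            )
            edges = {tuple(sorted(e)) for e in g.edges}
            if edges_prev is not None:
                assert edges <= edges_prev
            edges_prev = edges


class TestInterfaceGenes:
    def test_toy_interface_sets(self, toy_setup):
        interactions, mod_a, mod_b, expr = toy_setup
        g = net.build_np_network(interactions, mod_a, mod_b, expr)
        iface_a, iface_b = net.extract_interface_genes(g)
        assert list(iface_a["gene"]) == ["A1"]
        assert list(iface_b["gene"]) == ["B1"]

    def test_no_cross_edges_empty_sets(self):
        expr = pd.DataFrame(
            [[1.0, 2, 3, 4], [1.0, 2, 3, 4]],
            index=["A1", "A2"],
            columns=["S1", "S2", "S3", "S4"],
        )
        interactions = make_interactions([("A1", "A2", 950, "t")])
        g = net.build_np_network(
            interactions,
            ModuleDefinition("a", [], ["A1", "A2"]),
            ModuleDefinition("b", [], ["ZZ"]),
            expr,
        )
        iface_a, iface_b = net.extract_interface_genes(g)
        assert iface_a.empty and iface_b.empty

    def test_matches_bruteforce_on_random_networks(self):
        """Oracle equivalence on 100 random instances <= 50 nodes."""
        rng = np.random.default_rng(123)
        for trial in range(100):
            n = int(rng.integers(4, 51))
            genes = [f"G{i}" for i in range(n)]
            module_of = {
                g: ("A" if rng.random() < 0.5 else "B") for g in genes
            }
            # guarantee both modules non-empty
            module_of[genes[0]], module_of[genes[1]] = "A", "B"
            n_samples = 10
            expr = pd.DataFrame(
                rng.normal(size=(n, n_samples)),
                index=genes,
                columns=[f"S{i}" for i in range(n_samples)],
            )
            pairs = [
                (a, b)
                for i, a in enumerate(genes)
                for b in genes[i + 1 :]
                if rng.random() < 0.15
            ]
            interactions = make_interactions(
                [(a, b, 950, "t") for a, b in pairs]
            )
            mod_a = ModuleDefinition(
                "A", [], [g for g in genes if module_of[g] == "A"]
            )
            mod_b = ModuleDefinition(
                "B", [], [g for g in genes if module_of[g] == "B"]
            )
            if interactions.empty:
                continue
            g = net.build_np_network(
                interactions, mod_a, mod_b, expr, r_threshold=0.0
            )
            iface_a, iface_b = net.extract_interface_genes(g)
            got = dict(zip(iface_a["gene"], iface_a["cross_edges"]))
            got |= dict(zip(iface_b["gene"], iface_b["cross_edges"]))
            kept_edges = list(g.edges)
            expected = interface_bruteforce(kept_edges, module_of)
            assert got == expected, f"trial {trial}"


class TestNeighborhood:
    @pytest.fixture()
    def star(self):
        expr_cols = ["S1", "S2", "S3", "S4"]
        rng = np.random.default_rng(7)
        genes = ["HUB"] + [f"LEAF{i}" for i in range(5)]
        expr = pd.DataFrame(
            rng.normal(size=(6, 4)), index=genes, columns=expr_cols
        )
        # force strong correlation so all edges survive
        for g in genes[1:]:
            expr.loc[g] = expr.loc["HUB"] + rng.normal(0, 0.01, 4)
        interactions = make_interactions(
            [("HUB", leaf, 950, "t") for leaf in genes[1:]]
        )
        g = net.build_np_network(
            interactions,
            ModuleDefinition("a", [], ["HUB", "LEAF0", "LEAF1"]),
            ModuleDefinition("b", [], ["LEAF2", "LEAF3", "LEAF4"]),
            expr,
        )
        return g

    def test_star_center_order_one(self, star):
        sub = net.neighborhood(star, ["HUB"], order=1)
        assert sub.number_of_nodes() == 6

    def test_isolated_seed(self, star):
        star.add_node("LONER", module="a")
        sub = net.neighborhood(star, ["LONER"], order=1)
        assert list(sub.nodes) == ["LONER"]

    def test_absent_seed_skipped(self, star):
        sub = net.neighborhood(star, ["MISSING", "HUB"], order=1)
        assert "MISSING" not in sub
        assert sub.number_of_nodes() == 6
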