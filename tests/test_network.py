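import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sigflow as sf
from sigflow.errors import NetworkError


def idx(order, label):
    return list(order).index(label)


class TestSignedNetwork:
    def test_duplicate_ordered_pair_rejected(self):
        with pytest.raises(NetworkError, match=r"\(A, B\)"):
            sf.SignedNetwork(["A", "B"], [("A", "B", 1), ("A", "B", -1)])

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(NetworkError):
            sf.SignedNetwork(["A"], [("A", "B", 1)])

    def test_bad_sign_rejected(self):
        with pytest.raises(NetworkError):
            sf.SignedNetwork(["A", "B"], [("A", "B", 2)])

    def test_self_loop_permitted(self):
        net = sf.SignedNetwork(["A"], [("A", "A", 1)])
        assert net.n_links == 1


class TestAdjacency:
    @pytest.mark.parametrize(
        "sign,expected",
        [(1, [[0, 0], [1, 0]]), (-1, [[0, 0], [-1, 0]])],
    )
    def test_single_link_row_is_target(self, sign, expected):
        net = sf.SignedNetwork(["A", "B"], [("A", "B", sign)])
        adj = sf.build_adjacency(net)
        assert adj.matrix.tolist() == expected

    def test_no_links_gives_zero_matrix(self):
        net = sf.SignedNetwork(["A", "B", "C"], [])
        assert not sf.build_adjacency(net).matrix.any()

    def test_degree_vectors_sum_to_link_count(self):
        net = sf.make_random_network(12, n_links=30, seed=0)
        deg = sf.degree_vectors(sf.build_adjacency(net))
        assert deg.in_degree.sum() == deg.out_degree.sum() == 30


class TestNormalization:
    def test_single_link_weight_is_one(self):
        net = sf.SignedNetwork(["A", "B"], [("A", "B", 1)])
        w = sf.normalize_weights(sf.build_adjacency(net))
        assert w.matrix[1, 0] == 1.0

    def test_convergent_links_share_sqrt2(self):
        net = sf.SignedNetwork(
            ["A", "B", "C"], [("A", "C", 1), ("B", "C", 1)]
        )
        w = sf.normalize_weights(sf.build_adjacency(net))
        i = idx(w.node_order, "C")
        assert w.matrix[i, idx(w.node_order, "A")] == pytest.approx(1 / math.sqrt(2))
        assert w.matrix[i, idx(w.node_order, "B")] == pytest.approx(1 / math.sqrt(2))

    def test_two_by_two_degrees_give_half(self):
        net = sf.SignedNetwork(
            ["A", "B", "C", "D"],
            [("A", "B", 1), ("A", "C", 1), ("D", "B", 1)],
        )
        w = sf.normalize_weights(sf.build_adjacency(net))
        assert w.matrix[
            idx(w.node_order, "B"), idx(w.node_order, "A")
        ] == pytest.approx(0.5)

    @given(seed=st.integers(0, 200))
    def test_closed_form_and_sign_preservation(self, seed):
        """|W_ij| * sqrt(d_in(i) * d_out(j)) = 1 on every link; signs kept."""
        net = sf.make_random_network(15, n_links=35, fraction_negative=0.4, seed=seed)
        adj = sf.build_adjacency(net)
        w = sf.normalize_weights(adj)
        deg = sf.degree_vectors(adj)
        mask = adj.matrix != 0
        assert np.array_equal(np.sign(w.matrix), np.sign(adj.matrix))
        prods = np.abs(w.matrix[mask]) * np.sqrt(
            np.outer(deg.in_degree, deg.out_degree)[mask]
        )
        assert np.allclose(prods, 1.0, atol=1e-12)
        assert np.all(np.abs(w.matrix[mask]) <= 1.0 + 1e-12)

    def test_renormalization_guarded(self):
        net = sf.SignedNetwork(["A", "B"], [("A", "B", 1)])
        w = sf.normalize_weights(sf.build_adjacency(net))
        with pytest.raises(NetworkError, match="already normalized"):
            sf.normalize_weights(w)


class TestClassifyWeight:
    @pytest.mark.parametrize(
        "w,kind",
        [(0.5, "decay"), (-3.0, "amplification"), (1.0, "unit"), (-1.0, "unit")],
    )
    def test_kinds(self, w, kind):
        assert sf.classify_weight(w) == kind

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            sf.classify_weight(0.0)


class TestWeightMultipliers:
    def test_scales_named_link_only(self):
        net = sf.SignedNetwork(
            ["A", "B", "C", "D"],
            [("A", "B", 1), ("A", "C", 1), ("D", "B", 1)],
        )
        w = sf.normalize_weights(sf.build_adjacency(net))
        out = sf.apply_weight_multipliers(w, [("A", "B", 2.0)])
        i, j = idx(w.node_order, "B"), idx(w.node_order, "A")
        assert out.matrix[i, j] == pytest.approx(1.0)
        others = np.ones_like(w.matrix, dtype=bool)
        others[i, j] = False
        assert np.array_equal(out.matrix[others], w.matrix[others])

    def test_empty_list_is_identity(self, toy_weights):
        out = sf.apply_weight_multipliers(toy_weights, [])
        assert np.array_equal(out.matrix, toy_weights.matrix)

    def test_factor_20_amplifies_normalized_weight(self):
        net = sf.SignedNetwork(["A", "B", "C"], [("A", "B", 1), ("A", "C", 1)])
        w = sf.normalize_weights(sf.build_adjacency(net))
        out = sf.apply_weight_multipliers(w, [("A", "B", 20.0)])
        assert out.matrix[idx(w.node_order, "B"), 0] == pytest.approx(
            20 / math.sqrt(2)
        )

    def test_missing_link_and_bad_factor_rejected(self, toy_weights):
        with pytest.raises(NetworkError, match="F->A"):
            sf.apply_weight_multipliers(toy_weights, [("F", "A", 2.0)])
        with pytest.raises(ValueError):
            sf.apply_weight_multipliers(toy_weights, [("A", "B", -1.0)])

    def test_sign_preserved_under_scaling(self):
        net = sf.SignedNetwork(["A", "B"], [("A", "B", -1)])
        w = sf.normalize_weights(sf.build_adjacency(net))
        out = sf.apply_weight_multipliers(w, [("A", "B", 5.0)])
        assert out.matrix[1, 0] == -5.0


class TestNetworkIO:
    @pytest.mark.parametrize(
        "line,sign",
        [("A\tactivates\tB", 1), ("A\tinhibits\tB", -1), ("A\t+\tB", 1)],
    )
    def test_sif_tokens(self, tmp_path, line, sign):
        p = tmp_path / "net.sif"
        p.write_text(line + "\n")
        net = sf.read_network(p)
        assert net.links == (("A", "B", sign),)

    def test_tsv_signed_edge_list(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\t-1\tB\nB\t1\tC\n")
        net = sf.read_network(p)
        assert net.links == (("A", "B", -1), ("B", "C", 1))

    @pytest.mark.parametrize("fmt,suffix", [("sif", ".sif"), ("tsv", ".tsv")])
    def test_round_trip(self, tmp_path, fmt, suffix):
        net = sf.make_random_network(10, n_links=20, fraction_negative=0.5, seed=3)
        p = tmp_path / f"net{suffix}"
        sf.write_network(net, p, format=fmt)
        back = sf.read_network(p, format=fmt)
        assert set(back.links) == set(net.links)
        assert set(back.nodes) == set(net.nodes)

    def test_unknown_token_reports_line(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\t1\tB\nA\tmaybe\tC\n")
        with pytest.raises(NetworkError, match=":2"):
            sf.read_network(p)
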