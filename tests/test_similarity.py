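"""Gene-similarity construction against hand and brute-force oracles."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.sparse.csgraph import floyd_warshall
from scipy.stats import spearmanr

from snvforest.exceptions import DegenerateInputError, InputError
from snvforest.similarity import (
    SOURCES,
    build_similarity_matrix,
    cosine_similarity,
    expression_raw_similarity,
    exponential_transform,
    information_content_profile,
    shortest_path_raw_similarity,
)


class TestScalarMeasures:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ((1, 0, 1), (1, 0, 1), 1.0),
            ((1, 0), (0, 1), 0.0),
            ((1, 1, 0), (1, 0, 0), 1 / math.sqrt(2)),  # dot=1, norms 1, sqrt2
            ((0, 0), (1, 1), 0.0),  # null vector convention
        ],
    )
    def test_cosine(self, u, v, expected):
        assert cosine_similarity(u, v) == pytest.approx(expected, abs=1e-6)

    def test_cosine_dimension_mismatch(self):
        with pytest.raises(InputError):
            cosine_similarity((1, 2), (1, 2, 3))

    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (3, 2, 1), 1.0),  # anticorrelation is maximal under |r|
            ((1, 2, 3), (5, 5, 5), 0.0),  # constant profile: r undefined -> 0
        ],
    )
    def test_expression_similarity(self, u, v, expected):
        assert expression_raw_similarity(u, v) == pytest.approx(expected)

    def test_expression_needs_two_tissues(self):
        with pytest.raises(InputError):
            expression_raw_similarity((1,), (2,))


class TestInformationContent:
    def test_ubiquitous_term_has_zero_ic(self):
        ann = {f"g{i}": {"common", f"t{i}"} for i in range(5)}
        profiles = information_content_profile(ann)
        assert (profiles["common"] == 0).all()

    def test_rare_term_ic_value(self):
        ann = {f"g{i}": {"shared"} for i in range(9)}
        ann["g9"] = {"shared", "rare"}
        profiles = information_content_profile(ann)
        assert profiles.at["g9", "rare"] == pytest.approx(-math.log(0.1))

    def test_unannotated_gene_is_zero_vector(self):
        ann = {"a": {"t1"}, "b": set()}
        profiles = information_content_profile(ann)
        assert (profiles.loc["b"] == 0).all()
        assert cosine_similarity(profiles.loc["a"], profiles.loc["b"]) == 0.0

    def test_empty_corpus_rejected(self):
        with pytest.raises(InputError):
            information_content_profile({})

    def test_cosine_invariant_to_log_base(self):
        ann = {"a": {"t1", "t2"}, "b": {"t2", "t3"}, "c": {"t1"}, "d": {"t3", "t4"}}
        p_ln = information_content_profile(ann)
        p_log2 = information_content_profile(ann, base=2)
        for g, h in [("a", "b"), ("a", "c"), ("b", "d")]:
            assert cosine_similarity(p_ln.loc[g], p_ln.loc[h]) == pytest.approx(
                cosine_similarity(p_log2.loc[g], p_log2.loc[h]), abs=1e-12
            )


class TestShortestPathSimilarity:
    def test_path_graph(self):
        net = nx.path_graph(["a", "b", "c"])
        raw = shortest_path_raw_similarity(net)
        assert raw.at["a", "a"] == 1.0
        assert raw.at["a", "b"] == pytest.approx(0.5)  # d=1, D=2
        assert raw.at["a", "c"] == 0.0  # d = D = 2

    def test_disconnected_pair_is_zero(self):
        net = nx.Graph([("a", "b"), ("c", "d")])
        raw = shortest_path_raw_similarity(net)
        assert raw.at["a", "c"] == 0.0
        # diameter is 1, so adjacent pairs map to 1 - 1/1 = 0 and self-pairs stay 1
        assert raw.at["a", "b"] == 0.0
        assert raw.at["a", "a"] == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_floyd_warshall_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        g = nx.gnp_random_graph(n, 0.15, seed=seed)
        g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in range(n)})
        raw = shortest_path_raw_similarity(g)
        adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes()))
        dist = floyd_warshall(adj, unweighted=True, directed=False)
        finite = dist[np.isfinite(dist)]
        diameter = finite.max()
        expected = np.where(np.isfinite(dist), 1 - dist / max(diameter, 1), 0.0)
        np.testing.assert_allclose(raw.to_numpy(), expected, atol=1e-12)


class TestExponentialTransform:
    def test_raw_one_maps_to_one(self):
        raw = pd.DataFrame(
            [[1.0, 0.3, 0.6], [0.3, 1.0, 0.9], [0.6, 0.9, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        s, sigma = exponential_transform(raw)
        assert np.allclose(np.diag(s), 1.0)
        assert sigma > 0

    def test_matches_independent_scalar_oracle(self):
        values = {("a", "b"): 0.2, ("a", "c"): 0.5, ("b", "c"): 0.8}
        raw = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        for (g, h), r in values.items():
            raw.at[g, h] = raw.at[h, g] = r
        s, sigma = exponential_transform(raw)
        off = [r for r in values.values() for _ in range(2)]
        sigma_oracle = math.sqrt(
            sum((x - np.mean(off)) ** 2 for x in off) / len(off)
        )
        assert sigma == pytest.approx(sigma_oracle, rel=1e-12)
        for (g, h), r in values.items():
            assert s.at[g, h] == pytest.approx(math.exp((r - 1) / sigma_oracle))

    def test_constant_offdiagonal_is_degenerate(self):
        raw = pd.DataFrame(
            [[1.0, 0.5], [0.5, 1.0]], index=list("ab"), columns=list("ab")
        )
        with pytest.raises(DegenerateInputError):
            exponential_transform(raw)

    def test_preserves_ranking_of_raw_similarities(self):
        rng = np.random.default_rng(5)
        n = 8
        sym = rng.random((n, n))
        sym = (sym + sym.T) / 2
        np.fill_diagonal(sym, 1.0)
        ids = [f"g{i}" for i in range(n)]
        raw = pd.DataFrame(sym, index=ids, columns=ids)
        s, _ = exponential_transform(raw)
        mask = ~np.eye(n, dtype=bool)
        rho = spearmanr(raw.to_numpy()[mask], s.to_numpy()[mask]).statistic
        assert rho == pytest.approx(1.0)

    @given(
        r1=st.floats(0, 1, exclude_max=True),
        r2=st.floats(0, 1, exclude_max=True),
        sigma=st.floats(0.01, 2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_raw_similarity(self, r1, r2, sigma):
        s1 = math.exp((r1 - 1) / sigma)
        s2 = math.exp((r2 - 1) / sigma)
        assert (s1 - s2) * (r1 - r2) >= 0
        if abs(r1 - r2) > 1e-9:  # strict where floats can resolve it
            assert (r1 > r2) == (s1 > s2)


FIVE_GENES = ["g1", "g2", "g3", "g4", "g5"]


def _toy_source_data():
    rng = np.random.default_rng(11)
    return {
        "Exp": pd.DataFrame(
            rng.standard_normal((5, 6)), index=FIVE_GENES,
            columns=[f"t{j}" for j in range(6)],
        ),
        "GO": {
            "g1": {"go1", "go2"}, "g2": {"go2", "go3"}, "g3": {"go1"},
            "g4": {"go3", "go4"}, "g5": {"go4"},
        },
        "KEGG": {"p1": ["g1", "g2"], "p2": ["g2", "g3", "g4"], "p3": ["g5", "g1"]},
        "Seq": [("g1", "g2"), ("g2", "g3"), ("g4", "g5")],
        "Pfam": {"d1": ["g1", "g4"], "d2": ["g2", "g4", "g5"], "d3": ["g3"]},
        "PPI": [("g1", "g2"), ("g1", "g3"), ("g3", "g4")],
        "TSFC": pd.DataFrame(
            rng.poisson(2.0, size=(5, 4)).astype(float), index=FIVE_GENES,
            columns=[f"tf{j}" for j in range(4)],
        ),
        "miRNA": {"m1": ["g1", "g3", "g5"], "m2": ["g2", "g3"], "m3": ["g4"]},
    }


class TestBuildSimilarityMatrix:
    def test_identical_membership_gives_one(self):
        sets = {"p1": ["a", "b"], "p2": ["a", "b"], "p3": ["c"]}
        gsm = build_similarity_matrix("KEGG", sets)
        assert gsm.matrix.at["a", "b"] == pytest.approx(1.0)

    def test_absent_gene_is_all_zero(self):
        sets = {"p1": ["a", "b"], "p2": ["b", "c"]}
        gsm = build_similarity_matrix("KEGG", sets, gene_ids=["a", "b", "c", "zzz"])
        assert (gsm.matrix.loc["zzz"] == 0).all()
        assert (gsm.matrix["zzz"] == 0).all()

    def test_unknown_source_rejected(self):
        with pytest.raises(InputError):
            build_similarity_matrix("Phenotype", {})

    @pytest.mark.parametrize("source", SOURCES)
    def test_five_gene_fixture_matches_scalar_composition(self, source):
        """Matrix output equals the composition of the scalar operations."""
        data = _toy_source_data()[source]
        gsm = build_similarity_matrix(source, data, gene_ids=FIVE_GENES)

        # independent scalar recomputation of the raw matrix
        if source == "Exp":
            raw = {
                (g, h): expression_raw_similarity(data.loc[g], data.loc[h])
                for g in FIVE_GENES for h in FIVE_GENES if g != h
            }
        elif source == "GO":
            profiles = information_content_profile(data)
            raw = {
                (g, h): cosine_similarity(profiles.loc[g], profiles.loc[h])
                for g in FIVE_GENES for h in FIVE_GENES if g != h
            }
        elif source in ("KEGG", "Pfam", "miRNA"):
            vec = {
                g: [1.0 if g in data[name] else 0.0 for name in sorted(data)]
                for g in FIVE_GENES
            }
            raw = {
                (g, h): cosine_similarity(vec[g], vec[h])
                for g in FIVE_GENES for h in FIVE_GENES if g != h
            }
        elif source == "TSFC":
            raw = {
                (g, h): cosine_similarity(data.loc[g], data.loc[h])
                for g in FIVE_GENES for h in FIVE_GENES if g != h
            }
        else:  # Seq / PPI: raw similarities exist only over network nodes
            net = nx.Graph(data)
            nodes = sorted(net.nodes())
            oracle = shortest_path_raw_similarity(net)
            raw = {
                (g, h): oracle.at[g, h]
                for g in nodes for h in nodes if g != h
            }

        values = np.array(list(raw.values()))
        sigma = float(np.std(values))
        assert gsm.sigma == pytest.approx(sigma, rel=1e-9)
        for (g, h), r in raw.items():
            covered = gsm.matrix.at[g, g] == 1.0 and gsm.matrix.at[h, h] == 1.0
            expected = math.exp((r - 1) / sigma) if covered else 0.0
            assert gsm.matrix.at[g, h] == pytest.approx(expected, rel=1e-9), (g, h)

    def test_matrices_symmetric_and_bounded(self, small_universe):
        for source, gsm in small_universe.build_matrices().items():
            m = gsm.matrix.to_numpy()
            np.testing.assert_allclose(m, m.T, atol=1e-12, err_msg=source)
            assert (m >= 0).all() and (m <= 1 + 1e-12).all(), source
            covered = np.diag(m) == 1.0
            assert (m[covered][:, covered] > 0).all(), source
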