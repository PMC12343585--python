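"""Geometry features: closed-form examples, brute-force oracles, invariances."""

import numpy as np
import pandas as pd
import pytest

from semband.encoders import HashTokenEncoder, HashUnitEncoder
from semband.features import (EmbeddingMatrix, FEATURE_NAMES,
                              GEOMETRY_FEATURE_NAMES, compute_feature_table,
                              compute_unit_features, cumulative_distance,
                              encode_unit, hull_features, project_2d,
                              unit_vector_from_tokens, vector_norms)

from conftest import (gift_wrap_hull, hull_perimeter_oracle,
                      loop_cumulative_distance, loop_norms, shoelace_area)


def emb(rows, unit_id="u"):
    rows = np.asarray(rows, dtype=float)
    return EmbeddingMatrix(unit_id=unit_id, tokens=[f"t{i}" for i in range(len(rows))],
                           M=rows)


class OneHotEncoder:
    """Mock identity encoder: character c -> one-hot basis vector e_c."""

    def __init__(self, alphabet="abcdefghij"):
        self.alphabet = alphabet
        self.d = len(alphabet)

    def encode(self, text):
        toks = [c for c in text.strip() if not c.isspace()]
        M = np.zeros((len(toks), self.d))
        for i, c in enumerate(toks):
            M[i, self.alphabet.index(c)] = 1.0
        return toks, M


class TestEncodeUnit:
    def test_one_hot_rows_in_reading_order(self):
        M = encode_unit("abc", OneHotEncoder())
        assert M.n_tokens == 3
        expected = np.eye(10)[:3]
        np.testing.assert_array_equal(M.M, expected)

    def test_seven_characters_give_7_by_768(self):
        M = encode_unit("abcdefg", HashTokenEncoder(d=768, seed=0))
        assert M.M.shape == (7, 768)

    def test_hash_encoder_deterministic(self):
        enc = HashTokenEncoder(d=64, seed=5)
        _, a = enc.encode("xyzw")
        _, b = enc.encode("xyzw")
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("text", ["", "   "])
    def test_empty_text_rejected(self, text):
        with pytest.raises(ValueError, match="empty"):
            encode_unit(text, OneHotEncoder())


class TestCumulativeDistance:
    def test_3_4_5_triangle(self):
        M = emb([(0, 0), (3, 4)])
        assert cumulative_distance(M, "euclidean") == pytest.approx(5.0)
        assert cumulative_distance(M, "manhattan") == pytest.approx(7.0)
        assert cumulative_distance(M, "chebyshev") == pytest.approx(4.0)

    def test_cosine_orthogonal_and_antipodal(self):
        assert cumulative_distance(emb([(1, 0), (0, 1)]), "cosine") == pytest.approx(1.0)
        assert cumulative_distance(emb([(1, 0), (-1, 0)]), "cosine") == pytest.approx(2.0)

    def test_single_token_all_metrics_zero(self):
        M = emb([(2.0, 3.0)])
        for metric in ("euclidean", "cosine", "manhattan", "chebyshev"):
            assert cumulative_distance(M, metric) == 0.0

    def test_zero_norm_row_under_cosine_raises(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cumulative_distance(emb([(0, 0), (1, 1)]), "cosine")

    @pytest.mark.parametrize("metric", ["euclidean", "cosine", "manhattan", "chebyshev"])
    def test_matches_pairwise_loop_oracle(self, metric, rng):
        M = emb(rng.standard_normal((5, 768)))
        assert cumulative_distance(M, metric) == pytest.approx(
            loop_cumulative_distance(M.M, metric), abs=1e-10)

    def test_metric_chain_and_dimension_bound(self, rng):
        for _ in range(25):
            M = emb(rng.standard_normal((6, 17)))
            c = cumulative_distance(M, "chebyshev")
            e = cumulative_distance(M, "euclidean")
            m = cumulative_distance(M, "manhattan")
            assert c <= e + 1e-12 <= m + 1e-12
            assert m <= 17 * c + 1e-9

    def test_cosine_identical_directions_zero_and_bounded(self, rng):
        v = rng.standard_normal(30)
        M = emb(np.outer([1, 2, 5, 0.3], v))
        assert cumulative_distance(M, "cosine") == pytest.approx(0.0, abs=1e-12)
        A = emb(rng.standard_normal((9, 30)))
        assert cumulative_distance(A, "cosine") <= 2 * (9 - 1)


class TestUnitVectorAndNorms:
    def test_mean_of_two(self):
        uv = unit_vector_from_tokens(emb([(0, 2), (2, 0)]))
        np.testing.assert_allclose(uv.v, [1.0, 1.0])
        assert uv.provenance == "mean_of_tokens"

    def test_single_row_identity(self):
        uv = unit_vector_from_tokens(emb([(4.0, -1.0)]))
        np.testing.assert_allclose(uv.v, [4.0, -1.0])

    def test_mean_matches_loop_oracle(self, rng):
        M = emb(rng.standard_normal((7, 768)))
        oracle = np.array([sum(M.M[i, j] for i in range(7)) / 7 for j in range(768)])
        np.testing.assert_allclose(unit_vector_from_tokens(M).v, oracle, atol=1e-12)

    def test_norms_closed_form_and_zero(self):
        assert vector_norms(np.array([3.0, 4.0])) == pytest.approx((5.0, 7.0, 4.0))
        assert vector_norms(np.zeros(10)) == pytest.approx((0.0, 0.0, 0.0))

    def test_norms_match_loop_oracle(self, rng):
        v = rng.standard_normal(768)
        np.testing.assert_allclose(vector_norms(v), loop_norms(v), atol=1e-12)
        e, m, c = vector_norms(v)
        assert c <= e <= m


class TestProjection:
    def test_planted_2d_subspace_is_isometric(self, rng):
        # points live in a 2-D linear subspace of R^768: projection must
        # preserve pairwise distances
        A = rng.standard_normal((9, 2))
        R = np.linalg.qr(rng.standard_normal((768, 2)))[0].T  # 2x768 orthonormal rows
        M = emb(A @ R)
        P = project_2d(M).P
        orig = np.linalg.norm(M.M[:, None] - M.M[None, :], axis=-1)
        proj = np.linalg.norm(P[:, None] - P[None, :], axis=-1)
        np.testing.assert_allclose(proj, orig, atol=1e-8)

    def test_identical_rows_project_to_zeros(self):
        M = emb(np.tile([1.0, 2.0, 3.0], (4, 1)))
        res = project_2d(M)
        np.testing.assert_allclose(res.P, 0.0)
        assert res.degenerate

    def test_two_tokens_flagged_degenerate(self, rng):
        res = project_2d(emb(rng.standard_normal((2, 5))))
        assert res.degenerate
        assert np.allclose(res.P[:, 1], 0.0)

    def test_hull_features_invariant_to_component_sign_flips(self, rng):
        P = project_2d(emb(rng.standard_normal((10, 50)))).P
        base = hull_features(P)
        for flips in ([-1, 1], [1, -1], [-1, -1]):
            assert hull_features(P * np.array(flips)) == pytest.approx(base)


class TestHullFeatures:
    def test_unit_square(self):
        P = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], dtype=float)
        nbr, per, area = hull_features(P)
        assert (nbr, per, area) == pytest.approx((3.0, 4.0, 1.0))

    def test_collinear_points(self):
        nbr, per, area = hull_features(np.array([(0, 0), (1, 0), (2, 0)], dtype=float))
        assert (nbr, per, area) == pytest.approx((2.0, 4.0, 0.0))

    def test_degenerate_one_and_two_points(self):
        assert hull_features(np.array([[1.0, 2.0]])) == (0.0, 0.0, 0.0)
        nbr, per, area = hull_features(np.array([(0.0, 0.0), (3.0, 4.0)]))
        assert (nbr, per, area) == pytest.approx((5.0, 10.0, 0.0))

    def test_matches_gift_wrap_and_shoelace_oracle(self, rng):
        P = rng.standard_normal((10, 2))
        nbr, per, area = hull_features(P)
        hull = gift_wrap_hull(P)
        assert area == pytest.approx(shoelace_area(hull), abs=1e-10)
        assert per == pytest.approx(hull_perimeter_oracle(hull), abs=1e-10)
        assert nbr == pytest.approx(
            float(np.linalg.norm(np.diff(P, axis=0), axis=1).sum()))

    def test_perimeter_bounded_by_closed_reading_tour_in_convex_position(self, rng):
        # for points in convex position, hull perimeter <= any closed tour
        ang = np.sort(rng.uniform(0, 2 * np.pi, 8))
        P = np.column_stack([np.cos(ang), np.sin(ang)])
        order = rng.permutation(8)
        tour = P[order]
        closed = float(np.linalg.norm(np.diff(np.vstack([tour, tour[:1]]), axis=0),
                                      axis=1).sum())
        _, per, _ = hull_features(P)
        assert per <= closed + 1e-12


class TestScalingLaws:
    def test_positive_scaling(self, rng):
        M = emb(rng.standard_normal((8, 40)))
        c = 3.7
        Mc = emb(c * M.M)
        for metric in ("euclidean", "manhattan", "chebyshev"):
            assert cumulative_distance(Mc, metric) == pytest.approx(
                c * cumulative_distance(M, metric))
        assert cumulative_distance(Mc, "cosine") == pytest.approx(
            cumulative_distance(M, "cosine"), abs=1e-10)
        n1, p1, a1 = hull_features(project_2d(M))
        n2, p2, a2 = hull_features(project_2d(Mc))
        assert (n2, p2, a2) == pytest.approx((c * n1, c * p1, c * c * a1))
        np.testing.assert_allclose(
            vector_norms(unit_vector_from_tokens(Mc)),
            c * np.array(vector_norms(unit_vector_from_tokens(M))))

    def test_hull_area_bounded_by_bounding_box(self, rng):
        P = project_2d(emb(rng.standard_normal((12, 64)))).P
        _, _, area = hull_features(P)
        box = np.prod(P.max(axis=0) - P.min(axis=0))
        assert area <= box + 1e-12


class TestComposition:
    def test_one_token_unit_all_degenerate(self):
        uf = compute_unit_features("a", OneHotEncoder(), HashUnitEncoder(d=10, seed=0))
        assert uf.n_tokens == 1
        for f in ("total_euclidean", "total_cosine", "total_manhattan",
                  "total_chebyshev", "hull_neighbor_sum", "hull_perimeter",
                  "hull_area"):
            assert getattr(uf, f) == 0.0
        # norms of the single token's vector (one-hot): L2 = L1 = Linf = 1
        assert (uf.norm_euclid_tok, uf.norm_manhattan_tok,
                uf.norm_chebyshev_tok) == pytest.approx((1.0, 1.0, 1.0))

    def test_fields_equal_suboperation_values(self):
        tok = HashTokenEncoder(d=48, seed=3)
        unit = HashUnitEncoder(d=48, seed=4)
        text = "abcdefg"
        uf = compute_unit_features(text, tok, unit)
        M = encode_unit(text, tok)
        assert uf.total_euclidean == cumulative_distance(M, "euclidean")
        assert uf.total_cosine == cumulative_distance(M, "cosine")
        assert uf.norm_euclid_tok == vector_norms(unit_vector_from_tokens(M))[0]
        assert uf.norm_manhattan_unit == vector_norms(unit.encode_unit(text))[1]
        nbr, per, area = hull_features(project_2d(M))
        assert (uf.hull_neighbor_sum, uf.hull_perimeter, uf.hull_area) == (nbr, per, area)

    def test_batch_has_one_complete_row_per_unit(self):
        units = pd.DataFrame({"unit_id": [f"u{i}" for i in range(6)],
                              "text": ["abc", "de", "fgh", "ij", "abcde", "fa"]})
        table = compute_feature_table(units, HashTokenEncoder(d=32, seed=0),
                                      HashUnitEncoder(d=32, seed=1))
        assert len(table) == 6
        geometry = table[list(GEOMETRY_FEATURE_NAMES)]
        assert not geometry.isna().any().any()
        assert list(table["unit_id"]) == [f"u{i}" for i in range(6)]

    def test_feature_name_registry(self):
        assert len(FEATURE_NAMES) == 14
        assert FEATURE_NAMES[-1] == "cumulative_surprisal"
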