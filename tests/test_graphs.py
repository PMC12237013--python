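"""Standardization, k-NN / heterogeneous / patient graphs, encodings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cbcgraph.cohort import BLOOD_PARAMETERS, FEATURES
from cbcgraph.graphs import (CohortStandardizer, add_positional_encoding,
                             assign_bins, build_hetero_similarity_graph,
                             build_knn_similarity_graph, build_patient_graph,
                             compute_percentile_bins, split_masks)
from oracles import knn_neighbors


class TestStandardizer:
    def test_fit_split_has_zero_mean_unit_sd(self, small_cohort):
        std = CohortStandardizer().fit(small_cohort, split="train")
        X = std.transform(small_cohort[small_cohort["split"] == "train"])
        assert np.abs(X.mean(axis=0)).max() < 1e-8
        assert np.abs(X.std(axis=0) - 1).max() < 1e-8

    def test_simple_values(self):
        df = pd.DataFrame({f: [1.0, 2.0, 3.0] for f in FEATURES})
        std = CohortStandardizer().fit(df)
        assert std.mean_[0] == pytest.approx(2.0)
        row = pd.DataFrame({f: [2.0] for f in FEATURES})
        assert np.allclose(std.transform(row), 0.0)

    def test_apply_to_external_without_refit(self, small_cohort):
        std = CohortStandardizer().fit(small_cohort, split="train")
        ext = small_cohort[small_cohort["split"] == "external_test"]
        X = std.transform(ext)
        assert np.isfinite(X).all()
        # refit on external would change the parameters; transform must not
        assert std.fit_split_ == "train"

    def test_inverse_round_trip(self, small_cohort):
        std = CohortStandardizer().fit(small_cohort)
        X = std.transform(small_cohort)
        back = std.inverse_transform(X)
        raw = small_cohort[FEATURES].to_numpy(dtype=float)
        assert np.abs(back - raw).max() < 1e-10

    def test_constant_feature_error_names_it(self, small_cohort):
        df = small_cohort.copy()
        df["mcv"] = 90.0
        with pytest.raises(ValueError, match="mcv"):
            CohortStandardizer().fit(df)


class TestKNN:
    def test_three_point_line(self):
        X = np.array([[0.0], [1.0], [10.0]])
        g = build_knn_similarity_graph(X, k=1)
        assert set(map(tuple, g.edges)) == {(1, 0), (0, 1), (1, 2)}

    def test_k_equals_n_minus_1_is_complete(self, rng):
        X = rng.normal(size=(6, 3))
        g = build_knn_similarity_graph(X, k=5)
        assert set(map(tuple, g.edges)) == {
            (u, v) for u in range(6) for v in range(6) if u != v}

    def test_duplicate_points_tie_break_by_index(self):
        X = np.zeros((4, 2))
        g1 = build_knn_similarity_graph(X, k=2)
        g2 = build_knn_similarity_graph(X, k=2)
        assert np.array_equal(g1.edges, g2.edges)
        # ties resolved toward lower node index
        sources_of_3 = sorted(g1.edges[g1.edges[:, 1] == 3][:, 0])
        assert sources_of_3 == [0, 1]

    def test_k_too_large_connects_all(self, rng):
        X = rng.normal(size=(4, 2))
        g = build_knn_similarity_graph(X, k=10)
        assert len(g.edges) == 4 * 3

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            build_knn_similarity_graph(np.zeros((1, 2)), k=1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(3, 60), st.integers(1, 6), st.integers(0, 10_000))
    def test_neighbourhoods_match_bruteforce(self, n, k, seed):
        rng = np.random.default_rng(seed)
        X = np.round(rng.normal(size=(n, 3)), 2)  # rounding induces ties
        g = build_knn_similarity_graph(X, k=k)
        expect = knn_neighbors(X, min(k, n - 1))
        for v in range(n):
            got = sorted(g.edges[g.edges[:, 1] == v][:, 0])
            assert len(got) == min(k, n - 1)
            assert got == sorted(expect[v])


class TestPercentileBins:
    def test_deciles_of_1_to_100(self):
        bins = compute_percentile_bins(np.arange(1, 101), m=10)
        assert [b.upper_percentile for b in bins] == pytest.approx(
            [i / 10 for i in range(1, 11)])
        assert assign_bins([5], bins)[0] == 0
        assert assign_bins([95], bins)[0] == 9

    def test_m_one_rejected(self):
        with pytest.raises(ValueError):
            compute_percentile_bins(np.arange(10), m=1)

    def test_terciles_of_1_to_9(self):
        values = np.arange(1, 10)
        bins = compute_percentile_bins(values, m=3)
        member = assign_bins(values, bins)
        assert list(member) == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_bins_partition_range(self, rng):
        v = rng.normal(size=200)
        bins = compute_percentile_bins(v, m=10)
        assert bins[0].lower_value == pytest.approx(v.min())
        assert bins[-1].upper_value == pytest.approx(v.max())
        for a, b in zip(bins, bins[1:]):
            assert a.upper_value == pytest.approx(b.lower_value)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError, match="m"):
            compute_percentile_bins([1.0, 1.0, 2.0], m=3)

    def test_out_of_range_clamps(self):
        bins = compute_percentile_bins(np.arange(1, 101), m=10)
        assert assign_bins([-50], bins)[0] == 0
        assert assign_bins([1e6], bins)[0] == 9


class TestHeteroGraph:
    def test_default_m_gives_ten_bins_per_parameter(self, small_cohort):
        h = build_hetero_similarity_graph(small_cohort, m=10)
        for p in BLOOD_PARAMETERS:
            assert h.bin_features[p].shape == (10, 3)

    def test_every_measurement_has_bin_degree_five(self, small_cohort):
        h = build_hetero_similarity_graph(small_cohort, m=10)
        assert (h.measurement_bin_degree() == 5).all()

    def test_identical_measurements_share_bins(self, small_cohort):
        df = small_cohort.copy().reset_index(drop=True)
        df.loc[1, BLOOD_PARAMETERS] = df.loc[0, BLOOD_PARAMETERS]
        h = build_hetero_similarity_graph(df, m=5)
        for p in BLOOD_PARAMETERS:
            e = h.edges[("measurement", p)]
            assert e[e[:, 0] == 0, 1] == e[e[:, 0] == 1, 1]

    def test_toy_memberships_match_quantile_oracle(self, small_cohort):
        train = small_cohort[small_cohort["split"] == "train"]
        h = build_hetero_similarity_graph(small_cohort, m=3)
        for p in BLOOD_PARAMETERS:
            v = train[p].to_numpy(dtype=float)
            qs = np.quantile(v, [1 / 3, 2 / 3])
            e = h.edges[("measurement", p)]
            member = dict(zip(e[:, 0], e[:, 1]))
            for i, x in enumerate(small_cohort[p]):
                expect = int(np.clip(np.searchsorted(qs, x, side="left"),
                                     0, 2))
                assert member[i] == expect

    def test_edges_go_both_directions(self, small_cohort):
        h = build_hetero_similarity_graph(small_cohort, m=4)
        for p in BLOOD_PARAMETERS:
            fwd = h.edges[("measurement", p)]
            rev = h.edges[(p, "measurement")]
            assert np.array_equal(fwd, rev[:, ::-1])


class TestPatientGraphs:
    def test_five_measurements_directed_has_ten_arcs(self):
        rows = [("P", i, 60, 0, 8.5, 4.5, 7.0, 90.0, 250.0, 0, "train")
                for i in range(1, 6)]
        from cbcgraph.cohort import COHORT_COLUMNS
        df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
        std = _loose_standardizer(df)
        g = build_patient_graph(df, mode="directed", standardizer=std)
        assert len(g.edges) == 10

    def test_singleton_patient_has_no_arcs(self, toy_cohort):
        singleton = toy_cohort[toy_cohort["patient_id"] == "A"]
        std = _loose_standardizer(toy_cohort)
        for mode in ("directed", "reversed", "undirected"):
            g = build_patient_graph(singleton, mode=mode, standardizer=std)
            assert len(g.edges) == 0

    def test_undirected_closed_under_reversal(self, small_cohort):
        g = build_patient_graph(small_cohort, mode="undirected")
        arcs = set(map(tuple, g.edges))
        assert arcs == {(v, u) for (u, v) in arcs}

    @pytest.mark.parametrize("mode,factor", [
        ("directed", 0.5), ("reversed", 0.5), ("undirected", 1.0)])
    def test_arc_counts_closed_form(self, small_cohort, mode, factor):
        g = build_patient_graph(small_cohort, mode=mode)
        sizes = small_cohort.groupby("patient_id").size().to_numpy()
        assert len(g.edges) == int(sum(n * (n - 1) * factor for n in sizes))

    def test_direction_semantics(self, toy_cohort):
        std = _loose_standardizer(toy_cohort)
        b = toy_cohort[toy_cohort["patient_id"] == "B"].reset_index(drop=True)
        directed = build_patient_graph(b, mode="directed", standardizer=std)
        # past -> present: source position < target position
        pos = b["position"].to_numpy()
        assert all(pos[u] < pos[v] for u, v in directed.edges)
        reverse = build_patient_graph(b, mode="reversed", standardizer=std)
        assert all(pos[u] > pos[v] for u, v in reverse.edges)

    def test_no_arc_crosses_patients(self, small_cohort):
        g = build_patient_graph(small_cohort, mode="undirected")
        pid = small_cohort["patient_id"].to_numpy()
        assert all(pid[u] == pid[v] for u, v in g.edges)

    def test_unknown_mode_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            build_patient_graph(small_cohort, mode="sideways")


class TestPositionalEncoding:
    def test_default_scheme_is_monotone_in_position(self, small_cohort):
        g = build_patient_graph(small_cohort, mode="reversed")
        g2 = add_positional_encoding(g, small_cohort, scheme="linear")
        assert g2.n_features == g.n_features + 1
        pos = small_cohort["position"].to_numpy()
        enc = g2.node_features[:, -1]
        order = np.argsort(pos, kind="stable")
        assert (np.diff(enc[order]) >= 0).all()
        assert enc[pos == pos.max()][0] > enc[pos == 1][0]

    def test_none_scheme_is_identity(self, small_cohort):
        g = build_patient_graph(small_cohort, mode="directed")
        assert add_positional_encoding(g, small_cohort, scheme="none") is g

    def test_equal_positions_equal_encodings(self, small_cohort):
        g = build_patient_graph(small_cohort, mode="directed")
        g2 = add_positional_encoding(g, small_cohort, scheme="linear")
        enc = g2.node_features[:, -1]
        pos = small_cohort["position"].to_numpy()
        for p in np.unique(pos):
            assert np.unique(enc[pos == p]).size == 1

    def test_unknown_scheme_rejected(self, small_cohort):
        g = build_patient_graph(small_cohort, mode="directed")
        with pytest.raises(ValueError):
            add_positional_encoding(g, small_cohort, scheme="fourier")

    def test_sinusoidal_appends_channels(self, small_cohort):
        g = build_patient_graph(small_cohort, mode="directed")
        g2 = add_positional_encoding(g, small_cohort, scheme="sinusoidal",
                                     dim=4)
        assert g2.n_features == g.n_features + 5


class TestSerialization:
    def test_save_load_round_trip(self, small_cohort, tmp_path):
        std = CohortStandardizer().fit(small_cohort)
        g = build_knn_similarity_graph(
            std.transform(small_cohort), k=3,
            labels=small_cohort["label"].to_numpy(),
            masks=split_masks(small_cohort))
        g.save(tmp_path / "g")
        from cbcgraph.graphs import Graph
        back = Graph.load(tmp_path / "g")
        assert np.allclose(back.node_features, g.node_features)
        assert np.array_equal(back.edges, g.edges)
        assert np.array_equal(back.labels, g.labels)
        for tag, m in g.masks.items():
            assert np.array_equal(back.masks[tag], m)


def _loose_standardizer(df):
    """Standardizer fitted on all rows (toy frames lack a train split or
    vary too little for split fitting)."""
    std = CohortStandardizer()
    X = df[FEATURES].to_numpy(dtype=float)
    std.mean_ = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    std.scale_ = scale
    std.fit_split_ = "all"
    return std
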