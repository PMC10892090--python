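"""Cosine scoring, spectrum merging, network construction and bioactivity mapping."""

import json

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phytoactive import (
    BioactivityVector,
    FeatureMatrix,
    MsmsSpectrum,
    NetworkParams,
    SyntheticConfig,
    build_network,
    cosine_score,
    export_graphml,
    generate_dataset,
    map_bioactivity,
    merge_identical,
    read_graphml,
)


def spec(sid, pmz, frags, mode="NEG"):
    return MsmsSpectrum(spectrum_id=sid, precursor_mz=pmz, ion_mode=mode, fragments=frags)


@pytest.fixture()
def family():
    """Three spectra sharing 7 fragments with similar intensities."""
    base = [(100.0 + 10 * k, 1.0) for k in range(7)]
    return [
        spec("a", 400.0, base + [(300.0, 0.05)]),
        spec("b", 412.3, base + [(310.0, 0.05)]),
        spec("c", 425.1, base + [(320.0, 0.05)]),
    ]


class TestCosineScore:
    def test_self_similarity_is_exactly_one(self, small_dataset):
        for s in small_dataset.spectra[:5]:
            score, n = cosine_score(s, s)
            assert score == pytest.approx(1.0, abs=1e-12)
            assert n == len(s.fragments)

    def test_disjoint_spectra_score_zero(self):
        s1 = spec("x", 400.0, [(100.0, 1.0), (110.0, 2.0)])
        s2 = spec("y", 400.0, [(105.0, 1.0), (115.0, 2.0)])
        score, n = cosine_score(s1, s2, NetworkParams(use_modified_cosine=False))
        assert score == 0.0 and n == 0

    def test_hand_computed_half_overlap(self):
        # dot = 1 over ||(1,1)||*||(1,1)|| = 0.5, one matched pair
        s1 = spec("x", 400.0, [(100.0, 1.0), (200.0, 1.0)])
        s2 = spec("y", 400.0, [(100.0, 1.0), (300.0, 1.0)])
        score, n = cosine_score(s1, s2, NetworkParams(use_modified_cosine=False))
        assert score == pytest.approx(0.5, abs=1e-12)
        assert n == 1

    def test_symmetric(self, family):
        params = NetworkParams()
        for a in family:
            for b in family:
                sab = cosine_score(a, b, params)
                sba = cosine_score(b, a, params)
                assert sab[0] == pytest.approx(sba[0], abs=1e-12)
                assert sab[1] == sba[1]

    def test_modified_cosine_pairs_precursor_shifted_peaks(self):
        # analogue pair: same fragments shifted by the precursor difference
        delta = 14.0157  # CH2
        s1 = spec("x", 400.0, [(100.0, 1.0), (150.0, 1.0), (200.0, 1.0)])
        s2 = spec(
            "y", 400.0 + delta,
            [(100.0 + delta, 1.0), (150.0 + delta, 1.0), (200.0 + delta, 1.0)],
        )
        classic, _ = cosine_score(s1, s2, NetworkParams(use_modified_cosine=False))
        modified, n = cosine_score(s2, s1, NetworkParams(use_modified_cosine=True))
        assert classic == 0.0
        assert modified == pytest.approx(1.0, abs=1e-12)
        assert n == 3

    def test_greedy_never_exceeds_exact_assignment(self, small_dataset):
        spectra = small_dataset.spectra[:10]
        greedy = NetworkParams()
        exact = NetworkParams(exact_matching=True)
        for i in range(len(spectra)):
            for j in range(i + 1, len(spectra)):
                g, _ = cosine_score(spectra[i], spectra[j], greedy)
                e, _ = cosine_score(spectra[i], spectra[j], exact)
                assert g <= e + 1e-12

    def test_greedy_equals_exact_on_unambiguous_family(self, family):
        for i in range(3):
            for j in range(i + 1, 3):
                g, _ = cosine_score(family[i], family[j], NetworkParams())
                e, _ = cosine_score(family[i], family[j], NetworkParams(exact_matching=True))
                assert g == pytest.approx(e, abs=1e-12)


class TestMergeIdentical:
    def test_exact_duplicates_collapse(self, family):
        dup = [family[0], family[0], family[1]]
        merged = merge_identical(dup)
        assert len(merged) == 2

    def test_distinct_spectra_untouched(self):
        s1 = spec("x", 400.0, [(100.0, 1.0)] )
        s2 = spec("y", 500.0, [(105.0, 1.0)])
        assert len(merge_identical([s1, s2])) == 2

    def test_three_copies_plus_one(self, family):
        distinct = spec("z", 700.0, [(500.0, 1.0), (510.0, 1.0)])
        merged = merge_identical([family[0]] * 3 + [distinct])
        assert len(merged) == 2
        # oracle: brute-force pairwise check on the merged list
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                score, _ = cosine_score(merged[i], merged[j])
                assert score < 0.95


class TestBuildNetwork:
    def test_family_forms_single_component(self, family):
        net = build_network(family, NetworkParams(min_matched_peaks=6))
        assert net.components == [["a", "b", "c"]]
        assert net.n_edges == 3

    def test_cutoff_one_and_distinct_spectra(self):
        s1 = spec("x", 400.0, [(100.0, 1.0), (110.0, 1.0)])
        s2 = spec("y", 500.0, [(130.0, 1.0), (140.0, 1.0)])
        net = build_network([s1, s2], NetworkParams(cosine_cutoff=1.0, use_modified_cosine=False))
        assert net.n_edges == 0

    def test_every_edge_meets_both_thresholds(self, small_dataset):
        params = NetworkParams()
        net = build_network(small_dataset.spectra, params)
        for _, _, attrs in net.graph.edges(data=True):
            assert attrs["cosine"] >= params.cosine_cutoff
            assert attrs["n_matched"] >= params.min_matched_peaks

    def test_components_match_union_find_oracle(self, small_dataset):
        net = build_network(small_dataset.spectra)
        # independent union-find over the kept edge list
        parent = {n: n for n in net.graph.nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v in net.graph.edges:
            parent[find(u)] = find(v)
        groups = {}
        for n in net.graph.nodes:
            groups.setdefault(find(n), set()).add(n)
        oracle = sorted([sorted(g) for g in groups.values()], key=lambda c: (-len(c), c))
        assert net.components == oracle

    def test_synthetic_families_recovered(self):
        ds = generate_dataset(SyntheticConfig(n_features=150, seed=21))
        net = build_network(ds.spectra)
        # every generated family (>= 3 members) appears as one cluster
        assert len(net.clusters) == 6
        assert all(len(c) >= 3 for c in net.clusters)
        # singletons have degree zero
        singles = [n for n in net.graph.nodes if n.startswith("single")]
        assert all(net.graph.degree(n) == 0 for n in singles)

    def test_empty_spectrum_list(self):
        net = build_network([])
        assert net.n_nodes == 0 and net.components == []


class TestMapBioactivity:
    def make_matrix(self, values, fids):
        n = len(values)
        df = pd.DataFrame(
            np.array(values), index=[f"A{i+1}" for i in range(n)], columns=fids
        )
        return FeatureMatrix(df, ion_mode="NEG")

    def test_single_fraction_single_slice(self):
        m = self.make_matrix([[100.0], [0.0], [0.0]], ["1.00_400.0000"])
        v = BioactivityVector(["A1", "A2", "A3"], np.array([110.0, 60.0, 20.0]))
        s = spec("n1", 400.0, [(100.0, 1.0)])
        s.retention_min = 1.0
        net = build_network([s])
        net = map_bioactivity(net, m, v)
        slices = json.loads(net.graph.nodes["n1"]["slices"])
        assert slices == {
            "A1": {"weight": 1.0, "viability_pct": 110.0, "bin": "full"}
        }

    def test_equal_intensities_equal_slices(self):
        m = self.make_matrix(
            [[5.0], [5.0], [5.0], [5.0]], ["1.00_400.0000"]
        )
        v = BioactivityVector(
            ["A1", "A2", "A3", "A4"], np.array([100.0, 75.0, 50.0, 25.0])
        )
        s = spec("n1", 400.0, [(100.0, 1.0)])
        s.retention_min = 1.0
        net = map_bioactivity(build_network([s]), m, v)
        slices = json.loads(net.graph.nodes["n1"]["slices"])
        assert all(d["weight"] == pytest.approx(0.25) for d in slices.values())
        bins = {f: d["bin"] for f, d in slices.items()}
        assert bins == {"A1": "full", "A2": "partial", "A3": "partial", "A4": "low"}

    def test_unmatched_node_flagged_not_rejected(self):
        m = self.make_matrix([[5.0], [5.0], [5.0]], ["1.00_400.0000"])
        v = BioactivityVector(["A1", "A2", "A3"], np.array([50.0, 50.0, 50.0]))
        s = spec("n1", 900.0, [(100.0, 1.0)])
        net = map_bioactivity(build_network([s]), m, v)
        assert net.graph.nodes["n1"]["unmapped"] is True

    def test_spike_majority_weight_in_top_viability_bin(self):
        ds = generate_dataset(SyntheticConfig(n_features=150, seed=4, noise_sd=2.0))
        net = build_network(ds.spectra)
        net = map_bioactivity(net, ds.matrix, ds.viability)
        # spike features sit where the family elutes = high-viability fractions
        spike_nodes = [
            n for n in net.graph.nodes
            if any(n.endswith(s.feature_id) for s in ds.spikes)
            and not net.graph.nodes[n].get("unmapped", True)
        ]
        assert spike_nodes
        for n in spike_nodes:
            slices = json.loads(net.graph.nodes[n]["slices"])
            w_by_v = sorted(
                ((d["viability_pct"], d["weight"]) for d in slices.values()),
                reverse=True,
            )
            top_half = sum(w for _, w in w_by_v[: max(1, len(w_by_v) // 2)])
            assert top_half > 0.5

    def test_weights_sum_to_one(self, small_dataset):
        net = build_network(small_dataset.spectra)
        net = map_bioactivity(net, small_dataset.matrix, small_dataset.viability)
        mapped = 0
        for _, attrs in net.graph.nodes(data=True):
            if not attrs.get("unmapped", True):
                slices = json.loads(attrs["slices"])
                assert sum(d["weight"] for d in slices.values()) == pytest.approx(1.0)
                mapped += 1
        assert mapped > 0


class TestGraphmlRoundTrip:
    def test_empty_network(self, tmp_path):
        net = build_network([])
        path = tmp_path / "empty.graphml"
        export_graphml(net, path)
        back = read_graphml(path)
        assert back.n_nodes == 0

    def test_family_round_trip(self, tmp_path, family):
        net = build_network(family)
        path = tmp_path / "fam.graphml"
        export_graphml(net, path)
        back = read_graphml(path)
        assert back.n_nodes == 3 and back.n_edges == 3
        for u, v, attrs in net.graph.edges(data=True):
            battrs = back.graph.edges[u, v]
            assert battrs["cosine"] == pytest.approx(attrs["cosine"])
            assert battrs["n_matched"] == attrs["n_matched"]

    def test_attributes_survive(self, tmp_path, small_dataset):
        net = build_network(small_dataset.spectra)
        net = map_bioactivity(net, small_dataset.matrix, small_dataset.viability)
        path = tmp_path / "net.graphml"
        export_graphml(net, path)
        back = read_graphml(path)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        for n, attrs in net.graph.nodes(data=True):
            if "slices" in attrs:
                assert json.loads(back.graph.nodes[n]["slices"]) == json.loads(
                    attrs["slices"]
                )
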