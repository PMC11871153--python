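import numpy as np
import pytest

from leadgraph import (
    AugmentationGraph,
    Cohort,
    WaveformRecord,
    estimate_graph,
    lead_correlation,
    load_graph,
    save_graph,
)

from conftest import graph_brute, pearson_brute, random_cohort


class TestLeadCorrelation:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=37)
        assert lead_correlation(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip(self, rng):
        x = rng.normal(size=37)
        assert lead_correlation(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_hand_worked_triplet(self):
        x = np.array([1.0, 0.0, -1.0])
        y = np.array([-1.0, 0.0, 1.0])
        assert lead_correlation(x, y) == pytest.approx(-1.0)
        assert lead_correlation(x, x) == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_pairs(self, rng):
        for _ in range(20):
            x = rng.normal(size=25)
            y = rng.normal(size=25)
            assert lead_correlation(x, y) == pytest.approx(
                pearson_brute(list(x), list(y)), abs=1e-12
            )

    def test_constant_input_returns_zero(self, rng):
        assert lead_correlation(np.ones(10), rng.normal(size=10)) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            lead_correlation(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError, match="2 samples"):
            lead_correlation(np.zeros(1), np.zeros(1))

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(50):
            x = rng.normal(size=8) * rng.uniform(0.1, 100)
            y = rng.normal(size=8) * rng.uniform(0.1, 100)
            assert -1.0 - 1e-12 <= lead_correlation(x, y) <= 1.0 + 1e-12


class TestEstimateGraph:
    def test_duplicate_lead_gives_unit_edge(self, rng):
        records = []
        for k in range(4):
            base = rng.normal(size=30)
            sig = np.stack([base, base, rng.normal(size=30)])
            records.append(WaveformRecord(sig, ("a", "b", "c"), 1.0, f"r{k}"))
        g = estimate_graph(Cohort(records=records), split=None)
        assert g.weights[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diag(g.weights) == 0)

    def test_single_record_hand_worked(self):
        sig = np.array([[1.0, 0, -1], [1, 0, -1], [-1, 0, 1]])
        rec = WaveformRecord(sig, ("a", "b", "c"), 1.0, "r0")
        g = estimate_graph(Cohort(records=[rec]), split=None)
        expected = np.array([[0.0, 1, -1], [1, 0, -1], [-1, -1, 0]])
        np.testing.assert_allclose(g.weights, expected, atol=1e-12)

    def test_matches_bruteforce_average(self):
        cohort = random_cohort(n_records=30, L=4, T=25, seed=9)
        g = estimate_graph(cohort, split=None)
        np.testing.assert_allclose(g.weights, graph_brute(cohort), atol=1e-9)

    def test_constant_lead_records_excluded_per_pair(self, rng):
        """A record with one flat lead drops out of that lead's pairs only."""
        good = [
            WaveformRecord(rng.normal(size=(3, 20)), ("a", "b", "c"), 1.0, f"g{k}")
            for k in range(3)
        ]
        flat = rng.normal(size=(3, 20))
        flat[0] = 5.0
        bad = WaveformRecord(flat, ("a", "b", "c"), 1.0, "flat")
        g = estimate_graph(Cohort(records=good + [bad]), split=None)
        brute_good_only = graph_brute(Cohort(records=good))
        brute_all = graph_brute(Cohort(records=good + [bad]))
        assert g.weights[0, 1] == pytest.approx(brute_good_only[0, 1], abs=1e-9)
        assert g.weights[1, 2] == pytest.approx(brute_all[1, 2], abs=1e-9)

    def test_all_excluded_pair_is_zero(self):
        sig = np.array([[1.0, 1, 1], [0, 1, 2]])
        rec = WaveformRecord(sig, ("a", "b"), 1.0, "r")
        g = estimate_graph(Cohort(records=[rec]), split=None)
        assert g.weights[0, 1] == 0.0

    def test_permutation_equivariance(self):
        cohort = random_cohort(n_records=10, L=4, T=30, seed=2)
        g = estimate_graph(cohort, split=None)
        perm = [2, 0, 3, 1]
        names = cohort.lead_names
        permuted = Cohort(records=[
            WaveformRecord(r.signal[perm], tuple(names[i] for i in perm),
                           r.sampling_rate, r.record_id, r.labels)
            for r in cohort.records
        ])
        gp = estimate_graph(permuted, split=None)
        np.testing.assert_allclose(gp.weights, g.weights[np.ix_(perm, perm)], atol=1e-12)

    def test_scale_invariance(self):
        cohort = random_cohort(n_records=8, L=3, T=30, seed=4)
        g = estimate_graph(cohort, split=None)
        scaled = Cohort(records=[
            WaveformRecord(r.signal * np.array([[3.0], [0.01], [250.0]]),
                           r.lead_names, r.sampling_rate, r.record_id, r.labels)
            for r in cohort.records
        ])
        gs = estimate_graph(scaled, split=None)
        np.testing.assert_allclose(gs.weights, g.weights, atol=1e-12)

    def test_uses_requested_split_only(self):
        from leadgraph import split_cohort

        cohort = split_cohort(random_cohort(n_records=40, seed=6), (0.5, 0.25, 0.25), seed=1)
        g = estimate_graph(cohort, split="train")
        assert g.n_records == 20
        assert g.source_split == "train"
        manual = estimate_graph(cohort.subset("train"), split=None)
        np.testing.assert_allclose(g.weights, manual.weights, atol=1e-15)

    def test_empty_split_errors(self):
        cohort = random_cohort(n_records=3)
        with pytest.raises(ValueError, match="split"):
            estimate_graph(Cohort(records=[]), split=None)
        assert estimate_graph(cohort, split="train") is not None  # no tags -> all records


class TestGraphSerialization:
    def test_round_trip(self, tmp_path):
        g = estimate_graph(random_cohort(n_records=5, seed=1), split=None)
        save_graph(g, tmp_path / "g.json")
        back = load_graph(tmp_path / "g.json")
        np.testing.assert_array_equal(back.weights, g.weights)
        assert back.lead_names == g.lead_names
        assert back.n_records == g.n_records

    def test_nonzero_diagonal_rejected(self, tmp_path):
        g = estimate_graph(random_cohort(n_records=5, seed=1), split=None)
        save_graph(g, tmp_path / "g.json")
        text = (tmp_path / "g.json").read_text().replace('"n_records"', '"n_records"')
        import json

        payload = json.loads(text)
        payload["weights"][1][1] = 0.5
        (tmp_path / "bad.json").write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="diagonal"):
            load_graph(tmp_path / "bad.json")

    def test_asymmetric_rejected(self, tmp_path):
        import json

        g = estimate_graph(random_cohort(n_records=5, seed=1), split=None)
        save_graph(g, tmp_path / "g.json")
        payload = json.loads((tmp_path / "g.json").read_text())
        payload["weights"][0][1] = 0.9
        payload["weights"][1][0] = -0.9
        (tmp_path / "bad.json").write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="asymmetric"):
            load_graph(tmp_path / "bad.json")

    def test_malformed_file(self, tmp_path):
        (tmp_path / "bad.json").write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            load_graph(tmp_path / "bad.json")


def test_graph_invariant_validation():
    with pytest.raises(ValueError, match="asymmetric"):
        AugmentationGraph(np.array([[0.0, 0.5], [0.4, 0.0]]), ("a", "b"), 1)
    with pytest.raises(ValueError, match="outside"):
        AugmentationGraph(np.array([[0.0, 1.5], [1.5, 0.0]]), ("a", "b"), 1)
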