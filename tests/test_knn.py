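"""Distance-weighted kNN regression and its brute-force oracle."""

import numpy as np
import pytest

import fentaqsar as fq
from fentaqsar.fingerprints import Fingerprint
from fentaqsar.knn import KNNResults, knn_predict_one


def brute_force_knn(distances, activities, k, weighting):
    """Independent oracle: full stable sort, explicit formula."""
    order = sorted(range(len(distances)), key=lambda i: (distances[i], i))[:k]
    d = [distances[i] for i in order]
    y = [activities[i] for i in order]
    exact = [yi for di, yi in zip(d, y) if di < 1e-9]
    if exact:
        return sum(exact) / len(exact)
    if weighting == "uniform":
        return sum(y) / len(y)
    w = [1.0 / di for di in d]
    return sum(wi * yi for wi, yi in zip(w, y)) / sum(w)


class TestPredictFormula:
    def test_exact_match_short_circuits(self):
        assert knn_predict_one([0.3, 0.0, 0.5], [7, 9, 5], k=1) == 9.0

    def test_equidistant_neighbors_average(self):
        assert knn_predict_one([0.2, 0.2], [8.0, 9.0], k=2) == pytest.approx(8.5)

    def test_inverse_distance_worked_example(self):
        # w = (5, 2.5): (5*9 + 2.5*6) / 7.5 = 8
        assert knn_predict_one([0.2, 0.4], [9.0, 6.0], k=2) == pytest.approx(8.0)

    def test_uniform_weighting(self):
        assert knn_predict_one([0.2, 0.4], [9.0, 6.0], k=2, weighting="uniform") == 7.5

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(123)
        for trial in range(200):
            n = rng.integers(3, 30)
            d = rng.uniform(0, 1, n)
            if trial % 7 == 0:
                d[rng.integers(n)] = 0.0  # exercise exact-match branch
            if trial % 5 == 0:
                d[: n // 2] = np.round(d[: n // 2], 1)  # ties
            y = rng.uniform(5, 10, n)
            k = int(rng.integers(1, n + 1))
            w = "uniform" if trial % 3 == 0 else "inverse_distance"
            ours = knn_predict_one(d, y, k, w)
            oracle = brute_force_knn(list(d), list(y), k, w)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_prediction_bounded_by_neighbor_range(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            d = rng.uniform(0.01, 1, 10)
            y = rng.uniform(5, 10, 10)
            pred = knn_predict_one(d, y, 5)
            order = np.argsort(d, kind="stable")[:5]
            assert y[order].min() - 1e-12 <= pred <= y[order].max() + 1e-12


class TestModel:
    def test_fit_stores_all_training_molecules(self, small_table):
        res = fq.FingerprintKNN(small_table, k=3).fit()
        assert len(res.fingerprints) == len(small_table)

    @pytest.mark.parametrize("k", [0, 21])
    def test_bad_k_rejected(self, small_table, k):
        with pytest.raises(ValueError):
            fq.FingerprintKNN(small_table, k=k)

    def test_query_identical_to_training_molecule(self, small_table):
        res = fq.FingerprintKNN(small_table, k=1).fit()
        rec = small_table[0]
        assert res.predict_one(rec.smiles) == pytest.approx(rec.pki)

    def test_flavor_mismatch_rejected(self, small_table):
        res = fq.FingerprintKNN(small_table, flavor="ECFP6", k=1).fit()
        wrong = Fingerprint(frozenset([1]), length=2048, flavor="FCFP6")
        with pytest.raises(ValueError):
            res.predict_one(wrong)

    def test_monotone_degradation_with_k_on_noiseless_sar(self, noiseless115):
        table, _ = noiseless115
        sub = fq.MoleculeTable(table.records[:40])
        q2_k1 = fq.FingerprintKNN(sub, k=1).fit().q2
        q2_kn = fq.FingerprintKNN(sub, k=len(sub)).fit().q2
        assert q2_k1 >= q2_kn

    def test_serialization_round_trip(self, small_table, tmp_path):
        res = fq.FingerprintKNN(small_table, k=3).fit()
        res.save(tmp_path / "m.json")
        back = KNNResults.load(tmp_path / "m.json")
        query = "CCC(=O)N(c1ccccc1)C1CCN(CC2CC2)CC1"
        assert back.predict_one(query) == pytest.approx(res.predict_one(query))


class TestSelectK:
    def test_single_element_grid(self, small_table):
        best, _ = fq.select_k(small_table, k_grid=[4])
        assert best == 4

    def test_duplicated_dataset_prefers_k1(self, small_table):
        doubled = fq.MoleculeTable(
            [
                fq.MoleculeRecord(id=f"{r.id}_{tag}", smiles=r.smiles, pki=r.pki)
                for r in small_table
                for tag in ("a", "b")
            ]
        )
        best, q2s = fq.select_k(doubled, k_grid=[1, 3, 5])
        assert best == 1
        assert q2s[1] == pytest.approx(1.0)

    def test_empty_grid_rejected(self, small_table):
        with pytest.raises(ValueError):
            fq.select_k(small_table, k_grid=[])
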