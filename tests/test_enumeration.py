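"""R-group enumeration, applicability domain and gated consensus."""

import numpy as np
import pytest
from rdkit import Chem

import fentaqsar as fq
from fentaqsar.enumeration import gated_median
from fentaqsar.fingerprints import Fingerprint
from fentaqsar.knn import FingerprintKNN, KNNResults

SERIES4 = next(s for s in fq.DEFAULT_SERIES if s.name == "Series4")


def tiny_library(*bodies):
    return fq.FragmentLibrary(tuple(f"[*:1]{b}" for b in bodies))


class TestSeriesDefinitions:
    def test_six_series_with_one_attachment_each(self):
        assert len(fq.DEFAULT_SERIES) == 6
        for s in fq.DEFAULT_SERIES:
            mol = Chem.MolFromSmiles(s.scaffold)
            assert sum(a.GetAtomicNum() == 0 for a in mol.GetAtoms()) == 1

    def test_malformed_scaffold_rejected(self):
        with pytest.raises(ValueError):
            fq.SeriesDefinition("bad", "CCO")  # no attachment point
        with pytest.raises(ValueError):
            fq.SeriesDefinition("bad", "[*:1]C[*:1]")


class TestEnumerateSeries:
    def test_products_contain_scaffold_as_substructure(self):
        lib = tiny_library("C", "CC", "c1ccco1")
        table = fq.enumerate_series(SERIES4, lib)
        assert 1 <= len(table) <= 3
        core = SERIES4.core()
        for rec in table:
            assert rec.mol().HasSubstructMatch(core)

    def test_cap_limits_product_count(self, fragment_library):
        table = fq.enumerate_series(SERIES4, fragment_library, cap=500)
        assert len(table) == 500

    def test_native_substituent_reconstructs_parent(self):
        lib = tiny_library("CC")  # ethyl on the carbonyl -> propanoyl parent
        table = fq.enumerate_series(SERIES4, lib)
        parent = Chem.MolToSmiles(
            Chem.MolFromSmiles("CCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1")
        )
        assert [r.smiles for r in table.records] == [parent]

    def test_deterministic_canonical_ordering(self, fragment_library):
        a = fq.enumerate_series(SERIES4, fragment_library, cap=50)
        b = fq.enumerate_series(SERIES4, fragment_library, cap=50)
        assert [r.smiles for r in a] == [r.smiles for r in b]

    def test_bad_cap_rejected(self):
        with pytest.raises(ValueError):
            fq.enumerate_series(SERIES4, tiny_library("C"), cap=0)


class TestApplicabilityDomain:
    def test_training_molecule_is_in_domain(self, models):
        table, trained = models
        rec = table.train[0]
        assert fq.applicability_domain(trained.ecfp6, rec)

    def test_alien_molecule_is_out_of_domain(self, models):
        _, trained = models
        # perfluorinated chain: no common environments with fentanyl analogs
        alien = "FC(F)(F)C(F)(F)C(F)(F)C(F)(F)F"
        assert not fq.applicability_domain(trained.ecfp6, alien)

    def test_threshold_is_inclusive_at_exactly_040(self):
        # training fp {1,2,3,4}; query {1,2,5}: tanimoto = 2/5 = 0.40
        train_fp = Fingerprint(frozenset({1, 2, 3, 4}))
        model = FingerprintKNN.__new__(FingerprintKNN)
        model.train, model.flavor, model.length = None, "ECFP6", 2048
        model.k, model.weighting = 1, "inverse_distance"
        res = KNNResults(model, [train_fp], np.array([8.0]), ["t"])
        query = Fingerprint(frozenset({1, 2, 5}))
        assert res.max_similarity(query) == pytest.approx(0.40)
        assert fq.applicability_domain(res, query)


class TestConsensus:
    def test_median_of_three_in_domain(self):
        assert gated_median((8.0, 8.5, 9.0), (True, True, True)) == 8.5

    def test_median_of_two_is_their_mean(self):
        assert gated_median((8.0, 8.5, 9.0), (False, True, True)) == 8.75

    def test_absent_when_all_out_of_domain(self):
        assert gated_median((8.0, 8.5, 9.0), (False, False, False)) is None

    def test_nan_prediction_never_contributes(self):
        assert gated_median((float("nan"), 8.0, 9.0), (True, True, True)) == 8.5

    def test_consensus_within_span_of_contributors(self, models):
        table, trained = models
        rec = table.test[0]
        pred = fq.consensus_predict(rec, trained.field, trained.ecfp6, trained.fcfp6)
        contributing = [
            p
            for p, ok in [
                (pred.pred_field, pred.in_domain_field),
                (pred.pred_ecfp6, pred.in_domain_ecfp6),
                (pred.pred_fcfp6, pred.in_domain_fcfp6),
            ]
            if ok and np.isfinite(p)
        ]
        assert contributing, "a held-out analog should be in someone's domain"
        assert min(contributing) <= pred.consensus <= max(contributing)


class TestScreen:
    def test_small_screen_counts_and_ranking(self, models, fragment_library):
        _, trained = models
        lib = fq.FragmentLibrary(fragment_library.fragments[:5])
        df = fq.screen(
            fq.DEFAULT_SERIES[:2], lib, trained.field, trained.ecfp6, trained.fcfp6,
            cap=3, seed=1,
        )
        assert len(df) == 6  # 2 series x cap 3
        cons = df["consensus"].to_numpy()
        present = cons[~np.isnan(cons)]
        assert np.all(np.diff(present) <= 1e-12)  # descending
        # absent consensus (if any) ranks last
        if np.isnan(cons).any():
            assert np.isnan(cons[len(present):]).all()

    def test_rerun_is_byte_identical(self, models, fragment_library, tmp_path):
        _, trained = models
        lib = fq.FragmentLibrary(fragment_library.fragments[:4])
        out = []
        for name in ("a.csv", "b.csv"):
            df = fq.screen(
                fq.DEFAULT_SERIES[:1], lib, trained.field, trained.ecfp6,
                trained.fcfp6, cap=4, seed=1,
            )
            p = tmp_path / name
            df.to_csv(p, index=False)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_empty_library_gives_empty_report(self, models):
        _, trained = models
        df = fq.screen(
            fq.DEFAULT_SERIES, fq.FragmentLibrary(()), trained.field,
            trained.ecfp6, trained.fcfp6,
        )
        assert len(df) == 0
        assert "consensus" in df.columns
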