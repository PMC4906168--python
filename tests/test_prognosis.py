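import numpy as np
import pandas as pd
import pytest

from isosurv import (
    FeatureTable,
    SurvivalRecord,
    compare_models,
    concordance_index,
    cox_fit,
    l1_cox_fit,
    monte_carlo_cv,
    simulate_prediction_dataset,
    univariate_screen,
    zscore_normalize,
)
from isosurv.prognosis import CvReport


@pytest.fixture(scope="module")
def prediction_data():
    return simulate_prediction_dataset(n_patients=140, n_genes=15,
                                       n_splicing=12, seed=3)


def _tables(data):
    clin, genes, splicing, records, truth = data
    return {
        "clinical": FeatureTable("clinical", clin),
        "gene": FeatureTable("gene", genes),
        "splicing": FeatureTable.from_splicing_counts(splicing),
    }, records, truth


class TestScreen:
    def test_threshold_one_selects_everything(self, prediction_data):
        tables, records, _ = _tables(prediction_data)
        selected = univariate_screen(tables["gene"], records, threshold=1.0)
        assert set(selected) == set(tables["gene"].values.columns)

    def test_informative_features_selected(self, prediction_data):
        tables, records, truth = _tables(prediction_data)
        selected = univariate_screen(tables["clinical"], records, 0.01)
        informative = [f for f in truth if f.startswith("clin")]
        assert len(set(selected) & set(informative)) >= len(informative) - 1

    def test_null_features_rarely_selected(self):
        rng = np.random.default_rng(0)
        n = 200
        records = [SurvivalRecord(f"P{i:04d}", float(t), 1)
                   for i, t in enumerate(rng.exponential(size=n))]
        noise = pd.DataFrame(
            {f"g{j}": rng.normal(size=n) for j in range(60)},
            index=[r.patient_id for r in records],
        )
        selected = univariate_screen(FeatureTable("gene", noise), records, 0.01)
        assert len(selected) <= 5  # ~1% expected under the null

    def test_splicing_screened_with_measurement_error_model(self, prediction_data):
        tables, records, truth = _tables(prediction_data)
        selected = univariate_screen(tables["splicing"], records, 0.05)
        informative = [f for f in truth if f.startswith("ex")]
        assert len(set(selected) & set(informative)) >= 2


class TestZscore:
    def test_train_statistics_applied_to_test(self):
        train = pd.DataFrame({"f": [0.0, 2.0]})
        test = pd.DataFrame({"f": [1.0, 3.0]})
        tr, te = zscore_normalize(train, test)
        # sample SD (n-1) of (0,2) is sqrt(2)
        np.testing.assert_allclose(tr["f"], [-1 / np.sqrt(2), 1 / np.sqrt(2)])
        np.testing.assert_allclose(te["f"], [0.0, 2 / np.sqrt(2)])

    def test_constant_feature_dropped(self):
        train = pd.DataFrame({"f": [1.0, 1.0], "g": [0.0, 1.0]})
        tr, te = zscore_normalize(train, train.copy())
        assert list(tr.columns) == ["g"]

    def test_train_mean_zero(self):
        rng = np.random.default_rng(1)
        train = pd.DataFrame({"a": rng.normal(2, 3, 50)})
        tr, _ = zscore_normalize(train, train.copy())
        assert tr["a"].mean() == pytest.approx(0.0, abs=1e-12)


class TestL1Cox:
    def test_full_shrinkage_at_large_penalty(self, prediction_data):
        tables, records, _ = _tables(prediction_data)
        values = tables["gene"].values
        model = l1_cox_fit(values, records, penalty_grid=np.array([1e6]))
        assert not np.any(model.coefs)

    def test_unpenalized_limit_matches_cox_fit(self, prediction_data):
        tables, records, _ = _tables(prediction_data)
        col = tables["clinical"].values[["clin0"]]
        model = l1_cox_fit(col, records, penalty_grid=np.array([1e-8]))
        ref = cox_fit(col["clin0"].to_numpy(), records)
        assert model.coefs[0] == pytest.approx(ref.beta_hat, abs=1e-4)

    def test_duplicated_feature_keeps_risk_scores(self, prediction_data):
        tables, records, _ = _tables(prediction_data)
        x = tables["clinical"].values[["clin0", "clin1"]]
        x2 = x.copy()
        x2["clin0_dup"] = x["clin0"]
        grid = np.logspace(-3, -1, 10)
        m1 = l1_cox_fit(x, records, penalty_grid=grid, seed=1)
        m2 = l1_cox_fit(x2, records, penalty_grid=grid, seed=1)
        r1 = m1.risk_scores(x)
        r2 = m2.risk_scores(x2)
        assert np.corrcoef(r1, r2)[0, 1] > 0.999


class TestMonteCarloCv:
    def test_deterministic_given_seed(self, prediction_data):
        tables, records, _ = _tables(prediction_data)
        models = {"clinical": [tables["clinical"]]}
        a = monte_carlo_cv(models, records, rounds=2, seed=7)
        b = monte_carlo_cv(models, records, rounds=2, seed=7)
        pd.testing.assert_frame_equal(a.c_index, b.c_index)

    def test_informative_beats_noise(self, prediction_data):
        tables, records, _ = _tables(prediction_data)
        rng = np.random.default_rng(5)
        noise = pd.DataFrame(
            rng.normal(size=(len(records), 10)),
            index=[r.patient_id for r in records],
            columns=[f"n{j}" for j in range(10)],
        )
        models = {
            "informative": [tables["clinical"], tables["gene"]],
            "noise": [FeatureTable("gene", noise)],
        }
        report = monte_carlo_cv(models, records, rounds=8, seed=2)
        assert report.c_index["informative"].median() > report.c_index["noise"].median()
        # combined informative + noise at least matches noise alone
        models2 = {
            "combined": [tables["clinical"], tables["gene"],
                         FeatureTable("gene", noise)],
            "noise": [FeatureTable("gene", noise)],
        }
        report2 = monte_carlo_cv(models2, records, rounds=8, seed=2)
        assert (report2.c_index["combined"].median()
                >= report2.c_index["noise"].median())

    def test_no_leakage_permuted_test_labels(self, prediction_data):
        # a model trained on real data scores ~0.5 against permuted survival
        tables, records, _ = _tables(prediction_data)
        rng = np.random.default_rng(9)
        half = len(records) // 2
        train, test = records[:half], records[half:]
        sel = univariate_screen(tables["clinical"], train, 0.05)
        if not sel:
            pytest.skip("no features selected on this split")
        model = l1_cox_fit(tables["clinical"].values.loc[
            [r.patient_id for r in train], sel], train,
            penalty_grid=np.logspace(-3, -1, 10))
        risk = model.risk_scores(
            tables["clinical"].values.loc[[r.patient_id for r in test], sel]
        )
        cs = []
        for _ in range(30):
            perm = rng.permutation(len(test))
            permuted = [
                SurvivalRecord(test[i].patient_id, test[perm[i]].time,
                               test[perm[i]].event)
                for i in range(len(test))
            ]
            cs.append(concordance_index(risk, permuted))
        assert np.median(cs) == pytest.approx(0.5, abs=0.06)


class TestCompareModels:
    def test_identical_vectors_p_one(self):
        df = pd.DataFrame({"a": [0.6, 0.7, 0.65], "b": [0.6, 0.7, 0.65]})
        assert compare_models(CvReport(df), ("a", "b")) == 1.0

    def test_constant_shift_extreme(self):
        rng = np.random.default_rng(2)
        base = 0.6 + 0.01 * rng.normal(size=100)
        df = pd.DataFrame({"a": base + 0.05, "b": base})
        assert compare_models(CvReport(df), ("a", "b")) < 1e-10

    def test_symmetric_in_pair(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.uniform(0.5, 0.7, 20),
                           "b": rng.uniform(0.5, 0.7, 20)})
        report = CvReport(df)
        assert compare_models(report, ("a", "b")) == pytest.approx(
            compare_models(report, ("b", "a"))
        )

    def test_missing_model_errors(self):
        with pytest.raises(ValueError):
            compare_models(CvReport(pd.DataFrame({"a": [0.5]})), ("a", "zz"))
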