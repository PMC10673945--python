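import numpy as np
import pandas as pd
import pytest

from phenoadapt import Covariate, SyntheticConfig, apply_preprocess, fit_preprocess, generate_trial
from phenoadapt.core import SchemaError, TrialDataset
from phenoadapt.preprocess import PipelineError

from conftest import make_dataset


def _with_covariates(values: dict, kinds: dict, n=None, seed=0):
    """Dataset whose covariate columns are replaced by given arrays."""
    n = n or len(next(iter(values.values())))
    schema = tuple(
        Covariate(k, kinds[k], ("a", "b", "c") if kinds[k] == "categorical" else ())
        for k in values
    )
    ds = make_dataset(n=n, seed=seed, schema=schema)
    for k, v in values.items():
        ds.table[k] = v
    return TrialDataset(ds.table, schema)


class TestFit:
    def test_high_missingness_dropped(self):
        n = 40
        x = np.random.default_rng(0).normal(size=n)
        y = x.copy()
        y[:8] = np.nan  # 20% missing
        ds = _with_covariates({"x": x, "y": y}, {"x": "continuous", "y": "continuous"})
        fit = fit_preprocess(ds)
        assert fit.dropped_missing == ["y"]
        assert "y" not in fit.kept_features

    def test_collinear_member_with_larger_mean_corr_dropped(self):
        # A ~ B (r > 0.95); A also tracks C, so A has the larger mean |r|
        rng = np.random.default_rng(1)
        n = 200
        a = rng.normal(size=n)
        b = a + 0.1 * rng.normal(size=n)
        c = 0.6 * a + 0.8 * rng.normal(size=n)
        frame = pd.DataFrame({"A": a, "B": b, "C": c})
        corr = frame.corr().abs()
        assert corr.loc["A", "B"] > 0.9
        assert corr.loc["A", "C"] > corr.loc["B", "C"]  # A is the victim
        ds = _with_covariates(
            {"A": a, "B": b, "C": c}, dict.fromkeys("ABC", "continuous")
        )
        fit = fit_preprocess(ds)
        assert fit.dropped_collinear == ["A"]
        assert set(fit.kept_features) == {"B", "C"}

    def test_winsor_bounds_linear_percentile(self):
        vals = np.arange(1.0, 101.0)
        ds = _with_covariates({"x": vals}, {"x": "continuous"})
        fit = fit_preprocess(ds)
        lo, hi = fit.winsor_bounds["x"]
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_zero_variance_factor_dropped(self):
        n = 30
        ds = _with_covariates(
            {"x": np.random.default_rng(0).normal(size=n), "b": np.zeros(n)},
            {"x": "continuous", "b": "binary"},
        )
        fit = fit_preprocess(ds)
        assert fit.dropped_zero_var == ["b"]

    def test_all_dropped_is_error(self):
        n = 30
        ds = _with_covariates({"b": np.ones(n)}, {"b": "binary"})
        with pytest.raises(PipelineError):
            fit_preprocess(ds)


class TestApply:
    def test_training_transform_has_no_missing(self):
        cfg = SyntheticConfig(n_total=150, missing_frac=0.08, seed=5)
        ds = generate_trial(cfg)
        fit = fit_preprocess(ds)
        td = apply_preprocess(fit, ds)
        assert not td.X.isna().any().any()
        assert not td.gower_frame.isna().any().any()

    def test_complete_data_passes_through(self):
        cfg = SyntheticConfig(n_total=100, missing_frac=0.0, seed=5)
        ds = generate_trial(cfg)
        fit = fit_preprocess(ds)
        td = apply_preprocess(fit, ds)
        for name in fit.kept_features:
            kind = td.kinds[name]
            if kind == "continuous":
                lo, hi = fit.winsor_bounds[name]
                expected = ds.table[name].clip(lo, hi).to_numpy()
                assert np.allclose(td.gower_frame[name].to_numpy(), expected)
            elif kind == "binary":
                assert np.array_equal(td.gower_frame[name].to_numpy(), ds.table[name].to_numpy())

    def test_unseen_categorical_level_all_zero(self):
        n = 40
        rng = np.random.default_rng(2)
        ds = _with_covariates(
            {"x": rng.normal(size=n), "g": rng.choice(["a", "b"], n)},
            {"x": "continuous", "g": "categorical"},
        )
        fit = fit_preprocess(ds)
        new = ds.table.copy()
        new.loc[0, "g"] = "c"  # level absent at fit
        td = apply_preprocess(fit, TrialDataset(new, ds.schema))
        onehots = [c for c in td.X.columns if c.startswith("g=")]
        assert td.X.loc["p0", onehots].sum() == 0

    def test_missing_fit_feature_is_schema_error(self):
        ds = make_dataset(n=30)
        fit = fit_preprocess(ds)
        stripped = TrialDataset(ds.table.drop(columns=["age"]), (ds.schema[1],))
        with pytest.raises(SchemaError):
            apply_preprocess(fit, stripped)

    def test_no_leakage_test_extremes_clip_to_train_bounds(self):
        rng = np.random.default_rng(3)
        train = _with_covariates({"x": rng.normal(0, 1, 60)}, {"x": "continuous"})
        fit = fit_preprocess(train)
        lo, hi = fit.winsor_bounds["x"]
        test = _with_covariates({"x": rng.normal(0, 10, 60)}, {"x": "continuous"}, seed=9)
        td = apply_preprocess(fit, test)
        assert td.gower_frame["x"].max() <= hi
        assert td.gower_frame["x"].min() >= lo

    def test_winsor_clip_idempotent(self):
        rng = np.random.default_rng(4)
        ds = _with_covariates({"x": rng.normal(size=80)}, {"x": "continuous"})
        fit = fit_preprocess(ds)
        once = apply_preprocess(fit, ds).gower_frame["x"]
        clipped_ds = ds.table.copy()
        clipped_ds["x"] = once.to_numpy()
        twice = apply_preprocess(fit, TrialDataset(clipped_ds, ds.schema)).gower_frame["x"]
        assert np.allclose(once.to_numpy(), twice.to_numpy())

    def test_forest_imputation_beats_mean_imputation(self):
        # correlated covariates, MCAR mask: iterative forest RMSE < mean RMSE
        cfg = SyntheticConfig(
            n_total=400, n_continuous=5, n_binary=0, n_categorical=0, corr=0.7, seed=8
        )
        ds = generate_trial(cfg)
        truth = ds.table["x0"].to_numpy().copy()
        rng = np.random.default_rng(0)
        mask = rng.random(ds.n) < 0.08  # below the 10% drop rule
        t = ds.table.copy()
        t.loc[mask, "x0"] = np.nan
        masked = TrialDataset(t, ds.schema)
        fit = fit_preprocess(masked, seed=1)
        imputed = apply_preprocess(fit, masked).gower_frame["x0"].to_numpy()
        rmse_forest = np.sqrt(np.mean((imputed[mask] - truth[mask]) ** 2))
        mean_fill = np.nanmean(t["x0"])
        rmse_mean = np.sqrt(np.mean((mean_fill - truth[mask]) ** 2))
        assert rmse_forest < rmse_mean

    def test_apply_deterministic(self):
        cfg = SyntheticConfig(n_total=120, missing_frac=0.1, seed=6)
        ds = generate_trial(cfg)
        fit = fit_preprocess(ds, seed=3)
        a = apply_preprocess(fit, ds).X
        b = apply_preprocess(fit, ds).X
        pd.testing.assert_frame_equal(a, b)
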