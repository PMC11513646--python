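from datetime import date

import numpy as np
import pandas as pd
import pytest

from movesoc.lmm import RandomTerm, fit_lmm
from movesoc.models import (
    ModelSpec,
    build_dataset,
    build_design,
    default_specs,
    fit_model,
    prepare_frame,
    run_suite,
    suite_table,
    vif,
)


def _mini_dataset():
    metrics = pd.DataFrame(
        {
            "individual_id": ["a", "a", "b"],
            "date": [date(2018, 7, 1), date(2018, 7, 2), date(2018, 7, 1)],
            "total_distance_m": [100.0, 200.0, 150.0],
            "median_step_m": [5.0, 6.0, 7.0],
            "median_sinuosity": [0.5, 0.4, 0.3],
            "median_residence_min": [10.0, 8.0, 6.0],
            "n_fixes": [100, 100, 100],
        }
    )
    counts = pd.DataFrame(
        {
            "individual_id": ["a", "b"],
            "date": [date(2018, 7, 1)] * 2,
            "n_events": [3, 5],
            "n_active_collars": [10, 10],
        }
    )
    energy = pd.DataFrame(
        {
            "individual_id": ["a"],
            "behaviour_date": [date(2018, 7, 1)],
            "ft3_daily": [6.0],
            "ft3_mean": [6.0],
            "ft3_centred": [0.0],
        }
    )
    grooming = pd.DataFrame(
        {
            "individual_id": ["a"],
            "date": [date(2018, 7, 1)],
            "give_min": [12.0],
            "receive_min": [20.0],
            "daylength_h": [10.0],
        }
    )
    metadata = pd.DataFrame(
        {
            "individual_id": ["a", "b"],
            "sex": ["female", "male"],
            "reproductive_state": ["cyclic", "male"],
            "rank": [0.2, 0.9],
        }
    )
    return metrics, counts, energy, grooming, metadata


class TestBuildDataset:
    def test_manual_assembly(self):
        data = build_dataset(*_mini_dataset())
        assert len(data) == 3
        row = data[(data["individual_id"] == "a") & (data["date"] == date(2018, 7, 1))]
        assert row["n_events"].iloc[0] == 3
        assert row["give_min"].iloc[0] == 12.0
        assert row["ft3_mean"].iloc[0] == 6.0
        assert row["reproductive_state"].iloc[0] == "cyclic"
        # day without hormone record stays with missing covariate
        row2 = data[(data["individual_id"] == "a") & (data["date"] == date(2018, 7, 2))]
        assert np.isnan(row2["ft3_mean"].iloc[0])


class TestPrepareFrame:
    def _data(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "individual_id": rng.choice(list("abcd"), n),
                "date": rng.choice([date(2018, 7, k) for k in range(1, 11)], n),
                "resp": rng.uniform(1, 20, n),
                "p1": rng.normal(3, 2, n),
                "p2": rng.normal(-1, 0.5, n),
                "sex": rng.choice(["female", "male"], n),
                "reproductive_state": rng.choice(["acyclic", "cyclic"], n),
            }
        )

    def test_zscore_mean_zero_sd_one(self):
        spec = ModelSpec(name="m", response="resp", continuous=("p1", "p2"))
        frame, info = prepare_frame(spec, self._data())
        for c in ("p1", "p2"):
            assert frame[c].mean() == pytest.approx(0.0, abs=1e-12)
            assert frame[c].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_log_response(self):
        spec = ModelSpec(name="m", response="resp", transform="log")
        frame, _ = prepare_frame(spec, self._data())
        assert np.allclose(frame["_y"], np.log(frame["resp"]))

    def test_log_zero_rows_dropped_and_counted(self):
        data = self._data()
        data.loc[data.index[:3], "resp"] = 0.0
        spec = ModelSpec(name="m", response="resp", transform="log")
        frame, info = prepare_frame(spec, data)
        assert info["n_dropped_nonpositive"] == 3
        assert len(frame) == len(data) - 3

    def test_females_only_filter(self):
        spec = ModelSpec(name="m", response="resp", females_only=True)
        frame, _ = prepare_frame(spec, self._data())
        assert set(frame["sex"]) == {"female"}

    def test_constant_predictor_rejected(self):
        data = self._data()
        data["p1"] = 5.0
        spec = ModelSpec(name="m", response="resp", continuous=("p1",))
        with pytest.raises(ValueError, match="constant"):
            prepare_frame(spec, data)


class TestDesignAndVif:
    def test_treatment_coding_reference_level(self):
        frame = pd.DataFrame(
            {"reproductive_state": ["cyclic", "acyclic", "male", "acyclic"]}
        )
        X, names = build_design(frame, (), ("reproductive_state",))
        assert names == [
            "(Intercept)",
            "reproductive_state[cyclic]",
            "reproductive_state[male]",
        ]
        assert X[:, 0].tolist() == [1, 1, 1, 1]
        assert X[1, 1] == 0 and X[0, 1] == 1

    def test_interaction_column(self):
        frame = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        X, names = build_design(frame, ("a", "b"), (), interaction=("a", "b"))
        assert names[-1] == "a:b"
        assert X[:, -1].tolist() == [3.0, 8.0]

    def test_orthogonal_vifs_are_one(self):
        n = 400
        rng = np.random.default_rng(1)
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        X = np.column_stack([np.ones(n), a, b])
        out = vif(X, ["(Intercept)", "a", "b"], ("a", "b"))
        assert out["a"] == pytest.approx(1.0, abs=1e-9)
        assert out["b"] == pytest.approx(1.0, abs=1e-9)

    def test_correlation_point_six_closed_form(self):
        # construct predictors with sample correlation exactly 0.6
        n = 100
        u = np.tile([1.0, -1.0], n // 2)
        v = np.repeat([1.0, -1.0], n // 2)
        r = 0.6
        b = r * u + np.sqrt(1 - r**2) * v
        assert np.corrcoef(u, b)[0, 1] == pytest.approx(0.6, abs=1e-12)
        X = np.column_stack([np.ones(n), u, b])
        out = vif(X, ["(Intercept)", "u", "b"], ("u", "b"))
        assert out["u"] == pytest.approx(1.5625, abs=1e-6)
        assert out["b"] == pytest.approx(1.5625, abs=1e-6)

    def test_duplicated_predictor_infinite(self):
        n = 50
        x = np.random.default_rng(2).normal(size=n)
        X = np.column_stack([np.ones(n), x, x])
        out = vif(X, ["(Intercept)", "x1", "x2"], ("x1", "x2"))
        assert np.isinf(out["x1"]) and np.isinf(out["x2"])


class TestZTransformEquivalence:
    def test_beta_z_equals_beta_raw_times_sd(self):
        rng = np.random.default_rng(3)
        n = 200
        x = rng.normal(5, 3, n)
        y = 2.0 + 0.8 * x + rng.normal(0, 1, n)
        df = pd.DataFrame({"g": np.zeros(n, dtype=int)})
        sd = x.std(ddof=0)
        z = (x - x.mean()) / sd
        Xr = np.column_stack([np.ones(n), x])
        Xz = np.column_stack([np.ones(n), z])
        fr = fit_lmm(y, Xr, ["(Intercept)", "x"], df, [], method="REML")
        fz = fit_lmm(y, Xz, ["(Intercept)", "x"], df, [], method="REML")
        assert fz.beta[1] == pytest.approx(fr.beta[1] * sd, rel=1e-6)


class TestFitModelAndSuite:
    def test_fit_model_report_schema(self, small_sim, small_config):
        from movesoc.simulate import run_pipeline

        data = run_pipeline(small_sim, small_config)
        spec = [s for s in default_specs(min_collars=4) if s.name == "lmm4"][0]
        rep = fit_model(spec, data, categorical_p=True)
        assert not rep["skipped"]
        assert {"coefficients", "lrt", "vif", "n_individuals", "n_obs",
                "converged", "variance_components"} <= set(rep)
        assert rep["lrt"]["df"] == 2            # ft3_mean + ft3_centred
        assert "ft3_centred" in rep["coefficients"]
        assert all(v >= 1.0 for v in rep["vif"].values())
        assert "reproductive_state" in rep["categorical_p"]

    def test_run_suite_reports_all_models(self, small_sim, small_config):
        from movesoc.simulate import run_pipeline

        data = run_pipeline(small_sim, small_config)
        reports = run_suite(data, default_specs(min_collars=4), categorical_p=False)
        assert set(reports) == {f"lmm{i}" for i in range(1, 8)}
        table = suite_table(reports)
        assert {"model", "term", "estimate", "se", "t", "p", "N", "n"} <= set(
            table.columns
        )
        fitted = table["model"].unique()
        assert "lmm4" in fitted
        # lmm7 tests the interaction: 3 focal terms in the LRT
        assert reports["lmm7"]["lrt"]["df"] == 3 or reports["lmm7"].get("skipped")

    def test_empty_model_skipped_not_fatal(self):
        data = build_dataset(*_mini_dataset())
        reports = run_suite(data, default_specs(), categorical_p=False)
        assert all(rep.get("skipped") for rep in reports.values())
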