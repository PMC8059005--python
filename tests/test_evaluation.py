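"""NRMSE/PFC metrics, aggregation over repeats, method comparison."""

import numpy as np
import pandas as pd
import pytest

from gainimpute import (
    EvalReport,
    IncompleteTable,
    TableSchema,
    VariableSchema,
    compare_methods,
    evaluate_imputations,
    nrmse,
    pfc,
)


@pytest.fixture
def metric_setup():
    schema = TableSchema(
        [
            VariableSchema("x", "continuous"),
            VariableSchema("c", "categorical", categories=("a", "b")),
        ]
    )
    truth = pd.DataFrame(
        {"x": [2.0, 2.0, 2.0, 5.0], "c": ["a", "b", "a", "b"]}
    )
    mask = np.array(
        [[0, 0], [0, 0], [0, 1], [1, 1]], dtype=bool
    )  # x masked rows 0-2; c masked rows 0-1
    return schema, truth, mask


class TestNrmse:
    def test_perfect_imputation_is_zero(self, metric_setup):
        schema, truth, mask = metric_setup
        assert nrmse(truth, truth, mask, schema, "x") == 0.0

    def test_printed_formula_example(self, metric_setup):
        schema, truth, mask = metric_setup
        imputed = truth.copy()
        imputed["x"] = [1.0, 2.0, 3.0, 99.0]  # unmasked row ignored
        # sqrt(mean((1,2,3)-(2,2,2))^2) / mean(2,2,2) = sqrt(2/3)/2
        expected = np.sqrt(2.0 / 3.0) / 2.0
        assert nrmse(imputed, truth, mask, schema, "x") == pytest.approx(
            expected, abs=1e-12
        )

    def test_scale_invariance(self, metric_setup):
        schema, truth, mask = metric_setup
        imputed = truth.copy()
        imputed["x"] = [1.0, 2.5, 3.0, 5.0]
        base = nrmse(imputed, truth, mask, schema, "x")
        for c in (3.0, 0.25):
            t2, i2 = truth.copy(), imputed.copy()
            t2["x"] = truth["x"] * c
            i2["x"] = imputed["x"] * c
            assert nrmse(i2, t2, mask, schema, "x") == pytest.approx(base)

    def test_unmasked_cells_do_not_matter(self, metric_setup):
        schema, truth, mask = metric_setup
        a = truth.copy()
        a["x"] = [1.0, 2.5, 3.0, 5.0]
        b = a.copy()
        b["x"] = [1.0, 2.5, 3.0, -123.0]
        assert nrmse(a, truth, mask, schema, "x") == nrmse(
            b, truth, mask, schema, "x"
        )

    def test_zero_mean_target_errors(self, metric_setup):
        schema, truth, mask = metric_setup
        t = truth.copy()
        t["x"] = [-1.0, 0.0, 1.0, 4.0]
        with pytest.raises(ValueError, match="zero-mean"):
            nrmse(truth, t, mask, schema, "x")

    def test_no_masked_cells_errors(self, metric_setup):
        schema, truth, _ = metric_setup
        full = np.ones((4, 2), dtype=bool)
        with pytest.raises(ValueError, match="no masked cells"):
            nrmse(truth, truth, full, schema, "x")


class TestPfc:
    def test_all_correct_zero(self, metric_setup):
        schema, truth, mask = metric_setup
        assert pfc(truth, truth, mask, schema, "c") == 0.0

    def test_all_wrong_one(self, metric_setup):
        schema, truth, mask = metric_setup
        imputed = truth.copy()
        imputed["c"] = ["b", "a", "a", "b"]
        assert pfc(imputed, truth, mask, schema, "c") == 1.0

    def test_partial_fraction(self):
        schema = TableSchema(
            [VariableSchema("c", "categorical", categories=("a", "b"))]
        )
        truth = pd.DataFrame({"c": ["a"] * 5})
        imputed = pd.DataFrame({"c": ["a", "a", "a", "b", "b"]})
        mask = np.zeros((5, 1), dtype=bool)
        assert pfc(imputed, truth, mask, schema, "c") == pytest.approx(0.4)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        schema = TableSchema(
            [VariableSchema("c", "categorical", categories=("a", "b", "z"))]
        )
        cats = np.array(["a", "b", "z"], object)
        for _ in range(50):
            n = int(rng.integers(1, 30))
            truth = pd.DataFrame({"c": rng.choice(cats, n)})
            imputed = pd.DataFrame({"c": rng.choice(cats, n)})
            mask = rng.random((n, 1)) > 0.5
            if mask.all():
                mask[0, 0] = False
            v = pfc(imputed, truth, mask, schema, "c")
            assert 0.0 <= v <= 1.0


class TestEvaluateImputations:
    def test_single_imputation_sd_zero(self, metric_setup):
        schema, truth, mask = metric_setup
        imputed = truth.copy()
        imputed["x"] = [1.0, 2.0, 3.0, 5.0]
        report = evaluate_imputations([imputed], truth, mask, schema, "m")
        row = report.table.set_index("variable").loc["x"]
        assert row["sd"] == 0.0 and row["m"] == 1

    def test_identical_repeats_sd_zero(self, metric_setup):
        schema, truth, mask = metric_setup
        imputed = truth.copy()
        imputed["x"] = [1.0, 2.0, 3.0, 5.0]
        report = evaluate_imputations([imputed] * 10, truth, mask, schema, "m")
        assert (report.table["sd"] == 0.0).all()

    def test_mean_matches_bruteforce_recomputation(self, metric_setup):
        schema, truth, mask = metric_setup
        rng = np.random.default_rng(1)
        imps = []
        for _ in range(7):
            df = truth.copy()
            df["x"] = truth["x"] + rng.normal(0, 0.5, 4)
            df["c"] = rng.choice(np.array(["a", "b"], object), 4)
            imps.append(df)
        report = evaluate_imputations(imps, truth, mask, schema, "m")
        manual_x = np.mean(
            [nrmse(df, truth, mask, schema, "x") for df in imps]
        )
        got = report.table.set_index("variable").loc["x", "mean"]
        assert got == pytest.approx(manual_x, abs=1e-12)

    def test_permutation_invariant(self, metric_setup):
        schema, truth, mask = metric_setup
        rng = np.random.default_rng(2)
        imps = []
        for _ in range(5):
            df = truth.copy()
            df["x"] = truth["x"] + rng.normal(0, 0.5, 4)
            imps.append(df)
        a = evaluate_imputations(imps, truth, mask, schema, "m").table
        b = evaluate_imputations(imps[::-1], truth, mask, schema, "m").table
        pd.testing.assert_frame_equal(a, b)


def _report(method, values_by_var):
    rows = []
    per_repeat = {}
    for var, vals in values_by_var.items():
        vals = np.asarray(vals, float)
        per_repeat[var] = vals
        rows.append(
            {
                "variable": var,
                "metric": "NRMSE",
                "mean": vals.mean(),
                "sd": vals.std(ddof=1),
                "m": len(vals),
                "n_cells": 10,
            }
        )
    return EvalReport(method=method, table=pd.DataFrame(rows), per_repeat=per_repeat)


class TestCompareMethods:
    def test_identical_methods_not_flagged(self):
        vals = {"x": [0.1, 0.11, 0.09, 0.1, 0.12]}
        out = compare_methods([_report("a", vals), _report("b", vals)])
        row = out.iloc[0]
        assert row["omnibus_p"] > 0.05
        assert not row["p_a_vs_b_sig"]
        assert np.isnan(row["p_a_vs_b"])

    def test_separated_means_flagged(self):
        rng = np.random.default_rng(0)
        a = {"x": 0.1 + 0.01 * rng.standard_normal(100)}
        b = {"x": 0.5 + 0.01 * rng.standard_normal(100)}
        out = compare_methods([_report("a", a), _report("b", b)])
        row = out.iloc[0]
        assert row["omnibus_p"] < 0.05
        assert row["p_a_vs_b_sig"]

    def test_three_identical_methods_skip_pairwise(self):
        vals = {"x": [0.2, 0.2, 0.2, 0.2]}
        reports = [_report(m, vals) for m in ("a", "b", "c")]
        out = compare_methods(reports)
        row = out.iloc[0]
        assert row["omnibus_p"] == 1.0
        for key in ("p_a_vs_b", "p_a_vs_c", "p_b_vs_c"):
            assert np.isnan(row[key])

    def test_too_few_repeats_rejected(self):
        vals = {"x": [0.1, 0.2]}
        with pytest.raises(ValueError, match=">= 3"):
            compare_methods([_report("a", vals), _report("b", vals)])

    def test_single_method_rejected(self):
        with pytest.raises(ValueError, match="two methods"):
            compare_methods([_report("a", {"x": [0.1, 0.2, 0.3]})])
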