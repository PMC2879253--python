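"""Logistic signature models, confusion tables, Fisher exact test and the
reconstruction of printed performance rows."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tallgc import (
    ConfusionTable,
    SignatureModel,
    confusion_from_metrics,
    evaluate,
    fisher_exact_two_sided,
    fit_signature_model,
    predict_and_classify,
)
from tallgc.models import AmbiguousReconstructionError, round_half_up
from tallgc.reference import COHORT_SIZES, VALIDATION_PANEL
from tallgc.simulate import Cohort, SimulationConfig, simulate_cohort


def fisher_enumeration_oracle(t: ConfusionTable) -> float:
    """Full hypergeometric enumeration with exact binomial coefficients."""
    n, r1, c1 = t.n, t.tp + t.fn, t.tp + t.fp
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    denom = comb(n, c1)
    probs = {
        a: Fraction(comb(r1, a) * comb(n - r1, c1 - a), denom)
        for a in range(lo, hi + 1)
    }
    obs = float(probs[t.tp])
    return float(sum(float(p) for p in probs.values() if float(p) <= obs * (1 + 1e-7)))


class TestEvaluate:
    @pytest.mark.parametrize(
        "table,expected",
        [
            (ConfusionTable(17, 5, 4, 24), (82, 81, 83, 77, 86)),
            (ConfusionTable(2, 7, 0, 25), (79, 100, 78, 22, 100)),
            (ConfusionTable(5, 0, 0, 5), (100, 100, 100, 100, 100)),
        ],
    )
    def test_printed_metric_rows(self, table, expected):
        pred = ["R"] * (table.tp + table.fp) + ["CCR"] * (table.fn + table.tn)
        truth = (
            ["R"] * table.tp + ["CCR"] * table.fp
            + ["R"] * table.fn + ["CCR"] * table.tn
        )
        got_table, report = evaluate(pred, truth)
        assert got_table == table
        r = report.rounded()
        assert (
            r["accuracy"], r["ppv"], r["npv"], r["sensitivity"], r["specificity"]
        ) == expected

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            evaluate([], [])

    def test_undefined_ppv_is_nan(self):
        _, rep = evaluate(["CCR", "CCR"], ["R", "CCR"])
        assert np.isnan(rep.ppv)


class TestFisher:
    @pytest.mark.parametrize(
        "table,printed",
        [
            (ConfusionTable(2, 7, 0, 25), 0.064),
            (ConfusionTable(17, 5, 4, 24), 9.4e-6),
            (ConfusionTable(5, 5, 5, 5), 1.0),
        ],
    )
    def test_printed_p_values(self, table, printed):
        p = fisher_exact_two_sided(table)
        assert p == pytest.approx(printed, rel=0.02)

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact_two_sided(ConfusionTable(0, 0, 3, 7)) == 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_matches_enumeration_oracle(self, tp, fn, fp, tn):
        t = ConfusionTable(tp, fn, fp, tn)
        if t.n == 0 or min(tp + fn, fp + tn, tp + fp, fn + tn) == 0:
            assert fisher_exact_two_sided(t) == 1.0
        else:
            assert fisher_exact_two_sided(t) == pytest.approx(
                fisher_enumeration_oracle(t), rel=1e-9
            )


class TestConfusionFromMetrics:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((14, 30, 36, 93), ConfusionTable(5, 9, 2, 28)),   # COG 9404
            ((17, 24, 29, 96), ConfusionTable(5, 12, 1, 23)),  # POG 8704
            ((10, 10, 100, 100), ConfusionTable(10, 0, 0, 10)),
        ],
    )
    def test_unique_reconstruction(self, args, expected):
        assert confusion_from_metrics(*args) == expected

    def test_ambiguous_reconstruction_raises(self):
        with pytest.raises(AmbiguousReconstructionError):
            confusion_from_metrics(1000, 10, 50, 100)

    def test_round_trip_reproduces_every_printed_row(self):
        """Reconstructed tables reproduce all five metrics of every
        cohort row of the published validation panel exactly."""
        for (model, cohort), m in VALIDATION_PANEL.items():
            n_r, n_c = COHORT_SIZES[cohort]
            table = confusion_from_metrics(n_r, n_c, m["sens"], m["spec"])
            _, rep = evaluate(
                ["R"] * (table.tp + table.fp) + ["CCR"] * (table.fn + table.tn),
                ["R"] * table.tp + ["CCR"] * table.fp
                + ["R"] * table.fn + ["CCR"] * table.tn,
            )
            r = rep.rounded()
            assert (r["accuracy"], r["ppv"], r["npv"], r["sensitivity"],
                    r["specificity"]) == (
                m["acc"], m["ppv"], m["npv"], m["sens"], m["spec"]
            ), (model, cohort)


class TestSignatureModel:
    def test_perfect_separator_flags_and_hits_100(self):
        rng = np.random.default_rng(0)
        import pandas as pd

        n = 30
        labels = np.array(["R"] * 15 + ["CCR"] * 15)
        x = np.where(labels == "R", 9.0, 6.0) + rng.normal(0, 0.1, n)
        expr = pd.DataFrame([2.0**x], index=["SEP"],
                            columns=[f"s{i}" for i in range(n)])
        clin = pd.DataFrame(
            {"sample": expr.columns, "label": labels,
             "time_years": np.ones(n), "event": (labels == "R").astype(int),
             "age": 10.0, "wbc": 100.0, "sex": "M"}
        )
        cohort = Cohort(expr, clin)
        model = fit_signature_model(cohort, ["SEP"])
        assert model.separation_flag
        pred = predict_and_classify(model, cohort)
        _, rep = evaluate(pred["label"], labels)
        assert rep.accuracy == 100.0

    def test_cutoff_tie_classified_as_relapse(self, planted_cohort):
        model = SignatureModel(
            genes=[], coefficients=np.zeros(0), intercept=0.0
        )
        pred = predict_and_classify(model, planted_cohort)
        assert (pred["probability"] == 0.5).all()
        assert (pred["label"] == "R").all()

    def test_training_predictions_are_reproducible(self, planted_cohort):
        genes = [g for g in planted_cohort.expression.index[:5]]
        model = fit_signature_model(planted_cohort, genes)
        t1, _ = evaluate(
            predict_and_classify(model, planted_cohort)["label"],
            planted_cohort.clinical["label"],
        )
        t2, _ = evaluate(
            predict_and_classify(model, planted_cohort)["label"],
            planted_cohort.clinical["label"],
        )
        assert t1 == t2

    def test_null_single_gene_accuracy_near_prevalence(self):
        accs = []
        for seed in range(30):
            c = simulate_cohort(
                SimulationConfig(n_genes=5, planted_genes=(), seed=300 + seed)
            )
            model = fit_signature_model(c, [c.expression.index[0]])
            _, rep = evaluate(
                predict_and_classify(model, c)["label"], c.clinical["label"]
            )
            accs.append(rep.accuracy)
        assert np.mean(accs) == pytest.approx(56.0, abs=5.0)

    def test_planted_signature_training_accuracy(self, planted_cohort):
        genes = [f"SIG{i}" for i in range(5)]
        model = fit_signature_model(planted_cohort, genes)
        _, rep = evaluate(
            predict_and_classify(model, planted_cohort)["label"],
            planted_cohort.clinical["label"],
        )
        assert rep.accuracy >= 75.0

    def test_probability_monotone_in_each_gene(self, planted_cohort):
        genes = [f"SIG{i}" for i in range(3)]
        model = fit_signature_model(planted_cohort, genes)
        for j, g in enumerate(genes):
            bumped = planted_cohort.expression.copy()
            bumped.loc[g] *= 4.0  # +2 on log2 scale
            shifted = Cohort(bumped, planted_cohort.clinical)
            p0 = predict_and_classify(model, planted_cohort)["probability"]
            p1 = predict_and_classify(model, shifted)["probability"]
            direction = np.sign(model.coefficients[j])
            assert (direction * (p1 - p0) >= -1e-12).all()

    def test_missing_gene_error_lists_genes(self, planted_cohort):
        model = fit_signature_model(planted_cohort, ["SIG0"])
        model.genes = ["NOT_A_GENE"]
        from tallgc.models import MissingFeatureError

        with pytest.raises(MissingFeatureError, match="NOT_A_GENE"):
            predict_and_classify(model, planted_cohort)

    def test_json_round_trip(self, planted_cohort, tmp_path):
        model = fit_signature_model(planted_cohort, ["SIG0", "SIG1"])
        path = tmp_path / "model.json"
        model.to_json(path)
        back = SignatureModel.from_json(path)
        np.testing.assert_allclose(back.coefficients, model.coefficients)
        assert back.genes == model.genes
        assert back.intercept == pytest.approx(model.intercept)


def test_round_half_up():
    assert round_half_up(76.5) == 77
    assert round_half_up(85.4999) == 85
    assert round_half_up(93.5) == 94
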