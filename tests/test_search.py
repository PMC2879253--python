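"""PC1 projection scoring and the combinatorial signature search."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from tallgc import (
    SimulationConfig,
    combo_r2,
    pc1_scores,
    search_combinations,
    select_best_by_accuracy,
    simulate_cohort,
)
from tallgc.search import TruncatedSearchError
from tallgc.simulate import Cohort

PLANTED = tuple((f"SIG{i}", 2.0) for i in range(5))


class TestPC1Scores:
    def test_single_gene_gives_its_zscores(self, planted_cohort):
        sub = planted_cohort.expression.iloc[[0]]
        x = np.log2(sub.to_numpy()[0])
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(pc1_scores(sub), z, atol=1e-12)

    def test_perfectly_correlated_pair(self, planted_cohort):
        g = planted_cohort.expression.iloc[0]
        sub = pd.DataFrame({c: [g[c], g[c] ** 2] for c in g.index},
                           index=["a", "b"])
        scores = pc1_scores(sub)
        # PC1 carries all variance; scores proportional to either gene
        assert abs(np.corrcoef(scores, np.log2(g.to_numpy()))[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_matches_independent_eigendecomposition(self, rng):
        expr = pd.DataFrame(
            2.0 ** rng.normal(8, 1, (5, 20)),
            index=list("ABCDE"), columns=[f"s{i}" for i in range(20)],
        )
        scores = pc1_scores(expr)
        # oracle: scipy eigendecomposition of the covariance of z-scores
        x = np.log2(expr.to_numpy())
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        w, v = scipy.linalg.eigh(np.cov(z))
        lead = v[:, np.argmax(w)]
        oracle = lead @ z
        if np.corrcoef(oracle, scores)[0, 1] < 0:
            oracle = -oracle
        np.testing.assert_allclose(scores, oracle, atol=1e-8)

    def test_too_few_samples_raises(self, planted_cohort):
        with pytest.raises(ValueError):
            pc1_scores(planted_cohort.expression.iloc[:3, :2])

    def test_zero_variance_gene_dropped_with_warning(self, planted_cohort):
        sub = planted_cohort.expression.iloc[:2].copy()
        sub.iloc[1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            scores = pc1_scores(sub)
        np.testing.assert_allclose(scores, pc1_scores(sub.iloc[[0]]), atol=1e-12)


class TestComboR2:
    def test_single_gene_equals_point_biserial(self, planted_cohort):
        gene = "SIG0"
        cs = combo_r2(planted_cohort, (gene,))
        x = np.log2(planted_cohort.expression.loc[gene].to_numpy())
        r = np.corrcoef(x, planted_cohort.labels)[0, 1]
        assert cs.r2 == pytest.approx(r * r, abs=1e-12)

    def test_null_r2_expectation_is_one_over_n_minus_1(self, planted_cohort, rng):
        y = planted_cohort.labels.copy()
        x = pc1_scores(planted_cohort.expression.loc[["SIG0", "SIG1", "G00001"]])
        r2s = []
        for _ in range(400):
            yp = rng.permutation(y)
            r2s.append(np.corrcoef(x, yp)[0, 1] ** 2)
        n = planted_cohort.n
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), abs=0.006)

    def test_affine_transform_invariance(self, planted_cohort):
        warped = Cohort(3.0 * planted_cohort.expression**2.2, planted_cohort.clinical)
        genes = ("SIG0", "SIG1", "SIG2")
        assert combo_r2(planted_cohort, genes).r2 == pytest.approx(
            combo_r2(warped, genes).r2, abs=1e-10
        )

    def test_planted_combo_beats_random_tuples(self, planted_cohort, rng):
        planted = tuple(g for g, _ in PLANTED)
        target = combo_r2(planted_cohort, planted).r2
        others = [g for g in planted_cohort.expression.index if g not in planted]
        beaten = sum(
            combo_r2(planted_cohort, tuple(rng.choice(others, 5, replace=False))).r2 < target
            for _ in range(100)
        )
        assert beaten >= 99


class TestSearch:
    def test_exhaustive_matches_naive_enumeration(self, planted_cohort):
        shortlist = sorted(planted_cohort.expression.index[:8])
        got = search_combinations(planted_cohort, shortlist, k=3, top_t=56)
        naive = sorted(
            (combo_r2(planted_cohort, c) for c in itertools.combinations(shortlist, 3)),
            key=lambda cs: (-cs.r2, cs.genes),
        )
        assert len(got) == 56
        assert got[0].genes == naive[0].genes
        for a, b in zip(got, naive):
            assert a.genes == b.genes
            assert a.r2 == pytest.approx(b.r2, abs=1e-10)

    def test_k_equals_shortlist_returns_single_combo(self, planted_cohort):
        shortlist = list(planted_cohort.expression.index[:4])
        out = search_combinations(planted_cohort, shortlist, k=4)
        assert len(out) == 1
        assert out[0].genes == tuple(sorted(shortlist))

    def test_max_evals_exceeded_raises_not_truncates(self, planted_cohort):
        with pytest.raises(TruncatedSearchError):
            search_combinations(
                planted_cohort, list(planted_cohort.expression.index[:20]),
                k=5, max_evals=1000,
            )

    def test_result_independent_of_shortlist_order(self, planted_cohort, rng):
        shortlist = list(planted_cohort.expression.index[:10])
        a = search_combinations(planted_cohort, shortlist, k=3, top_t=10)
        b = search_combinations(
            planted_cohort, list(rng.permutation(shortlist)), k=3, top_t=10
        )
        assert [(c.genes, round(c.r2, 12)) for c in a] == [
            (c.genes, round(c.r2, 12)) for c in b
        ]

    def test_beam_bounded_by_exhaustive_and_exact_on_easy_case(self, planted_cohort):
        shortlist = [g for g, _ in PLANTED] + list(
            planted_cohort.expression.index[10:25]
        )
        ex = search_combinations(planted_cohort, shortlist, k=5, top_t=5)
        beam = search_combinations(
            planted_cohort, shortlist, k=5, strategy="beam", beam_width=40, top_t=5
        )
        assert beam[0].r2 <= ex[0].r2 + 1e-12
        assert beam[0].genes == ex[0].genes

    def test_select_best_by_accuracy_returns_fitted_model(self, planted_cohort):
        from tallgc import evaluate, fit_signature_model, predict_and_classify

        shortlist = [g for g, _ in PLANTED] + list(planted_cohort.expression.index[10:20])
        combos = search_combinations(planted_cohort, shortlist, k=5, top_t=10)
        combo, model, report = select_best_by_accuracy(planted_cohort, combos)
        assert set(model.genes) == set(combo.genes)
        accs = []
        for c in combos:
            m = fit_signature_model(planted_cohort, list(c.genes))
            pred = predict_and_classify(m, planted_cohort)
            _, rep = evaluate(pred["label"], planted_cohort.clinical["label"])
            accs.append(rep.accuracy)
        assert report.accuracy == max(accs)
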