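"""Logistic outcome classifier and the performance panel.

A signature model is a maximum-likelihood logistic regression of relapse
probability on the z-scored log2 expression of a fixed gene set,
thresholded at a 50% probability cutoff (ties classified as relapse —
conservative toward detecting relapse). Performance is summarised as a
2x2 confusion table, percent metrics (accuracy, PPV, NPV, sensitivity,
specificity) and a two-sided Fisher exact p-value.

On perfectly separable training data the unpenalised likelihood has no
maximum; the fit falls back to a weak L2 (ridge) penalty, lambda = 1e-4
on standardized features, and flags the model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .simulate import Cohort

__all__ = [
    "SignatureModel",
    "ConfusionTable",
    "PerformanceReport",
    "MissingFeatureError",
    "AmbiguousReconstructionError",
    "fit_signature_model",
    "predict_and_classify",
    "evaluate",
    "fisher_exact_two_sided",
    "confusion_from_metrics",
    "round_half_up",
]

RIDGE_LAMBDA = 1e-4  # separation fallback penalty on standardized features


class MissingFeatureError(KeyError):
    """A model gene is absent from the cohort it is applied to."""


class AmbiguousReconstructionError(ValueError):
    """Printed metrics do not pin down a unique integer confusion table."""


def round_half_up(x: float) -> int:
    """Round ties away from zero (for non-negative percentages)."""
    return int(math.floor(x + 0.5))


@dataclass
class SignatureModel:
    """Fitted logistic classifier over a fixed gene list.

    Coefficients act on per-gene z-scored log2 expression; the scaler
    (training means/sds on the log2 scale) travels with the model so it
    can be applied frozen to a new cohort.
    """

    genes: list
    coefficients: np.ndarray
    intercept: float
    cutoff: float = 0.5
    training_platform: str = ""
    separation_flag: bool = False
    scaler_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    scaler_sd: np.ndarray = field(default_factory=lambda: np.ones(0))

    def __post_init__(self):
        if len(self.coefficients) != len(self.genes):
            raise ValueError("one coefficient per gene required")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must be in (0, 1)")

    def to_json(self, path) -> None:
        d = asdict(self)
        for k in ("coefficients", "scaler_mean", "scaler_sd"):
            d[k] = np.asarray(d[k]).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("coefficients", "scaler_mean", "scaler_sd"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 outcome counts; tp = predicted-relapse and relapsed."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(
            self.tp + other.tp, self.fn + other.fn,
            self.fp + other.fp, self.tn + other.tn,
        )


@dataclass
class PerformanceReport:
    """Percent metrics + Fisher exact p for one confusion table.

    Metrics are kept at full precision; ``rounded()`` gives the integer
    percents used in formatted output. Undefined ratios (empty
    denominator) are NaN.
    """

    accuracy: float
    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    fisher_p: float
    n: int

    def rounded(self) -> dict:
        out = {}
        for k in ("accuracy", "ppv", "npv", "sensitivity", "specificity"):
            v = getattr(self, k)
            out[k] = round_half_up(v) if not math.isnan(v) else None
        out["fisher_p"] = self.fisher_p
        out["n"] = self.n
        return out

    def format_row(self, model: str = "", cohort: str = "") -> str:
        r = self.rounded()
        cells = [model, cohort] + [
            str(r[k]) if r[k] is not None else "-"
            for k in ("accuracy", "ppv", "npv", "sensitivity", "specificity")
        ]
        p = self.fisher_p
        cells.append("<0.0001" if p < 1e-4 else f"{p:.3g}")
        return "\t".join(cells)


def _design(cohort: Cohort, genes: list) -> np.ndarray:
    missing = [g for g in genes if g not in cohort.expression.index]
    if missing:
        raise MissingFeatureError(f"genes absent from cohort: {missing}")
    return np.log2(cohort.expression.loc[genes].to_numpy(dtype=float)).T


def fit_signature_model(
    cohort: Cohort, genes: list, cutoff: float = 0.5
) -> SignatureModel:
    """Maximum-likelihood logistic fit of relapse on z-scored log2
    expression of ``genes``; ridge fallback + flag on perfect separation."""
    y = cohort.labels
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    x = _design(cohort, genes)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd <= 1e-10, 1.0, sd)
    z = (x - mean) / sd

    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    clf.fit(z, y)
    # strict separation along the fitted direction means the unpenalised
    # likelihood has no maximum: fall back to a weak ridge and flag
    eta = z @ clf.coef_.ravel() + clf.intercept_[0]
    separated = bool(eta[y == 0].max() < eta[y == 1].min())
    if separated:
        clf = LogisticRegression(
            C=1.0 / RIDGE_LAMBDA, solver="lbfgs", max_iter=2000
        )
        clf.fit(z, y)

    return SignatureModel(
        genes=list(genes),
        coefficients=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        cutoff=cutoff,
        training_platform=cohort.platform,
        separation_flag=separated,
        scaler_mean=mean,
        scaler_sd=sd,
    )


def predict_and_classify(
    model: SignatureModel, cohort: Cohort, use_cohort_scaling: bool = False
) -> pd.DataFrame:
    """Relapse probability and R/CCR call per sample.

    By default features are standardized with the model's training scaler;
    ``use_cohort_scaling=True`` re-standardizes within the target cohort
    (robust to platform-wide shifts). Probability ties at the cutoff are
    called R.
    """
    x = _design(cohort, model.genes)
    if use_cohort_scaling:
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
    else:
        mean, sd = model.scaler_mean, model.scaler_sd
    z = (x - mean) / sd
    eta = z @ model.coefficients + model.intercept
    prob = 1.0 / (1.0 + np.exp(-eta))
    label = np.where(prob >= model.cutoff, "R", "CCR")
    return pd.DataFrame(
        {"probability": prob, "label": label},
        index=cohort.clinical["sample"].to_numpy(),
    )


def evaluate(predicted, truth) -> tuple[ConfusionTable, PerformanceReport]:
    """Confusion table and performance panel of predicted vs. true labels."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.size == 0:
        raise ValueError("no predictions to evaluate")
    if predicted.shape != truth.shape:
        raise ValueError("length mismatch")
    pred_r = predicted == ("R" if predicted.dtype.kind in "UOS" else 1)
    true_r = truth == ("R" if truth.dtype.kind in "UOS" else 1)
    table = ConfusionTable(
        tp=int((pred_r & true_r).sum()),
        fn=int((~pred_r & true_r).sum()),
        fp=int((pred_r & ~true_r).sum()),
        tn=int((~pred_r & ~true_r).sum()),
    )
    return table, performance_report(table)


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else float("nan")


def performance_report(t: ConfusionTable) -> PerformanceReport:
    return PerformanceReport(
        accuracy=_pct(t.tp + t.tn, t.n),
        ppv=_pct(t.tp, t.tp + t.fp),
        npv=_pct(t.tn, t.tn + t.fn),
        sensitivity=_pct(t.tp, t.tp + t.fn),
        specificity=_pct(t.tn, t.tn + t.fp),
        fisher_p=fisher_exact_two_sided(t),
        n=t.n,
    )


def fisher_exact_two_sided(table: ConfusionTable) -> float:
    """Two-sided Fisher exact p (point-probability method): the sum of
    hypergeometric probabilities of all tables with the observed margins
    whose point probability does not exceed the observed one."""
    a = table.as_array()
    if a.sum(axis=0).min() == 0 or a.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(a, alternative="two-sided")[1])


def confusion_from_metrics(
    n_relapse: int, n_ccr: int, sensitivity: float, specificity: float
) -> ConfusionTable:
    """Reconstruct the unique integer confusion table whose rounded percent
    sensitivity/specificity match the printed values."""
    tps = [
        tp for tp in range(n_relapse + 1)
        if round_half_up(_pct(tp, n_relapse)) == round(sensitivity)
    ]
    tns = [
        tn for tn in range(n_ccr + 1)
        if round_half_up(_pct(tn, n_ccr)) == round(specificity)
    ]
    if len(tps) != 1 or len(tns) != 1:
        raise AmbiguousReconstructionError(
            f"sensitivity candidates {tps}, specificity candidates {tns}"
        )
    tp, tn = tps[0], tns[0]
    return ConfusionTable(tp=tp, fn=n_relapse - tp, fp=n_ccr - tn, tn=tn)
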