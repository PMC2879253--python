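"""Multi-cohort validation of a gene signature.

A signature discovered in a training cohort is applied to independent
cohorts (possibly on other platforms or re-measured by qRT-PCR), giving
per-cohort confusion tables and performance panels, a pooled ("combined")
panel computed from the summed counts, and a combined exact p-value —
a two-sided Fisher test on the element-wise pooled 2x2 table, with
Fisher's-method combination of per-cohort p-values as an alternative.

Default application mode refits the logistic coefficients within each
cohort on the fixed gene set; this matches how a fixed classifier is
re-estimated when the measurement scale changes between platforms.
``frozen`` mode re-uses the training coefficients on within-cohort
z-scored features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    ConfusionTable,
    MissingFeatureError,
    PerformanceReport,
    SignatureModel,
    evaluate,
    fisher_exact_two_sided,
    fit_signature_model,
    performance_report,
    predict_and_classify,
)
from .simulate import Cohort

__all__ = [
    "ValidationRun",
    "match_genes",
    "validate_cohort",
    "pooled_performance",
    "combined_p",
    "run_validation",
]


@dataclass
class ValidationRun:
    """All per-cohort and pooled results of one validation campaign."""

    cohort_ids: list
    tables: list          # ConfusionTable per cohort
    reports: list         # PerformanceReport per cohort
    pooled_table: ConfusionTable
    pooled_report: PerformanceReport
    combined_p_all: float
    combined_p_excl_training: float
    refit_mode: str = "per-cohort"
    metadata: dict = field(default_factory=dict)

    def format_table(self, model_name: str = "signature") -> str:
        """Human-readable panel mirroring the validation-table layout."""
        header = "Model\tCohort\tAcc\tPPV\tNPV\tSens\tSpec\tP-value"
        rows = [header]
        for cid, rep in zip(self.cohort_ids, self.reports):
            rows.append(rep.format_row(model_name, cid))
        rows.append(self.pooled_report.format_row(model_name, "Combined"))
        return "\n".join(rows)


def match_genes(
    signature_genes: list,
    cohort: Cohort,
    annotation: pd.DataFrame | None = None,
    on_missing: str = "fail",
) -> pd.DataFrame:
    """Expression rows for the signature genes on this cohort's platform.

    With an annotation (probe_id, gene_symbol), each signature symbol maps
    to its probes and the probe with the highest mean expression is kept
    (the usual collapse rule); rows are re-labelled by symbol. Without an
    annotation the matrix is assumed to be keyed by symbol already.
    Unmatched genes raise (``on_missing='fail'``) or are dropped with the
    remaining rows returned (``'drop'``).
    """
    expr = cohort.expression
    rows, missing = [], []
    for gene in signature_genes:
        if annotation is not None:
            probes = annotation.loc[annotation["gene_symbol"] == gene, "probe_id"]
            probes = [p for p in probes if p in expr.index]
        else:
            probes = [gene] if gene in expr.index else []
        if not probes:
            missing.append(gene)
            continue
        best = max(probes, key=lambda p: expr.loc[p].mean())
        row = expr.loc[best].copy()
        row.name = gene
        rows.append(row)
    if missing and on_missing == "fail":
        raise MissingFeatureError(f"unmatched signature genes: {missing}")
    if not rows:
        raise MissingFeatureError("no signature gene matched the platform")
    return pd.DataFrame(rows)


def validate_cohort(
    signature_genes: list,
    cohort: Cohort,
    refit_mode: str = "per-cohort",
    model: SignatureModel | None = None,
    annotation: pd.DataFrame | None = None,
) -> tuple[ConfusionTable, PerformanceReport]:
    """Apply the signature to one cohort and score it.

    ``per-cohort`` refits logistic coefficients within the cohort on the
    fixed gene set (default); ``frozen`` applies ``model``'s training
    coefficients to within-cohort z-scored features.
    """
    matched = match_genes(signature_genes, cohort, annotation)
    sub = Cohort(matched, cohort.clinical, platform=cohort.platform)
    if refit_mode == "per-cohort":
        fitted = fit_signature_model(sub, list(matched.index))
        pred = predict_and_classify(fitted, sub)
    elif refit_mode == "frozen":
        if model is None:
            raise ValueError("frozen mode requires the training model")
        pred = predict_and_classify(model, sub, use_cohort_scaling=True)
    else:
        raise ValueError(f"unknown refit_mode: {refit_mode!r}")
    table, report = evaluate(pred["label"], cohort.clinical["label"])
    return table, report


def pooled_performance(
    tables: list[ConfusionTable],
) -> tuple[ConfusionTable, PerformanceReport]:
    """Sum confusion counts across cohorts and score the pooled table —
    the count-weighted ("weighted average") panel."""
    if not tables:
        raise ValueError("no tables to pool")
    pooled = tables[0]
    for t in tables[1:]:
        pooled = pooled + t
    return pooled, performance_report(pooled)


def combined_p(
    tables: list[ConfusionTable],
    exclude: list | None = None,
    cohort_ids: list | None = None,
    method: str = "pooled-fisher",
) -> float:
    """Combined significance of classifier performance across cohorts.

    ``pooled-fisher`` (default): two-sided Fisher exact test on the
    element-wise pooled 2x2 table. ``fisher-method``: Fisher's chi-square
    combination of the per-cohort Fisher p-values. ``exclude`` drops
    cohorts by id (requires ``cohort_ids``) or by position.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 cohorts to combine")
    keep = list(range(len(tables)))
    if exclude:
        if cohort_ids is not None:
            keep = [i for i in keep if cohort_ids[i] not in set(exclude)]
        else:
            keep = [i for i in keep if i not in set(exclude)]
    kept = [tables[i] for i in keep]
    if not kept:
        raise ValueError("all cohorts excluded")
    if method == "pooled-fisher":
        pooled, _ = pooled_performance(kept)
        return fisher_exact_two_sided(pooled)
    if method == "fisher-method":
        ps = [fisher_exact_two_sided(t) for t in kept]
        return float(stats.combine_pvalues(ps, method="fisher")[1])
    raise ValueError(f"unknown method: {method!r}")


def run_validation(
    signature_genes: list,
    cohorts: dict,
    training_id: str | None = None,
    refit_mode: str = "per-cohort",
    model: SignatureModel | None = None,
    annotations: dict | None = None,
    combine_method: str = "pooled-fisher",
) -> ValidationRun:
    """Validate a signature across a dict of ``{cohort_id: Cohort}``.

    Computes per-cohort panels, the pooled panel, the combined p over all
    cohorts and (when ``training_id`` is given) the combined p excluding
    the training cohort.
    """
    ids = list(cohorts)
    tables, reports = [], []
    for cid in ids:
        ann = (annotations or {}).get(cid)
        t, r = validate_cohort(
            signature_genes, cohorts[cid], refit_mode=refit_mode,
            model=model, annotation=ann,
        )
        tables.append(t)
        reports.append(r)
    pooled_table, pooled_report = pooled_performance(tables)
    p_all = combined_p(tables, method=combine_method) if len(tables) > 1 else (
        pooled_report.fisher_p
    )
    if training_id is not None and len(tables) > 2:
        p_excl = combined_p(
            tables, exclude=[training_id], cohort_ids=ids, method=combine_method
        )
    elif training_id is not None and len(tables) == 2:
        other = [t for cid, t in zip(ids, tables) if cid != training_id]
        p_excl = fisher_exact_two_sided(other[0]) if other else float("nan")
    else:
        p_excl = float("nan")
    return ValidationRun(
        cohort_ids=ids,
        tables=tables,
        reports=reports,
        pooled_table=pooled_table,
        pooled_report=pooled_report,
        combined_p_all=p_all,
        combined_p_excl_training=p_excl,
        refit_mode=refit_mode,
        metadata={"combine_method": combine_method},
    )
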