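"""Published reference values for the five-gene T-ALL relapse classifier.

These fixtures carry the printed study results that the pipeline's
reconstruction utilities operate on: the five classifier genes with their
expression levels and array/qRT-PCR fold changes, the cohort class sizes,
and the cohort-by-model validation panel (percent metrics and Fisher
exact p-values). The per-cohort confusion tables are not printed anywhere
— they are recovered from the class sizes and the rounded sensitivity /
specificity via :func:`tallgc.models.confusion_from_metrics`.
"""

from __future__ import annotations

# gene -> (probe_id, rf_rank, mean_R, mean_CCR, fold_array, fold_qpcr, cross_assay_r)
FIVE_GENE_CLASSIFIER = {
    "ABTB2": ("213497_at", 12, 119.8, 89.7, 1.34, 3.11, 0.76),
    "IL7R": ("205798_at", 43, 292.0, 542.7, 0.54, 0.47, 0.92),
    "LGALS8": ("208936_x_at", 288, 197.4, 231.8, 0.85, 0.37, 0.56),
    "PLAC8": ("219014_at", 297, 530.4, 979.5, 0.54, 0.22, 0.90),
    "FAM13A1": ("217047_s_at", 356, 70.0, 84.0, 0.83, 0.30, 0.69),
}

# cohort -> (n_relapse, n_ccr); induction-failure cases already removed
COHORT_SIZES = {
    "Training": (22, 28),
    "Validation": (9, 25),
    "COG 9404": (14, 30),
    "POG 8704": (17, 24),
}

# (model, cohort) -> dict of printed percent metrics + Fisher p
VALIDATION_PANEL = {
    ("5-GC", "Training"): dict(acc=82, ppv=81, npv=83, sens=77, spec=86, p=9.4e-6),
    ("5-GC", "Validation"): dict(acc=79, ppv=100, npv=78, sens=22, spec=100, p=0.064),
    ("5-GC", "COG 9404"): dict(acc=75, ppv=71, npv=76, sens=36, spec=93, p=0.025),
    ("5-GC", "POG 8704"): dict(acc=68, ppv=83, npv=66, sens=29, spec=96, p=0.066),
    ("NFkB", "Training"): dict(acc=76, ppv=71, npv=81, sens=77, spec=75, p=4.8e-4),
    ("NFkB", "COG 9404"): dict(acc=77, ppv=83, npv=76, sens=36, spec=97, p=0.009),
    ("NFkB", "POG 8704"): dict(acc=56, ppv=44, npv=59, sens=24, spec=79, p=1.0),
    ("Wnt", "Training"): dict(acc=76, ppv=75, npv=77, sens=68, spec=82, p=4.6e-4),
    ("Wnt", "COG 9404"): dict(acc=75, ppv=67, npv=77, sens=43, spec=90, p=0.019),
    ("Wnt", "POG 8704"): dict(acc=68, ppv=63, npv=72, sens=59, spec=75, p=0.05),
    ("CellAdhesion", "Training"): dict(acc=82, ppv=84, npv=81, sens=73, spec=89, p=8.6e-6),
    ("CellAdhesion", "COG 9404"): dict(acc=75, ppv=62, npv=81, sens=57, spec=83, p=0.012),
    ("CellAdhesion", "POG 8704"): dict(acc=85, ppv=87, npv=85, sens=76, spec=92, p=1.1e-5),
}

# model -> printed pooled ("Combined") metrics, combined p over all listed
# cohorts and, in parentheses in the source table, excluding Training
COMBINED_PANEL = {
    "5-GC": dict(acc=76, ppv=81, npv=75, sens=47, spec=93,
                 p=1.5e-9, p_excl_training=1.2e-4),
    "NFkB": dict(acc=70, ppv=67, npv=72, sens=49, spec=84,
                 p=7.2e-5, p_excl_training=0.073),
    "Wnt": dict(acc=73, ppv=69, npv=76, sens=58, spec=83,
                 p=8.7e-7, p_excl_training=0.0011),
    "CellAdhesion": dict(acc=81, ppv=79, npv=82, sens=70, spec=88,
                         p=8.2e-12, p_excl_training=4.5e-7),
}

# pathway model sizes: leading-edge genes entering each pathway classifier
PATHWAY_MODEL_SIZES = {"NFkB": 7, "Wnt": 12, "CellAdhesion": 14}

# survival structure of the two in-house cohorts (median years and range)
SURVIVAL_STRUCTURE = {
    "Training": dict(followup_median=7.3, followup_range=(3.3, 9.2),
                     relapse_median=1.3, relapse_range=(0.2, 3.8)),
    "Validation": dict(followup_median=8.8, followup_range=(4.3, 11.9),
                       relapse_median=1.4, relapse_range=(0.5, 3.3)),
}


def panel_cohorts(model: str) -> list[str]:
    """Cohorts with printed metrics for a model (the qRT-PCR validation
    cohort is only available for the five-gene classifier)."""
    return [c for (m, c) in VALIDATION_PANEL if m == model]
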