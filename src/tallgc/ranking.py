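"""Random-Forest gene ranking and shortlist filters.

Genes are ranked by permutation (mean-decrease-in-accuracy) importance of
a Random Forest trained to separate relapse from CCR samples on log2
expression. The candidate pool for the combination search is then the top
``top_n`` genes minus probe sets from the predecessor B chip (by numeric
probe-id prefix) and minus genes below a mean-expression floor — a
transparent proxy for qRT-PCR detectability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .simulate import Cohort

__all__ = ["ShortlistFilterConfig", "rank_genes", "apply_shortlist", "fold_change"]


@dataclass
class ShortlistFilterConfig:
    """Shortlist filters applied to a ranking.

    ``b_chip_id_threshold`` drops probe ids whose leading integer is at or
    above the threshold (the Affymetrix id ranges of the HG-U133B chip);
    ids without a numeric prefix (plain gene symbols) are kept.
    ``min_mean_expression`` is a linear-intensity floor standing in for a
    qRT-PCR detectability call.
    """

    top_n: int = 500
    b_chip_id_threshold: int | None = 222000
    min_mean_expression: float = 50.0

    def __post_init__(self):
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


def _log2_z(expr: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene z-scored log2 expression (samples x genes) and a mask of
    zero-variance genes (their columns are set to 0)."""
    x = np.log2(expr.to_numpy(dtype=float)).T
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    zero_var = sd <= 1e-10
    z = (x - mean) / np.where(zero_var, 1.0, sd)
    z[:, zero_var] = 0.0
    return z, zero_var


def rank_genes(
    cohort: Cohort,
    n_trees: int = 1000,
    seed: int = 0,
    n_repeats: int = 5,
) -> pd.DataFrame:
    """Rank all genes by RF permutation importance on log2 expression.

    Returns a DataFrame with columns ``gene``, ``score``, ``rank`` sorted by
    rank (1-based). Importance is the classical mean decrease in accuracy:
    for each tree, the accuracy on its own out-of-bag samples is compared
    before and after permuting the gene's column, and the drop is averaged
    over all trees and ``n_repeats`` permutations. (Out-of-bag, not
    training, accuracy: a fully grown forest reproduces its training
    labels even after permuting single features, which would zero out
    every score.) Only trees that actually split on a gene can change
    their predictions, so only those are re-evaluated. Zero-variance genes
    score 0 and rank last; remaining ties break by gene id.
    """
    y = cohort.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need >= 2 samples per class")
    if cohort.expression.isna().any().any():
        raise ValueError("expression contains missing values")

    genes = list(cohort.expression.index)
    x, zero_var = _log2_z(cohort.expression)
    n = x.shape[0]

    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed,
        bootstrap=True, n_jobs=1,
    )
    rf.fit(x, y)

    # per-tree OOB baseline accuracies and the features each tree splits on
    tree_info = []  # (oob_idx, base_correct_count)
    feature_trees: dict[int, list[int]] = {}
    for t_idx, (tree, inbag) in enumerate(zip(rf.estimators_, rf.estimators_samples_)):
        oob = np.setdiff1d(np.arange(n), inbag)
        if oob.size == 0:
            tree_info.append((oob, 0))
            continue
        correct = int((tree.predict(x[oob]) == y[oob]).sum())
        tree_info.append((oob, correct))
        for j in np.unique(tree.tree_.feature[tree.tree_.feature >= 0]):
            feature_trees.setdefault(int(j), []).append(t_idx)

    rng = np.random.default_rng(seed)
    scores = np.zeros(len(genes))
    for j, t_idxs in feature_trees.items():
        col = x[:, j].copy()
        drop = 0.0
        for _ in range(n_repeats):
            x[:, j] = col[rng.permutation(n)]
            for t_idx in t_idxs:
                oob, base_correct = tree_info[t_idx]
                if oob.size == 0:
                    continue
                new_correct = int(
                    (rf.estimators_[t_idx].predict(x[oob]) == y[oob]).sum()
                )
                drop += (base_correct - new_correct) / oob.size
        x[:, j] = col
        scores[j] = drop / (n_repeats * n_trees)
    # negative drops are permutation noise; importances are >= 0
    scores = np.maximum(scores, 0.0)

    order = sorted(
        range(len(genes)),
        key=lambda i: (-scores[i], bool(zero_var[i]), genes[i]),
    )
    out = pd.DataFrame(
        {
            "gene": [genes[i] for i in order],
            "score": scores[order],
            "rank": np.arange(1, len(genes) + 1),
        }
    )
    return out


def _numeric_prefix(probe_id: str) -> int | None:
    digits = ""
    for ch in str(probe_id):
        if ch.isdigit():
            digits += ch
        else:
            break
    return int(digits) if digits else None


def apply_shortlist(
    ranking: pd.DataFrame, expr: pd.DataFrame, cfg: ShortlistFilterConfig
) -> list[str]:
    """Top-``top_n`` genes of ``ranking`` after the B-chip and expression
    filters, in rank order. Warns (and returns []) if nothing survives."""
    missing = set(expr.index) - set(ranking["gene"])
    if missing:
        raise ValueError(f"ranking does not cover matrix genes: {sorted(missing)[:5]}")
    mean_expr = expr.mean(axis=1)
    shortlist = []
    for gene in ranking["gene"].head(cfg.top_n):
        if cfg.b_chip_id_threshold is not None:
            prefix = _numeric_prefix(gene)
            if prefix is not None and prefix >= cfg.b_chip_id_threshold:
                continue
        if mean_expr.loc[gene] < cfg.min_mean_expression:
            continue
        shortlist.append(gene)
    if not shortlist:
        warnings.warn("shortlist filters removed every gene", stacklevel=2)
    return shortlist


def fold_change(expr: pd.DataFrame, labels, gene: str) -> float:
    """Ratio of linear-scale class means, relapse over CCR."""
    labels = np.asarray(labels)
    is_r = labels == ("R" if labels.dtype.kind in "UOS" else 1)
    if is_r.all() or (~is_r).all():
        raise ValueError("both classes must be present")
    row = expr.loc[gene].to_numpy(dtype=float)
    ccr_mean = row[~is_r].mean()
    if ccr_mean == 0:
        raise ZeroDivisionError(f"CCR mean expression of {gene} is zero")
    return float(row[is_r].mean() / ccr_mean)
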