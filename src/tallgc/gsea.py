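"""Minimal ranked-list gene-set enrichment analysis (GSEA).

Given a gene list ranked by outcome association (here: Random-Forest
importance) and a collection of gene sets, computes the weighted
Kolmogorov-Smirnov enrichment score (ES), a permutation null for the
nominal p and normalized ES (NES), an NES-based false-discovery-rate q
across sets, and the leading edge — the set members at or before the
running-sum peak that drive the enrichment. Leading-edge genes feed a
pathway-level logistic outcome classifier.

The desk-scale default null permutes gene-set membership on the fixed
ranked list; a phenotype-permutation null (re-ranking genes under
permuted outcome labels) is available when a cohort is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "enrichment_score",
    "permutation_null",
    "fdr_across_sets",
    "leading_edge",
    "pathway_classifier",
    "run_gsea",
    "significant",
    "phenotype_null_rankings",
]

# Study-style significance defaults for calling a gene set enriched.
FDR_THRESHOLD = 0.25
NOMINAL_P_THRESHOLD = 0.001


@dataclass
class GeneSet:
    name: str
    members: set

    def __post_init__(self):
        self.members = set(self.members)
        if not self.members:
            raise ValueError("gene set must be non-empty")


@dataclass
class EnrichmentResult:
    """Enrichment of one gene set against one ranked list."""

    name: str
    es: float
    nes: float
    nominal_p: float
    peak_index: int
    leading_edge: list
    fdr_q: float = float("nan")
    below_resolution: bool = False  # observed |ES| beyond every null
    degenerate_null: bool = False
    null_es: np.ndarray = field(default_factory=lambda: np.zeros(0), repr=False)


def _check_ranked(genes) -> list:
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    return genes


def enrichment_score(genes, scores, gene_set: GeneSet, weight_exponent: float = 1.0):
    """Weighted KS running statistic over the ranked list.

    Hits advance the sum by |score|^w normalized by the in-set total;
    misses retreat by 1/(N - |set|). Returns ``(es, running, peak_index)``
    where es is the signed extremum of the running sum and peak_index its
    position. A set covering the whole list has no misses to deviate from
    and scores 0.
    """
    genes = _check_ranked(genes)
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(genes):
        raise ValueError("scores must align with genes")
    hit = np.fromiter((g in gene_set.members for g in genes), bool, len(genes))
    return _es_from_hits(hit, scores, weight_exponent)


def _es_from_hits(hit: np.ndarray, scores: np.ndarray, w: float):
    n = hit.shape[0]
    m = int(hit.sum())
    if m == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if m == n:
        return 0.0, np.zeros(n), 0
    weights = np.abs(scores) ** w if w != 0 else np.ones(n)
    total = weights[hit].sum()
    if total == 0:
        weights = np.ones(n)
        total = float(m)
    step = np.where(hit, weights / total, -1.0 / (n - m))
    running = np.cumsum(step)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), running, peak


def permutation_null(
    genes,
    scores,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    null_rankings=None,
) -> EnrichmentResult:
    """Observed ES plus a permutation null giving nominal p and NES.

    Default null: redraw the set membership uniformly on the fixed ranked
    list (``n_perm`` draws). Supplying ``null_rankings`` — a list of
    (genes, scores) re-rankings, e.g. from permuted phenotype labels via
    :func:`phenotype_null_rankings` — switches to a phenotype null.

    nominal p = fraction of same-sign null ES at least as extreme as the
    observed; when no null reaches it the p is reported at the resolution
    floor 1/n_perm with ``below_resolution`` set. NES = ES divided by the
    mean same-sign null ES magnitude.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    genes = _check_ranked(genes)
    scores = np.asarray(scores, dtype=float)
    es, running, peak = enrichment_score(genes, scores, gene_set, weight_exponent)
    m = len(gene_set.members & set(genes))
    n = len(genes)
    rng = np.random.default_rng(seed)

    null = np.empty(n_perm)
    if null_rankings is None:
        hit = np.zeros(n, dtype=bool)
        for i in range(n_perm):
            hit[:] = False
            hit[rng.choice(n, m, replace=False)] = True
            null[i], _, _ = _es_from_hits(hit, scores, weight_exponent)
    else:
        if len(null_rankings) < n_perm:
            raise ValueError("fewer null rankings than n_perm")
        for i in range(n_perm):
            g_i, s_i = null_rankings[i]
            null[i], _, _ = enrichment_score(g_i, s_i, gene_set, weight_exponent)

    degenerate = bool(np.all(null == 0.0))
    same_sign = null >= 0 if es >= 0 else null <= 0
    n_same = int(same_sign.sum())
    if degenerate or n_same == 0:
        warnings.warn(f"degenerate permutation null for set {gene_set.name}", stacklevel=2)
        nominal_p, nes, below = 1.0, float("nan"), False
    else:
        hits_as_extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        below = hits_as_extreme == 0
        nominal_p = max(hits_as_extreme, 1) / n_same
        denom = np.abs(null[same_sign]).mean()
        nes = float(es / denom) if denom > 0 else float("nan")

    return EnrichmentResult(
        name=gene_set.name,
        es=es,
        nes=nes,
        nominal_p=float(nominal_p),
        peak_index=peak,
        leading_edge=leading_edge(genes, gene_set, es, peak),
        below_resolution=below,
        degenerate_null=degenerate,
        null_es=null,
    )


def leading_edge(genes, gene_set: GeneSet, es: float, peak_index: int) -> list:
    """Set members at or before the running-sum peak (positive ES) or
    strictly after the trough (negative ES), in rank order."""
    genes = list(genes)
    if es >= 0:
        span = range(0, peak_index + 1)
    else:
        span = range(peak_index + 1, len(genes))
    return [genes[i] for i in span if genes[i] in gene_set.members]


def fdr_across_sets(results: list[EnrichmentResult]) -> np.ndarray:
    """NES-based GSEA false-discovery rate across sets.

    Each set's null ES values are normalized to null NES by the same
    same-sign mean used for the observed NES, pooled over sets; the raw q
    at an observed NES* is the ratio of null-to-observed tail fractions at
    NES*, clipped to [0, 1] and monotonized (within each sign, a more
    extreme NES never has a larger q). Results are updated in place.
    """
    if not results:
        raise ValueError("no enrichment results")
    null_nes = []
    for r in results:
        null = r.null_es
        pos, neg = null[null >= 0], null[null < 0]
        out = np.empty_like(null)
        out[null >= 0] = pos / pos.mean() if pos.size and pos.mean() > 0 else 0.0
        out[null < 0] = -neg / neg.mean() if neg.size else 0.0
        null_nes.append(out)
    pool = np.concatenate(null_nes)
    obs = np.array([r.nes for r in results])
    q = np.ones(len(results))
    for i, r in enumerate(results):
        if np.isnan(r.nes):
            q[i] = 1.0
            continue
        if r.nes >= 0:
            null_tail = (pool >= r.nes).sum() / max((pool >= 0).sum(), 1)
            obs_tail = (obs >= r.nes).sum() / max((obs >= 0).sum(), 1)
        else:
            null_tail = (pool <= r.nes).sum() / max((pool < 0).sum(), 1)
            obs_tail = (obs <= r.nes).sum() / max((obs < 0).sum(), 1)
        q[i] = min(null_tail / obs_tail, 1.0) if obs_tail > 0 else 1.0
    # monotonize within each sign, most extreme NES first
    for sign in (1, -1):
        side = [i for i in range(len(results)) if np.sign(obs[i]) == sign or
                (sign == 1 and obs[i] == 0)]
        side.sort(key=lambda i: -abs(obs[i]))
        running = np.minimum.accumulate(q[side][::-1])[::-1] if side else []
        for i, qi in zip(side, running):
            q[i] = qi
    for r, qi in zip(results, q):
        r.fdr_q = float(qi)
    return q


def significant(
    results: list[EnrichmentResult],
    fdr_threshold: float = FDR_THRESHOLD,
    p_threshold: float = NOMINAL_P_THRESHOLD,
) -> list[EnrichmentResult]:
    """Sets passing the FDR and nominal-p calls."""
    return [
        r for r in results
        if r.fdr_q < fdr_threshold and r.nominal_p < p_threshold
    ]


def run_gsea(
    genes,
    scores,
    gene_sets: list[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    null_rankings=None,
) -> list[EnrichmentResult]:
    """Enrichment + FDR for a whole gene-set collection."""
    results = [
        permutation_null(
            genes, scores, gs, n_perm=n_perm, seed=seed + j,
            weight_exponent=weight_exponent, null_rankings=null_rankings,
        )
        for j, gs in enumerate(gene_sets)
    ]
    fdr_across_sets(results)
    return results


def phenotype_null_rankings(cohort, n_perm: int, seed: int = 0) -> list:
    """Re-rank genes under permuted outcome labels (signal-to-noise ratio
    on log2 expression) for a phenotype-permutation null."""
    x = np.log2(cohort.expression.to_numpy(dtype=float))
    genes = list(cohort.expression.index)
    y = cohort.labels.astype(bool)
    rng = np.random.default_rng(seed)
    rankings = []
    for _ in range(n_perm):
        perm = rng.permutation(y)
        mu_r, mu_c = x[:, perm].mean(axis=1), x[:, ~perm].mean(axis=1)
        sd = x[:, perm].std(axis=1) + x[:, ~perm].std(axis=1)
        snr = (mu_r - mu_c) / np.where(sd == 0, 1.0, sd)
        order = np.argsort(-snr, kind="stable")
        rankings.append(([genes[i] for i in order], snr[order]))
    return rankings


def pathway_classifier(cohort, leading_edge_genes: list):
    """Logistic outcome classifier on a pathway's leading-edge genes
    (delegates to :func:`tallgc.models.fit_signature_model`)."""
    from .models import fit_signature_model

    present = [g for g in leading_edge_genes if g in cohort.expression.index]
    if not present:
        raise ValueError("no leading-edge gene present in cohort")
    if len(present) < len(leading_edge_genes):
        warnings.warn(
            f"{len(leading_edge_genes) - len(present)} leading-edge gene(s) "
            "absent from cohort; fitting on the rest", stacklevel=2
        )
    return fit_signature_model(cohort, present)
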