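"""Panel classification by IC50 cutoff and gene set enrichment analysis.

The GSEA engine is implemented from scratch:

* genes are ranked by the signal-to-noise statistic
  (mean_sensitive - mean_resistant) / (sd_sensitive + sd_resistant) with
  each class SD floored at max(0.2 * |class mean|, 0.2);
* the enrichment score is the signed maximum deviation of the weighted
  running sum (hits increment by |score|^p / sum over the set, misses
  decrement by 1 / (N - N_set); weight p defaults to 1);
* the null is built from phenotype-label permutations at fixed group
  sizes (exhaustive enumeration when the design admits fewer distinct
  label assignments than requested permutations); NES normalizes each ES
  by the mean same-sign permutation ES, nominal p comes from the
  same-sign permutation tail, and FDR q follows the standard
  positive/negative-NES pooled procedure.

Results are deterministic for a fixed seed and invariant to the gene order
of the input matrix and to sample order within a phenotype class (genes and
samples are canonically sorted internally).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import comb

from .dose_response import Censored, is_finite_value
from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "PanelEntry",
    "PanelClassification",
    "EnrichmentResult",
    "classify_panel",
    "rank_genes_s2n",
    "enrichment_score",
    "gsea",
]

SENSITIVE = "sensitive"
RESISTANT = "resistant"


@dataclass(frozen=True)
class PanelEntry:
    cell_line: str
    ic50_abs: float | Censored
    label: str  # sensitive | resistant | ambiguous


@dataclass
class PanelClassification:
    entries: list[PanelEntry]
    n_sensitive: int
    n_resistant: int
    ambiguous: list[str] = field(default_factory=list)


def classify_panel(
    ic50_by_line: Mapping[str, float | Censored], cutoff: float = 100.0
) -> PanelClassification:
    """Split a cell-line panel at an absolute-IC50 cutoff (default 100 nM).

    Strict inequality: finite IC50 < cutoff -> sensitive, > cutoff ->
    resistant; exactly the cutoff -> resistant (documented tie rule).
    Censored ">x" with x >= cutoff is resistant; "<x" with x <= cutoff is
    sensitive; any other censored value is flagged ambiguous and excluded
    from both groups.
    """
    entries: list[PanelEntry] = []
    ambiguous: list[str] = []
    for line in sorted(ic50_by_line):
        ic50 = ic50_by_line[line]
        if is_finite_value(ic50):
            label = SENSITIVE if ic50 < cutoff else RESISTANT
        elif isinstance(ic50, Censored):
            if ic50.direction == ">" and ic50.bound >= cutoff:
                label = RESISTANT
            elif ic50.direction == "<" and ic50.bound <= cutoff:
                label = SENSITIVE
            else:
                label = "ambiguous"
                ambiguous.append(line)
        else:
            raise ValueError(f"unusable IC50 for {line}: {ic50!r}")
        entries.append(PanelEntry(line, ic50, label))
    return PanelClassification(
        entries=entries,
        n_sensitive=sum(e.label == SENSITIVE for e in entries),
        n_resistant=sum(e.label == RESISTANT for e in entries),
        ambiguous=ambiguous,
    )


# ---------------------------------------------------------------------------
# gene ranking


def _s2n_scores(
    values: np.ndarray, sens_mask: np.ndarray, floor_frac: float = 0.2
) -> np.ndarray:
    """Signal-to-noise per gene for one label assignment (vectorized)."""
    vs, vr = values[:, sens_mask], values[:, ~sens_mask]
    ms, mr = vs.mean(axis=1), vr.mean(axis=1)
    ss = vs.std(axis=1, ddof=1)
    sr = vr.std(axis=1, ddof=1)
    ss = np.maximum(ss, np.maximum(floor_frac * np.abs(ms), floor_frac))
    sr = np.maximum(sr, np.maximum(floor_frac * np.abs(mr), floor_frac))
    return (ms - mr) / (ss + sr)


def rank_genes_s2n(
    expr: ExpressionMatrix, positive_class: str = SENSITIVE
) -> list[tuple[str, float]]:
    """Rank genes by signal-to-noise, descending; ties break by gene id."""
    classes = expr.classes
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 phenotype classes, got {classes}")
    if positive_class not in classes:
        raise ValueError(f"unknown class {positive_class!r}")
    scores = _s2n_scores(expr.values, expr.class_mask(positive_class))
    order = sorted(range(len(expr.genes)), key=lambda i: (-scores[i], expr.genes[i]))
    return [(expr.genes[i], float(scores[i])) for i in order]


# ---------------------------------------------------------------------------
# enrichment score


def enrichment_score(
    ranked: Sequence[tuple[str, float]] | None = None,
    gene_set: Sequence[str] | None = None,
    weight: float = 1.0,
    *,
    scores: np.ndarray | None = None,
    member: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """ES of one gene set against a ranked list; returns (es, running sum).

    Accepts either a ranked ``[(gene, score), ...]`` list plus the set's
    gene identifiers, or pre-computed arrays (``scores`` ordered descending
    and boolean ``member``).  The running sum increments by
    |score|^weight / sum(|score in set|^weight) on hits and decrements by
    1/(N - N_set) on misses; ES is the signed maximum deviation from zero.
    """
    if scores is None or member is None:
        if ranked is None or gene_set is None:
            raise ValueError("provide (ranked, gene_set) or (scores, member)")
        genes = [g for g, _ in ranked]
        scores = np.array([s for _, s in ranked], dtype=float)
        in_set = set(gene_set)
        member = np.array([g in in_set for g in genes])
    n = len(scores)
    n_set = int(member.sum())
    if n_set == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_set == n:
        raise ValueError("gene set covers the entire ranked list")
    w = np.abs(scores) ** weight
    hit_w = np.where(member, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all member scores zero: fall back to unweighted hits
        hit_w = member.astype(float)
        denom = float(n_set)
    running = np.cumsum(hit_w / denom - (~member) / (n - n_set))
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running


@dataclass
class EnrichmentResult:
    set_name: str
    size: int
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: list[str]
    direction: str  # class the set is enriched in


def _label_assignments(
    n_samples: int, n_positive: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean matrix (n_assignments, n_samples) of positive-label masks."""
    total = comb(n_samples, n_positive, exact=True)
    if total <= n_perm:
        masks = np.zeros((total, n_samples), dtype=bool)
        for i, combo in enumerate(
            itertools.combinations(range(n_samples), n_positive)
        ):
            masks[i, list(combo)] = True
        return masks
    masks = np.zeros((n_perm, n_samples), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n_samples, size=n_positive, replace=False)] = True
    return masks


def _es_for_ranking(
    scores: np.ndarray,
    member: np.ndarray,
    weight: float,
) -> np.ndarray:
    """ES for every set (rows of ``member``) against one ordered score vector."""
    n_sets, n = member.shape
    w = np.abs(scores) ** weight
    hit_w = member * w
    denom = hit_w.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    if zero.any():
        hit_w[zero] = member[zero].astype(float)
        denom[zero, 0] = member[zero].sum(axis=1)
    sizes = member.sum(axis=1, keepdims=True)
    running = np.cumsum(hit_w / denom - (~member) / (n - sizes), axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_sets), idx]


def gsea(
    expr: ExpressionMatrix,
    gene_sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 500,
    weight: float = 1.0,
    positive_class: str = SENSITIVE,
    fdr_threshold: float = 0.25,
) -> list[EnrichmentResult]:
    """Two-class GSEA with a phenotype-permutation null.

    Sets are filtered to [min_size, max_size] after intersection with the
    measured genes.  Positive ES means enrichment in ``positive_class``.
    Results are sorted by NES, descending.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is low; p and FDR estimates will be coarse",
            stacklevel=2,
        )
    classes = expr.classes
    if len(classes) != 2 or positive_class not in classes:
        raise ValueError(f"need 2 classes including {positive_class!r}")

    # canonical internal order: genes by id, samples by (class, id) --
    # makes results invariant to input gene/sample order
    gene_order = sorted(range(len(expr.genes)), key=lambda i: expr.genes[i])
    genes = [expr.genes[i] for i in gene_order]
    sample_order = sorted(
        range(len(expr.samples)),
        key=lambda j: (expr.phenotype[expr.samples[j]], expr.samples[j]),
    )
    samples = [expr.samples[j] for j in sample_order]
    values = expr.values[np.ix_(gene_order, sample_order)]
    sens_mask = np.array([expr.phenotype[s] == positive_class for s in samples])
    n_pos = int(sens_mask.sum())

    gene_index = {g: i for i, g in enumerate(genes)}
    kept_names: list[str] = []
    member_rows: list[np.ndarray] = []
    for set_name, set_genes in gene_sets:
        row = np.zeros(len(genes), dtype=bool)
        idx = [gene_index[g] for g in set_genes if g in gene_index]
        row[idx] = True
        size = int(row.sum())
        if min_size <= size <= max_size and size < len(genes):
            kept_names.append(set_name)
            member_rows.append(row)
    if not member_rows:
        return []
    member = np.vstack(member_rows)

    def ranked_es(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        scores = _s2n_scores(values, mask)
        order = np.argsort(-scores, kind="stable")  # genes pre-sorted by id
        return scores[order], member[:, order]

    obs_scores, obs_member = ranked_es(sens_mask)
    es_obs = _es_for_ranking(obs_scores, obs_member, weight)

    rng = np.random.default_rng(seed)
    masks = _label_assignments(len(samples), n_pos, n_perm, rng)
    es_perm = np.empty((member.shape[0], masks.shape[0]))
    for j in range(masks.shape[0]):
        s, m = ranked_es(masks[j])
        es_perm[:, j] = _es_for_ranking(s, m, weight)

    # per-set same-sign normalization
    nes_obs = np.full(len(kept_names), np.nan)
    p_nom = np.ones(len(kept_names))
    mean_pos = np.full(len(kept_names), np.nan)
    mean_neg = np.full(len(kept_names), np.nan)
    for i in range(len(kept_names)):
        pos = es_perm[i][es_perm[i] > 0]
        neg = es_perm[i][es_perm[i] < 0]
        mean_pos[i] = pos.mean() if len(pos) else np.nan
        mean_neg[i] = np.abs(neg).mean() if len(neg) else np.nan
        if es_obs[i] >= 0:
            if len(pos):
                nes_obs[i] = es_obs[i] / mean_pos[i]
                p_nom[i] = float(np.mean(pos >= es_obs[i]))
        else:
            if len(neg):
                nes_obs[i] = es_obs[i] / mean_neg[i]
                p_nom[i] = float(np.mean(neg <= es_obs[i]))

    # pooled permutation NES for the FDR procedure
    with np.errstate(invalid="ignore"):
        nes_perm = np.where(
            es_perm >= 0,
            es_perm / mean_pos[:, None],
            es_perm / mean_neg[:, None],
        )
    nes_perm_flat = nes_perm[np.isfinite(nes_perm)]
    perm_pos = nes_perm_flat[nes_perm_flat >= 0]
    perm_neg = nes_perm_flat[nes_perm_flat < 0]
    obs_finite = nes_obs[np.isfinite(nes_obs)]
    obs_pos = obs_finite[obs_finite >= 0]
    obs_neg = obs_finite[obs_finite < 0]

    fdr_q = np.ones(len(kept_names))
    for i, nes in enumerate(nes_obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            num = np.mean(perm_pos >= nes) if len(perm_pos) else 0.0
            den = np.mean(obs_pos >= nes) if len(obs_pos) else 1.0
        else:
            num = np.mean(perm_neg <= nes) if len(perm_neg) else 0.0
            den = np.mean(obs_neg <= nes) if len(obs_neg) else 1.0
        fdr_q[i] = min(1.0, num / den) if den > 0 else 1.0

    # leading edge from the observed running sum
    results = []
    negative_class = next(c for c in classes if c != positive_class)
    ranked_genes = [
        genes[i] for i in np.argsort(-_s2n_scores(values, sens_mask), kind="stable")
    ]
    for i, set_name in enumerate(kept_names):
        member_sorted = obs_member[i]
        running = _running_sum(obs_scores, member_sorted, weight)
        peak = int(np.argmax(np.abs(running)))
        if es_obs[i] >= 0:
            le = [g for k, g in enumerate(ranked_genes) if member_sorted[k] and k <= peak]
        else:
            le = [g for k, g in enumerate(ranked_genes) if member_sorted[k] and k >= peak]
        results.append(
            EnrichmentResult(
                set_name=set_name,
                size=int(member[i].sum()),
                es=float(es_obs[i]),
                nes=float(nes_obs[i]) if np.isfinite(nes_obs[i]) else math.nan,
                p_nominal=float(p_nom[i]),
                fdr_q=float(fdr_q[i]),
                leading_edge=le,
                direction=positive_class if es_obs[i] >= 0 else negative_class,
            )
        )
    results.sort(key=lambda r: (-(r.nes if math.isfinite(r.nes) else -math.inf),
                                r.set_name))
    return results


def _running_sum(scores: np.ndarray, member: np.ndarray, weight: float) -> np.ndarray:
    w = np.abs(scores) ** weight
    hit_w = np.where(member, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = member.astype(float)
        denom = float(member.sum())
    return np.cumsum(hit_w / denom - (~member) / (len(scores) - member.sum()))
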