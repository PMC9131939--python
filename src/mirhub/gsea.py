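"""Gene-set enrichment analysis: two-class ranking, running-sum enrichment
score with leading edge, and permutation significance.

The enrichment score (ES) walks the ranked list top to bottom, incrementing
the running sum by |metric|^p (normalized to sum to 1 over the set's hits)
at each set member and decrementing by 1/(N - |S|) at each miss; ES is the
signed maximum deviation from zero.  With weight p = 0 this is the classical
Kolmogorov-Smirnov running-sum statistic.

Significance: p = (1 + #{permutation ES at least as extreme, same sign}) /
(1 + #{permutation ES of the same sign}) - conditioning the denominator on
the sign keeps the null p-value uniform; NES divides the observed ES by the
mean |ES| of same-sign permutations.  Phenotype permutation re-ranks the matrix under shuffled
class labels; gene permutation redraws random sets on the fixed ranking
(the default whenever either class has fewer than 7 samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

METRICS = ("signal2noise", "t-like", "log-fold")
SIGMA_FLOOR_FRAC = 0.2
SIGMA_FLOOR_MIN = 0.2


@dataclass
class RankedList:
    """Gene ids ordered best-to-worst with the ranking metric per gene."""
    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")
        if not np.all(np.isfinite(self.metric)):
            raise ValueError("metric values must be finite")


@dataclass
class EnrichmentScoreResult:
    es: float
    running_sum: np.ndarray
    es_position: int               # 0-based index of the extremum
    leading_edge: list[str]
    p_value: float | None = None
    nes: float | None = None
    n_permutations: int = 0


def _floored_sigma(sigma: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return np.maximum(sigma, np.maximum(SIGMA_FLOOR_FRAC * np.abs(mu), SIGMA_FLOOR_MIN))


def _class_columns(labels: Sequence[str]) -> tuple[list[int], list[int], list[str]]:
    names = list(dict.fromkeys(labels))
    if len(names) != 2:
        raise ValueError(f"need exactly two classes, got {names}")
    c1 = [i for i, l in enumerate(labels) if l == names[0]]
    c2 = [i for i, l in enumerate(labels) if l == names[1]]
    if not c1 or not c2:
        raise ValueError("each class needs at least one sample")
    return c1, c2, names


def _metric_values(expr: pd.DataFrame, c1: list[int], c2: list[int], metric: str) -> np.ndarray:
    x1 = expr.iloc[:, c1].to_numpy(float)
    x2 = expr.iloc[:, c2].to_numpy(float)
    mu1, mu2 = x1.mean(axis=1), x2.mean(axis=1)
    if metric == "log-fold":
        return mu1 - mu2
    if min(len(c1), len(c2)) < 3:
        raise ValueError(f"{metric} needs >=3 samples per class")
    s1 = _floored_sigma(x1.std(axis=1, ddof=1), mu1)
    s2 = _floored_sigma(x2.std(axis=1, ddof=1), mu2)
    if metric == "signal2noise":
        return (mu1 - mu2) / (s1 + s2)
    if metric == "t-like":
        return (mu1 - mu2) / np.sqrt(s1 ** 2 / len(c1) + s2 ** 2 / len(c2))
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def rank_genes(expr: pd.DataFrame, labels: Sequence[str],
               metric: str = "signal2noise") -> RankedList:
    """Rank genes by a two-class differential metric, best (class-1-high)
    first.  Ties break deterministically by gene id."""
    if len(labels) != expr.shape[1]:
        raise ValueError("one label per sample column required")
    c1, c2, _ = _class_columns(labels)
    vals = _metric_values(expr, c1, c2, metric)
    order = sorted(range(len(vals)), key=lambda i: (-vals[i], str(expr.index[i])))
    return RankedList(genes=[str(expr.index[i]) for i in order],
                      metric=vals[order])


def enrichment_score(ranked: RankedList, gene_set: Iterable[str],
                     weight_p: float = 1.0) -> EnrichmentScoreResult:
    """Weighted running-sum ES with leading-edge extraction (no p-value)."""
    genes = ranked.genes
    n = len(genes)
    set_ids = set(gene_set)
    hits = np.array([g in set_ids for g in genes], dtype=bool)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hits == n:
        raise ValueError("gene set equals the whole ranked list (degenerate)")

    w = np.abs(ranked.metric) ** weight_p
    hit_w = np.where(hits, w, 0.0)
    total = hit_w.sum()
    if total == 0:          # all hit metrics zero: fall back to equal steps
        hit_w = hits.astype(float)
        total = hit_w.sum()
    p_hit = np.cumsum(hit_w) / total
    p_miss = np.cumsum(~hits) / (n - n_hits)
    rs = p_hit - p_miss
    pos = int(np.argmax(np.abs(rs)))
    es = float(rs[pos])
    if es >= 0:
        leading = [g for i, g in enumerate(genes[: pos + 1]) if hits[i]]
    else:
        leading = [g for i, g in enumerate(genes) if i >= pos and hits[i]]
    return EnrichmentScoreResult(es=es, running_sum=rs, es_position=pos,
                                 leading_edge=leading)


def permutation_significance(expr: pd.DataFrame | None, labels: Sequence[str] | None,
                             gene_set: Iterable[str], *, ranked: RankedList | None = None,
                             n_perm: int = 1000, scheme: str | None = None,
                             metric: str = "signal2noise", weight_p: float = 1.0,
                             seed: int = 0) -> EnrichmentScoreResult:
    """Permutation p-value and NES for one gene set.

    ``scheme`` is "phenotype" (shuffle class labels, re-rank the matrix) or
    "gene" (random sets of the same size on the fixed ranking); when None it
    is chosen automatically: phenotype if both classes have >=7 samples.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    gene_set = set(gene_set)
    if ranked is None:
        if expr is None or labels is None:
            raise ValueError("need either a ranked list or expression + labels")
        ranked = rank_genes(expr, labels, metric)
    if scheme is None:
        if labels is not None:
            c1, c2, _ = _class_columns(labels)
            scheme = "phenotype" if min(len(c1), len(c2)) >= 7 else "gene"
        else:
            scheme = "gene"
    if scheme == "phenotype" and (expr is None or labels is None):
        raise ValueError("phenotype permutation requires the expression matrix")

    obs = enrichment_score(ranked, gene_set, weight_p)
    rng = np.random.default_rng(seed)
    perm_es = np.empty(n_perm)
    n_in_set = sum(1 for g in ranked.genes if g in gene_set)
    labels_arr = np.asarray(labels) if labels is not None else None
    for b in range(n_perm):
        if scheme == "gene":
            idx = rng.choice(len(ranked.genes), size=n_in_set, replace=False)
            perm_set = {ranked.genes[i] for i in idx}
            perm_es[b] = enrichment_score(ranked, perm_set, weight_p).es
        elif scheme == "phenotype":
            shuffled = labels_arr[rng.permutation(len(labels_arr))]
            r = rank_genes(expr, list(shuffled), metric)
            perm_es[b] = enrichment_score(r, gene_set, weight_p).es
        else:
            raise ValueError(f"unknown permutation scheme {scheme!r}")

    if obs.es >= 0:
        same_sign = perm_es[perm_es >= 0]
        extreme = int(np.sum(same_sign >= obs.es))
    else:
        same_sign = perm_es[perm_es < 0]
        extreme = int(np.sum(same_sign <= obs.es))
    p = (1.0 + extreme) / (1.0 + same_sign.size)
    mean_abs = float(np.mean(np.abs(same_sign))) if same_sign.size else np.nan
    nes = obs.es / mean_abs if mean_abs and np.isfinite(mean_abs) and mean_abs > 0 else np.nan
    return EnrichmentScoreResult(es=obs.es, running_sum=obs.running_sum,
                                 es_position=obs.es_position,
                                 leading_edge=obs.leading_edge,
                                 p_value=float(p), nes=float(nes),
                                 n_permutations=n_perm)
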