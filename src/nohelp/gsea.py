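"""Gene-set enrichment analysis: weighted running-sum ES, NES, permutation p.

Genes are ranked by a signal-to-noise contrast between two conditions;
the enrichment score of a gene set is the extremum of the weighted
Kolmogorov-Smirnov-like running sum over the ranked list. Significance
comes from a permutation null — random same-size gene sets by default,
or phenotype-label permutation with re-ranking (enumerated exhaustively
when the number of distinct label splits is small).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSet, normalize_gene_id
from .matrix import ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "GseaResult",
    "rank_genes",
    "top_k_sets",
    "enrichment_score",
    "gsea_test",
]

SD_FLOOR_FRACTION = 0.2  # signal-to-noise sd floor, fraction of |mean|
EXHAUSTIVE_SPLIT_LIMIT = 10_000


@dataclass
class RankedList:
    """Genes ordered best-to-worst with their signed ranking metric."""

    gene_ids: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.gene_ids) != len(self.metric):
            raise ValueError("gene list and metric length differ")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene in ranked list")
        if np.any(np.diff(self.metric) > 1e-12):
            raise ValueError("metric not sorted descending")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    n_permutations: int
    leading_edge: list[str]
    seed: int
    size_used: int = 0

    def __post_init__(self) -> None:
        if self.es != 0 and np.sign(self.nes) != np.sign(self.es):
            raise ValueError("NES sign differs from ES sign")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value outside (0, 1]")


def rank_genes(expr: ExpressionMatrix, meta: SampleMetadata,
               conditions: tuple[str, str] | None = None) -> RankedList:
    """Signal-to-noise ranking: (mean_A - mean_B) / (sd_A + sd_B).

    Each group's sd is floored at max(0.2 * |group mean|, 1e-8). Ties are
    broken lexicographically by gene id, so the order is deterministic.
    """
    meta.check_against(expr)
    if conditions is None:
        conditions = meta.require_two_conditions()
    cond_a, cond_b = conditions
    samples_a = meta.samples_in(cond_a)
    samples_b = meta.samples_in(cond_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("signal-to-noise needs >= 2 replicates per condition")
    return _rank_from_values(
        expr.data.index.to_numpy(),
        expr.data[samples_a].to_numpy(dtype=float),
        expr.data[samples_b].to_numpy(dtype=float),
    )


def _signal_to_noise(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = np.maximum(a.std(axis=1, ddof=1),
                      np.maximum(SD_FLOOR_FRACTION * np.abs(mean_a), 1e-8))
    sd_b = np.maximum(b.std(axis=1, ddof=1),
                      np.maximum(SD_FLOOR_FRACTION * np.abs(mean_b), 1e-8))
    return (mean_a - mean_b) / (sd_a + sd_b)


def _rank_from_values(gene_ids: np.ndarray, a: np.ndarray,
                      b: np.ndarray) -> RankedList:
    metric = _signal_to_noise(a, b)
    order = np.lexsort((gene_ids.astype(str), -metric))
    return RankedList([str(g) for g in gene_ids[order]], metric[order])


def top_k_sets(ranking: RankedList, k: int = 200,
               name_prefix: str = "ranked") -> tuple[GeneSet, GeneSet]:
    """The top-k up-regulated and top-k down-regulated genes as two sets."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(ranking) < 2 * k:
        raise ValueError(
            f"ranked list of {len(ranking)} genes is shorter than 2k = {2 * k}; "
            "lower k"
        )
    up = GeneSet(f"{name_prefix}_top{k}_up", "top up-regulated genes",
                 frozenset(ranking.gene_ids[:k]))
    down = GeneSet(f"{name_prefix}_top{k}_down", "top down-regulated genes",
                   frozenset(ranking.gene_ids[-k:]))
    return up, down


def _hit_mask(ranking_ids: list[str], gene_set: GeneSet) -> np.ndarray:
    members = {normalize_gene_id(g) for g in gene_set.genes}
    return np.fromiter(
        (normalize_gene_id(g) in members for g in ranking_ids),
        dtype=bool, count=len(ranking_ids),
    )


def _es_from_mask(metric: np.ndarray, hits: np.ndarray,
                  weight_p: float) -> tuple[float, np.ndarray, int]:
    """ES, full running sum, extremum index, from a boolean hit mask."""
    n = len(metric)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hits == n:
        running = np.cumsum(np.abs(metric) ** weight_p)
        total = running[-1]
        running = running / total if total > 0 else np.linspace(1 / n, 1, n)
        return 1.0, running, n - 1
    weights = np.abs(metric) ** weight_p if weight_p > 0 else np.ones(n)
    hit_total = weights[hits].sum()
    if hit_total == 0:
        logger.warning("all hit metrics zero; falling back to unweighted ES")
        weights = np.ones(n)
        hit_total = float(n_hits)
    steps = np.where(hits, weights / hit_total, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running, idx


def enrichment_score(
    ranking: RankedList, gene_set: GeneSet, weight_p: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted running-sum enrichment score.

    At each hit the sum rises by |metric|^p normalized over hits; at each
    miss it falls by 1/(N - N_hits). ES is the running-sum value of
    largest magnitude; the leading edge is the hits at or before the
    extremum (at or after, for negative ES). Returns (es, running_sum,
    leading_edge).
    """
    if weight_p < 0:
        raise ValueError("weight_p must be >= 0")
    hits = _hit_mask(ranking.gene_ids, gene_set)
    es, running, idx = _es_from_mask(ranking.metric, hits, weight_p)
    ids = np.asarray(ranking.gene_ids, dtype=object)
    if es >= 0:
        leading = ids[: idx + 1][hits[: idx + 1]]
    else:
        leading = ids[idx:][hits[idx:]]
    return es, running, [str(g) for g in leading]


def gsea_test(
    ranking: RankedList,
    gene_set: GeneSet,
    n_perm: int = 1000,
    mode: str = "gene_set",
    seed: int = 0,
    weight_p: float = 1.0,
    expr: ExpressionMatrix | None = None,
    meta: SampleMetadata | None = None,
    conditions: tuple[str, str] | None = None,
) -> GseaResult:
    """Permutation GSEA for one gene set.

    ``gene_set`` mode draws random same-size gene sets from the ranked
    list; ``phenotype`` mode permutes the condition labels and re-ranks
    (``expr``/``meta`` required), enumerating all distinct splits
    exhaustively when there are at most 10,000 of them. The p-value uses
    the +1 pseudo-count over same-sign null ES values; NES divides ES by
    the mean magnitude of same-sign nulls.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if mode not in ("gene_set", "phenotype"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    rng = np.random.default_rng(seed)
    hits = _hit_mask(ranking.gene_ids, gene_set)
    size_used = int(hits.sum())
    es, _, leading = enrichment_score(ranking, gene_set, weight_p)

    if mode == "gene_set":
        n = len(ranking)
        null_es = np.empty(n_perm)
        for i in range(n_perm):
            perm_hits = np.zeros(n, dtype=bool)
            perm_hits[rng.choice(n, size=size_used, replace=False)] = True
            null_es[i], _, _ = _es_from_mask(ranking.metric, perm_hits, weight_p)
        n_used = n_perm
    else:
        if expr is None or meta is None:
            raise ValueError("phenotype mode requires expr and meta")
        meta.check_against(expr)
        if conditions is None:
            conditions = meta.require_two_conditions()
        samples_a = meta.samples_in(conditions[0])
        samples_b = meta.samples_in(conditions[1])
        all_samples = samples_a + samples_b
        n_a = len(samples_a)
        values = expr.data[all_samples].to_numpy(dtype=float)
        gene_ids = expr.data.index.to_numpy()
        from math import comb

        n_splits = comb(len(all_samples), n_a)
        if n_splits <= EXHAUSTIVE_SPLIT_LIMIT:
            splits = [
                np.array(c)
                for c in itertools.combinations(range(len(all_samples)), n_a)
            ]
            logger.info("phenotype mode: enumerating all %d splits", len(splits))
        else:
            splits = [
                rng.permutation(len(all_samples))[:n_a] for _ in range(n_perm)
            ]
        null_es = np.empty(len(splits))
        idx_all = np.arange(len(all_samples))
        for i, idx_a in enumerate(splits):
            idx_b = np.setdiff1d(idx_all, idx_a)
            perm_rank = _rank_from_values(gene_ids, values[:, idx_a],
                                          values[:, idx_b])
            perm_hits = _hit_mask(perm_rank.gene_ids, gene_set)
            null_es[i], _, _ = _es_from_mask(perm_rank.metric, perm_hits,
                                             weight_p)
        n_used = len(splits)

    same_sign = null_es >= 0 if es >= 0 else null_es <= 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        logger.warning("no same-sign null ES; p floored at 1/(1+n_perm)")
        p = 1.0 / (1 + n_used)
        nes = es  # no null scale available; report unscaled
    else:
        extreme = int((np.abs(null_es[same_sign]) >= abs(es) - 1e-12).sum())
        p = (1 + extreme) / (1 + n_same)
        mean_null = float(np.mean(np.abs(null_es[same_sign])))
        nes = es / mean_null if mean_null > 0 else 0.0
    return GseaResult(
        set_name=gene_set.name,
        es=float(es),
        nes=float(nes),
        p_value=float(p),
        n_permutations=n_used,
        leading_edge=leading,
        seed=seed,
        size_used=size_used,
    )
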