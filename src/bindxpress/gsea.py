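"""Preranked gene-set enrichment with a gene-permutation null.

The classic weighted Kolmogorov–Smirnov running-sum statistic: walking down
a ranked gene list, set members increment the sum by |stat|^weight
(normalized over members) and non-members decrement it by 1/(N - Nh); the
enrichment score (ES) is the extremum of largest magnitude. Significance
comes from ``n_perm`` random same-size gene draws, with a signed-null NES
and the (1 + x)/(1 + n) permutation p estimator; BH correction is applied
across the retained sets. This is a plain permutation implementation, not
an adaptive/multilevel p-value scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence, Set

import numpy as np

from .classify import _bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedList:
    """Gene identifiers with real statistics, sorted descending."""

    genes: tuple
    stats: tuple

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.stats):
            raise ValueError("genes and stats must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in ranked list")
        arr = np.asarray(self.stats, dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("statistics must be finite")
        if (np.diff(arr) > 0).any():
            raise ValueError("statistics must be sorted descending")

    @classmethod
    def from_pairs(cls, pairs) -> "RankedList":
        """Build from (gene, stat) pairs; ties keep stable input order."""
        pairs = list(pairs)
        stats = np.array([s for _, s in pairs], dtype=float)
        if len(np.unique(stats)) < len(stats):
            logger.warning("ties in ranking statistics; stable order kept")
        order = np.argsort(-stats, kind="stable")
        return cls(
            genes=tuple(pairs[i][0] for i in order),
            stats=tuple(stats[order]),
        )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GseaResult:
    name: str
    size: int              # after intersection with the ranked universe
    es: float
    nes: float
    p_value: float
    p_adjusted: float
    leading_edge: tuple    # set genes at or before the ES extremum


def _es_from_hits(
    hit_idx: np.ndarray, abs_stats: np.ndarray, n: int, weight: float
) -> float:
    """ES from sorted hit positions without building the full profile."""
    m = hit_idx.size
    w = abs_stats[hit_idx] ** weight
    total = w.sum()
    if total == 0:
        w = np.ones(m)
        total = float(m)
    cum = np.cumsum(w) / total
    miss_pen = 1.0 / (n - m)
    ranks = hit_idx.astype(float)
    at_hit = cum - miss_pen * (ranks - np.arange(m))          # just after hit
    before_hit = np.concatenate(([0.0], cum[:-1])) \
        - miss_pen * (ranks - np.arange(m))                   # just before hit
    hi = at_hit.max()
    lo = before_hit.min()
    return float(hi if hi >= -lo else lo)


def enrichment_score(
    ranked: RankedList,
    gene_set: Set[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """ES and the full running-sum profile for one gene set."""
    n = len(ranked)
    hits = np.array([g in gene_set for g in ranked.genes])
    nh = int(hits.sum())
    if nh == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if nh == n:
        raise ValueError(
            "gene set equals the entire universe; miss decrement undefined"
        )
    stats = np.abs(np.asarray(ranked.stats, dtype=float))
    incr = np.where(hits, stats ** weight, 0.0)
    total = incr.sum()
    if total == 0:
        incr = hits.astype(float)
        total = float(nh)
    steps = np.where(hits, incr / total, -1.0 / (n - nh))
    profile = np.cumsum(steps)
    es = float(profile[np.argmax(np.abs(profile))])
    return es, profile


def leading_edge_genes(
    ranked: RankedList, gene_set: Set[str], profile: np.ndarray, es: float
) -> tuple:
    """Set genes at or before the ES extremum (after it for negative ES)."""
    peak = int(np.argmax(np.abs(profile)))
    if es >= 0:
        idx = range(0, peak + 1)
    else:
        idx = range(peak, len(ranked))
    return tuple(g for i in idx for g in [ranked.genes[i]] if g in gene_set)


def gsea(
    ranked: RankedList,
    sets: Mapping[str, Set[str]],
    min_size: int = 10,
    max_size: int = 500,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    weight: float = 1.0,
) -> list[GseaResult]:
    """Run preranked GSEA over a gene-set collection.

    Sets are filtered to ``min_size <= size <= max_size`` after intersecting
    with the ranked universe; the null is ``n_perm`` uniform same-size gene
    draws; NES divides the ES by the mean |null ES| of matching sign.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = len(ranked)
    universe = set(ranked.genes)
    abs_stats = np.abs(np.asarray(ranked.stats, dtype=float))

    retained: list[tuple[str, set]] = []
    for name, genes in sets.items():
        inter = set(genes) & universe
        if min_size <= len(inter) <= max_size and len(inter) < n:
            retained.append((name, inter))
    if not retained:
        logger.warning("no gene sets survive size filtering")
        return []

    # one shared null per distinct set size, for speed and a common seed path
    null_by_size: dict[int, np.ndarray] = {}
    for _, inter in retained:
        m = len(inter)
        if m in null_by_size:
            continue
        null = np.empty(n_perm)
        for i in range(n_perm):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            null[i] = _es_from_hits(idx, abs_stats, n, weight)
        null_by_size[m] = null

    results = []
    for name, inter in retained:
        es, profile = enrichment_score(ranked, inter, weight)
        null = null_by_size[len(inter)]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        k = int((np.abs(same_sign) >= abs(es)).sum())
        p = (1 + k) / (1 + same_sign.size)
        mean_null = np.abs(same_sign).mean() if same_sign.size else np.nan
        nes = es / mean_null if mean_null and not np.isnan(mean_null) else np.nan
        results.append(
            GseaResult(
                name=name, size=len(inter), es=es, nes=float(nes),
                p_value=float(p), p_adjusted=np.nan,
                leading_edge=leading_edge_genes(ranked, inter, profile, es),
            )
        )

    adjusted = _bh_adjust([r.p_value for r in results])
    results = [
        GseaResult(
            name=r.name, size=r.size, es=r.es, nes=r.nes,
            p_value=r.p_value, p_adjusted=float(q),
            leading_edge=r.leading_edge,
        )
        for r, q in zip(results, adjusted)
    ]
    results.sort(key=lambda r: (r.p_value, -abs(r.es), r.name))
    return results
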