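"""Cross-tissue / cross-method overlap statistics and genotype correlation.

Covers shared-gene fractions across tissues, exclusive Venn region counts
for up to three sets, per-cell-type expression averaging, and Spearman
correlation of matched average-expression profiles between genotypes.
Fractions are always carried as numerator/denominator pairs so rounded
percentages never replace the counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

UNDEFINED = float("nan")


@dataclass(frozen=True)
class SharedFraction:
    fraction: float      # NaN when the focal set is empty
    numerator: int
    denominator: int


def shared_fraction(
    sets: Mapping[str, Set[str]], focal: str
) -> SharedFraction:
    """Fraction of the focal tissue's genes present in >=1 other tissue."""
    if focal not in sets:
        raise KeyError(f"focal tissue {focal!r} not in sets")
    focal_set = set(sets[focal])
    if not focal_set:
        return SharedFraction(UNDEFINED, 0, 0)
    others: set[str] = set()
    for name, s in sets.items():
        if name != focal:
            others |= set(s)
    num = len(focal_set & others)
    return SharedFraction(num / len(focal_set), num, len(focal_set))


def venn(sets: Mapping[str, Set[str]]) -> dict[frozenset, int]:
    """Exclusive region counts for up to three sets.

    Keys are frozensets of member set names (the non-empty membership
    patterns); counts sum to the size of the union.
    """
    if len(sets) > 3:
        raise ValueError(
            "venn supports at most 3 sets; use pairwise comparisons"
        )
    names = list(sets)
    out: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for members in combinations(names, r):
            region = set.intersection(*(set(sets[m]) for m in members))
            for other in names:
                if other not in members:
                    region -= set(sets[other])
            out[frozenset(members)] = len(region)
    return out


def avg_expression_by_type(
    expr: pd.DataFrame, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Average a gene x cell matrix into a gene x cell-type matrix.

    ``labels`` maps each cell (column) to its type; a type ending up with
    zero cells is omitted with a warning.
    """
    missing = [c for c in expr.columns if c not in labels]
    if missing:
        raise ValueError(f"cells without labels: {missing[:5]}")
    groups = pd.Series({c: labels[c] for c in expr.columns})
    means = expr.T.groupby(groups).mean().T
    empty = set(labels.values()) - set(means.columns)
    if empty:
        logger.warning("cell types with zero cells omitted: %s", sorted(empty))
    return means


def celltype_spearman(
    avg_wt: pd.DataFrame,
    avg_mut: pd.DataFrame,
    type_pairs: Sequence[tuple[str, str]],
) -> dict[tuple[str, str], float]:
    """Spearman rho of matched cell-type profiles between genotypes.

    For each (wt_type, mut_type) pair the gene universe is the intersection
    of genes with a positive mean in either genotype for that type; ties use
    average ranks. Pairs with < 3 shared genes get a NaN sentinel.
    """
    out: dict[tuple[str, str], float] = {}
    shared_genes = avg_wt.index.intersection(avg_mut.index)
    for wt_type, mut_type in type_pairs:
        wt = avg_wt.loc[shared_genes, wt_type]
        mut = avg_mut.loc[shared_genes, mut_type]
        expressed = (wt > 0) | (mut > 0)
        wt, mut = wt[expressed], mut[expressed]
        if len(wt) < 3:
            logger.warning(
                "pair (%s, %s): fewer than 3 shared expressed genes",
                wt_type, mut_type,
            )
            out[(wt_type, mut_type)] = UNDEFINED
            continue
        rho, _ = stats.spearmanr(wt.to_numpy(), mut.to_numpy())
        out[(wt_type, mut_type)] = float(rho)
    return out


def tissue_down_sets(
    de_records, lfc_down: float = -0.15, p_max: float = 0.05
) -> dict[str, set[str]]:
    """Per-tissue sets of significantly down genes from a multi-tissue DE
    table (the per-tissue ingredient of the cross-tissue overlap panels)."""
    sets: dict[str, set[str]] = {}
    for r in de_records:
        sets.setdefault(r.tissue, set())
        if r.log_fc < lfc_down and r.p_value < p_max:
            sets[r.tissue].add(r.gene_id)
    return sets


def tissue_up_sets(
    de_records, lfc_up: float = 0.15, p_max: float = 0.05
) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for r in de_records:
        sets.setdefault(r.tissue, set())
        if r.log_fc > lfc_up and r.p_value < p_max:
            sets[r.tissue].add(r.gene_id)
    return sets
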