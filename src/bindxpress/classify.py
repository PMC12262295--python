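"""Activated / repressed / unchanged target calling and network assembly.

A gene is *activated* when any of three evidence routes fires:

1. scRNA-seq: logFC < -0.15 and p < 0.05 in the focal-tissue knockout
   comparison (all inequalities strict);
2. in situ: membership in the curated in-situ-validated list;
3. microarray: whole-embryo fold change < -1.25 with p < 0.05, provided the
   gene is expressed in > 10 percent of wild-type focal-tissue cells and its
   focal logFC is < 0. A microarray gene absent from the focal DE table
   fails this route closed.

*Repressed* uses the scRNA-seq route only (logFC > +0.15, p < 0.05).
*Unchanged* is the n (default 150) genes of smallest absolute logFC.

A gene qualifying as both activated (via in-situ/microarray) and repressed
(via scRNA-seq) is a conflict: it is excluded from both sets and reported,
rather than silently given precedence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Set

from .io_formats import DiffExprRecord, MicroarrayRecord

logger = logging.getLogger(__name__)

UNDEFINED = float("nan")  # sentinel for fractions with an empty denominator


@dataclass(frozen=True)
class ClassificationThresholds:
    """Strict-inequality thresholds for target calling."""

    lfc_down: float = -0.15
    lfc_up: float = 0.15
    p_max: float = 0.05
    microarray_fc: float = -1.25
    microarray_p: float = 0.05
    pct_wt_min: float = 10.0
    unchanged_n: int = 150
    adjust_p: bool = False   # BH-adjust scRNA p-values before thresholding

    def __post_init__(self) -> None:
        if not (self.lfc_down < 0 < self.lfc_up):
            raise ValueError("need lfc_down < 0 < lfc_up")
        if not (0 < self.p_max < 1):
            raise ValueError("p_max must be in (0,1)")


@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    call: str                     # activated | repressed | unchanged | none
    evidence: frozenset = frozenset()   # subset of {scrna, insitu, microarray}
    bound: bool = False


@dataclass
class RegulatoryNetwork:
    """Bound x regulated sets and the summary fractions reported with them.

    Fractions are NaN (undefined) when their denominator is empty, never 0.
    """

    bound: set = field(default_factory=set)
    activated: set = field(default_factory=set)
    repressed: set = field(default_factory=set)
    bound_activated: set = field(default_factory=set)
    bound_repressed: set = field(default_factory=set)
    fraction_bound_regulated: float = UNDEFINED
    fraction_activated_bound: float = UNDEFINED
    fraction_repressed_bound: float = UNDEFINED
    spcg_bound_count: int = 0
    spcg_bound_down_count: int = 0


def _bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    import numpy as np

    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out.tolist()


def _effective_pvals(
    de_focal: Sequence[DiffExprRecord], thr: ClassificationThresholds
) -> dict[str, float]:
    if thr.adjust_p:
        adj = _bh_adjust([r.p_value for r in de_focal])
        return {r.gene_id: q for r, q in zip(de_focal, adj)}
    return {r.gene_id: r.p_value for r in de_focal}


def classify_activated(
    de_focal: Sequence[DiffExprRecord],
    insitu: Set[str],
    microarray: Sequence[MicroarrayRecord],
    thr: ClassificationThresholds = ClassificationThresholds(),
) -> dict[str, frozenset]:
    """Return activated gene -> evidence flags (every satisfied route)."""
    de_by_gene = {r.gene_id: r for r in de_focal}
    pvals = _effective_pvals(de_focal, thr)
    evidence: dict[str, set] = {}

    for r in de_focal:
        if r.log_fc < thr.lfc_down and pvals[r.gene_id] < thr.p_max:
            evidence.setdefault(r.gene_id, set()).add("scrna")

    for gene in insitu:
        evidence.setdefault(gene, set()).add("insitu")

    for m in microarray:
        if not (m.fold_change < thr.microarray_fc
                and m.p_value < thr.microarray_p):
            continue
        r = de_by_gene.get(m.gene_id)
        if r is None:
            logger.info(
                "microarray gene %s absent from focal DE table; "
                "microarray route fails closed", m.gene_id,
            )
            continue
        if r.pct_wt > thr.pct_wt_min and r.log_fc < 0:
            evidence.setdefault(m.gene_id, set()).add("microarray")

    return {g: frozenset(ev) for g, ev in evidence.items()}


def classify_repressed(
    de_focal: Sequence[DiffExprRecord],
    thr: ClassificationThresholds = ClassificationThresholds(),
) -> set[str]:
    """Genes with focal logFC > lfc_up and p < p_max (scRNA route only)."""
    pvals = _effective_pvals(de_focal, thr)
    return {
        r.gene_id
        for r in de_focal
        if r.log_fc > thr.lfc_up and pvals[r.gene_id] < thr.p_max
    }


def resolve_conflicts(
    activated: Mapping[str, frozenset], repressed: Set[str]
) -> tuple[dict[str, frozenset], set[str], set[str]]:
    """Drop genes called both activated and repressed from both sets.

    Returns (activated, repressed, conflicts); the surviving sets are
    disjoint by construction.
    """
    conflicts = set(activated) & set(repressed)
    if conflicts:
        logger.warning(
            "%d gene(s) called both activated and repressed; excluded from "
            "both sets: %s", len(conflicts), sorted(conflicts),
        )
    act = {g: ev for g, ev in activated.items() if g not in conflicts}
    rep = set(repressed) - conflicts
    return act, rep, conflicts


def select_unchanged(
    de_focal: Sequence[DiffExprRecord],
    thr: ClassificationThresholds = ClassificationThresholds(),
) -> set[str]:
    """The ``thr.unchanged_n`` genes of smallest |logFC|.

    Ties at the cutoff are broken toward the larger p-value, then the
    smaller gene_id, so the selection is order-independent.
    """
    n = thr.unchanged_n
    if len(de_focal) < n:
        logger.warning(
            "only %d genes available for the %d-gene unchanged set",
            len(de_focal), n,
        )
    ranked = sorted(
        de_focal, key=lambda r: (abs(r.log_fc), -r.p_value, r.gene_id)
    )
    return {r.gene_id for r in ranked[:n]}


def make_target_calls(
    activated: Mapping[str, frozenset],
    repressed: Set[str],
    unchanged: Set[str],
    bound: Set[str],
    universe: Iterable[str],
) -> list[TargetCall]:
    """Per-gene calls over ``universe`` with evidence and binding flags."""
    calls = []
    for gene in universe:
        if gene in activated:
            call, ev = "activated", activated[gene]
        elif gene in repressed:
            call, ev = "repressed", frozenset({"scrna"})
        elif gene in unchanged:
            call, ev = "unchanged", frozenset()
        else:
            call, ev = "none", frozenset()
        calls.append(
            TargetCall(gene_id=gene, call=call, evidence=ev,
                       bound=gene in bound)
        )
    return calls


def build_network(
    bound: Set[str],
    activated: Set[str],
    repressed: Set[str],
    spcg: Set[str] = frozenset(),
) -> RegulatoryNetwork:
    """Assemble the bound x regulated network and its summary fractions."""
    bound = set(bound)
    activated = set(activated)
    repressed = set(repressed)
    bound_act = bound & activated
    bound_rep = bound & repressed
    regulated = activated | repressed

    def frac(num: int, den: int) -> float:
        return num / den if den else UNDEFINED

    return RegulatoryNetwork(
        bound=bound,
        activated=activated,
        repressed=repressed,
        bound_activated=bound_act,
        bound_repressed=bound_rep,
        fraction_bound_regulated=frac(len(bound & regulated), len(bound)),
        fraction_activated_bound=frac(len(bound_act), len(activated)),
        fraction_repressed_bound=frac(len(bound_rep), len(repressed)),
        spcg_bound_count=len(set(spcg) & bound),
        spcg_bound_down_count=len(set(spcg) & bound & activated),
    )
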