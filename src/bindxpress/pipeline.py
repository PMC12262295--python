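"""End-to-end orchestration: intersect -> assign -> classify -> network ->
overlap -> motifs -> GSEA, from one declarative config, with a
provenance-stamped JSON report.

``analyze`` performs the full analysis on in-memory objects (what tests and
the synthetic bundle use directly); ``run_all`` wraps it with file reading,
stage outputs on disk, input hashing, and the report. Every fraction in the
report carries its numerator and denominator.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import io_formats as iof
from .binding import (
    AssignmentConfig, IntersectedPeak, PeakGeneAssignment, assign_peaks,
    bound_genes, intersect_keep_a, tss_distance_histogram,
)
from .classify import (
    ClassificationThresholds, build_network, classify_activated,
    classify_repressed, make_target_calls, resolve_conflicts,
    select_unchanged,
)
from .gsea import RankedList, gsea
from .motifs import (
    class_unique_motifs, dinucleotide_shuffle, extract_windows,
    generalize_word, word_enrichment,
)
from .overlap import shared_fraction, tissue_down_sets, venn

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    peaks_a: str = ""
    peaks_b: str = ""
    annotation: str = ""
    de_table: str = ""
    microarray: str = ""
    insitu: str = ""
    spcg: str = ""
    genome: str = ""
    gene_sets: str = ""
    outdir: str = "bindxpress_out"
    focal_tissue: str = "SG"
    max_distance: int = 1000
    histogram_bin: int = 100
    thresholds: dict = field(default_factory=dict)
    flank: int = 250
    k_min: int = 3
    k_max: int = 8
    e_threshold: float = 0.05
    n_generalize: int = 5
    run_motifs: bool = True
    run_gsea: bool = True
    gsea_min_size: int = 10
    gsea_max_size: int = 500
    gsea_n_perm: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def classification_thresholds(self) -> ClassificationThresholds:
        return ClassificationThresholds(**self.thresholds)


def _frac(num: int, den: int) -> dict:
    return {
        "numerator": num,
        "denominator": den,
        "fraction": num / den if den else None,
    }


def _peaks_for_genes(
    assignments: Sequence[PeakGeneAssignment], genes: set
) -> list[IntersectedPeak]:
    """The distinct intersected peaks assigned to any gene in ``genes``."""
    out, seen = [], set()
    for a in assignments:
        key = (a.peak.chrom, a.peak.source.start, a.peak.source.end)
        if a.gene_id in genes and key not in seen:
            seen.add(key)
            out.append(a.peak)
    return out


def analyze(
    peaks_a,
    peaks_b,
    transcripts,
    de_records,
    microarray,
    insitu_genes,
    spcg_genes,
    genome: Mapping[str, str] | None = None,
    gene_sets: Mapping[str, set] | None = None,
    config: RunConfig | None = None,
):
    """Run every analysis stage on in-memory inputs.

    Returns a dict holding each stage's objects plus the serializable
    ``report`` of headline numbers.
    """
    cfg = config or RunConfig()
    thr = cfg.classification_thresholds()
    rng = np.random.default_rng(cfg.seed)

    # binding map
    intersected = intersect_keep_a(peaks_a, peaks_b)
    tss = iof.gene_tss_table(transcripts)
    assignments = assign_peaks(
        intersected, tss, AssignmentConfig(max_distance=cfg.max_distance)
    )
    bound = bound_genes(assignments)
    hist_counts, hist_edges = tss_distance_histogram(
        assignments, cfg.histogram_bin
    )

    # target classification
    focal = [r for r in de_records if r.tissue == cfg.focal_tissue]
    activated_ev = classify_activated(focal, set(insitu_genes), microarray,
                                      thr)
    repressed = classify_repressed(focal, thr)
    activated_ev, repressed, conflicts = resolve_conflicts(
        activated_ev, repressed
    )
    activated = set(activated_ev)
    unchanged = (select_unchanged(focal, thr) - activated) - repressed
    network = build_network(bound, activated, repressed, set(spcg_genes))
    calls = make_target_calls(
        activated_ev, repressed, unchanged, bound,
        sorted({r.gene_id for r in focal}),
    )

    # scRNA-only activated count, reported alongside the union definition
    scrna_only_activated = {
        g for g, ev in activated_ev.items() if "scrna" in ev
    }

    # cross-tissue / cross-method overlaps
    down_sets = tissue_down_sets(de_records, thr.lfc_down, thr.p_max)
    shared = {
        t: shared_fraction(down_sets, t)
        for t in down_sets
        if len(down_sets) > 1
    }
    micro_down = {
        m.gene_id for m in microarray
        if m.fold_change < thr.microarray_fc and m.p_value < thr.microarray_p
    }
    venn_counts = venn({
        "scrna_down": down_sets.get(cfg.focal_tissue, set()),
        "microarray_down": micro_down,
        "spcg": set(spcg_genes),
    })

    results: dict = {
        "intersected": intersected,
        "assignments": assignments,
        "tss": tss,
        "bound": bound,
        "histogram": (hist_counts, hist_edges),
        "activated": activated,
        "activated_evidence": activated_ev,
        "repressed": repressed,
        "unchanged": unchanged,
        "conflicts": conflicts,
        "network": network,
        "calls": calls,
        "down_sets": down_sets,
        "shared": shared,
        "venn": venn_counts,
    }

    # motif enrichment
    if cfg.run_motifs and genome is not None:
        results["motifs"] = _motif_stage(
            assignments, bound, activated, repressed, unchanged,
            genome, cfg, rng,
        )

    # GSEA on the focal ranking
    if cfg.run_gsea and gene_sets:
        ranked = RankedList.from_pairs(
            [(r.gene_id, r.log_fc) for r in focal]
        )
        results["gsea"] = gsea(
            ranked, gene_sets,
            min_size=cfg.gsea_min_size, max_size=cfg.gsea_max_size,
            n_perm=cfg.gsea_n_perm, seed=rng,
        )

    results["report"] = _build_report(results, cfg, thr, focal)
    return results


def _motif_stage(assignments, bound, activated, repressed, unchanged,
                 genome, cfg: RunConfig, rng):
    class_windows = {}
    for label, genes in (
        ("activated", activated), ("repressed", repressed),
        ("unchanged", unchanged),
    ):
        peaks = _peaks_for_genes(assignments, set(genes) & bound)
        class_windows[label] = extract_windows(
            peaks, genome, flank=cfg.flank, label=label
        )
    control = class_windows["unchanged"]
    if not control:
        logger.warning("no bound-unchanged windows; motif stage skipped")
        return None

    per_class = {}
    for label in ("activated", "repressed"):
        if not class_windows[label]:
            per_class[label] = []
            continue
        cands = word_enrichment(
            class_windows[label], control, k_min=cfg.k_min, k_max=cfg.k_max
        )
        generalized = [
            generalize_word(c, class_windows[label], control)
            for c in cands[: cfg.n_generalize]
        ]
        # re-rank after IUPAC generalization: a widened word can overtake
        # the seed ordering
        generalized.sort(key=lambda c: (c.e_value, c.fisher_p, c.word))
        per_class[label] = generalized
    # the control class is contrasted against its own dinucleotide shuffle
    shuffled = [
        dinucleotide_shuffle(wnd.sequence, rng) for wnd in control
    ]
    cands = word_enrichment(
        control, shuffled, k_min=cfg.k_min, k_max=cfg.k_max
    )
    generalized = [
        generalize_word(c, control, shuffled)
        for c in cands[: cfg.n_generalize]
    ]
    generalized.sort(key=lambda c: (c.e_value, c.fisher_p, c.word))
    per_class["unchanged"] = generalized
    uniqueness = class_unique_motifs(per_class, e_threshold=cfg.e_threshold)
    return {
        "windows": class_windows,
        "candidates": per_class,
        "uniqueness": uniqueness,
    }


def _build_report(results, cfg: RunConfig, thr, focal) -> dict:
    network = results["network"]
    n_act, n_rep = len(results["activated"]), len(results["repressed"])
    report = {
        "parameters": {
            "max_distance": cfg.max_distance,
            "thresholds": asdict(thr),
            "flank": cfg.flank,
            "k_range": [cfg.k_min, cfg.k_max],
            "seed": cfg.seed,
            "focal_tissue": cfg.focal_tissue,
            "logfc_scale": "as-supplied",
        },
        "counts": {
            "peaks_intersected": len(results["intersected"]),
            "peak_gene_assignments": len(results["assignments"]),
            "genes_bound": len(results["bound"]),
            "genes_activated": n_act,
            "genes_activated_scrna_only": len({
                g for g, ev in results["activated_evidence"].items()
                if "scrna" in ev
            }),
            "genes_repressed": n_rep,
            "genes_unchanged": len(results["unchanged"]),
            "conflicts": len(results["conflicts"]),
            "focal_genes_tested": len(focal),
        },
        "network": {
            "bound_regulated": _frac(
                len(network.bound_activated | network.bound_repressed),
                len(network.bound),
            ),
            "activated_bound": _frac(len(network.bound_activated), n_act),
            "repressed_bound": _frac(len(network.bound_repressed), n_rep),
            "spcg_bound_count": network.spcg_bound_count,
            "spcg_bound_down_count": network.spcg_bound_down_count,
        },
        "overlap": {
            "shared_down_fraction": {
                t: _frac(s.numerator, s.denominator)
                for t, s in results["shared"].items()
            },
            "venn_regions": {
                "|".join(sorted(k)): v for k, v in results["venn"].items()
            },
        },
        "warnings": [],
    }
    motifs = results.get("motifs")
    if motifs:
        report["motifs"] = {
            label: [
                {
                    "word": c.word, "pos_with": c.pos_with,
                    "pos_total": c.pos_total, "neg_with": c.neg_with,
                    "neg_total": c.neg_total, "fisher_p": c.fisher_p,
                    "e_value": c.e_value,
                }
                for c in cands
            ]
            for label, cands in motifs["candidates"].items()
        }
        report["motif_uniqueness"] = {
            key: [c.word for c in cands]
            for key, cands in motifs["uniqueness"].items()
        }
    if "gsea" in results:
        report["gsea"] = [
            {
                "name": r.name, "size": r.size, "es": r.es, "nes": r.nes,
                "p_value": r.p_value, "p_adjusted": r.p_adjusted,
            }
            for r in results["gsea"]
        ]
    return report


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """File-level pipeline run: read inputs, analyze, write stage outputs
    and the JSON report. Identical config + inputs + seed give an identical
    report."""
    required = {
        "peaks_a": config.peaks_a, "peaks_b": config.peaks_b,
        "annotation": config.annotation, "de_table": config.de_table,
    }
    missing = [k for k, v in required.items() if not v or not Path(v).exists()]
    if missing:
        raise FileNotFoundError(f"missing required inputs: {missing}")

    peaks_a = iof.read_narrowpeak(config.peaks_a)
    peaks_b = iof.read_narrowpeak(config.peaks_b)
    if config.annotation.endswith((".bed", ".bed12")):
        transcripts = iof.read_bed12_transcripts(config.annotation)
    else:
        transcripts = iof.read_gtf_transcripts(config.annotation)
    de_records = iof.read_de_table(config.de_table)
    microarray = (
        iof.read_microarray_table(config.microarray)
        if config.microarray and Path(config.microarray).exists() else []
    )
    insitu = (
        iof.read_gene_list(config.insitu)
        if config.insitu and Path(config.insitu).exists() else []
    )
    spcg = (
        iof.read_gene_list(config.spcg)
        if config.spcg and Path(config.spcg).exists() else []
    )
    genome = (
        iof.read_fasta(config.genome)
        if config.genome and Path(config.genome).exists() else None
    )
    gene_sets = (
        iof.read_gmt(config.gene_sets)
        if config.gene_sets and Path(config.gene_sets).exists() else None
    )

    results = analyze(
        peaks_a, peaks_b, transcripts, de_records, microarray, insitu,
        spcg, genome=genome, gene_sets=gene_sets, config=config,
    )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    iof.write_narrowpeak(
        [p.source for p in results["intersected"]],
        outdir / "intersected.narrowPeak",
    )
    with open(outdir / "assignments.tsv", "w") as fh:
        fh.write("peak_name\tchrom\tcenter\tgene_id\tdistance\tside\n")
        for a in results["assignments"]:
            fh.write(
                f"{a.peak.source.name}\t{a.peak.chrom}\t{a.peak.center}\t"
                f"{a.gene_id}\t{a.distance}\t{a.side}\n"
            )
    with open(outdir / "calls.tsv", "w") as fh:
        fh.write("gene_id\tcall\tevidence\tbound\n")
        for c in results["calls"]:
            fh.write(
                f"{c.gene_id}\t{c.call}\t{','.join(sorted(c.evidence))}\t"
                f"{int(c.bound)}\n"
            )
    iof.write_gene_list(sorted(results["bound"]), outdir / "bound_genes.txt")

    report = results["report"]
    report["input_hashes"] = {
        k: _sha256(v)
        for k, v in {
            "peaks_a": config.peaks_a, "peaks_b": config.peaks_b,
            "annotation": config.annotation, "de_table": config.de_table,
            "microarray": config.microarray, "insitu": config.insitu,
            "spcg": config.spcg, "genome": config.genome,
            "gene_sets": config.gene_sets,
        }.items()
        if v and Path(v).exists()
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    results["report"] = report
    return results
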