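"""Synthetic input bundles with planted ground truth.

Generates a small multi-chromosome genome, stranded multi-transcript gene
models, two partially overlapping ChIP peak sets concentrated at the
promoters of planted target genes, per-tissue knockout DE tables, a
whole-embryo-microarray-style table, in-situ and secretory-pathway-style
curated gene lists, a small GMT collection with one planted-enriched set,
and a truth record — everything the pipeline reads, internally consistent,
so every stage is testable without external downloads.

Planted structure: target genes are both bound (a peak in each driver set
whose intersection center falls strictly within 1 kb of the gene's 5' TSS;
promoter-peak jitter is truncated at +/-900 bases to guarantee this) and
regulated (activated genes get log fold changes at or beyond the planted
effect size with small p-values, split across the scRNA / in-situ-only /
microarray-only evidence routes; repressed genes get the positive
counterpart). Decoy genes are bound but carry |logFC| < 0.15. A consensus
IUPAC motif (an arbitrary placeholder word, not any real TF's consensus) is
planted in the +/-250 bp window around every activated gene's intersected
peak center and in at most a small background fraction of other windows.

All randomness flows through one seeded numpy Generator; two calls with the
same config are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import json
import numpy as np

from . import io_formats as iof
from .io_formats import (
    DiffExprRecord, MicroarrayRecord, PeakRecord, TranscriptModel,
)
from .motifs import IUPAC_CODES

FOCAL_TISSUE = "SG"


class GenerationError(ValueError):
    """The requested bundle cannot be placed in the configured genome."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic bundle."""

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 500_000
    n_genes: int = 300
    transcripts_per_gene_max: int = 3
    n_true_targets: int = 30
    fraction_activated_of_regulated: float = 0.7
    n_decoy_bound: int = 30
    peak_width: int = 200
    peak_jitter_sd: float = 150.0
    motif: str = "TGACGTMA"      # arbitrary placeholder IUPAC word
    effect_size_lfc: float = 0.5
    noise_lfc_sd: float = 0.1
    n_tissues: int = 5
    background_motif_fraction: float = 0.02
    gc_fraction: float = 0.5
    # evidence-route mix among activated genes
    insitu_only_fraction: float = 0.1
    microarray_only_fraction: float = 0.1
    insitu_extra_fraction: float = 0.2       # scRNA-route genes also in situ
    microarray_extra_fraction: float = 0.3   # scRNA-route genes also on array
    shared_target_fraction: float = 0.6      # targets shared by other tissues
    n_background_peaks_per_set: int = 40
    n_spcg: int = 30

    def __post_init__(self) -> None:
        if self.n_true_targets + self.n_decoy_bound > self.n_genes:
            raise ValueError("targets + decoys exceed n_genes")
        if len(self.motif) < 4:
            raise ValueError("motif length must be >= 4")
        if any(c not in IUPAC_CODES for c in self.motif):
            raise ValueError("motif must be an IUPAC nucleotide word")
        if self.effect_size_lfc <= 0.15:
            raise ValueError(
                "effect_size_lfc must exceed the 0.15 classification "
                "threshold for the truth to be recoverable"
            )
        if not (0 <= self.fraction_activated_of_regulated <= 1):
            raise ValueError("fraction_activated_of_regulated not in [0,1]")


@dataclass
class SyntheticTruth:
    bound_genes: set
    activated_genes: set
    repressed_genes: set
    peak_to_gene: dict       # set-A promoter peak name -> intended gene
    motif: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "bound_genes": sorted(self.bound_genes),
                "activated_genes": sorted(self.activated_genes),
                "repressed_genes": sorted(self.repressed_genes),
                "peak_to_gene": dict(sorted(self.peak_to_gene.items())),
                "motif": self.motif,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            bound_genes=set(d["bound_genes"]),
            activated_genes=set(d["activated_genes"]),
            repressed_genes=set(d["repressed_genes"]),
            peak_to_gene=d["peak_to_gene"],
            motif=d["motif"],
        )


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    genome: dict
    transcripts: list
    peaks_a: list            # the "kept original entry" driver set
    peaks_b: list
    de_records: list         # all tissues, focal tissue label FOCAL_TISSUE
    microarray: list
    insitu_genes: list
    spcg_genes: list
    gene_sets: dict          # name -> set of genes; one planted-enriched set
    truth: SyntheticTruth


def sample_iupac_instance(motif: str, rng: np.random.Generator) -> str:
    """One concrete ACGT word drawn uniformly from the IUPAC pattern."""
    out = []
    for c in motif:
        bases = sorted(IUPAC_CODES[c])
        out.append(bases[rng.integers(len(bases))])
    return "".join(out)


def plant_motif(
    sequence: str,
    window_center: int,
    motif: str,
    rng: np.random.Generator,
    flank: int = 250,
) -> str:
    """Write one sampled concrete motif instance at a random offset within
    +/-flank of ``window_center``; the rest of the sequence is untouched."""
    if window_center - flank < 0 or window_center + flank + 1 > len(sequence):
        raise GenerationError(
            f"window around {window_center} exceeds sequence bounds"
        )
    instance = sample_iupac_instance(motif, rng)
    lo = window_center - flank
    hi = window_center + flank + 1 - len(instance)
    start = int(rng.integers(lo, hi + 1))
    return sequence[:start] + instance + sequence[start + len(instance):]


def _truncated_normal(
    rng: np.random.Generator, sd: float, bound: float
) -> float:
    """Normal(0, sd) redrawn until within +/-bound."""
    if sd == 0:
        return 0.0
    while True:
        x = rng.normal(0.0, sd)
        if abs(x) <= bound:
            return x


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the full internally consistent bundle for one seed."""
    rng = np.random.default_rng(config.seed)
    cfg = config

    # --- gene placement on a slot grid (guarantees TSS separation) -------
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    slot = cfg.chrom_length // per_chrom
    # 4500 bp per gene guarantees promoter peaks, background peaks and
    # motif windows of adjacent genes can never collide or cross-assign
    if slot < 4500:
        raise GenerationError(
            f"genome too small: {per_chrom} genes per {cfg.chrom_length} bp "
            f"chromosome leaves {slot} bp per gene (need >= 4500)"
        )

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    gene_chrom: dict[str, str] = {}
    gene_tss: dict[str, int] = {}
    gene_strand: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []

    gi = 0
    for chrom in chrom_names:
        for s in range(per_chrom):
            if gi >= cfg.n_genes:
                break
            gene = gene_ids[gi]
            base = s * slot
            tss = base + slot // 2 + int(rng.integers(-500, 501))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_chrom[gene] = chrom
            gene_tss[gene] = tss
            gene_strand[gene] = strand
            n_tx = int(rng.integers(1, cfg.transcripts_per_gene_max + 1))
            for t in range(n_tx):
                length = int(rng.integers(800, 2500))
                delta = 0 if t == 0 else int(rng.integers(0, 400))
                if strand == "+":
                    start = tss + delta
                    end = min(start + length, cfg.chrom_length)
                else:
                    end = tss + 1 - delta
                    start = max(end - length, 0)
                transcripts.append(
                    TranscriptModel(
                        gene_id=gene, transcript_id=f"{gene}.t{t + 1}",
                        chrom=chrom, strand=strand, start=start, end=end,
                    )
                )
            gi += 1

    # --- role assignment -------------------------------------------------
    shuffled = list(gene_ids)
    rng.shuffle(shuffled)
    targets = shuffled[: cfg.n_true_targets]
    decoys = shuffled[cfg.n_true_targets:
                      cfg.n_true_targets + cfg.n_decoy_bound]
    n_act = int(round(cfg.n_true_targets
                      * cfg.fraction_activated_of_regulated))
    activated = targets[:n_act]
    repressed = targets[n_act:]
    bound = targets + decoys
    background = shuffled[cfg.n_true_targets + cfg.n_decoy_bound:]

    # evidence routes among activated genes
    n_insitu_only = int(round(len(activated) * cfg.insitu_only_fraction))
    n_micro_only = int(round(len(activated) * cfg.microarray_only_fraction))
    insitu_only = activated[:n_insitu_only]
    micro_only = activated[n_insitu_only:n_insitu_only + n_micro_only]
    scrna_route = activated[n_insitu_only + n_micro_only:]

    # --- peaks ------------------------------------------------------------
    w = cfg.peak_width
    jitter_bound = 900.0  # truncation keeps the intersect center < 1 kb
    peaks_a: list[PeakRecord] = []
    peaks_b: list[PeakRecord] = []
    peak_to_gene: dict[str, str] = {}
    for i, gene in enumerate(bound):
        center = gene_tss[gene] + int(
            round(_truncated_normal(rng, cfg.peak_jitter_sd, jitter_bound))
        )
        name_a = f"peakA_{i:04d}"
        peaks_a.append(
            PeakRecord(
                chrom=gene_chrom[gene], start=center - w // 2,
                end=center - w // 2 + w, name=name_a,
                score=int(rng.integers(100, 1000)),
                signal_value=float(np.round(rng.uniform(2, 50), 3)),
                p_value_log=float(np.round(rng.uniform(3, 30), 3)),
                q_value_log=float(np.round(rng.uniform(2, 20), 3)),
                summit_offset=w // 2,
            )
        )
        shift = int(rng.integers(-w // 4, w // 4 + 1))
        peaks_b.append(
            PeakRecord(
                chrom=gene_chrom[gene], start=center - w // 2 + shift,
                end=center - w // 2 + w + shift, name=f"peakB_{i:04d}",
                score=int(rng.integers(100, 1000)),
                signal_value=float(np.round(rng.uniform(2, 50), 3)),
                p_value_log=float(np.round(rng.uniform(3, 30), 3)),
                q_value_log=float(np.round(rng.uniform(2, 20), 3)),
                summit_offset=w // 2,
            )
        )
        peak_to_gene[name_a] = gene

    # driver-specific background peaks: far from every TSS and disjoint
    # between the two sets, so the intersection stays the promoter peaks
    free_slots = [
        (chrom, s) for chrom in chrom_names for s in range(per_chrom)
    ]
    rng.shuffle(free_slots)
    n_bg = min(cfg.n_background_peaks_per_set, len(free_slots))
    for k in range(n_bg):
        chrom, s = free_slots[k]
        pos_a = s * slot + slot - 700
        peaks_a.append(
            PeakRecord(
                chrom=chrom, start=pos_a, end=pos_a + w,
                name=f"bgA_{k:04d}", score=int(rng.integers(50, 400)),
                signal_value=float(np.round(rng.uniform(1, 10), 3)),
                p_value_log=float(np.round(rng.uniform(2, 10), 3)),
                q_value_log=float(np.round(rng.uniform(1, 8), 3)),
                summit_offset=w // 2,
            )
        )
        chrom_b, s_b = free_slots[(k + 7) % n_bg]
        pos_b = s_b * slot + 250
        peaks_b.append(
            PeakRecord(
                chrom=chrom_b, start=pos_b, end=pos_b + w,
                name=f"bgB_{k:04d}", score=int(rng.integers(50, 400)),
                signal_value=float(np.round(rng.uniform(1, 10), 3)),
                p_value_log=float(np.round(rng.uniform(2, 10), 3)),
                q_value_log=float(np.round(rng.uniform(1, 8), 3)),
                summit_offset=w // 2,
            )
        )
    peaks_a.sort(key=lambda p: (p.chrom, p.start))
    peaks_b.sort(key=lambda p: (p.chrom, p.start))

    # --- differential expression -----------------------------------------
    de_records: list[DiffExprRecord] = []

    def noise() -> float:
        return float(rng.normal(0.0, cfg.noise_lfc_sd)) \
            if cfg.noise_lfc_sd > 0 else 0.0

    focal_lfc: dict[str, float] = {}
    focal_p: dict[str, float] = {}
    focal_pct: dict[str, float] = {}
    for gene in gene_ids:
        if gene in scrna_route:
            lfc = -cfg.effect_size_lfc + noise()
            p = float(rng.uniform(1e-6, 0.04))
            pct = float(np.round(rng.uniform(30, 90), 1))
        elif gene in insitu_only:
            lfc = -0.05 + noise()
            p = float(rng.uniform(0.1, 0.9))
            pct = float(np.round(rng.uniform(10.5, 90), 1))
        elif gene in micro_only:
            lfc = -0.08 + noise()
            p = float(rng.uniform(0.1, 0.9))
            pct = float(np.round(rng.uniform(15, 70), 1))
        elif gene in repressed:
            lfc = cfg.effect_size_lfc + noise()
            p = float(rng.uniform(1e-6, 0.04))
            pct = float(np.round(rng.uniform(10.5, 90), 1))
        elif gene in decoys:
            lfc = float(np.clip(noise(), -0.149, 0.149))
            p = float(rng.uniform(0.2, 1.0))
            pct = float(np.round(rng.uniform(5, 95), 1))
        else:
            lfc = noise()
            p = float(rng.uniform(0.2, 1.0))
            pct = float(np.round(rng.uniform(5, 95), 1))
        focal_lfc[gene] = lfc
        focal_p[gene] = p
        focal_pct[gene] = pct
        de_records.append(
            DiffExprRecord(
                gene_id=gene, tissue=FOCAL_TISSUE,
                log_fc=float(np.round(lfc, 6)), p_value=float(np.round(p, 8)),
                pct_wt=pct,
                pct_mut=float(np.round(np.clip(
                    pct * (1.0 + np.sign(lfc) * rng.uniform(0, 0.4)), 0, 100
                ), 1)),
            )
        )

    # other tissues: share a fraction of the focal targets, plus their own
    # regulated genes drawn from the background pool
    other_tissues = [f"tissue{i + 2}" for i in range(cfg.n_tissues - 1)]
    for tissue in other_tissues:
        n_shared = int(round(len(targets) * cfg.shared_target_fraction))
        shared_idx = rng.choice(len(targets), size=n_shared, replace=False)
        shared = {targets[i] for i in shared_idx}
        n_own = max(1, int(round(0.3 * len(targets))))
        own_idx = rng.choice(len(background), size=n_own, replace=False)
        own = {background[i] for i in own_idx}
        for gene in gene_ids:
            if gene in shared:
                sign = -1.0 if gene in activated else 1.0
                lfc = sign * cfg.effect_size_lfc + noise()
                p = float(rng.uniform(1e-6, 0.04))
            elif gene in own:
                lfc = (-1.0 if rng.random() < 0.5 else 1.0) \
                    * cfg.effect_size_lfc + noise()
                p = float(rng.uniform(1e-6, 0.04))
            else:
                lfc = noise()
                p = float(rng.uniform(0.2, 1.0))
            pct = float(np.round(rng.uniform(5, 95), 1))
            de_records.append(
                DiffExprRecord(
                    gene_id=gene, tissue=tissue,
                    log_fc=float(np.round(lfc, 6)),
                    p_value=float(np.round(p, 8)),
                    pct_wt=pct, pct_mut=pct,
                )
            )

    # --- microarray table -------------------------------------------------
    microarray: list[MicroarrayRecord] = []
    n_extra = int(round(len(scrna_route) * cfg.microarray_extra_fraction))
    micro_genes = list(micro_only) + list(scrna_route[:n_extra])
    for gene in micro_genes:
        microarray.append(
            MicroarrayRecord(
                gene_id=gene,
                fold_change=float(np.round(-rng.uniform(1.5, 4.0), 4)),
                p_value=float(np.round(rng.uniform(1e-5, 0.04), 8)),
            )
        )
    # null microarray entries that must never fire the microarray route
    null_idx = rng.choice(len(background), size=min(50, len(background)),
                          replace=False)
    for i in null_idx:
        fc = float(np.round(rng.uniform(-1.2, 1.2), 4)) or 0.5
        microarray.append(
            MicroarrayRecord(
                gene_id=background[i], fold_change=fc,
                p_value=float(np.round(rng.uniform(0.06, 1.0), 8)),
            )
        )
    # significant microarray genes absent from the DE table: the route
    # must fail closed on them
    for k in range(3):
        microarray.append(
            MicroarrayRecord(
                gene_id=f"offpanel{k}", fold_change=-2.0, p_value=0.01
            )
        )

    # --- curated lists ----------------------------------------------------
    n_insitu_extra = int(round(len(scrna_route) * cfg.insitu_extra_fraction))
    insitu_genes = list(insitu_only) + list(
        scrna_route[n_extra:n_extra + n_insitu_extra]
    )

    n_spcg = min(cfg.n_spcg, cfg.n_genes)
    n_from_act = min(len(activated), int(round(0.6 * n_spcg)))
    n_from_decoy = min(len(decoys), int(round(0.2 * n_spcg)))
    spcg = list(activated[:n_from_act]) + list(decoys[:n_from_decoy])
    spcg += background[: n_spcg - len(spcg)]

    # --- gene sets (GMT) --------------------------------------------------
    gene_sets: dict[str, set] = {}
    planted_set = set(activated) | set(
        background[rng.integers(0, len(background))]
        for _ in range(3)
    )
    gene_sets["geneset_planted"] = planted_set
    for i in range(10):
        size = int(rng.integers(10, 41))
        idx = rng.choice(len(gene_ids), size=size, replace=False)
        gene_sets[f"geneset_rand{i:02d}"] = {gene_ids[j] for j in idx}
    gene_sets["geneset_tiny"] = {
        gene_ids[j] for j in rng.choice(len(gene_ids), size=5, replace=False)
    }

    # --- genome and motif planting ---------------------------------------
    p_gc = cfg.gc_fraction
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    genome_arr = {
        chrom: rng.choice(list("ACGT"), size=cfg.chrom_length, p=probs)
        for chrom in chrom_names
    }

    def plant_at(chrom: str, center: int) -> None:
        instance = sample_iupac_instance(cfg.motif, rng)
        lo, hi = center - 250, center + 251 - len(instance)
        start = int(rng.integers(lo, hi + 1))
        genome_arr[chrom][start:start + len(instance)] = list(instance)

    activated_set = set(activated)
    for peak in peaks_a:
        gene = peak_to_gene.get(peak.name)
        center = (peak.start + peak.end) // 2
        if gene in activated_set:
            plant_at(peak.chrom, center)
        elif rng.random() < cfg.background_motif_fraction:
            plant_at(peak.chrom, center)

    genome = {chrom: "".join(arr) for chrom, arr in genome_arr.items()}

    truth = SyntheticTruth(
        bound_genes=set(bound),
        activated_genes=set(activated),
        repressed_genes=set(repressed),
        peak_to_gene=peak_to_gene,
        motif=cfg.motif,
    )
    return SyntheticBundle(
        config=cfg, genome=genome, transcripts=transcripts,
        peaks_a=peaks_a, peaks_b=peaks_b, de_records=de_records,
        microarray=microarray, insitu_genes=insitu_genes, spcg_genes=spcg,
        gene_sets=gene_sets, truth=truth,
    )


BUNDLE_FILES = {
    "genome": "genome.fa",
    "annotation": "genes.gtf",
    "peaks_a": "sage_role_peaks.narrowPeak",
    "peaks_b": "fkh_role_peaks.narrowPeak",
    "de_table": "de_tissues.tsv",
    "microarray": "microarray.tsv",
    "insitu": "insitu_genes.txt",
    "spcg": "spcg_genes.txt",
    "gene_sets": "gene_sets.gmt",
    "truth": "truth.json",
    "config": "config.json",
}


def write_bundle(bundle: SyntheticBundle, outdir) -> dict:
    """Write every bundle piece in its external format; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in BUNDLE_FILES.items()}
    iof.write_fasta(bundle.genome, paths["genome"])
    iof.write_gtf_transcripts(bundle.transcripts, paths["annotation"])
    iof.write_narrowpeak(bundle.peaks_a, paths["peaks_a"])
    iof.write_narrowpeak(bundle.peaks_b, paths["peaks_b"])
    iof.write_de_table(bundle.de_records, paths["de_table"])
    iof.write_microarray_table(bundle.microarray, paths["microarray"])
    iof.write_gene_list(bundle.insitu_genes, paths["insitu"])
    iof.write_gene_list(bundle.spcg_genes, paths["spcg"])
    iof.write_gmt(bundle.gene_sets, paths["gene_sets"])
    paths["truth"].write_text(bundle.truth.to_json())
    paths["config"].write_text(json.dumps(asdict(bundle.config), indent=1))
    return paths
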