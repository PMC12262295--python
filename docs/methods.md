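# Methods

## Scope and model

The package infers which genes a transcription factor (TF) *directly*
regulates in a focal tissue by requiring two independent lines of evidence
per gene: proximal binding (an intersected ChIP-seq peak whose center lies
strictly within 1 kb of the gene's 5′-most TSS) and a regulatory response
(differential expression in the TF knockout). The underlying assumptions
are the standard ones for promoter-proximal TFs: binding evidence shared by
two different tissue-specific driver conditions localizes binding to the
tissue where both drivers are active; the 5′-most TSS is the relevant
anchor for promoter-proximal regulation; and expression changes in the
knockout at strict effect-size/significance thresholds indicate regulation.
Genes bound but unchanged are retained as a within-experiment control class
for the motif comparison.

## Coordinate and identifier conventions

All internal coordinates are 0-based half-open (the narrowPeak/BED
convention); GTF input is converted at the parser boundary. On the + strand
the gene TSS is the minimum transcript start; on the − strand it is the
maximum transcript end − 1. Gene identifiers are compared as exact strings
with no aliasing, because identifier aliasing is data-source-specific.
Sequences are uppercased on load and restricted to ACGTN.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `max_distance` | 1000 bases | strict cutoff for peak-center-to-TSS assignment, one gene per genomic side of the center |
| `lfc_down` / `lfc_up` | −0.15 / +0.15 | strict logFC thresholds for activated / repressed calls |
| `p_max` | 0.05 | strict p-value threshold (raw by default; a BH-adjusted mode exists and is off by default) |
| `microarray_fc`, `microarray_p` | −1.25, 0.05 | strict thresholds for the microarray evidence route |
| `pct_wt_min` | 10 % | strict lower bound on wild-type percent-expressing for the microarray route |
| `unchanged_n` | 150 | size of the least-changed control class (smallest absolute logFC; ties broken toward larger p, then gene id) |
| `flank` | 250 bases | half-width of motif windows around intersected-peak centers |
| `k_min`…`k_max` | 3…8 | exact-word lengths seeded into motif discovery |
| `e_threshold` | 0.05 | E-value cutoff for calling a motif significant / class-unique |
| `gsea` sizes / `n_perm` | 10–500 / 1000 | set-size filter after intersection with the ranked universe; permutation count |

The logFC scale (natural log vs log2) is not assumed: thresholds are
applied to whatever scale the input table carries, and the report's
parameter echo records `logfc_scale: as-supplied`.

Deliberate reading of the classification rules: every inequality is strict,
exactly as the symbolic forms above; "least differentially expressed" means
smallest **absolute** logFC (signed-smallest would pick the most
down-regulated genes, contradicting the intent); the microarray route
requires presence in the focal DE table and fails closed when the gene is
absent; a gene reached as activated only via the in-situ/microarray routes
while simultaneously repressed via scRNA is excluded from both sets and
reported as a conflict, since silent precedence in either direction would
bias the network fractions. "Upstream/downstream" of a peak is genomic
left/right of its center (a `strand_relative` switch flips to gene-strand
sides); a TSS exactly at the center counts once, on the left side at
distance 0; same-side distance ties go to the lexicographically smaller
gene id with a logged warning. The narrowPeak summit field is ignored in
favor of the interval center.

## Motif stage

The discriminative motif search is an intentionally simple, fully testable
analogue of regular-expression motif discovery: every exact word of length
3–8 present in a positive window is a candidate; presence is counted once
per sequence on either strand (words and their reverse complements are
collapsed to a strand-canonical representative, so palindromes cannot
double-count); candidates are scored with the one-sided hypergeometric tail
and an E-value equal to p times the number of distinct words tested in that
run. The top seeds are generalized by a greedy hill-climb that widens one
position at a time to a 2- or 3-base IUPAC code, accepting only strict
p-value improvements, and candidates are re-ranked after generalization (a
widened word can overtake its seed). There is no heuristic word sampling
and no sequential motif erasure. The control set for the activated and
repressed classes is the bound-unchanged windows (the cross-class
comparison); the unchanged class itself is contrasted against an exact
dinucleotide-preserving (Eulerian-path) shuffle of its own windows.

PWM comparison scores a query against each library PWM as the maximum,
over ungapped offsets and both orientations, of the mean per-column Pearson
correlation with overlap ≥ 4 columns; a constant column contributes
correlation 0. There is no q-value machinery for these comparisons.

`motif_match` decides whether a discovered word rediscovers a known
pattern: some ungapped alignment on either strand must place ≥ 5 word
positions inside the pattern, each position's base set a subset of the
aligned pattern position, with overhanging flank positions allowed —
discovery frequently returns the planted core extended by one partially
constrained flanking base, which is the same biological motif.

## GSEA stage

Classic preranked GSEA: hits advance the running sum by |stat|^weight
(weight 1 by default) normalized over set members, misses retreat by
1/(N − Nh), and the enrichment score is the extremum of largest magnitude.
The null is `n_perm` uniform same-size gene draws; NES divides the ES by
the mean |null ES| of matching sign; p = (1 + x)/(1 + n) over same-sign
nulls, so p is never zero; BH correction runs across retained sets. This
gene-permutation scheme stands in for adaptive multilevel p-value
refinement, so extremely small p-values saturate at ~1/n_perm; ES values
are exact. Statistic ties keep stable input order with a logged warning.

## Synthetic bundles

The generator emulates the full input universe: a multi-chromosome uniform
(configurably GC-biased) genome; stranded multi-transcript gene models
placed on a slot grid that guarantees ≥ 4.5 kb between genes, so promoter
peaks, background peaks and motif windows of adjacent genes cannot collide
or cross-assign; two driver peak sets whose shared peaks sit at planted
target promoters (jitter truncated at ±900 bases so the intersected center
is always strictly within 1 kb of the TSS) plus driver-specific background
peaks placed where they can neither enter the intersection nor fall within
1 kb of any TSS; per-tissue DE tables in which activated targets carry
logFC ≤ −0.5 (p < 0.04), repressed targets the positive counterpart,
bound-but-unregulated decoys |logFC| < 0.15, and every unregulated gene a
p-value ≥ 0.2 so false positives cannot arise by construction; a
whole-embryo-microarray-style table, in-situ and secretory-pathway-style
curated lists wired so that activated genes split across the three evidence
routes (≈ 10 % in-situ-only, ≈ 10 % microarray-only, the rest scRNA with
partial extra evidence); a planted IUPAC motif written into the ±250 bp
window of every activated gene's shared peak and into 2 % of other bound
windows; and a GMT collection with one planted-enriched set. Default
conditions: 300 genes on 3 × 500 kb chromosomes, 30 true targets at 70 %
activated (21/9), 30 decoys, logFC noise SD 0.1, five tissues with 60 % of
targets shared into each non-focal tissue. The default planted word
`TGACGTMA` is an arbitrary placeholder chosen to exercise degenerate IUPAC
positions; it is **not** any real TF's consensus. All randomness flows
through one seeded generator; identical configs produce byte-identical
files.

What the generator does *not* emulate: read-level noise, count matrices,
correlated gene expression, realistic promoter composition or chromatin
state, overlapping genes, and peak-width/signal distributions of real
ChIP-seq. Passing recovery tests therefore demonstrates the integration
logic and its boundary behavior, not performance on real data.

## Numerical choices and degenerate inputs

Empty bound sets yield NaN (undefined) network fractions, never 0. An
empty TSS table or `max_distance = 0` produces zero assignments and an
empty network rather than an error. Histogram bins are aligned to multiples
of the bin width over signed center−TSS distances. The k-range is truncated
with a warning when `k_max` exceeds the shortest window. Candidate ranking
uses deterministic tie-breaks (E-value, then discriminative margin, then
longer word, then lexicographic), and classification is invariant to input
row order.

## Known limitations

- The class-vs-class motif control set is small by construction (bound ∩
  least-changed genes, typically 10–20 windows in default bundles), which
  limits the best attainable E-value; with an unlucky seed the planted
  core word's E-value can exceed the 0.05 cutoff even at perfect positive
  coverage, and the measured per-seed motif recovery rate varies roughly
  between 85 % and 100 % over 20-run batches. The dinucleotide-shuffle
  control is the higher-powered alternative when class sizes are small.
- Permutation GSEA p-values are floor-limited at ~1/n_perm.
- Bound-gene counting depends on the annotation's TSS choice; alternative
  promoters closer than 1 kb to a peak of a different gene are resolved
  purely by distance.
- The pipeline consumes already-computed DE summary tables; it performs no
  count-level statistics and no multiple-testing correction by default
  (matching the thresholds' plain "p-val" reading; a BH mode is available).
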