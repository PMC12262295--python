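"""Discriminative motif enrichment in binding-region windows.

A deliberately simple, self-contained analogue of discriminative motif
discovery: exact words of length ``k_min..k_max`` found in the positive
windows are scored by a one-sided hypergeometric (Fisher) test on
per-sequence presence (either strand), then greedily generalized one
position at a time into degenerate IUPAC codes while the Fisher p improves.
There is no heuristic word sampling and no sequential motif erasure.

PWM-library comparison scores a query against each target as the best mean
per-column Pearson correlation over all ungapped offsets and both
orientations (overlap >= 4 columns).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .binding import IntersectedPeak

logger = logging.getLogger(__name__)

# IUPAC degenerate nucleotide codes -> the set of concrete bases they admit
IUPAC_CODES: dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_SET_TO_CODE = {v: k for k, v in IUPAC_CODES.items()}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
# degenerate codes tried during generalization (2- and 3-base codes)
_DEGENERATE = "RYSWKMBDHV"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_word(word: str) -> str:
    """Strand-canonical representative: lexicographic min of word and its
    reverse complement (palindromes are their own canonical form)."""
    rc = reverse_complement(word)
    return word if word <= rc else rc


def iupac_regex(word: str) -> re.Pattern:
    return re.compile(
        "".join(
            "[" + "".join(sorted(IUPAC_CODES[c])) + "]" for c in word
        )
    )


def matches_iupac(word: str, pattern: str) -> bool:
    """True if ``word`` (possibly degenerate) is containable in ``pattern``
    at some offset, on either strand: every position's base set must be a
    subset of the aligned pattern position's set."""
    def fits(w: str, p: str) -> bool:
        if len(w) > len(p):
            return False
        for off in range(len(p) - len(w) + 1):
            if all(
                IUPAC_CODES[wc] <= IUPAC_CODES[pc]
                for wc, pc in zip(w, p[off:off + len(w)])
            ):
                return True
        return False

    return fits(word, pattern) or fits(reverse_complement(word), pattern)


def words_equivalent(a: str, b: str) -> bool:
    """IUPAC-aware identity: mutual containment on either strand."""
    return matches_iupac(a, b) and matches_iupac(b, a)


def motif_match(word: str, pattern: str, min_overlap: int = 5) -> bool:
    """True if a discovered word rediscovers a known pattern.

    Some ungapped alignment on either strand must place >= ``min_overlap``
    word positions inside the pattern, each a subset of the aligned pattern
    position; positions hanging off the pattern ends (flank extensions
    picked up around a planted site) are allowed.
    """
    def ok(w: str) -> bool:
        for off in range(-(len(w) - min_overlap),
                         len(pattern) - min_overlap + 1):
            n, good = 0, True
            for i, c in enumerate(w):
                j = off + i
                if 0 <= j < len(pattern):
                    if IUPAC_CODES[c] <= IUPAC_CODES[pattern[j]]:
                        n += 1
                    else:
                        good = False
                        break
            if good and n >= min_overlap:
                return True
        return False

    return ok(word) or ok(reverse_complement(word))


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifWindow:
    """A +/- flank window around an intersected-peak center, clipped at
    chromosome bounds, labeled with the regulatory class of its gene."""

    chrom: str
    start: int
    end: int
    sequence: str
    label: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length must equal end - start")


def extract_windows(
    peaks: Iterable[IntersectedPeak],
    genome: Mapping[str, str],
    flank: int = 250,
    label: str = "",
) -> list[MotifWindow]:
    """One window per peak: center - flank .. center + flank inclusive of
    the center base (half-open end = center + flank + 1), clipped."""
    out: list[MotifWindow] = []
    for peak in peaks:
        seq = genome.get(peak.chrom)
        if seq is None:
            raise KeyError(f"chromosome {peak.chrom!r} missing from genome")
        center = peak.center
        start = max(0, center - flank)
        end = min(len(seq), center + flank + 1)
        out.append(
            MotifWindow(chrom=peak.chrom, start=start, end=end,
                        sequence=seq[start:end], label=label)
        )
    return out


# ---------------------------------------------------------------------------
# word enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifCandidate:
    """An IUPAC word with its discriminative presence counts.

    ``fisher_p`` is the one-sided hypergeometric tail for enrichment in the
    positives; ``e_value`` multiplies it by the number of distinct candidate
    words tested in the run.
    """

    word: str
    pos_with: int
    pos_total: int
    neg_with: int
    neg_total: int
    fisher_p: float
    e_value: float


def _presence_sets(
    sequences: Sequence[str], k_min: int, k_max: int
) -> list[set]:
    """Per-sequence sets of strand-canonical words (N-containing skipped)."""
    out = []
    for seq in sequences:
        words: set = set()
        n = len(seq)
        for k in range(k_min, k_max + 1):
            for i in range(n - k + 1):
                w = seq[i:i + k]
                if "N" not in w:
                    words.add(canonical_word(w))
        out.append(words)
    return out


def fisher_enrichment_p(
    pos_with: int, pos_total: int, neg_with: int, neg_total: int
) -> float:
    """One-sided hypergeometric tail P(X >= pos_with) for presence counts."""
    return float(
        hypergeom.sf(
            pos_with - 1, pos_total + neg_total,
            pos_with + neg_with, pos_total,
        )
    )


def word_enrichment(
    pos: Sequence[MotifWindow | str],
    neg: Sequence[MotifWindow | str],
    k_min: int = 3,
    k_max: int = 8,
) -> list[MotifCandidate]:
    """Rank every exact word present in >=1 positive sequence by enrichment.

    Presence is per sequence, either strand, occurrences collapsed to 0/1
    (palindromes count once); words and their reverse complements are
    collapsed to one strand-canonical candidate. Ranking is by e-value
    ascending with deterministic tie-breaks.
    """
    pos_seqs = [w.sequence if isinstance(w, MotifWindow) else w for w in pos]
    neg_seqs = [w.sequence if isinstance(w, MotifWindow) else w for w in neg]
    if not pos_seqs or not neg_seqs:
        raise ValueError("both positive and negative sets must be non-empty")
    shortest = min(len(s) for s in list(pos_seqs) + list(neg_seqs))
    if k_max > shortest:
        logger.warning(
            "k_max %d exceeds shortest sequence (%d); truncating",
            k_max, shortest,
        )
        k_max = shortest
    if k_min > k_max:
        raise ValueError("k_min exceeds usable k_max")

    pos_sets = _presence_sets(pos_seqs, k_min, k_max)
    neg_sets = _presence_sets(neg_seqs, k_min, k_max)
    pos_counts: Counter = Counter()
    for s in pos_sets:
        pos_counts.update(s)
    neg_counts: Counter = Counter()
    for s in neg_sets:
        neg_counts.update(s)

    n_words = len(pos_counts)
    pos_total, neg_total = len(pos_seqs), len(neg_seqs)
    candidates = [
        MotifCandidate(
            word=w,
            pos_with=pw,
            pos_total=pos_total,
            neg_with=neg_counts.get(w, 0),
            neg_total=neg_total,
            fisher_p=(p := fisher_enrichment_p(
                pw, pos_total, neg_counts.get(w, 0), neg_total)),
            e_value=min(p * n_words, float("inf")),
        )
        for w, pw in pos_counts.items()
    ]
    candidates.sort(
        key=lambda c: (c.e_value, -(c.pos_with - c.neg_with), -len(c.word),
                       c.word)
    )
    return candidates


# ---------------------------------------------------------------------------
# IUPAC generalization
# ---------------------------------------------------------------------------

def _iupac_presence_counts(
    word: str, seqs: Sequence[str], rc_seqs: Sequence[str]
) -> int:
    pat = iupac_regex(word)
    n = 0
    for s, rc in zip(seqs, rc_seqs):
        if pat.search(s) or pat.search(rc):
            n += 1
    return n


def generalize_word(
    seed: MotifCandidate,
    pos: Sequence[MotifWindow | str],
    neg: Sequence[MotifWindow | str],
) -> MotifCandidate:
    """Greedy IUPAC hill-climb from an exact seed word.

    Each step tries replacing one position with every 2- or 3-base code and
    accepts the single replacement that most decreases the Fisher p; stops
    at a fixed point. The result's p never exceeds the seed's.
    """
    pos_seqs = [w.sequence if isinstance(w, MotifWindow) else w for w in pos]
    neg_seqs = [w.sequence if isinstance(w, MotifWindow) else w for w in neg]
    rc_pos = [reverse_complement(s) for s in pos_seqs]
    rc_neg = [reverse_complement(s) for s in neg_seqs]
    pos_total, neg_total = len(pos_seqs), len(neg_seqs)
    correction = seed.e_value / seed.fisher_p if seed.fisher_p > 0 else 1.0

    def score(word: str) -> tuple[float, int, int]:
        pw = _iupac_presence_counts(word, pos_seqs, rc_pos)
        nw = _iupac_presence_counts(word, neg_seqs, rc_neg)
        return fisher_enrichment_p(pw, pos_total, nw, neg_total), pw, nw

    best_word = seed.word
    best_p, best_pw, best_nw = score(best_word)
    while True:
        improved = None
        for i, cur in enumerate(best_word):
            for code in _DEGENERATE:
                if not (IUPAC_CODES[cur] < IUPAC_CODES[code]):
                    continue  # only strict widenings of the current set
                trial = best_word[:i] + code + best_word[i + 1:]
                p, pw, nw = score(trial)
                if p < best_p and (improved is None or p < improved[0]):
                    improved = (p, pw, nw, trial)
        if improved is None:
            break
        best_p, best_pw, best_nw, best_word = improved
    return MotifCandidate(
        word=best_word,
        pos_with=best_pw,
        pos_total=pos_total,
        neg_with=best_nw,
        neg_total=neg_total,
        fisher_p=best_p,
        e_value=best_p * correction,
    )


# ---------------------------------------------------------------------------
# PWM comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PwmModel:
    """A position weight matrix: columns are probability vectors (A,C,G,T)."""

    name: str
    matrix: tuple  # tuple of 4-tuples, one per motif position

    def __post_init__(self) -> None:
        arr = np.asarray(self.matrix, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if (arr < 0).any():
            raise ValueError("PWM entries must be non-negative")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    def reverse_complement(self) -> "PwmModel":
        # reverse position order and swap A<->T, C<->G probabilities
        rc = self.array[::-1, [3, 2, 1, 0]]
        return PwmModel(name=self.name, matrix=tuple(map(tuple, rc)))


def pwm_from_iupac(word: str, name: str = "") -> PwmModel:
    """Uniform-probability PWM over each position's admissible bases."""
    rows = []
    for c in word:
        bases = IUPAC_CODES[c]
        row = [1.0 / len(bases) if b in bases else 0.0 for b in "ACGT"]
        rows.append(tuple(row))
    return PwmModel(name=name or word, matrix=tuple(rows))


@dataclass(frozen=True)
class PwmMatch:
    target: str
    score: float     # mean per-column Pearson correlation, in [-1, 1]
    offset: int      # query offset relative to target start
    orientation: str  # "+" or "-"


def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _best_alignment(q: np.ndarray, t: np.ndarray, min_overlap: int):
    best = None
    lq, lt = len(q), len(t)
    for offset in range(-(lq - min_overlap), lt - min_overlap + 1):
        qs, ts = max(0, -offset), max(0, offset)
        n = min(lq - qs, lt - ts)
        if n < min_overlap:
            continue
        corrs = [
            _column_corr(q[qs + i], t[ts + i]) for i in range(n)
        ]
        score = float(np.mean(corrs))
        if best is None or score > best[0]:
            best = (score, offset)
    return best


def pwm_compare(
    query: PwmModel,
    library: Sequence[PwmModel],
    min_overlap: int = 4,
) -> list[PwmMatch]:
    """Best ungapped alignment of the query against each library PWM.

    The score is the maximum, over all offsets and both orientations, of the
    mean Pearson correlation between aligned columns; targets that cannot
    satisfy the overlap constraint are skipped with a warning. Results are
    sorted by score descending.
    """
    if len(query.matrix) < min_overlap:
        raise ValueError("query PWM shorter than the minimum overlap")
    q = query.array
    out: list[PwmMatch] = []
    for target in library:
        if len(target.matrix) < min_overlap:
            logger.warning(
                "target %s shorter than min overlap %d; skipped",
                target.name, min_overlap,
            )
            continue
        fwd = _best_alignment(q, target.array, min_overlap)
        rev = _best_alignment(
            q, target.reverse_complement().array, min_overlap
        )
        if fwd is not None and (rev is None or fwd[0] >= rev[0]):
            out.append(PwmMatch(target.name, fwd[0], fwd[1], "+"))
        elif rev is not None:
            out.append(PwmMatch(target.name, rev[0], rev[1], "-"))
    out.sort(key=lambda m: (-m.score, m.target))
    return out


def read_meme_motifs(path) -> list[PwmModel]:
    """Parse MEME minimal motif format into PWM models."""
    motifs: list[PwmModel] = []
    name = None
    rows: list[tuple] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    motifs.append(PwmModel(name=name, matrix=tuple(rows)))
                parts = line.split()
                name = parts[1] if len(parts) > 1 else "motif"
                rows = []
            elif line.startswith("letter-probability"):
                continue
            elif name is not None and line:
                try:
                    vals = [float(x) for x in line.split()]
                except ValueError:
                    continue
                if len(vals) == 4:
                    rows.append(tuple(vals))
    if name is not None and rows:
        motifs.append(PwmModel(name=name, matrix=tuple(rows)))
    return motifs


def write_meme_motifs(motifs: Sequence[PwmModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(m.matrix)}\n"
            )
            for row in m.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# class-uniqueness
# ---------------------------------------------------------------------------

def class_unique_motifs(
    per_class: Mapping[str, Sequence[MotifCandidate]],
    e_threshold: float = 0.05,
) -> dict[str, list]:
    """Split significant motifs into class-unique and shared.

    A motif is unique to a class when its e-value is below the threshold in
    that class and no IUPAC-equivalent word reaches the threshold in any
    other class; significant in every class means shared. Returns
    ``{"<class>_unique": [...], "shared": [...]}``.
    """
    significant = {
        cls: [c for c in cands if c.e_value < e_threshold]
        for cls, cands in per_class.items()
    }

    def found_in(word: str, cls: str) -> bool:
        return any(words_equivalent(word, c.word) for c in significant[cls])

    out: dict[str, list] = {f"{cls}_unique": [] for cls in per_class}
    out["shared"] = []
    for cls, cands in significant.items():
        others = [c for c in per_class if c != cls]
        for cand in cands:
            hits_elsewhere = [o for o in others if found_in(cand.word, o)]
            if not hits_elsewhere:
                out[f"{cls}_unique"].append(cand)
            elif len(hits_elsewhere) == len(others):
                if not any(
                    words_equivalent(cand.word, c.word) for c in out["shared"]
                ):
                    out["shared"].append(cand)
    return out


# ---------------------------------------------------------------------------
# dinucleotide-shuffle control
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts
    (Altschul–Erickson Eulerian-path shuffle)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)

    # choose one random "last edge" per non-terminal vertex such that the
    # chosen edges form a tree into the terminal vertex
    while True:
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    remaining: dict[str, list[str]] = {}
    for v, targets in edges.items():
        pool = list(targets)
        if v in last_edge:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        remaining[v] = pool

    out = [seq[0]]
    cur = seq[0]
    idx = {v: 0 for v in remaining}
    while True:
        pool = remaining.get(cur)
        if pool is None or idx[cur] >= len(pool):
            break
        nxt = pool[idx[cur]]
        idx[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)
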