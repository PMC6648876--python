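"""PWM scanning, motif co-occurrence, nearest-null maps, and k-mer weights.

PWM matches are reported on a relative score scale: the raw log-odds of
a window is rescaled so that the worst attainable window scores 0 and
the consensus scores 1. The k-mer classifier scores a sequence by the
summed weights of its canonical (reverse-complement collapsed) 6-mers,
with weights fit as smoothed log2 frequency ratios between a positive
and a null sequence set; it provides the ROC/AUC readout used to ask
whether a sequence set is distinguishable from its matched null.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Pwm:
    """Position weight matrix: 4 x L probabilities (rows A, C, G, T)."""

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        m = self.matrix + self.pseudocount
        self.matrix = m / m.sum(axis=0, keepdims=True)
        self.background = np.asarray(self.background, dtype=float)
        self.background = self.background / self.background.sum()

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background[:, None])

    @property
    def score_range(self) -> tuple[float, float]:
        lo = self.log_odds
        return float(lo.min(axis=0).sum()), float(lo.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            self.name + "_rc",
            self.matrix[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            pseudocount=0.0,  # matrix already normalized
        )

    @classmethod
    def from_consensus(
        cls, name: str, consensus: str, dominance: float = 0.85
    ) -> "Pwm":
        """Build a PWM from a consensus string: the consensus base gets
        probability ``dominance``, the rest split evenly; N columns are
        uniform."""
        mat = np.full((4, len(consensus)), np.nan)
        for j, b in enumerate(consensus.upper()):
            if b == "N":
                mat[:, j] = 0.25
            else:
                mat[:, j] = (1.0 - dominance) / 3.0
                mat[_BASE_INDEX[b], j] = dominance
        return cls(name, mat, pseudocount=0.0)


def read_pfm(path, name: str | None = None) -> Pwm:
    """Read a JASPAR-style PFM: optional '>' header, then 4 rows of counts
    (A, C, G, T), whitespace-separated, brackets tolerated."""
    rows = []
    header = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].split()[0]
                continue
            cleaned = line.replace("[", " ").replace("]", " ")
            fields = cleaned.split()
            if fields and fields[0].upper() in _BASES:
                fields = fields[1:]
            rows.append([float(x) for x in fields])
    if len(rows) != 4:
        raise ValueError(f"expected 4 matrix rows, got {len(rows)}")
    return Pwm(name or header or "pwm", np.array(rows))


def builtin_pwms() -> dict[str, Pwm]:
    """Synthetic stand-in PWMs for the NFIA and PPARG binding motifs.

    These are constructed from the well-known consensus forms (the NFI
    palindrome TTGGC..GCCAA; the PPARG:RXRA DR1 repeat), not from any
    database matrix, and are intended for simulation and testing.
    """
    return {
        "NFIA": Pwm.from_consensus("NFIA", "TTGGCNNNNNGCCAA"),
        "PPARG": Pwm.from_consensus("PPARG", "AGGTCAAAGGTCA"),
    }


@dataclass
class MotifHit:
    ocr_id: str
    pwm: str
    offset: int
    strand: str
    score: float
    relative_score: float


def _window_scores(seq: str, pwm: Pwm) -> np.ndarray:
    """Raw log-odds for every window on the forward strand; NaN where the
    window contains a non-ACGT base."""
    L = pwm.length
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0)
    codes = np.fromiter(
        (_BASE_INDEX.get(b, -1) for b in seq.upper()), dtype=np.int64, count=len(seq)
    )
    lo = pwm.log_odds
    out = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    for j in range(L):
        c = codes[j : j + n]
        ok = c >= 0
        bad |= ~ok
        out += np.where(ok, lo[np.clip(c, 0, 3), j], 0.0)
    out[bad] = np.nan
    return out


def scan_pwm(
    sequence: str,
    pwm: Pwm,
    threshold: float = 0.8,
    ocr_id: str = "",
) -> tuple[list[MotifHit], float]:
    """Scan both strands; report windows with relative score >= threshold
    and the best relative score over all scanned windows (0.0 if the
    sequence is shorter than the PWM or every window contains an N)."""
    smin, smax = pwm.score_range
    span = smax - smin
    hits: list[MotifHit] = []
    best = 0.0
    if len(sequence) < pwm.length:
        logger.info("sequence %s shorter than PWM %s; no windows", ocr_id, pwm.name)
        return hits, best
    any_window = False
    for strand, p in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = _window_scores(sequence, p)
        for off, s in enumerate(scores):
            if np.isnan(s):
                continue
            any_window = True
            rel = (s - smin) / span
            best = max(best, rel)
            if rel >= threshold:
                hits.append(MotifHit(ocr_id, pwm.name, off, strand, float(s), float(rel)))
    if not any_window:
        best = 0.0
    return hits, best


def best_hit_scores(
    sequences: dict[str, str], pwm: Pwm, threshold: float = 0.8
) -> pd.DataFrame:
    """Per-sequence best relative score and hit flag for one PWM."""
    rows = []
    for name, seq in sequences.items():
        hits, best = scan_pwm(seq, pwm, threshold=threshold, ocr_id=name)
        rows.append((name, best, len(hits) > 0, len(hits)))
    return pd.DataFrame(
        rows, columns=["ocr_id", "best_rel_score", "has_hit", "n_hits"]
    ).set_index("ocr_id")


def cooccurrence_rate(
    sequences: dict[str, str],
    pwm_a: Pwm,
    pwm_b: Pwm,
    threshold: float = 0.8,
) -> tuple[float, pd.DataFrame]:
    """Fraction of sequences with an A hit that also carry a B hit."""
    a = best_hit_scores(sequences, pwm_a, threshold)["has_hit"]
    b = best_hit_scores(sequences, pwm_b, threshold)["has_hit"]
    if int(a.sum()) == 0:
        raise ValueError(f"no sequence has a {pwm_a.name} hit at threshold {threshold}")
    rate = float((a & b).sum() / a.sum())
    flags = pd.DataFrame({pwm_a.name: a, pwm_b.name: b})
    return rate, flags


def ortholog_motif_delta(
    seq_a: str, seq_b: str, pwm: Pwm, threshold: float = 0.8
) -> dict:
    """Summed relative hit scores in two orthologous sequences and their
    difference (first minus second); no hits contribute 0."""
    hits_a, _ = scan_pwm(seq_a, pwm, threshold=threshold)
    hits_b, _ = scan_pwm(seq_b, pwm, threshold=threshold)
    sum_a = float(sum(h.relative_score for h in hits_a))
    sum_b = float(sum(h.relative_score for h in hits_b))
    return {"sum_a": sum_a, "sum_b": sum_b, "delta": sum_a - sum_b}


def nearest_null_map(
    state_calls: pd.DataFrame, atlas: pd.DataFrame
) -> pd.DataFrame:
    """Map each species-specific OCR to the closest common OCR by midpoint
    distance on the same chromosome; ties go to the lower start
    coordinate. Chromosomes without a common OCR leave those rows
    unmapped (logged)."""
    from .polarize import SPECIES_SPECIFIC_STATES

    common = atlas.loc[state_calls.index[state_calls["state"] == "common"]]
    specific = atlas.loc[
        state_calls.index[state_calls["state"].isin(SPECIES_SPECIFIC_STATES)]
    ]
    rows = []
    by_chrom = {
        chrom: sub.sort_values("start") for chrom, sub in common.groupby("chrom")
    }
    n_unmapped = 0
    for ocr, chrom, start, end in zip(
        specific.index, specific["chrom"], specific["start"], specific["end"]
    ):
        sub = by_chrom.get(chrom)
        if sub is None or sub.empty:
            n_unmapped += 1
            rows.append((ocr, None, np.nan))
            continue
        mid = (start + end) // 2
        cmid = ((sub["start"] + sub["end"]) // 2).to_numpy()
        d = np.abs(cmid - mid)
        best = d.min()
        cand = sub.loc[d == best]
        null_ocr = cand.sort_values("start").index[0]
        rows.append((ocr, null_ocr, int(best)))
    if n_unmapped:
        logger.warning("%d species-specific OCRs on chromosomes with no common OCR", n_unmapped)
    return pd.DataFrame(rows, columns=["ocr_id", "null_ocr_id", "distance"]).set_index(
        "ocr_id"
    )


# ---------------------------------------------------------------------------
# k-mer weights


def canonical_kmers(k: int = 6) -> list[str]:
    """All nonredundant k-mers: the lexicographic minimum of each
    k-mer/reverse-complement pair (palindromes appear once)."""
    out = []
    for tup in itertools.product(_BASES, repeat=k):
        kmer = "".join(tup)
        if kmer <= reverse_complement(kmer):
            out.append(kmer)
    return out


def _kmer_counts(sequences: list[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in sequences:
        seq = seq.upper()
        if len(seq) < k:
            raise ValueError(f"sequence shorter than k = {k}")
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if any(b not in _BASE_INDEX for b in kmer):
                continue
            canon = min(kmer, reverse_complement(kmer))
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def kmer_weights(
    pos_sequences: list[str], null_sequences: list[str], k: int = 6
) -> pd.Series:
    """Canonical k-mer weights: log2 ratio of pseudocounted frequencies in
    the positive vs the null set. Covers every canonical k-mer; a k-mer
    absent from both sets gets weight 0 by symmetry."""
    if not pos_sequences or not null_sequences:
        raise ValueError("both sequence sets must be non-empty")
    kmers = canonical_kmers(k)
    pos = _kmer_counts(pos_sequences, k)
    null = _kmer_counts(null_sequences, k)
    pos_tot = sum(pos.values()) + len(kmers)
    null_tot = sum(null.values()) + len(kmers)
    w = {
        km: np.log2(((pos.get(km, 0) + 1) / pos_tot) / ((null.get(km, 0) + 1) / null_tot))
        for km in kmers
    }
    return pd.Series(w, name="weight")


def kmer_score(sequence: str, weights: pd.Series, k: int = 6) -> float:
    """Sum of canonical k-mer weights over all windows of a sequence."""
    total = 0.0
    seq = sequence.upper()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if any(b not in _BASE_INDEX for b in kmer):
            continue
        total += float(weights.get(min(kmer, reverse_complement(kmer)), 0.0))
    return total


def kmer_classify_auc(
    pos_sequences: list[str],
    null_sequences: list[str],
    k: int = 6,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Cross-validated AUC of the k-mer weight scorer.

    Weights are fit on training folds only; each held-out sequence is
    scored by its summed canonical k-mer weights. Returns the pooled
    AUC and the per-sequence scores/labels (the ROC points follow from
    them)."""
    n_pos, n_null = len(pos_sequences), len(null_sequences)
    if min(n_pos, n_null) < folds:
        raise ValueError(f"need at least {folds} sequences per class")
    if max(n_pos, n_null) / min(n_pos, n_null) > 100:
        logger.warning("severe class imbalance (%d vs %d)", n_pos, n_null)
    seqs = list(pos_sequences) + list(null_sequences)
    labels = np.array([1] * n_pos + [0] * n_null)
    scores = np.zeros(len(seqs))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(seqs, labels):
        w = kmer_weights(
            [seqs[i] for i in train if labels[i] == 1],
            [seqs[i] for i in train if labels[i] == 0],
            k=k,
        )
        for i in test:
            scores[i] = kmer_score(seqs[i], w, k=k)
    auc = float(roc_auc_score(labels, scores))
    detail = pd.DataFrame({"label": labels, "score": scores})
    return auc, detail
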