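"""Promoter box counting, k-mer enrichment and degenerate element scanning.

Promoters are fixed upstream windows (canonically 1501 bp, positions
-1500..+1 relative to the transcription start, stored 5'->3' with local
index 1 corresponding to -1500). Box counting reports every overlapping
occurrence of a motif on the plus strand plus occurrences of its reverse
complement (reported as minus-strand hits); enrichment of k-mers in a
target promoter set is assessed empirically against repeated same-size
samples drawn from a background promoter pool, with an add-one empirical
p-value and Benjamini-Hochberg correction across words. An 18-bp
iron-deficiency element (IDE1-like) scan reports windows matching a
reference element at a minimum number of identical positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .sequtils import DNA_ALPHABET, reverse_complement


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    sequence: str
    source: str = "extracted"   # or "synthetic"

    def __post_init__(self):
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"promoter {self.gene_id!r}: non-dna characters {sorted(bad)}")

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class BoxHit:
    gene_id: str
    motif: str
    position: int          # local 1-based start of the hit window
    strand: str


def _occurrences(seq: str, motif: str) -> list[int]:
    """0-based starts of every (overlapping) occurrence."""
    hits = []
    start = seq.find(motif)
    while start != -1:
        hits.append(start)
        start = seq.find(motif, start + 1)
    return hits


def count_box(promoter: Promoter, motif: str, both_strands: bool = True) -> list[BoxHit]:
    """All occurrences of the motif; with ``both_strands`` the reverse
    complement is also searched (hits labelled '-'). A palindromic motif
    is counted once per site."""
    motif = motif.upper()
    bad = set(motif) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-dna characters in motif: {sorted(bad)}")
    if len(motif) > len(promoter):
        raise ValueError("motif longer than promoter")
    hits = [BoxHit(promoter.gene_id, motif, p + 1, "+")
            for p in _occurrences(promoter.sequence, motif)]
    rc = reverse_complement(motif)
    if both_strands and rc != motif:
        hits += [BoxHit(promoter.gene_id, motif, p + 1, "-")
                 for p in _occurrences(promoter.sequence, rc)]
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def mean_box_count(promoters: Sequence[Promoter], motif: str,
                   both_strands: bool = True) -> float:
    """Arithmetic mean of per-promoter (both-strand) box counts."""
    if not promoters:
        raise ValueError("empty promoter collection")
    return float(np.mean([len(count_box(p, motif, both_strands)) for p in promoters]))


# ---------------------------------------------------------------------------
# k-mer enrichment


@dataclass
class EnrichmentConfig:
    k: int = 5
    n_samples: int = 1000
    sample_size: Optional[int] = None   # defaults to the target-set size
    seed: int = 0
    fdr_q: float = 0.05

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_samples < 19:
            raise ValueError("n_samples must be >= 19 so p < 0.05 is attainable")


@dataclass
class EnrichmentResult:
    table: pd.DataFrame      # word, observed_mean, background_mean, p, q, enriched
    config: EnrichmentConfig

    def word(self, w: str) -> pd.Series:
        return self.table.set_index("word").loc[w]


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _kmer_occurrence_vector(seq: str, k: int) -> np.ndarray:
    """Occurrence count of every 4^k word on the plus strand (windows
    containing ambiguity codes are skipped)."""
    codes = np.array([_BASE_CODE.get(c, -1) for c in seq], dtype=np.int64)
    size = 4 ** k
    if len(codes) < k:
        return np.zeros(size, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1)
    valid = (windows >= 0).all(axis=1)
    word_codes = windows[valid] @ powers
    return np.bincount(word_codes, minlength=size)


def _word_code(word: str) -> int:
    code = 0
    for c in word:
        code = code * 4 + _BASE_CODE[c]
    return code


def _word_counts(promoters: Sequence[Promoter], words: list[str]) -> np.ndarray:
    """(n_promoters, n_words) both-strand occurrence counts.

    Both-strand count of a word = plus-strand occurrences of the word
    plus those of its reverse complement; palindromes counted once,
    consistent with count_box.
    """
    k = len(words[0])
    if any(len(w) != k for w in words):
        raise ValueError("all words must share one length")
    fwd = np.array([_word_code(w) for w in words])
    rc_words = [reverse_complement(w) for w in words]
    rc = np.array([_word_code(w) for w in rc_words])
    palindrome = np.array([w == r for w, r in zip(words, rc_words)])
    out = np.zeros((len(promoters), len(words)), dtype=float)
    for i, p in enumerate(promoters):
        occ = _kmer_occurrence_vector(p.sequence, k)
        out[i] = occ[fwd] + np.where(palindrome, 0, occ[rc])
    return out


def kmer_enrichment(
    targets: Sequence[Promoter],
    background: Sequence[Promoter],
    cfg: EnrichmentConfig | None = None,
    words: Optional[list[str]] = None,
) -> EnrichmentResult:
    """Empirical enrichment of k-mer words in the target promoters.

    For every word the observed mean count per target promoter is
    compared with the means of ``n_samples`` seeded draws (each of
    ``sample_size`` background promoters, without replacement within a
    draw): p = (1 + #samples with mean >= observed) / (1 + n_samples),
    then Benjamini-Hochberg across words.
    """
    cfg = cfg or EnrichmentConfig()
    sample_size = cfg.sample_size or len(targets)
    if sample_size > len(background):
        raise ValueError("sample_size exceeds background size")
    if words is None:
        words = ["".join(w) for w in itertools.product("ACGT", repeat=cfg.k)]
    else:
        words = [w.upper() for w in words]

    observed = _word_counts(targets, words).mean(axis=0)
    bg_counts = _word_counts(background, words)     # (n_bg, n_words)
    rng = np.random.default_rng(cfg.seed)
    n_bg = len(background)
    exceed = np.zeros(len(words))
    bg_mean_acc = np.zeros(len(words))
    for _ in range(cfg.n_samples):
        pick = rng.choice(n_bg, size=sample_size, replace=False)
        sample_mean = bg_counts[pick].mean(axis=0)
        exceed += sample_mean >= observed
        bg_mean_acc += sample_mean
    p = (1 + exceed) / (1 + cfg.n_samples)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({
        "word": words,
        "observed_mean": observed,
        "background_mean": bg_mean_acc / cfg.n_samples,
        "p": p,
        "q": q,
        "enriched": q <= cfg.fdr_q,
    }).sort_values("p", kind="stable").reset_index(drop=True)
    return EnrichmentResult(table=table, config=cfg)


# ---------------------------------------------------------------------------
# degenerate element scan


@dataclass(frozen=True)
class DegenerateHit:
    gene_id: str
    position: int
    strand: str
    matches: int


def scan_degenerate(promoter: Promoter, reference: str,
                    min_matches: int = 14) -> list[DegenerateHit]:
    """Both-strand sliding comparison against a degenerate reference
    element (canonically the 18-bp IDE1); windows with at least
    ``min_matches`` identical positions are reported."""
    reference = reference.upper()
    bad = set(reference) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-dna characters in reference: {sorted(bad)}")
    if min_matches > len(reference):
        raise ValueError("min_matches exceeds reference length")
    L = len(reference)
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    hits = []
    for strand, seq in (("+", promoter.sequence),
                        ("-", reverse_complement(promoter.sequence))):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        n = len(arr)
        for start in range(n - L + 1):
            m = int((arr[start:start + L] == ref).sum())
            if m >= min_matches:
                pos = start if strand == "+" else n - start - L
                hits.append(DegenerateHit(promoter.gene_id, pos + 1, strand, m))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def box_hit_table(hits: Sequence[BoxHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.gene_id, h.motif, h.position, h.strand) for h in hits],
        columns=["gene", "motif", "position", "strand"],
    )
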