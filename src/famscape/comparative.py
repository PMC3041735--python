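"""Pairwise identity matrices, windowed dot-plot duplication/inversion
detection, tandem-cluster detection and exon-structure comparison.

Percent identity is computed on a global Needleman-Wunsch alignment
with affine gaps, with the full alignment length (gap columns included)
as the denominator. The dot-plot scorer slides a fixed window along the
reference and scores it ungapped against every position of the
comparative sequence in both orientations with +5/match, -4/mismatch:
with the default window of 24 a perfect hit scores 120 and the default
cutoff of 80 tolerates up to four mismatches per window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io import GeneRow, SequenceRecord
from .sequtils import reverse_complement


@dataclass
class AlignParams:
    matrix: str = "BLOSUM62"        # "dna" selects +5/-4
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


@dataclass
class IdentityResult:
    percent_identity: float
    aligned_a: str
    aligned_b: str
    score: float


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if params.matrix == "dna":
        aligner.match_score = 5
        aligner.mismatch_score = -4
    else:
        aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # first gap residue costs gap_open, each further residue gap_extend
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_identity(a: SequenceRecord, b: SequenceRecord,
                    params: AlignParams | None = None) -> IdentityResult:
    """Global alignment percent identity: identical aligned residue pairs
    divided by alignment length (gap columns count in the denominator)."""
    params = params or AlignParams()
    if not a.sequence or not b.sequence:
        raise ValueError("empty sequence")
    if a.alphabet != b.alphabet:
        raise ValueError("sequences must share an alphabet")
    aln = _aligner(params).align(a.sequence, b.sequence)[0]
    ga, gb = str(aln[0]), str(aln[1])
    identical = sum(x == y and x != "-" for x, y in zip(ga, gb))
    return IdentityResult(
        percent_identity=100.0 * identical / len(ga),
        aligned_a=ga,
        aligned_b=gb,
        score=float(aln.score),
    )


def identity_matrix(seqs: Sequence[SequenceRecord],
                    params: AlignParams | None = None) -> pd.DataFrame:
    """All-vs-all percent identity, rounded to integer percent; symmetric
    with a 100 diagonal."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [s.id for s in seqs]
    n = len(ids)
    mat = np.full((n, n), 100, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            pid = int(round(global_identity(seqs[i], seqs[j], params).percent_identity))
            mat[i, j] = mat[j, i] = pid
    return pd.DataFrame(mat, index=ids, columns=ids)


def lower_triangle(matrix: pd.DataFrame) -> pd.DataFrame:
    """Display form: lower triangle with the diagonal omitted."""
    out = matrix.astype(object).copy()
    for i in range(len(out)):
        for j in range(i, len(out)):
            out.iat[i, j] = ""
    return out.iloc[1:, :-1]


# ---------------------------------------------------------------------------
# dot-plot matching


@dataclass
class DotPlotConfig:
    window: int = 24
    cutoff: float = 80.0
    match_score: float = 5.0
    mismatch_score: float = -4.0

    def __post_init__(self):
        if self.window < 4:
            raise ValueError("window must be >= 4")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class SegmentMatch:
    ref_start: int
    ref_end: int
    comp_start: int
    comp_end: int
    orientation: str            # "forward" or "reverse"
    score: float


def _window_hits_forward(ref: np.ndarray, comp: np.ndarray,
                         cfg: DotPlotConfig) -> list[tuple[int, int, float]]:
    """(ref_pos0, comp_pos0, score) for every window placement scoring
    >= cutoff, scanning per diagonal with a running window sum."""
    w = cfg.window
    n, m = len(ref), len(comp)
    hits = []
    kernel = np.ones(w)
    for off in range(-(n - w), m - w + 1):
        # diagonal: ref[i] vs comp[i + off]
        i0 = max(0, -off)
        i1 = min(n, m - off)
        if i1 - i0 < w:
            continue
        matches = (ref[i0:i1] == comp[i0 + off:i1 + off]).astype(float)
        sums = np.convolve(matches, kernel, mode="valid")
        scores = cfg.match_score * sums + cfg.mismatch_score * (w - sums)
        for k in np.nonzero(scores >= cfg.cutoff)[0]:
            i = i0 + int(k)
            hits.append((i, i + off, float(scores[k])))
    return hits


def _merge_diagonal(hits: list[tuple[int, int, float]], w: int, m: int,
                    orientation: str) -> list[SegmentMatch]:
    """Merge window hits adjacent on the same diagonal into maximal segments."""
    by_diag: dict[int, list[tuple[int, float]]] = {}
    for i, j, s in hits:
        by_diag.setdefault(j - i, []).append((i, s))
    segments = []
    for diag, entries in sorted(by_diag.items()):
        entries.sort()
        run_start, prev, best = entries[0][0], entries[0][0], entries[0][1]
        for i, s in entries[1:] + [(None, 0.0)]:
            if i is not None and i <= prev + w:
                prev = i
                best = max(best, s)
                continue
            ref_start, ref_end = run_start, prev + w - 1
            comp_start, comp_end = run_start + diag, prev + diag + w - 1
            if orientation == "reverse":
                # map back from reverse-complement coordinates
                comp_start, comp_end = m - 1 - comp_end, m - 1 - comp_start
            segments.append(SegmentMatch(
                ref_start=ref_start + 1, ref_end=ref_end + 1,
                comp_start=comp_start + 1, comp_end=comp_end + 1,
                orientation=orientation, score=best,
            ))
            if i is not None:
                run_start, prev, best = i, i, s
    return segments


def dotplot_match(ref: SequenceRecord, comp: SequenceRecord,
                  cfg: DotPlotConfig | None = None) -> list[SegmentMatch]:
    """Windowed ungapped matching of ref against comp in both orientations.

    Window hits adjacent on the same diagonal and orientation merge into
    maximal SegmentMatches; comp coordinates of reverse hits refer to the
    forward strand of comp.
    """
    cfg = cfg or DotPlotConfig()
    if ref.alphabet != "dna" or comp.alphabet != "dna":
        raise ValueError("dot-plot matching requires dna sequences")
    if cfg.window > len(ref.sequence) or cfg.window > len(comp.sequence):
        raise ValueError("window longer than sequence")
    r = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
    c_fwd = np.frombuffer(comp.sequence.encode(), dtype=np.uint8)
    c_rev = np.frombuffer(reverse_complement(comp.sequence).encode(), dtype=np.uint8)
    m = len(c_fwd)
    segments = _merge_diagonal(_window_hits_forward(r, c_fwd, cfg), cfg.window, m, "forward")
    segments += _merge_diagonal(_window_hits_forward(r, c_rev, cfg), cfg.window, m, "reverse")
    segments.sort(key=lambda s: (s.ref_start, s.comp_start, s.orientation))
    return segments


def segment_table(segments: Sequence[SegmentMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.ref_start, s.ref_end, s.comp_start, s.comp_end, s.orientation, s.score)
         for s in segments],
        columns=["ref_start", "ref_end", "comp_start", "comp_end", "orientation", "score"],
    )


# ---------------------------------------------------------------------------
# tandem clusters and exon structure


@dataclass
class ClusterReport:
    clusters: list[tuple[str, list[str], tuple[int, int]]]  # (chrom, gene ids, span)
    max_gap: int


def find_tandem_clusters(genes: Sequence[GeneRow], max_gap: int = 100_000) -> ClusterReport:
    """Maximal runs of >= 2 same-chromosome genes whose successive
    start-to-start gaps are all <= max_gap."""
    by_chrom: dict[str, list[GeneRow]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    clusters = []
    for chrom in sorted(by_chrom):
        rows = sorted(by_chrom[chrom], key=lambda g: g.start)
        run = [rows[0]]
        for g in rows[1:] + [None]:
            if g is not None and g.start - run[-1].start <= max_gap:
                run.append(g)
                continue
            if len(run) >= 2:
                clusters.append((chrom, [x.gene_id for x in run],
                                 (run[0].start, max(x.end for x in run))))
            if g is not None:
                run = [g]
    return ClusterReport(clusters=clusters, max_gap=max_gap)


@dataclass
class ExonComparison:
    n_exons_a: int
    n_exons_b: int
    length_diffs: Optional[tuple[int, ...]]     # positionally paired, when counts equal
    max_relative_diff: Optional[float]
    nearly_identical: bool


def compare_exon_structure(a: GeneRow, b: GeneRow) -> ExonComparison:
    """Compare exon counts and positionally paired exon lengths; the pair
    is "nearly identical" when counts match and no exon's length differs
    by more than 5% of the shorter one."""
    if not a.exons or not b.exons:
        raise ValueError("both genes need exon annotations")
    la, lb = a.exon_lengths, b.exon_lengths
    if len(la) != len(lb):
        return ExonComparison(len(la), len(lb), None, None, False)
    diffs = tuple(abs(x - y) for x, y in zip(la, lb))
    rel = max(d / min(x, y) for d, x, y in zip(diffs, la, lb))
    return ExonComparison(len(la), len(lb), diffs, rel, rel <= 0.05)
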