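"""Iterative profile-based family search.

A position-specific scoring matrix (PSSM) built from a seed alignment is
scanned against candidate proteomes; hits passing an empirical E-value
threshold together with similarity and coverage fractions join the
family, the profile is rebuilt from the enlarged membership, and the
loop repeats until no new sequence appears. E-values are calibrated
against scores of residue-shuffled decoys, so they measure the expected
number of equal-or-better hits in a composition-matched random proteome
of the same size.

The classical selection thresholds for this kind of search (E < 1e-30,
>30% similarity over >=30% of the query) are retained as defaults. The
empirical E-value estimator has a resolution floor of
N_proteome/(1 + n_null): it is an upper bound, and a score exceeding
every null score is consistent with any smaller true E-value. A
threshold below the floor is therefore applied *at* the floor, i.e. a
hit beating the entire null distribution satisfies it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .sequtils import AA_INDEX, PROTEIN_LETTERS, seq_to_aa_indices

logger = logging.getLogger(__name__)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class Profile:
    """Ungapped position-specific scoring model over the 20 amino acids."""

    probs: np.ndarray           # (length, 20) column emission probabilities
    background: np.ndarray      # (20,) background frequencies
    pseudocount_weight: float
    consensus: str

    def __post_init__(self):
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log(self.probs) - np.log(self.background)


@dataclass
class SearchThresholds:
    evalue_max: float = 1e-30
    min_similarity: float = 0.30
    min_coverage: float = 0.30
    max_iterations: int = 20

    def __post_init__(self):
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        for name in ("min_similarity", "min_coverage"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class SearchHit:
    target_id: str
    raw_score: float
    similarity: float
    coverage: float
    offset: int                  # 0-based placement of the profile on the target
    evalue: Optional[float] = None


@dataclass
class FamilySearchResult:
    members_per_iteration: list[set[str]]
    converged: bool
    final_members: set[str]
    hits: dict[str, SearchHit] = field(default_factory=dict)
    curation_flags: dict[str, str] = field(default_factory=dict)


def build_profile(seed_alignment: Sequence, pseudocount_weight: float = 1.0) -> Profile:
    """Estimate column probabilities from an aligned set of sequences.

    Gap cells are excluded from the counts; columns that are more than
    50% gaps are dropped. Each column is smoothed towards the alignment's
    overall residue composition:
    p = (counts + w * background) / (n_observed + w).
    """
    if len(seed_alignment) < 2:
        raise ValueError("profile needs at least 2 aligned sequences")
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    lengths = {len(r.sequence) for r in seed_alignment}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: rows have unequal lengths")

    rows = [seq_to_aa_indices(r.sequence) for r in seed_alignment]
    gap_rows = [np.array([c == "-" for c in r.sequence]) for r in seed_alignment]
    idx = np.stack(rows)
    gaps = np.stack(gap_rows)
    n_rows, n_cols = idx.shape

    keep = gaps.mean(axis=0) <= 0.5
    idx = idx[:, keep]
    gaps = gaps[:, keep]

    # background = overall residue composition (with a flat pseudocount),
    # matching the composition of shuffled decoys
    valid = (idx >= 0) & ~gaps
    bg_counts = np.bincount(idx[valid].ravel(), minlength=20).astype(float) + 1.0
    background = bg_counts / bg_counts.sum()

    n_kept = idx.shape[1]
    probs = np.zeros((n_kept, 20))
    for j in range(n_kept):
        col = idx[valid[:, j], j]
        counts = np.bincount(col, minlength=20).astype(float)
        n_obs = counts.sum()
        probs[j] = (counts + pseudocount_weight * background) / (n_obs + pseudocount_weight)
    consensus = "".join(PROTEIN_LETTERS[k] for k in probs.argmax(axis=1))
    return Profile(probs=probs, background=background,
                   pseudocount_weight=pseudocount_weight, consensus=consensus)


def _similarity(consensus: str, seq_window: str) -> float:
    """Fraction of aligned positions with a positive BLOSUM62 score
    against the profile consensus (the BLAST 'positives' convention)."""
    n = len(seq_window)
    if n == 0:
        return 0.0
    pos = 0
    for a, b in zip(consensus, seq_window):
        if a in AA_INDEX and b in AA_INDEX and _BLOSUM62[a][b] > 0:
            pos += 1
    return pos / n


def score_sequence(profile: Profile, seq) -> SearchHit:
    """Best ungapped placement of the profile on the sequence.

    Every offset is scored by the log-odds sum (brute force); residues
    outside the 20-letter alphabet contribute 0. Sequences shorter than
    the profile are placed inside it, and coverage reflects the
    truncation (aligned positions / profile length).
    """
    sequence = seq.sequence.replace("-", "")
    lo = profile.log_odds
    L = profile.length
    idx = seq_to_aa_indices(sequence)
    n = len(idx)

    if n >= L:
        n_offsets = n - L + 1
        scores = np.zeros(n_offsets)
        for off in range(n_offsets):
            window = idx[off:off + L]
            ok = window >= 0
            scores[off] = lo[np.arange(L)[ok], window[ok]].sum()
        best = int(scores.argmax())
        raw = float(scores[best])
        window_seq = sequence[best:best + L]
        sim = _similarity(profile.consensus, window_seq)
        coverage = 1.0
        offset = best
    else:
        # slide the whole sequence inside the profile
        n_offsets = L - n + 1
        scores = np.zeros(n_offsets)
        for off in range(n_offsets):
            ok = idx >= 0
            cols = np.arange(off, off + n)
            scores[off] = lo[cols[ok], idx[ok]].sum()
        best = int(scores.argmax())
        raw = float(scores[best])
        sim = _similarity(profile.consensus[best:best + n], sequence)
        coverage = n / L
        offset = -best
    return SearchHit(target_id=seq.id, raw_score=raw, similarity=sim,
                     coverage=coverage, offset=offset)


@dataclass
class EvalueCalibration:
    """Empirical score -> E-value mapping from a shuffled-decoy null."""

    null_scores: np.ndarray      # sorted ascending
    n_proteome: int

    def evalue(self, score: float) -> float:
        n_null = len(self.null_scores)
        n_ge = n_null - int(np.searchsorted(self.null_scores, score, side="left"))
        return self.n_proteome * (1 + n_ge) / (1 + n_null)

    @property
    def floor(self) -> float:
        """Smallest attainable E-value (the estimator's resolution)."""
        return self.n_proteome / (1 + len(self.null_scores))

    def passes(self, score: float, evalue_max: float) -> bool:
        """Threshold test honoring the resolution floor (see module docs)."""
        return self.evalue(score) <= max(evalue_max, self.floor)


def _shuffled(seq: str, rng: np.random.Generator) -> str:
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


class _Anon:
    __slots__ = ("id", "sequence")

    def __init__(self, id, sequence):
        self.id = id
        self.sequence = sequence


def calibrate_evalue(
    profile: Profile,
    decoys: Sequence,
    n_shuffles: int = 5,
    seed: int = 0,
    n_proteome: Optional[int] = None,
) -> EvalueCalibration:
    """Build the empirical null from residue-shuffled copies of the decoys.

    evalue(s) = N_proteome * (1 + #null >= s) / (1 + n_null), which is
    monotonically non-increasing in s and never zero.
    """
    rng = np.random.default_rng(seed)
    null_scores = []
    for rec in decoys:
        seq = rec.sequence.replace("-", "")
        for _ in range(n_shuffles):
            shuf = _Anon(rec.id, _shuffled(seq, rng))
            null_scores.append(score_sequence(profile, shuf).raw_score)
    if len(null_scores) < 100:
        raise ValueError(
            f"need >= 100 null scores for calibration, got {len(null_scores)}"
        )
    return EvalueCalibration(
        null_scores=np.sort(np.asarray(null_scores)),
        n_proteome=n_proteome if n_proteome is not None else len(decoys),
    )


def _stack_member(hit: SearchHit, sequence: str, profile_length: int) -> str:
    """Place a member's ungapped sequence into profile coordinates."""
    if hit.offset >= 0:
        window = sequence[hit.offset:hit.offset + profile_length]
        return window + "-" * (profile_length - len(window))
    start = -hit.offset
    return "-" * start + sequence + "-" * (profile_length - start - len(sequence))


def iterate_search(
    seeds: Sequence,
    proteomes: Sequence,
    thresholds: SearchThresholds | None = None,
    seed: int = 0,
    pseudocount_weight: float = 1.0,
    n_shuffles: int = 3,
) -> FamilySearchResult:
    """Profile search iterated to a fixed point.

    ``seeds`` is an aligned seed set (equal row lengths); ``proteomes``
    is the pooled collection of candidate sequences. Membership grows by
    union, so per-iteration member sets are monotonically non-decreasing;
    the search stops when an iteration adds nothing, or is flagged
    unconverged after ``max_iterations``.
    """
    thresholds = thresholds or SearchThresholds()
    all_seqs = {r.id: r for r in proteomes}
    members = {r.id for r in seeds}
    # aligned rows in profile coordinates, keyed by id
    aligned: dict[str, str] = {r.id: r.sequence for r in seeds}
    members_per_iteration: list[set[str]] = []
    hits_out: dict[str, SearchHit] = {}
    converged = False

    for iteration in range(thresholds.max_iterations):
        rows = [_Anon(mid, aligned[mid]) for mid in sorted(members)]
        profile = build_profile(rows, pseudocount_weight)
        calibration = calibrate_evalue(
            profile,
            list(all_seqs.values()),
            n_shuffles=n_shuffles,
            seed=seed + iteration,
            n_proteome=len(all_seqs),
        )
        new_members = set(members)
        for sid in sorted(all_seqs):
            rec = all_seqs[sid]
            hit = score_sequence(profile, rec)
            hit.evalue = calibration.evalue(hit.raw_score)
            accept = (
                calibration.passes(hit.raw_score, thresholds.evalue_max)
                and hit.similarity >= thresholds.min_similarity
                and hit.coverage >= thresholds.min_coverage
            )
            if sid in members or accept:
                hits_out[sid] = hit
            if accept:
                new_members.add(sid)
                if sid not in aligned:
                    aligned[sid] = _stack_member(
                        hit, rec.sequence.replace("-", ""), profile.length
                    )
        members_per_iteration.append(set(new_members))
        if new_members == members:
            converged = True
            break
        members = new_members

    if not converged:
        logger.warning("family search did not converge after %d iterations",
                       thresholds.max_iterations)
    return FamilySearchResult(
        members_per_iteration=members_per_iteration,
        converged=converged,
        final_members=set(members),
        hits=hits_out,
    )


def curate_members(
    members: Sequence,
    whitelist: frozenset[str] | set[str] = frozenset(),
) -> dict[str, str]:
    """Completeness curation: sequences must start with methionine and
    carry a stop annotation (trailing '*').

    Returns per-id flags: "ok", "no_start_met", "no_stop", or
    "whitelisted" for flagged ids that are retained anyway (known
    N-terminally truncated members, for example).
    """
    flags = {}
    for rec in members:
        seq = rec.sequence.replace("-", "")
        if not seq.startswith("M"):
            flag = "no_start_met"
        elif not seq.endswith("*"):
            flag = "no_stop"
        else:
            flag = "ok"
        if flag != "ok" and rec.id in whitelist:
            flag = "whitelisted"
        flags[rec.id] = flag
    return flags


def retained_after_curation(flags: dict[str, str]) -> set[str]:
    return {i for i, f in flags.items() if f in ("ok", "whitelisted")}
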