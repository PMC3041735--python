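"""Distance phylogenetics: p-distance with pairwise deletion, Poisson
correction, neighbor-joining, and bootstrap with a strict >cutoff
majority display rule.

The distance model is the classical Poisson correction d = -ln(1 - p)
applied to per-pair proportions of differing sites, where each pair
uses only columns in which both sequences have residues (pairwise
deletion). Neighbor joining follows Saitou & Nei's agglomeration with
deterministic lexicographic tie-breaking; bootstrap resamples alignment
columns with replacement and reports, for every internal branch of the
tree built from the full alignment, the percentage of replicates whose
tree contains the same split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tree import Node, Tree

logger = logging.getLogger(__name__)

GAP = ord("-")


class ZeroComparableSitesError(ValueError):
    def __init__(self, pair):
        self.pair = pair
        super().__init__(f"no comparable (both non-gap) sites for pair {pair}")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    model: str  # "p" or "poisson"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.isnan(v).any():
            raise ValueError("distance matrix contains NaN")
        self.values = v

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class BootstrapConfig:
    n_replicates: int = 1000
    consensus_cutoff: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0 <= self.consensus_cutoff < 100):
            raise ValueError("consensus_cutoff must be in [0, 100)")


def _alignment_array(msa) -> tuple[list[str], np.ndarray]:
    labels = [r.id for r in msa]
    lengths = {len(r.sequence) for r in msa}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: rows have unequal lengths")
    arr = np.frombuffer("".join(rec.sequence for rec in msa).encode(), dtype=np.uint8)
    return labels, arr.reshape(len(labels), -1)


def p_distance(msa: Sequence, deletion: str = "pairwise") -> DistanceMatrix:
    """Proportion of differing sites per pair under pairwise deletion."""
    if deletion != "pairwise":
        raise ValueError("only pairwise deletion is supported")
    labels, arr = _alignment_array(msa)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 rows")
    nongap = arr != GAP
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise ZeroComparableSitesError((labels[i], labels[j]))
            diff = int((arr[i][both] != arr[j][both]).sum())
            values[i, j] = values[j, i] = diff / comparable
    return DistanceMatrix(labels, values, "p")


def poisson_correct(p_matrix: DistanceMatrix) -> DistanceMatrix:
    """Multiple-hit correction d = -ln(1 - p); requires every p < 1."""
    if p_matrix.model != "p":
        raise ValueError("input must be a p-distance matrix")
    p = p_matrix.values
    saturated = np.argwhere((p >= 1.0) & ~np.eye(len(p), dtype=bool))
    if len(saturated):
        i, j = saturated[0]
        raise ValueError(
            f"p = 1 for pair ({p_matrix.labels[i]}, {p_matrix.labels[j]}): "
            "Poisson distance is infinite"
        )
    d = -np.log1p(-p)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(p_matrix.labels, d, "poisson")


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dist: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    The pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is joined at
    each step; exact Q ties are broken by the lexicographically smallest
    pair of cluster keys (a cluster's key is its smallest leaf label).
    Negative branch lengths are clamped to zero and logged.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes: dict[str, Node] = {lab: Node(lab) for lab in dist.labels}
    # pairwise distances keyed by unordered cluster-key pair
    d: dict[frozenset[str], float] = {}
    active = sorted(dist.labels)
    for i, a in enumerate(dist.labels):
        for b in dist.labels[i + 1:]:
            d[frozenset((a, b))] = float(dist.values[dist.labels.index(a),
                                                     dist.labels.index(b)])

    def dget(a: str, b: str) -> float:
        return d[frozenset((a, b))]

    def clamp(x: float, context: str) -> float:
        if x < 0:
            logger.debug("negative branch length %.4g clamped to 0 (%s)", x, context)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dget(a, b) for b in active if b != a) for a in active}
        best_q = None
        best_pair = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                a, b = active[ai], active[bi]
                q = (m - 2) * dget(a, b) - r[a] - r[b]
                if best_q is None or q < best_q:
                    best_q, best_pair = q, (a, b)
        a, b = best_pair
        dab = dget(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        la = clamp(la, f"{a} in join({a},{b})")
        lb = clamp(lb, f"{b} in join({a},{b})")
        nodes[a].length = la
        nodes[b].length = lb
        new_key = min(a, b)
        parent = Node(children=[nodes[a], nodes[b]])
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((new_key, c))] = 0.5 * (dget(a, c) + dget(b, c) - dab)
        active = sorted(set(active) - {a, b} | {new_key})
        nodes.pop(a)
        nodes.pop(b)
        nodes[new_key] = parent

    a, b, c = active
    la = clamp(0.5 * (dget(a, b) + dget(a, c) - dget(b, c)), f"{a} final")
    lb = clamp(0.5 * (dget(a, b) + dget(b, c) - dget(a, c)), f"{b} final")
    lc = clamp(0.5 * (dget(a, c) + dget(b, c) - dget(a, b)), f"{c} final")
    nodes[a].length, nodes[b].length, nodes[c].length = la, lb, lc
    root = Node(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root)


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    tree: Tree                      # full NJ tree with supports annotated
    consensus: Tree                 # branches with support <= cutoff collapsed
    n_valid: int
    n_discarded: int
    support_of_split: dict = field(default_factory=dict)


def _nj_from_alignment(msa) -> Tree:
    return nj_tree(poisson_correct(p_distance(msa)))


def bootstrap_support(msa: Sequence, cfg: BootstrapConfig) -> BootstrapResult:
    """Column-resampling bootstrap of the Poisson-corrected NJ tree.

    Replicates in which some pair has zero comparable sites are discarded
    and the support denominator adjusted. The display (consensus) tree
    retains only branches with support strictly greater than the cutoff.
    """
    base_tree = _nj_from_alignment(msa)
    splits = base_tree.bipartitions()
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(cfg.seed)
    labels, arr = _alignment_array(msa)
    L = arr.shape[1]
    n_valid = 0
    n_discarded = 0

    class _Row:
        __slots__ = ("id", "sequence")

        def __init__(self, id, sequence):
            self.id = id
            self.sequence = sequence

    for _ in range(cfg.n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = arr[:, cols]
        rows = [_Row(lab, rep[i].tobytes().decode()) for i, lab in enumerate(labels)]
        try:
            rep_tree = _nj_from_alignment(rows)
        except ZeroComparableSitesError as err:
            n_discarded += 1
            logger.debug("bootstrap replicate discarded: %s", err)
            continue
        n_valid += 1
        rep_splits = rep_tree.bipartitions()
        for s in splits:
            if s in rep_splits:
                counts[s] += 1

    if n_valid == 0:
        raise RuntimeError("all bootstrap replicates were discarded")
    support = {s: 100.0 * counts[s] / n_valid for s in splits}
    base_tree.annotate_supports(support)
    consensus = base_tree.collapse_low_support(cfg.consensus_cutoff)
    return BootstrapResult(
        tree=base_tree,
        consensus=consensus,
        n_valid=n_valid,
        n_discarded=n_discarded,
        support_of_split=support,
    )


def distance_matrix_to_frame(dm: DistanceMatrix):
    import pandas as pd

    return pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels)
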