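"""Synthetic data generators with recorded ground truth.

Each generator emulates the statistical structure one analysis stage
assumes, at desk scale, so every stage of the pipeline can be exercised
against a known answer:

* a protein family born by duplications along a species tree, with
  planted signature motifs, plus composition-matched decoy proteins;
* a pair of chromosomes sharing a segmental duplication that contains a
  tandem gene array, optionally inverted;
* promoter sets with Poisson-planted boxes at target vs background rates;
* qPCR plates whose noiseless threshold cycles invert the efficiency-
  corrected ratio equation exactly.

All generators are deterministic under a fixed seed, and every recorded
truth field is verifiable by exhaustive recount on the emitted data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import GeneRow, SequenceRecord
from .promoters import Promoter
from .qpcr import AmplificationCurve, WellRecord
from .sequtils import PROTEIN_LETTERS, reverse_complement
from .signatures import BUILTIN_SIGNATURES, MotifPattern
from .tree import Node, Tree

# ---------------------------------------------------------------------------
# protein family


@dataclass(frozen=True)
class PlantedSignature:
    pattern: MotifPattern
    anchor: int                 # 0-based start within the ancestral sequence
    retention: float            # per-lineage probability the motif is conserved

    def __post_init__(self):
        if not (0 <= self.retention <= 1):
            raise ValueError("retention probability must be in [0, 1]")


def _default_signatures() -> tuple[PlantedSignature, ...]:
    anchors = {"cys": 25, "mfs_w": 60, "antiporter": 150, "his": 230,
               "loop_tm8_tm9": 300}
    return tuple(
        PlantedSignature(BUILTIN_SIGNATURES[name], anchor, 0.9)
        for name, anchor in anchors.items()
    )


@dataclass
class FamilySimConfig:
    """Conditions for the family generator.

    Defaults emulate a plant transporter family sampled from nine
    genomes with per-species paralog expansion (about 50 members in
    expectation), average-length proteins, modest divergence, and the
    five family signatures planted with 90% per-lineage retention.
    """

    n_species: int = 9
    tree_height: float = 0.3        # expected substitutions/site, root to tip
    dup_rate: float = 4.5           # extra paralogs per species (Poisson mean)
    seq_length: int = 470
    sub_rate_scale: float = 1.0
    signature_plant: tuple[PlantedSignature, ...] = field(default_factory=_default_signatures)
    n_decoys: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1 or self.seq_length < 1:
            raise ValueError("counts must be >= 1")
        if self.tree_height < 0 or self.dup_rate < 0:
            raise ValueError("rates must be >= 0")
        spans = sorted((s.anchor, s.anchor + len(s.pattern)) for s in self.signature_plant)
        prev_end = 0
        for start, end in spans:
            if start < prev_end:
                raise ValueError("planted signatures overlap")
            prev_end = end
        if spans and spans[-1][1] > self.seq_length:
            raise ValueError("seq_length too small for planted signatures")


@dataclass
class SimTruth:
    membership: set[str]
    true_alignment: Optional[list[SequenceRecord]] = None
    true_tree: Optional[Tree] = None
    signature_presence: Optional[pd.DataFrame] = None
    layout: Optional["LayoutTruth"] = None
    promoter_planted: Optional[dict[str, int]] = None
    qpcr_ratios: Optional[dict[tuple[str, str], float]] = None
    qpcr_efficiencies: Optional[dict[str, float]] = None


def _join_times(lo: float, hi: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """n increasing join heights in (lo, hi), one per equal slot with the
    position jittered inside the slot's middle band. The stratification
    guarantees a minimum separation between successive joins, so every
    internal branch of the true tree is long enough to be identifiable --
    a prerequisite for using the generator as phylogenetic ground truth."""
    fracs = (np.arange(n) + rng.uniform(0.3, 0.7, size=n)) / n
    return lo + (hi - lo) * fracs


def _random_ultrametric(labels: list[str], height_range: tuple[float, float],
                        rng: np.random.Generator) -> tuple[Node, float]:
    """Random binary ultrametric topology over ``labels``; join heights are
    stratified draws from ``height_range``. Returns (root, root height)."""
    lo, hi = height_range
    nodes: list[tuple[Node, float]] = [(Node(lab), 0.0) for lab in labels]
    if len(nodes) == 1:
        return nodes[0]
    times = _join_times(lo, hi, len(nodes) - 1, rng)
    for t in times:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (a, ha), (b, hb) = nodes[i], nodes[j]
        a.length = t - ha
        b.length = t - hb
        parent = Node(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [(parent, t)]
    return nodes[0]


def _gene_tree(cfg: FamilySimConfig, rng: np.random.Generator) -> Tree:
    """Species tree (upper half of the height) with per-species paralog
    subtrees (lower half), rescaled so the root sits at tree_height."""
    h = cfg.tree_height if cfg.tree_height > 0 else 1.0
    subtrees = []
    for s in range(cfg.n_species):
        k = 1 + rng.poisson(cfg.dup_rate)
        labels = [f"sp{s + 1}_g{j + 1}" for j in range(k)]
        subtrees.append(_random_ultrametric(labels, (0, h / 2), rng))
    if cfg.n_species == 1:
        root, root_h = subtrees[0]
    else:
        nodes = list(subtrees)
        times = _join_times(h / 2, h, len(nodes) - 1, rng)
        for t in times:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            (a, ha), (b, hb) = nodes[i], nodes[j]
            a.length = t - ha
            b.length = t - hb
            parent = Node(children=[a, b])
            nodes = [n for k_, n in enumerate(nodes) if k_ not in (i, j)] + [(parent, t)]
        root, root_h = nodes[0]
    if root_h > 0 and cfg.tree_height > 0:
        scale = cfg.tree_height / root_h
        for node in Tree(root).iter_nodes():
            node.length *= scale
    return Tree(root)


def _evolve(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Site-wise Poisson substitution process over the 20-letter alphabet;
    each event replaces the residue with a uniform draw from the other 19."""
    out = seq.copy()
    if t <= 0:
        return out
    n_events = rng.poisson(t, size=len(seq))
    for site in np.nonzero(n_events)[0]:
        for _ in range(n_events[site]):
            new = rng.integers(0, 19)
            if new >= out[site]:
                new += 1
            out[site] = new
    return out


def _instantiate(pattern: MotifPattern, rng: np.random.Generator) -> list[Optional[int]]:
    """Concrete residue indices for the non-wildcard positions of a pattern."""
    inst = []
    for allowed in pattern.positions:
        if allowed is None:
            inst.append(None)
        else:
            choice = rng.choice(sorted(allowed))
            inst.append(PROTEIN_LETTERS.index(choice))
    return inst


def simulate_family(cfg: FamilySimConfig) -> tuple[list[SequenceRecord], SimTruth]:
    """Evolve an ancestral protein along a random duplication tree.

    Indel-free evolution keeps column homology, so the emitted member
    sequences are simultaneously the true alignment. Each planted
    signature is retained in a leaf lineage with its configured
    probability (one draw per leaf); retained motifs are held at their
    ancestral residues, released motifs evolve freely. Decoys are
    residue-shuffled copies of members, preserving composition.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = _gene_tree(cfg, rng)
    root_seq = rng.integers(0, 20, size=cfg.seq_length)
    instances = [_instantiate(s.pattern, rng) for s in cfg.signature_plant]
    for sig, inst in zip(cfg.signature_plant, instances):
        for off, res in enumerate(inst):
            if res is not None:
                root_seq[sig.anchor + off] = res

    leaf_seqs: dict[str, np.ndarray] = {}

    def walk(node: Node, seq: np.ndarray):
        evolved = _evolve(seq, node.length * cfg.sub_rate_scale, rng)
        if node.is_leaf:
            leaf_seqs[node.label] = evolved
        else:
            for child in node.children:
                walk(child, evolved)

    for child in tree.root.children:
        walk(child, root_seq)
    if not leaf_seqs:  # degenerate single-lineage tree
        leaf_seqs[tree.root.label] = root_seq.copy()

    presence_rows = []
    members = []
    for label in sorted(leaf_seqs):
        seq = leaf_seqs[label]
        flags = {}
        for sig, inst in zip(cfg.signature_plant, instances):
            retained = bool(rng.random() < sig.retention)
            if retained:
                for off, res in enumerate(inst):
                    if res is not None:
                        seq[sig.anchor + off] = res
            flags[sig.pattern.name] = retained
        presence_rows.append({"protein": label, **flags})
        members.append(SequenceRecord(
            id=label,
            sequence="".join(PROTEIN_LETTERS[i] for i in seq),
            alphabet="protein",
        ))

    decoys = []
    for i in range(cfg.n_decoys):
        src = members[i % len(members)]
        chars = np.array(list(src.sequence))
        rng.shuffle(chars)
        decoys.append(SequenceRecord(
            id=f"decoy_{i + 1:04d}",
            sequence="".join(chars),
            alphabet="protein",
        ))

    truth = SimTruth(
        membership={m.id for m in members},
        true_alignment=list(members),
        true_tree=tree,
        signature_presence=pd.DataFrame(presence_rows).set_index("protein"),
    )
    return members + decoys, truth


# ---------------------------------------------------------------------------
# genome layout


@dataclass
class LayoutTruth:
    ref_segment: tuple[int, int]       # 1-based inclusive on chrA
    comp_segment: tuple[int, int]      # 1-based inclusive on chrB
    orientation: str                   # "forward" or "reverse"
    clusters: dict[str, list[str]]     # chromosome -> tandem gene ids


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    hit = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hit:
        alt = [c for c in "ACGT" if c != chars[i]]
        chars[i] = alt[rng.integers(0, 3)]
    return "".join(chars)


def simulate_genome_layout(
    n_genes: int = 6,
    tandem_size: int = 5,
    inversion: bool = False,
    seed: int = 0,
    gene_length: int = 400,
    spacer_length: int = 600,
    flank: int = 1000,
    copy_mutation_rate: float = 0.005,
    paralog_mutation_rate: float = 0.02,
) -> tuple[dict[str, SequenceRecord], list[GeneRow], LayoutTruth]:
    """Two chromosomes sharing a duplicated segment with a tandem array.

    chrA carries the segment forward; chrB carries a lightly mutated copy,
    reverse-complemented when ``inversion``. The segment holds
    ``tandem_size`` tandem paralogs; any further genes (up to ``n_genes``)
    are isolated singletons on their own chromosomes.
    """
    if tandem_size > n_genes:
        raise ValueError("tandem_size must be <= n_genes")
    if tandem_size < 1:
        raise ValueError("tandem_size must be >= 1")
    rng = np.random.default_rng(seed)
    base_gene = _random_dna(gene_length, rng)
    parts = []
    gene_offsets = []   # 0-based start of each gene within the segment
    offset = 0
    for i in range(tandem_size):
        gene = _mutate_dna(base_gene, paralog_mutation_rate, rng)
        parts.append(gene)
        gene_offsets.append(offset)
        offset += gene_length
        if i < tandem_size - 1:
            parts.append(_random_dna(spacer_length, rng))
            offset += spacer_length
    segment = "".join(parts)
    S = len(segment)

    flank_a1, flank_a2 = _random_dna(flank, rng), _random_dna(flank, rng)
    flank_b1, flank_b2 = _random_dna(flank + 200, rng), _random_dna(flank - 200, rng)
    copy = _mutate_dna(segment, copy_mutation_rate, rng)
    if inversion:
        copy = reverse_complement(copy)
    chrom_a = flank_a1 + segment + flank_a2
    chrom_b = flank_b1 + copy + flank_b2

    def exons_for(start: int, end: int) -> tuple[tuple[int, int], tuple[int, int]]:
        length = end - start + 1
        e1_end = start + int(length * 0.4) - 1
        e2_start = e1_end + int(length * 0.1) + 1
        return ((start, e1_end), (e2_start, end))

    genes: list[GeneRow] = []
    clusters: dict[str, list[str]] = {"chrA": [], "chrB": []}
    for i, off in enumerate(gene_offsets):
        start = len(flank_a1) + off + 1
        end = start + gene_length - 1
        gid = f"geneA_{i + 1}"
        genes.append(GeneRow(gid, "chrA", start, end, "+", exons_for(start, end)))
        clusters["chrA"].append(gid)
    for i, off in enumerate(gene_offsets):
        if inversion:
            seg_start = S - (off + gene_length) + 1   # 1-based within copy
            start = len(flank_b1) + seg_start
            strand = "-"
        else:
            start = len(flank_b1) + off + 1
            strand = "+"
        end = start + gene_length - 1
        gid = f"geneB_{i + 1}"
        genes.append(GeneRow(gid, "chrB", start, end, strand, exons_for(start, end)))
        clusters["chrB"].append(gid)

    chroms = {
        "chrA": SequenceRecord("chrA", chrom_a, "dna"),
        "chrB": SequenceRecord("chrB", chrom_b, "dna"),
    }
    for i in range(n_genes - tandem_size):
        name = f"chrX{i + 1}"
        seq = _random_dna(2 * flank + gene_length, rng)
        chroms[name] = SequenceRecord(name, seq, "dna")
        start = flank + 1
        end = start + gene_length - 1
        genes.append(GeneRow(f"geneX_{i + 1}", name, start, end, "+",
                             exons_for(start, end)))

    truth = LayoutTruth(
        ref_segment=(len(flank_a1) + 1, len(flank_a1) + S),
        comp_segment=(len(flank_b1) + 1, len(flank_b1) + S),
        orientation="reverse" if inversion else "forward",
        clusters=clusters,
    )
    return chroms, genes, truth


# ---------------------------------------------------------------------------
# promoters


def simulate_promoters(
    n_target: int,
    n_background: int,
    length: int = 1501,
    lambda_target: float = 5.85,
    lambda_background: float = 3.24,
    box: str = "CATGC",
    seed: int = 0,
    letters: str = "ACGT",
) -> tuple[list[Promoter], list[Promoter], SimTruth]:
    """I.i.d. uniform-composition promoters with K ~ Poisson(lambda)
    planted non-overlapping boxes at random positions and strands.

    The recorded truth is the *planted* count per promoter; incidental
    background matches may add to observed counts.
    """
    if length < len(box):
        raise ValueError("promoter length must be >= box length")
    if lambda_target < 0 or lambda_background < 0:
        raise ValueError("lambdas must be >= 0")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(letters))
    planted: dict[str, int] = {}

    def make(name: str, lam: float, source_tag: str) -> Promoter:
        seq = list(alphabet[rng.integers(0, len(alphabet), size=length)])
        k = int(rng.poisson(lam))
        placed: list[tuple[int, int]] = []
        tries = 0
        count = 0
        while count < k:
            tries += 1
            if tries > 1000 * max(k, 1):
                raise ValueError("cannot place boxes without overlap; promoter too short")
            start = int(rng.integers(0, length - len(box) + 1))
            span = (start, start + len(box) - 1)
            if any(not (span[1] < s or span[0] > e) for s, e in placed):
                continue
            motif = box if rng.random() < 0.5 else reverse_complement(box)
            seq[span[0]:span[1] + 1] = list(motif)
            placed.append(span)
            count += 1
        planted[name] = k
        return Promoter(name, "".join(seq), source=source_tag)

    targets = [make(f"target_{i + 1}", lambda_target, "synthetic")
               for i in range(n_target)]
    background = [make(f"background_{i + 1}", lambda_background, "synthetic")
                  for i in range(n_background)]
    truth = SimTruth(membership={p.gene_id for p in targets},
                     promoter_planted=planted)
    return targets, background, truth


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    design: Sequence[tuple[str, str, float]],
    efficiencies: dict[str, float],
    ct_ref_base: float = 20.0,
    noise_sd: float = 0.0,
    n_reps: int = 3,
    curves: bool = False,
    seed: int = 0,
    reference_gene: str = "UBQ5",
    n_cycles: int = 40,
    threshold: float = 0.2,
    baseline: float = 0.05,
    plateau: float = 10.0,
    curve_noise: float = 0.0,
) -> tuple[list[WellRecord], list[AmplificationCurve], SimTruth]:
    """qPCR plate generator inverting the efficiency-corrected ratio.

    Noiseless threshold cycles satisfy
    ratio = E_ref^Ct_ref / E_target^Ct_target exactly, so the
    quantification pipeline round-trips planted ratios at zero noise;
    Gaussian Ct noise (sd in cycles) is added per well. With ``curves``,
    raw fluorescence F_c = baseline + min(x, plateau) with
    x = (threshold/E^Ct) * E^c is emitted per well: exactly exponential
    below saturation, flat at the plateau above it.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    for gene, E in efficiencies.items():
        if not (1.0 < E <= 2.0):
            raise ValueError(f"efficiency of {gene} must be in (1, 2]")
    rng = np.random.default_rng(seed)
    e_ref = efficiencies[reference_gene]
    wells: list[WellRecord] = []
    curve_list: list[AmplificationCurve] = []
    ratios: dict[tuple[str, str], float] = {}

    def emit(gene: str, sample: str, ct0: float):
        E = efficiencies[gene]
        for rep in range(1, n_reps + 1):
            ct = ct0 + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
            wells.append(WellRecord(gene, sample, rep, ct, efficiency=E))
            if curves:
                c = np.arange(1, n_cycles + 1)
                x = (threshold / E ** ct) * E ** c
                f = baseline + np.minimum(x, plateau)
                if curve_noise > 0:
                    f = f * (1 + rng.normal(0, curve_noise, size=n_cycles))
                curve_list.append(AmplificationCurve(
                    well_id=f"{gene}:{sample}:{rep}", gene=gene, sample=sample,
                    fluorescence=f))

    samples = sorted({sample for _, sample, _ in design})
    for sample in samples:
        emit(reference_gene, sample, ct_ref_base)
    for gene, sample, ratio in design:
        if ratio <= 0:
            raise ValueError("true_ratio must be > 0")
        e_t = efficiencies[gene]
        ct_target = (ct_ref_base * math.log(e_ref) - math.log(ratio)) / math.log(e_t)
        ratios[(gene, sample)] = ratio
        emit(gene, sample, ct_target)

    truth = SimTruth(
        membership=set(),
        qpcr_ratios=ratios,
        qpcr_efficiencies=dict(efficiencies),
    )
    return wells, curve_list, truth
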