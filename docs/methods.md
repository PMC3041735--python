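# Methods

This note describes the models and procedures famscape implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Family search

Family membership is found by an iterative profile search. The profile
is a position-specific scoring matrix (PSSM): per-column emission
probabilities over the 20 amino acids estimated from the current
members' alignment, smoothed toward the alignment's overall residue
composition with a pseudocount weight *w* (default 1.0):

    p_j(a) = (c_j(a) + w·q(a)) / (n_j + w)

Gap cells are excluded from the counts and columns that are more than
50% gaps are dropped. The background *q* is the alignment composition
(not a flat 1/20) because the decoy null consists of residue-shuffled
sequences, which preserve composition; positional signal is then the
only thing the log-odds score log p_j(a)/q(a) can reward.

A sequence is scored by the best ungapped placement of the profile
(brute force over all offsets). Three selection quantities follow the
conventions of iterative homology search: an E-value, a similarity
fraction (aligned positions with positive BLOSUM62 score against the
profile consensus — the BLAST "positives" convention; the underlying
tools leave "similarity" undefined), and coverage (aligned fraction of
the profile length; sequences shorter than the profile are placed
inside it and coverage reflects the truncation). Defaults: E ≤ 1e-30,
similarity ≥ 0.30, coverage ≥ 0.30, at most 20 iterations.

E-values are calibrated empirically: the null is the score distribution
of residue-shuffled copies of the scanned sequences, and

    evalue(s) = N · (1 + #{null ≥ s}) / (1 + n_null)

with N the number of sequences scanned. This estimator is an upper
bound with resolution floor N/(1 + n_null); at desk scale (a few
thousand null scores) the floor is far above thresholds like 1e-30 that
analytic E-value machinery can report. A threshold below the floor is
therefore applied *at* the floor: a hit whose score exceeds every null
score is taken to satisfy it. Without this reading no hit could ever
pass the conventional 1e-30 cut under an empirical null.

Each iteration rebuilds the profile with new members stacked at their
best-scoring placement (profile-anchored alignment) rather than
re-running an external aligner, so the loop is self-contained.
Membership grows by union and stops at a fixed point. Curation flags
sequences not starting with methionine or lacking a stop annotation
(trailing `*`); a whitelist retains known exceptions such as
N-terminally truncated members.

## Signature scanning

Patterns use the PROSITE-style grammar `residue | [class] | x | x(n)`,
expanded to one allowed-residue set per matched position. A window
matches at substitution tolerance *k* if at most *k* non-wildcard
positions are violated; wildcards never count. Overlapping matches are
all reported. The five built-in family signatures are the Cys motif
C-[PS]-G-C, the His motif [PQ]-E-[TS]-[LI]-H-x-[HKLRD] with strict core
P-E-T-L-H-x-H, the MFS signature G-x(3)-D-[RK]-x-G-R-[RK] stored both
with and without the family-specific leading tryptophan, the antiporter
signature S-x(8)-G-x(3)-G-P-x(2)-G-G, and the TM8–TM9 loop motif
[RK]-x(2)-G-P-[IV]-x(3)-R. Classification reports strict matches for
all signatures and a one-substitution class for the His core only (the
one signature for which single substitutions are tolerated in family
practice); the tolerant set is configurable.

Alignment conservation is the per-column frequency of the modal residue
among non-gap rows (columns >50% gaps score 0), smoothed by a centered
moving average (window 5). The variable region is the longest run of
smoothed scores below a threshold (default 0.5) of at least a minimum
length, leftmost on ties. The threshold and window are package choices;
no standard value exists for delimiting such regions.

## Phylogenetics

Distances: p-distance with pairwise deletion (per pair, only columns
where both rows have residues; a pair with no comparable column is an
error), then Poisson correction d = −ln(1 − p), which assumes equal
substitution rates across sites and residues — matching the generator's
uniform-exchangeability model. Trees: Saitou–Nei neighbor joining,
minimizing Q(i,j) = (n−2)d(i,j) − r_i − r_j with exact ties broken by
the lexicographically smallest pair of cluster keys (determinism);
branch lengths by the standard NJ formulas, small negatives clamped to
zero and logged. NJ is consistent on additive matrices; the test suite
verifies exact topology and path-length recovery and cross-checks the
topology against dendropy's independent NJ.

Bootstrap: columns resampled with replacement (seeded), p → Poisson →
NJ per replicate; the support of each internal branch of the
full-alignment tree is the percentage of replicates whose tree contains
the same bipartition. Replicates in which some pair loses all
comparable columns are discarded and the denominator adjusted (the
reference tools do not document their behaviour here). The display
convention keeps supports annotated on the full tree and collapses
branches with support ≤ cutoff (strict >, default 50) in the consensus
view. The canonical replicate count is 1,000; tests use 50 replicates
on 8–13-taxon families, which is sufficient because supports of
resolvable branches saturate quickly.

## Comparative genomics

Percent identity is computed on a global Needleman–Wunsch alignment
with affine gaps (BLOSUM62, open 10, extend 0.5; first gap residue
costs the open penalty) with identical pairs divided by the full
alignment length, gap columns included — published identity tables
rarely state their denominator, so this convention is fixed and
documented rather than matched to any tool.

The dot-plot scorer slides a window (default 24) along the reference
and scores it ungapped at every comparative position, both orientations,
with +5/match −4/mismatch: a perfect window scores 120, and the default
cutoff 80 tolerates exactly four mismatches (84 ≥ 80 > 75). Window hits
adjacent on the same diagonal merge into maximal segments; reverse-
orientation coordinates are reported on the forward strand of the
comparative sequence. This is an explicit, testable stand-in for
BLASTn-backed graphical aligners.

Tandem clusters are maximal runs of ≥2 same-chromosome genes with
successive start-to-start gaps ≤ 100 kb (the scale at which such
regions are customarily inspected). Exon-structure comparison pairs
exons positionally when counts agree and calls a pair nearly identical
when no exon's length differs by more than 5% of the shorter one.

## Promoter analysis

Promoters are fixed windows, canonically −1500..+1 (1501 bp). Box
counting reports every overlapping occurrence on the plus strand plus
occurrences of the reverse complement (minus-strand hits); palindromes
count once per site. Overlap counting is a fixed convention here —
per-promoter counts in the literature do not state it.

Enrichment of a k-mer (default k = 5) in a target set is assessed
against repeated same-size samples from a background promoter pool:
p = (1 + #{sample mean ≥ observed}) / (1 + n_samples), never zero by
construction, with Benjamini–Hochberg correction across the 4^k words
(a genome-wide scan needs a stated correction even when only one word
is of interest). Sampling is without replacement within a sample,
independent across samples, seeded.

The degenerate-element scan compares an 18-bp reference (e.g. the
iron-deficiency element IDE1) against every window on both strands and
reports windows with at least `min_matches` identical positions
(default 14/18 — a package default; the original similarity criterion
for IDE1-like elements is not publicly specified).

## qPCR quantification

The initial amount behind a well is Q0 = F_threshold/E^Ct, so the
normalized ratio is Q0_target/Q0_ref = E_ref^Ct_ref / E_target^Ct_target,
evaluated in log space. E is the per-cycle amplification factor
(2.0 = perfect doubling); reports can also show percent efficiency
(E−1)·100.

Efficiency is estimated per well from the raw curve by the
window-of-linearity approach: baseline = mean of the first three
cycles, subtracted; among contiguous 4–6-cycle windows with strictly
positive corrected readings, the window maximizing the r² of the
log10-linear fit wins (ties prefer longer, then earlier windows);
E = 10^slope, capped at 2.0 with a warning. Saturated stretches are
rejected by r² itself; an optional guard restricting candidates below a
fraction of the maximum corrected signal is available for curves with a
slow smooth approach to plateau. Per-amplicon efficiencies are plate
averages of well estimates and are used for all wells of that amplicon.

Replicates are summarized as mean ± SE on the ratio scale (as displayed
in expression bar charts; a log-scale option would be preferable for
strongly skewed ratios and is a known limitation). Treatment contrasts
use a two-sided two-sample Student's t test on replicate ratios with
stars at p ≤ 0.05 and p ≤ 0.01; multi-group comparisons use one-way
ANOVA with Tukey HSD (Tukey–Kramer for unequal n) and a greedy compact
letter display assigned from the largest mean. Wells at or above Ct 35
are flagged undetected and excluded; the threshold is configurable
since detection cutoffs are instrument conventions.

## Synthetic data

The generators produce data with the statistical structure each stage
assumes, plus a machine-checkable ground truth.

**Protein family.** A species tree (random topology, join heights in
the upper half of the configured height) carries per-species paralog
subtrees (lower half); leaf counts per species are 1 + Poisson(dup_rate).
Join heights are stratified — one per equal slot, jittered within the
slot's middle band — so every internal branch has non-vanishing length;
without that guarantee the true topology is routinely unidentifiable
and no inference method could be scored against it. Defaults (9
species, dup_rate 4.5 ≈ 50 members, 470 residues, height 0.3
substitutions/site root-to-tip) emulate a mid-sized plant transporter
family sampled from several genomes. Evolution is indel-free (the
emitted sequences are simultaneously the true alignment) under a
site-wise Poisson process with uniform exchangeability over 20 states —
the model whose distances the Poisson correction inverts exactly. Each
planted signature is retained per leaf lineage with probability 0.9
(held at ancestral residues) or released to evolve freely; presence is
recorded per leaf. Decoys are residue shuffles of members, so
composition carries no signal. Not emulated: indels and alignment
uncertainty, rate heterogeneity, codon structure, gene conversion /
concerted evolution — passing recovery tests therefore shows
correctness of the machinery under its own model, not robustness to
real-data misspecification.

**Genome layout.** Two chromosomes share a duplicated segment
containing a tandem array (default five paralogs of a 400-bp gene,
600-bp spacers, 0.5% copy divergence); the second copy is
reverse-complemented when an inversion is requested. Extra genes are
isolated singletons on their own chromosomes. Truth records segment
intervals, orientation and cluster membership. Chromosome sizes are
desk-scale (kilobases, not the 100-kb regions of real comparisons);
the dot-plot is O(n·m) and exact, so scale only affects runtime.

**Promoters.** I.i.d. uniform-composition sequences with
K ~ Poisson(λ) planted non-overlapping boxes at random positions and
strands; truth stores planted K. Observed counts also include
incidental matches (≈ 2(L−k+1)/4^k per promoter for both strands, plus
box-adjacency effects, e.g. a planted GCATG followed by C creates a
CATGC); tests therefore check planted-count recovery exactly and treat
observed ≥ planted. Default λs (5.85 target vs 3.24 background) mirror
the canonical box-per-promoter contrast for the CATGC core element.

**qPCR plates.** Noiseless threshold cycles invert the ratio equation
exactly (Ct_target = (Ct_ref·ln E_ref − ln ratio)/ln E_target), so the
quantification pipeline round-trips planted ratios to machine precision
at zero noise; Gaussian Ct noise is added per well. Optional raw curves
are F_c = baseline + min(x, plateau) with x = (F_threshold/E^Ct)·E^c —
exactly exponential below saturation, flat above, with optional
multiplicative noise. The hard clip keeps the exponential phase
unbiased; a smooth saturation model would attenuate every cycle and
make exact efficiency recovery impossible even without noise.

## Problem sizes used by the validation suite

The studies in the test suite run at desk scale as the package's own
choice of study conditions: NJ consistency on 200 random additive
matrices of 5–12 taxa; bootstrap on 20 simulated families (8–13 taxa,
1,500 columns, 50 replicates); family recovery on ≈ 50 members + 500
decoys; enrichment calibration on 500 null and 200 powered pipeline
replicates (13 targets, 500-bp windows, 200-promoter background pools
regenerated per replicate, 199 background samples); alignment oracle on
500 string pairs up to length 8; dot-plot recovery on 20 layouts; qPCR
ratio and efficiency recovery on 100 simulations each. The enrichment
studies use 500-bp windows because at the full 1,501-bp window
incidental background matches dilute a 2× planted-rate contrast below
any reasonable detection power; the statistic under test is unchanged.

## Known limitations

- The profile is a PSSM with ungapped placement, not a profile HMM:
  no insert/delete states, so members with large indels relative to the
  seed alignment would score poorly. Adequate for indel-free synthetic
  families; real families need the iteration's profile-anchored
  stacking replaced by a genuine MSA step.
- Empirical E-values cannot discriminate below their resolution floor;
  the floor rule makes the conventional strict thresholds usable but
  any threshold below the floor behaves identically.
- The enrichment p-value is slightly conservative when the observed
  mean ties a sample mean (the ≥ rule with discrete counts).
- SE on the ratio scale understates asymmetric uncertainty for
  strongly induced genes.
- The compact letter display is greedy and may not be the minimal
  letter assignment for pathological overlap structures.
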