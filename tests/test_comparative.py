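import functools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from famscape.comparative import (AlignParams, DotPlotConfig, compare_exon_structure,
                                  dotplot_match, find_tandem_clusters,
                                  global_identity, identity_matrix, lower_triangle)
from famscape.io import GeneRow
from famscape.sequtils import reverse_complement

from conftest import dna, prot

_BLOSUM = substitution_matrices.load("BLOSUM62")


def oracle_align_score(a: str, b: str, gap_open=10.0, gap_extend=0.5) -> float:
    """Exhaustive best global alignment score by recursion over all
    alignment paths (first gap residue costs gap_open, later ones
    gap_extend) -- independent of the production aligner."""

    @functools.lru_cache(maxsize=None)
    def rec(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            best = max(best, _BLOSUM[a[i]][b[j]] + rec(i + 1, j + 1, 0))
        if i < len(a):
            best = max(best, -(gap_extend if state == 1 else gap_open) + rec(i + 1, j, 1))
        if j < len(b):
            best = max(best, -(gap_extend if state == 2 else gap_open) + rec(i, j + 1, 2))
        return best

    return rec(0, 0, 0)


class TestGlobalIdentity:
    def test_identical_sequences_full_identity(self):
        res = global_identity(prot("a", "MKTWAED"), prot("b", "MKTWAED"))
        assert res.percent_identity == 100.0

    def test_single_gap_alignment(self):
        res = global_identity(prot("a", "ACDE"), prot("b", "ADE"))
        assert (res.aligned_a, res.aligned_b) == ("ACDE", "A-DE")
        assert res.percent_identity == pytest.approx(75.0)

    def test_score_matches_exhaustive_oracle_short_strings(self, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(60):
            a = "".join(letters[rng.integers(0, 20, rng.integers(1, 8))])
            b = "".join(letters[rng.integers(0, 20, rng.integers(1, 8))])
            res = global_identity(prot("a", a), prot("b", b))
            assert res.score == pytest.approx(oracle_align_score(a, b))

    def test_empty_or_mixed_alphabet_rejected(self):
        with pytest.raises(ValueError):
            global_identity(prot("a", "MK"), dna("b", "ACGT"))


class TestIdentityMatrix:
    def test_identical_sequences_all_100(self):
        mat = identity_matrix([prot("a", "MKTW"), prot("b", "MKTW"), prot("c", "MKTW")])
        assert (mat.to_numpy() == 100).all()

    def test_symmetric_with_100_diagonal(self, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seqs = [prot(f"s{i}", "".join(letters[rng.integers(0, 20, 30)]))
                for i in range(4)]
        mat = identity_matrix(seqs)
        assert (mat.to_numpy() == mat.to_numpy().T).all()
        assert (np.diag(mat.to_numpy()) == 100).all()
        tri = lower_triangle(mat)
        assert tri.shape == (3, 3)
        assert tri.iloc[0, 1] == ""  # upper triangle blanked

    def test_identity_declines_with_divergence(self, rng):
        """Paralog pairs mutated further from a common ancestor should show
        lower percent identity (rank correlation with divergence < 0)."""
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        base = letters[rng.integers(0, 20, 80)]
        divergences = [2, 8, 20, 40]
        idents = []
        for d in divergences:
            mutated = base.copy()
            pos = rng.choice(80, size=d, replace=False)
            mutated[pos] = letters[rng.integers(0, 20, d)]
            idents.append(global_identity(
                prot("a", "".join(base)), prot("b", "".join(mutated))).percent_identity)
        assert all(x >= y for x, y in zip(idents, idents[1:]))


class TestDotPlot:
    def test_self_comparison_spans_full_diagonal(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        rec = dna("r", seq)
        segs = dotplot_match(rec, rec)
        fwd = [s for s in segs if s.orientation == "forward"]
        main = max(fwd, key=lambda s: s.ref_end - s.ref_start)
        assert (main.ref_start, main.ref_end) == (1, 200)
        assert (main.comp_start, main.comp_end) == (1, 200)
        assert main.score == pytest.approx(120.0)

    def test_reverse_complement_detected_full_length(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 150)])
        segs = dotplot_match(dna("r", seq), dna("c", reverse_complement(seq)))
        rev = [s for s in segs if s.orientation == "reverse"]
        main = max(rev, key=lambda s: s.ref_end - s.ref_start)
        assert (main.ref_start, main.ref_end) == (1, 150)
        assert (main.comp_start, main.comp_end) == (1, 150)

    def test_window_mismatch_tolerance_boundary(self):
        """With window 24 and +5/-4 scoring, 4 mismatches score 84 (a hit at
        cutoff 80) while 5 score 75 (no hit)."""
        base = "ACGTACGTACGTACGTACGTACGT"
        def flip(s, k):
            out = list(s)
            for i in range(k):
                out[i * 4] = {"A": "C", "C": "A", "G": "T", "T": "G"}[out[i * 4]]
            return "".join(out)
        four = flip(base, 4)
        five = flip(base, 5)
        cfg = DotPlotConfig()
        assert any(s.score == pytest.approx(84.0)
                   for s in dotplot_match(dna("r", base), dna("c", four), cfg))
        assert not dotplot_match(dna("r", base), dna("c", five), cfg)

    def test_window_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            dotplot_match(dna("r", "ACGT"), dna("c", "ACGT"))


class TestTandemClusters:
    def test_gap_rule_direct_application(self):
        genes = [GeneRow("g1", "chr1", 1_000, 2_000, "+"),
                 GeneRow("g2", "chr1", 5_000, 6_000, "+"),
                 GeneRow("g3", "chr1", 500_000, 501_000, "+")]
        rep = find_tandem_clusters(genes, max_gap=100_000)
        assert len(rep.clusters) == 1
        chrom, ids, span = rep.clusters[0]
        assert ids == ["g1", "g2"]

    def test_singletons_form_no_clusters(self):
        genes = [GeneRow("g1", "chr1", 1, 10, "+"), GeneRow("g2", "chr2", 1, 10, "+")]
        assert find_tandem_clusters(genes).clusters == []


class TestExonStructure:
    def _gene(self, exons):
        end = max(e for _, e in exons)
        return GeneRow("g", "c", 1, end, "+", tuple(exons))

    def test_identical_structures(self):
        a = self._gene([(1, 100), (201, 400)])
        cmp = compare_exon_structure(a, a)
        assert cmp.nearly_identical and cmp.length_diffs == (0, 0)

    def test_five_percent_boundary(self):
        a = self._gene([(1, 100), (201, 400)])          # lengths 100, 200
        b = self._gene([(1, 100), (201, 410)])          # lengths 100, 210
        cmp = compare_exon_structure(a, b)
        assert cmp.length_diffs == (0, 10)
        assert cmp.max_relative_diff == pytest.approx(0.05)
        assert cmp.nearly_identical

    def test_unequal_counts_never_nearly_identical(self):
        a = self._gene([(1, 100)])
        b = self._gene([(1, 100), (201, 250)])
        cmp = compare_exon_structure(a, b)
        assert cmp.n_exons_a == 1 and cmp.n_exons_b == 2
        assert not cmp.nearly_identical and cmp.length_diffs is None

    def test_missing_exons_rejected(self):
        with pytest.raises(ValueError):
            compare_exon_structure(GeneRow("a", "c", 1, 10, "+"),
                                   self._gene([(1, 5)]))
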