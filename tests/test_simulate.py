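import numpy as np
import pytest
from scipy import stats

from famscape.promoters import count_box
from famscape.qpcr import quantify
from famscape.sequtils import reverse_complement
from famscape.signatures import scan_pattern
from famscape.simulate import (FamilySimConfig, simulate_family,
                               simulate_genome_layout, simulate_promoters,
                               simulate_qpcr)


class TestFamily:
    def test_degenerate_single_lineage(self):
        cfg = FamilySimConfig(n_species=1, dup_rate=0.0, n_decoys=5, seed=0)
        proteome, truth = simulate_family(cfg)
        assert len(truth.membership) == 1
        assert len(proteome) == 6

    def test_deterministic_under_seed(self):
        a, _ = simulate_family(FamilySimConfig(seed=11, n_decoys=10))
        b, _ = simulate_family(FamilySimConfig(seed=11, n_decoys=10))
        assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]

    def test_divergence_tracks_tree_path_length(self):
        """Pairwise p-distance should increase with patristic distance on
        the true tree (the substitution process accumulates along branches)."""
        proteome, truth = simulate_family(FamilySimConfig(seed=2, n_decoys=1))
        members = {r.id: r for r in proteome if r.id in truth.membership}
        labels, plm = truth.true_tree.path_length_matrix()
        pd_, tree_d = [], []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = members[labels[i]].sequence, members[labels[j]].sequence
                pd_.append(np.mean([x != y for x, y in zip(a, b)]))
                tree_d.append(plm[i, j])
        rho = stats.spearmanr(pd_, tree_d).statistic
        assert rho > 0

    def test_signature_truth_matches_emitted_sequences(self):
        """A signature recorded as retained must scan strictly in the
        emitted sequence at the planted anchor."""
        cfg = FamilySimConfig(seed=3, n_decoys=1)
        proteome, truth = simulate_family(cfg)
        members = {r.id: r for r in proteome if r.id in truth.membership}
        anchors = {s.pattern.name: (s.pattern, s.anchor) for s in cfg.signature_plant}
        for pid, row in truth.signature_presence.iterrows():
            for name, retained in row.items():
                pattern, anchor = anchors[name]
                hits = {h.position for h in scan_pattern(pattern, members[pid].sequence)}
                if retained:
                    assert anchor + 1 in hits

    def test_retention_rate_recovers_configured_probability(self):
        presences = []
        for seed in range(10):
            _, truth = simulate_family(FamilySimConfig(seed=seed, n_decoys=1))
            presences.append(truth.signature_presence.to_numpy().mean())
        observed = np.mean(presences)
        # 3 SE of Bernoulli(0.9) over ~2500 draws
        assert abs(observed - 0.9) < 3 * np.sqrt(0.9 * 0.1 / 2000)


class TestGenomeLayout:
    def test_forward_copy_is_shared_substring(self):
        chroms, genes, truth = simulate_genome_layout(
            inversion=False, seed=1, copy_mutation_rate=0.0)
        a, b = chroms["chrA"].sequence, chroms["chrB"].sequence
        sa, ea = truth.ref_segment
        sb, eb = truth.comp_segment
        assert a[sa - 1:ea] == b[sb - 1:eb]
        assert truth.orientation == "forward"

    def test_inverted_copy_is_reverse_complement(self):
        chroms, _, truth = simulate_genome_layout(
            inversion=True, seed=2, copy_mutation_rate=0.0)
        a, b = chroms["chrA"].sequence, chroms["chrB"].sequence
        sa, ea = truth.ref_segment
        sb, eb = truth.comp_segment
        assert b[sb - 1:eb] == reverse_complement(a[sa - 1:ea])
        assert truth.orientation == "reverse"

    def test_tandem_array_gaps_stay_below_cluster_threshold(self):
        _, genes, truth = simulate_genome_layout(tandem_size=5, seed=3)
        for chrom in ("chrA", "chrB"):
            rows = sorted((g for g in genes if g.chromosome == chrom),
                          key=lambda g: g.start)
            assert [g.gene_id for g in rows] and len(rows) == 5
            gaps = np.diff([g.start for g in rows])
            assert (gaps <= 100_000).all()

    def test_tandem_size_validation(self):
        with pytest.raises(ValueError):
            simulate_genome_layout(n_genes=3, tandem_size=5)


class TestPromoters:
    def test_zero_lambda_on_disjoint_alphabet_gives_zero_counts(self):
        targets, _, _ = simulate_promoters(
            5, 0, length=100, lambda_target=0.0, lambda_background=0.0,
            box="CCCCC", seed=0, letters="AT")
        assert all(len(count_box(p, "CCCCC")) == 0 for p in targets)

    def test_planted_counts_recover_poisson_mean(self):
        lam = 3.0
        _, bg, truth = simulate_promoters(0, 1000, lambda_background=lam, seed=4)
        planted = np.array([truth.promoter_planted[p.gene_id] for p in bg])
        se = np.sqrt(lam / len(bg))
        assert abs(planted.mean() - lam) < 3 * se
        # observed counts include incidental matches, never fewer than planted
        observed = np.array([len(count_box(p, "CATGC")) for p in bg])
        assert (observed >= planted).all()

    def test_deterministic_under_seed(self):
        a = simulate_promoters(3, 3, seed=9)[0]
        b = simulate_promoters(3, 3, seed=9)[0]
        assert [p.sequence for p in a] == [p.sequence for p in b]

    def test_too_short_promoter_raises(self):
        with pytest.raises(ValueError):
            simulate_promoters(1, 0, length=12, lambda_target=10.0, seed=0)


class TestQpcr:
    def test_zero_noise_ct_gap_inverts_ratio_exactly(self):
        wells, _, _ = simulate_qpcr([("G", "s", 0.25)], {"UBQ5": 2.0, "G": 2.0},
                                    ct_ref_base=20.0, noise_sd=0.0, seed=0)
        cts = {w.gene: w.ct for w in wells}
        assert cts["G"] - cts["UBQ5"] == pytest.approx(2.0, abs=1e-12)

    def test_zero_noise_round_trip_is_exact(self):
        design = [("G1", "s", 0.37), ("G2", "s", 14.0)]
        wells, _, truth = simulate_qpcr(design, {"UBQ5": 1.9, "G1": 1.85, "G2": 2.0},
                                        noise_sd=0.0, seed=1)
        for rel in quantify(wells):
            assert rel.mean == pytest.approx(truth.qpcr_ratios[(rel.gene, rel.sample)],
                                             rel=1e-12)

    def test_rejects_invalid_design(self):
        with pytest.raises(ValueError):
            simulate_qpcr([("G", "s", -1.0)], {"UBQ5": 2.0, "G": 2.0})
        with pytest.raises(ValueError):
            simulate_qpcr([("G", "s", 1.0)], {"UBQ5": 2.5, "G": 2.0})
        with pytest.raises(ValueError):
            simulate_qpcr([("G", "s", 1.0)], {"UBQ5": 2.0, "G": 2.0}, n_reps=1)
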