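"""End-to-end pipeline wiring: simulate -> search -> signatures -> phylo
-> comparative -> promoters -> qpcr, collected into report tables.

This is deliberately thin: each stage is a direct call into the
corresponding module with parameters taken from the RunConfig, and the
returned dict plugs straight into :func:`famscape.io.emit_report`.
"""

from __future__ import annotations

import pandas as pd

from . import comparative, phylo, promoters, qpcr, search, signatures, simulate
from .io import RunConfig


def run_pipeline(config: RunConfig) -> dict:
    seed = config.seed
    results: dict = {}

    # family + search
    fam_cfg = simulate.FamilySimConfig(seed=seed, **config.family)
    proteome, truth = simulate.simulate_family(fam_cfg)
    members = [r for r in proteome if r.id in truth.membership]
    thresholds = search.SearchThresholds(**config.search)
    seeds = members[: max(3, len(members) // 5)]
    res = search.iterate_search(seeds, proteome, thresholds, seed=seed)
    hit_rows = []
    for it, mset in enumerate(res.members_per_iteration):
        for mid in sorted(mset):
            hit = res.hits.get(mid)
            if hit is not None and not any(mid in prev for prev in res.members_per_iteration[:it]):
                hit_rows.append((mid, it + 1, hit.raw_score, hit.evalue,
                                 hit.similarity, hit.coverage,
                                 mid in truth.membership))
    results["membership"] = pd.DataFrame(
        hit_rows, columns=["id", "iteration_added", "score", "evalue",
                           "similarity", "coverage", "is_true_member"])

    # signatures
    sig_cfg = dict(config.signatures)
    results["signatures"] = signatures.classify_signatures(members)
    profile = signatures.conservation_profile(
        members, window=sig_cfg.get("window", 5))
    region = signatures.find_variable_region(
        profile, threshold=sig_cfg.get("threshold", 0.5),
        min_length=sig_cfg.get("min_length", 10))
    results["variable_region"] = {"interval": region}

    # phylogeny (bootstrap scaled by config)
    ph = dict(config.phylo)
    cfg_bs = phylo.BootstrapConfig(
        n_replicates=ph.get("n_replicates", 100),
        consensus_cutoff=ph.get("consensus_cutoff", 50),
        seed=seed,
    )
    bs = phylo.bootstrap_support(members, cfg_bs)
    results["tree"] = bs.tree

    # comparative: identities on a small subset + simulated layout
    subset = members[: min(8, len(members))]
    results["identity"] = comparative.identity_matrix(subset).reset_index(names="id")
    comp_cfg = dict(config.comparative)
    chroms, genes, layout_truth = simulate.simulate_genome_layout(
        inversion=comp_cfg.get("inversion", True), seed=seed)
    segs = comparative.dotplot_match(chroms["chrA"], chroms["chrB"])
    results["dotplot"] = comparative.segment_table(segs)
    clusters = comparative.find_tandem_clusters(
        genes, max_gap=comp_cfg.get("max_gap", 100_000))
    results["clusters"] = pd.DataFrame(
        [(c, ";".join(ids), s, e) for c, ids, (s, e) in clusters.clusters],
        columns=["chromosome", "genes", "start", "end"])

    # promoters
    pr = dict(config.promoters)
    targets, background, ptruth = simulate.simulate_promoters(
        n_target=pr.get("n_target", 13),
        n_background=pr.get("n_background", 500),
        lambda_target=pr.get("lambda_target", 5.85),
        lambda_background=pr.get("lambda_background", 3.24),
        box=pr.get("box", "CATGC"),
        seed=seed,
    )
    enr = promoters.kmer_enrichment(
        targets, background,
        promoters.EnrichmentConfig(n_samples=pr.get("n_samples", 199), seed=seed),
        words=[pr.get("box", "CATGC")],
    )
    results["enrichment"] = enr.table
    hits = [h for p in targets for h in promoters.count_box(p, pr.get("box", "CATGC"))]
    results["boxes"] = promoters.box_hit_table(hits)

    # qPCR
    qp = dict(config.qpcr)
    design = [("GOI1", "control", 1.0), ("GOI1", "treated", qp.get("fold", 3.5)),
              ("GOI2", "control", 1.0), ("GOI2", "treated", qp.get("fold2", 14.0))]
    eff = {"UBQ5": 1.9, "GOI1": 1.85, "GOI2": 1.95}
    wells, _, qtruth = simulate.simulate_qpcr(
        design, eff, noise_sd=qp.get("noise_sd", 0.2),
        n_reps=qp.get("n_reps", 3), seed=seed)
    rel = qpcr.quantify(wells)
    rows = []
    by_gene: dict[str, dict[str, qpcr.RelExpression]] = {}
    for r in rel:
        by_gene.setdefault(r.gene, {})[r.sample] = r
    for gene, by_sample in sorted(by_gene.items()):
        test = None
        if "control" in by_sample and "treated" in by_sample:
            test = qpcr.compare_treatment(by_sample["control"], by_sample["treated"])
        for sample, r in sorted(by_sample.items()):
            rows.append((gene, sample, r.mean, r.se,
                         test.fold_change if test else None,
                         test.p_value if test else None,
                         test.stars if test else ""))
    results["expression"] = pd.DataFrame(
        rows, columns=["gene", "sample", "mean", "se", "fold_change", "p", "stars"])

    return results
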