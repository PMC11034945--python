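"""End-to-end orchestration of the synthetic-study pipeline.

Chains simulate -> qc -> peaks -> differential -> network -> pagerank ->
compare -> episig on a generated cohort, entirely in memory, and writes
deterministic TSV outputs plus a run manifest. Every stage draws its
randomness from the config seed, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from epipair import cohort_compare as cc
from epipair import differential as diff
from epipair import episig_cluster as ec
from epipair import peaks_counts as pc
from epipair import qc_metrics as qc
from epipair import regnet_pagerank as rp
from epipair import synthetic_data as syn
from epipair.io_cli.config import PipelineConfig
from epipair.io_cli.manifest import write_results

log = logging.getLogger("epipair")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            out = fn(*args, **kwargs)
            log.info("stage %s done in %.1fs", name, time.time() - t0)
            return out

        return wrapped

    return deco


def subject_counts(matrix: pc.CountMatrix, samples) -> pc.CountMatrix:
    """Sum technical replicates into per-subject columns (ChIP assays)."""
    by_subject: dict[str, list[str]] = {}
    meta = {s.sample_id: s for s in samples}
    for sid in matrix.sample_ids:
        by_subject.setdefault(meta[sid].subject_id, []).append(sid)
    subjects = sorted(by_subject)
    cols = []
    libs = {}
    sidx = {s: j for j, s in enumerate(matrix.sample_ids)}
    for subj in subjects:
        members = by_subject[subj]
        cols.append(matrix.counts[:, [sidx[m] for m in members]].sum(axis=1))
        libs[subj] = int(sum(matrix.library_sizes[m] for m in members))
    return pc.CountMatrix(list(matrix.feature_ids), subjects, np.column_stack(cols), libs)


def expression_zscores(matrix: pc.CountMatrix) -> pd.DataFrame:
    """Per-gene z-scores of log-CPM across the samples of one cell fraction."""
    logcpm = matrix.cpm(log=True)
    mu = logcpm.mean(axis=1, keepdims=True)
    sd = logcpm.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (logcpm - mu) / sd
    return pd.DataFrame(z, index=matrix.feature_ids, columns=matrix.sample_ids)


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    n_pairs_af: int = 15,
    n_pairs_at: int = 14,
    n_genes: int = 120,
    n_tfs: int = 12,
    sim_params: syn.SimParams | None = None,
    overwrite: bool = True,
) -> dict:
    """Run the full synthetic pipeline and write results; returns the tables."""
    seed = config.seed
    params = sim_params or syn.SimParams()
    tables: dict[str, pd.DataFrame] = {}

    # --- simulate -------------------------------------------------------------
    model = syn.make_genome_model(n_chrom=2, n_genes=n_genes, n_tfs=n_tfs, seed=seed)
    samples, matrices, truth = syn.simulate_cohort(
        model, n_pairs_af, n_pairs_at, params, seed=seed + 1
    )
    meta = {s.sample_id: s for s in samples}
    tables["truth"] = syn.truth_frame(truth)
    log.info("simulated %d samples, %d truth features", len(samples), len(truth))

    # --- qc on simulated tag sets --------------------------------------------
    k27_feats = model.chip_features("H3K27ac")
    enriched_regions = [pk.interval for _, pk in k27_feats]
    qc_rows = []
    tagsets = {}
    for i, label in enumerate(["rep1", "rep2"]):
        tp = syn.TagParams(n_fragments=20_000, fragment_length=200, read_length=36,
                           in_peak_frac=0.5, dup_rate=0.05)
        tags = syn.simulate_tags(model, enriched_regions, tp, seed=seed + 10 + i)
        tagsets[label] = tags
        xcor = qc.cross_correlation(tags, max_shift=300, chrom_lengths=model.chrom_lengths)
        qc_rows.append(
            {
                "sample_id": label,
                "n_tags": tags.n_tags,
                "frip": qc.frip(tags, enriched_regions),
                "pbc": qc.pbc(tags),
                "nsc": xcor["nsc"],
                "rsc": xcor["rsc"],
                "fragment_length_est": xcor["fragment_length_est"],
            }
        )
    tables["qc"] = pd.DataFrame(qc_rows)

    # --- peak calling on the two replicates ----------------------------------
    def caller(ts):
        cov = qc.bin_tag_counts(ts, model.chrom_lengths, bin_width=50)
        return pc.call_peaks_poisson(cov, q_cutoff=0.05, bin_width=50)

    rep_peaks = {label: caller(ts) for label, ts in tagsets.items()}
    highconf = pc.high_confidence_peaks(rep_peaks["rep1"], rep_peaks["rep2"])
    master = pc.consensus_master([highconf])
    tables["called_peaks"] = pd.DataFrame(
        {
            "chrom": [p.interval.chrom for p in master.peaks],
            "start": [p.interval.start for p in master.peaks],
            "end": [p.interval.end for p in master.peaks],
            "summit": [p.summit for p in master.peaks],
            "score": [p.score for p in master.peaks],
            "support": master.support,
        }
    )

    # --- differential analysis ------------------------------------------------
    def run_diff(assay: str, fraction: str, cohort: str | None, adjust: str):
        mat = matrices[(assay, fraction)]
        members = [
            s for s in samples
            if s.assay == assay and s.fraction == fraction
            and (cohort is None or s.cohort == cohort)
        ]
        ids = sorted({s.sample_id for s in members})
        sub = pc.CountMatrix(
            list(mat.feature_ids),
            ids,
            mat.counts[:, [mat.sample_ids.index(i) for i in ids]],
            {i: mat.library_sizes[i] for i in ids},
        )
        if assay != "RNA":
            sub = subject_counts(sub, samples)
            labels = [
                "case" if col.endswith("S") else "control" for col in sub.sample_ids
            ]
        else:
            labels = [meta[i].group for i in sub.sample_ids]
        sub = pc.filter_low(sub, config.min_count, config.min_sample_frac)
        sub = pc.normalize_tmm(sub)
        return diff.nb_differential(
            sub, labels, adjust_method=adjust, alpha=config.fdr_alpha
        )

    rna_af = {f: run_diff("RNA", f, "AF", "bh") for f in ("NeuNpos", "NeuNneg")}
    rna_at = {f: run_diff("RNA", f, "AT", "bh") for f in ("NeuNpos", "NeuNneg")}
    rna_all = {f: run_diff("RNA", f, None, "bh") for f in ("NeuNpos", "NeuNneg")}
    k27_all = run_diff("H3K27ac", "NeuNpos", None, "bonferroni")
    k4_all = run_diff("H3K4me3", "NeuNpos", None, "bonferroni")
    for name, res in [
        ("diff_rna_af_neupos", rna_af["NeuNpos"]),
        ("diff_rna_at_neupos", rna_at["NeuNpos"]),
        ("diff_rna_all_neupos", rna_all["NeuNpos"]),
        ("diff_rna_af_neuneg", rna_af["NeuNneg"]),
        ("diff_rna_at_neuneg", rna_at["NeuNneg"]),
        ("diff_rna_all_neuneg", rna_all["NeuNneg"]),
        ("diff_h3k27ac_neupos", k27_all),
        ("diff_h3k4me3_neupos", k4_all),
    ]:
        tables[name] = diff.results_frame(res)
    tables["qq_lambda"] = pd.DataFrame(
        {
            "dataset": ["H3K27ac_NeuNpos", "H3K4me3_NeuNpos"],
            "lambda": [
                diff.qq_lambda([r.p for r in k27_all]),
                diff.qq_lambda([r.p for r in k4_all]),
            ],
        }
    )

    # --- annotation and network -----------------------------------------------
    feature_peaks = {fid: pk for fid, pk in k27_feats}
    annotations = []
    for fid, pk in k27_feats:
        if fid.startswith("prom:"):
            annotations.append(diff.FeatureAnnotation(fid, "promoter", fid[5:], "overlap"))
        else:
            gene, source = diff.link_enhancer(
                pk, model.loop_table, model.genes, config.promoter_up, config.promoter_down
            )
            annotations.append(diff.FeatureAnnotation(fid, "enhancer", gene, source))
    tables["annotations"] = pd.DataFrame(
        [(a.feature_id, a.cls, a.linked_gene, a.link_source) for a in annotations],
        columns=["feature_id", "class", "linked_gene", "link_source"],
    )

    motif_hits: dict[str, set[str]] = {}
    for fid, pk in k27_feats:
        win = rp.summit_window(pk, config.motif_window, model.chrom_lengths[pk.interval.chrom])
        if win is None:
            continue
        seq = model.sequences[win.chrom][win.start : win.end]
        hits = set()
        for tf, pwm in model.pwms.items():
            if rp.scan_motif(pwm, seq, p_threshold=1e-4):
                hits.add(tf)
        if hits:
            motif_hits[fid] = hits

    k27_pos = matrices[("H3K27ac", "NeuNpos")]
    pooled = pc.normalize_tmm(k27_pos)
    intensity = dict(zip(pooled.feature_ids, pooled.cpm(log=False).mean(axis=1)))
    active = rp.active_promoters(
        [pk for _, pk in k27_feats], model.genes, config.promoter_up, config.promoter_down
    )

    rna_pos = matrices[("RNA", "NeuNpos")]
    rna_pos = pc.normalize_tmm(rna_pos)
    zmat = expression_zscores(rna_pos)
    networks = {}
    ppr = {}
    for sid in zmat.columns:
        zs = zmat[sid].to_dict()
        net = rp.build_network(
            active, annotations, motif_hits, zs, intensity, tf_ids=set(model.tf_ids)
        )
        networks[sid] = net
        ppr[sid] = rp.personalized_pagerank(
            net, damping=config.damping, tol=config.ppr_tol, sample_id=sid
        )
    all_nodes = sorted({n for r in ppr.values() for n in r.scores})
    tables["ppr"] = pd.DataFrame(
        {sid: [ppr[sid].scores.get(n, 0.0) for n in all_nodes] for sid in sorted(ppr)},
        index=pd.Index(all_nodes, name="node"),
    ).reset_index()

    # --- cohort comparison ----------------------------------------------------
    rna_samples_pos = [s for s in samples if s.assay == "RNA" and s.fraction == "NeuNpos"]
    pairs_af = cc.pair_samples([s for s in rna_samples_pos if s.cohort == "AF"])
    pairs_at = cc.pair_samples([s for s in rna_samples_pos if s.cohort == "AT"])
    tf_scores = pd.DataFrame(
        {sid: [ppr[sid].scores.get(tf, 0.0) for tf in model.tf_ids] for sid in sorted(ppr)},
        index=model.tf_ids,
    )
    # scale PPR deltas to z-units per TF so the reversal threshold applies
    tf_z = tf_scores.sub(tf_scores.mean(axis=1), axis=0)
    sd = tf_scores.std(axis=1).replace(0, 1.0)
    tf_z = tf_z.div(sd, axis=0)
    af_deltas = pd.DataFrame(
        {p: tf_z[case] - tf_z[ctrl] for p, case, ctrl, _ in pairs_af}
    )
    at_deltas = pd.DataFrame(
        {p: tf_z[case] - tf_z[ctrl] for p, case, ctrl, _ in pairs_at}
    )
    calls = cc.classify_reversal(
        af_deltas, at_deltas, threshold=config.ppr_delta_threshold, alpha=config.fdr_alpha
    )
    tables["reversal"] = cc.reversal_frame(calls)

    tf_diff = [r for r in rna_all["NeuNpos"] if r.feature_id in set(model.tf_ids)]
    pair_tuples = [(p, c, t) for p, c, t, _ in pairs_af + pairs_at]
    ranked, _z = rp.ppr_rank_tfs(ppr, tf_diff, pair_tuples, alpha=config.fdr_alpha)
    tables["ppr_ranked_tfs"] = ranked
    top_tfs = list(ranked["tf"].head(4)) if len(ranked) else list(model.tf_ids[:4])
    regulatees = cc.extract_regulatees(
        networks, top_tfs, rna_all["NeuNpos"], pair_tuples,
        min_tf_count=min(3, len(top_tfs)), alpha=config.fdr_alpha,
    )
    tables["regulatees"] = pd.DataFrame({"gene_id": sorted(regulatees)})

    # the low-count filter runs per cohort, so restrict to the common universe
    common = {r.feature_id for r in rna_af["NeuNpos"]} & {
        r.feature_id for r in rna_at["NeuNpos"]
    }
    af_only, at_only, shared = cc.cohort_specific_sets(
        [r for r in rna_af["NeuNpos"] if r.feature_id in common],
        [r for r in rna_at["NeuNpos"] if r.feature_id in common],
    )
    tables["cohort_sets"] = pd.DataFrame(
        [(g, "af_only") for g in sorted(af_only)]
        + [(g, "at_only") for g in sorted(at_only)]
        + [(g, "shared") for g in sorted(shared)],
        columns=["feature_id", "set"],
    )

    age_tabs = []
    for fraction, thr in [
        ("NeuNpos", config.age_r_threshold_neuron),
        ("NeuNneg", config.age_r_threshold_glia),
    ]:
        mat = pc.normalize_tmm(matrices[("RNA", fraction)])
        logcpm = pd.DataFrame(mat.cpm(log=True), index=mat.feature_ids, columns=mat.sample_ids)
        frac_samples = [s for s in samples if s.assay == "RNA" and s.fraction == fraction]
        for cohort in ("AF", "AT"):
            members = [s for s in frac_samples if s.cohort == cohort]
            pairs = cc.pair_samples(members)
            deltas = pd.DataFrame(
                {p: logcpm[case] - logcpm[ctrl] for p, case, ctrl, _ in pairs}
            )
            ages = [a for _, _, _, a in pairs]
            corr = cc.age_correlation(deltas, ages, mode="pairwise_delta")
            hits, summary = cc.age_correlated_features(corr, thr)
            corr["fraction"] = fraction
            corr["cohort"] = cohort
            corr["above_threshold"] = np.abs(corr["r"]) >= thr
            age_tabs.append(corr)
    tables["age_correlation"] = pd.concat(age_tabs, ignore_index=True)

    # --- genome-binned clustering ---------------------------------------------
    episig_tags = {}
    for i, (label, regions) in enumerate(
        [
            ("H3K27ac_pool", enriched_regions),
            ("H3K4me3_pool", [model.promoter_peak(g).interval for g in model.genes["gene_id"]]),
            ("RNA_pool", [model.promoter_peak(g).interval for g in model.genes["gene_id"]]),
        ]
    ):
        tp = syn.TagParams(n_fragments=30_000, fragment_length=200, read_length=36,
                           in_peak_frac=0.7, dup_rate=0.0)
        episig_tags[label] = syn.simulate_tags(model, regions, tp, seed=seed + 50 + i)
    binmat = ec.bin_signals(episig_tags, model.chrom_lengths, config.bin_size)
    enriched_idx = ec.select_enriched(binmat)
    enriched = binmat.subset(enriched_idx)
    n_clusters = min(10, max(2, len(enriched.bins) // 3))
    clusters = ec.cluster_bins(enriched, n_clusters=n_clusters, seed=seed)
    clusters = ec.group_sections(clusters, n_sections=min(6, len(clusters)), seed=seed)
    tables["episig_annotation"] = ec.annotate_clusters(clusters, enriched, model.genes)
    # differential H3K27ac features -> enriched-bin indices
    sig_feats = {r.feature_id for r in k27_all if r.significant}
    diff_bins = set()
    enriched_bins = enriched.bins
    for fid in sig_feats:
        pk = feature_peaks[fid]
        for i, iv in enumerate(enriched_bins):
            if iv.overlaps(pk.interval):
                diff_bins.add(i)
    tables["episig_enrichment"] = ec.cluster_enrichment(
        clusters, diff_bins, len(enriched_bins)
    )

    manifest = write_results(tables, out_dir, config=config, overwrite=overwrite)
    log.info("wrote %d tables to %s", len(tables), out_dir)
    return {"tables": tables, "manifest": manifest, "model": model, "truth": truth}
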