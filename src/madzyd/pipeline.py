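"""End-to-end orchestration of the analysis stages.

Stage order: simulate (or load) -> signal filters/normalization ->
differential model per replicate -> peak and gene classification ->
enhancer clusters / motif activity / methylation / state dynamics ->
summary. The summary is a nested, JSON-serializable dict; identical seed
and config produce a byte-identical summary file.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import enhancers, manorm, methylation, motifs, signal, states
from .classify import (classify_gene_h3k4me3, classify_gene_h3k27me3,
                       classify_peaks, count_peaks_in_domains, great_regions)
from .config import PipelineConfig
from .io import write_json, write_matrix, write_peaks, write_segmentation
from .simulate import (simulate_amanitin_experiment, simulate_input_track,
                       simulate_methylome, simulate_motif_dataset,
                       simulate_p300_stages, simulate_state_segmentations)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage cannot run; names the missing upstream stage."""


def _round(x, nd=10):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        if np.isnan(x):
            return None
        return round(float(x), nd)
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def _rel_rpkm_table(dataset, config: PipelineConfig) -> pd.DataFrame:
    """Relative RPKM per sample for every peak, from the background model."""
    peaks = dataset.peaks
    lengths = (peaks["end"] - peaks["start"]).to_numpy()
    bg = signal.BackgroundModel.from_counts(
        dataset.background[["scaffold", "start", "end"]],
        dataset.background[dataset.samples],
        dataset.library_sizes,
        percentile=config.background_percentile,
    )
    rel = pd.DataFrame(index=peaks.index)
    for sample in dataset.samples:
        rpkm = signal.compute_rpkm(
            peaks[sample].to_numpy(), lengths, dataset.library_sizes[sample]
        )
        rel[sample] = signal.relative_rpkm(rpkm, bg.p95[sample])
    return rel


def run_amanitin_analysis(dataset, config: PipelineConfig) -> dict:
    """Filters, per-replicate differential model and MaD/ZyD classification."""
    peaks = dataset.peaks.copy()
    if config.scaffold_whitelist is not None:
        peaks = peaks[peaks["scaffold"].isin(config.scaffold_whitelist)].copy()
    rel = _rel_rpkm_table(dataset, config).loc[peaks.index]

    if config.apply_input_filter:
        track = simulate_input_track(config.simulation, config.seed)
        peaks = signal.input_exclusion_filter(
            peaks, track,
            overlap_fraction=config.input_overlap_fraction,
            count_threshold=config.input_count_threshold,
        )
    else:
        peaks["excluded"] = False
        peaks["exclusion_reason"] = ""
    # the enrichment filter keys on the control sample of replicate 1
    peaks["rel_rpkm"] = rel["ctrl_rep1"]
    peaks = signal.background_signal_filter(
        peaks, literal_mode=config.literal_background_mode
    )
    kept = peaks[~peaks["excluded"]].copy()
    n_excluded = int(peaks["excluded"].sum())

    table = kept.copy()
    fits = {}
    widths = (kept["end"] - kept["start"]).to_numpy()
    bg_widths = (dataset.background["end"] - dataset.background["start"]).to_numpy()
    for rep in (1, 2):
        # common peaks: detected as enriched in both samples of the pair
        # (and above background), mirroring the overlap of per-sample
        # peak calls on which the normalization assumption rests
        detected = {
            s: signal.detect_enriched(
                kept[s].to_numpy(), widths,
                dataset.background[s].to_numpy(), bg_widths,
            )
            for s in (f"ctrl_rep{rep}", f"aman_rep{rep}")
        }
        common = (
            (rel.loc[kept.index, f"ctrl_rep{rep}"] > 1).to_numpy()
            & (rel.loc[kept.index, f"aman_rep{rep}"] > 1).to_numpy()
            & detected[f"ctrl_rep{rep}"] & detected[f"aman_rep{rep}"]
        )
        res, fit = manorm.run_manorm(
            kept, f"ctrl_rep{rep}", f"aman_rep{rep}",
            common_flag=common, pseudocount=config.pseudocount,
        )
        fits[rep] = fit
        table[f"M_norm_rep{rep}"] = res["M_norm"]
        table[f"neg_log10_p_rep{rep}"] = res["neg_log10_p"]
        table[f"rel_rpkm_control_rep{rep}"] = rel.loc[kept.index, f"ctrl_rep{rep}"]
        table[f"rel_rpkm_treated_rep{rep}"] = rel.loc[kept.index, f"aman_rep{rep}"]
    table["rel_rpkm_reference"] = rel.loc[kept.index, "reference"]
    # synthetic peaks are all present by the reference stage
    table["first_stage"] = "10.5"

    classified = classify_peaks(table, config.thresholds, config.mark)
    counts = classified["label"].value_counts().to_dict()
    summary = {
        "n_peaks": len(dataset.peaks),
        "n_excluded": n_excluded,
        "n_classified": len(classified),
        "label_counts": {k: int(counts.get(k, 0)) for k in ("MaD", "ZyD", "ND")},
        "normalization": {
            str(rep): {"intercept": fits[rep].intercept,
                       "slope": fits[rep].slope,
                       "n_common": fits[rep].n_common,
                       "method": fits[rep].method}
            for rep in fits
        },
    }
    if "true_label" in classified.columns:
        truth = classified["true_label"]
        pred = classified["label"]
        recall = {}
        for cls, target in (("MaD", "MaD"), ("ZyD", "ZyD"), ("ambiguous", "ND")):
            mask = truth == cls
            recall[cls] = (
                float((pred[mask] == target).mean()) if mask.any() else None
            )
        summary["recall"] = {
            "MaD": recall["MaD"], "ZyD": recall["ZyD"],
            "ambiguous_as_ND": recall["ambiguous"],
        }
    return {"table": classified, "summary": summary}


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute all stages in dependency order and return the summary dict.

    With ``outdir`` given, per-stage tables and a ``summary.json`` are
    written there; the summary JSON is byte-identical across runs with the
    same config and seed.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_seed": config.seed}

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        sim = config.simulation
        if sim.seed != config.seed:
            sim = type(sim).from_dict({**sim.to_dict(), "seed": config.seed})
        dataset = simulate_amanitin_experiment(sim)
        tss_records = None  # derived below from the same simulation
        from .simulate import simulate_genome_annotation

        scaffold_lengths, tss_records = simulate_genome_annotation(sim)
    else:
        if config.peaks_file is None or config.counts_file is None:
            raise StageError(
                "differential stage requires outputs of stage 'inputs': "
                "peaks_file and counts_file must be set when simulate=False"
            )
        raise StageError(
            "external-input mode covers peak/gene classification only and "
            "is driven through the library API; see read_peaks/run_manorm"
        )

    # --- differential + classification -----------------------------------
    aman = run_amanitin_analysis(dataset, config)
    summary["amanitin"] = aman["summary"]
    classified = aman["table"]

    # --- gene-level classification ----------------------------------------
    if config.classify_genes:
        if tss_records is None:
            raise StageError(
                "gene classification requires stage 'annotation' (a TSS "
                "table); provide tss_file or enable simulation"
            )
        gene_k4 = classify_gene_h3k4me3(
            tss_records, classified, half_width=config.h3k4me3_gene_window
        )
        gene_k27 = classify_gene_h3k27me3(
            tss_records, classified, half_width=config.h3k27me3_gene_window
        )
        gene_summary = {
            "h3k4me3_rule": gene_k4.value_counts().to_dict(),
            "h3k27me3_rule": gene_k27.value_counts().to_dict(),
        }
        truth_genes = dataset.truth.gene_labels.get("synthetic")
        if truth_genes is not None:
            common = gene_k4.index.intersection(truth_genes.index)
            for cls in ("MaD", "ZyD"):
                mask = truth_genes.loc[common] == cls
                gene_summary[f"gene_recall_{cls}"] = (
                    float((gene_k4.loc[common][mask] == cls).mean())
                    if mask.any() else None
                )
        summary["genes"] = gene_summary

        domains = great_regions(
            tss_records, scaffold_lengths,
            basal_up=config.great_basal_up,
            basal_down=config.great_basal_down,
            max_extension=config.great_max_extension,
        )
        domain_counts = count_peaks_in_domains(domains, classified)
        summary["regulatory_domains"] = {
            "n_domains": len(domains),
            "total_MaD_peaks": int(domain_counts["MaD"].sum()),
            "total_ZyD_peaks": int(domain_counts["ZyD"].sum()),
        }
    else:
        gene_k4 = None

    # --- methylation ------------------------------------------------------
    meth_summary = None
    if config.classify_genes:
        truth_genes = dataset.truth.gene_labels.get("synthetic")
        cpg, meth_truth, _ = simulate_methylome(
            config.simulation, config.seed, gene_labels=truth_genes
        )
        prom = methylation.promoter_methylation(
            cpg, tss_records, half_width=config.simulation.promoter_half_width
        )
        called = {}
        for gene, row in prom.iterrows():
            if np.isnan(row["weighted_methylation"]):
                continue
            called[gene] = (
                "hypo"
                if row["weighted_methylation"] < config.bisulfite_hypo_threshold
                else "hyper"
            )
        called = pd.Series(called, name="methylation_class", dtype=object)
        joint = methylation.joint_table(gene_k4, called)
        agreement = (called.reindex(meth_truth.index) == meth_truth).mean()
        meth_summary = {
            "n_promoters_called": int(len(called)),
            "truth_agreement": float(agreement),
            "joint_counts": {
                str(lab): {str(c): int(joint.loc[lab, c])
                           for c in joint.columns if not str(c).startswith("median_")}
                for lab in joint.index
            },
        }
        summary["methylation"] = meth_summary

    # --- enhancer clusters ------------------------------------------------
    p300, p300_truth = simulate_p300_stages(config.simulation, config.seed)
    catalog = enhancers.build_catalog(
        p300, stitch_distance=config.stitch_distance
    )
    earliest = list(config.simulation.p300_stages)[0]
    seeding = enhancers.seeding_analysis(catalog, p300[earliest].reset_index())
    last = list(config.simulation.p300_stages)[-1]
    fractions = enhancers.label_fraction_in_ecs(
        p300[last].reset_index(), catalog
    )
    composition = enhancers.ec_madzyd_composition(
        catalog, p300[last].reset_index()
    )
    # planted-cluster recovery: an EC total region recovers a planted
    # cluster when it overlaps any of its member peaks
    final = p300[last]
    recovered = 0
    for ci, members in p300_truth.ec_members.items():
        rows = final.loc[[m for m in members if m in final.index]]
        hit = False
        for iv in catalog.total_region:
            on = rows[(rows["scaffold"] == iv.scaffold)
                      & (rows["start"] < iv.end) & (rows["end"] > iv.start)]
            if len(on):
                hit = True
                break
        recovered += hit
    summary["enhancer_clusters"] = {
        "n_total_regions": len(catalog.total_region),
        "coverage_per_stage": {st: catalog.coverage[st] for st in p300},
        "planted_cluster_recovery": recovered / max(len(p300_truth.ec_members), 1),
        "seeding_classes": seeding["seeding_class"].value_counts().to_dict(),
        "fraction_in_ec_by_label": {
            r["label"]: {"fraction": r["fraction_in_ec"], "p_over": r["p_over"]}
            for _, r in fractions.iterrows()
        },
        "composition_quartiles": enhancers.composition_quartiles(composition),
    }

    # --- motif activity ---------------------------------------------------
    N, E, motif_truth = simulate_motif_dataset(config.simulation, config.seed)
    lam = (
        motifs.select_lambda(N, E, seed=config.seed)
        if config.select_lambda_by_cv else config.ridge_lambda
    )
    model = motifs.fit_activities(N, E, lam)
    hits = motifs.significant_motifs(model, config.z_threshold)
    true_active = [
        m for m in motif_truth.motif_activities.index
        if motif_truth.motif_activities.loc[m].abs().sum() > 0
    ]
    active_est = model.activities.loc[true_active].to_numpy().ravel()
    active_true = motif_truth.motif_activities.loc[true_active].to_numpy().ravel()
    r = float(np.corrcoef(active_est, active_true)[0, 1])
    summary["motif_activity"] = {
        "lambda": lam,
        "significant_motifs": hits,
        "active_set_recovered": sorted(hits) == sorted(true_active),
        "pearson_r_active": r,
    }

    # --- chromatin state dynamics ----------------------------------------
    segs, seg_lengths, state_truth = simulate_state_segmentations(
        config.simulation, config.seed
    )
    matrix = states.build_state_matrix(
        segs, seg_lengths, bin_size=config.state_bin_size
    )
    mask = states.modified_genome_mask(matrix)
    coverage = states.coverage_per_stage(matrix, mask)
    flows = states.transition_flows(matrix, mask)
    flow_json = states.flows_to_json(flows, config.state_bin_size)
    summary["chromatin_dynamics"] = {
        "n_bins": matrix.n_bins,
        "modified_fraction": float(mask.mean()),
        "coverage_sums": {
            str(st): float(coverage[st].sum()) for st in coverage.columns
        },
        "n_flow_links": len(flow_json["links"]),
    }

    summary = _round(summary)

    if outdir is not None:
        write_peaks(classified.reset_index(), outdir / "peaks_classified.tsv")
        if gene_k4 is not None:
            gene_k4.rename_axis("gene_id").reset_index().to_csv(
                outdir / "gene_labels_h3k4me3.tsv", sep="\t", index=False
            )
        write_matrix(model.activities, outdir / "motif_activities.tsv")
        write_matrix(model.zscores, outdir / "motif_zscores.tsv")
        write_matrix(coverage, outdir / "state_coverage.tsv")
        write_json(flow_json, outdir / "state_flows.json")
        for st, seg in segs.items():
            write_segmentation(seg, outdir / f"segmentation_stage{st}.bed")
        write_json(summary, outdir / "summary.json")
    return summary
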