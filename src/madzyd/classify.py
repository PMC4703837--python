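"""Maternal (MaD) versus zygotic (ZyD) definition of chromatin features.

A chromatin feature (H3K4me3, H3K27me3 or p300 binding) is *maternally
defined* when it is acquired by mid-gastrulation (stage 11) even in
embryos whose transcription is blocked with alpha-amanitin, consistently
in both replicates; it is *zygotically defined* when blocking
transcription abolishes it in both replicates, or when it first appears
after stage 11. Everything else is *not defined* (ND): replicate-
inconsistent or below threshold.

Per-replicate change calls combine the normalized M value and the count
p-value from the MA differential model with relative-RPKM enrichment
requirements at the comparison and reference stages; per-mark p-value
cutoffs differ (H3K27me3 regions are broad and need the stricter cutoff).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import AMANITIN_STAGE, TSSRecord, stage_le

logger = logging.getLogger(__name__)

MARKS = ("H3K4me3", "H3K27me3", "p300")


@dataclass
class ClassifierThresholds:
    """All numeric cutoffs of the change-call / consensus classifier.

    Defaults are the published operating point: lost/increased calls need
    |M| > 1 and -log10 p above 5 (H3K27me3) or 1.3 (H3K4me3, p300), plus
    relative RPKM > 1 at stage 11 and at the reference stage (10.5 for
    H3K4me3/p300, 12 for H3K27me3). ``skip_control_cutoff`` lists
    (mark, replicate) pairs for which the stage-11-control enrichment
    requirement is waived (the published analysis waived it for H3K27me3
    replicate 1).
    """

    m_cutoff: float = 1.0
    neg_log10_p_cutoff: dict = field(
        default_factory=lambda: {"H3K27me3": 5.0, "H3K4me3": 1.3, "p300": 1.3}
    )
    rel_rpkm_min: float = 1.0
    reference_stage: dict = field(
        default_factory=lambda: {"H3K4me3": "10.5", "p300": "10.5",
                                 "H3K27me3": "12"}
    )
    skip_control_cutoff: set = field(
        default_factory=lambda: {("H3K27me3", 1)}
    )

    def __post_init__(self):
        if self.m_cutoff <= 0 or self.rel_rpkm_min <= 0:
            raise ValueError("cutoffs must be positive")
        for v in self.neg_log10_p_cutoff.values():
            if v <= 0:
                raise ValueError("p-value cutoffs must be positive")

    def to_dict(self) -> dict:
        return {
            "m_cutoff": self.m_cutoff,
            "neg_log10_p_cutoff": dict(self.neg_log10_p_cutoff),
            "rel_rpkm_min": self.rel_rpkm_min,
            "reference_stage": dict(self.reference_stage),
            "skip_control_cutoff": sorted(
                [list(t) for t in self.skip_control_cutoff]
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierThresholds":
        d = dict(d)
        if "skip_control_cutoff" in d:
            d["skip_control_cutoff"] = {tuple(t) for t in d["skip_control_cutoff"]}
        return cls(**d)


@dataclass(frozen=True)
class ChangeCall:
    """Per-replicate change flags for one peak.

    ``is_maintained`` and ``is_unchanged`` may co-hold; lost and increased
    are mutually exclusive (they require opposite signs of M), and a
    maintained peak is by definition not lost.
    """

    is_lost: bool
    is_increased: bool
    is_unchanged: bool
    is_maintained: bool

    def __post_init__(self):
        if self.is_lost and self.is_increased:
            raise ValueError("lost and increased are mutually exclusive")
        if self.is_maintained and self.is_lost:
            raise ValueError("a maintained peak cannot be lost")


def call_change(m_norm: float, neg_log10_p: float, rel_rpkm: dict,
                thresholds: ClassifierThresholds, mark: str,
                skip_control: bool = False) -> ChangeCall:
    """Per-replicate lost/increased/unchanged/maintained call.

    ``rel_rpkm`` must provide keys ``control`` (stage-11 control),
    ``treated`` (stage-11 alpha-amanitin) and ``reference`` (stage 10.5 or
    12 depending on the mark). ``skip_control`` waives the control
    enrichment requirement for this sample.
    """
    for key in ("control", "treated", "reference"):
        if key not in rel_rpkm or rel_rpkm[key] is None or (
            isinstance(rel_rpkm[key], float) and np.isnan(rel_rpkm[key])
        ):
            raise ValueError(f"missing relative RPKM for required stage: {key}")
    if mark not in thresholds.neg_log10_p_cutoff:
        raise ValueError(f"unknown mark {mark!r}")
    p_cut = thresholds.neg_log10_p_cutoff[mark]
    rmin = thresholds.rel_rpkm_min
    ctrl_ok = skip_control or rel_rpkm["control"] > rmin
    treat_ok = rel_rpkm["treated"] > rmin
    ref_ok = rel_rpkm["reference"] > rmin

    lost = (m_norm > thresholds.m_cutoff and neg_log10_p > p_cut
            and ctrl_ok and ref_ok)
    increased = (m_norm < -thresholds.m_cutoff and neg_log10_p > p_cut
                 and treat_ok and ref_ok)
    unchanged = (not lost and not increased and ctrl_ok and treat_ok and ref_ok)
    maintained = (not lost and ctrl_ok and treat_ok and ref_ok)
    return ChangeCall(lost, increased, unchanged, maintained)


def consensus(rep1: ChangeCall, rep2: ChangeCall, first_stage: str) -> str:
    """Cross-replicate MaD/ZyD/ND label for one peak.

    MaD: present at or before stage 11 and maintained under transcription
    blockade in both replicates. ZyD: present at or before stage 11 and
    lost in both replicates, or first appearing after stage 11. All other
    peaks are ND.
    """
    early = stage_le(first_stage, AMANITIN_STAGE)
    if not early:
        return "ZyD"
    if rep1.is_maintained and rep2.is_maintained:
        return "MaD"
    if rep1.is_lost and rep2.is_lost:
        return "ZyD"
    return "ND"


def classify_peaks(table: pd.DataFrame, thresholds: ClassifierThresholds,
                   mark: str) -> pd.DataFrame:
    """Vectorized per-peak classification over a differential table.

    Expects columns M_norm_rep{1,2}, neg_log10_p_rep{1,2},
    rel_rpkm_control_rep{1,2}, rel_rpkm_treated_rep{1,2},
    rel_rpkm_reference, first_stage. Adds per-replicate flag columns and a
    ``label`` column; every peak receives exactly one label in
    {MaD, ZyD, ND}.
    """
    out = table.copy()
    calls = {}
    for rep in (1, 2):
        skip = (mark, rep) in thresholds.skip_control_cutoff
        rep_calls = []
        for row in out.itertuples():
            rel = {
                "control": getattr(row, f"rel_rpkm_control_rep{rep}"),
                "treated": getattr(row, f"rel_rpkm_treated_rep{rep}"),
                "reference": getattr(row, "rel_rpkm_reference"),
            }
            rep_calls.append(
                call_change(getattr(row, f"M_norm_rep{rep}"),
                            getattr(row, f"neg_log10_p_rep{rep}"),
                            rel, thresholds, mark, skip_control=skip)
            )
        calls[rep] = rep_calls
        out[f"lost_rep{rep}"] = [c.is_lost for c in rep_calls]
        out[f"maintained_rep{rep}"] = [c.is_maintained for c in rep_calls]
    out["label"] = [
        consensus(c1, c2, fs)
        for c1, c2, fs in zip(calls[1], calls[2], out["first_stage"])
    ]
    return out


def _window_tree(peaks: pd.DataFrame) -> dict:
    trees: dict[str, IntervalTree] = {}
    for row in peaks.itertuples():
        trees.setdefault(row.scaffold, IntervalTree()).addi(
            row.start, row.end, row.Index
        )
    return trees


def _labels_in_window(trees, rec: TSSRecord, half_width: int, labels) -> list[str]:
    tree = trees.get(rec.scaffold)
    if tree is None:
        return []
    lo = max(0, rec.tss - half_width)
    hi = rec.tss + half_width
    return [labels[iv.data] for iv in tree.overlap(lo, hi)]


def classify_gene_h3k4me3(tss_records, peaks: pd.DataFrame,
                          half_width: int = 250) -> pd.Series:
    """Gene-level H3K4me3 label from promoter (+/-250 bp of TSS) peaks.

    A gene is MaD when its promoter peak is maintained in both replicates
    (consensus MaD), ZyD when the promoter peak is lost in both replicates
    or emerges after stage 11 (consensus ZyD), unmarked with no promoter
    peak, and ND otherwise (including conflicting promoter labels, which
    are logged).
    """
    trees = _window_tree(peaks)
    labels = peaks["label"].to_dict()
    out = {}
    for rec in tss_records:
        found = _labels_in_window(trees, rec, half_width, labels)
        if not found:
            out[rec.gene_id] = "unmarked"
            continue
        definitive = {l for l in found if l in ("MaD", "ZyD")}
        if len(definitive) > 1:
            logger.info("gene %s: conflicting promoter labels %s -> ND",
                        rec.gene_id, sorted(definitive))
            out[rec.gene_id] = "ND"
        elif definitive:
            out[rec.gene_id] = definitive.pop()
        else:
            out[rec.gene_id] = "ND"
    return pd.Series(out, name="h3k4me3_label")


def classify_gene_h3k27me3(tss_records, peaks: pd.DataFrame,
                           half_width: int = 2500) -> pd.Series:
    """Gene-level H3K27me3 label from peaks within +/-2.5 kb of the TSS.

    MaD with at least one MaD peak in the window (MaD dominates); ZyD with
    at least one ZyD peak and no MaD peak; ND with only ND peaks; unmarked
    with no peak.
    """
    trees = _window_tree(peaks)
    labels = peaks["label"].to_dict()
    out = {}
    for rec in tss_records:
        found = _labels_in_window(trees, rec, half_width, labels)
        if not found:
            out[rec.gene_id] = "unmarked"
        elif "MaD" in found:
            out[rec.gene_id] = "MaD"
        elif "ZyD" in found:
            out[rec.gene_id] = "ZyD"
        else:
            out[rec.gene_id] = "ND"
    return pd.Series(out, name="h3k27me3_label")


@dataclass(frozen=True)
class RegulatoryDomain:
    """Basal-plus-extension regulatory domain of one gene."""

    gene_id: str
    scaffold: str
    basal_start: int
    basal_end: int
    ext_start: int
    ext_end: int

    def __post_init__(self):
        if not (self.ext_start <= self.basal_start < self.basal_end <= self.ext_end):
            raise ValueError("basal domain must lie inside the extended domain")


def great_regions(tss_records, scaffold_lengths: dict, basal_up: int = 5000,
                  basal_down: int = 1000, max_extension: int = 1_000_000
                  ) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains around each TSS.

    The basal domain is strand-aware (default 5 kb upstream, 1 kb
    downstream of the TSS). Each side is then extended to the nearest
    neighboring gene's basal boundary, but no further than
    ``max_extension`` from the TSS, and clipped to the scaffold. Extension
    never shrinks the basal domain.
    """
    ids = [r.gene_id for r in tss_records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in TSS table")
    basal = {}
    for r in tss_records:
        if r.strand == "+":
            b = (r.tss - basal_up, r.tss + basal_down)
        else:
            b = (r.tss - basal_down, r.tss + basal_up)
        L = scaffold_lengths[r.scaffold]
        basal[r.gene_id] = (max(0, b[0]), min(L, b[1]))
    by_scaffold: dict[str, list[TSSRecord]] = {}
    for r in tss_records:
        by_scaffold.setdefault(r.scaffold, []).append(r)
    domains = []
    for scaffold, recs in by_scaffold.items():
        recs = sorted(recs, key=lambda r: r.tss)
        L = scaffold_lengths[scaffold]
        for i, r in enumerate(recs):
            b0, b1 = basal[r.gene_id]
            left = max(0, r.tss - max_extension)
            for other in recs[:i][::-1]:
                ob1 = basal[other.gene_id][1]
                if ob1 <= b0:
                    left = max(left, ob1)
                    break
            right = min(L, r.tss + max_extension)
            for other in recs[i + 1:]:
                ob0 = basal[other.gene_id][0]
                if ob0 >= b1:
                    right = min(right, ob0)
                    break
            domains.append(RegulatoryDomain(
                r.gene_id, scaffold, b0, b1, min(left, b0), max(right, b1)
            ))
    return domains


def count_peaks_in_domains(domains, peaks: pd.DataFrame) -> pd.DataFrame:
    """Per-gene counts of MaD/ZyD/ND peaks overlapping (>=1 bp) its domain.

    A peak overlapping several domains counts for each of them.
    """
    trees: dict[str, IntervalTree] = {}
    for d in domains:
        trees.setdefault(d.scaffold, IntervalTree()).addi(
            d.ext_start, d.ext_end, d.gene_id
        )
    counts = {d.gene_id: {"MaD": 0, "ZyD": 0, "ND": 0} for d in domains}
    for row in peaks.itertuples():
        tree = trees.get(row.scaffold)
        if tree is None:
            continue
        for iv in tree.overlap(row.start, row.end):
            counts[iv.data][row.label] += 1
    out = pd.DataFrame.from_dict(counts, orient="index").sort_index()
    out.index.name = "gene_id"
    return out


STAGE_GROUPS = ("blastula", "gastrula", "neurula", "tailbud")


def group_genes_by_expression(expression: pd.DataFrame,
                              maternal_cols,
                              group_cols: dict,
                              maternal_threshold: float = 1.0) -> pd.Series:
    """Assign strictly embryonic genes to their stage of maximum expression.

    Genes with any maternal/pre-MBT expression at or above
    ``maternal_threshold`` are ineligible; all-zero genes are excluded
    (logged). ``group_cols`` maps group name (blastula/gastrula/neurula/
    tailbud) to the expression column holding that group's level. Ties go
    to the earlier stage group.
    """
    out = {}
    ordered = [g for g in STAGE_GROUPS if g in group_cols]
    for gene, row in expression.iterrows():
        if any(row[c] >= maternal_threshold for c in maternal_cols):
            continue
        levels = [row[group_cols[g]] for g in ordered]
        if max(levels) <= 0:
            logger.info("gene %s has no expression at any stage; excluded", gene)
            continue
        out[gene] = ordered[int(np.argmax(levels))]  # argmax: earliest on ties
    return pd.Series(out, name="stage_group", dtype=object)


def summarize_gene_set(gene_set, gene_labels: pd.Series,
                       p300_counts: pd.DataFrame | None = None,
                       h3k27me3_rel_rpkm: pd.Series | None = None) -> dict:
    """Label counts and median covariates for a set of genes."""
    known = [g for g in gene_set if g in gene_labels.index]
    for g in gene_set:
        if g not in gene_labels.index:
            logger.warning("unknown gene id %s skipped", g)
    labels = gene_labels.loc[known]
    summary = {
        "n_genes": len(known),
        "n_MaD": int((labels == "MaD").sum()),
        "n_ZyD": int((labels == "ZyD").sum()),
        "n_ND": int((labels == "ND").sum()),
    }
    if p300_counts is not None and known:
        sub = p300_counts.reindex(known).fillna(0)
        summary["median_p300_MaD_peaks"] = float(sub["MaD"].median())
        summary["median_p300_ZyD_peaks"] = float(sub["ZyD"].median())
    if h3k27me3_rel_rpkm is not None and known:
        vals = h3k27me3_rel_rpkm.reindex(known).dropna()
        summary["median_h3k27me3_rel_rpkm"] = (
            float(vals.median()) if len(vals) else None
        )
    return summary
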