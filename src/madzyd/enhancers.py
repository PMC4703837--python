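"""Enhancer-cluster (EC) calling and composition analysis.

ECs are super-enhancer-like entities: p300 peaks within 12.5 kb of one
another are stitched into regions, regions are ranked by total signal, and
the ranked-signal curve's inflection (the point where the rescaled tangent
slope reaches 1) separates ECs from ordinary stitched enhancers. ECs are
called per developmental stage and merged into a total EC region, against
which per-stage coverage, seeding and MaD/ZyD composition are measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, interval_union_bp, merge_intervals


@dataclass
class StitchedRegion:
    """Maximal chain of peaks with inter-peak gaps <= stitch distance."""

    interval: GenomicInterval
    member_ids: list
    signal: float
    stage: str | None = None
    rank: int | None = None
    is_ec: bool = False


def stitch_peaks(peaks: pd.DataFrame, stitch_distance: int = 12_500,
                 signal_col: str = "signal", stage: str | None = None
                 ) -> list[StitchedRegion]:
    """Stitch sorted peaks into regions; gap <= stitch_distance merges.

    The gap is measured between the end of one peak and the start of the
    next; a gap of exactly the stitch distance still merges. Region signal
    is the sum of member signals; singleton regions are allowed.
    """
    df = peaks.sort_values(["scaffold", "start", "end"], kind="mergesort")
    regions: list[StitchedRegion] = []
    cur = None
    for row in df.itertuples():
        sig = float(getattr(row, signal_col)) if signal_col in df.columns else 0.0
        if (cur is not None and row.scaffold == cur["scaffold"]
                and row.start - cur["end"] <= stitch_distance):
            cur["end"] = max(cur["end"], row.end)
            cur["members"].append(row.Index)
            cur["signal"] += sig
        else:
            if cur is not None:
                regions.append(_close(cur, stage))
            cur = {"scaffold": row.scaffold, "start": row.start, "end": row.end,
                   "members": [row.Index], "signal": sig}
    if cur is not None:
        regions.append(_close(cur, stage))
    return regions


def _close(cur: dict, stage) -> StitchedRegion:
    return StitchedRegion(
        GenomicInterval(cur["scaffold"], int(cur["start"]), int(cur["end"])),
        cur["members"], cur["signal"], stage=stage,
    )


def elbow_cutoff(signals) -> tuple[float, np.ndarray]:
    """Ranked-signal inflection cutoff separating ECs from the background.

    Signals are sorted ascending against rank and both axes rescaled to
    [0, 1]; the cutoff is the point where the curve's tangent has slope 1,
    found as the touch point of the slope-1 line supporting the curve from
    below (the highest-rank touch point when there are several, i.e. the
    most stringent cutoff); regions with signal above the cutoff signal are
    flagged.
    Returns (signal_threshold, flags aligned with the input order).
    Degenerate profiles (all equal, or slope never crossing 1, e.g. an
    exactly linear profile) flag nothing, with a warning.
    """
    sig = np.asarray(signals, dtype=float)
    n = sig.size
    if n < 3:
        raise ValueError("elbow cutoff needs at least 3 regions")
    order = np.argsort(sig, kind="stable")
    y = sig[order]
    if y[-1] == y[0]:
        warnings.warn("all region signals equal; no enhancer clusters called")
        return np.inf, np.zeros(n, dtype=bool)
    ys = (y - y[0]) / (y[-1] - y[0])
    xs = np.arange(n) / (n - 1)
    # Tangent of slope 1 supporting the curve from below: the touch point is
    # where the (noise-free) derivative equals 1. Computed as the point of
    # maximal depth below the unit diagonal, which is the same point for
    # convex profiles but immune to pointwise slope noise.
    depth = ys - xs
    min_depth = depth.min()
    if min_depth >= -1e-12:
        warnings.warn("ranked-signal profile has no slope-1 inflection "
                      "(linear or concave); no enhancer clusters called")
        return np.inf, np.zeros(n, dtype=bool)
    at_min = np.nonzero(depth <= min_depth + 1e-12)[0]
    cut_idx = int(at_min[-1])  # highest-rank touch point: most stringent
    threshold = float(y[cut_idx])
    flags = sig > threshold
    return threshold, flags


@dataclass
class ECCatalog:
    """Per-stage EC calls, the merged total EC region, and coverage."""

    per_stage: dict  # stage -> list[StitchedRegion] (all regions, flagged)
    total_region: list = field(default_factory=list)  # merged EC intervals
    coverage: dict = field(default_factory=dict)  # stage -> fraction of total

    def ec_regions(self, stage) -> list[GenomicInterval]:
        return [r.interval for r in self.per_stage[stage] if r.is_ec]


def build_catalog(per_stage_peaks: dict, stitch_distance: int = 12_500,
                  signal_col: str = "signal") -> ECCatalog:
    """Stitch + elbow per stage, then merge EC calls into the total region.

    Per-stage coverage is the bp of that stage's EC intervals lying inside
    the total region, divided by the total-region bp.
    """
    if not per_stage_peaks:
        raise ValueError("need at least one stage")
    per_stage = {}
    for stage, peaks in per_stage_peaks.items():
        regions = stitch_peaks(peaks, stitch_distance, signal_col, stage=stage)
        signals = np.array([r.signal for r in regions])
        if len(regions) >= 3:
            _, flags = elbow_cutoff(signals)
        else:
            flags = np.zeros(len(regions), dtype=bool)
        for rank, i in enumerate(np.argsort(-signals, kind="stable")):
            regions[i].rank = rank + 1
        for r, f in zip(regions, flags):
            r.is_ec = bool(f)
        per_stage[stage] = regions
    all_ec = [r.interval for regs in per_stage.values() for r in regs if r.is_ec]
    total = merge_intervals(all_ec)
    total_bp = sum(len(iv) for iv in total)
    coverage = {}
    for stage, regions in per_stage.items():
        ecs = [r.interval for r in regions if r.is_ec]
        cov_bp = _overlap_bp(ecs, total)
        coverage[stage] = cov_bp / total_bp if total_bp else 0.0
    return ECCatalog(per_stage=per_stage, total_region=total, coverage=coverage)


def _overlap_bp(intervals_a, intervals_b) -> int:
    """bp of the union of A lying inside the union of B."""
    a = merge_intervals(intervals_a)
    total = 0
    for iv in a:
        for jv in intervals_b:
            if jv.scaffold != iv.scaffold:
                continue
            ov = min(iv.end, jv.end) - max(iv.start, jv.start)
            if ov > 0:
                total += ov
    return total


def seeding_analysis(catalog: ECCatalog, earliest_peaks: pd.DataFrame,
                     label_col: str = "label") -> pd.DataFrame:
    """Classify each total-region EC by its earliest-stage seeding peaks.

    Seeding peaks are the earliest-stage peaks overlapping the EC's total
    region. An EC is MaD-seeded when any seeding peak is MaD, ZyD-seeded
    when seeds exist and all definitive seeds are ZyD, otherwise seeded-ND
    or unseeded.
    """
    rows = []
    for i, iv in enumerate(catalog.total_region):
        on = earliest_peaks[
            (earliest_peaks["scaffold"] == iv.scaffold)
            & (earliest_peaks["start"] < iv.end)
            & (earliest_peaks["end"] > iv.start)
        ]
        labels = list(on[label_col]) if label_col in on.columns else []
        if len(on) == 0:
            cls = "unseeded"
        elif "MaD" in labels:
            cls = "MaD-seeded"
        elif "ZyD" in labels:
            cls = "ZyD-seeded"
        else:
            cls = "seeded-ND"
        rows.append({
            "ec_id": i, "scaffold": iv.scaffold, "start": iv.start,
            "end": iv.end, "n_seeding_peaks": len(on), "seeding_class": cls,
        })
    return pd.DataFrame(rows)


def hypergeom_enrichment(n_population: int, n_success: int, n_draws: int,
                         k_observed: int) -> dict:
    """Exact cumulative hypergeometric tails, evaluated in log space.

    Upper tail: probability of >= k_observed successes among the draws
    (over-representation); lower tail: probability of <= k_observed
    (under-representation).
    """
    hg = stats.hypergeom(n_population, n_success, n_draws)
    upper = float(np.exp(hg.logsf(k_observed - 1)))
    lower = float(np.exp(hg.logcdf(k_observed)))
    return {"p_over": min(upper, 1.0), "p_under": min(lower, 1.0)}


def label_fraction_in_ecs(peaks: pd.DataFrame, catalog: ECCatalog,
                          label_col: str = "label") -> pd.DataFrame:
    """Fraction of each label class mapping to ECs, with enrichment tests.

    The population is all labelled peaks; successes are peaks overlapping
    the total EC region; each label class is the drawn sample. Cumulative
    hypergeometric p-values for over- and under-representation are exact.
    """
    in_ec = np.zeros(len(peaks), dtype=bool)
    for j, row in enumerate(peaks.itertuples()):
        for iv in catalog.total_region:
            if (iv.scaffold == row.scaffold and row.start < iv.end
                    and iv.start < row.end):
                in_ec[j] = True
                break
    N = len(peaks)
    K = int(in_ec.sum())
    rows = []
    for label in sorted(peaks[label_col].unique()):
        mask = (peaks[label_col] == label).to_numpy()
        n = int(mask.sum())
        k = int((mask & in_ec).sum())
        if n == 0:
            rows.append({"label": label, "n_peaks": 0, "n_in_ec": 0,
                         "fraction_in_ec": np.nan, "p_over": np.nan,
                         "p_under": np.nan})
            continue
        p = hypergeom_enrichment(N, K, n, k)
        rows.append({"label": label, "n_peaks": n, "n_in_ec": k,
                     "fraction_in_ec": k / n, **p})
    return pd.DataFrame(rows)


def ec_madzyd_composition(catalog: ECCatalog, peaks: pd.DataFrame,
                          label_col: str = "label") -> pd.DataFrame:
    """Per-EC fraction of the region covered by MaD versus ZyD peaks.

    Coverage is union bp (overlapping same-label peaks are not double
    counted), divided by the EC length.
    """
    rows = []
    for i, iv in enumerate(catalog.total_region):
        on = peaks[
            (peaks["scaffold"] == iv.scaffold)
            & (peaks["start"] < iv.end) & (peaks["end"] > iv.start)
        ]
        rec = {"ec_id": i, "length": len(iv)}
        for label in ("MaD", "ZyD"):
            sub = on[on[label_col] == label]
            clipped = [
                GenomicInterval(iv.scaffold, max(r.start, iv.start),
                                min(r.end, iv.end))
                for r in sub.itertuples()
            ]
            rec[f"{label}_fraction"] = interval_union_bp(clipped) / len(iv)
        rows.append(rec)
    return pd.DataFrame(rows)


def composition_quartiles(composition: pd.DataFrame) -> dict:
    """Box-plot statistics (quartiles) of the per-EC composition fractions."""
    out = {}
    for label in ("MaD", "ZyD"):
        v = composition[f"{label}_fraction"].to_numpy()
        if v.size == 0:
            out[label] = None
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        out[label] = {"q1": float(q1), "median": float(med), "q3": float(q3)}
    return out


def nearest_gene(ec: GenomicInterval, tss_records) -> tuple[list[str], float]:
    """Gene(s) whose TSS is closest to the EC (0 if inside); ties all kept."""
    best: list[str] = []
    best_d = np.inf
    for rec in tss_records:
        if rec.scaffold != ec.scaffold:
            continue
        if ec.start <= rec.tss < ec.end:
            d = 0
        else:
            d = min(abs(rec.tss - ec.start), abs(rec.tss - (ec.end - 1)))
        if d < best_d:
            best, best_d = [rec.gene_id], d
        elif d == best_d:
            best.append(rec.gene_id)
    if not best:
        return [], np.nan
    return best, float(best_d)
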