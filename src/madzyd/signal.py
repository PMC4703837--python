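"""Peak signal quantification and enrichment filters.

Implements the signal side of enriched-region detection: RPKM, the
random-background 95th-percentile normalization yielding *relative RPKM*
(peak RPKM divided by the 95th-percentile RPKM of random background
regions), the high-input exclusion filter, and TSS-anchored profile
matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval


def compute_rpkm(count, length_bp, library_size):
    """Reads per kilobase per million mapped reads.

    rpkm = count / ((length/1000) * (library_size/1e6)). Vectorized over
    ``count``/``length_bp``.
    """
    length_bp = np.asarray(length_bp, dtype=float)
    if np.any(length_bp <= 0):
        raise ValueError("region length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return np.asarray(count, dtype=float) / (
        (length_bp / 1e3) * (library_size / 1e6)
    )


def nearest_rank_percentile(values, q: float = 0.95) -> float:
    """Nearest-rank percentile: the ceil(q*n)-th order statistic.

    Deliberately avoids interpolation dialects so the background cutoff is
    unambiguous and matches an enumeration oracle exactly.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("cannot take a percentile of an empty vector")
    k = max(1, math.ceil(q * n))
    return float(v[k - 1])


@dataclass
class BackgroundModel:
    """Random background regions and their per-sample 95th-percentile RPKM."""

    regions: pd.DataFrame  # scaffold, start, end
    rpkm: pd.DataFrame  # one column per sample, one row per region
    p95: dict = field(default_factory=dict)
    percentile: float = 0.95
    seed: int | None = None

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @classmethod
    def from_counts(cls, regions: pd.DataFrame, counts: pd.DataFrame,
                    library_sizes: dict, percentile: float = 0.95,
                    seed: int | None = None) -> "BackgroundModel":
        lengths = (regions["end"] - regions["start"]).to_numpy()
        rpkm = pd.DataFrame(index=regions.index)
        p95 = {}
        for sample in counts.columns:
            r = compute_rpkm(counts[sample].to_numpy(), lengths,
                             library_sizes[sample])
            rpkm[sample] = r
            p95[sample] = nearest_rank_percentile(r, percentile)
        return cls(regions=regions, rpkm=rpkm, p95=p95,
                   percentile=percentile, seed=seed)


def sample_background_regions(scaffold_lengths: dict, peak_widths,
                              n_regions: int, seed) -> pd.DataFrame:
    """Uniform random background regions with peak-matched widths.

    Widths are resampled with replacement from the observed peak-width
    distribution; positions are uniform over the whitelisted scaffolds
    (scaffold chosen proportional to length). Deterministic given seed.
    """
    if n_regions < 100:
        raise ValueError("need at least 100 background regions for a stable p95")
    rng = np.random.default_rng(seed)
    peak_widths = np.asarray(peak_widths, dtype=int)
    if peak_widths.size == 0 or np.any(peak_widths <= 0):
        raise ValueError("peak widths must be positive and non-empty")
    names = list(scaffold_lengths)
    lengths = np.array([scaffold_lengths[n] for n in names], dtype=float)
    probs = lengths / lengths.sum()
    rows = []
    for _ in range(n_regions):
        width = int(rng.choice(peak_widths))
        for attempt in range(100):
            si = rng.choice(len(names), p=probs)
            if scaffold_lengths[names[si]] > width:
                start = int(rng.integers(0, scaffold_lengths[names[si]] - width))
                rows.append((names[si], start, start + width))
                break
        else:
            raise ValueError(
                f"could not place a background region of width {width} "
                "after 100 attempts; scaffolds too short"
            )
    return pd.DataFrame(rows, columns=["scaffold", "start", "end"])


def relative_rpkm(peak_rpkm, p95: float):
    """Peak RPKM divided by the background 95th-percentile RPKM.

    The downstream classifier thresholds ("rel. RPKM > 1") operate on this
    ratio, which is invariant under uniform scaling of all counts in a
    sample.
    """
    if p95 <= 0:
        raise ValueError(
            "degenerate background: 95th-percentile RPKM is zero; "
            "increase background region count or coverage"
        )
    return np.asarray(peak_rpkm, dtype=float) / p95


def detect_enriched(counts, widths, background_counts, background_widths,
                    alpha: float = 1e-4, min_fold: float = 4.0):
    """Per-sample peak detection against the local background rate.

    A region is detected when its read count both exceeds the (1 - alpha)
    Poisson quantile of the expected background count at its width and is
    at least ``min_fold`` times that expectation — the significance-plus-
    fold-enrichment logic of a standard peak caller. The background rate
    is estimated as total background reads per bp. This stands in for the
    per-sample peak calls that define which merged peaks are "common" to
    both samples.
    """
    from scipy import stats

    counts = np.asarray(counts, dtype=float)
    widths = np.asarray(widths, dtype=float)
    bg_reads = float(np.sum(background_counts))
    bg_bp = float(np.sum(background_widths))
    if bg_bp <= 0:
        raise ValueError("background regions have zero total length")
    rate = bg_reads / bg_bp
    mu = np.maximum(rate * widths, 1e-12)
    crit = np.maximum(stats.poisson.ppf(1 - alpha, mu), min_fold * mu)
    return counts > crit


def input_exclusion_filter(peaks: pd.DataFrame, input_bins: pd.DataFrame,
                           overlap_fraction: float = 0.75,
                           count_threshold: float = 65,
                           bin_size: int = 1000) -> pd.DataFrame:
    """Flag peaks lying mostly in high-input 1-kb bins.

    A peak is excluded when at least ``overlap_fraction`` (default 75%) of
    its length falls in 1-kb input bins carrying more than
    ``count_threshold`` (default 65) input reads — such regions are
    copy-number or mapping artifacts. Bins with exactly the threshold count
    are NOT flagged (strictly "more than").

    Returns a copy of ``peaks`` with boolean ``excluded`` and string
    ``exclusion_reason`` columns updated (idempotent; reasons accumulate at
    most once).
    """
    widths = input_bins["end"] - input_bins["start"]
    # terminal scaffold bins may be short; all others must be exactly bin_size
    if not ((widths == bin_size) | (widths < bin_size)).all():
        raise ValueError(f"input track must be binned at {bin_size} bp")
    if (widths == bin_size).sum() == 0:
        raise ValueError(f"input track must be binned at {bin_size} bp")

    flagged = input_bins[input_bins["value"] > count_threshold]
    by_scaffold = {
        s: g[["start", "end"]].to_numpy() for s, g in flagged.groupby("scaffold")
    }
    out = peaks.copy()
    if "excluded" not in out.columns:
        out["excluded"] = False
        out["exclusion_reason"] = ""
    for idx, row in out.iterrows():
        bins = by_scaffold.get(row["scaffold"])
        if bins is None:
            continue
        ov = np.minimum(bins[:, 1], row["end"]) - np.maximum(bins[:, 0], row["start"])
        ov_bp = int(ov[ov > 0].sum())
        frac = ov_bp / (row["end"] - row["start"])
        if frac >= overlap_fraction and not out.at[idx, "excluded"]:
            out.at[idx, "excluded"] = True
            out.at[idx, "exclusion_reason"] = "high_input"
    return out


def background_signal_filter(peaks: pd.DataFrame, rel_rpkm_col: str = "rel_rpkm",
                             literal_mode: bool = False) -> pd.DataFrame:
    """Exclude peaks that do not rise above random background.

    Default interpretation: peaks with relative RPKM <= 1 (i.e. not above
    the background 95th percentile) are excluded, consistent with every
    "rel. RPKM > 1" retention rule applied downstream. ``literal_mode``
    applies the opposite direction (exclude peaks whose RPKM exceeds the
    background percentile); it exists so both readings of the filter can be
    compared, and is not the default.
    """
    out = peaks.copy()
    if "excluded" not in out.columns:
        out["excluded"] = False
        out["exclusion_reason"] = ""
    rel = out[rel_rpkm_col].to_numpy(dtype=float)
    hit = (rel > 1.0) if literal_mode else (rel <= 1.0)
    newly = hit & ~out["excluded"].to_numpy()
    out.loc[newly, "excluded"] = True
    out.loc[newly, "exclusion_reason"] = (
        "above_background_literal" if literal_mode else "below_background"
    )
    return out


def tss_profile_matrix(track: pd.DataFrame, tss_records, flank: int,
                       bin_size: int) -> np.ndarray:
    """Strand-aware signal matrix centered on TSSs (genes x bins).

    ``track`` is a bedGraph whose intervals are aligned to ``bin_size``.
    Rows follow the input gene order; minus-strand rows are reversed so
    that transcription runs left to right. Bins falling off a scaffold end
    are NaN.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin size")
    values: dict[str, dict[int, float]] = {}
    extents: dict[str, int] = {}
    for r in track.itertuples():
        d = values.setdefault(r.scaffold, {})
        for b in range(int(r.start) // bin_size, -(-int(r.end) // bin_size)):
            d[b] = float(r.value)
        extents[r.scaffold] = max(extents.get(r.scaffold, 0), int(r.end))
    n_bins = 2 * flank // bin_size
    mat = np.full((len(tss_records), n_bins), np.nan)
    for gi, rec in enumerate(tss_records):
        d = values.get(rec.scaffold)
        if d is None:
            continue
        first = (rec.tss - flank) // bin_size
        for j in range(n_bins):
            b = first + j
            if b < 0 or b * bin_size >= extents[rec.scaffold]:
                continue
            mat[gi, j] = d.get(b, 0.0)
        if rec.strand == "-":
            mat[gi] = mat[gi, ::-1]
    return mat
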