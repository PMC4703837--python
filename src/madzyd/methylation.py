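"""Promoter DNA-methylation state and its coupling to MaD/ZyD chromatin.

Weighted methylation is the coverage-weighted estimator
sum(methylated) / sum(total) over covered CpGs in a window — robust at
low per-CpG coverage. Hypomethylation can be called either from a
non-methylated-CpG capture (Bio-CAP) enrichment ratio over input on the
promoter (ratio > 1) or, for bisulfite-style data, by thresholding the
weighted methylation level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import TSSRecord

VALID_NUCLEOTIDES = set("ACGTNacgtn")


def weighted_methylation(methylated, total):
    """Coverage-weighted methylation: sum(meth) / sum(total) over CpGs.

    Returns NaN when no CpG in the window has coverage. Invariant under
    splitting a CpG's counts across records.
    """
    methylated = np.asarray(methylated, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(methylated > total) or np.any(methylated < 0):
        raise ValueError("need 0 <= methylated <= total per CpG")
    covered = total > 0
    if not covered.any():
        return float("nan")
    return float(methylated[covered].sum() / total[covered].sum())


def promoter_methylation(cpg_table: pd.DataFrame, tss_records,
                         half_width: int = 250) -> pd.DataFrame:
    """Weighted methylation per promoter window (+/- half_width of TSS).

    ``cpg_table`` columns: scaffold, pos, meth, total. Returns a per-gene
    frame with weighted_methylation (NaN when uncovered) and n_cpgs (CpGs
    with coverage in the window).
    """
    by_scaffold = {s: g.sort_values("pos") for s, g in cpg_table.groupby("scaffold")}
    rows = []
    for rec in tss_records:
        g = by_scaffold.get(rec.scaffold)
        if g is None:
            rows.append((rec.gene_id, float("nan"), 0))
            continue
        lo, hi = rec.tss - half_width, rec.tss + half_width
        window = g[(g["pos"] >= lo) & (g["pos"] < hi)]
        covered = window[window["total"] > 0]
        level = (
            weighted_methylation(covered["meth"], covered["total"])
            if len(covered) else float("nan")
        )
        rows.append((rec.gene_id, level, len(covered)))
    return pd.DataFrame(
        rows, columns=["gene_id", "weighted_methylation", "n_cpgs"]
    ).set_index("gene_id")


def cpg_density(sequence: str, observed_expected: bool = False,
                strict: bool = True) -> float:
    """CpG dinucleotide density of a sequence window.

    Default: observed CG dinucleotides per bp. With
    ``observed_expected=True`` the classic CpG o/e ratio
    (n_CG * L / (n_C * n_G)) is returned instead.
    """
    if not sequence:
        raise ValueError("window must be non-empty")
    if strict and not set(sequence) <= VALID_NUCLEOTIDES:
        bad = sorted(set(sequence) - VALID_NUCLEOTIDES)
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    s = sequence.upper()
    n_cg = s.count("CG")
    if not observed_expected:
        return n_cg / len(s)
    n_c, n_g = s.count("C"), s.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    return n_cg * len(s) / (n_c * n_g)


def biocap_hypomethylation_call(biocap_rpkm: float, input_rpkm: float) -> bool:
    """Hypomethylated promoter call from the Bio-CAP/input RPKM ratio.

    Non-methylated-CpG capture enriches hypomethylated islands, so a
    promoter (+/-1 kb of TSS by convention) is called hypomethylated when
    the input-corrected ratio is strictly greater than 1.
    """
    if input_rpkm <= 0:
        raise ValueError("input RPKM must be positive for the ratio call")
    return (biocap_rpkm / input_rpkm) > 1.0


def bisulfite_hypomethylation_call(weighted_level: float,
                                   threshold: float = 0.2) -> bool:
    """Alternative rule for bisulfite-style data: weighted level < threshold."""
    if np.isnan(weighted_level):
        raise ValueError("weighted level undefined (no covered CpGs)")
    return weighted_level < threshold


def joint_table(gene_labels: pd.Series, methylation_class: pd.Series,
                covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Contingency of MaD/ZyD/ND gene labels against methylation class.

    Rows are label values, columns methylation classes (hypo/hyper); cells
    hold gene counts. When ``covariates`` is given (indexed by gene, e.g.
    weighted methylation, CpG density, relative RPKM), per-cell medians of
    every covariate column are appended as extra columns
    ``median_<covariate>_<class>``. Marginals over the table equal the
    label counts of the genes shared by both inputs.
    """
    common = gene_labels.index.intersection(methylation_class.index)
    lab = gene_labels.loc[common]
    meth = methylation_class.loc[common]
    label_values = ["MaD", "ZyD", "ND", "unmarked"]
    meth_values = sorted(meth.unique())
    table = pd.DataFrame(0, index=label_values, columns=meth_values)
    for l, m in zip(lab, meth):
        if l not in table.index:
            table.loc[l] = 0
        table.loc[l, m] += 1
    if covariates is not None:
        for col in covariates.columns:
            for m in meth_values:
                medians = []
                for l in table.index:
                    genes = common[(lab == l) & (meth == m)]
                    vals = covariates.loc[covariates.index.intersection(genes), col].dropna()
                    medians.append(float(vals.median()) if len(vals) else np.nan)
                table[f"median_{col}_{m}"] = medians
    table.index.name = "label"
    return table
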