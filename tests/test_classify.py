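import numpy as np
import pandas as pd
import pytest

from madzyd.classify import (ChangeCall, ClassifierThresholds, call_change,
                             classify_gene_h3k27me3, classify_gene_h3k4me3,
                             consensus, count_peaks_in_domains, great_regions,
                             group_genes_by_expression, summarize_gene_set)
from madzyd.intervals import TSSRecord

TH = ClassifierThresholds()
REL_OK = {"control": 2.0, "treated": 2.0, "reference": 2.0}


class TestCallChange:
    def test_h3k4me3_lost_at_mild_pvalue(self):
        call = call_change(1.5, 2.0, REL_OK, TH, "H3K4me3")
        assert call.is_lost and not call.is_maintained

    def test_h3k27me3_needs_stricter_pvalue(self):
        call = call_change(1.5, 2.0, REL_OK, TH, "H3K27me3")
        assert not call.is_lost
        assert call.is_maintained  # not lost + all rel RPKM above 1

    def test_increased_call(self):
        rel = {"control": 0.5, "treated": 1.4, "reference": 1.2}
        call = call_change(-1.2, 6.0, rel, TH, "H3K27me3")
        assert call.is_increased and not call.is_lost

    def test_maintained_requires_all_three_enrichments(self):
        rel = {"control": 2.0, "treated": 0.8, "reference": 2.0}
        call = call_change(0.0, 0.1, rel, TH, "H3K4me3")
        assert not call.is_maintained and not call.is_unchanged

    def test_control_cutoff_waiver(self):
        rel = {"control": 0.5, "treated": 2.0, "reference": 2.0}
        strict = call_change(0.0, 0.1, rel, TH, "H3K27me3", skip_control=False)
        waived = call_change(0.0, 0.1, rel, TH, "H3K27me3", skip_control=True)
        assert not strict.is_maintained and waived.is_maintained

    def test_missing_rel_rpkm_named(self):
        with pytest.raises(ValueError, match="reference"):
            call_change(0.0, 0.1, {"control": 1.0, "treated": 1.0,
                                   "reference": float("nan")}, TH, "H3K4me3")

    def test_raising_m_cutoff_never_creates_lost(self):
        """Monotonicity: a stricter M cutoff cannot turn maintained to lost."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = float(rng.normal(0, 2))
            p = float(rng.exponential(3))
            base = call_change(m, p, REL_OK, TH, "H3K4me3")
            strict = call_change(
                m, p, REL_OK,
                ClassifierThresholds(m_cutoff=TH.m_cutoff + 1.0), "H3K4me3",
            )
            if base.is_maintained:
                assert not strict.is_lost


MAINT = ChangeCall(False, False, True, True)
LOST = ChangeCall(True, False, False, False)
NONE = ChangeCall(False, False, False, False)


class TestConsensus:
    def test_maintained_both_early_is_mad(self):
        assert consensus(MAINT, MAINT, "9") == "MaD"

    def test_replicate_disagreement_is_nd(self):
        assert consensus(LOST, MAINT, "9") == "ND"

    def test_late_emergence_is_zyd_regardless(self):
        assert consensus(MAINT, MAINT, "12.5") == "ZyD"
        assert consensus(NONE, NONE, "12.5") == "ZyD"

    def test_lost_both_early_is_zyd(self):
        assert consensus(LOST, LOST, "10.5") == "ZyD"

    def test_exhaustive_single_label(self):
        """Every call combination yields exactly one of MaD/ZyD/ND."""
        calls = [MAINT, LOST, NONE, ChangeCall(False, True, False, False)]
        for c1 in calls:
            for c2 in calls:
                for stage in ("9", "11", "12.5"):
                    assert consensus(c1, c2, stage) in ("MaD", "ZyD", "ND")


def _labelled_peaks(rows):
    df = pd.DataFrame(rows, columns=["scaffold", "start", "end", "label"])
    df.index = [f"p{i}" for i in range(len(df))]
    return df


class TestGeneClassification:
    def test_h3k4me3_rules(self):
        tss = [TSSRecord("gMaD", "s", 1000, "+"),
               TSSRecord("gZyD", "s", 10_000, "+"),
               TSSRecord("gNone", "s", 50_000, "+")]
        peaks = _labelled_peaks([
            ("s", 900, 1400, "MaD"),
            ("s", 9_900, 10_200, "ZyD"),
        ])
        out = classify_gene_h3k4me3(tss, peaks)
        assert out["gMaD"] == "MaD"
        assert out["gZyD"] == "ZyD"
        assert out["gNone"] == "unmarked"

    def test_h3k4me3_conflicting_labels_nd(self):
        tss = [TSSRecord("g", "s", 1000, "+")]
        peaks = _labelled_peaks([
            ("s", 800, 1000, "MaD"), ("s", 1100, 1300, "ZyD"),
        ])
        assert classify_gene_h3k4me3(tss, peaks)["g"] == "ND"

    def test_h3k27me3_mad_dominates(self):
        tss = [TSSRecord("g", "s", 10_000, "+")]
        peaks = _labelled_peaks([
            ("s", 8_000, 8_500, "ZyD"), ("s", 11_000, 11_500, "MaD"),
        ])
        assert classify_gene_h3k27me3(tss, peaks)["g"] == "MaD"

    def test_h3k27me3_zyd_only(self):
        tss = [TSSRecord("g", "s", 10_000, "+")]
        peaks = _labelled_peaks([("s", 8_000, 8_500, "ZyD")])
        assert classify_gene_h3k27me3(tss, peaks)["g"] == "ZyD"

    def test_h3k27me3_only_nd_peaks(self):
        tss = [TSSRecord("g", "s", 10_000, "+")]
        peaks = _labelled_peaks([("s", 9_000, 9_500, "ND")])
        assert classify_gene_h3k27me3(tss, peaks)["g"] == "ND"

    def test_distal_peaks_do_not_change_gene_labels(self):
        """Window locality: peaks outside the stated windows are inert."""
        tss = [TSSRecord("g", "s", 10_000, "+")]
        near = _labelled_peaks([("s", 9_900, 10_100, "MaD")])
        with_distal = _labelled_peaks([
            ("s", 9_900, 10_100, "MaD"), ("s", 40_000, 41_000, "ZyD"),
        ])
        assert (classify_gene_h3k4me3(tss, near)["g"]
                == classify_gene_h3k4me3(tss, with_distal)["g"])
        assert (classify_gene_h3k27me3(tss, near)["g"]
                == classify_gene_h3k27me3(tss, with_distal)["g"])


class TestGreatRegions:
    def test_single_gene_mid_scaffold(self):
        tss = [TSSRecord("g", "s", 500_000, "+")]
        (d,) = great_regions(tss, {"s": 1_000_000})
        assert (d.basal_start, d.basal_end) == (495_000, 501_000)
        assert (d.ext_start, d.ext_end) == (0, 1_000_000)

    def test_neighbors_stop_at_each_others_basal(self):
        tss = [TSSRecord("g1", "s", 100_000, "+"),
               TSSRecord("g2", "s", 200_000, "+")]
        d1, d2 = great_regions(tss, {"s": 1_000_000})
        # g2 basal starts at 195_000; g1 extension stops there
        assert d1.ext_end == 195_000
        # g1 basal ends at 101_000; g2 extension starts there
        assert d2.ext_start == 101_000

    def test_gene_at_scaffold_edge_clipped(self):
        tss = [TSSRecord("g", "s", 2_000, "+")]
        (d,) = great_regions(tss, {"s": 50_000})
        assert d.ext_start == 0 and d.basal_start == 0

    def test_duplicate_gene_ids_rejected(self):
        tss = [TSSRecord("g", "s", 1000, "+"), TSSRecord("g", "s", 2000, "+")]
        with pytest.raises(ValueError, match="duplicate"):
            great_regions(tss, {"s": 10_000})

    def test_minus_strand_basal_flipped(self):
        tss = [TSSRecord("g", "s", 500_000, "-")]
        (d,) = great_regions(tss, {"s": 1_000_000})
        assert (d.basal_start, d.basal_end) == (499_000, 505_000)


class TestCountPeaksInDomains:
    def test_counts_and_multi_domain_peaks(self):
        tss = [TSSRecord("g1", "s", 100_000, "+"),
               TSSRecord("g2", "s", 130_000, "+")]
        domains = great_regions(tss, {"s": 1_000_000})
        peaks = _labelled_peaks([
            ("s", 99_000, 99_500, "ZyD"),
            ("s", 99_600, 99_700, "ZyD"),
            ("s", 100_500, 100_800, "ZyD"),
        ])
        counts = count_peaks_in_domains(domains, peaks)
        assert counts.loc["g1", "ZyD"] == 3
        assert counts.loc["g1", "MaD"] == 0

    def test_matches_brute_force(self, rng):
        tss = [TSSRecord(f"g{i}", "s", int(p), "+")
               for i, p in enumerate(sorted(rng.integers(10_000, 990_000, 8)))]
        domains = great_regions(tss, {"s": 1_000_000})
        labels = ["MaD", "ZyD", "ND"]
        rows = []
        for _ in range(100):
            start = int(rng.integers(0, 999_000))
            rows.append(("s", start, start + int(rng.integers(100, 1000)),
                         labels[int(rng.integers(0, 3))]))
        peaks = _labelled_peaks(rows)
        counts = count_peaks_in_domains(domains, peaks)
        for d in domains:
            for lab in labels:
                expected = sum(
                    1 for (_, s, e, l) in rows
                    if l == lab and s < d.ext_end and e > d.ext_start
                )
                assert counts.loc[d.gene_id, lab] == expected


class TestExpressionGrouping:
    EXPR = pd.DataFrame(
        {
            "oocyte": [0.0, 5.0, 0.0, 0.0],
            "blastula": [0.1, 1.0, 0.0, 2.0],
            "gastrula": [0.2, 1.0, 0.0, 2.0],
            "neurula": [7.0, 1.0, 0.0, 1.0],
            "tailbud": [1.0, 9.0, 0.0, 0.5],
        },
        index=["gN", "gMaternal", "gSilent", "gTie"],
    )
    GROUPS = {g: g for g in ("blastula", "gastrula", "neurula", "tailbud")}

    def test_argmax_assignment(self):
        out = group_genes_by_expression(self.EXPR, ["oocyte"], self.GROUPS)
        assert out["gN"] == "neurula"

    def test_maternal_genes_excluded(self):
        out = group_genes_by_expression(self.EXPR, ["oocyte"], self.GROUPS)
        assert "gMaternal" not in out.index

    def test_all_zero_excluded_and_tie_goes_early(self):
        out = group_genes_by_expression(self.EXPR, ["oocyte"], self.GROUPS)
        assert "gSilent" not in out.index
        assert out["gTie"] == "blastula"


class TestSummarizeGeneSet:
    LABELS = pd.Series(
        ["MaD"] * 7 + ["ZyD"], index=[f"g{i}" for i in range(8)]
    )

    def test_counts(self):
        s = summarize_gene_set(list(self.LABELS.index), self.LABELS)
        assert (s["n_MaD"], s["n_ZyD"], s["n_ND"]) == (7, 1, 0)

    def test_empty_set(self):
        s = summarize_gene_set([], self.LABELS)
        assert s["n_genes"] == 0

    def test_unknown_genes_skipped(self):
        s = summarize_gene_set(["g0", "nope"], self.LABELS)
        assert s["n_genes"] == 1
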