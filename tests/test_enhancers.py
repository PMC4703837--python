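import math

import numpy as np
import pandas as pd
import pytest

from madzyd.enhancers import (build_catalog, composition_quartiles,
                              ec_madzyd_composition, elbow_cutoff,
                              hypergeom_enrichment, label_fraction_in_ecs,
                              nearest_gene, seeding_analysis, stitch_peaks)
from madzyd.intervals import GenomicInterval, TSSRecord
from madzyd.simulate import SimulationConfig, simulate_p300_stages


def _peaks(rows, extra=None):
    df = pd.DataFrame(rows, columns=["scaffold", "start", "end"])
    df["signal"] = extra if extra is not None else 1.0
    df.index = [f"p{i}" for i in range(len(df))]
    return df


def brute_force_chains(rows, d):
    """Naive chain construction oracle for stitching."""
    by_scaffold = {}
    for r in sorted(rows):
        by_scaffold.setdefault(r[0], []).append(r)
    regions = []
    for scaffold in sorted(by_scaffold):
        chain = None
        for (_, s, e) in sorted(by_scaffold[scaffold], key=lambda r: (r[1], r[2])):
            if chain is not None and s - chain[1] <= d:
                chain = (chain[0], max(chain[1], e), chain[2] + 1)
            else:
                if chain:
                    regions.append((scaffold,) + chain)
                chain = (s, e, 1)
        regions.append((scaffold,) + chain)
    return regions


class TestStitchPeaks:
    def test_gap_arithmetic(self):
        regions = stitch_peaks(_peaks([
            ("s", 0, 500), ("s", 10_000, 10_500), ("s", 30_000, 30_500),
        ]))
        spans = [(r.interval.start, r.interval.end, len(r.member_ids))
                 for r in regions]
        assert spans == [(0, 10_500, 2), (30_000, 30_500, 1)]

    def test_gap_exactly_at_threshold_merges(self):
        regions = stitch_peaks(_peaks([("s", 0, 500), ("s", 13_000, 13_500)]))
        assert len(regions) == 1  # gap 12,500 <= 12,500

    def test_gap_just_over_threshold_does_not(self):
        regions = stitch_peaks(_peaks([("s", 0, 500), ("s", 13_001, 13_500)]))
        assert len(regions) == 2

    def test_signal_is_member_sum(self):
        regions = stitch_peaks(_peaks([("s", 0, 500), ("s", 1_000, 1_500)],
                                      extra=[2.0, 3.0]))
        assert regions[0].signal == pytest.approx(5.0)

    def test_matches_brute_force_on_random_peaks(self, rng):
        rows = []
        for _ in range(1000):
            scaffold = str(rng.choice(["s1", "s2"]))
            start = int(rng.integers(0, 2_000_000))
            rows.append((scaffold, start, start + int(rng.integers(100, 1000))))
        regions = stitch_peaks(_peaks(rows))
        got = [(r.interval.scaffold, r.interval.start, r.interval.end,
                len(r.member_ids)) for r in regions]
        assert got == brute_force_chains(rows, 12_500)

    def test_order_independent(self, rng):
        rows = [("s", int(s), int(s) + 200)
                for s in rng.integers(0, 100_000, 50)]
        a = stitch_peaks(_peaks(rows))
        b = stitch_peaks(_peaks(list(reversed(rows))))
        assert [(r.interval.start, r.interval.end) for r in a] == \
               [(r.interval.start, r.interval.end) for r in b]


class TestElbowCutoff:
    def test_quadratic_profile_cuts_at_half(self):
        n = 1001
        x = np.arange(n) / (n - 1)
        threshold, flags = elbow_cutoff(x ** 2)
        # tangent slope 1 at x = 0.5 -> cutoff at scaled rank 0.5 +/- one rank
        cut_rank = (~flags).sum() / n
        assert abs(cut_rank - 0.5) <= 1.5 / n
        assert threshold == pytest.approx(0.25, abs=0.01)

    def test_two_population_recovery(self, rng):
        background = rng.exponential(1.0, 800)
        clusters = rng.exponential(1.0, 60) + 20.0
        signals = np.concatenate([background, clusters])
        _, flags = elbow_cutoff(signals)
        assert flags[800:].mean() >= 0.95

    def test_linear_profile_degenerate(self):
        with pytest.warns(UserWarning, match="no slope-1 inflection"):
            _, flags = elbow_cutoff(np.linspace(0, 1, 100))
        assert not flags.any()

    def test_all_equal_degenerate(self):
        with pytest.warns(UserWarning, match="all region signals equal"):
            _, flags = elbow_cutoff(np.full(10, 3.0))
        assert not flags.any()

    def test_too_few_regions(self):
        with pytest.raises(ValueError):
            elbow_cutoff([1.0, 2.0])


class TestCatalog:
    def _stage_peaks(self, offset=0, n_strong=3):
        rows, signals = [], []
        for i in range(n_strong):
            rows.append(("s", offset + i * 1_000, offset + i * 1_000 + 500))
            signals.append(50.0)
        for i in range(20):
            rows.append(("s", 500_000 + i * 50_000, 500_000 + i * 50_000 + 500))
            signals.append(1.0)
        return _peaks(rows, extra=signals)

    def test_single_stage_total_equals_own_ecs(self):
        catalog = build_catalog({"9": self._stage_peaks()})
        assert catalog.coverage["9"] == pytest.approx(1.0)
        assert catalog.total_region == [
            r.interval for r in catalog.per_stage["9"] if r.is_ec
        ]

    def test_disjoint_second_stage_dilutes_coverage(self):
        catalog = build_catalog({
            "9": self._stage_peaks(0),
            "10.5": self._stage_peaks(100_000),
        })
        assert catalog.coverage["9"] < 1.0
        assert catalog.coverage["10.5"] < 1.0

    def test_coverage_equals_brute_force_bp(self):
        catalog = build_catalog({
            "9": self._stage_peaks(0),
            "10.5": self._stage_peaks(1_000),
        })
        total_bp = sum(len(iv) for iv in catalog.total_region)
        for stage in ("9", "10.5"):
            ecs = catalog.ec_regions(stage)
            bp = 0
            for iv in catalog.total_region:
                base = np.zeros(len(iv), dtype=bool)
                for e in ecs:
                    if e.scaffold != iv.scaffold:
                        continue
                    lo = max(e.start, iv.start) - iv.start
                    hi = min(e.end, iv.end) - iv.start
                    if hi > lo:
                        base[lo:hi] = True
                bp += int(base.sum())
            assert catalog.coverage[stage] == pytest.approx(bp / total_bp)


class TestSeeding:
    def test_mad_seed_dominates(self):
        catalog = build_catalog({"9": TestCatalog()._stage_peaks()})
        early = pd.DataFrame({
            "scaffold": ["s"], "start": [100], "end": [300], "label": ["MaD"],
        })
        rec = seeding_analysis(catalog, early)
        assert rec.loc[0, "seeding_class"] == "MaD-seeded"

    def test_no_early_peak_unseeded(self):
        catalog = build_catalog({"9": TestCatalog()._stage_peaks()})
        early = pd.DataFrame({
            "scaffold": ["s"], "start": [900_000], "end": [900_100],
            "label": ["MaD"],
        })
        rec = seeding_analysis(catalog, early)
        assert rec.loc[0, "seeding_class"] == "unseeded"

    def test_simulated_seed_always_in_total_region(self, sim_config):
        frames, truth = simulate_p300_stages(sim_config)
        catalog = build_catalog(frames)
        last = frames["30"]
        for ci, seed_id in truth.ec_seed_peaks.items():
            row = last.loc[seed_id]
            hit = any(
                iv.scaffold == row["scaffold"]
                and row["start"] < iv.end and iv.start < row["end"]
                for iv in catalog.total_region
            )
            assert hit, f"seed of planted cluster {ci} outside total region"


def hypergeom_oracle(N, K, n, k_obs, tail):
    """Exact enumeration via binomial coefficients."""
    denom = math.comb(N, n)
    ks = range(k_obs, min(K, n) + 1) if tail == "over" else range(0, k_obs + 1)
    return sum(
        math.comb(K, k) * math.comb(N - K, n - k) for k in ks
        if n - k <= N - K
    ) / denom


class TestHypergeom:
    def test_worked_example(self):
        p = hypergeom_enrichment(20, 5, 5, 5)
        assert p["p_over"] == pytest.approx(1 / 15504, abs=1e-12)

    def test_matches_enumeration_for_small_populations(self):
        for N in range(1, 31, 3):
            for K in range(0, N + 1, 3):
                for n in range(0, N + 1, 3):
                    for k in range(max(0, n + K - N), min(K, n) + 1):
                        p = hypergeom_enrichment(N, K, n, k)
                        assert p["p_over"] == pytest.approx(
                            hypergeom_oracle(N, K, n, k, "over"), abs=1e-12)
                        assert p["p_under"] == pytest.approx(
                            hypergeom_oracle(N, K, n, k, "under"), abs=1e-12)

    def test_proportional_class_not_enriched(self):
        # 10 of 100 peaks in ECs; a 20-peak class with exactly 2 in ECs
        p = hypergeom_enrichment(100, 10, 20, 2)
        assert p["p_over"] >= 0.5


class TestLabelFractions:
    def test_no_peaks_in_ecs(self):
        catalog = build_catalog({"9": TestCatalog()._stage_peaks()})
        peaks = pd.DataFrame({
            "scaffold": ["s"] * 4, "start": [900_000 + i * 10_000 for i in range(4)],
            "end": [900_100 + i * 10_000 for i in range(4)],
            "label": ["MaD", "MaD", "ZyD", "ZyD"],
        })
        out = label_fraction_in_ecs(peaks, catalog)
        assert (out["fraction_in_ec"] == 0).all()
        assert np.allclose(out["p_over"], 1.0)


class TestComposition:
    def test_fully_tiled_by_zyd(self):
        catalog = build_catalog({"9": TestCatalog()._stage_peaks()})
        iv = catalog.total_region[0]
        peaks = pd.DataFrame({
            "scaffold": [iv.scaffold], "start": [iv.start - 100],
            "end": [iv.end + 100], "label": ["ZyD"],
        })
        comp = ec_madzyd_composition(catalog, peaks)
        assert comp.loc[0, "ZyD_fraction"] == pytest.approx(1.0)
        assert comp.loc[0, "MaD_fraction"] == 0.0

    def test_overlapping_same_label_peaks_not_double_counted(self):
        catalog = build_catalog({"9": TestCatalog()._stage_peaks()})
        iv = catalog.total_region[0]
        half = iv.start + len(iv) // 2
        peaks = pd.DataFrame({
            "scaffold": [iv.scaffold] * 2,
            "start": [iv.start, iv.start],
            "end": [half, half],
            "label": ["MaD", "MaD"],
        })
        comp = ec_madzyd_composition(catalog, peaks)
        assert comp.loc[0, "MaD_fraction"] == pytest.approx(
            (half - iv.start) / len(iv))

    def test_quartiles_match_numpy(self, rng):
        comp = pd.DataFrame({
            "MaD_fraction": rng.random(30), "ZyD_fraction": rng.random(30),
        })
        q = composition_quartiles(comp)
        assert q["MaD"]["median"] == pytest.approx(
            float(np.median(comp["MaD_fraction"])))


class TestNearestGene:
    def test_tss_inside_ec(self):
        ec = GenomicInterval("s", 1000, 2000)
        genes, d = nearest_gene(ec, [TSSRecord("g", "s", 1500, "+")])
        assert genes == ["g"] and d == 0

    def test_closest_wins(self):
        ec = GenomicInterval("s", 10_000, 11_000)
        genes, d = nearest_gene(ec, [
            TSSRecord("near", "s", 9_000, "+"),
            TSSRecord("far", "s", 16_000, "+"),
        ])
        assert genes == ["near"] and d == 1000

    def test_no_tss_on_scaffold(self):
        ec = GenomicInterval("s", 0, 100)
        genes, d = nearest_gene(ec, [TSSRecord("g", "other", 50, "+")])
        assert genes == [] and math.isnan(d)
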