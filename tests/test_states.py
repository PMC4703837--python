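import numpy as np
import pandas as pd
import pytest

from madzyd.simulate import (SimulationConfig, default_transition_matrix,
                             simulate_state_segmentations)
from madzyd.states import (STATE_GROUPS, UNMODIFIED, bin_segmentation,
                           build_state_matrix, coverage_per_stage,
                           flows_to_json, modified_genome_mask,
                           transition_flows)


def _seg(rows):
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "state"])


class TestBinSegmentation:
    LENGTHS = {"s": 2000}

    def test_whole_interval_bins(self):
        labels = bin_segmentation(_seg([("s", 0, 600, "Polycomb")]), self.LENGTHS)
        assert [STATE_GROUPS[i] for i in labels[:3]] == ["Polycomb"] * 3
        assert all(STATE_GROUPS[i] == UNMODIFIED for i in labels[3:])

    def test_majority_rule(self):
        # 150 bp Promoter vs 50 bp Polycomb in the first bin
        labels = bin_segmentation(
            _seg([("s", 0, 150, "Promoter"), ("s", 150, 200, "Polycomb")]),
            self.LENGTHS,
        )
        assert STATE_GROUPS[labels[0]] == "Promoter"

    def test_tie_breaks_to_earlier_listed_state(self):
        # exactly 100/100: Polycomb precedes Promoter in the group order
        labels = bin_segmentation(
            _seg([("s", 0, 100, "Promoter"), ("s", 100, 200, "Polycomb")]),
            self.LENGTHS,
        )
        assert STATE_GROUPS[labels[0]] == "Polycomb"

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            bin_segmentation(
                _seg([("s", 0, 300, "Promoter"), ("s", 200, 400, "Polycomb")]),
                self.LENGTHS,
            )

    def test_matches_per_base_majority_oracle(self, rng):
        length = 4000
        cuts = np.sort(rng.choice(np.arange(1, length), 15, replace=False))
        bounds = [0, *cuts.tolist(), length]
        rows = []
        base = np.full(length, STATE_GROUPS.index(UNMODIFIED))
        for a, b in zip(bounds[:-1], bounds[1:]):
            state = STATE_GROUPS[int(rng.integers(0, len(STATE_GROUPS)))]
            if state != UNMODIFIED:
                rows.append(("s", a, b, state))
                base[a:b] = STATE_GROUPS.index(state)
        labels = bin_segmentation(_seg(rows), {"s": length})
        for b in range(length // 200):
            counts = np.bincount(base[b * 200:(b + 1) * 200],
                                 minlength=len(STATE_GROUPS))
            assert labels[b] == int(np.argmax(counts))


class TestStateMatrix:
    def _matrix(self):
        segs = {
            "9": _seg([("s", 0, 400, "Promoter")]),
            "10.5": _seg([("s", 200, 400, "Polycomb")]),
        }
        return build_state_matrix(segs, {"s": 1000})

    def test_mask_any_stage(self):
        m = self._matrix()
        mask = modified_genome_mask(m)
        # bins 0-1 modified at stage 9; bin 1 also at 10.5; bins 2-4 never
        assert mask.tolist() == [True, True, False, False, False]

    def test_bin_modified_only_at_last_stage_included(self):
        segs = {
            "9": _seg([("s", 0, 200, "Promoter")]),
            "30": _seg([("s", 800, 1000, "Polycomb")]),
        }
        m = build_state_matrix(segs, {"s": 1000})
        mask = modified_genome_mask(m)
        assert mask[4]

    def test_coverage_sums_to_one(self):
        m = self._matrix()
        cov = coverage_per_stage(m, modified_genome_mask(m))
        np.testing.assert_allclose(cov.sum(axis=0), 1.0)

    def test_single_state_stage(self):
        segs = {"9": _seg([("s", 0, 1000, "Enhancer")])}
        m = build_state_matrix(segs, {"s": 1000})
        cov = coverage_per_stage(m, modified_genome_mask(m))
        assert cov.loc["Enhancer", "9"] == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        segs = {"9": _seg([])}
        m = build_state_matrix(segs, {"s": 1000})
        with pytest.raises(ValueError, match="empty"):
            coverage_per_stage(m, modified_genome_mask(m))


class TestTransitionFlows:
    def test_single_bin_flow_in_bp(self):
        segs = {
            "9": _seg([("s", 0, 200, "Promoter")]),
            "10.5": _seg([("s", 0, 200, "Polycomb")]),
        }
        m = build_state_matrix(segs, {"s": 1000})
        flows = transition_flows(m, modified_genome_mask(m))
        df = flows[("9", "10.5")]
        assert df.loc["Promoter", "Polycomb"] == 200
        assert df.to_numpy().sum() == 200

    def test_identity_matrix_diagonal_flows(self):
        seg = _seg([("s", 0, 600, "Transcribed")])
        m = build_state_matrix({"9": seg, "10.5": seg, "12.5": seg}, {"s": 1000})
        flows = transition_flows(m, modified_genome_mask(m))
        for df in flows.values():
            off_diag = df.to_numpy() - np.diag(np.diag(df.to_numpy()))
            assert off_diag.sum() == 0

    def test_conservation_against_coverage(self, sim_config):
        segs, lengths, _ = simulate_state_segmentations(sim_config)
        m = build_state_matrix(segs, lengths)
        mask = modified_genome_mask(m)
        cov = coverage_per_stage(m, mask)
        flows = transition_flows(m, mask)
        total_bp = int(m.widths()[mask].sum())
        for j, (pair, df) in enumerate(flows.items()):
            outflow = df.sum(axis=1) / total_bp
            np.testing.assert_allclose(outflow.to_numpy(),
                                       cov[pair[0]].to_numpy(), atol=1e-12)
            inflow = df.sum(axis=0) / total_bp
            np.testing.assert_allclose(inflow.to_numpy(),
                                       cov[pair[1]].to_numpy(), atol=1e-12)

    def test_matches_brute_force_pair_counting(self, rng):
        n = 300
        labels = rng.integers(0, len(STATE_GROUPS), size=(n, 2)).astype(np.int8)
        bins = pd.DataFrame({"scaffold": "s", "start": np.arange(n) * 200,
                             "end": (np.arange(n) + 1) * 200})
        from madzyd.states import StateMatrix
        m = StateMatrix(bins=bins, stages=["9", "10.5"], labels=labels)
        mask = modified_genome_mask(m)
        flows = transition_flows(m, mask)[("9", "10.5")]
        for i, s in enumerate(STATE_GROUPS):
            for j, t in enumerate(STATE_GROUPS):
                expected = 200 * int(
                    ((labels[mask, 0] == i) & (labels[mask, 1] == j)).sum()
                )
                assert flows.loc[s, t] == expected

    def test_focus_restriction(self):
        segs = {
            "9": _seg([("s", 0, 200, "Promoter"), ("s", 200, 400, "Enhancer")]),
            "10.5": _seg([("s", 0, 200, "Polycomb"), ("s", 200, 400, "Enhancer")]),
        }
        m = build_state_matrix(segs, {"s": 400})
        flows = transition_flows(m, modified_genome_mask(m),
                                 focus={"Promoter"})
        df = flows[("9", "10.5")]
        assert df.loc["Promoter", "Polycomb"] == 200
        assert df.loc["Enhancer", "Enhancer"] == 0  # not touching focus


class TestSimulatedSegmentations:
    def test_identity_transition_matrix_freezes_states(self):
        cfg = SimulationConfig(seed=3, n_state_bins=500)
        identity = np.eye(len(STATE_GROUPS))
        segs, lengths, truth = simulate_state_segmentations(
            cfg, transition_matrices=[identity] * (len(cfg.state_stages) - 1)
        )
        assert (truth.state_tracks == truth.state_tracks[:, [0]]).all()

    def test_absorbing_unmodified_non_increasing_coverage(self):
        cfg = SimulationConfig(seed=3, n_state_bins=2000)
        k = len(STATE_GROUPS)
        T = default_transition_matrix(cfg)
        u = STATE_GROUPS.index(UNMODIFIED)
        T[u] = 0.0
        T[u, u] = 1.0
        segs, lengths, truth = simulate_state_segmentations(
            cfg, transition_matrices=[T] * (len(cfg.state_stages) - 1)
        )
        modified = (truth.state_tracks != u).sum(axis=0)
        # unmodified is absorbing: the modified-genome size cannot grow
        assert (np.diff(modified) <= 0).all()

    def test_invalid_transition_rows_rejected(self):
        cfg = SimulationConfig(seed=3, n_state_bins=100)
        bad = np.full((len(STATE_GROUPS), len(STATE_GROUPS)), 0.1)
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_state_segmentations(
                cfg, transition_matrices=[bad] * (len(cfg.state_stages) - 1)
            )

    def test_empirical_frequencies_match_matrix(self):
        cfg = SimulationConfig(seed=13, n_state_bins=100_000)
        T = default_transition_matrix(cfg)
        segs, lengths, truth = simulate_state_segmentations(cfg)
        src = truth.state_tracks[:, 0]
        dst = truth.state_tracks[:, 1]
        n_within3 = n_cells = 0
        for i in range(len(STATE_GROUPS)):
            n_i = int((src == i).sum())
            if n_i < 500:
                continue
            for j in range(len(STATE_GROUPS)):
                phat = ((src == i) & (dst == j)).sum() / n_i
                se = np.sqrt(T[i, j] * (1 - T[i, j]) / n_i)
                # every cell within 4 SE; the vast majority within 3 SE
                # (a strict per-cell 3-SE bound over 49 cells would fail
                # by multiplicity about one run in eight)
                assert abs(phat - T[i, j]) <= 4 * se + 1e-9
                n_cells += 1
                n_within3 += abs(phat - T[i, j]) <= 3 * se + 1e-9
        assert n_within3 >= 0.93 * n_cells

    def test_binning_recovers_simulated_labels_exactly(self):
        cfg = SimulationConfig(seed=5, n_state_bins=3000)
        segs, lengths, truth = simulate_state_segmentations(cfg)
        m = build_state_matrix(segs, lengths, bin_size=cfg.state_bin_size)
        np.testing.assert_array_equal(m.labels, truth.state_tracks)

    def test_flows_json_structure(self, sim_config):
        segs, lengths, _ = simulate_state_segmentations(sim_config)
        m = build_state_matrix(segs, lengths)
        mask = modified_genome_mask(m)
        js = flows_to_json(transition_flows(m, mask))
        assert js["bp_per_bin"] == 200
        assert all({"source", "target", "bp"} <= set(l) for l in js["links"])
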