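"""Chromatin-state dynamics: 200-bp state matrix, coverage and flows.

Per-stage chromatin-state segmentations (BED with a state label per
interval) are binned at 200 bp into an m x n matrix a(i, j): the state of
bin i at stage j. The "modified genome" mask keeps bins that carry a
non-unmodified state at any stage; state coverage per stage and
stage-to-stage transition flows (the numbers behind Sankey/alluvial
plots) are measured on that mask. Flows are reported in bp (bins times
bin size, with short terminal bins counted at their true width);
conservation — outflows of a state reconcile exactly with its coverage at
the earlier stage — is asserted on every run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The seven main chromatin-state groups (Unmodified included).
STATE_GROUPS = (
    "Polycomb",
    "Poised",
    "Enhancer",
    "Transcribed",
    "Promoter",
    "Heterochromatin",
    "Unmodified",
)
UNMODIFIED = "Unmodified"


@dataclass
class StateMatrix:
    """Binned state labels: bins (scaffold, start, end) x ordered stages."""

    bins: pd.DataFrame  # scaffold, start, end
    stages: list
    labels: np.ndarray  # (n_bins, n_stages) small ints into ``states``
    states: tuple = STATE_GROUPS

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def widths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy()


def make_bins(scaffold_lengths: dict, bin_size: int = 200) -> pd.DataFrame:
    rows = []
    for scaffold, length in scaffold_lengths.items():
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame(
            {"scaffold": scaffold, "start": starts, "end": ends}
        ))
    return pd.concat(rows, ignore_index=True)


def bin_segmentation(segmentation: pd.DataFrame, scaffold_lengths: dict,
                     bin_size: int = 200,
                     states: tuple = STATE_GROUPS) -> np.ndarray:
    """Majority-label state per bin; unannotated bases are Unmodified.

    Each bin takes the state covering the majority of its bases; ties go
    to the state listed earlier in ``states``. Overlapping segmentation
    intervals are an error.
    """
    state_index = {s: i for i, s in enumerate(states)}
    unmod = state_index[UNMODIFIED]
    bins = make_bins(scaffold_lengths, bin_size)
    out = np.full(len(bins), unmod, dtype=np.int8)
    offsets = {}
    pos = 0
    for scaffold, length in scaffold_lengths.items():
        offsets[scaffold] = pos
        pos += int(np.ceil(length / bin_size))

    for scaffold, group in segmentation.groupby("scaffold"):
        if scaffold not in scaffold_lengths:
            continue
        g = group.sort_values("start")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(
                f"overlapping segmentation intervals on {scaffold}"
            )
        length = scaffold_lengths[scaffold]
        n_bins = int(np.ceil(length / bin_size))
        # per-bin bp per state, filled interval by interval
        cover = np.zeros((n_bins, len(states)), dtype=np.int32)
        for s, e, st in zip(starts, ends, g["state"]):
            if st not in state_index:
                raise ValueError(f"unknown state label {st!r}")
            si = state_index[st]
            b0, b1 = int(s) // bin_size, int(np.ceil(e / bin_size))
            for b in range(b0, b1):
                lo, hi = b * bin_size, min((b + 1) * bin_size, length)
                ov = min(e, hi) - max(s, lo)
                if ov > 0:
                    cover[b, si] += ov
        widths = np.minimum(
            (np.arange(n_bins) + 1) * bin_size, length
        ) - np.arange(n_bins) * bin_size
        cover[:, unmod] += (widths - cover.sum(axis=1)).astype(np.int32)
        # argmax takes the earlier-listed state on ties
        out[offsets[scaffold]:offsets[scaffold] + n_bins] = np.argmax(
            cover, axis=1
        ).astype(np.int8)
    return out


def build_state_matrix(segmentations: dict, scaffold_lengths: dict,
                       bin_size: int = 200,
                       states: tuple = STATE_GROUPS) -> StateMatrix:
    """Stack per-stage binned segmentations into a StateMatrix.

    ``segmentations`` maps stage token -> segmentation BED frame; stage
    order follows the mapping's insertion order.
    """
    if not segmentations:
        raise ValueError("need at least one stage segmentation")
    stages = list(segmentations)
    bins = make_bins(scaffold_lengths, bin_size)
    labels = np.stack(
        [
            bin_segmentation(segmentations[st], scaffold_lengths, bin_size, states)
            for st in stages
        ],
        axis=1,
    )
    return StateMatrix(bins=bins, stages=stages, labels=labels, states=states)


def modified_genome_mask(matrix: StateMatrix) -> np.ndarray:
    """Bins carrying a non-Unmodified state at any stage."""
    unmod = matrix.states.index(UNMODIFIED)
    return (matrix.labels != unmod).any(axis=1)


def coverage_per_stage(matrix: StateMatrix, mask: np.ndarray) -> pd.DataFrame:
    """Fraction of the modified genome in each state, per stage.

    Fractions are bp-weighted and sum to 1 within each stage.
    """
    if not mask.any():
        raise ValueError("modified-genome mask is empty")
    widths = matrix.widths()[mask]
    total = widths.sum()
    cov = pd.DataFrame(
        0.0, index=list(matrix.states), columns=matrix.stages
    )
    for j, stage in enumerate(matrix.stages):
        lab = matrix.labels[mask, j]
        for i, state in enumerate(matrix.states):
            cov.loc[state, stage] = widths[lab == i].sum() / total
    return cov


def transition_flows(matrix: StateMatrix, mask: np.ndarray,
                     focus: set | None = None) -> dict:
    """bp flows between states for each consecutive stage pair.

    Returns ``{(stage_n, stage_n+1): DataFrame}`` with source states as
    rows and target states as columns, restricted to the modified-genome
    mask. With ``focus`` given, only flows touching a focus state are kept
    (rows/columns not touching it are zeroed). Conservation against
    per-stage coverage is asserted exactly before any focus restriction.
    """
    if len(matrix.stages) < 2:
        raise ValueError("need at least two stages for flows")
    widths = matrix.widths()[mask]
    total = widths.sum()
    n_states = len(matrix.states)
    out = {}
    for j in range(len(matrix.stages) - 1):
        src = matrix.labels[mask, j].astype(np.int64)
        dst = matrix.labels[mask, j + 1].astype(np.int64)
        flow = np.zeros((n_states, n_states), dtype=np.int64)
        np.add.at(flow, (src, dst), widths)
        # conservation: outflows of s == coverage of s at stage j (in bp)
        per_state_bp = np.bincount(src, weights=widths, minlength=n_states)
        assert np.array_equal(flow.sum(axis=1), per_state_bp.astype(np.int64))
        assert flow.sum() == total
        df = pd.DataFrame(flow, index=list(matrix.states),
                          columns=list(matrix.states))
        if focus is not None:
            keep = np.zeros_like(flow, dtype=bool)
            for s in focus:
                i = matrix.states.index(s)
                keep[i, :] = True
                keep[:, i] = True
            df = df.where(pd.DataFrame(keep, index=df.index,
                                       columns=df.columns), 0)
        out[(matrix.stages[j], matrix.stages[j + 1])] = df
    return out


def flows_to_json(flows: dict, bin_size: int = 200) -> dict:
    """Sankey-renderer-ready structure: nodes = state@stage, links in bp."""
    nodes = []
    links = []
    for (s_from, s_to), df in flows.items():
        for state in df.index:
            for node in (f"{state}@{s_from}", f"{state}@{s_to}"):
                if node not in nodes:
                    nodes.append(node)
        for src in df.index:
            for dst in df.columns:
                bp = int(df.loc[src, dst])
                if bp > 0:
                    links.append({
                        "source": f"{src}@{s_from}",
                        "target": f"{dst}@{s_to}",
                        "bp": bp,
                    })
    return {"nodes": nodes, "links": links, "bp_per_bin": bin_size}
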