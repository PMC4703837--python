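"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the study conditions of a transcription-blockade
ChIP experiment at mid-gastrulation: replicate read counts at peaks for
control and alpha-amanitin samples in which a planted fraction of peaks
loses enrichment when transcription is blocked (the zygotically defined
class), a dominant maternally defined class that keeps it, and an
ambiguous class depleted in exactly one replicate (which should end up
ND). Further generators produce a multi-stage p300 landscape with
clustered enhancers, a bimodal promoter methylome coupled to the MaD/ZyD
truth, motif-count/signal matrices driven by a planted activity matrix,
and Markovian per-stage chromatin-state segmentations.

All generators are pure functions of (config, seed); sub-seeds are derived
per generator so partial re-runs are stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .intervals import TSSRecord
from .states import STATE_GROUPS, UNMODIFIED

#: stable sub-seed index per generator
_SUBSEED = {
    "annotation": 1,
    "amanitin": 2,
    "p300": 3,
    "methylome": 4,
    "motifs": 5,
    "states": 6,
    "background": 7,
    "input": 8,
}


def _rng(seed: int, generator: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _SUBSEED[generator]])


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generators.

    Count model defaults reflect the study conditions the classifier is
    meant to operate under: two replicates, negative-binomial counts with
    mean 30 and dispersion 0.1 at true peaks, an 8-fold depletion of the
    alpha-amanitin samples at zygotically defined peaks, and a 60/25/15
    split of maternally defined / zygotically defined / ambiguous peaks
    (the maternal class dominates, as observed for the promoter marks).
    """

    # genome / annotation
    n_scaffolds: int = 2
    scaffold_length: int = 5_000_000
    n_genes: int = 300
    min_gene_spacing: int = 10_000
    # amanitin experiment
    n_peaks: int = 2_000
    fraction_mad: float = 0.60
    fraction_zyd: float = 0.25
    fraction_ambiguous: float = 0.15
    mean_reads_per_peak: float = 30.0
    dispersion: float = 0.1
    depletion_factor: float = 8.0
    n_replicates: int = 2
    peak_width_min: int = 800
    peak_width_max: int = 1_600
    # ln-scale sd of the per-peak strength factor; modest because a merged
    # peak set is left-truncated by the caller's detection floor
    peak_enrichment_sigma: float = 0.3
    mean_background_reads: float = 1.0
    n_background_regions: int = 2_000
    library_size: int = 10_000_000
    input_mean_reads: float = 30.0
    n_hot_input_bins: int = 40
    hot_input_bin_mean: float = 200.0
    # p300 multi-stage landscape
    p300_stages: tuple = ("9", "10.5", "12.5", "16", "30")
    n_clusters: int = 20
    peaks_per_cluster: int = 6
    intra_cluster_spacing: int = 5_000
    n_singletons: int = 200
    cluster_signal_shift: float = 20.0
    p300_peak_width: int = 500
    cluster_zyd_prob: float = 0.85
    singleton_zyd_prob: float = 0.5
    # methylome
    hypo_beta: tuple = (1.0, 19.0)
    hyper_beta: tuple = (12.0, 3.0)
    cpg_coverage_mean: float = 10.0
    cpg_density_hypo: float = 0.05
    cpg_density_hyper: float = 0.015
    promoter_half_width: int = 250
    mad_hypo_coupling: float = 0.85
    zyd_hyper_coupling: float = 0.95
    # motifs
    n_motif_peaks: int = 500
    n_motifs: int = 20
    n_active_motifs: int = 3
    activity_amplitude: float = 0.5
    motif_noise_sd: float = 0.1
    motif_count_mean: float = 2.0
    n_motif_stages: int = 5
    # chromatin states
    state_stages: tuple = ("9", "10.5", "12.5", "16", "30")
    n_state_bins: int = 20_000
    state_bin_size: int = 200
    state_stickiness: float = 0.9
    unmodified_initial: float = 0.6
    # master seed
    seed: int = 0

    def __post_init__(self):
        fracs = (self.fraction_mad, self.fraction_zyd, self.fraction_ambiguous)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise ValueError("class fractions must be in [0,1] and sum to <= 1")
        if self.depletion_factor <= 1:
            raise ValueError("depletion_factor must exceed 1")
        if self.intra_cluster_spacing <= 0 or self.min_gene_spacing <= 0:
            raise ValueError("spacing parameters must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["p300_stages"] = list(self.p300_stages)
        d["state_stages"] = list(self.state_stages)
        d["hypo_beta"] = list(self.hypo_beta)
        d["hyper_beta"] = list(self.hyper_beta)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("p300_stages", "state_stages", "hypo_beta", "hyper_beta"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    peak_labels: pd.Series | None = None  # true MaD/ZyD/ambiguous per peak
    gene_labels: dict = field(default_factory=dict)  # mark -> Series
    promoter_methylation: pd.Series | None = None  # hypo/hyper per gene
    ec_members: dict = field(default_factory=dict)  # cluster id -> peak ids
    ec_seed_peaks: dict = field(default_factory=dict)
    motif_activities: pd.DataFrame | None = None
    state_tracks: np.ndarray | None = None


def _nb_counts(rng, mean, dispersion, size):
    """Negative-binomial counts with variance mean * (1 + dispersion).

    ``dispersion`` is the excess Fano factor of the counts (0 degenerates
    to Poisson); it is mean-free, so replicate noise stays proportional at
    enriched and depleted peaks alike. Means of zero (infinite depletion)
    yield zero counts.
    """
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size).copy()
    out = np.zeros(size, dtype=int)
    pos = mean > 0
    if dispersion == 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    n = mean[pos] / dispersion
    p = 1.0 / (1.0 + dispersion)
    out[pos] = rng.negative_binomial(n, p)
    return out


def simulate_genome_annotation(config: SimulationConfig, seed: int | None = None):
    """Scaffold lengths, TSS records and promoter windows.

    TSSs are placed uniformly with a minimum spacing (uniform placement in
    the gap-reduced coordinate system, then spread back out), deterministic
    given the seed.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "annotation")
    scaffold_lengths = {
        f"scaffold_{i + 1}": config.scaffold_length
        for i in range(config.n_scaffolds)
    }
    per_scaffold = np.full(config.n_scaffolds, config.n_genes // config.n_scaffolds)
    per_scaffold[: config.n_genes % config.n_scaffolds] += 1
    records = []
    gi = 0
    for si, (scaffold, L) in enumerate(scaffold_lengths.items()):
        k = int(per_scaffold[si])
        if k == 0:
            continue
        slack = L - k * config.min_gene_spacing
        if slack <= 0:
            raise ValueError(
                f"cannot place {k} genes with spacing {config.min_gene_spacing} "
                f"on a {L} bp scaffold"
            )
        raw = np.sort(rng.integers(0, slack, size=k))
        tss = raw + np.arange(k) * config.min_gene_spacing
        for t in tss:
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(TSSRecord(f"gene_{gi:05d}", scaffold, int(t), strand))
            gi += 1
    return scaffold_lengths, records


@dataclass
class AmanitinDataset:
    """Peaks with per-sample counts, background counts and the truth."""

    peaks: pd.DataFrame  # peak_id idx; scaffold,start,end,true_label + counts
    background: pd.DataFrame  # scaffold,start,end + counts per sample
    samples: list
    library_sizes: dict
    truth: GroundTruth


AMANITIN_SAMPLES = ["ctrl_rep1", "ctrl_rep2", "aman_rep1", "aman_rep2", "reference"]


def simulate_amanitin_experiment(config: SimulationConfig,
                                 seed: int | None = None) -> AmanitinDataset:
    """Replicate ChIP counts for control and transcription-blocked embryos.

    True-ZyD peaks have their alpha-amanitin mean divided by the depletion
    factor in both replicates; ambiguous peaks are depleted in exactly one
    (randomly chosen) replicate; maternally defined peaks are not depleted.
    A ``reference`` sample emulates the earlier reference stage at which
    all true peaks are enriched. Background regions receive low counts
    (mean ``mean_background_reads``).
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "amanitin")
    n = config.n_peaks
    n_mad = int(round(n * config.fraction_mad))
    n_zyd = int(round(n * config.fraction_zyd))
    n_amb = int(round(n * config.fraction_ambiguous))
    n_mad += n - n_mad - n_zyd - n_amb  # remainder folds into the MaD class
    labels = np.array(
        ["MaD"] * n_mad + ["ZyD"] * n_zyd + ["ambiguous"] * n_amb
    )
    rng.shuffle(labels)

    scaffold_lengths, tss_records = simulate_genome_annotation(config, seed)
    names = list(scaffold_lengths)
    widths = rng.integers(config.peak_width_min, config.peak_width_max + 1, n)
    # the first peaks sit on gene promoters (centered on the TSS) so that
    # gene-level classification and the methylome coupling have substance;
    # the rest are distal
    n_promoter = min(len(tss_records), n)
    scaffolds = []
    starts = np.empty(n, dtype=int)
    gene_ids = []
    for i in range(n):
        if i < n_promoter:
            rec = tss_records[i]
            scaffolds.append(rec.scaffold)
            starts[i] = max(0, rec.tss - int(widths[i]) // 2)
            gene_ids.append(rec.gene_id)
        else:
            s = names[int(rng.integers(0, len(names)))]
            scaffolds.append(s)
            starts[i] = int(rng.integers(0, scaffold_lengths[s] - int(widths[i])))
            gene_ids.append("")
    # per-peak expected counts: proportional to width, with a log-normal
    # per-peak enrichment strength shared across samples (real peak
    # landscapes span a wide signal range; M is unaffected since the
    # factor cancels between samples, and the across-peak mean stays
    # ``mean_reads_per_peak``)
    mean_width = 0.5 * (config.peak_width_min + config.peak_width_max)
    sigma = config.peak_enrichment_sigma
    strength = rng.lognormal(-0.5 * sigma ** 2, sigma, n) if sigma > 0 else 1.0
    mu = config.mean_reads_per_peak * (widths / mean_width) * strength
    dep = config.depletion_factor
    mu_dep = np.zeros(n) if math.isinf(dep) else mu / dep

    counts = {}
    for rep in (1, 2):
        counts[f"ctrl_rep{rep}"] = _nb_counts(rng, mu, config.dispersion, n)
    amb_dep_rep = rng.integers(1, 3, n)  # which replicate is depleted
    for rep in (1, 2):
        means = mu.copy()
        means[labels == "ZyD"] = mu_dep[labels == "ZyD"]
        amb = (labels == "ambiguous") & (amb_dep_rep == rep)
        means[amb] = mu_dep[amb]
        counts[f"aman_rep{rep}"] = _nb_counts(rng, means, config.dispersion, n)
    counts["reference"] = _nb_counts(rng, mu, config.dispersion, n)

    peaks = pd.DataFrame({
        "scaffold": scaffolds,
        "start": starts,
        "end": starts + widths,
        "gene_id": gene_ids,
        "true_label": labels,
        **counts,
    })
    peaks.index = [f"peak_{i:05d}" for i in range(n)]
    peaks.index.name = "peak_id"

    # gene-level truth: a gene inherits the true class of its promoter peak
    gene_truth = pd.Series(
        {g: l for g, l in zip(gene_ids, labels) if g},
        name="true_gene_label",
    )

    bg_rng = _rng(seed, "background")
    m = config.n_background_regions
    bg_widths = bg_rng.choice(widths, size=m)
    bg_scaff = bg_rng.integers(0, len(names), m)
    bg_starts = np.array([
        bg_rng.integers(0, scaffold_lengths[names[s]] - w)
        for s, w in zip(bg_scaff, bg_widths)
    ])
    bg = pd.DataFrame({
        "scaffold": [names[s] for s in bg_scaff],
        "start": bg_starts,
        "end": bg_starts + bg_widths,
    })
    bg_rate = config.mean_background_reads / mean_width
    for sample in AMANITIN_SAMPLES:
        bg[sample] = _nb_counts(
            bg_rng, bg_rate * bg_widths, config.dispersion, m
        )

    truth = GroundTruth(peak_labels=peaks["true_label"].copy(),
                        gene_labels={"synthetic": gene_truth})
    return AmanitinDataset(
        peaks=peaks,
        background=bg,
        samples=list(AMANITIN_SAMPLES),
        library_sizes={s: config.library_size for s in AMANITIN_SAMPLES},
        truth=truth,
    )


def simulate_input_track(config: SimulationConfig, seed: int | None = None,
                         bin_size: int = 1000) -> pd.DataFrame:
    """Input (chromatin) read counts in 1-kb bins as a bedGraph frame.

    Most bins carry Poisson counts around ``input_mean_reads``; a handful
    of "hot" bins (copy-number/mapping artifacts) carry much higher counts
    and should trip the high-input exclusion filter.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "input")
    scaffold_lengths, _ = simulate_genome_annotation(config, seed)
    frames = []
    for scaffold, L in scaffold_lengths.items():
        starts = np.arange(0, L, bin_size)
        ends = np.minimum(starts + bin_size, L)
        values = rng.poisson(config.input_mean_reads, size=starts.size)
        frames.append(pd.DataFrame({
            "scaffold": scaffold, "start": starts, "end": ends,
            "value": values,
        }))
    track = pd.concat(frames, ignore_index=True)
    hot = rng.choice(len(track), size=min(config.n_hot_input_bins, len(track)),
                     replace=False)
    track.loc[hot, "value"] = rng.poisson(config.hot_input_bin_mean,
                                          size=hot.size)
    return track


def simulate_p300_stages(config: SimulationConfig, seed: int | None = None):
    """Multi-stage p300 peak landscape with planted enhancer clusters.

    Each cluster is seeded by one peak at the earliest stage; member peaks
    (inter-peak gap = intra_cluster_spacing) accrue at later stages, so
    cluster genomic coverage grows during development. Isolated singleton
    peaks (>= 25 kb from anything) are scattered at every stage. Cluster
    members carry signal shifted up by ``cluster_signal_shift`` over the
    Exp(1) singleton background.

    Returns (per_stage dict of peak frames, GroundTruth with ec_members /
    ec_seed_peaks).
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "p300")
    stages = list(config.p300_stages)
    w = config.p300_peak_width
    gap = config.intra_cluster_spacing
    span = config.peaks_per_cluster * w + (config.peaks_per_cluster - 1) * gap
    scaffold_lengths, _ = simulate_genome_annotation(config, seed)
    names = list(scaffold_lengths)
    if span >= min(scaffold_lengths.values()):
        raise ValueError("cluster footprint exceeds scaffold length")

    # sequential layout: anchors separated by > 25 kb (double the stitch
    # distance) so distinct entities are never stitched together
    isolation = 26_000
    cluster_anchors: list[tuple[str, int]] = []
    singleton_anchors: list[tuple[str, int]] = []
    si = 0
    cursor = 1_000
    for _ in range(config.n_clusters):
        if cursor + span + isolation > scaffold_lengths[names[si]]:
            si += 1
            cursor = 1_000
            if si >= len(names):
                raise ValueError("too many clusters for the genome size")
        cluster_anchors.append((names[si], cursor))
        cursor += span + isolation
    for _ in range(config.n_singletons):
        if cursor + w + isolation > scaffold_lengths[names[si]]:
            si += 1
            cursor = 1_000
            if si >= len(names):
                raise ValueError("too many singletons for the genome size")
        singleton_anchors.append((names[si], cursor))
        cursor += w + isolation

    ec_members: dict[int, list[str]] = {}
    ec_seeds: dict[int, str] = {}
    per_stage = {st: [] for st in stages}
    for ci, (scaffold, pos) in enumerate(cluster_anchors):
        member_positions = [pos + k * (w + gap) for k in range(config.peaks_per_cluster)]
        ids = [f"ec{ci:03d}_p{k}" for k in range(config.peaks_per_cluster)]
        ec_members[ci] = ids
        ec_seeds[ci] = ids[0]
        member_labels = [
            "ZyD" if rng.random() < config.cluster_zyd_prob else "MaD"
            for _ in ids
        ]
        # members appear cumulatively: seed at the first stage, all present
        # by the last stage
        for sj, st in enumerate(stages):
            n_present = 1 + int(round(
                (config.peaks_per_cluster - 1) * sj / max(len(stages) - 1, 1)
            ))
            for k in range(n_present):
                per_stage[st].append({
                    "peak_id": ids[k], "scaffold": scaffold,
                    "start": member_positions[k],
                    "end": member_positions[k] + w,
                    "signal": config.cluster_signal_shift + rng.exponential(1.0),
                    "is_cluster_member": True, "cluster_id": ci,
                    "label": member_labels[k],
                })
    for si, (scaffold, pos) in enumerate(singleton_anchors):
        label = "ZyD" if rng.random() < config.singleton_zyd_prob else "MaD"
        for st in stages:
            per_stage[st].append({
                "peak_id": f"single{si:04d}", "scaffold": scaffold,
                "start": pos, "end": pos + w,
                "signal": rng.exponential(1.0),
                "is_cluster_member": False, "cluster_id": -1,
                "label": label,
            })
    frames = {
        st: pd.DataFrame(rows).set_index("peak_id").sort_values(
            ["scaffold", "start"]
        )
        for st, rows in per_stage.items()
    }
    truth = GroundTruth(ec_members=ec_members, ec_seed_peaks=ec_seeds)
    return frames, truth


def simulate_methylome(config: SimulationConfig, seed: int | None = None,
                       gene_labels: pd.Series | None = None):
    """Per-CpG methylation calls with bimodal promoter truth.

    Hypomethylated promoters draw per-CpG methylation fractions from a
    low-mode Beta and carry a higher CpG density; hypermethylated promoters
    use the high-mode Beta. Coverage is Poisson. When ``gene_labels``
    (MaD/ZyD per gene) is given, methylation class is coupled to it:
    MaD -> hypo with probability ``mad_hypo_coupling``, ZyD -> hyper with
    ``zyd_hyper_coupling``; otherwise classes are assigned 50/50.

    Returns (cpg table, promoter truth Series hypo/hyper, tss records).
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "methylome")
    _, tss_records = simulate_genome_annotation(config, seed)
    classes = {}
    for rec in tss_records:
        if gene_labels is not None and rec.gene_id in gene_labels.index:
            lab = gene_labels.loc[rec.gene_id]
            if lab == "MaD":
                hypo = rng.random() < config.mad_hypo_coupling
            elif lab == "ZyD":
                hypo = rng.random() >= config.zyd_hyper_coupling
            else:
                hypo = rng.random() < 0.5
        else:
            hypo = rng.random() < 0.5
        classes[rec.gene_id] = "hypo" if hypo else "hyper"

    width = 2 * config.promoter_half_width
    rows = []
    for rec in tss_records:
        cls = classes[rec.gene_id]
        density = (config.cpg_density_hypo if cls == "hypo"
                   else config.cpg_density_hyper)
        a, b = config.hypo_beta if cls == "hypo" else config.hyper_beta
        n_cpg = rng.poisson(density * width)
        if n_cpg == 0:
            continue
        positions = np.sort(rng.choice(width, size=min(n_cpg, width),
                                       replace=False))
        for p in positions:
            frac = rng.beta(a, b)
            total = int(rng.poisson(config.cpg_coverage_mean))
            meth = int(rng.binomial(total, frac)) if total else 0
            rows.append((rec.scaffold,
                         rec.tss - config.promoter_half_width + int(p),
                         meth, total))
    cpg = pd.DataFrame(rows, columns=["scaffold", "pos", "meth", "total"])
    cpg = cpg[cpg["pos"] >= 0].reset_index(drop=True)
    return cpg, pd.Series(classes, name="methylation_class"), tss_records


def simulate_motif_dataset(config: SimulationConfig, seed: int | None = None):
    """Motif-count matrix N, signal matrix E, and the planted activities.

    N entries are Poisson(``motif_count_mean``); E = peak offsets + stage
    offsets + N.A + Gaussian noise. The first ``n_active_motifs`` motifs
    carry nonzero activity rows (amplitude ``activity_amplitude``, centered
    across stages); all other rows are zero.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "motifs")
    P, M, S = config.n_motif_peaks, config.n_motifs, config.n_motif_stages
    peaks = [f"mp_{i:04d}" for i in range(P)]
    motifs = [f"motif_{j:02d}" for j in range(M)]
    stages = [f"stage_{k}" for k in range(S)]
    N = pd.DataFrame(rng.poisson(config.motif_count_mean, size=(P, M)),
                     index=peaks, columns=motifs)
    A = np.zeros((M, S))
    for j in range(config.n_active_motifs):
        row = rng.normal(0.0, config.activity_amplitude, size=S)
        A[j] = row - row.mean()  # identifiable: centered across stages
    peak_off = rng.normal(0.0, 1.0, size=P)
    stage_off = rng.normal(0.0, 0.5, size=S)
    E = (peak_off[:, None] + stage_off[None, :] + N.to_numpy() @ A
         + rng.normal(0.0, config.motif_noise_sd, size=(P, S)))
    E = pd.DataFrame(E, index=peaks, columns=stages)
    A = pd.DataFrame(A, index=motifs, columns=stages)
    truth = GroundTruth(motif_activities=A)
    return N, E, truth


def default_transition_matrix(config: SimulationConfig) -> np.ndarray:
    """Sticky default transition matrix over the state groups."""
    k = len(STATE_GROUPS)
    stick = config.state_stickiness
    T = np.full((k, k), (1 - stick) / (k - 1))
    np.fill_diagonal(T, stick)
    return T


def simulate_state_segmentations(config: SimulationConfig,
                                 seed: int | None = None,
                                 transition_matrices=None):
    """Markovian per-stage chromatin-state tracks, emitted as BED frames.

    Bin states evolve independently across stages under the per-stage-pair
    transition matrices (default: one sticky matrix for every pair, rows
    must sum to 1 within 1e-9). Intervals in the emitted segmentations are
    merged runs of the same non-Unmodified state.

    Returns (segmentations dict stage -> BED frame, scaffold_lengths,
    GroundTruth with the true per-bin label matrix).
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "states")
    stages = list(config.state_stages)
    n_pairs = len(stages) - 1
    if transition_matrices is None:
        transition_matrices = [default_transition_matrix(config)] * n_pairs
    k = len(STATE_GROUPS)
    for T in transition_matrices:
        T = np.asarray(T, dtype=float)
        if T.shape != (k, k) or np.any(np.abs(T.sum(axis=1) - 1) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1 (+/- 1e-9)")

    n_bins = config.n_state_bins
    bin_size = config.state_bin_size
    init = np.full(k, (1 - config.unmodified_initial) / (k - 1))
    init[STATE_GROUPS.index(UNMODIFIED)] = config.unmodified_initial
    labels = np.zeros((n_bins, len(stages)), dtype=np.int8)
    labels[:, 0] = rng.choice(k, size=n_bins, p=init)
    for j, T in enumerate(transition_matrices):
        T = np.asarray(T, dtype=float)
        cum = np.cumsum(T, axis=1)
        u = rng.random(n_bins)
        labels[:, j + 1] = np.array([
            np.searchsorted(cum[labels[i, j]], u[i], side="right")
            for i in range(n_bins)
        ], dtype=np.int8)
        np.clip(labels[:, j + 1], 0, k - 1, out=labels[:, j + 1])

    scaffold_lengths = {"scaffold_sim": n_bins * bin_size}
    segmentations = {}
    for j, st in enumerate(stages):
        rows = []
        i = 0
        while i < n_bins:
            s = labels[i, j]
            i0 = i
            while i < n_bins and labels[i, j] == s:
                i += 1
            if STATE_GROUPS[s] != UNMODIFIED:
                rows.append(("scaffold_sim", i0 * bin_size, i * bin_size,
                             STATE_GROUPS[s]))
        segmentations[st] = pd.DataFrame(
            rows, columns=["scaffold", "start", "end", "state"]
        )
    truth = GroundTruth(state_tracks=labels)
    return segmentations, scaffold_lengths, truth
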