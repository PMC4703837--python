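"""Motif activity response analysis for p300 recruitment.

Linear response model in the ISMARA style: the signal E_ps of peak p at
stage s is explained by a peak offset, a stage offset, and the motif
content of the peak weighted by unknown per-stage motif activities,

    E_ps = c~_p + c_s + sum_m N_pm * A_ms + noise,

where N counts binding sites of motif m in peak p. Offsets are removed in
closed form by double-centering E (and peak-centering N), after which the
activities solve a ridge-regularized least squares problem. Activities are
identifiable only up to a per-motif constant (absorbed by the peak
offsets), so they are reported centered across stages. A motif is called
significant when the magnitude of its activity z-score (activity divided
by its ridge posterior standard deviation) exceeds a threshold at any
stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg


@dataclass
class ActivityModel:
    activities: pd.DataFrame  # motifs x stages
    peak_offsets: pd.Series
    stage_offsets: pd.Series
    lam: float
    sigma2: float
    posterior_sd: pd.Series  # per motif
    zscores: pd.DataFrame  # motifs x stages


def _check_alignment(N: pd.DataFrame, E: pd.DataFrame) -> None:
    if list(N.index) != list(E.index):
        raise ValueError("peak ids of N and E must match")


def fit_activities(N: pd.DataFrame, E: pd.DataFrame, lam: float) -> ActivityModel:
    """Fit per-stage motif activities by centered ridge regression.

    ``N``: peaks x motifs binding-site counts; ``E``: peaks x stages signal
    (log2(RPKM+1) by convention). ``lam`` is the ridge parameter; with
    ``lam = 0`` the design must have full column rank after centering.
    """
    _check_alignment(N, E)
    if lam < 0:
        raise ValueError("ridge parameter must be >= 0")
    Nv = N.to_numpy(dtype=float)
    Ev = E.to_numpy(dtype=float)
    n_peaks, n_motifs = Nv.shape
    n_stages = Ev.shape[1]

    peak_means = Ev.mean(axis=1)
    stage_means = Ev.mean(axis=0)
    grand = Ev.mean()
    E_dc = Ev - peak_means[:, None] - stage_means[None, :] + grand
    Nc = Nv - Nv.mean(axis=0, keepdims=True)

    G = Nc.T @ Nc + lam * np.eye(n_motifs)
    if lam == 0:
        rank = np.linalg.matrix_rank(Nc.T @ Nc)
        if rank < n_motifs:
            raise ValueError(
                "motif design is rank-deficient; a ridge parameter > 0 is "
                "required for a unique solution"
            )
    A = linalg.solve(G, Nc.T @ E_dc, assume_a="pos")

    resid = E_dc - Nc @ A
    dof = max(n_peaks * n_stages - n_motifs * n_stages
              - n_peaks - n_stages + 1, 1)
    sigma2 = float((resid ** 2).sum() / dof)
    Ginv_diag = np.diag(linalg.inv(G))
    post_sd = np.sqrt(np.maximum(sigma2 * Ginv_diag, np.finfo(float).tiny))
    z = A / post_sd[:, None]

    return ActivityModel(
        activities=pd.DataFrame(A.T, index=E.columns, columns=N.columns).T,
        peak_offsets=pd.Series(peak_means - grand, index=E.index),
        stage_offsets=pd.Series(stage_means, index=E.columns),
        lam=lam,
        sigma2=sigma2,
        posterior_sd=pd.Series(post_sd, index=N.columns),
        zscores=pd.DataFrame(z, index=N.columns, columns=E.columns),
    )


def select_lambda(N: pd.DataFrame, E: pd.DataFrame, folds: int = 5,
                  grid=None, seed: int = 0) -> float:
    """Ridge parameter minimizing K-fold cross-validated prediction error.

    Peaks are partitioned into folds (deterministic given ``seed``); for
    each candidate lambda the activities are fitted on the training peaks
    and the double-centered signal of the held-out peaks is predicted from
    their motif counts.
    """
    _check_alignment(N, E)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    n_peaks = len(N)
    if n_peaks < folds:
        raise ValueError(f"only {n_peaks} peaks for {folds} folds")
    if grid is None:
        grid = np.logspace(-3, 3, 13)
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(n_peaks) % folds

    Nv = N.to_numpy(dtype=float)
    Ev = E.to_numpy(dtype=float)
    peak_means = Ev.mean(axis=1)
    stage_means = Ev.mean(axis=0)
    grand = Ev.mean()
    E_dc = Ev - peak_means[:, None] - stage_means[None, :] + grand
    Nc = Nv - Nv.mean(axis=0, keepdims=True)

    errors = []
    for lam in grid:
        sse = 0.0
        for f in range(folds):
            test = assignment == f
            train = ~test
            G = Nc[train].T @ Nc[train] + lam * np.eye(Nc.shape[1])
            A = np.linalg.solve(G + 1e-12 * np.eye(Nc.shape[1]),
                                Nc[train].T @ E_dc[train])
            pred = Nc[test] @ A
            sse += float(((E_dc[test] - pred) ** 2).sum())
        errors.append(sse)
    return float(grid[int(np.argmin(errors))])


def significant_motifs(model: ActivityModel, z_threshold: float = 13.0) -> list[str]:
    """Motifs whose activity |z| exceeds the threshold at any stage.

    Ordered by descending max |z|. The default threshold (13) is the
    stringent operating point used to pick the clearly driving motifs.
    """
    max_abs = model.zscores.abs().max(axis=1)
    hits = max_abs[max_abs > z_threshold]
    return list(hits.sort_values(ascending=False).index)
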