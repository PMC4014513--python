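"""The D, L and S matrices for one tutor x pupil comparison.

``D`` holds the Euclidean distance in normalized feature space between
every tutor frame i (rows) and pupil frame j (columns).  ``L`` smooths D
by the RMS along +-25 ms of the diagonal through each cell, which
suppresses frame-level noise while preserving diagonal structure (two
sounds evolving the same way in time).  ``S`` converts the pair to a
calibrated similarity: S_ij = 1 - P(D_ij) wherever P(L_ij) < alpha
(default 0.05) marks a region of similarity, 0 elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .calibration import ReferenceDistributions
from .config import RunConfig
from .features import FeatureSet

__all__ = ["SimilarityMatrices", "distance_matrix", "local_distance_matrix",
           "similarity_from_distances", "build_similarity"]


@dataclass
class SimilarityMatrices:
    D: np.ndarray
    L: np.ndarray
    S: np.ndarray
    frame_ms: float = 1.0


def distance_matrix(tutor: FeatureSet, pupil: FeatureSet) -> np.ndarray:
    """D_ij = Euclidean distance between tutor frame i and pupil frame j."""
    if tutor.names != pupil.names:
        raise ValueError(f"feature subsets differ: {tutor.names} vs {pupil.names}")
    if not (tutor.normalized and pupil.normalized):
        raise ValueError("both feature sets must be normalized")
    return cdist(tutor.values, pupil.values, metric="euclidean")


def local_distance_matrix(D: np.ndarray, window_ms: float = 25.0,
                          frame_step_ms: float = 1.0) -> np.ndarray:
    """RMS of D along diagonals +-window_ms around each cell.

    Windows are truncated (not zero-padded) at the matrix borders, so
    edge cells average over fewer in-bounds diagonal neighbours.
    """
    w = int(round(window_ms / frame_step_ms))
    M, N = D.shape
    d2 = D * D
    ssum = np.zeros_like(D)
    cnt = np.zeros_like(D)
    for d in range(-w, w + 1):
        if d >= 0:
            if d >= M or d >= N:
                continue
            ssum[: M - d, : N - d] += d2[d:, d:]
            cnt[: M - d, : N - d] += 1.0
        else:
            e = -d
            if e >= M or e >= N:
                continue
            ssum[e:, e:] += d2[: M - e, : N - e]
            cnt[e:, e:] += 1.0
    return np.sqrt(ssum / cnt)


def similarity_from_distances(D: np.ndarray, L: np.ndarray,
                              ref: ReferenceDistributions,
                              alpha: float = 0.05) -> np.ndarray:
    """S = (1 - P(D)) gated by the strict P(L) < alpha similarity regions."""
    if D.shape != L.shape:
        raise ValueError("D and L must have the same shape")
    p_d = ref.probability_of("D", D)
    p_l = ref.probability_of("L", L)
    return np.where(p_l < alpha, 1.0 - p_d, 0.0)


def build_similarity(tutor: FeatureSet, pupil: FeatureSet,
                     ref: ReferenceDistributions,
                     config: RunConfig | None = None) -> SimilarityMatrices:
    """D, L and S for one comparison, verifying calibration parameters."""
    cfg = config or RunConfig()
    ref.check_hash(cfg)
    t = tutor.subset(cfg.features) if tutor.names != tuple(cfg.features) else tutor
    p = pupil.subset(cfg.features) if pupil.names != tuple(cfg.features) else pupil
    D = distance_matrix(t, p)
    L = local_distance_matrix(D, cfg.diag_window_ms, cfg.step_ms)
    S = similarity_from_distances(D, L, ref, cfg.alpha)
    return SimilarityMatrices(D, L, S, cfg.step_ms)


def plot_similarity(S: np.ndarray, path=None, matches=None):
    """Render the similarity matrix (tutor rows at left, pupil columns).

    Optional ``matches`` (list of objects with i1/i2/j1/j2) overlays the
    matched diagonals.  Returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.imshow(S, aspect="auto", origin="upper", cmap="viridis",
              interpolation="nearest")
    if matches is not None:
        for m in matches:
            ax.plot([m.j1, m.j2 - 1], [m.i1, m.i2 - 1], "r-", lw=1.5)
    ax.set_xlabel("pupil time (ms)")
    ax.set_ylabel("tutor time (ms)")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
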