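"""Distance-to-probability calibration from unrelated-song comparisons.

Raw Euclidean feature distances carry no absolute meaning; they are
converted to probabilities against an empirical null: all D and L
distance-matrix entries pooled over cross-source pairwise comparisons of
unrelated songs.  ``P(value)`` is then the probability of observing a
*smaller* distance between unrelated songs, which is what the similarity
matrix thresholds and inverts.

The pooled samples are stored as 1001-point quantile tables (pooled D
entries scale with frames squared, easily 10^7+); queries interpolate
linearly between stored quantiles, which bounds the error by the local
inter-quantile spacing.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .config import RunConfig, params_hash
from .features import FeatureSet, NormalizationStats

__all__ = ["ReferenceDistributions", "build_reference", "CalibrationMismatchError"]

N_QUANTILES = 1001


class CalibrationMismatchError(ValueError):
    """Reference was built with different parameters than the scoring run."""


def _quantile_table(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strictly-increasing (value, cumulative-probability) grid."""
    probs = np.linspace(0.0, 1.0, N_QUANTILES)
    q = np.quantile(values, probs)
    # collapse ties so np.interp sees an increasing grid; keep the lowest
    # probability of a tie block ("strictly less than" semantics)
    keep = np.concatenate([[True], np.diff(q) > 0])
    return q[keep], probs[keep]


@dataclass
class ReferenceDistributions:
    """Empirical cumulative distributions of D and L null distances."""

    q_values_D: np.ndarray
    q_probs_D: np.ndarray
    q_values_L: np.ndarray
    q_probs_L: np.ndarray
    n_values_D: int
    n_values_L: int
    params_hash: str
    stats: NormalizationStats | None = None
    provenance: dict = field(default_factory=dict)

    def probability_of(self, which: str, value) -> np.ndarray | float:
        """P(unrelated-song distance < value), clamped to [0, 1]."""
        if which == "D":
            q, p = self.q_values_D, self.q_probs_D
        elif which == "L":
            q, p = self.q_values_L, self.q_probs_L
        else:
            raise ValueError("which must be 'D' or 'L'")
        if q.size == 0:
            raise ValueError("reference distributions not built")
        value = np.asarray(value, dtype=np.float64)
        out = np.interp(value, q, p)        # clamps to 0 below min, 1 above max
        out = np.where(value <= q[0], 0.0, out)
        return float(out) if out.ndim == 0 else out

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "q_values_D": self.q_values_D.tolist(),
            "q_probs_D": self.q_probs_D.tolist(),
            "q_values_L": self.q_values_L.tolist(),
            "q_probs_L": self.q_probs_L.tolist(),
            "n_values_D": self.n_values_D,
            "n_values_L": self.n_values_L,
            "params_hash": self.params_hash,
            "stats": None if self.stats is None else self.stats.to_dict(),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceDistributions":
        doc = json.loads(Path(path).read_text())
        return cls(
            np.array(doc["q_values_D"]), np.array(doc["q_probs_D"]),
            np.array(doc["q_values_L"]), np.array(doc["q_probs_L"]),
            int(doc["n_values_D"]), int(doc["n_values_L"]),
            doc["params_hash"],
            None if doc["stats"] is None
            else NormalizationStats.from_dict(doc["stats"]),
            doc.get("provenance", {}),
        )

    def check_hash(self, config: RunConfig) -> None:
        expected = params_hash(config, self.stats)
        if expected != self.params_hash:
            raise CalibrationMismatchError(
                "reference was calibrated under different parameters "
                f"(reference {self.params_hash}, run {expected})")


def build_reference(corpus: Sequence[FeatureSet],
                    config: RunConfig | None = None,
                    stats: NormalizationStats | None = None,
                    subsample: int | None = None,
                    seed: int | None = None) -> ReferenceDistributions:
    """Pool D and L entries over all cross-source pairs of a corpus.

    ``corpus`` holds normalized feature sets from at least two distinct
    sources (self-comparisons would bias the null toward similarity and
    are excluded).  ``subsample``, if given, caps the number of pooled
    entries per matrix via a seeded random draw.
    """
    from .similarity import distance_matrix, local_distance_matrix

    cfg = config or RunConfig()
    sets = [fs.subset(cfg.features) if fs.names != tuple(cfg.features) else fs
            for fs in corpus]
    sources = {fs.source_id for fs in sets}
    if len(sets) < 2 or len(sources) < 2:
        raise ValueError(
            "reference corpus needs feature sets from >= 2 distinct sources "
            f"(got {len(sources)})")
    for fs in sets:
        if not fs.normalized:
            raise ValueError("reference corpus must be normalized")

    rng = np.random.default_rng(seed)
    pooled_d: list[np.ndarray] = []
    pooled_l: list[np.ndarray] = []
    n_pairs = 0
    for a, b in itertools.combinations(range(len(sets)), 2):
        if sets[a].source_id == sets[b].source_id:
            continue
        d = distance_matrix(sets[a], sets[b])
        l = local_distance_matrix(d, cfg.diag_window_ms, cfg.step_ms)
        dv, lv = d.ravel(), l.ravel()
        if subsample is not None and dv.size > subsample:
            dv = rng.choice(dv, subsample, replace=False)
            lv = rng.choice(lv, subsample, replace=False)
        pooled_d.append(dv)
        pooled_l.append(lv)
        n_pairs += 1

    all_d = np.concatenate(pooled_d)
    all_l = np.concatenate(pooled_l)
    qd, pd_ = _quantile_table(all_d)
    ql, pl = _quantile_table(all_l)
    return ReferenceDistributions(
        qd, pd_, ql, pl, all_d.size, all_l.size,
        params_hash(cfg, stats), stats,
        provenance={"n_songs": len(sets), "n_sources": len(sources),
                    "n_pairs": n_pairs,
                    "sources": sorted(str(s) for s in sources)},
    )
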