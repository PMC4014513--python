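"""Self-/cross-similarity experiments, the contrast metric, feature sweeps.

A good similarity measure should score different renditions of one
bird's song as highly similar (self-similarity) and the songs of
unrelated birds as dissimilar (cross-similarity).  The *contrast*,
``(self - cross) / (self + cross)``, summarizes that separation on a
scale-invariant [-1, 1] scale; multiplying all scores by a constant
leaves it unchanged.  The feature-subset sweep reruns the experiment
with every feature combination of a given size under shared seeds, so
subset differences are attributable to the features alone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import ReferenceDistributions, build_reference
from .config import FEATURE_NAMES, RunConfig
from .features import FeatureSet, compute_features, fit_normalization, \
    normalize_features
from .scoring import TutorMotif, score_pair
from .selection import extract_segments, load_tutor_motif
from .synth import Colony

__all__ = ["ContrastResult", "contrast", "prepare_experiment",
           "self_cross_experiment", "enumerate_feature_subsets",
           "feature_subset_sweep"]


@dataclass
class ContrastResult:
    bird_id: str
    self_similarity: float
    cross_similarity: float
    contrast: float | None


def contrast(self_score: float, cross_score: float) -> float | None:
    """(self - cross) / (self + cross); None when the sum is zero."""
    total = self_score + cross_score
    if total == 0:
        return None
    return (self_score - cross_score) / total


# ---------------------------------------------------------------------------
# experiment plumbing


@dataclass
class ExperimentData:
    """Colony after feature extraction: motifs, segments, calibration."""

    motifs: dict[str, list[TutorMotif]]
    segments: dict[str, list[FeatureSet]]
    ref: ReferenceDistributions
    config: RunConfig


def prepare_experiment(colony: Colony, config: RunConfig | None = None,
                       seed: int = 0) -> ExperimentData:
    """Extract features, fit normalization, calibrate, select segments.

    Normalization stats are pooled over all motif recordings of the
    colony; the null distributions come from cross-bird pairs of one
    motif rendition per bird; pupil segments are cut from each bird's
    bouts at twice that bird's motif duration.
    """
    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)

    raw_motifs = {
        b: [compute_features(w, cfg) for w, _ in colony.birds[b].motifs]
        for b in colony.bird_ids
    }
    stats = fit_normalization(
        [f for sets in raw_motifs.values() for f in sets], cfg.normalization)

    motifs: dict[str, list[TutorMotif]] = {}
    for b in colony.bird_ids:
        motifs[b] = []
        for raw, (_, ann) in zip(raw_motifs[b], colony.birds[b].motifs):
            feats = normalize_features(raw, stats)
            feats.source_id = f"{b}/{ann['source_id'].iloc[0]}"
            motifs[b].append(load_tutor_motif(feats, ann, feats.source_id))

    corpus = []
    for b in colony.bird_ids:
        first = normalize_features(raw_motifs[b][0], stats)
        first.source_id = b
        corpus.append(first.subset(cfg.features))
    ref = build_reference(corpus, cfg, stats)

    segments: dict[str, list[FeatureSet]] = {}
    for b in colony.bird_ids:
        motif_ms = colony.birds[b].motif_spec.duration_ms
        segs: list[FeatureSet] = []
        for bout in colony.birds[b].bouts:
            segs.extend(extract_segments(bout, motif_ms, cfg, stats, rng))
        segments[b] = segs
    return ExperimentData(motifs, segments, ref, cfg)


def _mean_si(motifs: list[TutorMotif], segments: list[FeatureSet],
             data: ExperimentData) -> tuple[float, float, float]:
    """Mean (acoustic, sequence, SI) over all motif x segment pairs."""
    ac, seq, si = [], [], []
    for motif in motifs:
        for seg in segments:
            res = score_pair(motif, seg.subset(data.config.features),
                             data.ref, data.config)
            ac.append(res.acoustic)
            si.append(res.si)
            if res.sequence_defined:
                seq.append(res.sequence)
    return (float(np.mean(ac)),
            float(np.mean(seq)) if seq else float("nan"),
            float(np.mean(si)))


def self_cross_experiment(data: ExperimentData, seed: int = 0,
                          n_segments: int = 25, n_motifs: int = 3,
                          n_cross_birds: int = 10) -> pd.DataFrame:
    """Per-bird self- and cross-similarity and their contrast.

    Per bird: sample up to ``n_segments`` of its segments and
    ``n_motifs`` of its motifs; self-similarity is the mean SI over
    those pairs; cross-similarity is the mean SI of the same segments
    against motifs of up to ``n_cross_birds`` randomly chosen other
    birds.  Birds with fewer segments than requested use all available.
    """
    birds = sorted(data.motifs)
    if len(birds) < 2:
        raise ValueError("experiment needs >= 2 birds")
    rng = np.random.default_rng(seed)
    rows = []
    for b in birds:
        segs = data.segments[b]
        if not segs:
            continue
        take_segs = min(n_segments, len(segs))
        seg_idx = rng.choice(len(segs), take_segs, replace=False)
        segs = [segs[i] for i in seg_idx]
        own = data.motifs[b]
        own = [own[i] for i in
               rng.choice(len(own), min(n_motifs, len(own)), replace=False)]
        self_ac, self_seq, self_si = _mean_si(own, segs, data)

        others = [o for o in birds if o != b]
        pick = rng.choice(len(others), min(n_cross_birds, len(others)),
                          replace=False)
        cross_scores = []
        for o in (others[i] for i in pick):
            om = data.motifs[o]
            om = [om[i] for i in
                  rng.choice(len(om), min(n_motifs, len(om)), replace=False)]
            cross_scores.append(_mean_si(om, segs, data))
        cross_ac = float(np.mean([c[0] for c in cross_scores]))
        cross_seq = float(np.nanmean([c[1] for c in cross_scores]))
        cross_si = float(np.mean([c[2] for c in cross_scores]))
        rows.append({
            "bird": b,
            "self_acoustic": self_ac, "cross_acoustic": cross_ac,
            "self_sequence": self_seq, "cross_sequence": cross_seq,
            "self_si": self_si, "cross_si": cross_si,
            "contrast_si": contrast(self_si, cross_si),
            "contrast_acoustic": contrast(self_ac, cross_ac),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature-subset sweep


def enumerate_feature_subsets(sizes=(4, 5, 6),
                              names=FEATURE_NAMES) -> list[tuple[str, ...]]:
    """All feature combinations of the given sizes (deduplicated)."""
    seen = set()
    out = []
    for size in sizes:
        for combo in itertools.combinations(names, size):
            if combo not in seen:
                seen.add(combo)
                out.append(combo)
    return out


def feature_subset_sweep(colony: Colony,
                         subsets: list[tuple[str, ...]] | None = None,
                         config: RunConfig | None = None, seed: int = 0,
                         **experiment_kwargs) -> pd.DataFrame:
    """Mean SI contrast per feature subset under shared sampling seeds.

    Calibration is rebuilt per subset (distances depend on the feature
    set) but the sampled segments and motifs are identical across
    subsets, so contrast differences reflect the features alone.
    """
    cfg = config or RunConfig()
    subsets = subsets if subsets is not None else enumerate_feature_subsets()
    for sub in subsets:
        unknown = set(sub) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
    rows = []
    for sub in subsets:
        data = prepare_experiment(colony, cfg.replace(features=tuple(sub)),
                                  seed=seed)
        table = self_cross_experiment(data, seed=seed, **experiment_kwargs)
        rows.append({
            "subset": "+".join(sub),
            "n_features": len(sub),
            "mean_contrast": float(table["contrast_si"].mean()),
            "mean_self": float(table["self_si"].mean()),
            "mean_cross": float(table["cross_si"].mean()),
        })
    return pd.DataFrame(rows)
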