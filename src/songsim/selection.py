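"""Pupil segment selection and tutor-motif ingestion.

Pupil song bouts are never segmented into syllables; instead each bout
is cut into non-overlapping adjacent segments, each twice the tutor
motif duration, starting at a random offset drawn uniformly from
[0, motif duration) so that different time alignments are sampled.  The
trailing remainder shorter than a full segment is discarded.

Tutor motifs arrive with manual syllable annotations (onset/offset
seconds); these are converted to 1 ms frame indices (onsets round half
down, offsets half up, so boundary samples are covered inclusively).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import ReferenceDistributions
from .config import RunConfig
from .features import FeatureSet, Waveform, compute_features, normalize_features
from .scoring import TutorMotif, score_pair

__all__ = ["Segment", "segment_bout", "load_tutor_motif", "extract_segments",
           "batch_compare"]


@dataclass(frozen=True)
class Segment:
    start_ms: float
    end_ms: float

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


def segment_bout(bout_duration_ms: float, motif_ms: float,
                 rng: np.random.Generator | int | None = None,
                 ) -> list[Segment]:
    """Tile a bout with adjacent segments of twice the motif duration.

    The first segment starts at an offset drawn uniformly from
    [0, motif_ms); as many full segments as fit are returned (possibly
    none).  Deterministic given the generator/seed.
    """
    if motif_ms <= 0:
        raise ValueError("motif duration must be positive")
    if not hasattr(rng, "uniform"):
        rng = np.random.default_rng(rng)
    offset = float(rng.uniform(0.0, motif_ms))
    seg = 2.0 * motif_ms
    n = int(math.floor((bout_duration_ms - offset) / seg))
    return [Segment(offset + i * seg, offset + (i + 1) * seg)
            for i in range(max(n, 0))]


def _round_half_down(x: float) -> int:
    return int(math.ceil(x - 0.5))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def load_tutor_motif(features: FeatureSet,
                     annotation: pd.DataFrame | str | Path,
                     source_id: str | None = None) -> TutorMotif:
    """Build a TutorMotif from motif features and a syllable table.

    The annotation needs ``onset_s``/``offset_s`` columns, ordered and
    non-overlapping; times are converted to frame indices at the 1 ms
    framing and validated against the feature track length.
    """
    if not isinstance(annotation, pd.DataFrame):
        annotation = pd.read_csv(annotation)
    if annotation.empty:
        raise ValueError("motif must contain >= 1 syllable")
    m = features.n_frames
    syllables: list[tuple[int, int]] = []
    prev_end = -1
    for row_idx, row in enumerate(annotation.itertuples(index=False)):
        on, off = float(row.onset_s), float(row.offset_s)
        if off <= on:
            raise ValueError(f"annotation row {row_idx}: offset <= onset")
        i1 = max(_round_half_down(on * 1000.0), 0)
        i2 = min(_round_half_up(off * 1000.0), m)
        if i2 <= i1:
            raise ValueError(
                f"annotation row {row_idx}: syllable outside the feature "
                f"track ({on:.3f}-{off:.3f} s vs {m} frames)")
        if i1 < prev_end:
            raise ValueError(
                f"annotation row {row_idx}: overlaps the previous syllable")
        syllables.append((i1, i2))
        prev_end = i2
    return TutorMotif(features, syllables,
                      source_id or features.source_id)


def extract_segments(bout: Waveform, motif_ms: float,
                     config: RunConfig, stats,
                     rng: np.random.Generator | int | None = None,
                     ) -> list[FeatureSet]:
    """Feature sets for each automatically selected segment of a bout.

    Features are computed once over the whole bout and sliced per
    segment, so segment frames keep their full 9 ms analysis context.
    """
    feats = normalize_features(compute_features(bout, config), stats)
    window = int(round(config.window_ms / config.step_ms))
    out = []
    for i, seg in enumerate(segment_bout(bout.duration_ms, motif_ms, rng)):
        a = int(round(seg.start_ms / config.step_ms))
        b = a + int(round(seg.duration_ms / config.step_ms)) - window + 1
        b = min(b, feats.n_frames)
        if b <= a:
            continue
        piece = feats.slice_frames(a, b)
        piece.source_id = f"{bout.source_id}/seg{i}"
        out.append(piece)
    return out


def batch_compare(motifs: Sequence[TutorMotif],
                  segments: Sequence[FeatureSet],
                  ref: ReferenceDistributions,
                  config: RunConfig | None = None) -> pd.DataFrame:
    """Score every (motif, segment) pair; failed pairs are flagged rows."""
    cfg = config or RunConfig()
    rows = []
    for motif in motifs:
        for seg in segments:
            row = {"motif": motif.source_id, "segment": seg.source_id}
            try:
                res = score_pair(motif, seg, ref, cfg)
                row.update(acoustic=res.acoustic, sequence=res.sequence,
                           si=res.si, sequence_defined=res.sequence_defined,
                           error="")
            except Exception as exc:  # isolate failures, keep the batch going
                row.update(acoustic=np.nan, sequence=np.nan, si=np.nan,
                           sequence_defined=False, error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)
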