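"""Greedy tutor-syllable matching and the acoustic/sequence/SI scores.

The tutor motif is segmented into syllables; the pupil segment stays a
continuous stream.  Each tutor syllable k occupies a horizontal band of
the similarity matrix (rows [i1, i2), N_k = i2 - i1 frames).  Its
*partial similarity* at pupil offset j is the sum of S along the full
diagonal of the band starting at column j; the best offset maximizes
that sum.  Matching is greedy: the syllable with the highest partial
score is committed first, its rows and matched columns are zeroed, and
the remaining partial scores are recomputed until every syllable is
placed.  Offsets whose pupil fragment would overlap an already-matched
fragment are inadmissible, so matched fragments never overlap; if a
syllable has no admissible offset left it is placed at the
least-conflicting offset with score 0 and flagged.

The acoustic score is the length-weighted average of partial scores,
``sum_k S^k_max / sum_k N_k`` in [0, 1].  The sequence score asks, for
each syllable k, whether a good imitation of syllable k+1 follows the
matched fragment: the maximal clipped-diagonal sum inside an *area of
interest* starting at the end of fragment k and spanning the offset-to-
offset interval to syllable k+1 plus 50 ms of slack, normalized by
N_{k+1}.  The similarity index (SI) is the product of the two scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import ReferenceDistributions
from .config import RunConfig
from .features import FeatureSet
from .similarity import SimilarityMatrices, build_similarity

__all__ = ["TutorMotif", "SyllableMatch", "MatchResult",
           "SegmentTooShortError", "best_diagonal", "greedy_match",
           "acoustic_score", "sequence_score", "similarity_index",
           "score_pair"]


class SegmentTooShortError(ValueError):
    """Pupil segment shorter than a tutor syllable: no full diagonal fits."""


@dataclass
class TutorMotif:
    """Feature tracks plus syllable boundaries for one tutor motif.

    ``syllables`` are half-open frame-index pairs (i1, i2), strictly
    ordered and non-overlapping; gaps between them are never scored.
    """

    features: FeatureSet
    syllables: list[tuple[int, int]]
    source_id: str | None = None

    def __post_init__(self) -> None:
        if not self.syllables:
            raise ValueError("motif must contain >= 1 syllable")
        m = self.features.n_frames
        prev_end = 0
        for k, (i1, i2) in enumerate(self.syllables):
            if not (0 <= i1 < i2 <= m):
                raise ValueError(
                    f"syllable {k}: bounds ({i1}, {i2}) outside [0, {m}]")
            if i1 < prev_end:
                raise ValueError(
                    f"syllable {k} overlaps or precedes syllable {k - 1}")
            prev_end = i2
        if self.source_id is None:
            self.source_id = self.features.source_id

    @property
    def n_syllables(self) -> int:
        return len(self.syllables)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([i2 - i1 for i1, i2 in self.syllables])

    @property
    def duration_frames(self) -> int:
        return self.features.n_frames


@dataclass
class SyllableMatch:
    index: int          # tutor syllable index k
    i1: int
    i2: int
    j1: int             # matched pupil fragment [j1, j2), j2 - j1 = N_k
    j2: int
    score: float        # partial acoustic similarity S^k_max
    order: int          # greedy iteration at which it was committed
    flagged: bool = False


@dataclass
class MatchResult:
    matches: list[SyllableMatch]                 # in tutor-syllable order
    acoustic: float
    sequence: float | None
    sequence_partials: list[tuple[int, float | None, str]]
    si: float
    sequence_defined: bool = True

    def validate(self) -> None:
        placed = sorted((m.j1, m.j2) for m in self.matches if not m.flagged)
        for (a1, a2), (b1, b2) in zip(placed, placed[1:]):
            if b1 < a2:
                raise AssertionError("matched pupil fragments overlap")
        if not (0.0 <= self.acoustic <= 1.0 + 1e-12):
            raise AssertionError("acoustic score out of [0, 1]")


# ---------------------------------------------------------------------------
# diagonal machinery


def _diagonal_sums(band: np.ndarray) -> np.ndarray:
    """Sum of each full diagonal of a (h, N) band; index j = start column."""
    h, n = band.shape
    if h > n:
        raise SegmentTooShortError(
            f"syllable of {h} frames cannot fit in a {n}-frame pupil segment")
    sums = np.zeros(n - h + 1)
    for r in range(h):
        sums += band[r, r: r + n - h + 1]
    return sums


def _admissible(allowed: np.ndarray, h: int) -> np.ndarray:
    """adm[j] is True when columns [j, j+h) are all still allowed."""
    bad = np.concatenate([[0], np.cumsum(~allowed)])
    return bad[h:] - bad[:-h] == 0


def best_diagonal(S: np.ndarray, row_band: tuple[int, int],
                  allowed_columns: np.ndarray | None = None,
                  ) -> tuple[int, float]:
    """Best full-diagonal placement of one tutor syllable band.

    Returns ``(j*, S^k_max)`` maximizing the diagonal sum over admissible
    offsets (smallest offset on ties).  Raises ``SegmentTooShortError``
    when no full diagonal fits, and ``ValueError`` when a column mask
    leaves no admissible offset.
    """
    i1, i2 = row_band
    band = S[i1:i2]
    sums = _diagonal_sums(band)
    if allowed_columns is not None:
        adm = _admissible(np.asarray(allowed_columns, bool), i2 - i1)
        if not adm.any():
            raise ValueError("no admissible offset under the column mask")
        sums = np.where(adm, sums, -np.inf)
    j = int(np.argmax(sums))            # first maximum -> smallest offset
    return j, float(sums[j])


def _least_conflicting_offset(allowed: np.ndarray, h: int) -> int:
    """Offset whose fragment overlaps the fewest already-matched columns."""
    bad = np.concatenate([[0], np.cumsum(~allowed)])
    conflicts = bad[h:] - bad[:-h]
    return int(np.argmin(conflicts))


def greedy_match(S: np.ndarray, motif: TutorMotif) -> list[SyllableMatch]:
    """Match every tutor syllable to a pupil fragment, best match first.

    Each iteration recomputes all remaining partial scores on the
    progressively zeroed matrix, commits the syllable with the highest
    score (ties: longer syllable, then lower index), then zeroes its rows
    and matched columns inclusive.
    """
    n_cols = S.shape[1]
    if n_cols < int(motif.lengths.max()):
        raise SegmentTooShortError(
            f"pupil segment ({n_cols} frames) shorter than the longest "
            f"tutor syllable ({int(motif.lengths.max())} frames)")
    work = S.copy()
    allowed = np.ones(n_cols, dtype=bool)
    remaining = set(range(motif.n_syllables))
    committed: dict[int, SyllableMatch] = {}
    order = 0
    while remaining:
        candidates: list[tuple[float, int, int, int, bool]] = []
        for k in sorted(remaining):
            i1, i2 = motif.syllables[k]
            h = i2 - i1
            try:
                j, s = best_diagonal(work, (i1, i2), allowed)
                candidates.append((s, h, k, j, False))
            except ValueError:
                j = _least_conflicting_offset(allowed, h)
                candidates.append((0.0, h, k, j, True))
        feasible = [c for c in candidates if not c[4]] or candidates
        # highest score; ties -> longest syllable, then lowest index
        s, h, k, j, flagged = max(feasible, key=lambda c: (c[0], c[1], -c[2]))
        i1, i2 = motif.syllables[k]
        committed[k] = SyllableMatch(k, i1, i2, j, j + h, s, order, flagged)
        work[i1:i2, :] = 0.0
        work[:, j: j + h] = 0.0
        allowed[j: j + h] = False
        remaining.discard(k)
        order += 1
    return [committed[k] for k in range(motif.n_syllables)]


# ---------------------------------------------------------------------------
# scores


def acoustic_score(matches: list[SyllableMatch], motif: TutorMotif) -> float:
    """Sum of partial scores over the total tutor syllable length."""
    total = int(motif.lengths.sum())
    return float(sum(m.score for m in matches) / total)


def _max_clipped_diagonal(area: np.ndarray) -> float:
    """Max over all diagonals of the sum of in-area diagonal cells."""
    h, w = area.shape
    best = 0.0
    for off in range(-(h - 1), w):
        best = max(best, float(np.diagonal(area, offset=off).sum()))
    return best


def sequence_score(S: np.ndarray, matches: list[SyllableMatch],
                   motif: TutorMotif, slack_ms: float = 50.0,
                   frame_step_ms: float = 1.0,
                   ) -> tuple[float | None, list[tuple[int, float | None, str]]]:
    """Mean partial sequence score over applicable syllables.

    Uses the pristine (un-zeroed) similarity matrix.  For syllable k the
    area of interest spans the rows of syllable k+1 and the columns from
    the end of fragment k over the tutor offset-to-offset interval plus
    the slack; the partial score is the maximal clipped-diagonal sum in
    that area divided by N_{k+1}.  The last syllable, and any syllable
    matched too close to the segment end for the area to have width, are
    excluded.  Returns ``(None, partials)`` when no syllable applies.
    """
    slack = int(round(slack_ms / frame_step_ms))
    n_cols = S.shape[1]
    partials: list[tuple[int, float | None, str]] = []
    values: list[float] = []
    for k in range(motif.n_syllables):
        if k == motif.n_syllables - 1:
            partials.append((k, None, "last syllable"))
            continue
        j2 = matches[k].j2
        a1, a2 = motif.syllables[k + 1]
        width = (a2 - motif.syllables[k][1]) + slack
        c0, c1 = j2, min(j2 + width, n_cols)
        if c1 <= c0:
            partials.append((k, None, "matched too close to segment end"))
            continue
        area = S[a1:a2, c0:c1]
        val = _max_clipped_diagonal(area) / (a2 - a1)
        partials.append((k, val, "ok"))
        values.append(val)
    if not values:
        return None, partials
    return float(np.mean(values)), partials


def similarity_index(acoustic: float, sequence: float) -> float:
    """Composite SI: product of acoustic and sequence similarity scores."""
    return acoustic * sequence


def score_pair(motif: TutorMotif, pupil: FeatureSet,
               ref: ReferenceDistributions,
               config: RunConfig | None = None,
               matrices: SimilarityMatrices | None = None) -> MatchResult:
    """Full comparison of one tutor motif against one pupil segment.

    Builds D/L/S (unless ``matrices`` is supplied), runs the greedy
    acoustic matching, then scores sequencing on the pristine S.  When
    the sequence score is undefined (single-syllable motif, or every
    syllable excluded) the SI falls back to the acoustic score alone and
    ``sequence_defined`` is False.
    """
    cfg = config or RunConfig()
    if matrices is None:
        tutor_feats = motif.features
        matrices = build_similarity(tutor_feats, pupil, ref, cfg)
    S = matrices.S
    matches = greedy_match(S, motif)
    ac = acoustic_score(matches, motif)
    seq, partials = sequence_score(S, matches, motif, cfg.slack_ms, cfg.step_ms)
    if seq is None:
        result = MatchResult(matches, ac, None, partials, ac,
                             sequence_defined=False)
    else:
        result = MatchResult(matches, ac, seq, partials,
                             similarity_index(ac, seq))
    result.validate()
    return result
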