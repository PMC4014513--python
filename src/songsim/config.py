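"""Run configuration shared across the pipeline.

Defaults are the published analysis settings: 9 ms multitaper windows in
1 ms steps over the 500-8600 Hz band (time-bandwidth 1.5, 2 tapers), a
25 ms diagonal-RMS smoothing window, a 0.05 probability gate for regions
of similarity, 50 ms of sequence-alignment slack, and the optimal feature
subset {gravity center, spectral width, pitch goodness, Wiener entropy}.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from typing import Any

#: All features the pipeline can compute, in canonical order.
FEATURE_NAMES: tuple[str, ...] = (
    "wiener_entropy",
    "frequency_modulation",
    "pitch",
    "pitch_goodness",
    "gravity_center",
    "spectral_width",
)

#: The feature subset that maximizes self/cross contrast on adult song.
DEFAULT_FEATURES: tuple[str, ...] = (
    "gravity_center",
    "spectral_width",
    "pitch_goodness",
    "wiener_entropy",
)


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one reproducible similarity-scoring run."""

    window_ms: float = 9.0
    step_ms: float = 1.0
    band: tuple[float, float] = (500.0, 8600.0)
    time_bandwidth: float = 1.5
    n_tapers: int = 2
    diag_window_ms: float = 25.0
    alpha: float = 0.05
    slack_ms: float = 50.0
    features: tuple[str, ...] = DEFAULT_FEATURES
    normalization: str = "mad"  # "mad" (median |x - mean| = 1) or "sd"
    pitch_band: tuple[float, float] = (400.0, 3000.0)
    entropy_floor: float = -10.0

    def __post_init__(self) -> None:
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
        if self.normalization not in ("mad", "sd"):
            raise ValueError("normalization must be 'mad' or 'sd'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def replace(self, **changes: Any) -> "RunConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["pitch_band"] = list(self.pitch_band)
        d["features"] = list(self.features)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        for key in ("band", "pitch_band", "features"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def params_hash(config: RunConfig, stats: Any = None) -> str:
    """Digest of every setting a calibrated reference depends on.

    A reference distribution is only valid for scoring runs that use the
    same spectral parameters, diagonal window, feature subset and
    normalization; any mismatch at scoring time is a hard error.
    """
    payload: dict[str, Any] = {
        "window_ms": config.window_ms,
        "step_ms": config.step_ms,
        "band": list(config.band),
        "time_bandwidth": config.time_bandwidth,
        "n_tapers": config.n_tapers,
        "diag_window_ms": config.diag_window_ms,
        "features": list(config.features),
        "normalization": config.normalization,
        "pitch_band": list(config.pitch_band),
        "entropy_floor": config.entropy_floor,
    }
    if stats is not None:
        payload["stats"] = stats.to_dict()
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
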