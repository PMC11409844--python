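"""Shared signal container used across the feature-extraction modules.

Every predictor that enters the mixed models — tempo, loudness, note
density, kernel-encoded annotations, the starting factor — is a vector
sampled on the score-time lattice.  :class:`FeatureSignal` holds that
vector together with its name, units and provenance metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class FeatureSignal:
    """A score-time signal: one value per half-beat sample.

    Parameters
    ----------
    name:
        Predictor name, e.g. ``"tempo"`` or ``"climax"``.
    values:
        One value per half-beat grid sample.
    units:
        Physical or nominal units (``"BPM"``, ``"sone-like"``,
        ``"notes_per_halfbeat"``, ``"unitless"``).
    meta:
        Free-form provenance: source file, filter parameters, flags such
        as ``approximate`` for the simplified loudness frontend.
    """

    name: str
    values: np.ndarray
    units: str = "unitless"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("FeatureSignal values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"FeatureSignal {self.name!r} contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray, **meta: Any) -> "FeatureSignal":
        """Copy of this signal with new values and extra metadata."""
        merged = dict(self.meta)
        merged.update(meta)
        return FeatureSignal(self.name, values, self.units, merged)
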