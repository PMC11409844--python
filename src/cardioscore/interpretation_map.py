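"""Interpretation Map: categorical score annotations and their encodings.

The musicians jointly annotate the score with interpretive categories
(melody, dialogue, accompaniment, significant accompaniment, climax,
return/repose, moment of concern).  Each category becomes a length-L
binary vector (1 on every half-beat inside an annotated bar span) and,
from that, a predictor signal built as a sum of discrete Gaussian
kernels: each annotated half-beat contributes a unit-mass Gaussian
centered 16 half-beats (four bars) ahead with SD 8 half-beats (two
bars), modeling a delayed, smeared physiological response to the
annotated musical event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .score_time import ScoreTimeGrid, bar_span_to_samples

#: Annotation vocabulary.
CATEGORIES = (
    "melody",
    "melodic_interaction",
    "dialogue",
    "significant_accompaniment",
    "accompaniment",
    "climax",
    "return_repose",
    "moment_of_concern",
)

#: Aliases accepted on ingest.
_CATEGORY_ALIASES = {"melodic_interest": "melody"}

#: Kernel defaults: forward offset of four bars, SD of two bars.
KERNEL_CENTER_OFFSET = 16
KERNEL_SD = 8.0
KERNEL_SUPPORT_SDS = 6.0

#: Model terms and the annotation categories feeding each (melodic
#: interest and melodic interaction are pooled into one Melody term;
#: return/repose is excluded from the default design for low occurrence).
MODEL_TERM_CATEGORIES: dict[str, tuple[str, ...]] = {
    "melody": ("melody", "melodic_interaction"),
    "dialogue": ("dialogue",),
    "significant_accompaniment": ("significant_accompaniment",),
    "accompaniment": ("accompaniment",),
    "climax": ("climax",),
    "moment_of_concern": ("moment_of_concern",),
}


@dataclass(frozen=True)
class Annotation:
    """One annotated bar span of one category (inclusive bar range)."""

    category: str
    start_bar: int
    end_bar: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.start_bar > self.end_bar:
            raise ValueError("start_bar must not exceed end_bar")
        if self.start_bar < 1:
            raise ValueError("bars are 1-indexed")


@dataclass
class InterpretationMap:
    """All annotations of one musician."""

    musician_id: str
    annotations: list[Annotation] = field(default_factory=list)

    def of_category(self, category: str) -> list[Annotation]:
        return [a for a in self.annotations if a.category == category]


@dataclass
class KernelSignal:
    """Gaussian-kernel encoding of one category's binary vector.

    ``mass_lost`` is the kernel mass truncated at the grid edges (each
    source half-beat contributes unit mass when untruncated).
    """

    category: str
    values: np.ndarray
    center_offset: int = KERNEL_CENTER_OFFSET
    sd: float = KERNEL_SD
    mass_lost: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("kernel signal must be nonnegative")


def map_to_binary(
    imap: InterpretationMap, category: str, grid: ScoreTimeGrid
) -> np.ndarray:
    """Length-L 0/1 vector: 1 on every half-beat inside an annotated span.

    Overlapping spans stay binary (indicator semantics, not counts).
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    out = np.zeros(grid.n_samples)
    for ann in imap.of_category(category):
        first, last = bar_span_to_samples(ann.start_bar, ann.end_bar, grid)
        out[first - 1 : last] = 1.0
    return out


def term_binary(imap: InterpretationMap, term: str, grid: ScoreTimeGrid) -> np.ndarray:
    """Binary vector for a *model term* (union of its categories)."""
    cats = MODEL_TERM_CATEGORIES.get(term)
    if cats is None:
        raise ValueError(f"unknown model term {term!r}")
    out = np.zeros(grid.n_samples)
    for cat in cats:
        out = np.maximum(out, map_to_binary(imap, cat, grid))
    return out


def gaussian_template(sd: float = KERNEL_SD, support_sds: float = KERNEL_SUPPORT_SDS) -> np.ndarray:
    """Discrete unit-mass Gaussian over integer offsets within +/- support_sds."""
    half = int(np.ceil(support_sds * sd))
    d = np.arange(-half, half + 1)
    w = np.exp(-(d**2) / (2.0 * sd**2))
    return w / w.sum()


def binary_to_kernel(
    binary: np.ndarray,
    center_offset: int = KERNEL_CENTER_OFFSET,
    sd: float = KERNEL_SD,
    category: str = "annotation",
    support_sds: float = KERNEL_SUPPORT_SDS,
) -> KernelSignal:
    """Sum of forward-shifted unit-mass Gaussians, one per annotated half-beat.

    Each 1 at (1-indexed) position ``i`` adds a discrete Gaussian
    centered at ``i + center_offset`` with the given SD, normalized to
    unit sum on its untruncated support *before* any edge truncation;
    truncated mass is reported, not redistributed.
    """
    binary = np.asarray(binary, dtype=float)
    if binary.ndim != 1:
        raise ValueError("binary vector must be 1-D")
    if not np.all(np.isin(binary, (0.0, 1.0))):
        raise ValueError("input vector must be binary (0/1)")
    template = gaussian_template(sd, support_sds)
    half = (template.size - 1) // 2
    values = np.zeros(binary.size)
    src = np.flatnonzero(binary > 0)
    for i in src:
        center = i + center_offset
        a = center - half
        b = center + half + 1
        ta = max(0, a)
        tb = min(binary.size, b)
        if ta < tb:
            values[ta:tb] += template[ta - a : tb - a]
    mass_lost = float(binary.sum() - values.sum())
    return KernelSignal(category, values, center_offset, sd, mass_lost)


def read_annotations_csv(path: str | Path) -> dict[str, InterpretationMap]:
    """Read annotation CSV: columns musician, category, start_bar, end_bar."""
    frame = pd.read_csv(path)
    required = {"musician", "category", "start_bar", "end_bar"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"annotation CSV {path} missing columns: {sorted(missing)}")
    maps: dict[str, InterpretationMap] = {}
    for _, row in frame.iterrows():
        musician = str(row["musician"])
        category = _CATEGORY_ALIASES.get(str(row["category"]), str(row["category"]))
        maps.setdefault(musician, InterpretationMap(musician)).annotations.append(
            Annotation(category, int(row["start_bar"]), int(row["end_bar"]))
        )
    return maps


def write_annotations_csv(path: str | Path, maps: dict[str, InterpretationMap]) -> None:
    rows = []
    for musician, imap in sorted(maps.items()):
        for ann in imap.annotations:
            rows.append(
                {"musician": musician, "category": ann.category,
                 "start_bar": ann.start_bar, "end_bar": ann.end_bar}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def kernel_signals_to_csv(path: str | Path, signals: dict[str, KernelSignal]) -> None:
    """Export kernel signals in long format: sample, category, value."""
    rows = []
    for category, sig in sorted(signals.items()):
        for sample, value in enumerate(sig.values, start=1):
            rows.append({"sample": sample, "category": category, "value": value})
    pd.DataFrame(rows).to_csv(path, index=False)
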