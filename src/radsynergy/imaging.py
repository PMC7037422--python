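"""Nucleus counting on Hoechst-like fluorescence fields and growth curves.

The counting pipeline is deliberately plain: Gaussian smoothing, a global
threshold (Otsu by default), 8-connected component labelling and a
minimum-area filter.  There is no watershed splitting: nuclei closer than
the resolution of the global threshold merge into one component, which is
a documented limitation rather than a failure mode.  Image origin is the
top-left corner with 0-based (row, col) indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label

__all__ = [
    "NucleiImage",
    "GrowthSeries",
    "count_nuclei",
    "build_growth_series",
    "growth_inhibition",
]


@dataclass
class NucleiImage:
    """A 2D grayscale field of stained nuclei.

    ``metadata`` may carry generator ground truth (key ``true_count``).
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")

    @property
    def true_count(self) -> int | None:
        return self.metadata.get("true_count")


@dataclass
class GrowthSeries:
    """Per-day nucleus counts: the mean over fields is the growth readout."""

    days: list[int]
    field_counts: dict[int, list[int]]
    mean_counts: dict[int, float]

    def mean_at(self, day: int) -> float:
        if day not in self.mean_counts:
            raise KeyError(f"no counts recorded for day {day}")
        return self.mean_counts[day]


def count_nuclei(
    img: NucleiImage | np.ndarray,
    smooth_sigma: float = 2.0,
    min_area: int = 20,
    threshold_rule: str | float = "otsu",
) -> tuple[int, np.ndarray]:
    """Count nuclei in one field; returns (count, label map).

    Pipeline: Gaussian smooth (``smooth_sigma`` px) -> global threshold
    (``"otsu"`` or an explicit intensity value) -> 8-connected labelling
    -> drop components below ``min_area`` px.  A blank (constant) image
    yields count 0.  The Otsu rule operates on relative intensity, so the
    count is invariant to rescaling the image by a positive constant.
    """
    pixels = img.pixels if isinstance(img, NucleiImage) else np.asarray(img)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError("image must be a non-empty 2D array")
    if not np.all(np.isfinite(pixels)):
        raise ValueError("image contains non-finite pixels")

    smoothed = gaussian(pixels.astype(float), sigma=smooth_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return 0, np.zeros(pixels.shape, dtype=int)
    if threshold_rule == "otsu":
        thr = threshold_otsu(smoothed)
        # Otsu always splits, even a foreground-free noise field; demand the
        # two classes be far apart relative to the overall spread before
        # accepting any foreground.
        fg = smoothed > thr
        if fg.all() or not fg.any() or (
            smoothed[fg].mean() - smoothed[~fg].mean() < 2.0 * smoothed.std()
        ):
            return 0, np.zeros(pixels.shape, dtype=int)
    else:
        thr = float(threshold_rule)
    mask = smoothed > thr
    labels = sk_label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    keep = np.nonzero(counts >= min_area)[0]
    keep = keep[keep != 0]
    relabeled = np.zeros_like(labels)
    for new, old in enumerate(keep, start=1):
        relabeled[labels == old] = new
    return int(keep.size), relabeled


def build_growth_series(
    images_by_day: dict[int, list[NucleiImage | np.ndarray]],
    smooth_sigma: float = 2.0,
    min_area: int = 20,
    threshold_rule: str | float = "otsu",
) -> GrowthSeries:
    """Count every field of every day and average per day.

    Missing days are simply absent from the series (no interpolation).
    """
    if not images_by_day:
        raise ValueError("need at least one day of images")
    days = sorted(images_by_day)
    field_counts: dict[int, list[int]] = {}
    mean_counts: dict[int, float] = {}
    for day in days:
        fields = images_by_day[day]
        if not fields:
            raise ValueError(f"day {day} has no fields")
        counts = [
            count_nuclei(f, smooth_sigma=smooth_sigma, min_area=min_area,
                         threshold_rule=threshold_rule)[0]
            for f in fields
        ]
        field_counts[day] = counts
        mean_counts[day] = float(np.mean(counts))
    return GrowthSeries(days=days, field_counts=field_counts, mean_counts=mean_counts)


def growth_inhibition(treated: GrowthSeries, control: GrowthSeries, day: int) -> float:
    """Fractional growth inhibition 1 - treated/control at ``day``.

    0 means identical growth, 1 means no treated cells; negative values
    indicate faster growth than control.
    """
    t = treated.mean_at(day)
    c = control.mean_at(day)
    if c <= 0:
        raise ValueError(f"control count at day {day} must be > 0")
    return min(1.0, 1.0 - t / c)


def growth_table(series_by_condition: dict[str, GrowthSeries]) -> pd.DataFrame:
    """Tidy (condition, day, field, count) table from several growth series."""
    rows = []
    for condition, series in series_by_condition.items():
        for day in series.days:
            for i, c in enumerate(series.field_counts[day]):
                rows.append({"condition": condition, "day": day, "field": i, "count": c})
    return pd.DataFrame(rows)
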