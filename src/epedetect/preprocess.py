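"""MRI intensity processing: histogram-landmark standardization and Z-scoring.

The standardization step follows the Nyul–Udupa histogram-landmark scheme:
a set of intensity percentiles is computed on each training image (inside
the prostate mask when one is supplied), the per-percentile means over the
cohort become the *landmarks*, and at apply time each image's own
percentile values are mapped piecewise-linearly onto the landmarks.  The
map is monotone, exact at the knots, and linearly extrapolated beyond the
outer landmarks from the end segments.

Z-score normalization is computed over the prostate region only
(population standard deviation) and applied to the whole grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .volio import Volume3D, check_aligned

__all__ = ["LandmarkSet", "learn_landmarks", "standardize", "zscore_region", "DEFAULT_PERCENTILES"]

# deciles with robust 1/99 endpoints; the common configuration of the method
DEFAULT_PERCENTILES: tuple[float, ...] = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)


@dataclass
class LandmarkSet:
    """Percentile positions and cohort-mean intensities at those percentiles."""

    percentiles: tuple[float, ...]
    landmarks: tuple[float, ...]

    def __post_init__(self) -> None:
        self.percentiles = tuple(float(p) for p in self.percentiles)
        self.landmarks = tuple(float(v) for v in self.landmarks)
        if len(self.percentiles) != len(self.landmarks):
            raise ValueError("percentiles and landmarks must have equal length")
        if len(self.percentiles) < 2:
            raise ValueError("need at least two landmarks for a piecewise-linear map")
        if not all(0 < p < 100 for p in self.percentiles):
            raise ValueError("percentiles must lie strictly inside (0, 100)")
        if np.any(np.diff(self.percentiles) <= 0):
            raise ValueError("percentiles must be strictly increasing")
        if np.any(np.diff(self.landmarks) <= 0):
            raise ValueError("mean landmarks must be strictly increasing (monotone map)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"percentiles": self.percentiles, "landmarks": self.landmarks}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["percentiles"]), tuple(d["landmarks"]))


def _region_values(image: Volume3D, mask: Volume3D | None) -> np.ndarray:
    if mask is None:
        return image.data.ravel()
    check_aligned([image, mask], names=["image", "mask"])
    vals = image.data[mask.astype_bool()]
    if vals.size == 0:
        raise ValueError("mask selects no voxels")
    return vals


def _percentile_values(image: Volume3D, percentiles, mask: Volume3D | None) -> np.ndarray:
    vals = _region_values(image, mask)
    if np.ptp(vals) == 0:
        raise ValueError("constant image: percentile spread undefined")
    return np.percentile(vals, percentiles)


def learn_landmarks(
    images: list[Volume3D],
    masks: list[Volume3D | None] | None = None,
    percentiles=DEFAULT_PERCENTILES,
) -> LandmarkSet:
    """Learn cohort-mean intensity landmarks at the given percentiles.

    For each training image the intensities at `percentiles` are computed
    (within its prostate mask when provided); the landmark set is the
    per-percentile mean over the cohort.
    """
    if not images:
        raise ValueError("need at least one training image")
    if masks is None:
        masks = [None] * len(images)
    if len(masks) != len(images):
        raise ValueError("masks list must match images list")
    per_image = np.stack(
        [_percentile_values(im, percentiles, m) for im, m in zip(images, masks)]
    )
    return LandmarkSet(tuple(percentiles), tuple(per_image.mean(axis=0)))


def standardize(image: Volume3D, lm: LandmarkSet, mask: Volume3D | None = None) -> Volume3D:
    """Map an image's intensity histogram onto the learned landmarks.

    The image's own percentile values (within `mask` when given) become the
    source knots; values between knots are interpolated linearly, values
    outside the outer knots are extrapolated with the slope of the adjacent
    end segment.  Grid and spacing are unchanged.
    """
    knots = _percentile_values(image, lm.percentiles, mask)
    if np.any(np.diff(knots) <= 0):
        raise ValueError("image percentile values are not strictly increasing; cannot build a monotone map")
    targets = np.asarray(lm.landmarks)
    x = image.data.astype(float)
    out = np.interp(x, knots, targets)
    # linear extrapolation beyond the outer landmarks from the end segments
    lo_slope = (targets[1] - targets[0]) / (knots[1] - knots[0])
    hi_slope = (targets[-1] - targets[-2]) / (knots[-1] - knots[-2])
    below = x < knots[0]
    above = x > knots[-1]
    out[below] = targets[0] + (x[below] - knots[0]) * lo_slope
    out[above] = targets[-1] + (x[above] - knots[-1]) * hi_slope
    return image.like(out, kind="intensity")


def zscore_region(image: Volume3D, region: Volume3D) -> Volume3D:
    """Z-score the image using the mean/std of the voxels inside `region`.

    Uses the population standard deviation; after the transform the
    within-region mean is 0 and std is 1.  Applied to the whole grid.
    """
    check_aligned([image, region], names=["image", "region"])
    sel = region.astype_bool()
    if not sel.any():
        raise ValueError("region is empty")
    vals = image.data[sel].astype(float)
    mu = vals.mean()
    sigma = vals.std()  # population std (ddof=0)
    if sigma == 0:
        raise ValueError("zero variance within region")
    return image.like((image.data.astype(float) - mu) / sigma, kind="intensity")
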