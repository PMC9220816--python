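"""Division of the volume into the six standard prostate sextants.

Mirroring systematic 12-core biopsy sampling, the prostate is split into
{apex, mid, base} x {left, right}.  The zone of a voxel depends only on
its slice index, the side only on its x coordinate, and the partition
covers the *whole* grid (not just the gland) so that extraprostatic
prediction voxels are attributable to a sextant.

Slice allocation: with ``n`` prostate-bearing slices and ``k = n // 3``,
apex gets the first ``k`` slices, mid ``k`` (plus one when ``n % 3 == 2``),
base the rest — the remainder goes to base first, then mid.  Slices before
the prostate span inherit apex, slices after inherit base.  The left/right
boundary is the sagittal plane through the prostate centroid x (configurable
to the image midline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volio import Volume3D, check_aligned

__all__ = ["SextantPartition", "partition", "region_flags", "SEXTANT_NAMES"]

ZONES = ("apex", "mid", "base")
SIDES = ("left", "right")

#: label -> (zone, side); labels 1..6
SEXTANT_NAMES: dict[int, tuple[str, str]] = {
    1: ("apex", "left"),
    2: ("apex", "right"),
    3: ("mid", "left"),
    4: ("mid", "right"),
    5: ("base", "left"),
    6: ("base", "right"),
}


@dataclass
class SextantPartition:
    """Whole-grid sextant labelmap with labels 1..6 and their legend."""

    labelmap: Volume3D
    legend: dict[int, tuple[str, str]]

    def region(self, label: int) -> np.ndarray:
        return self.labelmap.data == label

    def label_of(self, zone: str, side: str) -> int:
        for lab, (z, s) in self.legend.items():
            if (z, s) == (zone, side):
                return lab
        raise KeyError(f"no sextant ({zone}, {side})")


def _zone_of_slices(shape_z: int, prostate_slices: np.ndarray) -> np.ndarray:
    """Zone index (0=apex, 1=mid, 2=base) for every slice of the grid."""
    n = len(prostate_slices)
    k, r = divmod(n, 3)
    n_apex = k
    n_mid = k + (1 if r == 2 else 0)
    zone = np.empty(shape_z, dtype=np.int8)
    first, last = prostate_slices[0], prostate_slices[-1]
    zone[: first] = 0
    zone[last + 1 :] = 2
    for i, z in enumerate(prostate_slices):
        if i < n_apex:
            zone[z] = 0
        elif i < n_apex + n_mid:
            zone[z] = 1
        else:
            zone[z] = 2
    return zone


def partition(prostate: Volume3D, side_split: str = "centroid") -> SextantPartition:
    """Partition the grid into six sextants from the prostate mask.

    side_split : "centroid" (sagittal plane through the prostate centroid x,
    the default) or "midline" (image center plane).  Voxels with x at or
    above the split plane are labeled "right", below it "left"; under the
    RAS+ load convention larger x is further toward the anatomical right.
    """
    pr = prostate.astype_bool()
    if not pr.any():
        raise ValueError("prostate mask is empty")
    nx, ny, nz = pr.shape
    prostate_slices = np.flatnonzero(pr.any(axis=(0, 1)))
    zone = _zone_of_slices(nz, prostate_slices)

    if side_split == "centroid":
        split_x = pr.nonzero()[0].mean()
    elif side_split == "midline":
        split_x = (nx - 1) / 2.0
    else:
        raise ValueError(f"side_split must be 'centroid' or 'midline', got {side_split!r}")
    xs = np.arange(nx)
    is_right = xs >= split_x  # (nx,)

    # label = zone-base + side offset: left columns get odd labels 1/3/5
    zone_base = {0: 1, 1: 3, 2: 5}
    labels = np.empty((nx, ny, nz), dtype=np.uint8)
    for zi, base in zone_base.items():
        zmask = zone == zi
        if not zmask.any():
            continue
        labels[:, :, zmask] = (base + is_right.astype(np.uint8))[:, None, None]
    lm = Volume3D(labels, prostate.spacing, kind="labelmap")
    return SextantPartition(labelmap=lm, legend=dict(SEXTANT_NAMES))


def region_flags(v: Volume3D, part: SextantPartition) -> dict[int, bool]:
    """Per-sextant positivity: any nonzero voxel of ``v`` inside the region.

    Works for EPE label volumes and prediction maps alike; voxels outside
    the anatomical prostate count toward the sextant whose whole-grid
    region contains them.
    """
    check_aligned([v, part.labelmap], names=["volume", "sextants"])
    nz = v.data != 0
    return {lab: bool(np.any(nz & part.region(lab))) for lab in sorted(part.legend)}
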