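"""Reading, writing and validating co-registered 3D volumes.

All volumes in the package live on a common axis convention: the array is
indexed ``(x, y, z)`` where *x* runs left–right, *y* posterior–anterior and
*z* is the slice index (apex to base for a standard axial acquisition).
Files are reoriented to the closest RAS+ orientation on load so that the
convention holds regardless of how the NIfTI was stored.  What matters
downstream is only that *x* is the left–right axis; which end of it is
called "left" is configurable in :mod:`epedetect.sextants`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "read_volume", "write_volume", "check_aligned", "AlignmentError"]

VALID_KINDS = ("probability", "intensity", "mask", "labelmap")

#: spacing comparisons are "identical within this many mm"
SPACING_ATOL_MM = 1e-6


class AlignmentError(ValueError):
    """Raised when volumes expected to share a grid do not."""


@dataclass
class Volume3D:
    """A scalar field on a regular 3D grid with physical spacing.

    Parameters
    ----------
    data
        3D array indexed ``(x, y, z)``.
    spacing
        ``(dx, dy, dz)`` voxel spacing in mm; ``dx, dy`` in-plane,
        ``dz`` the slice distance.
    kind
        Role of the values: ``probability`` (values in [0, 1]),
        ``intensity`` (unconstrained finite), ``mask`` (values in {0, 1})
        or ``labelmap`` (non-negative integers).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    kind: str = "intensity"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive mm values, got {self.spacing}")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")
        if self.kind == "probability":
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < 0.0 or hi > 1.0:
                raise ValueError(f"probability volume has values outside [0, 1]: min={lo}, max={hi}")
        elif self.kind == "mask":
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"mask volume has values outside {{0, 1}}: {vals[:10]}")
        elif self.kind == "labelmap":
            if self.data.min() < 0:
                raise ValueError("labelmap volume has negative labels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def astype_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    def like(self, data: np.ndarray, kind: str | None = None) -> "Volume3D":
        """New volume on the same grid."""
        return Volume3D(data, self.spacing, kind or self.kind)

    def __eq__(self, other: object) -> bool:  # grid + values, used in round-trip tests
        if not isinstance(other, Volume3D):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=SPACING_ATOL_MM)
            and np.array_equal(self.data, other.data)
        )


def read_volume(path: str | Path, kind: str = "intensity") -> Volume3D:
    """Load a NIfTI volume, reorienting to the package axis convention.

    Spacing is taken from the file header.  A non-3D image or non-finite
    voxel data is a hard error, as is any violation of the ``kind``
    invariants (e.g. a probability file containing 1.2).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return Volume3D(data, tuple(float(z) for z in zooms), kind)


def write_volume(v: Volume3D, path: str | Path) -> None:
    """Write a volume as NIfTI with an RAS+ affine built from its spacing."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    data = v.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = np.diag([*v.spacing, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def check_aligned(vs: Sequence[Volume3D], names: Iterable[str] | None = None) -> None:
    """Verify that all volumes share one grid (shape + spacing within 1e-6 mm).

    Raises :class:`AlignmentError` naming the first offending volume.
    """
    vs = list(vs)
    if len(vs) < 2:
        raise ValueError("check_aligned needs at least two volumes")
    names = list(names) if names is not None else [f"volume[{i}]" for i in range(len(vs))]
    ref = vs[0]
    for name, v in zip(names[1:], vs[1:]):
        if v.shape != ref.shape:
            raise AlignmentError(f"{name}: shape {v.shape} differs from {names[0]} shape {ref.shape}")
        if not np.allclose(v.spacing, ref.spacing, atol=SPACING_ATOL_MM):
            raise AlignmentError(
                f"{name}: spacing {v.spacing} differs from {names[0]} spacing {ref.spacing}"
            )
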