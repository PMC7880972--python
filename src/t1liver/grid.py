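"""Shared 3D volume container with NIfTI round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid"]


@dataclass
class VolumeGrid:
    """A 3D scalar lattice with voxel spacing and a voxel-to-mm affine.

    Carrier type for SPGR magnitude images, B1 maps, T1 maps and binary
    masks.  ``affine`` maps 0-based voxel indices to physical millimetre
    coordinates; when omitted it defaults to ``diag(spacing)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def like(self, values: np.ndarray) -> "VolumeGrid":
        """New grid holding ``values`` with this grid's geometry."""
        if np.shape(values) != self.shape:
            raise ValueError("values shape does not match grid shape")
        return VolumeGrid(np.asarray(values), self.spacing, self.affine.copy())

    def congruent(self, other: "VolumeGrid", rtol: float = 1e-5) -> bool:
        """True when shapes, spacings and affines match."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, rtol=rtol)
            and np.allclose(self.affine, other.affine, rtol=rtol, atol=1e-8)
        )

    def to_nifti(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(np.asarray(self.values), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VolumeGrid":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(data), spacing, np.asarray(img.affine))
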