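"""Voxel-grid containers shared by every pipeline stage.

A :class:`VoxelImage` is a 3-D scalar array on a regular grid with voxel
spacing in mm and a grid origin in mm (position of the corner of voxel
``(0, 0, 0)``); voxel centres sit at ``origin + (index + 0.5) * spacing``.
Array axes are ordered (x, y, z) = (left-right, anterior-posterior,
inferior-superior); axis 2 is the slice (axial) direction.

A :class:`StructureSet` holds named binary masks sharing one grid.
NIfTI round-tripping goes through nibabel with a diagonal affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class VoxelImage:
    """3-D scalar image with spacing (mm) and origin (mm).

    ``data`` may carry cT1 (ms), relative electron density (unitless),
    dose (Gy) or a binary mask (bool).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VoxelImage requires a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def voxel_centres(self) -> np.ndarray:
        """(N, 3) array of voxel-centre coordinates in mm, C-order flat."""
        axes = [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        ]
        grids = np.meshgrid(*axes, indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def same_grid(self, other: "VoxelImage", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def copy(self, data: np.ndarray | None = None) -> "VoxelImage":
        return VoxelImage(
            data=self.data.copy() if data is None else data,
            spacing=self.spacing,
            origin=self.origin,
            meta=dict(self.meta),
        )

    # ------------------------------------------------------------------ I/O
    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = np.asarray(self.origin) + 0.5 * np.asarray(self.spacing)
        arr = self.data.astype(np.uint8) if self.data.dtype == bool else self.data
        return nib.Nifti1Image(arr, affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path, as_mask: bool = False) -> "VoxelImage":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(affine[a, a]) for a in range(3))
        origin = tuple(
            float(affine[a, 3]) - 0.5 * spacing[a] for a in range(3)
        )
        data = np.asanyarray(img.dataobj)
        if as_mask:
            data = data > 0.5
        return cls(data=data, spacing=spacing, origin=origin)


class StructureSet:
    """Named binary masks sharing one grid (spacing/origin/shape)."""

    def __init__(
        self,
        spacing: tuple[float, float, float],
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
        masks: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        self.spacing = tuple(float(s) for s in spacing)
        self.origin = tuple(float(o) for o in origin)
        self._masks: dict[str, np.ndarray] = {}
        if masks:
            for name, m in masks.items():
                self[name] = m

    def __setitem__(self, name: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask)
        if mask.dtype != bool:
            mask = mask > 0.5
        if self._masks:
            ref = next(iter(self._masks.values()))
            if mask.shape != ref.shape:
                raise ValueError(
                    f"mask {name!r} shape {mask.shape} does not match "
                    f"structure-set grid {ref.shape}"
                )
        self._masks[name] = mask

    def __getitem__(self, name: str) -> np.ndarray:
        return self._masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self._masks

    def __iter__(self) -> Iterator[str]:
        return iter(self._masks)

    def names(self) -> list[str]:
        return list(self._masks)

    def image(self, name: str) -> VoxelImage:
        return VoxelImage(self._masks[name], self.spacing, self.origin)

    def save_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self._masks:
            self.image(name).save(directory / f"{name}.nii.gz")

    @classmethod
    def load_dir(cls, directory: str | Path) -> "StructureSet":
        directory = Path(directory)
        paths = sorted(directory.glob("*.nii.gz"))
        if not paths:
            raise FileNotFoundError(f"no NIfTI masks under {directory}")
        first = VoxelImage.load(paths[0], as_mask=True)
        ss = cls(first.spacing, first.origin)
        for p in paths:
            img = VoxelImage.load(p, as_mask=True)
            ss[p.name.replace(".nii.gz", "")] = img.data
        return ss


# --------------------------------------------------------------- operations
def expand_mask(
    mask: np.ndarray, margin_mm: float, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Isotropic Euclidean expansion of a binary mask by ``margin_mm``.

    Used for PTV = GTV + margin and PRV = OAR + margin.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin_mm


def resample_mask_nearest(
    mask_img: VoxelImage,
    target_shape: tuple[int, int, int],
    target_spacing: tuple[float, float, float],
    target_origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> VoxelImage:
    """Nearest-neighbour resampling of a binary mask onto a target grid.

    Each target voxel takes the value of the source voxel containing its
    centre; centres outside the source grid map to False.  Keeps the mask
    binary, as required when moving the functional-liver mask onto the
    planning grid.
    """
    src = mask_img.data
    idx = []
    inside = np.ones(target_shape, dtype=bool)
    for a in range(3):
        centres = target_origin[a] + (np.arange(target_shape[a]) + 0.5) * target_spacing[a]
        i = np.floor((centres - mask_img.origin[a]) / mask_img.spacing[a]).astype(int)
        ok = (i >= 0) & (i < src.shape[a])
        shape = [1, 1, 1]
        shape[a] = -1
        inside &= ok.reshape(shape)
        idx.append(np.clip(i, 0, src.shape[a] - 1))
    ii, jj, kk = np.meshgrid(*idx, indexing="ij")
    out = src[ii, jj, kk] & inside
    return VoxelImage(out, target_spacing, target_origin)


def downsample_mask_inplane(mask_img: VoxelImage, factor: int) -> VoxelImage:
    """In-plane block-vote downsampling of a mask: block mean >= 0.5 is inside."""
    from .segmentation import downsample_inplane  # local import, no cycle at call time

    ds = downsample_inplane(
        VoxelImage(mask_img.data.astype(float), mask_img.spacing, mask_img.origin),
        factor,
    )
    return VoxelImage(ds.data >= 0.5, ds.spacing, ds.origin, meta=ds.meta)
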