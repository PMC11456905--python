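"""Dose-volume-histogram and volume bookkeeping metrics.

Point-dose metrics (Dx%, Dycc) are computed on sorted voxel doses rather
than a binned histogram, so small worked examples are exact; the binned
:class:`DVH` is provided for plotting and agrees with the sorted-voxel
metrics to within one bin width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import VoxelImage


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure."""

    structure: str
    bin_edges_gy: np.ndarray  # len n_bins + 1
    cumulative_fraction: np.ndarray  # len n_bins + 1, fraction receiving >= edge
    voxel_volume_cc: float
    n_voxels: int

    @classmethod
    def from_dose(
        cls,
        dose: VoxelImage,
        mask: np.ndarray,
        structure: str = "",
        bin_width_gy: float = 0.05,
    ) -> "DVH":
        d = dose.data[np.asarray(mask, bool)]
        if d.size == 0:
            raise ValueError("empty structure mask")
        top = max(float(d.max()), bin_width_gy)
        edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
        frac = np.array([(d >= e).mean() for e in edges])
        return cls(structure, edges, frac, dose.voxel_volume_cc, int(d.size))

    @property
    def volume_cc(self) -> float:
        return self.n_voxels * self.voxel_volume_cc


def volume_cc(mask: np.ndarray, spacing_mm: tuple[float, float, float]) -> float:
    """Structure volume in cc: voxel count x voxel volume / 1000."""
    mask = np.asarray(mask, dtype=bool)
    return float(mask.sum()) * float(np.prod(spacing_mm)) / 1000.0


def functional_ratio_percent(flv_cc: float, fov_cc: float) -> int:
    """Functional fraction of the imaged liver as an integer percent.

    round(100 * FLV / FOV), half away from zero.
    """
    if fov_cc <= 0:
        raise ZeroDivisionError("FOV volume must be positive for the ratio")
    r = 100.0 * flv_cc / fov_cc
    return int(np.floor(r + 0.5)) if r >= 0 else -int(np.floor(-r + 0.5))


def _structure_doses(dose: VoxelImage | np.ndarray, mask: np.ndarray) -> np.ndarray:
    arr = dose.data if isinstance(dose, VoxelImage) else np.asarray(dose)
    d = arr[np.asarray(mask, bool)]
    if d.size == 0:
        raise ValueError("empty structure mask")
    return np.asarray(d, dtype=float)


def dose_at_volume_percent(dose, mask: np.ndarray, p_percent: float) -> float:
    """D_p%: maximum dose d such that at least p% of the structure gets >= d.

    Computed on sorted voxel doses (no binning); D100% is the minimum voxel
    dose and Dp of a uniform dose is that dose.
    """
    if not (0 < p_percent <= 100):
        raise ValueError("p_percent must be in (0, 100]")
    d = np.sort(_structure_doses(dose, mask))[::-1]
    k = int(np.ceil(p_percent / 100.0 * d.size))
    return float(d[k - 1])


def dose_at_volume_cc(dose, mask: np.ndarray, cc: float, voxel_volume_cc: float | None = None) -> float:
    """D_ycc: maximum dose such that at least y cc of the structure gets >= d.

    Fractional voxels are handled by linear interpolation on the sorted-dose
    cumulative-volume curve; cc -> 0+ gives the maximum voxel dose.
    """
    if isinstance(dose, VoxelImage) and voxel_volume_cc is None:
        voxel_volume_cc = dose.voxel_volume_cc
    if voxel_volume_cc is None:
        raise ValueError("voxel_volume_cc required for array input")
    d = np.sort(_structure_doses(dose, mask))[::-1]
    total = d.size * voxel_volume_cc
    if cc > total + 1e-12:
        raise ValueError(f"requested {cc} cc exceeds structure volume {total} cc")
    if cc <= 0:
        raise ValueError("cc must be positive")
    cum = (np.arange(1, d.size + 1)) * voxel_volume_cc
    return float(np.interp(cc, cum, d))


def volume_at_dose_percent(dose, mask: np.ndarray, level_gy: float, direction: str = "ge") -> float:
    """V_zGy as a percent of the structure volume.

    ``direction='ge'`` (default) is the fraction receiving >= level;
    ``direction='lt'`` is the fraction receiving < level — some liver
    criteria are stated as the volume kept BELOW a dose level, so both
    conventions are available by name.
    """
    d = _structure_doses(dose, mask)
    if direction == "ge":
        return float(100.0 * (d >= level_gy).mean())
    if direction == "lt":
        return float(100.0 * (d < level_gy).mean())
    raise ValueError("direction must be 'ge' or 'lt'")


def mean_dose(dose, mask: np.ndarray) -> float:
    """Arithmetic mean voxel dose over the structure."""
    return float(_structure_doses(dose, mask).mean())


@dataclass
class VolumeSummary:
    """Per-patient volume bookkeeping row (all volumes in cc)."""

    liver_cc: float
    gtv_cc: float
    liver_minus_gtv_cc: float
    fov_cc: float  # liver inside the cT1 field of view
    flv_cc: float
    ratio_percent: int
    rx_gy: float | None = None

    @classmethod
    def from_masks(
        cls,
        structures,
        flv: "VoxelImage",
        rx_gy: float | None = None,
    ) -> "VolumeSummary":
        """Build the row from a structure set plus the FLV mask image.

        The FLV may live on a different (working/planning) grid than the
        structures; its own spacing is used for its volume.
        """
        spacing = structures.spacing
        liver = structures["liver"]
        gtv = structures["gtv"]
        fov = structures["fov"]
        liver_cc_ = volume_cc(liver, spacing)
        gtv_cc_ = volume_cc(gtv & liver, spacing)
        fov_cc_ = volume_cc(liver & fov, spacing)
        flv_cc_ = volume_cc(flv.data, flv.spacing)
        return cls(
            liver_cc=liver_cc_,
            gtv_cc=gtv_cc_,
            liver_minus_gtv_cc=liver_cc_ - gtv_cc_,
            fov_cc=fov_cc_,
            flv_cc=flv_cc_,
            ratio_percent=functional_ratio_percent(flv_cc_, fov_cc_) if fov_cc_ > 0 else 0,
            rx_gy=rx_gy,
        )
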