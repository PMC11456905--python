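"""Seeded synthetic abdominal phantoms for the planning study.

Each phantom carries a cT1 map (ms) with spatially correlated heterogeneity
inside an ellipsoidal liver, a spherical tumour (GTV) inside the liver, a
body outline, lung and vertebral regions for electron-density overrides, two
organs at risk (a spinal-canal-like and a bowel-like tube), and a cT1
field-of-view mask that covers only part of the liver's axial extent, as
acquisitions restricted to a fixed slice stack do.

The fraction of liver∩FOV voxels below the functional threshold is imposed
exactly: the correlated field is cut at its empirical quantile and voxels on
each side draw cT1 values from Gaussians around the low/high component means,
clipped to their side of the threshold.  All geometry is deliberately simple
(ellipsoids and tubes); anatomical realism is a non-goal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import StructureSet, VoxelImage


@dataclass
class PhantomConfig:
    """Geometry and cT1-mixture parameters of one synthetic patient.

    Spacing defaults to 1.1 x 1.1 x 8.0 mm (thin in-plane pixels, 8 mm axial
    slices, as in abdominal quantitative-MR stacks).  ``ct1_low_mean`` and
    ``ct1_high_mean`` are the component means (ms) of the functional /
    non-functional cT1 mixture; ``functional_fraction_target`` controls the
    fraction of liver∩FOV voxels below ``ct1_boundary_ms``.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 24)
    spacing_mm: tuple[float, float, float] = (1.1, 1.1, 8.0)
    functional_fraction_target: float = 0.5
    ct1_low_mean: float = 700.0
    ct1_high_mean: float = 950.0
    ct1_sd: float = 40.0
    ct1_boundary_ms: float = 800.0
    correlation_length_mm: float = 15.0
    gtv_radius_mm: float = 12.0
    gtv_offset_mm: tuple[float, float, float] = (8.0, 6.0, -12.0)
    fov_coverage_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.functional_fraction_target <= 1.0):
            raise ValueError("functional_fraction_target must be in [0, 1]")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if any(int(n) != n or n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive integers")
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if self.correlation_length_mm < 0:
            raise ValueError("correlation_length_mm must be >= 0")
        if not (0.0 < self.fov_coverage_fraction <= 1.0):
            raise ValueError("fov_coverage_fraction must be in (0, 1]")


@dataclass
class SyntheticPatient:
    ct1_map: VoxelImage
    structures: StructureSet
    seed: int
    realized_functional_fraction: float
    config: PhantomConfig = field(repr=False, default=None)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.ct1_map.save(directory / "ct1.nii.gz")
        self.structures.save_dir(directory / "structures")
        manifest = {
            "seed": int(self.seed),
            "realized_functional_fraction": self.realized_functional_fraction,
            "config": _config_to_jsonable(self.config),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "SyntheticPatient":
        directory = Path(directory)
        ct1 = VoxelImage.load(directory / "ct1.nii.gz")
        structures = StructureSet.load_dir(directory / "structures")
        manifest = json.loads((directory / "manifest.json").read_text())
        cfg = manifest.get("config") or {}
        for key in ("grid_shape", "spacing_mm", "gtv_offset_mm"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return cls(
            ct1_map=ct1,
            structures=structures,
            seed=manifest["seed"],
            realized_functional_fraction=manifest["realized_functional_fraction"],
            config=PhantomConfig(**cfg) if cfg else None,
        )


def _config_to_jsonable(cfg: PhantomConfig | None) -> dict | None:
    if cfg is None:
        return None
    d = asdict(cfg)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def make_correlated_field(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    correlation_length_mm: float,
    seed: int,
) -> VoxelImage:
    """Zero-mean, unit-variance spatially correlated Gaussian field.

    White noise is convolved with a Gaussian whose sigma (in voxels) is
    ``correlation_length_mm / spacing`` per axis, then standardized
    empirically.  ``correlation_length_mm = 0`` returns plain white noise.
    Identical seeds give bit-identical fields.
    """
    if any(int(n) != n or n <= 0 for n in shape):
        raise ValueError("shape must be positive integers")
    if correlation_length_mm < 0:
        raise ValueError("correlation_length_mm must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(tuple(int(n) for n in shape))
    if correlation_length_mm > 0:
        sigma = tuple(correlation_length_mm / s for s in spacing)
        fieldv = ndimage.gaussian_filter(noise, sigma, mode="reflect")
    else:
        fieldv = noise
    fieldv = (fieldv - fieldv.mean()) / fieldv.std()
    return VoxelImage(fieldv, spacing)


def _ellipsoid(coords, centre, semi_axes) -> np.ndarray:
    x, y, z = coords
    return (
        ((x - centre[0]) / semi_axes[0]) ** 2
        + ((y - centre[1]) / semi_axes[1]) ** 2
        + ((z - centre[2]) / semi_axes[2]) ** 2
    ) <= 1.0


def _tube(coords, centre_xy, radius, z_lo=None, z_hi=None) -> np.ndarray:
    x, y, z = coords
    m = ((x - centre_xy[0]) ** 2 + (y - centre_xy[1]) ** 2) <= radius**2
    if z_lo is not None:
        m &= z >= z_lo
    if z_hi is not None:
        m &= z <= z_hi
    return m


def generate_patient(config: PhantomConfig) -> SyntheticPatient:
    """Build one synthetic patient: cT1 map plus structure set.

    Raises ``ValueError`` when the GTV sphere does not fit inside the liver.
    """
    nx, ny, nz = config.grid_shape
    sx, sy, sz = config.spacing_mm
    ext = (nx * sx, ny * sy, nz * sz)
    centre = tuple(e / 2 for e in ext)

    ax = (np.arange(nx) + 0.5) * sx
    ay = (np.arange(ny) + 0.5) * sy
    az = (np.arange(nz) + 0.5) * sz
    x, y, z = np.meshgrid(ax, ay, az, indexing="ij")
    coords = (x, y, z)

    # body: elliptical cylinder over all slices
    body = (((x - centre[0]) / (0.47 * ext[0])) ** 2 + ((y - centre[1]) / (0.43 * ext[1])) ** 2) <= 1.0

    # liver: ellipsoid shifted toward the patient's right and slightly posterior
    liver_centre = (centre[0] - 0.17 * ext[0], centre[1] - 0.02 * ext[1], centre[2])
    liver_axes = (0.27 * ext[0], 0.30 * ext[1], 0.37 * ext[2])
    liver = _ellipsoid(coords, liver_centre, liver_axes) & body

    gtv_centre = tuple(c + o for c, o in zip(liver_centre, config.gtv_offset_mm))
    gtv = _ellipsoid(coords, gtv_centre, (config.gtv_radius_mm,) * 3)
    if not gtv.any():
        raise ValueError("GTV is empty on this grid; increase gtv_radius_mm")
    if (gtv & ~liver).any():
        raise ValueError("GTV radius too large: tumour extends outside the liver")

    # lungs: two superior ellipsoids
    lung_z = ext[2] - 0.12 * ext[2]
    lung = (
        _ellipsoid(coords, (centre[0] - 0.21 * ext[0], centre[1] - 0.06 * ext[1], lung_z),
                   (0.17 * ext[0], 0.15 * ext[1], 0.22 * ext[2]))
        | _ellipsoid(coords, (centre[0] + 0.21 * ext[0], centre[1] - 0.06 * ext[1], lung_z),
                     (0.17 * ext[0], 0.15 * ext[1], 0.22 * ext[2]))
    ) & body & ~liver

    vertebrae = _tube(coords, (centre[0], centre[1] + 0.32 * ext[1]), 11.0) & body
    spinal_canal = _tube(coords, (centre[0], centre[1] + 0.32 * ext[1]), 4.0) & body
    bowel = (
        _tube(coords, (centre[0] + 0.22 * ext[0], centre[1] - 0.27 * ext[1]), 13.0, z_hi=centre[2])
        & body & ~liver
    )

    # cT1 FOV: whole-grid in-plane, axial slices truncated from the superior end
    liver_slices = np.nonzero(liver.any(axis=(0, 1)))[0]
    n_keep = max(1, int(round(config.fov_coverage_fraction * liver_slices.size)))
    fov = np.zeros((nx, ny, nz), dtype=bool)
    fov[:, :, liver_slices[0]: liver_slices[0] + n_keep] = True

    # cT1 map: background tissue / lung values plus the liver mixture
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(2)
    fld = make_correlated_field(
        config.grid_shape, config.spacing_mm, config.correlation_length_mm, int(seeds[0])
    ).data
    rng = np.random.default_rng(int(seeds[1]))

    ct1 = np.full(config.grid_shape, 1100.0)
    ct1[lung] = 300.0

    t = config.functional_fraction_target
    region = liver & fov
    if t <= 0.0:
        low_in_liver = np.zeros_like(liver)
    elif t >= 1.0:
        low_in_liver = liver.copy()
    else:
        thr = np.quantile(fld[region], t)
        low_in_liver = liver & (fld <= thr)
    high_in_liver = liver & ~low_in_liver

    b = config.ct1_boundary_ms
    n_low = int(low_in_liver.sum())
    n_high = int(high_in_liver.sum())
    # component draws clipped to their side of the boundary so the imposed
    # fraction is exact, including the degenerate targets 0 and 1
    ct1[low_in_liver] = np.clip(
        rng.normal(config.ct1_low_mean, config.ct1_sd, n_low), 1.0, b - 1.0
    )
    ct1[high_in_liver] = np.clip(
        rng.normal(config.ct1_high_mean, config.ct1_sd, n_high), b + 1.0, None
    )

    realized = float((ct1[region] < b).mean()) if region.any() else 0.0

    structures = StructureSet(config.spacing_mm)
    structures["body"] = body
    structures["liver"] = liver
    structures["gtv"] = gtv
    structures["lung"] = lung
    structures["vertebrae"] = vertebrae
    structures["spinal_canal"] = spinal_canal
    structures["bowel"] = bowel
    structures["fov"] = fov

    return SyntheticPatient(
        ct1_map=VoxelImage(ct1, config.spacing_mm),
        structures=structures,
        seed=config.seed,
        realized_functional_fraction=realized,
        config=config,
    )
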