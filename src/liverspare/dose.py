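"""Density-aware pencil-beam dose engine.

A deliberately simple, linear engine: parallel (non-divergent) beamlets on a
5 mm lattice, primary attenuation exp(-mu_eff * radiological depth) along
the ray, and a Gaussian lateral profile around each beamlet axis.  The
radiological depth is the exact line integral of relative electron density
through the voxel grid (plane-crossing ray traversal, no sampling error).

The engine exists to compare standard and functional-liver-sparing plans
under identical physics; its constants are toy values and are not calibrated
to any clinical beam model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from .grids import VoxelImage

#: dose-influence entries below this fraction of their column maximum are dropped
COLUMN_TRUNCATION = 1e-4
#: hard lateral cut for candidate voxels, in units of lateral_sigma
LATERAL_CUTOFF_SIGMA = 4.5


def beam_angles(n: int, start_deg: float = 168.0, end_deg: float = 24.0) -> list[float]:
    """``n`` equispaced gantry angles along the arc from start to end.

    The arc runs in the direction of increasing gantry angle (clockwise
    viewed from the patient's feet), wrapping through 360; the default
    168 -> 24 posterior arc spans (360 - 168) + 24 = 216 degrees, avoiding
    the anterior-left sector so contralateral organs stay out of the beams.
    """
    if n < 2:
        raise ValueError("need at least 2 beams")
    arc = (end_deg - start_deg) % 360.0
    angles = (start_deg + arc * np.arange(n) / (n - 1)) % 360.0
    return [float(a) for a in angles]


def gantry_unit_vectors(gantry_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Beam travel direction plus the two lateral axes for one gantry angle.

    Gantry 0 has the source anterior (beam travels +y, anterior to
    posterior); angles increase clockwise viewed from the feet.  Returns
    ``(d, u, w)``: travel direction, in-plane lateral axis, and the axial
    (z) axis.
    """
    g = np.deg2rad(gantry_deg)
    d = np.array([np.sin(g), np.cos(g), 0.0])
    u = np.array([np.cos(g), -np.sin(g), 0.0])
    w = np.array([0.0, 0.0, 1.0])
    return d, u, w


@dataclass
class BeamGeometry:
    gantry_angles: list[float]
    isocentre_mm: tuple[float, float, float]
    beamlet_size_mm: float = 5.0
    source_axis_distance_mm: float = 1430.0  # informational; beamlets are parallel

    def __post_init__(self) -> None:
        if self.beamlet_size_mm <= 0:
            raise ValueError("beamlet_size must be positive")
        self.gantry_angles = [float(a) % 360.0 for a in self.gantry_angles]


@dataclass
class KernelParams:
    """Toy pencil-beam kernel: exponential depth attenuation x lateral Gaussian."""

    mu_eff_per_mm: float = 0.005
    lateral_sigma_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.mu_eff_per_mm <= 0 or self.lateral_sigma_mm <= 0:
            raise ValueError("kernel parameters must be positive")


@dataclass
class DoseInfluence:
    """Sparse (n_voxels x n_beamlets) matrix of Gy per unit fluence."""

    matrix: sparse.csr_matrix
    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    beamlets: list[dict] = field(default_factory=list)  # gantry, u-offset, w-offset

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]

    def save(self, path: str | Path) -> None:
        """Documented sparse triplet format: header JSON + row,col,value CSV."""
        path = Path(path)
        coo = self.matrix.tocoo()
        header = {
            "grid_shape": list(self.grid_shape),
            "spacing": list(self.spacing),
            "origin": list(self.origin),
            "n_beamlets": self.n_beamlets,
            "beamlets": self.beamlets,
        }
        path.with_suffix(".json").write_text(json.dumps(header))
        np.savetxt(
            path.with_suffix(".csv"),
            np.column_stack([coo.row, coo.col, coo.data]),
            fmt="%d,%d,%.9e",
            delimiter=",",
        )

    @classmethod
    def load(cls, path: str | Path) -> "DoseInfluence":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        trip = np.loadtxt(path.with_suffix(".csv"), delimiter=",")
        trip = np.atleast_2d(trip)
        n_vox = int(np.prod(header["grid_shape"]))
        mat = sparse.coo_matrix(
            (trip[:, 2], (trip[:, 0].astype(int), trip[:, 1].astype(int))),
            shape=(n_vox, header["n_beamlets"]),
        ).tocsr()
        return cls(
            matrix=mat,
            grid_shape=tuple(header["grid_shape"]),
            spacing=tuple(header["spacing"]),
            origin=tuple(header["origin"]),
            beamlets=header["beamlets"],
        )


def ray_integrals(red_map: VoxelImage, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Exact line integrals of rED (mm of water-equivalent depth) per ray.

    For each ray the segment [start, end] is split at every grid-plane
    crossing; each sub-segment contributes its length times the rED of the
    voxel containing its midpoint.  Points outside the grid contribute 0.
    Fully vectorized over rays.
    """
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    ends = np.atleast_2d(np.asarray(ends, dtype=float))
    n_rays = starts.shape[0]
    red = red_map.data
    origin = np.asarray(red_map.origin)
    spacing = np.asarray(red_map.spacing)
    shape = np.asarray(red.shape)

    delta = ends - starts  # (N, 3)
    lengths = np.linalg.norm(delta, axis=1)
    ts = [np.zeros((n_rays, 1)), np.ones((n_rays, 1))]
    for a in range(3):
        planes = origin[a] + spacing[a] * np.arange(shape[a] + 1)  # (P,)
        da = delta[:, a : a + 1]  # (N, 1)
        safe = np.where(np.abs(da) < 1e-12, 1.0, da)
        t = (planes[None, :] - starts[:, a : a + 1]) / safe
        t = np.where(np.abs(da) < 1e-12, 2.0, t)  # parked outside [0,1]
        ts.append(t)
    t_all = np.clip(np.concatenate(ts, axis=1), 0.0, 1.0)
    t_all.sort(axis=1)
    dt = np.diff(t_all, axis=1)  # (N, M-1)
    t_mid = 0.5 * (t_all[:, :-1] + t_all[:, 1:])
    mids = starts[:, None, :] + t_mid[:, :, None] * delta[:, None, :]  # (N, M-1, 3)
    idx = np.floor((mids - origin) / spacing).astype(np.int64)
    inside = np.all((idx >= 0) & (idx < shape), axis=2)
    idx_clipped = np.clip(idx, 0, shape - 1)
    vals = red[idx_clipped[..., 0], idx_clipped[..., 1], idx_clipped[..., 2]]
    vals = np.where(inside, vals, 0.0)
    return (vals * dt).sum(axis=1) * lengths


def radiological_depth(
    red_map: VoxelImage,
    entry_point_mm,
    voxel_centre_mm,
) -> float:
    """Water-equivalent depth (mm) from the entry point to the voxel centre.

    The line integral of rED along the segment; since rED is zero outside
    the body, starting anywhere upstream of the body surface on the ray is
    equivalent to starting at the surface.  A ray missing the body has
    depth 0.
    """
    return float(
        ray_integrals(
            red_map,
            np.asarray(entry_point_mm, float)[None, :],
            np.asarray(voxel_centre_mm, float)[None, :],
        )[0]
    )


def _beamlet_offsets(
    target_pts: np.ndarray, iso: np.ndarray, u: np.ndarray, w: np.ndarray,
    size_mm: float, margin_mm: float,
) -> tuple[np.ndarray, np.ndarray]:
    pu = (target_pts - iso) @ u
    pw = (target_pts - iso) @ w
    def lattice(lo, hi):
        i0 = int(np.floor((lo - margin_mm) / size_mm))
        i1 = int(np.ceil((hi + margin_mm) / size_mm))
        return size_mm * np.arange(i0, i1 + 1)
    return lattice(pu.min(), pu.max()), lattice(pw.min(), pw.max())


def build_dose_influence(
    geometry: BeamGeometry,
    red_map: VoxelImage,
    kernel: KernelParams,
    target: VoxelImage | np.ndarray,
    margin_mm: float = 10.0,
) -> DoseInfluence:
    """Dose-influence matrix for all beams of ``geometry``.

    Beamlets form a lattice in the plane perpendicular to each beam covering
    the target's projection plus ``margin_mm``.  Entry (v, b) =
    exp(-mu_eff * depth(v, beam_b)) * exp(-r_vb^2 / (2 sigma^2)); entries
    below ``COLUMN_TRUNCATION`` of their column maximum are dropped.
    """
    tmask = target.data if isinstance(target, VoxelImage) else np.asarray(target)
    tmask = tmask.astype(bool)
    if not tmask.any():
        raise ValueError("target (PTV) mask is empty")
    centres = red_map.voxel_centres()  # (N, 3)
    n_vox = centres.shape[0]
    iso = np.asarray(geometry.isocentre_mm, dtype=float)
    target_pts = centres[tmask.ravel()]
    sigma = kernel.lateral_sigma_mm
    cutoff = LATERAL_CUTOFF_SIGMA * sigma
    diag = float(np.linalg.norm(np.asarray(red_map.spacing) * np.asarray(red_map.shape)))

    rows, cols, vals = [], [], []
    beamlets: list[dict] = []
    col0 = 0
    for g in geometry.gantry_angles:
        d, u, w = gantry_unit_vectors(g)
        offs_u, offs_w = _beamlet_offsets(
            target_pts, iso, u, w, geometry.beamlet_size_mm, margin_mm
        )
        rel = centres - iso
        vu = rel @ u
        vw = rel @ w
        cand = (
            (vu >= offs_u.min() - cutoff)
            & (vu <= offs_u.max() + cutoff)
            & (vw >= offs_w.min() - cutoff)
            & (vw <= offs_w.max() + cutoff)
        )
        cand_idx = np.nonzero(cand)[0]
        if cand_idx.size == 0:
            col0 += offs_u.size * offs_w.size
            continue
        c = centres[cand_idx]
        depth = ray_integrals(red_map, c - diag * d, c)
        att = np.exp(-kernel.mu_eff_per_mm * depth)
        gu = np.exp(-((vu[cand_idx, None] - offs_u[None, :]) ** 2) / (2 * sigma**2))
        gw = np.exp(-((vw[cand_idx, None] - offs_w[None, :]) ** 2) / (2 * sigma**2))
        for i, a in enumerate(offs_u):
            for j, b in enumerate(offs_w):
                col_vals = att * gu[:, i] * gw[:, j]
                keep = col_vals >= COLUMN_TRUNCATION * col_vals.max() if col_vals.size else np.zeros(0, bool)
                keep &= col_vals > 0
                if keep.any():
                    rows.append(cand_idx[keep])
                    cols.append(np.full(int(keep.sum()), col0, dtype=np.int64))
                    vals.append(col_vals[keep])
                beamlets.append({"gantry_deg": g, "u_mm": float(a), "w_mm": float(b)})
                col0 += 1
    n_beamlets = col0
    if rows:
        mat = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_vox, n_beamlets),
        ).tocsr()
    else:
        mat = sparse.csr_matrix((n_vox, n_beamlets))
    return DoseInfluence(
        matrix=mat,
        grid_shape=red_map.shape,
        spacing=red_map.spacing,
        origin=red_map.origin,
        beamlets=beamlets,
    )


def compute_dose(influence: DoseInfluence, fluence: np.ndarray) -> VoxelImage:
    """Dose grid (Gy) for a non-negative fluence vector: D @ f."""
    fluence = np.asarray(fluence, dtype=float)
    if fluence.ndim != 1 or fluence.size != influence.n_beamlets:
        raise ValueError("fluence length does not match beamlet count")
    if (fluence < 0).any():
        raise ValueError("fluence must be non-negative")
    dose = influence.matrix @ fluence
    return VoxelImage(
        dose.reshape(influence.grid_shape), influence.spacing, influence.origin
    )
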