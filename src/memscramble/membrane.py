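"""Ensemble-averaged leaflet surfaces, density grids, and Boltzmann PMFs.

Leaflet surfaces are built by bilinear splatting of each lipid's glycerol
beads (GL1/GL2) onto a 1 A rectilinear xy grid, averaging heights over all
analysed frames with per-frame leaflet assignment.  Nodes visited in fewer
than 2% of frames are discarded, as are connected clusters (4-connectivity)
detached from the bulk membrane surface.  Minimal membrane thickness is the
minimum 3D distance between any two valid points on the opposing surfaces.

Bead densities are accumulated on a 3D voxel grid (default 100x100x150 A at
0.5 A spacing) by nearest-voxel binning; a lipid free-energy profile along a
pathway follows from Boltzmann inversion, F(s) = -ln(rho(s)/rho_max) in kT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import MemscrambleError, SelectionError, SurfaceError
from .scramble import AngleTrace
from .trajio import Trajectory

logger = logging.getLogger(__name__)


@dataclass
class LeafletSurfacePair:
    """Two ensemble-averaged height fields on a shared xy grid."""

    x: np.ndarray  # node coordinates (nx,)
    y: np.ndarray  # (ny,)
    z_upper: np.ndarray  # (nx, ny), NaN where never visited
    z_lower: np.ndarray
    occ_upper: np.ndarray  # fraction of frames with occupancy
    occ_lower: np.ndarray
    mask_upper: np.ndarray  # valid: occupancy >= threshold & connected to bulk
    mask_lower: np.ndarray
    n_frames: int = 0

    def valid_points(self, leaflet: str) -> np.ndarray:
        """(n, 3) array of valid surface points for 'upper' or 'lower'."""
        mask = self.mask_upper if leaflet == "upper" else self.mask_lower
        z = self.z_upper if leaflet == "upper" else self.z_lower
        ii, jj = np.nonzero(mask)
        return np.column_stack([self.x[ii], self.y[jj], z[ii, jj]])


@dataclass
class DensityGrid:
    """3D voxel counts for a bead class, with origin/spacing metadata."""

    origin: np.ndarray  # (3,) corner of the grid, A
    spacing: float
    counts: np.ndarray  # (nx, ny, nz)
    n_frames: int
    n_out_of_bounds: int = 0
    normalization: str = "raw"

    def normalized(self, mode: str = "probability") -> np.ndarray:
        if mode == "raw":
            return self.counts
        total = self.counts.sum()
        if mode == "probability":
            return self.counts / total if total > 0 else self.counts
        if mode == "number_density":
            return self.counts / (self.n_frames * self.spacing**3)
        raise MemscrambleError(f"unknown normalization mode {mode!r}")

    def voxel_centers_1d(self, axis: int) -> np.ndarray:
        n = self.counts.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing


@dataclass
class FreeEnergyProfile:
    s: np.ndarray        # path coordinate, A
    f_kt: np.ndarray     # free energy in kT, min = 0; +inf where rho = 0
    rho: np.ndarray
    has_gaps: bool


def assign_leaflets_per_frame(traces: list[AngleTrace]) -> np.ndarray:
    """Per-frame leaflet labels: (n_frames, n_lipids) bool, True = upper."""
    return np.column_stack([tr.upper for tr in traces])


def average_surfaces(
    traj: Trajectory,
    upper_labels: np.ndarray,
    spacing: float = 1.0,
    occupancy_min: float = 0.02,
) -> LeafletSurfacePair:
    """Ensemble-averaged upper/lower leaflet surfaces from glycerol beads."""
    top = traj.topology
    if upper_labels.shape != (traj.n_frames, len(top.lipids)):
        raise MemscrambleError("leaflet labels shape mismatch")
    gl = np.stack([top.role_indices("GL1"), top.role_indices("GL2")], axis=1)
    nx = int(np.floor(traj.box[0, 0] / spacing)) + 1
    ny = int(np.floor(traj.box[0, 1] / spacing)) + 1
    x = np.arange(nx) * spacing
    y = np.arange(ny) * spacing

    wsum = np.zeros((2, nx, ny))
    wzsum = np.zeros((2, nx, ny))
    occ = np.zeros((2, nx, ny), dtype=np.int64)
    for f in range(traj.n_frames):
        for leaf, lip_mask in enumerate((upper_labels[f], ~upper_labels[f])):
            beads = gl[lip_mask].ravel()
            if beads.size == 0:
                continue
            pts = traj.coords[f, beads, :]
            _splat_bilinear(pts, spacing, nx, ny, wsum[leaf], wzsum[leaf],
                            occ[leaf])
    with np.errstate(invalid="ignore", divide="ignore"):
        zbar = np.where(wsum > 0, wzsum / np.where(wsum > 0, wsum, 1.0), np.nan)
    occ_frac = occ / traj.n_frames
    masks = []
    for leaf in range(2):
        m = occ_frac[leaf] >= occupancy_min
        masks.append(_keep_bulk_component(m))
    if not masks[0].any() or not masks[1].any():
        raise SurfaceError("no valid surface nodes after filtering")
    return LeafletSurfacePair(
        x=x, y=y,
        z_upper=zbar[0], z_lower=zbar[1],
        occ_upper=occ_frac[0], occ_lower=occ_frac[1],
        mask_upper=masks[0], mask_lower=masks[1],
        n_frames=traj.n_frames,
    )


def _splat_bilinear(pts, spacing, nx, ny, wsum, wzsum, occ) -> None:
    gx = pts[:, 0] / spacing
    gy = pts[:, 1] / spacing
    i0 = np.floor(gx).astype(int)
    j0 = np.floor(gy).astype(int)
    fx = gx - i0
    fy = gy - j0
    touched = np.zeros(wsum.shape, dtype=bool)
    for di, dj, w in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        ii = i0 + di
        jj = j0 + dj
        ok = (ii >= 0) & (ii < nx) & (jj >= 0) & (jj < ny) & (w > 0)
        np.add.at(wsum, (ii[ok], jj[ok]), w[ok])
        np.add.at(wzsum, (ii[ok], jj[ok]), w[ok] * pts[ok, 2])
        touched[ii[ok], jj[ok]] = True
    occ += touched


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _keep_bulk_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 4-connected component (the bulk surface)."""
    labels, n = ndimage.label(mask, structure=_CROSS)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return labels == keep


def min_thickness(
    pair: LeafletSurfacePair,
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Minimal 3D distance between valid points on the opposing surfaces."""
    up = pair.valid_points("upper")
    lo = pair.valid_points("lower")
    if up.size == 0 or lo.size == 0:
        raise SurfaceError("empty surface mask")
    tree = cKDTree(lo)
    d, j = tree.query(up)
    k = int(np.argmin(d))
    return float(d[k]), (up[k], lo[j[k]])


# ---------------------------------------------------------------------------
# density grids
# ---------------------------------------------------------------------------

def accumulate_density(
    traj: Trajectory,
    bead_indices: np.ndarray,
    center: tuple[float, float, float] | None = None,
    extent: tuple[float, float, float] = (100.0, 100.0, 150.0),
    spacing: float = 0.5,
    chains: list[str] | None = None,
) -> DensityGrid:
    """Accumulate nearest-voxel bead counts over all frames.

    ``center`` defaults to the box centre of frame 0.  With ``chains``, the
    frame is re-binned once per chain after the translation that maps that
    chain's reference backbone centroid onto the first chain's, and voxel
    counts are averaged over chains (per-subunit symmetrisation).
    """
    extent = np.asarray(extent, dtype=float)
    if np.any(extent <= 0) or spacing <= 0:
        raise MemscrambleError("grid extent and spacing must be positive")
    if center is None:
        center = traj.box[0] / 2.0
    origin = np.asarray(center, dtype=float) - extent / 2.0
    shape = np.maximum(1, np.round(extent / spacing).astype(int))

    shifts = [np.zeros(3)]
    if chains:
        ref = None
        shifts = []
        for ch in chains:
            recs = traj.topology.select_residues(chain=ch)
            if not recs:
                raise SelectionError(f"chain {ch!r} has no residues")
            bb = np.asarray([r.backbone for r in recs], dtype=int)
            cen = traj.coords[0, bb, :].mean(axis=0)
            if ref is None:
                ref = cen
            shifts.append(ref - cen)

    counts = np.zeros(tuple(shape))
    oob = 0
    pos_all = traj.coords[:, np.asarray(bead_indices, dtype=int), :].reshape(-1, 3)
    for shift in shifts:
        idx = np.floor((pos_all + shift - origin) / spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        oob += int((~ok).sum())
        flat = np.ravel_multi_index(tuple(idx[ok].T), tuple(shape))
        counts += np.bincount(flat, minlength=int(np.prod(shape))).reshape(
            tuple(shape)
        )
    if chains:
        counts /= len(shifts)
        oob = oob // len(shifts)
    if oob:
        logger.info("accumulate_density: %d bead-frames out of bounds", oob)
    return DensityGrid(
        origin=origin, spacing=spacing, counts=counts,
        n_frames=traj.n_frames, n_out_of_bounds=oob,
    )


def pmf_from_density(
    grid: DensityGrid,
    polyline: np.ndarray,
    tube_radius: float = 8.0,
) -> FreeEnergyProfile:
    """Boltzmann inversion of the pathway density: F(s) = -ln(rho/rho_max).

    The pathway is slabbed along z (one voxel layer per path point); rho(s)
    is the mean voxel count within ``tube_radius`` laterally of the path
    point in its layer.  F is in kT (temperature enters only through the
    kT unit itself) and offset so the profile minimum is zero; empty slabs
    give +inf with the gap flag set.
    """
    xc = grid.voxel_centers_1d(0)
    yc = grid.voxel_centers_1d(1)
    zc = grid.voxel_centers_1d(2)
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    rho = np.full(len(polyline), np.nan)
    for k, p in enumerate(polyline):
        iz = int(np.clip(round((p[2] - grid.origin[2]) / grid.spacing - 0.5),
                         0, len(zc) - 1))
        lateral = (xx - p[0]) ** 2 + (yy - p[1]) ** 2 <= tube_radius**2
        if not lateral.any():
            continue
        rho[k] = grid.counts[:, :, iz][lateral].mean()
    rho = np.nan_to_num(rho, nan=0.0)
    rho_max = rho.max()
    if rho_max <= 0:
        raise MemscrambleError("all-zero density along the pathway tube")
    with np.errstate(divide="ignore"):
        f = -np.log(rho / rho_max)
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return FreeEnergyProfile(
        s=s, f_kt=f, rho=rho, has_gaps=bool(np.any(~np.isfinite(f)))
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_surfaces_csv(pair: LeafletSurfacePair, path) -> None:
    """CSV grid dump: x, y, z_upper, z_lower, occupancies, masks."""
    import pandas as pd

    ii, jj = np.meshgrid(
        np.arange(len(pair.x)), np.arange(len(pair.y)), indexing="ij"
    )
    pd.DataFrame(
        {
            "x": pair.x[ii.ravel()],
            "y": pair.y[jj.ravel()],
            "z_upper": pair.z_upper.ravel(),
            "z_lower": pair.z_lower.ravel(),
            "occ_upper": pair.occ_upper.ravel(),
            "occ_lower": pair.occ_lower.ravel(),
            "mask_upper": pair.mask_upper.ravel().astype(int),
            "mask_lower": pair.mask_lower.ravel().astype(int),
        }
    ).to_csv(path, index=False)


def write_dx(grid: DensityGrid, path, mode: str = "probability") -> None:
    """Write the grid as an OpenDX scalar field (VMD/ChimeraX-loadable)."""
    from gridData import Grid

    edges = [
        grid.origin[d] + np.arange(grid.counts.shape[d] + 1) * grid.spacing
        for d in range(3)
    ]
    Grid(grid.normalized(mode), edges=edges).export(str(path), file_format="dx")
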