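"""Axial density / "free energy" profiles, pore radius, membrane thickness.

Profiles are computed along the pore axis (z, the membrane normal) inside
a cylinder centred on the per-frame xy COM of the filter C-alpha atoms,
with z measured relative to the Thr59 O-gamma plane so that profiles from
different replicates superpose.  The "free energy" is the Boltzmann
inversion -ln(rho/rho_max) in kBT of the z-binned density; under an
applied voltage this is a nonequilibrium ensemble average, hence the
quotation marks, and only differences (barrier heights) are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory_io import FrameSeries, Topology, select

__all__ = [
    "AxialProfile",
    "PoreProfile",
    "MembraneGeometry",
    "axial_density",
    "free_energy_profile",
    "barrier_height",
    "pore_radius_profile",
    "membrane_thickness",
]


@dataclass
class AxialProfile:
    """z-binned density (counts/frame) and optional free energy (kBT).

    Bins with zero counts carry NaN in ``F`` (explicitly missing, never 0);
    the minimum of ``F`` is 0 at the densest bin.
    """

    z_centers: np.ndarray  # nm, relative to the Thr59 O-gamma plane
    density: np.ndarray  # mean counts per frame per bin
    species: str
    F: np.ndarray | None = None  # kBT

    def to_frame(self) -> pd.DataFrame:
        F = np.full_like(self.density, np.nan) if self.F is None else self.F
        return pd.DataFrame(
            {
                "z_nm": self.z_centers,
                "density": self.density,
                "F_kBT": F,
                "masked": ~np.isfinite(F),
            }
        )


@dataclass
class PoreProfile:
    z_centers: np.ndarray
    radius: np.ndarray  # nm, clamped to [0, r_max]
    empty_slice: np.ndarray  # True where no atoms were near the slice
    r_max: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"z_nm": self.z_centers, "radius_nm": self.radius, "empty": self.empty_slice}
        )


@dataclass
class MembraneGeometry:
    thickness_nm: float
    sem_nm: float
    n_frames: int


def _pore_axis_xy(frames: FrameSeries, topology: Topology) -> np.ndarray:
    sel = select(topology, "filter and name CA")
    if len(sel) == 0:
        raise ValueError("filter C-alpha selection empty; cannot define pore axis")
    return frames.coordinates[:, sel.indices, :2].mean(axis=1)


def _reference_plane_z(frames: FrameSeries, topology: Topology) -> np.ndarray:
    sel = select(topology, "resid 59 and name OG1")
    if len(sel) == 0:
        raise ValueError("Thr59 O-gamma selection empty; cannot set z origin")
    return frames.coordinates[:, sel.indices, 2].mean(axis=1)


def axial_density(
    frames: FrameSeries,
    topology: Topology,
    species_expr: str,
    axis_radius: float = 0.5,
    bin_width: float = 0.05,
    z_range: tuple = (-3.0, 2.0),
    species: str | None = None,
) -> AxialProfile:
    """Mean per-frame count of selected atoms in z-bins along the pore.

    Only atoms within ``axis_radius`` of the pore axis are counted; z is
    relative to the Thr59 O-gamma plane (z = 0, filter entrance).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if frames.n_frames == 0:
        raise ValueError("no frames")
    sel = select(topology, species_expr)
    if len(sel) == 0:
        raise ValueError(f"species selection {species_expr!r} empty")
    xyz = frames.coordinates[:, sel.indices, :]
    axis_xy = _pore_axis_xy(frames, topology)
    z0 = _reference_plane_z(frames, topology)
    r = np.linalg.norm(xyz[:, :, :2] - axis_xy[:, None, :], axis=2)
    z_rel = xyz[:, :, 2] - z0[:, None]
    edges = np.arange(z_range[0], z_range[1] + bin_width / 2, bin_width)
    inside = r <= axis_radius
    counts, _ = np.histogram(z_rel[inside], bins=edges)
    return AxialProfile(
        z_centers=0.5 * (edges[:-1] + edges[1:]),
        density=counts / frames.n_frames,
        species=species or species_expr,
    )


def free_energy_profile(profile: AxialProfile) -> AxialProfile:
    """Boltzmann inversion: F(z) = -ln(rho/rho_max) in kBT, min F = 0.

    Zero-density bins are masked (NaN), not infinite.
    """
    rho = profile.density
    if not np.any(rho > 0):
        raise ValueError("all-zero density: cannot invert")
    F = np.full(rho.shape, np.nan)
    pos = rho > 0
    F[pos] = -np.log(rho[pos] / rho[pos].max())
    return AxialProfile(
        z_centers=profile.z_centers, density=rho, species=profile.species, F=F
    )


def barrier_height(
    profile: AxialProfile, region: tuple, reference_interval: tuple | None = None
) -> float:
    """Barrier in kBT: max F inside ``region`` minus the reference level.

    The reference is the mean F over ``reference_interval`` when given
    (e.g. the cavity entrance), else the profile minimum (0 by
    normalisation), so only differences enter.
    """
    if profile.F is None:
        raise ValueError("free energy not filled; call free_energy_profile first")
    z, F = profile.z_centers, profile.F
    in_region = (z >= region[0]) & (z <= region[1]) & np.isfinite(F)
    if not np.any(in_region):
        raise ValueError("region fully masked")
    peak = F[in_region].max()
    if reference_interval is None:
        ref = np.nanmin(F)
    else:
        in_ref = (
            (z >= reference_interval[0]) & (z <= reference_interval[1]) & np.isfinite(F)
        )
        if not np.any(in_ref):
            raise ValueError("reference interval fully masked")
        ref = F[in_ref].mean()
    return float(peak - ref)


def pore_radius_profile(
    frames: FrameSeries,
    topology: Topology,
    bin_width: float = 0.05,
    r_max: float = 1.0,
    z_range: tuple = (-3.0, 2.0),
    optimize_center: bool = False,
    atom_expr: str = "backbone or sidechain",
) -> PoreProfile:
    """Frame-averaged pore radius per z-slice, HOLE-style but fixed-axis.

    For each slice, r(z) = min over protein heavy atoms in the slab of
    (xy distance to the axis minus the atom's vdW radius), clamped to
    [0, r_max]; slices with no atoms report r_max and are flagged.  With
    ``optimize_center`` the slice centre is grid-searched (0.02 nm step,
    +/-0.1 nm) to maximise the radius, approximating HOLE's sphere
    placement without its sphere propagation.
    """
    sel = select(topology, atom_expr)
    if len(sel) == 0:
        raise ValueError("no protein heavy atoms selected")
    vdw = topology.vdw_radius[sel.indices]
    axis_xy = _pore_axis_xy(frames, topology)
    z0 = _reference_plane_z(frames, topology)
    edges = np.arange(z_range[0], z_range[1] + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_bins = len(centers)
    sums = np.zeros(n_bins)
    hits = np.zeros(n_bins, dtype=int)
    offsets = (
        [np.zeros(2)]
        if not optimize_center
        else [
            np.array([dx, dy])
            for dx in np.arange(-0.1, 0.101, 0.02)
            for dy in np.arange(-0.1, 0.101, 0.02)
        ]
    )
    for f in range(frames.n_frames):
        xyz = frames.coordinates[f, sel.indices, :]
        z_rel = xyz[:, 2] - z0[f]
        bin_idx = np.floor((z_rel - z_range[0]) / bin_width).astype(int)
        ok = (bin_idx >= 0) & (bin_idx < n_bins)
        best = np.full(n_bins, -np.inf)
        for off in offsets:
            dxy = np.linalg.norm(xyz[:, :2] - (axis_xy[f] + off), axis=1) - vdw
            r_slice = np.full(n_bins, np.inf)
            np.minimum.at(r_slice, bin_idx[ok], dxy[ok])
            best = np.maximum(best, r_slice)
        filled = np.isfinite(best)
        sums[filled] += np.clip(best[filled], 0.0, r_max)
        hits[filled] += 1
    empty = hits == 0
    radius = np.full(n_bins, r_max)
    radius[~empty] = sums[~empty] / hits[~empty]
    return PoreProfile(centers, radius, empty, r_max)


def membrane_thickness(
    frames: FrameSeries, topology: Topology, phosphate_expr: str = "name P"
) -> MembraneGeometry:
    """Bilayer thickness: mean upper-leaflet P z minus lower, +/- SEM.

    Leaflets are split per frame by z relative to the phosphate COM; a
    monolayer (one empty leaflet) is an error.
    """
    sel = select(topology, phosphate_expr)
    if len(sel) == 0:
        raise ValueError(f"phosphate selection {phosphate_expr!r} empty")
    z = frames.coordinates[:, sel.indices, 2]
    mid = z.mean(axis=1, keepdims=True)
    upper = z >= mid
    if np.any(upper.all(axis=1)) or np.any((~upper).all(axis=1)):
        raise ValueError("all phosphates in one leaflet: not a bilayer")
    per_frame = np.array(
        [z[f, upper[f]].mean() - z[f, ~upper[f]].mean() for f in range(z.shape[0])]
    )
    sem = (
        float(np.std(per_frame, ddof=1) / np.sqrt(len(per_frame)))
        if len(per_frame) > 1
        else 0.0
    )
    return MembraneGeometry(float(per_frame.mean()), sem, len(per_frame))
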