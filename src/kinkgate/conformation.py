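"""Geometric gating descriptors and the kinked/bent state classifier.

The inner helix of each subunit is treated as a two-state system: *kinked*
(broken Val81-Gly85 / Leu82-Thr86 backbone H-bonds, bending angle around
43 deg, filter entrance closed) versus *bent* (H-bonds formed, around
30 deg, filter entrance open).  The discriminating observable is the
Val81 backbone-O to Gly85 amide-H distance (d_VG); the other descriptors
(second H-bond distance, bending angle, Thr59 O-gamma ring, Ile84/Thr59
side-chain contact, Phe87 cavity orientation, Pro19 outer-helix spread)
corroborate and quantify the gate geometry.

All distances are minimum-image correct in the orthorhombic box; all
values are nm / degrees.  Per-subunit arrays are ordered by sorted subunit
label (A, B, C, D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory_io import FrameSeries, Topology, minimum_image, select

__all__ = [
    "KINKED",
    "BENT",
    "StateTrace",
    "DescriptorSeries",
    "hbond_distance",
    "bending_angle",
    "classify_state",
    "cross_subunit_distance",
    "sidechain_com_distance",
    "com_ring_distance",
    "phe87_cof_distance",
    "histogram2d",
    "compute_descriptors",
]

KINKED = 0
BENT = 1

# MthK numbering defaults
VAL81, LEU82, GLY83, ILE84, GLY85, THR86, PHE87 = 81, 82, 83, 84, 85, 86, 87
THR59, PRO19 = 59, 19
INNER_HELIX = (71, 98)


def _tetramer_labels(topology: Topology) -> list:
    labels = topology.protein_subunits()
    if len(labels) != 4:
        raise ValueError(
            f"expected a tetramer (4 protein subunits), found {labels!r}"
        )
    return labels


def _single_atom_per_subunit(topology: Topology, expr: str) -> np.ndarray:
    """Indices (4,) of one atom per subunit for ``expr``; error otherwise."""
    labels = _tetramer_labels(topology)
    idx = []
    for s in labels:
        sel = select(topology, f"subunit {s} and ({expr})")
        if len(sel) != 1:
            raise ValueError(
                f"selection {expr!r} resolved to {len(sel)} atoms in subunit {s}, "
                "expected exactly 1"
            )
        idx.append(sel.indices[0])
    return np.asarray(idx)


def _mi_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """|a-b| under minimum image; a,b (F, ..., 3), box (F, 3)."""
    d = a - b
    while box.ndim < d.ndim:
        box = box[:, None, :] if box.ndim == 2 else box[None]
    d = minimum_image(d, box)
    return np.linalg.norm(d, axis=-1)


def _sidechain_com(frames: FrameSeries, topology: Topology, subunit, resid) -> np.ndarray:
    """Mass-weighted COM of side-chain heavy atoms, (F, 3)."""
    sel = select(topology, f"subunit {subunit} and resid {resid} and sidechain")
    if len(sel) == 0:
        resname = set(topology.residue_name[(topology.residue_id == resid)
                                            & (topology.subunit == subunit)])
        if resname == {"GLY"}:
            raise ValueError(f"residue {resid} ({subunit}) is glycine: no side chain")
        raise ValueError(f"no side-chain heavy atoms for resid {resid} subunit {subunit}")
    w = topology.mass[sel.indices]
    xyz = frames.coordinates[:, sel.indices, :]
    return np.einsum("fai,a->fi", xyz, w) / w.sum()


# ---------------------------------------------------------------------------


def hbond_distance(
    frames: FrameSeries,
    topology: Topology,
    acceptor_resid: int = VAL81,
    donor_resid: int = GLY85,
    use_nitrogen: bool = False,
) -> np.ndarray:
    """Backbone O(acceptor) to amide-H(donor) distance, (n_frames, 4) nm.

    With ``use_nitrogen=True`` the heavy-atom O-N distance is returned
    instead (for hydrogen-free topologies; classification thresholds must
    then be shifted by +0.1 nm).
    """
    donor_name = "N" if use_nitrogen else "H"
    acc = _single_atom_per_subunit(topology, f"resid {acceptor_resid} and name O")
    try:
        don = _single_atom_per_subunit(topology, f"resid {donor_resid} and name {donor_name}")
    except ValueError as exc:
        if not use_nitrogen:
            raise ValueError(
                f"no amide hydrogen found for residue {donor_resid}: supply a "
                "topology with hydrogens or pass use_nitrogen=True (O-N "
                "distance; shift classification thresholds by +0.1 nm)"
            ) from exc
        raise
    return _mi_distance(
        frames.coordinates[:, acc, :], frames.coordinates[:, don, :], frames.box
    )


def _principal_axis(xyz: np.ndarray) -> np.ndarray:
    """Largest-variance axis of point sets, (F, m, 3) -> unit (F, 3),
    oriented from the first toward the last point (N->C)."""
    c = xyz - xyz.mean(axis=1, keepdims=True)
    cov = np.einsum("fmi,fmj->fij", c, c)
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[:, :, -1]
    direction = xyz[:, -1, :] - xyz[:, 0, :]
    flip = np.einsum("fi,fi->f", axis, direction) < 0
    axis[flip] *= -1.0
    return axis


def bending_angle(
    frames: FrameSeries,
    topology: Topology,
    helix_range: tuple = INNER_HELIX,
    hinge: int = GLY83,
) -> np.ndarray:
    """Inner-helix bending angle at the hinge glycine, (n_frames, 4) deg.

    The angle between the principal axes of the C-alpha sets before and
    after the hinge, each oriented N-terminal to C-terminal; 0 deg means a
    straight helix.  Subunits with fewer than 4 C-alpha atoms on either
    side are reported as NaN.
    """
    labels = _tetramer_labels(topology)
    lo, hi = helix_range
    out = np.full((frames.n_frames, 4), np.nan)
    for k, s in enumerate(labels):
        pre = select(topology, f"subunit {s} and resid {lo}:{hinge - 1} and name CA")
        post = select(topology, f"subunit {s} and resid {hinge + 1}:{hi} and name CA")
        if len(pre) < 4 or len(post) < 4:
            continue
        order_pre = np.argsort(topology.residue_id[pre.indices])
        order_post = np.argsort(topology.residue_id[post.indices])
        a1 = _principal_axis(frames.coordinates[:, pre.indices[order_pre], :])
        a2 = _principal_axis(frames.coordinates[:, post.indices[order_post], :])
        cosang = np.clip(np.einsum("fi,fi->f", a1, a2), -1.0, 1.0)
        out[:, k] = np.degrees(np.arccos(cosang))
    return out


@dataclass
class StateTrace:
    """Per-frame per-subunit kinked(0)/bent(1) labels and derived summaries."""

    labels: np.ndarray  # (n_frames, 4) int8
    t_low: float
    t_high: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def f_bent(self) -> float:
        """Bent-state fraction: mean of the bent indicator over frames and
        subunits (one permanently bent subunit of four gives 0.25)."""
        return float(self.labels.mean())

    @property
    def f_bent_per_subunit(self) -> np.ndarray:
        return self.labels.mean(axis=0)

    @property
    def n_bent_config(self) -> np.ndarray:
        """Per-frame count of bent subunits (0-4), the tetramer configuration."""
        return self.labels.sum(axis=1).astype(int)

    def config_residence(self) -> np.ndarray:
        """Fraction of frames spent in each configuration n_bent = 0..4."""
        return np.bincount(self.n_bent_config, minlength=5) / self.n_frames


def classify_state(
    d_vg: np.ndarray,
    t_low: float = 0.27,
    t_high: float = 0.45,
    hysteresis: bool = True,
) -> StateTrace:
    """Classify each (frame, subunit) as kinked or bent from d_VG.

    Hysteresis rule (default): bent when d_VG < t_low, kinked when
    d_VG > t_high, previous label kept inside the band.  The first frame
    inside the band takes the nearer threshold (tie -> kinked).  With
    ``hysteresis=False`` a single cutoff at the band midpoint is used.
    """
    d = np.asarray(d_vg, dtype=float)
    if d.ndim == 1:
        d = d[:, None]
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite d_VG values")
    if not hysteresis:
        cut = 0.5 * (t_low + t_high)
        return StateTrace((d < cut).astype(np.int8), t_low=cut, t_high=cut)
    raw = np.full(d.shape, -1, dtype=np.int8)
    raw[d < t_low] = BENT
    raw[d > t_high] = KINKED
    undecided0 = raw[0] == -1
    nearer_low = (d[0] - t_low) < (t_high - d[0])  # strict: tie -> kinked
    raw[0, undecided0] = np.where(nearer_low[undecided0], BENT, KINKED)
    # forward-fill the -1 entries with the previous decided label
    decided = raw != -1
    idx = np.where(decided, np.arange(d.shape[0])[:, None], 0)
    idx = np.maximum.accumulate(idx, axis=0)
    labels = np.take_along_axis(raw, idx, axis=0)
    return StateTrace(labels, t_low=t_low, t_high=t_high)


def _pair_mean(points: np.ndarray, box: np.ndarray, pairing: str) -> np.ndarray:
    if points.shape[1] != 4:
        raise ValueError(f"expected 4 points (one per subunit), got {points.shape[1]}")
    if pairing == "diagonal":
        pairs = [(0, 2), (1, 3)]
    elif pairing == "all_pairs":
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    d = [
        _mi_distance(points[:, i, :], points[:, j, :], box) for i, j in pairs
    ]
    return np.mean(d, axis=0)


def cross_subunit_distance(
    frames: FrameSeries,
    topology: Topology,
    atom_expr: str,
    pairing: str = "diagonal",
) -> np.ndarray:
    """Ring 'distance' of one point per subunit, (n_frames,) nm.

    ``atom_expr`` must resolve to exactly one atom, or a set whose
    mass-weighted COM is used, within each subunit (e.g. ``resid 19 and
    name CA`` for the Pro19 C-alpha spread, ``resid 59 and name OG1`` for
    the Thr59 O-gamma filter-gate distance).  Diagonal pairing (default)
    averages the two opposite-subunit distances (A-C, B-D); ``all_pairs``
    averages all six.
    """
    labels = _tetramer_labels(topology)
    points = []
    for s in labels:
        sel = select(topology, f"subunit {s} and ({atom_expr})")
        if len(sel) == 0:
            raise ValueError(f"{atom_expr!r} matched nothing in subunit {s}")
        if len(sel) == 1:
            points.append(frames.coordinates[:, sel.indices[0], :])
        else:
            w = topology.mass[sel.indices]
            points.append(
                np.einsum("fai,a->fi", frames.coordinates[:, sel.indices, :], w)
                / w.sum()
            )
    return _pair_mean(np.stack(points, axis=1), frames.box, pairing)


def sidechain_com_distance(
    frames: FrameSeries,
    topology: Topology,
    res_a: int = ILE84,
    res_b: int = THR59,
) -> np.ndarray:
    """Intra-subunit side-chain COM distance, (n_frames, 4) nm.

    Side chain = non-backbone heavy atoms (C-beta included), mass-weighted.
    Default pair Ile84-Thr59: the contact through which the inner-helix
    state is relayed to the filter gate.
    """
    labels = _tetramer_labels(topology)
    out = []
    for s in labels:
        ca = _sidechain_com(frames, topology, s, res_a)
        cb = _sidechain_com(frames, topology, s, res_b)
        out.append(_mi_distance(ca, cb, frames.box))
    return np.stack(out, axis=1)


def com_ring_distance(
    frames: FrameSeries, topology: Topology, resid: int = ILE84
) -> np.ndarray:
    """Diagonal mean distance between the four side-chain COMs, (n_frames,)."""
    labels = _tetramer_labels(topology)
    points = np.stack(
        [_sidechain_com(frames, topology, s, resid) for s in labels], axis=1
    )
    return _pair_mean(points, frames.box, "diagonal")


def phe87_cof_distance(
    frames: FrameSeries, topology: Topology, resid: int = PHE87
) -> np.ndarray:
    """Phe87 side-chain COM to Phe87 C-alpha-ring COM distance, (F, 4) nm.

    Small values mean the side chain points into the central cavity
    (occluding/dehydrating it); large values mean it points outward.
    """
    labels = _tetramer_labels(topology)
    ca_idx = _single_atom_per_subunit(topology, f"resid {resid} and name CA")
    ring_center = frames.coordinates[:, ca_idx, :].mean(axis=1)
    out = []
    for s in labels:
        com = _sidechain_com(frames, topology, s, resid)
        out.append(_mi_distance(com, ring_center, frames.box))
    return np.stack(out, axis=1)


def histogram2d(x, y, bins, normalize: bool = False):
    """2-D histogram over finite (x, y) pairs.

    Returns (grid, x_edges, y_edges); with ``normalize=True`` the grid sums
    to 1 (a probability histogram, the form used for the state maps).
    """
    x = np.ravel(np.asarray(x, dtype=float))
    y = np.ravel(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    grid, xe, ye = np.histogram2d(x[ok], y[ok], bins=bins)
    if normalize:
        total = grid.sum()
        if total > 0:
            grid = grid / total
    return grid, xe, ye


@dataclass
class DescriptorSeries:
    """All gating descriptors for one replicate.

    Per-subunit fields are (n_frames, 4); tetramer fields are (n_frames,).
    """

    times: np.ndarray
    subunits: list
    d_vg: np.ndarray
    d_lt: np.ndarray
    theta: np.ndarray
    d_i84_t59: np.ndarray
    d_cof: np.ndarray
    d_ogog: np.ndarray
    d_pro19: np.ndarray
    d_t59o: np.ndarray
    d_g61o: np.ndarray
    d_i84_ring: np.ndarray
    states: StateTrace = None  # type: ignore[assignment]

    def to_tidy(self, replicate: str = "rep0") -> pd.DataFrame:
        """Tidy per-subunit table (replicate, frame, time_ns, subunit, ...)."""
        f = np.arange(len(self.times))
        rows = []
        for k, s in enumerate(self.subunits):
            rows.append(
                pd.DataFrame(
                    {
                        "replicate": replicate,
                        "frame": f,
                        "time_ns": self.times,
                        "subunit": s,
                        "d_vg_nm": self.d_vg[:, k],
                        "d_lt_nm": self.d_lt[:, k],
                        "theta_deg": self.theta[:, k],
                        "d_i84_t59_nm": self.d_i84_t59[:, k],
                        "d_cof_nm": self.d_cof[:, k],
                        "state": np.where(
                            self.states.labels[:, k] == BENT, "bent", "kinked"
                        ),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def compute_descriptors(
    frames: FrameSeries,
    topology: Topology,
    t_low: float = 0.27,
    t_high: float = 0.45,
    use_nitrogen: bool = False,
) -> DescriptorSeries:
    """Compute the full descriptor set and classify states for one replicate."""
    d_vg = hbond_distance(frames, topology, VAL81, GLY85, use_nitrogen=use_nitrogen)
    d_lt = hbond_distance(frames, topology, LEU82, THR86, use_nitrogen=use_nitrogen)
    shift = 0.1 if use_nitrogen else 0.0
    states = classify_state(d_vg, t_low=t_low + shift, t_high=t_high + shift)
    return DescriptorSeries(
        times=frames.times,
        subunits=_tetramer_labels(topology),
        d_vg=d_vg,
        d_lt=d_lt,
        theta=bending_angle(frames, topology),
        d_i84_t59=sidechain_com_distance(frames, topology),
        d_cof=phe87_cof_distance(frames, topology),
        d_ogog=cross_subunit_distance(frames, topology, "resid 59 and name OG1"),
        d_pro19=cross_subunit_distance(frames, topology, "resid 19 and name CA"),
        d_t59o=cross_subunit_distance(frames, topology, "resid 59 and name O"),
        d_g61o=cross_subunit_distance(frames, topology, "resid 61 and name O"),
        d_i84_ring=com_ring_distance(frames, topology),
        states=states,
    )
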