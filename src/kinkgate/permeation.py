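"""K+ permeation counting, currents, binding-site occupancy, and voltage.

A permeation event is a full traversal of the selectivity-filter slab: the
ion's (unwrapped) z history must visit below -> inside -> above the slab
for an outward (+1) event, or the reverse for inward (-1).  Bounces and
partial entries count nothing.  The applied transmembrane voltage follows
the constant-field convention V = E * L with L the box height.

Outward (+z, intracellular -> extracellular) is the positive current
direction; elementary charge is CODATA e = 1.602176634e-19 C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory_io import FrameSeries, Topology, select

__all__ = [
    "ELEMENTARY_CHARGE_C",
    "PermeationRecord",
    "CurrentEstimate",
    "voltage_from_field",
    "filter_bounds",
    "compartments",
    "detect_permeation_events",
    "current_from_events",
    "aggregate_current",
    "site_occupancy",
    "ion_z_series",
    "events_table",
]

ELEMENTARY_CHARGE_C = 1.602176634e-19

BELOW, INSIDE, ABOVE = 0, 1, 2


def voltage_from_field(field_v_per_nm: float, box_z_nm: float) -> float:
    """Transmembrane voltage V = E * L, returned in millivolts."""
    if box_z_nm <= 0:
        raise ValueError("box z-dimension must be positive")
    return field_v_per_nm * box_z_nm * 1000.0


@dataclass(frozen=True)
class PermeationRecord:
    ion_id: int
    entry_frame: int
    exit_frame: int
    direction: int  # +1 outward, -1 inward

    def __post_init__(self):
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if not self.entry_frame < self.exit_frame:
            raise ValueError("entry_frame must precede exit_frame")


@dataclass
class CurrentEstimate:
    """Per-replicate currents and their mean +/- SEM.

    ``sem`` is the sample standard deviation over replicates divided by
    sqrt(n); it is None (reported missing, never 0) for a single replicate.
    """

    per_replicate_pA: np.ndarray
    mean_pA: float
    sem_pA: float | None
    n_replicates: int


def filter_bounds(
    frames: FrameSeries,
    topology: Topology,
    margin: float = 0.1,
    bottom_expr: str = "resid 59 and name OG1",
    top_expr: str = "resid 63 and name O",
) -> np.ndarray:
    """Per-frame (z_low, z_high) of the selectivity-filter slab, (F, 2) nm.

    z_low is the mean z of the Thr59 O-gamma atoms minus ``margin``;
    z_high the mean z of the topmost filter carbonyl oxygens plus it.
    """
    bot = select(topology, bottom_expr)
    top = select(topology, top_expr)
    if len(bot) == 0 or len(top) == 0:
        raise ValueError("filter plane selections resolved to no atoms")
    z_low = frames.coordinates[:, bot.indices, 2].mean(axis=1) - margin
    z_high = frames.coordinates[:, top.indices, 2].mean(axis=1) + margin
    if np.any(z_low >= z_high):
        raise ValueError("filter bounds inverted (z_low >= z_high)")
    return np.stack([z_low, z_high], axis=1)


def compartments(ion_z, bounds, box_z=None) -> np.ndarray:
    """Map z values to interval indices along the (lifted) pore axis.

    Without ``box_z``: 0 below the slab, 1 inside, 2 above.  With
    ``box_z`` the axis is treated as periodic and lifted to the real line,
    so an unwrapped series that has crossed the box k times lands in
    interval 2k/2k+1/2k+2; even indices are bulk, odd indices are the
    filter interior.  The two views agree when no wrap occurred.
    """
    z = np.asarray(ion_z, dtype=float)
    if np.any(~np.isfinite(z)):
        raise ValueError("NaN/inf in ion z series")
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim == 1:
        bounds = np.broadcast_to(bounds, z.shape[:1] + (2,))
    lo, hi = bounds[:, 0], bounds[:, 1]
    if z.ndim == 2:
        lo, hi = lo[:, None], hi[:, None]
    w = hi - lo
    if box_z is None:
        return np.where(z < lo, BELOW, np.where(z > hi, ABOVE, INSIDE))
    L = np.asarray(box_z, dtype=float)
    if z.ndim == 2 and L.ndim == 1:
        L = L[:, None]
    k = np.floor((z - lo) / L)
    r = z - lo - k * L
    return (2 * k + np.where(r <= w, 1, 2)).astype(int)


def _runs(values: np.ndarray):
    """Compress a sequence into (value, start_frame, end_frame) runs."""
    change = np.flatnonzero(np.diff(values) != 0)
    starts = np.r_[0, change + 1]
    ends = np.r_[change, len(values) - 1]
    return values[starts], starts, ends


def detect_permeation_events(ion_z, bounds, box_z=None, ion_ids=None) -> list:
    """Detect full filter traversals from unwrapped per-ion z series.

    ``ion_z`` is (n_frames,) for one ion or (n_frames, n_ions); ``bounds``
    is the (n_frames, 2) slab from :func:`filter_bounds` (constant bounds
    may be broadcast).  Pass ``box_z`` when the series is unwrapped from a
    periodic box so that traversals are counted modulo wrapping.  Returns
    :class:`PermeationRecord` objects; events are non-overlapping per ion.

    The automaton anchors on the last bulk interval visited and fires only
    when the filter interior has been entered and the *opposite* bulk side
    reached: below -> inside -> above is one +1 (outward) event, the
    reverse one -1; bounces and partial entries count nothing.
    ``entry_frame`` is the last frame on the origin side, ``exit_frame``
    the first frame on the destination side.
    """
    z = np.asarray(ion_z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    comp = compartments(z, bounds, box_z=box_z)
    if ion_ids is None:
        ion_ids = np.arange(z.shape[1])
    records: list[PermeationRecord] = []
    for col, ion in enumerate(ion_ids):
        vals, starts, ends = _runs(comp[:, col])
        anchor = None  # even (bulk) interval currently anchored on
        anchor_frame = 0
        armed = 0  # +1/-1: interior adjacent to anchor visited, that side
        for v, s, e in zip(vals.tolist(), starts.tolist(), ends.tolist()):
            if v % 2 != 0:  # filter interior
                if anchor is None:
                    continue
                if v == anchor + 1:
                    armed = +1
                elif v == anchor - 1:
                    armed = -1
                else:  # non-adjacent jump (nonphysical step); reset
                    anchor, armed = None, 0
                continue
            if anchor is None or v == anchor:
                anchor, anchor_frame, armed = v, e, 0
                continue
            if armed != 0 and v == anchor + 2 * armed:
                records.append(
                    PermeationRecord(int(ion), int(anchor_frame), int(s), int(armed))
                )
            anchor, anchor_frame, armed = v, e, 0
    return records


def current_from_events(n_plus: int, n_minus: int, t_total_ns: float) -> float:
    """Ionic current in pA from net outward crossings over t_total (ns)."""
    if t_total_ns <= 0:
        raise ValueError("t_total must be positive")
    charge_pC = (n_plus - n_minus) * ELEMENTARY_CHARGE_C * 1e12
    return charge_pC / (t_total_ns * 1e-9)


def aggregate_current(per_replicate_pA) -> CurrentEstimate:
    """Mean +/- SEM over replicate currents (SEM missing for n = 1)."""
    vals = np.asarray(list(per_replicate_pA), dtype=float)
    if vals.size == 0:
        raise ValueError("no replicates")
    sem = (
        float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else None
    )
    return CurrentEstimate(
        per_replicate_pA=vals,
        mean_pA=float(vals.mean()),
        sem_pA=sem,
        n_replicates=int(vals.size),
    )


# binding-site plane stack, bottom to top (MthK filter TVGYG, resids 59-63)
_SITE_PLANES = [
    ("resid 59 and name O", "resid 60 and name O", "S4"),
    ("resid 60 and name O", "resid 61 and name O", "S3"),
    ("resid 61 and name O", "resid 62 and name O", "S2"),
    ("resid 62 and name O", "resid 63 and name O", "S1"),
]


def site_occupancy(
    frames: FrameSeries,
    topology: Topology,
    ion_expr: str = "resname K",
    axis_radius: float = 0.4,
) -> dict:
    """Fractional occupancy of the filter sites S1-S4 and the cavity (Scav).

    A site is occupied in a frame when at least one selected ion lies in
    the slab between its bounding carbonyl-O planes and within
    ``axis_radius`` of the pore axis (the xy COM of the filter C-alpha
    atoms).  Scav spans the Phe87 C-alpha plane to the Thr59 O-gamma plane.
    """
    ions = select(topology, ion_expr)
    axis_sel = select(topology, "filter and name CA")
    if len(axis_sel) == 0:
        raise ValueError("filter C-alpha selection empty; cannot define pore axis")
    axis_xy = frames.coordinates[:, axis_sel.indices, :2].mean(axis=1)

    def plane_z(expr):
        sel = select(topology, expr)
        if len(sel) == 0:
            raise ValueError(f"plane selection {expr!r} empty")
        return frames.coordinates[:, sel.indices, 2].mean(axis=1)

    slabs = []
    for lo_expr, hi_expr, label in _SITE_PLANES:
        lo, hi = plane_z(lo_expr), plane_z(hi_expr)
        if np.any(lo >= hi):
            raise ValueError(f"site planes out of order for {label}")
        slabs.append((label, lo, hi))
    slabs.append(
        ("Scav", plane_z("resid 87 and name CA"), plane_z("resid 59 and name OG1"))
    )

    occ = {}
    if len(ions) == 0:
        return {label: 0.0 for label, _, _ in slabs}
    ion_xyz = frames.coordinates[:, ions.indices, :]
    r = np.linalg.norm(ion_xyz[:, :, :2] - axis_xy[:, None, :], axis=2)
    near_axis = r <= axis_radius
    for label, lo, hi in slabs:
        inside = (
            (ion_xyz[:, :, 2] >= lo[:, None])
            & (ion_xyz[:, :, 2] <= hi[:, None])
            & near_axis
        )
        occ[label] = float(inside.any(axis=1).mean())
    return occ


def ion_z_series(frames: FrameSeries, topology: Topology, ion_expr: str = "resname K"):
    """(ion_ids, raw z (F, n_ions), per-frame box_z) for the selected ions."""
    ions = select(topology, ion_expr)
    if len(ions) == 0:
        raise ValueError(f"ion selection {ion_expr!r} matched no atoms")
    return ions.indices, frames.coordinates[:, ions.indices, 2], frames.box[:, 2]


def analyze_permeation(
    frames: FrameSeries,
    topology: Topology,
    ion_expr: str = "resname K",
    margin: float = 0.1,
):
    """End-to-end crossing detection on one replicate.

    Unwraps the selected ions' z series, detects traversals of the filter
    slab (periodic-aware), and returns ``(records, current_pA)`` where the
    current uses the replicate's total simulated time.
    """
    from .trajectory_io import unwrap_z

    bounds = filter_bounds(frames, topology, margin=margin)
    ids, z_raw, box_z = ion_z_series(frames, topology, ion_expr)
    z_unwrapped = unwrap_z(z_raw, box_z)
    records = detect_permeation_events(z_unwrapped, bounds, box_z=box_z, ion_ids=ids)
    n_plus = sum(1 for r in records if r.direction > 0)
    n_minus = len(records) - n_plus
    current = current_from_events(n_plus, n_minus, frames.duration_ns)
    return records, current


def events_table(records, replicate: str = "rep0") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "replicate": replicate,
            "ion_id": [r.ion_id for r in records],
            "entry_frame": [r.entry_frame for r in records],
            "exit_frame": [r.exit_frame for r in records],
            "direction": [r.direction for r in records],
        }
    )
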