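"""Synthetic channel trajectories with planted, fully-known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at desk scale: a 4-fold pseudo-symmetric tetramer whose four
inner helices switch independently between a *kinked* template (broken
Val81O-Gly85H hydrogen bond, d_VG ~ 0.55 nm, bending angle 43 deg) and a
*bent* template (bond formed, d_VG ~ 0.20 nm, 30 deg) via a continuous-
time two-state Markov chain; a Thr59 O-gamma filter-gate ring whose
diameter grows with the number of bent subunits; Phe87 side chains that
rotate into the central cavity in the bent state; cavity waters whose
count drops as bent subunits accumulate; voltage-driven K+ filter
crossings drawn from a Poisson process whose rate depends on the tetramer
configuration; and two lipid-phosphate layers defining the membrane
thickness.

The geometry is schematic — helices are parametrised C-alpha traces with
the named key atoms, not a physical model.  Only the descriptors the
pipeline measures are planted faithfully; everything else (water
structure, lipid packing, forces) is decoration.  The same seed produces
bit-identical topology, frames and ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .trajectory_io import (
    ATOMIC_MASSES,
    VDW_RADII_NM,
    DEFAULT_VDW_RADIUS_NM,
    FrameSeries,
    Topology,
    infer_element,
    write_structure,
    write_trajectory,
)

__all__ = [
    "KINKED",
    "BENT",
    "StateTemplates",
    "SyntheticSpec",
    "GroundTruth",
    "preset_conduction_regime",
    "simulate_state_dynamics",
    "build_channel_topology",
    "generate_trajectory",
    "generate",
    "write_fixture",
]

KINKED, BENT = 0, 1

_CENTER_XY = np.array([4.0, 4.0])
_PHI_DEG = {"A": 45.0, "B": 135.0, "C": 225.0, "D": 315.0}

# absolute z landmarks (nm): filter entrance (Thr59 O-gamma plane) at 5.2,
# carbonyl-O planes of the TVGYG filter stacked 0.3 nm apart above it
_Z_OG = 5.2
_Z_O_PLANES = {59: 5.5, 60: 5.8, 61: 6.1, 62: 6.4, 63: 6.7}
_HINGE_RADIUS, _HINGE_Z = 1.1, 4.9
_ALPHA1_DEG = 10.0  # tilt of the pre-hinge inner-helix segment
_RISE = 0.15  # nm per residue along each helix segment
_Z_MEMBRANE_MID = 4.95

_FILTER_RESNAMES = {59: "THR", 60: "VAL", 61: "GLY", 62: "TYR", 63: "GLY"}
_INNER_RESNAMES = {81: "VAL", 82: "LEU", 83: "GLY", 84: "ILE", 85: "GLY",
                   86: "THR", 87: "PHE", 92: "GLU", 96: "GLU"}


@dataclass
class StateTemplates:
    """Planted per-state geometry (nm / degrees).

    ``og_ring_by_nbent`` maps the number of bent subunits (0-4) to the
    diagonal Thr59 O-gamma--O-gamma distance: the filter-gate opening grows
    with the bent count (crosstalk side 1).  Phe87-CoF shrinks in the bent
    state (the side chain swings into the cavity, crosstalk side 2).
    """

    d_vg: tuple = (0.55, 0.20)  # (kinked, bent) Val81 O - Gly85 H
    d_lt: tuple = (0.55, 0.20)  # Leu82 O - Thr86 H
    theta_deg: tuple = (43.0, 30.0)  # inner-helix bending angle
    cof: tuple = (0.836, 0.666)  # Phe87 side-chain COM to Calpha-ring COM
    d_i84_t59: tuple = (0.54, 0.59)  # Ile84-Thr59 side-chain COM distance
    og_ring_by_nbent: dict = field(
        default_factory=lambda: {0: 0.497, 1: 0.512, 2: 0.519, 3: 0.526, 4: 0.533}
    )


@dataclass
class SyntheticSpec:
    """Full parameterisation of one synthetic replicate.

    Rates are ns^-1 (k_kb: kinked->bent, k_bk: bent->kinked; stationary
    bent fraction k_kb/(k_kb+k_bk)).  ``lambda_by_config`` gives the K+
    crossing rate in events/us for each tetramer configuration n_bent;
    ``cavity_waters_by_nbent`` the planted cavity water count.
    ``potential`` switches the ions to equilibrium mode: i.i.d. Boltzmann
    samples from U(z) (shape in {"flat","harmonic","double_well",
    "gaussian_barrier"}) instead of driven crossings.  ``fixed_states``
    ("kinked"/"bent") emulates the restrained-subunit simulations.
    """

    n_frames: int = 10000
    dt: float = 0.1  # ns per frame
    seed: int = 0
    k_kb: float = 0.015
    k_bk: float = 0.035
    templates: StateTemplates = field(default_factory=StateTemplates)
    noise_sigma: float = 0.01  # nm, isotropic on protein atoms
    lambda_by_config: dict = field(
        default_factory=lambda: {0: 3.0, 1: 55.0, 2: 55.0, 3: 15.0, 4: 18.0}
    )
    cavity_waters_by_nbent: dict = field(
        default_factory=lambda: {0: 12, 1: 10, 2: 8, 3: 6, 4: 2}
    )
    thickness: float = 3.6  # nm, phosphate-to-phosphate
    n_ions: int = 24
    n_waters: int = 160
    box: tuple = (8.0, 8.0, 9.2308)
    field_v_per_nm: float = 0.0325  # with box_z 9.2308 nm: 300 mV
    crossing_duration: float = 2.0  # ns per driven filter traversal
    fixed_states: str | None = None
    ile84_ring_radius: float | None = None  # restraint override (nm)
    potential: dict | None = None  # equilibrium-ion mode
    water_jitter: float = 0.05
    ion_jitter: float = 0.04
    lipid_jitter: float = 0.05

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if "templates" in d and isinstance(d["templates"], dict):
            t = dict(d["templates"])
            for k in ("d_vg", "d_lt", "theta_deg", "cof", "d_i84_t59"):
                if k in t:
                    t[k] = tuple(t[k])
            if "og_ring_by_nbent" in t:
                t["og_ring_by_nbent"] = {int(k): v for k, v in t["og_ring_by_nbent"].items()}
            d["templates"] = StateTemplates(**t)
        for k in ("lambda_by_config", "cavity_waters_by_nbent"):
            if k in d:
                d[k] = {int(a): b for a, b in d[k].items()}
        if "box" in d:
            d["box"] = tuple(d["box"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def stationary_bent_fraction(self) -> float:
        if self.fixed_states is not None:
            return 1.0 if self.fixed_states == "bent" else 0.0
        return self.k_kb / (self.k_kb + self.k_bk)


def preset_conduction_regime(name: str) -> SyntheticSpec:
    """Presets planting the three current/bent-fraction groups plus the
    all-bent dewetted regime.

    high_current: bent fraction ~0.30, current on the ~6 pA scale;
    mid_current: ~0.125, 3.5-4.6 pA scale; low_current: ~0.03, <2 pA;
    all_bent_dewetted: all four subunits bent — widest filter gate but a
    dehydrated cavity and a suppressed crossing rate (the non-monotonic
    end of the crosstalk curve).
    """
    presets = {
        "high_current": dict(k_kb=0.015, k_bk=0.035),
        "mid_current": dict(k_kb=0.00625, k_bk=0.04375),
        "low_current": dict(k_kb=0.0015, k_bk=0.0485),
        "all_bent_dewetted": dict(fixed_states="bent"),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    spec = SyntheticSpec(**presets[name])
    lam = spec.lambda_by_config
    if not (lam[0] <= min(lam[1], lam[2]) and lam[4] <= min(lam[1], lam[2])):
        raise ValueError("crosstalk presets need lambda[0], lambda[4] <= lambda[1..2]")
    return spec


# ---------------------------------------------------------------------------
# state dynamics


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_state_dynamics(spec: SyntheticSpec, seed=None) -> np.ndarray:
    """Sample the four per-subunit two-state chains, (n_frames, 4) int8.

    Exact continuous-time sampling (exponential dwells) observed on the
    frame grid; the initial state is drawn from the stationary
    distribution, so the time average of the bent indicator is unbiased.
    """
    if spec.k_kb < 0 or spec.k_bk < 0:
        raise ValueError("rates must be non-negative")
    if spec.fixed_states is not None:
        val = BENT if spec.fixed_states == "bent" else KINKED
        return np.full((spec.n_frames, 4), val, dtype=np.int8)
    if spec.k_kb + spec.k_bk <= 0:
        raise ValueError("k_kb + k_bk must be positive")
    rng = _as_rng(spec.seed if seed is None else seed)
    f_b = spec.stationary_bent_fraction
    out = np.empty((spec.n_frames, 4), dtype=np.int8)
    t_end = spec.n_frames * spec.dt
    rates = {KINKED: spec.k_kb, BENT: spec.k_bk}
    for s in range(4):
        state = BENT if rng.random() < f_b else KINKED
        t = 0.0
        frame = 0
        while frame < spec.n_frames:
            rate = rates[state]
            dwell = rng.exponential(1.0 / rate) if rate > 0 else t_end + 1.0
            t_next = t + dwell
            last = min(spec.n_frames, int(np.ceil(t_next / spec.dt)))
            out[frame:last, s] = state
            frame = last
            t = t_next
            state = 1 - state
    return out


# ---------------------------------------------------------------------------
# topology and geometry


def _unit_vectors(phi_deg: float):
    phi = np.deg2rad(phi_deg)
    e_r = np.array([np.cos(phi), np.sin(phi), 0.0])
    e_t = np.array([-np.sin(phi), np.cos(phi), 0.0])
    return e_r, e_t


def _pos(r: float, e_r: np.ndarray, z: float) -> np.ndarray:
    return np.array([_CENTER_XY[0], _CENTER_XY[1], 0.0]) + r * e_r + np.array([0, 0, z])


class _Geometry:
    """Atom bookkeeping: names/resids plus per-state/config template coords."""

    def __init__(self):
        self.names, self.resnames, self.resids, self.subunits = [], [], [], []
        self.kinked, self.bent = [], []  # per-atom template positions
        self.tags = []  # "both" | "og_cfg" | "phe_sc"

    def add(self, subunit, resid, resname, name, pos_k, pos_b=None, tag="both"):
        self.names.append(name)
        self.resnames.append(resname)
        self.resids.append(resid)
        self.subunits.append(subunit)
        self.kinked.append(np.asarray(pos_k, dtype=float))
        self.bent.append(np.asarray(pos_b if pos_b is not None else pos_k, dtype=float))
        self.tags.append(tag)


def _build_geometry(spec: SyntheticSpec):
    tpl = spec.templates
    g = _Geometry()
    og_r = {n: d / 2.0 for n, d in tpl.og_ring_by_nbent.items()}
    alpha1 = np.deg2rad(_ALPHA1_DEG)

    mass_O = ATOMIC_MASSES["O"]
    mass_C = ATOMIC_MASSES["C"]

    phe_ca = {}  # subunit -> (2, 3) CA positions per state
    og_cfg_positions = {}  # (subunit, name) -> (5, 3) per n_bent
    t59_com_target = {}

    for sub, phi in _PHI_DEG.items():
        e_r, e_t = _unit_vectors(phi)
        # outer helix 10-19 (Pro19 C-alpha at the top end)
        for i in range(10, 20):
            rname = "PRO" if i == 19 else "ALA"
            g.add(sub, i, rname, "CA", _pos(1.6, e_r, 3.2 + 0.3333 * (i - 10)))
        # pore helix 50-58
        for i in range(50, 59):
            g.add(sub, i, "ALA", "CA", _pos(1.0, e_r, 6.6 - 0.15 * (i - 50)))
        # filter 59-63: C-alpha ring + carbonyl-O planes
        for i in range(59, 64):
            zO = _Z_O_PLANES[i]
            rname = _FILTER_RESNAMES[i]
            g.add(sub, i, rname, "CA", _pos(0.45, e_r, zO + 0.05))
            if i in (59, 61):
                # coupled to the gate: ring radius grows with n_bent
                base = 0.25
                per_n = np.stack(
                    [_pos(base + og_r[n] - og_r[0], e_r, zO) for n in range(5)]
                )
                og_cfg_positions[(sub, f"O{i}")] = per_n
                g.add(sub, i, rname, "O", per_n[0], tag="og_cfg")
            else:
                g.add(sub, i, rname, "O", _pos(0.25, e_r, zO))
            if i == 59:
                per_n = np.stack([_pos(og_r[n], e_r, _Z_OG) for n in range(5)])
                og_cfg_positions[(sub, "OG1")] = per_n
                g.add(sub, i, "THR", "OG1", per_n[0], tag="og_cfg")
                # side-chain COM target is held fixed; CB/CG2 compensate the
                # configuration-dependent OG1 below
                T = _pos(0.6, e_r, 5.05)
                t59_com_target[sub] = (T, e_t)
                cb_per_n, cg_per_n = [], []
                for n in range(5):
                    og1 = per_n[n]
                    total = mass_O + 2 * mass_C
                    Q = (total * T - mass_O * og1) / (2 * mass_C)
                    cb_per_n.append(Q + 0.06 * e_t)
                    cg_per_n.append(Q - 0.06 * e_t)
                og_cfg_positions[(sub, "CB59")] = np.stack(cb_per_n)
                og_cfg_positions[(sub, "CG259")] = np.stack(cg_per_n)
                g.add(sub, i, "THR", "CB", cb_per_n[0], tag="og_cfg")
                g.add(sub, i, "THR", "CG2", cg_per_n[0], tag="og_cfg")
        # inner helix 71-98, hinge at Gly83
        H = _pos(_HINGE_RADIUS, e_r, _HINGE_Z)
        u1 = np.sin(alpha1) * e_r - np.cos(alpha1) * np.array([0, 0, 1.0])
        segs = {}
        for st, theta in zip((KINKED, BENT), tpl.theta_deg):
            a2 = alpha1 + np.deg2rad(theta)
            segs[st] = np.sin(a2) * e_r - np.cos(a2) * np.array([0, 0, 1.0])
        ca = {st: {} for st in (KINKED, BENT)}
        for i in range(71, 99):
            rname = _INNER_RESNAMES.get(i, "ALA")
            if i < 83:
                p = H - _RISE * (83 - i) * u1
                g.add(sub, i, rname, "CA", p)
                for st in (KINKED, BENT):
                    ca[st][i] = p
            elif i == 83:
                g.add(sub, i, "GLY", "CA", H)
            else:
                pk = H + _RISE * (i - 83) * segs[KINKED]
                pb = H + _RISE * (i - 83) * segs[BENT]
                g.add(sub, i, rname, "CA", pk, pb)
                ca[KINKED][i] = pk
                ca[BENT][i] = pb
        phe_ca[sub] = np.stack([ca[KINKED][87], ca[BENT][87]])
        # kink H-bond atoms: Val81 O fixed, Gly85 amide H at the planted
        # d_VG along z (Leu82 O / Thr86 H likewise); N placed 0.1 nm beyond
        # H so the heavy-atom O-N fallback distance is d + 0.1
        v81o = ca[KINKED][81] + 0.10 * e_t
        g.add(sub, 81, "VAL", "O", v81o)
        for st_atoms, (acc, don, dist) in {
            "VG": (81, 85, tpl.d_vg),
            "LT": (82, 86, tpl.d_lt),
        }.items():
            base = v81o if acc == 81 else ca[KINKED][82] + 0.10 * e_t
            if acc == 82:
                g.add(sub, 82, "LEU", "O", base)
            hk = base + np.array([0, 0, dist[KINKED]])
            hb = base + np.array([0, 0, dist[BENT]])
            rname = _INNER_RESNAMES[don]
            g.add(sub, don, rname, "H", hk, hb)
            g.add(sub, don, rname, "N", hk + np.array([0, 0, 0.1]),
                  hb + np.array([0, 0, 0.1]))
        # Ile84 side chain: COM offset from the Thr59 side-chain COM target
        # along a fixed oblique direction, so |COM - T| is the planted value
        T, _ = t59_com_target[sub]
        e_d = 0.8 * e_r - 0.6 * np.array([0, 0, 1.0])
        if spec.ile84_ring_radius is not None:
            Ik = Ib = _pos(spec.ile84_ring_radius, e_r, 4.7)
        else:
            Ik = T + tpl.d_i84_t59[KINKED] * e_d
            Ib = T + tpl.d_i84_t59[BENT] * e_d
        g.add(sub, 84, "ILE", "CB", Ik + 0.06 * e_t, Ib + 0.06 * e_t)
        g.add(sub, 84, "ILE", "CG1", Ik - 0.06 * e_t, Ib - 0.06 * e_t)
        # Phe87 side chain: placed per frame from the CoF rule (placeholder)
        g.add(sub, 87, "PHE", "CB", _pos(1.0, e_r, 4.5), tag="phe_sc")
        g.add(sub, 87, "PHE", "CG", _pos(1.0, e_r, 4.5), tag="phe_sc")

    n_protein = len(g.names)

    # --- ions ------------------------------------------------------------
    ion_base = []
    for i in range(spec.n_ions):
        ang = 2 * np.pi * i / max(spec.n_ions, 1)
        ion_base.append(
            [_CENTER_XY[0] + 2.8 * np.cos(ang), _CENTER_XY[1] + 2.8 * np.sin(ang), 2.2]
        )
        g.add("I", 1000 + i, "K", "K", ion_base[-1])
    ion_base = np.asarray(ion_base)

    # --- waters: cavity-capable slots first, then bulk -------------------
    m_cav = max(spec.cavity_waters_by_nbent.values()) if spec.cavity_waters_by_nbent else 0
    m_cav = min(m_cav, spec.n_waters)
    cavity_slots, parking = [], []
    for j in range(m_cav):
        ang = 2.399963 * j  # golden-angle spiral
        r = 0.12 + 0.18 * ((j % 4) / 3.0)
        z = 4.62 + 0.48 * (j / max(m_cav - 1, 1))
        cavity_slots.append(
            [_CENTER_XY[0] + r * np.cos(ang), _CENTER_XY[1] + r * np.sin(ang), z]
        )
        parking.append(
            [_CENTER_XY[0] + 3.2 * np.cos(ang), _CENTER_XY[1] + 3.2 * np.sin(ang), 1.2]
        )
        g.add("W", 2000 + j, "SOL", "OW", cavity_slots[-1])
    bulk_base = []
    for j in range(spec.n_waters - m_cav):
        gx = j % 10
        gy = (j // 10) % 10
        z = 0.8 + 0.15 * (j // 100) if (j % 2 == 0) else 7.4 + 0.15 * (j // 100)
        bulk_base.append([0.4 + 0.76 * gx, 0.4 + 0.76 * gy, z])
        g.add("W", 2000 + m_cav + j, "SOL", "OW", bulk_base[-1])

    # --- lipid phosphate layers ------------------------------------------
    lip_base = []
    rid = 5000
    for zsign in (+1, -1):
        z = _Z_MEMBRANE_MID + zsign * spec.thickness / 2.0
        for ix in range(8):
            for iy in range(8):
                p = [0.5 + ix * 1.0, 0.5 + iy * 1.0, z]
                # keep lipids out of the protein footprint
                if (p[0] - 4.0) ** 2 + (p[1] - 4.0) ** 2 < 1.0:
                    p[0] += 2.0 if p[0] <= 4.0 else -0.0
                lip_base.append(p)
                g.add("L", rid, "LIP", "P", p)
                rid += 1
    lip_base = np.asarray(lip_base)

    elements = np.array([infer_element(n) for n in g.names], dtype=object)
    topo = Topology(
        atom_name=np.array(g.names, dtype=object),
        residue_name=np.array(g.resnames, dtype=object),
        residue_id=np.array(g.resids, dtype=int),
        subunit=np.array(g.subunits, dtype=object),
        element=elements,
        vdw_radius=np.array(
            [VDW_RADII_NM.get(e, DEFAULT_VDW_RADIUS_NM) for e in elements]
        ),
    )
    geom = {
        "g": g,
        "n_protein": n_protein,
        "phe_ca": phe_ca,
        "og_cfg_positions": og_cfg_positions,
        "ion_base": ion_base,
        "m_cav": m_cav,
        "cavity_slots": np.asarray(cavity_slots).reshape(-1, 3) if m_cav else np.zeros((0, 3)),
        "parking": np.asarray(parking).reshape(-1, 3) if m_cav else np.zeros((0, 3)),
        "lip_base": lip_base,
    }
    return topo, geom


def build_channel_topology(spec: SyntheticSpec) -> Topology:
    """Atom table of the pseudo-tetramer system (deterministic; no seed)."""
    topo, _ = _build_geometry(spec)
    return topo


# ---------------------------------------------------------------------------
# trajectory generation


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery checks."""

    states: np.ndarray  # (n_frames, 4) int8
    events: list  # dicts: ion_id, start_frame, end_frame, direction, n_bent
    cavity_water_count: np.ndarray  # (n_frames,)
    spec: SyntheticSpec

    @property
    def n_bent(self) -> np.ndarray:
        return self.states.sum(axis=1).astype(int)

    @property
    def f_bent(self) -> float:
        return float(self.states.mean())

    @property
    def n_events(self) -> int:
        return len(self.events)

    def to_json(self, path) -> None:
        payload = {
            "f_bent": self.f_bent,
            "n_events": self.n_events,
            "events": self.events,
            "states": self.states.tolist(),
            "cavity_water_count": self.cavity_water_count.tolist(),
            "spec": self.spec.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))


_POTENTIAL_Z_RANGE = (-2.8, 1.6)


def potential_energy(z: np.ndarray, potential: dict) -> np.ndarray:
    """Planted U(z) in kBT on the filter-relative z axis."""
    shape = potential.get("shape", "flat")
    z = np.asarray(z, dtype=float)
    if shape == "flat":
        return np.zeros_like(z)
    if shape == "harmonic":
        return potential.get("k", 2.0) * (z - potential.get("z0", -0.6)) ** 2
    if shape == "double_well":
        z0 = potential.get("z0", -0.6)
        a, b = potential.get("a", 4.0), potential.get("b", 0.5)
        return a * ((z - z0) ** 2 - b**2) ** 2 / b**4
    if shape == "gaussian_barrier":
        z0 = potential.get("z0", -0.6)
        h, w = potential.get("height", 5.1), potential.get("width", 0.25)
        return h * np.exp(-((z - z0) ** 2) / (2 * w**2))
    raise ValueError(f"unknown potential shape {shape!r}")


def generate_trajectory(spec: SyntheticSpec, states: np.ndarray | None = None,
                        seed=None):
    """Emit (Topology, FrameSeries, GroundTruth) for one replicate."""
    rng = _as_rng(spec.seed if seed is None else seed)
    if states is None:
        states = simulate_state_dynamics(spec, rng)
    states = np.asarray(states, dtype=np.int8)
    F = spec.n_frames
    if states.shape != (F, 4):
        raise ValueError(f"states must be ({F}, 4), got {states.shape}")
    topo, geom = _build_geometry(spec)
    g = geom["g"]
    n_atoms = topo.n_atoms
    n_bent = states.sum(axis=1).astype(int)

    coords = np.empty((F, n_atoms, 3))
    kinked_pos = np.stack(g.kinked)
    bent_pos = np.stack(g.bent)
    sub_arr = np.array(g.subunits, dtype=object)
    tag_arr = np.array(g.tags, dtype=object)

    # protein: per-subunit state templates
    for si, sub in enumerate("ABCD"):
        idx = np.flatnonzero((sub_arr == sub) & (tag_arr == "both"))
        tmpl = np.stack([kinked_pos[idx], bent_pos[idx]])  # (2, m, 3)
        coords[:, idx, :] = tmpl[states[:, si]]
        # configuration-coupled filter-gate atoms
        cfg_idx = np.flatnonzero((sub_arr == sub) & (tag_arr == "og_cfg"))
        cfg_keys = [
            (sub, {"OG1": "OG1", "O": f"O{g.resids[i]}", "CB": "CB59", "CG2": "CG259"}[g.names[i]])
            for i in cfg_idx
        ]
        cfg_arr = np.stack([geom["og_cfg_positions"][k] for k in cfg_keys], axis=1)
        coords[:, cfg_idx, :] = cfg_arr[n_bent]

    # Phe87 side chains: CoF rule against the per-frame C-alpha ring centre
    ca_choice = np.stack(
        [geom["phe_ca"][sub][states[:, si]] for si, sub in enumerate("ABCD")], axis=1
    )  # (F, 4, 3)
    c87 = ca_choice.mean(axis=1)
    direction = ca_choice - c87[:, None, :]
    direction /= np.linalg.norm(direction, axis=2, keepdims=True)
    cof = np.asarray(spec.templates.cof)[states]  # (F, 4)
    p_s = c87[:, None, :] + cof[:, :, None] * direction
    for si, sub in enumerate("ABCD"):
        _, e_t = _unit_vectors(_PHI_DEG[sub])
        idx = np.flatnonzero((sub_arr == sub) & (tag_arr == "phe_sc"))
        coords[:, idx[0], :] = p_s[:, si, :] + 0.07 * e_t
        coords[:, idx[1], :] = p_s[:, si, :] - 0.07 * e_t

    n_protein = geom["n_protein"]
    if spec.noise_sigma > 0:
        coords[:, :n_protein, :] += rng.normal(0.0, spec.noise_sigma, (F, n_protein, 3))

    # --- ions -------------------------------------------------------------
    ion_start = n_protein
    n_ions = spec.n_ions
    ion_base = geom["ion_base"]
    events: list[dict] = []
    if n_ions:
        ion_xyz = ion_base[None] + rng.normal(0.0, spec.ion_jitter, (F, n_ions, 3))
        if spec.potential is not None:
            grid = np.arange(*_POTENTIAL_Z_RANGE, 0.005)
            p = np.exp(-potential_energy(grid, spec.potential))
            p /= p.sum()
            z_rel = rng.choice(grid, size=(F, n_ions), p=p)
            z_rel += rng.uniform(-0.0025, 0.0025, z_rel.shape)
            rr = 0.3 * np.sqrt(rng.uniform(0, 1, (F, n_ions)))
            aa = rng.uniform(0, 2 * np.pi, (F, n_ions))
            ion_xyz = np.stack(
                [
                    _CENTER_XY[0] + rr * np.cos(aa),
                    _CENTER_XY[1] + rr * np.sin(aa),
                    _Z_OG + z_rel,
                ],
                axis=2,
            )
        else:
            lam = np.array([spec.lambda_by_config.get(n, 0.0) for n in range(5)])
            per_frame = lam[n_bent] * spec.dt * 1e-3  # events per frame
            counts = rng.poisson(per_frame)
            n_cross = max(3, int(round(spec.crossing_duration / spec.dt)))
            ramp = np.linspace(4.3, 7.6, n_cross)
            free_at = np.zeros(n_ions, dtype=int)
            for f in np.flatnonzero(counts):
                for _ in range(counts[f]):
                    avail = np.flatnonzero(free_at <= f)
                    if len(avail) == 0:
                        continue  # all carriers busy; crossing not realised
                    ion = int(avail[0])
                    end = min(F, f + n_cross)
                    e_off = 0.08 * np.array(
                        [np.cos(2.1 * ion), np.sin(2.1 * ion), 0.0]
                    )
                    ion_xyz[f:end, ion, 0] = _CENTER_XY[0] + e_off[0]
                    ion_xyz[f:end, ion, 1] = _CENTER_XY[1] + e_off[1]
                    ion_xyz[f:end, ion, 2] = ramp[: end - f]
                    free_at[ion] = end + 5
                    if end - f == n_cross:  # only completed traversals count
                        events.append(
                            {
                                "ion_id": ion,
                                "start_frame": int(f),
                                "end_frame": int(end - 1),
                                "direction": 1,
                                "n_bent": int(n_bent[f]),
                            }
                        )
        coords[:, ion_start : ion_start + n_ions, :] = ion_xyz

    # --- waters -----------------------------------------------------------
    w_start = ion_start + n_ions
    m_cav = geom["m_cav"]
    cav_count = np.array(
        [spec.cavity_waters_by_nbent.get(n, m_cav) for n in range(5)]
    )[n_bent]
    if m_cav:
        occupied = np.arange(m_cav)[None, :] < cav_count[:, None]  # (F, m_cav)
        slots = np.where(
            occupied[:, :, None], geom["cavity_slots"][None], geom["parking"][None]
        )
        coords[:, w_start : w_start + m_cav, :] = slots + rng.normal(
            0.0, min(spec.water_jitter, 0.03), (F, m_cav, 3)
        )
    n_bulk = spec.n_waters - m_cav
    if n_bulk > 0:
        base = np.stack(g.kinked)[w_start + m_cav : w_start + spec.n_waters]
        coords[:, w_start + m_cav : w_start + spec.n_waters, :] = base[
            None
        ] + rng.normal(0.0, spec.water_jitter, (F, n_bulk, 3))

    # --- lipids -----------------------------------------------------------
    l_start = w_start + spec.n_waters
    lip = geom["lip_base"]
    coords[:, l_start:, :] = lip[None] + rng.normal(
        0.0, spec.lipid_jitter, (F, len(lip), 3)
    )

    times = np.arange(F) * spec.dt
    box = np.broadcast_to(np.asarray(spec.box, dtype=float), (F, 3)).copy()
    frames = FrameSeries(times, coords, box)
    truth = GroundTruth(
        states=states, events=events, cavity_water_count=cav_count, spec=spec
    )
    return topo, frames, truth


def generate(spec: SyntheticSpec):
    """Convenience wrapper: states + trajectory from ``spec.seed``."""
    return generate_trajectory(spec)


def write_fixture(spec: SyntheticSpec, outdir) -> dict:
    """Write topology PDB, XTC trajectory, ground-truth JSON and spec YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    topo, frames, truth = generate(spec)
    paths = {
        "topology": outdir / "system.pdb",
        "trajectory": outdir / "traj.xtc",
        "ground_truth": outdir / "ground_truth.json",
        "spec": outdir / "spec.yaml",
    }
    write_structure(paths["topology"], topo, frames.coordinates[0], frames.box[0])
    write_trajectory(paths["trajectory"], topo, frames)
    truth.to_json(paths["ground_truth"])
    spec.to_yaml(paths["spec"])
    return paths
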