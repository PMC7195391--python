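"""Topology/trajectory I/O, atom selection, and periodic-boundary helpers.

Everything downstream works in a fixed unit system: lengths in nm, times in
ns, angles in degrees. File parsing and writing (PDB, GRO, XTC, DCD) is
delegated to MDAnalysis; this module converts to/from the internal
convention at the boundary (MDAnalysis positions are Å) and exposes the
in-memory containers (:class:`Topology`, :class:`FrameSeries`) plus a small
deterministic selection language used by every descriptor.

The z axis is taken as the membrane normal and pore axis throughout; only
orthorhombic boxes are supported.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Topology",
    "FrameSeries",
    "Selection",
    "FormatError",
    "EmptyInputError",
    "TopologyMismatchError",
    "SelectionSyntaxError",
    "UnsupportedBoxError",
    "load_topology",
    "iter_frames",
    "select",
    "unwrap_z",
    "minimum_image",
    "write_structure",
    "write_trajectory",
]


class FormatError(ValueError):
    """Input file could not be parsed in a supported format."""


class EmptyInputError(ValueError):
    """File parsed but contained no atoms/frames."""


class TopologyMismatchError(ValueError):
    """Trajectory atom count does not match the topology."""


class SelectionSyntaxError(ValueError):
    """Selection expression failed to parse; message carries the position."""


class UnsupportedBoxError(ValueError):
    """Non-orthorhombic (triclinic) or missing box."""


# van der Waals radii in nm (Bondi-style) and atomic masses in u, keyed by
# element symbol.  Unknown elements fall back to the carbon radius.
DEFAULT_VDW_RADIUS_NM = 0.17
VDW_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "F": 0.147,
    "K": 0.275,
    "NA": 0.227,
    "CL": 0.175,
    "MG": 0.173,
}
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "K": 39.098,
    "NA": 22.990,
    "CL": 35.45,
    "MG": 24.305,
}

_MONATOMIC_NAMES = {"K", "NA", "CL", "MG", "ZN", "FE", "CA2", "POT", "SOD", "CLA"}
_MONATOMIC_TO_ELEMENT = {"POT": "K", "SOD": "NA", "CLA": "CL", "CA2": "CA"}

PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
    "TYR", "VAL",
}

# Backbone atom names; the backbone amide hydrogen is normalised to "H"
# on load (CHARMM topologies call it "HN").
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

# MthK residue-range defaults for the named convenience selections.
NAMED_SELECTIONS = {
    "filter": "resid 59:63",
    "inner_helix": "resid 71:98",
    "outer_helix": "resid 10:19",
}


def infer_element(atom_name: str) -> str:
    """Guess the element symbol from a (PDB-style) atom name.

    Single-atom species (K, NA, CL, ...) are matched by full name first;
    otherwise the first alphabetic character wins, so "OG1" -> O,
    "1HB" -> H, "CA" -> C (protein alpha carbon, not calcium).
    """
    name = atom_name.strip().upper()
    if name in _MONATOMIC_NAMES:
        return _MONATOMIC_TO_ELEMENT.get(name, name)
    for ch in name:
        if ch.isalpha():
            return ch
    return ""


@dataclass
class Topology:
    """Atom table: identities, subunit labels, vdW radii and masses.

    ``atom_id`` is 0-based and contiguous; residue ids keep the input file's
    (1-based PDB) numbering.  ``subunit`` holds the chain label (A-D for a
    tetramer's protein chains; solvent/ions/lipids carry their own labels).
    """

    atom_name: np.ndarray
    residue_name: np.ndarray
    residue_id: np.ndarray
    subunit: np.ndarray
    element: np.ndarray
    vdw_radius: np.ndarray
    mass: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.residue_id = np.asarray(self.residue_id, dtype=int)
        self.subunit = np.asarray(self.subunit, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.vdw_radius = np.asarray(self.vdw_radius, dtype=float)
        if self.mass is None:
            self.mass = np.array(
                [ATOMIC_MASSES.get(e, 12.011) for e in self.element], dtype=float
            )
        else:
            self.mass = np.asarray(self.mass, dtype=float)
        if np.any(self.vdw_radius <= 0):
            raise ValueError("every atom needs a positive vdW radius")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def atom_id(self) -> np.ndarray:
        return np.arange(self.n_atoms)

    def protein_mask(self) -> np.ndarray:
        return np.isin(self.residue_name, list(PROTEIN_RESNAMES))

    def protein_subunits(self) -> list:
        """Sorted subunit labels of the protein chains."""
        labels = sorted(set(self.subunit[self.protein_mask()]))
        return labels


@dataclass
class FrameSeries:
    """Time-ordered coordinates (nm) with per-frame orthorhombic box (nm)."""

    times: np.ndarray  # (n_frames,) ns, strictly increasing
    coordinates: np.ndarray  # (n_frames, n_atoms, 3) nm
    box: np.ndarray  # (n_frames, 3) nm

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coordinates = np.asarray(self.coordinates)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 3:
            raise ValueError("coordinates must be (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.coordinates):
            raise ValueError("times/coordinates length mismatch")
        if np.any(self.box[:, 2] <= 0):
            raise ValueError("box z-dimension must be positive in every frame")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            if len(self.times) > 1:
                raise ValueError("times must be non-negative and strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def duration_ns(self) -> float:
        """Total simulated time: frame spacing times frame count."""
        if self.n_frames < 2:
            return 0.0
        dt = self.times[1] - self.times[0]
        return float(dt * self.n_frames)

    def __getitem__(self, item) -> "FrameSeries":
        if isinstance(item, int):
            item = slice(item, item + 1)
        return FrameSeries(self.times[item], self.coordinates[item], self.box[item])


@dataclass(frozen=True)
class Selection:
    expression: str
    indices: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# loading


def _mda():
    import MDAnalysis as mda

    return mda


def _subunits_from_universe(u) -> np.ndarray:
    n = len(u.atoms)
    labels = None
    if hasattr(u.atoms, "chainIDs"):
        cid = np.asarray(u.atoms.chainIDs, dtype=object)
        if any(str(c).strip() for c in cid):
            labels = np.array([str(c).strip() or "X" for c in cid], dtype=object)
    if labels is None and hasattr(u.atoms, "segids"):
        sid = np.asarray(u.atoms.segids, dtype=object)
        if any(str(s).strip() and str(s).strip() != "SYSTEM" for s in sid):
            labels = np.array([str(s).strip() or "X" for s in sid], dtype=object)
    if labels is None:
        # infer chains from residue-numbering blocks: a drop in resid starts
        # a new chain (GRO files carry no chain labels)
        resids = u.atoms.resids
        block = np.zeros(n, dtype=int)
        cur = 0
        for i in range(1, n):
            if resids[i] < resids[i - 1]:
                cur += 1
            block[i] = cur
        alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        labels = np.array(
            [alphabet[b % 26] if cur > 0 else "A" for b in block], dtype=object
        )
    return labels


def load_topology(
    path,
    radius_table: dict | None = None,
    default_radius: float = DEFAULT_VDW_RADIUS_NM,
) -> Topology:
    """Parse a PDB or GRO file into a :class:`Topology`.

    Elements missing from the file are inferred from atom names; vdW radii
    are assigned from ``radius_table`` (element symbol -> nm, defaulting to
    the module table) with ``default_radius`` for unknown elements.  The
    backbone amide hydrogen is normalised to the name "H".
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path} is empty")
    table = dict(VDW_RADII_NM)
    if radius_table:
        table.update({k.upper(): v for k, v in radius_table.items()})
    mda = _mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - normalise reader errors
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise EmptyInputError(f"{path} contains no atoms")

    names = np.array(
        ["H" if str(n).strip().upper() == "HN" else str(n).strip()
         for n in u.atoms.names],
        dtype=object,
    )
    elements = None
    if hasattr(u.atoms, "elements"):
        el = [str(e).strip().upper() for e in u.atoms.elements]
        if any(el):
            elements = np.array(
                [e if e else infer_element(n) for e, n in zip(el, names)],
                dtype=object,
            )
    if elements is None:
        elements = np.array([infer_element(n) for n in names], dtype=object)
    radii = np.array([table.get(e, default_radius) for e in elements], dtype=float)
    return Topology(
        atom_name=names,
        residue_name=np.array([str(r).strip() for r in u.atoms.resnames], dtype=object),
        residue_id=np.asarray(u.atoms.resids, dtype=int),
        subunit=_subunits_from_universe(u),
        element=elements,
        vdw_radius=radii,
    )


def _cryst1_box(path) -> np.ndarray | None:
    """Fallback: read the CRYST1 record of a PDB file directly (some
    coordinate readers do not propagate it per frame)."""
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith("CRYST1"):
                    return np.array(
                        [float(line[6:15]), float(line[15:24]), float(line[24:33]),
                         float(line[33:40]), float(line[40:47]), float(line[47:54])]
                    )
    except (OSError, ValueError):
        return None
    return None


def _check_box(dim, path, fallback=None) -> np.ndarray:
    if dim is None or np.all(np.asarray(dim)[:3] == 0):
        dim = fallback
    if dim is None or np.all(np.asarray(dim)[:3] == 0):
        raise UnsupportedBoxError(f"{path}: no box information in frame")
    dim = np.asarray(dim, dtype=float)
    if np.any(np.abs(dim[3:6] - 90.0) > 1e-3):
        raise UnsupportedBoxError(
            f"{path}: triclinic box (angles {dim[3:6]}) not supported"
        )
    return dim[:3] / 10.0  # Å -> nm


def iter_frames(path, topology: Topology, stride: int = 1, discard: int = 0) -> FrameSeries:
    """Read a trajectory (XTC, DCD, or multi-model PDB) into a FrameSeries.

    Coordinates are returned in nm regardless of the on-disk convention
    (DCD/PDB store Å).  ``discard`` drops leading (equilibration) frames
    before striding.  A truncated file produces a warning and the frames
    read so far, not an error.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    path = Path(path)
    mda = _mda()
    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.load_new(str(path))
    except Exception as exc:  # noqa: BLE001
        msg = str(exc)
        if "atoms" in msg and ("match" in msg or "number" in msg):
            raise TopologyMismatchError(msg) from exc
        raise FormatError(f"could not read trajectory {path}: {exc}") from exc
    if u.trajectory.n_atoms != topology.n_atoms:
        raise TopologyMismatchError(
            f"trajectory has {u.trajectory.n_atoms} atoms, topology {topology.n_atoms}"
        )

    fallback = _cryst1_box(path) if path.suffix.lower() == ".pdb" else None
    times, coords, boxes = [], [], []
    i = 0
    try:
        for ts in u.trajectory:
            if i >= discard and (i - discard) % stride == 0:
                times.append(ts.time / 1000.0)  # ps -> ns
                coords.append(ts.positions.astype(np.float64) / 10.0)
                boxes.append(_check_box(ts.dimensions, path, fallback=fallback))
            i += 1
    except (EOFError, OSError, RuntimeError) as exc:
        warnings.warn(f"{path}: truncated trajectory, stopping at frame {i}: {exc}")
    if not coords:
        raise EmptyInputError(f"{path}: no frames read")
    times = np.asarray(times)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        # some writers leave time zeroed; fall back to the frame index in ns
        times = np.arange(len(coords), dtype=float)
    return FrameSeries(times, np.asarray(coords), np.asarray(boxes))


# ---------------------------------------------------------------------------
# selection mini-language
#
#   expr   := or ; or := and ("or" and)* ; and := unary ("and" unary)*
#   unary  := "not" unary | "(" expr ")" | clause
#   clause := "resname" V | "resid" N[:M] | "name" V | "subunit" V
#           | "backbone" | "sidechain" | "filter" | "inner_helix" | "outer_helix"

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _Parser:
    def __init__(self, expression: str, topology: Topology):
        self.expression = expression
        self.top = topology
        self.tokens = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)]
        self.pos = 0

    def _fail(self, msg):
        at = self.tokens[self.pos][1] if self.pos < len(self.tokens) else len(self.expression)
        raise SelectionSyntaxError(f"{msg} at position {at} in {self.expression!r}")

    def _peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            self._fail("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self._or()
        if self._peek() is not None:
            self._fail(f"unexpected token {self._peek()!r}")
        return mask

    def _or(self):
        mask = self._and()
        while self._peek() == "or":
            self._next()
            mask = mask | self._and()
        return mask

    def _and(self):
        mask = self._unary()
        while self._peek() == "and":
            self._next()
            mask = mask & self._unary()
        return mask

    def _unary(self):
        tok = self._peek()
        if tok == "not":
            self._next()
            return ~self._unary()
        if tok == "(":
            self._next()
            mask = self._or()
            if self._peek() != ")":
                self._fail("expected ')'")
            self._next()
            return mask
        return self._clause()

    def _clause(self):
        top = self.top
        tok = self._next()
        if tok == "resname":
            return top.residue_name == self._next()
        if tok == "name":
            val = self._next().upper()
            if val == "HN":  # CHARMM alias for the backbone amide hydrogen
                val = "H"
            return top.atom_name == val
        if tok == "subunit":
            return top.subunit == self._next()
        if tok == "resid":
            val = self._next()
            try:
                if ":" in val:
                    lo, hi = (int(v) for v in val.split(":"))
                else:
                    lo = hi = int(val)
            except ValueError:
                self.pos -= 1
                self._fail(f"bad resid value {val!r}")
            return (top.residue_id >= lo) & (top.residue_id <= hi)
        if tok == "backbone":
            return np.isin(top.atom_name, list(BACKBONE_NAMES)) & top.protein_mask()
        if tok == "sidechain":
            return (
                ~np.isin(top.atom_name, list(BACKBONE_NAMES))
                & (top.element != "H")
                & top.protein_mask()
            )
        if tok in NAMED_SELECTIONS:
            return _Parser(NAMED_SELECTIONS[tok], top).parse()
        self.pos -= 1
        self._fail(f"unknown clause {tok!r}")


def select(topology: Topology, expression: str) -> Selection:
    """Resolve a selection expression to a deterministic, sorted index set.

    Grammar: ``resname X``, ``resid N[:M]``, ``name X``, ``subunit X``, the
    named sets ``backbone``/``sidechain``/``filter``/``inner_helix``/
    ``outer_helix``, combined with ``and``/``or``/``not`` and parentheses.
    An empty result warns but is returned (some descriptors treat it as an
    error at their own boundary).
    """
    if not expression.strip():
        raise SelectionSyntaxError("empty selection expression")
    mask = _Parser(expression, topology).parse()
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        warnings.warn(f"selection {expression!r} matched no atoms")
    return Selection(expression=expression, indices=indices)


# ---------------------------------------------------------------------------
# periodic-boundary helpers


def minimum_image(displacement: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement for an orthorhombic box (broadcasting)."""
    d = np.asarray(displacement, dtype=float)
    b = np.asarray(box, dtype=float)
    return d - b * np.round(d / b)


def unwrap_z(z_series, box_z):
    """Remove periodic wrapping from a z coordinate series.

    Steps of magnitude >= box_z/2 between consecutive frames are treated as
    wraps and corrected by the appropriate multiple of box_z; the first
    value is kept.  Accepts a 1-D series or a (n_frames, n_ions) array with
    per-frame ``box_z``.
    """
    z = np.asarray(z_series, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite values in z series")
    b = np.asarray(box_z, dtype=float)
    if z.ndim == 2 and b.ndim == 1:
        b = b[:, None]
    if z.shape[0] < 2:
        return z.copy()
    dz = np.diff(z, axis=0)
    bb = b[1:] if b.ndim and b.shape[0] == z.shape[0] else b
    dz = dz - bb * np.round(dz / bb)
    out = np.empty_like(z)
    out[0] = z[0]
    out[1:] = z[0] + np.cumsum(dz, axis=0)
    return out


# ---------------------------------------------------------------------------
# writing


def _build_universe(topology: Topology):
    mda = _mda()
    n = topology.n_atoms
    # residue partition: change of (subunit, resid, resname) starts a residue
    keys = list(zip(topology.subunit, topology.residue_id, topology.residue_name))
    resindex = np.zeros(n, dtype=int)
    r = 0
    for i in range(1, n):
        if keys[i] != keys[i - 1]:
            r += 1
        resindex[i] = r
    n_res = r + 1
    first = np.flatnonzero(np.r_[True, resindex[1:] != resindex[:-1]])
    res_sub = topology.subunit[first]
    seg_labels = list(dict.fromkeys(res_sub))
    segindex = np.array([seg_labels.index(s) for s in res_sub], dtype=int)
    u = mda.Universe.empty(
        n,
        n_residues=n_res,
        n_segments=len(seg_labels),
        atom_resindex=resindex,
        residue_segindex=segindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", topology.atom_name.astype(str))
    u.add_TopologyAttr("resnames", topology.residue_name[first].astype(str))
    u.add_TopologyAttr("resids", topology.residue_id[first])
    u.add_TopologyAttr("segids", [str(s) for s in seg_labels])
    u.add_TopologyAttr("chainIDs", [str(s)[0] for s in topology.subunit])
    u.add_TopologyAttr("elements", topology.element.astype(str))
    u.add_TopologyAttr("masses", topology.mass)
    return u


def write_structure(path, topology: Topology, coordinates_nm, box_nm) -> None:
    """Write a single structure (PDB) from nm coordinates."""
    path = Path(path)
    u = _build_universe(topology)
    u.atoms.positions = np.asarray(coordinates_nm) * 10.0
    b = np.asarray(box_nm, dtype=float) * 10.0
    u.dimensions = [b[0], b[1], b[2], 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(path, topology: Topology, frames: FrameSeries) -> None:
    """Write a FrameSeries as XTC, DCD, or multi-model PDB (by suffix)."""
    path = Path(path)
    mda = _mda()
    u = _build_universe(topology)
    dt_ps = (
        float(frames.times[1] - frames.times[0]) * 1000.0
        if frames.n_frames > 1
        else 1.0
    )
    kwargs = {}
    if path.suffix.lower() in (".xtc", ".trr", ".dcd"):
        kwargs["dt"] = dt_ps
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_atoms, **kwargs) as w:
            for i in range(frames.n_frames):
                u.atoms.positions = frames.coordinates[i] * 10.0
                b = frames.box[i] * 10.0
                u.dimensions = [b[0], b[1], b[2], 90.0, 90.0, 90.0]
                u.trajectory.ts.time = float(frames.times[i]) * 1000.0
                u.trajectory.ts.frame = i
                w.write(u.atoms)
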