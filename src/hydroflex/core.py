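"""Core data model: topology/trajectory containers, file I/O, selections,
periodic-boundary helpers, least-squares superposition and domain assignment.

Conventions
-----------
* Coordinates are Cartesian and in Angstrom, times in nanoseconds.
* The laboratory z axis is the membrane normal.  Analyses shift z by a
  configurable origin (``ChannelGeometry.z_origin``), by default the z of the
  lipid centre of mass, so that the membrane mirror plane sits at z = 0.
* Atom indices are 0-based internally; user-facing reports are 1-based.
* Boxes are orthorhombic only.

File formats (PDB structure, PSF connectivity/charges, DCD/XTC/multi-model
PDB trajectories) are read and written through MDAnalysis.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Topology",
    "Frame",
    "Trajectory",
    "ChannelGeometry",
    "HydroflexError",
    "FormatError",
    "ConsistencyError",
    "SelectionError",
    "read_topology",
    "read_trajectory",
    "write_trajectory",
    "write_pdb",
    "center_of_mass",
    "superpose",
    "apply_superposition",
    "assign_domains",
    "minimum_image",
    "select_atoms",
]

# kB in kcal/(mol K); CHARMM electrostatic constant in kcal*A/(mol e^2)
KB_KCAL = 0.0019872041
COULOMB_KCAL = 332.0636

#: residue-name lookup used to auto-label non-protein components
WATER_RESNAMES = {"TIP3", "TIP3P", "TIP4", "TIP4P", "HOH", "WAT", "SOL", "SPC", "SPCE"}
MEMBRANE_RESNAMES = {"POPC", "CHL1", "CHOL", "POPE", "POPS", "DPPC", "DOPC"}
ION_RESNAMES = {"SOD", "CLA", "POT", "NA", "CL", "K", "MG", "CAL", "CES", "ZN"}
PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}
PROTEIN_DOMAINS = ("bundle", "hash", "gating", "other")

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.9994, "S": 32.06,
    "P": 30.973762, "NA": 22.98977, "CL": 35.453, "K": 39.0983,
    "MG": 24.305, "CA": 40.078, "FE": 55.845, "ZN": 65.38,
}

_TM_DOMAIN = {
    "TM1": "bundle", "TM2": "bundle", "TM6": "bundle", "TM7": "bundle",
    "TM3": "hash", "TM4": "hash", "TM8": "hash", "TM9": "hash",
    "TM5": "gating", "TM10": "gating",
}


class HydroflexError(Exception):
    """Base class for package errors."""


class FormatError(HydroflexError):
    """An input file could not be parsed."""


class ConsistencyError(HydroflexError):
    """Inputs that must agree (atom counts, frame sizes) do not."""


class SelectionError(HydroflexError):
    """An atom/residue selection is empty or malformed."""


@dataclass(frozen=True)
class Atom:
    """A single atom with the metadata the analyses need.

    Lennard-Jones parameters follow the CHARMM convention: ``lj_epsilon``
    is the well depth in kcal/mol and ``lj_rmin_half`` is r_min/2 in
    Angstrom; both are optional and only required by the energetics module.
    """

    index: int
    name: str
    residue_id: int
    residue_name: str
    segment: str
    mass: float
    charge: float = 0.0
    lj_epsilon: Optional[float] = None
    lj_rmin_half: Optional[float] = None

    def __post_init__(self):
        if not self.mass > 0:
            raise ConsistencyError(
                f"atom {self.index} ({self.name}) has non-positive mass {self.mass}"
            )


@dataclass(frozen=True)
class Residue:
    residue_id: int
    residue_name: str
    atom_indices: np.ndarray  # 0-based, contiguous in file order

    def __len__(self):
        return len(self.atom_indices)


class Topology:
    """Ordered atom list plus residue grouping and per-residue domain labels.

    Domain labels partition residues into ``bundle``/``hash``/``gating``/
    ``other`` (protein), ``ligand``, ``water``, ``membrane`` and ``ion``.
    Water, membrane and ion residues are recognised by residue name at
    construction; transmembrane-helix domains are assigned later by
    :func:`assign_domains`.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        domain_map: Optional[Mapping[int, str]] = None,
        tm_map: Optional[Mapping[int, str]] = None,
    ):
        self.atoms: list[Atom] = list(atoms)
        if len({a.index for a in self.atoms}) != len(self.atoms):
            raise ConsistencyError("atom indices are not unique")
        # group consecutive atoms into residues (segment+resid identity)
        residues: list[Residue] = []
        key = None
        start = 0
        for i, a in enumerate(self.atoms):
            k = (a.segment, a.residue_id)
            if k != key:
                if key is not None:
                    residues.append(
                        Residue(self.atoms[start].residue_id,
                                self.atoms[start].residue_name,
                                np.arange(start, i))
                    )
                key, start = k, i
        if self.atoms:
            residues.append(
                Residue(self.atoms[start].residue_id,
                        self.atoms[start].residue_name,
                        np.arange(start, len(self.atoms)))
            )
        self.residues: list[Residue] = residues
        rids = [r.residue_id for r in residues]
        if len(set(rids)) != len(rids):
            warnings.warn("residue ids are not globally unique; domain maps "
                          "keyed by residue_id may be ambiguous")
        if domain_map is None:
            domain_map = {r.residue_id: _auto_domain(r.residue_name) for r in residues}
        self.domain_map: dict[int, str] = dict(domain_map)
        self.tm_map: dict[int, str] = dict(tm_map or {})
        for r in residues:
            if r.residue_id not in self.domain_map:
                raise ConsistencyError(f"residue {r.residue_id} has no domain label")

        #: False when charges were defaulted (no PSF); energetics checks this
        self.charges_known = True
        self.masses = np.array([a.mass for a in self.atoms])
        self.charges = np.array([a.charge for a in self.atoms])
        self.atom_residue_index = np.empty(len(self.atoms), dtype=int)
        for ri, r in enumerate(residues):
            self.atom_residue_index[r.atom_indices] = ri
        self.atom_domains = np.array(
            [self.domain_map[self.atoms[i].residue_id] for i in range(len(self.atoms))],
            dtype=object,
        )

    # -- convenience selections -------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residues_with_domain(self, *labels: str) -> list[Residue]:
        return [r for r in self.residues if self.domain_map[r.residue_id] in labels]

    def atom_indices_with_domain(self, *labels: str) -> np.ndarray:
        idx = [r.atom_indices for r in self.residues_with_domain(*labels)]
        if not idx:
            return np.empty(0, dtype=int)
        return np.concatenate(idx)

    @property
    def water_residues(self) -> list[Residue]:
        return self.residues_with_domain("water")

    @property
    def protein_atom_indices(self) -> np.ndarray:
        return self.atom_indices_with_domain(*PROTEIN_DOMAINS)

    def with_domain_map(self, domain_map: Mapping[int, str],
                        tm_map: Optional[Mapping[int, str]] = None) -> "Topology":
        out = Topology(self.atoms, domain_map,
                       tm_map if tm_map is not None else self.tm_map)
        out.charges_known = self.charges_known
        return out


def _auto_domain(resname: str) -> str:
    rn = resname.upper()
    if rn in WATER_RESNAMES:
        return "water"
    if rn in MEMBRANE_RESNAMES:
        return "membrane"
    if rn in ION_RESNAMES:
        return "ion"
    if rn in PROTEIN_RESNAMES:
        return "other"
    return "ligand"


@dataclass
class Frame:
    """One trajectory frame: N x 3 coordinates (A), orthorhombic box, time (ns)."""

    coords: np.ndarray
    box: np.ndarray
    time: float

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ConsistencyError("coords must be N x 3")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ConsistencyError(f"box must be three positive lengths, got {self.box}")


class Trajectory:
    """Time-ordered frames over a fixed topology."""

    def __init__(self, topology: Topology, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ConsistencyError("trajectory must contain at least one frame")
        n = topology.n_atoms
        for i, f in enumerate(frames):
            if f.coords.shape[0] != n:
                raise ConsistencyError(
                    f"frame {i} has {f.coords.shape[0]} atoms, topology has {n}"
                )
        times = np.array([f.time for f in frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ConsistencyError("frame times must be strictly increasing")
        self.topology = topology
        self.frames = frames
        self._coords = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def coords_array(self) -> np.ndarray:
        """All coordinates stacked as (n_frames, n_atoms, 3); cached."""
        if self._coords is None:
            self._coords = np.stack([f.coords for f in self.frames])
        return self._coords

    def frame_window(self, window: Optional[tuple[float, float]]) -> np.ndarray:
        """Indices of frames with window[0] <= t <= window[1]."""
        t = self.times
        if window is None:
            return np.arange(self.n_frames)
        t0, t1 = window
        if t0 > t[-1] or t1 < t[0]:
            raise ConsistencyError(
                f"window ({t0}, {t1}) ns lies outside trajectory span "
                f"({t[0]}, {t[-1]}) ns"
            )
        return np.nonzero((t >= t0) & (t <= t1))[0]

    def reversed(self) -> "Trajectory":
        """Time-reversed copy (frame order flipped, original time stamps kept)."""
        t = self.times
        new = [Frame(f.coords.copy(), f.box.copy(), tt)
               for f, tt in zip(reversed(self.frames), t)]
        return Trajectory(self.topology, new)


@dataclass
class ChannelGeometry:
    """Two-slab permeation geometry and channel-cylinder definition.

    ``delta`` is the separation of the two detection planes placed
    symmetrically about the membrane mirror plane; ``slab_thickness`` is the
    width of the inner/outer compartment slabs just beyond those planes;
    ``cylinder_radius`` is the lateral radius around the channel axis used to
    reject waters travelling along the protein-membrane interface.
    ``z_origin=None`` means "determine from the lipid centre of mass"
    (falling back to the protein CoM when the system has no membrane).
    """

    delta: float = 25.0
    slab_thickness: float = 5.0
    z_origin: Optional[float] = None
    cylinder_radius: float = 10.0

    def __post_init__(self):
        if not (self.delta > 0 and self.slab_thickness > 0 and self.cylinder_radius > 0):
            raise ConsistencyError("delta, slab_thickness and cylinder_radius must be > 0")

    def resolve_z_origin(self, traj: "Trajectory") -> float:
        """The z shift: explicit value, else mean lipid CoM z, else protein CoM z."""
        if self.z_origin is not None:
            return self.z_origin
        top = traj.topology
        for labels in (("membrane",), PROTEIN_DOMAINS):
            idx = top.atom_indices_with_domain(*labels)
            if len(idx):
                m = top.masses[idx]
                zs = traj.coords_array()[:, idx, 2]
                return float(np.mean(zs @ m / m.sum()))
        return 0.0


# ---------------------------------------------------------------------------
# file I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _mda():
    import MDAnalysis as mda
    return mda


def read_topology(structure_file: str | os.PathLike,
                  connectivity_file: Optional[str | os.PathLike] = None) -> Topology:
    """Read a PDB structure (optionally with a PSF for masses and charges).

    Without a PSF, masses come from an element lookup on the atom name and
    charges default to 0 (with a warning): energetics then refuses to run.
    """
    mda = _mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if connectivity_file is not None:
                u = mda.Universe(str(connectivity_file), str(structure_file))
            else:
                u = mda.Universe(str(structure_file))
    except ValueError as exc:
        msg = str(exc)
        if "atoms" in msg and ("match" in msg or "number" in msg):
            raise ConsistencyError(
                f"atom count mismatch between {structure_file} and "
                f"{connectivity_file}: {msg}"
            ) from exc
        raise FormatError(f"cannot parse {structure_file}: {msg}") from exc
    except Exception as exc:  # pragma: no cover - parser-specific
        raise FormatError(f"cannot parse {structure_file}: {exc}") from exc

    n = len(u.atoms)
    if n == 0:
        raise FormatError(f"{structure_file} contains no atoms")

    if connectivity_file is not None:
        masses = np.asarray(u.atoms.masses, dtype=float)
        charges = np.asarray(u.atoms.charges, dtype=float)
    else:
        masses = np.array([_guess_mass(nm) for nm in u.atoms.names])
        charges = np.zeros(n)
        warnings.warn(
            "no connectivity (PSF) file: masses guessed from atom names, "
            "charges set to 0 (energetics unavailable)"
        )

    segids = u.atoms.segids if hasattr(u.atoms, "segids") else ["SYS"] * n
    atoms = []
    for i in range(n):
        if not masses[i] > 0:
            raise FormatError(
                f"atom {i + 1} ({u.atoms.names[i]}): could not determine a "
                f"positive mass"
            )
        atoms.append(Atom(
            index=i,
            name=str(u.atoms.names[i]),
            residue_id=int(u.atoms.resids[i]),
            residue_name=str(u.atoms.resnames[i]),
            segment=str(segids[i]),
            mass=float(masses[i]),
            charge=float(charges[i]),
        ))
    top = Topology(atoms)
    top.charges_known = connectivity_file is not None
    return top


def _guess_mass(name: str) -> float:
    nm = name.strip().upper()
    if nm[:2] in _ELEMENT_MASSES and not nm[:1].isdigit():
        # two-letter elements (NA, CL, ...) only when the name is exactly them
        if nm in _ELEMENT_MASSES:
            return _ELEMENT_MASSES[nm]
    for ch in nm:
        if ch.isalpha():
            return _ELEMENT_MASSES.get(ch, -1.0)
    return -1.0


_READERS = {".dcd": "DCD", ".xtc": "XTC", ".pdb": "PDB"}


def read_trajectory(topology: Topology, traj_file: str | os.PathLike,
                    dt_ns: Optional[float] = None, t0_ns: float = 0.0,
                    box: Optional[Sequence[float]] = None) -> Trajectory:
    """Read a DCD, XTC or multi-model PDB trajectory against a topology.

    Frame times are taken from the file (ps, converted to ns) unless
    ``dt_ns`` is given, in which case times are ``t0_ns + k*dt_ns``.
    Multi-model PDBs carry no time; they default to 1 ns per model.
    ``box`` overrides missing unit-cell records.
    """
    mda = _mda()
    path = str(traj_file)
    ext = os.path.splitext(path)[1].lower()
    if ext not in _READERS:
        raise FormatError(f"unsupported trajectory format: {ext}")
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.PDB import PDBReader
    from MDAnalysis.coordinates.XTC import XTCReader
    cls = {"DCD": DCDReader, "XTC": XTCReader, "PDB": PDBReader}[_READERS[ext]]
    if ext == ".pdb" and box is None:
        box = _pdb_cryst1_box(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reader = cls(path)
    except Exception as exc:
        raise FormatError(f"cannot open trajectory {path}: {exc}") from exc

    frames: list[Frame] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k, ts in enumerate(reader):
                coords = np.array(ts.positions, dtype=float)
                if coords.shape[0] != topology.n_atoms:
                    raise ConsistencyError(
                        f"frame {k} has {coords.shape[0]} atoms, topology has "
                        f"{topology.n_atoms}"
                    )
                if dt_ns is not None:
                    t = t0_ns + k * dt_ns
                elif ext == ".pdb":
                    t = t0_ns + float(k)
                else:
                    t = float(ts.time) / 1000.0  # ps -> ns
                dims = getattr(ts, "dimensions", None)
                if dims is not None and np.all(np.asarray(dims[:3]) > 0):
                    b = np.asarray(dims[:3], dtype=float)
                elif box is not None:
                    b = np.asarray(box, dtype=float)
                else:
                    raise FormatError(
                        f"frame {k} of {path} has no unit cell; pass box="
                    )
                frames.append(Frame(coords, b, t))
    except (EOFError, OSError, RuntimeError) as exc:
        raise FormatError(
            f"truncated trajectory {path}: last complete frame index "
            f"{len(frames) - 1}: {exc}"
        ) from exc
    finally:
        reader.close()
    if not frames:
        raise FormatError(f"trajectory {path} contains no frames")
    return Trajectory(topology, frames)


def _pdb_cryst1_box(path: str) -> Optional[np.ndarray]:
    """First CRYST1 record's orthorhombic cell lengths, if present."""
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith("CRYST1"):
                    return np.array([float(line[6:15]), float(line[15:24]),
                                     float(line[24:33])])
    except (OSError, ValueError):
        return None
    return None


def _empty_universe(topology: Topology):
    mda = _mda()
    n = topology.n_atoms
    resindex = topology.atom_residue_index
    nres = len(topology.residues)
    segids, seen = [], {}
    seg_per_res = []
    for r in topology.residues:
        seg = topology.atoms[r.atom_indices[0]].segment
        seg_per_res.append(seg)
        if seg not in seen:
            seen[seg] = len(seen)
            segids.append(seg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n, n_residues=nres, n_segments=len(segids),
            atom_resindex=resindex,
            residue_segindex=[seen[s] for s in seg_per_res],
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in topology.atoms])
        u.add_TopologyAttr("resids", [r.residue_id for r in topology.residues])
        u.add_TopologyAttr("resnames", [r.residue_name for r in topology.residues])
        u.add_TopologyAttr("segids", segids)
        u.add_TopologyAttr("masses", topology.masses)
    return u


def write_pdb(topology: Topology, frames: Sequence[Frame] | Frame,
              path: str | os.PathLike) -> None:
    """Write one or more frames as a (multi-model) PDB file."""
    mda = _mda()
    if isinstance(frames, Frame):
        frames = [frames]
    u = _empty_universe(topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), topology.n_atoms, multiframe=len(frames) > 1) as w:
            for f in frames:
                u.atoms.positions = f.coords
                u.dimensions = [*f.box, 90.0, 90.0, 90.0]
                w.write(u.atoms)


def write_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory as DCD (CHARMM dialect) or multi-model PDB."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".pdb":
        write_pdb(traj.topology, traj.frames, path)
        return
    if ext != ".dcd":
        raise FormatError(f"unsupported output trajectory format: {ext}")
    from MDAnalysis.coordinates.DCD import DCDWriter
    u = _empty_universe(traj.topology)
    times = traj.times
    dt_ps = (times[1] - times[0]) * 1000.0 if len(times) > 1 else 1000.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with DCDWriter(str(path), traj.topology.n_atoms, dt=float(dt_ps)) as w:
            for f in traj.frames:
                u.atoms.positions = f.coords
                u.dimensions = [*f.box, 90.0, 90.0, 90.0]
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def center_of_mass(topology: Topology, frame: Frame,
                   selection: Iterable[int]) -> np.ndarray:
    """Mass-weighted mean position of the selected atoms (A)."""
    idx = np.asarray(list(selection) if not isinstance(selection, np.ndarray)
                     else selection, dtype=int)
    if idx.size == 0:
        raise SelectionError("center_of_mass: empty selection")
    m = topology.masses[idx]
    return (frame.coords[idx] * m[:, None]).sum(axis=0) / m.sum()


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement(s) for an orthorhombic box."""
    return d - box * np.round(d / box)


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights: Optional[np.ndarray] = None):
    """Weighted least-squares (Kabsch) superposition of ``mobile`` onto
    ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``;
    the rotation is proper (det +1) and the rmsd is weight-weighted.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ConsistencyError(
            f"superpose: shape mismatch {mobile.shape} vs {reference.shape}"
        )
    n = mobile.shape[0]
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ConsistencyError("superpose: invalid weights")
        w = w / w.sum()
    cm = w @ mobile
    cr = w @ reference
    P = mobile - cm
    Q = reference - cr
    H = (w[:, None] * P).T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    diff = P @ R.T - Q
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    return R, t, rmsd


def apply_superposition(coords: np.ndarray, rotation: np.ndarray,
                        translation: np.ndarray) -> np.ndarray:
    return coords @ rotation.T + translation


# ---------------------------------------------------------------------------
# domain assignment and selections
# ---------------------------------------------------------------------------

def assign_domains(topology: Topology,
                   tm_ranges: Mapping[str, tuple[int, int]]) -> Topology:
    """Label protein residues by transmembrane helix membership.

    TM1/2/6/7 form the bundle (core) domain, TM3/4/8/9 the hash (scaffold)
    domain and TM5/10 the gating domain of the LeuT fold; protein residues
    outside all ranges are labelled ``other``.  Ranges are inclusive
    ``(first_residue_id, last_residue_id)`` and must not overlap.
    """
    ranges = {}
    for tm, (lo, hi) in tm_ranges.items():
        if tm not in _TM_DOMAIN:
            raise SelectionError(f"unknown TM helix name {tm!r} (expected TM1..TM10)")
        if hi < lo:
            raise SelectionError(f"{tm}: empty range ({lo}, {hi})")
        ranges[tm] = (int(lo), int(hi))
    items = sorted(ranges.items(), key=lambda kv: kv[1])
    for (tm_a, (lo_a, hi_a)), (tm_b, (lo_b, hi_b)) in zip(items, items[1:]):
        if lo_b <= hi_a:
            raise SelectionError(f"TM ranges {tm_a} and {tm_b} overlap")

    known = {r.residue_id for r in topology.residues
             if topology.domain_map[r.residue_id] in PROTEIN_DOMAINS}
    for tm, (lo, hi) in ranges.items():
        if not any(lo <= rid <= hi for rid in known):
            raise SelectionError(f"{tm} range ({lo}, {hi}) matches no protein residue")

    new_map = dict(topology.domain_map)
    tm_map = dict(topology.tm_map)
    for rid in known:
        label = "other"
        for tm, (lo, hi) in ranges.items():
            if lo <= rid <= hi:
                label = _TM_DOMAIN[tm]
                tm_map[rid] = tm
                break
        new_map[rid] = label
    return topology.with_domain_map(new_map, tm_map)


def select_atoms(topology: Topology, expr: str) -> np.ndarray:
    """Select atom indices with the mini-language ``segment:residues:name``.

    Each of the three fields may be ``*``; ``residues`` is a single id or an
    inclusive ``lo-hi`` range.  Example: ``PROT:100-150:CA``.
    """
    parts = expr.split(":")
    if len(parts) != 3:
        raise SelectionError(
            f"selection {expr!r} must have the form segment:residues:atom_name"
        )
    seg, res, name = (p.strip() for p in parts)
    if res == "*":
        lo, hi = None, None
    elif "-" in res[1:]:
        a, b = res.rsplit("-", 1) if not res.startswith("-") else (res, res)
        try:
            lo, hi = int(a), int(b)
        except ValueError as exc:
            raise SelectionError(f"bad residue range {res!r}") from exc
    else:
        try:
            lo = hi = int(res)
        except ValueError as exc:
            raise SelectionError(f"bad residue id {res!r}") from exc
    out = [
        a.index for a in topology.atoms
        if (seg == "*" or a.segment == seg)
        and (lo is None or lo <= a.residue_id <= hi)
        and (name == "*" or a.name == name)
    ]
    if not out:
        raise SelectionError(f"selection {expr!r} matches no atoms")
    return np.array(out, dtype=int)
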