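"""Synthetic-system generators with known ground truth.

Every generator returns the exact quantity the corresponding analysis is
supposed to recover: scripted water transits come with their event list,
Gaussian bead trajectories with their analytic eigenpairs, toy charge
layouts with closed-form energies.  Fixtures are kinematic constructions
only — no forces, no thermostat.

Scripted waters carry a small positional jitter (sd 0.2 A, clamped to
0.6 A) on top of their parametric path so that distance computations are
exercised off-grid; the clamping margins guarantee the jitter never changes
a frame's slab classification, so the scripted ground truth stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Atom, ChannelGeometry, ConsistencyError, Frame, Topology, Trajectory
from .flexibility import BeadModel, BeadSeries, rigid_body_basis
from .permeation import (
    BETWEEN,
    INNER_SLAB,
    OUTER_SLAB,
    PermeationEvent,
    PermeationReport,
    classify_z_array,
    window_counts,
)

__all__ = [
    "GaussianBeadSpec",
    "make_channel_system",
    "make_gaussian_beads",
    "make_toy_charges",
    "vibrational_covariance",
    "write_psf_lite",
    "DEFAULT_TM_RANGES",
]

# masses, amu
_M_O, _M_H, _M_C = 15.9994, 1.008, 12.011
# rigid 3-site water offsets with zero mass-weighted mean, A
_WATER_OFFSETS = np.array([
    [0.0, -2 * _M_H * 0.6 / (_M_O + 2 * _M_H), 0.0],
    [0.8, 0.6 - 2 * _M_H * 0.6 / (_M_O + 2 * _M_H), 0.0],
    [-0.8, 0.6 - 2 * _M_H * 0.6 / (_M_O + 2 * _M_H), 0.0],
])
_JITTER_SD, _JITTER_CLAMP = 0.2, 0.6

#: TM ranges matching the 10-ring pseudo-protein of make_channel_system
DEFAULT_TM_RANGES = {
    "TM1": (1, 2), "TM6": (6, 7),      # bundle: lower + upper rings
    "TM3": (3, 4), "TM8": (8, 9),      # hash
    "TM5": (5, 5), "TM10": (10, 10),   # gating
}


def _jitter(rng: np.random.Generator, shape) -> np.ndarray:
    return np.clip(rng.normal(0.0, _JITTER_SD, shape), -_JITTER_CLAMP, _JITTER_CLAMP)


def _ring_protein(n_rings: int = 10, atoms_per_ring: int = 12,
                  radius: float = 8.0, z_lo: float = -16.0,
                  z_hi: float = 16.0) -> list[Atom]:
    """A static cylindrical pseudo-protein: stacked rings of carbons spanning
    the membrane region, one residue per ring (resids 1..n_rings)."""
    atoms = []
    zs = np.linspace(z_lo, z_hi, n_rings)
    ang = np.linspace(0, 2 * np.pi, atoms_per_ring, endpoint=False)
    i = 0
    for ri, z in enumerate(zs, start=1):
        for k in range(atoms_per_ring):
            atoms.append(Atom(index=i, name=f"C{k + 1}", residue_id=ri,
                              residue_name="GLY", segment="PROT",
                              mass=_M_C, charge=0.0))
            i += 1
    return atoms


#: lateral offset of the bundle (+x) and hash (-x) rings so the two domains
#: have distinct CoMs, as in a real two-domain transporter fold
_DOMAIN_OFFSET = 1.5
_BUNDLE_RINGS, _HASH_RINGS = {1, 2, 6, 7}, {3, 4, 8, 9}


def _protein_coords(atoms: Sequence[Atom], n_rings: int = 10,
                    atoms_per_ring: int = 12, radius: float = 8.0,
                    z_lo: float = -16.0, z_hi: float = 16.0) -> np.ndarray:
    zs = np.linspace(z_lo, z_hi, n_rings)
    ang = np.linspace(0, 2 * np.pi, atoms_per_ring, endpoint=False)
    out = np.empty((n_rings * atoms_per_ring, 3))
    i = 0
    for ri, z in enumerate(zs, start=1):
        dx = (_DOMAIN_OFFSET if ri in _BUNDLE_RINGS
              else -_DOMAIN_OFFSET if ri in _HASH_RINGS else 0.0)
        for a in ang:
            out[i] = (dx + radius * np.cos(a), radius * np.sin(a), z)
            i += 1
    return out


def make_channel_system(n_complete_out: int = 3, n_complete_in: int = 2,
                        n_partial: int = 5, n_interface: int = 2,
                        n_wrap: int = 2, n_bulk: int = 50,
                        geom: Optional[ChannelGeometry] = None,
                        box: tuple[float, float, float] = (44.0, 44.0, 50.0),
                        n_frames: int = 200, dt_ns: float = 1.0,
                        seed: int = 0
                        ) -> tuple[Topology, Trajectory, PermeationReport]:
    """Scripted channel system with an exactly known permeation event list.

    A static ring-stack pseudo-protein spans the membrane region; waters are
    scripted as complete outward/inward transits, partial excursions,
    interface decoys (crossing outside the channel cylinder), PBC-wrap
    decoys (a single > Lz/2 jump between the slabs) and laterally excluded
    bulk waters.  Returns ``(topology, trajectory, expected_report)`` where
    the report holds the exact expected events and 100-ns window counts.
    """
    geom = geom or ChannelGeometry(z_origin=0.0)
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    half, slab = geom.delta / 2.0, geom.slab_thickness
    z_in, z_out = -half - slab / 2.0, half + slab / 2.0  # slab centres
    if geom.delta + 2 * slab >= box[2]:
        raise ConsistencyError("box z-span must exceed Delta + 2*delta")
    if (geom.delta + slab) <= box[2] / 2.0 and n_wrap:
        raise ConsistencyError(
            "wrap decoys need the slab-to-slab jump (Delta + delta) to "
            "exceed Lz/2; shrink the box or drop n_wrap"
        )
    if n_frames < 60:
        raise ConsistencyError("need at least 60 frames for the scripts")

    atoms = _ring_protein()
    prot_xyz = _protein_coords(atoms)
    n_prot = len(atoms)

    # --- script CoM paths -------------------------------------------------
    kinds = (["complete_out"] * n_complete_out + ["complete_in"] * n_complete_in
             + ["partial"] * n_partial + ["interface"] * n_interface
             + ["wrap"] * n_wrap + ["bulk"] * n_bulk)
    paths = np.empty((len(kinds), n_frames, 3))
    r_lat_max = min(box[0], box[1]) / 2.0 - 2.0
    for wi, kind in enumerate(kinds):
        t_start = int(rng.integers(0, n_frames - 55))
        dur = int(rng.integers(20, 50))
        t_end = min(t_start + dur, n_frames - 1)
        z = np.empty(n_frames)
        if kind in ("complete_out", "complete_in", "interface"):
            a, b = (z_in, z_out) if kind != "complete_in" else (z_out, z_in)
            if kind == "interface":
                a, b = (z_in, z_out) if rng.random() < 0.5 else (z_out, z_in)
            z[:t_start] = a
            z[t_start:t_end + 1] = np.linspace(a, b, t_end + 1 - t_start)
            z[t_end + 1:] = b
            if kind == "interface":
                r0 = geom.cylinder_radius + 4.0
            else:
                r0 = rng.uniform(0.0, geom.cylinder_radius - 4.5)
        elif kind == "partial":
            a = z_in if rng.random() < 0.5 else z_out
            turn = np.sign(a) * rng.uniform(0.0, half - 2.0)
            m = (t_start + t_end) // 2
            z[:t_start] = a
            z[t_start:m + 1] = np.linspace(a, turn, m + 1 - t_start)
            z[m:t_end + 1] = np.linspace(turn, a, t_end + 1 - m)
            z[t_end + 1:] = a
            r0 = rng.uniform(0.0, geom.cylinder_radius - 4.5)
        elif kind == "wrap":
            a, b = (z_in, z_out) if rng.random() < 0.5 else (z_out, z_in)
            z[:t_start + 1] = a
            z[t_start + 1:] = b  # single > Lz/2 teleport
            r0 = rng.uniform(0.0, geom.cylinder_radius - 4.5)
        else:  # bulk: random z walk, always laterally outside the cylinder
            z0 = rng.uniform(-box[2] / 2 + 1, box[2] / 2 - 1)
            steps = rng.normal(0.0, 0.5, n_frames)
            z = z0 + np.cumsum(steps)
            z = np.clip(z, -box[2] / 2 + 1, box[2] / 2 - 1)
            r0 = rng.uniform(geom.cylinder_radius + 2.0, max(r_lat_max,
                             geom.cylinder_radius + 3.0))
        theta = rng.uniform(0, 2 * np.pi)
        xy = np.array([r0 * np.cos(theta), r0 * np.sin(theta)])
        paths[wi, :, 0] = xy[0] + _jitter(rng, n_frames)
        paths[wi, :, 1] = xy[1] + _jitter(rng, n_frames)
        paths[wi, :, 2] = z + (_jitter(rng, n_frames)
                               if kind != "bulk" else 0.0)

    # --- ground truth from the scripted CoM paths -------------------------
    events = []
    times = dt_ns * np.arange(n_frames)
    for wi, kind in enumerate(kinds):
        if kind not in ("complete_out", "complete_in"):
            continue
        reg = classify_z_array(paths[wi, :, 2], geom)
        origin = INNER_SLAB if kind == "complete_out" else OUTER_SLAB
        dest = OUTER_SLAB if kind == "complete_out" else INNER_SLAB
        t_primed = times[np.nonzero(reg == origin)[0][0]]
        t_completed = times[np.nonzero(reg == dest)[0][0]]
        events.append(PermeationEvent(
            water_residue_id=100 + wi + 1,
            direction="outward" if kind == "complete_out" else "inward",
            t_primed=float(t_primed), t_completed=float(t_completed),
        ))
    events.sort(key=lambda e: (e.t_completed, e.water_residue_id))

    # --- assemble atoms and frames ---------------------------------------
    names = ("OH2", "H1", "H2")
    for wi in range(len(kinds)):
        rid = 100 + wi + 1
        for k, nm in enumerate(names):
            atoms.append(Atom(index=n_prot + 3 * wi + k, name=nm,
                              residue_id=rid, residue_name="TIP3",
                              segment="WAT",
                              mass=_M_O if k == 0 else _M_H,
                              charge=-0.834 if k == 0 else 0.417))
    top = Topology(atoms)

    frames = []
    for f in range(n_frames):
        coords = np.empty((len(atoms), 3))
        coords[:n_prot] = prot_xyz
        wat = paths[:, f, None, :] + _WATER_OFFSETS[None, :, :]
        coords[n_prot:] = wat.reshape(-1, 3)
        frames.append(Frame(coords, box, float(times[f])))
    traj = Trajectory(top, frames)

    win = window_counts(events, float(times[0]), float(times[-1]), 100.0)
    expected = PermeationReport(events=events, window_width=100.0, windows=win)
    return top, traj, expected


# ---------------------------------------------------------------------------
# Gaussian bead fixtures
# ---------------------------------------------------------------------------

@dataclass
class GaussianBeadSpec:
    """Specification of an i.i.d. Gaussian bead trajectory.

    ``covariance`` is the 3M x 3M positive-semidefinite target (A^2);
    frames are drawn independently about ``mean_structure`` (a mild default
    non-collinear arrangement when omitted).  ``rigid_drift_deg_per_ns``
    superimposes a rigid rotation about the z axis through the CoM.
    """

    covariance: np.ndarray
    n_frames: int = 10_000
    dt_ns: float = 0.1
    seed: int = 0
    mean_structure: Optional[np.ndarray] = None
    masses: Optional[np.ndarray] = None
    rigid_drift_deg_per_ns: float = 0.0


@dataclass
class GaussianBeadResult:
    series: BeadSeries
    eigenvalues: np.ndarray   # analytic, descending
    eigenvectors: np.ndarray  # columns, matching order
    mean_structure: np.ndarray
    masses: np.ndarray


def _default_mean(M: int) -> np.ndarray:
    """A fixed, non-collinear bead arrangement (two offset squares)."""
    pts = []
    for i in range(M):
        a = 2 * np.pi * i / max(M, 1)
        pts.append([6.0 * np.cos(a), 6.0 * np.sin(a), 4.0 * (-1) ** i])
    return np.array(pts)


def make_gaussian_beads(spec: GaussianBeadSpec) -> GaussianBeadResult:
    """Sample a bead trajectory from a prescribed Gaussian and return it
    together with the analytic eigenpairs of the target covariance."""
    C = np.asarray(spec.covariance, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or C.shape[0] % 3:
        raise ConsistencyError("covariance must be 3M x 3M")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ConsistencyError("covariance must be symmetric")
    dim = C.shape[0]
    M = dim // 3
    w, V = np.linalg.eigh(0.5 * (C + C.T))
    if w.min() < -1e-8 * max(abs(w.max()), 1.0):
        raise ConsistencyError("covariance is not positive semidefinite")
    w = np.clip(w, 0.0, None)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]

    mean = (np.asarray(spec.mean_structure, dtype=float)
            if spec.mean_structure is not None else _default_mean(M))
    if mean.shape != (M, 3):
        raise ConsistencyError(f"mean structure must be ({M}, 3)")
    masses = (np.asarray(spec.masses, dtype=float)
              if spec.masses is not None else np.full(M, 100.0))

    rng = np.random.default_rng(spec.seed)
    A = V * np.sqrt(w)  # C = A A^T
    Z = rng.standard_normal((spec.n_frames, dim))
    X = mean.ravel()[None, :] + Z @ A.T
    pos = X.reshape(spec.n_frames, M, 3)

    times = spec.dt_ns * np.arange(spec.n_frames)
    if spec.rigid_drift_deg_per_ns:
        com = masses @ mean / masses.sum()
        ang = np.deg2rad(spec.rigid_drift_deg_per_ns) * times
        ca, sa = np.cos(ang), np.sin(ang)
        rel = pos - com
        x, y = rel[:, :, 0].copy(), rel[:, :, 1].copy()
        rel[:, :, 0] = ca[:, None] * x - sa[:, None] * y
        rel[:, :, 1] = sa[:, None] * x + ca[:, None] * y
        pos = rel + com

    series = BeadSeries(positions=pos, times=times, model=None)
    return GaussianBeadResult(series=series, eigenvalues=w, eigenvectors=V,
                              mean_structure=mean, masses=masses)


def vibrational_covariance(mean_structure: np.ndarray, masses: np.ndarray,
                           eigenvalues: Sequence[float]) -> np.ndarray:
    """A covariance whose eigenvectors are orthogonal to the rigid-body
    subspace of ``mean_structure``, with the given leading eigenvalues.

    PCA of samples from this covariance yields vibrational weights of ~1,
    so the overall flexibility is analytically sum(eigenvalues)/kBT.
    """
    mean = np.asarray(mean_structure, dtype=float)
    dim = mean.size
    Q = rigid_body_basis(mean, np.asarray(masses, dtype=float))  # (r, dim)
    # orthonormal basis of the complement, deterministic via SVD
    P = np.eye(dim) - Q.T @ Q
    U, S, _ = np.linalg.svd(P)
    comp = U[:, S > 0.5]  # singular values are 1 (complement) or ~0 (rigid)
    lams = np.asarray(eigenvalues, dtype=float)
    if len(lams) > comp.shape[1]:
        raise ConsistencyError(
            f"at most {comp.shape[1]} vibrational eigenvalues fit in "
            f"dimension {dim}"
        )
    B = comp[:, :len(lams)]
    return (B * lams) @ B.T


# ---------------------------------------------------------------------------
# toy charge/LJ systems
# ---------------------------------------------------------------------------

def make_toy_charges(layout: Sequence[tuple], box: float = 1000.0
                     ) -> tuple[Topology, Frame]:
    """Minimal point-particle system for energetics unit tests.

    ``layout`` is a list of ``(position, charge, epsilon, rmin_half)``;
    each particle becomes its own one-atom residue.
    """
    if not layout:
        raise ConsistencyError("empty layout")
    pos = np.array([np.asarray(p, dtype=float) for p, *_ in layout])
    if len(pos) > 1:
        from scipy.spatial.distance import pdist
        if pdist(pos).min() < 1e-8:
            raise ConsistencyError("layout contains coincident particles")
    atoms = [
        Atom(index=i, name=f"Q{i + 1}", residue_id=i + 1, residue_name="LJP",
             segment="TOY", mass=_M_C, charge=float(q),
             lj_epsilon=float(eps), lj_rmin_half=float(rmh))
        for i, (_, q, eps, rmh) in enumerate(layout)
    ]
    top = Topology(atoms)
    frame = Frame(pos, np.full(3, box), 0.0)
    return top, frame


# ---------------------------------------------------------------------------
# PSF-lite writer (atoms + charges/masses only)
# ---------------------------------------------------------------------------

def write_psf_lite(topology: Topology, path) -> None:
    """Write a minimal whitespace-formatted PSF carrying charges and masses
    (no bonds); readable back through :func:`hydroflex.core.read_topology`."""
    lines = ["PSF", "", f"{1:8d} !NTITLE", " REMARKS synthetic hydroflex system",
             "", f"{topology.n_atoms:8d} !NATOM"]
    for a in topology.atoms:
        lines.append(
            f"{a.index + 1:8d} {a.segment:<4s} {a.residue_id:<4d} "
            f"{a.residue_name:<4s} {a.name:<4s} {a.name:<4s} "
            f"{a.charge:14.6f}{a.mass:14.6f}{0:8d}"
        )
    lines += ["", f"{0:8d} !NBOND", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
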