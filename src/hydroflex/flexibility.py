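"""PCA-based protein-flexibility framework on coarse-grained bead models.

The protein is reduced to beads (four domain half-beads, or one bead per
binding-site residue), the covariance of the concatenated bead coordinates
is diagonalised, and each mode i receives

* an eigenvalue lambda_i (A^2), the mean-square fluctuation along the mode,
* a stiffness kappa_i = kBT / lambda_i (kcal/(mol A^2)),
* a flexibility sigma_i = lambda_i / kBT,
* a vibrational weight w_vi in [0, 1], the complement of the mode's squared
  projection onto the 6-dimensional rigid-body (translation + infinitesimal
  rotation) subspace of the mean structure.

The overall flexibility is sigma = (1/kBT) sum_i lambda_i w_vi and the
flexibility of a prescribed displacement pattern P (a unit 3M-vector) is
sigma_P = (1/kBT) sum_i lambda_i w_vi (P.e_i)^2, a quadratic form that is
independent of eigenvector sign and basis choice within degenerate
subspaces.  Three "rocking-bundle" patterns are provided: alternating
opening of the two channel mouths, up-down sliding of the bundle against
the hash domain, and simultaneous opening of the whole channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    KB_KCAL,
    ConsistencyError,
    SelectionError,
    Topology,
    Trajectory,
    superpose,
    apply_superposition,
)
from .permeation import group_com_series

__all__ = [
    "Bead",
    "BeadModel",
    "BeadSeries",
    "PCAResult",
    "ProjectionVector",
    "build_beads",
    "bead_trajectory",
    "pca",
    "vibrational_weights",
    "rigid_body_basis",
    "overall_flexibility",
    "rocking_bundle_projections",
    "projected_flexibility",
    "segment_analysis",
]

SIMULATION_TEMPERATURE = 303.15  # K
_EIG_FLOOR = 1e-10  # A^2; below this a mode is treated as frozen

FOUR_BEAD_LABELS = ("bundle_upper", "bundle_lower", "hash_upper", "hash_lower")


@dataclass(frozen=True)
class Bead:
    label: str
    atom_indices: np.ndarray
    mass: float


@dataclass
class BeadModel:
    """Coarse-grained representation: ordered beads over a topology."""

    beads: list[Bead]
    representation: str  # "four_bead_domain" | "binding_site_residues"

    def __post_init__(self):
        seen = set()
        for b in self.beads:
            s = set(map(int, b.atom_indices))
            if s & seen:
                raise ConsistencyError("bead atom sets overlap")
            seen |= s

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads])


@dataclass
class BeadSeries:
    """Per-frame bead positions (n_frames, M, 3) with time stamps."""

    positions: np.ndarray
    times: np.ndarray
    model: Optional[BeadModel] = None

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def masses(self) -> np.ndarray:
        if self.model is not None:
            return self.model.masses
        return np.ones(self.positions.shape[1])


@dataclass
class PCAResult:
    """Eigendecomposition of bead-coordinate fluctuations plus derived
    per-mode stiffness/flexibility and (optionally) vibrational weights."""

    eigenvalues: np.ndarray       # (3M,) descending, A^2
    eigenvectors: np.ndarray      # (3M, 3M), column i = e_i
    mean_structure: np.ndarray    # (M, 3)
    kBT: float                    # kcal/mol
    n_frames: int
    masses: np.ndarray
    vibrational_weights: Optional[np.ndarray] = None

    @property
    def stiffness(self) -> np.ndarray:
        """kappa_i = kBT / lambda_i; infinite for frozen modes."""
        with np.errstate(divide="ignore"):
            k = np.where(self.eigenvalues < _EIG_FLOOR, np.inf,
                         self.kBT / np.where(self.eigenvalues < _EIG_FLOOR, 1.0,
                                             self.eigenvalues))
        return k

    @property
    def flexibility(self) -> np.ndarray:
        """sigma_i = lambda_i / kBT; zero for frozen modes."""
        return np.where(self.eigenvalues < _EIG_FLOOR, 0.0,
                        self.eigenvalues / self.kBT)


@dataclass(frozen=True)
class ProjectionVector:
    """A unit-norm bead-displacement pattern of dimension 3M."""

    P: np.ndarray
    label: str

    def __post_init__(self):
        n = np.linalg.norm(self.P)
        if not np.isclose(n, 1.0, atol=1e-8):
            raise ConsistencyError(f"projection vector {self.label!r} is not unit norm")


# ---------------------------------------------------------------------------
# bead construction
# ---------------------------------------------------------------------------

def build_beads(topology: Topology, traj: Trajectory, representation: str,
                binding_site_center: Optional[np.ndarray] = None,
                ligand_selection: Optional[np.ndarray] = None,
                n_residues: int = 18,
                window: Optional[tuple[float, float]] = None) -> BeadModel:
    """Build the coarse-grained bead model.

    ``four_bead_domain``: the bundle and hash domains are each split at the
    domain's time-mean CoM z into upper and lower halves, giving four beads
    (bundle_upper, bundle_lower, hash_upper, hash_lower) whose positions are
    mass-weighted CoMs of their atom sets.

    ``binding_site_residues``: the ``n_residues`` protein residues whose
    time-mean CoM lies closest to the binding-site centre (given explicitly
    or as the mean CoM of ``ligand_selection``), one CoM bead per residue.
    """
    fidx = traj.frame_window(window)
    coords = traj.coords_array()[fidx]
    masses = topology.masses

    if representation == "four_bead_domain":
        beads = []
        mean_z_atoms = coords[:, :, 2].mean(axis=0)
        for dom in ("bundle", "hash"):
            idx = topology.atom_indices_with_domain(dom)
            if idx.size == 0:
                raise SelectionError(
                    f"domain {dom!r} has no atoms; run assign_domains first"
                )
            m = masses[idx]
            plane = float(mean_z_atoms[idx] @ m / m.sum())
            upper = idx[mean_z_atoms[idx] >= plane]
            lower = idx[mean_z_atoms[idx] < plane]
            for half, half_idx in (("upper", upper), ("lower", lower)):
                if half_idx.size == 0:
                    raise SelectionError(
                        f"{dom} {half} half is empty: cannot form bead"
                    )
            _warn_onesided_helices(topology, dom, upper, lower)
            beads.append(Bead(f"{dom}_upper", upper, float(masses[upper].sum())))
            beads.append(Bead(f"{dom}_lower", lower, float(masses[lower].sum())))
        # fixed order: bundle_upper, bundle_lower, hash_upper, hash_lower
        return BeadModel(beads=beads, representation="four_bead_domain")

    if representation == "binding_site_residues":
        if binding_site_center is None:
            if ligand_selection is None:
                lig = topology.atom_indices_with_domain("ligand")
                if lig.size == 0:
                    raise SelectionError(
                        "binding_site_residues needs a centre or a ligand"
                    )
            else:
                lig = np.asarray(ligand_selection, dtype=int)
            m = masses[lig]
            binding_site_center = np.einsum(
                "fla,l->fa", coords[:, lig, :], m / m.sum()).mean(axis=0)
        center = np.asarray(binding_site_center, dtype=float)
        residues = topology.residues_with_domain("bundle", "hash", "gating", "other")
        if len(residues) < n_residues:
            raise SelectionError(
                f"only {len(residues)} protein residues, need {n_residues}"
            )
        sub = Trajectory(topology, [traj.frames[i] for i in fidx])
        coms = group_com_series(sub, [r.atom_indices for r in residues]).mean(axis=0)
        dist = np.linalg.norm(coms - center, axis=1)
        order = sorted(range(len(residues)),
                       key=lambda i: (dist[i], residues[i].residue_id))
        chosen = sorted(order[:n_residues],
                        key=lambda i: residues[i].residue_id)
        beads = [
            Bead(f"res_{residues[i].residue_id}", residues[i].atom_indices,
                 float(masses[residues[i].atom_indices].sum()))
            for i in chosen
        ]
        return BeadModel(beads=beads, representation="binding_site_residues")

    raise ConsistencyError(f"unknown representation {representation!r}")


def _warn_onesided_helices(topology: Topology, dom: str,
                           upper: np.ndarray, lower: np.ndarray) -> None:
    if not topology.tm_map:
        return
    res_of = topology.atom_residue_index
    for tm in sorted({tm for rid, tm in topology.tm_map.items()
                      if topology.domain_map.get(rid) == dom}):
        rids = {rid for rid, t in topology.tm_map.items() if t == tm}
        in_upper = any(topology.atoms[int(i)].residue_id in rids for i in upper)
        in_lower = any(topology.atoms[int(i)].residue_id in rids for i in lower)
        if not (in_upper and in_lower):
            warnings.warn(
                f"helix {tm} of domain {dom} lies entirely in one half of "
                f"the split plane"
            )


def bead_trajectory(traj: Trajectory, model: BeadModel,
                    fit: bool = True,
                    window: Optional[tuple[float, float]] = None) -> BeadSeries:
    """Per-frame bead CoM positions, optionally Kabsch-fitted.

    With ``fit=True`` each frame's bead set is mass-weighted superposed onto
    the mean bead structure (two passes: mean, fit, re-mean, re-fit), which
    removes global translation and rotation before PCA.
    """
    fidx = traj.frame_window(window)
    sub = Trajectory(traj.topology, [traj.frames[i] for i in fidx])
    pos = group_com_series(sub, [b.atom_indices for b in model.beads])
    times = sub.times
    if fit:
        pos = fit_series(pos, model.masses)
    return BeadSeries(positions=pos, times=times, model=model)


def fit_series(positions: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Two-pass mass-weighted Kabsch fit of every frame onto the mean."""
    if positions.shape[1] < 3:
        raise ConsistencyError("need at least 3 beads to define a rotation")
    pos = positions.copy()
    for _ in range(2):
        mean = pos.mean(axis=0)
        for f in range(pos.shape[0]):
            R, t, _ = superpose(pos[f], mean, masses)
            pos[f] = apply_superposition(pos[f], R, t)
    return pos


# ---------------------------------------------------------------------------
# PCA and derived quantities
# ---------------------------------------------------------------------------

def pca(bead_series: Union[BeadSeries, np.ndarray],
        temperature: float = SIMULATION_TEMPERATURE,
        masses: Optional[np.ndarray] = None) -> PCAResult:
    """Diagonalise the covariance of concatenated bead coordinates.

    Eigenvalues are sorted descending; eigenvector signs are fixed by
    making each vector's largest-magnitude component positive.  kBT enters
    only the derived stiffness/flexibility scales.
    """
    if isinstance(bead_series, BeadSeries):
        pos = bead_series.positions
        if masses is None:
            masses = bead_series.masses
    else:
        pos = np.asarray(bead_series, dtype=float)
    if pos.ndim != 3 or pos.shape[2] != 3:
        raise ConsistencyError("bead series must have shape (n_frames, M, 3)")
    F, M, _ = pos.shape
    if F < 2:
        raise ConsistencyError("PCA needs at least 2 frames")
    if F <= 3 * M:
        warnings.warn(
            f"only {F} frames for a {3 * M}-dimensional covariance: "
            f"eigenvalues will be poorly conditioned"
        )
    if masses is None:
        masses = np.ones(M)

    X = pos.reshape(F, 3 * M)
    mean = X.mean(axis=0)
    dX = X - mean
    C = dX.T @ dX / F
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    w = np.clip(w[::-1], 0.0, None)
    V = V[:, ::-1]
    # sign convention: largest-|component| positive
    for i in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, i])))
        if V[j, i] < 0:
            V[:, i] = -V[:, i]
    return PCAResult(
        eigenvalues=w, eigenvectors=V, mean_structure=mean.reshape(M, 3),
        kBT=KB_KCAL * temperature, n_frames=F, masses=np.asarray(masses, float),
    )


def rigid_body_basis(mean_structure: np.ndarray,
                     masses: np.ndarray) -> np.ndarray:
    """Orthonormal basis (rows) of the rigid-body displacement subspace.

    Three uniform translations plus three infinitesimal rotations about the
    principal inertia axes through the centre of mass; near-degenerate
    directions (collinear structures) are dropped with a warning, leaving 5
    vectors.
    """
    mean = np.asarray(mean_structure, dtype=float)
    M = mean.shape[0]
    m = np.asarray(masses, dtype=float)
    com = m @ mean / m.sum()
    rel = mean - com

    vecs = []
    for k in range(3):
        t = np.zeros((M, 3))
        t[:, k] = 1.0
        vecs.append(t.ravel())
    # principal axes of the inertia tensor
    I = np.einsum("i,ij,ik->jk", m, rel, rel)
    I = np.trace(I) * np.eye(3) - I
    _, axes = np.linalg.eigh(I)
    for k in range(3):
        r = np.cross(axes[:, k], rel)
        vecs.append(r.ravel())
    A = np.stack(vecs)
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    keep = S > 1e-8 * max(S[0], 1.0)
    if keep.sum() < 6:
        warnings.warn(
            f"rigid-body subspace has dimension {int(keep.sum())} < 6 "
            f"(collinear mean structure?)"
        )
    return Vt[keep]


def vibrational_weights(result: PCAResult,
                        masses: Optional[np.ndarray] = None) -> PCAResult:
    """Attach w_vi = 1 - |proj of e_i on rigid-body subspace|^2 to a PCA."""
    m = result.masses if masses is None else np.asarray(masses, float)
    Q = rigid_body_basis(result.mean_structure, m)  # (r, 3M)
    proj2 = np.square(Q @ result.eigenvectors).sum(axis=0)  # (3M,)
    w = np.clip(1.0 - proj2, 0.0, 1.0)
    return replace(result, vibrational_weights=w)


def overall_flexibility(result: PCAResult) -> float:
    """sigma = (1/kBT) * sum_i lambda_i * w_vi (A^2 mol / kcal)."""
    if result.vibrational_weights is None:
        raise ConsistencyError(
            "vibrational weights not computed; call vibrational_weights first"
        )
    return float(np.sum(result.eigenvalues * result.vibrational_weights)
                 / result.kBT)


def rocking_bundle_projections(model: BeadModel,
                               mean_structure: np.ndarray
                               ) -> list[ProjectionVector]:
    """The three rocking-bundle displacement patterns on the four-bead model.

    With x the unit in-plane vector from the hash CoM to the bundle CoM and
    z the channel axis: (A) alternating opening — the two mouths open and
    close in antiphase; (B) up-down sliding of the bundle against the hash
    domain along z; (C) simultaneous opening of the whole channel.
    """
    if model.representation != "four_bead_domain":
        raise ConsistencyError(
            "rocking-bundle projections require the four_bead_domain model"
        )
    labels = [b.label for b in model.beads]
    if labels != list(FOUR_BEAD_LABELS):
        raise ConsistencyError(f"unexpected bead order {labels}")
    mean = np.asarray(mean_structure, dtype=float).reshape(4, 3)
    m = model.masses
    bundle_com = m[:2] @ mean[:2] / m[:2].sum()
    hash_com = m[2:] @ mean[2:] / m[2:].sum()
    xhat = bundle_com - hash_com
    xhat[2] = 0.0
    n = np.linalg.norm(xhat)
    if n < 1e-8:
        raise ConsistencyError("bundle and hash CoMs coincide laterally")
    xhat /= n
    zhat = np.array([0.0, 0.0, 1.0])

    def make(label, disp):
        P = np.asarray(disp, dtype=float).ravel()
        return ProjectionVector(P=P / np.linalg.norm(P), label=label)

    # bead order: bundle_upper, bundle_lower, hash_upper, hash_lower
    return [
        make("A_alternating_open", [xhat, -xhat, -xhat, xhat]),
        make("B_updown_slide", [zhat, zhat, -zhat, -zhat]),
        make("C_simultaneous_open", [xhat, xhat, -xhat, -xhat]),
    ]


def projected_flexibility(result: PCAResult, P: ProjectionVector) -> float:
    """sigma_P = (1/kBT) * sum_i lambda_i w_vi (P . e_i)^2."""
    if result.vibrational_weights is None:
        raise ConsistencyError(
            "vibrational weights not computed; call vibrational_weights first"
        )
    p = np.asarray(P.P, dtype=float)
    if p.shape != (result.eigenvectors.shape[0],):
        raise ConsistencyError(
            f"projection vector dimension {p.shape} does not match modes "
            f"({result.eigenvectors.shape[0]})"
        )
    overlap2 = np.square(p @ result.eigenvectors)
    return float(np.sum(result.eigenvalues * result.vibrational_weights
                        * overlap2) / result.kBT)


def segment_analysis(source: Union[Trajectory, BeadSeries],
                     model: BeadModel, segment_ns: float = 200.0,
                     temperature: float = SIMULATION_TEMPERATURE,
                     fit: bool = True) -> pd.DataFrame:
    """Independent PCA flexibility per non-overlapping time segment.

    Each segment gets its own bead fitting, PCA, vibrational weights and —
    for the four-bead model — rocking-bundle projected flexibilities.
    Returns one row per segment: t_start, t_end, n_frames, sigma and (four
    beads only) sigma_A, sigma_B, sigma_C, sigma_ABC.
    """
    if segment_ns <= 0:
        raise ConsistencyError("segment_ns must be > 0")
    if isinstance(source, Trajectory):
        series = bead_trajectory(source, model, fit=False)
    else:
        series = source
    times = series.times
    span = times[-1] - times[0]
    # nearest-integer segment count: a trailing remainder shorter than half a
    # window joins the last segment, a longer one becomes its own segment
    n_seg = max(1, int(round(span / segment_ns)))
    if span < segment_ns:
        warnings.warn(
            f"trajectory span {span} ns is shorter than one {segment_ns} ns "
            f"segment: analysing a single shortened segment"
        )
    k = np.minimum(((times - times[0]) // segment_ns).astype(int), n_seg - 1)

    rows = []
    four = model.representation == "four_bead_domain"
    for s in range(n_seg):
        sel = np.nonzero(k == s)[0]
        pos = series.positions[sel]
        if fit:
            pos = fit_series(pos, model.masses)
        res = pca(pos, temperature=temperature, masses=model.masses)
        res = vibrational_weights(res)
        row = {
            "segment": s,
            "t_start": float(times[sel[0]]),
            "t_end": float(times[sel[-1]]),
            "n_frames": len(sel),
            "sigma": overall_flexibility(res),
        }
        if four:
            projs = rocking_bundle_projections(model, res.mean_structure)
            sig = {pv.label[0]: projected_flexibility(res, pv) for pv in projs}
            row["sigma_A"] = sig["A"]
            row["sigma_B"] = sig["B"]
            row["sigma_C"] = sig["C"]
            row["sigma_ABC"] = sig["A"] + sig["B"] + sig["C"]
        rows.append(row)
    return pd.DataFrame(rows)
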