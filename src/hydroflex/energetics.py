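"""Pairwise nonbonded interaction energies and radius-of-gyration series.

The group-group interaction energy is the full double sum over atom pairs of
the Coulomb term (CHARMM electrostatic constant 332.0636 kcal*A/(mol*e^2),
vacuum dielectric) and the CHARMM-form Lennard-Jones term

    E_LJ(r) = eps_ij * ((rmin_ij/r)^12 - 2*(rmin_ij/r)^6),

with combining rules eps_ij = sqrt(eps_i*eps_j) and
rmin_ij = rmin_i/2 + rmin_j/2, under the minimum-image convention.  A
truncated mode (``mode="cutoff"``) reproducing a plain 12-A simulation
cutoff is provided for comparison; the full sum is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    COULOMB_KCAL,
    ChannelGeometry,
    ConsistencyError,
    SelectionError,
    Topology,
    Trajectory,
    minimum_image,
)
from .permeation import channel_axis_series, group_com_series

__all__ = [
    "InteractionEnergy",
    "GyrationSeries",
    "interaction_energy",
    "radius_of_gyration",
    "layer_selections",
    "with_lj_params",
    "load_lj_table",
]


@dataclass
class InteractionEnergy:
    """Per-frame and time-averaged group-group nonbonded energy (kcal/mol)."""

    elec: float
    vdw: float
    total: float
    group_a: str
    group_b: str
    per_frame: pd.DataFrame  # time, elec, vdw, total
    mean: float
    sd: float


@dataclass
class GyrationSeries:
    """Per-frame radius of gyration (A) of a selection."""

    selection_label: str
    times: np.ndarray
    rg: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.rg))

    @property
    def sd(self) -> float:
        return float(np.std(self.rg))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "rg": self.rg})


def _check_params(top: Topology, idx: np.ndarray, what: str) -> None:
    if getattr(top, "charges_known", True) is False:
        raise ConsistencyError(
            "topology has no charges (structure was read without a PSF); "
            "energetics refuses to run"
        )
    for i in idx:
        a = top.atoms[int(i)]
        if a.lj_epsilon is None or a.lj_rmin_half is None:
            raise ConsistencyError(
                f"atom {int(i) + 1} ({a.segment}:{a.residue_id}:{a.name}) in "
                f"{what} has no Lennard-Jones parameters"
            )


def interaction_energy(traj: Trajectory, group_a: np.ndarray,
                       group_b: np.ndarray, mode: str = "full",
                       cutoff: float = 12.0,
                       labels: tuple[str, str] = ("A", "B")
                       ) -> InteractionEnergy:
    """Electrostatic + Lennard-Jones energy between two disjoint atom groups.

    ``mode="full"`` sums over all pairs (no cutoff); ``mode="cutoff"``
    truncates pairs beyond ``cutoff`` A.
    """
    if mode not in ("full", "cutoff"):
        raise ConsistencyError(f"unknown mode {mode!r}")
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise SelectionError("interaction_energy: empty group")
    if np.intersect1d(a, b).size:
        raise ConsistencyError("interaction_energy: groups overlap")
    top = traj.topology
    _check_params(top, a, "group A")
    _check_params(top, b, "group B")

    qa, qb = top.charges[a], top.charges[b]
    ea = np.array([top.atoms[i].lj_epsilon for i in a])
    eb = np.array([top.atoms[i].lj_epsilon for i in b])
    ra = np.array([top.atoms[i].lj_rmin_half for i in a])
    rb = np.array([top.atoms[i].lj_rmin_half for i in b])
    eps = np.sqrt(np.outer(ea, eb))
    rmin = ra[:, None] + rb[None, :]
    qq = np.outer(qa, qb)

    coords = traj.coords_array()
    elec = np.empty(traj.n_frames)
    vdw = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        d = coords[f, a][:, None, :] - coords[f, b][None, :, :]
        d = minimum_image(d, traj.frames[f].box)
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        if np.any(r < 1e-6):
            raise ConsistencyError(
                f"frame {f}: coincident atoms between groups (r < 1e-6 A)"
            )
        mask = np.ones_like(r, dtype=bool) if mode == "full" else (r <= cutoff)
        s6 = (rmin / r) ** 6
        elec[f] = COULOMB_KCAL * np.sum((qq / r)[mask])
        vdw[f] = np.sum((eps * (s6 * s6 - 2.0 * s6))[mask])

    total = elec + vdw
    per_frame = pd.DataFrame({
        "time_ns": traj.times, "elec": elec, "vdw": vdw, "total": total,
    })
    return InteractionEnergy(
        elec=float(elec.mean()), vdw=float(vdw.mean()), total=float(total.mean()),
        group_a=labels[0], group_b=labels[1], per_frame=per_frame,
        mean=float(total.mean()), sd=float(total.std()),
    )


def radius_of_gyration(traj: Trajectory, selection: np.ndarray,
                       label: str = "selection") -> GyrationSeries:
    """Mass-weighted radius of gyration per frame:
    Rg = sqrt(sum_i m_i |r_i - r_CoM|^2 / sum_i m_i)."""
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise SelectionError("radius_of_gyration: empty selection")
    m = traj.topology.masses[idx]
    w = m / m.sum()
    sub = traj.coords_array()[:, idx, :]
    com = np.einsum("fla,l->fa", sub, w)
    d = sub - com[:, None, :]
    rg = np.sqrt(np.einsum("fla,fla,l->f", d, d, w))
    return GyrationSeries(selection_label=label, times=traj.times, rg=rg)


def layer_selections(topology: Topology, traj: Trajectory,
                     z_layers: Sequence[tuple[float, float]],
                     lateral_cutoff: float,
                     geom: Optional[ChannelGeometry] = None,
                     window: Optional[tuple[float, float]] = None
                     ) -> list[np.ndarray]:
    """Residue ids of channel-lining protein residues per z layer.

    A residue is selected for a layer when its time-mean CoM lies inside
    the layer's (z_lo, z_hi) interval (z shifted to the membrane mirror
    plane) and within ``lateral_cutoff`` of the mean channel axis.
    """
    layers = [(float(lo), float(hi)) for lo, hi in z_layers]
    for lo, hi in layers:
        if hi <= lo:
            raise ConsistencyError(f"empty layer ({lo}, {hi})")
    s = sorted(layers)
    for (lo_a, hi_a), (lo_b, hi_b) in zip(s, s[1:]):
        if lo_b < hi_a:
            raise ConsistencyError(f"layers ({lo_a},{hi_a}) and ({lo_b},{hi_b}) overlap")

    geom = geom or ChannelGeometry()
    z0 = geom.resolve_z_origin(traj)
    fidx = traj.frame_window(window)
    residues = topology.residues_with_domain("bundle", "hash", "gating", "other")
    if not residues:
        raise SelectionError("no protein residues in topology")
    coms = group_com_series(traj, [r.atom_indices for r in residues])[fidx]
    mean_com = coms.mean(axis=0)  # (R, 3)
    axis = channel_axis_series(traj)[fidx].mean(axis=0)
    lat = np.hypot(mean_com[:, 0] - axis[0], mean_com[:, 1] - axis[1])
    z = mean_com[:, 2] - z0

    out = []
    for lo, hi in layers:
        sel = [r.residue_id for r, zz, ll in zip(residues, z, lat)
               if lo < zz < hi and ll <= lateral_cutoff]
        if not sel:
            warnings.warn(f"layer ({lo}, {hi}) selects no residues")
        out.append(np.array(sel, dtype=int))
    return out


def load_lj_table(path) -> dict[str, tuple[float, float]]:
    """Read a flat TSV of per-atom-name Lennard-Jones parameters.

    Columns: atom_name, epsilon (kcal/mol), rmin_half (A).  Lines starting
    with ``#`` are comments.
    """
    table = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ConsistencyError(f"{path}:{ln}: expected 3 columns")
            table[parts[0]] = (float(parts[1]), float(parts[2]))
    return table


def with_lj_params(topology: Topology,
                   table: Mapping[str, tuple[float, float]]) -> Topology:
    """Attach Lennard-Jones parameters keyed by atom name; unknown names
    keep ``None`` parameters (and will fail loudly in the energy sum)."""
    atoms = []
    for a in topology.atoms:
        if a.name in table:
            eps, rmh = table[a.name]
            atoms.append(replace(a, lj_epsilon=eps, lj_rmin_half=rmh))
        else:
            atoms.append(a)
    out = Topology(atoms, topology.domain_map, topology.tm_map)
    out.charges_known = getattr(topology, "charges_known", True)
    return out
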