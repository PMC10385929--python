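"""Water and component density profiles along the membrane normal, 2D
cross-sectional density maps, the channel-opening (orifice-area) estimator
and the residue-wettability statistic.

Densities are reported as mean molecule (or atom) counts per bin per frame;
no smoothing is applied.  The channel opening converts the minimum of a
time-averaged water count profile into an area by multiplying with the
cross-section of a single water molecule (~7.1 A^2); for that conversion to
be meaningful the profile should be computed with a slab thickness of one
water diameter (2.8 A), which is the default bin width used by
:func:`opening_profile_bin_width`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    ChannelGeometry,
    ConsistencyError,
    HydroflexError,
    SelectionError,
    Topology,
    Trajectory,
    select_atoms,
    PROTEIN_DOMAINS,
)
from .permeation import (
    PermeationEvent,
    channel_axis_series,
    group_com_series,
    water_com_series,
)

__all__ = [
    "DensityProfile",
    "DensityMap2D",
    "WettabilityTable",
    "ChannelOpening",
    "WATER_CROSS_SECTION",
    "WATER_DIAMETER",
    "water_density_profile",
    "channel_opening",
    "density_map_2d",
    "component_profile_1d",
    "residue_wettability",
    "wettability_domain_summary",
]

#: cross-sectional area of a single water molecule, A^2
WATER_CROSS_SECTION = 7.1
#: one water diameter, A — the slab thickness for orifice-area profiles
WATER_DIAMETER = 2.8


@dataclass
class DensityProfile:
    """Mean molecule/atom count per z-bin per frame."""

    bin_edges: np.ndarray
    counts: np.ndarray
    bin_width: float
    averaging_window: tuple[float, float]
    selection_label: str

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_center": self.bin_centers, "count": self.counts})


@dataclass
class DensityMap2D:
    """Mean atom counts per xy cell per frame inside a z slab."""

    z_range: tuple[float, float]
    xy_bin: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    grid: np.ndarray  # shape (nx, ny)
    component: str


class ChannelOpening(NamedTuple):
    """Orifice-area estimate: location and area of the density minimum."""

    z_min: float
    area: float


@dataclass
class WettabilityTable:
    """Per-residue fraction of atoms contacted by permeating water.

    ``table`` has columns residue_id, residue_name, domain, w_r_out
    (extracellular-direction transits) and w_r_in (intracellular).
    """

    table: pd.DataFrame
    cutoff: float


def _bin_edges(z_range: tuple[float, float], bin_width: float) -> np.ndarray:
    lo, hi = float(z_range[0]), float(z_range[1])
    if bin_width <= 0:
        raise ConsistencyError("bin_width must be > 0")
    if hi <= lo:
        raise ConsistencyError(f"empty z range ({lo}, {hi})")
    n = int(np.ceil((hi - lo) / bin_width - 1e-9))
    return lo + bin_width * np.arange(n + 1)


def water_density_profile(traj: Trajectory, geom: ChannelGeometry,
                          z_range: tuple[float, float], bin_width: float,
                          window: Optional[tuple[float, float]] = None,
                          protein_selection: Optional[np.ndarray] = None
                          ) -> DensityProfile:
    """Time-averaged water-CoM counts per z-bin inside the channel cylinder.

    Only waters whose lateral distance from the per-frame channel axis is
    <= ``geom.cylinder_radius`` contribute.  z is shifted so the membrane
    mirror plane is at 0.
    """
    fidx = traj.frame_window(window)
    z0 = geom.resolve_z_origin(traj)
    _, coms = water_com_series(traj)
    axis = channel_axis_series(traj, protein_selection)
    edges = _bin_edges(z_range, bin_width)

    lat = np.hypot(coms[fidx, :, 0] - axis[fidx, None, 0],
                   coms[fidx, :, 1] - axis[fidx, None, 1])
    z = coms[fidx, :, 2] - z0
    inside = lat <= geom.cylinder_radius
    hist = np.histogram(z[inside], bins=edges)[0].astype(float)
    t = traj.times[fidx]
    return DensityProfile(
        bin_edges=edges,
        counts=hist / len(fidx),
        bin_width=bin_width,
        averaging_window=(float(t[0]), float(t[-1])),
        selection_label="water",
    )


def channel_opening(profile: DensityProfile,
                    search_range: tuple[float, float]) -> ChannelOpening:
    """Orifice area: min of the profile over ``search_range`` x 7.1 A^2.

    Returns the z of the minimising bin centre together with the area.
    """
    centers = profile.bin_centers
    mask = (centers >= search_range[0]) & (centers <= search_range[1])
    if not mask.any():
        raise ConsistencyError(
            f"search range {search_range} contains no profile bins"
        )
    sub = profile.counts[mask]
    k = int(np.argmin(sub))
    return ChannelOpening(z_min=float(centers[mask][k]),
                          area=float(sub[k] * WATER_CROSS_SECTION))


def _resolve_component(topology: Topology, component) -> tuple[np.ndarray, str]:
    if isinstance(component, (np.ndarray, list, tuple)):
        return np.asarray(component, dtype=int), "custom"
    label = str(component)
    if label == "protein":
        idx = topology.atom_indices_with_domain(*PROTEIN_DOMAINS)
    elif label in ("water", "membrane", "ion", "ligand", "bundle", "hash",
                   "gating", "other"):
        idx = topology.atom_indices_with_domain(label)
    elif ":" in label:
        idx = select_atoms(topology, label)
    else:
        raise SelectionError(f"unknown component label {label!r}")
    if idx.size == 0:
        raise SelectionError(f"component {label!r} matches no atoms")
    return idx, label


def density_map_2d(traj: Trajectory, z_range: tuple[float, float],
                   xy_bin: float, component,
                   window: Optional[tuple[float, float]] = None,
                   z_offset: float = 0.0,
                   xy_range: Optional[tuple[tuple[float, float],
                                            tuple[float, float]]] = None
                   ) -> DensityMap2D:
    """Mean atom counts per xy cell per frame for atoms in the slab
    ``z_range[0] <= z - z_offset < z_range[1]``."""
    if z_range[1] <= z_range[0]:
        raise ConsistencyError(f"empty slab {z_range}")
    if xy_bin <= 0:
        raise ConsistencyError("xy_bin must be > 0")
    idx, label = _resolve_component(traj.topology, component)
    fidx = traj.frame_window(window)
    coords = traj.coords_array()[np.ix_(fidx, idx)]
    z = coords[:, :, 2] - z_offset
    in_slab = (z >= z_range[0]) & (z < z_range[1])
    xy = coords[:, :, :2][in_slab]

    if xy_range is None:
        if xy.size:
            lo = np.floor(xy.min(axis=0) / xy_bin) * xy_bin
            hi = xy.max(axis=0)
        else:
            lo, hi = np.zeros(2), np.full(2, xy_bin)
        nx = max(1, int(np.ceil((hi[0] - lo[0]) / xy_bin - 1e-9)) + 1)
        ny = max(1, int(np.ceil((hi[1] - lo[1]) / xy_bin - 1e-9)) + 1)
        x_edges = lo[0] + xy_bin * np.arange(nx + 1)
        y_edges = lo[1] + xy_bin * np.arange(ny + 1)
    else:
        x_edges = _bin_edges(xy_range[0], xy_bin)
        y_edges = _bin_edges(xy_range[1], xy_bin)

    grid = np.histogram2d(xy[:, 0], xy[:, 1], bins=(x_edges, y_edges))[0]
    return DensityMap2D(
        z_range=(float(z_range[0]), float(z_range[1])),
        xy_bin=xy_bin, x_edges=x_edges, y_edges=y_edges,
        grid=grid / len(fidx), component=label,
    )


def component_profile_1d(traj: Trajectory, components: Sequence,
                         bin_width: float,
                         window: Optional[tuple[float, float]] = None,
                         z_range: Optional[tuple[float, float]] = None,
                         z_offset: float = 0.0) -> list[DensityProfile]:
    """Per-component atom-count z profiles (no lateral restriction)."""
    fidx = traj.frame_window(window)
    coords = traj.coords_array()[fidx]
    if z_range is None:
        zall = coords[:, :, 2] - z_offset
        z_range = (float(np.floor(zall.min())), float(np.ceil(zall.max()) + 1e-9))
    edges = _bin_edges(z_range, bin_width)
    t = traj.times[fidx]
    out = []
    for comp in components:
        idx, label = _resolve_component(traj.topology, comp)
        z = coords[:, idx, 2] - z_offset
        hist = np.histogram(z, bins=edges)[0].astype(float)
        out.append(DensityProfile(
            bin_edges=edges, counts=hist / len(fidx), bin_width=bin_width,
            averaging_window=(float(t[0]), float(t[-1])),
            selection_label=label,
        ))
    return out


def residue_wettability(traj: Trajectory, events: Sequence[PermeationEvent],
                        cutoff: float = 4.0) -> WettabilityTable:
    """Fraction of each protein residue's atoms found within ``cutoff`` of a
    permeating water's CoM during a transit, separately per direction.

    An atom is "wetted" in a direction if at any analysed frame inside any
    same-direction transit interval [t_primed, t_completed] it lies within
    ``cutoff`` A of that permeating water's centre of mass.
    """
    top = traj.topology
    prot = top.protein_atom_indices
    if prot.size == 0:
        raise SelectionError("no protein residues in topology")
    if not events:
        warnings.warn("no permeation events: wettability table is all zeros")
    wids, coms = (water_com_series(traj) if events else (np.empty(0, int), None))
    wid_to_col = {int(w): i for i, w in enumerate(wids)}
    times = traj.times
    coords = traj.coords_array()
    c2 = cutoff * cutoff

    wet = {"outward": np.zeros(top.n_atoms, dtype=bool),
           "inward": np.zeros(top.n_atoms, dtype=bool)}
    for e in events:
        try:
            col = wid_to_col[int(e.water_residue_id)]
        except KeyError:
            raise ConsistencyError(
                f"event references unknown water residue {e.water_residue_id}"
            ) from None
        fsel = np.nonzero((times >= e.t_primed) & (times <= e.t_completed))[0]
        mask = wet[e.direction]
        for f in fsel:
            d = coords[f, prot, :] - coms[f, col]
            hit = np.einsum("ij,ij->i", d, d) <= c2
            mask[prot[hit]] = True

    rows = []
    for r in top.residues_with_domain(*PROTEIN_DOMAINS):
        n = len(r.atom_indices)
        rows.append({
            "residue_id": r.residue_id,
            "residue_name": r.residue_name,
            "domain": top.domain_map[r.residue_id],
            "w_r_out": wet["outward"][r.atom_indices].sum() / n,
            "w_r_in": wet["inward"][r.atom_indices].sum() / n,
        })
    return WettabilityTable(table=pd.DataFrame(rows), cutoff=cutoff)


def wettability_domain_summary(table: WettabilityTable,
                               threshold: float = 0.9) -> pd.DataFrame:
    """Count residues with wettability strictly beyond ``threshold``, per
    domain (bundle/hash/gating/rest) and direction."""
    df = table.table.copy()
    df["domain"] = df["domain"].replace({"other": "rest"})
    out = []
    for dom in ("bundle", "hash", "gating", "rest"):
        sub = df[df["domain"] == dom]
        out.append({
            "domain": dom,
            "outward": int((sub["w_r_out"] > threshold).sum()),
            "inward": int((sub["w_r_in"] > threshold).sum()),
        })
    return pd.DataFrame(out).set_index("domain")
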