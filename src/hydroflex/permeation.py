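"""Water permeation event counting through a protein channel.

A water molecule completes a permeation event when its centre of mass is
first detected in one of two thin slabs (thickness delta_s) lying just
outside two planes separated by Delta about the membrane mirror plane, and
is later detected in the opposite slab.  Crossings produced by periodic
wrapping are rejected by resetting an episode whenever the water's z
coordinate jumps by more than half the box height between consecutive
frames, and waters sneaking along the protein-membrane interface are
rejected by requiring that, while between the two planes, the water stays
within a lateral cylinder around the channel axis.

The per-water finite-state machine:

* ``IDLE -> PRIMED(origin)`` on first observation inside a slab;
* ``PRIMED -> event`` on observation in the opposite slab (the water then
  immediately re-primes with that slab as the new origin);
* ``PRIMED -> IDLE`` (episode abandoned) on a periodic-wrap jump, on a
  between-planes frame outside the cylinder, or on any frame beyond either
  slab.  Abandoning on *either* beyond region (not just the origin side)
  makes counting exactly symmetric under time reversal: within each
  barrier-free stretch of frames the event count equals the number of
  alternations in the sequence of slab visits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    ChannelGeometry,
    ConsistencyError,
    HydroflexError,
    SelectionError,
    Trajectory,
)

__all__ = [
    "Region",
    "PermeationEvent",
    "PermeationReport",
    "classify_z",
    "classify_z_array",
    "count_permeations",
    "window_counts",
    "water_com_series",
    "channel_axis_series",
]

# region codes
BETWEEN, INNER_SLAB, OUTER_SLAB, BEYOND_INNER, BEYOND_OUTER = 0, 1, 2, 3, 4
_REGION_NAMES = {
    BETWEEN: "between_planes",
    INNER_SLAB: "inner_slab",
    OUTER_SLAB: "outer_slab",
    BEYOND_INNER: "beyond_inner",
    BEYOND_OUTER: "beyond_outer",
}


class Region(str):
    """Region names returned by :func:`classify_z`."""


@dataclass(frozen=True)
class PermeationEvent:
    """One complete water transit.

    ``outward`` means inner compartment (negative z) to outer slab
    (positive z, the extracellular side); ``inward`` is the reverse.
    ``t_primed`` is the time the water was first seen in the origin slab
    during this episode and ``t_completed`` the time of first detection in
    the destination slab.
    """

    water_residue_id: int
    direction: str  # "inward" | "outward"
    t_primed: float
    t_completed: float

    def __post_init__(self):
        if self.direction not in ("inward", "outward"):
            raise ConsistencyError(f"bad direction {self.direction!r}")
        if not self.t_completed > self.t_primed:
            raise ConsistencyError("t_completed must exceed t_primed")


@dataclass
class PermeationReport:
    """Event list plus per-window (inward, outward, total) counts."""

    events: list[PermeationEvent]
    window_width: float
    windows: pd.DataFrame  # window_start, window_end, inward, outward, total

    @property
    def n_inward(self) -> int:
        return sum(e.direction == "inward" for e in self.events)

    @property
    def n_outward(self) -> int:
        return sum(e.direction == "outward" for e in self.events)

    @property
    def n_total(self) -> int:
        return len(self.events)


def classify_z(z: float, geom: ChannelGeometry) -> str:
    """Classify a (z_origin-shifted) z position into the five slab regions."""
    return _REGION_NAMES[int(classify_z_array(np.array([z]), geom)[0])]


def classify_z_array(z: np.ndarray, geom: ChannelGeometry) -> np.ndarray:
    """Vectorised region codes for shifted z values.

    inner_slab iff -Delta/2 - delta < z < -Delta/2; outer_slab iff
    Delta/2 < z < Delta/2 + delta; between_planes iff \\|z\\| <= Delta/2;
    otherwise beyond_inner/beyond_outer by sign.
    """
    half = geom.delta / 2.0
    lo, hi = -half - geom.slab_thickness, half + geom.slab_thickness
    out = np.full(np.shape(z), BETWEEN, dtype=np.int8)
    z = np.asarray(z)
    out[(z < -half) & (z > lo)] = INNER_SLAB
    out[(z > half) & (z < hi)] = OUTER_SLAB
    out[z <= lo] = BEYOND_INNER
    out[z >= hi] = BEYOND_OUTER
    return out


def water_com_series(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame centre of mass of every water residue.

    Returns ``(residue_ids (W,), coms (n_frames, W, 3))``.
    """
    waters = traj.topology.water_residues
    if not waters:
        raise HydroflexError("topology contains no water residues")
    return (
        np.array([w.residue_id for w in waters]),
        group_com_series(traj, [w.atom_indices for w in waters]),
    )


def group_com_series(traj: Trajectory, groups: Sequence[np.ndarray]) -> np.ndarray:
    """Mass-weighted CoM of each atom group in every frame: (F, G, 3)."""
    coords = traj.coords_array()
    masses = traj.topology.masses
    F = traj.n_frames
    out = np.empty((F, len(groups), 3))
    # vectorise over groups that share an atom count
    by_len: dict[int, list[int]] = {}
    for gi, g in enumerate(groups):
        by_len.setdefault(len(g), []).append(gi)
    for L, gis in by_len.items():
        idx = np.stack([np.asarray(groups[gi]) for gi in gis])  # (g, L)
        w = masses[idx]
        w = w / w.sum(axis=1, keepdims=True)  # (g, L)
        sub = coords[:, idx.ravel(), :].reshape(F, len(gis), L, 3)
        out[:, gis, :] = np.einsum("fgla,gl->fga", sub, w)
    return out


def channel_axis_series(traj: Trajectory,
                        protein_selection: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-frame lateral (x, y) position of the channel axis.

    The axis is the mass-weighted xy centre of the protein core selection
    (all protein atoms by default), recomputed every frame.
    """
    top = traj.topology
    if protein_selection is None:
        protein_selection = top.protein_atom_indices
    protein_selection = np.asarray(protein_selection, dtype=int)
    if protein_selection.size == 0:
        raise SelectionError("channel axis: empty protein selection")
    m = top.masses[protein_selection]
    sub = traj.coords_array()[:, protein_selection, :2]
    return np.einsum("fla,l->fa", sub, m / m.sum())


def count_permeations(traj: Trajectory, geom: ChannelGeometry,
                      protein_selection: Optional[np.ndarray] = None,
                      window_width: float = 100.0) -> PermeationReport:
    """Detect and count complete water permeation events.

    Reports one :class:`PermeationEvent` per completed episode and bins
    them into ``window_width``-ns windows by completion time.
    """
    if traj.n_frames < 2:
        raise ConsistencyError("need at least 2 frames to detect permeation")
    boxes = np.stack([f.box for f in traj.frames])
    lz = boxes[:, 2]
    if np.any(geom.delta + 2 * geom.slab_thickness > lz):
        raise ConsistencyError(
            f"slab geometry (Delta + 2*delta = "
            f"{geom.delta + 2 * geom.slab_thickness} A) exceeds the box height "
            f"{lz.min()} A: slabs would wrap"
        )
    z0 = geom.resolve_z_origin(traj)
    wids, coms = water_com_series(traj)  # (W,), (F, W, 3)
    axis = channel_axis_series(traj, protein_selection)  # (F, 2)
    times = traj.times

    z = coms[:, :, 2] - z0  # (F, W)
    lat = np.hypot(coms[:, :, 0] - axis[:, None, 0],
                   coms[:, :, 1] - axis[:, None, 1])
    region = classify_z_array(z, geom)
    # PBC-wrap rule: raw consecutive-frame z displacement beyond Lz/2
    jump = np.abs(np.diff(z, axis=0)) > (lz[1:, None] / 2.0)  # (F-1, W)
    # barrier frames abandon any in-progress episode
    barrier = ((region == BETWEEN) & (lat > geom.cylinder_radius)) \
        | (region >= BEYOND_INNER)

    events: list[PermeationEvent] = []
    # waters that never visit both slabs cannot produce an event
    seen_inner = (region == INNER_SLAB).any(axis=0)
    seen_outer = (region == OUTER_SLAB).any(axis=0)
    for wi in np.nonzero(seen_inner & seen_outer)[0]:
        events.extend(
            _fsm_single(region[:, wi], barrier[:, wi], jump[:, wi],
                        times, int(wids[wi]))
        )
    events.sort(key=lambda e: (e.t_completed, e.water_residue_id))
    win = window_counts(events, float(times[0]), float(times[-1]), window_width)
    return PermeationReport(events=events, window_width=window_width, windows=win)


def _fsm_single(region: np.ndarray, barrier: np.ndarray, jump: np.ndarray,
                times: np.ndarray, water_id: int) -> list[PermeationEvent]:
    events = []
    primed = False
    origin = 0
    t_primed = 0.0
    for f in range(len(region)):
        if f > 0 and jump[f - 1]:
            primed = False
        r = region[f]
        if primed:
            if barrier[f]:
                primed = False
            elif r == INNER_SLAB or r == OUTER_SLAB:
                if r != origin:
                    direction = "outward" if origin == INNER_SLAB else "inward"
                    events.append(PermeationEvent(water_id, direction,
                                                  t_primed, float(times[f])))
                    primed = False  # fall through to re-prime below
        if not primed and (r == INNER_SLAB or r == OUTER_SLAB):
            primed, origin, t_primed = True, r, float(times[f])
    return events


def window_counts(events: Sequence[PermeationEvent], t0: float, t1: float,
                  width: float) -> pd.DataFrame:
    """Bin events by completion time into half-open windows of ``width`` ns.

    Windows are ``[t0 + k*width, t0 + (k+1)*width)``; the final window is
    truncated to end at ``t1`` (closed there, so an event completing exactly
    at ``t1`` is counted).
    """
    if width <= 0:
        raise ConsistencyError("window width must be > 0")
    if t1 <= t0:
        raise ConsistencyError(f"empty time range ({t0}, {t1})")
    n = int(np.ceil((t1 - t0) / width))
    starts = t0 + width * np.arange(n)
    ends = np.minimum(starts + width, t1)
    inward = np.zeros(n, dtype=int)
    outward = np.zeros(n, dtype=int)
    for e in events:
        if e.t_completed < t0 or e.t_completed > t1:
            raise ConsistencyError(
                f"event at t={e.t_completed} ns outside range ({t0}, {t1})"
            )
        k = min(int((e.t_completed - t0) // width), n - 1)
        if e.direction == "inward":
            inward[k] += 1
        else:
            outward[k] += 1
    return pd.DataFrame({
        "window_start": starts,
        "window_end": ends,
        "inward": inward,
        "outward": outward,
        "total": inward + outward,
    })
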