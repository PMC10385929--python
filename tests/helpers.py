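"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the package's region-classification and FSM code
paths: the slab inequalities are re-evaluated from scratch, episodes are
found by explicit timeline segmentation, and wettability is an all-pairs
distance scan.
"""

from __future__ import annotations

import numpy as np


def water_com_brute(traj):
    """Per-water CoM computed with a plain per-residue loop."""
    top = traj.topology
    waters = top.water_residues
    ids = [w.residue_id for w in waters]
    out = np.empty((traj.n_frames, len(waters), 3))
    for f, frame in enumerate(traj.frames):
        for wi, w in enumerate(waters):
            m = top.masses[w.atom_indices]
            out[f, wi] = np.average(frame.coords[w.atom_indices], axis=0,
                                    weights=m)
    return np.array(ids), out


def oracle_permeation(traj, geom):
    """Enumerate permeation events by explicit episode segmentation.

    For each water the timeline is cut wherever an episode cannot survive
    (a z jump > Lz/2 between frames, a between-planes frame outside the
    channel cylinder, or a frame beyond either slab).  Within each
    barrier-free stretch, events are the alternations of the sequence of
    slab visits: every inner->outer alternation is one outward event with
    t* the first origin-slab frame since the last alternation/cut.

    Returns a list of (water_id, direction, t_primed, t_completed).
    """
    top = traj.topology
    half = geom.delta / 2.0
    lo, hi = -half - geom.slab_thickness, half + geom.slab_thickness
    z0 = geom.resolve_z_origin(traj)
    ids, coms = water_com_brute(traj)

    # channel axis: per-frame protein xy CoM
    prot = top.protein_atom_indices
    mp = top.masses[prot]
    axis = np.array([
        np.average(fr.coords[prot, :2], axis=0, weights=mp)
        for fr in traj.frames
    ])
    times = traj.times
    lz = np.array([fr.box[2] for fr in traj.frames])

    events = []
    for wi, wid in enumerate(ids):
        z = coms[:, wi, 2] - z0
        lat = np.hypot(coms[:, wi, 0] - axis[:, 0], coms[:, wi, 1] - axis[:, 1])
        pending_side = None  # "inner" | "outer"
        pending_t = None
        for f in range(len(z)):
            if f > 0 and abs(z[f] - z[f - 1]) > lz[f] / 2.0:
                pending_side = None
            in_inner = lo < z[f] < -half
            in_outer = half < z[f] < hi
            between = abs(z[f]) <= half
            barrier = (between and lat[f] > geom.cylinder_radius) \
                or z[f] <= lo or z[f] >= hi
            if barrier:
                pending_side = None
                continue
            if in_inner or in_outer:
                side = "inner" if in_inner else "outer"
                if pending_side is None:
                    pending_side, pending_t = side, times[f]
                elif side != pending_side:
                    direction = "outward" if pending_side == "inner" else "inward"
                    events.append((int(wid), direction,
                                   float(pending_t), float(times[f])))
                    pending_side, pending_t = side, times[f]
    return sorted(events)


def event_tuples(events):
    """Normalise package PermeationEvent objects for comparison."""
    return sorted(
        (int(e.water_residue_id), e.direction, float(e.t_primed),
         float(e.t_completed))
        for e in events
    )


def oracle_wettability(traj, events, cutoff=4.0):
    """All-pairs distance wettability: per residue and direction, the
    fraction of atoms ever within ``cutoff`` of a transiting water's CoM."""
    top = traj.topology
    ids, coms = water_com_brute(traj)
    col = {int(w): i for i, w in enumerate(ids)}
    times = traj.times
    prot_res = [r for r in top.residues
                if top.domain_map[r.residue_id] in
                ("bundle", "hash", "gating", "other")]
    wet = {d: set() for d in ("inward", "outward")}
    for e in events:
        wcol = col[int(e.water_residue_id)]
        for f in range(traj.n_frames):
            if not (e.t_primed <= times[f] <= e.t_completed):
                continue
            c = coms[f, wcol]
            for r in prot_res:
                for ai in r.atom_indices:
                    d = traj.frames[f].coords[ai] - c
                    if float(d @ d) <= cutoff * cutoff:
                        wet[e.direction].add(int(ai))
    out = {}
    for r in prot_res:
        n = len(r.atom_indices)
        out[r.residue_id] = (
            sum(int(a) in wet["outward"] for a in r.atom_indices) / n,
            sum(int(a) in wet["inward"] for a in r.atom_indices) / n,
        )
    return out


def random_channel_kwargs(rng):
    """Randomised generator arguments for oracle-equivalence sweeps."""
    return dict(
        n_complete_out=int(rng.integers(0, 5)),
        n_complete_in=int(rng.integers(0, 5)),
        n_partial=int(rng.integers(0, 6)),
        n_interface=int(rng.integers(0, 4)),
        n_wrap=int(rng.integers(0, 3)),
        n_bulk=int(rng.integers(10, 40)),
        n_frames=int(rng.integers(100, 200)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
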