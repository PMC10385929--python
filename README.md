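# hydroflex

Analysis toolkit for water transport through membrane transporters in
molecular-dynamics trajectories. It was built around the questions raised by
sugar-uptake inhibition in SGLT1-like (LeuT-fold) cotransporters — does an
inhibitor block water by plugging the pore, by constricting it, or by
rigidifying the domain motions that gate it? — and provides the four
analyses needed to answer them:

* **Permeation counting** — complete water transits through the protein
  channel, detected with a two-slab criterion: two planes separated by
  Δ = 25 Å sit symmetrically about the membrane mirror plane, with detection
  slabs of thickness δ = 5 Å just outside them. A water's CoM must be seen
  in one slab (−Δ/2−δ < z(t\*) < −Δ/2) and later in the opposite slab
  (Δ/2 < z(t\*+τ) < Δ/2+δ). Episodes are discarded on periodic-wrap jumps
  (|Δz| > L<sub>z</sub>/2) and on protein–membrane interface pathways
  (lateral excursion beyond a cylinder around the channel axis). Counts are
  reported per direction in 100-ns windows.
* **Channel profiling** — water number-density profiles along the membrane
  normal, 2D cross-sectional density maps, the channel-opening (orifice
  area) estimator `min(density profile) × 7.1 Å²`, and the residue
  wettability w<sub>r</sub>: the fraction of a residue's atoms found within
  r<sub>c</sub> = 4 Å of a permeating water during its transit.
* **Energetics & geometry** — group–group nonbonded interaction energies
  (Coulomb with the CHARMM constant 332.0636 plus CHARMM-form
  Lennard-Jones, full double sum by default) for ligand:protein and
  bundle:hash pairs, and radius-of-gyration series of channel-lining
  selections.
* **PCA flexibility** — the protein coarse-grained into four domain beads
  (bundle/hash × upper/lower) or 18 binding-site residue beads; the
  covariance C of bead fluctuations is diagonalised, every mode i gets a
  stiffness κ<sub>i</sub> = k<sub>B</sub>T/λ<sub>i</sub>, a flexibility
  σ<sub>i</sub> = λ<sub>i</sub>/k<sub>B</sub>T and a vibrational weight
  w<sub>vi</sub> ∈ [0,1] (the complement of the mode's overlap with the
  rigid-body subspace). The overall flexibility is
  σ = (1/k<sub>B</sub>T) Σ λ<sub>i</sub> w<sub>vi</sub>, and the flexibility
  of a prescribed "rocking-bundle" displacement pattern P is
  σ<sub>P</sub> = (1/k<sub>B</sub>T) Σ λ<sub>i</sub> w<sub>vi</sub> (P·e<sub>i</sub>)².

A first-class synthetic module generates every fixture the analyses need —
scripted water transits with known event lists, decoy pathways, Gaussian
bead dynamics with prescribed covariance — so the whole suite is verifiable
without any external trajectory.

## Worked example

Generate a scripted channel system (a ring-stack pseudo-protein spanning
the membrane, 3 scripted outward transits, 2 inward, plus partial-,
interface-, wrap-decoys and bulk waters), then analyse it:

```sh
hydroflex synth channel -o fixture --n-frames 120 --seed 3
```

```yaml
# config.yaml
paths:
  topology: fixture/system.pdb
  connectivity: fixture/system.psf
  trajectory: fixture/traj.dcd
geometry:
  z_origin: 0.0          # the fixture is built symmetric about z = 0
selections:
  tm_ranges: {TM1: [1,2], TM6: [6,7], TM3: [3,4], TM8: [8,9],
              TM5: [5,5], TM10: [10,10]}
output:
  directory: out
```

```sh
hydroflex permeation -c config.yaml
# 5 events (3 outward, 2 inward) -> out
hydroflex opening -c config.yaml
# opening 0.89 A^2 at z=0.40 -> out
hydroflex flex -c config.yaml --segment-ns 200
# 1 segment(s) -> out
```

The permeation line confirms that exactly the five scripted transits were
counted, with the decoys rejected; `out/permeation_windows.tsv` holds the
per-100-ns (inward, outward, total) table and
`out/permeation_events.json` the event log. The opening value is the
minimum of the time-averaged in-channel water count per 2.8 Å slab times
the 7.1 Å² water cross-section — small here because the fixture's channel
holds only the scripted waters. The flex table (`out/flex.tsv`) reports σ
and the three rocking-bundle projections σ_A (alternating mouth opening),
σ_B (up–down domain sliding), σ_C (simultaneous opening) per 200-ns
segment; for this static pseudo-protein they are zero to machine
precision.

Other subcommands: `density`, `density2d`, `wettability`, `energy`,
`rgyr`, and `synth beads` / `synth charges` for the Gaussian-bead and
point-charge fixtures.

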