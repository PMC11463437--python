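# memscramble

Quantitative analysis of lipid scrambling by TMEM16 family scramblases in
coarse-grained molecular dynamics trajectories.

TMEM16 proteins collapse the asymmetric lipid distribution of biological
membranes by scrambling phospholipids between the two leaflets, most often
through a membrane-spanning hydrophilic groove between helices TM4 and TM6
(the "credit-card" mechanism: the headgroup slides along the polar groove
while the tails stay in the hydrophobic core). `memscramble` implements the
complete analysis pipeline used to survey this behaviour in long Martini
trajectories of DOPC bilayers:

- **Scrambling events and rates** — each lipid's orientation angle
  θ = arccos(v·ẑ/|v|), with v the mean of the NC3→C4A and NC3→C4B bead
  vectors, is smoothed with a 100 ns running average; a transition counts
  when an upper-leaflet lipid (resting near 150°) reaches ≤ 35°, or a
  lower-leaflet lipid (near 30°) reaches ≥ 145°. Rates are block-averaged
  over 1 μs blocks (mean ± SD in events/μs), and event streams are tested
  for Poisson statistics with a dispersion-index χ² test.
- **Pathway classification** — events whose PO4 bead passes within 4.7 Å of
  the maximum-density pathway (per-z-slab density argmax, smoothed) are
  in-the-groove; the rest are out-of-the-groove, sub-labelled dimer-cleft
  when nearer the TM3/TM10 dimer interface.
- **Membrane deformation** — ensemble-averaged leaflet surfaces from
  glycerol (GL1/GL2) beads on a 1 Å grid with per-frame leaflet assignment,
  a 2% occupancy filter and removal of clusters disconnected from the bulk
  surface; minimal membrane thickness is the minimum 3D distance between
  the two surfaces.
- **Densities and free energy** — 3D bead densities (100×100×150 Å grid,
  0.5 Å voxels, OpenDX export) and lipid free-energy profiles along the
  groove by Boltzmann inversion, F(s) = −ln(ρ(s)/ρ_max) in kT at 310 K.
- **Groove geometry** — per-frame minimum TM4–TM6 distance with per-homolog
  residue registries, EWMA smoothing (factor 0.1), open-fraction versus the
  6 Å dilation threshold, and the thickness(14 Å)/openness(6 Å) competence
  quadrant.
- **Contacts and permeation** — protein–lipid contact frequencies and dwell
  times (7 Å cutoff, 6 ns gap tolerance, top-50% dwell averaging), and
  water/ion permeation counting along the pathway with count-ratio
  selectivity (P_Na/P_Cl).

Because the original multi-microsecond trajectories are not redistributable,
the package ships a first-class synthetic trajectory generator
(`memscramble.synthgen`) that builds DOPC-like bilayers (30 Å
glycerol-to-glycerol separation) with scripted flips, partial excursions,
thinning fields, protein scaffolds and tracer crossings — every analysis
stage is validated against this known ground truth.

## Worked example

Scripted flips through a groove scaffold, detected and rated:

```python
import numpy as np
from memscramble.synthgen import (BilayerSpec, Flip, FlipSchedule,
                                  add_protein_scaffold, apply_flips,
                                  make_bilayer)
from memscramble import compute_angle_traces, detect_events, estimate_rate

spec = BilayerSpec(lipids_per_leaflet=64, box_xy=80.0, noise_sigma=0.5, seed=7)
traj = make_bilayer(spec, n_frames=2000)           # 2 us at 1 frame/ns
traj = add_protein_scaffold(traj, groove_center=(40.0, 40.0), groove_width=8.0)
path = [(40.0, 40.0, z) for z in (15.0, 0.0, -15.0)]
flips = [Flip(lipid_id=i if i % 2 == 0 else 64 + i,  # upper flip down, lower up
              start_ns=150.0 + 120.0 * i,
              direction="down" if i % 2 == 0 else "up", path=path)
         for i in range(10)]
traj = apply_flips(traj, FlipSchedule(flips=flips))

events = detect_events(compute_angle_traces(traj))
rate = estimate_rate([e.t_complete for e in events], 0.0, 2000.0)
print(f"{len(events)} events, {rate.mean_rate:.1f} +/- {rate.sd:.1f} events/us")
```

```
10 events, 5.0 +/- 2.0 events/us
```

All 10 scripted transitions are recovered (5 in each direction), and the
1 μs block average gives 5.0 events/μs — 10 events over the 2 μs window;
the events fall 7/3 across the two blocks, hence the block SD of 2.0.

The same pipeline runs from the shell on standard MD files or the package's
plain-text fixtures:

```sh
memscramble synth --preset scramble --seed 3 --frames 600 --out demo.mstrj
memscramble scramble demo.mstrj --equilibration-ns 0 --out-dir out/
```

## Layout

```
src/memscramble/
  trajio.py      data model, readers/writers, alignment
  synthgen.py    synthetic bilayers with scripted ground truth
  scramble.py    angle traces, event detection, rates, classification
  membrane.py    leaflet surfaces, thickness, densities, PMFs
  geometry.py    groove dilation, EWMA, competence quadrants, dimer cleft
  contacts.py    contact frequencies and dwell times
  permeation.py  permeation counting and selectivity
  cli.py         command-line interface
docs/methods.md  models, parameters, numerical choices, limitations
```
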