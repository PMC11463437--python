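# Methods

This note documents the models, conventions and numerical choices behind
`memscramble`, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Data model and units

A trajectory is a `(frames, beads, 3)` array of coordinates in Ångström
with times in nanoseconds on a strictly increasing uniform grid and
per-frame orthorhombic box lengths. The topology resolves, for every DOPC
lipid, the Martini beads NC3 (choline), PO4 (phosphate), GL1/GL2 (glycerol)
and C4A/C4B (terminal tail beads), and for every protein residue a backbone
bead plus side-chain beads (glycine has none). All time windows (100 ns
running average, 1 μs blocks, 6 ns gap tolerance) are converted to frame
counts by rounding to the nearest integer; the reference sampling rate is
1 frame/ns. Standard formats (GRO/PDB snapshots, XTC/DCD frames) are read
through MDAnalysis; analyses assume whole molecules and do not apply
minimum-image corrections to distances, which is appropriate for a protein
centred in a large (e.g. 220×220×180 ų) box far from the boundaries.
Triclinic boxes and variable frame spacing are out of scope.

Equilibration removal keeps a frame stamped at time t when its sampling
interval [t, t+dt) reaches past the cutoff (t + dt > cutoff): a 10 000-frame
trajectory sampled at 0…9999 ns loses exactly the first 1000 frames at the
default 1 μs cutoff, and a cutoff just before the end retains the final
frame. Times are never re-zeroed.

## Scrambling detection

The orientation angle of a lipid is θ = arccos(v·ẑ/|v|) in degrees, where v
is the mean of the NC3→C4A and NC3→C4B vectors: upper-leaflet lipids rest
near 150–180°, lower-leaflet lipids near 0–30°. The raw trace is smoothed
with a **centred** moving average whose window is the odd frame count
closest to 100 ns (edge frames use the truncated window). A centred window
avoids the systematic completion-time lag of a trailing average; the cost
is a timing uncertainty of up to half a window, which is why ground-truth
tests only require completion times within one window of the scripted
transition.

Detection is a hysteresis state machine per lipid: the leaflet state is
initialised by the side of 90° of the first smoothed angle and changes
*only* when the smoothed trace reaches the opposite far threshold
(≤ 35° for upper→lower, ≥ 145° for lower→upper). Partial excursions that
turn back before the far threshold are therefore never counted, and
repeated back-and-forth transits each count. The transition window used
for pathway classification opens at the last frame before completion at
which the trace was still beyond the origin leaflet's resting angle
(150°/30°) — a concrete, testable convention for a quantity the detection
rule itself leaves implicit.

Rates are block averages: the analysed window is tiled with consecutive
1 μs blocks (trailing partial block dropped), and the mean and population
standard deviation (ddof = 0) of per-block counts are reported in
events/μs. Population normalisation was chosen because the blocks tile the
window exhaustively rather than sample it. Poisson behaviour of an event
stream is assessed with a dispersion-index test: D = s²/c̄ over the block
counts, (n−1)·D ~ χ²(n−1) under a homogeneous Poisson process, two-sided
p-value so both regular (D ≪ 1) and clustered (D ≫ 1) streams are
rejected; streams with fewer than 10 events are flagged as insufficient
instead of tested.

## Pathway classification

The maximum-density pathway is built from a 3D density grid of headgroup
beads: in every 0.5 Å z-slab (optionally restricted laterally to the groove
region) the highest-density voxel centre is taken, ties broken toward the
lowest voxel index with a warning, empty slabs interpolated linearly, and
the xy chain smoothed with a 3-slab moving average. An event is
**in-the-groove** iff the minimum over its transition window of the PO4
distance to this polyline is ≤ 4.7 Å (inclusive boundary). Out-of-the-groove
events are sub-labelled `dimer_cleft` when, at their midplane crossing, the
headgroup is nearer the registered TM3/TM10 site than the TM4/TM6 site,
else `other`.

## Membrane surfaces and thickness

Leaflet surfaces are built by **bilinear splatting** of each lipid's GL1
and GL2 beads onto a 1 Å rectilinear xy grid — each bead's z is distributed
to the four surrounding nodes with bilinear weights, and weighted heights
are averaged over all analysed frames. ("Interpolating scattered beads to a
grid" only makes sense in the scatter→grid direction for surface
construction.) Leaflets are assigned **per frame** from the smoothed angle
(upper iff θ ≥ 90°, inclusive at the boundary), so a scrambling lipid
migrates between surfaces as it transits. Grid nodes occupied in fewer
than 2% of the analysed frames are discarded (the denominator is the
frames actually analysed, i.e. post-equilibration), and connected
components (4-connectivity) not attached to the largest component — the
bulk membrane surface — are removed. Minimal membrane thickness is the
minimum **3D** Euclidean distance between valid points of the two
surfaces, computed with a KD-tree but exactly equal to the exhaustive
all-pairs minimum (asserted against a brute-force oracle in the tests).

## Densities and free-energy profiles

Bead densities use nearest-voxel binning on a grid of configurable extent
(default 100×100×150 Å, 0.5 Å spacing); raw counts conserve in-bounds
bead-frames exactly, with out-of-bounds observations counted and logged.
Subunit symmetrisation re-bins each frame once per chain after the
translation mapping that chain's reference backbone centroid onto the first
chain's, then averages voxel counts over chains (consistent with the
translation-only subunit alignment, below). The default normalisation for
export is probability per voxel; raw counts are retained.

Free-energy profiles follow from Boltzmann inversion,
F(s) = −ln(ρ(s)/ρ_max) in kT (310 K enters only through the kT unit).
ρ(s) is the mean voxel density within a lateral tube radius (default 8 Å)
of the pathway point in its one-voxel-thick z-slab. Slabbing by z rather
than by arc length assumes the pathway is membrane-normal, which holds for
the TM4/TM6 groove and keeps the inversion exact on constructed densities;
the reference density is the profile maximum, so F ≥ 0 with min F = 0.
Empty slabs give +∞ with a gap flag.

## Alignment

Two alignments are used. (1) Subunit alignment is **translation-only** in
x, y and z: every frame is shifted so the chain's backbone centroid matches
its reference-frame position. No rotational superposition is applied, so
membrane geometry relative to the subunit is preserved; backbone beads only
are used (side chains would bias the centroid with their fluctuations).
(2) Membrane-frame alignment computes one rotation about z from the
reference frame's TM7/TM8 backbone xy covariance, mapping the largest
principal axis onto the global y axis, and applies it to all frames about
the selection centroid. An isotropic selection (equal eigenvalues) is an
error. Both operations are exact isometries per frame.

## Groove geometry and competence

The groove-width series is the per-frame minimum distance over **all**
beads (side-chain and backbone) between the registered TM4 and TM6 residue
ranges of one subunit — the most inclusive reading of a minimum-distance
measurement. The registry ships ranges for nhTMEM16 (327–339/430–452),
afTMEM16 (319–331/426–438), TMEM16K (365–377/434–446), TMEM16F
(512–524/613–625) and TMEM16A (541–553/635–647); every TM4 span is 13
residues. Display smoothing is the recursive EWMA s₀ = x₀,
sₜ = 0.1·xₜ + 0.9·sₜ₋₁; medians, quartiles and the open fraction
(share of frames above the 6 Å dilation threshold) are computed on the
**raw** series, per chain (with a pooled option), since smoothing is for
visualisation only. The competence quadrant combines two empirical
thresholds: robust scrambling requires minimal thickness < 14 Å *and*
median groove width > 6 Å. The dimer-cleft width restricts the TM3(chain
A)–TM10(chain B) minimum distance to beads below the membrane midplane
(midpoint of the two leaflet surface means); frames with an empty
restricted selection yield NaN.

## Contacts and dwell times

A contact exists when the residue's outermost side-chain bead — resolved
**per frame** as the side-chain bead farthest from the backbone, since
Martini side chains move — is strictly within 7 Å of the lipid's NC3 or
PO4 bead (the 7.0 Å boundary itself is not a contact). Dwell events merge
contact runs across breaks of at most 6 ns; the dwell duration counts both
endpoints and includes merged gap frames (a documented convention, flagged
for sensitivity testing). Per residue, the headgroup bead (NC3 vs PO4)
with the higher mean dwell is selected; contact frequency is the fraction
of frames with any lipid contact, averaged over the monomers; the top-50%
dwell statistic is the mean of the longest ⌈n/2⌉ events; the scrambler
share divides raw contact frames attributable to scrambling lipids by all
raw contact frames.

## Permeation

A particle (water bead, Na or Cl) completes a permeation event when it
moves from below the lower slab boundary to above the upper one (or the
reverse) while every in-slab frame lies within the lateral tube radius
(default 8 Å) of the pathway; leaving the tube mid-slab voids the transit
and returning to the origin side restarts the state machine. Slab bounds
default to the leaflet-surface heights at the groove. Martini waters are
4:1 mapped, so water counts are bead events. Selectivity is the count
ratio P_Na/P_Cl, flagged as low-count when either species has fewer than
10 events. No voltage is applied; counts are equilibrium crossings.

## Synthetic-data generator

The generator emulates the features of a Martini DOPC bilayer that the
analyses consume, with exact ground truth:

- **Geometry** — rigid six-bead lipid templates on a jittered lattice (one
  site exactly at the box centre); glycerol planes at ±(d−h(x,y))/2 with
  d = 30 Å (the bulk glycerol-to-glycerol thickness), NC3 8 Å above and
  tail ends 13 Å below the glycerol plane. Upper-leaflet lipids have
  θ exactly 180° at zero noise (the lateral tail-bead offsets cancel).
- **Dynamics** — two noise channels: per-lipid rigid lateral displacement
  per frame (`lateral_sigma`, default 1.2 Å, emulating in-plane diffusion
  within the 1 ns sampling interval; the lipid's plane height follows the
  thickness field at the displaced position, so surfaces stay exact) and
  per-bead isotropic jitter (`noise_sigma`, thermal noise the detector must
  tolerate). Identical spec + seed is bit-identical.
- **Flips** — scripted lipids move their centre along a 3D waypoint path
  (default: vertical) while the lipid axis rotates continuously; the
  default 20 ns duration matches the observed sub-20 ns groove dwell of
  scrambling lipids. Partial excursions tilt to a prescribed angle and
  return, and must never be detected.
- **Scaffold** — static vertical walls registered as TM4/TM6 (groove) and
  TM3/TM10 (dimer cleft) with configurable, optionally per-frame,
  separations; every fourth scaffold residue is glycine-like. There are no
  protein dynamics beyond the scripted wall separations.
- **Tracers** — waters/ions with scripted through-slab crossings along the
  registered path, plus wanderers confined to one bath.

What the generator does **not** emulate: lipid–lipid interactions,
energetics, realistic diffusion kinetics, curvature fluctuations or
protein flexibility. Passing the ground-truth suites therefore shows that
the estimators are correct on data satisfying their stated assumptions —
not that the assumptions hold in any particular force field or system.

## Validation problem sizes

The validation suites run at desk scale, chosen to preserve the analysed
time structure while staying cheap: detector-recovery trajectories scale
with the scripted event count up to 220 flips over a 10 μs-equivalent
window (10 000 frames, 128 lipids, σ = 1 Å jitter); surface/thickness
oracles use 578-lipid bilayers over 150 frames with Gaussian thinning
fields of 10 Å feature scale (recovering scripted thinning of 7/16/18 Å
within 0.1 Å); Poisson calibration uses 200 independent streams at
10 events/μs over 9 μs. Published per-structure event counts are shipped
in `memscramble.reference` and drive the arithmetic reconstruction of the
block-averaged rates.

## Known limitations

- Completion times carry the half-window timing uncertainty of the centred
  smoother; pathway classification inherits it through the transition
  window.
- The density pathway is voxel-quantised (0.5 Å) and its tie-break is
  index-ordered; a uniform density produces a warning, not an error.
- The dispersion-index χ² test is approximate for small block counts.
- Whether the original protocol's running average was centred or trailing,
  its block-SD normalisation, and its exact permeation crossing criterion
  are not derivable from the published description; the conventions here
  are documented stand-ins, fixed and tested.
- Scripted flips assume a locally flat membrane at the flip site; the
  thickness field is ignored along a flip path.
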