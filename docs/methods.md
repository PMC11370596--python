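# Methods

This note documents the models, conventions and numerical choices behind
`memflux`, and what the synthetic-data validation does and does not
establish about real trajectories.

## Units and conventions

Lengths in Å, times in ps (durations reported in ns), charges in elementary
charges (e), potentials in kT/e at 310 K (multiply by
`fields.KT_OVER_E_310_V` ≈ 0.02671 to get volts). Atom indices are 0-based;
residue ids are 1-based as read from files. Only orthorhombic boxes are
supported: slab geometry assumes an axis-aligned membrane normal, and the
analyses reject triclinic input rather than silently mis-wrapping it. The
membrane normal is a box axis (default z); no tilt fitting is attempted.

## Membrane frame of reference

Lipid headgroup atoms (the phosphate reference atom, one per lipid) are
partitioned into two leaflets once, on the first frame, by sign about the
frame-0 median. The partition is then fixed: each leaflet plane is the
per-frame mean of its own headgroups, and leaflet reassignment is
exclusively the scrambling detector's job, so a lipid in mid-flip cannot
perturb the frame of reference it is being measured against.

The per-frame midplane is the midpoint of the two fixed-partition leaflet
planes, not a global headgroup median. With an even number of lipids a
single flipped lipid leaves the leaflet populations uneven (e.g. 35/37), and
the median of the pooled headgroup coordinates then falls *inside* the
majority leaflet's cluster — an ~18 Å midplane error that corrupts every
midplane-relative quantity downstream. The plane-midpoint definition is
robust by construction: one transiting lipid moves its origin leaflet's mean
by at most (plane separation)/N, i.e. the midplane by half of that.

## Permeation detection

Each tracked ion is classified per frame into one of three zones along the
normal, using its minimum-image coordinate relative to the midplane:
below-bulk (z < lower plane − buffer), above-bulk (z > upper plane +
buffer), or the slab/transit zone between them. The bulk buffer defaults to
5 Å; commitment to a bulk zone requires `dwell` consecutive frames there
(default 1), suppressing double counting from boundary chatter.

A crossing is emitted when an ion committed to one bulk zone reaches
commitment in the opposite zone **and** every frame since it last sat in its
origin zone was spent contiguously in the slab zone. This single rule gives
three properties at once:

* re-entrant excursions (into the slab and back out the same side) produce
  no event, because commitment never switches;
* diffusion through the periodic box boundary — in a periodic slab system
  the two bulk regions are one connected water compartment — switches the
  committed zone with *no* intervening slab frames, so it is never scored;
* the event timestamp is well defined: entry = first slab frame of the
  transit, exit = first frame of the committing run in the destination bulk.

In radial mode (default) the event must additionally satisfy the pore
constraint on every in-slab frame: in-plane minimum-image distance to the
pore centre ≤ radius (default 10 Å; the pore centre may track a protein
selection's centroid per frame). Slab mode scores any transmembrane
crossing; both are provided because published counting scripts do not always
state whether a radial constraint was applied, and slab mode is the literal
reading of "crossed the bilayer from one side to the other".

A warning is raised when the median per-frame ion displacement along the
normal exceeds the buffer — at such coarse save strides an ion can hop a
zone boundary between stored frames and crossings may be missed.

## Conductance

The conductance estimate is the gross-count upper limit used with counting
simulations under voltage clamp: Λ = Q·e/(|V|·t) with e exact SI
(1.602176634·10⁻¹⁹ C), Q the number of field-consistent elementary charges
transported (each cation crossing with the field and each anion against it
contributes |valence|), t the sampled duration. Field-inconsistent crossings
are tallied separately as backward events and never subtracted — hence
"upper limit". Sign convention: positive voltage holds the upper (greater
normal coordinate) compartment at higher potential, driving cations down.
Values are reported at full precision and rounded to one decimal pS.

## Scrambling

Leaflet identity is a function of headgroup position only. The raw headgroup
coordinate is unwrapped (minimum-image continuous) relative to the midplane,
then labelled with hysteresis: the label changes only after the headgroup
spends `dwell` consecutive frames (default 10) beyond the ±`band` zone
(default ±5 Å, sized to POPC headgroup fluctuations of ~1–2 Å RMS) on the
opposite side, and the switch is recorded from the first frame of the
committing run. Any path confined to the band — or that crosses the midplane
and returns without committing — leaves the label untouched. Upper leaflet
means greater coordinate along the normal; mapping upper/lower onto
extracellular/intracellular is an annotation the user supplies, never
inferred.

## Ion–residue contacts

A contact frame is one where any ion of the target species is within the
cutoff (default 4.0 Å, the usual salt-bridge criterion) of any charged-group
atom of the residue (Arg: NE/CZ/NH1/NH2; Lys: NZ; all atoms if none
present). Occupancy is the contact-frame fraction; dwell segments are the
maximal contact runs. The channel pore-mouth basic residues discussed for
TMC4 (R419, R488, R635) and TMC5 (R641, R736, R659, K549) ship as annotation
presets (`permeation.PORE_CONTACT_RESIDUES`).

## Alignment, water density, hydration continuity

Alignment is the Kabsch least-squares rigid superposition of a selection
(≥3 non-collinear atoms; typically backbone) onto a reference frame, with
reflections excluded by flipping the smallest singular direction, and the
same transform applied to all atoms. Collinearity is detected from the
singular values of the centred reference selection.

Water density is nearest-voxel binning of water oxygens into an
axis-aligned grid covering the box (default 1 Å voxels, honouring
grid densities above 1 Å⁻³), averaged over frames sampled at a configurable
stride (default 25 ps between sampled frames); units Å⁻³. Total density
times voxel volume equals the mean in-box water count exactly. An optional
periodic Gaussian smoothing (KDE-style) is available; it conserves mass.

Hydration continuity: bulk density is estimated from voxels axially outside
the pore's extent; each axial voxel layer restricted to the pore cylinder is
"dry" when its mean density falls below threshold × bulk (default 0.25 — low
enough to tolerate single-file water, high enough to flag genuinely dewetted
bands). Maximal dry runs inside the slab are reported as gap intervals;
continuity holds iff there are none. With threshold 0 nothing is ever dry.

## Electrostatic maps

Partial charges are smeared into periodic Gaussians of width
σ = 1/(√2·κ), where κ is the Ewald splitting factor in Å⁻¹ (default 0.25,
the convention of common MD visualization tooling); the smearing is applied
exactly in reciprocal space through the structure factor, so there is no
assignment-order error. The periodic Poisson equation is then solved
spectrally on the grid with the k = 0 mode zeroed, which is identical to
adding a uniform background that neutralizes any net charge (the net charge
is logged). Per-frame potentials are averaged over the sampled frames and
converted to kT/e at 310 K. Because both the smearing and the solve are
spectral, the grid potential agrees with a direct reciprocal-space Ewald sum
for the same Gaussian charges to machine precision once the Gaussian decays
below the grid Nyquist frequency (σ ≈ 2.8 Å vs 1 Å voxels here); the test
suite verifies ≤ 10⁻³ kT/e against an independent direct sum. This is a
spectral solve on smeared charges, not a full PME implementation with
real-space pairwise corrections — adequate for maps, not for forces.

## Synthetic data and what it shows

The generator synthesizes coordinates *from* programmed events, never the
reverse, so the ground-truth ledger is exact by construction. Defaults
emulate the study conditions of a solvated channel system: a 50×50×100 Å
box, leaflet planes at ±19 Å (POPC-like), headgroup jitter σ = 1 Å, a pore
cylinder of radius 8 Å, 45 Na⁺ + 45 Cl⁻ (≈300 mM in that volume), ±0.5 V
annotations, and random-walk steps of 1 Å per stored frame. Non-programmed
ions are reflective walkers confined to a bulk compartment (non-crossing by
construction); a configurable share are "wrap walkers" that diffuse through
the periodic boundary between the two bulk regions, and optional excursion
ions dip through the pore past the midplane and return. Programmed
crossings follow a monotone three-phase transit (approach the pore axis in
bulk, cosine ramp through the slab inside the cylinder, settle beyond the
commitment depth); programmed flips carry one headgroup between the leaflet
planes through the pore axis over a declared window. Waters are resampled
uniformly each frame within the bulk slabs and the pore cylinder, skipping
any programmed dewetted band.

Preset scenarios: `open-conducting` (14 Na⁺ up / 2 Cl⁻ down under −0.5 V),
`open-conducting-17x3` (17/3), `closed-hydrated-discontinuous` (no
crossings; dry band at |z| < 4 Å; 25 ps stride), and `scrambling` (one
lower→upper flip transiting around t = 60 ns). Preset durations are scaled
to desk size (20 ns at 20 ps stride for the conducting presets, 5 ns at
25 ps for the hydration preset, 100 ns at 100 ps for scrambling): counts,
not durations, are the programmed ground truth, and the conductance worked
examples take the run durations (200/480 ns) as explicit inputs.

Passing against this generator establishes that the detectors implement
their definitions exactly — zero missed and zero spurious events across
randomized scenarios including wrap-heavy and re-entrant paths — and that
the field solvers agree with closed-form oracles. It does *not* establish
anything about force-field realism: the synthetic trajectories have no
physics (no correlations between ions, no lipid deformation around a
transiting lipid, i.i.d. waters), so detector thresholds (buffer, band,
dwell, contact cutoff, continuity threshold) remain declared analysis
choices to be reported alongside any real-data result, not calibrated
constants.

## Known limitations

* Orthorhombic boxes and axis-aligned membranes only; no curved membranes.
* Leaflet identity from the headgroup coordinate only (no tail orientation).
* The electrostatic map is a potential map, not an energy/force engine.
* PSF input is consumed only as a charge/mass overlay (no connectivity).
* Trajectory times for DCD/XTC are written from a constant stride starting
  at the first frame's time of 0.
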