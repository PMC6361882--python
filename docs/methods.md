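# Methods

`pgoe` implements list-mode image reconstruction for a three-stage
pixelated Compton camera observing prompt gammas (PGs) emitted during
proton irradiation, together with a synthetic data generator and the
profile metrics used for proton-range verification.  This note records
the models, the numerical choices, and what the synthetic studies do and
do not demonstrate.

## Camera model

The camera has three CZT stages on a common axis (lab `+x`),
perpendicular to the beam (lab `+z`, phantom entrance at `z = 0`).  Each
stage is a slab of pixelated crystals: the pixel grid spans the lab
`(y, z)` plane and the crystal depth runs along `x`.  The detector
reports, per interaction, the pixel-centre transverse coordinates, a
depth measurement with bounded uniform error (default total span
`delta_iz` = 1 mm), and a deposited energy blurred by the
energy-resolution model.

Two energy-resolution models are provided:

* `ab_fwhm` (default): `FWHM(E) = a + b*sqrt(E)` with `E` and the FWHM
  in keV, `sigma_E = FWHM / 2.355`, defaults `a = -0.2892` keV,
  `b = 0.4332` keV^1/2.  These coefficients reproduce a commercial CZT
  pixel array quoted at 1.64% relative FWHM at 662 keV and 5.13% at
  59.5 keV; keV is the only unit convention that reproduces both printed
  values, and the (unreachable above the 1 MeV analysis cut) negative
  branch below ~0.45 keV is clamped to zero.
* `eta_sqrt`: `sigma_E = eta * sqrt(E)` with `E` in MeV, default
  `eta = 0.015`.  The two models disagree numerically (at 6.13 MeV the
  `ab` model gives sigma ≈ 14 keV, the `eta` model ≈ 37 keV); both are
  selectable per run and the `ab` model is the default everywhere.

Default geometry ("small phantom"): stages 1–2 are 25×25 arrays of
2×2×15 mm pixels, stage 3 is 50×50 of the same pixels, adjacent stages
separated by 50 mm of air, stage 1 entrance 150 mm from the beam axis,
camera centred at depth `z = 100` mm.  A "large phantom" preset with
1×1×15 mm pixels (same total areas) is included.

## Event kinematics

A *double* event scatters once in stage 1 and is absorbed in stage 2;
its total energy is the deposit sum.  A *triple* scatters in stages 1
and 2 and interacts (not necessarily fully) in stage 3; its incident
energy is recovered without the third deposit from the geometric scatter
angle `theta_2` at the second vertex:

    E' = E2/2 + sqrt(E2^2/4 + E2 * m_e c^2 / (1 - cos theta_2)),
    E_total = E1 + E'.

Events are kept if `E_total > 1` MeV (rejecting annihilation gammas) and
inside a ±0.2 MeV window around one of the four PG lines 2.31 (14N),
4.44 (12C), 5.25 (15O), 6.13 MeV (16O).  Each kept event defines a
half-cone of candidate origins: apex at the first interaction, axis
along `L1 - L2`, half-angle from the Compton relation
`cos beta = 1 - m_e c^2 (1/(E_total - E1) - 1/E_total)`.  Interaction
ordering is taken as given (stage order = scatter order); sequence
ambiguity resolution for real data is out of scope.

## Synthetic data generator

The generator replaces Monte Carlo proton transport with a parametric
emission model and exact geometric construction, so that the
reconstruction operator — not transport physics — is what the package
exercises.

The depth-emission density is an entrance plateau with a linear rise, a
Bragg-peak Gaussian and a distal sigmoid cutoff:

    f(z) ∝ max(0, p0 + p1 z + A exp(-(z - z_p)^2 / 2 s_p^2))
           * logistic((z_f - z)/s),  z_f = z_p + offset,

with a transverse Gaussian beam spot (default sigma_t = 3 mm).  Origins
are sampled by inverse-CDF in depth on a fine grid.  Per-species presets
approximate the published depth-profile geometry of the four PG lines
for a 120 MeV beam in water: 12C/15O/16O are Bragg-peak-like
(concentrated peak just proximal of the distal edge), 14N is broad and
line-like with a shallow distal slope.  Preset peak/falloff positions
were fixed once against the published Monte Carlo truth values and are
not fit to any reconstruction output.  The analytic ground truth for a
preset is obtained by smoothing `f(z)` with the same 2.0 mm FWHM
Gaussian used in the measurement protocol on a 0.01 mm grid and applying
the same peak/falloff measurement; crossings are therefore deterministic
to ~0.01 mm and seed-invariant.

Given an origin, an event is built by drawing the first vertex uniformly
inside the stage-1 crystal, the second (and for triples third) vertex
uniformly in the designated stages, and setting the deposited energies
*exactly* consistent with Compton kinematics along that polyline (the
third deposit of a triple is the full remainder).  Detector degradation
is then applied on top: pixel quantization, uniform depth error, and
Gaussian energy blur.  With degradation disabled every cone contains its
origin to < 1e-9 rad — this exactness property is the generator's core
correctness oracle and is asserted in the tests.

The double/triple mix defaults to 0.26/0.74 and per-species event counts
default to 88k/74k/41k/45k (14N/12C/15O/16O), mirroring the published
coincidence statistics.

Deliberately not modelled (and therefore not demonstrated by passing
tests): Klein–Nishina angular weighting (available behind a flag),
photon attenuation and secondary scatter in the phantom, Doppler
broadening, background and annihilation contamination (a
``background_fraction`` flag injects 511 keV photons purely to exercise
the window rejection), detector efficiency versus energy,
timing/coincidence electronics.  Because every
emitted photon is importance-directed at the camera (the first vertex is
drawn inside stage 1), the per-origin detection probability is constant:
the depth density of detected-event origins equals the emission density,
and no solid-angle falloff with depth exists.  On real data the
uniform-sensitivity assumption of the reconstruction would have to be
revisited.

## Reconstruction: ordered origin ensembles with resolution recovery

The ensemble keeps one candidate origin per event, constrained to that
event's cone, and evolves by Metropolis moves.  For event `n_l` currently
in voxel `i`, a new point is proposed on its (resolution-corrected) cone
inside the VOI, in voxel `j`, and accepted with probability
`min(1, (c_j + 1) eps_i / (c_i eps_j))`, where `c` are per-voxel origin
counts and `eps` voxel sensitivities (uniform here, consistent with the
generator's uniform detection probability).  One *sweep* visits all `N`
events once in stored order; a stochastic order is available behind
`event_order="random"` for the ordered-vs-stochastic comparison.  The
output image is the post-burn-in mean of the count field (default
burn-in: half the sweeps; `burn_in = n_sweeps - 1` gives a last-state
image).

Variants map onto correction policies:

| variant      | position resampling | energy resampling | pre-calculated init |
|--------------|----------------------|-------------------|---------------------|
| `soe`        | –                    | –                 | –                   |
| `oerr`       | ✓                    | –                 | –                   |
| `oerr_e`     | ✓                    | ✓                 | –                   |
| `oerr_e_pre` | ✓                    | ✓                 | ✓                   |

Per Markov step the resolution-recovery variants redraw interaction
positions uniformly over the pixel footprint (`±D/2` transversally,
`±delta_iz/2` in depth, clipped to the crystal) and the first two
deposited energies from `N(E_i, sigma(E_i))` with sigma evaluated at the
measured energy (the `sigma(E) ≈ sigma(E_true)` approximation, applied
literally).  The third deposit of a triple is never redrawn — it does
not enter the energy recovery — so a triple consumes 9 position + 2
energy draws and a double 6 + 2, matching the published correction
counts.  Negative energy draws are redrawn (≤100 tries) rather than
truncated-renormalized; at PG energies the probability is negligible so
the bias is immaterial.  A resample with invalid kinematics (cos beta
outside [-1, 1], degenerate geometry) makes the step a rejection and the
event keeps its origin.

### Initialization

`oerr_e_pre` pre-calculates the initial ensemble: `k` (default 8)
candidate points per event are drawn on corrected cones, a provisional
density map is built from all `k·N` candidates, and each event starts at
one of its own candidates drawn with probability proportional to the
density in the candidate's voxel (uniform among candidates when all
densities vanish; `init_strategy="uniform"` disables the density
weighting).  Other variants initialize with `k = 1` from measured cones,
which reduces to plain random initialization.  Events with no valid
in-VOI candidate after bounded retries are dropped and counted in the
diagnostics.

### Cone sampling measure

"Uniformly on the conical surface inside the VOI" is implemented with
respect to the cone's surface-area element: an azimuth is drawn
uniformly, kept by rejection with probability proportional to the in-VOI
chord's area weight `t_hi^2 - t_lo^2` (bounded by the squared apex
distance to the farthest VOI corner), and the distance along the chosen
generatrix follows the area element.  An earlier chord-uniform variant
(azimuth uniform over the visible arc, then uniform on the chord) is
retained as `surface_measure="chord"` for sensitivity analysis only: it
weights short corner-grazing chords by the inverse of their length, and
the `c_v!` clustering dynamics amplify that into condensation of
ensemble mass onto VOI faces and corner columns.

### VOI

The default VOI is the measurement plane itself: a single-bin-thick
1 mm slab in the beam plane, clipped to the phantom cross-section
(y ∈ [-50, 50), z ∈ [0, 200) for the small phantom).  Two properties
motivated this default over a volumetric grid:

* occupancy — with ~45–90k events, a 1 mm volumetric grid leaves ~0.3
  events per voxel and the `(c_j + 1)/c_i` clustering force is then too
  weak to equilibrate in 100 sweeps (the distal 50% falloff stayed ~2 mm
  heavy); the planar grid restores occupancy ≈ 1–2;
* physicality — candidate origins must lie inside the phantom.  On a
  slab wider than the phantom, cone-tangency rims in the unphysical
  region attract ensemble mass and distort the central-row profile.

A volumetric preset (`VOIGrid.volumetric()`) is available for 3-D
reconstructions, with the caveats above.

### Backends, RNG, determinism

The sweep and initialization inner loops are numba-compiled; a pure
python backend with identical chain logic (and test hooks for proposal
override, forced acceptance and visit tracing) runs the enumerable toy
chains in the test suite and small problems.  One seed drives a run;
independent substreams are derived for the initialization kernel, the
sweep kernel and the initialization selection, so changing `k` does not
perturb the sweep randomness.  Identical (events, config, seed) give
bit-identical images per backend.

## Measurement protocol

Images are projected along the camera axis, smoothed with a 2.0 mm FWHM
separable Gaussian (reflective boundary; mass preserved — the governing
contract the boundary rule was chosen for), and profiles are taken along
the central beam row and transversally through the along-beam peak.
Profiles are normalized to max 1; the peak is the first value-1 sample
(plateau ties break to the shallowest position); the 80%/50% distal
falloffs are the first interpolated downward crossings beyond the peak
("distal" = larger depth); the width at 80% spans the outermost
0.8-crossings bracketing the peak, using smoothed profiles throughout.
Repeated-seed results are summarized as mean ± sample SD.

## Problem sizes and known limitations

The accuracy studies use the full default study conditions: 45k (16O)
and 88k (14N) events, 100 ordered sweeps, k = 8, 1 mm planar VOI, three
seeds.  Unit and property tests use reduced sizes (hundreds to a few
thousand events, tens of sweeps) chosen so each test isolates one
property.

Known limitations:

* The acceptance rule leaves the proposal density uncorrected (that is
  how the algorithm is defined), so the stationary law over event
  assignments is the proposal-weighted `∏_v c_v!`.  On concentrated
  Bragg-peak-like sources this is benign — the 6.13 MeV study recovers
  both distal falloffs to well under 1 mm — but on broad, line-like
  sources the factorial clustering amplifies the profile's peak relative
  to its plateau.  A controlled experiment isolates this: running plain
  SOE on *blur-free, unquantized* 2.31 MeV events (cones exact) still
  reconstructs the 80% distal falloff ~3 mm proximal of truth on some
  seeds, while the same pipeline on the 6.13 MeV line is sub-millimetre.
  Because the broad profile crosses the 0.8 level on a ~0.05/mm slope, a
  few-percent amplitude distortion moves that crossing by millimetres;
  the per-seed spread of the 2.31 MeV falloff estimate is accordingly
  1–3 mm (mirroring the multi-millimetre repeat SD published for this
  line), whereas its 3-seed mean error is much smaller.
* Peak positions of broad profiles are ill-conditioned outright (errors
  of several mm while the distal falloffs remain the useful
  observables).
* The simulator's idealizations above mean the accuracy numbers bound
  the algorithm under clean Compton kinematics, not detector reality.
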