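# Methods

## Scope and intent

`sloshsim` is a reduced-order (1-D, multi-coaxial-tube) surrogate of a 3-D
transient fluid–structure model of the canine spinal canal. It is built to
reproduce the *structure* of the classic slosh experiment — which anatomical
configurations are run, how the epidural excitation is applied, and how
stress statistics are reduced — and the *qualitative* mechanics: pressure
transmission, syrinx/SAS pressure locking, fluid–cord velocity differentials,
and the localized stress concentrations at syrinx ends. Absolute 3-D stress
magnitudes are reproduced only in order of magnitude, through a single
calibrated scale factor (below).

## Geometry

All compartments are circular and coaxial. The axial grid spans
[−15, 340] mm at 1 mm spacing; x = 0 is the cranial end of the 285 mm syrinx
region, and the cranial 15 mm extrusion keeps the end constraint away from
the region of interest. The syrinx region is divided into 28 segments
(27 × 10 mm + one caudal 15 mm); each segment is either fluid or cord
tissue. Station occupancy uses closed segment extents, so `S8` occupies
exactly [70, 80] mm and the fully developed cavity [0, 285] mm.

Because no subject-specific radius table is distributed, the default
anatomy is synthesized by shape-preserving (PCHIP) interpolation through a
small anchor table: cord radius 3.0 mm at x = 0 (cervical bulge), 2.6 mm at
140 mm (thoracic narrowing), 2.8 mm at 285 mm (mild lumbar widening),
tapering to 2.0 mm at the caudal terminus; the dura sits a uniform 1.5 mm
SAS gap outside the cord, with a 1 mm shell. Users can substitute measured
radii via a four-column CSV (`load_anatomy`). The "MRI-like" maximum syrinx
envelope is ~0.7 × cord radius modulated by a gentle window (0.85 at the
cavity ends, 1.0 mid-syrinx): a fully developed syrinx in an affected dog
fills most of the cord along its entire length, so the envelope stays
substantial even cranially. Isolated syringes `S_i` instead use a fixed
70 % radius ratio.

Region labels (C/T/L) use half-open bounds at 85 mm and 230 mm: segment 8
(70–80 mm) sits at the cervico-thoracic junction, and lumbar behaviour
emerges once a cavity passes ~250 mm.

## Governing equations

Three coupled 1-D subsystems on a staggered grid (pressures, areas, cord
displacement at cell centers; axial velocities at faces): SAS fluid, syrinx
fluid, and the cord as an axially elastic immersed rod. The README lists
the equations; the physically load-bearing choices are:

* **Tube laws.** The syrinx/cord annulus compliance `C_f` is the
  thick-walled Lamé solution, plane-strain by default (the cord is axially
  constrained); the plane-stress variant is selectable. The wall compliance
  `C_w` combines the thin-walled dura shell with the epidural fat layer in
  series and acts only on the excitation span — elsewhere the canal is rigid
  (vertebrae). The fat is nearly incompressible (ν = 0.4999) and radially
  confined, so its effective stiffness is the constrained (P-wave) modulus
  E(1−ν)/((1+ν)(1−2ν)) ≈ 1.67 MPa rather than its 1 kPa Young's modulus;
  with the bare modulus the implied venous injection would be tens of
  millilitres instead of the physiological ~0.1–0.3 mL.

* **Cord–pressure coupling.** The SAS area budget contains the cord's
  Poisson term 2ν A_c ∂w/∂x *and* the taper-advection term w dA_c/dx (an
  axially sliding tapered rod changes the local solid cross-section). The
  cord momentum equation carries their exact discrete adjoints,
  −2ν A_c ∂p_s/∂x + (1−2ν) p_s dA_c/dx, making the pressure–cord energy
  exchange conservative. This is essential: with the Poisson term alone the
  quasi-static axial stress scales as 2νp (~6 kPa) and cord velocities come
  out orders too large; the complete pair leaves the deviatoric (1−2ν)p
  scale (~10² Pa) that a von Mises measure sees.

* **End-cap forcing.** The syrinx rest area tapers to zero over one grid
  cell at each cavity end; the transmural force (p_f − p_s) dA_f0/dx is
  therefore concentrated at the termini. This is the discrete carrier of
  the slosh mechanism.

* **Boundary conditions.** Closed canal: u_s = 0 at both ends, u_f = 0 at
  cavity termini, cord pinned axially at both ends. The pins are applied at
  the boundary *faces* via mirror ghosts (w_ghost = −w_edge), which keeps
  the Dirichlet treatment second-order and matches the face-zero convention
  of the continuity coupling; pinning boundary centers leaves an O(Δx)
  boundary layer that spoils grid convergence of the peak-stress map.

* **Drag.** Poiseuille-type coefficients D_f = D_s = 8πμ. SAS drag is
  referenced to the fixed outer wall; syrinx drag acts on the relative
  velocity u_f − v_c with the full reaction on the cord. The discrete drag
  exchange uses one array with opposite signs on the two sides, so momentum
  bookkeeping is exact by construction (asserted in tests).

* **Body force.** None: the recumbent configuration is simulated and
  gravity never enters.

## Numerics

Explicit staggered (leapfrog-type) integration: velocities kick from old
pressures/displacements, then pressures update from a local 2 × 2
continuity/tube-law solve per station, then displacement drifts with the
new velocity. Time step Δt = 0.5 Δx / c_max, where c_max spans the
artificial-compressibility sound speed √(K_a/ρ), the (pressure-stiffened)
cord bar speed and the Korteweg speeds of both tubes; at defaults
Δt ≈ 5 × 10⁻⁶ s. Drag is handled semi-implicitly, which preserves exact
linearity in the excitation amplitude (asserted to ≤ 10⁻⁶ relative;
measured at machine precision).

Parameters that matter, with defaults:

| parameter | default | role |
|---|---|---|
| `K_a` (artificial bulk modulus) | 10⁷ Pa | storage regularizing the closed, nearly incompressible system |
| `artificial_viscosity` | 0.25 (× c_max Δx) | linear bulk viscosity damping grid-scale dispersive ringing |
| `cfl_safety` | 0.5 | time-step fraction of the CFL bound |
| `dx_mm` | 1 mm | grid spacing, aligned with the 1 mm slice statistics |
| `duration_s` | 0.4 s | pulse (0.2 s) plus equal follow-on |
| `output_stride_s` | 1 ms | field storage stride; running stress maxima update every step |
| `fat_thickness_mm` | 1 mm | fat share of the wall compliance |
| `gamma` | 3.135988525 | calibrated stress scale (see below) |

`K_a` = 10⁷ Pa is chosen so peak axial CSF velocities land at the observed
10⁻³ m/s order (at 10⁶ Pa the artificial storage dominates the canal and
inflates flows tenfold). The reported peak slice-median stress is *not*
insensitive to K_a at this default — doubling K_a raises the baseline peak
by ~11 %, saturating toward the incompressible limit (< 5 % change per
doubling only above ~4 × 10⁷ Pa, where runs are 2.5× slower and velocities
fall below the observed order). This trade-off is a known limitation of the
closed-canal closure and is documented rather than hidden.

The volume audit checks, at output times, that the wall volume injected by
the excitation equals compressibility storage plus the cord strain volume;
the discrete scheme satisfies this to ~10⁻⁷ of the peak injected volume
(criterion: < 1 %). Halving Δx (and hence Δt) changes the baseline
peak-stress profile by < 1 % in max-norm.

## Stress measure and calibration

The 3-D von Mises reduction is mirrored exactly in structure: per-element
peak over time (running maxima, independent of the output stride), 1 mm
half-open slices, slice value = median of element peaks, and the summary
parameters σ_max (peak slice value over the syrinx extent ± 5 mm window,
ties broken cranially) and Δσ (default: maximum pointwise excess over the
baseline profile within the window; the at-σ_max-location variant is
selectable). The underlying element measure is the scaled axial elastic
stress s = γ |E ∂w/∂x|.

γ is fixed once by `calibrate()`: run the baseline with γ = 1 and scale so
the peak slice-median lands at the midpoint (270 Pa) of the 180–360 Pa
band, the order of magnitude a healthy cord shows under a 6 kPa epidural
pulse. γ multiplies only the reported stress, never the dynamics, so every
relative and qualitative result is calibration-independent; calibration is
idempotent by linearity.

## What the synthetic anatomy does and does not emulate

It reproduces smooth cranio-caudal radius profiles with the correct nesting,
the segment bookkeeping, the 70 % radius ratio, and a plausible cervical
bulge / thoracic narrowing. It does not reproduce subject-specific radii
(the real table is not distributed), non-circular cross-sections, vertebral
anatomy, or the true caudal termination of the cord — the model terminus at
x = 340 mm with its axial pin produces a local stress riser where the cord
tapers, which is an artifact of the truncation, not of the slosh physics.
Passing tests therefore demonstrate the mechanism and the pipeline, not
patient-specific stress values.

## Known limitations

* 1-D surrogate: no radial inertia, no shear stress, no ALE advection, no
  3-D von Mises assembly; absolute stress magnitudes carry meaning only
  through the single calibrated scale.
* The caudal-terminus stress riser couples weakly to distant syringes
  through the global axial force balance of a pinned–pinned rod: a cervical
  syrinx *lowers* the terminus peak by up to ~12 %. The stress *increase*
  remains strictly confined to the syrinx vicinity (< 10 % of the baseline
  maximum outside ± 20 mm, verified for all 28 single-syrinx runs), but a
  two-sided deviation bound at 10 % is marginally exceeded at the terminus
  for mid-cervical cavities.
* K_a sensitivity as described above.
* The epidural venous "airbag" of the reference workflow is replaced by a
  prescribed external pressure acting through the wall compliance; the
  injected blood volume becomes a derived output (the volume audit), not an
  input. This preserves the transmitted waveform, which is the quantity the
  experiment interrogates.
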