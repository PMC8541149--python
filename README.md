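# sloshsim

A reduced-order, fully deterministic simulator of cerebrospinal-fluid (CSF)
"slosh" dynamics in the canine spinal canal, built to study how a transient
epidural venous pressure pulse — the kind produced by a Valsalva-like event
such as a cough or a bark — loads the spinal cord when fluid-filled cavities
(syringes) are present inside it. Syringomyelia, the disorder in which such
cavities form and grow, is extremely common in Cavalier King Charles
spaniels with Chiari-like malformation, and the *slosh hypothesis* holds
that impulsive axial movement of syrinx fluid hammers the cavity ends and
drives its expansion.

The package is aimed at biomechanics researchers who want a tractable,
scriptable counterpart to full 3-D fluid–structure models of the spinal
canal: it reproduces the canonical in-silico experiment — 57 model
configurations covering a syrinx-free cord, 28 isolated small syringes
`S1..S28`, and 28 stages of a cranially seeded, caudally expanding syrinx
`S1-1..S1-28` — in minutes on a laptop.

## Model

The canal is a set of nested circular compartments along a cranio-caudal
axis `x` (`x = 0` at the cranial end of the 285 mm syrinx region): syrinx
fluid inside the spinal cord, CSF in the subarachnoid space (SAS) between
cord and dura, and the dura as a 1 mm elastic shell. Collapsing the
cross-sections onto 1-D gives, per unit length,

```
(A_s0/K_a) ∂p_s/∂t + ∂a_s/∂t + ∂(A_s0 u_s)/∂x = 0        SAS continuity
ρ A_s0 ∂u_s/∂t = −A_s0 ∂p_s/∂x − D_s u_s                  SAS momentum
(A_f0/K_a) ∂p_f/∂t + ∂a_f/∂t + ∂(A_f0 u_f)/∂x = 0        syrinx continuity
ρ A_f0 ∂u_f/∂t = −A_f0 ∂p_f/∂x − D_f (u_f − v_c)          syrinx momentum
ρ_c A_c ∂v_c/∂t = ∂(E A_c ∂w/∂x)/∂x + (p_f − p_s) dA_f0/dx
               + D_f (u_f − v_c) − 2ν A_c ∂p_s/∂x + (1−2ν) p_s dA_c/dx
a_f = C_f (p_f − p_s)
a_s = −a_f + 2ν A_c ∂w/∂x + w dA_c/dx − C_w (p_ext − p_s)
```

with tube-law compliances `C_f` (thick-walled Lamé annulus of cord around
the syrinx) and `C_w` (thin-walled dura shell in series with the confined
epidural fat, nonzero only where the epidural veins act, x = 205–325 mm).
The epidural pulse is `p(t) = 3000·[1 − cos(10πt)]` Pa for `t < 0.2 s`
(peak 6000 Pa ≈ 45 mmHg) and zero afterwards. The von Mises stress of the
3-D problem is surrogated by a calibrated axial measure
`s(x,t) = γ |E ∂w/∂x|`; γ is fixed once so the syrinx-free baseline's peak
1 mm slice-median stress sits at the midpoint of the 180–360 Pa band.
All cross-coupling terms are exact discrete adjoints of one another, so the
explicit staggered (leapfrog-type) scheme conserves the pressure–elastic
energy budget; a volume audit verifies conservation at run time.

## Worked example

```python
import sloshsim as ss

anatomy = ss.synthesize_anatomy()            # smooth MRI-like radii, 1 mm grid
params = ss.default_params()                 # Table-style constants + calibration

for name in ("baseline", "S8"):
    result = ss.run_config(name, params, anatomy)
    coeffs = ss.derive_coefficients(
        params.materials,
        ss.apply_pattern(anatomy, ss.SyrinxPattern.from_name(name)),
        params.numerics,
    )
    profile = ss.slice_medians(ss.peak_stress_map(ss.peak_stress(result, coeffs), result.x_mm))
    print(name, f"peak slice-median stress {profile.value_pa.max():.1f} Pa")
```

prints

```
baseline peak slice-median stress 270.0 Pa
S8 peak slice-median stress 350.3 Pa
```

The baseline (syrinx-free) cord peaks at 270 Pa — inside the sub-360 Pa
band expected for a healthy cord under a 6 kPa epidural pulse. Introducing
a single 10 mm syrinx at x = 70–80 mm (`S8`, radius 70 % of the cord's)
raises the local peak by roughly a third while leaving the rest of the cord
essentially untouched: the stress increase is confined to the immediate
vicinity of the cavity, the signature by which the slosh mechanism promotes
expansion of small, isolated syringes.

The full study runs from the shell:

```
sloshsim suite --out results/study        # all 57 configurations
sloshsim report --results results/study   # shaded-baseline figures, bar charts
```

producing `singles_table.csv` (σ_max, Δσ and percent increase for each
isolated syrinx), `expansion_table.csv` (location of the stress peak versus
the advancing caudal end of the expanding syrinx) and per-run HDF5 field
histories.

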