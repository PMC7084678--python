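# lamdiff

1D lamellar neutron-diffraction analysis for oriented lipid multilayers:
Bragg-peak reduction, D₂O contrast-variation phasing, Fourier
reconstruction of the neutron scattering length density (NSLD) profile,
and extraction of the Luzzati bilayer structural parameters — together
with a synthetic forward model that makes the whole chain verifiable
end-to-end without instrument data.

## Who this is for

Membrane structural biologists and neutron-scattering practitioners who
measure stacked bilayers (e.g., archaeal-type diphytanyl phospholipid
multilayers on silicon wafers under controlled humidity and temperature)
and want a scripted, reproducible route from 1D diffractograms to the
numbers that characterize a bilayer: the lamellar repeat *D*, the
Gibbs–Luzzati bilayer thickness *D_B*, the hydrophobic core thickness
*2D_c*, the water layer thickness *D_w*, the area per lipid *A*, and the
hydration number *n_w*.

## The method

A stack of centrosymmetric bilayers diffracts at `q_n = 2πn/D`. The NSLD
profile across one unit cell is the truncated Fourier cosine series

    ρ(z) = (2/D) Σₙ ν_n |f_n| cos(2πnz/D),        ν_n ∈ {−1, +1}

where the amplitudes come from Lorentz-corrected integrated Bragg
intensities, `|f_n| = √(I_n · q_nᵖ)` with `p = 1` for oriented samples
(configurable). The signs ν_n — the phase problem — are solved by
contrast variation: measuring at several H₂O/D₂O ratios makes each signed
`f_n` an affine function of the D₂O fraction, and the slope vector is the
cosine transform of the interbilayer water distribution, a smoothed slab
at the unit-cell boundary. Fitting that slab model to the measured slopes
orients every order absolutely (heavy water raises the water SLD, fixing
the direction). From the reconstructed profile, Gaussian fits to the two
headgroup maxima give `D_B`, and the Luzzati relations

    D_w = D − D_B,   A = 2V_l/D_B,   2D_c = 2V_c/A,   n_w = A·D_w/(2V_w)

complete the parameter set, with first-order (delta-method) error
propagation and a Monte-Carlo cross-check.

The reduction stage also classifies the mesophase: a single lamellar
series (1:2:3:4), a hexagonal series (1:√3:√4:√7), or two coexisting
lamellar lattices (interleaved series), as encountered when scanning
relative humidity.

## Worked example

```python
import numpy as np
from pathlib import Path
from lamdiff import *

model = BilayerModel()                      # D = 50.4 A, D_B = 37.4 A
acq = AcquisitionModel(noise_scale=1.0, seed=42)
outdir = Path("demo"); outdir.mkdir(exist_ok=True)
fractions = [0.08, 0.20, 0.50, 1.00]
files = []
for x, d in zip(fractions, synthesize_contrast_series(model, fractions, acq)):
    path = outdir / f"x{int(100 * x):03d}.dat"
    write_diffractogram(d, path)
    files.append(str(path))

cfg = RunConfig(conditions={"RH100": files}, outdir="demo/out", seed=42)
result = run_condition(cfg, "RH100")
p = result.parameters
print(f"phase class : {result.phase_class}")
print(f"D    = {p.D:6.2f} ± {p.D_se:.2f} A")
print(f"D_B  = {p.D_B:6.2f} ± {p.D_B_se:.2f} A")
print(f"2D_c = {p.two_Dc:6.2f} ± {p.two_Dc_se:.2f} A")
print(f"D_w  = {p.D_w:6.2f} ± {p.D_w_se:.2f} A")
print(f"A    = {p.A:6.2f} ± {p.A_se:.2f} A^2")
print(f"n_w  = {p.n_w:6.2f} ± {p.n_w_se:.2f}")
```

prints

```
phase class : lamellar
D    =  50.40 ± 0.00 A
D_B  =  37.56 ± 0.01 A
2D_c =  31.53 ± 0.00 A
D_w  =  12.84 ± 0.01 A
A    =  74.54 ± 0.01 A^2
n_w  =  15.95 ± 0.01
```

The generator's ground truth is `D = 50.4 Å` and `D_B = 37.4 Å`: the
repeat distance is recovered essentially exactly from the peak positions,
while `D_B` lands ~0.4% high because a four-order Fourier synthesis
shifts the headgroup maxima slightly (truncation, not noise). The phase
vector determined from the four contrasts is (−, −, +, −). Statistical
uncertainties are small at this counting level; the truncation bias
dominates.

The same chain is available from a shell:

```sh
lamdiff simulate --out demo --seed 42
lamdiff reduce demo/x008.dat
lamdiff phase demo/x*.dat
lamdiff reconstruct demo/x*.dat --out profile.txt
lamdiff params profile.txt --d-spacing 50.4
```

## Layout

| module | contents |
| --- | --- |
| `lamdiff.synthetic` | bilayer forward model, water SLD, closed-form form factors, diffractogram generator |
| `lamdiff.io` | ASCII diffractogram / profile / truth-sidecar formats |
| `lamdiff.reduction` | background subtraction, Gaussian peak fitting, lattice indexing, phase classification |
| `lamdiff.phasing` | Lorentz correction, contrast-variation sign determination |
| `lamdiff.reconstruction` | Fourier synthesis of the NSLD profile, truncation diagnostics |
| `lamdiff.parameters` | Luzzati parameter chain with error propagation |
| `lamdiff.pipeline` / `lamdiff.cli` | multi-condition orchestration, reports, command-line interface |

See `docs/methods.md` for the model assumptions, parameter defaults, and
numerical choices.
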