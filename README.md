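# budscale

Quantitative tooling for growing **macroscopic engineered living materials
(ELMs)** in orbitally shaken flasks. Centimetre-scale materials made by
matrix-secreting engineered bacteria (e.g. *Caulobacter crescentus*
displaying a self-interacting surface-layer fusion protein) assemble at the
air–water interface of a shaken culture; whether the pellicle collapses into
one large piece or fragments into debris is controlled almost entirely by the
flask geometry, fill volume and shaking speed. `budscale` implements the
composite hydrodynamic predictor of that outcome, the inverse design of
culture conditions, and the two image-analysis pipelines used to quantify the
result — with seeded synthetic-data generators so everything is testable
without lab data.

Intended users: bioprocess and biomaterials researchers scaling ELM cultures
between flask sizes, and anyone needing a reproducible, deterministic
re-implementation of the apparent-size and mask-overlap measurements.

## The model

For a flask of inner diameter *d* (m), orbit diameter *d₀*, fill volume
*V_L* (m³) and shaking frequency *n* (s⁻¹), with medium density ρ, apparent
viscosity η_app, kinematic viscosity ν, O₂ diffusion coefficient *D* and
gravity *g*:

```
Re   = ρ n d² / η_app
Ne′  = 70 Re⁻¹ + 25 Re⁻⁰·⁶ + 1.5 Re⁻⁰·²          (modified Newton number)
P/V_L = Ne′ ρ n³ d⁴ / V_L^(2/3)                   (volumetric power input, W/m³)
k_La = 0.5 d^(73/36) n d₀^(1/4) V_L^(−8/9) D^(1/2) ν^(−13/54) g^(−7/54)   (s⁻¹)

P_V,A = d⁵ · k_La · (P/V_L)                        (modified volumetric power)
```

`P_V,A` is reported in mW·m²/s. Material size is maximal inside an
intermediate band of `P_V,A` (default classification band **0.72–1.65
mW·m²/s**, boundaries inclusive): below it the pellicle fragments without
collapsing, above it shear keeps pellicles small. Because `P_V,A` is strictly
monotone in both *n* and *V_L*, bisection inverts the model exactly — that is
how conditions for a new flask size are designed.

The two measurement pipelines are:

* **apparent size** — segment the blue channel of a flask-bottom photograph
  into background / scattered / bundled material, calibrate pixels to cm via
  the flask rim, and summarise each image as the mean area of the bundled
  pieces in the top five percentile of per-piece area;
* **matrix overlap** — threshold a cell channel and a stain channel, close
  their union into a region of interest (ROI), and report
  `100 · |stain ∩ (ROI \ cells)| / |ROI \ cells|`, the stained percentage of
  the cell-free matrix.

## Worked example

```python
from budscale import (CultureConditions, DesignQuery, VesselGeometry,
                      classify_regime, modified_volumetric_power, solve_frequency)

# reference bench condition: 250 mL Erlenmeyer (d = 8.5 cm), 80 mL, 250 rpm
cond = CultureConditions.from_practical(0.085, 80.0, 250.0)
h = modified_volumetric_power(cond)
print(f"Re = {h.reynolds:.0f}, Ne' = {h.newton_mod:.4f}")
print(f"P/V_L = {h.power_per_volume:.1f} W/m3, kLa = {h.kla:.3f} /s")
print(f"P_V,A = {h.pva_milli:.3f} mW.m2/s -> {classify_regime(h.pva_milli)}")

# design: what rpm puts a 500 mL flask (d = 10.5 cm, 160 mL) mid-band?
sol = solve_frequency(DesignQuery(VesselGeometry(0.105), target_pva=1.185,
                                  fixed_fill_volume=1.6e-4))
print(f"solve: {sol.value * 60:.1f} rpm -> {sol.achieved_pva:.3f} mW.m2/s ({sol.regime})")
```

prints

```
Re = 37608, Ne' = 0.2292
P/V_L = 464.2 W/m3, kLa = 3.222 /s
P_V,A = 6.635 mW.m2/s -> high
solve: 115.9 rpm -> 1.185 mW.m2/s (optimal)
```

So the 80 mL / 250 rpm bench condition sits well above the optimal band
(expect many small pieces), and shaking a 160 mL culture in a 500 mL flask at
about 116 rpm lands exactly mid-band.

The same operations are available from the shell:

```bash
budscale pva --conditions conditions.csv --out annotated.csv
budscale design --diameter 0.105 --volume-mL 160 --target-pva 1.185 --solve rpm
budscale size --manifest images.csv --out sizes.csv
budscale coloc --manifest stains.csv --out overlap.csv
budscale fit-range --data sizes_conditions.csv --out fit.json
budscale simulate conditions --seed 42 --out sim/
```

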