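# thrombosim

3D multiscale simulation of thrombus growth under flow with
single-platelet resolution.

When a vessel wall is injured, platelets adhere to exposed collagen,
activate through rising intracellular calcium, release the soluble
agonists ADP and thromboxane A2, and — where wall tissue factor (TF)
drives the coagulation cascade — are further stimulated by thrombin.
The growing aggregate obstructs the blood flow that feeds it.
`thrombosim` models this loop at the resolution of individual platelets
for researchers studying platelet function, antiplatelet drugs, and
thrombosis in channel, vessel, and stenosis geometries.

Four coupled solvers share one cubic lattice (spacing `h` ~ one
platelet):

| piece | model |
|---|---|
| blood flow | steady incompressible Navier-Stokes over the evolving clot (lattice Boltzmann D3Q19, no-slip on walls and bound platelets; constant-flow or constant-pressure-drop boundaries) |
| agonist transport | convection-diffusion-release for ADP/TXA2 (conservative upwind finite volume), exponential per-platelet granule release once activation crosses a threshold |
| platelet signaling | per-platelet calcium trace from agonist exposure (pluggable model; a phenomenological surrogate ships), activation integrals `xi`, `xi_dt` and Hill-normalized integrin activation `F` |
| coagulation | reduced 8-ODE cascade in a well-mixed 15-um thin film over the TF patch (effectiveness-factor-scaled Michaelis-Menten network, 2-s thrombin elution half-life) |
| platelet motion/bonding | rejection-free lattice kinetic Monte Carlo; convective + diffusive motion rates, shear-dependent attachment/detachment with VWF enhancement `E(gamma)` and Bell breakage `G(gamma)`, marginated inlet injection |

Key closed forms (shear rate `gamma` in 1/s):

```
E(gamma) = 1                         gamma <= 3000
           1 + 19 (gamma-3000)/5000  3000 < gamma <= 8000
           20                        gamma > 8000

G(gamma) = exp(gamma/gamma_c)                      gamma <= 1000
           exp(1000/gamma_c) exp(gamma/gamma_c')   gamma > 1000

F(theta) = alpha_min + (alpha_max - alpha_min) theta^n / (theta^n + theta_50^n)

attach:  k_att F(xi) F(xi_dt) E(gamma)        (collagen; geometric mean over pairs)
detach:  k_det G(gamma) / (F(xi) F(xi_dt) E(gamma))
```

See `docs/methods.md` for the full model description, parameter
provenance, and the limits of the desk-scale test world.

## Worked example

```bash
thrombosim run channel_200 --seed 1 --t-end 120 --out out/
```

runs the microfluidic scenario (about 15 min on one CPU): a 500 x 250 x
60 um channel, collagen + TF patch on the floor, constant inlet wall
shear 200 1/s.  Output:

```
final bound platelets: 5058
outputs in out/
```

meaning 5058 platelets are bound in the aggregate on the patch after
120 s of perfusion.  `out/metrics.csv` holds the time series; its last
row for this run,

```
t_s,bound_platelets,mobile_platelets,Q_uL_min,film_thrombin_nM,injected,exited,discarded
120.000,5058,64,1.55379,11.0038,49108,43986,12774
```

says that at t = 120 s the clot holds 5058 platelets with 64 still in
transit, the (constant-flow) inlet rate is 1.55 uL/min, and film
thrombin has climbed to 11 nM; 49108 tracked platelets entered, 43986
washed out.  `out/clot_final.vtk` (legacy ASCII VTK) and
`out/platelets_final.h5` hold the final clot for rendering.  Platelets
near the patch activate first (collagen, then thrombin in the 15-um
film), start releasing ADP/TXA2 after roughly a minute, and recruit a
shell of less-activated platelets; growth is biased toward the upstream
patch edge.

The same interface runs vessels and stenoses, e.g.

```bash
thrombosim run stenosis_75 --seed 1 --out out75/           # occlusive growth
thrombosim run stenosis_75 --no-vwf-enhancement --seed 1   # VWF ablation
thrombosim run channel_200 --treatment no_ADP --seed 1     # MRS-2179 mimicry
```

Python API: build a `SimulationConfig` (or `get_preset(...)`), call
`simulation.run(config)`, and read the returned `SimulationResult`
(metric arrays, final snapshot, clot-height profile, occlusion time).

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch: a platelet-free lattice Boltzmann solve of Poiseuille tube
flow (printing the inlet flow rate for a 60-um vessel at 1000 1/s wall
shear) followed by a coupled desk-scale channel simulation with all
modules active, then writes the results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
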