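# Methods

`thrombosim` simulates thrombus growth under flow at single-platelet
resolution by coupling four solvers on one cubic lattice (spacing
`h`, default 2.5 um, about one platelet footprint): a lattice Boltzmann
(LB) flow solver, a finite-volume (FVM) solver for the soluble agonists
ADP and thromboxane A2, a per-platelet calcium/activation model with a
thin-film coagulation ODE system, and a rejection-free lattice kinetic
Monte Carlo (LKMC) engine for platelet motion and bonding.  This note
records the model equations as implemented, the parameter choices and
their provenance, the numerical decisions, and what the desk-scale tests
do and do not establish.

## Flow

Blood is an incompressible Newtonian fluid (`rho` = 1060 kg/m^3, `mu` =
3.5 mPa s; both configurable).  At microfluidic scales the Reynolds and
Womersley numbers are small, so the flow is quasi-steady: the LB solver
(D3Q19, BGK collision, half-way bounce-back on walls and bound
platelets) is relaxed to steady state after the clot has changed, rather
than time-resolved.  Two boundary conditions are supported: a velocity
inlet carrying the analytic duct/Poiseuille profile scaled to a target
inlet wall shear rate (the constant-flow microfluidic condition), and
fixed inlet/outlet pressures (the physiological constant-pressure-drop
condition, under which occlusion is possible; we fix the total drop).
The solver's contract is the oracle suite — duct and Poiseuille profiles
to <1%, flow rate to <2%, station-to-station mass conservation to <1% —
not the particular scheme.

Shear-rate magnitude is `gamma = sqrt(2 D:D)` from central differences,
with a wall-aware one-sided formula at fluid-solid faces (quadratic fit
through the wall face, exact for locally parabolic profiles).  Wall
shear at a staircase-voxelized curved wall is noisy at individual
voxels; reported throat shear is the median over wall-adjacent voxels
in an axial band, which lands within ~10% of the analytic value at 24
voxels per diameter.

Relaxation time `tau = 1.2` balances convergence speed against
bounce-back wall-position error; convergence is declared when the
relative velocity change per check interval falls below
`convergence_tol` (1e-5 for oracle-grade solves; coupled runs use ~3e-4
with warm-started populations, which re-converge in a few hundred
sweeps after incremental clot growth).

## Agonist transport

ADP and TXA2 obey convection-diffusion-release equations solved with
conservative first-order upwind convection and central diffusion,
explicit in time with automatic sub-stepping to the positivity/CFL
bound.  Transport occurs in the lumen; bound platelets have zero
velocity, so the clot interior is diffusion-only.  Walls are zero-flux,
the inlet carries agonist-free blood, and the outlet is advective
outflow.  Released amounts use the exponential per-platelet source with
total load `M_j` and time constant `tau_j`, triggered irreversibly when
the platelet's activation integral crosses `xi_crit`; mobile activated
platelets remain moving sources.

Defaults: `D_ADP` = 2.4e-6 cm^2/s, `D_TXA2` = 2.1e-6 cm^2/s (classic
small-solute plasma values); `M_ADP` = 2.4e-17 mol/platelet over
`tau_ADP` = 5 s (dense-granule content), TXA2 load 2e-18 mol-equivalent
over 10 s (synthesized de novo, expressed in the same bookkeeping
units); EC50s 1 uM (ADP) and 0.1 uM (TXA2).  With these values the
agonist boundary layer over an active deposit is ~10 um thick and sits
in the 0.1-10 EC50 dynamic range at venous shear, matching the regime
the simulation is designed around.

## Platelet signaling

Each platelet's state is its sampled calcium trace and the activation
integrals

    xi      = integral of max([Ca] - 100 nM, 0) dt        (cumulative)
    xi_dt   = the same over the trailing window Dt = 10 s,

normalized by the Hill function `F` (exponent 2, `theta_50` = 5000 nM s,
bounds `alpha_min` = 0.1, `alpha_max` = 1) into the integrin-activation
factors used by the adhesion laws.  Sub-basal calcium contributes
nothing (the integrand is clipped at zero), keeping `xi` monotone.
Calcium is updated at a fixed 0.5 s signaling step, decoupled from the
KMC event clock; activation factors are frozen within a step.

The calcium model is a plug-in.  The shipped default is a
phenomenological ODE surrogate for a patient-trained neural-network
model that cannot be reproduced (weights and training traces are not
available).  It satisfies the behaviors the simulation depends on:

* basal fixed point at 100 nM with zero agonists;
* saturating drives per agonist (collagen contact flag, thrombin, ADP,
  TXA2 with EC50-normalized Hill inputs);
* "fast-on, slow-off" collagen/thrombin responses via a sustained-drive
  memory variable (onset 4 s, relaxation 120 s) that switches the
  calcium decay rate between 0.2 1/s (transient) and 0.003 1/s
  (sustained) — the post-pulse decay is >5x slower after thrombin than
  after ADP;
* ADP/TXA2 receptor desensitization (0.03 1/s under saturating agonist,
  recovery 0.003 1/s);
* saturating inhibition by iloprost (IP) and GSNO; an infinite
  normalized input suppresses calcium mobilization completely.

Potency weights (thrombin 1.2 > collagen 1.0 > ADP 0.8 > TXA2 0.25) were
calibrated so that (a) a platelet held on collagen crosses `xi_crit` =
1e4 nM s after roughly 30-60 s (the observed ~1 minute lag between
first adhesion and granule release), and (b) ADP removal suppresses
deposition substantially more than TXA2 removal, with iloprost the
strongest inhibitor, reproducing the reported drug-response ordering.
Drug treatments are implemented exactly as in-silico mimicry: `no_ADP`
and `no_TXA2` zero the respective concentration at the calcium-model
input (transport is unchanged); `iloprost` saturates the IP drive;
`no_TF` removes the wall tissue factor (and hence the thin film).

## Thin-film coagulation

Tissue factor on the patch drives thrombin production inside a 15-um
fibrin-rich film over the reactive surface, present from t = 0 and
treated as well mixed with zymogens held at plasma levels.  The reduced
network (8 ODEs) lumps: extrinsic tenase generation from TF, intrinsic
tenase assembly fed by extrinsic tenase and FXIa, prothrombinase
assembly fed by both tenases (with a membrane-site cap), thrombin
feedback activation of FXIa, fibrin generation from fibrinogen, and
thrombin-fibrin binding (sequestration).  Soluble enzymes (free
thrombin, FXIa) elute with a 2-s half-life, the single parameter that
stands in for transport out of the film.  Every reaction carries an
effectiveness factor in (0, 1].  Platelets sample film thrombin only
inside `film_mask`; thrombin is not tracked elsewhere.

The published reduced model's rate constants are not in the available
text, so the constants here are literature-guided defaults owned by the
configuration and calibrated to the qualitative contract: no thrombin
without TF; a sigmoidal rise with >30 s lag (thrombin becomes relevant
only once the film region is filling); tens of nM free thrombin at
steady state (far above the ~1 nM PAR-activation EC50); strong
sequestration by fibrin.  Only the network topology and the integration
contract (stiff-safe LSODA, nonnegativity) are fixed in code.

## Adhesion

The closed-form rate laws combine the activation factors, the
VWF shear-enhancement `E(gamma)` (1 below 3000 1/s, linear to 20 at
8000 1/s, saturated above — the globular-to-stretched VWF transition),
and the Bell-model breakage factor `G(gamma)` (characteristic shear
rates `gamma_c` = 1000 1/s, `gamma_c'` = 4000 1/s).  `G` is implemented
exactly as printed by default, although the printed form jumps by
`exp(1000/gamma_c')` at the 1000 1/s breakpoint; a continuity-corrected
variant is flag-selectable (`G_continuous_variant`) since the
discontinuity looks typographical.  A platelet's local shear is the
maximum over its own and face-adjacent fluid voxels (bound platelets
sit in zero-velocity voxels).

Baseline constants (`k_att` = 2000 1/s for a fully activated platelet,
collagen `k_det` = 0.002 1/s, platelet-pair `k_det` = 0.15 1/s) are
calibration choices with three anchors: an unactivated platelet visiting
the collagen patch at venous shear is captured within a few visits and
resides seconds — long enough to begin calcium mobilization; an
unactivated platelet landing on another platelet detaches in well under
a second unless soluble agonists activate it (this makes second-layer
growth agonist-dependent, which carries the drug-response ordering); at
a 8000 1/s stenotic throat the E and G factors nearly cancel, so capture
is possible with VWF enhancement and negligible without it.

Multiply-bonded platelets: the printed rate laws are per bond (collagen
face, each face-adjacent bound neighbor).  Detachment releases all
bonds at once at the serial-combination rate `1/sum_b(1/Gamma_b)` —
expected bond-breaking times add.  A platelet orphaned by a neighbor's
detachment (no remaining bonds) becomes mobile.

## LKMC engine

Platelets occupy single voxels with hard exclusion.  Motion rates are
the upwind projection of the local fluid velocity plus an isotropic
diffusive rate `D_platelet/h^2` with `D_platelet` = 10 um^2/s
representing RBC-enhanced dispersion (bare Brownian diffusion of a 2-um
sphere would be ~100x smaller).  The direct (rejection-free) algorithm
draws exponential waiting times from the total rate.  The hot loop runs
in a compiled kernel that maintains per-platelet total rates
incrementally (refreshing the neighborhoods touched by each move, with
periodic exact resynchronization of the total); attachment and
detachment events return to Python for bookkeeping.  Tests audit the
incremental table against a full rebuild.

Margination is imposed at injection: Poisson arrivals per inlet voxel
with intensity (axial velocity x voxel area x local concentration),
where the concentration profile is 3x the mean within 5 um of the wall
and the core is renormalized so the flux-weighted mean matches the
prescribed count.  The profile values are choices (the literature
reports near-wall excesses of 2-8x within a few um); both are
configurable.  Platelets crossing the outlet face are removed;
arrivals into occupied voxels are discarded and logged.

## Coupling and metrics

One macro step (0.5 s) advances injection + KMC, then signaling, then
transport, then coagulation; flow is re-solved (warm-started) when the
bound set changed by >= 20 voxels or 1 s elapsed, whichever first — a
config-exposed trigger, since the quasi-steady cadence is a numerical
choice.  Runs terminate at `t_end` or, under a pressure-drop boundary
condition, at occlusion (inlet flow strictly below 5% of its initial
value); occlusion time is linearly interpolated between samples.  The
aggregate-height profile mimics averaged fluorescence line scans: per
axial station, the mean over spanwise lines (that contain deposit) of
the topmost bound voxel height.

Presets cover the standard scenarios: `channel_200` (500 x 250 x 60 um
channel, 250-um collagen/TF patch, 200 1/s), `tube_100` (500 x 60 um
vessel, semicylindrical injury, 100 1/s), and `stenosis_{37,50,63,75}`
(cosine-profile stenosis over the central 250 um — the wall profile
shape is not constrained by the source geometry beyond % area
reduction, so a smooth symmetric bump is used — at constant pressure
drop matching an initial inlet wall shear of 1000 1/s, i.e. initial
throat shears of ~2000/3000/5000/8000 1/s).  Desk-scale presets use a
coarser channel lattice (5 um) and shorter horizons; `--full-scale`
restores 2.5 um and 400-500 s.

## What the desk-scale world does and does not establish

The simulations in the test suite are deliberately scaled down: smaller
patches and cross-sections, horizons of 2-4 minutes, and a tracked
platelet concentration of 2-3e4/uL instead of the physiological
2.5e5/uL (the full-scale problem was designed for parallel clusters).
Within that stated world the suite establishes mechanism-level
properties: analytic flow and transport oracles; exact closed-form
kinetics; calcium-model contracts; the activation gradient between
collagen/thrombin-exposed core platelets and soluble-agonist shell
platelets; upstream-biased venous growth; TF-dependence of deposition;
the drug-response ordering on collagen-only surfaces; and
VWF-dependence of capture at pathological shear.  It does not establish
quantitative clot heights, aggregate counts, or occlusion times at
experimental scale — those depend on the unavailable neural-network
signaling model and supplementary constants, and on physiological
platelet counts.

## Known limitations

* The calcium surrogate is qualitative; patient-specific predictions
  require plugging in a trained model via the `CalciumModel` interface.
* One global film ODE per run (well-mixed film), not per-voxel; no
  thrombin transport outside the film.
* First-order upwind transport is diffusive; boundary-layer thickness
  estimates are resolution-limited near h.
* Platelets are rigid single voxels; no deformation, no multi-voxel
  footprints, no explicit RBCs, no clot remodeling (3D growth makes
  the 2D dendritic artifact largely moot).
* Steady Stokes-regime flow only; no pulsatility or fluid-structure
  interaction.
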