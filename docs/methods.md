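# Methods

## Model

`hepaflow` treats the liver as a zero-dimensional hydraulic network.
Each vessel segment is a straight cylinder in steady laminar Poiseuille
flow (low Reynolds number throughout the hepatic circulation), with
conductance `c = π d⁴ / (128 μ L)`.  Nodes are branch points; volume
conservation at every node plus two inlet boundary rows gives one sparse
linear system in the node pressures and the unknown inlet flows.  The
vena cava is the global pressure reference (0); all reported pressures
are differences against it.

The graph is a union of five stochastic trees — HA and PV inflow, and
RHV/MHV/LHV outflow — wired at the microvascular level.  Each lobule has
one central vein and two portal triads; a triad merges one HA and one PV
terminal vessel and feeds the central vein through three lumped sinusoid
channels (six per lobule).  A lumped sinusoid channel stands for the
local sinusoid capillary mesh, collapsed to one equivalent conductor.
Central veins of segment 1 drain directly to the vena cava through a
terminal-calibre vessel; every other segment drains into one hepatic-vein
tree according to a configurable weight map (defaults below).

### Boundary conditions

* Hepatic artery: fixed pressure difference, 77 mmHg.
* Portal vein, healthy: fixed pressure difference, 5 mmHg.
* Portal vein, cirrhosis: fixed volume flow rate, 820 ml/min, imposed as
  a flow constraint through the PV base edge (the gut cannot down-regulate
  its venous outflow when intrahepatic resistance rises, so a pressure
  condition would be unphysiological).  The PV inlet unknown then equals
  portal plus collateral flow.

### Key parameters

| Parameter | Value | Notes |
|---|---|---|
| Lobule count (full organ) | 5×10⁶ | 6 sinusoid channels each |
| Splitting number HA / PV / HV | 2.76±1.01 / 2.80±0.61 / 3.11±1.46 | integer draws, clamp ≥ 2 |
| Length ratio HA / PV / HV | 4.85 / 5.11 / 5.00 | length = ratio × diameter |
| Base lumen radius HA | 2.2 mm | |
| Base lumen radius PV | 4.9 / 6.4 / 7.2 mm | healthy / early / advanced |
| Base lumen radius RHV / MHV / LHV | 11.7 / 4.0 / 6.5 mm | |
| Terminal lumen radius HA / PV / HV | 2.61 / 67.5 / 75.3 µm | healthy calibration optima |
| Segment volumes (healthy, cm³) | I 28, II–III 242, IV–VIII 1248 | split equally within groups |
| Segment volumes (advanced, cm³) | I 77, II–III 341, IV–VIII 1035 | |
| c⁰_sin | 1.2×10⁻⁵ ml/(min·mmHg) | healthy sinusoid conductance |
| c_sin floor | 1.2×10⁻⁶ ml/(min·mmHg) | applies to configured means |
| c_liver | 176 ml/(min·mmHg) | collateral normalization |
| μ_SM | 0.00134 Pa·s | plasma viscosity |
| Hct | 0.45 | discharge hematocrit |

Internal units are SI; clinical units (mm, mmHg, ml/min) appear only at
configuration and reporting boundaries.

## Tree generation

Trees grow breadth-first: every current leaf branches each round with an
independently sampled integer daughter count (rounded normal draw,
clamped below at 2 so branching cannot stall), until the leaf count first
reaches or exceeds the target terminal count; the excess leaves are then
pruned uniformly at random, together with any ancestors left childless,
so all terminals sit at the realized final depth.  Radii follow the
geometric schedule `r_k = γᵏ r₀` with the exponent taken from the
*realized* depth, so terminal edges sit exactly at the terminal radius —
this is what makes the scale reduction conductance-preserving.  For a
single-terminal tree the one edge carries the base radius.

Lobules are apportioned to the nine Couinaud segments by largest-
remainder rounding of the segment volume fractions (exact to one lobule).
The default segment→vein map sends 6, 7 → RHV; 5, 8 → RHV/MHV at
0.5/0.5; 4a, 4b → MHV/LHV at 0.6/0.4; 2, 3 → LHV; 1 → vena cava.  With
healthy volumes this reproduces outflow shares of about 41/30/26 % for
RHV/MHV/LHV.  The exact triad-to-tree attachment pattern is a documented
convention (terminal vessels of one tree are statistically
exchangeable, so attachment order does not affect organ-level flows).

## Scale reduction

A reduction by factor R divides the lobule count by R, multiplies each
lumped sinusoid edge's conductance by R (the edge now represents R
physical channels; the aggregate sinusoid conductance is preserved to
machine precision), and scales every tree terminal radius by R^(1/3), so
the aggregate terminal-layer conductance (∝ N r³ when length ∝ diameter)
is preserved.  Two distortions remain and are accepted: the apparent
viscosity is evaluated at the inflated terminal diameter, and a reduced
tree realizes fewer branching generations, which lowers its interior
resistance — the calibration below absorbs this.  Velocity and wall
shear stress on multiplexed edges are reported per physical channel.
For extreme toy reductions the rescaled terminal radius is capped at
half the base radius.

## Rheology

Apparent viscosity follows the Pries in-vitro correlation (diameter in
µm): `η_rel,0.45(D) = 220 e^{−1.3D} − 2.44 e^{−0.06 D^0.645} + 3.2`,
generalized to other hematocrits through the curvature exponent `C(D)`,
and `μ_ap = η_rel μ_SM`.  Every tree edge uses the apparent viscosity at
its own diameter.  Lumped sinusoids use the fixed effective viscosity
0.0018 Pa·s (mean of the apparent viscosities at 7 and 15 µm), never
altered when their conductance varies.  The collateral, a macro-vessel,
uses the large-diameter asymptote (≈ 3.2 μ_SM).

## Sinusoid conductance fields

Per segment, channel conductances are i.i.d. log-normal with arithmetic
mean `m = (c_sin/c⁰_sin)·c⁰_sin` and sd `s = (σ/c⁰_sin)·c⁰_sin`; the
underlying normal parameters are the moment match
`μ_ln = ln(m²/√(m²+s²))`, `σ_ln² = ln(1+s²/m²)`.  A Gaussian variant
(resampling the vanishingly rare non-positive draws) and a degenerate
family (healthy, σ = 0) are provided.  Stage defaults per segment group:

| Stage | 6,7 | 5,8 | 1,4a,4b | 2,3 |
|---|---|---|---|---|
| early mean / sd | 0.18 / 0.12 | 0.32 / 0.08 | 0.51 / 0.055 | **0.8** / 0.035 |
| advanced mean / sd | 0.10 / 0.16 | 0.16 / 0.13 | 0.25 / 0.10 | 0.40 / 0.08 |

The early-stage mean for segments 2/3 is not fixed by the reference
data; the default 0.8 (configurable) continues the advanced-row
geometric pattern and yields an early-stage portal pressure of ≈8 mmHg,
consistent with the rest of the early parameterization.  The
1.2×10⁻⁶ ml/(min·mmHg) floor constrains configured means, not individual
draws (portal pressures leave the physiological range below it).

### Sinusoid geometry and wall shear stress

Each lumped channel keeps a fixed reference geometry — diameter and
length derived from c⁰_sin via `c = π d⁴/(128 μ L)` with L/d = 5, giving
d ≈ 8 µm, inside the physiological 7–15 µm sinusoid range.  A sampled
conductance below c⁰_sin encodes microstructural narrowing *inside* that
conduit: velocity uses the fixed cross-section, and wall shear stress
uses the sampled conductance in
`WSS = U (32 π μ³ / (L c))^{1/4}`, so per channel WSS ∝ Δp·c^{3/4}.
This is the only convention that produces the observed segment pattern
(right-lobe WSS fold change < 1 in cirrhosis): re-deriving the diameter
from each sampled conductance instead makes WSS a function of the
channel pressure drop alone (at fixed L/d) or leaves right-lobe fold
changes above 1 (at fixed L).  Consequently the algebraic identity
`WSS ≡ 8 μ U / d` holds for every edge whose conductance is the
Poiseuille value of its own geometry — all edges of the healthy model,
and all non-sinusoid edges in cirrhosis.

## Collateral

One edge from the PV inlet to the vena cava, conductance `c_col`
expressed as a fraction of c_liver = 176 ml/(min·mmHg); default 1%
(1.76), sweep {1.76, 5.57, 17.6, 55.7, 176} (half-decade spacing).  Note
that c_liver is a normalization constant, not Q/Δp of this package's
healthy model (1300/5 = 260); it is retained because the collateral
fractions are defined against it (1.76 × 5 mmHg / 1308.8 ml/min = 0.67%
for the healthy liver).  Nominal collateral geometry is inverted from
c_col for reporting purposes.

## Calibration

The healthy model is calibrated to 1300 ml/min total inflow with
970 ml/min portal (≈75%) under the healthy pressure boundary conditions,
minimizing the sum of squared relative flow errors.  The optimizer is a
seeded derivative-free scheme in normalized log coordinates: a
Latin-hypercube exploration of the bound box (the geometric center —
the published optimum under the default 0.5–2× bounds — is always
evaluated first) followed by bounded Nelder–Mead refinement, within a
50-evaluation budget on one fixed network realization, so repeated runs
with one seed are identical.

Two presets exist.  The general problem frees all four parameters
(terminal HA/PV/HV lumen diameters and c_sin) within 0.5–2× bounds.  The
*reduced-scale* preset (`reduced_scale_problem`) pins c_sin at c⁰_sin —
recalibrating it would detach the cirrhosis tables from their
normalization — and frees only the three terminal diameters with the
lower bracket widened to 0.2×, because a reduced tree's fewer
generations make it intrinsically more conductive at matched terminal
radius, pushing the PV/HV optima below half their full-scale values.
Cirrhosis-stage models reuse the calibrated terminal diameters; their
sinusoid fields always anchor at the printed c⁰_sin.

## Analyses

* **Flow fractions** are percentages of total (liver + collateral) flow;
  HA + PV + collateral and RHV + MHV + LHV + segment-1 + collateral each
  sum to 100%.  PV means the flow entering the liver through the PV base
  edge; the collateral is counted separately.
* **Segment metrics**: segment inflow is the summed flow through its
  sinusoid channels; perfusion divides by segment mass at a tissue
  density of 1 g/cm³; WSS fold changes are against a healthy reference
  solved at the same scale and seeds.
* **Cumulative flow fraction**: channels sorted ascending by conductance
  (stable sort; percentile = rank/count), running flow sum normalized by
  total liver flow.
* **Sensitivity**: all sinusoid conductances are rescaled by 1±0.05 (or
  the field re-drawn with σ rescaled, same seed — common random numbers)
  and the model re-solved under fixed PV inflow; for the healthy stage
  the PV flow is first fixed at its own baseline pressure-BC solution.
  The reported quantity is the percent change of Δp_pv.
* **Collateral sweep**: the collateral conductance is swept at fixed
  stage parameters; the ≈70% shunt fraction at c_col = c_liver refers to
  the advanced stage.

## Numerics

Direct sparse LU (SuperLU) on the CSC system; relative residual
‖Cx − z‖/‖z‖ checked against 10⁻¹⁰ (typically ~10⁻²²).  A singular
system (e.g. a disconnected node) raises a solver error.  Flows are
positive tail→head with edges oriented inlet→sink; reversed flows are
negative.  Zero-flow edges report zero WSS.  Network generation and
sinusoid sampling use separate `numpy` Generators, so builds are
bit-reproducible per seed pair.

## Problem sizes

Calibrated runs and the acceptance script use 20 000 lobules
(≈3.2×10⁵ edges; ~1 s per solve), chosen so stochastic realization
scatter of global flows is well under the tolerance bands; unit tests
use 60–1200 lobules, and realization-variability studies 4000.  The
full-organ spread of global flows across realizations is below 1%; at
reduced scale the corresponding bound scales as √(5×10⁶/lobules).

## What the generator does and does not emulate

The synthetic networks reproduce branching statistics, calibre
schedules, segment volumetrics and lumped sinusoid conductance
distributions — not anatomical 3D geometry, image-derived vasculature,
or the internal topology of the sinusoid mesh (one channel stands for a
whole local network).  Passing tests therefore validate organ-level
hydraulics and distributional behaviour, not patient-specific anatomy.

## Limitations

Steady flow only (no pulsatility, compliance or inertance); no hepatic
artery buffer response; a single ideally-parallel collateral with no
rupture threshold or angiogenesis; no mechanistic fibrosis progression;
log-normality of sinusoid conductance is an assumption, not a measured
distribution; reduced-scale terminal-layer rheology is distorted as
described above.
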