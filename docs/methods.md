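# Methods

## Scope and intent

`rhinoflow` is a reduced-order stand-in for patient-specific nasal CFD: it
keeps the *protocol* (matched trans-nasal pressure drop, calibrated to
250 mL/s postoperatively), the *metric definitions* (unilateral/bilateral
nasal resistance, flow partition, plane-averaged temperature and humidity,
region-resolved sensible and latent wall heat flux), and the *statistical
layer* of the clinical analysis, while replacing the 3-D Navier–Stokes
solve on CT-derived geometry with a one-dimensional duct-network model.
Absolute flux and plane-humidity magnitudes therefore carry the fidelity of
a bulk model, not of resolved wall gradients; the package's quantitative
claims are confined to (a) network flow quantities, which are exact for the
model class, (b) closed-form-verified transport numerics, and (c) the
statistics computed from the packaged reference tables.

## Airway representation

Each side is an ordered list of tapered duct segments, grouped as Area-1
(vestibule + nasal valve, dry squamous wall), Area-2 (turbinate cavity, wet
mucosal wall), then a shared Area-3 nasopharynx after the choanal merge.
Cross-sections taper linearly in area and perimeter, so surface areas
(length × mean perimeter) and resistance integrals are closed-form
checkable. Plane-1/Plane-2 are bookkeeping stations at the choanal ends and
at the merge — "immediately before/after the choanae" holds exactly because
the model carries one bulk state per station.

The isoperimetric inequality P² ≥ 4πA is enforced per segment end;
validation returns a list of named violations rather than raising, so a
malformed configuration reports all problems at once.

### Default template

Symmetric, per side (SI values in `geometry.TEMPLATE_DEFAULTS`):

| segment      | kind     | size                  | length | wall |
|--------------|----------|-----------------------|--------|------|
| vestibule    | circular | D 8 mm                | 12 mm  | dry  |
| nasal valve  | slit     | 8 × 1.45 mm           | 4 mm   | dry  |
| cavity       | slit     | width 45 mm, gap 3 mm | 60 mm  | wet  |
| nasopharynx  | circular | D 12 mm (shared)      | 30 mm  | wet  |

The split of Area-1 into a wide vestibule plus a narrow valve is the one
genuinely free design choice in the template. It decouples the two
constraints Area-1 must satisfy simultaneously: its *wall surface* sets the
Area-2:Area-1 surface ratio (observed 11.5–18.6 in real airways; template
≈ 15.3), while its *flow resistance* sets where the synthetic cohort's
unilateral resistances and flow partitions land. A single circular duct
cannot satisfy both (a D 8 mm duct has negligible resistance; a duct
resistive enough would be far too narrow to supply the surface). The valve
dimensions were calibrated once, at design time, so that the cohort
defaults below place ≥ 90 % of subjects inside the clinically reported
pre-op envelopes (MOS partition 19–45 %, MOS unilateral NR
0.05–0.32 Pa/(mL·s)); the resulting anterior segment carries roughly 45 %
of a symmetric side's resistance, consistent with the nasal valve being the
flow-limiting anterior structure. The valve/cavity boundary is a modeling
station, not an anatomical claim. Slit velocities in the valve reach
~10 m/s at protocol flow (Re ≈ 1700); the model is laminar by construction
and does not switch regime.

## Flow model

Fully developed laminar viscous friction only, by default:
ΔP = Q ∫ fRe·μ/(2 D_h² A) dx with fRe = 64 (circular) / 96 (slit),
composite-Simpson quadrature on 64 panels (exact for uniform sections).
This keeps every side characteristic linear in Q, so the bilateral network
(two sides to a common choanal node, then the shared path) is solved in
closed form and outlet-pressure calibration is direct (ΔP = R·Q). Optional
minor losses (entrance contraction K = 0.5, Borda–Carnot expansions) make
the characteristics quadratic; the solver then runs a damped Newton
iteration (damping halves on residual growth, ≤ 200 iterations, relative
residual ≤ 1e-10) and calibration falls back to bracketed bisection with a
secant polish (|Q − target| ≤ 1e-9·target). Minor losses are **off** by
default and the choice is stamped in output metadata, because resistance
values depend on it.

Nasal resistance uses static gauge pressures — inlet chamber 0, common
choanal junction p_ch — with no dynamic-pressure correction; with a
zero-resistance inlet chamber the bilateral ("inlet to choanae") and
unilateral ("nostril to choanae") upstream references coincide. With
per-side choanal pressures (a future nonlinear extension) the bilateral NR
would use the flow-weighted mean choanal pressure.

Air properties are constant at 25 °C film conditions (ρ 1.184 kg/m³,
μ 1.849e-5 Pa·s, c_p 1006 J/(kg·K), Pr 0.707, Sc 0.60, D_v 2.6e-5 m²/s,
k = μc_p/Pr): the ambient-to-wall span is ≤ 9 K and property variation is
under 3 %, below the model-class error.

## Heat and humidity transport

Bulk (mixed-mean) temperature and specific humidity march downstream by
fixed-step RK4 (100 substeps per segment; halving the step changes the
outlet by < 1e-9, and the constant-coefficient case matches its exponential
closed form to better than 1e-8 relative). The wall is uniformly 34 °C and
saturated. This fixed-wall closure is the minimal stand-in for a mucosal
wall model: real mucosa cools under inspiratory load, so the wall
temperature is set *below* core (and above the reported choanal air
temperatures of 31–33 °C), uniform along the airway, and configurable.

Local coefficients come from the thermally developing Graetz solution,
Hausen form Nu = Nu_∞ + 0.0668·Gz/(1 + 0.04·Gz^{2/3}) with Gz = D_h·Re·Pr/x
and Nu_∞ = 3.66 (circular) / 7.54 (slit), mass transfer via Chilton–Colburn
Sh = Nu·(Sc/Pr)^{1/3}. The entrance coordinate x accumulates from the
nostril (one developing layer per passage; the shared path continues from
the mean side length) and is floored at 0.1 mm to avoid the x → 0
singularity of the similarity solution.

Three deliberate simplifications:

- the bulk energy equation tracks sensible exchange only; vapor enthalpy
  advected into the stream (≲ 1 % of the air enthalpy flux) is neglected,
  so latent heat appears solely as the reported wall-side flux
  q_lat = h_m ρ (w_sat(T_w) − w) L_v with L_v = 2.43e6 J/kg (≈ 34 °C);
- dry (squamous) walls exchange no water: q_lat ≡ 0 in Area-1;
- a saturation limiter caps w at w_sat(T) after each step. Under
  Chilton–Colburn the vapor field relaxes ~11 % faster than temperature
  (Le ≠ 1), so the bulk would transiently supersaturate by O(1e-6) RH near
  equilibrium; physically the excess condenses. An integrity error still
  fires if RH exceeds 1 + 1e-6, guarding against genuine numerical faults.

Saturation vapor pressure is the Arden Buck form
e_s = 611.21·exp(17.502·T/(240.97 + T)) everywhere (one formula, stamped in
metadata), valid −20…60 °C; psychrometric conversions use
w = 0.622·e/(p − e) and are exact round-trips.

Choanal mixing is dry-air-mass-flow weighted, conserving vapor mass and
sensible enthalpy to machine precision; with constant c_p the mass- and
enthalpy-weighted temperature averages coincide, which is the convention
adopted for Plane-2.

## Protocol and metrics

`run_subject_protocol` calibrates p_out on the postoperative model to the
target flow (default 250 mL/s, met to 1e-6 relative), solves the
preoperative model at the identical p_out, and integrates transport on
both. The more obstructed side (MOS) is the side with the smaller
preoperative flow fraction (ties: larger unilateral NR, then LEFT), frozen
for postoperative reporting even if the partition later crosses 50 %.
Regional heat fluxes are area-weighted means per unit wetted area (W/m²),
matching the clinical tables; combined Area-1+Area-2 values use
surface-area weights. The "% increase of surface heat flux" used in the
improvement correlations is 100·(post − pre)/pre on the preoperatively
labeled side's regional mean (the pre value is strictly positive since
T_wall > T everywhere).

## Synthetic cohort

The generator emulates the statistical structure of a septal-deviation
cohort, not anatomy: per subject, the MOS cavity gap is scaled by a
severity δ ~ U(0.35, 0.75), the LOS gap by a compensatory factor
U(1.0, 1.15); virtual surgery moves the MOS factor to δ + ρ(1 − δ) with
correction ρ ~ U(0.6, 1.0) and widens both cavities by a turbinate factor
U(1.05, 1.20). Because slit resistance follows the cubic-gap law, δ = 0.5
raises the *cavity* resistance ≈ 8× (the unilateral NR rises less, since
the valve resistance is unchanged by deviation).

NOSE scores come from a declared linear-plus-noise artifice (not a
physiological claim): nose_pre = clip(round(5 + 45·NR_mos_pre + ε₁), 0, 20),
improvement = clip(round(60·ΔNR_mos + ε₂), 0, nose_pre), with ε SDs 2.5 and
3.5. The intercept and slopes place scores in the observed 9–20 pre-op
range, and the improvement slope with the cohort's ΔNR spread
(σ ≈ 0.06 Pa/(mL·s)) gives a model-implied attenuated correlation
r = c·σ_ΔNR/√(c²σ²_ΔNR + σ²_ε) ≈ 0.72 (sampled ≈ 0.75 at n = 500; the
default 8-subject cohort gives ≈ 0.83), bracketing the strong
improvement-resistance correlations reported clinically. Raising the
implied r further would push pre-op resistances outside the observed
envelope, so the defaults stay where the envelopes put them.

Reproducibility: one integer seed defines a cohort bit-exactly; per-subject
substreams are keyed by (seed, index), so cohorts are prefix-stable in n.
Draws that would produce an invalid geometry raise a generation error
naming subject and stage — nothing is silently clipped.

What passing synthetic tests does *not* show: fidelity of absolute flux or
humidity magnitudes to real airways, anatomical realism of the template, or
the true NOSE–physiology relation. The synthetic cohort validates the
*pipeline* — solver correctness, protocol bookkeeping, metric definitions,
and the recoverability of a known generative structure by the statistics
layer.

## Reference fixtures

The per-subject NOSE scores and flow/resistance tables of the eight-subject
reference study are packaged as CSV transcriptions; every printed mean, SD,
p-value, and Pearson r is recomputed and compared at print precision
(±0.55 of a unit in the last printed decimal; ±0.01 for r; ±0.0015 for
exact printed p-values). Three conventions were identified by
recomputation and are encoded explicitly: the per-subject tables print
sample (n−1) SDs while the running text prints population (n) SDs; the
subgroup comparison reproduces only under Welch's test (p ≈ 0.004; pooled
variance gives ≈ 0.002); and the score-level correlations match pooled
pre+post states (16 points), not the 8 preoperative points — both variants
are computed and labeled. Statistics derived from already-rounded prints
(unilateral LOS resistance = printed MOS NR ÷ printed ratio) cannot match
print precision in second moments; their tolerances are doubled and their
p-values reported as informational. No multiple-testing correction is
applied (matching the reference); reports carry the count of tests
performed.

## Problem sizes and numerical defaults

Default runs: 8-subject cohorts with full transport (100 RK4 substeps per
segment, ~0.4 s total); parameter-recovery cohorts of 200–500 subjects with
flow metrics only (transport disabled via `CohortConfig.compute_transport`),
~0.5 s. Solver tolerances: network residual 1e-10 relative, calibration
1e-9 relative (direct for linear networks), quadrature 64 Simpson panels.
Degenerate inputs raise typed errors (zero-variance statistics, zero-flow
resistance scopes, two zero-flow streams at the merge) rather than
returning sentinel values.

## Known limitations

- Inspiration only, steady state; no breathing waveform, no exhalation-phase
  heat/moisture recovery, no nasal-cycle model.
- One bulk state per station: no secondary flows, no cross-sectional
  stratification, no vestibule jet — the phenomena that make resolved CFD
  fluxes differ from Graetz-correlation fluxes.
- Fixed uniform wall temperature and saturation; real mucosal temperature
  varies axially and with load.
- The template is an idealization tuned to reproduce *metric ranges*, not a
  reconstruction of any airway; the valve position is a free parameter.
- Laminar closure is applied regardless of local Reynolds number.
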