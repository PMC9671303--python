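# rhinoflow

Reduced-order modeling of bilateral nasal airflow and air conditioning for
pre/post **septoturbinoplasty** comparison, with the statistics layer that
links the physics to patient-reported **NOSE** (Nasal Obstruction Symptom
Evaluation) scores.

## The problem

Septoturbinoplasty (septum straightening plus inferior-turbinate reduction)
relieves nasal obstruction, but which *physical* change explains the
perceived improvement — the drop in nasal resistance, the reallocation of
flow between the two passages, or the change in mucosal cooling — is not
obvious. CFD studies of real patients address this by solving airflow and
heat/water-vapor transport in CT-derived airways before and after surgery
under a *matched breathing effort*: the trans-nasal pressure drop is
calibrated so the postoperative airway carries a target bilateral flow
(250 mL/s) and the same pressure is imposed on the preoperative airway.

`rhinoflow` reproduces this analysis at desk scale. The 3-D airway is
reduced to a network of tapered duct segments per side — vestibule/valve
(Area-1, dry squamous wall), turbinate cavity (Area-2, wet mucosal wall) —
merging at the choanae into a shared nasopharynx (Area-3). It is intended
for method development, teaching, and pipeline testing: a synthetic-cohort
generator stands in for the (non-public) CT subjects, and the per-subject
tables of the reference eight-subject clinical study are packaged so every
published summary statistic is reproducible exactly.

## The model

**Flow.** Steady inspiratory laminar flow, pressure-driven: inlet at 0
gauge, outlet pressure p_out < 0 at the nasopharynx. Each segment
contributes a fully developed viscous drop

    ΔP(Q) = Q ∫ fRe·μ / (2·D_h(x)²·A(x)) dx ,   D_h = 4A/P,

with fRe = 64 (circular) or 96 (slit), reducing to Hagen–Poiseuille
128μLQ/(πD⁴) and to the slit's cubic-gap law 12μLQ/(g³W). The two sides
meet at a common choanal pressure p_ch; nasal resistance is
NR = −p_ch/Q in Pa/(mL·s), unilateral (per passage) or bilateral (total).

**Air conditioning.** One bulk state (T, specific humidity w) per station,
relaxing toward a fixed 34 °C saturated mucosal wall:

    ṁ c_p dT/dx = h P (T_w − T),     ṁ_dry dw/dx = h_m ρ P (w_sat(T_w) − w),

with h from the developing-laminar Graetz problem (Hausen correlation,
Nu_∞ = 3.66 / 7.54), h_m via the Chilton–Colburn analogy, and the Arden
Buck saturation curve. Wall fluxes are reported per unit wetted area:
sensible h(T_w − T) everywhere, latent h_m ρ (w_sat − w) L_v on wet walls
only — the vestibule exchanges no water. Plane-1 (per side, just before the
choanae) and Plane-2 (merged, just after) carry the mass-weighted bulk
temperature and RH.

**Statistics.** Two-tailed paired t-tests pre vs post, Welch two-sample
tests between response subgroups, and Pearson correlations between NOSE
improvement and the physical changes, with both sample and population SD
conventions (the reference tables mix them).

## Worked example

```python
import rhinoflow as rf
from rhinoflow.geometry import SubjectState, default_template

pre  = default_template("demo", SubjectState.PREOP,  left_gap_factor=0.5, right_gap_factor=1.1)
post = default_template("demo", SubjectState.POSTOP, left_gap_factor=1.1, right_gap_factor=1.1)
result = rf.run_subject_protocol(pre, post)
m_pre  = rf.extract_subject_metrics(result, SubjectState.PREOP)
m_post = rf.extract_subject_metrics(result, SubjectState.POSTOP)
```

which prints (via `examples/01_single_subject_protocol.py`):

```
MOS (labeled preoperatively): LEFT
calibrated outlet pressure:   -8.081 Pa gauge

PREOP                               POSTOP
  total flow             180.0 mL/s   250.0 mL/s
  MOS flow partition      29.9 %       50.0 %
  unilateral NR (MOS)   0.1466        0.0625  Pa/(mL·s)
  bilateral NR          0.0438        0.0312  Pa/(mL·s)
  Plane-2 temperature    32.89        32.44   °C
  Plane-2 RH             96.1         94.3    %
```

At the same breathing effort the preoperative airway carries only 180 mL/s
and its narrowed side 30 % of it; surgery halves the unilateral resistance
of the more obstructed side (MOS), and the faster postoperative transit
leaves the air slightly cooler and drier at the choanae — the same
directions seen in the clinical study.

The other example scripts cover the synthetic cohort with its summary
statistics (`02`), the reference-table regression (`03`), and the
streamwise conditioning profile (`04`). A CLI wraps the same pipeline:

```bash
rhinoflow cohort --seed 1 --n-subjects 8 --output out/
rhinoflow reference-check --output out/
rhinoflow report out/cohort.csv
```

## Layout

- `src/rhinoflow/geometry.py` — segments, regions, bilateral model, template
- `src/rhinoflow/flow.py` — laminar network solve, outlet-pressure calibration
- `src/rhinoflow/conditioning.py` — psychrometrics, Graetz transfer, RK4 transport
- `src/rhinoflow/protocol.py` — matched-pressure protocol, metric extraction
- `src/rhinoflow/cohort.py` — synthetic subject generator and NOSE score model
- `src/rhinoflow/stats.py` — t-tests, correlations, reference-table regression
- `src/rhinoflow/pipeline.py`, `cli.py`, `config.py` — runs, artifacts, CLI
- `docs/methods.md` — modeling assumptions, parameters, limitations
- `docs/geometry_schema.md` — airway file format
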