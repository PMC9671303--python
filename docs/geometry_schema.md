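# Airway geometry file schema

Airway models are YAML (or JSON) mappings with lengths in **mm** and areas
in **mm²**, declared in-file. Loaders are strict: any key not listed below
is rejected by name.

## Top level

| key           | type    | required | notes                                   |
|---------------|---------|----------|-----------------------------------------|
| `subject_id`  | string  | no       | defaults to `"unnamed"`                 |
| `state`       | string  | no       | `PREOP` (default) or `POSTOP`           |
| `units`       | mapping | no       | must equal `{length: mm, area: mm2}`    |
| `left_path`   | list    | yes      | segments, nostril → choana              |
| `right_path`  | list    | yes      | segments, nostril → choana              |
| `shared_path` | list    | yes      | segments, choanae → nasopharynx outlet  |

Each unilateral path must contain at least one `AREA1_VESTIBULE` segment
strictly before at least one `AREA2_CAVITY` segment; the shared path holds
only `AREA3_NASOPHARYNX` segments.

## Segment

| key                  | type   | required | notes                                      |
|----------------------|--------|----------|--------------------------------------------|
| `label`              | string | yes      | unique name, used in error messages        |
| `region`             | string | yes      | `AREA1_VESTIBULE`, `AREA2_CAVITY`, `AREA3_NASOPHARYNX` |
| `length_mm`          | number | yes      | > 0                                        |
| `area_in_mm2`        | number | yes      | cross-section at the upstream end          |
| `area_out_mm2`       | number | yes      | linear taper between ends                  |
| `perimeter_in_mm`    | number | yes      | wetted perimeter, upstream end             |
| `perimeter_out_mm`   | number | yes      | linear taper between ends                  |
| `cross_section_kind` | string | yes      | `CIRCULAR` or `SLIT` (friction/Nusselt constants) |
| `wall_is_wet`        | bool   | no       | defaults to `false` in AREA1, else `true`; must be `false` in AREA1 |

Each end must satisfy the isoperimetric inequality
`perimeter² ≥ 4π·area`.

## Example

```yaml
subject_id: demo
state: PREOP
units: {length: mm, area: mm2}
left_path:
  - {label: left_vestibule, region: AREA1_VESTIBULE, length_mm: 12,
     area_in_mm2: 50.27, area_out_mm2: 50.27,
     perimeter_in_mm: 25.13, perimeter_out_mm: 25.13,
     cross_section_kind: CIRCULAR, wall_is_wet: false}
  - {label: left_valve, region: AREA1_VESTIBULE, length_mm: 4,
     area_in_mm2: 11.6, area_out_mm2: 11.6,
     perimeter_in_mm: 18.9, perimeter_out_mm: 18.9,
     cross_section_kind: SLIT, wall_is_wet: false}
  - {label: left_cavity, region: AREA2_CAVITY, length_mm: 60,
     area_in_mm2: 135.0, area_out_mm2: 135.0,
     perimeter_in_mm: 96.0, perimeter_out_mm: 96.0,
     cross_section_kind: SLIT, wall_is_wet: true}
right_path: []   # mirror of left_path in a real file
shared_path:
  - {label: nasopharynx, region: AREA3_NASOPHARYNX, length_mm: 30,
     area_in_mm2: 113.1, area_out_mm2: 113.1,
     perimeter_in_mm: 37.7, perimeter_out_mm: 37.7,
     cross_section_kind: CIRCULAR, wall_is_wet: true}
```

`rhinoflow.config.save_airway_file` writes this format from any
`BilateralAirwayModel` (e.g. the built-in template), which is the easiest
way to produce a starting file.
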