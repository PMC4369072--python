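# cardiocryo

Finite-element simulation of **cardiac cryoablation** freeze–thaw protocols.

Cardiac cryoablation treats arrhythmias by freezing the arrhythmogenic
myocardium with a refrigerant-cooled catheter tip.  Protocol design —
how long to freeze, whether and when to insert an interim thaw, how long the
applicator stays frozen to the tissue (cryoadhesion) — hinges on the
transmural temperature history, which is hard to measure and convenient to
simulate.  This package is for biomedical engineers and modellers who want a
self-contained, scriptable bench for such protocol studies.

## Model

The temperature field obeys the Pennes bioheat equation with phase change:

```
ρ C(x,T) ∂T/∂t = ∇·( λ(x,T) ∇T ) + Q_p(x,T) + Q_m(x,T)
```

* latent heat is spread over the −10…0 °C phase-transition range
  (effective-heat-capacity method); conductivity, perfusion `Q_p` and
  metabolism `Q_m` blend/shut down with the liquid fraction;
* the geometry is a 9 Fr 8 mm tip applicator on a 6 mm myocardial slab,
  wrapped in a 3 mm blood layer, meshed with graded tetrahedra;
* far-field surfaces carry Robin (convective) conditions; the refrigerant
  chamber carries a Robin law to the −88 °C boiling N₂O, modulated by
  fill/drain envelopes, with its magnitude calibrated to a −82.6 °C
  150 s minimum-temperature anchor;
* time integration is Crank–Nicolson (P1 elements, lumped capacity,
  lagged coefficients), with a per-step energy ledger.

Outputs are the metrics protocol studies actually compare: isotherm depths
over time, iceball volume, cryoadhesion release times and transmural
cooling/thawing rates over the central 60 % of the local rewarming span.
See `docs/methods.md` for the full model description and numerical choices.

## Worked example

Simulate the reference single freeze–thaw cycle (300 s freeze, scenario B1)
at reduced resolution and print the headline metrics:

```python
from cardiocryo import (GeometryConfig, build_model_mesh, default_materials,
                        BoundarySpec, calibrate_refrigerant, run_schedule,
                        make_scenario, extract_profile, isotherm_depth,
                        ice_volume)

mesh = build_model_mesh(GeometryConfig())          # ~49k tets, ~9k vertices
mats = default_materials()
params, achieved = calibrate_refrigerant(mesh, mats, BoundarySpec.main_defaults(),
                                         target_min_tissue_T=-82.6,
                                         freeze_duration=150.0)
bc = BoundarySpec.main_defaults(refrigerant=params)
series = run_schedule(mesh, mats, bc, make_scenario("B1"), dt=0.1)

prof = extract_profile(series, mesh)
print(f"calibrated h_steady = {params.h_steady:.0f} W/m²/°C ({achieved:.1f} °C)")
print(f"-10 °C depth @300 s : {isotherm_depth(prof.depths, prof.column(300), -10):.2f} mm")
print(f"-20 °C depth @300 s : {isotherm_depth(prof.depths, prof.column(300), -20):.2f} mm")
print(f"iceball volume      : {ice_volume(series.field_at(300), mesh, mats):.0f} mm³")
```

prints (a few minutes on one CPU):

```
calibrated h_steady = 50469 W/m²/°C (-83.1 °C)
-10 °C depth @300 s : 4.71 mm
-20 °C depth @300 s : 3.44 mm
iceball volume      : 307 mm³
```

i.e. after five minutes of continuous freezing the iceball reaches ~4.7 mm of
the 6 mm wall, the −20 °C (necrotic) front ~3.4 mm, and ~0.31 cm³ of
myocardium is frozen.

The same workflows are available from the shell:

```sh
cardiocryo scenarios                  # list the protocol catalogue
cardiocryo run config.yaml            # simulate + write VTU/CSV/metrics bundle
cardiocryo calibrate                  # refrigerant calibration
cardiocryo verify --h-steady 50469    # in-vitro slab verification bench
```

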