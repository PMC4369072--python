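"""In-vitro verification bench: freezing a thermally inactive myocardial slab.

Reproduces a bench experiment in which a 9 Fr 8 mm tip applicator freezes a
20 x 20 x 10 mm section of porcine myocardium with no superfusate flow, while
optical probes record temperatures 1, 2, 3 and 5 mm below the contact surface.
The simulation variant uses the slab geometry, zeroes all perfusion and
metabolic sources (tissue Q_m = Q_p = 0, blood layer Q_p = 0, i.e. water at
rest above the preparation) and softens the far-field Robin coefficients to
still-water values (alpha = 700 W m^-2 degC^-1, 37 degC bath).

The refrigerant parameters calibrated on the main model are reused unchanged:
it is the same applicator hardware.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import GeometryConfig, ModelMesh, build_model_mesh
from .materials import MaterialModel, inactive_materials
from .metrics import _contact_centre, interpolation_weights
from .solver import BoundarySpec, FieldSeries, RefrigerantParams, run_schedule

DEFAULT_PROBE_DEPTHS_MM = (1.0, 2.0, 3.0, 5.0)


@dataclass
class ProbeSeries:
    """Temperature traces at fixed depths below the contact centre."""

    depths: np.ndarray          # mm below the contact surface
    times: np.ndarray           # s
    temps: np.ndarray           # (n_times, n_depths), degC

    def at_time(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - t)))
        return self.temps[i]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.temps,
                          columns=[f"{d:g}mm_C" for d in self.depths])
        df.insert(0, "t_s", self.times)
        return df


def build_wood_variant(resolution: Optional[float] = None,
                       refrigerant: Optional[RefrigerantParams] = None,
                       ) -> Tuple[ModelMesh, MaterialModel, BoundarySpec]:
    """Slab geometry + inactive materials + still-water boundary table."""
    cfg = GeometryConfig(variant="wood_slab")
    if resolution is not None:
        from dataclasses import replace
        cfg = replace(cfg, resolution=resolution)
    mesh = build_model_mesh(cfg)
    materials = inactive_materials()
    boundaries = BoundarySpec.wood_defaults(refrigerant=refrigerant)
    return mesh, materials, boundaries


def probe_temperatures(series: FieldSeries,
                       depths: Sequence[float] = DEFAULT_PROBE_DEPTHS_MM,
                       ) -> ProbeSeries:
    """Interpolated temperatures at probe depths on the slab axis, for all
    stored times."""
    mesh = series.mesh
    centre = _contact_centre(mesh)
    pts = centre[None, :] + np.array([[0.0, 0.0, d] for d in depths])
    _, nodes, w = interpolation_weights(mesh, pts)
    temps = np.einsum("tpk,pk->tp", series.fields[:, nodes], w)
    return ProbeSeries(depths=np.asarray(depths, float),
                       times=series.times.copy(), temps=temps)


@dataclass
class _Freeze:
    phases: Tuple[Tuple[str, float], ...]


def run_wood_benchmark(refrigerant: RefrigerantParams,
                       freeze_duration: float = 300.0,
                       resolution: Optional[float] = None,
                       dt: float = 0.1,
                       store_every: float = 5.0) -> Tuple[FieldSeries, ProbeSeries]:
    """Run the bench freeze and return the field series plus probe traces."""
    mesh, materials, boundaries = build_wood_variant(resolution=resolution,
                                                     refrigerant=refrigerant)
    series = run_schedule(mesh, materials, boundaries,
                          _Freeze((("freeze", freeze_duration),)),
                          dt=dt, store_every=store_every, T0=37.0)
    return series, probe_temperatures(series)
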