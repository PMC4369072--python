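"""Temperature-dependent material laws for perfused, freezing tissue.

The freeze model follows the effective-heat-capacity treatment of latent heat:
the fusion enthalpy is spread uniformly over the phase-transition range between
the solidus (-10 degC) and liquidus (0 degC) temperatures as additional
volumetric heat capacity.  Conductivity blends linearly between frozen and
liquid values with the liquid fraction, and the Pennes perfusion and metabolic
source terms shut down linearly with freezing (frozen tissue has neither
circulation nor metabolism).

Numerical property values are literature-typical averages for myocardium and
blood (documented in docs/methods.md) and are fully overridable via config.
All laws are pure functions of temperature and the parameter set, and accept
scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Dict

import numpy as np

from .geometry import REGION_TISSUE, REGION_BLOOD, REGION_APPLICATOR, ConfigurationError

BODY_TEMPERATURE_C = 36.5


@dataclass(frozen=True)
class RegionMaterial:
    """Thermal properties of one mesh region (SI units, temperatures degC)."""

    rho: float                 # density, kg m^-3
    c_liquid: float            # specific heat above liquidus, J kg^-1 degC^-1
    c_frozen: float            # specific heat below solidus
    lambda_liquid: float       # conductivity above liquidus, W m^-1 degC^-1
    lambda_frozen: float       # conductivity below solidus
    latent_heat: float         # fusion enthalpy, J kg^-1 (0 = no phase change)
    T_solidus: float = -10.0
    T_liquidus: float = 0.0
    perfusion_coeff: float = 0.0   # volumetric perfusion heat coeff, W m^-3 degC^-1
    T_body: float = BODY_TEMPERATURE_C
    q_metabolic: float = 0.0       # metabolic heat, W m^-3

    def __post_init__(self):
        if self.T_solidus >= self.T_liquidus:
            raise ConfigurationError("T_solidus must be below T_liquidus")
        for name in ("rho", "c_liquid", "c_frozen", "lambda_liquid", "lambda_frozen"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.latent_heat < 0 or self.perfusion_coeff < 0:
            raise ConfigurationError("latent_heat and perfusion_coeff must be >= 0")


def liquid_fraction(T, m: RegionMaterial):
    """Fraction of unfrozen material: 0 below solidus, 1 above liquidus,
    linear ramp in between."""
    T = np.asarray(T, dtype=float)
    f = (T - m.T_solidus) / (m.T_liquidus - m.T_solidus)
    return np.clip(f, 0.0, 1.0)


def effective_heat_capacity(T, m: RegionMaterial):
    """Volumetric effective heat capacity rho*C(T), J m^-3 degC^-1.

    Inside the transition range the sensible capacity (interpolated between
    frozen and liquid values) is augmented by rho*L/(T_liq - T_sol), so the
    integral of the extra capacity over the range equals the full volumetric
    latent heat.
    """
    f = liquid_fraction(T, m)
    sensible = m.rho * (m.c_frozen + (m.c_liquid - m.c_frozen) * f)
    in_range = (np.asarray(T, float) > m.T_solidus) & (np.asarray(T, float) < m.T_liquidus)
    latent = np.where(in_range, m.rho * m.latent_heat / (m.T_liquidus - m.T_solidus), 0.0)
    return sensible + latent


def thermal_conductivity(T, m: RegionMaterial):
    """Conductivity blended linearly by liquid fraction, W m^-1 degC^-1."""
    f = liquid_fraction(T, m)
    return m.lambda_frozen + (m.lambda_liquid - m.lambda_frozen) * f


def volumetric_sources(T, m: RegionMaterial):
    """Pennes perfusion sink/source Q_p and metabolic heat Q_m, W m^-3.

    Both scale with the liquid fraction: frozen tissue is neither perfused nor
    metabolically active.  Q_p = f(T) * w * (T_body - T) heats sub-body-
    temperature tissue and would cool hyperthermic tissue.
    """
    f = liquid_fraction(T, m)
    Qp = f * m.perfusion_coeff * (m.T_body - np.asarray(T, float))
    Qm = f * m.q_metabolic
    return Qp, Qm


def enthalpy(T, m: RegionMaterial):
    """Volumetric enthalpy H(T) = integral of effective capacity from T_solidus,
    J m^-3.  Continuous and strictly increasing in T."""
    T = np.asarray(T, dtype=float)
    Cs = m.rho * m.c_frozen
    Cl = m.rho * m.c_liquid
    dT = m.T_liquidus - m.T_solidus
    Lv = m.rho * m.latent_heat

    below = np.minimum(T, m.T_solidus) - m.T_solidus
    x = np.clip(T - m.T_solidus, 0.0, dT)  # progress through the ramp
    # sensible capacity is linear in x: Cs + (Cl-Cs) x/dT; latent adds Lv/dT
    ramp = Cs * x + (Cl - Cs) * x**2 / (2 * dT) + Lv * x / dT
    above = np.maximum(T - m.T_liquidus, 0.0)
    return Cs * below + ramp + Cl * above


@dataclass(frozen=True)
class MaterialModel:
    """Per-region material laws for the tagged mesh."""

    tissue: RegionMaterial
    blood: RegionMaterial
    applicator: RegionMaterial

    def __post_init__(self):
        if self.blood.q_metabolic != 0 or self.applicator.q_metabolic != 0:
            raise ConfigurationError("only tissue may generate metabolic heat")
        if self.applicator.latent_heat != 0 or self.applicator.perfusion_coeff != 0:
            raise ConfigurationError("applicator region must have zero sources and latent heat")
        if self.tissue.latent_heat <= 0 or self.blood.latent_heat <= 0:
            raise ConfigurationError("tissue and blood must have latent heat > 0")

    def region(self, code: int) -> RegionMaterial:
        return {REGION_TISSUE: self.tissue, REGION_BLOOD: self.blood,
                REGION_APPLICATOR: self.applicator}[code]

    def to_dict(self) -> Dict[str, Dict[str, float]]:
        return {"tissue": asdict(self.tissue), "blood": asdict(self.blood),
                "applicator": asdict(self.applicator)}

    @classmethod
    def from_dict(cls, d: Dict[str, Dict[str, float]]) -> "MaterialModel":
        base = default_materials()
        return cls(
            tissue=replace(base.tissue, **d.get("tissue", {})),
            blood=replace(base.blood, **d.get("blood", {})),
            applicator=replace(base.applicator, **d.get("applicator", {})),
        )


def default_materials() -> MaterialModel:
    """Literature-typical myocardium/blood/metal-shell property table.

    Tissue perfusion corresponds to resting myocardial blood flow of roughly
    0.8 mL min^-1 g^-1 (w*rho_b*c_b ~ 5e4 W m^-3 degC^-1).  The blood layer
    stands in for the flowing blood pool: it carries a strongly enhanced
    perfusion coefficient emulating advective heat supply without solving a
    flow problem.  Its magnitude is set for consistency with the convective
    far-field boundary: the layer's equivalent surface conductance
    (perfusion_coeff x layer thickness ~ 5e5 * 3e-3 = 1500 W m^-2 degC^-1)
    matches the heat transfer coefficient used for flowing blood at the
    far-field boundary, so the stand-in cannot supply heat faster than the
    convection it replaces.  The applicator shell is a high-conductivity
    metal with no sources.
    """
    tissue = RegionMaterial(
        rho=1060.0, c_liquid=3600.0, c_frozen=1800.0,
        lambda_liquid=0.5, lambda_frozen=2.0,
        latent_heat=2.5e5, perfusion_coeff=5.0e4, q_metabolic=700.0,
    )
    blood = RegionMaterial(
        rho=1060.0, c_liquid=3600.0, c_frozen=1800.0,
        lambda_liquid=0.5, lambda_frozen=2.0,
        latent_heat=2.5e5, perfusion_coeff=5.0e5, q_metabolic=0.0,
    )
    applicator = RegionMaterial(
        rho=8000.0, c_liquid=500.0, c_frozen=500.0,
        lambda_liquid=15.0, lambda_frozen=15.0,
        latent_heat=0.0, perfusion_coeff=0.0, q_metabolic=0.0,
    )
    return MaterialModel(tissue=tissue, blood=blood, applicator=applicator)


def inactive_materials() -> MaterialModel:
    """Thermally inactive variant: all perfusion and metabolic sources zeroed
    (tissue Q_m = Q_p = 0; blood Q_p = 0), used by the slab verification bench."""
    base = default_materials()
    return MaterialModel(
        tissue=replace(base.tissue, perfusion_coeff=0.0, q_metabolic=0.0),
        blood=replace(base.blood, perfusion_coeff=0.0),
        applicator=base.applicator,
    )
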