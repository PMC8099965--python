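"""Absorbed-dose conversion from time-integrated activity.

Doses are computed as D = TIA x S(m) with a pluggable dose-factor table.
The shipped default is an electron local-deposition model: Lu-177 dose is
beta-dominated, so the self-dose S-value of a region of mass m is

    S = Delta_e * 1.602e-13 J/MeV * 3.6e9 decays/(MBq*h) / m[kg]   [Gy/(MBq*h)]

with Delta_e the mean electron energy per decay and the photon self-dose
fraction set to zero. Reference-organ entries (kidneys, liver) carry a
reference S-value at a reference mass and are rescaled to the
patient-specific mass as S_ref * m_ref / m; sphere-model entries (salivary
glands, lesions) use the measured mass directly. Cross-organ photon dose is
omitted by default (hook: extend the table with cross-fire terms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .nuclide import DECAYS_PER_MBQ_H, LU177_DELTA_E_MEV, MEV_TO_J


def sphere_s_value(mass_g: float, delta_e_mev: float = LU177_DELTA_E_MEV) -> float:
    """Local-deposition self-dose S-value, Gy per MBq*h, for a mass in grams."""
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    return delta_e_mev * MEV_TO_J * DECAYS_PER_MBQ_H / (mass_g * 1e-3)


@dataclass(frozen=True)
class DoseFactor:
    region: str
    model: str  # 'reference_organ' or 'sphere'
    reference_mass_g: float
    s_ref_gy_per_mbq_h: float
    delta_e_mev: float = LU177_DELTA_E_MEV
    photon_self_dose_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("reference_organ", "sphere"):
            raise ValueError("model must be 'reference_organ' or 'sphere'")
        if self.reference_mass_g <= 0 or self.s_ref_gy_per_mbq_h <= 0:
            raise ValueError("reference mass and S-value must be positive")
        if not (0 <= self.photon_self_dose_fraction < 1):
            raise ValueError("photon self-dose fraction must lie in [0, 1)")


@dataclass(frozen=True)
class DoseFactorTable:
    factors: tuple[DoseFactor, ...]

    def __getitem__(self, region: str) -> DoseFactor:
        for f in self.factors:
            if f.region == region:
                return f
        raise KeyError(f"region '{region}' not present in dose-factor table")

    def __contains__(self, region: str) -> bool:
        return any(f.region == region for f in self.factors)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump([f.__dict__ for f in self.factors], fh)

    @classmethod
    def from_yaml(cls, path) -> "DoseFactorTable":
        with open(path) as fh:
            rows = yaml.safe_load(fh)
        return cls(tuple(DoseFactor(**r) for r in rows))


#: Reference masses (adult male) for the reference-organ entries; tissue
#: densities and gland/lesion masses come from the measured volumes instead.
_DEFAULT_REGIONS = (
    ("kidneys", "reference_organ", 310.0),
    ("liver", "reference_organ", 1800.0),
    ("parotid", "sphere", 25.0),
    ("submandibular", "sphere", 12.5),
    ("lesion", "sphere", 5.0),
)


def default_dose_factor_table() -> DoseFactorTable:
    """Electron local-deposition table for the standard region classes."""
    return DoseFactorTable(
        tuple(
            DoseFactor(region, model, m_ref, sphere_s_value(m_ref))
            for region, model, m_ref in _DEFAULT_REGIONS
        )
    )


def organ_mass(volume_ml: float, density_g_ml: float) -> float:
    """Organ mass in grams from CT-delineated volume and tissue density."""
    if volume_ml <= 0 or density_g_ml <= 0:
        raise ValueError("volume and density must be positive")
    return volume_ml * density_g_ml


def mass_scaled_s_value(table: DoseFactorTable, region: str, mass_g: float) -> float:
    """Patient-mass-adjusted S-value: electron self-dose scales as m_ref/m.

    Under the local-deposition approximation the (zero by default) photon
    component scales the same way, so the whole S-value follows the
    inverse-mass law.
    """
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    f = table[region]
    return f.s_ref_gy_per_mbq_h * f.reference_mass_g / mass_g


@dataclass(frozen=True)
class DoseResult:
    region: str
    method: str
    absorbed_dose_gy: float
    dose_gy_per_gbq: float
    mass_g: float

    def __post_init__(self) -> None:
        if self.absorbed_dose_gy < 0:
            raise ValueError("absorbed dose must be non-negative")


def absorbed_dose(
    tia_mbq_h: float,
    s_value_gy_per_mbq_h: float,
    administered_gbq: float,
    *,
    region: str = "",
    method: str = "",
    mass_g: float = float("nan"),
) -> DoseResult:
    """D = TIA x S; also reports the dose per administered activity, Gy/GBq."""
    if tia_mbq_h < 0 or s_value_gy_per_mbq_h <= 0 or administered_gbq <= 0:
        raise ValueError("TIA must be non-negative, S and administered activity positive")
    d = tia_mbq_h * s_value_gy_per_mbq_h
    return DoseResult(
        region=region,
        method=method,
        absorbed_dose_gy=float(d),
        dose_gy_per_gbq=float(d / administered_gbq),
        mass_g=mass_g,
    )
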