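"""Landmark free energies, concentration enhancements and Henry's-law links.

A referenced interfacial free-energy profile is condensed into three numbers:

* ``dg_gs``   — gas phase (vacuum plateau, the zero) to the interfacial
  adsorption minimum;
* ``dg_hydr`` — gas phase to the bulk-water plateau (the hydration free
  energy; negative for hydrophilic species);
* ``dg_sl``   — interfacial minimum to bulk, defined as
  ``dg_hydr - dg_gs`` so the additive identity holds exactly.

Equilibrium concentration enhancements relative to the gas phase follow as
Boltzmann factors exp(-ΔG / RT), and experimental hydration free energies
are obtained from Henry's-law solubility constants via the dimensionless
aqueous/gas concentration ratio H_cc = H_cp * R * T.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import R, R_SI, kT
from .profiles import FreeEnergyProfile

__all__ = [
    "Regions",
    "Landmarks",
    "HenryConstant",
    "SpeciesSummary",
    "extract_landmarks",
    "barrier_max",
    "concentration_enhancement",
    "classify_species",
    "henry_to_dghydr",
    "summarize_species",
]

HYDROPHILIC = "hydrophilic"
HYDROPHOBIC = "hydrophobic"


@dataclass(frozen=True)
class Regions:
    """|z| intervals (nm) on which the landmarks are read.

    Defaults suit the default slab geometry (interface well near 1.6 nm,
    coordinate domain out to ±3.5 nm): the vacuum plateau is averaged over
    |z| in [3.0, 3.5], the adsorption minimum searched in [0.8, 2.6] and the
    bulk plateau averaged over [0, 0.7].
    """

    vacuum: tuple[float, float] = (3.0, 3.5)
    interface: tuple[float, float] = (0.8, 2.6)
    bulk: tuple[float, float] = (0.0, 0.7)


@dataclass(frozen=True)
class Landmarks:
    """The ΔG_gs / ΔG_sl / ΔG_hydr triplet plus where it was read."""

    dg_gs: float
    dg_sl: float
    dg_hydr: float
    z_min: float
    regions: Regions = field(default_factory=Regions)


@dataclass(frozen=True)
class HenryConstant:
    """Henry's-law solubility constant with an explicit unit convention.

    ``convention`` is either ``"mol/m3/Pa"`` (concentration per partial
    pressure, H_cp) or ``"dimensionless"`` (aqueous/gas concentration ratio,
    H_cc).  ``temperature`` is the reference temperature of the constant,
    conventionally 298.15 K for compiled values.
    """

    value: float
    convention: str = "mol/m3/Pa"
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("Henry constant must be positive")
        if self.convention not in ("mol/m3/Pa", "dimensionless"):
            raise ValueError(f"unknown Henry convention: {self.convention!r}")

    def dimensionless(self) -> float:
        """H_cc, the aqueous/gas concentration ratio."""
        if self.convention == "dimensionless":
            return self.value
        return self.value * R_SI * self.temperature


@dataclass(frozen=True)
class SpeciesSummary:
    """One species' landmark free energies, enhancements and class."""

    name: str
    landmarks: Landmarks
    enhancement_surface: float
    enhancement_bulk: float
    hydro_class: str
    temperature: float
    dg_hydr_expt: float | None = None


def extract_landmarks(
    profile: FreeEnergyProfile, regions: Regions = Regions()
) -> Landmarks:
    """Read ΔG_gs, ΔG_sl and ΔG_hydr off a referenced profile.

    The profile must be referenced (vacuum plateau at zero); a symmetrized
    profile is expected and only the z >= 0 half is used.  ``dg_gs`` is the
    minimum over the interface search region, ``dg_hydr`` the unweighted
    mean over the bulk plateau region, and ``dg_sl = dg_hydr - dg_gs``.
    Undefined (never-visited) bins inside the regions are tolerated.
    """
    if profile.reference is None:
        raise ValueError("profile must be referenced before landmark extraction")
    half = profile.z >= 0

    def region_values(interval, what):
        mask = profile.region_mask(interval) & half & profile.occupied
        if not np.any(mask):
            raise ValueError(
                f"{what} region |z| in [{interval[0]}, {interval[1]}] nm has "
                "no occupied bins"
            )
        return profile.z[mask], profile.g[mask]

    z_i, g_i = region_values(regions.interface, "interface")
    i_min = int(np.argmin(g_i))  # first minimum = smallest |z| on the half grid
    dg_gs = float(g_i[i_min])
    z_min = float(z_i[i_min])
    _, g_b = region_values(regions.bulk, "bulk")
    dg_hydr = float(np.mean(g_b))
    return Landmarks(
        dg_gs=dg_gs,
        dg_sl=dg_hydr - dg_gs,
        dg_hydr=dg_hydr,
        z_min=z_min,
        regions=regions,
    )


def barrier_max(
    profile: FreeEnergyProfile, landmarks: Landmarks
) -> float:
    """Diagnostic: maximum free energy between the interface minimum and bulk.

    Complements ``dg_sl`` (a plateau-minus-minimum difference) with the
    height of any intervening transition-state-like maximum.
    """
    lo = landmarks.regions.bulk[1]
    mask = (
        (profile.z >= 0)
        & (np.abs(profile.z) >= lo)
        & (np.abs(profile.z) <= landmarks.z_min)
        & profile.occupied
    )
    if not np.any(mask):
        return float("nan")
    return float(np.max(profile.g[mask]))


def concentration_enhancement(dg: float, temperature: float = 300.0) -> float:
    """Equilibrium concentration ratio exp(-ΔG / RT) relative to the gas phase.

    With ``dg = dg_gs`` this is the surface enhancement; with
    ``dg = dg_hydr`` the bulk enhancement.  ΔG in kJ/mol, T in K.
    """
    return math.exp(-dg / kT(temperature))


def classify_species(dg_hydr: float) -> str:
    """Hydrophilic (ΔG_hydr < 0) vs hydrophobic (ΔG_hydr > 0)."""
    if not math.isfinite(dg_hydr):
        raise ValueError(f"dg_hydr must be finite, got {dg_hydr}")
    if dg_hydr < 0:
        return HYDROPHILIC
    if dg_hydr == 0:
        warnings.warn(
            "dg_hydr is exactly 0; classifying as hydrophobic by convention",
            stacklevel=2,
        )
    return HYDROPHOBIC


def henry_to_dghydr(h: HenryConstant) -> float:
    """Hydration free energy (kJ/mol) implied by a Henry's-law constant.

    The constant is first converted to the dimensionless aqueous/gas
    concentration ratio H_cc (multiplying H_cp by R*T when given in
    mol m^-3 Pa^-1) and the free energy is -R*T*ln(H_cc) at the constant's
    own reference temperature.
    """
    h_cc = h.dimensionless()
    return -kT(h.temperature) * math.log(h_cc)


def summarize_species(
    name: str,
    profile: FreeEnergyProfile,
    regions: Regions = Regions(),
    temperature: float | None = None,
    henry: HenryConstant | None = None,
) -> SpeciesSummary:
    """Compose landmarks, enhancements, class and the optional Henry link."""
    try:
        lm = extract_landmarks(profile, regions)
        temp = profile.temperature if temperature is None else temperature
        return SpeciesSummary(
            name=name,
            landmarks=lm,
            enhancement_surface=concentration_enhancement(lm.dg_gs, temp),
            enhancement_bulk=concentration_enhancement(lm.dg_hydr, temp),
            hydro_class=classify_species(lm.dg_hydr),
            temperature=temp,
            dg_hydr_expt=None if henry is None else henry_to_dghydr(henry),
        )
    except ValueError as exc:
        raise ValueError(f"species {name!r}: {exc}") from exc
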