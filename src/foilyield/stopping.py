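"""Proton energy degradation through a stacked target.

The analysis needs the mid-foil proton energy and its uncertainty in
every layer of a stack (vacuum-window Kapton foil, air gap, Ti deposits
on Al backings, Ni monitor foils, Al catchers and degraders). A Bethe
stopping-power model with fixed mean excitation energies and Bragg-rule
additivity over elements replaces a full transport code: above ~10 MeV
the model is accurate to a few percent, which the downstream yield
tolerances absorb, and the per-foil energy spread is estimated with the
Bohr straggling formula and combined in quadrature with the cyclotron
extraction uncertainty.

Units: energies MeV, mass stopping power MeV*cm^2/mg, areal densities
ug/cm^2, uncertainties on beam energy keV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InvalidInputError, RangedOutError

__all__ = [
    "Element",
    "Material",
    "MATERIALS",
    "FoilSpec",
    "BeamState",
    "StackPoint",
    "mass_stopping_power",
    "degrade",
    "straggling",
    "propagate_stack",
]

# Physical constants (CODATA)
K_BETHE = 0.307075  # MeV cm^2 / mol (4 pi N_A r_e^2 m_e c^2)
M_ELECTRON = 0.51099895  # MeV
M_PROTON = 938.27208816  # MeV
BOHR_K = 0.156915  # MeV^2 cm^2/g per unit Z/A (4 pi r_e^2 (m_e c^2)^2 N_A)

#: Validity window of the stopping model for protons (MeV).
E_MIN, E_MAX = 1.0, 100.0


@dataclass(frozen=True)
class Element:
    symbol: str
    z: int
    a: float  # g/mol
    i_ev: float  # mean excitation energy


ELEMENTS: dict[str, Element] = {
    e.symbol: e
    for e in (
        Element("H", 1, 1.008, 19.2),
        Element("C", 6, 12.011, 78.0),
        Element("N", 7, 14.007, 82.0),
        Element("O", 8, 15.999, 95.0),
        Element("Al", 13, 26.9815385, 166.0),
        Element("Ar", 18, 39.948, 188.0),
        Element("Ti", 22, 47.867, 233.0),
        # Enriched 48Ti deposit: same Z and I, mass number 48.
        Element("Ti48", 22, 47.9479, 233.0),
        Element("Ni", 28, 58.6934, 311.0),
    )
}


@dataclass(frozen=True)
class Material:
    """Homogeneous material as (element, mass-fraction) pairs."""

    name: str
    composition: tuple[tuple[str, float], ...]
    density_g_cm3: float

    def __post_init__(self):
        total = sum(w for _, w in self.composition)
        if abs(total - 1.0) > 1e-6:
            raise InvalidInputError(
                f"mass fractions of {self.name} sum to {total}, expected 1"
            )
        if not self.density_g_cm3 > 0:
            raise InvalidInputError(f"density of {self.name} must be positive")
        for sym, _ in self.composition:
            if sym not in ELEMENTS:
                raise InvalidInputError(f"unknown element {sym!r} in {self.name}")

    @property
    def z_over_a(self) -> float:
        return sum(w * ELEMENTS[s].z / ELEMENTS[s].a for s, w in self.composition)


MATERIALS: dict[str, Material] = {
    m.name: m
    for m in (
        Material("Ti", (("Ti", 1.0),), 4.506),
        Material("Ti48", (("Ti48", 1.0),), 4.506),
        Material("Al", (("Al", 1.0),), 2.699),
        Material("Ni", (("Ni", 1.0),), 8.902),
        # Kapton polyimide C22H10N2O5
        Material(
            "Kapton",
            (("C", 0.691133), ("H", 0.026362), ("N", 0.073270), ("O", 0.209235)),
            1.42,
        ),
        # Dry air near sea level
        Material(
            "Air",
            (("C", 0.000124), ("N", 0.755268), ("O", 0.231781), ("Ar", 0.012827)),
            1.20479e-3,
        ),
    )
}


@dataclass(frozen=True)
class FoilSpec:
    """One layer of the stack, by material and areal density."""

    material: Material
    areal_density_ug_cm2: float
    role: str = "target"  # target | monitor | catcher | degrader | window | air_gap
    name: str = ""
    areal_density_unc_ug_cm2: float = 0.0

    def __post_init__(self):
        if self.areal_density_ug_cm2 < 0:
            raise InvalidInputError("areal density must be non-negative")

    @classmethod
    def from_thickness(
        cls, material: Material, thickness_um: float, role: str = "degrader", name: str = ""
    ) -> "FoilSpec":
        areal = thickness_um * 1e-4 * material.density_g_cm3 * 1e6  # ug/cm^2
        return cls(material, areal, role, name or material.name)


@dataclass(frozen=True)
class BeamState:
    """Proton energy and its combined (extraction + straggling) uncertainty."""

    energy_mev: float
    energy_unc_kev: float = 500.0

    def __post_init__(self):
        if self.energy_mev < 0:
            raise InvalidInputError("beam energy must be non-negative")
        if self.energy_unc_kev < 0:
            raise InvalidInputError("beam energy uncertainty must be non-negative")


@dataclass(frozen=True)
class StackPoint:
    layer: FoilSpec
    entry: BeamState
    mid: BeamState
    exit: BeamState


def _bethe_element(energy_mev, element: Element):
    """Bethe mass stopping power of one element, MeV cm^2/g (array-aware)."""
    E = np.asarray(energy_mev, dtype=float)
    gamma = 1.0 + E / M_PROTON
    beta2 = 1.0 - 1.0 / gamma**2
    # Heavy-projectile limit: T_max ~ 2 m_e c^2 beta^2 gamma^2
    arg = 2.0 * M_ELECTRON * beta2 * gamma**2 / (element.i_ev * 1e-6)
    return K_BETHE * element.z / (element.a * beta2) * (np.log(arg) - beta2)


def mass_stopping_power(energy_mev, material: Material):
    """Proton mass stopping power in MeV*cm^2/mg.

    Bragg-rule sum of elemental Bethe terms; valid for energies in
    [1, 100] MeV (no shell or Barkas corrections).
    """
    E = np.asarray(energy_mev, dtype=float)
    if np.any(E < E_MIN) or np.any(E > E_MAX):
        raise DomainError(
            f"stopping power requested outside validity range [{E_MIN}, {E_MAX}] MeV"
        )
    total = sum(w * _bethe_element(E, ELEMENTS[s]) for s, w in material.composition)
    result = total / 1000.0  # MeV cm^2/mg
    return float(result) if np.isscalar(energy_mev) else result


def _step_mg(areal_mg: float) -> float:
    """Quadrature step: 1 mg/cm^2 or 1/100 of the foil, whichever is finer."""
    return min(1.0, areal_mg / 100.0) if areal_mg > 0 else 0.0


def _integrate_loss(e0: float, areal_mg: float, material: Material, foil_name: str) -> float:
    """Exit energy after a mass thickness, midpoint rule in areal density."""
    if areal_mg == 0.0:
        return e0
    h = _step_mg(areal_mg)
    n = max(1, math.ceil(areal_mg / h))
    h = areal_mg / n
    e = e0
    for _ in range(n):
        try:
            half = e - 0.5 * h * mass_stopping_power(e, material)
            e = e - h * mass_stopping_power(half, material)
        except DomainError:
            raise RangedOutError(foil_name) from None
        if e < E_MIN:
            raise RangedOutError(foil_name)
    return e


def straggling(foil: FoilSpec, entry_energy_mev: float) -> float:
    """Bohr energy-straggling width (1 sigma, keV) across the whole foil.

    The non-relativistic Bohr variance depends only on the traversed
    electron column, so it grows with the square root of thickness; the
    entry energy is only validated against the model window.
    """
    if not (E_MIN <= entry_energy_mev <= E_MAX):
        raise DomainError("entry energy outside stopping-model validity range")
    x_g = foil.areal_density_ug_cm2 * 1e-6  # g/cm^2
    var_mev2 = BOHR_K * foil.material.z_over_a * x_g
    return math.sqrt(var_mev2) * 1000.0


def degrade(beam: BeamState, foil: FoilSpec) -> tuple[BeamState, BeamState]:
    """Propagate a beam through one foil -> (mid-foil state, exit state).

    Energy loss is integrated with a midpoint rule over areal density;
    Bohr straggling for half/full thickness is added in quadrature to
    the incoming uncertainty.
    """
    areal_mg = foil.areal_density_ug_cm2 / 1000.0
    name = foil.name or foil.material.name
    e_mid = _integrate_loss(beam.energy_mev, areal_mg / 2.0, foil.material, name)
    e_exit = _integrate_loss(e_mid, areal_mg / 2.0, foil.material, name)

    half = FoilSpec(foil.material, foil.areal_density_ug_cm2 / 2.0, foil.role, name)
    s_half = straggling(half, beam.energy_mev)
    s_full = straggling(foil, beam.energy_mev)
    mid = BeamState(e_mid, math.hypot(beam.energy_unc_kev, s_half))
    exit_ = BeamState(e_exit, math.hypot(beam.energy_unc_kev, s_full))
    return mid, exit_


def propagate_stack(e0: BeamState, layers: list[FoilSpec]) -> list[StackPoint]:
    """Run the beam through every layer, returning per-layer energy states.

    Raises :class:`RangedOutError` (with the layer index) if the beam
    stops before the end of the stack.
    """
    if not layers:
        raise InvalidInputError("stack must contain at least one layer")
    points: list[StackPoint] = []
    state = e0
    for i, layer in enumerate(layers):
        try:
            mid, exit_ = degrade(state, layer)
        except RangedOutError as exc:
            raise RangedOutError(exc.foil_name, layer_index=i) from None
        points.append(StackPoint(layer=layer, entry=state, mid=mid, exit=exit_))
        state = exit_
    return points
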