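"""Forward pipeline: excitation functions, thick-target yields, purity evolution.

Given measured cross-section points, an excitation curve is a
shape-preserving interpolant anchored to zero at the reaction
threshold. A thick-target irradiation scenario (entry energy,
irradiation time, beam current) then fixes the end-of-bombardment (EOB)
activity of every co-produced scandium radionuclide through the
standard activation integral

    A = (I/e) * (N_A/M) * (1 - exp(-lam*t_irr)) * integral sigma(E)/S(E) dE

taken from the reaction threshold (the target is assumed thick enough
to degrade the beam below threshold) up to the entry energy, with S the
proton mass stopping power of the target material.

After EOB the activity set evolves by exponential decay, with the
44mSc -> 44gSc isomeric transition feeding the ground state through the
two-member Bateman solution. The radionuclidic purity (RNP) of 47Sc is
its activity fraction among all scandium radionuclides; 48V is a
different element and is removed chemically, so it never enters the
denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, minimize_scalar

from .activation import MB_TO_CM2, AVOGADRO, CrossSectionPoint
from .errors import InvalidInputError
from .nuclides import NuclideRegistry, default_registry
from .stopping import MATERIALS, Material, mass_stopping_power

__all__ = [
    "ExcitationFunction",
    "Scenario",
    "ActivitySet",
    "fit_excitation",
    "saturation_factor",
    "thick_target_eob_activity",
    "yield_table",
    "decay_activities",
    "rnp",
    "time_to_rnp",
    "max_rnp",
    "MaxRnp",
    "MBQ_PER_MCI",
]

PROTONS_PER_UA = 6.241509074e12  # 1 uA / elementary charge
MBQ_PER_MCI = 37.0
#: Post-EOB search horizon for purity questions (hours).
RNP_HORIZON_H = 5000.0


class ExcitationFunction:
    """sigma(E) for one product: PCHIP through a threshold anchor and data.

    Zero below threshold, shape-preserving through the points, constant
    (flagged) extrapolation above the last measured energy.
    """

    def __init__(self, product: str, points: Iterable[CrossSectionPoint], threshold_mev: float):
        pts = sorted(points, key=lambda p: p.energy_mev)
        if len(pts) < 2:
            raise InvalidInputError("need at least 2 cross-section points")
        energies = [p.energy_mev for p in pts]
        if len(set(energies)) != len(energies):
            raise InvalidInputError("duplicate energies in cross-section points")
        if energies[0] <= threshold_mev:
            raise InvalidInputError(
                f"threshold {threshold_mev} MeV must lie below the first point"
            )
        self.product = product
        self.points = tuple(pts)
        self.threshold_mev = float(threshold_mev)
        self.e_max = energies[-1]
        x = np.concatenate([[threshold_mev], energies])
        y = np.concatenate([[0.0], [p.sigma_mb for p in pts]])
        self._interp = PchipInterpolator(x, y)
        #: set to True whenever a query relied on constant extrapolation
        self.extrapolated = False

    def __call__(self, energy_mev):
        E = np.asarray(energy_mev, dtype=float)
        if np.any(E > self.e_max):
            self.extrapolated = True
        clipped = np.clip(E, self.threshold_mev, self.e_max)
        sigma = np.clip(self._interp(clipped), 0.0, None)
        sigma = np.where(E < self.threshold_mev, 0.0, sigma)
        return float(sigma) if np.isscalar(energy_mev) else sigma


def fit_excitation(
    points: Iterable[CrossSectionPoint], threshold_mev: float, product: str = ""
) -> ExcitationFunction:
    """Fit an excitation curve through measured points with a zero anchor."""
    pts = list(points)
    name = product or (pts[0].product if pts else "")
    return ExcitationFunction(name, pts, threshold_mev)


@dataclass(frozen=True)
class Scenario:
    """One thick-target irradiation scenario."""

    e_entry_mev: float
    e_exit_mev: float = 0.0
    t_irr_h: float = 24.0
    current_ua: float = 1.0

    def __post_init__(self):
        if not self.e_entry_mev > self.e_exit_mev >= 0:
            raise InvalidInputError("need e_entry > e_exit >= 0")
        if not self.t_irr_h > 0:
            raise InvalidInputError("irradiation time must be positive")

    @property
    def label(self) -> str:
        return f"E<{self.e_entry_mev:g} MeV, {self.t_irr_h:g} h"


def saturation_factor(lam_per_h: float, t_irr_h: float) -> float:
    """Fraction of the asymptotic activity reached: 1 - exp(-lam t_irr)."""
    if lam_per_h <= 0:
        raise InvalidInputError("decay constant must be positive")
    if t_irr_h < 0:
        raise InvalidInputError("irradiation time must be non-negative")
    return -math.expm1(-lam_per_h * t_irr_h)


def thick_target_eob_activity(
    xs: ExcitationFunction,
    scenario: Scenario,
    lam_per_h: float,
    material: Material | None = None,
    molar_mass_g_mol: float = 47.9479,
    e_step_mev: float = 0.02,
) -> float:
    """EOB activity (MBq) of one product for a thick-target scenario.

    Trapezoidal integration of sigma(E)/S(E) from max(threshold, e_exit)
    to the entry energy; linear in the beam current. With
    ``current_ua=1`` the result is the usual MBq/uA production yield.
    """
    material = material or MATERIALS["Ti48"]
    e_hi = scenario.e_entry_mev
    e_lo = max(scenario.e_exit_mev, xs.threshold_mev)
    if e_hi <= e_lo:
        return 0.0
    n = max(2, int(math.ceil((e_hi - e_lo) / e_step_mev)) + 1)
    grid = np.linspace(e_lo, e_hi, n)
    integrand = xs(grid) * MB_TO_CM2 / mass_stopping_power(grid, material)  # mg/MeV... -> mg
    integral = float(np.trapezoid(integrand, grid))  # cm^2 * mg/cm^2 per atom basis
    rate = (
        scenario.current_ua
        * PROTONS_PER_UA
        * AVOGADRO
        / (molar_mass_g_mol * 1000.0)
        * integral
    )
    return rate * saturation_factor(lam_per_h, scenario.t_irr_h) / 1e6  # Bq -> MBq


def yield_table(
    xs_map: Mapping[str, ExcitationFunction],
    scenarios: Iterable[Scenario],
    registry: NuclideRegistry | None = None,
    material: Material | None = None,
    molar_mass_g_mol: float = 47.9479,
) -> pd.DataFrame:
    """Yield matrix (MBq and mCi) per nuclide and scenario.

    Cells where the excitation curve has no support below the entry
    energy (the integral vanishes) are left blank (NaN), mirroring how
    below-threshold products are reported.
    """
    registry = registry or default_registry()
    rows = []
    for sc in scenarios:
        row: dict[str, float | str] = {
            "scenario": sc.label,
            "e_entry_mev": sc.e_entry_mev,
            "t_irr_h": sc.t_irr_h,
        }
        for product, xs in xs_map.items():
            lam = registry.decay_constant(product)
            a = thick_target_eob_activity(
                xs, sc, lam, material=material, molar_mass_g_mol=molar_mass_g_mol
            )
            row[f"{product} [MBq]"] = a if a > 0 else np.nan
            row[f"{product} [mCi]"] = a / MBQ_PER_MCI if a > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ActivitySet:
    """Per-nuclide activities (MBq) at a given time offset from EOB."""

    activities: Mapping[str, float]
    t_offset_h: float = 0.0

    def __post_init__(self):
        for nuc, a in self.activities.items():
            if a < 0:
                raise InvalidInputError(f"negative activity for {nuc}")

    def get(self, nuclide: str) -> float:
        return self.activities.get(nuclide, 0.0)

    def total(self, element: str | None = None) -> float:
        if element is None:
            return sum(self.activities.values())
        return sum(a for n, a in self.activities.items() if n.startswith(element + "-"))


def _bateman_daughter(
    a_g0: float, a_m0: float, lam_g: float, lam_m: float, branch: float, dt: float
) -> float:
    """Ground-state activity after dt with isomeric feeding (branch b).

    A_g(t) = A_g(0) e^{-lg t} + b lg/(lg-lm) A_m(0) (e^{-lm t} - e^{-lg t});
    the lg -> lm degenerate limit is A_g0 e^{-l t} + b l A_m0 t e^{-l t}.
    """
    if abs(lam_g - lam_m) < 1e-12 * lam_g:
        return (a_g0 + branch * lam_g * a_m0 * dt) * math.exp(-lam_g * dt)
    feed = (
        branch
        * (lam_g / (lam_g - lam_m))
        * a_m0
        * (math.exp(-lam_m * dt) - math.exp(-lam_g * dt))
    )
    return a_g0 * math.exp(-lam_g * dt) + feed


def decay_activities(
    a0: ActivitySet, dt_h: float, registry: NuclideRegistry | None = None
) -> ActivitySet:
    """Evolve an activity set dt hours forward.

    Independent nuclides scale by exp(-lam dt); any nuclide with a decay
    branch to another member of the set (44mSc -> 44gSc isomeric
    transition) feeds it through the two-member Bateman solution. The
    branching fraction lives in the registry.
    """
    if dt_h < 0:
        raise InvalidInputError("time step must be non-negative")
    registry = registry or default_registry()
    out: dict[str, float] = {}
    fed: dict[str, tuple[str, float]] = {}  # daughter -> (parent, branch)
    for nuc in a0.activities:
        for daughter, branch in registry.get(nuc).decay_branches:
            if daughter in a0.activities:
                fed[daughter] = (nuc, branch)
    for nuc, a in a0.activities.items():
        lam = registry.decay_constant(nuc)
        if nuc in fed:
            parent, branch = fed[nuc]
            lam_p = registry.decay_constant(parent)
            out[nuc] = _bateman_daughter(a, a0.get(parent), lam, lam_p, branch, dt_h)
        else:
            out[nuc] = a * math.exp(-lam * dt_h)
    return ActivitySet(out, t_offset_h=a0.t_offset_h + dt_h)


def rnp(a: ActivitySet, nuclide: str = "Sc-47", element: str = "Sc") -> float:
    """Radionuclidic purity: activity fraction of ``nuclide`` among its element."""
    total = a.total(element)
    if total <= 0:
        raise InvalidInputError(f"no {element} activity in the set")
    return a.get(nuclide) / total


def time_to_rnp(
    a0: ActivitySet,
    target: float,
    registry: NuclideRegistry | None = None,
    horizon_h: float = RNP_HORIZON_H,
    grid_step_h: float = 1.0,
) -> float:
    """Smallest post-EOB time (h) at which the 47Sc RNP reaches ``target``.

    Scans a coarse grid and refines the first crossing by root bracketing;
    returns ``math.inf`` ("never") when the purity stays below target over
    the whole horizon, as happens when long-lived 46Sc caps the purity.
    """
    if not (0.0 < target < 1.0):
        raise InvalidInputError("target purity must lie in (0, 1)")
    registry = registry or default_registry()

    def purity(t: float) -> float:
        return rnp(decay_activities(a0, t, registry))

    if purity(0.0) >= target:
        return 0.0
    t_grid = np.arange(0.0, horizon_h + grid_step_h, grid_step_h)
    prev = 0.0
    for t in t_grid[1:]:
        if purity(float(t)) >= target:
            return float(brentq(lambda u: purity(u) - target, prev, float(t), xtol=1e-6))
        prev = float(t)
    return math.inf


class MaxRnp(NamedTuple):
    t_h: float
    rnp: float
    at_horizon: bool  # purity still rising at the end of the search window


def max_rnp(
    a0: ActivitySet,
    registry: NuclideRegistry | None = None,
    horizon_h: float = RNP_HORIZON_H,
    grid_step_h: float = 1.0,
) -> MaxRnp:
    """Maximum post-EOB 47Sc purity: 1 h grid search refined by golden section.

    Without 46Sc every impurity decays faster than 47Sc, the purity is
    monotone increasing, and the maximum sits at the horizon end
    (``at_horizon=True``).
    """
    registry = registry or default_registry()

    def purity(t: float) -> float:
        return rnp(decay_activities(a0, t, registry))

    t_grid = np.arange(0.0, horizon_h + grid_step_h, grid_step_h)
    values = np.array([purity(float(t)) for t in t_grid])
    i = int(np.argmax(values))
    # monotone (or flat) purity: the supremum sits at the horizon end
    if i == len(t_grid) - 1 or values[-1] >= values[i] - 1e-12:
        return MaxRnp(float(t_grid[-1]), float(values[-1]), True)
    lo = float(t_grid[max(i - 1, 0)])
    hi = float(t_grid[min(i + 1, len(t_grid) - 1)])
    res = minimize_scalar(
        lambda t: -purity(t), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4},
    )
    return MaxRnp(float(res.x), float(-res.fun), False)
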