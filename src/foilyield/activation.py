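"""Inverse pipeline: gamma-peak counts -> EOB activities -> flux -> cross-sections.

One counted photo-peak, together with the detection efficiency, the
gamma intensity and the timing of the acquisition, fixes the activity
of the emitting nuclide at the end of bombardment (EOB). A natNi
monitor foil next to each target converts that activity scale into an
effective proton flux through the IAEA-recommended natNi(p,x)57Ni
cross-section, and the flux in turn converts target activities into
production cross-sections, quoted for a 100% isotopically enriched
48Ti target.

Uncertainties are propagated as relative contributions summed in
quadrature (counting statistics, efficiency, gamma intensity, monitor
cross-section, areal density); dead time enters as the multiplicative
real/live-time ratio, legitimate while the dead fraction stays below
10%.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import DomainError, InvalidInputError, SchemaError
from .nuclides import GammaLine

__all__ = [
    "ValueUnc",
    "GammaMeasurement",
    "TargetFoil",
    "IrradiationRun",
    "CrossSectionPoint",
    "eob_activity",
    "combine_activities",
    "MonitorTable",
    "monitor_sigma",
    "add_recoil",
    "average_flux",
    "atoms_per_cm2",
    "production_cross_section",
    "uncertainty_budget",
    "MAX_DEAD_TIME_FRACTION",
]

AVOGADRO = 6.02214076e23
MB_TO_CM2 = 1e-27
#: Acquisitions were arranged so the dead fraction never exceeded this.
MAX_DEAD_TIME_FRACTION = 0.10


class ValueUnc(NamedTuple):
    """A scalar with absolute 1-sigma uncertainty."""

    value: float
    unc: float

    @property
    def rel(self) -> float:
        return self.unc / self.value if self.value else math.inf


@dataclass(frozen=True)
class GammaMeasurement:
    """Everything needed to turn one net peak area into an EOB activity."""

    foil_id: str
    line: GammaLine
    counts: float
    counts_unc: float
    t_cool_h: float  # EOB -> acquisition start
    t_real_h: float
    t_live_h: float
    efficiency: float  # full-energy peak efficiency at the counting geometry
    efficiency_unc: float = 0.0

    def __post_init__(self):
        if self.counts < 0:
            raise InvalidInputError("net peak counts must be non-negative")
        if self.t_live_h > self.t_real_h:
            raise InvalidInputError("live time cannot exceed real time")
        if self.t_real_h <= 0:
            raise InvalidInputError("real time must be positive")
        dead = (self.t_real_h - self.t_live_h) / self.t_real_h
        if dead >= MAX_DEAD_TIME_FRACTION:
            raise InvalidInputError(
                f"dead-time fraction {dead:.3f} exceeds {MAX_DEAD_TIME_FRACTION:.0%}"
            )
        if self.t_cool_h < 0:
            raise InvalidInputError("cooling time must be non-negative")


@dataclass(frozen=True)
class TargetFoil:
    """An enriched-48Ti deposit (or a monitor foil) as an atom inventory."""

    foil_id: str
    nuclide: str  # reference isotope of the deposit, e.g. "Ti-48"
    areal_density_ug_cm2: float
    areal_density_unc_ug_cm2: float = 0.0
    molar_mass_g_mol: float = 47.9479
    enrichment: float = 0.9932

    def __post_init__(self):
        if not self.areal_density_ug_cm2 > 0:
            raise InvalidInputError("areal density must be positive")
        if not (0.0 < self.enrichment <= 1.0):
            raise InvalidInputError("enrichment fraction must lie in (0, 1]")

    @property
    def atoms_per_cm2(self) -> float:
        """Total atoms of the deposit element per cm^2 (all isotopes)."""
        return atoms_per_cm2(self.areal_density_ug_cm2, self.molar_mass_g_mol)


@dataclass(frozen=True)
class IrradiationRun:
    run_id: str
    t_irr_h: float
    current_na: float
    eob: str = ""  # ISO-8601 timestamp, informational

    def __post_init__(self):
        if not self.t_irr_h > 0:
            raise InvalidInputError("irradiation time must be positive")


@dataclass(frozen=True)
class CrossSectionPoint:
    product: str
    energy_mev: float
    energy_unc_kev: float
    sigma_mb: float
    sigma_unc_mb: float

    def __post_init__(self):
        if self.sigma_mb < 0:
            raise InvalidInputError("cross-section must be non-negative")


def atoms_per_cm2(areal_density_ug_cm2: float, molar_mass_g_mol: float) -> float:
    return areal_density_ug_cm2 * 1e-6 * AVOGADRO / molar_mass_g_mol


def eob_activity(m: GammaMeasurement, lam_per_h: float) -> ValueUnc:
    """Activity (Bq) at EOB inferred from one counted gamma peak.

    A = C * lam * (t_real/t_live) / (eps * I_g * exp(-lam t_c) * (1 - exp(-lam t_real)))

    with the decay constant in h^-1 and times in hours; the live/real
    ratio is the dead-time correction and decay during the acquisition
    uses the real time. Relative uncertainties of counts, efficiency
    and gamma intensity combine in quadrature.
    """
    if lam_per_h <= 0:
        raise InvalidInputError("decay constant must be positive")
    if m.efficiency <= 0:
        raise InvalidInputError("detection efficiency must be positive")
    if m.line.intensity <= 0:
        raise InvalidInputError("gamma intensity must be positive")
    lam_s = lam_per_h / 3600.0  # counts accumulate per second
    decay_cool = math.exp(-lam_per_h * m.t_cool_h)
    growth = -math.expm1(-lam_per_h * m.t_real_h)
    a = (
        m.counts
        * lam_s
        * (m.t_real_h / m.t_live_h)
        / (m.efficiency * m.line.intensity * decay_cool * growth)
    )
    rels = [
        m.counts_unc / m.counts if m.counts > 0 else 0.0,
        m.efficiency_unc / m.efficiency,
        (m.line.intensity_unc or 0.0) / m.line.intensity,
    ]
    return ValueUnc(a, a * math.sqrt(sum(r * r for r in rels)))


def combine_activities(activities: Sequence[ValueUnc]) -> ValueUnc:
    """Inverse-variance weighted mean of repeated EOB activity estimates."""
    if not activities:
        raise InvalidInputError("no activities to combine")
    if len(activities) == 1:
        return activities[0]
    w = np.array([1.0 / a.unc**2 for a in activities])
    v = np.array([a.value for a in activities])
    mean = float(np.sum(w * v) / np.sum(w))
    return ValueUnc(mean, float(1.0 / math.sqrt(np.sum(w))))


class MonitorTable:
    """Shape-preserving interpolation of a recommended monitor excitation curve.

    Piecewise-cubic Hermite (PCHIP) through the tabulated cross-sections;
    the relative uncertainty is interpolated linearly between the
    tabulated points. Queries outside the tabulated energy span raise a
    :class:`DomainError`.
    """

    def __init__(self, energies_mev, sigmas_mb, sigma_uncs_mb):
        e = np.asarray(energies_mev, float)
        s = np.asarray(sigmas_mb, float)
        u = np.asarray(sigma_uncs_mb, float)
        if e.size < 2 or np.any(np.diff(e) <= 0):
            raise SchemaError("monitor table needs strictly increasing energies")
        self.energies = e
        self.sigmas = s
        self.rel_unc = u / s
        self._interp = PchipInterpolator(e, s)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MonitorTable":
        rows = list(csv.DictReader(open(path, newline="")))
        if not rows:
            raise SchemaError(f"monitor table {path} is empty")
        return cls(
            [float(r["energy_mev"]) for r in rows],
            [float(r["sigma_mb"]) for r in rows],
            [float(r["sigma_unc_mb"]) for r in rows],
        )

    @classmethod
    def natni_ni57(cls) -> "MonitorTable":
        """IAEA-recommended natNi(p,x)57Ni monitor curve (packaged fixture)."""
        return cls.from_csv(Path(__file__).parent / "data" / "monitor_natNi_ni57.csv")

    def __call__(self, energy_mev: float) -> ValueUnc:
        e0, e1 = self.energies[0], self.energies[-1]
        if energy_mev < e0 or energy_mev > e1:
            raise DomainError(
                f"monitor energy {energy_mev} MeV outside tabulated range [{e0}, {e1}]"
            )
        sigma = float(self._interp(energy_mev))
        rel = float(np.interp(energy_mev, self.energies, self.rel_unc))
        return ValueUnc(sigma, sigma * rel)


_DEFAULT_MONITOR: MonitorTable | None = None


def monitor_sigma(energy_mev: float) -> ValueUnc:
    """natNi(p,x)57Ni monitor cross-section (mb) at the given energy."""
    global _DEFAULT_MONITOR
    if _DEFAULT_MONITOR is None:
        _DEFAULT_MONITOR = MonitorTable.natni_ni57()
    return _DEFAULT_MONITOR(energy_mev)


def add_recoil(a_monitor_bq: float, a_catcher_bq: float) -> tuple[float, float]:
    """Total monitor activity including recoils caught downstream.

    Returns (summed activity, recoil fraction). For thin Ni monitors the
    recoil fraction is of order 1%.
    """
    if a_monitor_bq < 0 or a_catcher_bq < 0:
        raise InvalidInputError("activities must be non-negative")
    total = a_monitor_bq + a_catcher_bq
    fraction = a_catcher_bq / total if total > 0 else 0.0
    return total, fraction


def average_flux(
    a57_eob: ValueUnc,
    n_t_ni_per_cm2: float,
    sigma_mon: ValueUnc,
    lam57_per_h: float,
    t_irr_h: float,
) -> ValueUnc:
    """Run-averaged proton flux (protons/s) from the 57Ni monitor activity.

    phi = A_EOB / (N_t * sigma * (1 - exp(-lam t_irr))); the relative
    uncertainty combines the activity and monitor-cross-section terms.
    """
    if t_irr_h <= 0:
        raise InvalidInputError("irradiation time must be positive")
    if n_t_ni_per_cm2 <= 0 or sigma_mon.value <= 0 or lam57_per_h <= 0:
        raise InvalidInputError("monitor inputs must be positive")
    sat = -math.expm1(-lam57_per_h * t_irr_h)
    phi = a57_eob.value / (n_t_ni_per_cm2 * sigma_mon.value * MB_TO_CM2 * sat)
    rel = math.hypot(a57_eob.rel, sigma_mon.rel)
    return ValueUnc(phi, phi * rel)


def production_cross_section(
    a_eob: ValueUnc,
    flux: ValueUnc,
    foil: TargetFoil,
    lam_per_h: float,
    t_irr_h: float,
    energy: tuple[float, float],
    product: str,
) -> CrossSectionPoint:
    """Cross-section point from an EOB activity and the measured flux.

    sigma = A_EOB / (phi * N_t * (1 - exp(-lam t_irr))) / f, rescaled by
    the enrichment fraction f so the value refers to a 100% enriched
    48Ti target. ``energy`` is the (mid-foil energy MeV, uncertainty keV)
    pair from the stack propagation.
    """
    if t_irr_h <= 0 or lam_per_h <= 0:
        raise InvalidInputError("irradiation time and decay constant must be positive")
    sat = -math.expm1(-lam_per_h * t_irr_h)
    sigma_cm2 = a_eob.value / (flux.value * foil.atoms_per_cm2 * sat) / foil.enrichment
    sigma_mb = sigma_cm2 / MB_TO_CM2
    rel_nt = foil.areal_density_unc_ug_cm2 / foil.areal_density_ug_cm2
    rel = uncertainty_budget(
        [("activity", a_eob.rel), ("flux", flux.rel), ("areal_density", rel_nt)]
    )[0]
    return CrossSectionPoint(
        product=product,
        energy_mev=energy[0],
        energy_unc_kev=energy[1],
        sigma_mb=sigma_mb,
        sigma_unc_mb=sigma_mb * rel,
    )


def uncertainty_budget(
    components: Sequence[tuple[str, float]],
) -> tuple[float, list[tuple[str, float]]]:
    """Quadrature sum of relative contributions.

    Returns (total relative uncertainty, components sorted largest first).
    """
    for name, rel in components:
        if rel < 0:
            raise InvalidInputError(f"negative uncertainty component {name!r}")
    total = math.sqrt(sum(rel * rel for _, rel in components))
    return total, sorted(components, key=lambda c: -c[1])
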