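"""Decay-data registry: half-lives, gamma lines, branchings.

Half-lives are stored with their original unit tag (s/h/d); every
derived quantity (decay constants, saturation factors, Bateman terms)
works in hours. The packaged fixture covers the scandium products of
proton-irradiated enriched 48Ti plus the 48V co-product and the 57Ni
beam monitor.

Only gamma lines flagged ``usable`` take part in activity
quantification; the 1120 keV line of 46Sc is shipped unusable because
it interferes with ambient 214Bi background, and the 1157 keV line of
44mSc is unusable because it coincides with the 44gSc line.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

from .errors import InvalidInputError, SchemaError, UnknownNuclideError

__all__ = [
    "HalfLife",
    "GammaLine",
    "Nuclide",
    "NuclideRegistry",
    "decay_constant",
    "load_nuclide_table",
    "write_nuclide_table",
    "default_registry",
    "load_thresholds",
    "SC44M_IT_BRANCH",
]

#: Isomeric-transition branching fraction 44mSc -> 44gSc.  Evaluated
#: decay-scheme value; configurable wherever Bateman feeding is applied.
SC44M_IT_BRANCH = 0.988

_HOURS_PER_UNIT = {"s": 1.0 / 3600.0, "min": 1.0 / 60.0, "h": 1.0, "d": 24.0}

_ELEMENT_Z = {"Sc": 21, "Ti": 22, "V": 23, "Cr": 24, "Mn": 25, "Fe": 26, "Co": 27, "Ni": 28}


@dataclass(frozen=True)
class HalfLife:
    value: float
    unit: str = "h"
    unc: float | None = None

    def __post_init__(self):
        if self.unit not in _HOURS_PER_UNIT:
            raise SchemaError(f"unknown half-life unit {self.unit!r}")
        if not self.value > 0:
            raise InvalidInputError(f"half-life must be positive, got {self.value}")

    @property
    def hours(self) -> float:
        return self.value * _HOURS_PER_UNIT[self.unit]

    @property
    def hours_unc(self) -> float | None:
        if self.unc is None:
            return None
        return self.unc * _HOURS_PER_UNIT[self.unit]


@dataclass(frozen=True)
class GammaLine:
    nuclide: str
    energy_kev: float
    intensity: float
    intensity_unc: float | None = None
    usable: bool = True

    def __post_init__(self):
        if not self.energy_kev > 0:
            raise InvalidInputError("gamma energy must be positive")
        if not (0.0 < self.intensity <= 1.0):
            raise InvalidInputError(
                f"gamma intensity must lie in (0, 1], got {self.intensity}"
            )


@dataclass(frozen=True)
class Nuclide:
    """One nuclear species, possibly an isomer (``Sc-44m``)."""

    symbol: str
    z: int
    a: int
    isomer: str  # "ground" | "metastable"
    half_life: HalfLife
    gamma_lines: tuple[GammaLine, ...] = ()
    #: (daughter symbol, branching fraction) pairs used for feeding terms.
    decay_branches: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        total = 0.0
        for daughter, frac in self.decay_branches:
            if not (0.0 <= frac <= 1.0):
                raise InvalidInputError(
                    f"branching fraction for {self.symbol}->{daughter} out of [0,1]"
                )
            total += frac
        if total > 1.0 + 1e-9:
            raise InvalidInputError(f"branching fractions of {self.symbol} sum to {total} > 1")

    @property
    def decay_constant_per_h(self) -> float:
        """ln2 / t1/2 in h^-1, always derived from the stored half-life."""
        return decay_constant(self.half_life)


def decay_constant(half_life: HalfLife | float) -> float:
    """Decay constant in h^-1 for a half-life (a :class:`HalfLife` or hours)."""
    hours = half_life.hours if isinstance(half_life, HalfLife) else float(half_life)
    if not hours > 0 or not math.isfinite(hours):
        raise InvalidInputError(f"half-life must be positive and finite, got {hours}")
    return math.log(2.0) / hours


def _parse_symbol(symbol: str) -> tuple[int, int, str]:
    try:
        element, mass = symbol.split("-")
        isomer = "ground"
        if mass.endswith("m"):
            isomer, mass = "metastable", mass[:-1]
        elif mass.endswith("g"):
            mass = mass[:-1]
        return _ELEMENT_Z[element], int(mass), isomer
    except (ValueError, KeyError) as exc:
        raise SchemaError(f"cannot parse nuclide symbol {symbol!r}") from exc


class NuclideRegistry:
    """Mapping of nuclide symbol -> :class:`Nuclide`."""

    def __init__(self, nuclides: dict[str, Nuclide]):
        self._nuclides = dict(nuclides)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._nuclides

    def __iter__(self):
        return iter(self._nuclides.values())

    def __len__(self) -> int:
        return len(self._nuclides)

    def get(self, symbol: str) -> Nuclide:
        try:
            return self._nuclides[symbol]
        except KeyError:
            raise UnknownNuclideError(symbol) from None

    def decay_constant(self, symbol: str) -> float:
        return self.get(symbol).decay_constant_per_h

    def quantification_lines(self, symbol: str) -> list[GammaLine]:
        """Gamma lines approved for activity quantification, by intensity."""
        lines = [g for g in self.get(symbol).gamma_lines if g.usable]
        return sorted(lines, key=lambda g: -g.intensity)


_MANDATORY = (
    "nuclide",
    "half_life_value",
    "half_life_unit",
    "gamma_energy_kev",
    "gamma_intensity",
    "usable",
)


def load_nuclide_table(path: str | Path, it_branch: float = SC44M_IT_BRANCH) -> NuclideRegistry:
    """Read the nuclide fixture CSV (one row per gamma line).

    ``it_branch`` sets the 44mSc -> 44gSc isomeric-transition branching
    applied wherever the metastable/ground pair is present.
    """
    rows = list(csv.DictReader(open(path, newline="")))
    if not rows:
        raise SchemaError(f"nuclide table {path} is empty")
    for field_name in _MANDATORY:
        if field_name not in rows[0]:
            raise SchemaError(f"nuclide table missing mandatory field {field_name!r}")

    by_symbol: dict[str, dict] = {}
    for i, row in enumerate(rows, start=2):
        sym = row["nuclide"].strip()
        if not sym:
            raise SchemaError(f"row {i}: empty nuclide symbol")
        try:
            hl = HalfLife(
                float(row["half_life_value"]),
                row["half_life_unit"].strip(),
                float(row["half_life_unc"]) if row.get("half_life_unc") else None,
            )
            line = GammaLine(
                nuclide=sym,
                energy_kev=float(row["gamma_energy_kev"]),
                intensity=float(row["gamma_intensity"]),
                intensity_unc=float(row["intensity_unc"]) if row.get("intensity_unc") else None,
                usable=row["usable"].strip().lower() in ("true", "1", "yes"),
            )
        except (InvalidInputError, ValueError) as exc:
            raise InvalidInputError(f"row {i} of {path}: {exc}") from exc
        entry = by_symbol.setdefault(sym, {"half_life": hl, "lines": []})
        if abs(entry["half_life"].hours - hl.hours) > 1e-9 * hl.hours:
            raise SchemaError(f"row {i}: inconsistent half-life for {sym}")
        entry["lines"].append(line)

    nuclides = {}
    for sym, entry in by_symbol.items():
        z, a, isomer = _parse_symbol(sym)
        branches: tuple[tuple[str, float], ...] = ()
        if sym == "Sc-44m" and "Sc-44g" in by_symbol:
            branches = (("Sc-44g", it_branch),)
        nuclides[sym] = Nuclide(
            symbol=sym,
            z=z,
            a=a,
            isomer=isomer,
            half_life=entry["half_life"],
            gamma_lines=tuple(entry["lines"]),
            decay_branches=branches,
        )
    return NuclideRegistry(nuclides)


def write_nuclide_table(path: str | Path, registry: NuclideRegistry) -> None:
    """Serialize a registry back to the fixture CSV schema (round-trips)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "nuclide",
                "half_life_value",
                "half_life_unit",
                "half_life_unc",
                "gamma_energy_kev",
                "gamma_intensity",
                "intensity_unc",
                "usable",
            ]
        )
        for nuc in registry:
            hl = nuc.half_life
            for g in nuc.gamma_lines:
                writer.writerow(
                    [
                        nuc.symbol,
                        _fmt(hl.value),
                        hl.unit,
                        _fmt(hl.unc) if hl.unc is not None else "",
                        _fmt(g.energy_kev),
                        _fmt(g.intensity),
                        _fmt(g.intensity_unc) if g.intensity_unc is not None else "",
                        "true" if g.usable else "false",
                    ]
                )


def _fmt(x: float) -> str:
    return format(x, ".10g")


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def default_registry(it_branch: float = SC44M_IT_BRANCH) -> NuclideRegistry:
    """Registry loaded from the packaged decay-data fixture."""
    return load_nuclide_table(_data_path("nuclides.csv"), it_branch=it_branch)


def load_thresholds(path: str | Path | None = None) -> dict[str, float]:
    """Reaction thresholds (MeV, lab frame) for p + 48Ti -> product.

    Computed from atomic mass evaluations for the lowest-energy open
    channel of each product; used as the zero anchor of excitation-curve
    fits. Override by pointing ``path`` to a CSV with the same schema.
    """
    path = Path(path) if path is not None else _data_path("thresholds.csv")
    out = {}
    for row in csv.DictReader(open(path, newline="")):
        out[row["product"]] = float(row["threshold_mev"])
    if not out:
        raise SchemaError(f"threshold table {path} is empty")
    return out
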