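"""Tabular I/O, configuration and the end-to-end pipeline.

The on-disk formats are deliberately plain: wide CSV for cross-section
tables (one column pair per product, blank cells meaning below
detection, never zero), CSV for measurement lists and yield/purity
curves, JSON for stack descriptions and scenarios. All times are hours
as floats; timestamps, where present, are ISO-8601 strings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activation import (
    CrossSectionPoint,
    GammaMeasurement,
    MonitorTable,
    TargetFoil,
    ValueUnc,
    add_recoil,
    average_flux,
    combine_activities,
    eob_activity,
    production_cross_section,
)
from .errors import InvalidInputError, SchemaError
from .nuclides import NuclideRegistry, default_registry, load_nuclide_table, load_thresholds
from .planning import (
    ActivitySet,
    ExcitationFunction,
    Scenario,
    decay_activities,
    fit_excitation,
    rnp,
    yield_table,
)
from .stopping import MATERIALS, BeamState, FoilSpec, propagate_stack

__all__ = [
    "PRODUCTS",
    "data_path",
    "read_xs_csv",
    "write_xs_csv",
    "xs_points",
    "fit_points",
    "load_xs_fixture",
    "fitted_excitations",
    "load_yield_fixture",
    "activity_set_from_yields",
    "load_stack_json",
    "RunConfig",
    "run_pipeline",
]

PRODUCTS = ("Sc-47", "Sc-46", "Sc-44g", "Sc-44m", "Sc-43", "V-48")
SC_PRODUCTS = ("Sc-47", "Sc-46", "Sc-44g", "Sc-44m", "Sc-43")


def data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


# ---------------------------------------------------------------- xs tables


def read_xs_csv(path: str | Path) -> pd.DataFrame:
    """Read a wide cross-section table (blank cells preserved as NaN)."""
    df = pd.read_csv(path, dtype={"target_id": str})
    for col in ("energy_mev", "energy_unc_mev"):
        if col not in df.columns:
            raise SchemaError(f"cross-section table missing column {col!r}")
    for i, row in df.iterrows():
        for col in df.columns:
            if col == "target_id":
                continue
            v = row[col]
            if pd.notna(v) and not isinstance(v, (int, float, np.floating, np.integer)):
                raise SchemaError(f"row {i + 2}: malformed numeric in column {col!r}")
        for product in PRODUCTS:
            if product in df.columns and pd.notna(row[product]) and row[product] < 0:
                raise SchemaError(f"row {i + 2}: negative cross-section for {product}")
    return df


def write_xs_csv(path: str | Path, df: pd.DataFrame) -> None:
    """Write a cross-section table; NaN cells serialize as empty strings."""
    df.to_csv(path, index=False, na_rep="")


def xs_points(df: pd.DataFrame, product: str) -> list[CrossSectionPoint]:
    """Measured (non-blank) points of one product as CrossSectionPoint list."""
    if product not in df.columns:
        raise SchemaError(f"no column for product {product!r}")
    pts = []
    for _, row in df.iterrows():
        if pd.isna(row[product]):
            continue
        pts.append(
            CrossSectionPoint(
                product=product,
                energy_mev=float(row["energy_mev"]),
                energy_unc_kev=float(row["energy_unc_mev"]) * 1000.0,
                sigma_mb=float(row[product]),
                sigma_unc_mb=float(row.get(f"{product}_unc", 0.0) or 0.0),
            )
        )
    return pts


def fit_points(
    df: pd.DataFrame, product: str, threshold_mev: float, blanks_as_zero: bool = True
) -> list[CrossSectionPoint]:
    """Point set used to fit one excitation curve.

    With ``blanks_as_zero`` (the default) every measured energy above
    the reaction threshold where the product was below detection enters
    the fit as a zero cross-section, so the curve does not invent
    production where the experiment saw none.
    """
    pts = xs_points(df, product)
    if blanks_as_zero:
        for _, row in df.iterrows():
            e = float(row["energy_mev"])
            if pd.isna(row[product]) and e > threshold_mev:
                pts.append(
                    CrossSectionPoint(
                        product=product,
                        energy_mev=e,
                        energy_unc_kev=float(row["energy_unc_mev"]) * 1000.0,
                        sigma_mb=0.0,
                        sigma_unc_mb=0.0,
                    )
                )
    return sorted(pts, key=lambda p: p.energy_mev)


def load_xs_fixture() -> pd.DataFrame:
    """The packaged measured 48Ti(p,x) cross-section table (15 foils)."""
    return read_xs_csv(data_path("xs_ti48.csv"))


def fitted_excitations(
    df: pd.DataFrame | None = None,
    products: tuple[str, ...] = SC_PRODUCTS,
    thresholds: dict[str, float] | None = None,
    blanks_as_zero: bool = True,
) -> dict[str, ExcitationFunction]:
    """Excitation curves for the requested products, threshold-anchored."""
    df = df if df is not None else load_xs_fixture()
    thresholds = thresholds or load_thresholds()
    out = {}
    for product in products:
        pts = fit_points(df, product, thresholds[product], blanks_as_zero)
        out[product] = fit_excitation(pts, thresholds[product], product)
    return out


# ---------------------------------------------------------------- yields


def load_yield_fixture() -> pd.DataFrame:
    """Packaged per-scenario EOB yields (MBq per uA) for the Sc products."""
    return pd.read_csv(data_path("yields_ti48.csv"))


def activity_set_from_yields(
    df: pd.DataFrame, t_irr_h: float, e_entry_mev: float
) -> ActivitySet:
    """EOB activity set for one scenario row of a yield table."""
    sel = df[(df["t_irr_h"] == t_irr_h) & (df["e_entry_mev"] == e_entry_mev)]
    if len(sel) != 1:
        raise InvalidInputError(
            f"no unique scenario with t_irr={t_irr_h} h, E<{e_entry_mev} MeV"
        )
    row = sel.iloc[0]
    acts = {
        nuc: float(row[nuc])
        for nuc in SC_PRODUCTS
        if nuc in df.columns and pd.notna(row[nuc])
    }
    return ActivitySet(acts)


# ---------------------------------------------------------------- stacks


def load_stack_json(path: str | Path) -> list[FoilSpec]:
    """Stack description: JSON list of layers.

    Each layer gives ``material``, a ``role`` and either
    ``areal_density_ug_cm2`` or ``thickness_um`` (areal density then
    follows from the material's bulk density).
    """
    layers = json.loads(Path(path).read_text())
    if not isinstance(layers, list) or not layers:
        raise SchemaError("stack file must be a non-empty JSON list")
    out = []
    for i, spec in enumerate(layers):
        try:
            material = MATERIALS[spec["material"]]
        except KeyError:
            raise SchemaError(f"layer {i}: unknown material {spec.get('material')!r}")
        role = spec.get("role", "degrader")
        name = spec.get("name", f"{spec['material']}-{i}")
        if "areal_density_ug_cm2" in spec:
            out.append(
                FoilSpec(material, float(spec["areal_density_ug_cm2"]), role, name,
                         float(spec.get("areal_density_unc_ug_cm2", 0.0)))
            )
        elif "thickness_um" in spec:
            out.append(FoilSpec.from_thickness(material, float(spec["thickness_um"]), role, name))
        else:
            raise SchemaError(f"layer {i}: needs areal_density_ug_cm2 or thickness_um")
    return out


# ---------------------------------------------------------------- pipeline


@dataclass
class RunConfig:
    """Paths and options for one end-to-end extraction + planning run."""

    stack: str
    measurements: str
    nuclides: str | None = None  # default packaged fixture
    monitor: str | None = None
    thresholds: str | None = None
    scenarios: str | None = None  # JSON list of scenario dicts
    e0_mev: float = 70.0
    e0_unc_kev: float = 500.0
    t_irr_h: float = 1.0
    enrichment: float = 0.9932
    it_branch: float = 0.988
    rnp_target: float = 0.99
    rnp_horizon_h: float = 5000.0
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise SchemaError("config must be a mapping")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise SchemaError(f"bad config field: {exc}") from exc
        base = Path(path).parent
        for attr in ("stack", "measurements", "nuclides", "monitor", "thresholds", "scenarios"):
            val = getattr(cfg, attr)
            if val is not None:
                p = (base / val) if not Path(val).is_absolute() else Path(val)
                if not p.exists():
                    raise SchemaError(f"config field {attr!r}: file {p} does not exist")
                setattr(cfg, attr, str(p))
        return cfg


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def extract_cross_sections(
    config: RunConfig,
    registry: NuclideRegistry | None = None,
) -> pd.DataFrame:
    """Measurements CSV + stack -> wide cross-section table.

    The measurements CSV has columns (foil_id, nuclide, line_kev, counts,
    counts_unc, t_cool_h, t_real_h, t_live_h, eff, eff_unc) plus
    per-foil metadata columns (areal_density_ug_cm2, areal_density_unc_ug_cm2,
    layer_index); the Ni monitor rows carry the 57Ni line. Repeated
    acquisitions of one (foil, product) pair are combined by
    inverse-variance weighting after individual decay correction.
    """
    registry = registry or (
        load_nuclide_table(config.nuclides) if config.nuclides else default_registry()
    )
    monitor = (
        MonitorTable.from_csv(config.monitor) if config.monitor else MonitorTable.natni_ni57()
    )
    layers = load_stack_json(config.stack)
    states = propagate_stack(BeamState(config.e0_mev, config.e0_unc_kev), layers)
    meas = pd.read_csv(config.measurements)

    def line_for(nuclide: str, line_kev: float):
        for g in registry.get(nuclide).gamma_lines:
            if abs(g.energy_kev - line_kev) < 0.5:
                return g
        raise SchemaError(f"no gamma line at {line_kev} keV for {nuclide}")

    # EOB activity per (layer, nuclide), weighted over repeated acquisitions
    activities: dict[tuple[int, str], ValueUnc] = {}
    foil_meta: dict[int, dict] = {}
    for (layer_idx, nuclide), group in meas.groupby(["layer_index", "nuclide"]):
        estimates = []
        for _, row in group.iterrows():
            g = line_for(nuclide, float(row["line_kev"]))
            m = GammaMeasurement(
                foil_id=str(row["foil_id"]),
                line=g,
                counts=float(row["counts"]),
                counts_unc=float(row["counts_unc"]),
                t_cool_h=float(row["t_cool_h"]),
                t_real_h=float(row["t_real_h"]),
                t_live_h=float(row["t_live_h"]),
                efficiency=float(row["eff"]),
                efficiency_unc=float(row.get("eff_unc", 0.0) or 0.0),
            )
            estimates.append(eob_activity(m, registry.decay_constant(nuclide)))
            foil_meta[int(layer_idx)] = {
                "foil_id": str(row["foil_id"]),
                "areal_density_ug_cm2": float(row["areal_density_ug_cm2"]),
                "areal_density_unc_ug_cm2": float(row.get("areal_density_unc_ug_cm2", 0.0) or 0.0),
            }
        activities[(int(layer_idx), str(nuclide))] = combine_activities(estimates)

    # catcher recoil correction: add Al-catcher 57Ni to the preceding monitor
    monitor_layers = [i for i, p in enumerate(states) if p.layer.role == "monitor"]
    for i in monitor_layers:
        catcher = (i + 1, "Ni-57")
        if catcher in activities and states[i + 1].layer.role == "catcher":
            total, _ = add_recoil(activities[(i, "Ni-57")].value, activities[catcher].value)
            rel = activities[(i, "Ni-57")].rel
            activities[(i, "Ni-57")] = ValueUnc(total, total * rel)

    lam57 = registry.decay_constant("Ni-57")
    rows: dict[int, dict] = {}
    for i in [i for i, p in enumerate(states) if p.layer.role == "target"]:
        # nearest downstream monitor measures the flux for this target
        mon_idx = min((j for j in monitor_layers if j >= i), default=None)
        if mon_idx is None or (mon_idx, "Ni-57") not in activities:
            continue
        mon_layer = states[mon_idx].layer
        n_t_ni = (
            mon_layer.areal_density_ug_cm2 * 1e-6 * 6.02214076e23 / 58.6934
        )
        sig = monitor(states[mon_idx].mid.energy_mev)
        phi = average_flux(activities[(mon_idx, "Ni-57")], n_t_ni, sig, lam57, config.t_irr_h)
        meta = foil_meta.get(i)
        if meta is None:
            continue
        foil = TargetFoil(
            foil_id=meta["foil_id"],
            nuclide="Ti-48",
            areal_density_ug_cm2=meta["areal_density_ug_cm2"],
            areal_density_unc_ug_cm2=meta["areal_density_unc_ug_cm2"],
            enrichment=config.enrichment,
        )
        row = rows.setdefault(
            i,
            {
                "target_id": meta["foil_id"],
                "energy_mev": states[i].mid.energy_mev,
                "energy_unc_mev": states[i].mid.energy_unc_kev / 1000.0,
            },
        )
        for product in PRODUCTS:
            key = (i, product)
            if key not in activities:
                continue
            pt = production_cross_section(
                activities[key],
                phi,
                foil,
                registry.decay_constant(product),
                config.t_irr_h,
                (states[i].mid.energy_mev, states[i].mid.energy_unc_kev),
                product,
            )
            row[product] = pt.sigma_mb
            row[f"{product}_unc"] = pt.sigma_unc_mb
    return pd.DataFrame(sorted(rows.values(), key=lambda r: -r["energy_mev"]))


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute extraction + planning and write the artifact bundle.

    Writes the cross-section table, the per-scenario yield table, one
    RNP curve per scenario, and a provenance log (hashes of inputs, seed,
    package/library versions, options actually used).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = (
        load_nuclide_table(config.nuclides, it_branch=config.it_branch)
        if config.nuclides
        else default_registry(it_branch=config.it_branch)
    )
    artifacts: dict[str, Path] = {}

    xs_df = extract_cross_sections(config, registry)
    xs_path = outdir / "cross_sections.csv"
    write_xs_csv(xs_path, xs_df)
    artifacts["cross_sections"] = xs_path

    if config.scenarios:
        thresholds = load_thresholds(config.thresholds)
        scen_raw = json.loads(Path(config.scenarios).read_text())
        scenarios = [
            Scenario(
                e_entry_mev=s["e_entry_mev"],
                e_exit_mev=s.get("e_exit_mev", 0.0),
                t_irr_h=s.get("t_irr_h", 24.0),
                current_ua=s.get("current_ua", 1.0),
            )
            for s in scen_raw
        ]
        products = [p for p in SC_PRODUCTS if p in xs_df.columns and xs_df[p].notna().any()]
        xs_map = fitted_excitations(xs_df, tuple(products), thresholds)
        ytab = yield_table(xs_map, scenarios, registry)
        ypath = outdir / "yields.csv"
        ytab.to_csv(ypath, index=False, na_rep="")
        artifacts["yields"] = ypath

        for sc, (_, yrow) in zip(scenarios, ytab.iterrows()):
            acts = {
                p: float(yrow[f"{p} [MBq]"])
                for p in products
                if pd.notna(yrow[f"{p} [MBq]"])
            }
            if not acts or "Sc-47" not in acts:
                continue
            a0 = ActivitySet(acts)
            t_grid = np.arange(0.0, config.rnp_horizon_h + 1.0, 10.0)
            curve = pd.DataFrame(
                {
                    "t_h": t_grid,
                    "rnp": [rnp(decay_activities(a0, float(t), registry)) for t in t_grid],
                }
            )
            tag = f"e{sc.e_entry_mev:g}_t{sc.t_irr_h:g}"
            cpath = outdir / f"rnp_{tag}.csv"
            curve.to_csv(cpath, index=False)
            artifacts[f"rnp_{tag}"] = cpath

    prov = {
        "package": "foilyield",
        "version": __version__,
        "seed": config.seed,
        "options": {
            "e0_mev": config.e0_mev,
            "e0_unc_kev": config.e0_unc_kev,
            "t_irr_h": config.t_irr_h,
            "enrichment": config.enrichment,
            "it_branch": config.it_branch,
            "rnp_target": config.rnp_target,
            "rnp_horizon_h": config.rnp_horizon_h,
        },
        "inputs": {
            name: _sha256(path)
            for name, path in (
                ("stack", config.stack),
                ("measurements", config.measurements),
                ("nuclides", config.nuclides),
                ("monitor", config.monitor),
                ("thresholds", config.thresholds),
                ("scenarios", config.scenarios),
            )
            if path
        },
        "libraries": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    ppath = outdir / "provenance.json"
    ppath.write_text(json.dumps(prov, indent=2, sort_keys=True))
    artifacts["provenance"] = ppath
    return artifacts
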