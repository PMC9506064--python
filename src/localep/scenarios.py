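"""Scenario dispatch and tabular/JSON reporting.

Each scenario ties the solvers into one reproducible experiment with
CSV/JSON artifacts and a manifest.  The bundled scenarios reproduce the
package's headline computations:

``fig2d``
    Electroporated membrane fraction versus U_subs for the three
    commercial substrates and both cell sizes.
``fig3``
    U_subs/U_app fraction and homogeneity per electrode configuration
    in the full insert model.
``table1-check``
    Recomputes the effective substrate conductances and diffs them
    against the reference parameter table.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, write_manifest
from .design import (
    design_sweep,
    effective_substrate_conductance,
    pore_areal_fraction,
    substrate_resistance,
)
from .insert import (
    ElectrodeConfig,
    InsertGeometry,
    solve_insert,
    usubs_homogeneity,
)
from .params import (
    default_cells,
    default_dna,
    default_liquids,
    default_membrane,
    default_substrates,
)
from .traces import PulseSpec, generate_trace, resistance_from_trace, trace_to_csv
from .unitcell import (
    build_unit_cell,
    electroporated_area_fraction,
    solve_pulse,
)

__all__ = ["run_scenario", "epmap_to_csv", "epmap_summary"]

#: reference effective conductances for the bundled parameter check, S/m^2
TABLE_G_EFF = {"0.4um": 366.0, "1.0um": 1748.0}


def epmap_to_csv(ep_map, path) -> None:
    """Element table: id, radius, class, area and N at each sampled time."""
    cols = {
        "element": np.arange(ep_map.N.shape[1]),
        "r_m": ep_map.element_r,
        "class": ep_map.classes,
        "area_m2": ep_map.areas,
    }
    for k, t in enumerate(ep_map.times):
        cols[f"N_per_m2_t{t:.3e}s"] = ep_map.N[k]
    pd.DataFrame(cols).to_csv(path, index=False)


def epmap_summary(ep_map, threshold: float = 1e13) -> dict:
    return {
        "U_subs_V": ep_map.U_subs,
        "duration_s": ep_map.duration,
        "electroporated_fraction": electroporated_area_fraction(ep_map, threshold),
        "max_N_per_m2": float(ep_map.N_final.max()),
        "total_pore_count_final": float(ep_map.pore_count[-1]),
        "current_imbalance": ep_map.current_imbalance,
    }


def _resolved(config: RunConfig, extra: dict) -> dict:
    out = dict(config.sections)
    out.update(extra)
    return out


def _default_cell(config: RunConfig):
    return config.sections.get("cell", default_cells()["large"])


def _default_substrate(config: RunConfig):
    return config.sections.get("substrate", default_substrates()["0.4um"])


def _liquids(config: RunConfig) -> dict:
    liq = default_liquids()
    for k in ("extracellular", "intracellular"):
        if k in config.sections:
            liq[k] = config.sections[k]
    return liq


def _run_unit_cell(config: RunConfig, outdir: Path) -> dict:
    cell = _default_cell(config)
    substrate = _default_substrate(config)
    membrane = config.sections.get("membrane", default_membrane())
    grid = config.options.get("voltage_grid", [1.0, 2.5, 5.0, 7.5, 10.0])
    duration = config.options.get("duration", 10e-3)
    problem = build_unit_cell(cell, substrate, _liquids(config), membrane)
    rows, onset = [], None
    for u in grid:
        m = solve_pulse(problem, u, duration)
        frac = electroporated_area_fraction(m)
        if onset is None and m.N_final.max() > 1e13:
            onset = u
        rows.append({"U_subs_V": u, **epmap_summary(m)})
        epmap_to_csv(m, outdir / f"epmap_{u:g}V.csv")
    pd.DataFrame(rows).to_csv(outdir / "fractions.csv", index=False)
    summary = {"onset_V": onset, "voltage_grid_V": list(grid)}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return {"cell": cell, "substrate": substrate, "membrane": membrane,
            "voltage_grid": list(grid), "duration": duration}


def _run_insert(config: RunConfig, outdir: Path) -> dict:
    geom = InsertGeometry(**config.options.get("geometry", {}))
    electrodes = ElectrodeConfig(**config.options.get("electrodes", {}))
    substrate = _default_substrate(config)
    sol = solve_insert(geom, electrodes, substrate,
                       mesh_size=config.options.get("mesh_size", 1e-4))
    pd.DataFrame(
        {"r_m": sol.profile_r, "U_subs_V": sol.usubs_profile,
         "area_m2": sol.profile_areas}
    ).to_csv(outdir / "usubs_profile.csv", index=False)
    summary = {
        "resistance_ohm": sol.resistance,
        "mean_usubs_fraction": sol.mean_usubs_fraction,
        "homogeneity_spread": usubs_homogeneity(sol),
        "total_current_A": sol.total_current,
        "current_imbalance": sol.current_imbalance,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return {"geometry": geom, "electrodes": electrodes, "substrate": substrate}


def _run_design(config: RunConfig, outdir: Path) -> dict:
    dna = config.sections.get("dna", default_dna())
    dias = config.options.get("pore_diameters",
                              [0.1e-6, 0.2e-6, 0.3e-6, 0.4e-6, 1.0e-6])
    rhos = config.options.get("porosities", [2.0e10])
    area = config.options.get("substrate_area", 0.33e-4)
    grid = config.options.get("voltage_grid", [2.5, 5.0])
    table = design_sweep(dias, rhos, area, dna, grid)
    table.to_csv(outdir / "design_sweep.csv", index=False)
    return {"dna": dna, "pore_diameters": dias, "porosities": rhos,
            "substrate_area": area, "voltage_grid": grid}


def _run_fixture(config: RunConfig, outdir: Path) -> dict:
    pulse = PulseSpec(**config.options.get("pulse", {}))
    r_true = config.options.get("true_resistance", 159.0)
    noise = config.options.get("noise_level", 0.05)
    trace = generate_trace(pulse, r_true, noise, seed=config.seed)
    trace_to_csv(trace, outdir / "trace.csv")
    summary = {
        "true_resistance_ohm": r_true,
        "estimated_resistance_ohm": resistance_from_trace(trace),
        "estimated_resistance_peak_ohm": resistance_from_trace(trace, "peak"),
        "noise_level": noise,
        "seed": config.seed,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return {"pulse": pulse, "true_resistance": r_true, "noise_level": noise}


def _run_fig2d(config: RunConfig, outdir: Path) -> dict:
    grid = config.options.get("voltage_grid", [1.0, 2.5, 5.0, 7.5, 10.0])
    duration = config.options.get("duration", 10e-3)
    membrane = config.sections.get("membrane", default_membrane())
    rows = []
    for cell_name, cell in default_cells().items():
        for sub_name, sub in default_substrates().items():
            problem = build_unit_cell(cell, sub, _liquids(config), membrane)
            for u in grid:
                m = solve_pulse(problem, u, duration)
                rows.append(
                    {
                        "cell": cell_name,
                        "substrate": sub_name,
                        "U_subs_V": u,
                        "electroporated_fraction": electroporated_area_fraction(m),
                        "max_N_per_m2": float(m.N_final.max()),
                    }
                )
    pd.DataFrame(rows).to_csv(outdir / "fig2d_fractions.csv", index=False)
    return {"voltage_grid": list(grid), "duration": duration}


def _run_fig3(config: RunConfig, outdir: Path) -> dict:
    geom = InsertGeometry(**config.options.get("geometry", {}))
    configs = {
        "II-ring": ElectrodeConfig(bottom_kind="ring", ring_radius=5e-3),
        "IV-spiral-wire-top": ElectrodeConfig(bottom_kind="spiral", top_kind="wire"),
        "V-plate": ElectrodeConfig(bottom_kind="plate", top_kind="plate"),
    }
    out: dict = {}
    for sub_name in ("0.4um", "1.0um"):
        sub = default_substrates()[sub_name]
        for cfg_name, el in configs.items():
            sol = solve_insert(geom, el, sub)
            out[f"{sub_name}/{cfg_name}"] = {
                "mean_usubs_fraction": sol.mean_usubs_fraction,
                "homogeneity_spread": usubs_homogeneity(sol),
                "resistance_ohm": sol.resistance,
            }
    (outdir / "fig3_configurations.json").write_text(
        json.dumps(out, indent=2) + "\n"
    )
    return {"geometry": geom, "configurations": list(configs)}


def _run_table_check(config: RunConfig, outdir: Path) -> dict:
    liq = _liquids(config)
    sigma_e = liq["extracellular"].sigma
    rows = []
    for name, sub in default_substrates().items():
        g = effective_substrate_conductance(sub, sigma_e)
        ref = TABLE_G_EFF.get(name)
        rows.append(
            {
                "substrate": name,
                "G_eff_S_per_m2": g,
                "reference_S_per_m2": ref if ref is not None else math.nan,
                "relative_difference": (g - ref) / ref if ref else math.nan,
                "areal_fraction": pore_areal_fraction(sub),
                "R_ohm_at_0.33cm2": substrate_resistance(sub, 0.33e-4, sigma_e),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "table_check.csv", index=False)
    ok = bool(
        np.all(np.abs(df["relative_difference"].dropna()) < 5e-3)
    )
    (outdir / "summary.json").write_text(
        json.dumps({"all_within_0.5_percent": ok}, indent=2) + "\n"
    )
    return {"sigma_e": sigma_e}


_DISPATCH = {
    "unit-cell": _run_unit_cell,
    "insert": _run_insert,
    "design-sweep": _run_design,
    "fixture": _run_fixture,
    "fig2d": _run_fig2d,
    "fig3": _run_fig3,
    "table1-check": _run_table_check,
}


def run_scenario(config: RunConfig) -> Path:
    """Execute a scenario, writing artifacts and the manifest; returns
    the output directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    resolved = _DISPATCH[config.scenario](config, outdir)
    write_manifest(config, _resolved(config, resolved), outdir)
    return outdir
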