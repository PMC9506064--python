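"""Closed-form design layer for choosing substrates and pulse parameters.

Three desk calculators govern the practical design space of
insert-based gene electrotransfer:

* the effective areal conductance of the homogenized porous substrate,
  ``G_subs_eff = rho * 2 sigma_e pi r^2 / (pi r + 2 d)`` — the parallel
  combination of every pore's channel resistance ``d/(sigma pi r^2)``
  and two-sided access resistance ``1/(2 sigma r)``;
* the electrophoretic translocation time of plasmid DNA across the
  substrate, ``t_trans = d^2 / (mu * U_subs)``, using the in-pore field
  approximation ``E = U_subs / d``;
* the pore areal fraction ``pi r^2 rho``, which scales the diffusive
  flux of solutes (wanted: plasmid; unwanted: electrochemical
  by-products) across the substrate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .params import DNASpec, InvalidInputError, SubstrateSpec

__all__ = [
    "effective_substrate_conductance",
    "pore_conductance",
    "translocation_time",
    "substrate_resistance",
    "pore_areal_fraction",
    "design_sweep",
    "SubstrateDesignPoint",
    "UnfoldedTranslocationWarning",
]


class UnfoldedTranslocationWarning(UserWarning):
    """The plasmid coil is wider than the substrate pore; the
    unfolded-translocation assumption behind the time estimate fails."""


def pore_conductance(pore_radius: float, thickness: float, sigma_e: float) -> float:
    """Conductance of a single liquid-filled cylindrical pore (S),
    including access resistance on both faces:
    ``2 sigma pi r^2 / (pi r + 2 d)``."""
    r, d = pore_radius, thickness
    return 2.0 * sigma_e * math.pi * r * r / (math.pi * r + 2.0 * d)


def effective_substrate_conductance(spec: SubstrateSpec, sigma_e: float) -> float:
    """Homogenized areal conductance of the substrate, S/m²; linear in
    porosity."""
    if sigma_e <= 0:
        raise InvalidInputError("sigma_e must be > 0")
    return spec.porosity * pore_conductance(spec.pore_radius, spec.thickness, sigma_e)


def translocation_time(dna: DNASpec, substrate: SubstrateSpec, U_subs: float) -> float:
    """Time (s) for a plasmid to traverse the substrate electrophoretically.

    Inversely proportional to ``U_subs``; independent of the pore radius
    because the in-pore field ``U_subs/d`` is.  Warns when the coil
    (diameter ``2 R_g``) does not fit through a pore unfolded.
    """
    if U_subs <= 0:
        raise InvalidInputError(f"U_subs must be > 0, got {U_subs}")
    if 2.0 * dna.radius_of_gyration > substrate.pore_diameter:
        warnings.warn(
            f"plasmid coil (2 R_g = {2 * dna.radius_of_gyration * 1e6:.3f} um "
            f"unstained; stained 2 R_g = "
            f"{2 * dna.radius_of_gyration_stained * 1e6:.3f} um) exceeds the "
            f"pore diameter {substrate.pore_diameter * 1e6:.3f} um; the "
            "unfolded-translocation estimate is optimistic",
            UnfoldedTranslocationWarning,
            stacklevel=2,
        )
    return substrate.thickness**2 / (dna.electrophoretic_mobility * U_subs)


def substrate_resistance(spec: SubstrateSpec, area: float, sigma_e: float) -> float:
    """Electrical resistance (Ω) of a substrate patch of the given area.

    A zero-porosity substrate is a perfect insulator and returns
    ``math.inf`` rather than raising.
    """
    if area <= 0:
        raise InvalidInputError(f"area must be > 0, got {area}")
    g = effective_substrate_conductance(spec, sigma_e)
    if g == 0.0:
        return math.inf
    return 1.0 / (g * area)


def pore_areal_fraction(spec: SubstrateSpec) -> float:
    """Fraction of the substrate face occupied by pore mouths."""
    return spec.areal_fraction


@dataclass(frozen=True)
class SubstrateDesignPoint:
    """One substrate candidate with its derived electrical figures."""

    substrate: SubstrateSpec
    G_subs_eff: float
    resistance: float
    areal_fraction: float


def design_sweep(
    pore_diameters: list[float],
    porosities: list[float],
    area: float,
    dna: DNASpec,
    U_subs_grid: list[float],
    thickness: float = 10e-6,
    sigma_e: float = 1.5,
) -> pd.DataFrame:
    """Tabulate the design calculators over a Cartesian grid.

    Row order is deterministic: diameter-major, porosity-minor.  One
    translocation-time column per grid voltage, in milliseconds.
    """
    if not pore_diameters or not porosities or not U_subs_grid:
        raise InvalidInputError("sweep grids must be non-empty")
    rows = []
    for dia in pore_diameters:
        for rho in porosities:
            spec = SubstrateSpec(
                thickness=thickness, pore_radius=dia / 2.0, porosity=rho
            )
            row = {
                "diameter_um": dia * 1e6,
                "porosity_per_cm2": rho * 1e-4,
                "G_eff_S_per_m2": effective_substrate_conductance(spec, sigma_e),
                "R_ohm": substrate_resistance(spec, area, sigma_e),
                "areal_fraction": pore_areal_fraction(spec),
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UnfoldedTranslocationWarning)
                for u in U_subs_grid:
                    row[f"t_trans_ms_at_{u:g}V"] = (
                        translocation_time(dna, spec, u) * 1e3
                    )
            rows.append(row)
    return pd.DataFrame(rows)
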