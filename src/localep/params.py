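"""Domain parameter types and the bundled default parameter set.

The defaults reproduce the model-parameter table used throughout:
CHO-like adherent cells on track-etched PET insert substrates, pulsed in
physiological saline.  Every quantity is stored in SI; configuration
files may use the mixed lab units handled by :mod:`localep.units`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .units import parse_quantity

__all__ = [
    "MembraneParams",
    "MembraneState",
    "LiquidProperties",
    "CellGeometry",
    "SubstrateSpec",
    "DNASpec",
    "default_membrane",
    "default_liquids",
    "default_cells",
    "default_substrates",
    "default_dna",
    "derived_pore_conductivity",
]


class InvalidInputError(ValueError):
    """A physically invalid or non-finite input."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidInputError(msg)


def derived_pore_conductivity(sigma_e: float, sigma_i: float) -> float:
    """Electropore conductivity (σe − σi)/ln(σe/σi).

    The logarithmic mean of the two liquid conductivities; it always lies
    between σi and σe for σe ≠ σi.
    """
    _require(sigma_e > 0 and sigma_i > 0, "conductivities must be positive")
    if sigma_e == sigma_i:
        return sigma_e
    return (sigma_e - sigma_i) / math.log(sigma_e / sigma_i)


@dataclass(frozen=True)
class MembraneParams:
    """Passive electrical properties and electroporation kinetics of the
    cell membrane.

    Attributes
    ----------
    G_cm : float
        Passive (resting) membrane conductance, S/m².
    C_cm : float
        Membrane capacitance, F/m².
    d_cm : float
        Membrane thickness, m.
    r_p : float
        Radius of a single electropore, m (fixed; pore expansion is not
        modelled).
    sigma_p : float
        Conductivity of the solution inside an electropore, S/m.
    alpha : float
        Electropore creation-rate prefactor, m⁻² s⁻¹.
    q : float
        Electroporation constant (dimensionless asymmetry of creation vs
        equilibrium).
    V_ep : float
        Characteristic voltage of electroporation, V.
    N_0 : float
        Equilibrium electropore density at U_cm = 0, m⁻².
    """

    G_cm: float = 2.0
    C_cm: float = 1e-2
    d_cm: float = 5e-9
    r_p: float = 1e-9
    sigma_p: float = derived_pore_conductivity(1.5, 0.5)
    alpha: float = 1e9
    q: float = 2.46
    V_ep: float = 0.25
    N_0: float = 1.5e9

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _require(
                isinstance(v, (int, float)) and math.isfinite(v) and v > 0,
                f"MembraneParams.{f.name} must be finite and positive, got {v!r}",
            )


@dataclass(frozen=True)
class MembraneState:
    """Instantaneous local state of one membrane element.

    ``G_ep`` is the deterministic image of ``N`` under the electropore
    conductance law and is stored only for convenience.
    """

    U_cm: float = 0.0
    N: float = 1.5e9
    G_ep: float = 0.0

    def __post_init__(self) -> None:
        _require(math.isfinite(self.U_cm), "U_cm must be finite")
        _require(math.isfinite(self.N) and self.N >= 0.0, "N must be finite and >= 0")
        _require(math.isfinite(self.G_ep) and self.G_ep >= 0.0, "G_ep must be >= 0")


@dataclass(frozen=True)
class LiquidProperties:
    """Electrical properties of an electrolyte (intra- or extracellular)."""

    sigma: float  # conductivity, S/m
    relative_permittivity: float | None = None

    def __post_init__(self) -> None:
        _require(math.isfinite(self.sigma) and self.sigma > 0, "sigma must be > 0")


@dataclass(frozen=True)
class CellGeometry:
    """Adherent cell modelled as a half oblate spheroid (spheroidal cap)
    with its flat face toward the substrate, separated by a thin liquid gap.
    """

    height: float = 15e-6
    largest_semiaxis: float = 40e-6
    shape: str = "spheroidal-cap"
    gap_to_substrate: float = 100e-9

    def __post_init__(self) -> None:
        _require(self.height > 0 and self.largest_semiaxis > 0, "dimensions must be > 0")
        _require(
            self.height <= self.largest_semiaxis,
            "cell height must not exceed the largest semiaxis",
        )
        _require(
            50e-9 <= self.gap_to_substrate <= 150e-9,
            "gap_to_substrate outside the supported 50-150 nm sensitivity range",
        )

    @property
    def footprint_radius(self) -> float:
        return self.largest_semiaxis

    def dome_height(self, r):
        """Height of the dome membrane above the substrate plane at
        radius ``r`` (scalar or array); zero outside the footprint."""
        import numpy as np

        a, c = self.largest_semiaxis, self.height
        rr = np.minimum(np.abs(np.asarray(r, dtype=float)) / a, 1.0)
        h = c * np.sqrt(1.0 - rr**2)
        return h if h.ndim else float(h)

    @property
    def footprint_area(self) -> float:
        return math.pi * self.largest_semiaxis**2

    @property
    def dome_area(self) -> float:
        """Surface area of the half oblate spheroid dome."""
        a, c = self.largest_semiaxis, self.height
        if abs(a - c) / a < 1e-12:
            return 2.0 * math.pi * a * a  # hemisphere
        e = math.sqrt(1.0 - (c / a) ** 2)
        full = 2.0 * math.pi * a * a * (1.0 + ((1.0 - e * e) / e) * math.atanh(e))
        return 0.5 * full

    @property
    def membrane_area(self) -> float:
        """Total membrane area: dome plus substrate-facing flat face."""
        return self.dome_area + self.footprint_area


@dataclass(frozen=True)
class SubstrateSpec:
    """Track-etched porous substrate: cylindrical pores through an
    insulating film.

    ``porosity`` is the areal number density of pores (pores per m²),
    matching manufacturer datasheets.
    """

    thickness: float = 10e-6
    pore_radius: float = 0.2e-6
    porosity: float = 2.0e10

    def __post_init__(self) -> None:
        _require(self.thickness > 0, "thickness must be > 0")
        _require(self.pore_radius > 0, "pore_radius must be > 0")
        _require(self.porosity >= 0, "porosity must be >= 0")
        _require(
            self.areal_fraction < 1.0,
            f"pore areal fraction {self.areal_fraction:.3g} must be < 1",
        )

    @property
    def areal_fraction(self) -> float:
        return math.pi * self.pore_radius**2 * self.porosity

    @property
    def pore_diameter(self) -> float:
        return 2.0 * self.pore_radius


@dataclass(frozen=True)
class DNASpec:
    """Plasmid DNA properties for the electrophoretic translocation
    estimate."""

    electrophoretic_mobility: float = 3.75e-8  # m^2/(V s), bulk, unstained
    radius_of_gyration: float = 0.110e-6  # m, unstained
    radius_of_gyration_stained: float = 0.131e-6  # m, intercalator-stained
    plasmid_size_bp: int = 4700  # informational

    def __post_init__(self) -> None:
        _require(self.electrophoretic_mobility > 0, "mobility must be > 0")
        _require(self.radius_of_gyration > 0, "radius_of_gyration must be > 0")


# --- bundled defaults (model-parameter table) -------------------------------

def default_membrane() -> MembraneParams:
    """Membrane parameter set of the reference model table."""
    return MembraneParams()


def default_liquids() -> dict[str, LiquidProperties]:
    """Extracellular saline (measured, 1.5 S/m) and cytoplasm (0.5 S/m)."""
    return {
        "extracellular": LiquidProperties(sigma=1.5),
        "intracellular": LiquidProperties(sigma=0.5),
    }


def default_cells() -> dict[str, CellGeometry]:
    """The two adherent cell sizes considered (height x largest semiaxis)."""
    return {
        "large": CellGeometry(height=15e-6, largest_semiaxis=40e-6),
        "small": CellGeometry(height=7e-6, largest_semiaxis=20e-6),
    }


def default_substrates() -> dict[str, SubstrateSpec]:
    """Commercial insert substrates by pore diameter (10 µm PET film)."""
    return {
        "0.4um": SubstrateSpec(thickness=10e-6, pore_radius=0.2e-6, porosity=2.0e10),
        "1.0um": SubstrateSpec(thickness=10e-6, pore_radius=0.5e-6, porosity=1.6e10),
        "3.0um": SubstrateSpec(thickness=10e-6, pore_radius=1.5e-6, porosity=0.8e10),
    }


def default_dna() -> DNASpec:
    return DNASpec()


_SECTION_TYPES = {
    "membrane": MembraneParams,
    "cell": CellGeometry,
    "substrate": SubstrateSpec,
    "dna": DNASpec,
    "extracellular": LiquidProperties,
    "intracellular": LiquidProperties,
}


def build_section(section: str, data: dict | None):
    """Instantiate the dataclass for a configuration section.

    Values may be numbers (SI) or strings with units.  Unknown keys are
    rejected so that typos never silently fall back to defaults.
    """
    cls = _SECTION_TYPES.get(section)
    if cls is None:
        raise InvalidInputError(f"unknown configuration section {section!r}")
    data = dict(data or {})
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise InvalidInputError(
            f"unknown keys in section {section!r}: {sorted(unknown)}"
        )
    kwargs = {}
    for k, v in data.items():
        if k == "shape":
            kwargs[k] = str(v)
        elif k == "plasmid_size_bp":
            kwargs[k] = int(v)
        else:
            kwargs[k] = parse_quantity(v)
    return cls(**kwargs)
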