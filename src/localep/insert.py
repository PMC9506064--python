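"""Steady-state potential solver for the full insert-in-well device.

The hanging cell-culture insert sits in one well of a multiwell plate:
bottom liquid (plasmid solution) fills the 0.8 mm space between the
well bottom and the porous substrate, top liquid (growth medium) fills
the insert above it.  At the pulse plateau the electrolytes are ohmic,
so the potential obeys Laplace's equation in each liquid, and the
homogenized substrate enters as a purely conductive interface carrying
the normal current density ``G_subs_eff * U_subs``.

The device is discretized by a conservative finite-volume scheme on an
axisymmetric (r, z) grid: two rectangular domains (well bottom, insert
interior) coupled column-by-column through the substrate interface.
Wire electrodes are idealized as equipotential boundary patches; the
experimentally preferred spiral bottom electrode behaves like a plate
and is modelled as one.  Solving the sparse linear system yields the
potential field, the radial profile of the substrate voltage U_subs,
the total current, and the system resistance U_app / I.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .design import effective_substrate_conductance
from .params import InvalidInputError, LiquidProperties, SubstrateSpec

__all__ = [
    "InsertGeometry",
    "ElectrodeConfig",
    "SystemSolution",
    "solve_insert",
    "system_resistance",
    "usubs_homogeneity",
    "ConfigurationError",
    "UndefinedResistanceError",
]


class ConfigurationError(ValueError):
    """Electrode/geometry combination that cannot be solved."""


class UndefinedResistanceError(ZeroDivisionError):
    """Resistance requested for a solution carrying no current."""


@dataclass(frozen=True)
class InsertGeometry:
    """Axisymmetric dimensions of a 24-well hanging insert in its well.

    Defaults correspond to commercial 24-well inserts with 0.33 cm²
    growth area hanging 0.8 mm above the well bottom; the exact insert
    and well radii are configurable because manufacturers only publish
    the growth area.
    """

    substrate_radius: float = math.sqrt(0.33e-4 / math.pi)  # 3.24 mm
    insert_radius: float = 4.1e-3
    well_radius: float = 7.8e-3
    bottom_gap: float = 0.8e-3
    top_liquid_height: float = 5.7e-3  # 300 uL over the insert section
    top_electrode_standoff: float = 2.0e-3

    def __post_init__(self) -> None:
        if not (self.substrate_radius < self.insert_radius < self.well_radius):
            raise InvalidInputError(
                "require substrate_radius < insert_radius < well_radius"
            )
        for name in (
            "substrate_radius",
            "bottom_gap",
            "top_liquid_height",
            "top_electrode_standoff",
        ):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        if self.top_electrode_standoff > self.top_liquid_height:
            raise InvalidInputError("top electrode must be immersed in the top liquid")

    @property
    def substrate_area(self) -> float:
        return math.pi * self.substrate_radius**2


@dataclass(frozen=True)
class ElectrodeConfig:
    """Electrode shapes and drive.

    ``bottom_kind`` is one of ``plate``, ``ring`` or ``spiral``; a spiral
    with enough turns is electrically equivalent to a plate and is
    modelled as one.  The top electrode is always treated as a
    plate-equivalent at its minimum standoff.  ``polarity``
    ``top-positive`` drives DNA (anion) from the bottom well into the
    cells; ``bottom-positive`` drives propidium the other way.
    """

    bottom_kind: str = "spiral"
    ring_radius: float | None = None
    applied_voltage: float = 1.0
    polarity: str = "top-positive"
    wire_radius: float = 0.25e-3  # 0.5 mm diameter wire
    top_kind: str = "wire"
    # Default None: the L-shaped top wire arm is represented as a ring
    # arc whose circumference equals the immersed wire length, computed
    # from the geometry at solve time.
    top_ring_radius: float | None = None

    def __post_init__(self) -> None:
        if self.bottom_kind not in ("plate", "ring", "spiral"):
            raise InvalidInputError(f"unknown bottom electrode {self.bottom_kind!r}")
        if self.top_kind not in ("wire", "plate"):
            raise InvalidInputError(f"unknown top electrode {self.top_kind!r}")
        if self.polarity not in ("top-positive", "bottom-positive"):
            raise InvalidInputError(f"unknown polarity {self.polarity!r}")
        if self.bottom_kind == "ring" and self.ring_radius is None:
            raise InvalidInputError("ring electrode requires ring_radius")


@dataclass
class SystemSolution:
    """Solved potential field and derived device metrics (SI units).

    ``usubs_profile`` is signed with the polarity of the drive;
    ``mean_usubs_fraction`` is ``mean(|U_subs|)/U_app``.
    """

    geometry: InsertGeometry
    electrodes: ElectrodeConfig
    G_subs_eff: float
    r_bottom: np.ndarray
    z_bottom: np.ndarray
    V_bottom: np.ndarray
    r_top: np.ndarray
    z_top: np.ndarray
    V_top: np.ndarray
    profile_r: np.ndarray
    usubs_profile: np.ndarray
    profile_areas: np.ndarray
    mean_usubs_fraction: float
    total_current: float
    resistance: float
    current_imbalance: float = 0.0
    extras: dict = field(default_factory=dict)


def _column_areas(r_centers: np.ndarray, dr: float, radius: float) -> np.ndarray:
    """Annulus area of each grid column clipped to a disc of given radius."""
    inner = np.maximum(r_centers - dr / 2.0, 0.0)
    outer = np.minimum(r_centers + dr / 2.0, radius)
    a = math.pi * (outer**2 - inner**2)
    return np.where(outer > inner, a, 0.0)


def solve_insert(
    geom: InsertGeometry,
    electrodes: ElectrodeConfig,
    substrate: SubstrateSpec,
    liquids: dict[str, LiquidProperties] | None = None,
    mesh_size: float = 1.0e-4,
) -> SystemSolution:
    """Solve the axisymmetric steady-state device problem.

    Parameters
    ----------
    liquids:
        Mapping with keys ``top`` and ``bottom`` (defaults: 1.5 S/m
        saline on both sides, the measured medium conductivity).
    mesh_size:
        Target grid spacing in metres (default 0.1 mm).
    """
    if liquids is None:
        liquids = {"top": LiquidProperties(1.5), "bottom": LiquidProperties(1.5)}
    sig_t, sig_b = liquids["top"].sigma, liquids["bottom"].sigma
    g_eff = effective_substrate_conductance(substrate, sig_b)
    if g_eff <= 0:
        raise ConfigurationError("substrate with zero porosity blocks all current")

    a = geom.substrate_radius
    dr = mesh_size
    # bottom domain: r in [0, R_well], z in [0, bottom_gap]
    nrb = max(int(round(geom.well_radius / dr)), 4)
    nzb = max(int(round(geom.bottom_gap / mesh_size)), 4)
    drb = geom.well_radius / nrb
    dzb = geom.bottom_gap / nzb
    rb = (np.arange(nrb) + 0.5) * drb
    zb = (np.arange(nzb) + 0.5) * dzb
    # top domain: tapered insert interior above the substrate; a plate
    # top electrode truncates the domain at its standoff, a wire hangs
    # inside the full liquid column
    H_top = (
        geom.top_liquid_height
        if electrodes.top_kind == "wire"
        else geom.top_electrode_standoff
    )
    nrt = max(int(round(geom.insert_radius / dr)), 4)
    nzt = max(int(round(H_top / mesh_size)), 4)
    drt = geom.insert_radius / nrt
    dzt = H_top / nzt
    rt = (np.arange(nrt) + 0.5) * drt
    zt = (np.arange(nzt) + 0.5) * dzt
    # hanging inserts taper from the substrate up to the nominal radius
    slope = (geom.insert_radius - a) / geom.top_liquid_height
    r_wall = a + slope * zt  # local inner wall radius per layer
    active = rt[None, :] - drt / 2.0 < r_wall[:, None]  # (nzt, nrt)

    nb = nrb * nzb
    nt = nrt * nzt
    n = nb + nt

    def idx_b(i: int, j: int) -> int:  # bottom domain, column i, layer j
        return j * nrb + i

    def idx_t(i: int, j: int) -> int:
        return nb + j * nrt + i

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    diag = np.zeros(n)
    rhs = np.zeros(n)

    def couple(p: int, q: int, g: float) -> None:
        rows.extend((p, q))
        cols.extend((q, p))
        vals.extend((-g, -g))
        diag[p] += g
        diag[q] += g

    def dirichlet(p: int, g: float, v: float) -> None:
        diag[p] += g
        rhs[p] += g * v

    # interior conductances, bottom domain
    for j in range(nzb):
        for i in range(nrb - 1):
            r_face = (i + 1) * drb
            couple(idx_b(i, j), idx_b(i + 1, j), sig_b * 2 * math.pi * r_face * dzb / drb)
    ring_area_b = 2 * math.pi * rb * drb  # lateral (axial-face) areas per column
    for j in range(nzb - 1):
        for i in range(nrb):
            couple(idx_b(i, j), idx_b(i, j + 1), sig_b * ring_area_b[i] / dzb)
    # interior conductances, top domain (only between active cells)
    for j in range(nzt):
        for i in range(nrt - 1):
            if active[j, i] and active[j, i + 1]:
                r_face = (i + 1) * drt
                couple(
                    idx_t(i, j), idx_t(i + 1, j),
                    sig_t * 2 * math.pi * r_face * dzt / drt,
                )
    ring_area_t = 2 * math.pi * rt * drt
    for j in range(nzt - 1):
        for i in range(nrt):
            if active[j, i] and active[j + 1, i]:
                couple(idx_t(i, j), idx_t(i, j + 1), sig_t * ring_area_t[i] / dzt)

    # substrate interface: column-wise series (half bottom cell, G_eff, half top cell)
    sub_cols_b = np.nonzero(rb - drb / 2.0 < a)[0]
    areas_int = _column_areas(rb, drb, a)
    iface: list[tuple[int, int, float, float]] = []  # (pb, pt, g_series, A_int)
    for i in sub_cols_b:
        A = areas_int[i]
        if A <= 0:
            continue
        # matching top-domain column index (same dr up to rounding)
        it = min(int(rb[i] / drt), nrt - 1)
        g_half_b = sig_b * A / (dzb / 2.0)
        g_half_t = sig_t * A / (dzt / 2.0)
        g_sub = g_eff * A
        g_series = 1.0 / (1.0 / g_half_b + 1.0 / g_sub + 1.0 / g_half_t)
        pb, pt = idx_b(i, nzb - 1), idx_t(it, 0)
        couple(pb, pt, g_series)
        iface.append((pb, pt, g_series, A))
    if not iface:
        raise ConfigurationError("substrate interface has no conducting columns")

    # electrode boundary conditions
    v_top_e = electrodes.applied_voltage if electrodes.polarity == "top-positive" else 0.0
    v_bot_e = 0.0 if electrodes.polarity == "top-positive" else electrodes.applied_voltage

    bottom_faces: list[tuple[int, float]] = []
    if electrodes.bottom_kind in ("plate", "spiral"):
        for i in range(nrb):
            g = sig_b * ring_area_b[i] / (dzb / 2.0)
            bottom_faces.append((idx_b(i, 0), g))
    else:  # ring
        rr = float(electrodes.ring_radius)  # type: ignore[arg-type]
        if rr >= geom.well_radius:
            raise ConfigurationError("ring radius must be inside the well")
        sel = np.nonzero(np.abs(rb - rr) <= electrodes.wire_radius)[0]
        if sel.size == 0:
            sel = np.array([int(np.argmin(np.abs(rb - rr)))])
        for i in sel:
            g = sig_b * ring_area_b[i] / (dzb / 2.0)
            bottom_faces.append((idx_b(i, 0), g))
    for p, g in bottom_faces:
        dirichlet(p, g, v_bot_e)

    top_faces: list[tuple[int, float]] = []
    if electrodes.top_kind == "plate":
        for i in range(nrt):
            if active[nzt - 1, i]:
                g = sig_t * ring_area_t[i] / (dzt / 2.0)
                top_faces.append((idx_t(i, nzt - 1), g))
    else:
        # Wire arc at the minimum standoff; its circular cross-section
        # is pinned as an equipotential patch of cells.  The physical
        # top electrode is an L-shaped arm (vertical drop plus a
        # horizontal reach of about one insert radius); the
        # axisymmetric surrogate is a ring with the same wetted length.
        rr = electrodes.top_ring_radius
        if rr is None:
            immersed = (
                geom.top_liquid_height
                - geom.top_electrode_standoff
                + geom.insert_radius
            )
            rr = immersed / (2.0 * math.pi)
        zc = geom.top_electrode_standoff + electrodes.wire_radius
        g_pin = 1e8 * sig_t * float(np.max(ring_area_t)) / dzt
        for j in range(nzt):
            for i in range(nrt):
                if not active[j, i]:
                    continue
                if (rt[i] - rr) ** 2 + (zt[j] - zc) ** 2 <= electrodes.wire_radius**2:
                    top_faces.append((idx_t(i, j), g_pin))
        if not top_faces:
            cand = [
                (abs(rt[i] - rr) + abs(zt[j] - zc), idx_t(i, j))
                for j in range(nzt)
                for i in range(nrt)
                if active[j, i]
            ]
            top_faces.append((min(cand)[1], g_pin))
    for p, g in top_faces:
        dirichlet(p, g, v_top_e)

    # inactive (outside the tapered wall) nodes get a trivial equation
    diag[diag == 0.0] = 1.0

    A_mat = sp.coo_matrix(
        (np.concatenate([np.asarray(vals), diag]),
         (np.concatenate([np.asarray(rows), np.arange(n)]),
          np.concatenate([np.asarray(cols), np.arange(n)]))),
        shape=(n, n),
    ).tocsr()
    V = spla.spsolve(A_mat, rhs)
    if not np.all(np.isfinite(V)):
        raise ConfigurationError("singular device system (electrode missing?)")

    Vb = V[:nb].reshape(nzb, nrb)
    Vt = V[nb:].reshape(nzt, nrt).copy()
    Vt[~active] = np.nan

    # electrode currents (positive = current injected into the liquid)
    I_bot = sum(g * (v_bot_e - V[p]) for p, g in bottom_faces)
    if electrodes.top_kind == "plate":
        I_top = sum(g * (v_top_e - V[p]) for p, g in top_faces)
    else:
        # sum physical link currents leaving the pinned wire cells;
        # this is far better conditioned than the penalty ghost links
        wire = np.zeros(n, dtype=bool)
        wire[[p for p, _ in top_faces]] = True
        rr_a = np.asarray(rows)
        cc_a = np.asarray(cols)
        gg_a = -np.asarray(vals)
        m = wire[rr_a] & ~wire[cc_a]
        I_top = float(np.sum(gg_a[m] * (V[rr_a[m]] - V[cc_a[m]])))
    imbalance = abs(I_bot + I_top) / max(abs(I_bot), abs(I_top), 1e-300)

    # substrate voltage profile: flux through each interface column
    prof_r, prof_u, prof_a = [], [], []
    for pb, pt, g_series, A in iface:
        f = g_series * (V[pb] - V[pt])  # current bottom -> top
        prof_r.append(rb[pb % nrb])
        prof_u.append(f / (g_eff * A))
        prof_a.append(A)
    prof_r = np.asarray(prof_r)
    prof_u = np.asarray(prof_u)
    prof_a = np.asarray(prof_a)
    mean_u = float(np.sum(np.abs(prof_u) * prof_a) / np.sum(prof_a))
    u_app = electrodes.applied_voltage
    frac = mean_u / u_app if u_app != 0 else 0.0

    current = abs(I_top)
    res = u_app / current if current > 0 else math.inf

    return SystemSolution(
        geometry=geom,
        electrodes=electrodes,
        G_subs_eff=g_eff,
        r_bottom=rb,
        z_bottom=zb,
        V_bottom=Vb,
        r_top=rt,
        z_top=zt,
        V_top=Vt,
        profile_r=prof_r,
        usubs_profile=prof_u,
        profile_areas=prof_a,
        mean_usubs_fraction=frac,
        total_current=float(np.sign(I_top) * current) if u_app else 0.0,
        resistance=float(res),
        current_imbalance=float(imbalance),
        extras={"I_bottom": float(I_bot), "I_top": float(I_top),
                "mesh_size": mesh_size, "active_mask": active},
    )


def system_resistance(solution: SystemSolution) -> float:
    """Device resistance U_app / I (Ω)."""
    if abs(solution.total_current) <= 0.0 or not math.isfinite(solution.resistance):
        raise UndefinedResistanceError("no current flows; resistance undefined")
    return solution.resistance


def usubs_homogeneity(solution: SystemSolution) -> float:
    """Spread statistic (max - min)/mean of the |U_subs| radial profile."""
    u = np.abs(solution.usubs_profile)
    m = float(np.mean(u))
    if m == 0.0:
        return 0.0
    return float((np.max(u) - np.min(u)) / m)
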