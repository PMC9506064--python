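"""Coupled cell-on-porous-substrate electroporation solver.

The single-cell model is a periodic "unit cell": one adherent cell
(half oblate spheroid, flat face down) hovering 100 nm above the
track-etched substrate, with substrate pores on a square lattice that
reproduces the manufacturer porosity.  A voltage pulse applied across
the substrate localizes the field inside the substrate pores; the field
leaks out of each pore mouth, charges the adjacent patch of cell
membrane, and drives electropore formation there.

Discretization is a pseudo-3D hybrid network chosen so that the three
controlling resistances (pore channel+access ≫ gap spreading ≫ bulk)
are each represented explicitly:

* every substrate pore under the cell footprint is a lumped conduit
  (cylindrical channel plus bottom-side access resistance);
* the 100 nm cell-substrate gap is a laterally conducting film,
  refined around every pore mouth by log-spaced annular rings so the
  membrane directly above a pore is resolved to a fraction of the pore
  radius;
* the substrate-facing membrane is a set of area-weighted nonlinear
  interface elements (one per annulus plus the pore-mouth disc), each
  carrying its own electropore density N;
* the cell interior is a coarse conducting sheet (one node per pore
  site, laterally linked with the local cell height as film
  thickness);
* the dome membrane is split per-site by slant-corrected area so the
  top surface porates gradually, and the surrounding bath is an
  equipotential reservoir.

Time integration couples the quasi-static network solve (membrane
capacitance by implicit Euler companion models) with the exact
exponential update of the electropore density ODE, iterated to a
self-consistent fixed point within every step.  Everything is
deterministic: the mesh derives from the geometry alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .design import pore_conductance
from .membrane import electropore_conductance, step_density
from .params import (
    CellGeometry,
    InvalidInputError,
    LiquidProperties,
    MembraneParams,
    SubstrateSpec,
)

__all__ = [
    "UnitCellProblem",
    "EpMap",
    "SolverError",
    "build_unit_cell",
    "solve_pulse",
    "electroporated_area_fraction",
    "onset_voltage_sweep",
    "EP_DETECTION_THRESHOLD",
]

#: electropore density regarded as detectable electroporation, m^-2
EP_DETECTION_THRESHOLD = 1e13


class SolverError(RuntimeError):
    """Nonlinear field/membrane coupling failed to converge."""


@dataclass
class UnitCellProblem:
    """Discretized unit-cell geometry ready for pulse solves.

    Built once by :func:`build_unit_cell`; the linear (liquid) part of
    the network is assembled here and reused across voltages.
    """

    cell: CellGeometry
    substrate: SubstrateSpec
    liquids: dict[str, LiquidProperties]
    membrane: MembraneParams
    # pore layout
    site_xy: np.ndarray  # (S, 2) pore positions under the footprint
    site_r: np.ndarray  # (S,) distance from the cell axis
    lattice_pitch: float
    n_outside_pores: float  # pores of the unit-cell square not under the cell
    # per-site annular refinement (shared by all sites)
    ring_edges: np.ndarray  # (M+1,) radii bounding the gap annuli
    # network bookkeeping (filled by build)
    n_nodes: int = 0
    fixed_rows: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    fixed_cols: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    fixed_vals: np.ndarray = field(default_factory=lambda: np.empty(0))
    fixed_diag: np.ndarray = field(default_factory=lambda: np.empty(0))
    conduit_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    conduit_g: float = 0.0
    edge_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    edge_g: np.ndarray = field(default_factory=lambda: np.empty(0))
    outside_g: float = 0.0
    # membrane element tables
    elem_node_int: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    elem_node_ext: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    elem_area: np.ndarray = field(default_factory=lambda: np.empty(0))
    elem_class: np.ndarray = field(default_factory=lambda: np.empty(0, object))
    elem_r: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_sites(self) -> int:
        return len(self.site_xy)

    @property
    def n_elements(self) -> int:
        return len(self.elem_area)


@dataclass
class EpMap:
    """Spatio-temporal electropore-density map from one pulse solve."""

    problem: UnitCellProblem
    U_subs: float
    duration: float
    times: np.ndarray  # (T,) sampled times
    N: np.ndarray  # (T, E) electropore density per element
    areas: np.ndarray  # (E,)
    classes: np.ndarray  # (E,) "substrate" | "dome"
    element_r: np.ndarray  # (E,) radial position of the element's site
    pore_count: np.ndarray  # (T,) total number of electropores on the cell
    U_cm_final: np.ndarray  # (E,) transmembrane voltage at end of pulse
    in_pore_field_initial: float  # |E| inside a substrate pore, first step
    current_imbalance: float

    @property
    def N_final(self) -> np.ndarray:
        return self.N[-1]


def _ring_edges(r_in: float, r_out: float, max_ratio: float = 1.5) -> np.ndarray:
    """Log-spaced annulus edges from the pore radius to the site radius."""
    if r_out <= r_in * (1.0 + 1e-9):
        return np.array([r_in, max(r_out, r_in * 1.0001)])
    n = max(3, int(math.ceil(math.log(r_out / r_in) / math.log(max_ratio))))
    return np.geomspace(r_in, r_out, n + 1)


def _conduit_resistance(r_p: float, d_s: float, sigma_e: float, h_gap: float) -> float:
    """Series resistance of one substrate-pore conduit: cylindrical
    channel, bottom-side access into the reservoir half-space, and the
    expansion above the mouth when the pore is narrower than the gap."""
    R = d_s / (sigma_e * math.pi * r_p**2) + 1.0 / (4.0 * sigma_e * r_p)
    if r_p < h_gap:
        R += 1.0 / (4.0 * sigma_e * r_p) - 1.0 / (4.0 * sigma_e * h_gap)
    return R


def _gap_radial_conductances(
    edges: np.ndarray, sigma_e: float, h_gap: float
) -> tuple[np.ndarray, np.ndarray]:
    """Ring-node radii and the gap-film conductances between consecutive
    ring nodes of one pore site.

    The innermost node carries the membrane element above the pore
    mouth.  The membrane plane does not see the in-pore stagnation
    potential: the emerging jet expands across the gap thickness, so the
    element samples the spreading-film potential at an effective radius
    ``0.62 r_p + 0.24 h_gap``, a rule calibrated against the fine-grid
    single-pore oracle (matching the membrane-plane potential above the
    mouth to a few percent over pore diameters 0.1-1.0 µm and gaps
    50-150 nm).
    """
    r_mouth = 0.62 * edges[0] + 0.24 * h_gap
    mids = 0.5 * (edges[:-1] + edges[1:])
    r_mouth = min(r_mouth, 0.95 * mids[0])
    r_mid = np.concatenate([[r_mouth], mids])
    g_rad = (
        2.0 * math.pi * sigma_e * h_gap
        / np.log(r_mid[1:] / np.maximum(r_mid[:-1], 1e-12))
    )
    return r_mid, g_rad


def _dome_slant(cell: CellGeometry, r: np.ndarray) -> np.ndarray:
    """Area slant factor of the dome surface above radius r (capped near
    the rim where the surface turns vertical)."""
    a, c = cell.largest_semiaxis, cell.height
    rr = np.minimum(r / a, 0.97)
    dzdr = c * rr / (a * np.sqrt(1.0 - rr**2))
    return np.sqrt(1.0 + dzdr**2)


def build_unit_cell(
    cell: CellGeometry,
    substrate: SubstrateSpec,
    liquids: dict[str, LiquidProperties] | None = None,
    membrane: MembraneParams | None = None,
) -> UnitCellProblem:
    """Discretize the cell-on-substrate geometry into the hybrid network.

    The unit-cell square has side ``2 * largest_semiaxis`` (cells tiling
    the substrate side by side); pores whose lattice position falls
    under the circular footprint couple to the cell, the remainder
    short the two reservoirs directly.
    """
    if liquids is None:
        liquids = {
            "extracellular": LiquidProperties(1.5),
            "intracellular": LiquidProperties(0.5),
        }
    if membrane is None:
        membrane = MembraneParams()
    if substrate.areal_fraction >= 1.0:  # defensive; SubstrateSpec enforces it
        raise InvalidInputError("pore areal fraction must be < 1")

    sig_e = liquids["extracellular"].sigma
    sig_i = liquids["intracellular"].sigma
    a = cell.footprint_radius
    h = cell.gap_to_substrate
    L = 2.0 * a  # periodic unit-cell side
    rho = substrate.porosity
    r_p = substrate.pore_radius
    d_s = substrate.thickness

    if rho <= 0:
        site_xy = np.empty((0, 2))
        pitch = math.inf
        n_out = 0.0
    else:
        pitch = 1.0 / math.sqrt(rho)
        n_side = max(int(math.floor(L / pitch)), 0)
        coords = (np.arange(n_side) + 0.5) * pitch - (n_side * pitch) / 2.0
        xx, yy = np.meshgrid(coords, coords)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        under = np.hypot(pts[:, 0], pts[:, 1]) < a
        site_xy = pts[under]
        n_out = rho * L * L - len(site_xy)

    prob = UnitCellProblem(
        cell=cell,
        substrate=substrate,
        liquids=liquids,
        membrane=membrane,
        site_xy=site_xy,
        site_r=np.hypot(site_xy[:, 0], site_xy[:, 1]) if len(site_xy) else np.empty(0),
        lattice_pitch=pitch,
        n_outside_pores=max(n_out, 0.0),
        ring_edges=np.empty(0),
    )

    S = len(site_xy)
    if S == 0:
        # degenerate: insulating floor, nothing couples to the membrane;
        # keep a single dome element so the map is well-formed
        prob.ring_edges = np.array([0.0, 0.0])
        prob.n_nodes = 1
        prob.fixed_diag = np.zeros(1)
        prob.elem_node_int = np.array([0])
        prob.elem_node_ext = np.array([-1])
        prob.elem_area = np.array([cell.membrane_area])
        prob.elem_class = np.array(["dome"], dtype=object)
        prob.elem_r = np.array([0.0])
        prob.outside_g = prob.n_outside_pores * pore_conductance(r_p, d_s, sig_e)
        return prob

    r_site = pitch / math.sqrt(math.pi)  # equal-area site radius
    edges = _ring_edges(r_p, r_site)
    M = len(edges) - 1
    prob.ring_edges = edges
    # node numbering: gap nodes (site-major, ring-minor incl. mouth node 0),
    # then one interior node per site
    n_gap = S * (M + 1)
    n_nodes = n_gap + S
    prob.n_nodes = n_nodes

    def gap_node(k: int, j: int) -> int:
        return k * (M + 1) + j

    def int_node(k: int) -> int:
        return n_gap + k

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(n_nodes)

    def couple_arr(p: np.ndarray, q: np.ndarray, g: np.ndarray) -> None:
        rows.append(np.concatenate([p, q]))
        cols.append(np.concatenate([q, p]))
        vals.append(np.concatenate([-g, -g]))
        np.add.at(diag, p, g)
        np.add.at(diag, q, g)

    ks = np.arange(S)

    # pore conduit: Dirichlet to the driven bottom reservoir, so it only
    # stamps the diagonal
    g_cd = 1.0 / _conduit_resistance(r_p, d_s, sig_e, h)
    prob.conduit_g = g_cd
    prob.conduit_nodes = gap_node(ks, 0)
    np.add.at(diag, prob.conduit_nodes, g_cd)

    # radial conductances in the gap film between consecutive ring nodes
    r_mid, g_rad = _gap_radial_conductances(edges, sig_e, h)
    for j in range(M):
        couple_arr(gap_node(ks, j), gap_node(ks, j + 1), np.full(S, g_rad[j]))

    # Site-to-site links (gap film and interior film) on the square
    # lattice: standard finite-volume sheet links, one lattice square
    # each.  Through-traffic between sites hops between the outer ring
    # nodes directly; the intra-site radial chain carries only the
    # injected pore current, whose local spreading resistance it
    # represents.
    key = {tuple(np.round(site_xy[k] / pitch).astype(int)): k for k in range(S)}
    heights = np.maximum(cell.dome_height(prob.site_r), 0.02 * cell.height)
    n_neighbors = np.zeros(S, int)
    pa, pb_, gi = [], [], []
    for k in range(S):
        ix, iy = np.round(site_xy[k] / pitch).astype(int)
        for dx, dy in ((1, 0), (0, 1)):
            nb = key.get((ix + dx, iy + dy))
            if nb is not None:
                pa.append(k)
                pb_.append(nb)
                gi.append(sig_i * 0.5 * (heights[k] + heights[nb]))
                n_neighbors[k] += 1
                n_neighbors[nb] += 1
    if pa:
        pa_a, pb_a = np.asarray(pa), np.asarray(pb_)
        couple_arr(gap_node(pa_a, M), gap_node(pb_a, M), np.full(len(pa), sig_e * h))
        couple_arr(int_node(pa_a), int_node(pb_a), np.asarray(gi))

    # open edges of rim sites drain the gap film into the bath
    open_edges = 4 - n_neighbors
    rim = np.nonzero(open_edges > 0)[0]
    g_edge = open_edges[rim] / (1.0 / (sig_e * h) + 1.0 / (4.0 * sig_e * pitch))
    prob.edge_nodes = gap_node(rim, M)
    prob.edge_g = g_edge
    np.add.at(diag, prob.edge_nodes, g_edge)

    # membrane elements: mouth disc + annuli (substrate-facing), one dome
    # element per site; areas normalised so the classes sum exactly to
    # the geometric membrane areas
    ann_area = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    mouth_area = math.pi * r_p**2
    bot_areas = np.concatenate([[mouth_area], ann_area])  # per ring index j
    bot_scale = cell.footprint_area / (S * (mouth_area + ann_area.sum()))
    slant = _dome_slant(cell, prob.site_r)
    dome_areas = slant * pitch**2
    dome_areas *= cell.dome_area / dome_areas.sum()

    e_int, e_ext, e_area, e_cls, e_r = [], [], [], [], []
    for j in range(M + 1):
        e_int.append(int_node(ks))
        e_ext.append(gap_node(ks, j))
        e_area.append(np.full(S, bot_areas[j] * bot_scale))
        e_cls.append(np.full(S, "substrate", dtype=object))
        e_r.append(prob.site_r)
    e_int.append(int_node(ks))
    e_ext.append(np.full(S, -1))  # -1 denotes the grounded bath
    e_area.append(dome_areas)
    e_cls.append(np.full(S, "dome", dtype=object))
    e_r.append(prob.site_r)

    prob.elem_node_int = np.concatenate(e_int)
    prob.elem_node_ext = np.concatenate(e_ext)
    prob.elem_area = np.concatenate(e_area)
    prob.elem_class = np.concatenate(e_cls)
    prob.elem_r = np.concatenate(e_r)

    prob.fixed_rows = np.concatenate(rows) if rows else np.empty(0, int)
    prob.fixed_cols = np.concatenate(cols) if cols else np.empty(0, int)
    prob.fixed_vals = np.concatenate(vals) if vals else np.empty(0)
    prob.fixed_diag = diag
    prob.outside_g = prob.n_outside_pores * pore_conductance(r_p, d_s, sig_e)
    return prob


def _time_grid(duration: float, dt0: float = 2e-8, growth: float = 1.3,
               dt_max: float = 2.5e-4) -> np.ndarray:
    ts = [0.0]
    dt = dt0
    while ts[-1] < duration:
        ts.append(min(ts[-1] + dt, duration))
        dt = min(dt * growth, dt_max)
    return np.asarray(ts)


def solve_pulse(
    problem: UnitCellProblem,
    U_subs: float,
    duration: float = 10e-3,
    n_samples: int = 25,
    max_picard: int = 60,
    picard_tol: float = 2e-3,
) -> EpMap:
    """Time-integrate the coupled field/electroporation problem for one
    rectangular pulse of amplitude ``U_subs`` across the substrate.

    Within each time step the liquid potential problem (with the
    current membrane conductances and implicit-Euler capacitive
    companions) and the exact pore-density update are iterated to a
    damped fixed point; non-convergent steps are bisected.
    """
    if duration <= 0:
        raise InvalidInputError("duration must be > 0")
    mem = problem.membrane
    E = problem.n_elements
    times = _time_grid(duration)
    sample_idx = np.unique(
        np.linspace(0, len(times) - 1, min(n_samples, len(times))).astype(int)
    )

    N = np.full(E, mem.N_0)
    U_prev = np.zeros(E)
    samples = [N.copy()]
    pore_count = [float(np.sum(N * problem.elem_area))]
    sample_times = [0.0]
    in_pore_field = None
    imbalance = 0.0

    if problem.n_sites == 0 or U_subs == 0.0:
        # no driving field reaches the membrane: N stays at rest
        T = len(sample_idx)
        Ns = np.tile(N, (T, 1))
        return EpMap(
            problem=problem,
            U_subs=U_subs,
            duration=duration,
            times=times[sample_idx],
            N=Ns,
            areas=problem.elem_area.copy(),
            classes=problem.elem_class.copy(),
            element_r=problem.elem_r.copy(),
            pore_count=np.full(T, pore_count[0]),
            U_cm_final=np.zeros(E),
            in_pore_field_initial=0.0,
            current_imbalance=0.0,
        )

    ext = problem.elem_node_ext
    is_grounded = ext < 0
    eidx = problem.elem_node_int
    area = problem.elem_area

    def solve_step(N_in, U_in, dt):
        """One implicit step from (N_in, U_in) over dt.

        Returns ``(N, U, V, ga, U_in, dt)`` on convergence (``ga`` is the
        stamped element admittance, kept for exact flux bookkeeping) or
        ``None`` if the damped fixed point failed.
        """
        N_it = np.maximum(step_density(N_in, U_in, dt, mem), 1.0)
        beta = 0.5
        last_err = math.inf
        for it in range(max_picard):
            G = mem.G_cm + electropore_conductance(N_it, mem) + mem.C_cm / dt
            ga = G * area
            rows = [problem.fixed_rows]
            cols = [problem.fixed_cols]
            vals = [problem.fixed_vals]
            diag = problem.fixed_diag.copy()
            rhs = np.zeros(problem.n_nodes)
            # drive: bottom reservoir at U_subs through the conduits
            np.add.at(rhs, problem.conduit_nodes, problem.conduit_g * U_subs)
            # membrane companion stamps (U = V_int - V_ext)
            src = mem.C_cm * area * U_in / dt
            np.add.at(diag, eidx, ga)
            np.add.at(rhs, eidx, src)
            ni, xe = eidx[~is_grounded], ext[~is_grounded]
            rows.append(np.concatenate([ni, xe]))
            cols.append(np.concatenate([xe, ni]))
            vals.append(np.concatenate([-ga[~is_grounded]] * 2))
            np.add.at(diag, xe, ga[~is_grounded])
            np.subtract.at(rhs, xe, src[~is_grounded])
            n = problem.n_nodes
            A = sp.coo_matrix(
                (
                    np.concatenate(vals + [diag]),
                    (
                        np.concatenate(rows + [np.arange(n)]),
                        np.concatenate(cols + [np.arange(n)]),
                    ),
                ),
                shape=(n, n),
            ).tocsr()
            V = spla.spsolve(A, rhs)
            V_ext = np.where(is_grounded, 0.0, V[np.where(is_grounded, 0, ext)])
            U_new = V[eidx] - V_ext
            N_new = np.maximum(step_density(N_in, U_new, dt, mem), 1.0)
            # self-consistency measured on the pore density, which spans
            # many decades; damping acts in log space because the
            # creation rate is doubly exponential in the voltage and an
            # undamped iteration oscillates around the self-limited state
            err = float(np.max(np.abs(np.log(N_new) - np.log(N_it))))
            if err <= picard_tol:
                return N_new, U_new, V, ga, U_in, dt
            if err > last_err:
                beta = max(beta * 0.5, 1.0 / 64.0)
            last_err = err
            N_it = np.exp(np.log(N_it) + beta * (np.log(N_new) - np.log(N_it)))
        return None

    def advance(N_in, U_in, dt, depth=0):
        out = solve_step(N_in, U_in, dt)
        if out is not None:
            return out
        if depth >= 6:
            raise SolverError(
                f"nonlinear membrane coupling failed to converge at dt={dt:g}s "
                f"(U_subs={U_subs} V); try smaller time steps"
            )
        half = dt / 2.0
        mid = advance(N_in, U_in, half, depth + 1)
        return advance(mid[0], mid[1], half, depth + 1)

    for step in range(1, len(times)):
        dt = times[step] - times[step - 1]
        N, U_prev, V, ga_used, U_start, dt_used = advance(N, U_prev, dt)
        if in_pore_field is None:
            # field inside a pore channel on the first step, membrane
            # still essentially intact and uncharged
            i_pore = problem.conduit_g * (U_subs - V[problem.conduit_nodes])
            e_chan = np.abs(i_pore) / (
                problem.liquids["extracellular"].sigma
                * math.pi
                * problem.substrate.pore_radius**2
            )
            in_pore_field = float(np.max(e_chan))
        if step == len(times) - 1:
            # current balance of the final (sub)step's linear solve:
            # everything entering through the conduits must leave through
            # the gap-film rim and the dome membrane
            i_in = float(
                np.sum(problem.conduit_g * (U_subs - V[problem.conduit_nodes]))
            )
            i_edge = float(np.sum(problem.edge_g * V[problem.edge_nodes]))
            i_elem = ga_used * U_prev - mem.C_cm * area * U_start / dt_used
            i_dome = float(np.sum(i_elem[is_grounded]))
            imbalance = abs(i_in - (i_edge + i_dome)) / max(abs(i_in), 1e-300)
        if step in sample_idx:
            samples.append(N.copy())
            pore_count.append(float(np.sum(N * area)))
            sample_times.append(times[step])

    return EpMap(
        problem=problem,
        U_subs=U_subs,
        duration=duration,
        times=np.asarray(sample_times),
        N=np.asarray(samples),
        areas=area.copy(),
        classes=problem.elem_class.copy(),
        element_r=problem.elem_r.copy(),
        pore_count=np.asarray(pore_count),
        U_cm_final=U_prev.copy(),
        in_pore_field_initial=in_pore_field or 0.0,
        current_imbalance=imbalance,
    )


def single_site_transmembrane_profile(
    substrate: SubstrateSpec,
    h_gap: float = 100e-9,
    sigma_e: float = 1.5,
    G_m: float = 2.0,
    U_drive: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Steady transmembrane voltage of one isolated pore site, built
    from the production site primitives (conduit + annular gap film +
    membrane elements), with the gap rim and the cell interior both held
    at bath potential and the membrane linearized at ``G_m``.

    Returns ``(r, U_cm)`` with one entry per membrane element (pore
    mouth first).  This reduced configuration matches the single-pore
    fine-grid oracle geometry and is used to verify the site reduction.
    """
    r_p = substrate.pore_radius
    r_site = (1.0 / math.sqrt(substrate.porosity)) / math.sqrt(math.pi)
    edges = _ring_edges(r_p, r_site)
    M = len(edges) - 1
    r_mid, g_rad = _gap_radial_conductances(edges, sigma_e, h_gap)
    g_cd = 1.0 / _conduit_resistance(r_p, substrate.thickness, sigma_e, h_gap)
    areas = np.concatenate(
        [[math.pi * r_p**2], math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)]
    )
    # rim: last ring node to the grounded bath at the site boundary
    g_rim = 2.0 * math.pi * sigma_e * h_gap / math.log(r_site / r_mid[-1])

    n = M + 1
    A = np.zeros((n, n))
    b = np.zeros(n)
    A[0, 0] += g_cd
    b[0] += g_cd * U_drive
    for j in range(M):
        A[j, j] += g_rad[j]
        A[j + 1, j + 1] += g_rad[j]
        A[j, j + 1] -= g_rad[j]
        A[j + 1, j] -= g_rad[j]
    A[M, M] += g_rim
    A[np.arange(n), np.arange(n)] += G_m * areas  # membrane to grounded interior
    V = np.linalg.solve(A, b)
    return r_mid, -V  # U_cm = V_interior(0) - V_gap


def electroporated_area_fraction(
    ep_map: EpMap, threshold: float = EP_DETECTION_THRESHOLD
) -> float:
    """Area-weighted fraction of the whole membrane whose end-of-pulse
    electropore density exceeds ``threshold``."""
    if threshold <= 0:
        raise InvalidInputError("threshold must be > 0")
    hot = ep_map.N_final > threshold
    return float(np.sum(ep_map.areas[hot]) / np.sum(ep_map.areas))


def onset_voltage_sweep(
    problem: UnitCellProblem,
    grid: list[float],
    threshold: float = EP_DETECTION_THRESHOLD,
    duration: float = 10e-3,
) -> float | None:
    """Smallest grid voltage at which any membrane element exceeds the
    detection threshold at end of pulse; ``None`` if none does.

    The grid must be strictly increasing; the sweep stops at the first
    electroporating voltage.
    """
    grid = list(grid)
    if not grid:
        raise InvalidInputError("voltage grid must be non-empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise InvalidInputError("voltage grid must be strictly increasing")
    for u in grid:
        m = solve_pulse(problem, u, duration)
        if np.any(m.N_final > threshold):
            return float(u)
    return None
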