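"""Brute-force fine-grid verification oracle.

A direct axisymmetric finite-volume solve on a nonuniform tensor grid,
with the membrane linearized at a given conductance.  It is deliberately
independent of the production solvers: no lumping, no annular
refinement, no homogenization — every liquid cell is a resistor, every
interface a film, and the sparse system is solved by direct
factorization, so current is conserved to machine precision by
construction.  Intended for small reduced geometries (single substrate
pore, homogenized slab, stacked-slab dividers) used to verify the
production network reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .params import InvalidInputError, SubstrateSpec

__all__ = [
    "AxisymmetricGrid",
    "single_pore_patch_oracle",
    "slab_conductance_oracle",
    "stacked_slab_divider_oracle",
]

MAX_ORACLE_NODES = 100_000


class AxisymmetricGrid:
    """Axisymmetric (r, z) finite-volume resistor network.

    Cells are defined by ``r_edges`` (nr+1) and ``z_edges`` (nz+1) with a
    per-cell conductivity array ``sigma[(nz, nr)]`` (0 marks an
    insulator).  Face conductances combine the half-cells in series, so
    piecewise-constant media are represented exactly.  Thin conductive
    films (a membrane) can replace an axial face; Dirichlet patches are
    attached through half-cell face conductances.
    """

    def __init__(self, r_edges, z_edges, sigma):
        self.re = np.asarray(r_edges, dtype=float)
        self.ze = np.asarray(z_edges, dtype=float)
        self.nr = len(self.re) - 1
        self.nz = len(self.ze) - 1
        self.sigma = np.asarray(sigma, dtype=float)
        if self.sigma.shape != (self.nz, self.nr):
            raise InvalidInputError("sigma must have shape (nz, nr)")
        if self.nr * self.nz > MAX_ORACLE_NODES:
            raise InvalidInputError("oracle grid too large for a direct solve")
        self.rc = 0.5 * (self.re[:-1] + self.re[1:])
        self.zc = 0.5 * (self.ze[:-1] + self.ze[1:])
        self.dr = np.diff(self.re)
        self.dz = np.diff(self.ze)
        # ring area of the axial faces of column i
        self.face_area = math.pi * (self.re[1:] ** 2 - self.re[:-1] ** 2)
        # films[j] maps interface below layer j -> (G_area, r_lo, r_hi)
        self._films: dict[int, tuple[float, float, float]] = {}
        self._dirichlet: list[tuple[np.ndarray, np.ndarray, float]] = []

    def idx(self, i, j):
        return j * self.nr + i

    def add_film(self, j: int, G_per_area: float,
                 r_lo: float = 0.0, r_hi: float = math.inf) -> None:
        """Insert a conductive film at the interface between layers j-1
        and j for columns whose centre lies in [r_lo, r_hi]."""
        if not 1 <= j <= self.nz - 1:
            raise InvalidInputError("film interface out of range")
        self._films[j] = (G_per_area, r_lo, r_hi)

    def add_dirichlet(self, side: str, potential: float,
                      r_lo: float = 0.0, r_hi: float = math.inf,
                      z_lo: float = -math.inf, z_hi: float = math.inf) -> None:
        """Pin a boundary patch (``bottom``, ``top`` or ``outer``)."""
        if side == "bottom":
            i = np.nonzero((self.rc >= r_lo) & (self.rc <= r_hi))[0]
            nodes = self.idx(i, 0)
            g = self.sigma[0, i] * self.face_area[i] / (self.dz[0] / 2.0)
        elif side == "top":
            i = np.nonzero((self.rc >= r_lo) & (self.rc <= r_hi))[0]
            nodes = self.idx(i, self.nz - 1)
            g = self.sigma[-1, i] * self.face_area[i] / (self.dz[-1] / 2.0)
        elif side == "outer":
            j = np.nonzero((self.zc >= z_lo) & (self.zc <= z_hi))[0]
            nodes = self.idx(self.nr - 1, j)
            area = 2.0 * math.pi * self.re[-1] * self.dz[j]
            g = self.sigma[j, self.nr - 1] * area / (self.dr[-1] / 2.0)
        else:
            raise InvalidInputError(f"unknown boundary side {side!r}")
        keep = g > 0
        self._dirichlet.append((nodes[keep], g[keep], potential))

    def solve(self):
        """Direct solve; returns the potential field (nz, nr) and the
        current injected through each Dirichlet patch."""
        if not self._dirichlet:
            raise InvalidInputError("no Dirichlet patch; system is singular")
        n = self.nr * self.nz
        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        rhs = np.zeros(n)

        def couple(p, q, g):
            rows.append(p)
            cols.append(q)
            vals.append(-g)
            rows.append(q)
            cols.append(p)
            vals.append(-g)
            np.add.at(diag, p, g)
            np.add.at(diag, q, g)

        # radial faces
        for j in range(self.nz):
            s = self.sigma[j]
            for i in range(self.nr - 1):
                if s[i] <= 0 or s[i + 1] <= 0:
                    continue
                area = 2.0 * math.pi * self.re[i + 1] * self.dz[j]
                rsum = (self.dr[i] / 2.0) / (s[i] * area) + (
                    self.dr[i + 1] / 2.0
                ) / (s[i + 1] * area)
                couple(
                    np.array([self.idx(i, j)]),
                    np.array([self.idx(i + 1, j)]),
                    np.array([1.0 / rsum]),
                )
        # axial faces (with optional films)
        for j in range(self.nz - 1):
            film = self._films.get(j + 1)
            for i in range(self.nr):
                s0, s1 = self.sigma[j, i], self.sigma[j + 1, i]
                if s0 <= 0 or s1 <= 0:
                    continue
                area = self.face_area[i]
                rsum = (self.dz[j] / 2.0) / (s0 * area) + (
                    self.dz[j + 1] / 2.0
                ) / (s1 * area)
                if film is not None:
                    G_a, r_lo, r_hi = film
                    if r_lo <= self.rc[i] <= r_hi:
                        if G_a <= 0:
                            continue
                        rsum += 1.0 / (G_a * area)
                couple(
                    np.array([self.idx(i, j)]),
                    np.array([self.idx(i, j + 1)]),
                    np.array([1.0 / rsum]),
                )
        for nodes, g, v in self._dirichlet:
            np.add.at(diag, nodes, g)
            np.add.at(rhs, nodes, g * v)

        dead = diag == 0.0
        diag[dead] = 1.0
        A = sp.coo_matrix(
            (
                np.concatenate([np.concatenate(vals), diag]),
                (
                    np.concatenate([np.concatenate(rows), np.arange(n)]),
                    np.concatenate([np.concatenate(cols), np.arange(n)]),
                ),
            ),
            shape=(n, n),
        ).tocsr()
        V = spla.spsolve(A, rhs)
        if not np.all(np.isfinite(V)):
            raise InvalidInputError("singular oracle system")
        currents = [
            float(np.sum(g * (v - V[nodes]))) for nodes, g, v in self._dirichlet
        ]
        field = V.reshape(self.nz, self.nr).copy()
        field[self.sigma <= 0] = np.nan
        return field, currents


def _geom_edges(r_min: float, r_max: float, n: int) -> np.ndarray:
    return np.concatenate([[0.0], np.geomspace(r_min, r_max, n)])


def _stretched_span(z_from: float, z_to: float, d_min: float, growth: float = 1.4):
    """Edges from ``z_from`` to ``z_to`` starting with spacing ``d_min``
    at the ``z_from`` side and growing geometrically (for resolving the
    access constriction at an aperture plane)."""
    span = abs(z_to - z_from)
    steps = [0.0]
    d = d_min
    while steps[-1] < span:
        steps.append(min(steps[-1] + d, span))
        d *= growth
    arr = np.asarray(steps)
    return z_from + np.sign(z_to - z_from) * arr


@dataclass
class SinglePoreOracleResult:
    r: np.ndarray  # membrane-column centre radii
    U_cm: np.ndarray  # transmembrane voltage per column (V_int - V_ext)
    V: np.ndarray
    mouth_U_cm: float
    current_in: float
    current_out: float


def single_pore_patch_oracle(
    substrate: SubstrateSpec,
    h_gap: float = 100e-9,
    sigma_e: float = 1.5,
    sigma_i: float = 0.5,
    G_m: float = 2.0,
    U_drive: float = 1.0,
    domain_radius: float | None = None,
    n_r: int = 90,
) -> SinglePoreOracleResult:
    """Reduced single-pore geometry: one substrate pore feeding the thin
    gap under a flat membrane patch, gap rim and interior both held at
    bath potential, membrane linearized at ``G_m``.

    Verifies the production site reduction (conduit + annular gap film +
    membrane elements) on the quantity that controls electroporation
    onset: the pre-poration transmembrane voltage above the pore mouth.
    """
    r_p = substrate.pore_radius
    d_s = substrate.thickness
    R = domain_radius or (1.0 / math.sqrt(substrate.porosity)) / math.sqrt(math.pi)
    re = _geom_edges(r_p / 8.0, R, n_r)
    # snap an edge exactly onto the pore radius
    k = int(np.argmin(np.abs(re - r_p)))
    re[k] = r_p
    h_res = 5.0e-6  # bottom reservoir depth
    h_int = 5.0e-6  # interior liquid above the membrane
    lower = _stretched_span(0.0, -h_res, r_p / 4.0)[::-1]
    ze = np.concatenate(
        [
            lower[:-1],
            np.linspace(0.0, d_s, 10 + 1)[:-1],
            np.linspace(d_s, d_s + h_gap, 6 + 1)[:-1],
            _stretched_span(d_s + h_gap, d_s + h_gap + h_int, h_gap / 2.0),
        ]
    )
    nz, nr = len(ze) - 1, len(re) - 1
    rc = 0.5 * (re[:-1] + re[1:])
    zc = 0.5 * (ze[:-1] + ze[1:])
    sigma = np.zeros((nz, nr))
    sigma[zc < 0.0] = sigma_e  # reservoir
    in_subs = (zc >= 0.0) & (zc < d_s)
    sigma[np.ix_(in_subs, rc < r_p)] = sigma_e  # pore channel
    in_gap = (zc >= d_s) & (zc < d_s + h_gap)
    sigma[in_gap] = sigma_e
    sigma[zc >= d_s + h_gap] = sigma_i  # interior

    grid = AxisymmetricGrid(re, ze, sigma)
    j_mem = int(np.searchsorted(ze, d_s + h_gap))  # interface below interior
    grid.add_film(j_mem, G_m)
    grid.add_dirichlet("bottom", U_drive)
    grid.add_dirichlet("outer", U_drive, z_lo=-h_res, z_hi=0.0)  # reservoir wall
    grid.add_dirichlet("outer", 0.0, z_lo=d_s, z_hi=d_s + h_gap)  # gap rim -> bath
    grid.add_dirichlet("top", 0.0)  # interior reference
    V, currents = grid.solve()

    j_gap_top = j_mem - 1
    j_int_bot = j_mem
    U_cm = V[j_int_bot] - V[j_gap_top]
    mouth = float(np.nanmean(np.where(rc < r_p, U_cm, np.nan)))
    i_in = currents[0] + currents[1]
    i_out = -(currents[2] + currents[3])
    return SinglePoreOracleResult(
        r=rc, U_cm=U_cm, V=V, mouth_U_cm=mouth,
        current_in=i_in, current_out=i_out,
    )


def slab_conductance_oracle(
    substrate: SubstrateSpec, sigma_e: float = 1.5, n_r: int = 80
) -> float:
    """Areal conductance (S/m²) of a homogenized pore slab: one pore in
    its equal-area unit cell between two reservoirs.

    Independent check of the closed-form pore kernel
    ``2 sigma pi r^2/(pi r + 2 d)`` (channel plus two-sided access).
    """
    r_p = substrate.pore_radius
    d_s = substrate.thickness
    R = (1.0 / math.sqrt(substrate.porosity)) / math.sqrt(math.pi)
    re = _geom_edges(r_p / 8.0, R, n_r)
    re[int(np.argmin(np.abs(re - r_p)))] = r_p
    h_res = max(4.0 * R, 2.0 * d_s)
    lower = _stretched_span(0.0, -h_res, r_p / 4.0)[::-1]
    upper = _stretched_span(d_s, d_s + h_res, r_p / 4.0)
    ze = np.concatenate(
        [lower[:-1], np.linspace(0.0, d_s, 10 + 1)[:-1], upper]
    )
    nz, nr = len(ze) - 1, len(re) - 1
    rc, zc = 0.5 * (re[:-1] + re[1:]), 0.5 * (ze[:-1] + ze[1:])
    sigma = np.full((nz, nr), sigma_e)
    in_subs = (zc >= 0.0) & (zc < d_s)
    sigma[np.ix_(in_subs, rc >= r_p)] = 0.0
    grid = AxisymmetricGrid(re, ze, sigma)
    grid.add_dirichlet("bottom", 1.0)
    grid.add_dirichlet("top", 0.0)
    _, currents = grid.solve()
    g_pore = currents[0]  # per pore at 1 V
    return float(g_pore * substrate.porosity)


def stacked_slab_divider_oracle(
    sigma_1: float, d_1: float, sigma_2: float, d_2: float, U: float = 1.0
) -> float:
    """Two uniform conducting slabs in series: returns the interface
    potential, which must equal the textbook divider value."""
    re = np.array([0.0, 1e-3])
    ze = np.concatenate(
        [np.linspace(0.0, d_1, 9)[:-1], np.linspace(d_1, d_1 + d_2, 9)]
    )
    zc = 0.5 * (ze[:-1] + ze[1:])
    sigma = np.where(zc < d_1, sigma_1, sigma_2)[:, None]
    grid = AxisymmetricGrid(re, ze, sigma)
    grid.add_dirichlet("bottom", U)
    grid.add_dirichlet("top", 0.0)
    V, _ = grid.solve()
    j = int(np.searchsorted(ze, d_1)) - 1
    # interpolate the face potential between the two adjacent centres
    w = (d_1 - zc[j]) / (zc[j + 1] - zc[j])
    return float(V[j, 0] * (1 - w) + V[j + 1, 0] * w)
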