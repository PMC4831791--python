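"""Quasi-static actin filament field.

The coarse-grained actin density c solves a screened Poisson equation on the
bulk domain,

    -Lap(c) + eta * c = 0,

driven purely through its outer boundary: actin nucleation at the membrane
is proportional to the local membrane Cdc42 density mu, the receptor
activity kappa, and the Michaelis-Menten pheromone saturation S/(S0+S).
The package adopts the influx orientation of the boundary condition,

    grad(c) . e_x = phi(theta) = kappa(theta) * S/(S0+S) * mu_tilde(theta) >= 0,

so that c is largest near strongly nucleating membrane regions and the
advective drift chi*grad(c) in the bulk equation attracts Cdc42 toward
them — the orientation under which the feedback aggregates, cross-checked
against the one-dimensional reduced model.  The inner (nuclear) boundary is
a zero-flux wall.  mu enters nondimensionalized as mu_tilde = mu*2*pi*R/M
(averaging 1 if the whole pool sat uniformly on the membrane); any other
linear convention merely rescales the fitted kappa*chi product.

Since eta and the geometry are fixed within a run, the operator is
factorized once and reused; only the boundary load changes per time step,
and solves are batched over ensemble members.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .mesh import AnnulusMesh
from .params import ModelParams

__all__ = ["PheromoneField", "make_pheromone_field", "ActinSolver", "solve_actin", "nucleation_flux"]


@dataclasses.dataclass(frozen=True)
class PheromoneField:
    """Pheromone concentration at the membrane, per boundary segment (nM).

    The profile is S(theta) = S_mean * (1 + (g/2) cos(theta - theta_g)), so
    the edge-to-edge difference equals ``g`` times the mean.
    """

    S_mean: float
    g: float
    theta_g: float
    values: np.ndarray  # (n_theta,)


def make_pheromone_field(
    S_mean: float, g: float, theta_g: float, mesh: AnnulusMesh
) -> PheromoneField:
    """Cosine pheromone profile with relative edge-to-edge gradient ``g``."""
    if S_mean < 0 or g < 0:
        raise ValueError(f"S_mean and g must be >= 0, got {S_mean}, {g}")
    if S_mean * (1.0 - g / 2.0) < 0:
        raise ValueError(f"gradient g={g} would make the concentration negative")
    values = S_mean * (1.0 + (g / 2.0) * np.cos(mesh.theta_centers - theta_g))
    return PheromoneField(S_mean=S_mean, g=g, theta_g=theta_g, values=values)


def nucleation_flux(
    mu: np.ndarray, kappa_seg: np.ndarray, S_values: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Boundary nucleation flux phi = kappa * S/(S0+S) * mu*2*pi*R/M (1/um).

    All arguments broadcast; ``mu`` and ``kappa_seg`` may carry a leading
    batch axis.
    """
    saturation = S_values / (params.S0 + S_values)
    return kappa_seg * saturation * (mu * (2.0 * math.pi * params.R / params.M))


class ActinSolver:
    """Cached factorization of the finite-volume Helmholtz operator."""

    def __init__(self, mesh: AnnulusMesh, eta: float):
        if eta <= 0:
            raise ValueError(f"eta must be > 0 for a well-posed flux problem, got {eta}")
        self.mesh = mesh
        self.eta = eta
        self._lu = splu(_helmholtz_matrix(mesh, eta).tocsc())

    def solve(self, phi: np.ndarray) -> np.ndarray:
        """Solve for c given the outer-boundary influx ``phi`` per segment.

        ``phi`` has shape (..., n_theta); the result has shape
        (..., n_r, n_theta).
        """
        m = self.mesh
        phi = np.asarray(phi, dtype=float)
        if np.any(phi < -1e-12):
            raise ValueError("negative nucleation flux")
        lead = phi.shape[:-1]
        b = np.zeros(lead + (m.n_r, m.n_theta))
        b[..., -1, :] = phi * m.boundary_seg_len
        rhs = b.reshape(-1, m.n_cells).T  # (n_cells, batch)
        sol = self._lu.solve(rhs)
        return np.ascontiguousarray(sol.T).reshape(lead + (m.n_r, m.n_theta))


def _helmholtz_matrix(mesh: AnnulusMesh, eta: float) -> sp.coo_matrix:
    """FV discretization of c -> -Lap(c) + eta*c on the annulus.

    Row p: sum_faces g_f (c_p - c_nb) + eta A_p c_p; boundary fluxes are
    pure loads and do not enter the matrix.
    """
    nr, nt = mesh.n_r, mesh.n_theta
    idx = np.arange(nr * nt).reshape(nr, nt)
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(np.broadcast_to(v, r.shape).ravel())

    # radial faces between ring i and i+1: conductance L/dr
    g_rad = mesh.radial_face_len[1:-1] / mesh.dr  # (nr-1,)
    p, q = idx[:-1, :], idx[1:, :]
    gr = np.repeat(g_rad[:, None], nt, axis=1)
    add(p, p, gr); add(q, q, gr); add(p, q, -gr); add(q, p, -gr)

    # angular faces between (i,j) and (i,j+1 mod nt): conductance dr/(r_i dtheta)
    g_ang = mesh.angular_face_len / (mesh.r_centers * mesh.dtheta)  # (nr,)
    p, q = idx, np.roll(idx, -1, axis=1)
    ga = np.repeat(g_ang[:, None], nt, axis=1)
    add(p, p, ga); add(q, q, ga); add(p, q, -ga); add(q, p, -ga)

    # screening
    diag = np.repeat(eta * mesh.cell_areas[:, None], nt, axis=1)
    add(idx, idx, diag)

    n = nr * nt
    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


_SOLVER_CACHE: dict = {}


def solve_actin(
    mesh: AnnulusMesh,
    mu: np.ndarray,
    kappa_seg: np.ndarray,
    S: PheromoneField,
    eta: float,
    params: ModelParams,
) -> np.ndarray:
    """One-shot actin solve (factorization memoized per mesh geometry and eta)."""
    key = (mesh.n_r, mesh.n_theta, mesh.R, mesh.R_n, eta)
    solver = _SOLVER_CACHE.get(key)
    if solver is None or solver.mesh is not mesh:
        solver = ActinSolver(mesh, eta)
        _SOLVER_CACHE[key] = solver
    phi = nucleation_flux(np.asarray(mu, dtype=float), np.asarray(kappa_seg, dtype=float), S.values, params)
    return solver.solve(phi)
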