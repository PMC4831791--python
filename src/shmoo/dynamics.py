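"""Time integration of the coupled bulk/membrane Cdc42 system.

Bulk Cdc42 n(t, x) diffuses (D_b) and is advected up the actin-field
gradient with velocity chi*grad(c) on the annulus; membrane Cdc42 mu(t, s)
diffuses along the membrane (D_m) and exchanges with the boundary-adjacent
bulk through attachment/detachment (k_on, k_off).  The total normal flux at
the outer boundary equals the exchange flux, which is what conserves the
total Cdc42 pool exactly; the inner (nuclear) boundary is a zero-flux wall.
The actin field is quasi-static: it is re-solved from the current membrane
state every step.

Numerics (first order in time, finite volume in space):

* operator splitting per step: exact Ornstein-Uhlenbeck update of kappa ->
  quasi-static actin solve -> implicit radial sweep (radial diffusion +
  upwind radial advection + membrane exchange, one tridiagonal system per
  angular column, the membrane segment appended as the outermost unknown)
  -> implicit angular sweep (angular diffusion + upwind angular advection,
  one cyclic tridiagonal system per ring, plus the membrane diffusion ring);
* advection and diffusion live in the *same* implicit sweep: bulk diffusion
  relaxes in R^2/D_b ~ 4.5 s, faster than a practical time step, so
  splitting them would let each sub-step reach its own equilibrium and
  cancel the transport they jointly produce;
* every sweep is written in flux form, so total mass is conserved to solver
  precision per step, and every implicit operator is an M-matrix, so
  nonnegativity is preserved without clipping;
* implicit (rather than CFL-limited explicit) upwinding is what keeps the
  10-hour horizon tractable: near the aggregation transition the advective
  speed in the forming cap would drive an explicit time step far below 1 s.

The ensemble engine advances many independent cells simultaneously: the
diffusion/exchange and actin factorizations are shared across members (they
do not depend on chi, delta, the dose, or the noise path), so the linear
solves are batched over right-hand sides, while the advection sweeps are
vectorized batched tridiagonal (Thomas / Sherman-Morrison) solves.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import metrics
from .actin import ActinSolver, PheromoneField, nucleation_flux
from .mesh import AnnulusMesh, build_mesh
from .noise import init_kappa, sample_kappa_mean, sector_of_segment
from .params import ModelParams

__all__ = [
    "CellState",
    "initial_state",
    "step_state",
    "run_simulation",
    "BatchSimulator",
    "default_mesh",
]

#: Default time step (s) for single-cell runs.
DT_DEFAULT = 5.0
#: Cadence (s) at which the polarization criterion is checked.
CHECK_INTERVAL = 60.0
#: Default horizon (s): cells not polarized within 10 h count as unpolarized.
T_MAX_DEFAULT = 10.0 * 3600.0


def default_mesh(params: ModelParams, n_r: int = 24, n_theta: int = 60) -> AnnulusMesh:
    """The standard 24x60 polar mesh for the given geometry."""
    return build_mesh(params.R, params.R_n, n_r, n_theta)


@dataclasses.dataclass
class CellState:
    """Bulk field n (molecules/um^2), membrane density mu (molecules/um),
    and the current actin field c, at time t (s)."""

    t: float
    n: np.ndarray   # (n_r, n_theta)
    mu: np.ndarray  # (n_theta,)
    c: np.ndarray | None = None

    def mass(self, mesh: AnnulusMesh) -> float:
        return float(
            np.sum(self.n * mesh.areas2d()) + np.sum(self.mu) * mesh.boundary_seg_len
        )


def initial_state(params: ModelParams, mesh: AnnulusMesh) -> CellState:
    """Resting (S = 0) steady state: spatially uniform fields with
    mu/n = k_on/k_off, the membrane holding ``membrane_fraction_rest`` of M."""
    f = params.membrane_fraction_rest
    area = math.pi * (params.R**2 - params.R_n**2)
    n0 = params.M * (1.0 - f) / area
    mu0 = params.M * f / (2.0 * math.pi * params.R)
    return CellState(
        t=0.0,
        n=np.full((mesh.n_r, mesh.n_theta), n0),
        mu=np.full(mesh.n_theta, mu0),
        c=np.zeros((mesh.n_r, mesh.n_theta)),
    )


# ----------------------------------------------------------------------------
# batched tridiagonal solvers
# ----------------------------------------------------------------------------

def _thomas_kernel_py(a, b, c, d, x):
    nsys, n = b.shape
    for s in range(nsys):
        cp = np.empty(n)
        dp = np.empty(n)
        cp[0] = c[s, 0] / b[s, 0]
        dp[0] = d[s, 0] / b[s, 0]
        for i in range(1, n):
            denom = b[s, i] - a[s, i] * cp[i - 1]
            cp[i] = c[s, i] / denom
            dp[i] = (d[s, i] - a[s, i] * dp[i - 1]) / denom
        x[s, n - 1] = dp[n - 1]
        for i in range(n - 2, -1, -1):
            x[s, i] = dp[i] - cp[i] * x[s, i + 1]


try:  # jit-compiled sweeps carry the inner loops of every time step
    import numba

    _thomas_kernel = numba.njit(cache=False)(_thomas_kernel_py)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _thomas_kernel = _thomas_kernel_py


def solve_tridiag(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Thomas algorithm along the last axis, batched over leading axes.

    ``a`` couples to the previous unknown (a[..., 0] ignored), ``c`` to the
    next (c[..., -1] ignored).
    """
    shape = np.broadcast_shapes(a.shape, b.shape, c.shape, d.shape)
    n = shape[-1]
    a2 = np.ascontiguousarray(np.broadcast_to(a, shape)).reshape(-1, n)
    b2 = np.ascontiguousarray(np.broadcast_to(b, shape)).reshape(-1, n)
    c2 = np.ascontiguousarray(np.broadcast_to(c, shape)).reshape(-1, n)
    d2 = np.ascontiguousarray(np.broadcast_to(d, shape)).reshape(-1, n)
    x = np.empty_like(d2)
    _thomas_kernel(a2, b2, c2, d2, x)
    return x.reshape(shape)


def solve_cyclic_tridiag(a, b, c, d):
    """Periodic tridiagonal solve (Sherman-Morrison), vectorized like
    :func:`solve_tridiag`; a[..., 0] couples to the last unknown and
    c[..., -1] to the first."""
    beta = a[..., 0]    # A[0, n-1]
    alpha = c[..., -1]  # A[n-1, 0]
    gamma = -b[..., 0]
    b2 = b.copy()
    b2[..., 0] = b[..., 0] - gamma
    b2[..., -1] = b[..., -1] - alpha * beta / gamma
    y = solve_tridiag(a, b2, c, d)
    u = np.zeros_like(d)
    u[..., 0] = gamma
    u[..., -1] = alpha
    q = solve_tridiag(a, b2, c, u)
    num = y[..., 0] + beta * y[..., -1] / gamma
    den = 1.0 + q[..., 0] + beta * q[..., -1] / gamma
    return y - q * (num / den)[..., None]


# ----------------------------------------------------------------------------
# cached operators
# ----------------------------------------------------------------------------

class DynamicsOperators:
    """Geometry- and rate-dependent pieces shared across a run and across
    ensemble members (the sweeps take the advection potential chi*c as an
    argument, so members with different chi, dose or noise path share one
    operator set)."""

    def __init__(self, params: ModelParams, mesh: AnnulusMesh):
        if mesh.n_theta % params.N_sectors != 0:
            raise ValueError(
                f"n_theta={mesh.n_theta} not divisible by N_sectors={params.N_sectors}"
            )
        self.params = params
        self.mesh = mesh
        self.actin = ActinSolver(mesh, params.eta)
        self.sector_map = sector_of_segment(mesh.n_theta, params.N_sectors)

    def radial_sweep(self, n: np.ndarray, mu: np.ndarray, chi_c: np.ndarray, dt: float):
        """Implicit radial transport: diffusion D_b, upwind advection with
        velocity d(chi*c)/dr, and membrane exchange.

        Each angular column j is one tridiagonal system in the unknowns
        (n_0j, ..., n_{nr-1,j}, mu_j); the membrane segment is the outermost
        'cell' with area ds and exchange flux ds*(k_on n_out - k_off mu_j)
        through the shared face.  ``n``: (..., nr, nt), ``mu``: (..., nt),
        ``chi_c``: (..., nr, nt).
        """
        p, m = self.params, self.mesh
        nr, nt = m.n_r, m.n_theta
        ds = m.boundary_seg_len
        lead = mu.shape[:-1]

        # interior faces 1..nr-1 (face k between cells k-1 and k)
        g = p.D_b * m.radial_face_len[1:-1] / m.dr                    # (nr-1,)
        v = (chi_c[..., 1:, :] - chi_c[..., :-1, :]) / m.dr           # (..., nr-1, nt)
        Lf = m.radial_face_len[1:-1, None]
        vp = np.maximum(v, 0.0) * Lf
        vm = np.minimum(v, 0.0) * Lf

        N = nr + 1
        shape = lead + (nt, N)
        a = np.zeros(shape); b = np.empty(shape); c = np.zeros(shape); d = np.empty(shape)
        # move the radial axis last: helpers with shape (..., nt, nr-1)
        vp_t = np.swapaxes(vp, -1, -2)
        vm_t = np.swapaxes(vm, -1, -2)
        g_t = g[None, :]
        areas = m.cell_areas
        b[...] = 0.0
        b[..., :nr] = areas
        b[..., nr] = ds
        # face k (between cells k-1, k), k=1..nr-1: outflow of k-1 is g+vp, etc.
        out_lo = dt * (g_t + vp_t)   # contribution to diag of cell k-1
        out_hi = dt * (g_t - vm_t)   # contribution to diag of cell k
        b[..., : nr - 1] += out_lo
        b[..., 1:nr] += out_hi
        c[..., : nr - 1] = -dt * (g_t - vm_t)   # coeff of n_k in row k-1
        a[..., 1:nr] = -dt * (g_t + vp_t)       # coeff of n_{k-1} in row k
        # exchange face between cell nr-1 and membrane: flux ds*(k_on n - k_off mu)
        b[..., nr - 1] += dt * ds * p.k_on
        c[..., nr - 1] = -dt * ds * p.k_off
        a[..., nr] = -dt * ds * p.k_on
        b[..., nr] += dt * ds * p.k_off
        d[..., :nr] = np.swapaxes(n, -1, -2) * areas
        d[..., nr] = mu * ds
        x = solve_tridiag(a, b, c, d)
        n_new = np.swapaxes(x[..., :nr], -1, -2)
        mu_new = x[..., nr]
        return n_new, mu_new

    def angular_sweep(self, n: np.ndarray, mu: np.ndarray, chi_c: np.ndarray, dt: float):
        """Implicit angular transport: bulk angular diffusion + upwind
        advection (one cyclic tridiagonal system per ring) and membrane
        diffusion D_m on the boundary ring."""
        p, m = self.params, self.mesh
        areas = m.cell_areas[:, None]
        dist = m.r_centers[:, None] * m.dtheta
        g = p.D_b * m.angular_face_len / dist                     # (nr, 1)
        v = (np.roll(chi_c, -1, axis=-1) - chi_c) / dist          # face j+1/2
        vp = np.maximum(v, 0.0) * m.angular_face_len
        vm = np.minimum(v, 0.0) * m.angular_face_len
        out_lo = dt * (g + vp)          # outflow of cell j through face j+1/2
        out_hi = dt * (g - vm)          # outflow of cell j+1 through face j+1/2
        b = areas + out_lo + np.roll(out_hi, 1, axis=-1)
        c = -out_hi                      # coeff of n_{j+1} in row j
        a = -np.roll(out_lo, 1, axis=-1)  # coeff of n_{j-1} in row j
        n_new = solve_cyclic_tridiag(a, b, c, areas * n)

        # membrane diffusion ring (constant coefficients)
        ds = m.boundary_seg_len
        gm = dt * p.D_m / ds**2 * ds     # conductance * dt, mass units (weight ds)
        shape = mu.shape
        am = np.full(shape, -gm)
        bm = np.full(shape, ds + 2.0 * gm)
        cm = np.full(shape, -gm)
        mu_new = solve_cyclic_tridiag(am, bm, cm, mu * ds)
        return n_new, mu_new

    def step_fields(self, n: np.ndarray, mu: np.ndarray, chi_c: np.ndarray, dt: float):
        """One full transport step (radial sweep with exchange, then angular
        sweep).  ``chi_c`` is the advection potential chi*c per member."""
        n, mu = self.radial_sweep(n, mu, chi_c, dt)
        n, mu = self.angular_sweep(n, mu, chi_c, dt)
        return n, mu


_OPS_CACHE: dict = {}


def _get_ops(params: ModelParams, mesh: AnnulusMesh) -> DynamicsOperators:
    key = (
        mesh.n_r, mesh.n_theta, mesh.R, mesh.R_n,
        params.D_b, params.D_m, params.k_on, params.k_off,
        params.eta, params.chi, params.N_sectors,
    )
    ops = _OPS_CACHE.get(key)
    if ops is None:
        ops = DynamicsOperators(params, mesh)
        _OPS_CACHE[key] = ops
        if len(_OPS_CACHE) > 16:
            _OPS_CACHE.pop(next(iter(_OPS_CACHE)))
    return ops


def step_state(
    state: CellState,
    params: ModelParams,
    kappa_seg: np.ndarray,
    S: PheromoneField,
    dt: float,
    mesh: AnnulusMesh,
    ops: DynamicsOperators | None = None,
) -> CellState:
    """Advance one cell by one operator-split step (kappa held fixed).

    Raises :class:`FloatingPointError` if the state goes non-finite.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    ops = ops or _get_ops(params, mesh)
    phi = nucleation_flux(state.mu, np.asarray(kappa_seg, dtype=float), S.values, params)
    c = ops.actin.solve(phi)
    n, mu = ops.step_fields(state.n, state.mu, params.chi * c, dt)
    new = CellState(t=state.t + dt, n=n, mu=mu, c=c)
    if not np.isfinite(n).all() or not np.isfinite(mu).all():
        raise FloatingPointError(f"non-finite state at t={new.t:.1f}s")
    return new


# ----------------------------------------------------------------------------
# ensembles
# ----------------------------------------------------------------------------

def member_rng(master_seed: int, index: int) -> np.random.Generator:
    """Independent, order-invariant substream for ensemble member ``index``."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    )


class BatchSimulator:
    """Advance a batch of independent cells sharing (mesh, D_b, D_m, k_on,
    k_off, eta, N_sectors) but with per-member pheromone fields, chi, delta
    and noise paths.

    Members whose polarization criterion has fired are frozen (their first
    polarization time and cap angle are what the experiments score), which
    also keeps the shared time step from collapsing into the post-onset
    blow-up regime.
    """

    def __init__(
        self,
        params: ModelParams,
        mesh: AnnulusMesh,
        S_fields: list[PheromoneField],
        master_seed: int,
        chi: np.ndarray | None = None,
        delta: np.ndarray | None = None,
        dt: float = DT_DEFAULT,
        t_max: float = T_MAX_DEFAULT,
        check_interval: float = CHECK_INTERVAL,
        record_every: float | None = None,
        member_offset: int = 0,
        member_keys: list[int] | None = None,
    ):
        self.params = params
        self.mesh = mesh
        self.B = len(S_fields)
        self.S_values = np.stack([f.values for f in S_fields])
        self.theta_g = np.array([f.theta_g for f in S_fields])
        self.chi = np.full(self.B, params.chi) if chi is None else np.asarray(chi, float)
        delta_arr = np.full(self.B, params.delta) if delta is None else np.asarray(delta, float)
        self.dt = float(dt)
        self.t_max = float(t_max)
        self.check_interval = float(check_interval)
        self.record_every = record_every
        # operators are built with chi=0 placeholder; advection uses per-member chi
        self.ops = _get_ops(params.with_(chi=0.0, delta=0.0), mesh)
        if member_keys is None:
            member_keys = [member_offset + i for i in range(self.B)]
        if len(member_keys) != self.B:
            raise ValueError("member_keys must match the number of members")
        self.rngs = [member_rng(master_seed, k) for k in member_keys]
        kmean = np.array(
            [
                sample_kappa_mean(params.kappa_mean, float(delta_arr[i]), self.rngs[i])
                for i in range(self.B)
            ]
        )
        self.kappa = np.stack(
            [
                init_kappa(kmean[i], params.lam, params.sigma, params.N_sectors, self.rngs[i]).kappa
                for i in range(self.B)
            ]
        )
        self.kappa_mean_cell = kmean
        st = initial_state(params, mesh)
        self.n = np.repeat(st.n[None, :, :], self.B, axis=0)
        self.mu = np.repeat(st.mu[None, :], self.B, axis=0)
        self.t = 0.0
        self.active = np.ones(self.B, dtype=bool)
        self.polarized = np.zeros(self.B, dtype=bool)
        self.t_pol = np.full(self.B, np.nan)
        self.cap = np.full(self.B, np.nan)
        self.kymographs: list[np.ndarray] = []
        self.kymograph_times: list[float] = []

    def _ou_update(self):
        p = self.params
        if p.sigma == 0.0:
            return
        decay = math.exp(-p.lam * self.dt)
        sd = math.sqrt(p.sigma**2 * (1.0 - decay**2) / (2.0 * p.lam))
        idx = np.flatnonzero(self.active)
        xi = np.stack([self.rngs[i].standard_normal(p.N_sectors) for i in idx])
        m = self.kappa_mean_cell[idx, None]
        self.kappa[idx] = np.maximum(m + (self.kappa[idx] - m) * decay + sd * xi, 0.0)

    def _check_polarization(self):
        idx = np.flatnonzero(self.active)
        if idx.size == 0:
            return
        fr = metrics.window_fractions(self.mu[idx])
        hits = fr.max(axis=-1) > metrics.POLARIZED_MASS_FRACTION
        for k, i in enumerate(idx):
            if hits[k]:
                self.polarized[i] = True
                self.t_pol[i] = self.t
                self.cap[i] = metrics.cap_angle(self.mu[i])
                self.active[i] = False

    def run(self) -> dict:
        """Integrate to t_max (or until every member froze); returns summary
        arrays keyed ``polarized``, ``t_pol``, ``cap_angle``."""
        p = self.params
        next_check = self.check_interval
        next_record = 0.0
        smap = self.ops.sector_map
        while self.t < self.t_max - 1e-9 and self.active.any():
            if self.record_every is not None and self.t >= next_record - 1e-9:
                self.kymographs.append(self.mu.copy())
                self.kymograph_times.append(self.t)
                next_record += self.record_every
            self._ou_update()
            idx = np.flatnonzero(self.active)
            kappa_seg = self.kappa[idx][:, smap]
            phi = nucleation_flux(self.mu[idx], kappa_seg, self.S_values[idx], p)
            c = self.ops.actin.solve(phi)
            # per-member chi enters by pre-scaling c (transport uses chi*c)
            n, mu = self.ops.step_fields(
                self.n[idx], self.mu[idx], c * self.chi[idx, None, None], self.dt
            )
            self.n[idx] = n
            self.mu[idx] = mu
            self.t += self.dt
            if self.t >= next_check - 1e-9:
                self._check_polarization()
                next_check += self.check_interval
        if self.record_every is not None:
            self.kymographs.append(self.mu.copy())
            self.kymograph_times.append(self.t)
        if not np.isfinite(self.mu).all() or not np.isfinite(self.n).all():
            raise FloatingPointError("non-finite state in ensemble run")
        return {
            "polarized": self.polarized.copy(),
            "t_pol": self.t_pol.copy(),
            "cap_angle": self.cap.copy(),
            "theta_g": self.theta_g.copy(),
        }


def run_simulation(
    params: ModelParams,
    S: PheromoneField,
    seed: int,
    t_max: float = T_MAX_DEFAULT,
    record_every: float = 60.0,
    mesh: AnnulusMesh | None = None,
    dt: float = DT_DEFAULT,
) -> metrics.SimResult:
    """Simulate one cell: draw its kappa_mean, integrate with OU noise until
    first polarization or ``t_max``; returns the outcome with a membrane
    kymograph sampled every ``record_every`` seconds.  Bit-reproducible for
    fixed (params, S, seed)."""
    mesh = mesh or default_mesh(params)
    sim = BatchSimulator(
        params,
        mesh,
        [S],
        master_seed=seed,
        dt=dt,
        t_max=t_max,
        record_every=record_every,
    )
    out = sim.run()
    kym = np.stack([k[0] for k in sim.kymographs])
    times = np.asarray(sim.kymograph_times)
    pol = bool(out["polarized"][0])
    return metrics.SimResult(
        polarized=pol,
        t_pol=float(out["t_pol"][0]) if pol else None,
        cap_angle=float(out["cap_angle"][0]) if pol else None,
        kymograph=kym,
        kymograph_times=times,
        seed=seed,
    )
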