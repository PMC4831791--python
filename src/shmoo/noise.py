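"""Stochastic effective pheromone receptor activity.

Everything downstream of receptor binding (G-protein activation, lateral
diffusion, receptor endocytosis) is summarized by a single sector-wise
activity kappa(t, sector).  The membrane is divided into ``N_sectors``
independent sectors (a polarisome occupies roughly 10% of the perimeter, so
the default is 10); within a sector kappa is constant, and in time each
sector follows an Ornstein-Uhlenbeck process

    d kappa = -lam * (kappa - kappa_mean_cell) dt + sigma dW

whose stationary law is Normal(kappa_mean_cell, sigma^2/(2 lam)).  The
per-cell mean kappa_mean_cell is itself drawn once per cell from
Normal(kappa_mean, (delta*kappa_mean)^2), modelling cell-to-cell
variability; draws and trajectories are clamped at zero (a negative
activity would reverse the actin nucleation flux unphysically).

The OU update is the exact transition law, not an Euler scheme, so the time
step can follow the PDE step without discretization bias.  All functions are
vectorized: ``kappa`` may carry a leading batch axis for ensembles.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["KappaProcess", "sample_kappa_mean", "init_kappa", "ou_step", "sector_of_segment"]


def sample_kappa_mean(kappa_mean: float, delta: float, rng: np.random.Generator, size=None):
    """Per-cell draw of the OU mean, Normal(kappa_mean, (delta*kappa_mean)^2),
    truncated at 0."""
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    if delta == 0:
        return kappa_mean if size is None else np.full(size, float(kappa_mean))
    draw = rng.normal(kappa_mean, delta * kappa_mean, size=size)
    return np.maximum(draw, 0.0)


@dataclasses.dataclass
class KappaProcess:
    """Per-sector OU state; ``kappa`` has shape (..., N_sectors)."""

    kappa: np.ndarray
    kappa_mean_cell: np.ndarray  # shape broadcastable to kappa[..., 0]
    lam: float
    sigma: float

    @property
    def n_sectors(self) -> int:
        return self.kappa.shape[-1]

    @property
    def stationary_var(self) -> float:
        return self.sigma**2 / (2.0 * self.lam)


def init_kappa(
    kappa_mean_cell,
    lam: float,
    sigma: float,
    n_sectors: int,
    rng: np.random.Generator,
    batch: int | None = None,
) -> KappaProcess:
    """Initialize each sector from the stationary law (clamped at 0).

    The stationary draw doubles as the symmetry-breaking seed: it stands in
    for initial-condition heterogeneity of the signalling pathway.
    """
    mean = np.asarray(kappa_mean_cell, dtype=float)
    shape = (n_sectors,) if batch is None else (batch, n_sectors)
    if sigma == 0.0:
        kappa = np.broadcast_to(mean[..., None], shape).copy()
    else:
        sd = np.sqrt(sigma**2 / (2.0 * lam))
        kappa = np.maximum(mean[..., None] + sd * rng.standard_normal(shape), 0.0)
    return KappaProcess(kappa=kappa, kappa_mean_cell=mean, lam=lam, sigma=sigma)


def ou_step(proc: KappaProcess, dt: float, rng: np.random.Generator) -> KappaProcess:
    """Advance every sector by the exact OU transition over ``dt``, then clamp.

    kappa' = m + (kappa - m) e^{-lam dt} + sqrt(sigma^2 (1-e^{-2 lam dt})/(2 lam)) xi
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    m = np.asarray(proc.kappa_mean_cell, dtype=float)[..., None]
    decay = np.exp(-proc.lam * dt)
    new = m + (proc.kappa - m) * decay
    if proc.sigma > 0:
        sd = np.sqrt(proc.sigma**2 * (1.0 - decay**2) / (2.0 * proc.lam))
        new = new + sd * rng.standard_normal(proc.kappa.shape)
    return KappaProcess(
        kappa=np.maximum(new, 0.0),
        kappa_mean_cell=proc.kappa_mean_cell,
        lam=proc.lam,
        sigma=proc.sigma,
    )


def sector_of_segment(n_theta: int, n_sectors: int) -> np.ndarray:
    """Map membrane segment j to its noise sector floor(j * N / n_theta).

    Requires ``n_theta`` divisible by ``n_sectors`` so sectors align with
    whole segments.
    """
    if n_theta % n_sectors != 0:
        raise ValueError(
            f"n_theta={n_theta} must be divisible by N_sectors={n_sectors}"
        )
    return (np.arange(n_theta) * n_sectors) // n_theta
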