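"""Finite-volume mesh on the annular cell domain.

The cytoplasm is the annulus R_n < ||x|| < R, discretized by a structured
polar mesh, uniform in r and in theta.  The plasma membrane is the outer
circle, discretized into the n_theta arcs facing the outermost cell ring, so
membrane segment j shares its face with bulk cell (n_r - 1, j).  Angles are
measured counterclockwise from the gradient axis; arclength s = R * theta.

Cell areas and face lengths are exact (polar geometry), so the total area
sums to pi*(R^2 - R_n^2) and the outer perimeter to 2*pi*R at machine
precision, which is what makes discrete mass conservation exact.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = ["AnnulusMesh", "build_mesh", "window_masses", "window_size"]


@dataclasses.dataclass(frozen=True)
class AnnulusMesh:
    """Structured polar mesh of the annulus plus its outer boundary circle.

    Bulk fields are arrays of shape ``(n_r, n_theta)`` (radial index grows
    outward); membrane fields are arrays of shape ``(n_theta,)``.
    """

    R: float
    R_n: float
    n_r: int
    n_theta: int
    r_edges: np.ndarray        # (n_r+1,)
    r_centers: np.ndarray      # (n_r,)
    theta_centers: np.ndarray  # (n_theta,)
    dtheta: float
    dr: float
    cell_areas: np.ndarray     # (n_r,) area of a cell in ring i (same for all j)
    radial_face_len: np.ndarray  # (n_r+1,) arc length r_edge * dtheta
    angular_face_len: float    # dr (faces between angular neighbours)
    boundary_seg_len: float    # outer arc length R * dtheta

    @property
    def n_cells(self) -> int:
        return self.n_r * self.n_theta

    @property
    def total_area(self) -> float:
        return float(self.n_theta * self.cell_areas.sum())

    @property
    def perimeter(self) -> float:
        return float(self.n_theta * self.boundary_seg_len)

    def areas2d(self) -> np.ndarray:
        """Cell areas broadcast to the (n_r, n_theta) field shape."""
        return np.repeat(self.cell_areas[:, None], self.n_theta, axis=1)


def build_mesh(R: float, R_n: float, n_r: int, n_theta: int) -> AnnulusMesh:
    """Build the uniform polar mesh of the annulus ``R_n < r < R``."""
    if not (0.0 <= R_n < R):
        raise ValueError(f"need 0 <= R_n < R, got R_n={R_n}, R={R}")
    if n_r < 4 or n_theta < 16:
        raise ValueError(f"mesh too coarse: n_r={n_r} (min 4), n_theta={n_theta} (min 16)")
    r_edges = np.linspace(R_n, R, n_r + 1)
    dr = (R - R_n) / n_r
    dtheta = 2.0 * math.pi / n_theta
    r_centers = 0.5 * (r_edges[:-1] + r_edges[1:])
    theta_centers = (np.arange(n_theta) + 0.5) * dtheta
    cell_areas = 0.5 * (r_edges[1:] ** 2 - r_edges[:-1] ** 2) * dtheta
    return AnnulusMesh(
        R=R,
        R_n=R_n,
        n_r=n_r,
        n_theta=n_theta,
        r_edges=r_edges,
        r_centers=r_centers,
        theta_centers=theta_centers,
        dtheta=dtheta,
        dr=dr,
        cell_areas=cell_areas,
        radial_face_len=r_edges * dtheta,
        angular_face_len=dr,
        boundary_seg_len=R * dtheta,
    )


def window_size(n_theta: int, window_fraction: float) -> int:
    """Number of contiguous segments in a window covering ``window_fraction``
    of the perimeter (rounded up)."""
    if not 0.0 < window_fraction <= 1.0:
        raise ValueError(f"window_fraction must lie in (0, 1], got {window_fraction}")
    return int(math.ceil(window_fraction * n_theta))


def window_masses(mu: np.ndarray, window_fraction: float, seg_len: float = 1.0) -> np.ndarray:
    """Mass in every contiguous circular window of the membrane.

    ``mu`` is the membrane density per segment (uniform segment length
    ``seg_len``); the window spans ``ceil(window_fraction * n_theta)``
    consecutive segments.  Returns one total per possible start segment.
    """
    mu = np.asarray(mu, dtype=float)
    if mu.size == 0:
        raise ValueError("empty membrane density")
    w = window_size(mu.size, window_fraction)
    # circular windowed sums via cumulative sums on a doubled array
    ext = np.concatenate([mu, mu[: w - 1]])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    return (csum[w:] - csum[: mu.size]) * seg_len
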