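"""Polarization criterion, polar-cap angle and gradient-detection accuracy.

A cell counts as polarized when more than half of the total membrane Cdc42
sits in a single contiguous window covering 10% of the cell perimeter (the
footprint of a polarisome).  The window slides freely over the membrane (the
maximum over all circular windows is used), which makes the criterion
invariant under mesh rotation and strictly harder than any fixed-sector
variant.  The polar-cap direction is the circular (vector) mean angle of the
membrane density restricted to the winning window, and gradient-detection
accuracy over an ensemble is the mean cosine between cap directions and the
gradient axis at the first polarized time point.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .mesh import window_masses, window_size

__all__ = [
    "WINDOW_FRACTION",
    "POLARIZED_MASS_FRACTION",
    "SimResult",
    "is_polarized",
    "window_fractions",
    "cap_angle",
    "accuracy",
    "polarization_time",
]

WINDOW_FRACTION = 0.1          # window covers 10% of the perimeter
POLARIZED_MASS_FRACTION = 0.5  # strict threshold on the window's mass share


@dataclasses.dataclass
class SimResult:
    """Outcome of a single simulated cell."""

    polarized: bool
    t_pol: float | None          # s, first time the criterion held
    cap_angle: float | None      # rad, cap direction at that time
    kymograph: np.ndarray | None  # (n_samples, n_theta) membrane density
    kymograph_times: np.ndarray | None  # (n_samples,) s
    seed: int | None = None

    def __post_init__(self):
        if self.polarized != (self.t_pol is not None) or self.polarized != (
            self.cap_angle is not None
        ):
            raise ValueError("polarized flag must match presence of t_pol and cap_angle")


def window_fractions(mu: np.ndarray, window_fraction: float = WINDOW_FRACTION) -> np.ndarray:
    """Mass share of every circular window; ``mu`` may carry a batch axis."""
    mu = np.asarray(mu, dtype=float)
    if mu.ndim == 1:
        total = mu.sum()
        if total <= 0:
            raise ValueError("zero total membrane mass")
        return window_masses(mu, window_fraction) / total
    total = mu.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero total membrane mass")
    out = np.empty_like(mu)
    for b in range(mu.shape[0]):
        out[b] = window_masses(mu[b], window_fraction)
    return out / total


def is_polarized(
    mu: np.ndarray,
    window_fraction: float = WINDOW_FRACTION,
    threshold: float = POLARIZED_MASS_FRACTION,
) -> tuple[bool, int]:
    """Whether >50% of membrane mass sits in one 10%-of-perimeter window.

    Returns the flag and the start segment of the best window (ties go to
    the smallest start index).  The inequality is strict: a window holding
    exactly half the mass does not qualify.
    """
    fr = window_fractions(mu, window_fraction)
    best = int(np.argmax(fr))
    return bool(fr[best] > threshold), best


def cap_angle(
    mu: np.ndarray,
    window_fraction: float = WINDOW_FRACTION,
    threshold: float = POLARIZED_MASS_FRACTION,
) -> float:
    """Circular mean angle of the membrane density over the winning window.

    Raises if the polarization criterion does not hold.  Segment j is taken
    to sit at angle (j + 1/2) * 2 pi / n_theta.
    """
    mu = np.asarray(mu, dtype=float)
    flag, start = is_polarized(mu, window_fraction, threshold)
    if not flag:
        raise ValueError("cap angle undefined for an unpolarized state")
    n = mu.size
    w = window_size(n, window_fraction)
    idx = (start + np.arange(w)) % n
    theta = (idx + 0.5) * (2.0 * math.pi / n)
    weights = mu[idx]
    z = np.sum(weights * np.exp(1j * theta))
    return float(np.angle(z) % (2.0 * math.pi))


def accuracy(angles, theta_g: float) -> float:
    """Mean cosine between cap directions and the gradient direction."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("accuracy of an empty ensemble is undefined")
    return float(np.mean(np.cos(angles - theta_g)))


def polarization_time(
    kymograph: np.ndarray,
    times: np.ndarray,
    window_fraction: float = WINDOW_FRACTION,
    threshold: float = POLARIZED_MASS_FRACTION,
) -> float | None:
    """First sampled time at which the criterion holds, or None."""
    kymograph = np.asarray(kymograph, dtype=float)
    for k in range(kymograph.shape[0]):
        row = kymograph[k]
        if row.sum() <= 0:
            continue
        if is_polarized(row, window_fraction, threshold)[0]:
            return float(times[k])
    return None
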