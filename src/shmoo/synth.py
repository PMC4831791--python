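"""Synthetic uniform-field dose-response experiments.

Generates per-cell bud/shmoo outcomes with the statistical structure of the
microfluidic uniform-pheromone experiments: the probability of shmooing
follows a Hill curve in dose (half-max S50 = 1.02 nM, Hill coefficient
h = 6.5), the number of shmooing cells per dose is binomial over n_cells
(default 160 per dose), and polarization delays have a dose-dependent mean
that falls with dose plus per-cell noise.  The printed per-dose anchors
(4% shmooing at 0.6 nM, 50% at 1 nM, 93% at 2 nM) are available as a
separate dataset; note that the printed Hill fit implies p(2 nM) ~ 0.99,
which is not perfectly consistent with the printed 93% point — the
generator follows the fit, the anchor table keeps the printed points, and
nothing downstream requires the two to agree.

The delay curve mean_delay(S) = d0*(S50/S)^alpha + d_inf is a configuration
choice (the experiments plot delays but print no values); its default scale
puts the near-threshold delay at ~3.5 h, matching the reported hours-long
cap formation near threshold.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fitting import DoseResponseDataset

__all__ = [
    "SyntheticDesign",
    "shmoo_probability",
    "generate_dataset",
    "fit_hill",
    "in_paper_anchors",
    "HillFit",
]

#: Default synthetic dose grid (nM): anchors plus the quarter-decade grid.
SYNTH_DOSE_GRID = (0.6, 0.8, 1.0, 1.25, 1.6, 2.0, 10.0 ** 0.5, 10.0 ** 0.75, 10.0)


@dataclasses.dataclass(frozen=True)
class SyntheticDesign:
    """Design of one synthetic uniform-field experiment."""

    doses: tuple = SYNTH_DOSE_GRID
    n_cells: int = 160           # cells per dose (experimental floor)
    S50: float = 1.02            # half-max of the bud->shmoo transition, nM
    hill: float = 6.5            # Hill coefficient
    d0: float = 3.0              # delay curve amplitude, h
    alpha: float = 1.0           # delay curve exponent
    d_inf: float = 0.5           # asymptotic delay at high dose, h
    delay_sd: float = 0.8        # per-cell delay noise SD, h
    seed: int = 0

    def __post_init__(self):
        if self.S50 <= 0 or self.hill <= 0 or self.n_cells < 1:
            raise ValueError("need S50 > 0, hill > 0, n_cells >= 1")


def shmoo_probability(S, S50: float = 1.02, h: float = 6.5):
    """Hill probability of shmooing at dose S: p = S^h / (S50^h + S^h)."""
    S = np.asarray(S, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(S > 0, (S50 / np.where(S > 0, S, 1.0)) ** h, np.inf)
    p = 1.0 / (1.0 + ratio)
    return p if p.ndim else float(p)


def mean_delay(S, design: SyntheticDesign):
    """Mean polarization delay (h) at dose S; decreasing in S."""
    S = np.asarray(S, dtype=float)
    return design.d0 * (design.S50 / S) ** design.alpha + design.d_inf


def generate_dataset(design: SyntheticDesign) -> DoseResponseDataset:
    """Draw one synthetic experiment: binomial shmoo counts and truncated-
    normal delays per dose, summarized per dose.  Reproducible by seed."""
    rng = np.random.default_rng(design.seed)
    rows = []
    for S in design.doses:
        p = shmoo_probability(S, design.S50, design.hill)
        n_shmoo = int(rng.binomial(design.n_cells, p))
        if n_shmoo > 0:
            d = rng.normal(mean_delay(S, design), design.delay_sd, size=n_shmoo)
            d = np.maximum(d, 0.0)
            md = float(d.mean())
            sd = float(d.std(ddof=1)) if n_shmoo > 1 else np.nan
        else:
            md, sd = np.nan, np.nan
        rows.append(
            {
                "S_nM": float(S),
                "n_cells": design.n_cells,
                "n_shmoo": n_shmoo,
                "mean_delay_h": md,
                "sd_delay_h": sd,
            }
        )
    return DoseResponseDataset(table=pd.DataFrame(rows), provenance="synthetic")


@dataclasses.dataclass(frozen=True)
class HillFit:
    S50: float
    hill: float
    se_S50: float
    se_hill: float


def fit_hill(data: DoseResponseDataset) -> HillFit:
    """Binomial maximum-likelihood fit of the two-parameter Hill curve.

    In log-dose the Hill curve is a logistic regression,
    logit(p) = h*(ln S - ln S50), fitted as a binomial GLM; standard errors
    of (S50, h) follow from the coefficient covariance by the delta method.
    """
    t = data.table[data.table["S_nM"] > 0]
    frac = (t["n_shmoo"] / t["n_cells"]).to_numpy()
    if len(t) < 3 or np.all(frac <= 0.0) or np.all(frac >= 1.0):
        raise ValueError(
            "Hill fit is non-identifiable: need >= 3 positive doses with "
            "non-degenerate shmoo fractions"
        )
    x = sm.add_constant(np.log(t["S_nM"].to_numpy()))
    endog = np.column_stack(
        [t["n_shmoo"].to_numpy(dtype=float),
         (t["n_cells"] - t["n_shmoo"]).to_numpy(dtype=float)]
    )
    res = sm.GLM(endog, x, family=sm.families.Binomial()).fit()
    b0, b1 = res.params
    if b1 <= 0:
        raise ValueError("Hill fit non-identifiable: non-increasing dose response")
    h = b1
    lnS50 = -b0 / b1
    S50 = float(np.exp(lnS50))
    cov = res.cov_params()
    # delta method: lnS50 = -b0/b1; grad = (-1/b1, b0/b1^2)
    grad = np.array([-1.0 / b1, b0 / b1**2])
    var_ln = float(grad @ cov @ grad)
    se_S50 = S50 * np.sqrt(max(var_ln, 0.0))
    se_h = float(np.sqrt(cov[1, 1]))
    return HillFit(S50=S50, hill=float(h), se_S50=float(se_S50), se_hill=se_h)


def in_paper_anchors() -> DoseResponseDataset:
    """The three printed uniform-field anchors: shmoo fractions 0.04, 0.50
    and 0.93 at 0.6, 1 and 2 nM (160 cells each, the per-dose floor of the
    published experiment); no delay columns."""
    n = 160
    # fractional counts keep the printed fractions exact
    rows = [
        {"S_nM": 0.6, "n_cells": n, "n_shmoo": 0.04 * n,
         "mean_delay_h": np.nan, "sd_delay_h": np.nan},
        {"S_nM": 1.0, "n_cells": n, "n_shmoo": 0.50 * n,
         "mean_delay_h": np.nan, "sd_delay_h": np.nan},
        {"S_nM": 2.0, "n_cells": n, "n_shmoo": 0.93 * n,
         "mean_delay_h": np.nan, "sd_delay_h": np.nan},
    ]
    return DoseResponseDataset(table=pd.DataFrame(rows), provenance="in-paper")
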