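"""Grid-search calibration of (chi, k_off, delta) against uniform-field
dose-response data.

The free parameters of the model — the advection coefficient chi, the
membrane detachment rate k_off and the cell-to-cell variability delta — are
fitted to the fraction of cells polarizing within the horizon and, when the
dataset provides them, the mean and standard deviation of the polarization
delay, per dose.  The cost is a normalized weighted least-squares sum; the
published experiments constrain these three parameters tightly (the
dose-response is matched only in a narrow parameter valley), after which
gradient runs are pure prediction and must consume a frozen fit.

Implementation notes: triples sharing k_off also share every cached
operator, so the search batches all (chi, delta, dose, replicate) members
per k_off into one integrator; replicates use common random numbers across
triples so the cost surface is smooth in the grid despite stochastic
simulation.  k_off changes re-derive k_on (fixed 13% resting membrane
fraction) and D_m (fixed sqrt(D_m/k_off) length).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .actin import make_pheromone_field
from .dynamics import BatchSimulator, T_MAX_DEFAULT, default_mesh
from .ensemble import DT_ENSEMBLE, EnsembleSummary
from .mesh import AnnulusMesh
from .params import ModelParams

__all__ = ["DoseResponseDataset", "FitResult", "cost", "grid_search"]


@dataclasses.dataclass
class DoseResponseDataset:
    """Per-dose bud/shmoo outcomes (and optional delays): the calibration
    target.  ``table`` columns: S_nM, n_cells, n_shmoo, mean_delay_h,
    sd_delay_h."""

    table: pd.DataFrame
    provenance: str = "synthetic"

    def __post_init__(self):
        t = self.table
        if (t["n_shmoo"] > t["n_cells"]).any() or (t["n_shmoo"] < 0).any():
            raise ValueError("need 0 <= n_shmoo <= n_cells")
        self.table = t.sort_values("S_nM").reset_index(drop=True)

    @property
    def doses(self) -> np.ndarray:
        return self.table["S_nM"].to_numpy()

    @property
    def fractions(self) -> np.ndarray:
        return (self.table["n_shmoo"] / self.table["n_cells"]).to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "file") -> "DoseResponseDataset":
        return cls(table=pd.read_csv(path), provenance=provenance)


@dataclasses.dataclass
class FitResult:
    """Best (chi, k_off, delta) and the full cost grid."""

    chi: float
    k_off: float
    delta: float
    cost: float
    cost_grid: pd.DataFrame      # columns chi, k_off, delta, cost
    n_reps: int
    master_seed: int

    def apply(self, params: ModelParams) -> ModelParams:
        """Parameters with the fitted triple frozen in (k_on, D_m re-derived)."""
        return params.with_(chi=self.chi, k_off=self.k_off, delta=self.delta)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "chi": self.chi,
                    "k_off": self.k_off,
                    "delta": self.delta,
                    "cost": self.cost,
                    "n_reps": self.n_reps,
                    "master_seed": self.master_seed,
                    "cost_grid": self.cost_grid.to_dict(orient="list"),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "FitResult":
        d = json.loads(Path(path).read_text())
        return cls(
            chi=d["chi"], k_off=d["k_off"], delta=d["delta"], cost=d["cost"],
            cost_grid=pd.DataFrame(d["cost_grid"]), n_reps=d["n_reps"],
            master_seed=d["master_seed"],
        )


def cost(
    sim: EnsembleSummary | pd.DataFrame,
    data: DoseResponseDataset,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """Normalized weighted least squares between simulated and observed
    per-dose summaries.

    Terms: squared discrepancy in fraction polarized, mean delay and delay
    SD, each divided by the squared data-side scale (max over doses).  Delay
    terms are skipped at doses where either side has no polarized cells or
    the dataset carries no delays.  Dose grids must match.
    """
    table = sim.table if isinstance(sim, EnsembleSummary) else sim
    sim_doses = table["S_mean_nM"].to_numpy()
    if sim_doses.size != data.doses.size or not np.allclose(
        sim_doses, data.doses, rtol=1e-9
    ):
        raise ValueError(
            f"dose grids differ: sim {sim_doses}, data {data.doses}"
        )
    w_frac, w_mean, w_sd = weights
    total = 0.0
    frac_scale = max(data.fractions.max(), 1e-12)
    d_mean = data.table["mean_delay_h"].to_numpy(dtype=float)
    d_sd = data.table["sd_delay_h"].to_numpy(dtype=float)
    mean_scale = np.nanmax(d_mean) if np.isfinite(d_mean).any() else np.nan
    sd_scale = np.nanmax(d_sd) if np.isfinite(d_sd).any() else np.nan
    s_frac = table["frac_polarized"].to_numpy(dtype=float)
    s_mean = table["mean_delay_h"].to_numpy(dtype=float)
    s_sd = table["sd_delay_h"].to_numpy(dtype=float)
    for k in range(len(data.doses)):
        total += w_frac * ((s_frac[k] - data.fractions[k]) / frac_scale) ** 2
        if np.isfinite(d_mean[k]) and np.isfinite(s_mean[k]):
            total += w_mean * ((s_mean[k] - d_mean[k]) / mean_scale) ** 2
        if np.isfinite(d_sd[k]) and np.isfinite(s_sd[k]):
            total += w_sd * ((s_sd[k] - d_sd[k]) / sd_scale) ** 2
    return float(total)


def _summaries_for_koff(
    params: ModelParams,
    k_off: float,
    chi_grid: np.ndarray,
    delta_grid: np.ndarray,
    doses: np.ndarray,
    n_reps: int,
    master_seed: int,
    mesh: AnnulusMesh,
    dt: float,
    t_max: float,
) -> dict[tuple[float, float], pd.DataFrame]:
    """One batched run covering every (chi, delta, dose, rep) at this k_off."""
    p = params.with_(k_off=float(k_off))
    combos = list(itertools.product(chi_grid, delta_grid))
    fields, chi_arr, delta_arr, keys = [], [], [], []
    for chi, delta in combos:
        for di, dose in enumerate(doses):
            f = make_pheromone_field(float(dose), 0.0, 0.0, mesh)
            for rep in range(n_reps):
                fields.append(f)
                chi_arr.append(chi)
                delta_arr.append(delta)
                keys.append(di * n_reps + rep)  # common random numbers
    sim = BatchSimulator(
        p, mesh, fields, master_seed=master_seed,
        chi=np.array(chi_arr), delta=np.array(delta_arr),
        dt=dt, t_max=t_max, member_keys=keys,
    )
    out = sim.run()
    res = {}
    per_combo = len(doses) * n_reps
    for ci, (chi, delta) in enumerate(combos):
        sl = slice(ci * per_combo, (ci + 1) * per_combo)
        pol = out["polarized"][sl].reshape(len(doses), n_reps)
        tp = (out["t_pol"][sl] / 3600.0).reshape(len(doses), n_reps)
        rows = []
        for di, dose in enumerate(doses):
            delays = tp[di][pol[di]]
            rows.append(
                {
                    "S_mean_nM": float(dose),
                    "n_reps": n_reps,
                    "frac_polarized": pol[di].mean(),
                    "mean_delay_h": delays.mean() if delays.size else np.nan,
                    "sd_delay_h": delays.std(ddof=1) if delays.size > 1 else np.nan,
                }
            )
        res[(float(chi), float(delta))] = pd.DataFrame(rows)
    return res


def grid_search(
    chi_grid,
    koff_grid,
    delta_grid,
    data: DoseResponseDataset,
    n_reps: int = 50,
    master_seed: int = 0,
    params: ModelParams | None = None,
    mesh: AnnulusMesh | None = None,
    dt: float = DT_ENSEMBLE,
    t_max: float = T_MAX_DEFAULT,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> FitResult:
    """Exhaustive grid search; ties break toward the smallest chi, then
    k_off, then delta.  Reproducible bit-for-bit from
    (data, grids, n_reps, master_seed)."""
    chi_grid = np.asarray(sorted(chi_grid), dtype=float)
    koff_grid = np.asarray(sorted(koff_grid), dtype=float)
    delta_grid = np.asarray(sorted(delta_grid), dtype=float)
    if chi_grid.size == 0 or koff_grid.size == 0 or delta_grid.size == 0:
        raise ValueError("parameter grids must be non-empty")
    params = params or ModelParams()
    mesh = mesh or default_mesh(params)
    rows = []
    for k_off in koff_grid:
        summaries = _summaries_for_koff(
            params, k_off, chi_grid, delta_grid, data.doses,
            n_reps, master_seed, mesh, dt, t_max,
        )
        for (chi, delta), table in summaries.items():
            rows.append(
                {
                    "chi": chi, "k_off": float(k_off), "delta": delta,
                    "cost": cost(table, data, weights),
                }
            )
    grid = pd.DataFrame(rows)
    # lexicographic tie-break: iterate in (chi, k_off, delta) order
    grid_sorted = grid.sort_values(["chi", "k_off", "delta"]).reset_index(drop=True)
    best_i = None
    best_c = np.inf
    for i, r in grid_sorted.iterrows():
        if r["cost"] < best_c - 0.0:
            best_c = r["cost"]
            best_i = i
    b = grid_sorted.loc[best_i]
    return FitResult(
        chi=float(b["chi"]), k_off=float(b["k_off"]), delta=float(b["delta"]),
        cost=float(b["cost"]), cost_grid=grid, n_reps=n_reps,
        master_seed=master_seed,
    )
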