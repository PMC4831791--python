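"""Model parameters for the yeast polarization model.

The model tracks the polarity GTPase Cdc42 in the cytoplasmic bulk (an
annulus between the nuclear radius ``R_n`` and the cell radius ``R``) and on
the plasma membrane (the outer circle), coupled through attachment/detachment
exchange and an actin-mediated long-range advection of strength ``chi``.
The effective pheromone receptor activity ``kappa`` fluctuates in time as an
Ornstein-Uhlenbeck process of damping ``lam`` and intensity ``sigma``, with a
per-cell spread ``delta`` on its mean.

Three fields are dependent on others and are re-derived rather than set
independently:

* ``k_on`` from ``k_off`` and the resting membrane fraction (13% of Cdc42 is
  membrane-bound with no pheromone, which fixes k_on/k_off ~ 0.16 um on the
  default geometry);
* ``D_m`` from ``k_off`` through the measured length scale
  sqrt(D_m/k_off) = 0.37 um;
* ``sigma`` from ``lam`` through the stationarity constraint
  sigma^2/(2 lam) = kappa_mean.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import yaml

__all__ = [
    "ModelParams",
    "ParameterError",
    "derive_kon",
    "derive_membrane_fraction",
    "load_params",
    "save_params",
]

#: Length scale sqrt(D_m/k_off) of membrane diffusion, um.
DM_LENGTH_SCALE = 0.37

#: Default advection coefficient, um^2/s, in this package's flux convention
#: (boundary nucleation flux uses mu_tilde = mu * 2 pi R / M).  Value set by
#: the grid-search calibration against the uniform-field dose-response
#: anchors; see docs/methods.md.
CHI_DEFAULT = 1.22


class ParameterError(ValueError):
    """Invalid or inconsistent model parameter."""


def derive_kon(k_off: float, membrane_fraction: float, R: float, R_n: float) -> float:
    """Attachment coefficient k_on (um/s) from the resting membrane fraction.

    At the no-pheromone steady state the exchange k_on*n = k_off*mu balances
    a uniform bulk concentration n on the annulus of area pi*(R^2-R_n^2)
    against a uniform membrane density mu on the circle of length 2*pi*R.
    Requiring the membrane to hold a fraction ``membrane_fraction`` of the
    total pool gives k_on = k_off * r with

        r = membrane_fraction * (R^2 - R_n^2) / ((1 - membrane_fraction) * 2 R)

    which evaluates to ~0.16 um for the default f=0.13, R=2.5, R_n=1.
    """
    if not 0.0 < membrane_fraction < 1.0:
        raise ParameterError(
            f"membrane_fraction must lie in (0, 1), got {membrane_fraction}"
        )
    if not 0.0 <= R_n < R:
        raise ParameterError(f"need 0 <= R_n < R, got R_n={R_n}, R={R}")
    if k_off <= 0:
        raise ParameterError(f"k_off must be positive, got {k_off}")
    ratio = membrane_fraction * (R**2 - R_n**2) / ((1.0 - membrane_fraction) * 2.0 * R)
    return k_off * ratio


def derive_membrane_fraction(k_on: float, k_off: float, R: float, R_n: float) -> float:
    """Inverse of :func:`derive_kon`: resting membrane fraction from the rates."""
    r = k_on / k_off
    area_per_perim = (R**2 - R_n**2) / (2.0 * R)
    return r / (area_per_perim + r)


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """All model parameters, with units.

    Lengths in um, times in s, concentrations in nM, counts in molecules.
    ``eta`` is the dimensionless screening coefficient of the actin field
    equation; ``kappa_mean``, ``sigma``, ``delta`` are dimensionless.
    """

    R: float = 2.5               # cell radius, um
    R_n: float = 1.0             # nuclear radius, um
    D_b: float = 1.4             # bulk diffusion, um^2/s
    D_m: float = DM_LENGTH_SCALE**2 * 0.12   # membrane diffusion, um^2/s
    M: float = 1000.0            # total Cdc42 pool, molecules
    S0: float = 6.0              # receptor K_d, nM
    eta: float = 1e-3            # actin screening (dimensionless)
    k_off: float = 0.12          # membrane detachment rate, 1/s
    k_on: float | None = None    # attachment coeff, um/s (None -> derived)
    kappa_mean: float = 13.0     # mean effective receptor activity
    N_sectors: int = 10          # independent membrane noise sectors
    lam: float = 1.0 / 600.0     # OU damping, 1/s (1/lam = 10 min)
    sigma: float | None = None   # OU intensity (None -> derived; 0 = frozen noise)
    delta: float = 0.2           # cell-to-cell CV of kappa_mean
    chi: float = CHI_DEFAULT     # advection coefficient, um^2/s
    membrane_fraction_rest: float = 0.13  # resting membrane fraction

    def __post_init__(self):
        # fill dependent defaults before validating
        if self.k_on is None:
            object.__setattr__(
                self,
                "k_on",
                derive_kon(self.k_off, self.membrane_fraction_rest, self.R, self.R_n),
            )
        if self.sigma is None:
            object.__setattr__(self, "sigma", math.sqrt(2.0 * self.lam * self.kappa_mean))
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        positive = ["R", "D_b", "D_m", "S0", "M", "eta", "k_off", "k_on", "lam"]
        for name in positive:
            v = getattr(self, name)
            if not v > 0:
                raise ParameterError(f"{name} must be strictly positive, got {v}")
        if not 0.0 <= self.R_n < self.R:
            raise ParameterError(f"need 0 <= R_n < R, got R_n={self.R_n}, R={self.R}")
        if self.delta < 0:
            raise ParameterError(f"delta must be >= 0, got {self.delta}")
        if not 0.0 <= self.membrane_fraction_rest < 1.0:
            raise ParameterError(
                f"membrane_fraction_rest must lie in [0, 1), got "
                f"{self.membrane_fraction_rest}"
            )
        if self.kappa_mean < 0 or self.sigma < 0:
            raise ParameterError("kappa_mean and sigma must be >= 0")
        if self.chi < 0:
            raise ParameterError(f"chi must be >= 0, got {self.chi}")
        if self.N_sectors < 1:
            raise ParameterError(f"N_sectors must be >= 1, got {self.N_sectors}")
        # stationarity constraint sigma^2/(2 lam) = kappa_mean
        # (sigma = 0 is the documented frozen-noise mode and is exempt)
        if self.kappa_mean > 0 and self.sigma > 0:
            stat = self.sigma**2 / (2.0 * self.lam)
            if abs(stat - self.kappa_mean) > 1e-8 * max(1.0, self.kappa_mean):
                raise ParameterError(
                    f"sigma^2/(2 lam) = {stat:g} violates the stationarity "
                    f"constraint (= kappa_mean = {self.kappa_mean:g})"
                )

    # -- derived updates ----------------------------------------------------

    def with_(self, **updates) -> "ModelParams":
        """Return a copy with ``updates`` applied and dependent fields re-derived.

        Changing ``k_off`` re-derives ``k_on`` and ``D_m``; changing ``lam``
        or ``kappa_mean`` re-derives ``sigma``; changing geometry or the
        resting fraction re-derives ``k_on`` — unless the dependent field is
        itself among ``updates``.
        """
        fields = {f.name for f in dataclasses.fields(self)}
        unknown = set(updates) - fields
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        new = {f: getattr(self, f) for f in fields}
        new.update(updates)
        if "k_on" not in updates and {"k_off", "R", "R_n", "membrane_fraction_rest"} & set(updates):
            new["k_on"] = derive_kon(
                new["k_off"], new["membrane_fraction_rest"], new["R"], new["R_n"]
            )
        if "k_on" in updates and "membrane_fraction_rest" not in updates:
            new["membrane_fraction_rest"] = derive_membrane_fraction(
                new["k_on"], new["k_off"], new["R"], new["R_n"]
            )
        if "D_m" not in updates and "k_off" in updates:
            new["D_m"] = DM_LENGTH_SCALE**2 * new["k_off"]
        if "sigma" not in updates and {"lam", "kappa_mean"} & set(updates):
            new["sigma"] = math.sqrt(2.0 * new["lam"] * new["kappa_mean"])
        return ModelParams(**new)


# Config files use lam_per_hour (scan grids are specified in 1/h);
# internally lam is 1/s.
_CONFIG_KEYS = {
    "R", "R_n", "D_b", "D_m", "M", "S0", "eta", "k_off", "k_on",
    "kappa_mean", "N_sectors", "lam_per_hour", "sigma", "delta", "chi",
    "membrane_fraction_rest",
}


def load_params(config_path: str | Path) -> ModelParams:
    """Load :class:`ModelParams` from a flat YAML/JSON key-value file.

    Absent keys take the defaults; dependent fields (``k_on``, ``D_m``,
    ``sigma``) are re-derived from their constraints unless explicitly set,
    in which case the constraints are re-checked and violations rejected.
    Unknown keys are an error.
    """
    text = Path(config_path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"config must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
    kw = dict(raw)
    if "lam_per_hour" in kw:
        kw["lam"] = float(kw.pop("lam_per_hour")) / 3600.0
    # dataclass __post_init__ re-derives k_on/sigma when left at sentinel 0;
    # explicit overrides are passed through and validated.
    base = ModelParams()
    if "D_m" not in kw and "k_off" in kw:
        kw["D_m"] = DM_LENGTH_SCALE**2 * float(kw["k_off"])
    if "k_on" in kw and "membrane_fraction_rest" not in kw:
        kw["membrane_fraction_rest"] = derive_membrane_fraction(
            float(kw["k_on"]),
            float(kw.get("k_off", base.k_off)),
            float(kw.get("R", base.R)),
            float(kw.get("R_n", base.R_n)),
        )
    return ModelParams(**{k: (int(v) if k == "N_sectors" else float(v)) for k, v in kw.items()})


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write a params config (YAML or JSON by extension) that round-trips."""
    d = dataclasses.asdict(params)
    d["lam_per_hour"] = d.pop("lam") * 3600.0
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def params_to_dict(params: ModelParams) -> dict:
    """Plain-dict form (for manifests)."""
    return dataclasses.asdict(params)
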