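"""Model parameters and the shipped default set.

Units are nM and minutes throughout (the command-line surface reports time
in hours). The Wnt stimulus ``W`` is dimensionless, nondimensionalised
against a reference of 100 ng/ml, so ``W = 1`` is the reference stimulus
(crypt base), ``W = 0`` no stimulus (crypt orifice) and ``W = 2`` a
hyperstimulated state.

The shipped defaults were produced with the package's own calibration
pipeline (see :mod:`notchwnt.calibration` and ``docs/methods.md``):

* the beta-catenin production coefficients ``alpha3``, ``alpha4`` and the
  Wnt/GSK dissociation constant ``kappa_GW`` solve the decoupled Wnt
  steady-state conditions pinned to the hyperstimulation fold changes
  (B*(2)/B*(1) = 2.2, B*(2)/B*(0) = 8.3) at a reference B*(1) = 25 nM;
* the Notch-side constants were fitted with the sensitivity-ranked
  sequential 1D grid search so that a homogeneous cell pair running the
  decoupled Notch submodel shows damped Hes1 oscillations with a period
  within 10% of the 2 h benchmark, and heterogeneous starts fall in the
  2-4 h band.

``default_params()`` returns a fresh copy of this set; the same values ship
as ``data/defaults.yaml`` for use as a config-file starting point.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .errors import ParameterError

__all__ = ["ModelParams", "default_params", "load_params", "save_params"]


@dataclass
class ModelParams:
    """Rate constants and regulatory constants of the 12-species model.

    Attributes follow the model notation: ``alpha_*`` are maximal production
    rates (nM/min), ``mu_*`` first-order decay rates (min^-1), ``kappa*``
    Hill/dissociation constants (nM, or W-units for ``kappa_psi`` and
    ``kappa_GW``), ``k3``/``k_CB`` second-order binding rates
    (nM^-1 min^-1), ``k_cl`` the Notch cleavage rate, ``k_rev``/``k_I2``
    complex release rates (min^-1).
    """

    # Notch-side production rates (nM/min)
    alpha_N: float = 0.026054
    alpha_D: float = 0.097703
    alpha_P: float = 0.065135
    alpha_H1: float = 1.424842
    alpha_H2: float = 0.05
    # Wnt-side production rates
    alpha_A: float = 0.4
    alpha3: float = 0.231995  # basal beta-catenin production (nM/min)
    alpha4: float = 8.36493  # Wnt-coupled beta-catenin production (nM/min per unit W)

    # first-order decay rates (min^-1)
    mu_N: float = 0.065135
    mu_D: float = 0.065135
    mu_F: float = 0.065135
    mu_I1: float = 0.065135
    mu_H1: float = 0.065135
    mu_H2: float = 0.03
    mu_P: float = 0.065135
    mu_B: float = 6.36e-6
    mu_A: float = 0.2

    # binding / conversion rates
    k3: float = 0.15         # NICD + B -> I1 (nM^-1 min^-1)
    k_CB: float = 0.0108797      # C + B -> I2 (nM^-1 min^-1)
    k_cl: float = 0.065135   # Notch cleavage N -> F (min^-1)
    k_rev: float = 0.0495997     # C -> G release (min^-1)
    k_I2: float = 3.93185   # I2 -> C release (min^-1)

    # Hill / dissociation constants
    kappa1: float = 0.35     # Delta -> Notch production (nM)
    kappa2: float = 5.0      # Hes1 -| Ngn3 (nM)
    kappa3: float = 0.5      # Ngn3 -> Delta (nM)
    kappa4: float = 0.1      # I1 -> Hes1, Notch-mediated route (nM)
    kappa5: float = 6.5      # Hes1 autorepression (nM)
    kappa6: float = 5.0      # Hes1 -| Hath1 (nM)
    kappa7: float = 25.0     # B -> Hes1, Wnt-mediated route (nM)
    kappa_psi: float = 1.3   # Dsh-mediated Hes1 repression (W units)
    kappa_GA: float = 3.01847    # Axin half-saturation of complex formation (nM)
    kappa_GW: float = 2.77168    # Wnt inhibition of complex formation (W units)
    kappa_A: float = 8.97449     # beta-catenin -> Axin production (nM)

    # destruction-complex formation scale (min^-1)
    c_GC: float = 0.5

    # Hill exponents
    m: float = 3.0
    n: float = 3.0

    # promoter crosstalk and mutation multipliers
    theta2: float = 0.75     # proportion of Notch-mediated Hes1 control
    rho_apc: float = 1.0     # destruction-complex formation multiplier

    # reference quantities
    b_ref: float = 25.0      # beta-catenin held constant in the decoupled Notch submodel (nM)
    gsk_total: float = 50.0  # total GSK3beta pool G + C + I2 (nM)

    # model-variant switches
    gsk_open: bool = False   # add first-order decay to G and C
    mu_G: float = 0.0
    mu_C: float = 0.0

    def validate(self) -> "ModelParams":
        """Raise :class:`ParameterError` on any out-of-range value."""
        for f in dataclasses.fields(self):
            if f.name == "gsk_open":
                continue
            v = getattr(self, f.name)
            if not (v >= 0):
                raise ParameterError(f"parameter {f.name} must be >= 0, got {v}")
        if not 0.0 <= self.theta2 <= 1.0:
            raise ParameterError(f"theta2 must lie in [0, 1], got {self.theta2}")
        if not 0.0 <= self.rho_apc <= 1.0:
            raise ParameterError(f"rho_apc must lie in [0, 1], got {self.rho_apc}")
        if self.m < 1 or self.n < 1:
            raise ParameterError("Hill exponents m, n must be >= 1")
        for name in ("kappa1", "kappa2", "kappa3", "kappa4", "kappa5", "kappa6",
                     "kappa7", "kappa_psi", "kappa_GA", "kappa_GW", "kappa_A"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        return self

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d).validate()

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs).validate()

    def copy(self) -> "ModelParams":
        return dataclasses.replace(self)


def default_params() -> ModelParams:
    """The shipped calibrated parameter set (fresh copy)."""
    return ModelParams().validate()


def load_params(path) -> ModelParams:
    """Read a parameter set from a YAML config file.

    Keys missing from the file keep their default values, so a config may
    specify only the parameters it overrides.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    base = default_params().to_dict()
    known = set(base)
    unknown = set(doc) - known
    if unknown:
        raise ParameterError(f"unknown parameter(s) in {path}: {sorted(unknown)}")
    base.update(doc)
    return ModelParams.from_dict(base)


def save_params(params: ModelParams, path) -> None:
    """Write a parameter set as a YAML config file."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def packaged_defaults_path():
    """Path-like handle on the shipped ``defaults.yaml`` config."""
    return resources.files("notchwnt").joinpath("data/defaults.yaml")
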