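"""Voxel-wise proton RBE and RBE-weighted dose.

Four schemes are supported, all operating on physical dose (Gy) and
dose-averaged LET (keV/um):

``constant_1p1``
    the clinical standard, RBE = 1.1 everywhere.
``mcmahon_linear``
    linear LET fit, RBE = 1 + 0.055 * LETd (applied bare, no renormalisation).
``mcnamara``
    phenomenological LQ model with
    RBEmax = 0.99064 + 0.35605 * LETd / (alpha/beta) and
    RBEmin = 1.1012 - 0.0038703 * sqrt(alpha/beta) * LETd.
``wedenberg``
    phenomenological LQ model with
    RBEmax = 1 + 0.434 * LETd / (alpha/beta) and RBEmin = 1.

For the two LQ-based models the dose-dependent RBE is the solution of the
linear-quadratic survival-equivalence condition

    RBEmax * d + RBEmin^2 * d^2 / (a/b) = RBE * d + (RBE * d)^2 / (a/b)

whose closed form is

    RBE(d, LETd) = [ sqrt( (a/b)^2 + 4 d (a/b) RBEmax + 4 d^2 RBEmin^2 )
                     - (a/b) ] / (2 d),

interpolating between RBEmax (d -> 0) and RBEmin (d -> infinity).  The LQ
formalism is defined on the dose per fraction, so by default d is the
physical voxel dose divided by the number of fractions; evaluating on the
total dose is selectable for sensitivity checks.

LET maps produced by Monte Carlo scoring are unreliable in very-low-dose
voxels; voxels below a 10 cGy physical-dose threshold fall back to the
clinical RBE of 1.1 so that all dose variants agree there and comparisons
against the constant-RBE dose are not driven by LET noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import PatientCase, VoxelGrid

__all__ = [
    "MODEL_NAMES",
    "RBEModelSpec",
    "RBEFieldResult",
    "UnsupportedModelError",
    "model_spec",
    "rbe_max_min",
    "rbe_lq",
    "rbe_field",
]

logger = logging.getLogger(__name__)

# model-specific coefficients (alpha/beta enters separately)
_COEFFS: dict[str, dict[str, float]] = {
    "constant_1p1": {"rbe": 1.1},
    "mcmahon_linear": {"slope_um_per_keV": 0.055},
    "mcnamara": {
        "max_intercept": 0.99064,
        "max_slope": 0.35605,      # Gy um/keV
        "min_intercept": 1.1012,
        "min_slope": 0.0038703,    # Gy^(-1/2) um/keV
    },
    "wedenberg": {"max_slope": 0.434},  # Gy um/keV
}

MODEL_NAMES = tuple(_COEFFS)
_LQ_MODELS = ("mcnamara", "wedenberg")


class UnsupportedModelError(ValueError):
    """The requested operation is undefined for this RBE model."""


@dataclass(frozen=True)
class RBEModelSpec:
    """A named RBE parameterization with its coefficients and alpha/beta."""

    name: str
    alpha_beta_Gy: float = 3.0
    coefficients: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.name not in _COEFFS:
            raise UnsupportedModelError(
                f"unknown RBE model {self.name!r}; known: {MODEL_NAMES}"
            )
        if self.alpha_beta_Gy <= 0:
            raise ValueError("alpha_beta_Gy must be > 0")
        coeffs = dict(_COEFFS[self.name]) if self.coefficients is None else dict(self.coefficients)
        if set(coeffs) != set(_COEFFS[self.name]):
            raise ValueError(
                f"coefficients for {self.name} must be exactly {sorted(_COEFFS[self.name])}"
            )
        object.__setattr__(self, "coefficients", coeffs)

    @property
    def is_lq(self) -> bool:
        return self.name in _LQ_MODELS


def model_spec(name: str, alpha_beta_Gy: float = 3.0) -> RBEModelSpec:
    """Convenience constructor with the published default coefficients."""
    return RBEModelSpec(name=name, alpha_beta_Gy=alpha_beta_Gy)


@dataclass(frozen=True)
class RBEFieldResult:
    """RBE map and RBE-weighted dose for one case under one model."""

    rbe: VoxelGrid            # dimensionless
    weighted_dose: VoxelGrid  # GyRBE
    model: RBEModelSpec
    fractionation_mode: str
    n_clamped_rbe_min: int = 0


def rbe_max_min(model: RBEModelSpec, letd):
    """Asymptotic RBE at zero and infinite dose for the LQ-based models.

    RBEmin below zero (possible for the McNamara fit at extreme
    LETd * sqrt(alpha/beta)) is clamped at 0 to keep the LQ closed form
    real-valued; the number of clamped entries is logged as a warning.
    """
    if not model.is_lq:
        raise UnsupportedModelError(
            f"model {model.name!r} has no RBEmax/RBEmin structure"
        )
    letd = np.asarray(letd, dtype=np.float64)
    ab = model.alpha_beta_Gy
    c = model.coefficients
    if model.name == "mcnamara":
        rbe_max = c["max_intercept"] + c["max_slope"] * letd / ab
        rbe_min = c["min_intercept"] - c["min_slope"] * np.sqrt(ab) * letd
        n_neg = int(np.count_nonzero(rbe_min < 0))
        if n_neg:
            logger.warning("mcnamara RBEmin < 0 at %d LETd values; clamped to 0", n_neg)
            rbe_min = np.maximum(rbe_min, 0.0)
    else:  # wedenberg
        rbe_max = 1.0 + c["max_slope"] * letd / ab
        rbe_min = np.ones_like(rbe_max)
    return rbe_max, rbe_min


def rbe_lq(model: RBEModelSpec, dose_per_fraction, letd):
    """Dose-dependent RBE from the LQ closed form (see module docstring).

    Values lie between RBEmin and RBEmax and approach RBEmax as the fraction
    dose goes to zero and RBEmin as it goes to infinity.
    """
    d = np.asarray(dose_per_fraction, dtype=np.float64)
    if np.any(d <= 0):
        raise ValueError("dose_per_fraction must be > 0 (use the low-dose fallback upstream)")
    rbe_max, rbe_min = rbe_max_min(model, letd)
    ab = model.alpha_beta_Gy
    disc = ab * ab + 4.0 * d * ab * rbe_max + 4.0 * d * d * rbe_min * rbe_min
    return (np.sqrt(disc) - ab) / (2.0 * d)


def rbe_field(
    case: PatientCase,
    model: RBEModelSpec,
    fractionation_mode: str = "per_fraction",
    low_dose_threshold_Gy: float = 0.10,
) -> RBEFieldResult:
    """Voxel-wise RBE map and RBE-weighted dose for a whole case.

    Voxels whose physical dose is below ``low_dose_threshold_Gy`` (default
    10 cGy, matching the LET scoring cutoff) are assigned the clinical RBE
    from the plan metadata so the low-dose region contributes identically
    across all dose variants.
    """
    if fractionation_mode not in ("per_fraction", "total_dose"):
        raise ValueError(f"unknown fractionation_mode {fractionation_mode!r}")
    if low_dose_threshold_Gy < 0:
        raise ValueError("low_dose_threshold_Gy must be >= 0")

    dose = case.physical_dose.values
    letd = case.letd.values
    supra = dose >= low_dose_threshold_Gy
    n_bad = int(np.count_nonzero(~np.isfinite(letd) & supra))
    if n_bad:
        raise ValueError(f"letd is non-finite at {n_bad} supra-threshold voxels")

    rbe = np.full(dose.shape, case.plan.rbe_clinical, dtype=np.float64)
    n_clamped = 0
    if model.name == "constant_1p1":
        rbe[:] = model.coefficients["rbe"]
    elif model.name == "mcmahon_linear":
        rbe[supra] = 1.0 + model.coefficients["slope_um_per_keV"] * letd[supra]
    else:
        d = dose[supra]
        if fractionation_mode == "per_fraction":
            d = d / case.plan.n_fractions
        rbe[supra] = rbe_lq(model, d, letd[supra])
        if model.name == "mcnamara":
            c = model.coefficients
            raw_min = c["min_intercept"] - c["min_slope"] * np.sqrt(model.alpha_beta_Gy) * letd[supra]
            n_clamped = int(np.count_nonzero(raw_min < 0))

    rbe_grid = case.physical_dose.with_values(rbe, units="1")
    weighted = case.physical_dose.with_values(rbe * dose, units="GyRBE")
    return RBEFieldResult(
        rbe=rbe_grid,
        weighted_dose=weighted,
        model=model,
        fractionation_mode=fractionation_mode,
        n_clamped_rbe_min=n_clamped,
    )
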