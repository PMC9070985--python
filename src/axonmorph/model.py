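"""Forward biophysical model of a white-matter axon population.

The tract is described by two laws:

* a Gamma distribution of axonal (inner) radius ``r``, parameterised by its
  mode ``M`` (μm) and scale ``θ`` (μm), so the shape is ``k = M/θ + 1``;
* a power-law radius dependence of the per-axon g-ratio,
  ``g(r) = β·r^α``.

From these, two in-vivo observables follow in closed form:

* the MRI-measured aggregate g-ratio — the cross-sectional-area-weighted
  ensemble average ``g_MRI² = E[r²] / E[r²/g(r)²]``, which for the Gamma
  law evaluates to ``β² θ^{2α} Γ(k+2)/Γ(k+2−2α)``;
* the EEG-derived conduction velocity — assuming every axon contributes
  equally, ``V = p ∫ 2r/g(r) P(r) dr = (2p/β) θ^{1−α} Γ(k+1−α)/Γ(k)``
  with ``p ≈ 5.5`` (m/s)/μm the axonal propagation prefactor.

All gamma-function ratios are evaluated as exponentials of log-gamma
differences so that very small scales (shape parameters in the thousands)
do not overflow.  Units are fixed at the module boundary: radii in μm,
velocities in m/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.special import gammaincc, gammaln
from scipy.stats import gamma as gamma_dist

from .exceptions import InvalidParameterError, QuadratureError

__all__ = [
    "GammaRadiusDistribution",
    "PowerLawGRatio",
    "AxonPopulationModel",
    "radius_pdf",
    "mean_radius",
    "tail_fraction",
    "predict_g_mri",
    "predict_velocity",
    "quadrature_g_mri",
    "quadrature_velocity",
]

DEFAULT_VELOCITY_PREFACTOR = 5.5  # (m/s)/μm; literature range ~5.5-6.0


@dataclass(frozen=True)
class GammaRadiusDistribution:
    """Gamma law of axonal radius, parameterised by mode and scale.

    Parameters
    ----------
    mode_um
        Mode ``M`` of the radius distribution (μm), the most frequent
        axonal radius in the tract.
    scale_um
        Scale ``θ`` (μm), the width of the right tail — a measure of the
        prevalence of large axons.
    """

    mode_um: float
    scale_um: float

    def __post_init__(self) -> None:
        if not (self.mode_um > 0 and np.isfinite(self.mode_um)):
            raise InvalidParameterError(f"mode_um must be positive, got {self.mode_um}")
        if not (self.scale_um > 0 and np.isfinite(self.scale_um)):
            raise InvalidParameterError(f"scale_um must be positive, got {self.scale_um}")

    @property
    def shape(self) -> float:
        """Gamma shape parameter ``k = M/θ + 1`` (> 1 by construction)."""
        return self.mode_um / self.scale_um + 1.0

    @property
    def mean_um(self) -> float:
        """Mean radius ``k·θ = M + θ`` (μm)."""
        return self.mode_um + self.scale_um

    def pdf(self, r):
        """Probability density (1/μm) at radius ``r`` (μm); vectorised."""
        r = np.asarray(r, dtype=float)
        if np.any(r < 0):
            raise InvalidParameterError("radius must be non-negative")
        return gamma_dist.pdf(r, a=self.shape, scale=self.scale_um)

    def quantile(self, q: float) -> float:
        return float(gamma_dist.ppf(q, a=self.shape, scale=self.scale_um))

    def tail_fraction(self, r_min: float) -> float:
        """P(r > r_min): regularised upper incomplete gamma at r_min/θ."""
        if r_min < 0:
            raise InvalidParameterError("r_min must be non-negative")
        return float(gammaincc(self.shape, r_min / self.scale_um))

    def moment(self, order: float) -> float:
        """Fractional raw moment ``E[r^s] = θ^s Γ(k+s)/Γ(k)``; s > −k."""
        k = self.shape
        if order <= -k:
            raise InvalidParameterError(f"moment of order {order} does not exist for shape {k}")
        return float(self.scale_um**order * np.exp(gammaln(k + order) - gammaln(k)))


@dataclass(frozen=True)
class PowerLawGRatio:
    """Radius-dependent per-axon g-ratio ``g(r) = β·r^α``.

    ``α`` is the (dimensionless) slope of the radius dependence and ``β``
    its scale (μm^−α).  ``α`` is restricted to [0, 0.5) so every
    gamma-function argument in the aggregate closed form stays positive.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.beta > 0 and np.isfinite(self.beta)):
            raise InvalidParameterError(f"beta must be positive, got {self.beta}")
        if not (0.0 <= self.alpha < 0.5):
            raise InvalidParameterError(f"alpha must lie in [0, 0.5), got {self.alpha}")
        # Physiological sanity: per-axon g-ratio should stay below 1 over
        # the radius range observed in white matter.  Soft check only.
        r_probe = np.array([0.05, 3.0])
        if np.any(self.beta * r_probe**self.alpha >= 1.0):
            warnings.warn(
                f"g(r) = {self.beta}*r^{self.alpha} reaches 1 within r in [0.05, 3] um; "
                "the power law leaves the physiological range",
                stacklevel=2,
            )

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        return self.beta * r**self.alpha


@dataclass(frozen=True)
class AxonPopulationModel:
    """Radius distribution + g-ratio law + conduction prefactor ``p``."""

    radius_dist: GammaRadiusDistribution
    gratio_law: PowerLawGRatio
    velocity_prefactor: float = DEFAULT_VELOCITY_PREFACTOR

    def __post_init__(self) -> None:
        if not (self.velocity_prefactor > 0 and np.isfinite(self.velocity_prefactor)):
            raise InvalidParameterError("velocity_prefactor must be positive")
        if not (5.0 <= self.velocity_prefactor <= 6.5):
            warnings.warn(
                f"velocity prefactor p={self.velocity_prefactor} outside the "
                "literature range [5.0, 6.5] (m/s)/um",
                stacklevel=2,
            )

    @classmethod
    def from_params(
        cls,
        mode_um: float,
        scale_um: float,
        alpha: float,
        beta: float,
        velocity_prefactor: float = DEFAULT_VELOCITY_PREFACTOR,
    ) -> "AxonPopulationModel":
        return cls(
            GammaRadiusDistribution(mode_um, scale_um),
            PowerLawGRatio(alpha, beta),
            velocity_prefactor,
        )


# ---------------------------------------------------------------------------
# closed-form scalar kernels (also used by the inverse solvers in hot loops)
# ---------------------------------------------------------------------------

def _check_gamma_args(mode, scale, alpha):
    k = mode / scale + 1.0
    if np.any(k - 2.0 * alpha <= 0.0):
        raise InvalidParameterError(
            f"gamma-function argument M/th+1-2a = {np.min(k - 2 * alpha):.3g} must be positive"
        )
    return k


def _g_mri(mode, scale, alpha, beta):
    """Aggregate g-ratio: β θ^α sqrt(Γ(k+2)/Γ(k+2−2α)), k = M/θ+1."""
    k = _check_gamma_args(mode, scale, alpha)
    return beta * scale**alpha * np.exp(0.5 * (gammaln(k + 2.0) - gammaln(k + 2.0 - 2.0 * alpha)))


def _velocity(mode, scale, alpha, beta, p=DEFAULT_VELOCITY_PREFACTOR):
    """Conduction velocity: (2p/β) θ^{1−α} Γ(k+1−α)/Γ(k)."""
    k = _check_gamma_args(mode, scale, alpha)
    return (2.0 * p / beta) * scale ** (1.0 - alpha) * np.exp(gammaln(k + 1.0 - alpha) - gammaln(k))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def radius_pdf(dist: GammaRadiusDistribution, r):
    """Gamma radius density (1/μm) at ``r`` (μm)."""
    return dist.pdf(r)


def mean_radius(dist: GammaRadiusDistribution) -> float:
    """Mean axonal radius ``M + θ`` (μm)."""
    return dist.mean_um


def tail_fraction(dist: GammaRadiusDistribution, r_min: float) -> float:
    """Fraction of axons with radius above ``r_min``."""
    return dist.tail_fraction(r_min)


def predict_g_mri(model: AxonPopulationModel) -> float:
    """Closed-form MRI-measured aggregate g-ratio for the population."""
    return float(
        _g_mri(
            model.radius_dist.mode_um,
            model.radius_dist.scale_um,
            model.gratio_law.alpha,
            model.gratio_law.beta,
        )
    )


def predict_velocity(model: AxonPopulationModel) -> float:
    """Closed-form ensemble conduction velocity (m/s)."""
    return float(
        _velocity(
            model.radius_dist.mode_um,
            model.radius_dist.scale_um,
            model.gratio_law.alpha,
            model.gratio_law.beta,
            model.velocity_prefactor,
        )
    )


_TAIL_QUANTILE = 1.0 - 1e-12


def _quad(fn, upper):
    val, err = integrate.quad(fn, 0.0, upper, epsabs=1e-12, epsrel=1e-10, limit=300)
    if not np.isfinite(val) or (abs(val) > 0 and err > 1e-6 * abs(val)):
        raise QuadratureError(f"integral did not converge: value={val}, abs err={err}")
    return val


def quadrature_g_mri(model: AxonPopulationModel) -> float:
    """Definitional aggregate g-ratio by numerical integration.

    Integrates the fiber-cross-section-weighted average of g² with fiber
    radius ``R = r/g(r)``:  g_MRI² = ∫R²g²P dr / ∫R²P dr = E[r²]/E[r²/g²].
    Serves as the independent oracle for :func:`predict_g_mri`.
    """
    dist, law = model.radius_dist, model.gratio_law
    upper = dist.quantile(_TAIL_QUANTILE)
    num = _quad(lambda r: r**2 * dist.pdf(r), upper)
    den = _quad(lambda r: (r / law(r)) ** 2 * dist.pdf(r), upper)
    return float(np.sqrt(num / den))


def quadrature_velocity(model: AxonPopulationModel) -> float:
    """Definitional conduction velocity V = p ∫ 2r/g(r) P(r) dr (m/s)."""
    dist, law = model.radius_dist, model.gratio_law
    upper = dist.quantile(_TAIL_QUANTILE)
    return float(model.velocity_prefactor * _quad(lambda r: 2.0 * r / law(r) * dist.pdf(r), upper))
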