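"""Inversion of the forward model from in-vivo observables.

Two of the four model parameters {M, θ, α, β} are estimated from the
observables (a vector of g_MRI samples and one conduction velocity); the
other two are held at reference constants.  Estimation minimises the
stacked residual vector ``[g_i − ĝ]_i ⧺ [V − V̂]`` by bounded
trust-region-reflective least squares, mirroring the original MATLAB
``lsqnonlin`` setup with initial values θ = 0.10 μm, β = 0.70 μm^−α.

Because the forward model predicts a single g value, the least-squares
optimum coincides with the exact solution of the 2×2 system
``ĝ = mean(g)``, ``V̂ = V`` whenever that system has a root within
bounds; :func:`solve_two_equations` computes it directly and serves both
as the deterministic oracle for :func:`estimate` and as the fast path for
the simulation grid scans.

Confidence intervals are propagated from the velocity confidence interval
(itself derived from the transfer-time uncertainty) by refitting at both
interval endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares, root

from .exceptions import (
    EstimationError,
    IncompatibleObservablesError,
    InvalidParameterError,
)
from .model import DEFAULT_VELOCITY_PREFACTOR, _g_mri, _velocity

__all__ = ["FitConfig", "FitResult", "estimate", "solve_two_equations", "confidence_interval"]

PARAM_NAMES = ("mode", "theta", "alpha", "beta")

_DEFAULT_BOUNDS = {
    "mode": (0.01, 2.0),
    "theta": (1e-4, 5.0),
    "alpha": (0.0, 0.45),
    "beta": (0.1, 1.5),
}
_DEFAULT_INIT = {"mode": 0.40, "theta": 0.10, "alpha": 0.14, "beta": 0.70}
_DEFAULT_FIXED = {"alpha": 0.14, "mode": 0.40}


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the two-parameter inversion.

    ``free`` names the two estimated parameters; every other parameter is
    taken from ``fixed``.  Defaults estimate (θ, β) with α = 0.14 and
    M = 0.40 μm fixed.
    """

    free: tuple[str, str] = ("theta", "beta")
    fixed: dict = field(default_factory=dict)
    init: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    tol: float = 1e-10
    velocity_prefactor: float = DEFAULT_VELOCITY_PREFACTOR

    def __post_init__(self) -> None:
        if len(self.free) != 2 or len(set(self.free)) != 2:
            raise InvalidParameterError("exactly two distinct free parameters required")
        for name in self.free:
            if name not in PARAM_NAMES:
                raise InvalidParameterError(f"unknown parameter {name!r}")
        if self.tol <= 0:
            raise InvalidParameterError("tol must be positive")
        for name in self.free:
            lo, hi = self.bounds_for(name)
            x0 = self.init_for(name)
            if not lo <= x0 <= hi:
                raise InvalidParameterError(f"init for {name} ({x0}) outside bounds [{lo}, {hi}]")

    def fixed_for(self, name: str) -> float:
        if name in self.fixed:
            return float(self.fixed[name])
        if name in _DEFAULT_FIXED:
            return _DEFAULT_FIXED[name]
        return _DEFAULT_INIT[name]

    def init_for(self, name: str) -> float:
        return float(self.init.get(name, _DEFAULT_INIT[name]))

    def bounds_for(self, name: str) -> tuple[float, float]:
        return tuple(self.bounds.get(name, _DEFAULT_BOUNDS[name]))

    def params_from(self, free_values) -> dict:
        """Full parameter dict from values of the free pair."""
        params = {name: self.fixed_for(name) for name in PARAM_NAMES if name not in self.free}
        params.update(dict(zip(self.free, free_values)))
        return params


@dataclass
class FitResult:
    """Estimated free parameters with diagnostics."""

    estimates: dict
    residual_norm: float
    converged: bool
    n_g_samples: int
    ci: dict | None = None
    ci_warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ci is not None:
            for name, (lo, hi) in self.ci.items():
                est = self.estimates[name]
                if not (lo <= est + 1e-12 and est - 1e-12 <= hi):
                    raise InvalidParameterError(
                        f"confidence interval [{lo}, {hi}] does not bracket estimate {est} for {name}"
                    )


def _forward(params: dict, p: float) -> tuple[float, float]:
    g = _g_mri(params["mode"], params["theta"], params["alpha"], params["beta"])
    v = _velocity(params["mode"], params["theta"], params["alpha"], params["beta"], p)
    return float(g), float(v)


# ---------------------------------------------------------------------------
# exact two-equation solve
# ---------------------------------------------------------------------------

def _solve_separable(g_mean, velocity, config, other):
    """Free pair contains β: β cancels in g·V, leaving 1-D root in `other`.

    g ∝ β and V ∝ 1/β, so the product g·V depends only on the non-β free
    parameter; β then follows from the g equation.
    """
    target = g_mean * velocity
    lo, hi = config.bounds_for(other)

    def product(x):
        params = config.params_from([x, 1.0] if config.free[0] == other else [1.0, x])
        g, v = _forward(params, config.velocity_prefactor)
        return g * v

    f = lambda x: product(x) - target
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise IncompatibleObservablesError(
            f"no {other} in [{lo}, {hi}] reproduces g*V = {target:.4g} "
            f"(range [{min(flo, fhi) + target:.4g}, {max(flo, fhi) + target:.4g}])"
        )
    x = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
    params = config.params_from([x, 1.0] if config.free[0] == other else [1.0, x])
    g_unit, _ = _forward(params, config.velocity_prefactor)
    beta = g_mean / g_unit
    blo, bhi = config.bounds_for("beta")
    if not blo <= beta <= bhi:
        raise IncompatibleObservablesError(
            f"implied beta = {beta:.4g} outside bounds [{blo}, {bhi}]"
        )
    values = {other: float(x), "beta": float(beta)}
    return {name: values[name] for name in config.free}


def _solve_mode_theta(g_mean, velocity, config):
    """Free pair (M, θ) with (α, β) fixed: 2-D root in log space.

    Solved in (log M, log θ) so that boundary-pushed solutions (M down to
    ~1e-14 μm for high-g/low-V combinations) remain reachable.  Newton-type
    root finding from several starts, with a vectorised coarse scan as a
    fallback start generator.
    """
    log_g, log_v = np.log(g_mean), np.log(velocity)

    def resid(x):
        if np.any(np.abs(x) > 80.0):  # keep exp() in range; softly repel the iterate
            return np.array([10.0, 10.0]) + np.abs(x) / 80.0
        m, th = np.exp(x)
        try:
            g, v = _forward(config.params_from((m, th)), config.velocity_prefactor)
        except InvalidParameterError:
            return np.array([10.0, 10.0])
        return np.array([np.log(g) - log_g, np.log(v) - log_v])

    starts = [(0.4, 0.2), (0.1, 0.5), (0.8, 0.05), (1e-6, 0.2), (1e-12, 0.4), (1.5, 0.02)]
    best = None
    for m0, th0 in starts:
        sol = root(resid, np.log([m0, th0]), method="hybr", options={"xtol": 1e-13})
        err = float(np.max(np.abs(resid(sol.x))))
        if best is None or err < best[1]:
            best = (sol.x, err)
        if err < 1e-9:
            break
    if best[1] >= 1e-9:
        # coarse vectorised scan for a better start
        mm, tt = np.meshgrid(np.geomspace(1e-14, 2.0, 60), np.geomspace(1e-3, 5.0, 60))
        with np.errstate(all="ignore"):
            gg = _g_mri(mm, tt, config.fixed_for("alpha"), config.fixed_for("beta"))
            vv = _velocity(
                mm, tt, config.fixed_for("alpha"), config.fixed_for("beta"),
                config.velocity_prefactor,
            )
            err2 = (np.log(gg) - log_g) ** 2 + (np.log(vv) - log_v) ** 2
        i = np.nanargmin(err2)
        sol = root(
            resid, np.log([mm.ravel()[i], tt.ravel()[i]]), method="hybr",
            options={"xtol": 1e-13},
        )
        err = float(np.max(np.abs(resid(sol.x))))
        if err < best[1]:
            best = (sol.x, err)
    if best[1] >= 1e-9:
        raise IncompatibleObservablesError(
            f"no (mode, theta) solution for g={g_mean:.4g}, V={velocity:.4g} "
            f"(best residual {best[1]:.3g})"
        )
    m, th = np.exp(best[0])
    values = {"mode": float(m), "theta": float(th)}
    return {name: values[name] for name in config.free}


def solve_two_equations(g_mean: float, velocity: float, config: FitConfig | None = None) -> dict:
    """Exactly solve ``ĝ(p) = g_mean`` and ``V̂(p) = velocity`` for the free pair.

    Deterministic oracle for :func:`estimate` and fast path for grid
    scans.  Raises :class:`IncompatibleObservablesError` when the
    observable pair lies outside the model's attainable band.
    """
    config = config or FitConfig()
    if not (0.0 < g_mean < 1.0):
        raise InvalidParameterError(f"g_mean must lie in (0, 1), got {g_mean}")
    if velocity <= 0:
        raise InvalidParameterError("velocity must be positive")
    free = set(config.free)
    if "beta" in free:
        other = (free - {"beta"}).pop()
        if other == "alpha":
            return _solve_generic(g_mean, velocity, config)
        return _solve_separable(g_mean, velocity, config, other)
    if free == {"mode", "theta"}:
        return _solve_mode_theta(g_mean, velocity, config)
    return _solve_generic(g_mean, velocity, config)


def _solve_generic(g_mean, velocity, config):
    """Bounded least-squares fallback for free pairs involving α."""
    result = estimate(np.array([g_mean]), velocity, config)
    if result.residual_norm > 1e-7:
        raise IncompatibleObservablesError(
            f"no exact solution for g={g_mean}, V={velocity} with free={config.free} "
            f"(residual {result.residual_norm:.3g})"
        )
    return result.estimates


# ---------------------------------------------------------------------------
# least-squares estimation from sample vectors
# ---------------------------------------------------------------------------

def estimate(
    g_samples,
    velocity: float,
    config: FitConfig | None = None,
    weights=None,
) -> FitResult:
    """Least-squares inversion from g_MRI samples and one velocity.

    Minimises ``sum_i (g_i − ĝ)² + (V − V̂)²`` over the two free
    parameters with a bounded trust-region-reflective solver.  Residuals
    are unweighted by default (g dimensionless, V in m/s); an optional
    weight vector of length ``len(g_samples) + 1`` scales them.
    """
    config = config or FitConfig()
    g = np.atleast_1d(np.asarray(g_samples, dtype=float))
    if g.size == 0:
        raise InvalidParameterError("g_samples must be non-empty")
    if np.any(~np.isfinite(g)) or np.any(g <= 0) or np.any(g >= 1):
        raise InvalidParameterError("g_samples must all lie in (0, 1)")
    if velocity <= 0:
        raise InvalidParameterError("velocity must be positive")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (g.size + 1,):
            raise InvalidParameterError("weights must have length len(g_samples) + 1")

    lo = np.array([config.bounds_for(n)[0] for n in config.free])
    hi = np.array([config.bounds_for(n)[1] for n in config.free])
    x0 = np.array([config.init_for(n) for n in config.free])

    def residuals(x):
        try:
            gh, vh = _forward(config.params_from(x), config.velocity_prefactor)
        except InvalidParameterError:
            return np.full(g.size + 1, 1e6)
        r = np.concatenate([g - gh, [velocity - vh]])
        return r * weights if weights is not None else r

    sol = least_squares(
        residuals, x0, bounds=(lo, hi), method="trf",
        xtol=config.tol, ftol=config.tol, gtol=None,
    )
    if sol.status <= 0:
        raise EstimationError(f"least-squares did not converge: {sol.message}")
    estimates = {name: float(v) for name, v in zip(config.free, sol.x)}
    return FitResult(
        estimates=estimates,
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.status > 0),
        n_g_samples=int(g.size),
    )


def confidence_interval(
    g_samples,
    velocity_ci: tuple[float, float],
    config: FitConfig | None = None,
    point_velocity: float | None = None,
) -> FitResult:
    """Parameter intervals propagated from the velocity confidence interval.

    Refits at both velocity endpoints; each free parameter's interval is
    the [min, max] envelope over the two endpoint fits and the point fit
    (at ``point_velocity``, default midpoint of the CI).  Endpoint fit
    failures degrade gracefully to a partial interval with a warning flag.
    """
    config = config or FitConfig()
    v_lo, v_hi = velocity_ci
    if not 0.0 < v_lo <= v_hi:
        raise InvalidParameterError("velocity CI must satisfy 0 < lo <= hi")
    v_point = 0.5 * (v_lo + v_hi) if point_velocity is None else point_velocity
    result = estimate(g_samples, v_point, config)
    fits = {v_point: result.estimates}
    warnings_list = []
    for v in (v_lo, v_hi):
        try:
            fits[v] = estimate(g_samples, v, config).estimates
        except (EstimationError, IncompatibleObservablesError) as exc:
            warnings_list.append(f"endpoint V={v}: {exc}")
    ci = {}
    for name in config.free:
        vals = [f[name] for f in fits.values()]
        ci[name] = (min(vals), max(vals))
    result.ci = ci
    result.ci_warnings = warnings_list
    # re-validate the bracket invariant now that ci is attached
    FitResult(result.estimates, result.residual_norm, result.converged,
              result.n_g_samples, ci=ci)
    return result
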