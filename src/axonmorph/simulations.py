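"""Numerical-simulation studies of the forward/inverse model.

Four studies, each exercising the inverse map over a grid or ensemble of
synthetic observables:

* :func:`compatibility_map` — which (g_MRI, V) combinations yield
  biologically plausible radius-distribution parameters (M, θ);
* :func:`parameter_maps` — the (θ, β) surfaces over the (g_MRI, V) plane
  with α and M held at reference values;
* :func:`noise_variability` — Monte-Carlo spread of the (θ, β) estimates
  under measurement noise (per-sample g noise sd 0.03, velocity noise sd
  0.50 m/s, 700 g samples and one velocity sample per repetition);
* :func:`group_average_bias` — bias incurred by substituting a cohort-mean
  velocity for each subject's own;
* :func:`constant_inaccuracy_bias` — bias on the estimated pair caused by
  a relative error in one of the fixed constants.

Per-repetition fits use the exact two-equation solve on the sample means:
with two free parameters and an attainable zero-residual point this is
the optimum of the stacked least-squares problem, at a fraction of the
cost.  Every stochastic operation draws from per-repetition substreams
derived deterministically from (seed, repetition index), so enlarging the
repetition count never reshuffles earlier repetitions.

Percent error is defined as sd(estimates)/true × 100; percent bias as
(estimate − reference)/reference × 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import FitConfig, solve_two_equations
from .exceptions import IncompatibleObservablesError, InvalidParameterError
from .model import _g_mri, _velocity

__all__ = [
    "GridSpec",
    "NoiseSpec",
    "CohortSpec",
    "CompatibilityMap",
    "ParameterMaps",
    "NoiseVariabilityResult",
    "GroupBiasResult",
    "ConstantBiasResult",
    "compatibility_map",
    "parameter_maps",
    "noise_variability",
    "group_average_bias",
    "constant_inaccuracy_bias",
    "PLAUSIBLE_MODE_RANGE",
    "PLAUSIBLE_THETA_RANGE",
]

# biologically plausible parameter windows used for the compatibility mask
PLAUSIBLE_MODE_RANGE = (0.05, 0.9)   # μm
PLAUSIBLE_THETA_RANGE = (0.01, 0.9)  # μm


@dataclass(frozen=True)
class GridSpec:
    """Rectangular (g_MRI, V) evaluation grid.

    The default 50×50 grid over g ∈ [0.55, 0.85] and V ∈ [5, 15] m/s
    contains both literature reference points and the plausibility band.
    Steps, when given, override the point counts.
    """

    g_range: tuple[float, float] = (0.55, 0.85)
    v_range: tuple[float, float] = (5.0, 15.0)
    n_g: int = 50
    n_v: int = 50
    g_step: float | None = None
    v_step: float | None = None

    def __post_init__(self) -> None:
        if not (self.g_range[0] < self.g_range[1] and self.v_range[0] < self.v_range[1]):
            raise InvalidParameterError("grid ranges must be non-empty")
        if (self.g_step is not None and self.g_step <= 0) or (
            self.v_step is not None and self.v_step <= 0
        ):
            raise InvalidParameterError("grid steps must be positive")
        if self.n_g < 2 or self.n_v < 2:
            raise InvalidParameterError("grids need at least 2 points per axis")

    @property
    def g_values(self) -> np.ndarray:
        if self.g_step is not None:
            return np.arange(self.g_range[0], self.g_range[1] + 1e-12, self.g_step)
        return np.linspace(*self.g_range, self.n_g)

    @property
    def v_values(self) -> np.ndarray:
        if self.v_step is not None:
            return np.arange(self.v_range[0], self.v_range[1] + 1e-12, self.v_step)
        return np.linspace(*self.v_range, self.n_v)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for the Monte-Carlo variability study."""

    sd_g: float = 0.03
    sd_v: float = 0.50   # m/s
    n_g: int = 700
    n_v: int = 1
    n_rep: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_g < 0 or self.sd_v < 0:
            raise InvalidParameterError("noise sds must be non-negative")
        if min(self.n_g, self.n_v, self.n_rep) < 1:
            raise InvalidParameterError("sample and repetition counts must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort of (g_MRI, V) observables for the group-velocity study."""

    n_subjects: int = 15
    mean_g: float = 0.70
    sd_g: float = 0.05
    mean_v: float = 10.0  # m/s
    sd_v: float = 0.80    # m/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        if self.sd_g < 0 or self.sd_v < 0:
            raise InvalidParameterError("cohort sds must be non-negative")


@dataclass
class CompatibilityMap:
    g_values: np.ndarray
    v_values: np.ndarray
    mode: np.ndarray      # shape (n_v, n_g); NaN where unsolvable
    theta: np.ndarray
    plausible: np.ndarray  # bool mask


@dataclass
class ParameterMaps:
    g_values: np.ndarray
    v_values: np.ndarray
    theta: np.ndarray
    beta: np.ndarray
    valid: np.ndarray


@dataclass
class NoiseVariabilityResult:
    theta_pct_sd: float
    beta_pct_sd: float
    theta_estimates: np.ndarray
    beta_estimates: np.ndarray
    n_redraws: int


@dataclass
class GroupBiasResult:
    theta_bias_pct: np.ndarray  # per subject, signed
    beta_bias_pct: np.ndarray
    n_redraws: int

    @property
    def mean_abs_theta_pct(self) -> float:
        return float(np.mean(np.abs(self.theta_bias_pct)))

    @property
    def mean_abs_beta_pct(self) -> float:
        return float(np.mean(np.abs(self.beta_bias_pct)))

    @property
    def max_abs_theta_pct(self) -> float:
        return float(np.max(np.abs(self.theta_bias_pct)))

    @property
    def max_abs_beta_pct(self) -> float:
        return float(np.max(np.abs(self.beta_bias_pct)))


@dataclass
class ConstantBiasResult:
    which: str
    rel_error: float
    free: tuple[str, str]
    mean_abs_bias_pct: dict
    bias_pct: dict           # per free parameter: 2-D signed arrays (NaN off-band)
    n_nodes: int
    n_failed: int


# ---------------------------------------------------------------------------


def compatibility_map(
    grid: GridSpec | None = None, alpha: float = 0.14, beta: float = 0.71
) -> CompatibilityMap:
    """Solve for (M, θ) at each (g, V) node and mask the plausible band.

    Nodes whose implied mode or tail scale falls outside the plausibility
    windows (0.05 < M < 0.9 μm, 0.01 < θ < 0.9 μm) are masked; nodes with
    no solution at all are NaN and masked.
    """
    grid = grid or GridSpec()
    config = FitConfig(free=("mode", "theta"), fixed={"alpha": alpha, "beta": beta})
    gs, vs = grid.g_values, grid.v_values
    mode = np.full((vs.size, gs.size), np.nan)
    theta = np.full_like(mode, np.nan)
    for i, v in enumerate(vs):
        for j, g in enumerate(gs):
            try:
                sol = solve_two_equations(g, v, config)
            except IncompatibleObservablesError:
                continue
            mode[i, j] = sol["mode"]
            theta[i, j] = sol["theta"]
    with np.errstate(invalid="ignore"):
        plausible = (
            (mode > PLAUSIBLE_MODE_RANGE[0])
            & (mode < PLAUSIBLE_MODE_RANGE[1])
            & (theta > PLAUSIBLE_THETA_RANGE[0])
            & (theta < PLAUSIBLE_THETA_RANGE[1])
        )
    return CompatibilityMap(gs, vs, mode, theta, plausible)


def parameter_maps(
    grid: GridSpec | None = None, alpha: float = 0.14, mode: float = 0.40
) -> ParameterMaps:
    """(θ, β) surfaces over the (g, V) grid with α and M fixed."""
    grid = grid or GridSpec()
    config = FitConfig(free=("theta", "beta"), fixed={"alpha": alpha, "mode": mode})
    gs, vs = grid.g_values, grid.v_values
    theta = np.full((vs.size, gs.size), np.nan)
    beta = np.full_like(theta, np.nan)
    for i, v in enumerate(vs):
        for j, g in enumerate(gs):
            try:
                sol = solve_two_equations(g, v, config)
            except IncompatibleObservablesError:
                continue
            theta[i, j] = sol["theta"]
            beta[i, j] = sol["beta"]
    return ParameterMaps(gs, vs, theta, beta, ~np.isnan(theta))


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    # independent, repetition-stable substream
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(rep,)))


_MAX_REDRAWS = 100


def noise_variability(
    theta: float,
    beta: float,
    alpha: float = 0.14,
    mode: float = 0.40,
    noise: NoiseSpec | None = None,
) -> NoiseVariabilityResult:
    """Monte-Carlo percent-sd of the (θ, β) estimates under noise.

    Per repetition, draws ``n_g`` Gaussian g samples and ``n_v`` Gaussian
    velocity samples around the forward-model values, averages them, and
    inverts for (θ, β).  Draws yielding an incompatible observable pair
    (or a g sample outside (0, 1)) are redrawn, not clipped, to preserve
    Gaussianity; redraw counts are reported.
    """
    noise = noise or NoiseSpec()
    g_true = float(_g_mri(mode, theta, alpha, beta))
    v_true = float(_velocity(mode, theta, alpha, beta))
    config = FitConfig(free=("theta", "beta"), fixed={"alpha": alpha, "mode": mode})
    th_hat = np.empty(noise.n_rep)
    b_hat = np.empty(noise.n_rep)
    redraws = 0
    for rep in range(noise.n_rep):
        rng = _rep_rng(noise.seed, rep)
        for _ in range(_MAX_REDRAWS):
            g = rng.normal(g_true, noise.sd_g, noise.n_g)
            v = rng.normal(v_true, noise.sd_v, noise.n_v)
            if np.any(g <= 0) or np.any(g >= 1) or np.mean(v) <= 0:
                redraws += 1
                continue
            try:
                sol = solve_two_equations(float(np.mean(g)), float(np.mean(v)), config)
            except IncompatibleObservablesError:
                redraws += 1
                continue
            th_hat[rep], b_hat[rep] = sol["theta"], sol["beta"]
            break
        else:  # pragma: no cover - would need pathological noise settings
            raise IncompatibleObservablesError(
                f"repetition {rep}: no compatible draw in {_MAX_REDRAWS} attempts"
            )
    ddof = 1 if noise.n_rep > 1 else 0
    return NoiseVariabilityResult(
        theta_pct_sd=float(np.std(th_hat, ddof=ddof) / theta * 100.0),
        beta_pct_sd=float(np.std(b_hat, ddof=ddof) / beta * 100.0),
        theta_estimates=th_hat,
        beta_estimates=b_hat,
        n_redraws=redraws,
    )


def group_average_bias(
    cohort: CohortSpec | None = None, alpha: float = 0.14, mode: float = 0.40
) -> GroupBiasResult:
    """Bias from substituting the cohort-mean velocity for subject velocities.

    Per subject, reference (θ, β) use the subject's own (g, V); comparison
    estimates use (g, mean V across the cohort).  Bias is the signed
    percent difference (comparison − reference)/reference × 100.
    """
    cohort = cohort or CohortSpec()
    config = FitConfig(free=("theta", "beta"), fixed={"alpha": alpha, "mode": mode})
    gs = np.empty(cohort.n_subjects)
    vs = np.empty(cohort.n_subjects)
    redraws = 0
    for s in range(cohort.n_subjects):
        rng = _rep_rng(cohort.seed, s)
        for _ in range(_MAX_REDRAWS):
            g = rng.normal(cohort.mean_g, cohort.sd_g)
            v = rng.normal(cohort.mean_v, cohort.sd_v)
            if not (0.0 < g < 1.0) or v <= 0:
                redraws += 1
                continue
            try:
                solve_two_equations(g, v, config)
            except IncompatibleObservablesError:
                redraws += 1
                continue
            gs[s], vs[s] = g, v
            break
        else:  # pragma: no cover
            raise IncompatibleObservablesError(f"subject {s}: no compatible draw")
    v_bar = float(np.mean(vs))
    th_bias = np.empty(cohort.n_subjects)
    b_bias = np.empty(cohort.n_subjects)
    for s in range(cohort.n_subjects):
        ref = solve_two_equations(gs[s], vs[s], config)
        cmp_ = solve_two_equations(gs[s], v_bar, config)
        th_bias[s] = (cmp_["theta"] - ref["theta"]) / ref["theta"] * 100.0
        b_bias[s] = (cmp_["beta"] - ref["beta"]) / ref["beta"] * 100.0
    return GroupBiasResult(th_bias, b_bias, redraws)


_FREE_FOR_PERTURBED = {
    # perturbed constant -> (free pair, other fixed constant)
    "alpha": (("mode", "theta"), "beta"),
    "mode": (("theta", "beta"), "alpha"),
    "beta": (("mode", "theta"), "alpha"),
}


def constant_inaccuracy_bias(
    which: str,
    rel_error: float,
    grid: GridSpec | None = None,
    constants: dict | None = None,
) -> ConstantBiasResult:
    """Average percent bias caused by a relative error in one fixed constant.

    ``which`` names the perturbed constant (``alpha``, ``mode`` or
    ``beta``); the free pair is the complementary one the study estimates
    (M and θ for an α or β inaccuracy; θ and β for an M inaccuracy).  The
    evaluation is restricted to the biologically plausible band of the
    compatibility map; over the band nodes where both the true-constant
    and perturbed-constant inversions succeed, reports the mean absolute
    percent bias of each free parameter.
    """
    if which not in _FREE_FOR_PERTURBED:
        raise InvalidParameterError(f"which must be one of {sorted(_FREE_FOR_PERTURBED)}")
    if not abs(rel_error) < 0.5:
        raise InvalidParameterError("rel_error must satisfy |rel_error| < 0.5")
    grid = grid or GridSpec()
    consts = {"alpha": 0.14, "mode": 0.40, "beta": 0.71}
    if constants:
        consts.update(constants)
    free, other = _FREE_FOR_PERTURBED[which]
    fixed_true = {which: consts[which], other: consts[other]}
    fixed_pert = {which: consts[which] * (1.0 + rel_error), other: consts[other]}
    cfg_true = FitConfig(free=free, fixed=fixed_true)
    cfg_pert = FitConfig(free=free, fixed=fixed_pert)
    band = compatibility_map(grid, alpha=consts["alpha"], beta=consts["beta"]).plausible
    gs, vs = grid.g_values, grid.v_values
    bias = {name: np.full((vs.size, gs.size), np.nan) for name in free}
    n_nodes = n_failed = 0
    for i, v in enumerate(vs):
        for j, g in enumerate(gs):
            if not band[i, j]:
                continue  # outside the plausible band
            try:
                ref = solve_two_equations(g, v, cfg_true)
            except IncompatibleObservablesError:
                continue
            n_nodes += 1
            try:
                pert = solve_two_equations(g, v, cfg_pert)
            except IncompatibleObservablesError:
                n_failed += 1
                continue
            for name in free:
                bias[name][i, j] = (pert[name] - ref[name]) / ref[name] * 100.0
    mean_abs = {
        name: float(np.nanmean(np.abs(arr))) if np.any(~np.isnan(arr)) else float("nan")
        for name, arr in bias.items()
    }
    return ConstantBiasResult(
        which=which,
        rel_error=rel_error,
        free=free,
        mean_abs_bias_pct=mean_abs,
        bias_pct=bias,
        n_nodes=n_nodes,
        n_failed=n_failed,
    )
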