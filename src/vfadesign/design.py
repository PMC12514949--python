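"""Flip-angle scheme optimization robust to transmit-field (B1) variation.

The design criterion is the B1-prior-marginalized, weighted L-optimality

    f(alpha) = sum_g p(B1S_g) * tr( W * I(theta, B1S_g * alpha)^-1 )
               + n * sigma^2 * lambda * sum_t sin(alpha_t)^2,

where the prior ``p`` is a discretized normal over the transmit scale, W is a
diagonal weight matrix on the kinetic parameters and the second term is a
weak shrinkage penalty that suppresses uninformative late pulses (it only
matters once the hyperpolarized magnetization is depleted).  Minimization is
bounded L-BFGS-B with batched finite-difference gradients and multistart
initialization; constant-angle (CFA) schemes are the one-dimensional special
case and are optimized without the penalty.

Because the FIM scales as 1/sigma^2 the criterion's argmin is independent of
the noise level; internally the optimizer works on the sigma-free objective
(criterion divided by sigma^2) so that convergence tolerances act on an O(1)
quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize as sciopt
from scipy import stats
from sklearn.base import BaseEstimator

from . import _engine
from .exceptions import (
    DomainError,
    OptimizationFailureError,
    SingularInformationError,
)
from .fisher import CONDITION_THRESHOLD, WeightSpec
from .kinetics import WITHOUT_B1S, FlipAngleScheme, KineticParameters, param_names

__all__ = [
    "B1Prior",
    "DesignConfig",
    "StartRecord",
    "DesignResult",
    "make_b1_prior",
    "regularization",
    "design_objective",
    "ernst_angle",
    "optimize_cfa",
    "optimize_vfa",
    "optimize_cfa_tr",
    "ConstantFlipAngleDesign",
    "VariableFlipAngleDesign",
    "ConstantFlipAngleTRDesign",
]


@dataclass(frozen=True)
class B1Prior:
    """Discrete prior over the transmit scale B1S.

    ``grid`` holds the support points (strictly increasing) and ``weights``
    the probability masses (summing to one).  A single-point prior reproduces
    the fixed-B1 design path exactly.
    """

    grid: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        grid = np.atleast_1d(np.asarray(self.grid, dtype=float))
        weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "weights", weights)
        if grid.shape != weights.shape or grid.ndim != 1:
            raise ValueError("grid and weights must be 1-D arrays of equal length")
        if grid.size > 1 and np.any(np.diff(grid) <= 0.0):
            raise DomainError("B1 grid must be strictly increasing")
        if np.any(grid <= 0.0):
            raise DomainError("B1 grid points must be positive")
        if np.any(weights < 0.0) or not np.isclose(weights.sum(), 1.0):
            raise DomainError("prior weights must be nonnegative and sum to 1")

    @classmethod
    def delta(cls, value: float = 1.0) -> "B1Prior":
        return cls(np.array([value]), np.array([1.0]))

    @property
    def n_points(self) -> int:
        return self.grid.size


def make_b1_prior(
    n_points: int = 11,
    interval: Tuple[float, float] = (0.5, 1.5),
    mean: float = 1.0,
    sd: float = 0.15,
) -> B1Prior:
    """Equidistant discretization of a normal B1S prior.

    Weights are proportional to the N(mean, sd) density at the grid points
    and normalized to unit mass.  ``n_points=1`` returns the delta prior at
    ``mean`` (the fixed-B1 objective used for the in-vitro designs).
    """
    if n_points < 1:
        raise DomainError("n_points must be >= 1")
    if not (sd > 0.0):
        raise DomainError("sd must be > 0")
    if n_points == 1:
        return B1Prior.delta(mean)
    lo, hi = interval
    if not (lo < hi):
        raise DomainError("interval must satisfy low < high")
    grid = np.linspace(lo, hi, n_points)
    dens = stats.norm.pdf(grid, loc=mean, scale=sd)
    return B1Prior(grid, dens / dens.sum())


@dataclass(frozen=True)
class DesignConfig:
    """Settings of the scheme optimization.

    Defaults follow the reference acquisition: TR = 2 s with 76 excitations
    (t = 0...150 s), design noise sd 5e-3, lambda = 0.1 and the L-BFGS-B
    settings tolerance 1e-9, max 10000 iterations, finite-difference step
    1e-4, max 100 line-search steps and max 100000 function evaluations.
    """

    tr: float = 2.0
    n_excitations: int = 76
    lam: float = 0.1
    sigma: float = 5e-3
    angle_bounds: Tuple[float, float] = (0.0, 90.0)
    first_angle_min: float = 0.1
    ftol: float = 1e-9
    gtol: float = 1e-8
    maxiter: int = 10_000
    fd_step: float = 1e-4
    maxls: int = 100
    maxfun: int = 100_000
    n_starts: int = 25
    init_range: Tuple[float, float] = (10.0, 80.0)
    seed: int = 0
    penalty_factor: float = 1e6
    cfa_inits: Tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)

    def __post_init__(self):
        if self.lam < 0.0:
            raise DomainError("lambda must be >= 0")
        lo, hi = self.angle_bounds
        if not (0.0 <= lo < hi <= 90.0):
            raise DomainError("angle bounds must lie within [0, 90] degrees")
        if self.n_starts < 1:
            raise DomainError("multistart count must be >= 1")


@dataclass(frozen=True)
class StartRecord:
    """Outcome of one multistart initialization."""

    index: int
    init_angles_deg: np.ndarray
    converged: bool
    objective: float
    objective_unregularized: float
    angles_deg: np.ndarray
    message: str = ""


@dataclass(frozen=True)
class DesignResult:
    """Optimized scheme with objective values and multistart provenance."""

    scheme: FlipAngleScheme
    objective: float
    objective_unregularized: float
    starts: Tuple[StartRecord, ...]
    best_within_1pct: int


def regularization(angles_deg: np.ndarray, lam: float, n: int, sigma: float) -> float:
    """Shrinkage penalty ``n sigma^2 lambda sum_t sin(alpha_t)^2``.

    ``n`` is the number of strictly positive parameter weights in the design.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    s = np.sin(np.deg2rad(np.asarray(angles_deg, dtype=float)))
    return float(n * sigma**2 * lam * np.sum(s * s))


def ernst_angle(tr: float, r1: float) -> float:
    """Ernst angle ``arccos(exp(-TR * R1))`` in degrees.

    The constant angle that maximizes steady-state signal efficiency for a
    metabolite relaxing at rate R1 sampled every TR seconds.
    """
    if not (tr > 0.0) or r1 < 0.0:
        raise DomainError("TR must be > 0 and R1 >= 0")
    return float(np.degrees(np.arccos(np.exp(-tr * r1))))


def _criterion_batch(
    angles_deg: np.ndarray,
    params: KineticParameters,
    weights: WeightSpec,
    prior: B1Prior,
    tr: float,
    *,
    lam: float,
    n_active: int,
    penalty: Optional[float],
) -> np.ndarray:
    """Sigma-free design criterion for a batch of angle vectors.

    Returns values of ``sum_g p_g tr(W I_1(g)^-1) + n lam sum sin^2`` where
    ``I_1`` is the unit-noise FIM; multiply by sigma^2 for the physical-scale
    objective.  Singular grid points contribute ``penalty`` (sigma-free) or
    raise when ``penalty`` is None.
    """
    A = np.atleast_2d(np.asarray(angles_deg, dtype=float))
    fims = _engine.fim_design_batch(params, np.deg2rad(A), prior.grid, tr)
    B, G = fims.shape[:2]
    w = weights.vector(param_names(WITHOUT_B1S))
    # symmetric PSD matrices: 2-norm condition from eigenvalues (cheaper than SVD)
    eigs = np.linalg.eigvalsh(fims)
    amax = np.abs(eigs).max(axis=-1)
    amin = np.abs(eigs).min(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(amin > 0.0, amax / amin, np.inf)
    ok = np.isfinite(cond) & (cond < CONDITION_THRESHOLD)
    vals = np.empty((B, G))
    safe = np.where(ok[..., None, None], fims, np.eye(5))
    inv = np.linalg.inv(safe)
    vals = np.einsum("i,bgii->bg", w, inv)
    if not ok.all():
        if penalty is None:
            raise SingularInformationError(
                "singular FIM at a B1 grid point (no penalty value in direct call)"
            )
        vals = np.where(ok, vals, penalty)
    obj = vals @ prior.weights
    if lam > 0.0:
        s = np.sin(np.deg2rad(A))
        obj = obj + n_active * lam * np.sum(s * s, axis=1)
    return obj


def design_objective(
    angles_deg: np.ndarray,
    params: KineticParameters,
    weights: WeightSpec,
    prior: B1Prior,
    config: DesignConfig,
    *,
    include_regularization: bool = True,
    penalty: Optional[float] = None,
) -> float:
    """Prior-marginalized, optionally regularized L-optimality of a scheme.

    Evaluated at the effective angles ``B1S_g * alpha`` for every prior grid
    point; a singular FIM raises unless a finite ``penalty`` (on the returned
    scale) is supplied, as done internally during optimization.
    """
    lam = config.lam if include_regularization else 0.0
    internal_penalty = None if penalty is None else penalty / config.sigma**2
    val = _criterion_batch(
        angles_deg,
        params,
        weights,
        prior,
        config.tr,
        lam=lam,
        n_active=max(weights.n_active, 1),
        penalty=internal_penalty,
    )[0]
    return float(val * config.sigma**2)


def _lbfgsb_options(config: DesignConfig) -> dict:
    return {
        "maxiter": config.maxiter,
        "maxfun": config.maxfun,
        "maxls": config.maxls,
        "ftol": config.ftol,
        "gtol": config.gtol,
    }


def _minimize_fd(fun_batch, x0, bounds, config: DesignConfig):
    """L-BFGS-B with batched forward-difference gradients (step in degrees)."""
    h = config.fd_step
    dim = x0.size

    def value_and_grad(x):
        pts = np.repeat(x[np.newaxis, :], dim + 1, axis=0)
        pts[1:] += h * np.eye(dim)
        vals = fun_batch(pts)
        return vals[0], (vals[1:] - vals[0]) / h

    return sciopt.minimize(
        value_and_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options=_lbfgsb_options(config),
    )


def _multistart(
    inits: Sequence[np.ndarray],
    expand,
    params: KineticParameters,
    weights: WeightSpec,
    prior: B1Prior,
    config: DesignConfig,
    *,
    lam: float,
) -> DesignResult:
    """Shared multistart driver for the CFA and VFA optimizations.

    ``expand`` maps optimizer variables to the full angle vector (identity
    for VFA, broadcast for the scalar CFA).  The singular-FIM penalty is set
    to ``penalty_factor`` times the best feasible initialization value so
    that line searches can back off from infeasible regions; starts that end
    at the penalty level or fail to converge are recorded as outliers.
    """
    n_active = max(weights.n_active, 1)

    def batch(xs):
        A = np.stack([expand(x) for x in np.atleast_2d(xs)])
        return _criterion_batch(
            A, params, weights, prior, config.tr,
            lam=lam, n_active=n_active, penalty=penalty[0],
        )

    # establish the penalty level from the feasible initializations
    penalty = [None]
    init_vals = []
    for x0 in inits:
        try:
            init_vals.append(batch(x0[np.newaxis, :])[0])
        except SingularInformationError:
            init_vals.append(np.inf)
    finite = [v for v in init_vals if np.isfinite(v)]
    if not finite:
        raise OptimizationFailureError("no feasible initialization (singular FIM)")
    penalty[0] = config.penalty_factor * min(finite)

    lo, hi = config.angle_bounds
    records: List[StartRecord] = []
    sigma2 = config.sigma**2
    for i, x0 in enumerate(inits):
        if x0.size == 1:
            bounds = [(config.first_angle_min, hi)]
        else:
            bounds = [(config.first_angle_min, hi)] + [(lo, hi)] * (x0.size - 1)
        res = _minimize_fd(batch, np.asarray(x0, float), bounds, config)
        angles = expand(res.x)
        feasible = res.fun < 0.5 * penalty[0]
        if feasible:
            # recompute both values from the converged angles through the
            # same single-row path so reg >= 0 holds exactly in the records
            unreg = _criterion_batch(
                angles[np.newaxis, :], params, weights, prior, config.tr,
                lam=0.0, n_active=n_active, penalty=penalty[0],
            )[0]
            reg = (
                regularization(angles, lam, n_active, 1.0) if lam > 0.0 else 0.0
            )
            final = unreg + reg
        else:
            unreg = final = np.inf
        records.append(
            StartRecord(
                index=i,
                init_angles_deg=expand(np.asarray(x0, float)),
                converged=bool(res.success and feasible),
                objective=float(final * sigma2),
                objective_unregularized=float(unreg * sigma2),
                angles_deg=angles,
                message=str(res.message),
            )
        )

    converged = [r for r in records if r.converged]
    if not converged:
        raise OptimizationFailureError("all multistart optimizations failed")
    best = min(converged, key=lambda r: (r.objective_unregularized, r.index))
    within = sum(
        1
        for r in converged
        if r.objective_unregularized <= 1.01 * best.objective_unregularized
    )
    return DesignResult(
        scheme=FlipAngleScheme(best.angles_deg, config.tr),
        objective=best.objective,
        objective_unregularized=best.objective_unregularized,
        starts=tuple(records),
        best_within_1pct=within,
    )


def optimize_cfa(
    params: KineticParameters,
    weights: WeightSpec,
    prior: B1Prior,
    config: Optional[DesignConfig] = None,
) -> DesignResult:
    """Optimize a single constant flip angle (no regularization).

    Bounded 1-D quasi-Newton from the initialization grid 10..80 degrees;
    the best converged start is reported.
    """
    config = config or DesignConfig()
    T = config.n_excitations

    def expand(x):
        return np.full(T, float(np.atleast_1d(x)[0]))

    inits = [np.array([a]) for a in config.cfa_inits]
    return _multistart(inits, expand, params, weights, prior, config, lam=0.0)


def optimize_vfa(
    params: KineticParameters,
    weights: WeightSpec,
    prior: B1Prior,
    config: Optional[DesignConfig] = None,
) -> DesignResult:
    """Jointly optimize all flip angles with the shrinkage penalty active.

    ``config.n_starts`` random initializations, each drawn uniformly over
    ``config.init_range`` with the per-start seed ``config.seed + index``;
    reported objectives are also recomputed without regularization and the
    best start is selected on that unregularized value.
    """
    config = config or DesignConfig()
    T = config.n_excitations
    inits = [
        np.random.default_rng(config.seed + i).uniform(*config.init_range, size=T)
        for i in range(config.n_starts)
    ]
    return _multistart(inits, lambda x: np.asarray(x, float), params, weights, prior, config, lam=config.lam)


def optimize_cfa_tr(
    params: KineticParameters,
    weights: WeightSpec,
    prior: B1Prior,
    window: float = 150.0,
    config: Optional[DesignConfig] = None,
    *,
    tr_bounds: Tuple[float, float] = (0.5, 50.0),
) -> Tuple[float, float, float]:
    """Jointly optimize repetition time and constant angle in a fixed window.

    For each TR the scheme has ``floor(window / TR) + 1`` excitations filling
    the acquisition window; the constant angle is optimized per TR (coarse
    1 s sweep then 0.1 s refinement around the incumbent) and the best
    (TR, angle) pair is returned with its unregularized objective.
    """
    if not (window > 0.0):
        raise DomainError("window must be > 0")
    config = config or DesignConfig()
    n_active = max(weights.n_active, 1)
    sigma2 = config.sigma**2

    def best_angle_for(tr: float):
        T = int(np.floor(window / tr)) + 1

        def scalar(angle):
            A = np.full((1, T), float(angle))
            try:
                return _criterion_batch(
                    A, params, weights, prior, tr,
                    lam=0.0, n_active=n_active, penalty=None,
                )[0]
            except SingularInformationError:
                return np.inf

        res = sciopt.minimize_scalar(
            scalar,
            bounds=(config.first_angle_min, config.angle_bounds[1]),
            method="bounded",
            options={"xatol": 1e-3},
        )
        return float(res.x), float(res.fun)

    lo, hi = tr_bounds
    coarse = np.arange(lo, hi + 1e-9, 0.5) if hi > lo else np.array([lo])
    evals = {float(tr): best_angle_for(tr) for tr in coarse}
    best_tr = min(evals, key=lambda tr: evals[tr][1])
    if hi > lo:
        fine = np.arange(max(lo, best_tr - 0.5), min(hi, best_tr + 0.5) + 1e-9, 0.05)
        for tr in fine:
            tr = float(round(tr, 10))
            if tr not in evals:
                evals[tr] = best_angle_for(tr)
        best_tr = min(evals, key=lambda tr: evals[tr][1])
    angle, val = evals[best_tr]
    if not np.isfinite(val):
        raise OptimizationFailureError("CFA-TR optimization found no feasible scheme")
    return best_tr, angle, float(val * sigma2)


class _DesignerBase(BaseEstimator):
    """Shared plumbing of the scheme-design estimators."""

    def __init__(self, params=None, weights=None, prior=None, config=None):
        self.params = params
        self.weights = weights
        self.prior = prior
        self.config = config

    def _resolved(self):
        if self.params is None or self.weights is None:
            raise ValueError("params and weights must be set before fit()")
        prior = self.prior if self.prior is not None else make_b1_prior()
        config = self.config if self.config is not None else DesignConfig()
        return self.params, self.weights, prior, config


class ConstantFlipAngleDesign(_DesignerBase):
    """Estimator wrapper: optimized constant-flip-angle scheme.

    After ``fit()`` exposes ``angle_`` (degrees), ``scheme_``, ``objective_``
    and the full multistart ``result_``.
    """

    def fit(self, X=None, y=None):
        params, weights, prior, config = self._resolved()
        self.result_ = optimize_cfa(params, weights, prior, config)
        self.scheme_ = self.result_.scheme
        self.angle_ = float(self.scheme_.angles_deg[0])
        self.objective_ = self.result_.objective
        self.objective_unregularized_ = self.result_.objective_unregularized
        return self


class VariableFlipAngleDesign(_DesignerBase):
    """Estimator wrapper: optimized variable-flip-angle scheme."""

    def fit(self, X=None, y=None):
        params, weights, prior, config = self._resolved()
        self.result_ = optimize_vfa(params, weights, prior, config)
        self.scheme_ = self.result_.scheme
        self.objective_ = self.result_.objective
        self.objective_unregularized_ = self.result_.objective_unregularized
        return self


class ConstantFlipAngleTRDesign(_DesignerBase):
    """Estimator wrapper: CFA jointly optimized over TR and angle."""

    def __init__(self, params=None, weights=None, prior=None, config=None,
                 window=150.0, tr_bounds=(0.5, 50.0)):
        super().__init__(params=params, weights=weights, prior=prior, config=config)
        self.window = window
        self.tr_bounds = tr_bounds

    def fit(self, X=None, y=None):
        params, weights, prior, config = self._resolved()
        tr, angle, obj = optimize_cfa_tr(
            params, weights, prior, self.window, config, tr_bounds=self.tr_bounds
        )
        self.tr_ = tr
        self.angle_ = angle
        self.objective_ = obj
        n = int(np.floor(self.window / tr)) + 1
        self.scheme_ = FlipAngleScheme.constant(angle, n, tr)
        return self
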