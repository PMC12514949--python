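"""Fisher information, Cramér–Rao bounds and the L-optimality criterion.

For the Gaussian-noise signal model the Fisher information matrix (FIM) is

    I_ij = sum_t sum_m (1 / sigma_m^2) * dy[m,t]/dtheta_i * dy[m,t]/dtheta_j,

whose inverse lower-bounds the covariance of any unbiased estimator
(Cramér–Rao).  The design criterion used throughout the package is
L-optimality, ``tr(W I^-1)`` with a diagonal weight matrix W; with weights
``1/theta_i^2`` each term is a squared relative uncertainty, so the criterion
is invariant under the TR/signal non-dimensionalization and can be computed
in physical units.

Sensitivities are analytic (forward tangent recursion, see ``_engine``); the
test suite holds them against central finite differences, which is the
primary oracle for everything downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from . import _engine
from .exceptions import DomainError, SingularInformationError
from .kinetics import (
    WITH_B1S,
    WITHOUT_B1S,
    FlipAngleScheme,
    KineticParameters,
    param_names,
)

__all__ = [
    "WeightSpec",
    "FIMResult",
    "SensitivitySet",
    "ParameterScales",
    "transition_matrix_grad",
    "sensitivities",
    "fim",
    "fim_from_sensitivities",
    "crlb",
    "l_optimality",
    "nondimensionalize",
]

#: FIMs with a condition number above this are reported as non-invertible.
CONDITION_THRESHOLD = 1e12


@dataclass(frozen=True)
class WeightSpec:
    """Nonnegative scalar weight per parameter name.

    ``n_active`` (the number of strictly positive weights) enters the
    regularization scaling of the design objective.
    """

    weights: Mapping[str, float]

    def __post_init__(self):
        clean = {}
        for name, w in dict(self.weights).items():
            if name not in param_names(WITH_B1S):
                raise ValueError(f"unknown parameter name {name!r}")
            if w < 0.0:
                raise DomainError(f"weight for {name} must be >= 0, got {w}")
            clean[name] = float(w)
        object.__setattr__(self, "weights", clean)

    @classmethod
    def relative(cls, params: KineticParameters, *names: str) -> "WeightSpec":
        """Weights ``1/theta^2`` on the named parameters (zero elsewhere).

        This is the weighting used for the k/R1S/R1P-targeted designs: each
        weighted term of tr(W I^-1) becomes a squared relative uncertainty.
        """
        return cls({n: 1.0 / getattr(params, n) ** 2 for n in names})

    @property
    def n_active(self) -> int:
        return sum(1 for w in self.weights.values() if w > 0.0)

    def vector(self, order: Tuple[str, ...]) -> np.ndarray:
        return np.array([self.weights.get(n, 0.0) for n in order])

    def requires_b1s(self) -> bool:
        return self.weights.get("B1S", 0.0) > 0.0


@dataclass(frozen=True)
class FIMResult:
    """Fisher information matrix with its parameter ordering and health flags."""

    matrix: np.ndarray
    order: Tuple[str, ...]
    condition: float
    invertible: bool
    sigma: float


@dataclass(frozen=True)
class SensitivitySet:
    """Per-parameter signal and state sensitivities (each ``(2, T)``)."""

    dy: np.ndarray
    dx: np.ndarray
    order: Tuple[str, ...]
    normalization: float


def transition_matrix_grad(params: KineticParameters, tr: float) -> Dict[str, np.ndarray]:
    """Closed-form partials of the propagator G w.r.t. every parameter.

    Only the rates move G; ``dG/dS0 = dG/dP0 = dG/dB1S = 0``.  The
    off-diagonal derivatives share the cancellation-safe ``phi`` evaluation
    with the propagator itself, so they stay accurate through the
    ``R1P == k + R1S`` degeneracy.
    """
    if not (tr > 0.0):
        raise DomainError(f"TR must be > 0, got {tr}")
    _, dg = _engine.g_and_grads(params.k, params.R1S, params.R1P, tr)
    zero = np.zeros((2, 2))
    return {
        "k": dg[0],
        "R1S": dg[1],
        "R1P": dg[2],
        "S0": zero.copy(),
        "P0": zero.copy(),
        "B1S": zero.copy(),
    }


def sensitivities(
    params: KineticParameters,
    scheme: FlipAngleScheme,
    variant: str = WITHOUT_B1S,
    *,
    normalization: str = "none",
    differentiate_normalization: bool = False,
) -> SensitivitySet:
    """Analytic sensitivities dy/dtheta (and dx/dtheta) under ``scheme``.

    Parameters
    ----------
    normalization : {"none", "s0-sin-alpha0"}
        ``"s0-sin-alpha0"`` divides all sensitivities (and states) by the
        first-point calibration factor ``S0 sin(B1S alpha_0)``, matching a
        dataset normalized the same way.
    differentiate_normalization : bool
        By default the factor is treated as a fixed calibration constant.
        When True, the S0 (and, with B1S, the B1S) derivative additionally
        differentiates through the factor; this makes the normalized model
        genuinely scale-free in S0.
    """
    order = param_names(variant)
    x, y, dx, dy = _engine.propagate_sens(params, scheme.angles_rad, scheme.tr, variant)
    c = 1.0
    if normalization == "s0-sin-alpha0":
        eff0 = params.B1S * scheme.angles_rad[0]
        c = params.S0 * np.sin(eff0)
        if c == 0.0:
            raise DomainError("normalization factor S0*sin(alpha0) is zero")
        dx = dx / c
        dy = dy / c
        if differentiate_normalization:
            # d(y/c)/dth = dy/c - y * (dc/dth) / c^2
            yn = y / c
            dy[_engine.IDX["S0"]] -= yn * (np.sin(eff0) / c)
            if variant == WITH_B1S:
                dcdb1 = params.S0 * scheme.angles_rad[0] * np.cos(eff0)
                dy[_engine.IDX["B1S"]] -= yn * (dcdb1 / c)
    elif normalization != "none":
        raise ValueError(f"unknown normalization mode {normalization!r}")
    return SensitivitySet(dy=dy, dx=dx, order=order, normalization=float(c))


def fim_from_sensitivities(sens: SensitivitySet, sigma: float) -> FIMResult:
    """Assemble the FIM from a sensitivity set at noise sd ``sigma``.

    ``sigma`` must live on the same scale as the sensitivities (the factor
    cancels, so raw sensitivities with raw sigma and normalized sensitivities
    with normalized sigma give the identical matrix).
    """
    if not (sigma > 0.0):
        raise DomainError(f"sigma must be > 0, got {sigma}")
    p = sens.dy.shape[0]
    flat = sens.dy.reshape(p, -1)
    mat = (flat @ flat.T) / sigma**2
    mat = 0.5 * (mat + mat.T)  # enforce exact symmetry
    if np.all(mat == 0.0):
        cond = np.inf
    else:
        cond = float(np.linalg.cond(mat))
    return FIMResult(
        matrix=mat,
        order=sens.order,
        condition=cond,
        invertible=bool(np.isfinite(cond) and cond < CONDITION_THRESHOLD),
        sigma=float(sigma),
    )


def fim(
    params: KineticParameters,
    scheme: FlipAngleScheme,
    sigma: float,
    variant: str = WITHOUT_B1S,
) -> FIMResult:
    """Fisher information of the signal model under ``scheme``.

    Computed on the raw signal scale; by the cancellation noted in the module
    docstring this equals the matrix assembled from first-point-normalized
    sensitivities and the correspondingly normalized sigma.
    """
    return fim_from_sensitivities(sensitivities(params, scheme, variant), sigma)


def crlb(fimres: FIMResult) -> np.ndarray:
    """Cramér–Rao covariance lower bound, ``I^-1``.

    Raises
    ------
    SingularInformationError
        If the FIM condition number exceeds the invertibility threshold.
    """
    if not fimres.invertible:
        raise SingularInformationError(
            f"FIM is singular or ill-conditioned (cond={fimres.condition:.3g})"
        )
    return np.linalg.inv(fimres.matrix)


def l_optimality(fimres: FIMResult, weights: WeightSpec) -> float:
    """L-optimality criterion ``tr(W I^-1)`` for diagonal weights W.

    Returns 0 for an all-zero weight vector without touching the inverse.
    """
    w = weights.vector(fimres.order)
    if not np.any(w):
        return 0.0
    cov = crlb(fimres)
    return float(np.sum(w * np.diag(cov)))


@dataclass(frozen=True)
class ParameterScales:
    """Invertible record of the non-dimensionalization applied to theta.

    ``scaled = physical * factors`` elementwise; rates carry a factor of TR
    (making them dimensionless decay-per-sample quantities) and the
    magnetizations are divided by the t = 0 substrate signal scale.
    """

    factors: np.ndarray
    order: Tuple[str, ...]

    def to_scaled(self, theta_physical: np.ndarray) -> np.ndarray:
        return np.asarray(theta_physical, float) * self.factors

    def to_physical(self, theta_scaled: np.ndarray) -> np.ndarray:
        return np.asarray(theta_scaled, float) / self.factors


def nondimensionalize(
    params: KineticParameters,
    tr: float,
    variant: str = WITHOUT_B1S,
    *,
    signal_scale: Optional[float] = None,
) -> Tuple[np.ndarray, ParameterScales]:
    """Scale theta to dimensionless form (rates by TR, magnetizations by S0).

    The natural time unit of the sampled experiment is TR and the natural
    signal unit is the first substrate measurement; ``signal_scale`` overrides
    the default magnetization unit (``params.S0``) when the caller knows the
    measured t = 0 signal.  Returns the scaled vector and an invertible
    ``ParameterScales`` record so estimates can be reported in physical units.
    """
    if not (tr > 0.0):
        raise DomainError(f"TR must be > 0, got {tr}")
    order = param_names(variant)
    mag = float(signal_scale) if signal_scale is not None else params.S0
    if not (mag > 0.0):
        raise DomainError("signal scale must be > 0")
    per_name = {"k": tr, "R1S": tr, "R1P": tr, "S0": 1.0 / mag, "P0": 1.0 / mag, "B1S": 1.0}
    factors = np.array([per_name[n] for n in order])
    scales = ParameterScales(factors=factors, order=order)
    return scales.to_scaled(params.as_array(variant)), scales
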