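"""Forward model for hyperpolarized two-metabolite kinetics.

A hyperpolarized substrate S converts unidirectionally into a product P with
apparent first-order rate ``k`` while both pools relax longitudinally with
rates ``R1S`` and ``R1P``.  Between excitations the longitudinal magnetization
``x = (S, P)`` evolves as ``dx/dt = A x`` with

    A = [[-(k + R1S), 0],
         [      k,  -R1P]],

and each RF excitation with flip angle ``alpha`` converts ``sin(alpha) * x``
into measurable transverse signal, leaving ``cos(alpha) * x`` behind.  A
dimensionless transmit-scale ``B1S`` multiplies every prescribed flip angle to
model RF miscalibration/inhomogeneity.

This module provides the discrete-time propagator (matrix exponential in
closed form), the deterministic signal simulation, Gaussian noise injection
and the normalization conventions used before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .exceptions import DegenerateNormalizationError, DomainError

__all__ = [
    "WITH_B1S",
    "WITHOUT_B1S",
    "PARAM_NAMES",
    "KineticParameters",
    "FlipAngleScheme",
    "Trajectory",
    "Dataset",
    "transition_matrix",
    "simulate",
    "add_noise",
    "normalize",
    "param_names",
]

WITH_B1S = "with-b1s"
WITHOUT_B1S = "without-b1s"

#: Canonical parameter ordering used everywhere in the package.
PARAM_NAMES = ("k", "R1S", "R1P", "S0", "P0", "B1S")

#: Rates closer than this (in 1/s) to the eigenvalue-degeneracy
#: ``R1P == k + R1S`` switch the off-diagonal propagator entry to its
#: series limit to avoid 0/0.
DEGENERACY_TOL = 1e-8


def param_names(variant: str = WITHOUT_B1S) -> tuple:
    """Parameter names for a model variant, in canonical order."""
    if variant == WITH_B1S:
        return PARAM_NAMES
    if variant == WITHOUT_B1S:
        return PARAM_NAMES[:5]
    raise ValueError(f"unknown model variant: {variant!r}")


@dataclass(frozen=True)
class KineticParameters:
    """Kinetic model parameter vector.

    Parameters
    ----------
    k : float
        Substrate-to-product conversion rate, 1/s.
    R1S, R1P : float
        Longitudinal relaxation rates of substrate and product, 1/s.
    S0, P0 : float
        Initial longitudinal magnetizations (arbitrary units).
    B1S : float, default 1.0
        Dimensionless scale between prescribed and delivered flip angles.
        Only a free parameter in the ``"with-b1s"`` model variant.
    """

    k: float
    R1S: float
    R1P: float
    S0: float
    P0: float
    B1S: float = 1.0

    def __post_init__(self):
        if not (self.k >= 0.0):
            raise DomainError(f"k must be >= 0, got {self.k}")
        if not (self.R1S > 0.0):
            raise DomainError(f"R1S must be > 0, got {self.R1S}")
        if not (self.R1P > 0.0):
            raise DomainError(f"R1P must be > 0, got {self.R1P}")
        if not (self.S0 > 0.0):
            raise DomainError(f"S0 must be > 0, got {self.S0}")
        if not (self.P0 >= 0.0):
            raise DomainError(f"P0 must be >= 0, got {self.P0}")
        if not (self.B1S > 0.0):
            raise DomainError(f"B1S must be > 0, got {self.B1S}")

    def as_array(self, variant: str = WITHOUT_B1S) -> np.ndarray:
        """Parameter values as a vector in canonical order."""
        vals = [getattr(self, n) for n in param_names(variant)]
        return np.asarray(vals, dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray, variant: str = WITHOUT_B1S) -> "KineticParameters":
        names = param_names(variant)
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(names),):
            raise ValueError(f"expected shape ({len(names)},), got {theta.shape}")
        return cls(**dict(zip(names, theta)))

    def replace(self, **kwargs) -> "KineticParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FlipAngleScheme:
    """A prescribed flip-angle schedule on a uniform TR grid.

    ``angles_deg[t]`` is applied at time ``t * tr`` seconds; all angles are in
    degrees at the interface (radians are used internally).
    """

    angles_deg: np.ndarray
    tr: float

    def __post_init__(self):
        angles = np.atleast_1d(np.asarray(self.angles_deg, dtype=float))
        object.__setattr__(self, "angles_deg", angles)
        angles.setflags(write=False)
        if angles.ndim != 1 or angles.size < 1:
            raise DomainError("a scheme needs at least one flip angle")
        if np.any(angles < 0.0) or np.any(angles > 90.0):
            raise DomainError("flip angles must lie in [0, 90] degrees")
        if not (self.tr > 0.0):
            raise DomainError(f"TR must be > 0, got {self.tr}")

    @classmethod
    def constant(cls, angle_deg: float, n_excitations: int, tr: float) -> "FlipAngleScheme":
        """A constant flip angle (CFA) scheme with ``n_excitations`` pulses."""
        return cls(np.full(int(n_excitations), float(angle_deg)), tr)

    @property
    def n_excitations(self) -> int:
        return self.angles_deg.size

    @property
    def times(self) -> np.ndarray:
        """Sampling instants 0, TR, 2 TR, ... in seconds."""
        return np.arange(self.n_excitations) * self.tr

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(self.angles_deg)

    @property
    def is_constant(self) -> bool:
        return bool(np.ptp(self.angles_deg) == 0.0)


@dataclass(frozen=True)
class Trajectory:
    """Noiseless magnetization/signal trajectory.

    ``x[m, t]`` is the longitudinal magnetization of metabolite ``m``
    (0 = substrate, 1 = product) immediately before the excitation at index
    ``t``; ``y[m, t]`` is the transverse signal right after it.  If
    ``normalization != 1`` both arrays have already been divided by it.
    """

    x: np.ndarray
    y: np.ndarray
    scheme: FlipAngleScheme
    params: KineticParameters
    normalization: float = 1.0


@dataclass(frozen=True)
class Dataset:
    """Observed (possibly noisy) signals ready for fitting.

    ``signals`` and ``sigma`` are on the scale obtained after dividing the raw
    signal by ``normalization``.  ``included[t]`` marks time points that enter
    the fit; points with a prescribed flip angle of exactly 0 degrees carry no
    signal and are excluded.
    """

    signals: np.ndarray
    sigma: float
    normalization: float
    included: np.ndarray
    scheme: Optional[FlipAngleScheme] = None

    def __post_init__(self):
        if not (self.sigma > 0.0):
            raise DomainError(f"sigma must be > 0, got {self.sigma}")


def _phi(delta: float, tr: float) -> float:
    """(1 - exp(-delta*TR)) / delta, evaluated without cancellation."""
    if abs(delta) < DEGENERACY_TOL:
        return tr * (1.0 - 0.5 * delta * tr)
    return -np.expm1(-delta * tr) / delta


def transition_matrix(params: KineticParameters, tr: float) -> np.ndarray:
    """Closed-form one-TR propagator ``G = expm(TR * A)``.

    With ``a = k + R1S`` and ``d = R1P - a``::

        G11 = exp(-a TR),  G22 = exp(-R1P TR),
        G21 = k (G11 - G22) / d   ->   k TR G11 as d -> 0.

    The off-diagonal entry is evaluated through ``expm1`` so it stays accurate
    arbitrarily close to the degeneracy ``R1P == k + R1S``.
    """
    if not (tr > 0.0):
        raise DomainError(f"TR must be > 0, got {tr}")
    a = params.k + params.R1S
    g11 = np.exp(-a * tr)
    g22 = np.exp(-params.R1P * tr)
    delta = params.R1P - a
    # k * (g11 - g22)/delta == k * g11 * (1 - exp(-delta*TR))/delta
    g21 = params.k * g11 * _phi(delta, tr)
    return np.array([[g11, 0.0], [g21, g22]])


def simulate(params: KineticParameters, scheme: FlipAngleScheme) -> Trajectory:
    """Simulate the noiseless hybrid dynamical system under ``scheme``.

    Starting from ``x0 = (S0, P0)``, every step emits
    ``y_t = sin(B1S * alpha_t) * x_t`` and propagates the post-pulse state
    ``cos(B1S * alpha_t) * x_t`` through the transition matrix.
    """
    g = transition_matrix(params, scheme.tr)
    eff = params.B1S * scheme.angles_rad
    sin_a, cos_a = np.sin(eff), np.cos(eff)
    n = scheme.n_excitations
    x = np.empty((2, n))
    x[:, 0] = (params.S0, params.P0)
    for t in range(n - 1):
        x[:, t + 1] = g @ (cos_a[t] * x[:, t])
    y = sin_a[np.newaxis, :] * x
    return Trajectory(x=x, y=y, scheme=scheme, params=params)


def add_noise(
    traj: Trajectory,
    sigma: float,
    seed: Optional[int] = None,
    *,
    noise: Optional[np.ndarray] = None,
    on: str = "current",
) -> Dataset:
    """Add i.i.d. zero-mean Gaussian noise to every signal value.

    Parameters
    ----------
    traj : Trajectory
        Noiseless trajectory (raw or already normalized).
    sigma : float
        Noise standard deviation, interpreted on the scale selected by ``on``.
    seed : int, optional
        Seed for the noise generator; ignored when ``noise`` is given.
    noise : ndarray of shape (2, n_excitations), optional
        A pre-drawn standard-normal matrix, enabling common-random-number
        reuse of the identical realization across schemes of equal length.
    on : {"current", "raw"}
        ``"current"``: sigma refers to the scale ``traj.y`` is on.
        ``"raw"``: sigma refers to the unnormalized signal scale and is
        divided by ``traj.normalization`` before being applied.

    Returns
    -------
    Dataset
        Signals with noise, the effective (current-scale) sigma, and an
        inclusion mask that drops 0-degree excitations.
    """
    if not (sigma > 0.0):
        raise DomainError(f"sigma must be > 0, got {sigma}")
    if on not in ("current", "raw"):
        raise ValueError(f"unknown noise scale {on!r}")
    sd = sigma / traj.normalization if on == "raw" else sigma
    if noise is None:
        noise = np.random.default_rng(seed).standard_normal(traj.y.shape)
    elif noise.shape != traj.y.shape:
        raise ValueError(f"noise shape {noise.shape} != signal shape {traj.y.shape}")
    signals = traj.y + sd * noise
    included = traj.scheme.angles_deg > 0.0
    return Dataset(
        signals=signals,
        sigma=sd,
        normalization=traj.normalization,
        included=included,
        scheme=traj.scheme,
    )


def _normalization_factor(obj: Union[Trajectory, Dataset], mode: str) -> float:
    scheme = obj.scheme
    if scheme is None:
        raise ValueError("cannot normalize a Dataset without an attached scheme")
    if scheme.angles_deg[0] <= 0.0:
        raise DegenerateNormalizationError(
            "normalization requires a non-zero first flip angle"
        )
    if mode == "first-substrate-point":
        sig = obj.y if isinstance(obj, Trajectory) else obj.signals
        return float(sig[0, 0])
    if mode == "s0-sin-alpha0":
        if isinstance(obj, Trajectory):
            params = obj.params
        else:
            raise ValueError("mode 's0-sin-alpha0' needs a Trajectory (has parameters)")
        eff0 = params.B1S * np.deg2rad(scheme.angles_deg[0])
        return float(params.S0 * np.sin(eff0) / obj.normalization)
    raise ValueError(f"unknown normalization mode {mode!r}")


def normalize(obj: Union[Trajectory, Dataset], mode: str = "first-substrate-point"):
    """Divide all signals (and sigma) by a normalization factor.

    Two conventions are supported and coincide on noiseless data:

    - ``"first-substrate-point"``: divide by the measured substrate signal at
      t = 0, the convention used for experimental data.
    - ``"s0-sin-alpha0"``: divide by the model value
      ``S0 * sin(B1S * alpha_0)`` (trajectories only).

    The applied factor accumulates in the ``normalization`` field so raw-scale
    quantities can always be recovered.
    """
    c = _normalization_factor(obj, mode)
    if c == 0.0:
        raise DegenerateNormalizationError("normalization factor is zero")
    if isinstance(obj, Trajectory):
        return replace(
            obj, x=obj.x / c, y=obj.y / c, normalization=obj.normalization * c
        )
    return replace(
        obj,
        signals=obj.signals / c,
        sigma=obj.sigma / c,
        normalization=obj.normalization * c,
    )
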