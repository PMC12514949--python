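"""Shared fixtures: nominal parameters, schemes, and the optimized-design suite.

The expensive session fixtures (multistart scheme optimization, n=1000 Monte
Carlo runs) are shared between the acceptance tests and the property tests
so the whole suite performs each of them once.
"""

import numpy as np
import pytest
from hypothesis import settings

from vfadesign import (
    DesignConfig,
    FlipAngleScheme,
    KineticParameters,
    WeightSpec,
    make_b1_prior,
    optimize_cfa,
    optimize_vfa,
)
from vfadesign.experiments import mc_distribution

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

#: noise sd (raw signal scale) used throughout the Monte Carlo studies
SIGMA = 5e-3
MC_REPS = 1000
MC_SEED = 7
DESIGN_SEED = 1


@pytest.fixture(scope="session")
def nominal():
    """Nominal kinetic parameters of the carboxyl-esterase conversion system."""
    return KineticParameters(k=0.0135, R1S=1 / 35, R1P=1 / 54, S0=5.0, P0=0.1)


@pytest.fixture(scope="session")
def prior():
    """11-point equidistant N(1, 0.15) prior on [0.5, 1.5]."""
    return make_b1_prior()


@pytest.fixture(scope="session")
def sparse_vfa_scheme():
    """A hand-built sparse VFA-like scheme (identifiable for all variants)."""
    angles = np.zeros(76)
    angles[0] = 32.0
    angles[[11, 12, 13]] = (29.0, 36.0, 31.0)
    angles[62] = 87.0
    angles[68] = 58.0
    return FlipAngleScheme(angles, 2.0)


@pytest.fixture(scope="session")
def design_suite(nominal, prior):
    """Optimized CFA and VFA schemes (full 25-start protocol, seeded)."""
    cfg = DesignConfig(n_starts=25, seed=DESIGN_SEED)
    wk = WeightSpec.relative(nominal, "k")
    results = {"CFA-k": optimize_cfa(nominal, wk, prior, cfg)}
    for name, targets in [
        ("VFA-k", ("k",)),
        ("VFA-R1S", ("R1S",)),
        ("VFA-R1P", ("R1P",)),
        ("VFA-all", ("k", "R1S", "R1P")),
    ]:
        w = WeightSpec.relative(nominal, *targets)
        results[name] = optimize_vfa(nominal, w, prior, cfg)
    return {
        "results": results,
        "schemes": {k: r.scheme for k, r in results.items()},
        "config": cfg,
        "weights_k": wk,
    }


@pytest.fixture(scope="session")
def mc_suite(design_suite, nominal):
    """n=1000 parameter-recovery runs for every optimized scheme (shared noise)."""
    return {
        sid: mc_distribution(
            scheme, nominal, SIGMA, MC_REPS, seed=MC_SEED, scheme_id=sid
        )
        for sid, scheme in design_suite["schemes"].items()
    }
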