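"""Virtual-population generation (nonlinear mixed-effects individual model).

Each virtual dog is obtained by drawing one independent normal random effect
``eta ~ N(0, omega^2)`` per parameter with inter-individual variability and
passing it through the parameter's link function:

* log-normal:   ``phi = mu * exp(eta)`` (strictly positive parameters),
* logit-normal: ``logit(phi) = logit(mu) + eta`` (parameters bounded in (0,1)),
* none:         ``phi = mu`` (no random effect).

There are no covariate effects; the random-effect covariance is diagonal.
The clock time of peak angiotensin I production (``PRA``) is drawn
log-normally and wrapped modulo 24 so it stays a valid clock time.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .parameters import ConfigurationError, FixedEffects, IIVSpec

__all__ = ["IndividualParameters", "apply_link", "sample_individuals"]


@dataclasses.dataclass(frozen=True)
class IndividualParameters:
    """One virtual dog: realized parameters plus the eta draws that made them."""

    individual_id: int
    fe: FixedEffects
    eta: dict[str, float]


def apply_link(mu: float, eta: float, link: str) -> float:
    """Realize an individual parameter from its typical value and eta draw."""
    if link == "lognormal":
        if mu <= 0:
            raise ConfigurationError(f"log-normal link requires mu > 0, got {mu}")
        return mu * math.exp(eta)
    if link == "logitnormal":
        if not 0.0 < mu < 1.0:
            raise ConfigurationError(f"logit-normal link requires 0 < mu < 1, got {mu}")
        z = math.log(mu / (1.0 - mu)) + eta
        return 1.0 / (1.0 + math.exp(-z))
    if link == "none":
        return mu
    raise ConfigurationError(f"unknown link {link!r}")


def sample_individuals(
    fe: FixedEffects,
    iiv: IIVSpec,
    n: int,
    seed: int | np.random.Generator,
) -> list[IndividualParameters]:
    """Draw ``n`` virtual dogs from the population model.

    Draws are deterministic given the seed and independent across both
    individuals and parameters.  ``PRA`` is wrapped modulo 24 after its
    log-normal draw so it remains a clock time.
    """
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    varying = iiv.varying()
    etas = rng.normal(0.0, 1.0, size=(n, len(varying)))
    individuals = []
    for i in range(n):
        eta: dict[str, float] = {}
        values: dict[str, float] = {}
        for j, name in enumerate(varying):
            e = float(etas[i, j] * iiv.omega[name])
            eta[name] = e
            v = apply_link(getattr(fe, name), e, iiv.link[name])
            if name == "PRA":
                v = v % 24.0
            values[name] = v
        individuals.append(
            IndividualParameters(individual_id=i, fe=fe.replace(**values), eta=eta)
        )
    return individuals
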