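import numpy as np
import pytest

import raassim as rs


@pytest.fixture(scope="session")
def defaults():
    """Packaged population parameters: (fixed effects, IIV spec, constants)."""
    return rs.load_defaults()


@pytest.fixture(scope="session")
def fe(defaults):
    return defaults[0]


@pytest.fixture(scope="session")
def iiv(defaults):
    return defaults[1]


@pytest.fixture(scope="session")
def consts(defaults):
    return defaults[2]


@pytest.fixture(scope="session")
def dr(fe):
    return rs.derive_rates(fe)


@pytest.fixture(scope="session")
def typical_individual(fe):
    """The typical dog (eta = 0)."""
    from raassim.population import IndividualParameters

    return IndividualParameters(individual_id=0, fe=fe, eta={})


@pytest.fixture(scope="session")
def short_design():
    """A cheap 3-day design used by engine-level tests."""
    return rs.TrialDesign(
        regimens=(rs.DosingRegimen("q12h 0.25", 0.25, 12.0),),
        n_individuals=3,
        horizon_days=3.0,
        n_grid=73,
        burn_in_days=2.0,
        auec_window=(24.0, 48.0),
        seed=123,
    )


def make_result(time_h, conc_by_arm, seed=0):
    """Assemble a SimulationResult from raw concentration arrays.

    ``conc_by_arm`` maps arm label -> array (n_individuals, 6, n_t).
    Used to unit-test the analysis layer without running the ODE engine.
    """
    arms = list(conc_by_arm)
    n_ind = next(iter(conc_by_arm.values())).shape[0]
    n_t = len(time_h)
    design = rs.TrialDesign(
        regimens=tuple(
            rs.DosingRegimen(a, 0.25, 12.0) for a in arms if a != "placebo"
        ),
        n_individuals=n_ind,
        horizon_days=time_h[-1] / 24.0,
        n_grid=n_t,
        burn_in_days=0.0,
        auec_window=(float(time_h[0]), float(time_h[-1])),
        seed=seed,
    )
    return rs.SimulationResult(
        time_h=np.asarray(time_h, dtype=float),
        arms=arms,
        concentrations={k: np.asarray(v, dtype=float) for k, v in conc_by_arm.items()},
        individuals=[],
        seed=seed,
        config_hash=design.config_hash(),
        design=design,
    )
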