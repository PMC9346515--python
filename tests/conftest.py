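import numpy as np
import pytest

from natprog.simulate import mutant_config, simulate_cohort, wildtype_config


@pytest.fixture(scope="session")
def small_mutant_cohort():
    """12 untreated mutant mice with muscle panels; shared read-only."""
    return simulate_cohort(mutant_config(n_mice=12, seed=7))


@pytest.fixture(scope="session")
def wt_cohort():
    """30 wild-type mice; shared read-only."""
    return simulate_cohort(wildtype_config(n_mice=30, seed=2))


@pytest.fixture(scope="session")
def recovery_config():
    """Model-matched generator for parameter-recovery checks.

    Terminal decline is disabled (so the generator's law equals the
    estimator's model family) and the hazard is milder than the mutant
    default, giving ~8 observations per mouse and ~60% deaths by study
    end — conditions under which all joint-model parameters are
    identifiable at moderate cohort sizes.
    """
    return mutant_config(
        n_mice=200,
        seed=0,
        decline_loss_mean=0.0,
        decline_loss_sd=0.0,
        haz_scale=3.2,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220725)
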