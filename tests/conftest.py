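import logging

import numpy as np
import pytest

from tlscp.simulate import ScenarioConfig, generate_target, run_benchmark

logging.getLogger("tlscp").setLevel(logging.ERROR)


def make_dataset(seed=0, n=50, p=3, beta=None, censor_rate=0.3, noise_sd=0.5):
    """Small random cohort via the package's own generator.

    Passing an explicit beta sidesteps the p-divisible-by-3 constraint of
    the default three-cluster truth.
    """
    cfg = ScenarioConfig(n_target=n, p=p, censor_rate=censor_rate,
                         noise_sd=noise_sd, seed=seed)
    if beta is None:
        beta = np.random.default_rng(seed).normal(size=p)
    return generate_target(cfg, beta=beta)


@pytest.fixture(scope="session")
def scenario1():
    """The scenario-1 replicate benchmark shared by the acceptance tests.

    25 paired replicates of the consistent-ranking design (target n=200,
    p=90, three coefficient clusters at 2/0.5/-1, 30% censoring; source
    n=2000 with log-rank coefficients), all three methods, BIC over
    k in {1..5}.  Run once per session.
    """
    rows, summary = run_benchmark({"s1": ScenarioConfig()},
                                  replicates=25, base_seed=1)
    return rows, summary
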