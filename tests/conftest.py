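import warnings

import pandas as pd
import pytest

from moralddm.simulate import SCENARIOS, generate_design, generate_true_params, simulate_dataset

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """8-participant cohort under the default effect pattern (both tasks)."""
    sc = SCENARIOS["emotional-dominance"]
    stim, sched = generate_design(seed=11, n_participants=8)
    truth = generate_true_params(sc, 8, seed=12)
    return simulate_dataset((stim, sched), truth, seed=13, scenario=sc)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """One moderately sized fit shared by the read-only hierarchical tests."""
    from moralddm.hierarchical import HierarchicalDDM

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return HierarchicalDDM(
            draws=1500, burn_in=300, seed=21, include_errors=True
        ).fit(small_cohort)
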