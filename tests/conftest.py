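import numpy as np
import pandas as pd
import pytest

from crfpm.data import CompetingRisksDataset
from crfpm.simulate import CSHSimSpec, FGSimSpec, simulate_csh, simulate_fine_gray


@pytest.fixture(scope="session")
def weibull_ds():
    """One cause, Weibull baseline (lam=0.2, p=1.4, beta=0.7), uniform
    censoring; n=5000."""
    return simulate_csh(
        CSHSimSpec(
            n=5000,
            scales=(0.2,),
            shapes=(1.4,),
            betas=((0.7,),),
            censoring=("uniform", 0.0, 8.0),
            seed=5,
        )
    )


@pytest.fixture(scope="session")
def two_cause_ds():
    """Two competing exponential causes with a binary covariate; n=5000.

    Cause 1: h = 0.2 exp(0.693 x); cause 2: h = 0.3; ~20% uniform
    censoring."""
    return simulate_csh(
        CSHSimSpec(
            n=5000,
            scales=(0.2, 0.3),
            shapes=(1.0, 1.0),
            betas=((0.693,), (0.0,)),
            censoring=("uniform", 0.0, 12.0),
            seed=17,
        )
    )


@pytest.fixture(scope="session")
def fg_ds():
    """One n=5000 draw of the proportional subdistribution hazards
    design (p=0.3, beta1=0.5, ~30% censoring)."""
    return simulate_fine_gray(FGSimSpec(n=5000, seed=99))


@pytest.fixture()
def tiny_ds():
    return CompetingRisksDataset(
        subject_id=np.arange(6),
        time=np.array([1.0, 2.0, 3.0, 1.5, 2.5, 4.0]),
        event=np.array([1, 2, 0, 1, 2, 1]),
        covariates=pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0]}),
    )
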