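import numpy as np
import pandas as pd
import pytest

from panoptikit import packaged_signature, synthetic
from panoptikit.datatypes import ExpressionMatrix, SurvivalTable


@pytest.fixture(scope="session")
def signature():
    return packaged_signature()


@pytest.fixture(scope="session")
def planted_cohort(signature):
    """n=300 cohort with 3 latent strata and 4 planted prognostic genes."""
    return synthetic.generate_bulk_cohort(
        300, 150, signature,
        true_beta={g: 0.4 for g in signature.genes[:4]},
        tumor_shift=1.0,
        seed=101,
    )


@pytest.fixture(scope="session")
def null_cohort(signature):
    """n=300 cohort with no latent structure and no planted hazard."""
    return synthetic.generate_bulk_cohort(300, 150, signature, delta=0.0, seed=202)


@pytest.fixture()
def toy_survival():
    return SurvivalTable(
        pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "time_days": [1.0, 2.0, 3.0],
                "event": [1, 1, 0],
            }
        )
    )


def make_expression(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def random_survival(n, rng, censor=0.3):
    time = rng.exponential(500, n) + 1
    event = (rng.random(n) > censor).astype(int)
    return SurvivalTable(
        pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(n)], "time_days": time, "event": event}
        )
    )
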