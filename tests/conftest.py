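import numpy as np
import pytest
from hypothesis import settings

from tissuevar import GeneratorParams, generate_dataset
from tissuevar.synthetic import Individual

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_individuals(n, prefix="i", cases=None, **kwargs):
    """n individuals with deterministic covariates."""
    inds = []
    for k in range(n):
        status = "case" if (cases is None or k < cases) else "control"
        inds.append(Individual(
            individual_id=f"{prefix}{k:03d}",
            case_status=status,
            age=30.0 + (k % 15),
            cycle_day=float(1 + (k * 5) % 28),
            smoking=bool(k % 3 == 0),
            bmi=22.0 + (k % 10),
            whr=0.75 + 0.01 * (k % 10),
            **kwargs,
        ))
    return inds


def nested_params(n_probes=20, n_individuals=12, var_individual=0.8,
                  var_split=0.2, var_technical=0.06, seed=0, **overrides):
    """A small single-tissue nested design on the unbounded scale."""
    inds = make_individuals(n_individuals, cases=n_individuals // 2)
    defaults = dict(
        n_probes=n_probes,
        individuals=inds,
        tissue_samples={"endometrium": [i.individual_id for i in inds]},
        default_splits=2,
        replicated_fraction=0.5,
        var_individual=var_individual,
        var_split=var_split,
        var_technical=var_technical,
        scale="log2_intensity",
        seed=seed,
    )
    defaults.update(overrides)
    return GeneratorParams(**defaults)


@pytest.fixture(scope="session")
def small_data():
    """20 probes x 12 individuals x 2 splits, replicates on half the splits."""
    return generate_dataset(nested_params(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
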