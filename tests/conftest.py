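import numpy as np
import pytest

import rrnlandmarks as r


@pytest.fixture(scope="session")
def template():
    return r.make_cmf_template(0)


@pytest.fixture(scope="session")
def complete_case(template):
    return r.sample_case(template, "normal", r.DEFAULT_SPACING, seed=11)


@pytest.fixture(scope="session")
def small_cohort(template):
    """12 base + 30 augmented cases — enough for fold/training smoke tests."""
    return r.generate_dataset(template, 12, r.AugmentationConfig(n_output=30, seed=7))


@pytest.fixture(scope="session")
def tiny_mlp_spec():
    return r.RUSpec(ru_type="mlp", relation_dim=8, mlp_hidden=(16, 16))


@pytest.fixture(scope="session")
def tiny_dense_spec():
    return r.RUSpec(ru_type="dense_block", relation_dim=8)


@pytest.fixture(scope="session")
def five_config():
    return r.builtin_configuration("five")


def random_complete_case(rng, case_id="rand", spacing=(0.754, 0.754, 0.377)):
    """A geometrically unstructured complete case (for pure-math properties)."""
    positions = {lm: rng.uniform(10.0, 200.0, size=3) for lm in r.VOCABULARY}
    return r.LandmarkCase(case_id=case_id, spacing=np.asarray(spacing),
                          positions=positions)
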