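import numpy as np
import pytest

from spfp.curation import CompoundRecord
from spfp.encoding import PotencyModuleSpec
from spfp.synthetic import SyntheticClassSpec, generate, generate_activity_class


@pytest.fixture(scope="session")
def default_spec():
    return PotencyModuleSpec()


@pytest.fixture(scope="session")
def small_class():
    """Small noisy synthetic activity class for quick model runs."""
    return generate_activity_class(SyntheticClassSpec(n_compounds=120, seed=11))


@pytest.fixture(scope="session")
def noiseless_class_with_truth():
    """Deterministic structure->potency map (noise_sd = 0) plus truth."""
    return generate(SyntheticClassSpec(n_compounds=150, noise_sd=0.0, seed=5))


@pytest.fixture
def toy_records():
    def rec(cid, **kw):
        base = dict(
            compound_id=cid,
            smiles="CCO",
            pIC50=6.5,
            target_id="T1",
            mw=46.07,
            relation="=",
            comment="",
            confidence=9,
        )
        base.update(kw)
        return CompoundRecord(**base)

    return rec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
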