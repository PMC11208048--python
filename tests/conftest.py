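import numpy as np
import pytest

from h3opt.fixtures import FixtureSpec, make_toy_fv, perturb_model
from h3opt.featurize import featurize


@pytest.fixture(scope="session")
def toy_pair():
    """One native/model pair with a 10-residue loop on a 60-residue framework."""
    spec = FixtureSpec(n_framework=60, h3_length=10, seed=11)
    native, ann = make_toy_fv(spec)
    model = perturb_model(native, ann, target_rmsd=3.0, seed=12)
    return native, model, ann


@pytest.fixture(scope="session")
def small_pair():
    """A smaller pair for network and refinement tests."""
    spec = FixtureSpec(n_framework=28, h3_length=6, seed=7)
    native, ann = make_toy_fv(spec)
    model = perturb_model(native, ann, target_rmsd=2.5, seed=8)
    return native, model, ann


@pytest.fixture(scope="session")
def small_feats(small_pair):
    native, model, ann = small_pair
    feats = featurize(model, ann)
    target = np.array([native.chain(ann.chain_id)[i].coord("CA") for i in ann.indices])
    return feats, target
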