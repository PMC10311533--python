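import numpy as np
import pytest

from lnshift.synthetic_data import TemplateParams, build_template


@pytest.fixture(scope="session")
def template():
    """Default exact-C3 template frame + donor map."""
    return build_template(TemplateParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(20230616)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
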