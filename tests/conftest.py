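import numpy as np
import pytest

from fetalbiom import default_centile_reference, init_state, PriorConfig


@pytest.fixture(scope="session")
def ref():
    """Synthetic default centile reference (non-clinical)."""
    return default_centile_reference()


@pytest.fixture()
def fl_state(ref):
    """Default-prior FL estimator state at 20 weeks."""
    return init_state(ref, "FL", 20.0, PriorConfig())


@pytest.fixture(scope="session")
def fl_window(ref):
    """FL plausibility window (a, b) at 20 weeks: p3 at 17w, p97 at 23w."""
    return ref.p3("FL", 17.0), ref.p97("FL", 23.0)
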