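import pytest

from cryptdrift import MOUSE_SI, YEAST_DFE


@pytest.fixture(scope="session")
def mouse_crypt():
    """Mouse small-intestine crypt parameters (Table-level literature values)."""
    return MOUSE_SI.crypt


@pytest.fixture(scope="session")
def yeast_dfe():
    """Yeast mutation-accumulation DFE used throughout the analysis."""
    return YEAST_DFE
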