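import numpy as np
import pytest

from tardis_barseq import (
    AmpliconLayout,
    BarcodeTemplate,
    MoleculePool,
    form_array,
    sample_library,
)


@pytest.fixture
def template() -> BarcodeTemplate:
    return BarcodeTemplate()


@pytest.fixture
def small_library() -> MoleculePool:
    """A modest uniform library to found arrays from."""
    return sample_library(BarcodeTemplate(), 5000, seed=11)


@pytest.fixture
def small_array(small_library) -> MoleculePool:
    """30-founder array with ZT-Poisson(3) copy numbers, no jackpots."""
    return form_array(small_library, 30, copy_lambda=3.0, seed=12)


@pytest.fixture
def clean_layout() -> AmpliconLayout:
    """Noise-free layout: no errors, no duplicates, flat qualities."""
    return AmpliconLayout(error_rate=0.0, duplicate_rate=0.0,
                          quality_model=(38.0, 0.0, 0.0))
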