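import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from acralpdx import synthdata as sd


@pytest.fixture
def disjoint_phase_image():
    """Two well-separated blobs with known integrated OPL."""
    return sd.gen_phase_image(
        [((64, 64), 20, 500.0), ((64, 160), 24, 800.0)], shape=(128, 224)
    )


@pytest.fixture
def qpi_spec():
    return sd.SimQPISpec(n_cells=60, mass_noise_cv=0.05, seed=11)
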