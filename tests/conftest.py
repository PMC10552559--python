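import numpy as np
import pytest

from thrombosim.mesh import BlockSpec, build_single_block


@pytest.fixture
def box_mesh():
    """Closed 8x6 box, 40x30 μm, all walls."""
    return build_single_block(
        BlockSpec(0.0, 40.0, 0.0, 30.0, 8, 6),
        {"left": "walls", "right": "walls", "bottom": "walls", "top": "walls"},
    )


@pytest.fixture
def channel_mesh():
    """Open 16x8 channel, 80x40 μm: inlet/outlet/walls."""
    return build_single_block(
        BlockSpec(0.0, 80.0, 0.0, 40.0, 16, 8),
        {"left": "inlet", "right": "outlet", "bottom": "walls", "top": "walls"},
    )


@pytest.fixture
def injury_box():
    """Closed 10x6 box whose bottom is an injuryWalls patch (25x15 μm,
    cells 2.5 μm so a 3 μm platelet diameter resolves)."""
    return build_single_block(
        BlockSpec(0.0, 25.0, 0.0, 15.0, 10, 6),
        {"left": "walls", "right": "walls", "bottom": "injuryWalls", "top": "walls"},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
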