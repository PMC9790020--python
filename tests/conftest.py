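import numpy as np
import pytest

from segcomplexity import make_blob_mask, make_vessel_mask


@pytest.fixture(scope="session")
def blob_masks() -> list[np.ndarray]:
    """Twenty seeded low-complexity (blob) masks at 256x256."""
    return [make_blob_mask(seed=s) for s in range(20)]


@pytest.fixture(scope="session")
def vessel_masks() -> list[np.ndarray]:
    """Twenty seeded high-complexity (branching-tree) masks at 256x256."""
    return [make_vessel_mask(seed=s) for s in range(20)]
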