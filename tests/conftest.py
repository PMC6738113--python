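import numpy as np
import pandas as pd
import pytest

from coexnet.preprocess import CountMatrix
from coexnet.simulate import SimDesign, simulate_counts


@pytest.fixture(scope="session")
def toy_counts() -> CountMatrix:
    """20 genes x 4 samples, two cell lines, fixed integers."""
    mat = np.array(
        [
            [120, 240, 60, 500], [30, 70, 15, 120], [900, 1800, 400, 4000],
            [10, 25, 5, 40], [250, 480, 130, 1000], [55, 110, 30, 220],
            [0, 5, 0, 10], [700, 1500, 350, 2800], [35, 60, 20, 150],
            [15, 40, 10, 60], [450, 900, 230, 1800], [80, 160, 45, 300],
            [5, 10, 2, 25], [300, 650, 160, 1200], [60, 130, 35, 240],
            [20, 45, 12, 90], [150, 310, 80, 600], [40, 85, 25, 170],
            [10, 20, 6, 35], [500, 1000, 260, 9000],
        ]
    )
    design = pd.DataFrame(
        {
            "cell_line": ["wt", "wt", "mt", "mt"],
            "time_min": [0, 0, 0, 0],
            "replicate": [1, 2, 1, 2],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return CountMatrix(
        counts=pd.DataFrame(mat, index=[f"g{i:02d}" for i in range(20)], columns=design.index),
        design=design,
    )


@pytest.fixture(scope="session")
def planted_run():
    """One simulated study: 2000 genes, 8 modules at r=0.9, background r~0.

    No DE effects are planted here: strongly DE genes are genuinely
    co-expressed with respect to genotype, which would put real structure
    into the background and defeat tests that assume it is empty.
    """
    design = SimDesign(
        n_genes=2000,
        module_sizes=(100,) * 8,
        module_correlation=0.9,
        seed=42,
    )
    cm, truth = simulate_counts(design)
    return design, cm, truth
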