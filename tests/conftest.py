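import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module


def make_cells(n, seed=0, box=200.0, classes=("tumor", "immune"),
               probs=None, roi_id="R1"):
    """Random classified cells uniform in a square; test scaffolding only."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, box, size=(n, 2))
    cls = rng.choice(list(classes), size=n, p=probs)
    return pd.DataFrame(
        {
            "roi_id": roi_id,
            "cell_id": [f"c{i}" for i in range(n)],
            "x_px": xy[:, 0],
            "y_px": xy[:, 1],
            "cls": cls,
        }
    )


@pytest.fixture
def mixed_cells():
    return make_cells(40, seed=11)


@pytest.fixture
def line_cells():
    """Alternating tumor/immune cells on a line at 10-px spacing."""
    n = 12
    return pd.DataFrame(
        {
            "roi_id": "R1",
            "cell_id": [f"c{i}" for i in range(n)],
            "x_px": 10.0 * np.arange(n),
            "y_px": np.zeros(n),
            "cls": ["tumor", "immune"] * (n // 2),
        }
    )
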