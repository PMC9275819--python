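"""Shared fixtures: small layouts and tables built programmatically."""

import numpy as np
import pandas as pd
import pytest

from fieldkrige.core import OTUTable, PlotGrid


@pytest.fixture
def tiny_layout() -> PlotGrid:
    """2 treatments x 3 genotypes x 2 blocks on a 4 x 3 grid (12 plots)."""
    rows = []
    for b in range(2):
        for w, trt in enumerate(["WW", "WS"]):
            for g in range(3):
                r = 2 * b + w
                c = g
                rows.append(
                    {
                        "plot_id": f"P{r}{c}",
                        "row": r,
                        "col": c,
                        "block": f"B{b + 1}",
                        "treatment": trt,
                        "genotype": f"G{g + 1}",
                    }
                )
    return PlotGrid(pd.DataFrame(rows))


@pytest.fixture
def small_otu_table(tiny_layout) -> OTUTable:
    """12 samples (one per plot, soil compartment) x 5 OTUs, seeded counts."""
    rng = np.random.default_rng(42)
    frame = tiny_layout.frame
    samples = pd.DataFrame(
        {
            "sample_id": ["S" + pid for pid in frame["plot_id"]],
            "plot_id": frame["plot_id"],
            "compartment": "soil",
        }
    )
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(len(samples), 5)),
        index=samples["sample_id"],
        columns=[f"OTU{j}" for j in range(1, 6)],
    ).astype(float)
    return OTUTable(samples=samples, counts=counts, layout=tiny_layout)


@pytest.fixture
def grid_coords():
    """Coordinates of a 16 x 24 plot grid."""
    return np.array([(r, c) for r in range(16) for c in range(24)], dtype=float)
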