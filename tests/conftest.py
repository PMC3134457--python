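"""Shared fixtures: small plots, parameter sets, and step tables."""

import numpy as np
import pandas as pd
import pytest

from weevilwalk.kernel import ParameterSet
from weevilwalk.lattice import HABITATS, PlotRaster, raster_from_codes


@pytest.fixture
def uniform_params():
    """Equal attractiveness, one β everywhere."""
    return ParameterSet(alpha={h: 0.25 for h in HABITATS},
                        beta={h: 1.0 for h in HABITATS})


@pytest.fixture
def collinear_plot():
    """1×3 plot with habitats P, B, D at x = 0.5, 1.5, 2.5."""
    return raster_from_codes("collinear", [["P", "B", "D"]])


@pytest.fixture
def two_cell_plot():
    return raster_from_codes("pair", [["P", "P"]])


def random_raster(rng, n_rows, n_cols, plot_id="rand"):
    return PlotRaster(plot_id=plot_id,
                      habitat=rng.integers(0, 4, size=(n_rows, n_cols)))


def random_params(rng, tie_beta=False):
    a = rng.dirichlet(np.ones(4) * 2.0)
    b = rng.uniform(0.2, 3.0, size=4)
    if tie_beta:
        b[:] = b[0]
    return ParameterSet(alpha=dict(zip(HABITATS, a.tolist())),
                        beta=dict(zip(HABITATS, b.tolist())))


def random_steps(rng, plot, n_steps):
    """Uniformly random (from, to) step table on one plot."""
    f = rng.integers(0, plot.n_cells, size=n_steps)
    t = rng.integers(0, plot.n_cells, size=n_steps)
    return pd.DataFrame({
        "individual_id": [f"i{k}" for k in range(n_steps)],
        "plot_id": plot.plot_id,
        "day": 0,
        "from_row": f // plot.n_cols, "from_col": f % plot.n_cols,
        "to_row": t // plot.n_cols, "to_col": t % plot.n_cols,
    })


def brute_force_log_likelihood(steps, plots, params):
    """Independent oracle: build each full transition row by direct
    normalization of α_{h_j}·exp(−β_{h_i}·d_ij) and sum log probabilities
    in extended precision."""
    import math

    total = 0.0
    for _, s in steps.iterrows():
        plot = plots[s["plot_id"]]
        i = int(s["from_row"]) * plot.n_cols + int(s["from_col"])
        j = int(s["to_row"]) * plot.n_cols + int(s["to_col"])
        centres = plot.cell_centres()
        hab = plot.habitat_flat
        beta_i = params.beta[HABITATS[hab[i]]]
        weights = [
            params.alpha[HABITATS[hab[k]]]
            * math.exp(-beta_i * math.hypot(centres[k, 0] - centres[i, 0],
                                            centres[k, 1] - centres[i, 1]))
            for k in range(plot.n_cells)
        ]
        total += math.log(weights[j] / math.fsum(weights))
    return total
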