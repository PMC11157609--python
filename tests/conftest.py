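import numpy as np
import pytest

import nichecast as nc


@pytest.fixture(scope="session")
def demo():
    """The packaged synthetic study world (fixed seed), thinned."""
    stack, niche, occ = nc.demo_world(seed=0)
    thinned, report = nc.thin_to_grid(occ, stack)
    return {"stack": stack, "niche": niche, "occurrences": occ,
            "thinned": thinned, "report": report}


@pytest.fixture(scope="session")
def demo_fit(demo):
    """One converged LQ fit on the demo world with a 2000-cell background."""
    stack, thinned = demo["stack"], demo["thinned"]
    prow, pcol = stack.grid.cell_index(thinned.lon, thinned.lat)
    brow, bcol = nc.sample_background(stack, n=2000, seed=0,
                                      include_cells=list(zip(prow, pcol)))
    variables = stack.variable_names
    bg = stack.env_at_cells(brow, bcol, variables)
    pres = stack.env_at_cells(prow, pcol, variables)
    model = nc.fit_maxent(pres, bg, variables, rm=1.0, fc="lq", seed=0)
    return {"model": model, "background": bg, "presences": pres,
            "bg_cells": (brow, bcol), "pres_cells": (prow, pcol)}


@pytest.fixture(scope="session")
def small_stack():
    """A small all-purpose synthetic stack (3 layers, 40x40, no sea)."""
    return nc.generate_climate_stack(
        seed=7, n_rows=40, n_cols=40,
        layer_spec=[("t_mean", 100.0, 30.0), ("prec_ann", 800.0, 200.0),
                    ("noise", 0.0, 1.0)],
        smoothing_length=2.0,
    )
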