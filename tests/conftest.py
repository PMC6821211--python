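"""Shared fixtures: small hand-made sets and one default synthetic world.

The expensive world/screen fixtures are session-scoped; tests must not
mutate them.
"""

import numpy as np
import pandas as pd
import pytest

from cvsig.data_io import SignatureSet
from cvsig.matching import collapse_conditions, match_records, split_by_time
from cvsig.synthetic_data import (WorldConfig, build_world,
                                  simulate_baseline_panel,
                                  simulate_compound_screen,
                                  simulate_shrna_screen)


def make_sigset(values, cells=None, perts=None, ptype="compound",
                doses=None, times=None):
    """Small SignatureSet factory for hand-made fixtures."""
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    idx = pd.Index([f"inst{i}" for i in range(n)], name="instance_id")
    genes = pd.Index([f"g{j}" for j in range(g)], name="gene_id")
    vals = pd.DataFrame(values, index=idx, columns=genes)
    row_meta = pd.DataFrame({
        "cell_line_id": cells if cells is not None else ["c0"] * n,
        "perturbagen_id": perts if perts is not None else [f"p{i}" for i in range(n)],
        "perturbagen_type": ptype,
        "dose_um": (doses if doses is not None
                    else ([1.0] * n if ptype == "compound" else [np.nan] * n)),
        "time_h": times if times is not None else [24.0] * n,
    }, index=idx)
    col_meta = pd.DataFrame({"gene_symbol": genes}, index=genes)
    return SignatureSet(vals, row_meta, col_meta)


@pytest.fixture(scope="session")
def world():
    return build_world(WorldConfig(seed=1))


@pytest.fixture(scope="session")
def compound_screen(world):
    return simulate_compound_screen(world)


@pytest.fixture(scope="session")
def shrna_screen(world):
    return simulate_shrna_screen(world)


@pytest.fixture(scope="session")
def compound_by_time(compound_screen):
    sig, viab = compound_screen
    ds = match_records(collapse_conditions(sig), viab, tag="CTRP-L1000")
    return split_by_time(ds)


@pytest.fixture(scope="session")
def shrna_by_time(shrna_screen):
    sig, viab = shrna_screen
    ds = match_records(collapse_conditions(sig), viab, tag="Achilles-L1000")
    return split_by_time(ds)


@pytest.fixture(scope="session")
def compound_24h(compound_by_time):
    return compound_by_time[24.0]


@pytest.fixture(scope="session")
def shrna_96h(shrna_by_time):
    return shrna_by_time[96.0]


@pytest.fixture(scope="session")
def baseline_panel(world):
    return simulate_baseline_panel(world)
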