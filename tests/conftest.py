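import numpy as np
import pytest

import threshmap as tm


@pytest.fixture(scope="session")
def argus_grid() -> tm.ElectrodeGrid:
    """Full 6 x 10 grid, all electrodes active."""
    return tm.build_grid(6, 10)


@pytest.fixture(scope="session")
def smooth_map() -> tm.ThresholdMap:
    """One smooth-preset synthetic map (seed 0)."""
    return tm.generate_map(tm.make_preset("smooth", seed=0))


def manual_map(thresholds, n_rows=1, grid=None, **kwargs) -> tm.ThresholdMap:
    """Build a ThresholdMap from explicit microamp values on a small grid."""
    thr = np.asarray(thresholds, dtype=float)
    if grid is None:
        grid = tm.build_grid(n_rows, thr.size // n_rows)
    censored = np.isclose(thr, 677.0)
    return tm.ThresholdMap(
        grid=grid, thresholds_uA=thr, censored=censored, **kwargs
    )


@pytest.fixture()
def tiny_map() -> tm.ThresholdMap:
    """Deterministic 2 x 5 map with moderate spatial structure, no censoring."""
    vals = [100.0, 120.0, 150.0, 200.0, 260.0, 110.0, 130.0, 160.0, 210.0, 250.0]
    return manual_map(vals, n_rows=2)
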