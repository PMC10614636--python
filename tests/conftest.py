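import numpy as np
import pytest

import scnkit as sk


@pytest.fixture(scope="session")
def two_group_cohort():
    """Small two-group null cohort (identical generating distributions)."""
    cfg = sk.SimulationConfig(group_sizes={"A": 30, "B": 40}, n_regions=8, seed=11)
    return sk.generate_cohort(cfg)


@pytest.fixture(scope="session")
def reference():
    """The packaged 61-region reference profile matrix."""
    return sk.load_reference_profiles()


def make_difference_network(
    mask: np.ndarray,
    region_names,
    pair=("B", "A"),
    delta_z: np.ndarray | None = None,
    n_perm: int = 999,
    alpha: float = 0.05,
) -> sk.DifferenceNetwork:
    """Hand-built DifferenceNetwork for tests that need a known mask."""
    mask = np.asarray(mask, dtype=bool)
    if delta_z is None:
        delta_z = mask.astype(float)
    p = np.where(mask, 1.0 / (n_perm + 1), 1.0)
    np.fill_diagonal(p, 1.0)
    return sk.DifferenceNetwork(
        pair=sk.pair_label(*pair),
        group_a=pair[0],
        group_b=pair[1],
        delta_z=np.asarray(delta_z, dtype=float),
        p_values=p,
        mask=mask,
        alpha=alpha,
        n_perm=n_perm,
        seed=0,
        region_names=tuple(region_names),
    )
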