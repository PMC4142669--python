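import numpy as np
import pytest

from nervestereo import (
    DistributionSpec,
    FiberPhenotypeParams,
    control_params,
    generate_section,
)


def tiny_phenotype(n: int, d: float = 2.0, g: float = 0.6) -> FiberPhenotypeParams:
    """Degenerate-distribution phenotype: every fiber has d and D = d/g."""
    return FiberPhenotypeParams(
        group_label="control",
        axon_diameter_dist=DistributionSpec("constant", {"value": d}),
        g_ratio_dist=DistributionSpec("constant", {"value": g}),
        target_fiber_count=n,
    )


@pytest.fixture(scope="session")
def small_section():
    """150 control-like fibers in a small nerve (fast shared fixture)."""
    params = control_params(150)
    return generate_section(params, nerve_radius=60.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
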