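import pytest

from fusewalk.simulate import (
    SimConfig,
    default_fusion_specs,
    plant_fusions,
    simulate_reads_and_expression,
    simulate_reference,
)


@pytest.fixture(scope="session")
def cohort():
    """One deterministic synthetic cohort shared by the read-level tests.

    Eight planted fusions covering all six copy-number mechanisms and all
    eight transcript structure classes, error-free 50 bp color-space reads.
    """
    config = SimConfig(seed=1, fusions=default_fusion_specs())
    ref = simulate_reference(config)
    segsets, truths = plant_fusions(config, ref)
    reads = simulate_reads_and_expression(config, ref, truths)
    return config, ref, segsets, truths, reads


@pytest.fixture(scope="session")
def reference(cohort):
    return cohort[1]


@pytest.fixture(scope="session")
def truths(cohort):
    return cohort[3]
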