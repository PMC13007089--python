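import numpy as np
import pytest

from perimech import pipeline, synthetic
from perimech.instability import InstabilityField, RimReference

#: fixed cohort seed for the group-level tests (the package default)
COHORT_SEED = 42
N_PER_GROUP = (10, 5, 13)


@pytest.fixture(scope="session")
def cohort_cases():
    """Default synthetic cohort: 10 compact / 5 irregular / 13 branched."""
    return synthetic.make_cohort_cases(N_PER_GROUP, base_seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_results(cohort_cases):
    """Per-case metric table (case x threshold) and primary-tau case maps."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, case_maps = pipeline.compute_cohort(cohort_cases)
    return table, case_maps


@pytest.fixture(scope="session")
def compact_processed():
    """One compact case with its regions, field and threshold sweep."""
    case = synthetic.generate_phantom(synthetic.case_spec(7),
                                      synthetic.ArchetypeParams.default("compact"))
    masks, fld, sweep = pipeline.process_case(case)
    return case, masks, fld, sweep


def field_from_values(values):
    """InstabilityField carrying the given shell values (test helper)."""
    vals = np.asarray(values, dtype=float)
    shape = (vals.size, 1, 1)
    I = vals.reshape(shape)
    finite = np.isfinite(I)
    return InstabilityField(
        I=I, valid_mask=finite.astype(np.uint8),
        shell=np.ones(shape, dtype=np.uint8), band_valid=finite.astype(np.uint8),
        reference=RimReference(g_loss_med=1.0, tan_delta_med=0.4, n_valid_rim_voxels=5),
    )
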