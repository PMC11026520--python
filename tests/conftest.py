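import numpy as np
import pandas as pd
import pytest

from plastcov import deconfound
from plastcov.registry import amygdala_labels, brain_labels
from plastcov.synth import PhenotypeSpec, SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """300-subject cohort with two planted modes and one confound."""
    cfg = SynthConfig(
        n_subjects=300,
        n_modes=2,
        mode_strengths=[5.0, 2.5],
        noise_sd=1.0,
        confound_effects={"bmi": 0.4},
        phenotype_spec=[
            PhenotypeSpec(mode=0, effect=0.6, datatype="numerical"),
            PhenotypeSpec(mode=None, effect=0.0, datatype="binary"),
        ],
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def std_matrices(small_cohort):
    cohort, _ = small_cohort
    _, am_std = deconfound.prepare_change_matrix(cohort, amygdala_labels())
    _, br_std = deconfound.prepare_change_matrix(cohort, brain_labels())
    return am_std, br_std


def random_standardized(rng, n, labels):
    """Standardized ChangeMatrix of iid noise (helper, not a fixture)."""
    vals = pd.DataFrame(rng.standard_normal((n, len(labels))), columns=labels)
    return deconfound.zscore_columns(deconfound.ChangeMatrix(vals, state="raw"))
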