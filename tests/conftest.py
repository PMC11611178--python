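import numpy as np
import pytest

import lumenflow as lf


@pytest.fixture(scope="session")
def spec():
    return lf.AcquisitionSpec()


@pytest.fixture(scope="session")
def small_cohort():
    """Two phantom subjects, 300 frames each — shared across tests."""
    return lf.make_cohort(2, 300, master_seed=11)


@pytest.fixture(scope="session")
def small_envelopes(small_cohort):
    """All subjects' normalized envelope frames, stacked (frames, length)."""
    from lumenflow.preprocess import envelope_stack
    return np.concatenate([envelope_stack(s.rf.samples).T.astype(np.float32)
                           for s in small_cohort.subjects])


@pytest.fixture(scope="session")
def small_walls(small_cohort):
    """Matching ground-truth (anterior, posterior) per frame, (frames, 2)."""
    return np.concatenate(
        [np.column_stack([s.annotation.anterior, s.annotation.posterior])
         for s in small_cohort.subjects])
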