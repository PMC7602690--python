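import numpy as np
import pytest

import facemaxent as fm


@pytest.fixture(scope="session")
def small_study():
    """Two-class study with no planted difference, modest size."""
    spec = fm.SyntheticStudySpec(
        n_subjects_per_class=12, reps_per_subject=6, difference_order=0, seed=42
    )
    return fm.make_two_class_study(spec)


@pytest.fixture(scope="session")
def gaussian_fluct():
    """Full-frame fluctuations of the small study plus moments and basis."""
    spec = fm.SyntheticStudySpec(
        n_subjects_per_class=20, reps_per_subject=10, difference_order=0, seed=7
    )
    ds = fm.make_two_class_study(spec)
    fl = fm.compute_fluctuations(ds)
    mom = fm.moment_statistics(fl, max_order=2)
    basis = fm.find_constraints(mom)
    return ds, fl, mom, basis
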