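"""Shared fixtures: small montages, specs and cohorts kept cheap on purpose."""

import numpy as np
import pytest

from mstate_mci.montage import spherical_montage
from mstate_mci.synth import GroupSpec, _uniform_rows


@pytest.fixture(scope="session")
def montage62():
    return spherical_montage(62)


@pytest.fixture(scope="session")
def montage16():
    return spherical_montage(16)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spec(
    group="HC",
    n_subjects=4,
    durations=(60.0, 64.0, 68.0, 76.0),
    into=None,
    snr=5.0,
    moca_mean=25.5,
    subject_cv=0.15,
    **kw,
):
    return GroupSpec(
        group_label=group,
        n_subjects=n_subjects,
        transition_matrix=_uniform_rows(into=into),
        mean_durations_ms=np.asarray(durations, dtype=float),
        snr=snr,
        moca_mean=moca_mean,
        moca_sd=1.48,
        duration_subject_cv=subject_cv,
        **kw,
    )


@pytest.fixture
def hc_spec():
    return make_spec("HC")


@pytest.fixture
def mci_spec():
    return make_spec("MCI", durations=(72.0, 64.0, 68.0, 64.0), into=[1, 1, 1, 0.6], moca_mean=19.2)
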