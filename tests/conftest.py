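import dataclasses

import pytest

from previnc.idm_core import LexisGrid
from previnc.mrr_model import fit_mrr
from previnc.prevalence_model import fit_prevalence
from previnc.synthetic_data import S1, make_bundle, simulate_truth


@pytest.fixture(scope="session")
def s1_truth():
    return simulate_truth(S1)


@pytest.fixture(scope="session")
def noise_free_bundle():
    cfg = dataclasses.replace(S1, prevalence_noise=False, mrr_noise=False)
    return make_bundle(cfg)


@pytest.fixture(scope="session")
def noisy_bundle():
    return make_bundle(S1)


@pytest.fixture(scope="session")
def grid():
    return LexisGrid()


@pytest.fixture(scope="session")
def noise_free_fits(noise_free_bundle):
    b = noise_free_bundle
    return fit_prevalence(b.prevalence_table), fit_mrr(b.mrr_table)


@pytest.fixture(scope="session")
def noisy_fits(noisy_bundle):
    b = noisy_bundle
    return fit_prevalence(b.prevalence_table), fit_mrr(b.mrr_table)
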