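"""Shared fixtures: a small labeled template, planted bases, phantom cohorts."""

import numpy as np
import pytest

import pclasso as p


@pytest.fixture(scope="session")
def template():
    return p.make_template()


@pytest.fixture(scope="session")
def basis2(template):
    """Two planted patterns over the putamen: global + AP gradient."""
    return p.make_planted_basis(template, 1, ["global_positive", "ap_gradient"])


@pytest.fixture(scope="session")
def basis4(template):
    """Four planted patterns: global, AP gradient, IS gradient, noise texture."""
    return p.make_planted_basis(
        template, 1, ["global_positive", "ap_gradient", "is_gradient", "noise_pattern"]
    )


@pytest.fixture(scope="session")
def cohort4(template, basis4):
    """One default 40-subject cohort on the 4-pattern basis, with images."""
    spec = p.default_cohort_spec(4, seed=11)
    table, truth = p.sample_cohort(spec, basis4)
    images = p.render_cohort(template, basis4, truth, spec, subject_ids=table.subject_ids)
    return {"spec": spec, "table": table, "truth": truth, "images": images}


@pytest.fixture(scope="session")
def noiseless_cohort(template, basis2):
    """Zero-voxel-noise cohort on the 2-pattern basis (generative identities)."""
    spec = p.default_cohort_spec(2, seed=5, noise_sigma=0.0)
    table, truth = p.sample_cohort(spec, basis2)
    images = p.render_images(
        template, basis2, truth.better, 0.0, seed=1, subject_ids=table.subject_ids
    )
    return {"spec": spec, "table": table, "truth": truth, "images": images}


@pytest.fixture(scope="session")
def putamen_matrix(template, cohort4):
    return p.extract_voxel_matrix(cohort4["images"]["better"], template, 1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
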